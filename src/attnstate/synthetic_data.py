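"""Synthetic multi-unit-activity sessions with planted latent behavioral states.

Emulates a 100%-validity cued luminance-detection task: four landmarks at the
corners of a square of ~28 degree diagonal (~14 degree eccentricity), a spatial
cue that orients covert attention to the upcoming target landmark, and trial
outcomes (hit / miss / false alarm) that depend both on where the attentional
spotlight actually landed (its distance to the target, TA) and on two slowly
drifting, task-independent behavioral states:

* ``s1`` — *optimality*: an AR(1) state whose magnitude degrades performance.
  Positive excursions promote misses (distractibility), negative excursions
  promote false alarms (impulsivity); hits concentrate near ``s1 = 0``. Its
  neural expression is a *shared multiplicative gain* proportional to the even
  transform ``o = E|s1| - |s1|``, so trial types differ in shared-gain
  variance (hence in noise correlations) and condition means are U-shaped in
  (miss, hit, fa) with hits extreme.
* ``s2`` — *responsiveness*: an AR(1) state entering the firing rate
  additively, with a linear relation to outcome (miss > hit > false alarm in
  both state value and mean rate).

Spike counts are conditionally Poisson per 10 ms bin given the per-trial rate

    rate = (baseline + w_s2 * s2) * (1 + gain * K(d)) * (1 + w_s1 * o)

floored at zero, where ``K`` is a monotone-decreasing logistic spatial kernel
of the distance ``d`` between the true spotlight and the unit's
response-field center (the attentional factor applies only after cue onset).

The simulated time axis covers three contiguous segments: a pre-cue window, a
pre-target window, and a short post-stimulus window holding a minimal evoked
transient on responded trials; the variable cue-to-target delay is metadata
only. All randomness derives from explicit integer seeds.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

OUTCOMES = ("hit", "miss", "fa", "cr")

#: steeper gain sensitivity on the distractibility (s1 > 0) tail than on the
#: impulsivity tail; separates shared-gain variance in misses from false alarms
DEFAULT_GAIN_ASYMMETRY = 0.0

_SQ = 28.0 / (2.0 * np.sqrt(2.0))  # landmark |x| = |y| for a 28 deg diagonal


def _default_landmarks() -> np.ndarray:
    # up-right, up-left, down-left, down-right
    return np.array([[_SQ, _SQ], [-_SQ, _SQ], [-_SQ, -_SQ], [_SQ, -_SQ]])


@dataclass
class TaskConfig:
    """Geometry and timing of the cued-detection task."""

    landmark_positions: np.ndarray = field(default_factory=_default_landmarks)
    cue_validity: float = 1.0
    cue_to_target_range_ms: tuple[float, float] = (750.0, 3300.0)
    distractor_D_fraction: float = 0.17
    distractor_d_fraction: float = 0.33
    bin_width_ms: int = 10
    pre_stim_window_ms: int = 400
    post_stim_window_ms: int = 200

    def __post_init__(self) -> None:
        self.landmark_positions = np.asarray(self.landmark_positions, dtype=float)
        if self.landmark_positions.shape != (4, 2):
            raise ValueError("landmark_positions must be four (x, y) points")
        if len(np.unique(self.landmark_positions, axis=0)) != 4:
            raise ValueError("landmark positions must be distinct")
        if not (0.0 <= self.distractor_D_fraction
                and 0.0 <= self.distractor_d_fraction
                and self.distractor_D_fraction + self.distractor_d_fraction < 1.0):
            raise ValueError("distractor fractions must be non-negative and sum < 1")
        if self.bin_width_ms <= 0 or self.pre_stim_window_ms <= 0 \
                or self.post_stim_window_ms <= 0:
            raise ValueError("windows and bin width must be positive")
        if self.cue_validity != 1.0:
            raise ValueError("task is defined with 100% cue validity")

    # -- fixed bin layout: [pre-cue | pre-target | post-stimulus] -----------
    @property
    def n_segment_bins(self) -> int:
        return self.pre_stim_window_ms // self.bin_width_ms

    @property
    def cue_onset_bin(self) -> int:
        return self.n_segment_bins

    @property
    def stim_onset_bin(self) -> int:
        return 2 * self.n_segment_bins

    @property
    def n_bins(self) -> int:
        return 2 * self.n_segment_bins + self.post_stim_window_ms // self.bin_width_ms

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["landmark_positions"] = self.landmark_positions.tolist()
        d["cue_to_target_range_ms"] = list(self.cue_to_target_range_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "TaskConfig":
        d = dict(d)
        d["cue_to_target_range_ms"] = tuple(d["cue_to_target_range_ms"])
        return cls(**d)


@dataclass
class PopulationConfig:
    """Per-unit tuning and state-loading parameters.

    ``w_s1`` loads the optimality state onto a shared multiplicative gain;
    ``w_s2`` loads the responsiveness state onto the additive baseline
    (spikes/s per state SD).
    """

    n_units: int
    baseline_rates: np.ndarray
    rf_centers: np.ndarray
    tuning_gain: np.ndarray
    tuning_width: np.ndarray
    w_s1: np.ndarray
    w_s2: np.ndarray
    mixed_fraction: float = 0.3
    overlap_mix: float = 0.3
    kernel_midpoint: float = 9.0
    evoked_amplitude: float = 0.5
    gain_asymmetry: float = DEFAULT_GAIN_ASYMMETRY
    roles: np.ndarray | None = None  # optional ground-truth labels

    def __post_init__(self) -> None:
        for name in ("baseline_rates", "tuning_gain", "tuning_width", "w_s1", "w_s2"):
            arr = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, arr)
            if arr.shape != (self.n_units,):
                raise ValueError(f"{name} must have length n_units")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} must be finite")
        self.rf_centers = np.asarray(self.rf_centers, dtype=float)
        if self.rf_centers.shape != (self.n_units, 2):
            raise ValueError("rf_centers must be (n_units, 2)")
        if np.any(self.baseline_rates <= 0):
            raise ValueError("baseline_rates must be positive")
        if np.any(self.tuning_width <= 0):
            raise ValueError("tuning_width must be positive")

    def to_dict(self) -> dict:
        d = {k: (v.tolist() if isinstance(v, np.ndarray) else v)
             for k, v in dataclasses.asdict(self).items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PopulationConfig":
        d = dict(d)
        if d.get("roles") is not None:
            d["roles"] = np.asarray(d["roles"])
        return cls(**d)


@dataclass
class StateConfig:
    """Latent-state dynamics and the outcome link.

    The outcome link is a three-way multinomial logit on (hit, miss, fa):

        eta_hit  = bias_hit - beta_ta * TA + beta_s2_hit * s2
        eta_miss = bias_miss + beta_s1_miss * max(s1, 0) + beta_s2 * s2
        eta_fa   = bias_fa + beta_s1_fa * max(-s1, 0) - beta_s2 * s2

    so TA degrades hits, the two tails of s1 drive misses (distractibility)
    and false alarms (impulsivity) respectively, and s2 orders outcomes
    linearly (miss > hit > fa). ``beta_s2_hit`` is a small positive term that
    keeps the hits' mean s2 strictly between the error types' means; without
    it, hits and false alarms end up nearly equal in s2 and the planted
    linear ordering is not identifiable at session size. The default miss
    slope is soft (small ``beta_s1_miss``) and the false-alarm slope sharp
    (large ``beta_s1_fa``): both error types then occupy equally low mean
    optimality (a symmetric U) while the soft miss selection spans a wider
    optimality range, giving misses the largest shared-gain variance and
    hence the noise-correlation ordering hit < fa < miss.
    """

    ar_coeff: tuple[float, float] = (0.7, 0.7)
    state_sd: tuple[float, float] = (1.0, 1.0)
    beta_ta: float = 0.22
    beta_s1_miss: float = 2.0
    beta_s1_fa: float = 16.0
    beta_s2: float = 1.4
    beta_s2_hit: float = 0.6
    attention_jitter_sd: float = 8.0
    bias_hit: float = 5.6
    bias_miss: float = 1.1
    bias_fa: float = -3.4

    def __post_init__(self) -> None:
        vals = [*self.ar_coeff, *self.state_sd, self.beta_ta, self.beta_s1_miss,
                self.beta_s1_fa, self.beta_s2, self.beta_s2_hit,
                self.attention_jitter_sd,
                self.bias_hit, self.bias_miss, self.bias_fa]
        if not np.all(np.isfinite(vals)):
            raise ValueError("state configuration values must be finite")
        if not all(0.0 <= a < 1.0 for a in self.ar_coeff):
            raise ValueError("ar_coeff must lie in [0, 1)")
        if not all(s > 0 for s in self.state_sd):
            raise ValueError("state_sd must be positive")
        if self.attention_jitter_sd < 0:
            raise ValueError("attention_jitter_sd must be non-negative")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "StateConfig":
        d = dict(d)
        for k in ("ar_coeff", "state_sd"):
            d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class LatentStates:
    """Ground-truth per-trial states and true spotlight positions."""

    s1: np.ndarray
    s2: np.ndarray
    true_as_xy: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.s1 = np.asarray(self.s1, dtype=float)
        self.s2 = np.asarray(self.s2, dtype=float)
        if self.s1.shape != self.s2.shape or self.s1.ndim != 1:
            raise ValueError("s1 and s2 must be 1-D and of equal length")
        if self.true_as_xy is not None:
            self.true_as_xy = np.asarray(self.true_as_xy, dtype=float)
            if self.true_as_xy.shape != (len(self.s1), 2):
                raise ValueError("true_as_xy must be (n_trials, 2)")

    @property
    def n_trials(self) -> int:
        return len(self.s1)

    @property
    def optimality(self) -> np.ndarray:
        """Even neural expression of s1: positive when the state is optimal."""
        return optimality_transform(self.s1)


TRIAL_COLUMNS = ["trial_id", "cue_landmark", "cue_x", "cue_y",
                 "target_x", "target_y", "stim_onset_bin", "outcome"]


@dataclass
class SessionData:
    """Spike-count tensor (trials x channels x time bins) plus trial metadata."""

    counts: np.ndarray
    trial_table: pd.DataFrame
    task: TaskConfig
    session_id: str = "session"

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 3:
            raise ValueError("counts must be trials x channels x time-bins")
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        missing = [c for c in TRIAL_COLUMNS if c not in self.trial_table.columns]
        if missing:
            raise ValueError(f"trial_table missing columns: {missing}")
        if len(self.trial_table) != self.counts.shape[0]:
            raise ValueError("trial_table length must match counts")
        bad = set(self.trial_table["outcome"]) - set(OUTCOMES)
        if bad:
            raise ValueError(f"unknown outcome labels: {sorted(bad)}")
        if not self.trial_table["cue_landmark"].isin(range(4)).all():
            raise ValueError("cue_landmark must index one of the four landmarks")

    @property
    def n_trials(self) -> int:
        return self.counts.shape[0]

    @property
    def n_units(self) -> int:
        return self.counts.shape[1]

    def rates_hz(self, window_bins: slice) -> np.ndarray:
        """Mean firing rate (spikes/s) per trial and channel over a bin slice."""
        nbins = len(range(*window_bins.indices(self.counts.shape[2])))
        seconds = nbins * self.task.bin_width_ms / 1000.0
        return self.counts[:, :, window_bins].sum(axis=2) / seconds

    def window_to_bins(self, window_ms: tuple[float, float],
                       align: str = "stim") -> slice:
        """Convert a window in ms relative to an alignment event to a bin slice.

        ``align`` is "stim" (target/distractor onset) or "cue" (cue onset).
        """
        anchor = {"stim": self.task.stim_onset_bin,
                  "cue": self.task.cue_onset_bin}[align]
        w = self.task.bin_width_ms
        lo = anchor + int(np.floor(window_ms[0] / w))
        hi = anchor + int(np.ceil(window_ms[1] / w))
        lo, hi = max(lo, 0), min(hi, self.counts.shape[2])
        if hi <= lo:
            raise ValueError(f"window {window_ms} maps to an empty bin range")
        return slice(lo, hi)

    # ------------------------------------------------------------------ I/O
    def save(self, out_dir: str | Path,
             latents: LatentStates | None = None) -> Path:
        """Write the session container: counts.npy, trial_table.csv, JSON configs."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        np.save(out / "counts.npy", self.counts)
        self.trial_table[TRIAL_COLUMNS].to_csv(out / "trial_table.csv", index=False)
        (out / "task.json").write_text(json.dumps(self.task.to_dict(), indent=1))
        manifest = {
            "session_id": self.session_id,
            "bin_width_ms": self.task.bin_width_ms,
            "cue_onset_bin": self.task.cue_onset_bin,
            "stim_onset_bin": self.task.stim_onset_bin,
            "n_trials": int(self.n_trials),
            "n_units": int(self.n_units),
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
        if latents is not None:
            lat = pd.DataFrame({"s1": latents.s1, "s2": latents.s2})
            if latents.true_as_xy is not None:
                lat["true_as_x"] = latents.true_as_xy[:, 0]
                lat["true_as_y"] = latents.true_as_xy[:, 1]
            lat.to_csv(out / "latent_states.csv", index=False)
        return out

    @classmethod
    def load(cls, in_dir: str | Path) -> "SessionData":
        p = Path(in_dir)
        if not p.is_dir():
            raise FileNotFoundError(f"session directory not found: {p}")
        counts = np.load(p / "counts.npy")
        table = pd.read_csv(p / "trial_table.csv")
        task = TaskConfig.from_dict(json.loads((p / "task.json").read_text()))
        manifest = json.loads((p / "manifest.json").read_text())
        return cls(counts=counts, trial_table=table, task=task,
                   session_id=manifest.get("session_id", p.name))


def load_latent_states(in_dir: str | Path) -> LatentStates:
    df = pd.read_csv(Path(in_dir) / "latent_states.csv")
    xy = None
    if "true_as_x" in df.columns:
        xy = df[["true_as_x", "true_as_y"]].to_numpy()
    return LatentStates(s1=df["s1"].to_numpy(), s2=df["s2"].to_numpy(),
                        true_as_xy=xy)


# --------------------------------------------------------------------------
# Latent states
# --------------------------------------------------------------------------

def optimality_transform(s1: np.ndarray,
                         asym: float = DEFAULT_GAIN_ASYMMETRY) -> np.ndarray:
    """Map the optimality state to its neural gain expression.

    ``o = E|s1| - |s1| - asym * s1`` for a standard-normal stationary state:
    mean-zero, maximal when s1 sits at its optimum (zero), decreasing in
    either tail so that misses (s1 >> 0) and false alarms (s1 << 0) share a
    low-gain regime with hits extreme (the U-shape). ``asym`` (default 0, a
    pure even transform) optionally tilts the gain toward one tail.
    """
    s1 = np.asarray(s1, dtype=float)
    return np.sqrt(2.0 / np.pi) - np.abs(s1) - asym * s1


def sample_latent_states(state_config: StateConfig, n_trials: int,
                         seed: int) -> LatentStates:
    """Draw the two independent stationary AR(1) state sequences."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for phi, sd in zip(state_config.ar_coeff, state_config.state_sd):
        innov_sd = sd * np.sqrt(1.0 - phi ** 2)
        eps = rng.normal(0.0, innov_sd, size=n_trials)
        s = np.empty(n_trials)
        s[0] = rng.normal(0.0, sd)
        for t in range(1, n_trials):
            s[t] = phi * s[t - 1] + eps[t]
        out.append(s)
    return LatentStates(s1=out[0], s2=out[1])


# --------------------------------------------------------------------------
# Attention and outcomes
# --------------------------------------------------------------------------

def sample_attention_and_outcomes(task: TaskConfig, states: LatentStates,
                                  state_config: StateConfig,
                                  seed: int) -> tuple[pd.DataFrame, np.ndarray]:
    """Sample cue positions, true spotlight locations, and trial outcomes.

    Returns the trial table and the (n_trials, 2) true spotlight positions;
    the positions are also stored on ``states.true_as_xy``.
    """
    rng = np.random.default_rng(seed)
    n = states.n_trials
    cue_idx = rng.integers(0, 4, size=n)
    cue_xy = task.landmark_positions[cue_idx]
    target_xy = cue_xy.copy()  # 100% cue validity
    true_as = cue_xy + rng.normal(0.0, state_config.attention_jitter_sd,
                                  size=(n, 2))
    ta_true = np.linalg.norm(true_as - target_xy, axis=1)

    sc = state_config
    eta = np.column_stack([
        sc.bias_hit - sc.beta_ta * ta_true + sc.beta_s2_hit * states.s2,
        sc.bias_miss + sc.beta_s1_miss * np.maximum(states.s1, 0.0)
        + sc.beta_s2 * states.s2,
        sc.bias_fa + sc.beta_s1_fa * np.maximum(-states.s1, 0.0)
        - sc.beta_s2 * states.s2,
    ])
    eta -= eta.max(axis=1, keepdims=True)
    p = np.exp(eta)
    p /= p.sum(axis=1, keepdims=True)
    u = rng.random(n)
    choice = (u[:, None] > np.cumsum(p, axis=1)).sum(axis=1)
    outcome = np.array(["hit", "miss", "fa"])[choice]

    table = pd.DataFrame({
        "trial_id": np.arange(n),
        "cue_landmark": cue_idx,
        "cue_x": cue_xy[:, 0],
        "cue_y": cue_xy[:, 1],
        "target_x": target_xy[:, 0],
        "target_y": target_xy[:, 1],
        "stim_onset_bin": np.full(n, task.stim_onset_bin),
        "outcome": outcome,
    })
    states.true_as_xy = true_as
    return table, true_as


# --------------------------------------------------------------------------
# Spike counts
# --------------------------------------------------------------------------

def generate_spike_counts(pop: PopulationConfig, states: LatentStates,
                          trial_table: pd.DataFrame, task: TaskConfig,
                          seed: int) -> SessionData:
    """Poisson spike counts for every trial, channel, and time bin."""
    if states.true_as_xy is None:
        raise ValueError("states must carry true spotlight positions; "
                         "run sample_attention_and_outcomes first")
    rng = np.random.default_rng(seed)
    n_trials = states.n_trials
    n_units = pop.n_units

    dist = np.linalg.norm(states.true_as_xy[:, None, :]
                          - pop.rf_centers[None, :, :], axis=2)
    # monotone-decreasing logistic kernel: ~1 on a plateau around the RF,
    # ~0 beyond the midpoint, transition steepness set by tuning_width. The
    # plateau keeps trial-to-trial spotlight jitter from injecting shared
    # rate variance when attention sits squarely on (or far from) the RF.
    kernel = expit((pop.kernel_midpoint - dist) / pop.tuning_width[None, :])
    o = optimality_transform(states.s1, pop.gain_asymmetry)

    base = pop.baseline_rates[None, :] + pop.w_s2[None, :] * states.s2[:, None]
    shared = 1.0 + pop.w_s1[None, :] * o[:, None]
    attn = 1.0 + pop.tuning_gain[None, :] * kernel

    rate_precue = base * shared            # attention not yet deployed
    rate_pretarget = base * attn * shared
    floored = (rate_precue < 0) | (rate_pretarget < 0)
    if floored.mean() > 0.15:
        warnings.warn(
            f"rate floor engaged on {100 * floored.mean():.1f}% of unit-trials; "
            "state loadings are implausibly large for the baseline rates",
            stacklevel=2)
    rate_precue = np.maximum(rate_precue, 0.0)
    rate_pretarget = np.maximum(rate_pretarget, 0.0)

    nseg = task.n_segment_bins
    n_bins = task.n_bins
    dt = task.bin_width_ms / 1000.0

    lam = np.empty((n_trials, n_units, n_bins))
    lam[:, :, :nseg] = rate_precue[:, :, None] * dt
    lam[:, :, nseg:2 * nseg] = rate_pretarget[:, :, None] * dt
    # minimal evoked transient on responded (hit / fa) trials
    n_post = n_bins - 2 * nseg
    t_post = (np.arange(n_post) + 0.5) * task.bin_width_ms
    bump = pop.evoked_amplitude * np.exp(-t_post / 80.0)
    responded = trial_table["outcome"].isin(["hit", "fa"]).to_numpy()
    evoked = 1.0 + np.where(responded[:, None], 1.0, 0.0)[:, :, None] \
        * bump[None, None, :]
    lam[:, :, 2 * nseg:] = rate_pretarget[:, :, None] * dt * evoked

    counts = rng.poisson(lam).astype(np.int32)
    return SessionData(counts=counts, trial_table=trial_table.copy(), task=task)


# --------------------------------------------------------------------------
# Population sampler
# --------------------------------------------------------------------------

def sample_population(n_units: int = 48, seed: int = 0,
                      fractions: tuple[float, float, float, float] = (
                          0.20, 0.20, 0.45, 0.15),
                      overlap_mix: float = 0.3,
                      tuning_gain_range: tuple[float, float] = (2.5, 4.0),
                      tuning_width_range: tuple[float, float] = (2.5, 2.5),
                      w_s1_scale: float = 0.75,
                      w_s2_scale: float = 9.0,
                      baseline_mean: float = 30.0,
                      rf_scatter: float = 0.0) -> PopulationConfig:
    """Sample a population with attention / outcome / mixed / untuned roles.

    ``overlap_mix`` in [0, 1] is the planted cosine between the attention
    rate pattern (gain * baseline) and the shared-gain rate pattern
    (w_s1 * baseline) on the loaded units: 0 plants orthogonal attention and
    outcome subspaces, values near 1 make them collinear. ``w_s1_scale`` is
    the RMS of the (dimensionless) gain loadings over loaded units;
    ``w_s2_scale`` the RMS of the additive responsiveness loadings in
    spikes/s per state SD.
    """
    if not np.isclose(sum(fractions), 1.0):
        raise ValueError("role fractions must sum to 1")
    rng = np.random.default_rng(seed)
    counts = np.floor(np.asarray(fractions) * n_units).astype(int)
    while counts.sum() < n_units:
        counts[int(rng.integers(0, 4))] += 1
    roles = np.repeat(np.array(["attention", "outcome", "mixed", "none"]),
                      counts)
    rng.shuffle(roles)

    baseline = np.exp(rng.normal(np.log(baseline_mean), 0.35, n_units))
    baseline = np.clip(baseline, 5.0, 2.0 * baseline_mean)
    tuned = np.isin(roles, ["attention", "mixed"])
    gain = np.where(tuned, rng.uniform(*tuning_gain_range, n_units), 0.0)
    width = rng.uniform(*tuning_width_range, n_units)
    # response fields scattered around the four landmarks
    lm = _default_landmarks()[np.arange(n_units) % 4]
    rf = lm + rng.normal(0.0, rf_scatter, size=(n_units, 2))

    # State loadings are planted geometrically on the loaded (outcome/mixed)
    # units. In firing-rate space the attention pattern is gain*baseline; the
    # gain-loading rate pattern w_s1*baseline is constructed as
    #     overlap_mix * u_t + sqrt(1 - overlap_mix^2) * u_perp
    # with u_t the unit-norm attention pattern restricted to loaded units
    # (supported on the mixed units, since pure-outcome units are untuned)
    # and u_perp a positive vector supported on the pure-outcome units only.
    # Disjoint supports make u_perp exactly orthogonal to u_t while keeping
    # every gain loading non-negative (co-fluctuation, not anti-correlation),
    # so the cosine between the attention and shared-gain population patterns
    # equals overlap_mix by construction. The responsiveness loading w_s2 is
    # drawn orthogonal to both, keeping the linear (s2) component demixable
    # from the gain pattern. Magnitudes are RMS-scaled and capped so rates
    # stay positive for typical state excursions.
    loaded = np.isin(roles, ["outcome", "mixed"])
    li = np.flatnonzero(loaded)

    def _unit(v: np.ndarray) -> np.ndarray:
        n = np.linalg.norm(v)
        return v / n if n > 0 else v

    u_t = _unit((gain * baseline)[li])
    pure_out = (roles[li] == "outcome")
    u_p = np.where(pure_out, rng.uniform(0.5, 1.5, len(li)), 0.0)
    u_p = _unit(u_p)
    v = overlap_mix * u_t + np.sqrt(max(0.0, 1.0 - overlap_mix ** 2)) * u_p
    w1 = v / baseline[li]
    rms = np.sqrt((w1 ** 2).mean())
    if rms > 0:
        w1 *= w_s1_scale / rms
    w_s1 = np.zeros(n_units)
    w_s1[li] = np.clip(w1, 0.0, 0.85)

    r2 = rng.normal(size=len(li))
    for b in (u_t, _unit(v)):
        r2 = r2 - (r2 @ b) * b
    w2 = _unit(r2) * w_s2_scale * np.sqrt(len(li))
    w_s2 = np.zeros(n_units)
    w_s2[li] = np.clip(w2, -0.3 * baseline[li], 0.3 * baseline[li])

    return PopulationConfig(
        n_units=n_units, baseline_rates=baseline, rf_centers=rf,
        tuning_gain=gain, tuning_width=width, w_s1=w_s1, w_s2=w_s2,
        mixed_fraction=float(fractions[2]), overlap_mix=float(overlap_mix),
        roles=roles)


# --------------------------------------------------------------------------
# Sessions
# --------------------------------------------------------------------------

def simulate_session(task: TaskConfig, pop: PopulationConfig,
                     state_config: StateConfig, n_trials: int,
                     seed: int) -> tuple[SessionData, LatentStates]:
    """One full session: latent states -> outcomes -> spike counts."""
    ss = np.random.SeedSequence(seed)
    s_lat, s_beh, s_spk = (int(c.generate_state(1)[0] % (2 ** 31))
                           for c in ss.spawn(3))
    states = sample_latent_states(state_config, n_trials, s_lat)
    table, _ = sample_attention_and_outcomes(task, states, state_config, s_beh)
    session = generate_spike_counts(pop, states, table, task, s_spk)
    return session, states


@dataclasses.dataclass
class SessionBundle:
    """A simulated session together with its ground truth."""

    session: SessionData
    states: LatentStates
    population: PopulationConfig
    state_config: StateConfig

    def __iter__(self):
        # allow ``for session, states in bundles`` unpacking
        return iter((self.session, self.states))


def simulate_sessions(n_sessions: int, n_trials: int, seed: int,
                      task: TaskConfig | None = None,
                      state_config: StateConfig | None = None,
                      pop: PopulationConfig | None = None,
                      n_units: int = 48,
                      overlap_gain_sweep: bool = True,
                      overlap_mix_range: tuple[float, float] = (0.02, 0.98),
                      beta_ta_range: tuple[float, float] = (0.30, 0.10),
                      ) -> "list[SessionBundle]":
    """Simulate independent sessions from one master seed.

    By default each session draws its own population, with a planted
    across-session coupling: the overlap between attention tuning and state
    loadings increases across sessions while the behavioral TA sensitivity
    (``beta_ta``) decreases, emulating the observed negative relation between
    component overlap and the behavioral gain of good attention orientation.
    Pass an explicit ``pop`` (and/or ``overlap_gain_sweep=False``) for
    homogeneous sessions.
    """
    if n_sessions < 1:
        raise ValueError("n_sessions must be >= 1")
    task = task or TaskConfig()
    state_config = state_config or StateConfig()
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(n_sessions)
    order = np.random.default_rng(seed).permutation(n_sessions)

    out = []
    for i, child in enumerate(children):
        s_pop, s_sess = (int(c.generate_state(1)[0] % (2 ** 31))
                         for c in child.spawn(2))
        if pop is not None:
            pop_i, sc_i = pop, state_config
        elif overlap_gain_sweep and n_sessions > 1:
            frac = order[i] / (n_sessions - 1)
            mix = overlap_mix_range[0] + frac * (
                overlap_mix_range[1] - overlap_mix_range[0])
            beta = beta_ta_range[0] + frac * (
                beta_ta_range[1] - beta_ta_range[0])
            pop_i = sample_population(n_units=n_units, seed=s_pop,
                                      overlap_mix=mix)
            sc_i = dataclasses.replace(state_config, beta_ta=beta)
        else:
            pop_i = sample_population(n_units=n_units, seed=s_pop)
            sc_i = state_config
        session, states = simulate_session(task, pop_i, sc_i, n_trials, s_sess)
        session.session_id = f"session_{i:02d}"
        out.append(SessionBundle(session=session, states=states,
                                 population=pop_i, state_config=sc_i))
    return out
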