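"""Multi-session orchestration and session-level derived statistics.

The pipeline ties the per-session analyses together: decode the attentional
spotlight, classify unit selectivity, compute noise correlations, fit the
joint and single-parameter dPCA variants, and reduce each session to a
:class:`SessionSummary`. Across sessions it computes the overlap-versus-gain
rank correlation, the demixing-cost comparison, and the lag-1 cross-trial
state persistence, and :func:`run_all` writes a deterministic report (JSON
summary, CSV tables, static figures).

Session-level definitions
-------------------------
* ``behavioral_gain`` is the hit-rate difference between the decoded-TA
  "close" and "far" bins (close minus far). An equalized variant recomputes
  the per-bin hit rates after subsampling every (bin, cue location) cell to a
  common trial count, controlling for cue composition.
* ``overlap`` is the absolute normalized dot product between the first
  attention (TA-bin) and first outcome dPC *decoding* axes, each fitted on
  its own single-parameter condition tensor obtained by collapsing the
  balanced TA x outcome tensor over the other factor. The estimate is
  averaged over a small number of independent balanced-tensor draws (each
  with its own cross-validated ridge penalty) to reduce subsampling noise.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from . import __version__ as _pkg_version
from .as_decoder import estimates_to_frame, hit_rate_by_ta, rolling_decode
from .dpca import (build_condition_tensor, collapse_factor, decode_with_axis,
                   fit_dpca, select_lambda, axis_overlap)
from .noise_corr import noise_corr_by_outcome
from .selectivity import records_to_frame, unit_selectivity
from .synthetic_data import (SessionData, StateConfig, TaskConfig,
                             simulate_sessions)

PIPELINE_STAGES = ("simulate", "decode", "selectivity", "noise_corr",
                   "dpca", "summarize")


class PipelineError(RuntimeError):
    """A pipeline stage failed; the stage name is recorded on the exception."""

    def __init__(self, stage: str, original: BaseException):
        self.stage = stage
        super().__init__(f"pipeline stage '{stage}' failed: {original!r}")


# --------------------------------------------------------------------------
# Session summary
# --------------------------------------------------------------------------

@dataclass
class SessionSummary:
    session_id: str
    behavioral_gain: float
    behavioral_gain_equalized: float
    overlap: float
    overlap_repeats: list[float] = field(default_factory=list)
    joint_accuracy: dict[str, float] = field(default_factory=dict)
    single_accuracy: dict[str, float] = field(default_factory=dict)
    noise_corr: dict[str, dict[str, float]] = field(default_factory=dict)
    hit_rate: dict[str, float] = field(default_factory=dict)
    lag1: dict[str, dict[str, float]] = field(default_factory=dict)
    n_trials: int = 0
    n_decoded: int = 0
    seeds: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.isfinite(self.behavioral_gain) \
                and not -1.0 <= self.behavioral_gain <= 1.0:
            raise ValueError("behavioral_gain must lie in [-1, 1]")
        if np.isfinite(self.overlap) and not 0.0 <= self.overlap <= 1.0:
            raise ValueError("overlap must lie in [0, 1]")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def _equalized_gain(estimates: pd.DataFrame, table: pd.DataFrame,
                    seed: int, n_resamples: int = 20) -> float:
    """Close-minus-far hit-rate gain with cue composition equalized per bin.

    Every (TA bin, cue landmark) cell is subsampled to the common minimum
    count before the per-bin hit rates are computed; the gain is averaged
    over seeded resamples. NaN when any cell is empty.
    """
    m = estimates.merge(table[["trial_id", "outcome", "cue_landmark"]],
                        on="trial_id")
    m = m[m["ta_bin"].isin(["close", "far"])]
    cells = {}
    for b in ("close", "far"):
        for c in sorted(m["cue_landmark"].unique()):
            idx = m.index[(m["ta_bin"] == b) & (m["cue_landmark"] == c)]
            if len(idx) == 0:
                return float("nan")
            cells[(b, c)] = idx
    k = min(len(v) for v in cells.values())
    rng = np.random.default_rng(seed)
    gains = []
    for _ in range(n_resamples):
        rate = {}
        for b in ("close", "far"):
            picked = np.concatenate([
                rng.choice(cells[(b, c)], k, replace=False)
                for c in sorted(m["cue_landmark"].unique())])
            rate[b] = (m.loc[picked, "outcome"] == "hit").mean()
        gains.append(rate["close"] - rate["far"])
    return float(np.mean(gains))


def session_overlap(session: SessionData, estimates: pd.DataFrame,
                    seed: int = 0, n_repeats: int = 3) -> tuple[float, list]:
    """Attention/outcome decoding-axis overlap, averaged over seeded repeats.

    Each repeat draws its own balanced TA x outcome tensor, collapses it to
    the two single-parameter tensors, fits each at a cross-validated ridge
    penalty, and takes the |dot| of the two first decoding axes.
    """
    reps = []
    for r, child in enumerate(np.random.SeedSequence([seed, 7]
                                                     ).spawn(n_repeats)):
        s_tensor, s_ta, s_ou = (int(c.generate_state(1)[0] % (2 ** 31))
                                for c in child.spawn(3))
        tj = build_condition_tensor(session, estimates=estimates,
                                    grid_spec="ta_x_outcome", seed=s_tensor)
        t_ta = collapse_factor(tj, "ta_bin")
        t_ou = collapse_factor(tj, "outcome")
        d_ta = fit_dpca(t_ta, lam=select_lambda(t_ta, seed=s_ta)
                        ).first("ta_bin").decoder
        d_ou = fit_dpca(t_ou, lam=select_lambda(t_ou, seed=s_ou)
                        ).first("outcome").decoder
        reps.append(axis_overlap(d_ta, d_ou).dot)
    return float(np.mean(reps)), [float(x) for x in reps]


def summarize_session(session: SessionData,
                      estimates: pd.DataFrame | None = None,
                      seed: int = 0,
                      overlap_repeats: int = 3,
                      decode_cv: int = 25,
                      decode_shuffles: int = 50,
                      nc_epochs: tuple[str, ...] = ("pre_target", "pre_cue"),
                      equalize_nc: bool = True,
                      lam: float | str = "auto") -> SessionSummary:
    """Reduce one session to its summary statistics.

    ``estimates`` are decoded if not supplied. ``decode_cv``/``decode_shuffles``
    control the axis-decoding accuracy estimates (joint vs single-parameter
    dPCA axes, one per parameter).
    """
    if estimates is None:
        estimates = estimates_to_frame(rolling_decode(session, lam=lam))
    table = session.trial_table
    hr = hit_rate_by_ta(estimates, table)
    gain = hr.get("close", np.nan) - hr.get("far", np.nan)
    gain_eq = _equalized_gain(estimates, table, seed=seed + 11)

    ov, reps = session_overlap(session, estimates, seed=seed,
                               n_repeats=overlap_repeats)

    # joint (demixed) vs independent single-parameter axis decoding
    # accuracies; the single-parameter fit uses the raw one-factor grid, so
    # it keeps any information shared with the other parameter, while the
    # joint fit's balanced marginalization removes it. The same CV seed pairs
    # the held-out draws of the two variants.
    tj = build_condition_tensor(session, estimates=estimates,
                                grid_spec="ta_x_outcome", seed=seed)
    joint = fit_dpca(tj, lam=select_lambda(tj, seed=seed + 1))
    joint_acc, single_acc = {}, {}
    for j, (param, grid) in enumerate((("ta_bin", "ta"),
                                       ("outcome", "outcome"))):
        res = decode_with_axis(joint, tj, f"{param}_0", n_cv=decode_cv,
                               n_shuffles=decode_shuffles, seed=seed + 2 + j)
        joint_acc[param] = res.accuracy
        t1 = build_condition_tensor(session, estimates=estimates,
                                    grid_spec=grid, seed=seed)
        m1 = fit_dpca(t1, lam=select_lambda(t1, seed=seed + 4 + j))
        res1 = decode_with_axis(m1, t1, f"{param}_0", n_cv=decode_cv,
                                n_shuffles=decode_shuffles, seed=seed + 2 + j)
        single_acc[param] = res1.accuracy

    nc_results = noise_corr_by_outcome(
        session, epochs=nc_epochs, equalize_ta=equalize_nc,
        estimates=estimates if equalize_nc else None, seed=seed + 8)
    nc = {r.epoch: {k: float(v) for k, v in r.mean_by_type.items()}
          for r in nc_results}

    # lag-1 persistence of trial-type component projections
    tt = build_condition_tensor(session, grid_spec="trial_type")
    mod_tt = fit_dpca(tt, lam=select_lambda(tt, seed=seed + 9))
    lag1 = cross_trial_state_correlation(
        mod_tt, tt, components=("trial_type_0", "trial_type_1"))

    return SessionSummary(
        session_id=session.session_id,
        behavioral_gain=float(gain), behavioral_gain_equalized=gain_eq,
        overlap=ov, overlap_repeats=reps,
        joint_accuracy=joint_acc, single_accuracy=single_acc,
        noise_corr=nc,
        hit_rate={k: float(v) for k, v in hr.items()},
        lag1=lag1,
        n_trials=int(session.n_trials), n_decoded=int(len(estimates)),
        seeds={"summary": int(seed)})


# --------------------------------------------------------------------------
# Across-session statistics
# --------------------------------------------------------------------------

def demixing_cost(session: SessionData,
                  estimates: pd.DataFrame | None = None,
                  seed: int = 0, decode_cv: int = 25,
                  decode_shuffles: int = 50) -> dict:
    """Per-parameter decoding-accuracy cost of demixing for one session.

    Compares the first-axis decoding accuracy of the joint (demixed) dPCA
    against the single-parameter dPCA fitted on the collapsed tensor, for the
    TA-bin and outcome parameters. Positive ``difference`` means the
    single-parameter axis decodes better, i.e. demixing costs accuracy.
    """
    if estimates is None:
        estimates = estimates_to_frame(rolling_decode(session))
    s = summarize_session(session, estimates, seed=seed, overlap_repeats=1,
                          decode_cv=decode_cv, decode_shuffles=decode_shuffles)
    return {param: {"single": s.single_accuracy[param],
                    "joint": s.joint_accuracy[param],
                    "difference": s.single_accuracy[param]
                    - s.joint_accuracy[param]}
            for param in s.joint_accuracy}


def demixing_cost_test(summaries: list[SessionSummary]) -> dict:
    """Paired across-session test of the demixing cost, per parameter.

    Two-sided Wilcoxon signed-rank test on the per-session differences
    (single-parameter minus joint accuracy).
    """
    out = {}
    for param in summaries[0].joint_accuracy:
        diff = np.array([s.single_accuracy[param] - s.joint_accuracy[param]
                         for s in summaries])
        if np.allclose(diff, 0):
            p = 1.0
        else:
            p = float(stats.wilcoxon(diff, alternative="two-sided").pvalue)
        out[param] = {"mean_difference": float(diff.mean()),
                      "median_difference": float(np.median(diff)),
                      "p_value": p, "n_sessions": len(diff)}
    return out


def overlap_vs_gain(summaries: list[SessionSummary],
                    gain_field: str = "behavioral_gain") -> dict:
    """Spearman rank correlation between axis overlap and behavioral gain.

    Returns rho, p, n, and the scatter (one row per session). Requires at
    least 5 sessions; a constant overlap (or gain) vector yields missing
    (NaN) statistics with a warning.
    """
    if len(summaries) < 5:
        raise ValueError("overlap_vs_gain requires at least 5 sessions")
    scatter = pd.DataFrame({
        "session_id": [s.session_id for s in summaries],
        "overlap": [s.overlap for s in summaries],
        "behavioral_gain": [getattr(s, gain_field) for s in summaries]})
    ok = scatter[["overlap", "behavioral_gain"]].notna().all(axis=1)
    sub = scatter[ok]
    if len(sub) < 5 or sub["overlap"].nunique() == 1 \
            or sub["behavioral_gain"].nunique() == 1:
        warnings.warn("constant or insufficient overlap/gain values; "
                      "correlation undefined", stacklevel=2)
        return {"rho": float("nan"), "p_value": float("nan"),
                "n_sessions": int(ok.sum()), "scatter": scatter}
    res = stats.spearmanr(sub["overlap"], sub["behavioral_gain"])
    return {"rho": float(res.statistic), "p_value": float(res.pvalue),
            "n_sessions": int(len(sub)), "scatter": scatter}


def cross_trial_state_correlation(model, tensor, components=None,
                                  min_trials: int = 20) -> dict:
    """Lag-1 correlation of component projections across consecutive trials.

    Projects every single trial on each requested component's decoding axis
    (time-averaged), orders trials by their position in the session, and
    correlates trial t with trial t-1 (Pearson, with p-value). Fewer than
    ``min_trials`` trials yields missing (NaN) values.
    """
    if components is None:
        components = [f"{m}_0" for m in model.marginalizations()
                      if m != "condition_independent"]
    order = np.argsort(tensor.trial_labels["row"].to_numpy())
    out = {}
    for name in components:
        comp = model.get(name)
        proj = np.einsum("u,nut->n", comp.decoder,
                         tensor.single_trials) / tensor.single_trials.shape[2]
        proj = proj[order]
        if len(proj) < min_trials:
            out[name] = {"r": float("nan"), "p_value": float("nan"),
                         "n_trials": int(len(proj))}
            continue
        r, p = stats.pearsonr(proj[1:], proj[:-1])
        out[name] = {"r": float(r), "p_value": float(p),
                     "n_trials": int(len(proj))}
    return out


# --------------------------------------------------------------------------
# Type-I error calibration under null simulations
# --------------------------------------------------------------------------

def _shuffled_labels(session: SessionData, estimates: pd.DataFrame,
                     rng: np.random.Generator
                     ) -> tuple[SessionData, pd.DataFrame]:
    """Null copy: permute behavioral labels relative to the spike counts."""
    table = session.trial_table.copy()
    perm = rng.permutation(len(table))
    for col in ("outcome", "cue_landmark"):
        table[col] = table[col].to_numpy()[perm]
    est = estimates.copy()
    perm_e = rng.permutation(len(est))
    for col in ("x_as", "y_as", "ta", "ta_bin"):
        est[col] = est[col].to_numpy()[perm_e]
    null = dataclasses.replace(session, trial_table=table)
    return null, est


def selectivity_type_one_error(n_replicates: int = 200, seed: int = 0,
                               n_trials: int = 800,
                               alpha: float = 0.05) -> dict:
    """Empirical per-unit test size under label-permutation nulls.

    One default session is simulated and decoded once; every replicate
    permutes the outcome/cue labels and the decoded-TA assignments relative
    to the spike counts (an exact null by exchangeability) and re-runs the
    per-unit selectivity tests. Returns the average rejection rates of the
    attention and outcome tests at level ``alpha``.
    """
    bundle = simulate_sessions(1, n_trials, seed=seed)[0]
    session = bundle.session
    est = estimates_to_frame(rolling_decode(session))
    rng = np.random.default_rng(seed + 1)
    rej_att, rej_out = [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _ in range(n_replicates):
            null, est_null = _shuffled_labels(session, est, rng)
            df = records_to_frame(unit_selectivity(null, est_null,
                                                   alpha=alpha))
            rej_att.append((df["p_attention"] < alpha).mean())
            rej_out.append((df["p_outcome"] < alpha).mean())
    return {"attention_rejection_rate": float(np.mean(rej_att)),
            "outcome_rejection_rate": float(np.mean(rej_out)),
            "nominal_alpha": alpha, "n_replicates": n_replicates}


def decoding_type_one_error(n_replicates: int = 200, seed: int = 0,
                            n_trials: int = 300, n_cv: int = 20,
                            n_shuffles: int = 99,
                            alpha: float = 0.05) -> dict:
    """Empirical size of the axis-decoding permutation test.

    A trial-type dPCA is fitted once on a default simulated session; every
    replicate permutes the trial-type labels (null) and tests the first
    component's decoding accuracy against its shuffle distribution. Returns
    the rejection rate of the permutation p-value at level ``alpha``.
    """
    bundle = simulate_sessions(1, n_trials, seed=seed)[0]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        tensor = build_condition_tensor(bundle.session,
                                        grid_spec="trial_type")
        model = fit_dpca(tensor)
        rng = np.random.default_rng(seed + 1)
        rejections = 0
        for r in range(n_replicates):
            labels = tensor.trial_labels.copy()
            labels["trial_type_idx"] = rng.permutation(
                labels["trial_type_idx"].to_numpy())
            null = dataclasses.replace(tensor, trial_labels=labels)
            res = decode_with_axis(model, null, "trial_type_0", n_cv=n_cv,
                                   n_shuffles=n_shuffles, seed=seed + 2 + r)
            rejections += res.p_value < alpha
    return {"rejection_rate": rejections / n_replicates,
            "nominal_alpha": alpha, "n_replicates": n_replicates}


# --------------------------------------------------------------------------
# Full pipeline
# --------------------------------------------------------------------------

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": {
        "n_sessions": 18,
        "n_trials": 800,
        "n_units": 48,
        "overlap_gain_sweep": True,
        "overlap_mix_range": [0.02, 0.98],
        "beta_ta_range": [0.30, 0.10],
        "sessions_dir": None,       # load saved sessions instead of simulating
        "task": TaskConfig().to_dict(),
        "states": StateConfig().to_dict(),
    },
    "decoder": {
        "lambda": "auto",           # GCV over the log grid, or a float
        "train_size": 200,
        "step": 20,
        "training_window_ms": [-220.0, 30.0],
        "testing_window_ms": [-150.0, 0.0],
    },
    "selectivity": {
        "alpha": 0.05,
        "analysis_window_ms": [-250.0, -50.0],
        "min_trials": 10,
    },
    "noise_corr": {
        "epochs": ["pre_target", "pre_cue"],
        "equalize_ta": True,
        "window_ms": 200.0,
    },
    "dpca": {
        "window_ms": [-300.0, 0.0],
        "smoothing_ms": 30.0,
        "lambda": "auto",           # cross-validated, or a float
        "n_components": 20,
        "balance_resamples": 10,
    },
    "pipeline": {
        "overlap_repeats": 3,
        "decode_cv": 25,
        "decode_shuffles": 50,
        "figures": True,
    },
}


def load_config(path_or_dict=None) -> dict:
    """Merge a user config (dict or JSON file path) over the defaults."""
    cfg = json.loads(json.dumps(DEFAULT_CONFIG))  # deep copy
    if path_or_dict is None:
        return cfg
    user = path_or_dict if isinstance(path_or_dict, dict) \
        else json.loads(Path(path_or_dict).read_text())
    for key, value in user.items():
        if key not in cfg:
            raise ValueError(f"unknown config section '{key}'")
        if isinstance(value, dict):
            for k, v in value.items():
                if k not in cfg[key]:
                    raise ValueError(f"unknown config key '{key}.{k}'")
                cfg[key][k] = v
        else:
            cfg[key] = value
    return cfg


def _session_seeds(master: int, n: int) -> list[int]:
    return [int(c.generate_state(1)[0] % (2 ** 31))
            for c in np.random.SeedSequence([master, 2]).spawn(n)]


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, exc) from exc
        return wrapped
    return deco


@_stage("simulate")
def _stage_simulate(cfg: dict) -> list:
    sim = cfg["simulate"]
    if sim["sessions_dir"]:
        root = Path(sim["sessions_dir"])
        if not root.is_dir():
            raise FileNotFoundError(f"session directory not found: {root}")
        dirs = sorted(p for p in root.iterdir() if p.is_dir())
        if not dirs:
            raise FileNotFoundError(f"no session subdirectories in {root}")
        return [SessionData.load(p) for p in dirs]
    bundles = simulate_sessions(
        sim["n_sessions"], sim["n_trials"], seed=cfg["seed"],
        task=TaskConfig.from_dict(sim["task"]),
        state_config=StateConfig.from_dict(sim["states"]),
        n_units=sim["n_units"],
        overlap_gain_sweep=sim["overlap_gain_sweep"],
        overlap_mix_range=tuple(sim["overlap_mix_range"]),
        beta_ta_range=tuple(sim["beta_ta_range"]))
    return [b.session for b in bundles]


@_stage("decode")
def _stage_decode(cfg: dict, sessions: list) -> list[pd.DataFrame]:
    d = cfg["decoder"]
    return [estimates_to_frame(rolling_decode(
        s, lam=d["lambda"], train_size=d["train_size"], step=d["step"],
        training_window_ms=tuple(d["training_window_ms"]),
        testing_window_ms=tuple(d["testing_window_ms"])))
        for s in sessions]


@_stage("selectivity")
def _stage_selectivity(cfg: dict, sessions, estimates) -> pd.DataFrame:
    sel = cfg["selectivity"]
    frames = []
    for s, est in zip(sessions, estimates):
        df = records_to_frame(unit_selectivity(
            s, est, analysis_window_ms=tuple(sel["analysis_window_ms"]),
            min_trials=sel["min_trials"], alpha=sel["alpha"]))
        df.insert(0, "session_id", s.session_id)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


@_stage("noise_corr")
def _stage_noise_corr(cfg: dict, sessions, estimates,
                      seeds) -> pd.DataFrame:
    nc = cfg["noise_corr"]
    rows = []
    for s, est, sd in zip(sessions, estimates, seeds):
        for r in noise_corr_by_outcome(
                s, epochs=tuple(nc["epochs"]),
                equalize_ta=nc["equalize_ta"],
                estimates=est if nc["equalize_ta"] else None,
                seed=sd, window_ms=nc["window_ms"]):
            for t, v in r.mean_by_type.items():
                rows.append({"session_id": s.session_id, "epoch": r.epoch,
                             "trial_type": t, "mean_nc": v,
                             "n_pairs": r.n_pairs_by_type.get(t)})
    return pd.DataFrame(rows)


@_stage("dpca")
def _stage_summaries(cfg: dict, sessions, estimates,
                     seeds) -> list[SessionSummary]:
    p = cfg["pipeline"]
    return [summarize_session(s, est, seed=sd,
                              overlap_repeats=p["overlap_repeats"],
                              decode_cv=p["decode_cv"],
                              decode_shuffles=p["decode_shuffles"],
                              equalize_nc=cfg["noise_corr"]["equalize_ta"])
            for s, est, sd in zip(sessions, estimates, seeds)]


def _figures(out: Path, summaries, ov_gain, pooled_hit) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    figdir = out / "figures"
    figdir.mkdir(exist_ok=True)
    written = []

    fig, ax = plt.subplots(figsize=(4, 3))
    bins = ["close", "medium", "far"]
    ax.bar(bins, [pooled_hit.get(b, np.nan) for b in bins], color="#4878a8")
    ax.set_xlabel("decoded TA bin")
    ax.set_ylabel("hit rate")
    ax.set_title("Pooled hit rate by decoded TA")
    fig.tight_layout()
    fig.savefig(figdir / "hit_rate_by_ta.png", dpi=120)
    plt.close(fig)
    written.append("figures/hit_rate_by_ta.png")

    sc = ov_gain["scatter"]
    fig, ax = plt.subplots(figsize=(4, 3))
    ax.scatter(sc["overlap"], sc["behavioral_gain"], color="#a84848")
    ax.set_xlabel("attention/outcome axis overlap |dot|")
    ax.set_ylabel("behavioral gain (close - far hit rate)")
    ax.set_title(f"rho={ov_gain['rho']:.2f}, p={ov_gain['p_value']:.3f}")
    fig.tight_layout()
    fig.savefig(figdir / "overlap_vs_gain.png", dpi=120)
    plt.close(fig)
    written.append("figures/overlap_vs_gain.png")

    fig, ax = plt.subplots(figsize=(4, 3))
    types = ["hit", "miss", "fa"]
    vals = {t: [s.noise_corr.get("pre_target", {}).get(t, np.nan)
                for s in summaries] for t in types}
    ax.bar(types, [np.nanmean(vals[t]) for t in types], color="#48a878")
    ax.set_xlabel("trial type")
    ax.set_ylabel("mean noise correlation")
    ax.set_title("Pre-target noise correlation by trial type")
    fig.tight_layout()
    fig.savefig(figdir / "noise_corr_by_type.png", dpi=120)
    plt.close(fig)
    written.append("figures/noise_corr_by_type.png")
    return written


def run_all(config=None, out_dir: str | Path = "attnstate_report") -> dict:
    """Run the full pipeline and write the report.

    ``config`` is a dict, a JSON file path, or None for defaults. The report
    directory receives ``summary.json``, CSV tables (session summaries,
    selectivity, noise correlations, overlap/gain scatter), and static
    figures. Every random element derives from ``config['seed']``, so two
    runs with the same config produce identical summaries. Any stage failure
    raises :class:`PipelineError` naming the stage.
    """
    cfg = load_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sessions = _stage_simulate(cfg)
        seeds = _session_seeds(cfg["seed"], len(sessions))
        estimates = _stage_decode(cfg, sessions)
        sel_df = _stage_selectivity(cfg, sessions, estimates)
        nc_df = _stage_noise_corr(cfg, sessions, estimates, seeds)
        summaries = _stage_summaries(cfg, sessions, estimates, seeds)

    try:
        pooled = pd.concat(
            [est.merge(s.trial_table[["trial_id", "outcome"]], on="trial_id")
             for s, est in zip(sessions, estimates)], ignore_index=True)
        pooled_hit = {
            b: float((pooled[pooled.ta_bin == b].outcome == "hit").mean())
            for b in ("close", "medium", "far")}
        ov_gain = overlap_vs_gain(summaries)
        demix = demixing_cost_test(summaries)

        sess_df = pd.DataFrame([{
            "session_id": s.session_id,
            "behavioral_gain": s.behavioral_gain,
            "behavioral_gain_equalized": s.behavioral_gain_equalized,
            "overlap": s.overlap,
            "joint_acc_ta": s.joint_accuracy.get("ta_bin"),
            "joint_acc_outcome": s.joint_accuracy.get("outcome"),
            "single_acc_ta": s.single_accuracy.get("ta_bin"),
            "single_acc_outcome": s.single_accuracy.get("outcome"),
            "lag1_r_tt0": s.lag1.get("trial_type_0", {}).get("r"),
            "lag1_r_tt1": s.lag1.get("trial_type_1", {}).get("r"),
            "n_trials": s.n_trials, "n_decoded": s.n_decoded,
        } for s in summaries])

        sess_df.to_csv(out / "session_summaries.csv", index=False)
        sel_df.to_csv(out / "selectivity.csv", index=False)
        nc_df.to_csv(out / "noise_corr.csv", index=False)
        ov_gain["scatter"].to_csv(out / "overlap_vs_gain.csv", index=False)

        figures = []
        if cfg["pipeline"]["figures"]:
            figures = _figures(out, summaries, ov_gain, pooled_hit)

        import matplotlib
        import scipy
        summary = {
            "stages": list(PIPELINE_STAGES),
            "config": cfg,
            "versions": {"attnstate": _pkg_version,
                         "numpy": np.__version__,
                         "scipy": scipy.__version__,
                         "pandas": pd.__version__,
                         "matplotlib": matplotlib.__version__},
            "session_seeds": seeds,
            "n_sessions": len(sessions),
            "pooled_hit_rate_by_ta": pooled_hit,
            "overlap_vs_gain": {k: v for k, v in ov_gain.items()
                                if k != "scatter"},
            "demixing_cost": demix,
            "sessions": [s.to_dict() for s in summaries],
            "tables": ["session_summaries.csv", "selectivity.csv",
                       "noise_corr.csv", "overlap_vs_gain.csv"],
            "figures": figures,
        }
        (out / "summary.json").write_text(
            json.dumps(summary, indent=1, sort_keys=True, default=float))
    except PipelineError:
        raise
    except Exception as exc:
        raise PipelineError("summarize", exc) from exc
    return summary
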