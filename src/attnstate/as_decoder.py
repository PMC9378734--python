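"""Regularized optimal linear estimation (RegOLE) of the attentional spotlight.

A ridge decoder maps the pre-target population response vector R to the cued
quadrant code C (two independent regressions: one for the x sign, one for the
y sign, each coded -1/+1). Its continuous readout is not thresholded into a
class: after an affine calibration fitted on the training cue positions it is
taken as the (x, y) position of the attentional spotlight in degrees of visual
angle. The distance of that estimate to the expected target location (TA) is
the single-trial proxy of attentional focus.

Decoding follows a rolling schedule: the decoder is (re)trained on the most
recent 200 correct trials and then applied to subsequent trials, retraining
after every 20 new correct responses. Trials seen before the warm-up is
complete are not decoded.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic_data import SessionData

TA_BIN_EDGES = (0.0, 6.0, 12.0, 18.0)
TA_BIN_LABELS = ("close", "medium", "far")

DEFAULT_TRAINING_WINDOW_MS = (-220.0, 30.0)
DEFAULT_TESTING_WINDOW_MS = (-150.0, 0.0)
LAMBDA_GRID = tuple(10.0 ** k for k in range(-3, 4))


@dataclass
class DecoderWeights:
    """Fitted ridge weights for the two axes plus the degree calibration."""

    W: np.ndarray                       # (2, n_channels): rows decode x, y
    intercept: np.ndarray               # (2,)
    lam: float
    calibration: np.ndarray             # (2, 2): per-axis (scale, offset)
    training_window_ms: tuple[float, float] = DEFAULT_TRAINING_WINDOW_MS
    testing_window_ms: tuple[float, float] = DEFAULT_TESTING_WINDOW_MS

    def __post_init__(self) -> None:
        if self.lam < 0:
            raise ValueError("lambda must be >= 0")

    def predict_code(self, R: np.ndarray) -> np.ndarray:
        """Continuous (x, y) class code for response rows R (trials x channels)."""
        return np.atleast_2d(R) @ self.W.T + self.intercept

    def predict_degrees(self, R: np.ndarray) -> np.ndarray:
        code = self.predict_code(R)
        return code * self.calibration[:, 0] + self.calibration[:, 1]


def fit_regole(R: np.ndarray, C: np.ndarray, lam: float) -> DecoderWeights:
    """Exact minimizer of ||W (R + b) - C||^2 + lambda ||W||^2.

    Implemented as ridge regression on the column-centered response matrix
    with the intercept refit afterwards, which is the same estimator up to the
    reparameterization of the additive term. ``C`` has one column per axis
    with entries in {-1, +1}.
    """
    R = np.asarray(R, dtype=float)
    C = np.atleast_2d(np.asarray(C, dtype=float))
    if C.ndim != 2 or C.shape[0] != R.shape[0]:
        raise ValueError("C must be (n_trials, n_axes) matching R")
    if not np.all(np.isfinite(R)):
        raise ValueError("R must be finite")
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    for j in range(C.shape[1]):
        if len(np.unique(C[:, j])) < 2:
            raise ValueError(f"axis {j} has fewer than 2 distinct classes")

    mu_R = R.mean(axis=0)
    mu_C = C.mean(axis=0)
    Rc = R - mu_R
    G = Rc.T @ Rc + lam * np.eye(R.shape[1])
    if lam == 0.0:
        # unregularized: fail loudly on a collinear (singular) design
        cond = np.linalg.cond(G)
        if not np.isfinite(cond) or cond > 1e12:
            raise np.linalg.LinAlgError(
                "singular normal equations at lambda=0 (collinear channels); "
                "use lambda > 0")
    W = np.linalg.solve(G, Rc.T @ (C - mu_C)).T        # (n_axes, n_channels)
    intercept = mu_C - W @ mu_R
    return DecoderWeights(W=W, intercept=intercept, lam=float(lam),
                          calibration=np.tile([1.0, 0.0], (C.shape[1], 1)))


def _gcv_lambda(R: np.ndarray, C: np.ndarray,
                grid: tuple[float, ...] = LAMBDA_GRID) -> float:
    """Generalized cross-validation for the ridge penalty on centered data."""
    Rc = R - R.mean(axis=0)
    Cc = C - C.mean(axis=0)
    n = R.shape[0]
    U, s, Vt = np.linalg.svd(Rc, full_matrices=False)
    UtC = U.T @ Cc
    best, best_score = grid[0], np.inf
    for lam in grid:
        shrink = s ** 2 / (s ** 2 + lam)
        fitted = U @ (shrink[:, None] * UtC)
        df = shrink.sum()
        denom = max(1.0 - df / n, 1e-12)
        score = ((Cc - fitted) ** 2).sum() / (n * denom ** 2)
        if score < best_score:
            best, best_score = lam, score
    return float(best)


@dataclass
class AttentionalEstimate:
    """Per-trial decoded spotlight position and target-to-attention distance."""

    trial_id: int
    x_as: float
    y_as: float
    ta: float
    ta_bin: str

    def __post_init__(self) -> None:
        if self.ta < 0:
            raise ValueError("TA must be non-negative")
        if self.ta_bin != bin_ta(self.ta):
            raise ValueError("ta_bin inconsistent with TA value")


def compute_ta(as_xy, target_xy) -> float:
    """Euclidean distance between the decoded spotlight and the target."""
    a = np.asarray(as_xy, dtype=float)
    t = np.asarray(target_xy, dtype=float)
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(t))):
        raise ValueError("coordinates must be finite")
    return float(np.linalg.norm(a - t))


def bin_ta(ta: float) -> str:
    """Half-open TA bins: close (0,6], medium (6,12], far (12,18)."""
    if ta < 0:
        raise ValueError("TA must be non-negative")
    if ta <= TA_BIN_EDGES[1]:
        return "close"
    if ta <= TA_BIN_EDGES[2]:
        return "medium"
    if ta < TA_BIN_EDGES[3]:
        return "far"
    return "out_of_range"


def _calibrate(weights: DecoderWeights, R_train: np.ndarray,
               cue_xy: np.ndarray) -> DecoderWeights:
    """Fit the per-axis affine map from decoder code units to screen degrees."""
    code = weights.predict_code(R_train)
    calib = np.empty((2, 2))
    for j in range(2):
        A = np.column_stack([code[:, j], np.ones(len(code))])
        calib[j], *_ = np.linalg.lstsq(A, cue_xy[:, j], rcond=None)
    weights.calibration = calib
    return weights


def rolling_decode(session: SessionData, lam: float | str = "auto",
                   train_size: int = 200, step: int = 20,
                   training_window_ms=DEFAULT_TRAINING_WINDOW_MS,
                   testing_window_ms=DEFAULT_TESTING_WINDOW_MS,
                   ) -> list[AttentionalEstimate]:
    """Rolling train/test decoding of the spotlight over a session.

    Returns estimates for every trial decoded after the warm-up (the first
    ``train_size`` correct trials); earlier trials are left undecoded. The
    number of performed decoder fits is stored on the returned list as the
    ``n_retrainings`` attribute of :func:`decoding_schedule`.
    """
    table = session.trial_table
    train_R = session.rates_hz(session.window_to_bins(training_window_ms, "stim"))
    test_R = session.rates_hz(session.window_to_bins(testing_window_ms, "stim"))
    cue_xy = table[["cue_x", "cue_y"]].to_numpy()
    target_xy = table[["target_x", "target_y"]].to_numpy()
    is_hit = (table["outcome"] == "hit").to_numpy()

    n_hits_total = int(is_hit.sum())
    if n_hits_total < train_size:
        warnings.warn(
            f"only {n_hits_total} correct trials; need {train_size} to train",
            stacklevel=2)
        return []

    estimates: list[AttentionalEstimate] = []
    hit_idx: list[int] = []
    weights: DecoderWeights | None = None
    stale = True  # retrain pending before decoding the next trial
    n_fits = 0
    for t in range(session.n_trials):
        n_hits = len(hit_idx)
        if stale and n_hits >= train_size:
            sel = np.array(hit_idx[-train_size:])
            R = train_R[sel]
            C = np.sign(cue_xy[sel])
            use_lam = _gcv_lambda(R, C) if lam == "auto" else float(lam)
            weights = _calibrate(fit_regole(R, C, use_lam), R, cue_xy[sel])
            weights.training_window_ms = tuple(training_window_ms)
            weights.testing_window_ms = tuple(testing_window_ms)
            n_fits += 1
            stale = False
        if weights is not None:
            xy = weights.predict_degrees(test_R[t])[0]
            ta = compute_ta(xy, target_xy[t])
            estimates.append(AttentionalEstimate(
                trial_id=int(table["trial_id"].iloc[t]), x_as=float(xy[0]),
                y_as=float(xy[1]), ta=ta, ta_bin=bin_ta(ta)))
        if is_hit[t]:
            hit_idx.append(t)
            if len(hit_idx) >= train_size and \
                    (len(hit_idx) - train_size) % step == 0:
                stale = True
    rolling_decode.last_n_fits = n_fits  # bookkeeping for schedule tests
    return estimates


def estimates_to_frame(estimates: list[AttentionalEstimate]) -> pd.DataFrame:
    return pd.DataFrame([{
        "trial_id": e.trial_id, "x_as": e.x_as, "y_as": e.y_as,
        "ta": e.ta, "ta_bin": e.ta_bin} for e in estimates],
        columns=["trial_id", "x_as", "y_as", "ta", "ta_bin"])


def hit_rate_by_ta(estimates: list[AttentionalEstimate] | pd.DataFrame,
                   trial_table: pd.DataFrame, equalize: bool = False,
                   seed: int = 0) -> dict[str, float]:
    """Detection accuracy hit/(hit+miss) per TA bin.

    With ``equalize``, hit and miss trials are subsampled (seeded) to equal
    counts within each bin before the rate is computed. Bins with no hit or
    miss trials are omitted with a warning.
    """
    df = estimates if isinstance(estimates, pd.DataFrame) \
        else estimates_to_frame(estimates)
    merged = df.merge(trial_table[["trial_id", "outcome"]], on="trial_id")
    merged = merged[merged["outcome"].isin(["hit", "miss"])]
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for label in (*TA_BIN_LABELS, "out_of_range"):
        sub = merged[merged["ta_bin"] == label]
        if len(sub) == 0:
            if label != "out_of_range":
                warnings.warn(f"TA bin '{label}' is empty; omitted", stacklevel=2)
            continue
        hits = sub[sub["outcome"] == "hit"]
        misses = sub[sub["outcome"] == "miss"]
        if equalize:
            k = min(len(hits), len(misses))
            if k == 0:
                warnings.warn(f"TA bin '{label}' lacks one class; omitted",
                              stacklevel=2)
                continue
            hits = hits.sample(k, random_state=rng.integers(2 ** 31))
            misses = misses.sample(k, random_state=rng.integers(2 ** 31))
        denom = len(hits) + len(misses)
        out[label] = len(hits) / denom
    return out
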