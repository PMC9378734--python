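"""Demixed principal component analysis of condition-averaged population data.

dPCA decomposes trial-averaged population activity into components whose
variance is attributable to designated task parameters. The centered
units x conditions x time tensor is first split exactly into factorial
marginalizations (per-parameter averages with lower-order terms removed,
time-interaction terms folded into their parameter). For each marginalization
X_phi, a reduced-rank ridge regression

    min_{F, D} || X_phi - F D X ||^2 + lambda ||F D||^2

yields paired encoder (F, columns) and decoder (D, rows) axes: the decoder
projects single trials onto the component, the encoder maps the component
back into unit space. Unlike PCA, encoder axes from different
marginalizations need not be orthogonal; their overlap (normalized dot
product) measures how strongly the corresponding neural subpopulations are
shared.

Decoder axes double as linear classifiers: single trials are projected on an
axis and assigned to the nearest class mean of the projection, with
chance estimated as the maximum accuracy over label shuffles.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .as_decoder import estimates_to_frame
from .synthetic_data import SessionData

DEFAULT_WINDOW_MS = (-300.0, 0.0)
DEFAULT_SMOOTHING_MS = 30.0
DEFAULT_LAMBDA = 1e-6
LAMBDA_GRID = tuple(float(x) for x in np.logspace(-6, 0.5, 14))
CONDITION_INDEPENDENT = "condition_independent"
INTERACTION = "interaction"

GRID_FACTORS = {
    "ta_x_outcome": (("ta_bin", ("close", "medium", "far")),
                     ("outcome", ("hit", "miss"))),
    "ta": (("ta_bin", ("close", "medium", "far")),),
    "outcome": (("outcome", ("hit", "miss")),),
    "trial_type": (("trial_type", ("hit", "miss", "fa")),),
}


# --------------------------------------------------------------------------
# Condition tensor
# --------------------------------------------------------------------------

@dataclass
class ConditionTensor:
    """Trial-averaged tensor plus the retained single trials.

    ``X`` is units x (factor levels...) x time (smoothed firing rates, Hz);
    ``single_trials`` is trials x units x time with per-trial factor labels in
    ``trial_labels`` (integer level indices per factor plus ``trial_id``).
    """

    X: np.ndarray
    factors: tuple[str, ...]
    levels: dict[str, tuple[str, ...]]
    counts: np.ndarray
    single_trials: np.ndarray
    trial_labels: pd.DataFrame
    window_ms: tuple[float, float] = DEFAULT_WINDOW_MS
    smoothing_ms: float = DEFAULT_SMOOTHING_MS
    align: str = "stim"

    @property
    def n_units(self) -> int:
        return self.X.shape[0]

    @property
    def grid_shape(self) -> tuple[int, ...]:
        return self.X.shape[1:-1]

    @property
    def n_timebins(self) -> int:
        return self.X.shape[-1]

    def flat(self) -> np.ndarray:
        """Units x (conditions*time) view of the tensor."""
        return self.X.reshape(self.n_units, -1)

    def centered(self) -> np.ndarray:
        Xf = self.flat()
        return Xf - Xf.mean(axis=1, keepdims=True)


def _trial_factor_levels(session: SessionData,
                         estimates: pd.DataFrame | None,
                         factors) -> pd.DataFrame:
    table = session.trial_table[["trial_id", "outcome"]].copy()
    if estimates is not None:
        table = table.merge(estimates[["trial_id", "ta_bin"]], on="trial_id")
    table["trial_type"] = table["outcome"]
    rows = pd.Series(np.arange(session.n_trials),
                     index=session.trial_table["trial_id"])
    table["row"] = table["trial_id"].map(rows)
    keep = np.ones(len(table), dtype=bool)
    for name, levels in factors:
        if name not in table.columns:
            raise ValueError(f"factor '{name}' requires decoded estimates"
                             if name == "ta_bin" else f"unknown factor '{name}'")
        keep &= table[name].isin(levels).to_numpy()
    table = table[keep].copy()
    for name, levels in factors:
        table[f"{name}_idx"] = table[name].map(
            {lv: i for i, lv in enumerate(levels)})
    return table


def build_condition_tensor(session: SessionData,
                           estimates=None,
                           grid_spec: str = "ta_x_outcome",
                           window_ms=DEFAULT_WINDOW_MS,
                           smoothing_ms: float = DEFAULT_SMOOTHING_MS,
                           align: str = "stim",
                           balanced: bool | None = None,
                           balance_resamples: int = 10,
                           seed: int = 0) -> ConditionTensor:
    """Trial-averaged, Gaussian-smoothed condition tensor plus single trials.

    ``grid_spec`` is one of "ta_x_outcome", "ta", "outcome", "trial_type".
    ``balanced`` subsamples every cell to the minimum cell count (seeded)
    before averaging; default on for the two-factor grid. The balanced cell
    means are averaged over ``balance_resamples`` independent subsample draws,
    which keeps the equal-trials-per-cell estimand while recovering most of
    the information in the discarded trials. Raises on empty cells and warns
    on cells with fewer than 5 trials.
    """
    if grid_spec not in GRID_FACTORS:
        raise ValueError(f"unknown grid_spec '{grid_spec}'")
    factors = GRID_FACTORS[grid_spec]
    if balanced is None:
        balanced = len(factors) == 2
    if estimates is not None and not isinstance(estimates, pd.DataFrame):
        estimates = estimates_to_frame(estimates)
    labels = _trial_factor_levels(session, estimates, factors)

    w = session.window_to_bins(window_ms, align)
    rates = session.counts[:, :, w].astype(float) \
        * (1000.0 / session.task.bin_width_ms)
    if smoothing_ms > 0:
        sigma = smoothing_ms / session.task.bin_width_ms
        rates = gaussian_filter1d(rates, sigma, axis=2, mode="nearest")
    rows = labels["row"].to_numpy()
    single = rates[rows]

    shape = tuple(len(lv) for _, lv in factors)
    n_units, n_t = session.n_units, single.shape[2]
    idx_cols = [f"{name}_idx" for name, _ in factors]
    cell_of_trial = labels[idx_cols].to_numpy()
    counts = np.zeros(shape, dtype=int)
    for cell in np.ndindex(shape):
        counts[cell] = int(np.all(cell_of_trial == cell, axis=1).sum())
    if (counts == 0).any():
        empty = [tuple(factors[d][1][c] for d, c in enumerate(cell))
                 for cell in zip(*np.nonzero(counts == 0))]
        raise ValueError(f"empty condition cell(s): {empty}")
    if (counts < 5).any():
        warnings.warn(f"condition cells with fewer than 5 trials: "
                      f"min count {counts.min()}", stacklevel=2)

    rng = np.random.default_rng(seed)
    k = counts.min() if balanced else None
    n_draws = max(1, balance_resamples) if balanced else 1
    X = np.zeros((n_units, *shape, n_t))
    for cell in np.ndindex(shape):
        sel = np.flatnonzero(np.all(cell_of_trial == cell, axis=1))
        if balanced and len(sel) > k:
            mean = np.mean([single[rng.choice(sel, k, replace=False)]
                            .mean(axis=0) for _ in range(n_draws)], axis=0)
        else:
            mean = single[sel].mean(axis=0)
        X[(slice(None), *cell, slice(None))] = mean

    levels = {name: tuple(lv) for name, lv in factors}
    return ConditionTensor(X=X, factors=tuple(n for n, _ in factors),
                           levels=levels, counts=counts, single_trials=single,
                           trial_labels=labels.reset_index(drop=True),
                           window_ms=tuple(window_ms),
                           smoothing_ms=smoothing_ms, align=align)


def collapse_factor(tensor: ConditionTensor, keep: str) -> ConditionTensor:
    """Collapse a multi-factor tensor to a single factor by averaging cells.

    Cells of the other factor(s) enter with equal weight, so the collapsed
    per-level means inherit the parent tensor's balanced composition: the
    result is the single-parameter condition tensor with the other parameter
    controlled, suitable for a single-parameter dPCA fit. Single trials and
    labels are carried over unchanged.
    """
    if keep not in tensor.factors:
        raise ValueError(f"unknown factor '{keep}'")
    axis = 1 + tensor.factors.index(keep)
    other = [i for i in range(1, 1 + len(tensor.factors)) if i != axis]
    X = tensor.X.mean(axis=tuple(other)) if other else tensor.X.copy()
    counts = tensor.counts.sum(
        axis=tuple(i - 1 for i in other)) if other else tensor.counts.copy()
    return ConditionTensor(
        X=X, factors=(keep,), levels={keep: tensor.levels[keep]},
        counts=counts, single_trials=tensor.single_trials,
        trial_labels=tensor.trial_labels, window_ms=tensor.window_ms,
        smoothing_ms=tensor.smoothing_ms, align=tensor.align)


# --------------------------------------------------------------------------
# Marginalization
# --------------------------------------------------------------------------

def marginalize(tensor: ConditionTensor | np.ndarray,
                factors: tuple[str, ...] | None = None
                ) -> dict[str, np.ndarray]:
    """Exact factorial decomposition of the centered condition tensor.

    Returns marginalized tensors (same shape as the centered tensor) keyed by
    factor name, plus "interaction" (two-factor grids) and
    "condition_independent" (the pure time course). Time-interaction terms
    are folded into their parameter's marginalization, and the pieces sum to
    the centered tensor exactly.
    """
    if isinstance(tensor, ConditionTensor):
        X = tensor.X
        factors = tensor.factors
    else:
        X = np.asarray(tensor, dtype=float)
        if factors is None:
            factors = tuple(f"factor{i}" for i in range(X.ndim - 2))
    n_cond_axes = X.ndim - 2
    if len(factors) != n_cond_axes:
        raise ValueError("factor names must match condition axes")

    Xc = X - X.mean(axis=tuple(range(1, X.ndim)), keepdims=True)
    # condition-independent: average over all condition axes (keeps time)
    cond_axes = tuple(range(1, 1 + n_cond_axes))
    X_t = Xc.mean(axis=cond_axes, keepdims=True)
    out: dict[str, np.ndarray] = {
        CONDITION_INDEPENDENT: np.broadcast_to(X_t, Xc.shape).copy()}
    if n_cond_axes == 1:
        out[factors[0]] = Xc - X_t
        return out
    if n_cond_axes != 2:
        raise ValueError("only one- and two-factor grids are supported")
    # per-factor marginals: average over the other factor, minus X_t
    X_a = Xc.mean(axis=2, keepdims=True) - X_t
    X_b = Xc.mean(axis=1, keepdims=True) - X_t
    out[factors[0]] = np.broadcast_to(X_a, Xc.shape).copy()
    out[factors[1]] = np.broadcast_to(X_b, Xc.shape).copy()
    out[INTERACTION] = Xc - X_t - X_a - X_b
    return out


# --------------------------------------------------------------------------
# Model
# --------------------------------------------------------------------------

@dataclass
class DPCAComponent:
    marginalization: str
    index: int                      # rank within its marginalization
    encoder: np.ndarray             # unit-norm, (n_units,)
    decoder: np.ndarray             # (n_units,)
    explained_variance: float       # fraction of total centered variance

    @property
    def name(self) -> str:
        return f"{self.marginalization}_{self.index}"


@dataclass
class DPCAModel:
    components: list[DPCAComponent]
    marginalization_variance: dict[str, float]  # ||X_phi||^2 shares
    total_variance: float
    lam: float
    factors: tuple[str, ...] = ()
    levels: dict = field(default_factory=dict)

    def get(self, name: str) -> DPCAComponent:
        for c in self.components:
            if c.name == name:
                return c
        raise KeyError(f"unknown component '{name}'")

    def first(self, marginalization: str) -> DPCAComponent:
        return self.get(f"{marginalization}_0")

    def marginalizations(self) -> list[str]:
        return list(self.marginalization_variance)


def _fix_sign(F: np.ndarray, D: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # bit-reproducible convention: largest-|element| of each decoder axis > 0
    for k in range(D.shape[0]):
        j = int(np.argmax(np.abs(D[k])))
        if D[k, j] < 0:
            D[k] = -D[k]
            F[:, k] = -F[:, k]
    return F, D


def fit_dpca(tensor: ConditionTensor, marginals=None,
             lam: float = DEFAULT_LAMBDA, n_components: int = 20) -> DPCAModel:
    """Reduced-rank ridge solution per marginalization.

    ``lam`` scales the ridge penalty relative to the total squared norm of
    the centered tensor. Components within each marginalization are ordered
    by explained variance; signs follow a fixed convention so fits are
    bit-reproducible.
    """
    if lam < 0:
        raise ValueError("lambda must be >= 0")
    if marginals is None:
        marginals = marginalize(tensor)
    Xf = tensor.centered()
    total = float((Xf ** 2).sum())
    lam_abs = lam * total
    n_units = Xf.shape[0]
    G = Xf @ Xf.T + lam_abs * np.eye(n_units)
    G_inv_X = np.linalg.solve(G, Xf)

    components: list[DPCAComponent] = []
    marg_var: dict[str, float] = {}
    for phi, Xphi in marginals.items():
        Xphi_f = Xphi.reshape(n_units, -1)
        marg_var[phi] = float((Xphi_f ** 2).sum())
        # ridge map W = X_phi X^T (X X^T + lam I)^{-1}; G^{-1} is symmetric
        Wmap = Xphi_f @ G_inv_X.T                # (units x units)
        M = Wmap @ Xf                            # ridge prediction of X_phi
        q = min(n_components, n_units, M.shape[1])
        U, s, Vt = _robust_svd(M)
        U = U[:, :q]
        D = U.T @ Wmap                           # decoders
        F, D = _fix_sign(U.copy(), D)
        for k in range(q):
            ev = _component_ev(F[:, k], D[k], Xf, total)
            components.append(DPCAComponent(
                marginalization=phi, index=k, encoder=F[:, k],
                decoder=D[k], explained_variance=ev))
    # order within marginalization already by singular value; re-rank by ev
    by_phi: dict[str, list[DPCAComponent]] = {}
    for c in components:
        by_phi.setdefault(c.marginalization, []).append(c)
    ordered = []
    for phi, comps in by_phi.items():
        comps.sort(key=lambda c: -c.explained_variance)
        for i, c in enumerate(comps):
            c.index = i
        ordered.extend(comps)
    return DPCAModel(components=ordered, marginalization_variance=marg_var,
                     total_variance=total, lam=lam, factors=tensor.factors,
                     levels=dict(tensor.levels))


def _robust_svd(M: np.ndarray):
    """SVD with a fallback for the rare LAPACK gesdd non-convergence."""
    try:
        return np.linalg.svd(M, full_matrices=False)
    except np.linalg.LinAlgError:
        from scipy.linalg import svd as _ssvd
        return _ssvd(M, full_matrices=False, lapack_driver="gesvd")


def select_lambda(tensor: ConditionTensor,
                  grid: tuple[float, ...] = LAMBDA_GRID,
                  n_repeats: int = 10, seed: int = 0) -> float:
    """Cross-validated ridge scale for :func:`fit_dpca`.

    Repeatedly holds out one random trial per condition cell, refits the
    condition means on the remaining trials, and scores every ``lam`` on the
    grid by the squared error between the dPCA reconstruction (sum of
    per-marginalization rank-reduced predictions) and the held-out trials.
    Returns the grid value with the smallest summed held-out error.
    """
    idx_cols = [f"{name}_idx" for name in tensor.factors]
    cells = tensor.trial_labels[idx_cols].to_numpy()
    shape = tuple(len(tensor.levels[n]) for n in tensor.factors)
    cell_trials = {cell: np.flatnonzero(np.all(cells == cell, axis=1))
                   for cell in np.ndindex(shape)}
    if any(len(v) < 2 for v in cell_trials.values()):
        raise ValueError("every condition cell needs >= 2 trials for CV")
    rng = np.random.default_rng(seed)
    n_units, n_t = tensor.n_units, tensor.n_timebins
    errs = np.zeros(len(grid))
    for _ in range(n_repeats):
        Xtr = np.zeros((n_units, *shape, n_t))
        Xte = np.zeros_like(Xtr)
        for cell, tr in cell_trials.items():
            held = tr[rng.integers(len(tr))]
            rest = tr[tr != held]
            Xtr[(slice(None), *cell)] = \
                tensor.single_trials[rest].mean(axis=0)
            Xte[(slice(None), *cell)] = tensor.single_trials[held]
        marg = marginalize(Xtr, tensor.factors)
        Xf = Xtr.reshape(n_units, -1)
        mu = Xf.mean(axis=1, keepdims=True)
        Xf = Xf - mu
        total = float((Xf ** 2).sum())
        Xte_f = Xte.reshape(n_units, -1) - mu
        U_x, s_x, Vt_x = _robust_svd(Xf)
        for j, lam in enumerate(grid):
            # ridge prediction of each marginalization via the SVD of X
            shrink = s_x / (s_x ** 2 + lam * total)
            recon = np.zeros_like(Xf)
            for phi, Xphi in marg.items():
                Xphi_f = Xphi.reshape(n_units, -1)
                Wmap = (Xphi_f @ Vt_x.T) @ np.diag(shrink) @ U_x.T
                M = Wmap @ Xf
                q = min(20, n_units, M.shape[1])
                U = _robust_svd(M)[0][:, :q]
                recon += U @ (U.T @ (Wmap @ Xf))
            errs[j] += float(((Xte_f - recon) ** 2).sum())
    return float(grid[int(np.argmin(errs))])


def _component_ev(f: np.ndarray, d: np.ndarray, Xf: np.ndarray,
                  total: float) -> float:
    proj = d @ Xf
    # ||X - f d X||^2 = ||X||^2 - 2 (f^T X) . (d X) + ||d X||^2
    return float((2.0 * (f @ Xf) @ proj - proj @ proj) / total)


def explained_variance(model: DPCAModel, tensor: ConditionTensor) -> dict:
    """Variance accounting: marginalization shares and per-component fractions.

    ``marginalization_shares`` split the total centered (signal) variance
    among the parameters, their interaction, and the condition-independent
    part; ``component_variance`` gives each component's fraction of total
    variance, and ``component_marginalized`` its variance captured within its
    own marginalization.
    """
    Xf = tensor.centered()
    total = float((Xf ** 2).sum())
    marginals = marginalize(tensor)
    shares = {phi: float((m.reshape(Xf.shape[0], -1) ** 2).sum()) / total
              for phi, m in marginals.items()}
    comp_var = {}
    comp_marg = {}
    for c in model.components:
        comp_var[c.name] = _component_ev(c.encoder, c.decoder, Xf, total)
        Xphi = marginals[c.marginalization].reshape(Xf.shape[0], -1)
        comp_marg[c.name] = float(((c.decoder @ Xphi) ** 2).sum()) / total
    return {"marginalization_shares": shares,
            "component_variance": comp_var,
            "component_marginalized": comp_marg,
            "total_variance": total}


def cumulative_variance(model: DPCAModel, tensor: ConditionTensor,
                        n_components: int | None = None) -> np.ndarray:
    """Cumulative explained variance using the globally best-ranked components."""
    Xf = tensor.centered()
    total = float((Xf ** 2).sum())
    comps = sorted(model.components, key=lambda c: -c.explained_variance)
    if n_components is not None:
        comps = comps[:n_components]
    out = np.empty(len(comps))
    recon = np.zeros_like(Xf)
    for i, c in enumerate(comps):
        recon += np.outer(c.encoder, c.decoder @ Xf)
        out[i] = 1.0 - ((Xf - recon) ** 2).sum() / total
    return out


# --------------------------------------------------------------------------
# PCA baseline
# --------------------------------------------------------------------------

def pca_baseline(tensor: ConditionTensor, n_components: int = 20) -> dict:
    """Standard PCA on the centered units x (conditions*time) matrix."""
    Xf = tensor.centered()
    U, s, Vt = np.linalg.svd(Xf, full_matrices=False)
    var = s ** 2
    q = min(n_components, len(s))
    cum = np.cumsum(var)[:q] / var.sum()
    proj = (U[:, :q].T @ Xf).reshape(q, *tensor.X.shape[1:])
    return {"components": U[:, :q], "singular_values": s[:q],
            "cumulative_variance": cum,
            "explained_variance_ratio": var[:q] / var.sum(),
            "condition_projections": proj}


# --------------------------------------------------------------------------
# Axis decoding with shuffle chance
# --------------------------------------------------------------------------

@dataclass
class AxisDecodingResult:
    component: str
    accuracy: float
    accuracy_timecourse: np.ndarray
    chance_distribution: np.ndarray
    chance_threshold: float
    p_value: float
    significant: bool
    n_classes: int


def _class_labels(tensor: ConditionTensor, marginalization: str) -> np.ndarray:
    labels = tensor.trial_labels
    if marginalization in tensor.factors:
        return labels[f"{marginalization}_idx"].to_numpy()
    if marginalization == INTERACTION:
        idx = np.zeros(len(labels), dtype=int)
        for name in tensor.factors:
            idx = idx * len(tensor.levels[name]) + labels[f"{name}_idx"]
        return idx
    raise ValueError(
        f"components of '{marginalization}' do not define trial classes")


def _cv_accuracy(proj: np.ndarray, y: np.ndarray, n_classes: int,
                 n_cv: int, rng: np.random.Generator
                 ) -> tuple[float, np.ndarray]:
    """Hold-one-trial-per-class cross-validated nearest-class-mean accuracy.

    ``proj`` is trials x time; classification uses the time-averaged
    projection, and a per-timebin accuracy time course is also returned.
    """
    pbar = proj.mean(axis=1)
    class_idx = [np.flatnonzero(y == c) for c in range(n_classes)]
    hits = 0.0
    tc = np.zeros(proj.shape[1])
    for _ in range(n_cv):
        test = np.array([idx[rng.integers(len(idx))] for idx in class_idx])
        mask = np.ones(len(y), dtype=bool)
        mask[test] = False
        means = np.array([pbar[mask & (y == c)].mean()
                          for c in range(n_classes)])
        pred = np.argmin(np.abs(pbar[test][:, None] - means[None, :]), axis=1)
        hits += (pred == np.arange(n_classes)).mean()
        means_t = np.stack([proj[mask & (y == c)].mean(axis=0)
                            for c in range(n_classes)])  # classes x time
        pred_t = np.argmin(
            np.abs(proj[test][:, None, :] - means_t[None, :, :]), axis=1)
        tc += (pred_t == np.arange(n_classes)[:, None]).mean(axis=0)
    return hits / n_cv, tc / n_cv


def decode_with_axis(model: DPCAModel, tensor: ConditionTensor,
                     component: str, n_cv: int = 100, n_shuffles: int = 100,
                     seed: int = 0) -> AxisDecodingResult:
    """Use a component's decoder axis as a linear classifier with shuffle chance.

    Cross-validation holds out one trial per class per repeat and classifies
    by nearest class mean of the axis projection. Chance is estimated by
    repeating the identical procedure on label-shuffled data; the permutation
    p-value ``p = (1 + #{shuffle >= observed}) / (n_shuffles + 1)`` is exact
    under exchangeability, so ``significant`` (p < 0.05) holds type-I error
    at the nominal 5% under the null. ``chance_threshold`` is the maximum of
    the shuffle distribution, following the source convention.
    """
    comp = model.get(component)
    y = _class_labels(tensor, comp.marginalization)
    n_classes = int(y.max()) + 1
    counts = np.bincount(y, minlength=n_classes)
    if (counts < 2).any():
        raise ValueError("every class needs at least 2 trials for CV decoding")
    proj = np.einsum("u,nut->nt", comp.decoder, tensor.single_trials)
    rng = np.random.default_rng(seed)
    acc, tc = _cv_accuracy(proj, y, n_classes, n_cv, rng)
    chance = np.empty(n_shuffles)
    for s in range(n_shuffles):
        y_shuf = rng.permutation(y)
        chance[s], _ = _cv_accuracy(proj, y_shuf, n_classes, n_cv, rng)
    thr = float(chance.max())
    p = float((1 + (chance >= acc).sum()) / (n_shuffles + 1))
    return AxisDecodingResult(component=component, accuracy=float(acc),
                              accuracy_timecourse=tc,
                              chance_distribution=chance,
                              chance_threshold=thr, p_value=p,
                              significant=bool(p < 0.05),
                              n_classes=n_classes)


def theoretical_chance(n_classes: int) -> float:
    """Theoretical chance accuracy (percent) of an n-class classifier."""
    if n_classes < 1:
        raise ValueError("n_classes must be >= 1")
    return 100.0 / n_classes


# --------------------------------------------------------------------------
# Overlap and component removal
# --------------------------------------------------------------------------

@dataclass
class AxisOverlap:
    dot: float
    angle_deg: float
    threshold: float
    non_orthogonal: bool


def axis_overlap(axis_a: np.ndarray, axis_b: np.ndarray,
                 n_mc: int = 10000, seed: int = 0) -> AxisOverlap:
    """Absolute normalized dot product, angle, and non-orthogonality test.

    Significance is assessed against a Monte-Carlo null of independent random
    unit vectors in the same dimension (threshold: 97.5th percentile of the
    null |dot| distribution).
    """
    a = np.asarray(axis_a, dtype=float).ravel()
    b = np.asarray(axis_b, dtype=float).ravel()
    if a.shape != b.shape:
        raise ValueError("axes must have the same dimension")
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("zero vector has no direction")
    dot = float(np.abs(a @ b) / (na * nb))
    dot = min(dot, 1.0)
    angle = float(np.degrees(np.arccos(dot)))
    rng = np.random.default_rng(seed)
    u = rng.normal(size=(n_mc, len(a)))
    v = rng.normal(size=(n_mc, len(a)))
    null = np.abs(np.einsum("ij,ij->i", u, v)) \
        / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
    thr = float(np.percentile(null, 97.5))
    return AxisOverlap(dot=dot, angle_deg=angle, threshold=thr,
                       non_orthogonal=dot > thr)


def remove_component_backproject(model: DPCAModel, data: np.ndarray,
                                 component: str) -> np.ndarray:
    """Remove one component's variance and back-project to unit space.

    ``data`` may be the condition tensor (units first) or single trials
    (trials x units x time): X_cleaned = X - F_k (D_k X).
    """
    comp = model.get(component)
    X = np.asarray(data, dtype=float)
    if X.ndim >= 2 and X.shape[0] == len(comp.decoder):
        proj = np.tensordot(comp.decoder, X, axes=(0, 0))
        return X - np.multiply.outer(comp.encoder, proj)
    if X.ndim == 3 and X.shape[1] == len(comp.decoder):
        proj = np.einsum("u,nut->nt", comp.decoder, X)
        return X - comp.encoder[None, :, None] * proj[:, None, :]
    raise ValueError("data shape does not match the model's unit dimension")
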