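"""Pre-stimulus pairwise noise correlations by trial type.

Noise correlations are Pearson correlations between the z-scored windowed
responses of simultaneously recorded channel pairs, computed over the trials
of one type (hit / miss / false alarm) in a 200 ms window before stimulus
onset (pre-target) or before cue onset (pre-cue). Following the source
convention, only positive significant pair correlations enter the summary.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .synthetic_data import SessionData

DEFAULT_WINDOW_MS = 200.0
TRIAL_TYPES = ("hit", "miss", "fa")
EPOCH_ALIGN = {"pre_target": "stim", "pre_cue": "cue"}


@dataclass
class NoiseCorrResult:
    session_id: str
    epoch: str
    mean_by_type: dict = field(default_factory=dict)
    median_by_type: dict = field(default_factory=dict)
    n_pairs_by_type: dict = field(default_factory=dict)
    window_ms: float = DEFAULT_WINDOW_MS


def trial_responses(session: SessionData, epoch: str = "pre_target",
                    trial_subset: np.ndarray | None = None,
                    window_ms: float = DEFAULT_WINDOW_MS,
                    groups: np.ndarray | None = None,
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Windowed mean responses, z-scored per channel across the subset's trials.

    Returns ``(Z, kept_channels)``: Z has exact per-channel mean 0 and sample
    SD 1 (ddof=1) over trials; zero-variance channels are excluded with a
    warning. When ``groups`` (one label per subset trial) is given, per-group
    condition means are subtracted first, so the correlations downstream are
    noise correlations proper — shared trial-to-trial variability around the
    stimulus-conditioned response — rather than signal correlations driven by
    the varying cue location.
    """
    if epoch not in EPOCH_ALIGN:
        raise ValueError(f"epoch must be one of {sorted(EPOCH_ALIGN)}")
    idx = np.arange(session.n_trials) if trial_subset is None \
        else np.asarray(trial_subset)
    if len(idx) < 3:
        raise ValueError("need at least 3 trials to z-score responses")
    w = session.window_to_bins((-window_ms, 0.0), EPOCH_ALIGN[epoch])
    resp = session.rates_hz(w)[idx]
    if groups is not None:
        groups = np.asarray(groups)
        if groups.shape != (len(idx),):
            raise ValueError("groups must have one label per subset trial")
        for g in np.unique(groups):
            sel = groups == g
            resp[sel] -= resp[sel].mean(axis=0)
    sd = resp.std(axis=0, ddof=1)
    kept = np.flatnonzero(sd > 0)
    if len(kept) < resp.shape[1]:
        warnings.warn(
            f"excluded {resp.shape[1] - len(kept)} zero-variance channel(s)",
            stacklevel=2)
    z = (resp[:, kept] - resp[:, kept].mean(axis=0)) / sd[kept]
    return z, kept


def noise_correlation(responses: np.ndarray,
                      alpha: float = 0.05) -> dict:
    """Pairwise Pearson matrix with per-pair significance and filtered summary.

    The summary statistics (mean and median) are taken over off-diagonal pairs
    with r > 0 and p < alpha (two-sided test). Returns a dict with keys
    ``corr`` (symmetric matrix, unit diagonal), ``pvals``, ``mean``,
    ``median`` and ``n_pairs``.
    """
    R = np.asarray(responses, dtype=float)
    n, k = R.shape
    if n < 3:
        raise ValueError("need at least 3 trials")
    C = np.corrcoef(R.T)
    C = np.clip((C + C.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(C, 1.0)
    # two-sided Pearson test via the exact t transform
    with np.errstate(divide="ignore", invalid="ignore"):
        t = C * np.sqrt((n - 2) / np.maximum(1.0 - C ** 2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    np.fill_diagonal(p, 1.0)
    iu = np.triu_indices(k, 1)
    r_pairs, p_pairs = C[iu], p[iu]
    keep = (r_pairs > 0) & (p_pairs < alpha)
    if keep.sum() == 0:
        mean = median = float("nan")
    else:
        mean = float(r_pairs[keep].mean())
        median = float(np.median(r_pairs[keep]))
    return {"corr": C, "pvals": p, "mean": mean, "median": median,
            "n_pairs": int(keep.sum())}


def _equalize_ta_subsets(session: SessionData, estimates: pd.DataFrame,
                         seed: int) -> dict[str, np.ndarray]:
    """Subsample trial types (seeded) to matching decoded-TA bin distributions."""
    table = session.trial_table
    merged = estimates.merge(table[["trial_id", "outcome"]], on="trial_id")
    pos = {tid: i for i, tid in enumerate(table["trial_id"])}
    merged["row"] = merged["trial_id"].map(pos)
    rng = np.random.default_rng(seed)
    bins = sorted(merged["ta_bin"].unique())
    out: dict[str, list[int]] = {t: [] for t in TRIAL_TYPES}
    for b in bins:
        sub = merged[merged["ta_bin"] == b]
        groups = {t: sub[sub["outcome"] == t]["row"].to_numpy()
                  for t in TRIAL_TYPES}
        k = min(len(g) for g in groups.values())
        if k == 0:
            continue
        for t, g in groups.items():
            out[t].extend(rng.choice(g, k, replace=False))
    return {t: np.sort(np.array(v, dtype=int)) for t, v in out.items()}


def noise_corr_by_outcome(session: SessionData,
                          epochs: tuple[str, ...] = ("pre_target", "pre_cue"),
                          equalize_ta: bool = False,
                          estimates: pd.DataFrame | None = None,
                          seed: int = 0,
                          n_resamples: int = 20,
                          window_ms: float = DEFAULT_WINDOW_MS,
                          remove_cue_means: bool = True,
                          ) -> list[NoiseCorrResult]:
    """Per-trial-type noise-correlation summaries for the requested epochs.

    The positive-significant pair filter is applied once per session and
    epoch, on the correlations over all trials: the retained channel pairs
    are then summarized within every trial-type subset. Re-selecting pairs
    inside each (small) subset would couple the filter's selection bias to
    the subset size and wash out between-type differences; fixing the pair
    set keeps the per-type summaries comparable estimands.

    With ``equalize_ta`` (requires decoded ``estimates``), trial types are
    subsampled so their decoded-TA bin distributions match before the
    correlations are computed; the summary is averaged over ``n_resamples``
    random subsamples to reduce subsampling noise. Types absent from the
    session are reported as missing (NaN). With ``remove_cue_means`` (default)
    per-cue-landmark condition means are subtracted within each trial subset,
    so cue-driven (signal) covariance does not masquerade as noise
    correlation.
    """
    table = session.trial_table
    outcome = table["outcome"].to_numpy()
    cue = table["cue_landmark"].to_numpy()
    if equalize_ta:
        if estimates is None:
            raise ValueError("equalize_ta requires decoded estimates")
        rng = np.random.default_rng(seed)
        subset_draws = [_equalize_ta_subsets(session, estimates,
                                             int(rng.integers(2 ** 31)))
                        for _ in range(max(1, n_resamples))]
    else:
        subset_draws = [{t: np.flatnonzero(outcome == t)
                         for t in TRIAL_TYPES}]

    results = []
    for epoch in epochs:
        z_all, kept = trial_responses(
            session, epoch, None, window_ms,
            groups=cue if remove_cue_means else None)
        summ_all = noise_correlation(z_all)
        iu = np.triu_indices(len(kept), 1)
        master = (summ_all["corr"][iu] > 0) & (summ_all["pvals"][iu] < 0.05)

        res = NoiseCorrResult(session_id=session.session_id, epoch=epoch,
                              window_ms=window_ms)
        for t in TRIAL_TYPES:
            means, medians, n_pairs = [], [], []
            for subsets in subset_draws:
                idx = subsets.get(t, np.array([], dtype=int))
                if len(idx) < 3:
                    continue
                z, kept_t = trial_responses(
                    session, epoch, idx, window_ms,
                    groups=cue[idx] if remove_cue_means else None)
                C_t = np.corrcoef(z.T)
                full = np.full((session.n_units, session.n_units), np.nan)
                full[np.ix_(kept_t, kept_t)] = C_t
                vals = full[np.ix_(kept, kept)][iu][master]
                if np.all(np.isnan(vals)):
                    continue
                means.append(float(np.nanmean(vals)))
                medians.append(float(np.nanmedian(vals)))
                n_pairs.append(int(np.isfinite(vals).sum()))
            if not means:
                res.mean_by_type[t] = float("nan")
                res.median_by_type[t] = float("nan")
                res.n_pairs_by_type[t] = 0
                warnings.warn(f"trial type '{t}' missing or too small",
                              stacklevel=2)
                continue
            res.mean_by_type[t] = float(np.nanmean(means))
            res.median_by_type[t] = float(np.nanmean(medians))
            res.n_pairs_by_type[t] = int(round(np.mean(n_pairs)))
        results.append(res)
    return results


def results_to_frame(results: list[NoiseCorrResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        for t in TRIAL_TYPES:
            rows.append({"session_id": r.session_id, "epoch": r.epoch,
                         "trial_type": t, "mean_nc": r.mean_by_type.get(t),
                         "median_nc": r.median_by_type.get(t),
                         "n_pairs": r.n_pairs_by_type.get(t)})
    return pd.DataFrame(rows)
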