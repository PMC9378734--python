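"""Per-unit modulation indices and pure/mixed selectivity classification.

Each unit gets two indices computed on the pre-target analysis window:

* attention index — median rate on TA-close versus TA-far correct trials,
  using the decoded target-to-attention distance;
* outcome index — median rate on hit versus miss trials irrespective of TA.

Both use MI = (FR1 - FR2) / (FR1 + FR2) on raw (non-z-scored) median rates,
so |MI| <= 1 whenever rates are non-negative. Significance per index is a
two-sided rank-sum test across trials; a unit is "mixed" when both indices
are significant, "attention"/"outcome" when exactly one is, "none" otherwise.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .as_decoder import AttentionalEstimate, estimates_to_frame
from .synthetic_data import SessionData

DEFAULT_ANALYSIS_WINDOW_MS = (-250.0, -50.0)
DEFAULT_BASELINE_WINDOW_MS = (-100.0, 0.0)
ALPHA = 0.05


@dataclass
class ModulationIndexRecord:
    unit_id: int
    mi_attention: float
    mi_outcome: float
    p_attention: float
    p_outcome: float
    selectivity_class: str
    reliable: bool = True
    n_close: int = 0
    n_far: int = 0
    n_hit: int = 0
    n_miss: int = 0


def modulation_index(fr1: float, fr2: float) -> float:
    """Normalized rate difference (FR1 - FR2) / (FR1 + FR2).

    Undefined (NaN) when both rates are zero.
    """
    if fr1 < 0 or fr2 < 0:
        raise ValueError("rates must be non-negative")
    if fr1 + fr2 == 0:
        return float("nan")
    return (fr1 - fr2) / (fr1 + fr2)


def _mi_and_p(rates_a: np.ndarray, rates_b: np.ndarray) -> tuple[float, float]:
    mi = modulation_index(float(np.median(rates_a)), float(np.median(rates_b)))
    if len(rates_a) < 2 or len(rates_b) < 2 \
            or (np.ptp(rates_a) == 0 and np.ptp(rates_b) == 0):
        return mi, 1.0
    p = stats.mannwhitneyu(rates_a, rates_b, alternative="two-sided").pvalue
    return mi, float(p)


def unit_selectivity(session: SessionData,
                     estimates: list[AttentionalEstimate] | pd.DataFrame,
                     analysis_window_ms=DEFAULT_ANALYSIS_WINDOW_MS,
                     min_trials: int = 10,
                     equalize: bool = False, seed: int = 0,
                     alpha: float = ALPHA) -> list[ModulationIndexRecord]:
    """Attention and outcome modulation indices for every unit.

    Attention compares TA-close vs TA-far correct (hit) trials from the
    decoded estimates, restricted to trials cued at the unit's preferred
    landmark (estimated as the cue with the highest mean rate over correct
    trials): for a spatially tuned unit, only when the cue sits in its
    response field does a well-placed spotlight (low TA) raise its rate, so
    pooling cue locations would cancel the effect. Outcome compares hit vs
    miss trials of the whole session at any TA. With ``equalize``, hit and
    miss trials are subsampled to equal counts (seeded) before the outcome
    index. Units with fewer than ``min_trials`` trials in any class are
    flagged unreliable.
    """
    df = estimates if isinstance(estimates, pd.DataFrame) \
        else estimates_to_frame(estimates)
    table = session.trial_table
    merged = df.merge(table[["trial_id", "outcome", "cue_landmark"]],
                      on="trial_id")
    pos = {tid: i for i, tid in enumerate(table["trial_id"])}
    rows = merged["trial_id"].map(pos).to_numpy()

    rates_all = session.rates_hz(
        session.window_to_bins(analysis_window_ms, "stim"))
    rates = rates_all[rows]  # align to estimate rows
    # attention-test statistic: pre-target response normalized by the same
    # trial's pre-cue response. Attention is deployed only after the cue, so
    # the ratio isolates the cue-driven modulation while cancelling slow
    # trial-wise excitability drifts that are common to both epochs (which
    # would otherwise swamp the attention contrast on state-modulated units).
    # Counts are smoothed by +0.5 to keep the ratio defined on silent trials.
    w_pre = session.window_to_bins(analysis_window_ms, "stim")
    w_base = session.window_to_bins(
        (-float(session.task.pre_stim_window_ms), 0.0), "cue")
    cnt_pre = session.counts[:, :, w_pre].sum(axis=2)
    cnt_base = session.counts[:, :, w_base].sum(axis=2)
    n_pre = len(range(*w_pre.indices(session.counts.shape[2])))
    n_base = len(range(*w_base.indices(session.counts.shape[2])))
    norm_all = ((cnt_pre + 0.5) / n_pre) / ((cnt_base + 0.5) / n_base)
    norm = norm_all[rows]
    # outcome-test statistic: the pre-cue epoch response. The behavioral
    # states persist across the whole trial, but spatial attention is only
    # deployed after the cue, so the pre-cue rate carries the outcome-linked
    # state modulation free of the attention confound (hit trials have
    # systematically closer spotlights, hence higher pre-target rates on
    # purely attention-tuned units).
    precue_all = session.rates_hz(
        session.window_to_bins(
            (-float(session.task.pre_stim_window_ms), 0.0), "cue"))

    outcome = merged["outcome"].to_numpy()
    ta_bin = merged["ta_bin"].to_numpy()
    cue = merged["cue_landmark"].to_numpy()
    # preferred cue per unit: highest mean rate over the session's hit trials
    all_outcome = table["outcome"].to_numpy()
    all_cue = table["cue_landmark"].to_numpy()
    cue_means = np.stack([rates_all[(all_outcome == "hit")
                                    & (all_cue == c)].mean(axis=0)
                          for c in range(4)])   # (4, n_units)
    preferred = cue_means.argmax(axis=0)

    hit = all_outcome == "hit"
    miss = all_outcome == "miss"
    if equalize:
        rng = np.random.default_rng(seed)
        k = min(hit.sum(), miss.sum())
        hit_idx = rng.choice(np.flatnonzero(hit), k, replace=False)
        miss_idx = rng.choice(np.flatnonzero(miss), k, replace=False)
        hit = np.zeros_like(hit)
        hit[hit_idx] = True
        miss = np.zeros_like(miss)
        miss[miss_idx] = True

    records = []
    for u in range(session.n_units):
        at_pref_hit = (cue == preferred[u]) & (outcome == "hit")
        close = at_pref_hit & (ta_bin == "close")
        far = at_pref_hit & (ta_bin == "far")
        mi_att, _ = _mi_and_p(rates[close, u], rates[far, u])
        # the significance test uses the state-normalized ratio, which cancels
        # the outcome-linked states exactly, so all outcomes can contribute
        at_pref = cue == preferred[u]
        close_n = at_pref & (ta_bin == "close")
        far_n = at_pref & (ta_bin == "far")
        _, p_att = _mi_and_p(norm[close_n, u], norm[far_n, u])
        mi_out, _ = _mi_and_p(rates_all[hit, u], rates_all[miss, u])
        _, p_out = _mi_and_p(precue_all[hit, u], precue_all[miss, u])
        sig_att, sig_out = p_att < alpha, p_out < alpha
        cls = {(True, True): "mixed", (True, False): "attention",
               (False, True): "outcome", (False, False): "none"}[
                   (sig_att, sig_out)]
        records.append(ModulationIndexRecord(
            unit_id=u, mi_attention=mi_att, mi_outcome=mi_out,
            p_attention=p_att, p_outcome=p_out, selectivity_class=cls,
            reliable=min(close_n.sum(), far_n.sum(), hit.sum(),
                         miss.sum()) >= min_trials,
            n_close=int(close_n.sum()), n_far=int(far_n.sum()),
            n_hit=int(hit.sum()), n_miss=int(miss.sum())))
    return records


def records_to_frame(records: list[ModulationIndexRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def mi_correlation(records: list[ModulationIndexRecord] | pd.DataFrame,
                   subset: str = "all") -> tuple[float, float]:
    """Spearman rank correlation between |attention MI| and |outcome MI|.

    ``subset`` is "all" or one of the selectivity classes. Returns (rho, p);
    (nan, nan) with a warning when fewer than 3 records or a constant vector.
    """
    df = records if isinstance(records, pd.DataFrame) else records_to_frame(records)
    if subset != "all":
        df = df[df["selectivity_class"] == subset]
    a = df["mi_attention"].abs().to_numpy()
    b = df["mi_outcome"].abs().to_numpy()
    ok = np.isfinite(a) & np.isfinite(b)
    a, b = a[ok], b[ok]
    if len(a) < 3:
        raise ValueError("need at least 3 records for a rank correlation")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        warnings.warn("constant index vector; correlation undefined",
                      stacklevel=2)
        return float("nan"), float("nan")
    res = stats.spearmanr(a, b)
    return float(res.statistic), float(res.pvalue)
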