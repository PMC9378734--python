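import dataclasses
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import attnstate as at
from attnstate.as_decoder import _gcv_lambda, LAMBDA_GRID
from attnstate.synthetic_data import (StateConfig, TaskConfig,
                                      sample_population, simulate_session)


# -- fit_regole -------------------------------------------------------------

def test_fit_regole_interpolation():
    rng = np.random.default_rng(0)
    R = rng.normal(size=(12, 5))  # full column rank after centering
    W0 = rng.normal(size=(2, 5))
    C = R @ W0.T
    w = at.fit_regole(R, C, lam=0.0)
    assert np.allclose(w.predict_code(R), C, atol=1e-8)
    assert np.allclose(w.W, W0, atol=1e-8)


def test_fit_regole_shrinkage_limit():
    rng = np.random.default_rng(1)
    R = rng.normal(size=(50, 6))
    R = (R - R.mean(axis=0)) / R.std(axis=0)
    C = np.sign(rng.normal(size=(50, 2)))
    w = at.fit_regole(R, C, lam=1e9)
    assert np.linalg.norm(w.W) < 1e-3


def test_fit_regole_normal_equation_oracle():
    rng = np.random.default_rng(2)
    R = rng.normal(size=(20, 5))
    C = np.sign(rng.normal(size=(20, 2)))
    lam = 0.7
    w = at.fit_regole(R, C, lam)
    # independent oracle: augmented least squares on centered data
    Rc = R - R.mean(axis=0)
    Cc = C - C.mean(axis=0)
    aug = np.vstack([Rc, np.sqrt(lam) * np.eye(5)])
    target = np.vstack([Cc, np.zeros((5, 2))])
    W_oracle = np.linalg.lstsq(aug, target, rcond=None)[0].T
    assert np.max(np.abs(w.W - W_oracle)) < 1e-8


def test_fit_regole_singular_lambda_zero():
    rng = np.random.default_rng(3)
    col = rng.normal(size=(20, 1))
    R = np.hstack([col, col, rng.normal(size=(20, 1))])  # collinear
    C = np.sign(rng.normal(size=(20, 2)))
    with pytest.raises(np.linalg.LinAlgError):
        at.fit_regole(R, C, lam=0.0)


def test_fit_regole_input_validation():
    R = np.zeros((4, 2))
    with pytest.raises(ValueError):
        at.fit_regole(R, np.ones((4, 1)), lam=1.0)  # single class
    with pytest.raises(ValueError):
        at.fit_regole(R, np.sign(np.random.default_rng(0).normal(size=(4, 1))),
                      lam=-1.0)


def test_gcv_lambda_in_grid():
    rng = np.random.default_rng(4)
    R = rng.normal(size=(60, 8))
    C = np.sign(rng.normal(size=(60, 2)))
    lam = _gcv_lambda(R, C)
    assert lam in LAMBDA_GRID
    assert LAMBDA_GRID == tuple(10.0 ** k for k in range(-3, 4))


# -- TA computation and binning --------------------------------------------

def test_compute_ta_examples():
    assert at.compute_ta((0, 0), (0, 0)) == 0.0
    assert at.compute_ta((3, 4), (0, 0)) == pytest.approx(5.0)
    assert at.compute_ta((10, 10), (14, 14)) == pytest.approx(5.6569, abs=1e-4)


def test_compute_ta_symmetry_and_triangle():
    rng = np.random.default_rng(5)
    for _ in range(20):
        a, b, c = rng.normal(scale=10, size=(3, 2))
        assert at.compute_ta(a, b) == pytest.approx(at.compute_ta(b, a))
        assert at.compute_ta(a, c) <= at.compute_ta(a, b) \
            + at.compute_ta(b, c) + 1e-12


def test_bin_ta_boundaries():
    assert at.bin_ta(0.1) == "close"
    assert at.bin_ta(6.0) == "close"
    assert at.bin_ta(6.0001) == "medium"
    assert at.bin_ta(12.0) == "medium"
    assert at.bin_ta(17.9) == "far"
    assert at.bin_ta(18.0) == "out_of_range"
    assert at.bin_ta(18.5) == "out_of_range"
    with pytest.raises(ValueError):
        at.bin_ta(-0.5)


# -- rolling decode ---------------------------------------------------------

def _force_outcomes(session, n_hits):
    """Copy of the session whose first ``n_hits`` trials are hits, rest miss."""
    table = session.trial_table.copy()
    out = np.array(["miss"] * len(table), dtype=object)
    out[:n_hits] = "hit"
    table["outcome"] = out
    return dataclasses.replace(session, trial_table=table)


def test_retraining_schedule_260_hits(bundle800):
    """260 correct trials -> 3 retrainings after the initial fit."""
    session = _force_outcomes(bundle800.session, 260)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est = at.rolling_decode(session, lam=1.0)
    # initial fit at hit 200, retrainings at hits 220, 240, 260
    assert at.rolling_decode.last_n_fits - 1 == 3
    assert len(est) == session.n_trials - 200  # decoded after the warm-up


def test_warmup_trials_excluded(bundle800, estimates800):
    table = bundle800.session.trial_table
    hits = np.flatnonzero((table["outcome"] == "hit").to_numpy())
    first_decoded_row = hits[199] + 1  # trial after the 200th correct trial
    decoded_ids = set(estimates800["trial_id"])
    assert int(table["trial_id"].iloc[first_decoded_row]) in decoded_ids
    for row in range(first_decoded_row):
        assert int(table["trial_id"].iloc[row]) not in decoded_ids


def test_too_few_hits_warns_and_returns_empty(bundle800):
    session = _force_outcomes(bundle800.session, 50)
    with pytest.warns(UserWarning):
        est = at.rolling_decode(session)
    assert est == []


def test_estimates_frame_columns(estimates800):
    assert list(estimates800.columns) == ["trial_id", "x_as", "y_as",
                                          "ta", "ta_bin"]
    assert (estimates800["ta"] >= 0).all()
    for ta, b in zip(estimates800["ta"], estimates800["ta_bin"]):
        assert b == at.bin_ta(ta)


def test_decoded_ta_tracks_true_ta(bundle800, estimates800):
    ses, states = bundle800.session, bundle800.states
    table = ses.trial_table
    pos = {tid: i for i, tid in enumerate(table["trial_id"])}
    rows = estimates800["trial_id"].map(pos).to_numpy()
    true_ta = np.linalg.norm(
        states.true_as_xy - table[["target_x", "target_y"]].to_numpy(),
        axis=1)[rows]
    rho = stats.spearmanr(estimates800["ta"], true_ta).statistic
    assert rho > 0.5


def test_noiseless_tuning_quadrant_agreement():
    """Noiseless planted tuning decodes the cued quadrant > 95%."""
    pop = sample_population(n_units=48, seed=0, tuning_gain_range=(8.0, 8.0),
                            w_s1_scale=0.0, w_s2_scale=0.0)
    sc = StateConfig(attention_jitter_sd=0.0, state_sd=(1e-6, 1e-6))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        session, _ = simulate_session(TaskConfig(), pop, sc, 700, seed=1)
        est = at.estimates_to_frame(at.rolling_decode(session))
    m = est.merge(session.trial_table[["trial_id", "cue_x", "cue_y"]],
                  on="trial_id")
    agree = ((np.sign(m["x_as"]) == np.sign(m["cue_x"]))
             & (np.sign(m["y_as"]) == np.sign(m["cue_y"]))).mean()
    assert agree > 0.95


def test_shuffled_labels_give_chance_quadrants(bundle800):
    """Training on permuted cue labels yields ~25% quadrant agreement."""
    session = bundle800.session
    table = session.trial_table
    R = session.rates_hz(session.window_to_bins((-220.0, 30.0), "stim"))
    rng = np.random.default_rng(0)
    cue = table[["cue_x", "cue_y"]].to_numpy()
    train = rng.choice(len(table), 200, replace=False)
    rest = np.setdiff1d(np.arange(len(table)), train)
    agreements = []
    for rep in range(10):  # 10 x 600 = 6000 test trials
        C_shuf = np.sign(cue[rng.permutation(train)])
        w = at.fit_regole(R[train], C_shuf, lam=1.0)
        pred = w.predict_code(R[rest])
        agreements.append(np.mean(
            (np.sign(pred[:, 0]) == np.sign(cue[rest, 0]))
            & (np.sign(pred[:, 1]) == np.sign(cue[rest, 1]))))
    assert abs(np.mean(agreements) - 0.25) < 0.05


def test_leakage_probe(bundle800):
    """Corrupting the last trial's responses leaves earlier estimates intact."""
    session = bundle800.session
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        base = at.estimates_to_frame(at.rolling_decode(session))
        counts = session.counts.copy()
        counts[-1] = 0  # corrupt only the final trial
        probe_session = dataclasses.replace(session, counts=counts)
        probe = at.estimates_to_frame(at.rolling_decode(probe_session))
    assert base.iloc[:-1].equals(probe.iloc[:-1])
    assert base.iloc[-1]["x_as"] != probe.iloc[-1]["x_as"]


# -- hit rate by TA ---------------------------------------------------------

def test_hit_rate_all_hits():
    est = pd.DataFrame({"trial_id": range(30), "x_as": 0.0, "y_as": 0.0,
                        "ta": np.linspace(1, 17, 30),
                        "ta_bin": [at.bin_ta(t)
                                   for t in np.linspace(1, 17, 30)]})
    table = pd.DataFrame({"trial_id": range(30), "outcome": "hit"})
    hr = at.hit_rate_by_ta(est, table)
    assert all(v == 1.0 for v in hr.values())


def test_hit_rate_equalize_balances_classes():
    rng = np.random.default_rng(6)
    n = 400
    ta = rng.uniform(0.5, 17.5, n)
    est = pd.DataFrame({"trial_id": range(n), "x_as": 0.0, "y_as": 0.0,
                        "ta": ta, "ta_bin": [at.bin_ta(t) for t in ta]})
    outcome = np.where(rng.random(n) < 0.8, "hit", "miss")
    table = pd.DataFrame({"trial_id": range(n), "outcome": outcome})
    hr = at.hit_rate_by_ta(est, table, equalize=True, seed=0)
    for v in hr.values():
        assert v == pytest.approx(0.5)  # equal counts by construction


def test_hit_rate_empty_bin_warns():
    est = pd.DataFrame({"trial_id": [0, 1], "x_as": 0.0, "y_as": 0.0,
                        "ta": [1.0, 2.0], "ta_bin": ["close", "close"]})
    table = pd.DataFrame({"trial_id": [0, 1], "outcome": ["hit", "miss"]})
    with pytest.warns(UserWarning):
        hr = at.hit_rate_by_ta(est, table)
    assert "medium" not in hr and "far" not in hr
    assert hr["close"] == pytest.approx(0.5)
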