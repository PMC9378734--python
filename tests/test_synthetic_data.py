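import warnings

import numpy as np
import pytest

import attnstate as at
from attnstate.synthetic_data import (TRIAL_COLUMNS, TaskConfig, StateConfig,
                                      sample_population, simulate_session)

TRIAL_COLUMNS_SPEC = ["trial_id", "cue_landmark", "cue_x", "cue_y",
                      "target_x", "target_y", "stim_onset_bin", "outcome"]


def test_trial_table_columns(bundle800):
    assert list(TRIAL_COLUMNS) == TRIAL_COLUMNS_SPEC
    for col in TRIAL_COLUMNS_SPEC:
        assert col in bundle800.session.trial_table.columns


def test_counts_are_nonnegative_integers(bundle800):
    counts = bundle800.session.counts
    assert np.issubdtype(counts.dtype, np.integer)
    assert counts.min() >= 0
    assert counts.shape == (800, 48, bundle800.session.task.n_bins)


def test_simulation_determinism():
    a = simulate_session(TaskConfig(), sample_population(seed=5),
                         StateConfig(), 120, seed=9)
    b = simulate_session(TaskConfig(), sample_population(seed=5),
                         StateConfig(), 120, seed=9)
    assert np.array_equal(a[0].counts, b[0].counts)
    assert a[0].trial_table.equals(b[0].trial_table)
    assert np.allclose(a[1].s1, b[1].s1)


def test_different_seeds_differ():
    a = simulate_session(TaskConfig(), sample_population(seed=5),
                         StateConfig(), 120, seed=9)
    b = simulate_session(TaskConfig(), sample_population(seed=5),
                         StateConfig(), 120, seed=10)
    assert not np.array_equal(a[0].counts, b[0].counts)


def test_save_load_roundtrip(tmp_path, bundle800):
    ses, states = bundle800.session, bundle800.states
    ses.save(tmp_path / "s0", latents=states)
    loaded = at.SessionData.load(tmp_path / "s0")
    assert np.array_equal(loaded.counts, ses.counts)
    assert loaded.trial_table["outcome"].equals(ses.trial_table["outcome"])
    lat = at.load_latent_states(tmp_path / "s0")
    assert np.allclose(lat.s1, states.s1)
    assert np.allclose(lat.true_as_xy, states.true_as_xy)


def test_load_missing_directory(tmp_path):
    with pytest.raises(FileNotFoundError):
        at.SessionData.load(tmp_path / "nope")


def test_task_config_validation():
    with pytest.raises(ValueError):
        TaskConfig(landmark_positions=np.zeros((4, 2)))  # not distinct
    with pytest.raises(ValueError):
        TaskConfig(cue_validity=0.8)  # task defined with 100% validity
    with pytest.raises(ValueError):
        TaskConfig(distractor_D_fraction=0.6, distractor_d_fraction=0.5)


def test_state_config_validation():
    with pytest.raises(ValueError):
        StateConfig(ar_coeff=(1.0, 0.5))
    with pytest.raises(ValueError):
        StateConfig(state_sd=(0.0, 1.0))
    with pytest.raises(ValueError):
        StateConfig(attention_jitter_sd=-1.0)


def test_default_landmarks_symmetric():
    task = TaskConfig()
    ecc = np.linalg.norm(task.landmark_positions, axis=1)
    assert np.allclose(ecc, ecc[0])
    assert len(np.unique(task.landmark_positions, axis=0)) == 4


def test_optimality_transform_properties():
    s1 = np.linspace(-3, 3, 101)
    o = at.optimality_transform(s1)
    assert o.argmax() == 50  # peak at s1 = 0
    assert np.allclose(o, o[::-1])  # symmetric
    assert np.all(np.diff(o[s1 >= 0]) <= 0)  # decreasing in |s1|


def test_population_roles_match_fractions():
    pop = sample_population(n_units=48, seed=2)
    counts = {r: int(np.sum(pop.roles == r))
              for r in ("attention", "outcome", "mixed", "none")}
    assert sum(counts.values()) == 48
    assert counts["mixed"] > counts["attention"]  # mixed-heavy default


def test_beta_ta_degrades_hits(bundle800):
    """Trials with the spotlight far from the target are missed more often."""
    ses, states = bundle800.session, bundle800.states
    t = ses.trial_table
    ta = np.linalg.norm(
        states.true_as_xy - t[["target_x", "target_y"]].to_numpy(), axis=1)
    hit = (t["outcome"] == "hit").to_numpy()
    close = ta <= np.median(ta)
    assert hit[close].mean() > hit[~close].mean()


def test_simulate_sessions_plants_mix_beta_sweep():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        bundles = at.simulate_sessions(6, 50, seed=0)
    mixes = np.array([b.population.overlap_mix for b in bundles])
    betas = np.array([b.state_config.beta_ta for b in bundles])
    # anti-parallel sweep: high overlap pairs with low TA sensitivity
    assert np.corrcoef(mixes, betas)[0, 1] < -0.99
    assert mixes.min() >= 0.02 and mixes.max() <= 0.98


def test_simulate_sessions_validation():
    with pytest.raises(ValueError):
        at.simulate_sessions(0, 100, seed=1)
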