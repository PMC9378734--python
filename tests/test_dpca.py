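import itertools
import warnings

import numpy as np
import pytest

import attnstate as at
from attnstate.dpca import (CONDITION_INDEPENDENT, GRID_FACTORS, INTERACTION,
                            LAMBDA_GRID, _robust_svd, collapse_factor,
                            decode_with_axis)


# -- condition tensors -------------------------------------------------------

def test_grid_factor_levels():
    assert GRID_FACTORS["ta_x_outcome"] == (
        ("ta_bin", ("close", "medium", "far")), ("outcome", ("hit", "miss")))
    assert GRID_FACTORS["trial_type"] == (
        ("trial_type", ("hit", "miss", "fa")),)


def test_tensor_shapes(joint_tensor, trial_type_tensor):
    assert joint_tensor.X.shape[1:3] == (3, 2)
    assert joint_tensor.n_units == 48
    assert trial_type_tensor.grid_shape == (3,)
    n, u, t = trial_type_tensor.single_trials.shape
    assert u == 48 and t == trial_type_tensor.n_timebins
    assert len(trial_type_tensor.trial_labels) == n


def test_ta_grid_requires_estimates(bundle800):
    with pytest.raises(ValueError):
        at.build_condition_tensor(bundle800.session, grid_spec="ta_x_outcome")
    with pytest.raises(ValueError):
        at.build_condition_tensor(bundle800.session, grid_spec="nonsense")


def test_empty_cell_raises(bundle800, estimates800):
    est = estimates800[estimates800["ta_bin"] != "far"]
    with pytest.raises(ValueError, match="empty"):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            at.build_condition_tensor(bundle800.session, estimates=est,
                                      grid_spec="ta_x_outcome")


def test_collapse_factor_equal_weight(joint_tensor):
    c = collapse_factor(joint_tensor, "ta_bin")
    assert c.factors == ("ta_bin",)
    assert np.allclose(c.X, joint_tensor.X.mean(axis=2))
    with pytest.raises(ValueError):
        collapse_factor(joint_tensor, "reward")


# -- marginalization ---------------------------------------------------------

def test_marginalize_sums_to_centered_exactly(joint_tensor):
    parts = at.marginalize(joint_tensor)
    X = joint_tensor.X
    Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
    assert set(parts) == {"ta_bin", "outcome", INTERACTION,
                          CONDITION_INDEPENDENT}
    total = sum(parts.values())
    assert np.array_equal(total, total)  # finite
    assert np.max(np.abs(sum(parts.values()) - Xc)) == 0.0 or \
        np.max(np.abs(sum(parts.values()) - Xc)) < 1e-12


def test_marginalize_matches_nested_loop_oracle():
    """Brute-force per-cell averaging reproduces marginalize() to 1e-12."""
    rng = np.random.default_rng(0)
    X = rng.normal(size=(4, 3, 2, 7))  # units x A x B x time
    parts = at.marginalize(X, factors=("a", "b"))
    Xc = X - X.mean(axis=(1, 2, 3), keepdims=True)
    n_u, n_a, n_b, n_t = X.shape
    oracle = {k: np.zeros_like(Xc) for k in
              ("a", "b", INTERACTION, CONDITION_INDEPENDENT)}
    for u in range(n_u):
        for t in range(n_t):
            m_t = np.mean([Xc[u, i, j, t] for i in range(n_a)
                           for j in range(n_b)])
            for i, j in itertools.product(range(n_a), range(n_b)):
                m_a = np.mean([Xc[u, i, jj, t] for jj in range(n_b)]) - m_t
                m_b = np.mean([Xc[u, ii, j, t] for ii in range(n_a)]) - m_t
                oracle[CONDITION_INDEPENDENT][u, i, j, t] = m_t
                oracle["a"][u, i, j, t] = m_a
                oracle["b"][u, i, j, t] = m_b
                oracle[INTERACTION][u, i, j, t] = \
                    Xc[u, i, j, t] - m_t - m_a - m_b
    for k in oracle:
        assert np.max(np.abs(parts[k] - oracle[k])) < 1e-12


def test_marginalize_one_factor():
    rng = np.random.default_rng(1)
    X = rng.normal(size=(5, 3, 9))
    parts = at.marginalize(X, factors=("ta",))
    Xc = X - X.mean(axis=(1, 2), keepdims=True)
    assert set(parts) == {"ta", CONDITION_INDEPENDENT}
    assert np.max(np.abs(parts["ta"] + parts[CONDITION_INDEPENDENT] - Xc)) \
        < 1e-14


def test_marginalize_rejects_three_factors():
    with pytest.raises(ValueError):
        at.marginalize(np.zeros((4, 2, 2, 2, 5)), factors=("a", "b", "c"))


# -- dPCA fit ----------------------------------------------------------------

@pytest.fixture(scope="module")
def joint_model(joint_tensor):
    return at.fit_dpca(joint_tensor, lam=1e-4)


def test_fit_is_deterministic(joint_tensor):
    a = at.fit_dpca(joint_tensor, lam=1e-4, n_components=3)
    b = at.fit_dpca(joint_tensor, lam=1e-4, n_components=3)
    for ca, cb in zip(a.components, b.components):
        assert np.array_equal(ca.encoder, cb.encoder)
        assert np.array_equal(ca.decoder, cb.decoder)
    # sign convention: largest-|element| of each decoder positive
    for c in a.components:
        assert c.decoder[np.argmax(np.abs(c.decoder))] > 0


def test_marginalization_variance_decomposition(joint_model, joint_tensor):
    mv = joint_model.marginalization_variance
    assert set(mv) == {"ta_bin", "outcome", INTERACTION,
                       CONDITION_INDEPENDENT}
    assert sum(mv.values()) == pytest.approx(joint_model.total_variance,
                                             rel=1e-10)


def test_encoder_decoder_near_biorthogonal(joint_model):
    c = joint_model.first("ta_bin")
    assert c.decoder @ c.encoder == pytest.approx(1.0, abs=0.05)


def test_remove_component_kills_its_projection(joint_model, joint_tensor):
    c = joint_model.first("ta_bin")
    before = float(np.abs(c.decoder @ joint_tensor.centered()).max())
    cleaned = at.remove_component_backproject(joint_model, joint_tensor.X,
                                              c.name)
    cf = cleaned.reshape(48, -1)
    after = float(np.abs(c.decoder @ (cf - cf.mean(axis=1, keepdims=True))).max())
    # residual is (1 - D.F) of the original projection; D.F ~ 1 for dPCA axes
    assert after < 0.05 * before
    # single-trial layout works too and preserves shape
    st = at.remove_component_backproject(joint_model,
                                         joint_tensor.single_trials, c.name)
    assert st.shape == joint_tensor.single_trials.shape
    with pytest.raises(KeyError):
        at.remove_component_backproject(joint_model, joint_tensor.X, "bogus_9")


def test_fit_validation(joint_tensor):
    with pytest.raises(ValueError):
        at.fit_dpca(joint_tensor, lam=-1.0)


# -- PCA baseline and variance curves ----------------------------------------

def test_pca_baseline_matches_eigendecomposition(joint_tensor):
    base = at.pca_baseline(joint_tensor, n_components=10)
    Xf = joint_tensor.centered()
    evals, evecs = np.linalg.eigh(Xf @ Xf.T)
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    cum_oracle = np.cumsum(evals)[:10] / evals.sum()
    assert np.max(np.abs(base["cumulative_variance"] - cum_oracle)) < 1e-10
    # leading subspaces coincide (up to sign)
    for k in range(3):
        dot = abs(base["components"][:, k] @ evecs[:, order[k]])
        assert dot == pytest.approx(1.0, abs=1e-8)


def test_dpca_cumulative_variance_below_pca(joint_model, joint_tensor):
    cum_dpca = at.cumulative_variance(joint_model, joint_tensor,
                                      n_components=20)
    cum_pca = at.pca_baseline(joint_tensor, n_components=20)[
        "cumulative_variance"]
    k = min(len(cum_dpca), len(cum_pca))
    assert np.all(cum_dpca[:k] <= cum_pca[:k] + 1e-10)
    assert (cum_pca[k - 1] - cum_dpca[k - 1]) * 100 < 5.0


def test_explained_variance_report(joint_model, joint_tensor):
    ev = at.explained_variance(joint_model, joint_tensor)
    shares = ev["marginalization_shares"]
    assert sum(shares.values()) == pytest.approx(1.0, rel=1e-9)
    assert all(v >= 0 for v in shares.values())
    assert all(0 <= v <= 1 + 1e-9 for v in ev["component_variance"].values())


# -- lambda selection ---------------------------------------------------------

def test_select_lambda_on_grid(trial_type_tensor):
    lam = at.select_lambda(trial_type_tensor, n_repeats=3, seed=0)
    assert lam in LAMBDA_GRID
    assert lam == at.select_lambda(trial_type_tensor, n_repeats=3, seed=0)


# -- axis decoding ------------------------------------------------------------

def test_theoretical_chance_values():
    assert at.theoretical_chance(3) == pytest.approx(100.0 / 3.0)
    assert at.theoretical_chance(2) == 50.0
    assert at.theoretical_chance(6) == pytest.approx(100.0 / 6.0)
    with pytest.raises(ValueError):
        at.theoretical_chance(0)


def test_decode_with_axis_beats_chance(joint_model, joint_tensor):
    res = decode_with_axis(joint_model, joint_tensor, "outcome_0",
                           n_cv=30, n_shuffles=49, seed=0)
    assert res.accuracy > at.theoretical_chance(2) / 100.0  # fraction vs pct
    assert res.accuracy > res.chance_threshold
    assert 0 < res.p_value <= 1.0
    assert res.p_value >= 1.0 / 50.0  # exact permutation lower bound


def test_decode_shuffled_labels_near_chance(joint_model, joint_tensor):
    """Decoding a label the axis cannot carry stays near shuffle chance."""
    rng = np.random.default_rng(0)
    tl = joint_tensor.trial_labels.copy()
    tl["outcome_idx"] = rng.permutation(tl["outcome_idx"].to_numpy())
    shuffled = at.ConditionTensor(
        X=joint_tensor.X, factors=joint_tensor.factors,
        levels=joint_tensor.levels, counts=joint_tensor.counts,
        single_trials=joint_tensor.single_trials, trial_labels=tl)
    res = decode_with_axis(joint_model, shuffled, "outcome_0",
                           n_cv=50, n_shuffles=99, seed=0)
    assert abs(res.accuracy - 0.5) < 0.1
    assert res.p_value > 0.05
    assert not res.significant


# -- axis overlap -------------------------------------------------------------

def test_axis_overlap_reference_angles():
    e1, e2 = np.eye(2)
    assert at.axis_overlap(e1, e2).angle_deg == pytest.approx(90.0)
    assert at.axis_overlap(e1, 3.0 * e1).angle_deg == pytest.approx(0.0)
    assert at.axis_overlap(e1, -e1).dot == pytest.approx(1.0)  # sign-invariant
    a = np.zeros(50)
    a[0] = 1.0
    b = np.zeros(50)
    b[0], b[1] = 0.22, np.sqrt(1 - 0.22 ** 2)
    ov = at.axis_overlap(a, b)
    assert ov.dot == pytest.approx(0.22)
    assert ov.angle_deg == pytest.approx(np.degrees(np.arccos(0.22)), abs=1e-6)
    assert ov.angle_deg == pytest.approx(77.29, abs=0.01)


def test_axis_overlap_null_calibration():
    # in 300 dimensions a 0.22 overlap clears the 97.5% random-vector null
    a = np.zeros(300)
    a[0] = 1.0
    b = np.zeros(300)
    b[0], b[1] = 0.22, np.sqrt(1 - 0.22 ** 2)
    ov = at.axis_overlap(a, b)
    assert 0 < ov.threshold < 0.22
    assert ov.non_orthogonal
    # in 10 dimensions the same 0.22 overlap stays within the null
    assert not at.axis_overlap(a[:10], b[:10] / np.linalg.norm(b[:10])
                               ).non_orthogonal
    with pytest.raises(ValueError):
        at.axis_overlap(np.zeros(5), np.ones(5))
    with pytest.raises(ValueError):
        at.axis_overlap(np.ones(4), np.ones(5))


# -- numerics -----------------------------------------------------------------

def test_robust_svd_matches_numpy():
    rng = np.random.default_rng(2)
    M = rng.normal(size=(12, 30))
    U, s, Vt = _robust_svd(M)
    U2, s2, Vt2 = np.linalg.svd(M, full_matrices=False)
    assert np.allclose(s, s2)
    assert np.allclose(np.abs(np.diag(U.T @ U2)), 1.0)
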