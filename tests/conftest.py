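"""Shared fixtures: one default simulated session with decoded estimates."""

import warnings

import pytest

import attnstate as at


@pytest.fixture(scope="session")
def bundle800():
    """One default 800-trial session (with ground truth)."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return at.simulate_sessions(1, 800, seed=3)[0]


@pytest.fixture(scope="session")
def estimates800(bundle800):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return at.estimates_to_frame(at.rolling_decode(bundle800.session))


@pytest.fixture(scope="session")
def trial_type_tensor(bundle800):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return at.build_condition_tensor(bundle800.session,
                                         grid_spec="trial_type")


@pytest.fixture(scope="session")
def joint_tensor(bundle800, estimates800):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return at.build_condition_tensor(bundle800.session,
                                         estimates=estimates800,
                                         grid_spec="ta_x_outcome", seed=0)


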