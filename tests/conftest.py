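"""Shared fixtures: published intensity sets and small simulated cohorts."""

import numpy as np
import pytest

from cormsm import (
    ModelSpec,
    PanelData,
    ProcessParams,
    REDistribution,
    SimConfig,
    Subject,
    generate_cohort,
)

# Fitted transition intensities (per year) for the kidney-function (eGFR)
# and proteinuria (PU) processes, as published for the lupus-nephritis
# cohort: the no-random-effect model and the shared inverse-frailty model.
EG_MARGINAL = {(1, 2): 0.051, (2, 1): 0.461, (2, 3): 0.112, (3, 2): 0.346}
PU_MARGINAL = {(1, 2): 0.272, (2, 1): 0.565, (2, 3): 0.158, (3, 2): 1.224}
EG_INVERSE = {(1, 2): 0.053, (2, 1): 0.496, (2, 3): 0.073, (3, 2): 0.453}
PU_INVERSE = {(1, 2): 0.468, (2, 1): 0.653, (2, 3): 0.127, (3, 2): 2.111}
THETA_INVERSE = 0.549


@pytest.fixture
def eg_marginal():
    return ProcessParams(baseline=dict(EG_MARGINAL))


@pytest.fixture
def pu_marginal():
    return ProcessParams(baseline=dict(PU_MARGINAL))


@pytest.fixture
def eg_inverse():
    return ProcessParams(baseline=dict(EG_INVERSE))


@pytest.fixture
def pu_inverse():
    return ProcessParams(baseline=dict(PU_INVERSE))


@pytest.fixture
def inverse_params(eg_inverse, pu_inverse):
    return [eg_inverse, pu_inverse]


@pytest.fixture
def spec_inverse():
    return ModelSpec.birth_death("inverse")


@pytest.fixture
def fixture_subject():
    """Three visits, both processes observed, with a worsening pattern."""
    return Subject(
        id="fx1",
        times=np.array([0.0, 1.1, 2.4]),
        states=(np.array([1, 2, 2]), np.array([2, 3, 2])),
    )


@pytest.fixture
def single_visit_subject():
    return Subject(id="sv", times=np.array([0.0]), states=(np.array([1]), np.array([2])))


@pytest.fixture(scope="session")
def small_inverse_panel():
    """20 subjects simulated from the inverse model, annual visits."""
    cfg = SimConfig(
        spec=ModelSpec.birth_death("inverse"),
        n_subjects=20,
        schedule="fixed",
        n_visits=6,
        gap=1.0,
        seed=7,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def informative_none_panel():
    """60 subjects from the no-frailty model with uniform initial states and
    moderate rates, so every transition intensity is well identified."""
    from cormsm import ProcessParams

    cfg = SimConfig(
        spec=ModelSpec.birth_death("none"),
        params=(
            ProcessParams(baseline={(1, 2): 0.3, (2, 1): 0.4, (2, 3): 0.25, (3, 2): 0.5}),
            ProcessParams(baseline={(1, 2): 0.35, (2, 1): 0.5, (2, 3): 0.2, (3, 2): 0.6}),
        ),
        n_subjects=60,
        schedule="fixed",
        n_visits=6,
        gap=1.0,
        initial_probs=((1 / 3, 1 / 3, 1 / 3), (1 / 3, 1 / 3, 1 / 3)),
        seed=23,
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def medium_inverse_panel_with_frailties():
    """120 subjects from the inverse model with the true frailties kept."""
    cfg = SimConfig(
        spec=ModelSpec.birth_death("inverse"),
        n_subjects=120,
        schedule="fixed",
        n_visits=8,
        gap=1.0,
        seed=11,
    )
    return generate_cohort(cfg, return_frailties=True)
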