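"""Conditional and frailty-integrated panel log-likelihoods."""

import numpy as np
import pytest

from cormsm import (
    ModelSpec,
    PanelData,
    PanelLikelihood,
    ProcessParams,
    QuadratureOptions,
    REDistribution,
    RELink,
    StateSpace,
    Subject,
    subject_conditional_loglik,
    subject_integrated_loglik,
    total_loglik,
)
from cormsm.likelihood import _process_conditional_loglik


def dense_grid_oracle(subject, spec, params, theta, moment=0, n=20_001, u_max=40.0):
    """Brute-force reference for the frailty integral: dense Simpson rule on
    a logarithmic grid over u in [1e-6, u_max] (du = u d log u), independent
    of the package's quadrature."""
    from scipy import stats
    from scipy.integrate import simpson

    x = np.linspace(np.log(1e-6), np.log(u_max), n)
    u = np.exp(x)
    ll = np.array([subject_conditional_loglik(subject, spec, params, float(v)) for v in u])
    a = 1.0 / theta
    f = stats.gamma.pdf(u, a, scale=1.0 / a)
    w = np.exp(ll - ll.max()) * f * u ** (moment + 1)
    return ll.max() + np.log(simpson(w, x=x))


@pytest.fixture
def two_state_setup():
    ss = StateSpace.birth_death(2)
    spec = ModelSpec(statespaces=(ss,), link=RELink("none"))
    params = [ProcessParams(baseline={(1, 2): 0.3, (2, 1): 0.7})]
    return spec, params


class TestConditional:
    def test_single_visit_contributes_zero(self, single_visit_subject, spec_inverse, inverse_params):
        assert subject_conditional_loglik(
            single_visit_subject, spec_inverse, inverse_params, u=1.7
        ) == 0.0

    def test_two_state_closed_form(self, two_state_setup):
        spec, params = two_state_setup
        subj = Subject(id="x", times=[0.0, 1.0], states=(np.array([1, 1]),))
        expected = np.log(0.7 + 0.3 * np.exp(-1.0))
        assert subject_conditional_loglik(subj, spec, params, 1.0) == pytest.approx(expected)

    def test_factorizes_over_processes(self, fixture_subject, spec_inverse, inverse_params):
        u = 1.9
        joint = subject_conditional_loglik(fixture_subject, spec_inverse, inverse_params, u)
        parts = sum(
            _process_conditional_loglik(fixture_subject, spec_inverse, inverse_params[j], j + 1, u)
            for j in range(2)
        )
        assert joint == pytest.approx(parts, rel=1e-12)

    def test_missing_state_bridges_interval(self, spec_inverse, inverse_params):
        # process 2 missing at the middle visit: its chain runs 0 -> 2.4 directly
        s = Subject(
            id="m", times=[0.0, 1.1, 2.4],
            states=(np.array([1, 2, 2]), np.array([2, 0, 2])),
        )
        full = Subject(id="f", times=[0.0, 2.4], states=(np.array([0, 0]), np.array([2, 2])))
        p2_only = _process_conditional_loglik(s, spec_inverse, inverse_params[1], 2, 1.3)
        p2_ref = _process_conditional_loglik(full, spec_inverse, inverse_params[1], 2, 1.3)
        assert p2_only == pytest.approx(p2_ref, rel=1e-12)


class TestIntegrated:
    def test_single_visit_is_zero_for_any_theta(self, single_visit_subject, spec_inverse, inverse_params):
        for theta in [1e-6, 0.5, 3.0]:
            val = subject_integrated_loglik(
                single_visit_subject, spec_inverse, inverse_params, REDistribution(theta)
            )
            assert val == pytest.approx(0.0, abs=1e-9)

    def test_degenerate_frailty_recovers_conditional(self, fixture_subject, spec_inverse, inverse_params):
        cond = subject_conditional_loglik(fixture_subject, spec_inverse, inverse_params, 1.0)
        integ = subject_integrated_loglik(
            fixture_subject, spec_inverse, inverse_params, REDistribution(1e-8)
        )
        assert abs(integ - cond) < 1e-4

    @pytest.mark.parametrize("method", ["adaptive", "fixed"])
    def test_matches_dense_grid_oracle(self, fixture_subject, spec_inverse, inverse_params, method):
        oracle = dense_grid_oracle(fixture_subject, spec_inverse, inverse_params, theta=0.5)
        val = subject_integrated_loglik(
            fixture_subject, spec_inverse, inverse_params, REDistribution(0.5),
            QuadratureOptions(method=method),
        )
        assert val == pytest.approx(oracle, rel=1e-6)

    def test_separate_variant_sums_per_process_integrals(self, fixture_subject, inverse_params):
        spec = ModelSpec.birth_death("separate")
        redist = REDistribution(theta=0.5, theta2=0.8)
        val = subject_integrated_loglik(fixture_subject, spec, inverse_params, redist)
        parts = 0.0
        for j, th in [(0, 0.5), (1, 0.8)]:
            spec1 = ModelSpec(
                statespaces=(spec.statespaces[j],), link=RELink("inverse"),
            )
            sub1 = Subject(
                id="s", times=fixture_subject.times,
                states=(fixture_subject.states[j],),
            )
            parts += subject_integrated_loglik(
                sub1, spec1, [inverse_params[j]], REDistribution(th)
            )
        assert val == pytest.approx(parts, rel=1e-9)

    def test_mixture_bound(self, fixture_subject, spec_inverse, inverse_params):
        integ = subject_integrated_loglik(
            fixture_subject, spec_inverse, inverse_params, REDistribution(0.7)
        )
        grid = np.geomspace(1e-3, 60, 4000)
        sup = max(
            subject_conditional_loglik(fixture_subject, spec_inverse, inverse_params, float(u))
            for u in grid
        )
        assert integ <= sup + 1e-9

    def test_fixed_rule_stable_under_doubling(self, spec_inverse, inverse_params):
        spec = ModelSpec.birth_death("simple")
        subj = Subject(id="s", times=[0.0, 1.0], states=(np.array([1, 2]), np.array([0, 0])))
        v1 = subject_integrated_loglik(
            subj, spec, inverse_params, REDistribution(0.5),
            QuadratureOptions(method="fixed", n_nodes=96),
        )
        v2 = subject_integrated_loglik(
            subj, spec, inverse_params, REDistribution(0.5),
            QuadratureOptions(method="fixed", n_nodes=192),
        )
        # stability is asserted on the likelihood (integral) scale
        assert abs(np.exp(v1) - np.exp(v2)) <= 1e-8

    def test_invalid_theta_rejected(self):
        with pytest.raises(ValueError):
            REDistribution(theta=-0.5)


class TestTotalLoglik:
    def test_panel_of_one_single_visit_subject(self, single_visit_subject, spec_inverse, inverse_params):
        panel = PanelData(subjects=[single_visit_subject])
        assert total_loglik(
            panel, spec_inverse, inverse_params, REDistribution(0.5)
        ) == pytest.approx(0.0, abs=1e-9)

    def test_no_frailty_model_separates_into_marginals(self, small_inverse_panel, inverse_params):
        spec = ModelSpec.birth_death("none")
        joint = total_loglik(small_inverse_panel, spec, inverse_params, None)
        parts = 0.0
        for j in range(2):
            spec1 = ModelSpec(statespaces=(spec.statespaces[j],), link=RELink("none"))
            subs = [
                Subject(id=s.id, times=s.times, states=(s.states[j],))
                for s in small_inverse_panel.subjects
            ]
            parts += total_loglik(PanelData(subjects=subs), spec1, [inverse_params[j]], None)
        assert joint == pytest.approx(parts, rel=1e-12)

    def test_matches_per_subject_oracle_sum(self, small_inverse_panel, spec_inverse, inverse_params):
        oracle = sum(
            dense_grid_oracle(s, spec_inverse, inverse_params, theta=0.5, n=4001)
            for s in small_inverse_panel.subjects
        )
        val = total_loglik(
            small_inverse_panel, spec_inverse, inverse_params, REDistribution(0.5)
        )
        assert val == pytest.approx(oracle, rel=1e-6)

    def test_invariant_to_subject_order_and_splitting(self, small_inverse_panel, spec_inverse, inverse_params):
        redist = REDistribution(0.5)
        base = total_loglik(small_inverse_panel, spec_inverse, inverse_params, redist)
        shuffled = PanelData(subjects=list(reversed(small_inverse_panel.subjects)))
        assert total_loglik(shuffled, spec_inverse, inverse_params, redist) == pytest.approx(
            base, abs=1e-9
        )
        half = len(small_inverse_panel.subjects) // 2
        a = PanelData(subjects=small_inverse_panel.subjects[:half])
        b = PanelData(subjects=small_inverse_panel.subjects[half:])
        split_sum = total_loglik(a, spec_inverse, inverse_params, redist) + total_loglik(
            b, spec_inverse, inverse_params, redist
        )
        assert split_sum == pytest.approx(base, abs=1e-9)


class TestPanelLikelihoodFastPath:
    @pytest.mark.parametrize("variant", ["none", "simple", "inverse", "separate"])
    def test_agrees_with_per_subject_path(self, small_inverse_panel, inverse_params, variant):
        spec = ModelSpec.birth_death(variant)
        redist = REDistribution(theta=0.5, theta2=0.8) if variant != "none" else None
        pl = PanelLikelihood(small_inverse_panel, spec, n_nodes=96)
        fast = pl.total_loglik(inverse_params, redist)
        slow = total_loglik(
            small_inverse_panel, spec, inverse_params, redist,
            QuadratureOptions(method="fixed", n_nodes=96),
        )
        assert fast == pytest.approx(slow, rel=1e-10)
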