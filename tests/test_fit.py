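"""Maximum-likelihood fitting, information criteria and Wald intervals."""

import numpy as np
import pytest

from cormsm import (
    FittedModel,
    ModelSpec,
    PanelData,
    ProcessParams,
    REDistribution,
    RELink,
    Subject,
    aic,
    crude_init,
    fit_mle,
    lr_test,
    total_loglik,
    wald_confint,
)
from cormsm.fit import ParamLayout


class TestAic:
    @pytest.mark.parametrize(
        "loglik,k,expected",
        [(-2448.96, 8, 4913.92), (-2367.93, 9, 4753.86), (-2367.46, 10, 4754.92), (0.0, 0, 0.0)],
    )
    def test_definition(self, loglik, k, expected):
        assert aic(loglik, k) == pytest.approx(expected)

    def test_negative_k_rejected(self):
        with pytest.raises(ValueError):
            aic(0.0, -1)


def _dummy_fit(variant, loglik, k):
    spec = ModelSpec.birth_death(variant)
    return FittedModel(
        spec=spec, layout=ParamLayout(spec), x=np.zeros(k), cov=None,
        loglik=loglik, k=k, n_subjects=10,
    )


class TestLRTest:
    def test_statistic_definition(self):
        stat, df, p = lr_test(_dummy_fit("none", -101.05, 8), _dummy_fit("inverse", -100.0, 9))
        assert stat == pytest.approx(2.10)
        assert df == 1
        assert 0 < p < 1

    def test_identical_fits_give_zero_statistic(self):
        a = _dummy_fit("inverse", -50.0, 9)
        b = _dummy_fit("inverse", -50.0, 9)
        stat, df, p = lr_test(a, b)
        assert stat == 0.0 and p == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            lr_test(_dummy_fit("none", -10.0, 8), _dummy_fit("inverse", -11.0, 9))


class TestWaldConfint:
    def test_zero_estimate_zero_se_maps_to_unit_interval(self):
        spec = ModelSpec.birth_death("inverse")
        layout = ParamLayout(spec)
        fit = FittedModel(
            spec=spec, layout=layout, x=np.zeros(layout.n_params),
            cov=np.zeros((layout.n_params, layout.n_params)),
            loglik=0.0, k=9, n_subjects=5,
        )
        tab = wald_confint(fit)
        row = tab.loc["p1.q12"]
        assert (row["estimate"], row["lower"], row["upper"]) == (1.0, 1.0, 1.0)

    def test_exponentiation_preserves_ordering(self):
        spec = ModelSpec.birth_death("inverse")
        layout = ParamLayout(spec)
        rng = np.random.default_rng(3)
        x = rng.normal(size=layout.n_params)
        cov = np.diag(rng.uniform(0.01, 0.2, layout.n_params))
        fit = FittedModel(spec=spec, layout=layout, x=x, cov=cov,
                          loglik=0.0, k=9, n_subjects=5)
        tab = wald_confint(fit)
        assert (tab["lower"] < tab["estimate"]).all()
        assert (tab["estimate"] < tab["upper"]).all()

    def test_missing_covariance_rejected(self):
        fit = _dummy_fit("inverse", -1.0, 9)
        with pytest.raises(ValueError):
            wald_confint(fit)


class TestParamLayout:
    @pytest.mark.parametrize("variant,n", [("none", 8), ("inverse", 9), ("separate", 10),
                                           ("power_inverse", 10)])
    def test_layout_size_matches_free_parameter_count(self, variant, n):
        assert ParamLayout(ModelSpec.birth_death(variant)).n_params == n

    def test_pack_unpack_roundtrip(self, inverse_params):
        spec = ModelSpec.birth_death("inverse")
        layout = ParamLayout(spec)
        x = layout.pack(inverse_params, REDistribution(0.549))
        params, redist = layout.unpack(x)
        for j in range(2):
            for t, v in inverse_params[j].baseline.items():
                assert params[j].baseline[t] == pytest.approx(v, rel=1e-12)
        assert redist.theta == pytest.approx(0.549, rel=1e-12)


class TestCrudeInit:
    def test_rates_floored_and_positive(self, small_inverse_panel):
        spec = ModelSpec.birth_death("inverse")
        init = crude_init(small_inverse_panel, spec)
        for p in init:
            for v in p.baseline.values():
                assert v >= 0.01

    def test_unobserved_transition_gets_floor(self):
        # both subjects stay put: every crude rate collapses to the floor
        subs = [
            Subject(id=f"s{i}", times=[0.0, 1.0, 2.0],
                    states=(np.array([1, 1, 1]), np.array([2, 2, 2])))
            for i in range(2)
        ]
        init = crude_init(PanelData(subjects=subs), ModelSpec.birth_death("none"))
        assert all(v == 0.01 for p in init for v in p.baseline.values())


class TestFitMLE:
    def test_needs_two_informative_subjects(self, single_visit_subject):
        panel = PanelData(subjects=[single_visit_subject])
        with pytest.raises(ValueError):
            fit_mle(panel, ModelSpec.birth_death("inverse"))

    def test_no_frailty_fit_matches_per_process_fits(self, informative_none_panel):
        spec = ModelSpec.birth_death("none")
        joint = fit_mle(informative_none_panel, spec, compute_hessian=False, gtol=1e-7)
        est = joint.estimates
        for j in range(2):
            spec1 = ModelSpec(
                statespaces=(spec.statespaces[j],), link=RELink("none"),
                process_names=(f"p{j + 1}",),
            )
            subs = [
                Subject(id=s.id, times=s.times, states=(s.states[j],))
                for s in informative_none_panel.subjects
            ]
            alone = fit_mle(PanelData(subjects=subs), spec1,
                            compute_hessian=False, gtol=1e-7)
            for name, val in alone.estimates.items():
                assert est[name] == pytest.approx(val, abs=1e-4)

    def test_frailty_model_fits_no_worse_than_marginal(self, small_inverse_panel):
        none_fit = fit_mle(small_inverse_panel, ModelSpec.birth_death("none"),
                           compute_hessian=False)
        inv_fit = fit_mle(small_inverse_panel, ModelSpec.birth_death("inverse"),
                          compute_hessian=False)
        assert inv_fit.loglik >= none_fit.loglik - 1e-6

    def test_refit_from_optimum_is_stable(self, informative_none_panel):
        spec = ModelSpec.birth_death("none")
        first = fit_mle(informative_none_panel, spec, compute_hessian=False)
        again = fit_mle(informative_none_panel, spec, init=first.x, compute_hessian=False)
        assert abs(again.loglik - first.loglik) <= 1e-6

    def test_fit_reaches_a_stationary_point(self, small_inverse_panel):
        fit = fit_mle(small_inverse_panel, ModelSpec.birth_death("none"),
                      compute_hessian=False)
        assert fit.converged
        assert fit.grad_norm < 1e-3

    def test_loglik_agrees_with_adaptive_total(self, small_inverse_panel):
        fit = fit_mle(small_inverse_panel, ModelSpec.birth_death("inverse"),
                      compute_hessian=False)
        recomputed = total_loglik(small_inverse_panel, fit.spec, fit.params, fit.redist)
        assert recomputed == pytest.approx(fit.loglik, abs=1e-4)

    def test_serialization_roundtrip(self, small_inverse_panel, tmp_path):
        import json

        fit = fit_mle(small_inverse_panel, ModelSpec.birth_death("none"),
                      compute_hessian=False)
        path = tmp_path / "fit.json"
        fit.to_json(path)
        with open(path) as fh:
            d = json.load(fh)
        assert d["aic"] == pytest.approx(fit.aic)
        assert np.allclose(d["working"]["x"], fit.x)
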