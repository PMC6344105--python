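import math

import numpy as np
import pytest

from prefdrift import (
    BiasParameters,
    CompiledSubject,
    ModelSpec,
    ResponseParameters,
    build_regressors,
    compute_bias,
    enumerate_model_space,
    model_loglik,
    predict_actions,
    predict_ratings,
    simulate_subject,
)
from prefdrift.models import SCALAR_ORDER, loglik_hess, loglik_terms
from conftest import make_dataset, small_config, toy_trial

RESP = ResponseParameters(
    rho_c=0.1, eta_c=-3.0, c0=2.0, rho_s=0.05, eta_s=-5.0, s0=4.0,
    rho_f=0.002, eta_f=0.8, f0=0.2, sigma_f=0.1, sigma_r=6.0,
)


class TestModelSpace:
    @pytest.mark.parametrize(
        "request_,expected",
        [(("H0",), 2), (("H0", "H1"), 16), (("H0", "H1", "H2", "H3"), 44), (("H1",), 14)],
    )
    def test_enumeration_counts(self, request_, expected):
        assert len(enumerate_model_space(request_)) == expected

    def test_null_models_share_partition(self):
        space = enumerate_model_space(("H0", "H1", "H2", "H3"))
        nulls = [m for m in space if m.family == "H0"]
        assert len(nulls) == 2
        assert {m.active_biases for m in nulls} == {(), ("time",)}

    def test_spec_invariants(self):
        with pytest.raises(ValueError):
            ModelSpec("H0", choice=True)
        with pytest.raises(ValueError):
            ModelSpec("H2")
        with pytest.raises(ValueError):
            enumerate_model_space(("H0", "H3"), scope="ratings_only")

    def test_spec_json_roundtrip(self):
        spec = ModelSpec("H3", choice=True, time=True)
        assert ModelSpec.from_dict(spec.to_dict()) == spec


class TestBias:
    def test_weighted_sum_and_structural_zero(self, small_cohort):
        ds = small_cohort[0]
        reg = build_regressors(ds, "signed")
        zero = compute_bias(reg, BiasParameters())
        assert (zero["bias"] == 0).all()
        # earned trial with the recovered-regime weights: 1.8 + 0.7 - 0.3
        bias = compute_bias(reg, BiasParameters(choice=1.8, success=0.7, time=-0.3))
        t = reg.table
        earned_f0 = (t["S"] == 1) & (t["F"] == 0)
        assert np.allclose(bias.loc[earned_f0, "bias"], 2.2)
        # excluded items never appear, hence carry no bias
        assert not set(ds.excluded_items) & set(bias["item_id"])

    def test_rejects_zscored_scheme(self, small_cohort):
        reg = build_regressors(small_cohort[0], "zscored")
        with pytest.raises(ValueError, match="signed"):
            compute_bias(reg, BiasParameters())


class TestRatingLikelihood:
    def test_zero_residual_density(self):
        items = ["A", "B", "C", "D"]
        v = {it: 40.0 + i for i, it in enumerate(items)}
        ratings = [
            {"item_id": it, "session": s, "rating": v[it], "excluded": 1}
            for it in items
            for s in (1, 2, 3)
        ]
        ds = make_dataset(ratings=ratings)
        sigma = 3.0
        ll = predict_ratings(ds, ModelSpec("H0"), v, BiasParameters(), sigma)
        assert ll == pytest.approx(3 * 4 * math.log(1.0 / (sigma * math.sqrt(2 * math.pi))))

    def test_time_only_cumulates_under_h2(self):
        from conftest import small_config
        from prefdrift.synthetic import DEFAULT_RESPONSE
        import dataclasses

        cfg = small_config(
            model=ModelSpec("H0", time=True, structure="H2"),
            bias=BiasParameters(time=-2.0),
            resp=dataclasses.replace(DEFAULT_RESPONSE, sigma_r=1e-9),
        )
        ds = simulate_subject(cfg, seed=5)
        _, R = ds.rating_matrix()
        items, _ = ds.rating_matrix()
        pres = [i for i, it in enumerate(items) if it in set(ds.presented_items)]
        exc = [i for i, it in enumerate(items) if it not in set(ds.presented_items)]
        assert np.allclose(R[pres, 2] - R[pres, 0], -4.0, atol=1e-6)
        assert np.allclose(R[exc, 2] - R[exc, 0], 0.0, atol=1e-6)

    def test_h2_h3_rating_equivalence(self, small_cohort):
        """The cumulative rating-bias model and the value-update model make
        identical rating predictions; they differ only through actions."""
        ds = small_cohort[0]
        cs = CompiledSubject(ds)
        rng = np.random.default_rng(2)
        v = rng.normal(50, 15, cs.M)
        bias = BiasParameters(1.2, 0.4, 0.1, -0.2)
        h2 = ModelSpec("H2", choice=True, success=True, force=True, time=True)
        h3 = ModelSpec("H3", choice=True, success=True, force=True, time=True)
        assert predict_ratings(cs, h2, v, bias, 6.0) == pytest.approx(
            predict_ratings(cs, h3, v, bias, 6.0), abs=1e-10
        )
        assert predict_actions(cs, h2, v, bias, RESP) != pytest.approx(
            predict_actions(cs, h3, v, bias, RESP), abs=1e-6
        )

    def test_extended_additivity_and_h3_scope_error(self, small_cohort):
        ds = small_cohort[0]
        cs = CompiledSubject(ds)
        v = np.full(cs.M, 50.0)
        bias = BiasParameters(1.0, 0.5, 0.0, -0.3)
        spec = ModelSpec("H3", choice=True, success=True, time=True)
        total = model_loglik(cs, spec, v, bias, resp=RESP, scope="extended")
        parts = predict_ratings(cs, spec, v, bias, RESP.sigma_r) + predict_actions(
            cs, spec, v, bias, RESP
        )
        assert total == pytest.approx(parts, abs=1e-8)
        with pytest.raises(ValueError, match="extended"):
            model_loglik(cs, spec, v, bias, resp=RESP, scope="ratings_only")


class TestActionLikelihood:
    def _one_trial_ds(self, L):
        ratings = [
            {"item_id": "A", "session": s, "rating": 0.0, "excluded": 0} for s in (1, 2, 3)
        ]
        trials = [
            toy_trial("A", 1, L, accepted=False),
            toy_trial("A", 2, L, accepted=False),
        ]
        return make_dataset(ratings=ratings, trials=trials)

    @pytest.mark.parametrize(
        "rho,eta,v,L,p_accept",
        [(1.0, -2.0, 1.0, 0.5, 0.5), (1.0, -1.0, 2.0, 1.0, 0.7310585786300049)],
    )
    def test_choice_probability(self, rho, eta, v, L, p_accept):
        ds = self._one_trial_ds(L)
        resp = ResponseParameters(
            rho_c=rho, eta_c=eta, c0=0.0, sigma_f=0.1, sigma_r=1.0
        )
        ll = predict_actions(ds, ModelSpec("H0"), {"A": v}, BiasParameters(), resp)
        # two declined trials at the same probability
        assert ll == pytest.approx(2 * math.log(1.0 - p_accept), rel=1e-9)

    def test_densities_finite_for_finite_parameters(self, small_cohort):
        cs = CompiledSubject(small_cohort[0])
        v = np.full(cs.M, 95.0)
        resp = ResponseParameters(
            rho_c=3.0, eta_c=8.0, c0=-5.0, rho_s=2.0, eta_s=7.0, s0=-4.0,
            rho_f=0.5, eta_f=2.0, f0=1.0, sigma_f=0.01, sigma_r=0.5,
        )
        spec = ModelSpec("H3", choice=True, success=True, force=True, time=True)
        ll = model_loglik(cs, spec, v, BiasParameters(9, 9, 9, 9), resp=resp)
        assert np.isfinite(ll)


class TestDerivatives:
    def test_gradient_matches_finite_differences(self, small_cohort):
        cs = CompiledSubject(small_cohort[1])
        rng = np.random.default_rng(7)
        v = rng.normal(50, 10, cs.M)
        bias = BiasParameters(0.8, 0.3, 0.1, -0.2)
        spec = ModelSpec("H3", choice=True, success=True, force=True, time=True)
        ll, grads = loglik_terms(cs, spec, v, bias, RESP, 6.0, "extended", want_grad=True)
        h = 1e-5
        for i in (0, cs.M // 2):
            vp, vm = v.copy(), v.copy()
            vp[i] += h
            vm[i] -= h
            fp, _ = loglik_terms(cs, spec, vp, bias, RESP, 6.0, "extended")
            fm, _ = loglik_terms(cs, spec, vm, bias, RESP, 6.0, "extended")
            fd = (fp - fm) / (2 * h)
            assert grads["v"][i] == pytest.approx(fd, rel=1e-5, abs=1e-7)

    def test_hessian_matches_gradient_differences(self, small_cohort):
        cs = CompiledSubject(small_cohort[1])
        rng = np.random.default_rng(8)
        v = rng.normal(50, 10, cs.M)
        bias = BiasParameters(0.8, 0.3, 0.1, -0.2)
        spec = ModelSpec("H3", choice=True, success=True, force=True, time=True)
        ll, g, H = loglik_hess(cs, spec, v, bias, RESP, 6.0, "extended")
        x0 = np.concatenate(
            [v, bias.as_array(), [math.log(6.0)],
             [getattr(RESP, n) for n in SCALAR_ORDER[5:14]], [math.log(RESP.sigma_f)]]
        )

        def grad_at(x):
            vv = x[: cs.M]
            bb = BiasParameters(*x[cs.M : cs.M + 4])
            rr = ResponseParameters(
                **dict(zip(SCALAR_ORDER[5:14], x[cs.M + 5 : cs.M + 14])),
                sigma_f=math.exp(x[cs.M + 14]),
                sigma_r=math.exp(x[cs.M + 4]),
            )
            _, gg, _ = loglik_hess(cs, spec, vv, bb, rr, rr.sigma_r, "extended")
            return gg

        for j in (cs.M, cs.M + 4, cs.M + 5, cs.M + 14, 3):
            h = 1e-5 * (1 + abs(x0[j]))
            xp, xm = x0.copy(), x0.copy()
            xp[j] += h
            xm[j] -= h
            fd = (grad_at(xp) - grad_at(xm)) / (2 * h)
            assert np.allclose(H[:, j], fd, rtol=5e-4, atol=5e-5)
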