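import numpy as np
import pytest

from prefdrift import (
    BiasParameters,
    ModelSpec,
    balanced_accuracy,
    excluded_item_contrast,
    fit_action_regressions,
    fit_delta_rating_regression,
    group_ttest,
    simulate_cohort,
)
from prefdrift.model_free import DegenerateDataError, irls_logistic, ols
from conftest import small_config


class TestEstimators:
    def test_ols_matches_normal_equations(self):
        rng = np.random.default_rng(0)
        X = np.column_stack([rng.normal(size=(200, 3)), np.ones(200)])
        y = rng.normal(size=200)
        beta, r2 = ols(X, y)
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        assert np.allclose(beta, ref, rtol=1e-10)
        assert r2 <= 1

    def test_irls_reaches_local_optimum(self):
        rng = np.random.default_rng(1)
        X = np.column_stack([rng.normal(size=(300, 2)), np.ones(300)])
        true = np.array([1.0, -2.0, 0.3])
        y = (rng.random(300) < 1 / (1 + np.exp(-X @ true))).astype(float)
        beta, ok = irls_logistic(X, y)
        assert ok

        def ll(b):
            z = X @ b
            return float(y @ z - np.logaddexp(0, z).sum())

        best = ll(beta)
        for _ in range(100):
            assert best >= ll(beta + 0.1 * rng.standard_normal(3)) - 1e-9

    @pytest.mark.parametrize(
        "prob,y,expected",
        [
            ([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0], 1.0),
            ([0.9, 0.8, 0.6, 0.1, 0.7, 0.2], [1, 1, 1, 1, 0, 0], (0.75 + 0.5) / 2),
        ],
    )
    def test_balanced_accuracy(self, prob, y, expected):
        assert balanced_accuracy(np.array(prob), np.array(y)) == pytest.approx(expected)

    def test_balanced_accuracy_chance_and_errors(self):
        rng = np.random.default_rng(3)
        y = np.repeat([0, 1], 50)
        # probabilities never cross the threshold -> all predicted negative is
        # degenerate; use near-chance probabilities instead
        prob = np.full(100, 0.5) + rng.normal(0, 1e-6, 100)
        assert balanced_accuracy(prob, y) == pytest.approx(0.5, abs=0.15)
        with pytest.raises(DegenerateDataError):
            balanced_accuracy(np.array([0.4, 0.6]), np.array([1, 1]))


class TestGroupTests:
    def test_one_sample_closed_form(self):
        res = group_ttest([1.0, 2.0, 3.0])
        assert res.t == pytest.approx(3.4641016, rel=1e-6)
        assert res.p == pytest.approx(0.0741799, rel=1e-4)

    def test_identical_samples_welch(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        res = group_ttest(a, mode="welch_two_sample", other=a.copy())
        assert res.t == 0.0 and res.p == 1.0

    def test_welch_calibration_under_unequal_variance(self):
        rng = np.random.default_rng(4)
        ps = []
        for _ in range(2000):
            a = rng.normal(0, 1, 12)
            b = rng.normal(0, 4, 30)
            ps.append(group_ttest(a, mode="welch_two_sample", other=b).p)
        assert np.mean(np.asarray(ps) < 0.05) == pytest.approx(0.05, abs=0.02)

    def test_rejects_single_observation(self):
        with pytest.raises(DegenerateDataError):
            group_ttest([1.0])


class TestSubjectRegressions:
    def test_action_regressions_recover_signs(self, small_cohort):
        res = fit_action_regressions(small_cohort[0])
        assert res["choice"].coefficients["R"] > 0
        assert res["choice"].coefficients["L"] < 0
        assert res["force"].coefficients["L"] > 0  # imposed by instructions
        assert 0.5 <= res["choice"].fit_quality <= 1.0
        assert res["force"].fit_quality > 0.5

    def test_delta_regression_matches_independent_solver(self, small_cohort):
        """The packaged estimator equals an independently coded z-score +
        least-squares oracle."""
        from prefdrift import build_regressors

        ds = small_cohort[1]
        res = fit_delta_rating_regression(ds)

        items, R = ds.rating_matrix()
        idx = {it: i for i, it in enumerate(items)}
        Z = (R - R.mean()) / R.std()
        reg = build_regressors(ds, "zscored").table
        y = np.array(
            [Z[idx[r.item_id], int(r.session)] - Z[idx[r.item_id], int(r.session) - 1]
             for r in reg.itertuples()]
        )
        X = np.column_stack([reg["C"], reg["S"], reg["F"], np.ones(len(reg))])
        ref = np.linalg.solve(X.T @ X, X.T @ y)
        got = [res.coefficients[k] for k in ("C", "S", "F", "T")]
        assert np.allclose(got, ref, atol=1e-10)

    def test_delta_regression_all_zero_predictors(self):
        """With every offer declined, C/S/F are degenerate (all-zero) and the
        intercept equals the mean delta-rating."""
        from conftest import make_dataset, toy_trial

        items = [f"I{i}" for i in range(6)]
        rng = np.random.default_rng(9)
        ratings = [
            {"item_id": it, "session": s, "rating": float(rng.normal(50, 5)), "excluded": 0}
            for it in items
            for s in (1, 2, 3)
        ]
        trials = [
            toy_trial(it, k, 0.9, accepted=False, idx=i)
            for k in (1, 2)
            for i, it in enumerate(items)
        ]
        ds = make_dataset(ratings=ratings, trials=trials)
        res = fit_delta_rating_regression(ds)
        _, R = ds.rating_matrix()
        Z = (R - R.mean()) / R.std()
        deltas = np.concatenate([Z[:, 1] - Z[:, 0], Z[:, 2] - Z[:, 1]])
        assert res.coefficients["C"] == 0.0
        assert res.coefficients["T"] == pytest.approx(deltas.mean(), abs=1e-10)


class TestExcludedItems:
    def test_ordering_under_choice_bias(self):
        cfg = small_config(
            n_subjects=10,
            model=ModelSpec("H3", choice=True),
            bias=BiasParameters(choice=6.0),
        )
        cohort = simulate_cohort(cfg, seed=17)
        res = excluded_item_contrast(cohort)
        assert res["chosen_mean"].mean > res["excluded_mean"].mean > res["unchosen_mean"].mean
        assert res["chosen_vs_excluded"].p < 0.05
        assert res["unchosen_vs_excluded"].p < 0.05

    def test_errors(self, small_cohort):
        with pytest.raises(DegenerateDataError):
            excluded_item_contrast(small_cohort[:1])
        cfg = small_config(n_random_excluded=0, n_items=32)
        cohort = simulate_cohort(cfg, seed=2)
        with pytest.raises(DegenerateDataError):
            excluded_item_contrast(cohort)
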