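import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from survtopic.io_preprocess import SurvivalLabels
from survtopic.survival_models import (
    ConvergenceError,
    build_time_grid,
    cox_partial_loglik,
    cox_survival_curve,
    fit_cox,
)
from survtopic.survival_models import _risk_set_stats
from tests.conftest import make_survival_labels


def brute_force_partial_loglik(W, X, time, event):
    """Materializes every risk set explicitly (independent oracle)."""
    ll = 0.0
    for i in range(len(time)):
        if event[i] == 1:
            risk = [k for k in range(len(time)) if time[k] >= time[i]]
            ll += X[i] @ W - np.log(sum(np.exp(X[k] @ W) for k in risk))
    return ll


class TestPartialLoglik:
    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_risk_set_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(4, 15)
        X = rng.normal(size=(n, 2))
        # integer times force ties through the Breslow convention
        time = rng.integers(1, 6, size=n).astype(float)
        event = rng.integers(0, 2, size=n)
        labels = SurvivalLabels([str(i) for i in range(n)], time, event)
        W = rng.normal(size=2)
        assert cox_partial_loglik(W, X, labels) == pytest.approx(
            brute_force_partial_loglik(W, X, time, event)
        )

    def test_all_censored_gives_zero_for_any_weights(self):
        rng = np.random.default_rng(0)
        labels = SurvivalLabels(["a", "b", "c"], [1.0, 2.0, 3.0], [0, 0, 0])
        X = rng.normal(size=(3, 2))
        for _ in range(3):
            assert cox_partial_loglik(rng.normal(size=2), X, labels) == 0.0

    def test_single_uncensored_patient_contributes_zero(self):
        labels = SurvivalLabels(["a"], [5.0], [1])
        assert cox_partial_loglik(np.array([2.0]), np.array([[3.0]]), labels) == 0.0

    def test_invariant_to_shifting_a_covariate_by_a_constant(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 3))
        labels = make_survival_labels(n=20, seed=2)
        W = rng.normal(size=3)
        Xs = X.copy()
        Xs[:, 1] += 7.3
        assert cox_partial_loglik(W, X, labels) == pytest.approx(
            cox_partial_loglik(W, Xs, labels)
        )


class TestFitCox:
    def test_all_censored_with_ridge_gives_zero_coefficients(self):
        labels = SurvivalLabels(["a", "b", "c"], [1.0, 2.0, 3.0], [0, 0, 0])
        m = fit_cox(np.eye(3), labels, lam=1.0, fit_baseline=False)
        assert np.allclose(m.coef, 0.0)

    def test_hazard_ratio_is_time_free_and_reciprocal(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(50, 2))
        labels = make_survival_labels(n=50, seed=3, beta=np.array([1.0, 0.0]), X=X)
        m = fit_cox(X, labels, lam=0.1, fit_baseline=False)
        hr12 = np.exp((X[0] - X[1]) @ m.coef)
        hr21 = np.exp((X[1] - X[0]) @ m.coef)
        assert hr12 * hr21 == pytest.approx(1.0)

    def test_one_covariate_matches_scalar_optimization_oracle(self):
        x = np.array([[0.0], [1.0], [0.0], [1.0], [1.0], [0.0]])
        labels = SurvivalLabels(
            [str(i) for i in range(6)],
            [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            [1, 1, 0, 1, 1, 0],
        )
        lam = 0.5
        res = minimize_scalar(
            lambda w: -(
                brute_force_partial_loglik(np.array([w]), x, labels.time, labels.event)
                - lam * w**2
            ),
            bounds=(-5, 5),
            method="bounded",
            options={"xatol": 1e-10},
        )
        m = fit_cox(x, labels, lam=lam, fit_baseline=False)
        assert m.coef[0] == pytest.approx(res.x, abs=1e-4)

    def test_matches_lifelines_on_tie_free_data(self):
        from lifelines import CoxPHFitter

        rng = np.random.default_rng(4)
        n = 150
        X = rng.normal(size=(n, 3))
        labels = make_survival_labels(
            n=n, seed=4, beta=np.array([0.8, -0.5, 0.0]), X=X
        )
        m = fit_cox(X, labels, lam=0.0, fit_baseline=False)
        df = pd.DataFrame(X, columns=["a", "b", "c"])
        df["T"], df["E"] = labels.time, labels.event
        cph = CoxPHFitter().fit(df, "T", "E")
        assert np.allclose(m.coef, cph.params_.to_numpy(), atol=1e-4)

    def test_recovers_known_log_hazard_ratio_within_three_se(self):
        rng = np.random.default_rng(5)
        n = 600
        x = rng.integers(0, 2, size=(n, 1)).astype(float)
        labels = make_survival_labels(n=n, seed=5, beta=np.array([0.7]), X=x)
        m = fit_cox(x, labels, lam=0.0, fit_baseline=False)
        _, _, hess = _risk_set_stats(m.coef, x, labels.time, labels.event, True)
        se = np.sqrt(np.linalg.inv(-hess)[0, 0])
        assert abs(m.coef[0] - 0.7) < 3 * se

    def test_separable_data_without_ridge_raises_with_advice(self):
        # covariate perfectly ranks the death order -> MLE diverges
        n = 20
        time = np.arange(1.0, n + 1)
        x = (-time)[:, None]
        labels = SurvivalLabels([str(i) for i in range(n)], time, np.ones(n, dtype=int))
        with pytest.raises(ConvergenceError, match="lam"):
            fit_cox(x, labels, lam=0.0, fit_baseline=False)


class TestKalbfleischPrenticeBaseline:
    def test_null_model_baseline_equals_kaplan_meier(self):
        from lifelines import KaplanMeierFitter

        labels = make_survival_labels(n=80, seed=6)
        m = fit_cox(np.zeros((80, 1)), labels, lam=1.0)
        curve = cox_survival_curve(m, [0.0])
        km = KaplanMeierFitter().fit(labels.time, labels.event)
        km_vals = km.survival_function_at_times(curve.times[1:]).to_numpy()
        assert np.allclose(curve.probs[1:], km_vals, atol=1e-10)

    def test_zero_score_patient_gets_the_baseline(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 2))
        labels = make_survival_labels(n=60, seed=7, beta=np.array([0.5, 0.5]), X=X)
        m = fit_cox(X, labels, lam=0.1)
        c0 = cox_survival_curve(m, np.zeros(2))
        assert np.allclose(c0.probs[1:], m.baseline_surv)

    def test_higher_risk_patient_has_pointwise_lower_curve(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(60, 1))
        labels = make_survival_labels(n=60, seed=8, beta=np.array([1.0]), X=X)
        m = fit_cox(X, labels, lam=0.1)
        lo = cox_survival_curve(m, [-1.0])
        hi = cox_survival_curve(m, [1.0])
        assert np.all(hi.probs[1:] <= lo.probs[1:] + 1e-12)

    def test_unfitted_baseline_errors(self):
        labels = make_survival_labels(n=10, seed=9)
        m = fit_cox(np.zeros((10, 1)), labels, lam=1.0, fit_baseline=False)
        with pytest.raises(ValueError, match="baseline"):
            cox_survival_curve(m, [0.0])


class TestTimeGrid:
    def test_default_grid_length_is_floor_sqrt_n(self):
        labels = make_survival_labels(n=100, censor_frac=0.0, seed=10)
        assert len(build_time_grid(labels)) == 10

    def test_points_sit_at_evenly_spaced_quantiles(self):
        labels = SurvivalLabels(
            [str(i) for i in range(100)], np.arange(1.0, 101.0), np.ones(100, dtype=int)
        )
        grid = build_time_grid(labels, m=4)
        oracle = np.quantile(np.arange(1.0, 101.0), [0.2, 0.4, 0.6, 0.8])
        assert np.allclose(grid, oracle)

    def test_identical_times_collapse_to_single_point(self):
        labels = SurvivalLabels(["a", "b", "c"], [5.0, 5.0, 5.0], [1, 1, 0])
        grid = build_time_grid(labels, m=3)
        assert list(grid) == [5.0]
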