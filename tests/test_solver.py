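import numpy as np
import pytest
from scipy.optimize import minimize
from scipy.special import expit

from mtpen import (
    GroupedDataset,
    PenaltySpec,
    compute_lambda_entry,
    fit_path,
    fit_weighted_en_logistic,
)

from conftest import make_logistic_data
from oracles import kkt_residual, proximal_fit


def _objective(X, y, wpen, alpha, lam, b0, beta):
    eta = b0 + X @ beta
    nll = np.mean(np.logaddexp(0.0, eta)) - np.mean(y * eta)
    pen = lam * np.sum(wpen * ((1 - alpha) * 0.5 * beta**2 + alpha * np.abs(beta)))
    return nll + pen


class TestSingleFit:
    def test_fully_penalized_balanced_outcome_is_null_model(self):
        data = make_logistic_data(seed=1, n=30)
        # force exact class balance
        y = np.array([0.0, 1.0] * 15)
        data = GroupedDataset(data.features, y, data.group_sizes)
        w = np.ones(data.n_features)
        lam_entry = compute_lambda_entry(data, 0.5, w)
        fit = fit_weighted_en_logistic(data, PenaltySpec(0.5, lam_entry * 1.01, w))
        assert np.all(fit.coefficients == 0.0)
        assert fit.intercept == pytest.approx(0.0, abs=1e-10)

    def test_unit_penalty_factors_match_kappa_one(self, small_data):
        spec_a = PenaltySpec(0.5, 0.08, np.ones(small_data.n_features))
        spec_b = PenaltySpec.from_kappa(small_data.group_sizes, 1.0, 0.5, 0.08)
        fa = fit_weighted_en_logistic(small_data, spec_a)
        fb = fit_weighted_en_logistic(small_data, spec_b)
        np.testing.assert_allclose(fa.coefficients, fb.coefficients, atol=1e-12)

    def test_matches_proximal_oracle_on_reference_instance(self):
        rng = np.random.default_rng(42)
        n, p = 20, 5
        X = rng.standard_normal((n, p))
        y = (rng.random(n) < expit(X[:, 0] - X[:, 2])).astype(float)
        data = GroupedDataset(X, y, (3, 2))
        w = np.array([1.0, 1.0, 1.0, 2.0, 2.0])
        fit = fit_weighted_en_logistic(
            data, PenaltySpec(0.5, 0.1, w), standardize=False
        )
        b0o, betao = proximal_fit(X, y, w, 0.5, 0.1)
        assert fit.converged
        np.testing.assert_allclose(fit.coefficients, betao, atol=1e-5)
        assert fit.intercept == pytest.approx(b0o, abs=1e-5)

    def test_objective_no_worse_than_zero_and_warm_start(self, small_data):
        w = np.ones(small_data.n_features)
        pen = PenaltySpec(0.5, 0.05, w)
        # a deliberately poor warm start
        warm = fit_weighted_en_logistic(small_data, PenaltySpec(0.5, 0.5, w))
        fit = fit_weighted_en_logistic(small_data, pen, warm_start=warm)
        X, y = small_data.features, small_data.outcome
        obj_fit = _objective(X, y, w, 0.5, 0.05, fit.intercept, fit.coefficients)
        obj_zero = _objective(X, y, w, 0.5, 0.05, 0.0, np.zeros_like(w))
        obj_warm = _objective(X, y, w, 0.5, 0.05, warm.intercept, warm.coefficients)
        assert obj_fit <= obj_zero + 1e-12
        assert obj_fit <= obj_warm + 1e-12

    def test_lasso_single_feature_matches_numeric_minimizer(self):
        rng = np.random.default_rng(7)
        n = 60
        X = rng.standard_normal((n, 1))
        y = (rng.random(n) < expit(1.5 * X[:, 0] - 0.2)).astype(float)
        data = GroupedDataset(X, y, (1,))
        lam = 0.05
        fit = fit_weighted_en_logistic(
            data, PenaltySpec(1.0, lam, np.ones(1)), standardize=False
        )

        def obj(z):
            return _objective(X, y, np.ones(1), 1.0, lam, z[0], z[1:])

        res = minimize(obj, np.array([fit.intercept, fit.coefficients[0]]),
                       method="Nelder-Mead",
                       options=dict(xatol=1e-12, fatol=1e-14, maxiter=50_000))
        assert fit.coefficients[0] == pytest.approx(res.x[1], abs=1e-6)

    @pytest.mark.parametrize("bad", ["single_class", "neg_lam", "neg_w"])
    def test_invalid_inputs_rejected(self, small_data, bad):
        if bad == "single_class":
            data = GroupedDataset(
                small_data.features, np.ones(small_data.n_samples),
                small_data.group_sizes,
            )
            with pytest.raises(ValueError, match="both classes"):
                fit_weighted_en_logistic(
                    data, PenaltySpec(0.5, 0.1, np.ones(data.n_features))
                )
        elif bad == "neg_lam":
            with pytest.raises(ValueError, match="nonnegative"):
                PenaltySpec(0.5, -0.1, np.ones(small_data.n_features))
        else:
            with pytest.raises(ValueError, match="nonnegative"):
                PenaltySpec(0.5, 0.1, -np.ones(small_data.n_features))


class TestLambdaEntry:
    def test_scaling_identity(self, small_data):
        w = np.abs(np.random.default_rng(0).normal(1.0, 0.2, small_data.n_features))
        base = compute_lambda_entry(small_data, 0.5, w)
        scaled = compute_lambda_entry(small_data, 0.5, 3.0 * w)
        assert scaled == pytest.approx(base / 3.0, rel=1e-12)

    def test_orthogonal_features_give_zero(self):
        rng = np.random.default_rng(5)
        n, p = 24, 4
        y = np.array([0.0, 1.0] * (n // 2))
        X = rng.standard_normal((n, p))
        c = y - y.mean()
        X = X - np.outer(c, c @ X) / (c @ c)  # project out the outcome direction
        data = GroupedDataset(X, y, (2, 2))
        assert compute_lambda_entry(data, 0.5, np.ones(p), standardize=False) == (
            pytest.approx(0.0, abs=1e-12)
        )

    def test_brackets_the_support_entry_point(self):
        data = make_logistic_data(seed=11, n=50, p1=5, p2=5)
        w = np.ones(10)
        lam_e = compute_lambda_entry(data, 0.5, w)
        hi = fit_weighted_en_logistic(data, PenaltySpec(0.5, 1.001 * lam_e, w))
        lo = fit_weighted_en_logistic(data, PenaltySpec(0.5, 0.9 * lam_e, w))
        assert hi.n_selected == 0
        assert lo.n_selected >= 1

    def test_alpha_zero_signals_undefined(self, small_data):
        with pytest.raises(ValueError, match="alpha = 0"):
            compute_lambda_entry(small_data, 0.0, np.ones(small_data.n_features))

    def test_unpenalized_features_excluded_from_max(self, small_data):
        w = np.ones(small_data.n_features)
        w[0] = 0.0  # unpenalized feature must not drive the entry point
        lam = compute_lambda_entry(small_data, 0.5, w)
        assert np.isfinite(lam) and lam > 0


class TestPath:
    def test_two_point_path_has_exact_endpoints(self, small_data):
        w = np.ones(small_data.n_features)
        path = fit_path(small_data, 0.5, w, n_lambda=2, lambda_min_ratio=0.1)
        lam_e = compute_lambda_entry(small_data, 0.5, w)
        np.testing.assert_allclose(path.lambdas, [lam_e, 0.1 * lam_e], rtol=1e-12)

    def test_first_fit_is_null_model(self, small_data):
        w = np.ones(small_data.n_features)
        path = fit_path(small_data, 0.5, w, n_lambda=10, lambda_min_ratio=0.05)
        assert path.fits[0].n_selected == 0

    def test_support_grows_along_most_of_the_path(self):
        data = make_logistic_data(seed=9, n=50, p1=5, p2=5)
        path = fit_path(data, 0.5, np.ones(10), n_lambda=25, lambda_min_ratio=0.02)
        nnz = np.array([f.n_selected for f in path.fits])
        frac_nondecreasing = np.mean(np.diff(nnz) >= 0)
        assert frac_nondecreasing >= 0.9

    def test_every_path_fit_satisfies_kkt(self):
        data = make_logistic_data(seed=13, n=40, p1=4, p2=4)
        w = PenaltySpec.from_kappa(data.group_sizes, 0.6, 0.5, 1.0).penalty_factors
        path = fit_path(data, 0.5, w, n_lambda=12, lambda_min_ratio=0.05,
                        standardize=False)
        for lam, fit in zip(path.lambdas, path.fits):
            assert fit.converged
            res = kkt_residual(
                data.features, data.outcome, w, 0.5, lam,
                fit.intercept, fit.coefficients,
            )
            assert res <= 1e-6


class TestInvariances:
    @pytest.mark.parametrize("seed", range(6))
    def test_kkt_certificate_on_converged_fits(self, seed):
        data = make_logistic_data(seed=seed, n=35, p1=5, p2=5)
        rng = np.random.default_rng(seed)
        w = np.abs(rng.normal(1.0, 0.4, 10)) + 0.1
        lam = 0.3 * compute_lambda_entry(data, 0.5, w, standardize=False)
        fit = fit_weighted_en_logistic(
            data, PenaltySpec(0.5, lam, w), standardize=False
        )
        assert fit.converged
        assert kkt_residual(
            data.features, data.outcome, w, 0.5, lam, fit.intercept, fit.coefficients
        ) <= 1e-6

    @pytest.mark.parametrize("kappa", [0.25, 0.5, 2.0])
    def test_two_penalty_reparameterization_invariance(self, small_data, kappa):
        """(lam1, w=(1, kappa)) and (lam2 = kappa*lam1, w=(1/kappa, 1)) agree."""
        p1 = small_data.group_sizes[0]
        p = small_data.n_features
        lam1 = 0.06
        w_a = np.concatenate([np.ones(p1), np.full(p - p1, kappa)])
        w_b = np.concatenate([np.full(p1, 1.0 / kappa), np.ones(p - p1)])
        fa = fit_weighted_en_logistic(small_data, PenaltySpec(0.5, lam1, w_a))
        fb = fit_weighted_en_logistic(small_data, PenaltySpec(0.5, kappa * lam1, w_b))
        np.testing.assert_allclose(fa.coefficients, fb.coefficients, atol=1e-6)

    def test_standardized_objective_reported(self, small_data):
        w = np.ones(small_data.n_features)
        pen = PenaltySpec(0.5, 0.05, w)
        fit = fit_weighted_en_logistic(small_data, pen, standardize=False)
        expected = _objective(
            small_data.features, small_data.outcome, w, 0.5, 0.05,
            fit.intercept, fit.coefficients,
        )
        assert fit.objective_value == pytest.approx(expected, rel=1e-10)
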