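"""Weighted elastic-net penalized logistic regression by coordinate descent.

The estimator minimizes, over the intercept ``b0`` and coefficients ``beta``,

    (1/n) * sum_i [ log(1 + exp(eta_i)) - y_i * eta_i ]
        + lam * sum_j w_j * [ (1 - alpha)/2 * beta_j^2 + alpha * |beta_j| ]

with ``eta_i = b0 + x_i' beta``.  The per-feature penalty factors ``w_j``
implement differential shrinkage across feature groups: with factors
``(1, ..., 1, kappa, ..., kappa)`` and overall strength ``lam = lam1``, the
problem is exactly the two-penalty model ``lam1 * N(beta1) + lam2 * N(beta2)``
with ``kappa = lam2 / lam1``; ``kappa = 1`` recovers the standard elastic net.

Algorithm: outer iteratively-reweighted least squares (IRLS) on the logistic
loss, inner cyclic coordinate descent with soft-thresholding on an active
set.  After each inner solve the full weighted-least-squares gradient is
checked and any Karush-Kuhn-Tucker (KKT) violators are added to the active
set; the outer loop terminates when the KKT residual of the *logistic*
problem is below tolerance.  The intercept is never penalized.  Features are
standardized internally (unit population variance) by default and
coefficients returned on the original scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.special import expit

from ._cd import fit_path_points, irls_active
from .data import GroupedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "PenaltySpec",
    "ENFit",
    "ENPath",
    "fit_weighted_en_logistic",
    "compute_lambda_entry",
    "fit_path",
]

# numerical constants (see docs/methods.md)
WEIGHT_FLOOR = 1e-5       # IRLS observation-weight floor near p in {0, 1}
TOL_INNER = 1e-7          # max abs coefficient change, inner CD
OBJ_RTOL = 1e-8           # relative objective change, IRLS convergence
KKT_TOL = 1e-6            # logistic KKT residual declaring convergence
MAX_CYCLES = 100_000      # total coordinate cycles per fit
MAX_OUTER = 100           # active-set rounds per fit
MAX_IRLS = 10             # IRLS iterations per active-set round


@dataclass
class PenaltySpec:
    """Elastic-net penalty: mixing weight, overall strength, per-feature factors.

    ``penalty_factors`` holds the weight vector ``w``; under the two-group
    kappa parameterization the first ``p1`` entries are 1 and the remaining
    ``p2`` entries equal ``kappa = lam2 / lam1 >= 0``.
    """

    alpha: float
    lam: float
    penalty_factors: np.ndarray

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be nonnegative")
        self.penalty_factors = np.asarray(self.penalty_factors, dtype=np.float64).ravel()
        if not np.all(np.isfinite(self.penalty_factors)) or np.any(self.penalty_factors < 0):
            raise ValueError("penalty factors must be finite and nonnegative")

    @classmethod
    def from_kappa(
        cls, group_sizes: tuple[int, ...], kappa: float, alpha: float, lam: float
    ) -> "PenaltySpec":
        """Factors 1 for group 1 and ``kappa`` for every later group."""
        if kappa < 0:
            raise ValueError("kappa must be nonnegative")
        w = np.concatenate(
            [np.full(g, 1.0 if k == 0 else kappa) for k, g in enumerate(group_sizes)]
        )
        return cls(alpha=alpha, lam=lam, penalty_factors=w)


@dataclass
class ENFit:
    """One fitted model: intercept ``b0`` and coefficients on the input scale."""

    intercept: float
    coefficients: np.ndarray
    converged: bool
    n_iterations: int
    objective_value: float
    kkt_residual: float = np.nan

    @property
    def n_selected(self) -> int:
        return int(np.count_nonzero(self.coefficients))

    def predict_linear(self, features: np.ndarray) -> np.ndarray:
        return self.intercept + features @ self.coefficients

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        return expit(self.predict_linear(features))


@dataclass
class ENPath:
    """Warm-started fits along a strictly decreasing lambda sequence."""

    lambdas: np.ndarray
    fits: list[ENFit]
    alpha: float
    penalty_factors: np.ndarray

    def coefficients(self) -> np.ndarray:
        """Stacked ``(n_lambda, p)`` coefficient matrix."""
        return np.vstack([f.coefficients for f in self.fits])

    def predict_linear(self, features: np.ndarray) -> np.ndarray:
        """Linear predictor, shape ``(n_samples, n_lambda)``."""
        b0 = np.array([f.intercept for f in self.fits])
        return b0[None, :] + features @ self.coefficients().T


# ---------------------------------------------------------------------------
# internal standardized-scale machinery
# ---------------------------------------------------------------------------

def _standardize(X: np.ndarray):
    """Center and scale columns to unit population variance.

    Zero-variance columns get scale 1 (their centered values are all zero,
    so the coefficient stays at zero).  Returns (Xs, mean, scale) with Xs in
    Fortran order for fast column access.
    """
    m = X.mean(axis=0)
    s = X.std(axis=0)  # population denominator
    s = np.where(s > 0, s, 1.0)
    return np.asfortranarray((X - m) / s), m, s


def _lambda_entry_std(Xs: np.ndarray, y: np.ndarray, alpha: float, wpen: np.ndarray) -> float:
    """max_j |x_j'(y - ybar)| / (n * alpha * w_j) over features with w_j > 0."""
    if alpha <= 0:
        raise ValueError(
            "lambda entry point is undefined for alpha = 0 (no sparsity); "
            "use a fixed lambda grid instead"
        )
    pos = wpen > 0
    if not np.any(pos):
        raise ValueError("at least one penalty factor must be positive")
    n = y.shape[0]
    g = np.abs(Xs.T @ (y - y.mean())) / n
    return float(np.max(g[pos] / (alpha * wpen[pos])))


def _irls_fit_std(
    Xs: np.ndarray,
    y: np.ndarray,
    wpen: np.ndarray,
    alpha: float,
    lam: float,
    beta: np.ndarray,
    b0: float,
    tol_inner: float = TOL_INNER,
    kkt_tol: float = KKT_TOL,
    max_cycles: int = MAX_CYCLES,
    max_outer: int = MAX_OUTER,
    obj_rtol: float = OBJ_RTOL,
):
    """Fit at one lambda on standardized data; ``beta`` is updated in place.

    Active-set strategy: IRLS + coordinate descent run on the active
    features only; after each converged round the full logistic gradient is
    checked and KKT-violating features join the set.  Returns
    (b0, converged, n_cycles, kkt_residual).
    """
    n, p = Xs.shape
    l1 = lam * alpha * wpen
    active = beta != 0.0
    eta = np.ascontiguousarray(b0 + Xs @ beta)
    cycles_total = 0
    converged = False
    kkt = np.inf
    ti, ortol = tol_inner, obj_rtol
    for _ in range(max_outer):
        idx = np.flatnonzero(active)
        b0, cyc = irls_active(
            Xs, idx, wpen, lam, alpha, y, eta, beta, b0,
            ti, ortol, WEIGHT_FLOOR, max(1, max_cycles - cycles_total), MAX_IRLS,
        )
        cycles_total += int(cyc)

        prob = expit(eta)
        grad = Xs.T @ (prob - y) / n  # gradient of the (1/n)-scaled neg log-lik
        nz = beta != 0.0
        res = np.where(
            nz,
            np.abs(grad + lam * (1.0 - alpha) * wpen * beta
                   + lam * alpha * wpen * np.sign(beta)),
            np.maximum(np.abs(grad) - l1, 0.0),
        )
        kkt = max(float(res.max(initial=0.0)), abs(float(np.mean(prob - y))))
        if kkt <= kkt_tol:
            converged = True
            break
        if cycles_total >= max_cycles:
            break
        viol = (np.abs(grad) > l1 + 1e-12) & ~active
        if viol.any():
            active |= viol
        else:
            # KKT unmet with a stable active set: tighten inner tolerances
            ti = max(ti * 0.1, 1e-13)
            ortol = max(ortol * 0.01, 1e-15)
    return b0, converged, cycles_total, kkt


def _fit_path_std(
    Xs: np.ndarray,
    y: np.ndarray,
    wpen: np.ndarray,
    alpha: float,
    lambdas: np.ndarray,
    init_betas: np.ndarray | None = None,
    init_b0s: np.ndarray | None = None,
    **kw,
):
    """Warm-started fits at each lambda (decreasing) on standardized data.

    By default each point is warm-started from the previous one.  When
    ``init_betas``/``init_b0s`` are given (e.g. the solutions for a
    neighbouring penalty-factor vector at the same grid positions), point
    ``l`` starts from ``init_betas[l]`` instead, which converges in fewer
    cycles when sweeping the penalty ratio.  Warm starts only affect the
    iteration count: every returned fit is KKT-certified.

    Returns (intercepts, betas ``(L, p)``, converged flags, cycle counts).
    """
    n, p = Xs.shape
    lambdas = np.ascontiguousarray(lambdas, dtype=np.float64)
    ybar = float(y.mean())
    b0_null = float(np.log(ybar / (1.0 - ybar)))
    use_init = init_betas is not None
    if not use_init:
        init_betas = np.zeros((1, p))
        init_b0s = np.zeros(1)
    b0s, betas, flags, cyc, _kkts = fit_path_points(
        Xs, y, np.ascontiguousarray(wpen, dtype=np.float64), alpha, lambdas,
        np.ascontiguousarray(init_betas, dtype=np.float64),
        np.ascontiguousarray(init_b0s, dtype=np.float64),
        use_init, b0_null,
        kw.get("tol_inner", TOL_INNER), kw.get("obj_rtol", OBJ_RTOL),
        kw.get("kkt_tol", KKT_TOL), WEIGHT_FLOOR,
        kw.get("max_cycles", MAX_CYCLES), kw.get("max_outer", MAX_OUTER),
        MAX_IRLS,
    )
    if not flags.all():
        for k in np.flatnonzero(~flags):
            logger.warning("path fit at lambda=%.4g did not converge", lambdas[k])
    return b0s, betas, flags, cyc


def _objective_std(Xs, y, wpen, alpha, lam, b0, beta) -> float:
    eta = b0 + Xs @ beta
    n = y.shape[0]
    nll = float(np.mean(np.logaddexp(0.0, eta)) - np.mean(y * eta))
    pen = float(np.sum(wpen * ((1.0 - alpha) * 0.5 * beta**2 + alpha * np.abs(beta))))
    return nll + lam * pen


def _lambda_grid(lam_max: float, n_lambda: int, lambda_min_ratio: float) -> np.ndarray:
    if n_lambda < 2:
        raise ValueError("n_lambda must be at least 2")
    if not 0.0 < lambda_min_ratio < 1.0:
        raise ValueError("lambda_min_ratio must be in (0, 1)")
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


# ---------------------------------------------------------------------------
# public surface
# ---------------------------------------------------------------------------

def _check_penalty_dims(data: GroupedDataset, wpen: np.ndarray) -> None:
    if wpen.shape[0] != data.n_features:
        raise ValueError(
            f"penalty factors length {wpen.shape[0]} != p = {data.n_features}"
        )


def fit_weighted_en_logistic(
    data: GroupedDataset,
    penalty: PenaltySpec,
    warm_start: ENFit | None = None,
    standardize: bool = True,
    tol_inner: float = TOL_INNER,
    kkt_tol: float = KKT_TOL,
    max_cycles: int = MAX_CYCLES,
    max_outer: int = MAX_OUTER,
) -> ENFit:
    """Fit the weighted elastic-net logistic model at a single penalty.

    Non-convergence after the iteration budget is flagged on the result
    (``converged=False``), never silent.  The reported ``objective_value``
    is on the internal fitting scale (standardized features when
    ``standardize=True``).
    """
    data.require_both_classes()
    wpen = penalty.penalty_factors
    _check_penalty_dims(data, wpen)
    y = data.outcome
    if standardize:
        Xs, m, s = _standardize(data.features)
    else:
        Xs, m, s = np.asfortranarray(data.features), np.zeros(data.n_features), np.ones(data.n_features)

    beta = np.zeros(data.n_features)
    ybar = float(y.mean())
    b0 = float(np.log(ybar / (1.0 - ybar)))
    if warm_start is not None:
        # map an original-scale warm start onto the fitting scale
        beta = warm_start.coefficients * s
        b0 = warm_start.intercept + float(warm_start.coefficients @ m)

    b0, ok, cyc, kkt = _irls_fit_std(
        Xs, y, wpen, penalty.alpha, penalty.lam, beta, b0,
        tol_inner=tol_inner, kkt_tol=kkt_tol,
        max_cycles=max_cycles, max_outer=max_outer,
    )
    obj = _objective_std(Xs, y, wpen, penalty.alpha, penalty.lam, b0, beta)
    if not ok:
        logger.warning(
            "fit did not converge (lam=%.4g, kkt residual %.3g)", penalty.lam, kkt
        )
    coef = beta / s
    intercept = b0 - float((beta / s) @ m)
    return ENFit(
        intercept=intercept,
        coefficients=coef,
        converged=ok,
        n_iterations=cyc,
        objective_value=obj,
        kkt_residual=kkt,
    )


def compute_lambda_entry(
    data: GroupedDataset,
    alpha: float,
    penalty_factors: np.ndarray,
    standardize: bool = True,
) -> float:
    """Smallest overall strength at which every coefficient is zero.

    ``max_j |x_j'(y - ybar)| / (n * alpha * w_j)`` over features with
    ``w_j > 0`` (unpenalized ``w_j = 0`` features are excluded from the
    max).  Fitting at any ``lam`` at or above this value returns the
    intercept-only model.  Raises for ``alpha = 0``, where no finite
    entry point exists.
    """
    wpen = np.asarray(penalty_factors, dtype=np.float64).ravel()
    if np.any(wpen < 0):
        raise ValueError("penalty factors must be nonnegative")
    _check_penalty_dims(data, wpen)
    if standardize:
        Xs, _, _ = _standardize(data.features)
    else:
        Xs = data.features
    return _lambda_entry_std(Xs, data.outcome, alpha, wpen)


def fit_path(
    data: GroupedDataset,
    alpha: float,
    penalty_factors: np.ndarray,
    n_lambda: int = 50,
    lambda_min_ratio: float = 0.01,
    standardize: bool = True,
    **kw,
) -> ENPath:
    """Warm-started fits along a log-spaced lambda grid.

    The grid runs from the data-derived entry value ``lambda_entry`` (where
    the fit is exactly the intercept-only model) down to
    ``lambda_entry * lambda_min_ratio``.
    """
    data.require_both_classes()
    wpen = np.asarray(penalty_factors, dtype=np.float64).ravel()
    _check_penalty_dims(data, wpen)
    y = data.outcome
    if standardize:
        Xs, m, s = _standardize(data.features)
    else:
        Xs, m, s = np.asfortranarray(data.features), np.zeros(data.n_features), np.ones(data.n_features)
    lam_max = _lambda_entry_std(Xs, y, alpha, wpen)
    lambdas = _lambda_grid(lam_max, n_lambda, lambda_min_ratio)
    b0s, betas, flags, cyc = _fit_path_std(Xs, y, wpen, alpha, lambdas, **kw)
    fits = []
    for k in range(len(lambdas)):
        beta = betas[k]
        obj = _objective_std(Xs, y, wpen, alpha, float(lambdas[k]), b0s[k], beta)
        fits.append(
            ENFit(
                intercept=float(b0s[k] - (beta / s) @ m),
                coefficients=beta / s,
                converged=bool(flags[k]),
                n_iterations=int(cyc[k]),
                objective_value=obj,
            )
        )
    return ENPath(lambdas=lambdas, fits=fits, alpha=alpha, penalty_factors=wpen)
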