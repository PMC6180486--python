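"""Two-platform synthetic data from a sparse logistic model.

Features are multivariate normal with unit variances.  Within each
platform block the first ``q_j`` features are informative (true
coefficient ``beta_j``); the first ``r_j`` of those are equicorrelated at
``rho_j`` within the platform and correlated at ``rho12`` with the
corresponding set in the other platform; all other correlations are zero.
The binary outcome is Bernoulli with success probability
``logistic(beta0 + x' beta)``.

The seven preset scenarios share n=200 samples and 250 features per
platform and differ in effect sizes, numbers of informative features, and
correlation structure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy.special import expit

from .data import GroupedDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioSpec",
    "SimulatedDataset",
    "build_covariance",
    "sample_dataset",
    "preset_scenarios",
]


@dataclass(frozen=True)
class ScenarioSpec:
    """Generative parameters for one two-platform simulation scenario."""

    n: int = 200
    p1: int = 250
    p2: int = 250
    q1: int = 5
    q2: int = 20
    beta1: float = 0.6
    beta2: float = 0.8
    beta0: float = 0.0
    r1: int = 0
    r2: int = 0
    rho1: float = 0.0
    rho2: float = 0.0
    rho12: float = 0.0
    seed: int = 0
    name: str = ""

    def __post_init__(self) -> None:
        if self.q1 > self.p1 or self.q2 > self.p2:
            raise ValueError("informative counts q_j cannot exceed p_j")
        if self.r1 > self.q1 or self.r2 > self.q2:
            raise ValueError("correlated counts r_j cannot exceed q_j")
        for rho in (self.rho1, self.rho2, self.rho12):
            if not -1.0 < rho < 1.0:
                raise ValueError("correlations must lie strictly within (-1, 1)")
        if self.n < 1:
            raise ValueError("n must be positive")

    @property
    def p(self) -> int:
        return self.p1 + self.p2

    def true_coefficients(self) -> np.ndarray:
        beta = np.zeros(self.p)
        beta[: self.q1] = self.beta1
        beta[self.p1 : self.p1 + self.q2] = self.beta2
        return beta

    def true_support(self) -> np.ndarray:
        return np.concatenate(
            [np.arange(self.q1), self.p1 + np.arange(self.q2)]
        ).astype(int)

    def correlated_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Column indices of the correlated sets (first r_j informative)."""
        return np.arange(self.r1), self.p1 + np.arange(self.r2)


@dataclass
class SimulatedDataset:
    data: GroupedDataset
    true_coefficients: np.ndarray
    true_support: np.ndarray
    scenario: ScenarioSpec


def _correlated_block(spec: ScenarioSpec) -> np.ndarray:
    """The (r1 + r2) x (r1 + r2) correlation block; the rest of Sigma is identity."""
    b = spec.r1 + spec.r2
    C = np.eye(b)
    C[: spec.r1, : spec.r1] = spec.rho1
    C[spec.r1 :, spec.r1 :] = spec.rho2
    C[: spec.r1, spec.r1 :] = spec.rho12
    C[spec.r1 :, : spec.r1] = spec.rho12
    np.fill_diagonal(C, 1.0)
    return C


def build_covariance(spec: ScenarioSpec) -> np.ndarray:
    """Full p x p population covariance; raises if not positive semidefinite."""
    C = _correlated_block(spec)
    if C.size:
        min_eig = float(np.linalg.eigvalsh(C).min())
        if min_eig < -1e-10:
            raise ValueError(
                f"correlation parameters give a non-PSD covariance "
                f"(min eigenvalue {min_eig:.3e})"
            )
    sigma = np.eye(spec.p)
    i1, i2 = spec.correlated_indices()
    idx = np.concatenate([i1, i2])
    sigma[np.ix_(idx, idx)] = C
    return sigma


def sample_dataset(spec: ScenarioSpec) -> SimulatedDataset:
    """Draw one dataset; identical spec and seed give identical data.

    Only the small correlated block needs a Cholesky-type factor; all
    remaining features are independent standard normals, which yields the
    same distribution as sampling from the full covariance.  A degenerate
    draw whose outcome is single-class is resampled with an incremented
    sub-seed (logged).
    """
    beta = spec.true_coefficients()
    for attempt in range(100):
        rng = np.random.default_rng(
            np.random.SeedSequence((int(spec.seed), attempt))
        )
        X = rng.standard_normal((spec.n, spec.p))
        b = spec.r1 + spec.r2
        if b and (spec.rho1 or spec.rho2 or spec.rho12):
            C = _correlated_block(spec)
            min_eig = float(np.linalg.eigvalsh(C).min())
            if min_eig < -1e-10:
                raise ValueError(
                    f"correlation parameters give a non-PSD covariance "
                    f"(min eigenvalue {min_eig:.3e})"
                )
            # eigenvalue factor tolerates exactly singular blocks
            evals, evecs = np.linalg.eigh(C)
            factor = evecs * np.sqrt(np.clip(evals, 0.0, None))
            i1, i2 = spec.correlated_indices()
            idx = np.concatenate([i1, i2])
            X[:, idx] = X[:, idx] @ factor.T
        eta = spec.beta0 + X @ beta
        y = (rng.random(spec.n) < expit(eta)).astype(np.float64)
        if y.min() < y.max():
            break
        logger.warning(
            "single-class outcome draw (seed=%s, attempt=%d); resampling",
            spec.seed, attempt,
        )
    else:
        raise RuntimeError("could not draw a two-class outcome in 100 attempts")
    data = GroupedDataset(X, y, (spec.p1, spec.p2))
    return SimulatedDataset(
        data=data,
        true_coefficients=beta,
        true_support=spec.true_support(),
        scenario=spec,
    )


def preset_scenarios() -> list[ScenarioSpec]:
    """The seven preset scenarios (effects, sparsity, correlation settings).

    Scenarios 1-5 have independent features; 6 and 7 add correlation among
    the first three informative features of each platform.
    """
    base = ScenarioSpec()
    return [
        replace(base, beta1=0.6, beta2=0.8, q1=5, q2=20, name="scenario1"),
        replace(base, beta1=0.6, beta2=0.6, q1=5, q2=20, name="scenario2"),
        replace(base, beta1=0.8, beta2=0.6, q1=5, q2=20, name="scenario3"),
        replace(base, beta1=0.8, beta2=0.8, q1=5, q2=5, name="scenario4"),
        replace(base, beta1=0.8, beta2=0.6, q1=5, q2=5, name="scenario5"),
        replace(base, beta1=0.8, beta2=0.6, q1=5, q2=20,
                r1=3, r2=3, rho1=0.4, rho2=0.2, rho12=0.0, name="scenario6"),
        replace(base, beta1=0.8, beta2=0.6, q1=5, q2=20,
                r1=3, r2=3, rho1=0.4, rho2=0.2, rho12=0.4, name="scenario7"),
    ]


def scenario_by_name(name: str) -> ScenarioSpec:
    for s in preset_scenarios():
        if s.name == name:
            return s
    raise KeyError(f"unknown scenario preset {name!r}")
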