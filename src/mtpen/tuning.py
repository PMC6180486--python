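"""Cross-validated tuning of the penalty ratio and overall strength.

The tuning protocol searches a grid over ``(kappa, lambda)``: for each
penalty ratio ``kappa`` a log-spaced lambda path is derived from the full
training data, every cell is scored by stratified k-fold cross-validated
AUC (identical fold assignments across ``kappa``, so comparisons between
ratios are paired), and the winning cell is the one maximizing the mean
AUC across folds.  The parsimony ("one standard error") rule then picks
the largest lambda on the winning ratio's path whose mean AUC is within
one standard error of that maximum.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import StratifiedKFold

from .data import GroupedDataset
from .solver import (
    PenaltySpec,
    _fit_path_std,
    _lambda_entry_std,
    _lambda_grid,
    _standardize,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TuningGrid",
    "CVSurface",
    "CVSelection",
    "stratified_folds",
    "cv_auc_surface",
    "select_kappa_lambda",
    "select_lambda_for_kappa",
]

DEFAULT_KAPPA_GRID = np.round(np.arange(1, 31) * 0.05, 10)  # 0.05 .. 1.50


@dataclass
class TuningGrid:
    """Search grid and cross-validation design.

    ``n_folds=10`` matches the simulation protocol; real-data analyses use
    5-fold with ``n_repeats=10``.  ``cd_tol``/``kkt_tol`` optionally relax
    the solver tolerances for the many fold-level fits (``None`` keeps the
    solver defaults).
    """

    kappa_values: np.ndarray = field(default_factory=lambda: DEFAULT_KAPPA_GRID.copy())
    n_lambda: int = 50
    lambda_min_ratio: float = 0.01
    n_folds: int = 10
    n_repeats: int = 1
    seed: int = 0
    cd_tol: float | None = None
    kkt_tol: float | None = None

    def __post_init__(self) -> None:
        self.kappa_values = np.asarray(self.kappa_values, dtype=np.float64).ravel()
        if self.kappa_values.size == 0:
            raise ValueError("kappa grid must be nonempty")
        if np.any(self.kappa_values <= 0) or np.any(np.diff(self.kappa_values) <= 0):
            raise ValueError("kappa grid must be positive and strictly increasing")
        if self.n_folds < 2:
            raise ValueError("n_folds must be at least 2")
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be at least 1")

    def solver_kwargs(self) -> dict:
        kw = {}
        if self.cd_tol is not None:
            kw["tol_inner"] = self.cd_tol
        if self.kkt_tol is not None:
            kw["kkt_tol"] = self.kkt_tol
        return kw


@dataclass
class CVSurface:
    """Mean and standard error of CV AUC over the (kappa, lambda) grid."""

    kappas: np.ndarray            # (K,)
    lambdas: np.ndarray           # (K, L) per-ratio lambda paths, decreasing
    fold_aucs: np.ndarray         # (K, L, n_folds * n_repeats)
    mean_auc: np.ndarray          # (K, L)
    se_auc: np.ndarray            # (K, L)

    def to_frame(self) -> pd.DataFrame:
        """Long format: one row per (repeat-fold, kappa, lambda) AUC."""
        K, L, F = self.fold_aucs.shape
        rows = {
            "fold": np.tile(np.arange(F), K * L),
            "kappa": np.repeat(self.kappas, L * F),
            "lambda": np.repeat(self.lambdas.ravel(), F),
            "auc": self.fold_aucs.ravel(),
        }
        return pd.DataFrame(rows)


@dataclass
class CVSelection:
    kappa_max: float
    lambda_max: float
    lambda_1se: float
    mean_auc: float               # at (kappa_max, lambda_max)
    se_auc: float                 # at (kappa_max, lambda_max)
    mean_auc_1se: float
    kappa_index: int
    lambda_max_index: int
    lambda_1se_index: int


def stratified_folds(outcome: np.ndarray, k: int, seed: int) -> list[np.ndarray]:
    """Disjoint, exhaustive folds preserving the class ratio.

    Every fold's positive count is within one of ``n_pos / k``.  ``k`` must
    be at least 2 and no larger than the minority-class count.
    """
    outcome = np.asarray(outcome).ravel()
    if k < 2:
        raise ValueError("k must be at least 2 (no validation fold otherwise)")
    n_min = int(min((outcome == 1).sum(), (outcome == 0).sum()))
    if k > n_min:
        raise ValueError(f"k={k} exceeds the minority class count {n_min}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=int(seed))
    return [va for _, va in skf.split(np.zeros_like(outcome), outcome)]


def _auc_columns(scores: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Rank-based AUC of each column of ``scores`` against binary labels."""
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.shape[0] - n1
    if n1 == 0 or n0 == 0:
        return np.full(scores.shape[1], np.nan)
    ranks = rankdata(scores, axis=0)
    return (ranks[pos].sum(axis=0) - n1 * (n1 + 1) / 2.0) / (n1 * n0)


def _repeat_seed(seed: int, repeat: int) -> int:
    return int(np.random.SeedSequence((int(seed), int(repeat))).generate_state(1)[0] % (2**31))


def cv_auc_surface(data: GroupedDataset, grid: TuningGrid, alpha: float = 0.5) -> CVSurface:
    """Cross-validated AUC over the full (kappa, lambda) grid.

    For each ratio, penalty factors are 1 on the first platform block and
    ``kappa`` on the rest; the lambda path is derived from the full
    training data at that ratio.  Fold assignments are shared across
    ratios.  A validation fold with a single class yields an undefined AUC
    for that fold, which is excluded from the mean with a warning.
    """
    data.require_both_classes()
    y = data.outcome
    X = data.features
    K = grid.kappa_values.size
    L = grid.n_lambda
    F = grid.n_folds * grid.n_repeats
    skw = grid.solver_kwargs()

    # per-ratio lambda paths from the full training data
    Xs_full, _, _ = _standardize(X)
    lambdas = np.empty((K, L))
    wmat = np.empty((K, data.n_features))
    for ik, kappa in enumerate(grid.kappa_values):
        w = PenaltySpec.from_kappa(data.group_sizes, float(kappa), alpha, 1.0).penalty_factors
        wmat[ik] = w
        lam_max = _lambda_entry_std(Xs_full, y, alpha, w)
        lambdas[ik] = _lambda_grid(lam_max, L, grid.lambda_min_ratio)

    fold_aucs = np.full((K, L, F), np.nan)
    fidx = 0
    for rep in range(grid.n_repeats):
        folds = stratified_folds(y, grid.n_folds, _repeat_seed(grid.seed, rep))
        for va_idx in folds:
            tr_mask = np.ones(data.n_samples, dtype=bool)
            tr_mask[va_idx] = False
            Xtr = X[tr_mask]
            ytr = y[tr_mask]
            yva = y[va_idx]
            if yva.min() == yva.max():
                logger.warning("validation fold %d has a single class; AUC undefined", fidx)
                fidx += 1
                continue
            Xtr_s, m, s = _standardize(Xtr)
            Xva_s = (X[va_idx] - m) / s
            ytr = np.ascontiguousarray(ytr)
            prev_betas = prev_b0s = None
            for ik in range(K):
                b0s, betas, flags, _ = _fit_path_std(
                    Xtr_s, ytr, wmat[ik], alpha, lambdas[ik],
                    init_betas=prev_betas, init_b0s=prev_b0s, **skw,
                )
                eta_val = b0s[None, :] + Xva_s @ betas.T
                fold_aucs[ik, :, fidx] = _auc_columns(eta_val, yva)
                prev_betas, prev_b0s = betas, b0s
            fidx += 1

    with np.errstate(invalid="ignore"):
        mean = np.nanmean(fold_aucs, axis=2)
        n_ok = np.sum(~np.isnan(fold_aucs), axis=2)
        sd = np.nanstd(fold_aucs, axis=2, ddof=1)
        se = sd / np.sqrt(np.maximum(n_ok, 1))
    return CVSurface(
        kappas=grid.kappa_values.copy(),
        lambdas=lambdas,
        fold_aucs=fold_aucs,
        mean_auc=mean,
        se_auc=se,
    )


def select_lambda_for_kappa(surface: CVSurface, kappa_index: int):
    """(lambda_max_index, lambda_1se_index) on one ratio's path.

    ``lambda_max`` maximizes the row's mean AUC (ties go to the larger
    lambda); ``lambda_1se`` is the largest lambda whose mean AUC is within
    one standard error of the row maximum.
    """
    row = surface.mean_auc[kappa_index]
    if np.all(np.isnan(row)):
        raise ValueError("all-NaN AUC row; cannot select lambda")
    best = np.nanmax(row)
    # lambdas are decreasing: the first index attaining the max is the largest lambda
    l_max = int(np.flatnonzero(row == best)[0])
    thr = best - surface.se_auc[kappa_index, l_max]
    l_1se = int(np.flatnonzero(row >= thr)[0])
    return l_max, l_1se


def select_kappa_lambda(surface: CVSurface) -> CVSelection:
    """Global argmax of mean AUC with the one-standard-error lambda rule.

    Ties in mean AUC are broken toward the ratio closest to 1, then toward
    the larger lambda.
    """
    mean = surface.mean_auc
    if np.all(np.isnan(mean)):
        raise ValueError("all-NaN CV surface; cannot select tuning parameters")
    best = np.nanmax(mean)
    ik_cand = np.unique(np.nonzero(mean == best)[0])
    ik = int(ik_cand[np.argmin(np.abs(surface.kappas[ik_cand] - 1.0))])
    l_max, l_1se = select_lambda_for_kappa(surface, ik)
    return CVSelection(
        kappa_max=float(surface.kappas[ik]),
        lambda_max=float(surface.lambdas[ik, l_max]),
        lambda_1se=float(surface.lambdas[ik, l_1se]),
        mean_auc=float(mean[ik, l_max]),
        se_auc=float(surface.se_auc[ik, l_max]),
        mean_auc_1se=float(mean[ik, l_1se]),
        kappa_index=ik,
        lambda_max_index=l_max,
        lambda_1se_index=l_1se,
    )
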