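"""Replicate experiments: scenario reproduction, parameter sweeps, user data.

``run_scenario`` follows the simulation protocol: per replicate, draw
paired training and test sets, tune lambda for every penalty ratio kappa
by stratified cross-validated AUC on the training set (with the
one-standard-error parsimony rule), apply each tuned model to the test
set, and aggregate the per-ratio test metrics across replicates.  Because
replicate seeds depend only on the master seed and the replicate index,
all kappa values — and all sweep settings — are compared on common random
numbers.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, replace, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import GroupedDataset, load_dataset
from .evaluate import accuracy, auc, selection_metrics
from .simulate import ScenarioSpec, sample_dataset, scenario_by_name
from .solver import PenaltySpec, _fit_path_std, _standardize
from .tuning import (
    CVSurface,
    TuningGrid,
    cv_auc_surface,
    select_kappa_lambda,
    select_lambda_for_kappa,
)

logger = logging.getLogger(__name__)

__all__ = [
    "ExperimentConfig",
    "ExperimentSummary",
    "run_scenario",
    "run_sweep",
    "fit_user_data",
    "simulation_grid",
    "SWEEP_AXES",
]


def simulation_grid(**overrides) -> TuningGrid:
    """The desk-scale simulation tuning protocol.

    Ratio grid 0.05..1.50 in steps of 0.05, 30-point lambda paths down to
    5% of the entry value, 10-fold CV, and mildly relaxed solver
    tolerances for the fold-level fits (final refits always use the tight
    defaults).  See docs/methods.md for the reasoning behind these sizes.
    """
    kw = dict(n_lambda=30, lambda_min_ratio=0.05, n_folds=10,
              cd_tol=1e-5, kkt_tol=1e-4)
    kw.update(overrides)
    return TuningGrid(**kw)


@dataclass
class ExperimentConfig:
    scenario: ScenarioSpec | str
    n_replicates: int = 200
    grid: TuningGrid = field(default_factory=TuningGrid)
    alpha: float = 0.5
    selection_rule: str = "1se"          # "max" or "1se"
    output_dir: str | None = None
    master_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be at least 1")
        if self.selection_rule not in ("max", "1se"):
            raise ValueError("selection_rule must be 'max' or '1se'")

    def resolved_scenario(self) -> ScenarioSpec:
        if isinstance(self.scenario, str):
            return scenario_by_name(self.scenario)
        return self.scenario


@dataclass
class ExperimentSummary:
    """Per-ratio test metrics aggregated over replicates (paired across kappa)."""

    kappas: np.ndarray                   # (K,)
    test_auc: np.ndarray                 # (n_reps, K) per-replicate test AUC
    test_accuracy: np.ndarray            # (n_reps, K)
    sel_sensitivity: np.ndarray          # (n_reps, K)
    sel_specificity: np.ndarray          # (n_reps, K)
    n_selected: np.ndarray               # (n_reps, K)
    n_failed: int
    config: ExperimentConfig

    @property
    def mean_auc(self) -> np.ndarray:
        return self.test_auc.mean(axis=0)

    @property
    def se_auc(self) -> np.ndarray:
        n = self.test_auc.shape[0]
        return self.test_auc.std(axis=0, ddof=1) / np.sqrt(n)

    @property
    def optimal_kappa(self) -> float:
        """Argmax of the mean test-AUC curve (ties go to the kappa nearest 1)."""
        m = self.mean_auc
        cand = np.flatnonzero(m == m.max())
        return float(self.kappas[cand[np.argmin(np.abs(self.kappas[cand] - 1.0))]])

    def replicate_argmax_kappas(self) -> np.ndarray:
        """Per-replicate AUC-maximizing kappa (ties toward 1)."""
        out = np.empty(self.test_auc.shape[0])
        for i, row in enumerate(self.test_auc):
            cand = np.flatnonzero(row == row.max())
            out[i] = self.kappas[cand[np.argmin(np.abs(self.kappas[cand] - 1.0))]]
        return out

    @property
    def optimal_kappa_replicate_mean(self) -> tuple[float, float]:
        """Mean and SE of the per-replicate argmax kappa (figure-style summary)."""
        k = self.replicate_argmax_kappas()
        return float(k.mean()), float(k.std(ddof=1) / np.sqrt(len(k)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "kappa": self.kappas,
                "mean_test_auc": self.mean_auc,
                "se_test_auc": self.se_auc,
                "mean_accuracy": self.test_accuracy.mean(axis=0),
                "mean_selection_sensitivity": self.sel_sensitivity.mean(axis=0),
                "mean_selection_specificity": self.sel_specificity.mean(axis=0),
                "mean_n_selected": self.n_selected.mean(axis=0),
            }
        )


def _replicate_seeds(master_seed: int, rep: int) -> tuple[int, int, int]:
    """Counter-based child seeds (train draw, test draw, CV folds)."""
    ss = np.random.SeedSequence(entropy=int(master_seed), spawn_key=(int(rep),))
    a, b, c = ss.generate_state(3)
    return int(a % 2**31), int(b % 2**31), int(c % 2**31)


def _tuned_models_per_kappa(
    train: GroupedDataset,
    surface: CVSurface,
    alpha: float,
    selection_rule: str,
    solver_kwargs: dict,
):
    """Refit the full training data at each ratio's selected lambda.

    Returns (intercepts (K,), betas (K, p) on the standardized training
    scale, standardization (mean, scale), selected lambda index per ratio).
    Refits always use the solver's tight default tolerances, independent of
    any relaxation applied to the fold-level fits.
    """
    Xs, m, s = _standardize(train.features)
    y = train.outcome
    K = surface.kappas.size
    p = train.n_features
    b0_sel = np.empty(K)
    beta_sel = np.empty((K, p))
    l_sel = np.empty(K, dtype=int)
    for ik in range(K):
        l_max, l_1se = select_lambda_for_kappa(surface, ik)
        l = l_1se if selection_rule == "1se" else l_max
        w = PenaltySpec.from_kappa(
            train.group_sizes, float(surface.kappas[ik]), alpha, 1.0
        ).penalty_factors
        b0s, betas, flags, _ = _fit_path_std(
            Xs, y, w, alpha, surface.lambdas[ik, : l + 1], **solver_kwargs
        )
        b0_sel[ik] = b0s[-1]
        beta_sel[ik] = betas[-1]
        l_sel[ik] = l
    return b0_sel, beta_sel, (m, s), l_sel


def run_scenario(config: ExperimentConfig) -> ExperimentSummary:
    """Replicate experiment over one scenario; see module docstring."""
    spec = config.resolved_scenario()
    kappas = config.grid.kappa_values
    K = kappas.size
    rows_auc, rows_acc, rows_sens, rows_spec, rows_nsel = [], [], [], [], []
    n_failed = 0
    t0 = time.perf_counter()
    for rep in range(config.n_replicates):
        seed_tr, seed_te, seed_cv = _replicate_seeds(config.master_seed, rep)
        try:
            train = sample_dataset(replace(spec, seed=seed_tr))
            test = sample_dataset(replace(spec, seed=seed_te))
            surface = cv_auc_surface(
                train.data, replace(config.grid, seed=seed_cv), config.alpha
            )
            b0_sel, beta_sel, (m, s), _ = _tuned_models_per_kappa(
                train.data, surface, config.alpha, config.selection_rule, {}
            )
            Xte_s = (test.data.features - m) / s
            eta = b0_sel[None, :] + Xte_s @ beta_sel.T
            proba = expit(eta)
            yte = test.data.outcome
            rows_auc.append([auc(eta[:, ik], yte) for ik in range(K)])
            rows_acc.append([accuracy(proba[:, ik], yte) for ik in range(K)])
            sens_spec = [
                selection_metrics(beta_sel[ik], train.true_support, spec.p)
                for ik in range(K)
            ]
            rows_sens.append([ss[0] for ss in sens_spec])
            rows_spec.append([ss[1] for ss in sens_spec])
            rows_nsel.append([int(np.count_nonzero(beta_sel[ik])) for ik in range(K)])
        except Exception:
            n_failed += 1
            logger.exception("replicate %d failed; excluded", rep)
            if n_failed > 0.1 * config.n_replicates:
                raise RuntimeError(
                    f"more than 10% of replicates failed ({n_failed})"
                )
        if (rep + 1) % 10 == 0:
            logger.info(
                "scenario %s: replicate %d/%d (%.1f s elapsed)",
                spec.name or "custom", rep + 1, config.n_replicates,
                time.perf_counter() - t0,
            )
    summary = ExperimentSummary(
        kappas=kappas.copy(),
        test_auc=np.asarray(rows_auc),
        test_accuracy=np.asarray(rows_acc),
        sel_sensitivity=np.asarray(rows_sens),
        sel_specificity=np.asarray(rows_spec),
        n_selected=np.asarray(rows_nsel),
        n_failed=n_failed,
        config=config,
    )
    if config.output_dir:
        _write_experiment(summary, Path(config.output_dir))
    return summary


SWEEP_AXES = ("beta1", "q2", "total_sparsity", "r", "rho2", "rho12")


def _apply_axis(spec: ScenarioSpec, axis: str, value: float) -> ScenarioSpec:
    if axis == "beta1":
        return replace(spec, beta1=float(value))
    if axis == "q2":
        return replace(spec, q2=int(value))
    if axis == "total_sparsity":
        # value = features per platform; informative counts stay fixed, so
        # larger values mean a smaller informative proportion (q1+q2)/p
        return replace(spec, p1=int(value), p2=int(value))
    if axis == "r":
        return replace(spec, r1=int(value), r2=int(value))
    if axis == "rho2":
        return replace(spec, rho2=float(value))
    if axis == "rho12":
        return replace(spec, rho12=float(value))
    raise ValueError(f"unknown sweep axis {axis!r}; one of {SWEEP_AXES}")


@dataclass
class SweepResult:
    axis: str
    values: np.ndarray
    summaries: list[ExperimentSummary]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for v, s in zip(self.values, self.summaries):
            mean_k, se_k = s.optimal_kappa_replicate_mean
            rows.append(
                {
                    "axis": self.axis,
                    "value": v,
                    "optimal_kappa_mean_curve": s.optimal_kappa,
                    "optimal_kappa_replicate_mean": mean_k,
                    "optimal_kappa_replicate_se": se_k,
                    "max_mean_auc": float(s.mean_auc.max()),
                }
            )
        return pd.DataFrame(rows)


def run_sweep(base: ExperimentConfig, axis: str, values) -> SweepResult:
    """One replicate experiment per axis value, sharing replicate seeds.

    The per-value optimal ratio is reported both as the argmax of the mean
    AUC curve and as the mean of the per-replicate argmax (with its
    standard error, matching the error-cap convention of sweep figures).
    """
    spec = base.resolved_scenario()
    summaries = []
    for v in values:
        cfg = replace(base, scenario=_apply_axis(spec, axis, v), output_dir=None)
        summaries.append(run_scenario(cfg))
    result = SweepResult(axis=axis, values=np.asarray(values, dtype=float), summaries=summaries)
    if base.output_dir:
        out = Path(base.output_dir)
        out.mkdir(parents=True, exist_ok=True)
        result.to_frame().to_csv(out / f"sweep_{axis}.csv", index=False)
    return result


@dataclass
class UserDataReport:
    kappas: np.ndarray
    test_auc: np.ndarray                 # (n_splits, K) per-split, per-ratio
    selected_kappa: np.ndarray           # (n_splits,) jointly selected ratio
    selected_lambda: np.ndarray          # (n_splits,)
    selected_test_auc: np.ndarray        # (n_splits,) AUC of the tuned model
    selection_counts: pd.Series          # feature -> times selected

    @property
    def mean_auc(self) -> np.ndarray:
        return self.test_auc.mean(axis=0)

    def to_frame(self) -> pd.DataFrame:
        n = self.test_auc.shape[0]
        return pd.DataFrame(
            {
                "kappa": self.kappas,
                "mean_test_auc": self.mean_auc,
                "se_test_auc": self.test_auc.std(axis=0, ddof=1) / np.sqrt(n),
            }
        )


def fit_user_data(
    features_csv,
    outcome_csv,
    platform_csv,
    grid: TuningGrid | None = None,
    alpha: float = 0.5,
    n_splits: int = 50,
    test_fraction: float = 0.2,
    master_seed: int = 0,
    selection_rule: str = "1se",
    data: GroupedDataset | None = None,
) -> UserDataReport:
    """Repeated stratified train/test splits with full (kappa, lambda) tuning.

    Per split, a random ``1 - test_fraction`` share of samples (stratified
    by outcome) is used for cross-validated tuning; the jointly selected
    ``(kappa, lambda)`` model and every per-ratio model are then scored on
    the held-out share.  Feature-selection counts across splits identify
    features whose selection depends on differential penalization.  Passing
    ``data`` directly skips file parsing (used for round-trip checks).
    """
    if data is None:
        data = load_dataset(features_csv, outcome_csv, platform_csv)
    if grid is None:
        grid = TuningGrid(n_folds=5, n_repeats=10)
    skw = grid.solver_kwargs()
    y = data.outcome
    K = grid.kappa_values.size
    counts = np.zeros(data.n_features, dtype=int)
    rows_auc, sel_k, sel_l, sel_auc = [], [], [], []
    for split in range(n_splits):
        seed_split, seed_cv, _ = _replicate_seeds(master_seed, split)
        rng = np.random.default_rng(seed_split)
        # stratified shuffle split preserving the class ratio
        te_idx = []
        for cls in (0.0, 1.0):
            idx = np.flatnonzero(y == cls)
            n_te = int(round(test_fraction * idx.size))
            te_idx.append(rng.permutation(idx)[:n_te])
        te_idx = np.sort(np.concatenate(te_idx))
        tr_mask = np.ones(data.n_samples, dtype=bool)
        tr_mask[te_idx] = False
        train = data.subset(np.flatnonzero(tr_mask))
        test = data.subset(te_idx)
        surface = cv_auc_surface(train, replace(grid, seed=seed_cv), alpha)
        b0_sel, beta_sel, (m, s), _ = _tuned_models_per_kappa(
            train, surface, alpha, selection_rule, {}
        )
        Xte_s = (test.features - m) / s
        eta = b0_sel[None, :] + Xte_s @ beta_sel.T
        rows_auc.append([auc(eta[:, ik], test.outcome) for ik in range(K)])
        sel = select_kappa_lambda(surface)
        counts += beta_sel[sel.kappa_index] != 0.0
        sel_k.append(sel.kappa_max)
        l_idx = sel.lambda_1se_index if selection_rule == "1se" else sel.lambda_max_index
        sel_l.append(surface.lambdas[sel.kappa_index, l_idx])
        sel_auc.append(auc(eta[:, sel.kappa_index], test.outcome))
        logger.info("user-data split %d/%d done", split + 1, n_splits)
    return UserDataReport(
        kappas=grid.kappa_values.copy(),
        test_auc=np.asarray(rows_auc),
        selected_kappa=np.asarray(sel_k),
        selected_lambda=np.asarray(sel_l),
        selected_test_auc=np.asarray(sel_auc),
        selection_counts=pd.Series(counts, index=data.feature_ids),
    )


def _write_experiment(summary: ExperimentSummary, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    summary.to_frame().to_csv(out_dir / "summary_by_kappa.csv", index=False)
    n_reps, K = summary.test_auc.shape
    long = pd.DataFrame(
        {
            "replicate": np.repeat(np.arange(n_reps), K),
            "kappa": np.tile(summary.kappas, n_reps),
            "test_auc": summary.test_auc.ravel(),
            "accuracy": summary.test_accuracy.ravel(),
            "selection_sensitivity": summary.sel_sensitivity.ravel(),
            "selection_specificity": summary.sel_specificity.ravel(),
            "n_selected": summary.n_selected.ravel(),
        }
    )
    long.to_csv(out_dir / "replicates.csv", index=False)
    spec = summary.config.resolved_scenario()
    manifest = {
        "scenario": asdict(spec),
        "n_replicates": summary.config.n_replicates,
        "master_seed": summary.config.master_seed,
        "alpha": summary.config.alpha,
        "selection_rule": summary.config.selection_rule,
        "kappa_grid": summary.kappas.tolist(),
        "n_lambda": summary.config.grid.n_lambda,
        "lambda_min_ratio": summary.config.grid.lambda_min_ratio,
        "n_folds": summary.config.grid.n_folds,
        "n_repeats": summary.config.grid.n_repeats,
        "optimal_kappa": summary.optimal_kappa,
        "n_failed": summary.n_failed,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
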