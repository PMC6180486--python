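"""Predictive and feature-selection metrics.

AUC is computed as the Mann-Whitney statistic — the probability that a
random positive sample outscores a random negative one, with ties counted
one half — via midranks, which is exactly equivalent to the brute-force
average over all positive-negative pairs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = ["EvalReport", "auc", "accuracy", "selection_metrics", "evaluate_fit"]


@dataclass
class EvalReport:
    test_auc: float
    accuracy: float
    selection_sensitivity: float
    selection_specificity: float
    n_selected: int


def auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formula."""
    scores = np.asarray(scores, dtype=np.float64).ravel()
    labels = np.asarray(labels).ravel()
    pos = labels == 1
    n1 = int(pos.sum())
    n0 = labels.shape[0] - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC is undefined when only one class is present")
    ranks = rankdata(scores)  # midranks handle ties as 1/2
    return float((ranks[pos].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


def accuracy(probabilities: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of samples whose thresholded probability matches the label.

    The boundary case ``probability == threshold`` is classified positive.
    """
    probabilities = np.asarray(probabilities, dtype=np.float64).ravel()
    if np.any((probabilities < 0) | (probabilities > 1)):
        raise ValueError("probabilities must lie in [0, 1]")
    labels = np.asarray(labels).ravel()
    pred = (probabilities >= threshold).astype(labels.dtype)
    return float(np.mean(pred == labels))


def selection_metrics(coefficients: np.ndarray, true_support: np.ndarray, p: int):
    """Sensitivity and specificity of support recovery.

    A feature counts as selected iff its fitted coefficient is exactly
    nonzero (coordinate descent produces exact zeros).  Sensitivity is the
    fraction of truly informative features selected; specificity the
    fraction of null features left out.
    """
    coefficients = np.asarray(coefficients).ravel()
    if coefficients.shape[0] != p:
        raise ValueError("coefficient length does not match p")
    support = np.zeros(p, dtype=bool)
    support[np.asarray(true_support, dtype=int)] = True
    selected = coefficients != 0.0
    q = int(support.sum())
    sens = float((selected & support).sum() / q) if q else np.nan
    n_null = p - q
    spec = float((~selected & ~support).sum() / n_null) if n_null else np.nan
    return sens, spec


def evaluate_fit(
    coefficients: np.ndarray,
    scores: np.ndarray,
    probabilities: np.ndarray,
    labels: np.ndarray,
    true_support: np.ndarray,
    threshold: float = 0.5,
) -> EvalReport:
    """Bundle test-set prediction metrics with selection quality."""
    sens, spec = selection_metrics(coefficients, true_support, len(coefficients))
    return EvalReport(
        test_auc=auc(scores, labels),
        accuracy=accuracy(probabilities, labels, threshold),
        selection_sensitivity=sens,
        selection_specificity=spec,
        n_selected=int(np.count_nonzero(coefficients)),
    )
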