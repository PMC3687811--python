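"""Test-set performance measures and variable-selection accounting.

Class-imbalanced evaluation centres on the class-specific predictive
accuracies PA_k and their geometric mean (g-means), which weighs every class
equally and is zero as soon as one class is never predicted correctly.  For
two classes the AUC of the continuous discriminant-difference score is also
reported.  When the identity of the truly informative variables is known
(simulations), the active set is audited via FDR (fraction of active
variables that are non-informative) and FNR (fraction of informative
variables left inactive).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

from .classify import PriorSpec, predicted_labels, two_class_score
from .core import ExpressionData
from .shrinkage import ShrunkenModel

__all__ = ["EvaluationReport", "evaluate", "gmeans", "rank_auc",
           "per_class_accuracy", "overall_error"]


@dataclass
class EvaluationReport:
    per_class_pa: np.ndarray        # (K,)
    overall_pa: float               # weighted by test-set class fractions
    gmeans: float
    auc: float | None               # None unless K == 2
    n_active: int
    n_active_informative: int | None = None
    n_active_noninformative: int | None = None
    fdr: float | None = None
    fnr: float | None = None


def gmeans(pa: np.ndarray) -> float:
    """Geometric mean of the class-specific accuracies; 0 if any PA_k is 0."""
    pa = np.asarray(pa, dtype=float)
    if np.any(pa < 0) or np.any(pa > 1):
        raise ValueError("accuracies must lie in [0, 1]")
    if np.any(pa == 0.0):
        return 0.0
    return float(np.exp(np.mean(np.log(pa))))


def per_class_accuracy(true_labels: np.ndarray, pred_labels: np.ndarray,
                       n_classes: int) -> np.ndarray:
    """PA_k: fraction of class-k samples predicted as class k."""
    true_labels = np.asarray(true_labels)
    pred_labels = np.asarray(pred_labels)
    pa = np.empty(n_classes)
    for k in range(1, n_classes + 1):
        mask = true_labels == k
        if not np.any(mask):
            raise ValueError(f"class {k} absent from the test set")
        pa[k - 1] = np.mean(pred_labels[mask] == k)
    return pa


def overall_error(true_labels: np.ndarray, pred_labels: np.ndarray) -> float:
    """Pooled misclassification rate (empirically weighted overall error)."""
    true_labels = np.asarray(true_labels)
    return float(np.mean(np.asarray(pred_labels) != true_labels))


def rank_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC of a score for class 2 vs class 1, half credit for ties.

    ``labels`` are 1/2; larger scores are taken as more class-2-like.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = labels == 2
    n2 = int(pos.sum())
    n1 = scores.size - n2
    if n1 == 0 or n2 == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(scores)            # average ranks handle ties at 1/2
    u = ranks[pos].sum() - n2 * (n2 + 1) / 2.0
    return float(u / (n1 * n2))


def evaluate(model: ShrunkenModel, test_data: ExpressionData,
             truth_informative: np.ndarray | None = None,
             priors: PriorSpec | None = None,
             seed: int | np.random.Generator = 0) -> EvaluationReport:
    """Score a fitted model on labeled test data.

    FDR / FNR are computed only when ``truth_informative`` (boolean mask of
    truly informative variables) is supplied; FDR is defined as 0 when no
    variable is active.
    """
    K = model.d_hat.shape[0]
    pred = predicted_labels(model, test_data.values, priors=priors,
                            rng_seed=seed)
    pa = per_class_accuracy(test_data.labels, pred, K)
    weights = test_data.class_counts / test_data.n_samples
    report = EvaluationReport(
        per_class_pa=pa,
        overall_pa=float((pa * weights).sum()),
        gmeans=gmeans(pa),
        auc=None,
        n_active=model.n_active,
    )
    if K == 2:
        scores = two_class_score(model, test_data.values)
        report.auc = rank_auc(scores, test_data.labels)
    if truth_informative is not None:
        truth = np.asarray(truth_informative, dtype=bool)
        active = model.active
        n_act = int(active.sum())
        n_info_act = int((active & truth).sum())
        n_noninfo_act = n_act - n_info_act
        n_info = int(truth.sum())
        report.n_active_informative = n_info_act
        report.n_active_noninformative = n_noninfo_act
        report.fdr = (n_noninfo_act / n_act) if n_act > 0 else 0.0
        report.fnr = ((n_info - n_info_act) / n_info) if n_info > 0 else 0.0
    return report
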