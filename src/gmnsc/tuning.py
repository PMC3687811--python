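"""Cross-validated threshold selection for the NSC classifiers.

The shrinkage threshold is chosen on a grid of T values spanning
[0, lambda_max] by stratified K-fold cross-validation.  Two selection rules
are supported:

* ``min_error`` — the conventional rule: minimize the pooled CV
  misclassification rate.  On imbalanced data this favours tiny thresholds
  and classifiers biased toward the majority class.
* ``max_gmeans`` — the GM rule: maximize the pooled CV geometric mean of the
  class-specific accuracies, which weighs all classes equally.

Held-out predictions are pooled over folds before computing the per-class
accuracies (micro aggregation); ties on the criterion are broken toward the
largest threshold (fewest active variables).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.model_selection import StratifiedKFold

from .classify import PriorSpec, predicted_labels
from .core import CentroidStatistics, ExpressionData, compute_statistics
from .metrics import gmeans, overall_error, per_class_accuracy
from .shrinkage import ShrunkenModel, adaptive_weights, lambda_max, shrink

__all__ = ["ThresholdGrid", "TuningResult", "make_grid", "cross_validate",
           "select_threshold", "fit"]

CRITERIA = ("min_error", "max_gmeans")


@dataclass
class ThresholdGrid:
    values: np.ndarray      # (T,) strictly increasing, 0 ... lambda_max
    spacing: str = "linear"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size >= 2 and not np.all(np.diff(self.values) > 0):
            raise ValueError("grid values must be strictly increasing")

    @property
    def T(self) -> int:
        return self.values.size


@dataclass
class TuningResult:
    grid: ThresholdGrid
    cv_error: np.ndarray          # (T,) pooled CV misclassification rate
    cv_pa: np.ndarray             # (T, K) pooled per-class CV accuracies
    cv_gmeans: np.ndarray         # (T,)
    mean_active: np.ndarray       # (T,) mean active count over folds
    folds: int = 0
    fold_seed: int = 0
    criterion: str | None = None
    selected_threshold: float | None = None


def make_grid(stats: CentroidStatistics, method: str, T: int = 30,
              spacing: str = "linear",
              weights: dict | None = None) -> ThresholdGrid:
    """Threshold grid of T values from 0 to lambda_max for the given method.

    ``linear`` spacing is the default; ``log`` prepends 0 to a geometric
    sequence over [lambda_max * 1e-3, lambda_max], which places more
    thresholds near the many-active-variables end.
    """
    if T < 2:
        raise ValueError("grid needs at least 2 thresholds")
    lmax = lambda_max(stats, method, weights=weights)
    if lmax == 0.0:
        warnings.warn("lambda_max is 0 (all d_kj zero); degenerate grid")
        return ThresholdGrid(values=np.zeros(1), spacing=spacing)
    if spacing == "linear":
        values = np.linspace(0.0, lmax, T)
    elif spacing == "log":
        values = np.concatenate(
            [[0.0], np.geomspace(lmax * 1e-3, lmax, T - 1)])
    else:
        raise ValueError(f"unknown spacing {spacing!r}")
    return ThresholdGrid(values=values, spacing=spacing)


def _fold_assignments(labels: np.ndarray, folds: int, fold_seed: int):
    """Stratified fold index lists; reduces fold count if a class is small.

    ``folds == n`` requests leave-one-out CV (no stratification involved);
    it needs at least 3 samples per class so every training fold keeps 2.
    """
    n = labels.size
    if folds == n:
        all_idx = np.arange(n)
        return n, [(np.delete(all_idx, i), np.array([i])) for i in range(n)]
    counts = np.bincount(labels)[1:]
    min_count = int(counts[counts > 0].min())
    if min_count < folds:
        warnings.warn(
            f"smallest class has {min_count} samples; reducing folds "
            f"from {folds} to {min_count}")
        folds = min_count
    if folds < 2:
        raise ValueError("cannot stratify with fewer than 2 folds")
    skf = StratifiedKFold(n_splits=folds, shuffle=True,
                          random_state=fold_seed)
    dummy = np.zeros(labels.size)
    return folds, list(skf.split(dummy[:, None], labels))


def cross_validate(data: ExpressionData, method: str, grid: ThresholdGrid,
                   folds: int = 10, fold_seed: int = 0,
                   priors: PriorSpec | None = None,
                   tie_seed: int = 0) -> TuningResult:
    """Pooled cross-validated performance at every grid threshold.

    Per fold, statistics and adaptive weights are recomputed on the training
    portion and the held-out samples are scored at every threshold; the
    held-out predictions are pooled across folds before computing the error,
    per-class accuracies and g-means per threshold.
    """
    if priors is None:
        priors = PriorSpec()
    K = data.n_classes
    T = grid.T
    folds, splits = _fold_assignments(data.labels, folds, fold_seed)
    pred = np.zeros((T, data.n_samples), dtype=int)
    active_counts = np.zeros((T, len(splits)))
    for f, (train_idx, test_idx) in enumerate(splits):
        train = data.subset_samples(train_idx)
        if len(np.unique(train.labels)) != K:
            raise ValueError(f"fold {f}: a class is absent from training data")
        stats = compute_statistics(train)
        w = adaptive_weights(stats) if method != "pam" else None
        X_test = data.values[:, test_idx]
        for t, lam in enumerate(grid.values):
            model = shrink(stats, method, lam, weights=w)
            active_counts[t, f] = model.n_active
            # independent tie-break stream per (fold, threshold) so that
            # tie-rich thresholds do not perturb the others
            rng_ft = np.random.default_rng([tie_seed, f, t])
            pred[t, test_idx] = predicted_labels(model, X_test,
                                                 priors=priors,
                                                 rng_seed=rng_ft)
    cv_error = np.empty(T)
    cv_pa = np.empty((T, K))
    cv_gm = np.empty(T)
    for t in range(T):
        cv_error[t] = overall_error(data.labels, pred[t])
        cv_pa[t] = per_class_accuracy(data.labels, pred[t], K)
        cv_gm[t] = gmeans(cv_pa[t])
    return TuningResult(grid=grid, cv_error=cv_error, cv_pa=cv_pa,
                        cv_gmeans=cv_gm, mean_active=active_counts.mean(axis=1),
                        folds=folds, fold_seed=fold_seed)


def select_threshold(result: TuningResult, criterion: str) -> float:
    """Apply the selection rule; ties go to the largest threshold."""
    if criterion == "min_error":
        score = -result.cv_error
    elif criterion == "max_gmeans":
        score = result.cv_gmeans
    else:
        raise ValueError(f"unknown criterion {criterion!r}; "
                         f"expected one of {CRITERIA}")
    best = score.max()
    idx = int(np.flatnonzero(score == best)[-1])
    return float(result.grid.values[idx])


def fit(data: ExpressionData, method: str = "pam",
        criterion: str = "max_gmeans", T: int = 30, folds: int = 10,
        fold_seed: int = 0, tie_seed: int = 0,
        priors: PriorSpec | None = None, spacing: str = "linear",
        cv_result: TuningResult | None = None
        ) -> tuple[ShrunkenModel, TuningResult]:
    """End-to-end training: grid, CV, threshold selection, full-data refit.

    ``method`` in {"pam", "alp", "ahp"} crossed with ``criterion``
    "max_gmeans" gives the GM variants (GM-PAM etc.); "min_error" gives the
    conventional classifiers.  A precomputed ``cv_result`` (from
    :func:`cross_validate` on the same data/method) can be reused to fit
    both criteria without repeating the cross-validation.
    """
    stats = compute_statistics(data)
    weights = adaptive_weights(stats) if method != "pam" else None
    if cv_result is None:
        grid = make_grid(stats, method, T=T, spacing=spacing, weights=weights)
        cv_result = cross_validate(data, method, grid, folds=folds,
                                   fold_seed=fold_seed, priors=priors,
                                   tie_seed=tie_seed)
    lam = select_threshold(cv_result, criterion)
    result = TuningResult(grid=cv_result.grid, cv_error=cv_result.cv_error,
                          cv_pa=cv_result.cv_pa, cv_gmeans=cv_result.cv_gmeans,
                          mean_active=cv_result.mean_active,
                          folds=cv_result.folds, fold_seed=cv_result.fold_seed,
                          criterion=criterion, selected_threshold=lam)
    model = shrink(stats, method, lam, weights=weights)
    return model, result
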