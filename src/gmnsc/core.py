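"""Sufficient statistics of the nearest-shrunken-centroid (NSC) family.

The NSC classifiers (PAM and its adaptive variants) operate on a small set of
per-variable statistics computed from a labeled expression matrix: class
centroids, the overall centroid, pooled within-class standard deviations and
the standardized centroid differences

    d_kj = (xbar_kj - xbar_j) / (m_k * (s_j + s0)),

where m_k = sqrt(1/n_k - 1/n) and s0 is a fudge constant set to the median of
the pooled standard deviations.  All shrinkage penalties act on d_kj; the
shrunken centroids are recovered by inverting the standardization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["ExpressionData", "CentroidStatistics", "compute_statistics",
           "shrunken_centroids"]


@dataclass
class ExpressionData:
    """A variables-by-samples expression matrix with integer class labels.

    Parameters
    ----------
    values : ndarray of shape (p, n)
        Expression values, variables in rows, samples in columns.
    variable_ids : list of str
        Unique identifiers for the p variables.
    sample_ids : list of str
        Identifiers for the n samples.
    labels : ndarray of shape (n,)
        Integer class label per sample, coded 1..K with every class present.
    """

    values: np.ndarray
    variable_ids: list[str]
    sample_ids: list[str]
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D (variables x samples) array")
        p, n = self.values.shape
        if p < 1:
            raise ValueError("need at least one variable")
        if len(self.variable_ids) != p:
            raise ValueError(f"{len(self.variable_ids)} variable_ids for {p} rows")
        if len(self.sample_ids) != n:
            raise ValueError(f"{len(self.sample_ids)} sample_ids for {n} columns")
        if len(set(self.variable_ids)) != p:
            raise ValueError("variable_ids are not unique")
        if self.labels.shape != (n,):
            raise ValueError("labels must have one entry per sample")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("values contain non-finite entries")
        k = self.labels.max(initial=0)
        if k < 2:
            raise ValueError("need at least two classes")
        present = np.unique(self.labels)
        expected = np.arange(1, k + 1)
        if not np.array_equal(present, expected):
            missing = sorted(set(expected) - set(present))
            raise ValueError(f"labels must cover 1..{k}; missing classes {missing}")
        if n < k:
            raise ValueError("fewer samples than classes")

    @property
    def n_variables(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    @property
    def n_classes(self) -> int:
        return int(self.labels.max())

    @property
    def class_counts(self) -> np.ndarray:
        """Number of samples per class, indexed 0..K-1 for classes 1..K."""
        return np.bincount(self.labels, minlength=self.n_classes + 1)[1:]

    def subset_samples(self, idx: np.ndarray) -> "ExpressionData":
        """A new dataset restricted to the given sample indices.

        Labels are kept as-is, so the index set must leave every class
        represented (enforced by the constructor).
        """
        idx = np.asarray(idx)
        return ExpressionData(
            values=self.values[:, idx],
            variable_ids=list(self.variable_ids),
            sample_ids=[self.sample_ids[i] for i in idx],
            labels=self.labels[idx],
        )


@dataclass
class CentroidStatistics:
    """Per-variable statistics underlying all NSC shrinkage rules.

    Arrays indexed by (class, variable) use 0-based class index for class k+1.
    """

    class_centroids: np.ndarray   # (K, p)  xbar_kj
    overall_centroid: np.ndarray  # (p,)    xbar_j
    pooled_sd: np.ndarray         # (p,)    s_j, divisor n - K
    s0: float                     # median of pooled_sd
    m: np.ndarray                 # (K,)    sqrt(1/n_k - 1/n)
    d: np.ndarray                 # (K, p)  standardized differences
    class_counts: np.ndarray = field(default=None)  # (K,)
    n: int = 0

    @property
    def n_classes(self) -> int:
        return self.class_centroids.shape[0]

    @property
    def n_variables(self) -> int:
        return self.class_centroids.shape[1]

    @property
    def scale(self) -> np.ndarray:
        """s_j + s0, the denominator of the standardized distances."""
        return self.pooled_sd + self.s0


def compute_statistics(data: ExpressionData) -> CentroidStatistics:
    """Compute centroids, pooled SDs and standardized differences d_kj.

    The pooled within-class variance uses divisor ``n - K``; s0 is the median
    of the pooled SDs over all variables (zero-variance variables included).

    Raises
    ------
    ValueError
        If any class has fewer than two samples (no within-class residuals),
        or if the matrix is constant so that every s_j and s0 are zero.
    """
    X = data.values
    p, n = X.shape
    K = data.n_classes
    counts = data.class_counts
    for k in range(K):
        if counts[k] < 2:
            raise ValueError(
                f"class {k + 1} has {counts[k]} sample(s); "
                "at least 2 per class are required for the pooled SD")

    centroids = np.empty((K, p))
    ss_within = np.zeros(p)
    for k in range(K):
        cols = X[:, data.labels == k + 1]
        centroids[k] = cols.mean(axis=1)
        ss_within += ((cols - centroids[k][:, None]) ** 2).sum(axis=1)
    pooled_sd = np.sqrt(ss_within / (n - K))
    s0 = float(np.median(pooled_sd))
    overall = X.mean(axis=1)

    scale = pooled_sd + s0
    if np.any(scale == 0.0):
        raise ValueError(
            "zero pooled SD with zero s0: standardized differences undefined "
            "(is the matrix constant?)")

    m = np.sqrt(1.0 / counts - 1.0 / n)
    d = (centroids - overall[None, :]) / (m[:, None] * scale[None, :])
    return CentroidStatistics(
        class_centroids=centroids,
        overall_centroid=overall,
        pooled_sd=pooled_sd,
        s0=s0,
        m=m,
        d=d,
        class_counts=counts,
        n=n,
    )


def shrunken_centroids(stats: CentroidStatistics, d_hat: np.ndarray) -> np.ndarray:
    """Map shrunken differences back to centroids.

    Returns ``xbar_j + d_hat_kj * m_k * (s_j + s0)`` as a (K, p) array.
    """
    d_hat = np.asarray(d_hat, dtype=float)
    if d_hat.shape != stats.d.shape:
        raise ValueError(
            f"d_hat has shape {d_hat.shape}, expected {stats.d.shape}")
    return (stats.overall_centroid[None, :]
            + d_hat * stats.m[:, None] * stats.scale[None, :])
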