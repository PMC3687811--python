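"""Monte-Carlo experiments on block-correlated Gaussian expression data.

The generator draws p-variable samples from a multivariate normal with a
block-exchangeable correlation structure: variables are partitioned into
blocks (default 100 per block) with pairwise correlation rho within a block
(default 0.8), independence across blocks and unit variances.  Class
structure enters only through mean shifts on a leading set of informative
variables.  Exchangeable blocks are sampled exactly as
``sqrt(rho) * z_block + sqrt(1 - rho) * z_indep``.

Experiments pair an imbalanced training set with a large balanced test set,
fit the NSC / GM-NSC classifiers per replicate and aggregate the evaluation
reports across replicates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .classify import PriorSpec
from .core import ExpressionData, compute_statistics
from .metrics import evaluate
from .shrinkage import adaptive_weights
from .tuning import cross_validate, fit, make_grid

__all__ = ["SimulationScenario", "two_class_scenario", "three_class_scenario",
           "generate", "oversample_minority", "run_experiment",
           "RESULT_COLUMNS"]


@dataclass
class SimulationScenario:
    """Full parameterization of one Monte-Carlo experiment."""

    p: int
    block_size: int
    rho: float
    class_means: np.ndarray          # (K, p)
    class_sizes: np.ndarray          # (K,) training samples per class
    test_size: int
    test_balanced: bool = True
    n_replicates: int = 50
    base_seed: int = 0
    oversample: bool = False

    def __post_init__(self) -> None:
        self.class_means = np.asarray(self.class_means, dtype=float)
        self.class_sizes = np.asarray(self.class_sizes, dtype=int)
        if not (0.0 <= self.rho < 1.0):
            raise ValueError(f"rho must be in [0, 1), got {self.rho}")
        if self.class_means.shape[1] != self.p:
            raise ValueError("class_means must have p columns")

    @property
    def n_classes(self) -> int:
        return self.class_means.shape[0]

    @property
    def truth_informative(self) -> np.ndarray:
        """Variables whose class means are not all equal."""
        return np.any(self.class_means != self.class_means[0][None, :], axis=0)


def two_class_scenario(k1: float = 0.9, mu2: float = 1.0, p: int = 10_000,
                       n_informative: int = 100, n_train: int = 100,
                       test_size: int = 1000, rho: float = 0.8,
                       block_size: int = 100, n_replicates: int = 50,
                       base_seed: int = 0,
                       oversample: bool = False) -> SimulationScenario:
    """Two-class design: class 1 at mean 0, class 2 shifted by mu2 on the
    first ``n_informative`` variables; training split k1 / (1 - k1)."""
    means = np.zeros((2, p))
    means[1, :n_informative] = mu2
    n1 = int(round(k1 * n_train))
    sizes = np.array([n1, n_train - n1])
    return SimulationScenario(p=p, block_size=block_size, rho=rho,
                              class_means=means, class_sizes=sizes,
                              test_size=test_size, n_replicates=n_replicates,
                              base_seed=base_seed, oversample=oversample)


def three_class_scenario(p: int = 5000, n_informative: int = 100,
                         mu: float = 1.0,
                         class_sizes: tuple = (100, 20, 100),
                         test_size: int = 1500, rho: float = 0.8,
                         block_size: int = 100, n_replicates: int = 50,
                         base_seed: int = 0) -> SimulationScenario:
    """Three-class design with the minority class nested between the outer
    classes: mu_1 = -mu_3 = mu and mu_2 = 0 on the informative variables."""
    means = np.zeros((3, p))
    means[0, :n_informative] = mu
    means[2, :n_informative] = -mu
    return SimulationScenario(p=p, block_size=block_size, rho=rho,
                              class_means=means,
                              class_sizes=np.asarray(class_sizes),
                              test_size=test_size, n_replicates=n_replicates,
                              base_seed=base_seed)


def _block_noise(rng: np.random.Generator, p: int, n: int,
                 block_size: int, rho: float) -> np.ndarray:
    """(p, n) draws with exchangeable correlation rho inside each block."""
    z = rng.standard_normal((p, n))
    if rho == 0.0:
        return z
    out = np.empty((p, n))
    sr, si = np.sqrt(rho), np.sqrt(1.0 - rho)
    for start in range(0, p, block_size):
        stop = min(start + block_size, p)
        shared = rng.standard_normal(n)
        out[start:stop] = sr * shared[None, :] + si * z[start:stop]
    return out


def _draw(rng: np.random.Generator, scenario: SimulationScenario,
          sizes: np.ndarray, tag: str) -> ExpressionData:
    n = int(sizes.sum())
    labels = np.repeat(np.arange(1, scenario.n_classes + 1), sizes)
    X = _block_noise(rng, scenario.p, n, scenario.block_size, scenario.rho)
    X += scenario.class_means.T[:, labels - 1]
    return ExpressionData(
        values=X,
        variable_ids=[f"v{j}" for j in range(scenario.p)],
        sample_ids=[f"{tag}{i}" for i in range(n)],
        labels=labels,
    )


def replicate_seeds(scenario: SimulationScenario, replicate_index: int):
    """Deterministic per-replicate seed bundle.

    Seeds are derived from ``SeedSequence([base_seed, replicate_index])`` so
    replicates are mutually independent and individually re-runnable.
    """
    ss = np.random.SeedSequence([scenario.base_seed, replicate_index])
    train_ss, test_ss, aux = ss.spawn(3)
    fold_seed, tie_seed, eval_seed, over_seed = (
        int(s) for s in aux.generate_state(4) >> 1)  # keep below 2**31
    return {
        "train": train_ss, "test": test_ss,
        "fold_seed": fold_seed, "tie_seed": tie_seed,
        "eval_seed": eval_seed, "oversample_seed": over_seed,
    }


def generate(scenario: SimulationScenario, replicate_index: int):
    """One replicate: (train, test, truth_informative)."""
    seeds = replicate_seeds(scenario, replicate_index)
    train = _draw(np.random.default_rng(seeds["train"]), scenario,
                  scenario.class_sizes, tag="tr")
    K = scenario.n_classes
    if scenario.test_balanced:
        per = scenario.test_size // K
        test_sizes = np.full(K, per)
        test_sizes[:scenario.test_size - per * K] += 1
    else:
        frac = scenario.class_sizes / scenario.class_sizes.sum()
        test_sizes = np.round(frac * scenario.test_size).astype(int)
    test = _draw(np.random.default_rng(seeds["test"]), scenario,
                 test_sizes, tag="te")
    return train, test, scenario.truth_informative


def oversample_minority(train: ExpressionData,
                        seed: int | np.random.Generator = 0) -> ExpressionData:
    """Balance a two-class training set by replicating random minority samples.

    Appends ``max(n1, n2) - min(n1, n2)`` copies drawn uniformly with
    replacement from the minority class; returns the input unchanged when the
    classes are already balanced.
    """
    if train.n_classes != 2:
        raise ValueError("oversampling is defined for two classes")
    counts = train.class_counts
    if counts[0] == counts[1]:
        return train
    minority = 2 if counts[0] > counts[1] else 1
    n_extra = int(abs(counts[0] - counts[1]))
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    pool = np.flatnonzero(train.labels == minority)
    picks = rng.choice(pool, size=n_extra, replace=True)
    values = np.concatenate([train.values, train.values[:, picks]], axis=1)
    labels = np.concatenate([train.labels, train.labels[picks]])
    sample_ids = list(train.sample_ids) + [
        f"{train.sample_ids[i]}_copy{c}" for c, i in enumerate(picks)]
    return ExpressionData(values=values, variable_ids=list(train.variable_ids),
                          sample_ids=sample_ids, labels=labels)


RESULT_COLUMNS = ["method", "criterion", "replicate", "lambda_star",
                  "n_active", "n_active_informative", "pct_informative_active",
                  "n_active_noninformative", "pct_noninformative_active",
                  "fdr", "fnr"]


def run_experiment(scenario: SimulationScenario,
                   methods: list[str] = ("pam",),
                   criteria: list[str] = ("min_error", "max_gmeans"),
                   folds: int = 10, T: int = 30, spacing: str = "linear",
                   priors: PriorSpec | None = None,
                   n_replicates: int | None = None,
                   progress: bool = False):
    """Run the full Monte-Carlo experiment.

    Per replicate and method the cross-validation is run once and both
    selection criteria are applied to it (they share the CV predictions).
    Returns ``(summary, replicates)`` DataFrames: per-replicate rows and the
    across-replicate mean / SD / SE per method x criterion, with the column
    layout of the simulation tables (threshold, active-variable accounting,
    per-class accuracies, g-means, AUC).
    """
    if priors is None:
        priors = PriorSpec()
    n_rep = scenario.n_replicates if n_replicates is None else n_replicates
    K = scenario.n_classes
    rows = []
    failures = []
    for r in range(n_rep):
        seeds = replicate_seeds(scenario, r)
        train, test, truth = generate(scenario, r)
        if scenario.oversample:
            train = oversample_minority(train, seeds["oversample_seed"])
        for method in methods:
            try:
                cv = cross_validate(train, method,
                                    _grid_for(train, method, T, spacing),
                                    folds=folds, fold_seed=seeds["fold_seed"],
                                    priors=priors, tie_seed=seeds["tie_seed"])
                for criterion in criteria:
                    model, result = fit(train, method, criterion,
                                        priors=priors, cv_result=cv)
                    rep = evaluate(model, test, truth_informative=truth,
                                   priors=priors, seed=seeds["eval_seed"])
                    row = {
                        "method": method, "criterion": criterion,
                        "replicate": r,
                        "lambda_star": result.selected_threshold,
                        "n_active": rep.n_active,
                        "n_active_informative": rep.n_active_informative,
                        "pct_informative_active":
                            100.0 * rep.n_active_informative
                            / max(int(truth.sum()), 1),
                        "n_active_noninformative": rep.n_active_noninformative,
                        "pct_noninformative_active":
                            100.0 * rep.n_active_noninformative
                            / max(int((~truth).sum()), 1),
                        "fdr": rep.fdr, "fnr": rep.fnr,
                    }
                    for k in range(K):
                        row[f"pa_{k + 1}"] = rep.per_class_pa[k]
                    row["gmeans"] = rep.gmeans
                    row["auc"] = rep.auc if rep.auc is not None else np.nan
                    rows.append(row)
            except Exception as exc:  # record, do not silently drop
                failures.append({"replicate": r, "method": method,
                                 "error": repr(exc)})
        if progress:
            print(f"replicate {r + 1}/{n_rep} done", flush=True)
    replicates = pd.DataFrame(rows)
    if failures:
        import warnings
        warnings.warn(f"{len(failures)} replicate fits failed: {failures[:3]}")
    value_cols = [c for c in replicates.columns
                  if c not in ("method", "criterion", "replicate")]
    grouped = replicates.groupby(["method", "criterion"])[value_cols]
    summary = grouped.mean().add_suffix("_mean")
    sd = grouped.std(ddof=1).add_suffix("_sd")
    se = (grouped.std(ddof=1) / np.sqrt(grouped.count())).add_suffix("_se")
    summary = pd.concat([summary, sd, se], axis=1).reset_index()
    summary["n_replicates"] = grouped.size().values
    return summary, replicates


def _grid_for(train: ExpressionData, method: str, T: int, spacing: str):
    stats = compute_statistics(train)
    weights = adaptive_weights(stats) if method != "pam" else None
    return make_grid(stats, method, T=T, spacing=spacing, weights=weights)
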