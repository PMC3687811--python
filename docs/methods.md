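# Methods

## Model and statistics

All classifiers in this package are nearest-shrunken-centroid (NSC)
methods.  The sufficient statistics of a labeled expression matrix
(p variables × n samples, K classes with n_k samples each) are the class
centroids x̄_kj, the overall centroid x̄_j (the count-weighted mean, so
Σ_k (n_k/n) x̄_kj = x̄_j), the pooled within-class standard deviation s_j
(divisor n − K), the fudge constant s₀ = median_j(s_j) taken over all p
variables including any with zero variance, and the standardized
differences

    d_kj = (x̄_kj − x̄_j) / (m_k (s_j + s₀)),   m_k = sqrt(1/n_k − 1/n).

m_k is read as the square root of 1/n_k − 1/n, which makes the denominator
the standard error of the centroid difference and d_kj a standardized mean
difference.  Classification uses the distance-to-shrunken-centroid score
δ_k(x*) = Σ_j (x*_j − x̄'_kj)²/(s_j + s₀)² − 2 log(π_k).  Equal priors
(π_k = 1/K) are the default: with empirical priors and mostly-inactive
variables the −2 log(π_k) term dominates and forces every assignment to
the majority class, which is precisely the imbalance pathology the package
is designed to avoid.  Score ties within a relative tolerance of 1e−12 are
broken uniformly at random; ties occur systematically under complete
shrinkage (all δ_k identical) and the tolerance keeps near-ties caused by
floating-point summation order from flipping deterministically.

## Shrinkage penalties

Each method solves, independently per variable j, a penalized
least-squares problem in v ≈ d_·j:

* **PAM**: L1 penalty λ Σ_k |v_k|; closed form
  d̂_kj = sgn(d_kj)(|d_kj| − λ)₊.
* **ALP**: adaptive L∞ penalty λ w_j max_k |v_k|.  The solution clips each
  |d_kj| at a cap c_j solving Σ_{|d_kj|>c}(|d_kj| − c) = λ w_j, with
  c_j = 0 (variable inactive) exactly when Σ_k |d_kj| ≤ λ w_j.  The cap is
  computed in closed form from the sorted absolute values (vectorized over
  variables); a relative guard of 1e−12 on the all-zero condition makes
  the cap exactly zero at the λ_max boundary despite rounding.
* **AHP**: hierarchical penalty on the factorization v_k = γ θ_k with
  γ ≥ 0: ½ Σ_k (γθ_k − d_kj)² + λ_γ w_jᵞ γ + λ_θ Σ_k w_kjᶿ |θ_k|.
  Minimized by alternating exact updates — θ-step: per-component soft
  threshold θ_k = sgn(d)(γ|d| − λ_θ w)₊/γ²; γ-step: nonnegative 1-D least
  squares γ = max((Σθ_k d_kj − λ_γ w_jᵞ)/Σθ_k², 0) — started from
  several γ initializations (scales 1, ¼ and 4 of max_k |d_kj|).  Only
  the product γθ is returned, so the scale ambiguity of the factorization
  is immaterial.  The objective is nonconvex and the all-zero point is
  always a local minimum; the solver keeps the best converged stationary
  point across starts and then compares it against zero, returning the
  better of the two.  Multi-start matters: from the max_k|d_kj| start
  alone roughly one random column in a few hundred converges to an
  inferior basin.  Convergence is declared on a relative objective
  decrease below 1e−10 with a cap of 20000 iterations; near-zero
  thresholds converge slowly, and a looser tolerance leaves the objective
  measurably (≈1e−6) above the per-variable optimum.

**Adaptive weights.**  The weights follow the adaptive-LASSO convention of
the source method for ALP/AHP: w_j = w_jᵞ = 1/max_k|d_kj| and
w_kjᶿ = 1/|d_kj|, clamped at 1/ε with ε = 1e−8 for near-zero
denominators.  They are recomputed on each training portion (including
within every CV fold) and are exposed as configuration.  AHP is tuned
through a single user-facing threshold with λ_γ = λ_θ by default; the link
is configurable.

**λ_max.**  The smallest threshold with zero active variables:
max_kj |d_kj| for PAM and max_j Σ_k |d_kj|/w_j for ALP (both closed form,
from the respective zero-solution conditions).  For AHP no closed form is
available for the nonconvex objective; λ_max is found by per-variable
bisection (vectorized, 60 iterations, relative tolerance 1e−8) on the
zero/nonzero outcome of the solver, using the threshold that zeroes the
first θ-step, max_k γ₀|d_kj|/w_kjᶿ with γ₀ = max_k|d_kj|, as the upper
bracket.  For all three methods shrinking at λ_max yields zero active
variables and shrinking at λ_max(1 − 1e−6) yields at least one.

## Threshold tuning

A grid of T = 30 thresholds (default) spans [0, λ_max]; linear spacing is
the default, with an optional log spacing (zero prepended to a geometric
sequence over [λ_max·10⁻³, λ_max]) for problems where many variables
separate the classes.  Cross-validation is stratified by class — at the
imbalance levels of interest (10 minority samples, 10 folds) unstratified
folds would routinely lose the minority class from a training portion —
and the held-out predictions are pooled over folds before computing the
per-threshold error, per-class accuracies PA_k and g-means
GM = (Π_k PA_k)^{1/K} (micro aggregation, matching the indicator-sum
estimator of PA_k).  Setting folds = n requests leave-one-out CV.  Two
selection rules are available: `min_error` (classical) and `max_gmeans`
(the GM variants).  Criterion ties are broken toward the largest
threshold, i.e. the most parsimonious model.  The final model refits the
shrinkage on the full training data at the selected threshold.

## Simulation engine

The generator emulates the benchmark designs used to study the imbalance
bias: multivariate Gaussian samples with unit variances and a
block-exchangeable correlation structure — blocks of 100 variables with
pairwise correlation ρ = 0.8 within a block and independence across
blocks, drawn exactly as sqrt(ρ)·z_block + sqrt(1−ρ)·z_indep.  Class
structure is a mean shift on the leading n_informative = 100 variables
(contiguous from position 0, i.e. filling the first correlated block(s);
configurable).  Defaults: two-class — n = 100 training samples with
k₁ ∈ [0.5, 0.9], μ₂ ∈ {0, 0.5, 1, 2, 5}, p = 10000, balanced test set of
1000; three-class — p = 5000, n = (100, 20, 100), μ₁ = −μ₃ = 1, μ₂ = 0,
balanced test set of 1500.  10-fold CV with T = 30 thresholds.

Replicate r of a scenario derives all randomness from
`SeedSequence([base_seed, r])`, split into independent streams for the
training draw, the test draw, fold assignment, tie-breaking and
oversampling, so replicates are independent and individually re-runnable.
Random oversampling replicates max(n₁,n₂) − min(n₁,n₂) uniformly chosen
minority samples (exact copies), yielding a balanced training set of size
2·max(n₁,n₂).

Experiments default to 50 replicates with means, SDs and standard errors
reported; at 50 replicates the standard errors of the accuracy means are
≈0.03 or less, which is the package's standing compromise between
Monte-Carlo precision and turnaround on a single CPU.  For each method the
cross-validation is run once per replicate and both selection rules are
applied to the same CV trace, halving the cost of method-vs-GM-method
comparisons (the comparison is also less noisy because it is paired).

What the generator does *not* emulate: heavy-tailed or skewed expression
distributions, variable-specific variances, batch effects, and
informative variables scattered across correlation blocks.  Passing the
simulation benchmarks therefore demonstrates correctness of the
estimators and of the tuning machinery under the stated Gaussian design,
not robustness to real-data artifacts.

## Numerical and design notes

* Pooled SD divisor n − K; every class must have ≥ 2 samples, and a
  constant matrix (all s_j = 0, hence s₀ = 0) is rejected.
* Statistics are invariant to sample order; adding a constant to a
  variable shifts its centroids but leaves s_j and d_kj unchanged.
* Discriminant scores are computed via the expanded quadratic form
  (‖u‖² − 2 v·u + ‖v‖²) on the (s_j + s₀)-scaled data, which turns
  per-threshold scoring into small matrix products.
* The per-variable numeric oracle (`pergene_numeric_oracle`) minimizes
  the penalized objective by multi-start Powell search with the zero
  vector always evaluated; for AHP it works in the product
  parameterization e = γθ with the scale-minimized penalty
  2·sqrt(λ_γ w_jᵞ λ_θ Σ_k w_kjᶿ|e_k|), which coincides with the
  factorized objective at any stationary point of the alternating solver.
  It exists for testing and is deliberately independent of the
  closed-form/alternating code paths.
* Model files are versioned, checksummed JSON; predictions from a
  reloaded model are bit-identical.  Expression matrices are written with
  `%.17g` and read with round-trip float parsing, so matrix I/O is also
  bit-exact.
* External class labels may be arbitrary strings; they are mapped to
  1..K in sorted order and the mapping is stored in the model container.

## Known limitations

* AHP's alternating solver is guaranteed to find a stationary point, not
  the global minimum, of its nonconvex objective; the zero-comparison
  removes the dominant failure mode and the numeric oracle bounds the
  residual gap at ≤ 1e−6 in objective on random instances, but
  pathological columns could in principle converge to an inferior
  nonzero stationary point.
* The alternative overall-centroid definition x̄_j = Σ_k x̄_kj/K (equal
  class weights) is not implemented.
* Per-class (adaptive) thresholds, misclassification-cost weighting,
  F-measure / sum-of-accuracies tuning objectives and posterior class
  probabilities are out of scope.
* AUC is reported for two-class problems only (Mann–Whitney rank form,
  half credit for ties, on the δ₁ − δ₂ score).
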