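"""Shrinkage rules producing d-hat from d: PAM, ALP and AHP penalties.

All three methods solve, per variable j, a penalized least-squares problem in
the standardized differences d_kj:

* PAM  — an L1 penalty on each d_kj; the solution is the elementwise soft
  threshold sign(d) * (|d| - lambda)_+.
* ALP  — an adaptive L-infinity penalty ``lambda * w_j * max_k |v_k|`` per
  variable; the solution clips all components of a variable to a common cap.
* AHP  — a hierarchical penalty on the factorization d_kj = gamma_j * theta_kj
  with gamma_j >= 0 penalized linearly and theta_kj by a weighted L1 norm;
  solved by alternating closed-form updates.

``lambda_max`` is the smallest threshold at which every variable becomes
inactive (all shrunken centroids collapse onto the overall centroid); the
cross-validation grids span [0, lambda_max].
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .core import CentroidStatistics, shrunken_centroids

__all__ = [
    "ShrinkageSpec", "ShrunkenModel", "adaptive_weights",
    "pam_shrink", "alp_shrink", "ahp_shrink", "shrink",
    "lambda_max", "pergene_numeric_oracle",
]

METHODS = ("pam", "alp", "ahp")

#: clamp for adaptive weights when the denominator |d| is near zero
WEIGHT_EPS = 1e-8


@dataclass
class ShrinkageSpec:
    """Method, threshold and weights of one shrinkage fit."""

    method: str
    threshold: float
    alp_weights: np.ndarray | None = None        # (p,) w_j
    ahp_weights_gamma: np.ndarray | None = None  # (p,) w_j^gamma
    ahp_weights_theta: np.ndarray | None = None  # (K, p) w_kj^theta
    # AHP is tuned through a single threshold; by default the same value is
    # used for both penalty terms (lambda_gamma = link * lambda_theta).
    ahp_lambda_link: float = 1.0


@dataclass
class ShrunkenModel:
    """Result of penalizing d at one threshold: the fitted classifier state."""

    spec: ShrinkageSpec
    d_hat: np.ndarray              # (K, p)
    shrunken_centroids: np.ndarray  # (K, p)
    active: np.ndarray             # (p,) bool
    stats: CentroidStatistics = field(repr=False, default=None)

    @property
    def n_active(self) -> int:
        return int(self.active.sum())


def adaptive_weights(stats: CentroidStatistics, eps: float = WEIGHT_EPS) -> dict:
    """Adaptive-LASSO style weights derived from the unshrunken d.

    Variables (or components) with large |d| receive small weights and are
    shrunken less.  Near-zero denominators are clamped at 1/eps.
    """
    absd = np.abs(stats.d)
    colmax = absd.max(axis=0)
    w_alp = 1.0 / np.maximum(colmax, eps)
    w_gamma = 1.0 / np.maximum(colmax, eps)
    w_theta = 1.0 / np.maximum(absd, eps)
    return {"alp": w_alp, "ahp_gamma": w_gamma, "ahp_theta": w_theta}


def _finish(stats: CentroidStatistics, spec: ShrinkageSpec,
            d_hat: np.ndarray) -> ShrunkenModel:
    active = np.any(d_hat != 0.0, axis=0)
    return ShrunkenModel(
        spec=spec,
        d_hat=d_hat,
        shrunken_centroids=shrunken_centroids(stats, d_hat),
        active=active,
        stats=stats,
    )


# ---------------------------------------------------------------------------
# PAM

def pam_shrink(stats: CentroidStatistics, lam: float) -> ShrunkenModel:
    """Soft-threshold every d_kj by lambda (the original PAM rule)."""
    if lam < 0:
        raise ValueError(f"threshold must be >= 0, got {lam}")
    d = stats.d
    d_hat = np.sign(d) * np.maximum(np.abs(d) - lam, 0.0)
    spec = ShrinkageSpec(method="pam", threshold=float(lam))
    return _finish(stats, spec, d_hat)


# ---------------------------------------------------------------------------
# ALP

def _alp_caps(absd: np.ndarray, lamw: np.ndarray) -> np.ndarray:
    """Per-variable cap c_j of the L-infinity penalized solution.

    For each column the solution clips |d_kj| at c_j, where c_j solves
    ``sum_{|d_kj| > c} (|d_kj| - c) = lam * w_j`` (0 if the total absolute
    mass is below lam * w_j).  Vectorized over variables.
    """
    K, p = absd.shape
    A = -np.sort(-absd, axis=0)          # sorted descending per column
    csum = np.cumsum(A, axis=0)
    r = np.arange(1, K + 1)[:, None]
    cand = (csum - lamw[None, :]) / r    # stationary cap if rank-r set is right
    nxt = np.vstack([A[1:], np.zeros((1, p))])
    valid = cand >= nxt - 1e-15 * np.maximum(1.0, nxt)
    any_valid = valid.any(axis=0)
    first = np.argmax(valid, axis=0)
    caps = cand[first, np.arange(p)]
    caps = np.where(any_valid, caps, 0.0)
    # all-zero condition sum|d| <= lam*w with a relative guard so the cap is
    # exactly 0 at the lambda_max boundary despite rounding
    caps = np.where(csum[-1] <= lamw * (1.0 + 1e-12), 0.0, caps)
    return np.maximum(caps, 0.0)


def alp_shrink(stats: CentroidStatistics, lam: float,
               weights: np.ndarray | None = None) -> ShrunkenModel:
    """Adaptive L-infinity penalized shrinkage.

    Per variable j the solution of
    ``min_v 0.5 * sum_k (v_k - d_kj)^2 + lam * w_j * max_k |v_k|``
    clips each |d_kj| at a common cap c_j and keeps the signs; c_j = 0
    (variable inactive) exactly when sum_k |d_kj| <= lam * w_j.
    """
    if lam < 0:
        raise ValueError(f"threshold must be >= 0, got {lam}")
    if weights is None:
        weights = adaptive_weights(stats)["alp"]
    weights = np.asarray(weights, dtype=float)
    if np.any(weights <= 0) or not np.all(np.isfinite(weights)):
        raise ValueError("ALP weights must be strictly positive and finite")
    d = stats.d
    caps = _alp_caps(np.abs(d), lam * weights)
    d_hat = np.sign(d) * np.minimum(np.abs(d), caps[None, :])
    spec = ShrinkageSpec(method="alp", threshold=float(lam), alp_weights=weights)
    return _finish(stats, spec, d_hat)


# ---------------------------------------------------------------------------
# AHP

def _ahp_objective(d, gamma, theta, lam_g, wg, lam_t, wt):
    e = gamma[None, :] * theta
    loss = 0.5 * ((e - d) ** 2).sum(axis=0)
    return (loss + lam_g * wg * gamma
            + lam_t * (wt * np.abs(theta)).sum(axis=0))


def _ahp_iterate(d, lam_g, lam_t, wg, wt, gamma0, max_iter, tol):
    """One alternating-minimization run from a given gamma initialization.

    Returns (gamma, theta, obj, converged) with per-column convergence based
    on a relative objective-decrease criterion.
    """
    gamma = gamma0.copy()
    theta = np.zeros_like(d)
    live = gamma > 0
    obj = _ahp_objective(d, gamma, theta, lam_g, wg, lam_t, wt)
    converged = ~live
    for _ in range(max_iter):
        if not np.any(live):
            break
        g = gamma[live]
        dl = d[:, live]
        # theta-step: componentwise soft threshold of g*d at lam_t*wt, / g^2
        th = np.sign(dl) * np.maximum(
            g[None, :] * np.abs(dl) - lam_t[live][None, :] * wt[:, live], 0.0
        ) / (g ** 2)[None, :]
        # gamma-step: nonnegative 1-D least squares with linear penalty
        den = (th ** 2).sum(axis=0)
        num = (th * dl).sum(axis=0) - lam_g[live] * wg[live]
        g_new = np.where(den > 0,
                         np.maximum(num / np.maximum(den, 1e-300), 0.0), 0.0)
        new_obj = _ahp_objective(dl, g_new, th, lam_g[live], wg[live],
                                 lam_t[live], wt[:, live])
        idx = np.flatnonzero(live)
        gamma[idx] = g_new
        theta[:, idx] = th
        done = (obj[idx] - new_obj) < tol * np.maximum(1.0, new_obj)
        done |= g_new == 0.0  # collapsed to zero: finished
        obj[idx] = new_obj
        converged[idx[done]] = True
        live[idx[done]] = False
    return gamma, theta, obj, converged


#: gamma initialization scales tried by the AHP solver (times max_k |d_kj|)
AHP_INIT_SCALES = (1.0, 0.25, 4.0)


def _ahp_solve(d: np.ndarray, lam_g, lam_t, wg: np.ndarray, wt: np.ndarray,
               max_iter: int = 20000, tol: float = 1e-10,
               raise_on_nonconvergence: bool = True):
    """Per-variable AHP minimization by multi-start alternating updates.

    ``lam_g``/``lam_t`` may be scalars or (p,) arrays (per-variable
    thresholds, used by the lambda_max bisection).  Returns (gamma, theta).
    The objective is nonconvex: runs are started from several gamma scales
    and the best converged stationary point per column is kept, then
    compared against the all-zero solution (always a local minimum), and
    the better of the two is returned.
    """
    K, p = d.shape
    lam_g = np.broadcast_to(np.asarray(lam_g, dtype=float), (p,))
    lam_t = np.broadcast_to(np.asarray(lam_t, dtype=float), (p,))
    gamma_base = np.abs(d).max(axis=0)
    best = None
    for scale in AHP_INIT_SCALES:
        run = _ahp_iterate(d, lam_g, lam_t, wg, wt, scale * gamma_base,
                           max_iter, tol)
        if best is None:
            best = list(run)
            continue
        gamma_r, theta_r, obj_r, conv_r = run
        better = conv_r & ((obj_r < best[2] - 1e-15) | ~best[3])
        best[0] = np.where(better, gamma_r, best[0])
        best[1] = np.where(better[None, :], theta_r, best[1])
        best[2] = np.where(better, obj_r, best[2])
        best[3] = best[3] | conv_r
    gamma, theta, obj, converged = best
    if raise_on_nonconvergence and not np.all(converged):
        j = int(np.flatnonzero(~converged)[0])
        raise RuntimeError(
            f"AHP alternating solver did not converge for variable index {j}")
    # keep the all-zero local minimum when it beats the stationary point
    obj_zero = 0.5 * (d ** 2).sum(axis=0)
    take_zero = obj >= obj_zero - 1e-12
    gamma = np.where(take_zero, 0.0, gamma)
    theta = np.where(take_zero[None, :], 0.0, theta)
    return gamma, theta


def ahp_shrink(stats: CentroidStatistics, lam_theta: float,
               lam_gamma: float | None = None,
               wg: np.ndarray | None = None,
               wt: np.ndarray | None = None,
               max_iter: int = 20000, tol: float = 1e-10) -> ShrunkenModel:
    """Adaptive hierarchically penalized shrinkage.

    Per variable j, (gamma_j, theta_.j) minimize
    ``0.5 * sum_k (gamma*theta_k - d_kj)^2 + lam_gamma*wg_j*gamma
    + lam_theta * sum_k wt_kj*|theta_k|`` with gamma_j >= 0, and
    d_hat_kj = gamma_j * theta_kj.  By default lam_gamma = lam_theta (single
    tuned threshold).  Only the product gamma*theta is returned, so the
    scale ambiguity of the factorization is immaterial.
    """
    if lam_theta < 0 or (lam_gamma is not None and lam_gamma < 0):
        raise ValueError("thresholds must be >= 0")
    if lam_gamma is None:
        lam_gamma = lam_theta
    w = adaptive_weights(stats)
    if wg is None:
        wg = w["ahp_gamma"]
    if wt is None:
        wt = w["ahp_theta"]
    wg = np.asarray(wg, dtype=float)
    wt = np.asarray(wt, dtype=float)
    if np.any(wg <= 0) or np.any(wt <= 0):
        raise ValueError("AHP weights must be strictly positive")
    gamma, theta = _ahp_solve(stats.d, lam_gamma, lam_theta, wg, wt,
                              max_iter=max_iter, tol=tol)
    d_hat = gamma[None, :] * theta
    spec = ShrinkageSpec(method="ahp", threshold=float(lam_theta),
                         ahp_weights_gamma=wg, ahp_weights_theta=wt,
                         ahp_lambda_link=float(lam_gamma / lam_theta)
                         if lam_theta > 0 else 1.0)
    return _finish(stats, spec, d_hat)


# ---------------------------------------------------------------------------
# dispatch and lambda_max

def shrink(stats: CentroidStatistics, method: str, threshold: float,
           weights: dict | None = None) -> ShrunkenModel:
    """Apply the named shrinkage method at the given threshold.

    ``weights`` is the dict returned by :func:`adaptive_weights`; computed
    from ``stats`` when omitted.
    """
    method = method.lower()
    if method == "pam":
        return pam_shrink(stats, threshold)
    if weights is None:
        weights = adaptive_weights(stats)
    if method == "alp":
        return alp_shrink(stats, threshold, weights=weights["alp"])
    if method == "ahp":
        return ahp_shrink(stats, threshold, wg=weights["ahp_gamma"],
                          wt=weights["ahp_theta"])
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


def _ahp_lambda_max(d, wg, wt, link: float = 1.0, rel_tol: float = 1e-8):
    """Smallest common threshold at which every AHP variable is inactive.

    There is no closed form for the nonconvex hierarchical objective, so a
    per-variable bisection is run (vectorized over variables) on the
    zero/nonzero outcome of the solver.  The upper bound is the threshold at
    which the first theta-step from gamma0 = max|d| already zeroes the
    variable: lam >= gamma0 * max_k |d_k| / wt_k.
    """
    K, p = d.shape
    gamma0 = np.abs(d).max(axis=0)
    hi = (gamma0[None, :] * np.abs(d) / wt).max(axis=0)
    hi = np.maximum(hi, 1e-12)
    lo = np.zeros(p)
    nonzero_cols = gamma0 > 0
    if not np.any(nonzero_cols):
        return 0.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        gam, th = _ahp_solve(d, link * mid, mid, wg, wt,
                             raise_on_nonconvergence=False)
        active = np.any(gam[None, :] * th != 0.0, axis=0)
        lo = np.where(active, mid, lo)
        hi = np.where(active, hi, mid)
        if np.all(hi - lo <= rel_tol * hi):
            break
    return float(hi[nonzero_cols].max())


def lambda_max(stats: CentroidStatistics, method: str,
               weights: dict | None = None) -> float:
    """Minimum threshold that shrinks every class centroid to the overall one.

    PAM: ``max_kj |d_kj|``.  ALP: ``max_j sum_k |d_kj| / w_j`` (the
    subgradient condition for the all-zero L-infinity solution).  AHP: found
    by bisection on the per-variable zero-solution condition.
    """
    method = method.lower()
    d = stats.d
    if not np.any(d):
        return 0.0
    if method == "pam":
        return float(np.abs(d).max())
    if weights is None:
        weights = adaptive_weights(stats)
    if method == "alp":
        return float((np.abs(d).sum(axis=0) / weights["alp"]).max())
    if method == "ahp":
        return _ahp_lambda_max(d, weights["ahp_gamma"], weights["ahp_theta"])
    raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")


# ---------------------------------------------------------------------------
# numeric test oracle

def pergene_numeric_oracle(d_col: np.ndarray, penalty: dict,
                           n_starts: int = 8, seed: int = 0) -> np.ndarray:
    """Brute-force minimizer of a single variable's penalized objective.

    Reference answer for unit tests; independent of the closed-form /
    alternating solvers.  ``penalty`` is a descriptor dict:

    * ``{"kind": "l1", "lam": float}`` — PAM's penalty ``lam * sum|v|``.
    * ``{"kind": "linf", "lam": float, "w": float}`` — ALP's
      ``lam * w * max|v|``.
    * ``{"kind": "hier", "lam_g": float, "wg": float, "lam_t": float,
      "wt": (K,) array}`` — AHP, minimized over the product e = gamma*theta
      using the scale-minimized penalty ``2*sqrt(lam_g*wg*lam_t*sum(wt|e|))``.

    Minimization is multi-start Powell over the K-vector, with the zero
    vector always evaluated explicitly.
    """
    d_col = np.asarray(d_col, dtype=float)
    K = d_col.size
    if K > 5:
        raise ValueError("oracle is intended for small K (<= 5)")
    kind = penalty["kind"]

    if kind == "l1":
        lam = penalty["lam"]
        pen = lambda v: lam * np.abs(v).sum()
    elif kind == "linf":
        lam, w = penalty["lam"], penalty["w"]
        pen = lambda v: lam * w * np.abs(v).max(initial=0.0)
    elif kind == "hier":
        c = penalty["lam_g"] * penalty["wg"] * penalty["lam_t"]
        wt = np.asarray(penalty["wt"], dtype=float)
        pen = lambda v: 2.0 * np.sqrt(c * (wt * np.abs(v)).sum())
    else:
        raise ValueError(f"unknown penalty kind {kind!r}")

    def obj(v):
        return 0.5 * ((v - d_col) ** 2).sum() + pen(v)

    rng = np.random.default_rng(seed)
    starts = [d_col, 0.5 * d_col, np.zeros(K)]
    scale = max(np.abs(d_col).max(initial=0.0), 1.0)
    for _ in range(n_starts):
        starts.append(d_col + rng.normal(scale=0.5 * scale, size=K))
    best_v, best_f = np.zeros(K), obj(np.zeros(K))
    for v0 in starts:
        res = optimize.minimize(obj, v0, method="Powell",
                                options={"xtol": 1e-10, "ftol": 1e-12,
                                         "maxiter": 2000})
        if res.fun < best_f:
            best_v, best_f = res.x, res.fun
    return np.asarray(best_v, dtype=float)
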