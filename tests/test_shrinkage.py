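"""Shrinkage solvers vs closed forms and the numeric per-variable oracle."""

import numpy as np
import pytest

from gmnsc import (CentroidStatistics, ahp_shrink, alp_shrink, lambda_max,
                   pam_shrink, pergene_numeric_oracle, shrink)
from gmnsc.shrinkage import _ahp_objective, _ahp_solve, _alp_caps


def stats_from_d(d):
    """Minimal consistent statistics object with a prescribed d matrix."""
    d = np.asarray(d, dtype=float)
    K, p = d.shape
    m = np.full(K, 0.5)
    sd = np.ones(p)
    s0 = 1.0
    overall = np.zeros(p)
    centroids = overall[None, :] + d * m[:, None] * (sd + s0)[None, :]
    counts = np.full(K, 8)
    return CentroidStatistics(class_centroids=centroids,
                              overall_centroid=overall, pooled_sd=sd, s0=s0,
                              m=m, d=d, class_counts=counts,
                              n=int(counts.sum()))


# ---------------------------------------------------------------------------
# PAM

def test_pam_soft_threshold_closed_form():
    st = stats_from_d([[2.5, -0.7, 0.0], [-1.2, 0.3, 1.0]])
    model = pam_shrink(st, 1.0)
    np.testing.assert_allclose(model.d_hat,
                               [[1.5, 0.0, 0.0], [-0.2, 0.0, 0.0]])
    assert model.active.tolist() == [True, False, False]


def test_pam_zero_threshold_is_identity(stats2):
    np.testing.assert_array_equal(pam_shrink(stats2, 0.0).d_hat, stats2.d)


def test_pam_complete_shrinkage(stats2):
    lam = np.abs(stats2.d).max()
    model = pam_shrink(stats2, lam)
    assert model.n_active == 0
    np.testing.assert_array_equal(model.d_hat, 0.0)


def test_pam_negative_threshold_raises(stats2):
    with pytest.raises(ValueError):
        pam_shrink(stats2, -0.1)


def test_pam_never_increases_magnitude_or_flips_sign(stats3):
    for lam in (0.1, 0.5, 1.3):
        d_hat = pam_shrink(stats3, lam).d_hat
        assert np.all(np.abs(d_hat) <= np.abs(stats3.d) + 1e-15)
        nz = d_hat != 0
        assert np.all(np.sign(d_hat[nz]) == np.sign(stats3.d[nz]))


# ---------------------------------------------------------------------------
# ALP

def test_alp_zero_threshold_is_identity(stats3):
    np.testing.assert_allclose(alp_shrink(stats3, 0.0).d_hat, stats3.d,
                               rtol=1e-12)


def test_alp_cap_absorbs_largest_component():
    st = stats_from_d(np.array([[3.0], [1.0]]))
    model = alp_shrink(st, 0.5, weights=np.ones(1))
    np.testing.assert_allclose(model.d_hat[:, 0], [2.5, 1.0])


def test_alp_all_zero_boundary():
    st = stats_from_d(np.array([[3.0], [1.0]]))
    model = alp_shrink(st, 4.0, weights=np.ones(1))  # sum|d| == lam*w
    np.testing.assert_array_equal(model.d_hat, 0.0)
    assert model.n_active == 0


def test_alp_nonpositive_weights_raise(stats2):
    with pytest.raises(ValueError):
        alp_shrink(stats2, 1.0, weights=np.zeros(stats2.n_variables))


def test_alp_matches_numeric_oracle():
    rng = np.random.default_rng(11)
    for trial in range(40):
        K = int(rng.integers(2, 5))
        d = rng.normal(scale=2.0, size=(K, 1))
        lam = float(rng.uniform(0, 3))
        w = float(rng.uniform(0.2, 2.0))
        cap = _alp_caps(np.abs(d), np.array([lam * w]))[0]
        v = (np.sign(d) * np.minimum(np.abs(d), cap))[:, 0]
        vo = pergene_numeric_oracle(d[:, 0],
                                    {"kind": "linf", "lam": lam, "w": w},
                                    n_starts=4, seed=trial)

        def obj(u):
            return (0.5 * ((u - d[:, 0]) ** 2).sum()
                    + lam * w * np.abs(u).max(initial=0.0))

        assert obj(v) <= obj(vo) + 1e-6
        # components below the cap are returned unchanged
        below = np.abs(d[:, 0]) <= cap
        np.testing.assert_array_equal(v[below], d[:, 0][below])


# ---------------------------------------------------------------------------
# AHP

def test_ahp_zero_thresholds_identity(stats3):
    model = ahp_shrink(stats3, 0.0)
    np.testing.assert_allclose(model.d_hat, stats3.d, rtol=1e-8, atol=1e-10)


def test_ahp_zero_column_stays_zero():
    d = np.array([[0.0, 1.5], [0.0, -0.5]])
    st = stats_from_d(d)
    model = ahp_shrink(st, 0.7, wg=np.ones(2), wt=np.ones((2, 2)))
    np.testing.assert_array_equal(model.d_hat[:, 0], 0.0)


def test_ahp_nonpositive_weights_raise(stats2):
    K, p = stats2.d.shape
    with pytest.raises(ValueError):
        ahp_shrink(stats2, 1.0, wg=-np.ones(p), wt=np.ones((K, p)))


def test_ahp_objective_not_worse_than_oracle():
    rng = np.random.default_rng(13)
    for trial in range(25):
        K = int(rng.integers(2, 4))
        d = rng.normal(scale=2.0, size=(K, 1))
        lam = float(rng.uniform(0, 2))
        wg = np.array([rng.uniform(0.2, 2.0)])
        wt = rng.uniform(0.2, 2.0, size=(K, 1))
        gamma, theta = _ahp_solve(d, lam, lam, wg, wt)
        f_sol = float(_ahp_objective(d, gamma, theta, np.array([lam]), wg,
                                     np.array([lam]), wt)[0])
        e = pergene_numeric_oracle(
            d[:, 0], {"kind": "hier", "lam_g": lam, "wg": float(wg[0]),
                      "lam_t": lam, "wt": wt[:, 0]}, n_starts=6, seed=trial)
        c = lam * float(wg[0]) * lam
        f_oracle = (0.5 * ((e - d[:, 0]) ** 2).sum()
                    + 2.0 * np.sqrt(c * (wt[:, 0] * np.abs(e)).sum()))
        assert f_sol <= f_oracle + 1e-6


# ---------------------------------------------------------------------------
# oracle self-checks

def test_oracle_reproduces_pam_soft_threshold():
    rng = np.random.default_rng(17)
    for trial in range(30):
        K = int(rng.integers(2, 5))
        d = rng.normal(scale=2.0, size=K)
        lam = float(rng.uniform(0, 2.5))
        v = pergene_numeric_oracle(d, {"kind": "l1", "lam": lam},
                                   n_starts=4, seed=trial)
        closed = np.sign(d) * np.maximum(np.abs(d) - lam, 0.0)
        f = lambda u: 0.5 * ((u - d) ** 2).sum() + lam * np.abs(u).sum()
        assert abs(f(v) - f(closed)) <= 1e-6


def test_oracle_linf_limits():
    d = np.array([1.0, -2.0, 0.5])
    v0 = pergene_numeric_oracle(d, {"kind": "linf", "lam": 0.0, "w": 1.0})
    np.testing.assert_allclose(v0, d, atol=1e-5)
    vbig = pergene_numeric_oracle(d, {"kind": "linf", "lam": 1e6, "w": 1.0})
    np.testing.assert_allclose(vbig, 0.0, atol=1e-6)


# ---------------------------------------------------------------------------
# lambda_max

def test_lambda_max_pam_single_entry():
    d = np.zeros((2, 3))
    d[0, 1] = 2.0
    assert lambda_max(stats_from_d(d), "pam") == 2.0


def test_lambda_max_alp_unit_weights():
    d = np.zeros((2, 2))
    d[:, 0] = [3.0, 1.0]
    st = stats_from_d(d)
    w = {"alp": np.ones(2)}
    assert lambda_max(st, "alp", weights=w) == pytest.approx(4.0)


def test_lambda_max_zero_for_null_d():
    st = stats_from_d(np.zeros((2, 3)))
    for method in ("pam", "alp", "ahp"):
        assert lambda_max(st, method) == 0.0


@pytest.mark.parametrize("method", ["pam", "alp", "ahp"])
def test_lambda_max_boundary_property(method, stats3):
    lmax = lambda_max(stats3, method)
    assert shrink(stats3, method, lmax).n_active == 0
    assert shrink(stats3, method, lmax * (1 - 1e-6)).n_active >= 1


@pytest.mark.parametrize("method", ["pam", "alp", "ahp"])
def test_active_count_monotone_in_threshold(method, stats2):
    lmax = lambda_max(stats2, method)
    grid = np.linspace(0, lmax, 12)
    counts = [shrink(stats2, method, lam).n_active for lam in grid]
    assert counts[0] == stats2.n_variables  # generic data: all active at 0
    assert counts[-1] == 0
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_unknown_method_raises(stats2):
    with pytest.raises(ValueError, match="unknown method"):
        shrink(stats2, "dlda", 0.1)
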