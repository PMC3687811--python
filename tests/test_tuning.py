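"""Grid construction, cross-validation (incl. a LOOCV oracle) and selection."""

import numpy as np
import pytest

from gmnsc import (ThresholdGrid, TuningResult, compute_statistics,
                   cross_validate, fit, lambda_max, make_grid,
                   predicted_labels, select_threshold, shrink)
from gmnsc.tuning import _fold_assignments

from conftest import make_data
from test_shrinkage import stats_from_d


# ---------------------------------------------------------------------------
# grids

def test_grid_endpoints():
    st = stats_from_d([[1.7, -0.3], [0.2, 0.9]])
    grid = make_grid(st, "pam", T=2)
    np.testing.assert_allclose(grid.values, [0.0, 1.7])


def test_grid_equal_spacing():
    d = np.zeros((2, 3))
    d[0, 0] = 2.9
    grid = make_grid(stats_from_d(d), "pam", T=30)
    assert grid.T == 30
    np.testing.assert_allclose(np.diff(grid.values), 0.1, rtol=1e-12)


def test_log_grid_monotone_with_endpoints(stats2):
    grid = make_grid(stats2, "pam", T=4, spacing="log")
    assert grid.values[0] == 0.0
    assert grid.values[-1] == pytest.approx(lambda_max(stats2, "pam"))
    assert np.all(np.diff(grid.values) > 0)


def test_degenerate_grid_warns():
    st = stats_from_d(np.zeros((2, 2)))
    with pytest.warns(UserWarning, match="lambda_max is 0"):
        grid = make_grid(st, "pam", T=10)
    assert grid.T == 1


def test_grid_requires_two_points(stats2):
    with pytest.raises(ValueError):
        make_grid(stats2, "pam", T=1)


# ---------------------------------------------------------------------------
# folds

def test_stratified_folds_preserve_class_counts():
    labels = np.r_[np.ones(40, int), np.full(10, 2)]
    folds, splits = _fold_assignments(labels, 5, fold_seed=3)
    assert folds == 5
    for _, test_idx in splits:
        counts = np.bincount(labels[test_idx], minlength=3)[1:]
        assert abs(counts[0] - 8) <= 1 and abs(counts[1] - 2) <= 1


def test_fold_reduction_warns():
    labels = np.r_[np.ones(20, int), np.full(3, 2)]
    with pytest.warns(UserWarning, match="reducing folds"):
        folds, _ = _fold_assignments(labels, 10, fold_seed=0)
    assert folds == 3


def test_loocv_splits():
    labels = np.r_[np.ones(4, int), np.full(4, 2)]
    folds, splits = _fold_assignments(labels, 8, fold_seed=0)
    assert folds == 8
    held_out = sorted(int(t[0]) for _, t in splits)
    assert held_out == list(range(8))


# ---------------------------------------------------------------------------
# cross-validation

def test_loocv_matches_naive_refit_oracle():
    """Pooled LOOCV accuracies equal a from-scratch leave-one-out loop."""
    rng = np.random.default_rng(21)
    n, p = 20, 30
    labels = np.r_[np.ones(10, int), np.full(10, 2)]
    X = rng.normal(size=(p, n))
    X[:5, labels == 2] += 1.0
    data = make_data(X, labels)
    stats = compute_statistics(data)
    grid = make_grid(stats, "pam", T=8)
    tie_seed = 77
    res = cross_validate(data, "pam", grid, folds=n, fold_seed=0,
                         tie_seed=tie_seed)

    # oracle: explicit re-fit for each held-out sample
    pred = np.zeros((grid.T, n), dtype=int)
    for i in range(n):
        keep = np.array([j for j in range(n) if j != i])
        st_i = compute_statistics(data.subset_samples(keep))
        for t, lam in enumerate(grid.values):
            model = shrink(st_i, "pam", lam)
            rng_ft = np.random.default_rng([tie_seed, i, t])
            pred[t, i] = predicted_labels(model, X[:, i], rng_seed=rng_ft)[0]
    for t in range(grid.T):
        pa1 = np.mean(pred[t, labels == 1] == 1)
        pa2 = np.mean(pred[t, labels == 2] == 2)
        assert res.cv_pa[t, 0] == pytest.approx(pa1)
        assert res.cv_pa[t, 1] == pytest.approx(pa2)
        assert res.cv_error[t] == pytest.approx(np.mean(pred[t] != labels))


def test_separable_data_reaches_zero_error():
    rng = np.random.default_rng(23)
    labels = np.r_[np.ones(15, int), np.full(15, 2)]
    X = rng.normal(size=(10, 30))
    X[:, labels == 2] += 8.0
    data = make_data(X, labels)
    stats = compute_statistics(data)
    grid = make_grid(stats, "pam", T=10)
    res = cross_validate(data, "pam", grid, folds=5, fold_seed=1)
    mid = grid.T // 2
    assert res.cv_error[mid] == 0.0
    assert res.cv_gmeans[mid] == 1.0


def test_pure_noise_error_near_half():
    rng = np.random.default_rng(25)
    labels = np.r_[np.ones(30, int), np.full(30, 2)]
    data = make_data(rng.normal(size=(40, 60)), labels)
    stats = compute_statistics(data)
    grid = make_grid(stats, "pam", T=6)
    res = cross_validate(data, "pam", grid, folds=6, fold_seed=2)
    assert np.all(res.cv_error > 0.25) and np.all(res.cv_error < 0.75)


def test_threshold_zero_identical_across_methods(toy2):
    stats = compute_statistics(toy2)
    preds = {}
    for method in ("pam", "alp", "ahp"):
        grid = ThresholdGrid(values=np.array(
            [0.0, lambda_max(stats, method)]))
        res = cross_validate(toy2, method, grid, folds=4, fold_seed=5,
                             tie_seed=9)
        preds[method] = (res.cv_error[0], tuple(res.cv_pa[0]))
    assert preds["pam"] == preds["alp"] == preds["ahp"]


def test_gmeans_consistency_of_cv_trace(toy2):
    stats = compute_statistics(toy2)
    grid = make_grid(stats, "pam", T=8)
    res = cross_validate(toy2, "pam", grid, folds=4, fold_seed=1)
    K = toy2.n_classes
    expected = np.where(np.any(res.cv_pa == 0, axis=1), 0.0,
                        np.prod(np.clip(res.cv_pa, 1e-300, None),
                                axis=1) ** (1.0 / K))
    np.testing.assert_allclose(res.cv_gmeans, expected, rtol=1e-12)


# ---------------------------------------------------------------------------
# selection

def _result_with(grid_values, error=None, gm=None):
    T = len(grid_values)
    return TuningResult(
        grid=ThresholdGrid(values=np.asarray(grid_values, dtype=float)),
        cv_error=np.asarray(error if error is not None else np.zeros(T)),
        cv_pa=np.zeros((T, 2)),
        cv_gmeans=np.asarray(gm if gm is not None else np.zeros(T)),
        mean_active=np.zeros(T))


def test_select_unique_maximum():
    res = _result_with([0.0, 1.0, 2.0], gm=[0.2, 0.9, 0.4])
    assert select_threshold(res, "max_gmeans") == 1.0


def test_select_all_equal_takes_largest():
    res = _result_with([0.0, 1.0, 2.0], gm=[0.5, 0.5, 0.5])
    assert select_threshold(res, "max_gmeans") == 2.0


def test_select_error_tie_takes_larger():
    res = _result_with([0.0, 1.0, 2.0], error=[0.3, 0.1, 0.1])
    assert select_threshold(res, "min_error") == 2.0


def test_select_unknown_criterion():
    res = _result_with([0.0, 1.0])
    with pytest.raises(ValueError, match="criterion"):
        select_threshold(res, "max_auc")


# ---------------------------------------------------------------------------
# end-to-end fit

def test_fit_is_deterministic(toy2):
    a_model, a_res = fit(toy2, "pam", "max_gmeans", T=8, folds=4,
                         fold_seed=11, tie_seed=13)
    b_model, b_res = fit(toy2, "pam", "max_gmeans", T=8, folds=4,
                         fold_seed=11, tie_seed=13)
    assert a_res.selected_threshold == b_res.selected_threshold
    np.testing.assert_array_equal(a_model.d_hat, b_model.d_hat)


def test_criteria_agree_on_easy_balanced_data():
    rng = np.random.default_rng(29)
    labels = np.r_[np.ones(15, int), np.full(15, 2)]
    X = rng.normal(size=(20, 30))
    X[:8, labels == 2] += 6.0
    data = make_data(X, labels)
    m_err, r_err = fit(data, "pam", "min_error", T=10, folds=5, fold_seed=3)
    m_gm, r_gm = fit(data, "pam", "max_gmeans", T=10, folds=5, fold_seed=3)
    # both rules find a perfect CV point and therefore the same threshold
    assert r_err.selected_threshold == r_gm.selected_threshold
    np.testing.assert_array_equal(m_err.d_hat, m_gm.d_hat)


def test_fit_reuses_cv_result(toy2):
    stats = compute_statistics(toy2)
    grid = make_grid(stats, "pam", T=8)
    cv = cross_validate(toy2, "pam", grid, folds=4, fold_seed=7, tie_seed=1)
    m1, r1 = fit(toy2, "pam", "min_error", cv_result=cv)
    m2, r2 = fit(toy2, "pam", "min_error", T=8, folds=4, fold_seed=7,
                 tie_seed=1)
    assert r1.selected_threshold == r2.selected_threshold
    np.testing.assert_array_equal(m1.d_hat, m2.d_hat)
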