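"""Penalized selection: closed-form soft-threshold oracle, KKT
optimality, path consistency, the 1SE tuning rule and the rank-by-p
comparator strategies."""

import numpy as np
import pandas as pd
import pytest

from gsfs.featselect import (RegularizationConfig, cv_select_1se, enet_fit,
                             enet_objective, kkt_max_violation, lambda_max,
                             top_n_by_pvalue)
from gsfs.gwas import GwasResult


def orthonormal_design(rng, n, m):
    """Centered X with X'X = n*I (so the lasso separates coordinate-wise)."""
    A = rng.standard_normal((n, m))
    A -= A.mean(axis=0)
    Q, _ = np.linalg.qr(A)
    return np.sqrt(n) * Q[:, :m]


def soft(z, t):
    return np.sign(z) * np.maximum(np.abs(z) - t, 0.0)


def test_lambda_at_path_boundary_zeroes_everything():
    rng = np.random.default_rng(41)
    X = rng.integers(0, 3, size=(80, 30)).astype(float)
    y = rng.standard_normal(80) + X[:, 0]
    Xc = X - X.mean(axis=0)
    lmax = lambda_max(Xc, y, alpha=1.0)
    coef, _ = enet_fit(Xc, y, alpha=1.0, lam=lmax * 1.0001)
    assert np.all(coef == 0)
    # just inside the path something activates
    coef2, _ = enet_fit(Xc, y, alpha=1.0, lam=lmax * 0.95)
    assert np.any(coef2 != 0)


@pytest.mark.parametrize("lam", [0.02, 0.1, 0.4])
def test_lasso_orthonormal_matches_soft_threshold(lam):
    rng = np.random.default_rng(42)
    n, m = 64, 8
    X = orthonormal_design(rng, n, m)
    beta = np.array([1.0, -0.6, 0.3, 0.0, 0.0, 0.15, -0.05, 0.0])
    y = X @ beta + 0.1 * rng.standard_normal(n)
    coef, intercept = enet_fit(X, y, alpha=1.0, lam=lam)
    b_ols = X.T @ (y - y.mean()) / n
    np.testing.assert_allclose(coef, soft(b_ols, lam), atol=1e-8)
    assert intercept == pytest.approx(y.mean(), abs=1e-8)


@pytest.mark.parametrize("alpha,lam", [(0.5, 0.1), (0.05, 0.3)])
def test_enet_orthonormal_matches_closed_form(alpha, lam):
    rng = np.random.default_rng(43)
    n, m = 64, 6
    X = orthonormal_design(rng, n, m)
    beta = np.array([0.8, -0.5, 0.25, 0.0, 0.1, 0.0])
    y = X @ beta + 0.1 * rng.standard_normal(n)
    coef, _ = enet_fit(X, y, alpha=alpha, lam=lam)
    b_ols = X.T @ (y - y.mean()) / n
    expected = soft(b_ols, lam * alpha) / (1.0 + lam * (1.0 - alpha))
    np.testing.assert_allclose(coef, expected, atol=1e-8)


@pytest.mark.parametrize("seed", [0, 1, 2])
@pytest.mark.parametrize("alpha", [1.0, 0.5, 0.05])
def test_fitted_solutions_satisfy_kkt(seed, alpha):
    rng = np.random.default_rng(seed)
    X = rng.integers(0, 3, size=(100, 60)).astype(float)
    y = rng.standard_normal(100) + 0.5 * X[:, 3] - 0.3 * X[:, 40]
    lam = 0.3 * lambda_max(X - X.mean(axis=0), y, alpha)
    coef, intercept = enet_fit(X, y, alpha=alpha, lam=lam)
    assert kkt_max_violation(X, y, coef, intercept, alpha, lam) < 1e-6


def test_fitted_objective_beats_perturbations():
    rng = np.random.default_rng(44)
    X = rng.integers(0, 3, size=(90, 40)).astype(float)
    y = rng.standard_normal(90) + 0.6 * X[:, 5]
    alpha, lam = 0.7, 0.05
    coef, intercept = enet_fit(X, y, alpha=alpha, lam=lam)
    f0 = enet_objective(X, y, coef, intercept, alpha, lam)
    for _ in range(20):
        pert = coef + 0.01 * rng.standard_normal(coef.shape)
        assert f0 <= enet_objective(X, y, pert, intercept, alpha, lam) + 1e-12


def test_path_solutions_match_cold_started_fits():
    from sklearn.linear_model import enet_path

    rng = np.random.default_rng(45)
    X = rng.integers(0, 3, size=(70, 25)).astype(float)
    Xc = X - X.mean(axis=0)
    y = rng.standard_normal(70) + 0.5 * X[:, 2]
    yc = y - y.mean()
    lmax = lambda_max(Xc, y, 1.0)
    lambdas = np.geomspace(lmax, 0.01 * lmax, 20)
    _, warm_coefs, _ = enet_path(Xc, yc, l1_ratio=1.0, alphas=lambdas,
                                 tol=1e-10, max_iter=100_000)
    for k, lam in enumerate(lambdas):
        cold, _ = enet_fit(Xc, yc, alpha=1.0, lam=lam)
        np.testing.assert_allclose(warm_coefs[:, k], cold, atol=1e-6)


@pytest.fixture(scope="module")
def signal_data():
    rng = np.random.default_rng(46)
    n, m = 250, 120
    X = (rng.binomial(1, 0.3, (n, m)) + rng.binomial(1, 0.3, (n, m))).astype(float)
    beta = np.zeros(m)
    beta[[3, 30, 77]] = [0.8, -0.6, 0.7]
    y = X @ beta + rng.standard_normal(n)
    return X, y


def test_cv_selection_is_seed_deterministic(signal_data):
    X, y = signal_data
    cfg = RegularizationConfig(fold_seed=5, lambda_path_length=50)
    a = cv_select_1se(X, y, cfg, mode="lasso")
    b = cv_select_1se(X, y, cfg, mode="lasso")
    np.testing.assert_array_equal(a.snp_indices, b.snp_indices)
    np.testing.assert_array_equal(a.coefficients, b.coefficients)
    assert (a.alpha, a.lam) == (b.alpha, b.lam)


def test_chosen_lambda_satisfies_1se_rule_on_curve(signal_data):
    X, y = signal_data
    cfg = RegularizationConfig(fold_seed=6, lambda_path_length=50)
    fs = cv_select_1se(X, y, cfg, mode="en")
    assert fs.alpha in fs.cv_curves
    curve = fs.cv_curves[fs.alpha]
    mean, se = curve["mean"], curve["se"]
    i_min, i_1se = curve["i_min"], curve["i_1se"]
    thresh = mean[i_min] + se[i_min]
    assert mean[i_1se] <= thresh
    # largest qualifying lambda: nothing earlier on the descending path
    assert np.all(mean[:i_1se] > thresh)
    assert fs.lam == pytest.approx(curve["lambdas"][i_1se])
    # winning alpha has the smallest 1SE-rule CV error across the grid
    errs = {a: c["mean"][c["i_1se"]] for a, c in fs.cv_curves.items()}
    assert errs[fs.alpha] == min(errs.values())


def test_cv_recovers_true_support(signal_data):
    X, y = signal_data
    cfg = RegularizationConfig(fold_seed=7, lambda_path_length=50)
    fs = cv_select_1se(X, y, cfg, mode="lasso")
    assert {3, 30, 77} <= set(fs.snp_indices)


def test_near_ridge_alpha_selects_at_least_as_many_as_lasso(signal_data):
    X, y = signal_data
    cfg = RegularizationConfig(fold_seed=8, lambda_path_length=50)
    lasso = cv_select_1se(X, y, cfg, mode="lasso")
    en = cv_select_1se(X, y, cfg, mode="en")
    assert en.n_selected >= lasso.n_selected


def test_pure_noise_selection_is_usually_empty():
    # a shallow path suffices: with no signal the CV curve is flat and
    # the 1SE rule should land at the all-zero end near lambda_max
    cfg_base = dict(lambda_path_length=30, lambda_eps=0.05)
    empty = 0
    for seed in range(10):
        rng = np.random.default_rng(100 + seed)
        X = rng.integers(0, 3, size=(200, 500)).astype(float)
        y = rng.standard_normal(200)
        cfg = RegularizationConfig(fold_seed=seed, **cfg_base)
        with pytest.warns(UserWarning):
            fs = cv_select_1se(X, y, cfg, mode="lasso")
        empty += fs.n_selected == 0
    assert empty >= 8


def _scan_result(p, beta):
    m = len(p)
    table = pd.DataFrame({
        "snp_id": [f"s{j}" for j in range(m)], "chrom": np.ones(m, int),
        "pos": np.arange(1, m + 1), "beta": beta, "se": np.ones(m),
        "wald": np.square(beta), "p_value": p, "testable": np.isfinite(p),
    })
    return GwasResult(table=table, n_used=50)


def test_top_n_picks_smallest_pvalues():
    res = _scan_result([0.5, 0.01, 0.03], [0.1, 0.2, 0.3])
    fs = top_n_by_pvalue(res, 2)
    np.testing.assert_array_equal(fs.snp_indices, [1, 2])


def test_top_n_tie_break_prefers_larger_effect_then_map_order():
    res = _scan_result([0.02, 0.02, 0.02, 0.5], [0.1, -0.9, 0.1, 1.0])
    fs = top_n_by_pvalue(res, 2)
    # p ties at 0.02: |beta|=0.9 wins, then map order among |0.1| ties
    np.testing.assert_array_equal(np.sort(fs.snp_indices), [0, 1])
    # determinism across calls
    fs2 = top_n_by_pvalue(res, 2)
    np.testing.assert_array_equal(fs.snp_indices, fs2.snp_indices)


def test_top_n_skips_untestable_and_validates_n():
    res = _scan_result([0.5, np.nan, 0.03], [0.1, 0.0, 0.3])
    fs = top_n_by_pvalue(res, 2)
    assert 1 not in fs.snp_indices
    with pytest.raises(ValueError):
        top_n_by_pvalue(res, 0)
    with pytest.raises(ValueError):
        top_n_by_pvalue(res, 3)  # only 2 testable
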