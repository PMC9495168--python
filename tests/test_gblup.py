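"""AI-REML and BLUP: recovery of variance components, equivalence with
mixed-model-equation and SNP-BLUP oracles, and the convergence contract."""

import numpy as np
import pytest

from gsfs.gblup import (aireml_fit, predict_gebv, predict_validation,
                        residual_weights)
from gsfs.grm import grm_vanraden1

from conftest import toy_genotypes


def random_genotype_grm(rng, n, m):
    codes = (rng.binomial(1, 0.35, (n, m))
             + rng.binomial(1, 0.35, (n, m))).astype(float)
    return grm_vanraden1(toy_genotypes(codes))


def sample_y(rng, K, sigma2_a, sigma2_e, d=None):
    n = K.shape[0]
    lam, U = np.linalg.eigh(K)
    lam = np.clip(lam, 0, None)
    a = U @ (np.sqrt(sigma2_a * lam) * rng.standard_normal(n))
    scale = np.ones(n) if d is None else np.sqrt(d)
    return a + np.sqrt(sigma2_e) * scale * rng.standard_normal(n), a


def test_residual_weight_arithmetic():
    w = residual_weights(np.array([0.5, 0.4]))
    np.testing.assert_allclose(w.d, [1.0, 1.5])


def test_residual_weight_floored_at_full_reliability():
    with pytest.warns(UserWarning, match="floored"):
        w = residual_weights(np.array([1.0, 0.5]))
    assert w.d[0] == pytest.approx(1e-6)
    assert w.floored[0] and not w.floored[1]


def test_residual_weight_rejects_nonpositive_reliability():
    with pytest.raises(ValueError):
        residual_weights(np.array([0.0, 0.5]))


def test_single_grm_variance_recovery_small():
    rng = np.random.default_rng(51)
    G = random_genotype_grm(rng, 300, 700)
    est = []
    for _ in range(3):
        y, _ = sample_y(rng, G.matrix, 0.3, 0.7)
        fit = aireml_fit(y, G)
        assert fit.converged
        est.append([fit.variance_components[0], fit.sigma2_e])
    est = np.mean(est, axis=0)
    assert abs(est[0] - 0.3) < 0.1
    assert abs(est[1] - 0.7) < 0.1


def test_null_second_grm_gets_near_zero_variance():
    rng = np.random.default_rng(52)
    hits = 0
    for _ in range(5):
        G1 = random_genotype_grm(rng, 250, 500)
        G2 = random_genotype_grm(rng, 250, 500)
        y, _ = sample_y(rng, G1.matrix, 0.4, 0.6)
        fit = aireml_fit(y, [G1, G2])
        total = fit.variance_components.sum() + fit.sigma2_e
        hits += fit.variance_components[1] / total < 0.05
    assert hits >= 3


def test_nonconvergence_reported_not_raised():
    rng = np.random.default_rng(53)
    G = random_genotype_grm(rng, 100, 200)
    G2 = G.matrix + 1e-10 * np.eye(100)  # nearly identical: confounded
    y, _ = sample_y(rng, G.matrix, 0.5, 0.5)
    with pytest.warns(UserWarning, match="did not converge"):
        fit = aireml_fit(y, [G.matrix, G2], max_iter=3)
    assert not fit.converged
    assert fit.n_iter == 3


def test_gebv_conditional_mean_matches_mme_oracle():
    # full-rank SPD G so the mixed-model equations can invert it
    rng = np.random.default_rng(54)
    n = 60
    A = rng.standard_normal((n, 2 * n))
    G = A @ A.T / (2 * n) + 0.5 * np.eye(n)
    d = rng.uniform(0.5, 2.0, n)
    sigma2_a, sigma2_e = 0.4, 0.6
    y = rng.standard_normal(n)
    mu, gebv, _ = predict_gebv(
        y, G, [sigma2_a], sigma2_e,
        weights=residual_weights(1.0 / (1.0 + d)),  # r2 s.t. (1-r2)/r2 = d
    )
    # MME oracle: [X'R⁻¹X  X'R⁻¹Z; Z'R⁻¹X  Z'R⁻¹Z + G⁻¹λ] [b; a]
    R_inv = np.diag(1.0 / (sigma2_e * d))
    X = np.ones((n, 1))
    lhs = np.block([
        [X.T @ R_inv @ X, X.T @ R_inv],
        [R_inv @ X, R_inv + np.linalg.inv(G) / sigma2_a],
    ])
    rhs = np.concatenate([X.T @ R_inv @ y, R_inv @ y])
    sol = np.linalg.solve(lhs, rhs)
    assert mu == pytest.approx(sol[0], abs=1e-8)
    np.testing.assert_allclose(gebv, sol[1:], atol=1e-8)


def test_noiseless_limit_returns_centered_response():
    rng = np.random.default_rng(55)
    n = 40
    A = rng.standard_normal((n, 3 * n))
    G = A @ A.T / (3 * n)
    y = rng.standard_normal(n)
    mu, gebv, _ = predict_gebv(y, G, [1.0], 1e-10)
    np.testing.assert_allclose(gebv, y - mu, atol=1e-5)


def test_two_grm_with_zero_first_variance_reduces_to_one_grm():
    rng = np.random.default_rng(56)
    G1 = random_genotype_grm(rng, 80, 150).matrix
    G2 = random_genotype_grm(rng, 80, 150).matrix
    y = rng.standard_normal(80)
    mu2, gebv2, comps = predict_gebv(y, [G1, G2], [0.0, 0.5], 0.5)
    mu1, gebv1, _ = predict_gebv(y, G2, [0.5], 0.5)
    assert mu2 == pytest.approx(mu1, abs=1e-10)
    np.testing.assert_allclose(gebv2, gebv1, atol=1e-10)
    np.testing.assert_allclose(comps[0], 0.0, atol=1e-12)


def test_location_equivariance():
    rng = np.random.default_rng(57)
    G = random_genotype_grm(rng, 70, 120).matrix
    y = rng.standard_normal(70)
    mu1, gebv1, _ = predict_gebv(y, G, [0.3], 0.7)
    mu2, gebv2, _ = predict_gebv(y + 5.0, G, [0.3], 0.7)
    assert mu2 == pytest.approx(mu1 + 5.0, abs=1e-8)
    np.testing.assert_allclose(gebv1, gebv2, atol=1e-8)


def test_component_gebvs_sum_to_total():
    rng = np.random.default_rng(58)
    G1 = random_genotype_grm(rng, 90, 150)
    G2 = random_genotype_grm(rng, 90, 150)
    y, _ = sample_y(rng, G1.matrix, 0.4, 0.6)
    fit = aireml_fit(y, [G1, G2])
    np.testing.assert_allclose(
        fit.gebv_components[0] + fit.gebv_components[1], fit.gebv,
        atol=1e-12,
    )
    assert np.all(fit.variance_components >= 0)


def test_em_iteration_is_monotone_in_restricted_likelihood():
    rng = np.random.default_rng(59)
    G = random_genotype_grm(rng, 120, 240)
    y, _ = sample_y(rng, G.matrix, 0.4, 0.6)
    with np.testing.suppress_warnings() as sup:
        sup.filter(UserWarning)  # EM at tiny tol may hit the cap; fine here
        fit = aireml_fit(y, G, algorithm="em", max_iter=60, tol=1e-12)
    diffs = np.diff(fit.loglik_path)
    assert np.all(diffs > -1e-8)


def test_snp_blup_ridge_equivalence_small():
    rng = np.random.default_rng(60)
    n, m = 80, 300
    codes = (rng.binomial(1, 0.3, (n, m))
             + rng.binomial(1, 0.3, (n, m))).astype(float)
    geno = toy_genotypes(codes)
    G = grm_vanraden1(geno)
    y = rng.standard_normal(n) + 0.02 * codes @ rng.standard_normal(m)
    sigma2_a, sigma2_e = 0.5, 0.5
    mu, gebv, _ = predict_gebv(y, G, [sigma2_a], sigma2_e)
    p = codes.mean(axis=0)[G.snp_subset] / 2.0
    Z = codes[:, G.snp_subset] - 2 * p
    lam_ridge = sigma2_e * G.scale_constant / sigma2_a
    bhat = np.linalg.solve(Z.T @ Z + lam_ridge * np.eye(Z.shape[1]),
                           Z.T @ (y - mu))
    np.testing.assert_allclose(gebv, Z @ bhat, atol=1e-6)


def test_validation_projection_matches_joint_fit_partition():
    # projecting through the cross-block must equal the conditional mean
    # of validation GEBVs given reference data under the same components
    rng = np.random.default_rng(61)
    G = random_genotype_grm(rng, 100, 300)
    y, a = sample_y(rng, G.matrix, 0.5, 0.5)
    ref, val = np.arange(80), np.arange(80, 100)
    fit = aireml_fit(y[ref], G.matrix[np.ix_(ref, ref)])
    gebv_val = predict_validation(fit, G, y[ref], ref, val)
    V_ref = (fit.variance_components[0] * G.matrix[np.ix_(ref, ref)]
             + fit.sigma2_e * np.eye(80))
    expected = (fit.variance_components[0] * G.matrix[np.ix_(val, ref)]
                @ np.linalg.solve(V_ref, y[ref] - fit.mu))
    np.testing.assert_allclose(gebv_val, expected, atol=1e-10)
    # and it should actually predict the held-out genetic values
    assert np.corrcoef(gebv_val, a[val])[0, 1] > 0.2


def test_dimension_mismatch_rejected():
    rng = np.random.default_rng(62)
    G = random_genotype_grm(rng, 30, 60)
    with pytest.raises(ValueError, match="dimension"):
        aireml_fit(rng.standard_normal(29), G)
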