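import numpy as np
import pytest

from svdbayesc import (
    VarianceConfig,
    bayesc_snp_effects,
    economy_svd,
    effective_info,
    fit_bayesc,
    fit_snp_blup,
    log_likelihood_ratio,
    merge_chromosome_svds,
    per_snp_posterior,
    posterior_probability,
    predict_gebv,
    rhs_from_blup,
    snp_variance_weights,
    solve_bayesc_components,
    standardize,
)


def _full_svd(X):
    return merge_chromosome_svds([economy_svd(X, chrom="all")], mode="hierarchical")


@pytest.fixture
def fitted(rng, genotypes):
    Xs = standardize(genotypes)
    X = Xs.X
    var = VarianceConfig.from_variances(1.0, 1.0, X.shape[1], pi=0.05)
    y = rng.normal(size=X.shape[0]) + X[:, 10] * 0.4
    svd = _full_svd(X)
    return X, y, var, svd, fit_snp_blup(svd, y, var)


def test_effective_info_algebra():
    """c recovers the quantity the PEV encodes: sig_e2/(c + lam_b) = PEV."""
    lam_b, sig_e2 = 400.0, 1.0
    assert effective_info(np.array([sig_e2 / (100 + lam_b)]), lam_b, sig_e2)[0] == pytest.approx(100.0)
    # no-information SNP: PEV = sigma_b2 => c = 0
    assert effective_info(np.array([sig_e2 / lam_b]), lam_b, sig_e2)[0] == pytest.approx(0.0, abs=1e-9)
    with pytest.raises(ValueError):
        effective_info(np.array([0.0]), lam_b, sig_e2)


def test_rhs_recovery_arithmetic():
    assert rhs_from_blup(np.array([100.0]), 400.0, np.array([0.01]))[0] == pytest.approx(5.0)
    assert rhs_from_blup(np.array([7.0]), 400.0, np.array([0.0]))[0] == 0.0


def test_info_and_rhs_match_dense_single_snp_oracle(fitted):
    """c_j and rhs_j agree with x_j'R^-1 x_j and x_j'R^-1 y_c computed with an
    explicit R = I + G_{-j}/sig_e2 (well within the 5% regime)."""
    X, y, var, svd, fit = fitted
    post = per_snp_posterior(fit, var)
    yc = y - y.mean()
    for j in (0, 10, 57):
        X_others = np.delete(X, j, axis=1)
        R = np.eye(X.shape[0]) + X_others @ X_others.T * var.sigma_b2 / var.sigma_e2
        Rinv_x = np.linalg.solve(R, X[:, j])
        c_true = X[:, j] @ Rinv_x
        rhs_true = Rinv_x @ yc
        assert post.c[j] == pytest.approx(c_true, rel=0.05)
        assert post.rhs[j] == pytest.approx(rhs_true, rel=0.05)


def test_llr_zero_data_and_large_lambda_limits():
    assert log_likelihood_ratio(np.array([0.0]), np.array([0.0]), 10.0, 1.0)[0] == 0.0
    # sigma^2 -> 0 collapses the mixture: LLR -> 0
    big = log_likelihood_ratio(np.array([50.0]), np.array([3.0]), 1e12, 1.0)[0]
    assert abs(big) < 1e-6


def test_llr_matches_dense_log_density_difference(rng):
    """LLR equals the difference of the two multivariate-normal log-densities
    on a single-SNP problem with an explicit R."""
    N = 200
    sig_e2, sigma2 = 1.0, 0.04
    lam = sig_e2 / sigma2
    x = rng.normal(size=N)
    A = rng.normal(size=(N, 5))
    R = np.eye(N) + A @ A.T * 0.002  # any SPD records-covariance will do
    y = rng.normal(size=N) + x * 0.3
    yc = y - y.mean()
    Rinv_x = np.linalg.solve(R, x)
    c = x @ Rinv_x
    rhs = Rinv_x @ yc

    def mvn_logdens(cov):
        sign, logdet = np.linalg.slogdet(cov)
        return -0.5 * (logdet + yc @ np.linalg.solve(cov, yc))

    ll0 = mvn_logdens(R * sig_e2)
    ll1 = mvn_logdens(R * sig_e2 + np.outer(x, x) * sigma2)
    llr = log_likelihood_ratio(np.array([c]), np.array([rhs]), lam, sig_e2)[0]
    assert llr == pytest.approx(ll1 - ll0, abs=1e-6)


def test_posterior_probability_cases():
    lppr, pp = posterior_probability(np.array([0.0]), 0.5)
    assert pp[0] == pytest.approx(0.5)
    # zero evidence recovers the prior exactly
    _, pp = posterior_probability(np.array([0.0]), 0.01)
    assert pp[0] == pytest.approx(0.01)
    # LLR solving LPPR = 0 gives pp = 0.5: llr = -log(pi/(1-pi))
    llr_star = -np.log(0.01 / 0.99)
    assert llr_star == pytest.approx(4.59512, abs=1e-5)
    _, pp = posterior_probability(np.array([llr_star]), 0.01)
    assert pp[0] == pytest.approx(0.5)
    # stability at extreme log-odds
    _, pp = posterior_probability(np.array([-800.0, 800.0]), 0.5)
    assert pp[0] == 0.0 and pp[1] == 1.0


def test_pp_monotone_in_llr_and_pi():
    llr = np.linspace(-5, 5, 41)
    _, pp = posterior_probability(llr, 0.1)
    assert np.all(np.diff(pp) > 0)
    pps = [posterior_probability(np.array([1.3]), pi)[1][0] for pi in (0.01, 0.1, 0.5, 0.9)]
    assert np.all(np.diff(pps) > 0)


def test_variance_weights_conservation(rng):
    # uniform pp -> unit weights
    np.testing.assert_allclose(snp_variance_weights(np.full(7, 0.3), 0.01), np.ones(7))
    np.testing.assert_allclose(snp_variance_weights(np.array([0.9, 0.1]), 0.5), [1.8, 0.2])
    for _ in range(5):
        pp = rng.uniform(0, 1, size=rng.integers(3, 400))
        d = snp_variance_weights(pp, 0.02)
        assert d.sum() == pytest.approx(len(pp), rel=1e-12)
        assert np.all(d > 0)


def test_uniform_weights_reduce_to_snp_blup(fitted):
    """D = I with full-rank orthonormal V reproduces the SNP-BLUP solution."""
    X, y, var, svd, fit = fitted
    d = np.ones(X.shape[1])
    s_c, W_inv = solve_bayesc_components(svd, y, d, var.lambda_b)
    np.testing.assert_allclose(s_c, fit.s_hat, atol=1e-6)
    b_c = bayesc_snp_effects(d, svd, s_c, W_inv)
    np.testing.assert_allclose(b_c, fit.b_hat, atol=1e-6)


def test_zero_phenotype_gives_zero_solution(fitted):
    X, y, var, svd, _ = fitted
    s_c, W_inv = solve_bayesc_components(svd, np.zeros(X.shape[0]), np.ones(X.shape[1]), var.lambda_b)
    assert np.max(np.abs(s_c)) == 0
    assert np.max(np.abs(bayesc_snp_effects(np.ones(X.shape[1]), svd, s_c, W_inv))) == 0


def test_weighted_solution_matches_dense_weighted_ridge(fitted):
    """BayesC effects equal the dense weighted-ridge oracle
    b = (X'X + D^-1 lam_b)^-1 X' y_c on a full-rank instance."""
    X, y, var, svd, fit = fitted
    post = per_snp_posterior(fit, var)
    yc = y - y.mean()
    sol = fit_bayesc(svd, y, var, posterior=post)
    dense = np.linalg.solve(
        X.T @ X + np.diag(var.lambda_b / post.d_tilde), X.T @ yc
    )
    np.testing.assert_allclose(sol.b_c_hat, dense, atol=1e-6)
    # component effects agree through s = V'b
    V = svd.dense_V()
    np.testing.assert_allclose(sol.s_c_hat, V.T @ dense, atol=1e-6)
    # training GEBV identity
    np.testing.assert_allclose(sol.gebv, X @ sol.b_c_hat, atol=1e-6)


def test_pi_near_one_with_blup_slab_recovers_snp_blup(fitted):
    """pi -> 1 with sigma^2 = sigma_b^2 makes all weights uniform, so the
    BayesC path collapses onto SNP-BLUP."""
    X, y, _, svd, _ = fitted
    k = X.shape[1]
    var = VarianceConfig(sigma_g2=1.0, sigma_e2=1.0, sigma_b2=1.0 / k, pi=1 - 1e-12, sigma2=1.0 / k)
    fit = fit_snp_blup(svd, y, var)
    post = per_snp_posterior(fit, var)
    assert np.allclose(post.pp, 1.0, atol=1e-6)
    np.testing.assert_allclose(post.d_tilde, np.ones(k), rtol=1e-9)
    sol = fit_bayesc(svd, y, var, posterior=post)
    np.testing.assert_allclose(sol.b_c_hat, fit.b_hat, atol=1e-6)


def test_predict_gebv_contracts(fitted, rng):
    X, y, var, svd, fit = fitted
    assert np.all(predict_gebv(np.zeros(X.shape[1]), X) == 0)
    # identity weights: predictions equal SNP-BLUP fitted values
    np.testing.assert_allclose(predict_gebv(fit.b_hat, X), X @ fit.b_hat, atol=1e-12)
    with pytest.raises(ValueError):
        predict_gebv(fit.b_hat[:-1], X)
    # per-individual dot-product oracle
    b = rng.normal(size=X.shape[1])
    g = predict_gebv(b, X[:7])
    for i in range(7):
        assert g[i] == pytest.approx(float(np.dot(X[i], b)), rel=1e-12)
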