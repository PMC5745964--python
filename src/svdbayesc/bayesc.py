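"""Direct (non-iterative) BayesC via SNP-BLUP prediction error variances.

The BayesC prior puts b_j ~ N(0, sigma^2) with probability pi and b_j = 0
otherwise.  Instead of sampling, this module recovers, for every SNP, the
effective information c_j = x_j' R^-1 x_j from the SNP-BLUP PEV
(c_j = sigma_e^2 / PEV_j - lambda_b, where R sigma_e^2 is the covariance of
the records with SNP j's effect excluded), then the right-hand side
x_j' R^-1 (y - 1 mu) = (c_j + lambda_b) b_hat_j from the SNP-BLUP estimate.
These two scalars determine the log-likelihood ratio of a non-zero versus
zero effect,

    LLR_j = 1/2 [ log(lambda) - log(lambda + c_j)
                  + (rhs_j^2 / sigma_e^2) / (c_j + lambda) ],

with lambda = sigma_e^2 / sigma^2.  Adding the prior log-odds gives the log
posterior-probability ratio and the posterior QTL probability
PP_j = 1 / (1 + exp(-LPPR_j)).  The posterior probabilities become per-SNP
variance weights D_j = PP_j sigma^2, rescaled so their sum equals the SNP
count (total prior variance matches SNP-BLUP), and a single weighted
mixed-model solve in component space,

    [S^2 + (V'DV)^-1 lambda_b] s_c = S U'(y - 1 mu),

yields the BayesC component effects; SNP effects follow from
b_c = D V (V'DV)^-1 s_c.  No iteration anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
import logging

import numpy as np
import scipy.linalg

from .blup import BlupSolution, estimate_mu
from .io import StandardizedGenotypes, VarianceConfig
from .svd import MergedSVD

logger = logging.getLogger(__name__)

PP_FLOOR = 1e-6
COMPONENT_CAP = 10_000


@dataclass
class PerSnpPosterior:
    """Per-SNP effective information, likelihood ratio and posterior weight."""

    c: np.ndarray  # effective number of records x_j'R^-1 x_j
    rhs: np.ndarray  # x_j'R^-1 (y - 1 mu)
    llr: np.ndarray
    lppr: np.ndarray
    pp: np.ndarray
    d_tilde: np.ndarray  # scaled variance weights, sum = k


@dataclass
class BayesCSolution:
    mu_hat: float
    s_c_hat: np.ndarray
    b_c_hat: np.ndarray
    gebv: np.ndarray  # training individuals, U S s_c_hat


def effective_info(pev: np.ndarray, lambda_b: float, sigma_e2: float) -> np.ndarray:
    """c_j = sigma_e^2 / PEV_j - lambda_b, clamped at zero from below."""
    pev = np.asarray(pev, dtype=float)
    if np.any(pev <= 0):
        raise ValueError("PEV must be strictly positive (no-information SNPs carry the prior variance)")
    return np.clip(sigma_e2 / pev - lambda_b, 0.0, None)


def rhs_from_blup(c: np.ndarray, lambda_b: float, b_hat: np.ndarray) -> np.ndarray:
    """Invert the single-SNP normal equation: rhs_j = (c_j + lambda_b) b_hat_j.

    lambda_b (not lambda) appears because b_hat_j is the SNP-BLUP estimate, so
    (c_j + lambda_b) is the coefficient that produced it.
    """
    return (np.asarray(c, float) + lambda_b) * np.asarray(b_hat, float)


def log_likelihood_ratio(c, rhs, lambda_, sigma_e2) -> np.ndarray:
    """LLR of b_j ~ N(0, sigma^2) versus b_j = 0 from the two recovered scalars."""
    if lambda_ <= 0:
        raise ValueError("lambda must be > 0")
    c = np.asarray(c, dtype=float)
    rhs = np.asarray(rhs, dtype=float)
    return 0.5 * (np.log(lambda_) - np.log(lambda_ + c) + (rhs**2 / sigma_e2) / (c + lambda_))


def posterior_probability(llr, pi: float):
    """(LPPR_j, PP_j): add prior log-odds, pass through a stable sigmoid."""
    if not 0 < pi < 1:
        raise ValueError("pi must be in (0, 1)")
    lppr = np.asarray(llr, dtype=float) + np.log(pi) - np.log1p(-pi)
    return lppr, _expit(lppr)


def _expit(x: np.ndarray) -> np.ndarray:
    # overflow-safe logistic
    out = np.empty_like(x, dtype=float)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def snp_variance_weights(pp: np.ndarray, sigma2: float, floor: float = PP_FLOOR) -> np.ndarray:
    """D_j = PP_j sigma^2 rescaled so sum(d_tilde) = k exactly.

    PP is floored at ``floor`` first so the weighted Gram matrix V'DV stays
    invertible.
    """
    pp = np.clip(np.asarray(pp, dtype=float), floor, None)
    d = pp * sigma2
    total = d.sum()
    if total <= 0:
        raise ValueError("sum of posterior probabilities is zero")
    return d * (len(d) / total)


def per_snp_posterior(blup: BlupSolution, var: VarianceConfig, floor: float = PP_FLOOR) -> PerSnpPosterior:
    """The full PEV -> LLR -> PP -> weight chain from a SNP-BLUP solution."""
    c = effective_info(blup.pev, var.lambda_b, var.sigma_e2)
    rhs = rhs_from_blup(c, var.lambda_b, blup.b_hat)
    llr = log_likelihood_ratio(c, rhs, var.lambda_, var.sigma_e2)
    lppr, pp = posterior_probability(llr, var.pi)
    d_tilde = snp_variance_weights(pp, var.sigma2, floor=floor)
    return PerSnpPosterior(c=c, rhs=rhs, llr=llr, lppr=lppr, pp=np.clip(pp, floor, None), d_tilde=d_tilde)


def solve_bayesc_components(
    svd: MergedSVD, y: np.ndarray, d_tilde: np.ndarray, lambda_b: float, mu_hat: float | None = None
):
    """Solve [S^2 + (V'DV)^-1 lambda_b] s_c = S U'(y - 1 mu).

    W = V'DV is accumulated blockwise over chromosomes; the system is solved
    as the symmetric positive-definite m x m problem
    (diag(S^2) + lambda_b W^-1) s_c = S U' y_c.  Returns (s_c_hat, W_inv) so
    the factorization is reused by the back-transform.
    """
    if svd.m > COMPONENT_CAP:
        raise ValueError(
            f"{svd.m} components exceed the cap of {COMPONENT_CAP}; truncate the SVD harder"
        )
    d_tilde = np.asarray(d_tilde, dtype=float)
    if np.any(d_tilde <= 0):
        raise ValueError("all variance weights must be > 0 (apply the PP floor)")
    y = np.asarray(y, dtype=float)
    mu = estimate_mu(y) if mu_hat is None else mu_hat
    yc = y - mu
    W = svd.weighted_gram(d_tilde)
    W_inv = _spd_inverse(W)
    A = np.diag(svd.S**2) + lambda_b * W_inv
    rhs = svd.S * (svd.U.T @ yc)
    s_c = scipy.linalg.solve(A, rhs, assume_a="pos")
    return s_c, W_inv


def _spd_inverse(W: np.ndarray) -> np.ndarray:
    try:
        cf = scipy.linalg.cho_factor(W)
    except np.linalg.LinAlgError:
        jitter = 1e-10 * float(np.mean(np.diag(W)))
        logger.warning("V'DV factorization failed; retrying with jitter %g (raise the PP floor if this recurs)", jitter)
        try:
            cf = scipy.linalg.cho_factor(W + jitter * np.eye(W.shape[0]))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                "V'DV is numerically singular even after jitter; raise the PP floor"
            ) from err
    return scipy.linalg.cho_solve(cf, np.eye(W.shape[0]))


def bayesc_snp_effects(d_tilde: np.ndarray, svd: MergedSVD, s_c_hat: np.ndarray, W_inv: np.ndarray) -> np.ndarray:
    """b_c = D V (V'DV)^-1 s_c, streamed per chromosome block."""
    return np.asarray(d_tilde, float) * svd.V_matvec(W_inv @ s_c_hat)


def fit_bayesc(
    svd: MergedSVD,
    y: np.ndarray,
    var: VarianceConfig,
    posterior: PerSnpPosterior | None = None,
    blup: BlupSolution | None = None,
) -> BayesCSolution:
    """End-to-end direct BayesC fit.

    Accepts a precomputed :class:`PerSnpPosterior` (or :class:`BlupSolution`
    to derive one); otherwise runs SNP-BLUP internally first.
    """
    if posterior is None:
        if blup is None:
            from .blup import fit_snp_blup

            blup = fit_snp_blup(svd, y, var)
        posterior = per_snp_posterior(blup, var)
    mu = estimate_mu(np.asarray(y, float))
    s_c, W_inv = solve_bayesc_components(svd, y, posterior.d_tilde, var.lambda_b, mu_hat=mu)
    b_c = bayesc_snp_effects(posterior.d_tilde, svd, s_c, W_inv)
    gebv = svd.U @ (svd.S * s_c)
    return BayesCSolution(mu_hat=mu, s_c_hat=s_c, b_c_hat=b_c, gebv=gebv)


def predict_gebv(effects: np.ndarray, target: StandardizedGenotypes | np.ndarray) -> np.ndarray:
    """GEBV = X_target @ effects; X_target must be standardized with the
    reference-population allele frequencies."""
    X = target.X if isinstance(target, StandardizedGenotypes) else np.asarray(target, float)
    effects = np.asarray(effects, dtype=float)
    if X.shape[1] != len(effects):
        raise ValueError(
            f"SNP set mismatch: target has {X.shape[1]} SNPs, effects has {len(effects)}"
        )
    return X @ effects
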