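"""SNP-BLUP (ridge regression of marker effects) solved in SVD component space.

With X = U S V' and standardized genotypes (X'1 = 0), Henderson's mixed model
equations for the component effects s = V'b are diagonal:

    N mu_hat = 1'y,    (S^2 + I lambda_b) s_hat = S U'(y - 1 mu_hat),

with lambda_b = sigma_e^2 / sigma_b^2.  SNP effects are b_hat = V s_hat and
the per-SNP prediction error variance is the quadratic form
V_j. (S^2 + I lambda_b)^-1 V_j.' sigma_e^2, augmented with the prior-variance
mass sigma_b^2 (1 - ||V_j.||^2) carried by any loading outside the retained
component space (present whenever k > N or after truncation).  With that term
the PEV equals the dense MME-inverse diagonal exactly at full rank, and a SNP
orthogonal to every retained component reports the no-information value
sigma_b^2 rather than zero.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import VarianceConfig
from .svd import MergedSVD


@dataclass
class BlupSolution:
    mu_hat: float
    s_hat: np.ndarray
    b_hat: np.ndarray
    pev: np.ndarray
    lambda_b: float


def estimate_mu(y: np.ndarray) -> float:
    """Intercept from the first MME row: N mu = 1'y (valid since X'1 = 0)."""
    y = np.asarray(y, dtype=float)
    if y.size == 0:
        raise ValueError("empty phenotype vector")
    return float(y.mean())


def solve_components(svd: MergedSVD, y_centered: np.ndarray, lambda_b: float) -> np.ndarray:
    """s_hat_i = S_i (U'y_c)_i / (S_i^2 + lambda_b) — element-wise diagonal solve."""
    if lambda_b <= 0:
        raise ValueError("lambda_b must be > 0")
    return svd.S * (svd.U.T @ y_centered) / (svd.S**2 + lambda_b)


def snp_effects(svd: MergedSVD, s_hat: np.ndarray) -> np.ndarray:
    """b_hat = V s_hat, streamed per chromosome block."""
    return svd.V_matvec(s_hat)


def snp_pev(svd: MergedSVD, lambda_b: float, sigma_e2: float) -> np.ndarray:
    """Per-SNP prediction error variance including the null-space prior mass."""
    if lambda_b <= 0 or sigma_e2 <= 0:
        raise ValueError("lambda_b and sigma_e2 must be > 0")
    sigma_b2 = sigma_e2 / lambda_b
    core = svd.row_weighted_sq(sigma_e2 / (svd.S**2 + lambda_b))
    residual_norm = np.clip(1.0 - svd.row_norm_sq(), 0.0, None)
    return core + sigma_b2 * residual_norm


def fit_snp_blup(svd: MergedSVD, y: np.ndarray, var: VarianceConfig) -> BlupSolution:
    """Full SNP-BLUP fit: intercept, component effects, SNP effects, PEV."""
    mu = estimate_mu(y)
    s_hat = solve_components(svd, np.asarray(y, float) - mu, var.lambda_b)
    return BlupSolution(
        mu_hat=mu,
        s_hat=s_hat,
        b_hat=snp_effects(svd, s_hat),
        pev=snp_pev(svd, var.lambda_b, var.sigma_e2),
        lambda_b=var.lambda_b,
    )


def fitted_gebv(svd: MergedSVD, s_hat: np.ndarray) -> np.ndarray:
    """Breeding values of the training individuals, U S s_hat."""
    return svd.U @ (svd.S * s_hat)
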