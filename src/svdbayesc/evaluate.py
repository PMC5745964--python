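"""Accuracy/bias evaluation over descendant generations and study orchestration.

Accuracy is the Pearson correlation between true and estimated breeding
values; bias is the coefficient of the regression of TBV on GEBV (1 means
unbiased; values below 1 mean the GEBV spread is too large).  ``run_study``
executes the whole protocol — simulate, SVD, fit each method in the reference
generation, predict forward — for several replicates, and also reports the
sum of posterior QTL probabilities per method (the two sums are reported side
by side and are not expected to agree).
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, replace

import numpy as np
import pandas as pd
import scipy.stats

from . import bayesc as _bayesc
from . import blup as _blup
from . import mcmc as _mcmc
from .io import VarianceConfig, standardize
from .simulate import SimConfig, simulate_study
from .svd import svd_by_chromosome

logger = logging.getLogger(__name__)

METHODS = ("snp_blup", "bayesc_svd", "bayesc_mcmc")


def accuracy(tbv, gebv) -> float:
    """Pearson correlation of true and estimated breeding values."""
    tbv = np.asarray(tbv, float)
    gebv = np.asarray(gebv, float)
    if len(tbv) != len(gebv) or len(tbv) < 3:
        raise ValueError("need two aligned vectors of length >= 3")
    if tbv.std() == 0 or gebv.std() == 0:
        return float("nan")
    return float(np.corrcoef(tbv, gebv)[0, 1])


def bias(tbv, gebv) -> float:
    """Slope of the OLS regression of TBV on GEBV (cov/var of the GEBV)."""
    tbv = np.asarray(tbv, float)
    gebv = np.asarray(gebv, float)
    v = gebv.var()
    if v == 0:
        return float("nan")
    return float(np.cov(tbv, gebv, ddof=0)[0, 1] / v)


def declining_trend(values, generations=None) -> bool:
    """True when the profile declines overall (Kendall tau < 0), tolerating
    single-step noise inversions."""
    values = np.asarray(values, float)
    if generations is None:
        generations = np.arange(1, len(values) + 1)
    tau = scipy.stats.kendalltau(generations, values).statistic
    return bool(tau < 0)


def run_study(
    cfg: SimConfig,
    methods=METHODS,
    replicates: int = 4,
    seed: int = 0,
    pi: float = 0.01,
    slab_mode: str = "fixed_slab",
    svd_frac: float = 0.95,
    mcmc_config: _mcmc.McmcConfig | None = None,
    collect_reports: bool = False,
):
    """Run the full evaluation protocol and return (profiles, summary).

    ``profiles`` is a tidy DataFrame (replicate, method, generation,
    accuracy, bias, n); ``summary`` holds per-replicate sums of posterior
    probabilities and the run manifest.  Randomness derives from ``seed``:
    replicate r uses seed + r for the simulation and the sampler.
    """
    unknown = set(methods) - set(METHODS)
    if unknown:
        raise ValueError(f"unknown methods: {sorted(unknown)}")
    rows = []
    sum_pp = {"bayesc_svd": [], "bayesc_mcmc": []}
    reports = []
    t0 = time.time()
    for rep in range(replicates):
        study = simulate_study(replace(cfg, seed=seed + rep))
        panel = study.reference
        Xs = standardize(panel)
        var = VarianceConfig.from_variances(
            sigma_g2=1.0,  # Var(TBV) is forced to 1 in the reference
            sigma_e2=(1.0 - cfg.h2) / cfg.h2,
            n_snps=panel.n_snps,
            pi=pi,
            slab_mode=slab_mode,
        )
        svd = svd_by_chromosome(Xs.X, panel.snp_map["chrom"].to_numpy(), frac=svd_frac)
        p = panel.freq
        scale = np.sqrt(2 * p * (1 - p))

        effects = {}
        rep_report = {"replicate": rep, "snp_map": panel.snp_map, "freq": p}
        if "snp_blup" in methods or "bayesc_svd" in methods:
            fit = _blup.fit_snp_blup(svd, study.phenotypes.y, var)
            effects["snp_blup"] = fit.b_hat
            rep_report["snp_blup"] = fit
        if "bayesc_svd" in methods:
            post = _bayesc.per_snp_posterior(fit, var)
            bc = _bayesc.fit_bayesc(svd, study.phenotypes.y, var, posterior=post)
            effects["bayesc_svd"] = bc.b_c_hat
            sum_pp["bayesc_svd"].append(float(post.pp.sum()))
            rep_report["bayesc_svd"] = post
        if "bayesc_mcmc" in methods:
            mcfg = mcmc_config or _mcmc.McmcConfig()
            mcfg = replace(
                mcfg, seed=seed + rep, pi=pi, sigma2=var.sigma2, sigma_e2=var.sigma_e2
            )
            mres = _mcmc.gibbs_bayesc(Xs.X, study.phenotypes.y, mcfg)
            effects["bayesc_mcmc"] = mres.b_bar
            sum_pp["bayesc_mcmc"].append(float(mres.pp_mcmc.sum()))
            rep_report["bayesc_mcmc"] = mres

        for gen, (counts, tbv) in enumerate(
            zip(study.genotypes_by_generation, study.tbv_by_generation), start=1
        ):
            Xg = (counts - 2 * p) / scale
            for method, b in effects.items():
                if method not in methods:
                    continue
                gebv = Xg @ b
                rows.append(
                    dict(
                        replicate=rep,
                        method=method,
                        generation=gen,
                        accuracy=accuracy(tbv, gebv),
                        bias=bias(tbv, gebv),
                        n=len(tbv),
                    )
                )
        if collect_reports:
            reports.append(rep_report)
    profiles = pd.DataFrame(rows)
    manifest = {
        "config": {k: v for k, v in asdict(cfg).items()},
        "config_hash": hashlib.sha256(json.dumps(asdict(cfg), sort_keys=True, default=str).encode()).hexdigest()[:12],
        "seed": seed,
        "replicates": replicates,
        "methods": list(methods),
        "pi": pi,
        "slab_mode": slab_mode,
        "svd_frac": svd_frac,
        "elapsed_s": round(time.time() - t0, 2),
    }
    summary = {
        "sum_pp": {k: v for k, v in sum_pp.items() if v},
        "manifest": manifest,
    }
    if collect_reports:
        summary["reports"] = reports
    return profiles, summary


def holdout_tune(
    X: np.ndarray,
    y: np.ndarray,
    chrom_labels: np.ndarray,
    sigma_g2: float,
    sigma_e2: float,
    pi_grid,
    n_folds: int = 2,
    seed: int = 0,
    slab_mode: str = "pi_consistent",
    svd_frac: float = 1.0,
):
    """Grid search over pi by individual-level hold-out validation accuracy.

    The SVD of each training fold is computed once and reused across the
    whole grid.  Returns a DataFrame (pi, fold, accuracy) and the best pi by
    mean validation accuracy (validation accuracy is measured against the
    held-out phenotypes, the only proxy for TBV available in real data).
    """
    if n_folds < 2:
        raise ValueError("need at least 2 folds")
    rng = np.random.default_rng(seed)
    N = X.shape[0]
    fold_of = rng.integers(0, n_folds, size=N)
    if len(np.unique(fold_of)) < n_folds or np.min(np.bincount(fold_of, minlength=n_folds)) < 3:
        fold_of = np.arange(N) % n_folds  # degenerate random split; fall back to round robin
    rows = []
    for fold in range(n_folds):
        train = fold_of != fold
        test = ~train
        svd = svd_by_chromosome(X[train], chrom_labels, frac=svd_frac)
        for pi in pi_grid:
            var = VarianceConfig.from_variances(
                sigma_g2, sigma_e2, X.shape[1], pi=pi, slab_mode=slab_mode
            )
            fit = _blup.fit_snp_blup(svd, y[train], var)
            post = _bayesc.per_snp_posterior(fit, var)
            bc = _bayesc.fit_bayesc(svd, y[train], var, posterior=post)
            pred = X[test] @ bc.b_c_hat
            rows.append(dict(pi=pi, fold=fold, accuracy=accuracy(y[test], pred)))
    table = pd.DataFrame(rows)
    best = table.groupby("pi")["accuracy"].mean().idxmax()
    return table, float(best)
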