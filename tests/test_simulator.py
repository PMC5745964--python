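import numpy as np
import pytest
import scipy.stats

from svdbayesc import (
    SimConfig,
    assign_tbv_and_phenotypes,
    sample_qtl,
    simulate_population,
    simulate_study,
    standardize,
    thin_to_chip,
    watterson_expectation,
)
from svdbayesc.simulate import population_to_genotypes


def _tiny_cfg(**overrides):
    base = dict(
        n_hist_gen=150,
        chrom_len_bp=200_000,
        mut_rate_per_bp=4e-6,
        ne_hist=50,
        n_ref=50,
        n_qtl_per_chrom=5,
        ne_forward=30,
        seed=3,
    )
    base.update(overrides)
    return SimConfig.desk(**base)


def test_zero_mutation_rate_gives_no_sites():
    cfg = _tiny_cfg(mut_rate_per_bp=0.0, n_hist_gen=30)
    pop, _ = simulate_population(cfg)
    g = population_to_genotypes(pop, cfg)
    assert g.n_snps == 0


def test_same_seed_identical_haplotypes():
    cfg = _tiny_cfg(n_hist_gen=60)
    g1 = population_to_genotypes(simulate_population(cfg)[0], cfg)
    g2 = population_to_genotypes(simulate_population(cfg)[0], cfg)
    np.testing.assert_array_equal(g1.counts, g2.counts)
    np.testing.assert_array_equal(g1.snp_map["pos"].to_numpy(), g2.snp_map["pos"].to_numpy())
    # distinct seeds diverge
    cfg2 = _tiny_cfg(seed=4, n_hist_gen=60)
    g3 = population_to_genotypes(simulate_population(cfg2)[0], cfg2)
    assert g3.n_snps != g1.n_snps or not np.array_equal(g3.counts, g1.counts)


def test_segregating_sites_near_watterson():
    """Observed segregating-site count within 3 SD of theta * a_{n-1};
    the population itself is the sample (n_ref = ne_hist)."""
    cfg = _tiny_cfg(n_hist_gen=600, ne_hist=60, n_ref=60, chrom_len_bp=300_000)
    pop, _ = simulate_population(cfg)
    g = population_to_genotypes(pop, cfg)
    mean, sd = watterson_expectation(cfg, n_haplotypes=2 * cfg.n_ref)
    assert abs(g.n_snps - mean) < 3 * sd


def test_site_frequency_spectrum_shape():
    """Folded-unfolded check: derived-allele counts are enriched at low
    frequencies roughly like 1/i (loose chi-square on coarse bins)."""
    cfg = _tiny_cfg(n_hist_gen=600, ne_hist=60, n_ref=60, chrom_len_bp=300_000)
    pop, _ = simulate_population(cfg)
    g = population_to_genotypes(pop, cfg)
    counts = g.counts.sum(axis=0)  # derived-allele counts, 1..2n-1
    n = 2 * cfg.n_ref
    edges = np.array([1, 3, 8, 20, n])
    obs = np.array([np.sum((counts >= lo) & (counts < hi)) for lo, hi in zip(edges[:-1], edges[1:])])
    i = np.arange(1, n)
    expect_w = np.array([np.sum(1.0 / i[(i >= lo) & (i < hi)]) for lo, hi in zip(edges[:-1], edges[1:])])
    expected = expect_w / expect_w.sum() * obs.sum()
    chi2 = np.sum((obs - expected) ** 2 / expected)
    # very loose: LD makes sites non-independent, so only gross shape failure
    # (e.g. uniform spectrum) would exceed this
    assert chi2 < 30 * len(obs)
    # per-class comparison: singletons outnumber any intermediate-frequency class
    assert np.sum(counts == 1) > np.sum(counts == n // 2)


def test_qtl_sampling_contracts(mini_study, rng):
    g = mini_study.reference
    cfg = mini_study.config
    qtl, t = sample_qtl(g, cfg, rng)
    assert len(qtl) == cfg.n_chrom * cfg.n_qtl_per_chrom
    maf = np.minimum(g.freq, 1 - g.freq)
    assert np.all(maf[qtl] > cfg.maf_threshold)
    assert np.all(t[np.setdiff1d(np.arange(g.n_snps), qtl)] == 0)
    # n_qtl = 0 -> zero effect vector
    from dataclasses import replace

    qtl0, t0 = sample_qtl(g, replace(cfg, n_qtl_per_chrom=0), rng)
    assert len(qtl0) == 0 and np.all(t0 == 0)
    with pytest.raises(ValueError):
        sample_qtl(g, replace(cfg, n_qtl_per_chrom=g.n_snps + 1), rng)


def test_qtl_sampling_uniformity(rng):
    """Selection frequencies across resamples are uniform (chi-square)."""
    from conftest import make_genotypes
    from dataclasses import replace

    g = make_genotypes(rng, n=80, k=60, min_p=0.2, n_chrom=1)
    cfg = _tiny_cfg(n_qtl_per_chrom=6)
    hits = np.zeros(60)
    n_draws = 500
    for _ in range(n_draws):
        qtl, _ = sample_qtl(g, cfg, rng)
        hits[qtl] += 1
    expected = n_draws * 6 / 60
    chi2 = np.sum((hits - expected) ** 2 / expected)
    assert scipy.stats.chi2.sf(chi2, df=59) > 1e-4


def test_tbv_scaling_and_heritability(mini_study):
    assert np.var(mini_study.tbv_reference) == pytest.approx(1.0, abs=1e-10)
    y = mini_study.phenotypes.y
    h2_real = np.var(mini_study.tbv_reference) / np.var(y)
    se = 0.25 * np.sqrt(6 / len(y))
    assert abs(h2_real - mini_study.config.h2) < 3 * se + 0.05


def test_phenotype_regression_slope(mini_study):
    """y = tbv + independent noise, so the regression of y on tbv has slope 1."""
    tbv = mini_study.tbv_reference
    y = mini_study.phenotypes.y
    slope = np.cov(y, tbv)[0, 1] / np.var(tbv)
    assert slope == pytest.approx(1.0, abs=3 / np.sqrt(len(y)))


def test_single_qtl_tbv_is_rescaled_column(rng):
    from conftest import make_genotypes

    g = make_genotypes(rng, n=100, k=20, min_p=0.2)
    X = standardize(g).X
    t = np.zeros(20)
    t[4] = 2.5
    alpha, tbv, y = assign_tbv_and_phenotypes(X, t, 0.5, rng)
    assert np.var(tbv) == pytest.approx(1.0, abs=1e-12)
    assert abs(np.corrcoef(tbv, X[:, 4])[0, 1]) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        assign_tbv_and_phenotypes(X, np.zeros(20), 0.5, rng)


def test_forward_generations_structure(mini_study):
    cfg = mini_study.config
    assert len(mini_study.genotypes_by_generation) == cfg.n_forward_gen
    for counts, tbv in zip(mini_study.genotypes_by_generation, mini_study.tbv_by_generation):
        assert counts.shape == (cfg.ne_forward, mini_study.reference.n_snps)
        assert len(tbv) == cfg.ne_forward
        assert np.all((counts >= 0) & (counts <= 2))


def test_drift_erodes_heterozygosity(mini_study):
    """Mean expected heterozygosity declines across forward generations at
    roughly (1 - 1/(2Ne)) per generation."""
    cfg = mini_study.config
    p_ref = mini_study.reference.freq
    het = [np.mean(2 * p_ref * (1 - p_ref))]
    for counts in mini_study.genotypes_by_generation:
        p = counts.mean(axis=0) / 2
        het.append(np.mean(2 * p * (1 - p)))
    het = np.array(het)
    expected_ratio = (1 - 1 / (2 * cfg.ne_forward)) ** cfg.n_forward_gen
    observed_ratio = het[-1] / het[0]
    assert 0.5 * expected_ratio < observed_ratio < 1.02
    # overall monotone-ish decline
    assert het[-1] < het[0]


def test_thin_to_chip(mini_study):
    g = mini_study.reference
    keep = thin_to_chip(g, g.n_snps)
    assert len(keep) == g.n_snps  # identity at full size
    keep = thin_to_chip(g, 20)
    assert 15 <= len(keep) <= 25
    # approximately even spacing: no gap exceeds ~4x the ideal gap per chrom
    for chrom in g.snp_map["chrom"].unique():
        sel = keep[(g.snp_map["chrom"].to_numpy()[keep]) == chrom]
        pos = g.snp_map["pos"].to_numpy()[sel]
        span = g.snp_map.loc[g.snp_map["chrom"] == chrom, "pos"]
        ideal = (span.max() - span.min()) / max(len(sel) - 1, 1)
        assert np.max(np.diff(pos)) < 6 * ideal
    # exclusion contract
    keep = thin_to_chip(g, 20, exclude=mini_study.qtl_indices)
    assert len(np.intersect1d(keep, mini_study.qtl_indices)) == 0


def test_forward_determinism():
    cfg = _tiny_cfg(n_hist_gen=60)
    s1 = simulate_study(cfg)
    s2 = simulate_study(cfg)
    np.testing.assert_array_equal(s1.tbv_by_generation[-1], s2.tbv_by_generation[-1])
    np.testing.assert_array_equal(s1.genotypes_by_generation[0], s2.genotypes_by_generation[0])
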