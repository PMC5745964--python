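import numpy as np
import pandas as pd
import pytest

from svdbayesc import GenotypeMatrix, SimConfig, simulate_study, standardize


def make_genotypes(rng, n=50, k=200, n_chrom=2, min_p=0.05):
    """Random polymorphic allele-count matrix with a sorted SNP map."""
    while True:
        p = rng.uniform(min_p, 1 - min_p, size=k)
        counts = rng.binomial(2, p, size=(n, k)).astype(np.int8)
        freq = counts.mean(axis=0) / 2
        if np.all((freq > 0) & (freq < 1)):
            break
    per = k // n_chrom
    chroms = np.repeat([f"chr{i+1}" for i in range(n_chrom)], per)
    chroms = np.concatenate([chroms, np.repeat(f"chr{n_chrom}", k - len(chroms))])
    pos = np.concatenate(
        [np.sort(rng.choice(np.arange(1, 10 * k), size=np.sum(chroms == c), replace=False)) for c in pd.unique(chroms)]
    )
    snp_map = pd.DataFrame({"chrom": chroms, "pos": pos, "id": [f"snp{j}" for j in range(k)]})
    return GenotypeMatrix(counts=counts, snp_map=snp_map)


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)


@pytest.fixture
def genotypes(rng):
    return make_genotypes(rng)


@pytest.fixture(scope="session")
def mini_study():
    """A fast but complete simulated study shared by end-to-end unit tests."""
    cfg = SimConfig.desk(
        n_hist_gen=200,
        chrom_len_bp=300_000,
        mut_rate_per_bp=3e-6,
        ne_hist=60,
        n_ref=150,
        n_qtl_per_chrom=8,
        ne_forward=40,
        seed=7,
    )
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def mini_standardized(mini_study):
    return standardize(mini_study.reference)
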