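"""Forward-in-time Wright-Fisher simulator with recombination and
infinite-sites mutation.

The historical population evolves under Wright's idealized structure (random
union of gametes with replacement, constant size, non-overlapping
generations, hermaphroditic, selfing allowed) for ``n_hist_gen`` generations
to build up mutation-drift equilibrium and LD; the final generation is
expanded to ``n_ref`` individuals and becomes the reference population.  Each
gamete receives Poisson(chrom_morgans) crossovers at uniform positions and
Poisson(mut_rate_per_bp * chrom_len_bp) new mutations, each at a
never-before-used base-pair position (infinite sites).  Haplotypes are sparse
sorted position arrays; sites fixed in the whole population are pruned
periodically (they are monomorphic and carry no information).

From the reference panel (MAF-filtered), causative SNPs are drawn uniformly
per chromosome with standard-normal effects; true breeding values are
TBV = alpha X t with alpha forcing Var(TBV) = 1 in the reference, and
phenotypes add N(0, (1-h2)/h2) noise.  Ten further generations at a reduced
effective size provide the forward-prediction sets; their TBV reuse the
reference alpha, effects and allele frequencies.  No new mutations arise in
the forward generations by default (new variants would carry zero estimated
effect and are absent from the reference panel anyway).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, PhenotypeVector, filter_maf, standardize

# individual = list over chromosomes of (hap1, hap2), hap = sorted int64 array
MAX_SEGREGATING_SITES = 5_000_000


@dataclass
class SimConfig:
    """Study design; the full-scale defaults mirror the validated protocol
    (20 chromosomes of 1 Morgan / 1e8 bp, Ne=1000 for 10,000 historical
    generations, reference of 10,000, mu=1e-8/bp, 200 QTL per chromosome,
    h2=0.5, 10 forward generations at Ne=100)."""

    n_chrom: int = 20
    chrom_len_bp: int = 100_000_000
    chrom_morgans: float = 1.0
    ne_hist: int = 1000
    n_hist_gen: int = 10_000
    n_ref: int = 10_000
    mut_rate_per_bp: float = 1e-8
    maf_threshold: float = 0.01
    n_qtl_per_chrom: int = 200
    h2: float = 0.5
    ne_forward: int = 100
    n_forward_gen: int = 10
    mutations_in_forward: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_len_bp", "ne_hist", "n_hist_gen", "n_ref"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.h2 < 1:
            raise ValueError("h2 must be in (0, 1)")

    @classmethod
    def desk(cls, **overrides) -> "SimConfig":
        """Desk-scale preset: 2 chromosomes of 1 Morgan / 1e6 bp, Ne=100 for
        1000 generations, reference of 500, mu=1e-6/bp (same per-bp SNP
        density regime as full scale), 20 QTL per chromosome, forward Ne=50."""
        base = dict(
            n_chrom=2,
            chrom_len_bp=1_000_000,
            ne_hist=100,
            n_hist_gen=1000,
            n_ref=500,
            mut_rate_per_bp=1e-6,
            n_qtl_per_chrom=20,
            ne_forward=50,
        )
        base.update(overrides)
        return cls(**base)

    @classmethod
    def full_scale(cls, **overrides) -> "SimConfig":
        """Full-scale preset (cluster-only: days of compute at this size)."""
        return cls(**overrides)


@dataclass
class SimulatedStudy:
    """Everything the evaluation protocol needs: reference data, the causal
    architecture, and per-generation descendant genotypes with their TBV."""

    reference: GenotypeMatrix
    phenotypes: PhenotypeVector
    qtl_indices: np.ndarray  # column indices into the reference panel
    qtl_effects: np.ndarray  # full k vector t (0 off-QTL)
    alpha: float
    tbv_reference: np.ndarray
    genotypes_by_generation: list  # counts matrices over the reference panel, gens 1..n
    tbv_by_generation: list  # TBV arrays, gens 1..n
    config: SimConfig = None  # type: ignore[assignment]


# ---------------------------------------------------------------------------
# gamete formation


def _recombine(h1: np.ndarray, h2: np.ndarray, morgans: float, length: int, rng) -> np.ndarray:
    n_cx = rng.poisson(morgans)
    if n_cx == 0:
        return (h1 if rng.integers(2) == 0 else h2).copy()
    cuts = np.sort(rng.integers(1, length + 1, size=n_cx))
    bounds = np.concatenate(([0], cuts, [length + 1]))
    start = rng.integers(2)
    pieces = []
    for seg in range(len(bounds) - 1):
        src = h1 if (start + seg) % 2 == 0 else h2
        lo = np.searchsorted(src, bounds[seg])
        hi = np.searchsorted(src, bounds[seg + 1])
        if hi > lo:
            pieces.append(src[lo:hi])
    if not pieces:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(pieces)


def _mutate(hap: np.ndarray, cfg: SimConfig, used: set, rng) -> np.ndarray:
    n_mut = rng.poisson(cfg.mut_rate_per_bp * cfg.chrom_len_bp)
    if n_mut == 0:
        return hap
    new = []
    while len(new) < n_mut:
        pos = int(rng.integers(1, cfg.chrom_len_bp + 1))
        if pos not in used:  # infinite sites: each mutation at a fresh position
            used.add(pos)
            new.append(pos)
    merged = np.concatenate((hap, np.array(new, dtype=np.int64)))
    merged.sort()
    return merged


def _gamete(ind, cfg: SimConfig, used_by_chrom, rng, mutate: bool):
    gam = []
    for c in range(cfg.n_chrom):
        h = _recombine(ind[c][0], ind[c][1], cfg.chrom_morgans, cfg.chrom_len_bp, rng)
        if mutate:
            h = _mutate(h, cfg, used_by_chrom[c], rng)
        gam.append(h)
    return gam


def _wf_generation(pop, n_offspring: int, cfg: SimConfig, used_by_chrom, rng, mutate: bool):
    n_parents = len(pop)
    offspring = []
    for _ in range(n_offspring):
        pa = pop[int(rng.integers(n_parents))]
        ma = pop[int(rng.integers(n_parents))]
        g1 = _gamete(pa, cfg, used_by_chrom, rng, mutate)
        g2 = _gamete(ma, cfg, used_by_chrom, rng, mutate)
        offspring.append([(g1[c], g2[c]) for c in range(cfg.n_chrom)])
    return offspring


def _prune_fixed(pop, n_chrom: int) -> None:
    """Drop positions carried by every haplotype (fixed => monomorphic)."""
    for c in range(n_chrom):
        fixed = pop[0][c][0]
        for ind in pop:
            for h in ind[c]:
                if fixed.size == 0:
                    break
                fixed = np.intersect1d(fixed, h, assume_unique=True)
            if fixed.size == 0:
                break
        if fixed.size:
            for ind in pop:
                ind[c] = tuple(h[~np.isin(h, fixed, assume_unique=True)] for h in ind[c])


def simulate_population(cfg: SimConfig, rng=None):
    """Run the historical generations and the reference expansion.

    Returns (population, used_positions_by_chrom); the population has
    ``cfg.n_ref`` individuals.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    empty = np.empty(0, dtype=np.int64)
    pop = [[(empty, empty) for _ in range(cfg.n_chrom)] for _ in range(cfg.ne_hist)]
    used_by_chrom = [set() for _ in range(cfg.n_chrom)]
    for gen in range(cfg.n_hist_gen - 1):
        pop = _wf_generation(pop, cfg.ne_hist, cfg, used_by_chrom, rng, mutate=True)
        if (gen + 1) % 100 == 0:
            _prune_fixed(pop, cfg.n_chrom)
            _check_site_budget(pop, cfg)
    # final historical generation: expand to the reference size
    pop = _wf_generation(pop, cfg.n_ref, cfg, used_by_chrom, rng, mutate=True)
    _prune_fixed(pop, cfg.n_chrom)
    return pop, used_by_chrom


def _check_site_budget(pop, cfg: SimConfig) -> None:
    total = sum(ind[c][0].size + ind[c][1].size for ind in pop for c in range(cfg.n_chrom))
    if total > MAX_SEGREGATING_SITES:
        raise MemoryError(
            f"segregating-site budget exceeded ({total} haplotype entries); "
            "reduce chromosome length or the mutation rate"
        )


# ---------------------------------------------------------------------------
# genotype extraction


def population_to_genotypes(pop, cfg: SimConfig) -> GenotypeMatrix:
    """Dense allele-count matrix over all segregating sites (lossless)."""
    n = len(pop)
    counts_blocks = []
    map_rows = []
    for c in range(cfg.n_chrom):
        haps = [h for ind in pop for h in ind[c]]
        if haps and any(h.size for h in haps):
            positions = np.unique(np.concatenate([h for h in haps if h.size]))
        else:
            positions = np.empty(0, dtype=np.int64)
        block = np.zeros((n, positions.size), dtype=np.int8)
        for i, ind in enumerate(pop):
            for h in ind[c]:
                if h.size:
                    block[i, np.searchsorted(positions, h)] += 1
        # keep polymorphic sites only (fixed-in-sample columns carry p=1)
        col_sums = block.sum(axis=0, dtype=np.int64)
        poly = (col_sums > 0) & (col_sums < 2 * n)
        positions, block = positions[poly], block[:, poly]
        counts_blocks.append(block)
        map_rows.append(
            pd.DataFrame(
                {"chrom": f"chr{c + 1}", "pos": positions, "id": [f"chr{c + 1}_{p}" for p in positions]}
            )
        )
    counts = np.hstack(counts_blocks) if counts_blocks else np.zeros((n, 0), dtype=np.int8)
    snp_map = pd.concat(map_rows, ignore_index=True) if map_rows else pd.DataFrame(columns=["chrom", "pos", "id"])
    return GenotypeMatrix(counts=counts, snp_map=snp_map)


def _counts_on_panel(pop, panel_map: pd.DataFrame, cfg: SimConfig) -> np.ndarray:
    """Allele counts of a population restricted to the reference SNP panel."""
    n = len(pop)
    counts = np.zeros((n, len(panel_map)), dtype=np.int8)
    col0 = 0
    for c in range(cfg.n_chrom):
        chrom = f"chr{c + 1}"
        panel_pos = panel_map.loc[panel_map["chrom"] == chrom, "pos"].to_numpy()
        for i, ind in enumerate(pop):
            for h in ind[c]:
                if h.size and panel_pos.size:
                    idx = np.searchsorted(panel_pos, h)
                    ok = (idx < panel_pos.size)
                    ok[ok] = panel_pos[idx[ok]] == h[ok]
                    counts[i, col0 + idx[ok]] += 1
        col0 += panel_pos.size
    return counts


# ---------------------------------------------------------------------------
# trait architecture


def sample_qtl(g: GenotypeMatrix, cfg: SimConfig, rng):
    """Uniformly sample ``n_qtl_per_chrom`` causative SNPs per chromosome
    among the MAF-eligible ones; effects are standard normal, zero elsewhere."""
    maf = np.minimum(g.freq, 1 - g.freq)
    t = np.zeros(g.n_snps)
    chosen = []
    for chrom in pd.unique(g.snp_map["chrom"]):
        eligible = np.flatnonzero((g.snp_map["chrom"] == chrom).to_numpy() & (maf > cfg.maf_threshold))
        if eligible.size < cfg.n_qtl_per_chrom:
            raise ValueError(
                f"only {eligible.size} MAF-eligible SNPs on {chrom}; "
                f"lower n_qtl_per_chrom (currently {cfg.n_qtl_per_chrom})"
            )
        if cfg.n_qtl_per_chrom:
            idx = rng.choice(eligible, size=cfg.n_qtl_per_chrom, replace=False)
            chosen.append(np.sort(idx))
    qtl = np.concatenate(chosen) if chosen else np.empty(0, dtype=int)
    t[qtl] = rng.standard_normal(qtl.size)
    return qtl, t


def assign_tbv_and_phenotypes(X: np.ndarray, t: np.ndarray, h2: float, rng):
    """TBV = alpha X t with Var(TBV) = 1 forced; y = TBV + N(0, (1-h2)/h2)."""
    raw = X @ t
    sd = raw.std()
    if sd == 0:
        raise ValueError("X t is constant; cannot scale TBV")
    alpha = 1.0 / sd
    tbv = alpha * raw
    sigma_e2 = (1.0 - h2) / h2
    y = tbv + rng.normal(0.0, np.sqrt(sigma_e2), size=len(tbv))
    return alpha, tbv, y


def forward_generations(pop, panel: GenotypeMatrix, alpha: float, t: np.ndarray, cfg: SimConfig, rng):
    """Simulate the descendant generations and their TBV on the reference panel.

    TBV use the reference alpha, effects and allele frequencies throughout.
    """
    p = panel.freq
    scale = np.sqrt(2 * p * (1 - p))
    counts_list, tbv_list = [], []
    current = pop
    for _ in range(cfg.n_forward_gen):
        current = _wf_generation(
            current, cfg.ne_forward, cfg, [set() for _ in range(cfg.n_chrom)], rng,
            mutate=cfg.mutations_in_forward,
        )
        counts = _counts_on_panel(current, panel.snp_map, cfg)
        Xg = (counts - 2 * p) / scale
        counts_list.append(counts)
        tbv_list.append(alpha * (Xg @ t))
    return counts_list, tbv_list


def thin_to_chip(g: GenotypeMatrix, n_snps: int, exclude: np.ndarray | None = None) -> np.ndarray:
    """Evenly spaced (by position) chip subsample; returns kept column indices.

    ``exclude`` (e.g. the causative SNPs) are removed first; the remaining
    SNPs of each chromosome are thinned proportionally to its share of k.
    """
    if n_snps > g.n_snps:
        raise ValueError("cannot thin to more SNPs than available")
    mask = np.ones(g.n_snps, dtype=bool)
    if exclude is not None:
        mask[np.asarray(exclude, dtype=int)] = False
    candidates = np.flatnonzero(mask)
    if n_snps >= candidates.size:
        return candidates
    keep = []
    chroms = g.snp_map["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        on_c = candidates[chroms[candidates] == chrom]
        quota = int(round(n_snps * on_c.size / candidates.size))
        quota = max(1, min(quota, on_c.size))
        sel = np.unique(np.linspace(0, on_c.size - 1, quota).round().astype(int))
        keep.append(on_c[sel])
    return np.sort(np.concatenate(keep))


# ---------------------------------------------------------------------------


def simulate_study(cfg: SimConfig, rng=None) -> SimulatedStudy:
    """Full protocol: history -> reference -> QTL -> phenotypes -> descendants."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    pop, _ = simulate_population(cfg, rng)
    raw = population_to_genotypes(pop, cfg)
    panel = filter_maf(raw, cfg.maf_threshold)
    qtl, t = sample_qtl(panel, cfg, rng)
    Xs = standardize(panel)
    alpha, tbv, y = assign_tbv_and_phenotypes(Xs.X, t, cfg.h2, rng)
    counts_by_gen, tbv_by_gen = forward_generations(pop, panel, alpha, t, cfg, rng)
    return SimulatedStudy(
        reference=panel,
        phenotypes=PhenotypeVector(ids=panel.ids, y=y),
        qtl_indices=qtl,
        qtl_effects=t,
        alpha=alpha,
        tbv_reference=tbv,
        genotypes_by_generation=counts_by_gen,
        tbv_by_generation=tbv_by_gen,
        config=cfg,
    )


def watterson_expectation(cfg: SimConfig, n_haplotypes: int):
    """(E[S], SD[S]) for the whole genome under neutral equilibrium.

    theta = 4 Ne mu L per chromosome; E[S] = theta a_{n-1} with
    a_{n-1} = sum_{i<n} 1/i.  The SD uses the no-recombination variance
    theta a + theta^2 b (an upper bound when chromosomes recombine).
    """
    theta = 4.0 * cfg.ne_hist * cfg.mut_rate_per_bp * cfg.chrom_len_bp
    i = np.arange(1, n_haplotypes)
    a = float(np.sum(1.0 / i))
    b = float(np.sum(1.0 / i**2))
    mean_one = theta * a
    var_one = theta * a + theta**2 * b
    return cfg.n_chrom * mean_one, float(np.sqrt(cfg.n_chrom * var_one))
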