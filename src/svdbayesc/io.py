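"""Genotype/phenotype ingestion, MAF filtering, standardization and tabular output.

Genotypes are stored as allele-1 dosage counts in {0, 1, 2}. For VCF input the
ALT allele is allele 1; for the plain matrix format the counts are taken as
given. Allele frequencies are always computed from the data itself; descendant
genotypes are standardized with the *reference* population frequencies so that
effect estimates transfer across generations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MAP_COLUMNS = ("chrom", "pos", "id")


@dataclass
class GenotypeMatrix:
    """N x k allele-count matrix with its SNP map and allele-1 frequencies.

    ``counts[i, j]`` is the number of copies of allele 1 carried by individual
    ``i`` at SNP ``j``.  ``snp_map`` is a DataFrame with columns (chrom, pos,
    id), sorted by (chrom, pos).  ``freq[j]`` is the frequency of allele 1
    computed as ``mean(counts[:, j]) / 2``.
    """

    counts: np.ndarray
    snp_map: pd.DataFrame
    freq: np.ndarray = field(default=None)  # type: ignore[assignment]
    ids: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D array")
        if self.counts.shape[1] != len(self.snp_map):
            raise ValueError("snp_map length does not match number of SNP columns")
        self.snp_map = self.snp_map.reset_index(drop=True)
        if self.freq is None:
            self.freq = self.counts.mean(axis=0) / 2.0
        self.freq = np.asarray(self.freq, dtype=float)
        if self.ids is None:
            self.ids = np.array([f"ind{i + 1}" for i in range(self.counts.shape[0])])

    @property
    def n_individuals(self) -> int:
        return self.counts.shape[0]

    @property
    def n_snps(self) -> int:
        return self.counts.shape[1]

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Column subset with map and frequencies kept consistent."""
        return GenotypeMatrix(
            counts=self.counts[:, keep],
            snp_map=self.snp_map.iloc[np.atleast_1d(keep)].reset_index(drop=True),
            freq=self.freq[keep],
            ids=self.ids,
        )


@dataclass
class StandardizedGenotypes:
    """Centered/scaled genotype matrix X plus the frequencies used to build it."""

    X: np.ndarray
    freq: np.ndarray
    snp_map: pd.DataFrame
    ids: np.ndarray

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0]

    @property
    def n_snps(self) -> int:
        return self.X.shape[1]


@dataclass
class PhenotypeVector:
    ids: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=float)
        self.ids = np.asarray(self.ids)
        if len(self.ids) != len(self.y):
            raise ValueError("ids and y must have equal length")
        if not np.all(np.isfinite(self.y)):
            raise ValueError("phenotypes must be finite")


@dataclass
class VarianceConfig:
    """Variance/prior configuration for SNP-BLUP and BayesC.

    sigma_b2 is the per-SNP effect variance under SNP-BLUP (sigma_g2 / k);
    sigma2 is the BayesC slab variance of a non-zero effect; pi is the prior
    probability of a SNP having a non-zero effect.
    """

    sigma_g2: float
    sigma_e2: float
    sigma_b2: float
    pi: float = 0.01
    sigma2: float = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        for name in ("sigma_g2", "sigma_e2", "sigma_b2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not 0 < self.pi <= 1:
            raise ValueError("pi must be in (0, 1]")
        if self.sigma2 is None:
            self.sigma2 = 0.001 * self.sigma_g2
        if self.sigma2 <= 0:
            raise ValueError("sigma2 must be > 0")

    @property
    def lambda_b(self) -> float:
        return self.sigma_e2 / self.sigma_b2

    @property
    def lambda_(self) -> float:
        return self.sigma_e2 / self.sigma2

    @classmethod
    def from_variances(
        cls,
        sigma_g2: float,
        sigma_e2: float,
        n_snps: int,
        pi: float = 0.01,
        slab_mode: str = "fixed_slab",
    ) -> "VarianceConfig":
        """Build a config from the genetic/residual variances.

        slab_mode "fixed_slab": sigma2 = 0.001 * sigma_g2 (each causal SNP
        explains a fraction 0.001 of the genetic variance).  slab_mode
        "pi_consistent": sigma2 = sigma_g2 / (n_snps * pi), so that the total
        genetic variance assumed by the mixture equals sigma_g2.
        """
        if slab_mode == "fixed_slab":
            sigma2 = 0.001 * sigma_g2
        elif slab_mode == "pi_consistent":
            sigma2 = sigma_g2 / (n_snps * pi)
        else:
            raise ValueError("slab_mode must be 'fixed_slab' or 'pi_consistent'")
        return cls(
            sigma_g2=sigma_g2,
            sigma_e2=sigma_e2,
            sigma_b2=sigma_g2 / n_snps,
            pi=pi,
            sigma2=sigma2,
        )


# ---------------------------------------------------------------------------
# ingestion


def read_genotypes(path, format: str = "matrix", map_path=None) -> GenotypeMatrix:
    """Read genotypes from a VCF or a plain whitespace-delimited count matrix.

    For ``format="vcf"`` only biallelic SNP records are used (others are
    skipped with a logged count); missing genotypes are mean-imputed to 2 p_j.
    For ``format="matrix"`` a sidecar 3-column map file (chrom, pos, id) is
    required via ``map_path`` (default: ``<path>.map``).
    """
    if format == "vcf":
        return _read_vcf(path)
    if format == "matrix":
        return _read_matrix(path, map_path)
    raise ValueError("format must be 'vcf' or 'matrix'")


def _read_vcf(path) -> GenotypeMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    ids = np.array(vcf.samples)
    rows = []
    records = []
    n_skipped = 0
    n_missing = 0
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            n_skipped += 1
            continue
        g = np.asarray(variant.gt_types, dtype=float)  # 0,1,2; 3 = missing
        miss = g == 3
        if miss.any():
            n_missing += int(miss.sum())
            obs = g[~miss]
            g[miss] = obs.mean() if obs.size else 0.0
        rows.append(g)
        records.append((variant.CHROM, variant.POS, variant.ID or f"{variant.CHROM}_{variant.POS}"))
    vcf.close()
    if n_skipped:
        logger.info("skipped %d non-biallelic/non-SNP records", n_skipped)
    if n_missing:
        logger.info("mean-imputed %d missing genotype calls", n_missing)
    if not rows:
        raise ValueError(f"no usable biallelic SNP records in {path}")
    counts = np.vstack(rows).T
    snp_map = pd.DataFrame(records, columns=list(MAP_COLUMNS))
    order = np.lexsort((snp_map["pos"].to_numpy(), snp_map["chrom"].to_numpy()))
    g = GenotypeMatrix(counts=counts[:, order], snp_map=snp_map.iloc[order], ids=ids)
    return g


def _read_matrix(path, map_path) -> GenotypeMatrix:
    counts = np.loadtxt(str(path), dtype=float, ndmin=2)
    if not np.all(np.isin(counts, (0, 1, 2))):
        raise ValueError("matrix genotypes must be allele counts in {0, 1, 2}")
    counts = counts.astype(np.int8)
    if map_path is None:
        map_path = str(path) + ".map"
    snp_map = pd.read_csv(map_path, sep=r"\s+", header=None, names=list(MAP_COLUMNS))
    if len(snp_map) != counts.shape[1]:
        raise ValueError("map file length does not match matrix columns")
    return GenotypeMatrix(counts=counts, snp_map=snp_map)


def write_matrix(g: GenotypeMatrix, path, map_path=None) -> None:
    """Write the plain matrix format (counts + sidecar map); round-trips exactly."""
    np.savetxt(str(path), g.counts, fmt="%d")
    if map_path is None:
        map_path = str(path) + ".map"
    g.snp_map.to_csv(map_path, sep="\t", header=False, index=False)


def write_vcf(g: GenotypeMatrix, path) -> None:
    """Emit a minimal VCF 4.2 with GT fields (REF=A, ALT=C placeholders)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in g.ids) + "\n")
        gt_codes = ("0/0", "0/1", "1/1")
        for j, rec in enumerate(g.snp_map.itertuples(index=False)):
            gts = "\t".join(gt_codes[c] for c in g.counts[:, j])
            fh.write(f"{rec.chrom}\t{rec.pos}\t{rec.id}\tA\tC\t.\t.\t.\tGT\t{gts}\n")


def read_phenotypes(path) -> PhenotypeVector:
    df = pd.read_csv(path, sep="\t", header=None, names=["id", "value"], comment="#")
    return PhenotypeVector(ids=df["id"].to_numpy(), y=df["value"].to_numpy(float))


def write_phenotypes(p: PhenotypeVector, path) -> None:
    pd.DataFrame({"id": p.ids, "value": p.y}).to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# filtering and standardization


def filter_maf(g: GenotypeMatrix, threshold: float) -> GenotypeMatrix:
    """Keep columns whose minor allele frequency exceeds ``threshold``."""
    if not 0 <= threshold < 0.5:
        raise ValueError("threshold must be in [0, 0.5)")
    maf = np.minimum(g.freq, 1.0 - g.freq)
    keep = np.flatnonzero(maf > threshold)
    if keep.size == 0:
        raise ValueError("MAF filter removed every SNP")
    return g.subset_snps(keep)


def standardize(g: GenotypeMatrix, freq: np.ndarray | None = None) -> StandardizedGenotypes:
    """Center and scale allele counts to the codes
    -2p/sqrt(2p(1-p)), (1-2p)/sqrt(2p(1-p)), (2-2p)/sqrt(2p(1-p)).

    ``freq`` defaults to the frequencies computed from ``g`` itself; pass the
    reference-population frequencies to standardize descendant genotypes.
    """
    p = g.freq if freq is None else np.asarray(freq, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("standardization requires 0 < p < 1 for every SNP")
    scale = np.sqrt(2.0 * p * (1.0 - p))
    X = (g.counts - 2.0 * p) / scale
    return StandardizedGenotypes(X=X, freq=p, snp_map=g.snp_map, ids=g.ids)


# ---------------------------------------------------------------------------
# reports

SNP_REPORT_COLUMNS = ("snp_id", "chrom", "pos", "freq", "b_hat", "pev", "llr", "pp", "d_weight")


def write_snp_report(path, snp_map, freq, b_hat, pev=None, llr=None, pp=None, d_weight=None):
    """Write the per-SNP TSV report; missing columns are filled with NaN."""
    k = len(snp_map)
    cols = {"b_hat": b_hat, "pev": pev, "llr": llr, "pp": pp, "d_weight": d_weight}
    data = {"snp_id": snp_map["id"], "chrom": snp_map["chrom"], "pos": snp_map["pos"], "freq": freq}
    for name, arr in cols.items():
        if arr is None:
            arr = np.full(k, np.nan)
        arr = np.asarray(arr, dtype=float)
        if len(arr) != k:
            raise ValueError(f"column {name} has length {len(arr)}, expected {k}")
        data[name] = arr
    if len(np.asarray(freq)) != k:
        raise ValueError("freq length mismatch")
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.12g")


def read_snp_report(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gebv(path, ids, gebv, generation=None) -> None:
    ids = np.asarray(ids)
    gebv = np.asarray(gebv, dtype=float)
    if len(ids) != len(gebv):
        raise ValueError("ids and gebv must have equal length")
    if generation is None:
        generation = np.zeros(len(ids), dtype=int)
    generation = np.broadcast_to(np.asarray(generation), ids.shape)
    pd.DataFrame({"id": ids, "generation": generation, "gebv": gebv}).to_csv(
        path, sep="\t", index=False, float_format="%.12g"
    )


def read_gebv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")
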