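"""Economy SVD of the genotype matrix, per-chromosome, with truncation and merging.

The genome-wide factorization X = U S V' is assembled hierarchically: an
economy SVD per chromosome, truncation of each to the components explaining a
target fraction of Trace(S^2), then an overall SVD of the horizontal
concatenation of the per-chromosome U_c S_c score matrices.  The global V is
never materialized as one dense k x m matrix; it is stored as per-chromosome
row blocks (V_c @ V0_rows-of-c) so consumers stream it chromosome by
chromosome.  When family structure is weak the overall SVD can be skipped
(block-diagonal shortcut), leaving U only approximately orthonormal —
``orthogonality_check`` quantifies the damage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ChromosomeSVD:
    """Economy SVD of one chromosome's (or segment's) standardized genotypes."""

    chrom: object
    U: np.ndarray  # N x m_c, orthonormal columns
    S: np.ndarray  # m_c singular values, descending
    V: np.ndarray  # k_c x m_c, orthonormal columns
    var_explained: float = 1.0
    total_sq: float = None  # type: ignore[assignment]  # Trace(S^2) before truncation

    def __post_init__(self) -> None:
        if self.total_sq is None:
            self.total_sq = float(np.sum(self.S**2))

    @property
    def m(self) -> int:
        return len(self.S)

    @property
    def n_snps(self) -> int:
        return self.V.shape[0]


@dataclass
class VBlock:
    """One chromosome's row block of the global V, occupying columns
    [col_start, col_start + width) of V."""

    chrom: object
    rows: np.ndarray  # k_c x width
    col_start: int

    @property
    def width(self) -> int:
        return self.rows.shape[1]


@dataclass
class MergedSVD:
    """Genome-wide (possibly truncated) SVD with V stored per chromosome block.

    Row blocks are ordered by chromosome, and within each block rows follow
    the SNP (position) order of that chromosome, so concatenating blocks
    reproduces the genome-wide SNP order.
    """

    U: np.ndarray  # N x m
    S: np.ndarray  # m
    blocks: list = field(default_factory=list)
    merged: bool = True

    @property
    def m(self) -> int:
        return len(self.S)

    @property
    def n_snps(self) -> int:
        return sum(b.rows.shape[0] for b in self.blocks)

    # -- streamed V consumers ------------------------------------------------

    def V_matvec(self, s: np.ndarray) -> np.ndarray:
        """b = V @ s, assembled blockwise over chromosomes."""
        out = np.empty(self.n_snps)
        r0 = 0
        for b in self.blocks:
            out[r0 : r0 + b.rows.shape[0]] = b.rows @ s[b.col_start : b.col_start + b.width]
            r0 += b.rows.shape[0]
        return out

    def V_rmatvec(self, b_vec: np.ndarray) -> np.ndarray:
        """s = V' @ b, assembled blockwise."""
        out = np.zeros(self.m)
        r0 = 0
        for b in self.blocks:
            out[b.col_start : b.col_start + b.width] += b.rows.T @ b_vec[r0 : r0 + b.rows.shape[0]]
            r0 += b.rows.shape[0]
        return out

    def row_weighted_sq(self, w: np.ndarray) -> np.ndarray:
        """Per SNP j: sum_i V_ji^2 * w_i (used for the PEV quadratic form)."""
        out = np.empty(self.n_snps)
        r0 = 0
        for b in self.blocks:
            out[r0 : r0 + b.rows.shape[0]] = (b.rows**2) @ w[b.col_start : b.col_start + b.width]
            r0 += b.rows.shape[0]
        return out

    def row_norm_sq(self) -> np.ndarray:
        return self.row_weighted_sq(np.ones(self.m))

    def weighted_gram(self, d: np.ndarray) -> np.ndarray:
        """W = V' diag(d) V accumulated blockwise (m x m)."""
        W = np.zeros((self.m, self.m))
        r0 = 0
        for b in self.blocks:
            sl = slice(b.col_start, b.col_start + b.width)
            dj = d[r0 : r0 + b.rows.shape[0]]
            W[sl, sl] += b.rows.T @ (dj[:, None] * b.rows)
            r0 += b.rows.shape[0]
        return W

    def dense_V(self) -> np.ndarray:
        """Materialize the full k x m V (small problems / tests only)."""
        V = np.zeros((self.n_snps, self.m))
        r0 = 0
        for b in self.blocks:
            V[r0 : r0 + b.rows.shape[0], b.col_start : b.col_start + b.width] = b.rows
            r0 += b.rows.shape[0]
        return V


# ---------------------------------------------------------------------------


def economy_svd(X: np.ndarray, chrom="all") -> ChromosomeSVD:
    """Economy SVD keeping only components with non-zero singular values."""
    X = np.asarray(X, dtype=float)
    if not np.all(np.isfinite(X)):
        raise ValueError("genotype matrix contains non-finite values")
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    tol = max(X.shape) * np.finfo(float).eps * (S[0] if S.size else 0.0)
    nz = S > tol
    return ChromosomeSVD(chrom=chrom, U=U[:, nz], S=S[nz], V=Vt[nz].T)


def truncate(svd: ChromosomeSVD, frac: float = 0.95, max_components: int | None = None) -> ChromosomeSVD:
    """Retain the smallest leading set of components whose cumulative S^2
    fraction reaches ``frac`` of Trace(S^2); an absolute cap may bind further."""
    if not 0 < frac <= 1:
        raise ValueError("frac must be in (0, 1]")
    total = float(np.sum(svd.S**2))
    if total == 0 or svd.m == 0:
        return svd
    cum = np.cumsum(svd.S**2) / total
    m = int(np.searchsorted(cum, frac - 1e-12) + 1)
    m = min(m, svd.m)
    if max_components is not None:
        m = min(m, max_components)
    kept = float(np.sum(svd.S[:m] ** 2))
    return ChromosomeSVD(
        chrom=svd.chrom,
        U=svd.U[:, :m],
        S=svd.S[:m],
        V=svd.V[:, :m],
        var_explained=kept / svd.total_sq if svd.total_sq else 1.0,
        total_sq=svd.total_sq,
    )


def merge_chromosome_svds(parts: list, mode: str = "hierarchical") -> MergedSVD:
    """Assemble genome-wide U, S, V from per-chromosome SVDs.

    hierarchical — SVD of T = [U_1 S_1  U_2 S_2  ...]; the global V row block
    for chromosome c is V_c @ V0[rows of c].  block_diagonal — concatenate
    factors directly without re-orthogonalization (valid when the chromosome
    component scores are approximately uncorrelated); flagged merged=False.
    """
    if not parts:
        raise ValueError("no chromosome SVDs to merge")
    N = parts[0].U.shape[0]
    if any(p.U.shape[0] != N for p in parts):
        raise ValueError("all chromosome SVDs must share the same number of individuals")

    if mode == "hierarchical":
        T = np.hstack([p.U * p.S for p in parts])
        U0, S0, V0t = np.linalg.svd(T, full_matrices=False)
        tol = max(T.shape) * np.finfo(float).eps * (S0[0] if S0.size else 0.0)
        nz = S0 > tol
        U0, S0, V0 = U0[:, nz], S0[nz], V0t[nz].T
        blocks = []
        r0 = 0
        for p in parts:
            blocks.append(VBlock(chrom=p.chrom, rows=p.V @ V0[r0 : r0 + p.m], col_start=0))
            r0 += p.m
        return MergedSVD(U=U0, S=S0, blocks=blocks, merged=True)

    if mode == "block_diagonal":
        S = np.concatenate([p.S for p in parts])
        U = np.hstack([p.U for p in parts])
        offsets = np.concatenate([[0], np.cumsum([p.m for p in parts])])[:-1]
        blocks = [
            VBlock(chrom=p.chrom, rows=p.V, col_start=int(off)) for p, off in zip(parts, offsets)
        ]
        return MergedSVD(U=U, S=S, blocks=blocks, merged=False)

    raise ValueError("mode must be 'hierarchical' or 'block_diagonal'")


def orthogonality_check(U: np.ndarray) -> float:
    """max |(U'U - I)_ij| over i != j — how far U is from column-orthonormal."""
    G = U.T @ U
    np.fill_diagonal(G, 0.0)
    return float(np.max(np.abs(G))) if G.size else 0.0


# ---------------------------------------------------------------------------
# HDF5 container


def save_svd(svd: MergedSVD, path) -> None:
    """Store the merged SVD as /svd/{U,S}, /svd/V/<chrom>, /svd/meta attrs."""
    import h5py

    with h5py.File(path, "w") as f:
        grp = f.create_group("svd")
        grp.create_dataset("U", data=svd.U)
        grp.create_dataset("S", data=svd.S)
        vg = grp.create_group("V")
        for i, b in enumerate(svd.blocks):
            ds = vg.create_dataset(f"block{i:04d}", data=b.rows)
            ds.attrs["chrom"] = str(b.chrom)
            ds.attrs["col_start"] = b.col_start
        grp.attrs["m"] = svd.m
        grp.attrs["merged"] = svd.merged


def load_svd(path) -> MergedSVD:
    import h5py

    with h5py.File(path, "r") as f:
        grp = f["svd"]
        U = grp["U"][...]
        S = grp["S"][...]
        blocks = []
        for name in sorted(grp["V"].keys()):
            ds = grp["V"][name]
            blocks.append(
                VBlock(chrom=ds.attrs["chrom"], rows=ds[...], col_start=int(ds.attrs["col_start"]))
            )
        return MergedSVD(U=U, S=S, blocks=blocks, merged=bool(grp.attrs["merged"]))


def svd_by_chromosome(
    X: np.ndarray,
    chrom_labels: np.ndarray,
    frac: float = 0.95,
    max_components: int | None = None,
    mode: str = "hierarchical",
) -> MergedSVD:
    """Convenience pipeline: per-chromosome economy SVD -> truncation -> merge.

    ``chrom_labels`` gives the chromosome of each SNP column; columns must be
    grouped by chromosome (position-sorted maps guarantee this).
    """
    chrom_labels = np.asarray(chrom_labels)
    parts = []
    for chrom in dict.fromkeys(chrom_labels.tolist()):  # preserve order
        cols = chrom_labels == chrom
        part = economy_svd(X[:, cols], chrom=chrom)
        parts.append(truncate(part, frac=frac, max_components=max_components))
    return merge_chromosome_svds(parts, mode=mode)
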