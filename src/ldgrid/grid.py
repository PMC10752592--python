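"""High-resolution within-chromosome LD grids.

A chromosome of m_i SNPs is cut, in file order, into beta = ceil(m_i / B)
consecutive bins of B SNPs (the last bin may be short).  Every diagonal grid
value l_u (mean LD of one bin, self-pairs included) and off-diagonal value
l_uv (mean LD between two bins) is computed from block GRMs: each block GRM
costs O(n^2 B) once, and every pairwise combination only O(n^2), so a full
chromosome costs O(n^2 (m_i + beta^2)).
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass

import numpy as np

from .grm import GRM, build_grm, cross_moment, grm_moments
from .io import StandardizedMatrix
from .ld import LDEstimate, intra_ld


@dataclass
class BlockPartition:
    """Consecutive half-open SNP-index ranges covering one chromosome."""

    chromosome: str
    bin_size: int
    boundaries: list[tuple[int, int]]

    @property
    def beta(self) -> int:
        return len(self.boundaries)

    @property
    def n_offdiag(self) -> int:
        b = self.beta
        return b * (b - 1) // 2

    def bin_snp_count(self, u: int) -> int:
        s, e = self.boundaries[u]
        return e - s


@dataclass
class GridResult:
    partition: BlockPartition
    diag: np.ndarray              # beta values l_u
    offdiag: dict                 # (u, v) u < v -> l_uv


def partition_blocks(m_i: int, B: int, chromosome: str = "") -> BlockPartition:
    """Cut m_i SNPs into ceil(m_i / B) consecutive B-SNP bins."""
    if B < 2:
        raise ValueError("bin size must be at least 2 SNPs")
    if m_i < 1:
        raise ValueError("need at least one SNP")
    boundaries = [(s, min(s + B, m_i)) for s in range(0, m_i, B)]
    return BlockPartition(chromosome=chromosome, bin_size=B,
                          boundaries=boundaries)


class _GrmCache:
    """LRU cache of block GRMs under a byte budget; recomputes on miss.

    Grid values are pure functions of the data, so results are identical
    whatever the budget — only the recompute count changes.
    """

    def __init__(self, Z: StandardizedMatrix, partition: BlockPartition,
                 budget: int | None):
        self.Z = Z
        self.partition = partition
        grm_bytes = Z.n * Z.n * 8
        if budget is not None and budget < 2 * grm_bytes:
            raise MemoryError(
                f"cache budget {budget} B cannot hold two {grm_bytes} B block GRMs")
        self.max_items = None if budget is None else max(2, budget // grm_bytes)
        self._store: OrderedDict[int, GRM] = OrderedDict()

    def get(self, u: int) -> GRM:
        if u in self._store:
            self._store.move_to_end(u)
            return self._store[u]
        s, e = self.partition.boundaries[u]
        K = build_grm(self.Z, snp_subset=np.arange(s, e),
                      label=f"{self.partition.chromosome}:{u}")
        self._store[u] = K
        if self.max_items is not None:
            while len(self._store) > self.max_items:
                self._store.popitem(last=False)
        return K


def grid_ld_matrix(Z: StandardizedMatrix, partition: BlockPartition,
                   cache_budget: int | None = None) -> GridResult:
    """All diagonal l_u and off-diagonal l_uv grid values for one chromosome.

    ``Z`` must hold exactly the chromosome's SNPs in position order.
    ``cache_budget`` bounds the bytes of block GRMs held at once.
    """
    if Z.m != partition.boundaries[-1][1]:
        raise ValueError("partition does not cover the panel's SNP columns")
    cache = _GrmCache(Z, partition, cache_budget)
    beta = partition.beta
    diag = np.empty(beta)
    offdiag: dict[tuple[int, int], float] = {}
    for u in range(beta):
        Ku = cache.get(u)
        diag[u] = grm_moments(Ku).mean_off_sq
        for v in range(u + 1, beta):
            Kv = cache.get(v)
            offdiag[(u, v)] = cross_moment(Ku, Kv)
            cache.get(u)  # keep the pinned row block most-recently used
    return GridResult(partition=partition, diag=diag, offdiag=offdiag)


def chromosome_ld_from_grid(grid: GridResult) -> float:
    """Reassemble the chromosome mean LD from its grid:
    l_i = [sum_u m_u^2 l_u + sum_{u != v} m_u m_v l_uv] / m_i^2 (exact)."""
    part = grid.partition
    m_i = float(part.boundaries[-1][1])
    total = 0.0
    for u in range(part.beta):
        total += part.bin_snp_count(u) ** 2 * grid.diag[u]
    for (u, v), l in grid.offdiag.items():
        total += 2.0 * part.bin_snp_count(u) * part.bin_snp_count(v) * l
    return total / m_i**2


def _range_mask(Z: StandardizedMatrix, bp_range: tuple[int, int]) -> np.ndarray:
    start, end = bp_range
    bp = Z.snps["bp"].to_numpy()
    return (bp >= start) & (bp <= end)


def region_mean_ld(Z: StandardizedMatrix, bp_range: tuple[int, int]) -> LDEstimate:
    """Mean LD over exactly the SNPs whose 1-based positions fall in
    [start, end] (inclusive), e.g. an HLA cluster or a centromere."""
    mask = _range_mask(Z, bp_range)
    if mask.sum() < 2:
        raise ValueError(f"fewer than 2 SNPs in region {bp_range}")
    return intra_ld(build_grm(Z, snp_subset=mask, label=f"{bp_range}"))


def region_knockout(Z: StandardizedMatrix, bp_range: tuple[int, int]) -> LDEstimate:
    """Chromosome mean LD after excluding the SNPs in [start, end]."""
    mask = ~_range_mask(Z, bp_range)
    if mask.sum() < 2:
        raise ValueError(f"fewer than 2 SNPs survive knockout of {bp_range}")
    return intra_ld(build_grm(Z, snp_subset=mask, label=f"-{bp_range}"))


def grid_to_tsv(grid: GridResult, Z: StandardizedMatrix, path) -> None:
    """Write the grid as TSV: one row per (u, v) with bin coordinates."""
    part = grid.partition
    bp = Z.snps["bp"].to_numpy()

    def coords(u):
        s, e = part.boundaries[u]
        return s, e, int(bp[s]), int(bp[e - 1])

    with open(path, "w") as fh:
        fh.write("chrom\tbin_u\tbin_v\tsnp_count_u\tsnp_count_v\t"
                 "start_bp_u\tend_bp_u\tstart_bp_v\tend_bp_v\tld\n")
        for u in range(part.beta):
            s, e, b0, b1 = coords(u)
            fh.write(f"{part.chromosome}\t{u}\t{u}\t{e - s}\t{e - s}\t"
                     f"{b0}\t{b1}\t{b0}\t{b1}\t{grid.diag[u]!r}\n")
        for (u, v), l in sorted(grid.offdiag.items()):
            su, eu, bu0, bu1 = coords(u)
            sv, ev, bv0, bv1 = coords(v)
            fh.write(f"{part.chromosome}\t{u}\t{v}\t{eu - su}\t{ev - sv}\t"
                     f"{bu0}\t{bu1}\t{bv0}\t{bv1}\t{l!r}\n")


def plot_grid_heatmap(grid: GridResult, path, floor: float = 1e-6) -> None:
    """Optional -log10-scale heatmap of the grid (requires matplotlib)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    beta = grid.partition.beta
    M = np.full((beta, beta), np.nan)
    for u in range(beta):
        M[u, u] = grid.diag[u]
    for (u, v), l in grid.offdiag.items():
        M[u, v] = M[v, u] = l
    M = -np.log10(np.maximum(M, floor))
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(M, cmap="RdYlBu", origin="lower")
    fig.colorbar(im, ax=ax, label="-log10 mean LD")
    ax.set_xlabel("bin")
    ax.set_ylabel("bin")
    ax.set_title(f"chromosome {grid.partition.chromosome}")
    fig.savefig(path, dpi=150)
    plt.close(fig)
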