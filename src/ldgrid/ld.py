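"""Mean-LD estimators built on GRM moments.

Notation follows the population-genetics convention: for chromosome (or SNP
set) i with m_i SNPs, ``l_i`` is the mean squared correlation rho^2 over all
m_i^2 ordered SNP pairs (self-pairs, rho^2 = 1, included), ``l_ij`` the mean
over the m_i * m_j cross pairs of two sets, and ``l_g`` the genome-wide mean.
The GRM route estimates these in O(n^2 m) time instead of O(n m^2):

    l_i   = E(k_io^2)        (off-diagonal second moment of K_i)
    l_ij  = E(k_io k_jo)     (off-diagonal cross moment of K_i, K_j)
    l_g   = sum_i (m_i/m)^2 l_i + sum_{i != j} (m_i m_j / m^2) l_ij

Sampling variances come from the delta method:
var(l_i) = 4 var(k_io)^2 / (n(n-1)).  ``l~_i = (m_i l_i - 1)/(m_i - 1)``
removes the self-pair contribution, and the scaled inter statistic
``l~_ij = l_ij / sqrt(l~_i l~_j)`` is a 0-1 index of extended LD.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .grm import GRM, GrmMoments, build_grm, cross_moment, grm_moments
from .io import GenotypeMatrix, StandardizedMatrix


@dataclass
class LDEstimate:
    """A mean-LD value on the r^2 scale with its standard error."""

    value: float
    se: float
    n: int
    snp_count_i: int
    snp_count_j: int


@dataclass
class LDPartition:
    """Chromosome-level decomposition of genome-wide mean LD.

    ``intra`` holds one estimate per chromosome, ``inter`` one per unordered
    chromosome pair, ``scaled_inter`` the matching (value, variance) of the
    scaled statistic, and ``genome`` the whole-genome mean.
    """

    chromosomes: list
    snp_counts: dict
    intra: dict
    inter: dict
    scaled_inter: dict
    genome: LDEstimate

    @property
    def C(self) -> int:
        return len(self.chromosomes)

    @property
    def m(self) -> int:
        return sum(self.snp_counts.values())

    def mean_intra(self) -> float:
        return float(np.mean([e.value for e in self.intra.values()]))

    def mean_inter(self) -> float:
        if not self.inter:
            raise ValueError("partition has a single chromosome; no inter terms")
        return float(np.mean([e.value for e in self.inter.values()]))


def intra_ld(K: GRM) -> LDEstimate:
    """Mean LD of the SNP set behind ``K``: the off-diagonal second moment.

    SE follows var(l_i) = 4 var(k_io)^2 / (n(n-1)) with the empirical
    off-diagonal variance substituted.
    """
    mo = grm_moments(K)
    se = 2.0 * mo.var_off / np.sqrt(mo.n * (mo.n - 1))
    return LDEstimate(value=mo.mean_off_sq, se=float(se), n=mo.n,
                      snp_count_i=K.snp_count, snp_count_j=K.snp_count)


def inter_ld(Ki: GRM, Kj: GRM, n_boot: int = 200, seed: int = 0) -> LDEstimate:
    """Mean LD between two SNP sets: the off-diagonal cross moment.

    No closed-form sampling variance is available for the raw cross moment,
    so the SE is a seeded nonparametric bootstrap over samples.
    """
    value = cross_moment(Ki, Kj)
    n = Ki.n
    se = float("nan")
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        A, B = Ki.matrix, Kj.matrix
        mask = ~np.eye(n, dtype=bool)
        reps = np.empty(n_boot)
        for b in range(n_boot):
            idx = rng.integers(0, n, n)
            sub = A[np.ix_(idx, idx)] * B[np.ix_(idx, idx)]
            reps[b] = sub[mask].mean()
        se = float(reps.std(ddof=1))
    return LDEstimate(value=value, se=se, n=n,
                      snp_count_i=Ki.snp_count, snp_count_j=Kj.snp_count)


def self_adjusted_ld(l_i: float, m_i: int) -> float:
    """l~_i = (m_i l_i - 1) / (m_i - 1): mean LD with self-pairs removed."""
    if m_i < 2:
        raise ValueError("self-adjusted LD needs at least two SNPs")
    return (m_i * l_i - 1.0) / (m_i - 1.0)


def scaled_inter_ld(l_ij: float, lt_i: float, lt_j: float, n: int,
                    moments_i: GrmMoments, moments_j: GrmMoments
                    ) -> tuple[float, float]:
    """Scaled inter LD l~_ij = l_ij / sqrt(l~_i l~_j) and its delta-method variance.

    The variance is 2 l~_ij^2 / (n(n-1)) * [v + 1/v - 2] with
    v = var(k_io) var(k_jo) / cov(k_io, k_jo)^2 and
    cov(k_io, k_jo) = l_ij - 1/(n-1)^2.
    """
    if lt_i <= 0 or lt_j <= 0:
        raise ValueError("self-adjusted intra LD must be positive for scaling")
    value = l_ij / np.sqrt(lt_i * lt_j)
    cov = l_ij - 1.0 / (n - 1) ** 2
    var_prod = moments_i.var_off * moments_j.var_off
    if cov == 0.0 or var_prod == 0.0:
        variance = float("inf")
    else:
        v = var_prod / (cov * cov)
        variance = 2.0 * value * value / (n * (n - 1)) * (v + 1.0 / v - 2.0)
    return float(value), float(variance)


def combine_genome_ld(intra_values, inter_values, snp_counts) -> float:
    """l_g = sum_i (m_i/m)^2 l_i + sum_{i != j} (m_i m_j/m^2) l_ij.

    ``inter_values`` is keyed by unordered chromosome pair; each pair is
    counted for both orderings.
    """
    m = float(sum(snp_counts.values()))
    total = 0.0
    for c, l in intra_values.items():
        total += (snp_counts[c] / m) ** 2 * l
    for (a, b), l in inter_values.items():
        total += 2.0 * snp_counts[a] * snp_counts[b] / m**2 * l
    return total


def genome_ld(partition: LDPartition) -> LDEstimate:
    """Recombine a partition's components into the genome-wide mean LD."""
    intra = {c: e.value for c, e in partition.intra.items()}
    inter = {k: e.value for k, e in partition.inter.items()}
    missing = [c for c in partition.chromosomes if c not in intra]
    if missing:
        raise ValueError(f"missing intra estimates for chromosomes {missing}")
    value = combine_genome_ld(intra, inter, partition.snp_counts)
    g = partition.genome
    return LDEstimate(value=value, se=g.se, n=g.n,
                      snp_count_i=partition.m, snp_count_j=partition.m)


def ld_partition(Z: StandardizedMatrix, n_boot: int = 200, seed: int = 0,
                 chunk_width: int = 8192) -> LDPartition:
    """Full chromosome-level LD decomposition of a standardized panel.

    Builds one GRM per chromosome (O(n^2 m) total), combines them pairwise
    for the inter terms, and assembles the whole-genome GRM as the exact
    SNP-count-weighted average sum_i (m_i/m) K_i, so the genome estimate
    satisfies the decomposition identity algebraically.
    """
    chroms = list(dict.fromkeys(Z.snps["chrom"]))
    if not chroms:
        raise ValueError("no SNPs in panel")
    grms = {}
    snp_counts = {}
    for c in chroms:
        mask = (Z.snps["chrom"] == c).to_numpy()
        grms[c] = build_grm(Z, snp_subset=mask, label=str(c),
                            chunk_width=chunk_width)
        snp_counts[c] = int(mask.sum())
    m = sum(snp_counts.values())
    n = Z.n

    moments = {c: grm_moments(K) for c, K in grms.items()}
    intra = {}
    for c, K in grms.items():
        mo = moments[c]
        se = 2.0 * mo.var_off / np.sqrt(n * (n - 1))
        intra[c] = LDEstimate(value=mo.mean_off_sq, se=float(se), n=n,
                              snp_count_i=K.snp_count, snp_count_j=K.snp_count)

    inter = {}
    scaled = {}
    for a, b in itertools.combinations(chroms, 2):
        est = inter_ld(grms[a], grms[b], n_boot=n_boot,
                       seed=_pair_seed(seed, chroms.index(a), chroms.index(b)))
        inter[(a, b)] = est
        lt_a = self_adjusted_ld(intra[a].value, snp_counts[a])
        lt_b = self_adjusted_ld(intra[b].value, snp_counts[b])
        if lt_a > 0 and lt_b > 0:
            scaled[(a, b)] = scaled_inter_ld(est.value, lt_a, lt_b, n,
                                             moments[a], moments[b])
        else:
            scaled[(a, b)] = (float("nan"), float("nan"))

    Kg = np.zeros((n, n))
    for c, K in grms.items():
        Kg += (snp_counts[c] / m) * K.matrix
    genome = intra_ld(GRM(matrix=Kg, snp_count=m, label="genome"))

    return LDPartition(chromosomes=chroms, snp_counts=snp_counts, intra=intra,
                       inter=inter, scaled_inter=scaled, genome=genome)


def _pair_seed(seed: int, i: int, j: int) -> int:
    return (seed * 1_000_003 + i * 1009 + j) % (2**31 - 1)


def intra_fraction_summary(mean_li: float, mean_lij: float, C: int) -> float:
    """Intra-chromosomal share C l-bar_i / (C l-bar_i + C(C-1) l-bar_ij).

    With C = 22 this is the 22 : 462 weighting of mean intra against mean
    inter components; it lower-bounds the fraction of genomic LD that is
    genuinely intra-chromosomal.
    """
    denom = C * mean_li + C * (C - 1) * mean_lij
    if denom == 0:
        raise ValueError("zero denominator in intra-fraction summary")
    return C * mean_li / denom


def true_ld_summary(mean_li: float, b0: float) -> float:
    """Share of intra-chromosomal LD not attributable to the long-range floor:
    l-bar_i / (l-bar_i + b0), with b0 the decay-regression intercept."""
    denom = mean_li + b0
    if denom == 0:
        raise ValueError("zero denominator in true-LD summary")
    return mean_li / denom


def plink_mean_r2(G: GenotypeMatrix, set_i, set_j=None,
                  include_self: bool = False) -> float:
    """Brute-force mean squared sample Pearson correlation of dosage columns.

    This is the O(n m_i m_j) reference the GRM route is reconciled against;
    on no-LD panels it exceeds the GRM estimate by about 1/n because the
    sample correlation of independent SNPs has expectation ~ 1/(n-1).
    ``include_self`` adds the self-pairs (r^2 = 1) when both sets coincide.
    """
    set_i = np.asarray(set_i)
    same = set_j is None
    set_j = set_i if same else np.asarray(set_j)
    same = same or (set_i.size == set_j.size and (set_i == set_j).all())

    cols = np.concatenate([set_i, set_j])
    X = G.dosages[:, cols].astype(np.float64)
    sd = X.std(axis=0)
    if (sd == 0).any():
        snp = G.snps.iloc[int(cols[int(np.argmax(sd == 0))])]["id"]
        raise ValueError(f"SNP {snp} has zero variance; r^2 undefined")
    C = np.corrcoef(X.T)
    R2 = C * C
    mi, mj = set_i.size, set_j.size
    block = R2[:mi, mi:]
    if same:
        total = block.sum()
        if include_self:
            return float(total / (mi * mj))
        return float((total - np.trace(block)) / (mi * (mi - 1)))
    return float(block.mean())
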