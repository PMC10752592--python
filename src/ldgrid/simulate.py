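"""Synthetic genotype panels with controlled LD architecture, plus oracles.

The generator draws haplotypes from a latent-Gaussian copula: inside each
s-SNP block the latent variables follow either an AR(1) chain (correlation
r between neighbours, r^d at lag d) or an exchangeable model (correlation r
between every pair in the block); distinct blocks are independent except for
an optional genome-wide background factor that induces a uniform latent
correlation across all SNPs (the knob for long-range / inter-chromosomal
LD).  An allele is the indicator that the latent value falls below the
frequency quantile, and a genotype is the sum of two independent haplotypes,
so marginally each SNP is binomial(2, p) under Hardy-Weinberg.

Population structure follows the Balding-Nichols model: subpopulation
frequencies are Beta(p(1-Fst)/Fst, q(1-Fst)/Fst) draws around the ancestral
frequency p.  Admixture replaces hard subpopulation assignment with an
individual ancestry proportion pi ~ Beta(a, b) mixing the two frequency
sets.

Everything is deterministic given the config seed.  The module also houses
the brute-force oracles (exhaustive pairwise r^2 and explicit-loop GRM
moments) that the fast GRM route is validated against.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .grm import GRM
from .io import GenotypeMatrix

#: refuse brute-force enumerations beyond this many SNP pairs
ORACLE_PAIR_GUARD = 10_000_000


@dataclass
class ChromosomeSpec:
    """One simulated chromosome: m SNPs in blocks of ``block_size`` with
    within-block latent correlation ``within_r``."""

    m: int
    block_size: int = 50
    within_r: float = 0.0
    corr_model: str = "ar1"  # "ar1" or "exchangeable"


@dataclass
class SimulationConfig:
    n: int
    chromosomes: list[ChromosomeSpec]
    maf_range: tuple[float, float] = (0.05, 0.5)
    structure: tuple[int, int, float] | None = None  # (n1, n2, Fst)
    admixture: tuple[float, float] | None = None     # Beta(a, b) ancestry
    background_r: float = 0.0                        # latent cross-SNP corr
    seed: int = 0

    def validate(self) -> None:
        if self.n < 2:
            raise ValueError("need at least two samples")
        if not self.chromosomes:
            raise ValueError("need at least one chromosome")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        for spec in self.chromosomes:
            if not (abs(spec.within_r) < 1.0):
                raise ValueError("|within_r| must be < 1")
            if spec.block_size < 1 or spec.m < 1:
                raise ValueError("chromosome sizes must be positive")
            if spec.corr_model not in ("ar1", "exchangeable"):
                raise ValueError(f"unknown correlation model {spec.corr_model}")
        if not (0.0 <= self.background_r < 1.0):
            raise ValueError("background_r must lie in [0, 1)")
        if self.structure is not None:
            n1, n2, fst = self.structure
            if n1 + n2 != self.n:
                raise ValueError("subpopulation sizes must sum to n")
            if not (0.0 < fst < 1.0):
                raise ValueError("Fst must lie in (0, 1)")
        if self.admixture is not None:
            if self.structure is None:
                raise ValueError("admixture requires a structure spec for the "
                                 "subpopulation frequencies")
            a, b = self.admixture
            if a <= 0 or b <= 0:
                raise ValueError("Beta ancestry parameters must be positive")


def _latent_block(rng: np.random.Generator, n: int, spec: ChromosomeSpec
                  ) -> np.ndarray:
    """Latent Gaussians for one chromosome (one haplotype)."""
    eps = rng.standard_normal((n, spec.m))
    r = spec.within_r
    if r == 0.0:
        return eps
    L = np.empty_like(eps)
    if spec.corr_model == "ar1":
        decay = np.sqrt(1.0 - r * r)
        for start in range(0, spec.m, spec.block_size):
            end = min(start + spec.block_size, spec.m)
            L[:, start] = eps[:, start]
            for j in range(start + 1, end):
                L[:, j] = r * L[:, j - 1] + decay * eps[:, j]
    else:  # exchangeable
        for start in range(0, spec.m, spec.block_size):
            end = min(start + spec.block_size, spec.m)
            shared = rng.standard_normal(n)
            L[:, start:end] = (np.sqrt(r) * shared[:, None]
                               + np.sqrt(1.0 - r) * eps[:, start:end])
    return L


def simulate_panel(cfg: SimulationConfig) -> GenotypeMatrix:
    """Draw a complete genotype panel under the configured architecture."""
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n
    m_total = sum(spec.m for spec in cfg.chromosomes)

    # 1. ancestral frequencies of the counted allele
    lo, hi = cfg.maf_range
    maf = rng.uniform(lo, hi, m_total)
    flip = rng.random(m_total) < 0.5
    p = np.where(flip, 1.0 - maf, maf)

    # 2. subpopulation frequencies (Balding-Nichols) and per-individual p
    if cfg.structure is not None:
        n1, n2, fst = cfg.structure
        shape = (1.0 - fst) / fst
        p_sub = np.empty((2, m_total))
        for s in range(2):
            p_sub[s] = rng.beta(p * shape, (1.0 - p) * shape)
        p_sub = np.clip(p_sub, 1e-6, 1.0 - 1e-6)
        if cfg.admixture is not None:
            a, b = cfg.admixture
            pi = rng.beta(a, b, n)
            p_ind = pi[:, None] * p_sub[0] + (1.0 - pi[:, None]) * p_sub[1]
        else:
            pop = np.repeat([0, 1], [n1, n2])
            p_ind = p_sub[pop]
    else:
        p_ind = np.broadcast_to(p, (n, m_total))
    thresholds = ndtri(np.clip(p_ind, 1e-12, 1.0 - 1e-12))

    # 3. two haplotypes per individual
    c = cfg.background_r
    X = np.zeros((n, m_total), dtype=np.int8)
    for _hap in range(2):
        cols = []
        for spec in cfg.chromosomes:
            cols.append(_latent_block(rng, n, spec))
        L = np.concatenate(cols, axis=1)
        if c > 0.0:
            g = rng.standard_normal(n)
            L = np.sqrt(1.0 - c) * L + np.sqrt(c) * g[:, None]
        X += (L < thresholds).astype(np.int8)

    # 4. metadata: 1-based positions, 1 kb spacing, alleles A (other) / B (counted)
    chroms, bps, ids = [], [], []
    for ci, spec in enumerate(cfg.chromosomes, start=1):
        chroms.extend([ci] * spec.m)
        bps.extend(1000 * (j + 1) for j in range(spec.m))
        ids.extend(f"c{ci}s{j + 1}" for j in range(spec.m))
    snps = pd.DataFrame({"chrom": chroms, "id": ids, "cm": 0.0, "bp": bps,
                         "a1": "A", "a2": "B"})
    samples = [f"ind{k + 1}" for k in range(n)]
    G = GenotypeMatrix(dosages=X, samples=samples, snps=snps)
    G.validate()
    return G


# ---------------------------------------------------------------------------
# brute-force oracles


@dataclass
class OracleReport:
    """Exhaustive pair-level r^2 table plus grid-level aggregate means."""

    pairs: pd.DataFrame
    aggregates: dict


def _pair_r2_block(X: np.ndarray, set_i, set_j) -> np.ndarray:
    Ci = X[:, set_i] - X[:, set_i].mean(axis=0)
    Cj = X[:, set_j] - X[:, set_j].mean(axis=0)
    num = Ci.T @ Cj
    denom = np.sqrt((Ci * Ci).sum(axis=0))[:, None] * \
        np.sqrt((Cj * Cj).sum(axis=0))[None, :]
    return (num / denom) ** 2


def brute_force_grid(G: GenotypeMatrix, sets: dict) -> OracleReport:
    """Exhaustive sample-r^2 oracle over labelled SNP sets.

    ``sets`` maps a label to an index array of SNP columns.  Aggregates hold
    ``intra[label]`` (mean over all ordered pairs including self-pairs) and
    ``inter[(a, b)]`` (mean over cross pairs) recomputed from the pair table.
    """
    if G.has_missing:
        raise ValueError("oracle requires a complete panel")
    total_pairs = sum(len(v) * len(w) for v in sets.values() for w in sets.values())
    if total_pairs > ORACLE_PAIR_GUARD:
        raise ValueError(
            f"{total_pairs} SNP pairs exceeds the oracle guard of "
            f"{ORACLE_PAIR_GUARD}; shrink the instance")
    X = G.dosages.astype(np.float64)
    ids = G.snps["id"].to_numpy()
    rows = []
    aggregates = {"intra": {}, "inter": {}}
    for label, idx in sets.items():
        idx = np.asarray(idx)
        R2 = _pair_r2_block(X, idx, idx)
        for a in range(idx.size):
            for b in range(a, idx.size):
                rows.append((ids[idx[a]], ids[idx[b]], R2[a, b]))
        aggregates["intra"][label] = float(R2.mean())
    for (la, ia), (lb, ib) in itertools.combinations(sets.items(), 2):
        ia, ib = np.asarray(ia), np.asarray(ib)
        R2 = _pair_r2_block(X, ia, ib)
        for a in range(ia.size):
            for b in range(ib.size):
                rows.append((ids[ia[a]], ids[ib[b]], R2[a, b]))
        aggregates["inter"][(la, lb)] = float(R2.mean())
    pairs = pd.DataFrame(rows, columns=["snp_a", "snp_b", "r2"])
    return OracleReport(pairs=pairs, aggregates=aggregates)


def loop_grm_moments(K: GRM) -> tuple[float, float]:
    """Off-diagonal mean and second moment by explicit enumeration of the
    n(n-1) ordered sample pairs — the independent check on the fast path."""
    M = K.matrix
    n = K.n
    s1 = 0.0
    s2 = 0.0
    for k1 in range(n):
        for k2 in range(n):
            if k1 == k2:
                continue
            v = M[k1, k2]
            s1 += v
            s2 += v * v
    return s1 / (n * (n - 1)), s2 / (n * (n - 1))


def loop_cross_moment(Ki: GRM, Kj: GRM) -> float:
    """Explicit-loop counterpart of the GRM cross moment."""
    A, B = Ki.matrix, Kj.matrix
    n = Ki.n
    s = 0.0
    for k1 in range(n):
        for k2 in range(n):
            if k1 != k2:
                s += A[k1, k2] * B[k1, k2]
    return s / (n * (n - 1))


def oracle_to_tsv(report: OracleReport, path) -> None:
    report.pairs.to_csv(path, sep="\t", index=False)
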