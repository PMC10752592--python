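"""Genetic relatedness matrices and the moments that drive LD estimation.

For a standardized genotype block Z (n samples x m SNPs) the GRM is
K = Z Z' / m.  Its off-diagonal second moment equals, by the Isserlis
fourth-moment identity for unrelated individuals, the mean squared
correlation over all m^2 SNP pairs of the block — the quantity every mean-LD
estimator in this package consumes.  The top eigenvalue of a GRM serves as a
population-structure surrogate, with lambda_1 / n approximating Fst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .io import StandardizedMatrix

#: sample size above which the full symmetric eigendecomposition is replaced
#: by power iteration (only the top eigenvalue is ever needed)
_DENSE_EIG_MAX_N = 4000


@dataclass
class GRM:
    """n x n genetic relatedness matrix for one SNP set.

    ``relatedness_assumption`` records the theta model under which the
    GRM-to-LD identity is applied; only "unrelated" (theta = 0 for all
    distinct pairs) is supported.
    """

    matrix: np.ndarray
    snp_count: int
    label: str = ""
    relatedness_assumption: str = "unrelated"

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass
class GrmMoments:
    """Moments of the n(n-1) ordered off-diagonal entries of a GRM.

    ``var_off`` uses the population convention (divide by the count), which
    is what the delta-method sampling variances substitute directly.
    """

    mean_off: float
    mean_off_sq: float
    var_off: float
    diag: np.ndarray
    n: int


@dataclass
class StructureStats:
    lambda1: float
    fst_proxy: float


def build_grm(Z: StandardizedMatrix | np.ndarray, snp_subset=None,
              label: str = "", chunk_width: int = 8192) -> GRM:
    """K = (1/m) Z Z' over the given SNP subset (default: all columns).

    The multiply runs in double precision over SNP chunks of at most
    ``chunk_width`` columns to bound peak memory; the result is independent
    of the chunking.
    """
    V = Z.values if isinstance(Z, StandardizedMatrix) else np.asarray(Z, dtype=np.float64)
    if snp_subset is not None:
        idx = np.asarray(snp_subset)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        if idx.size == 0:
            raise ValueError("empty SNP subset")
        V = V[:, idx]
    m = V.shape[1]
    if m == 0:
        raise ValueError("empty SNP subset")
    n = V.shape[0]
    K = np.zeros((n, n), dtype=np.float64)
    for start in range(0, m, chunk_width):
        block = np.ascontiguousarray(V[:, start:start + chunk_width])
        K += block @ block.T
    K /= m
    return GRM(matrix=K, snp_count=m, label=label)


def grm_moments(K: GRM) -> GrmMoments:
    """Mean, second moment and variance of the ordered off-diagonal entries."""
    M = K.matrix
    n = K.n
    if n < 2:
        raise ValueError("GRM moments need at least two samples")
    diag = np.diagonal(M).copy()
    denom = n * (n - 1)
    mean_off = (M.sum() - diag.sum()) / denom
    mean_off_sq = ((M * M).sum() - (diag * diag).sum()) / denom
    var_off = mean_off_sq - mean_off * mean_off
    return GrmMoments(mean_off=float(mean_off), mean_off_sq=float(mean_off_sq),
                      var_off=float(var_off), diag=diag, n=n)


def cross_moment(Ki: GRM, Kj: GRM) -> float:
    """Mean over ordered pairs k1 != k2 of (Ki)_{k1k2} (Kj)_{k1k2}."""
    if Ki.matrix.shape != Kj.matrix.shape:
        raise ValueError("GRMs must share sample dimension and ordering")
    n = Ki.n
    if n < 2:
        raise ValueError("cross moment needs at least two samples")
    prod = (Ki.matrix * Kj.matrix).sum()
    diag = (np.diagonal(Ki.matrix) * np.diagonal(Kj.matrix)).sum()
    return float((prod - diag) / (n * (n - 1)))


def largest_eigenvalue(K: GRM) -> StructureStats:
    """Top eigenvalue of the GRM and the Fst surrogate lambda_1 / n.

    Uses a full symmetric solve for n <= 4000 and otherwise power iteration
    (fixed start vector, tolerance 1e-8, at most 1000 iterations).
    """
    M = K.matrix
    if not np.isfinite(M).all():
        raise ValueError("GRM contains non-finite entries")
    n = K.n
    if n <= _DENSE_EIG_MAX_N:
        lam = scipy.linalg.eigh(M, eigvals_only=True,
                                subset_by_index=(n - 1, n - 1))[0]
    else:
        lam = _power_iteration(M)
    return StructureStats(lambda1=float(lam), fst_proxy=float(lam) / n)


def _power_iteration(M: np.ndarray, tol: float = 1e-8,
                     max_iter: int = 1000) -> float:
    n = M.shape[0]
    v = np.full(n, 1.0 / np.sqrt(n))
    lam = 0.0
    for _ in range(max_iter):
        w = M @ v
        norm = np.linalg.norm(w)
        if norm == 0.0:
            return 0.0
        v_new = w / norm
        lam_new = float(v_new @ (M @ v_new))
        if abs(lam_new - lam) <= tol * max(1.0, abs(lam_new)):
            return lam_new
        v, lam = v_new, lam_new
    return lam


def grm_to_tsv(K: GRM, samples: list[str], path) -> None:
    """Export the lower triangle (including diagonal) as sample_i, sample_j, value."""
    with open(path, "w") as fh:
        fh.write("sample_i\tsample_j\tvalue\n")
        for i in range(K.n):
            for j in range(i + 1):
                fh.write(f"{samples[i]}\t{samples[j]}\t{K.matrix[i, j]!r}\n")
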