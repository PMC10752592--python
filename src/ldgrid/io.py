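"""PLINK binary genotype I/O, quality control, imputation, and standardization.

Genotypes are biallelic dosages in {0, 1, 2} with ``-1`` marking missing
calls.  Dosage counts copies of the second .bim allele (PLINK "A2", usually
the major allele), so the 2-bit codes ``00 / 10 / 11`` decode to ``0 / 1 / 2``
and ``01`` to missing.  All downstream LD statistics are squared correlations
and therefore invariant to flipping which allele is counted.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

MISSING = -1

_BED_MAGIC = b"\x6c\x1b"
_SNP_MAJOR = b"\x01"

# 2-bit PLINK code -> dosage of allele2 (00 hom A1, 01 missing, 10 het, 11 hom A2)
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, 1: 0b10, 2: 0b11, MISSING: 0b01}

BIM_COLUMNS = ["chrom", "id", "cm", "bp", "a1", "a2"]


class PlinkFormatError(ValueError):
    """Raised for malformed .bed/.bim/.fam filesets."""


@dataclass
class GenotypeMatrix:
    """An n x m dosage matrix with its sample and SNP metadata.

    dosages : int8 array, entries in {0, 1, 2} or -1 (missing); rows are
        samples in .fam order, columns SNPs in .bim order.
    samples : sample identifiers.
    snps : DataFrame with columns chrom, id, cm, bp, a1, a2 in file order.
    """

    dosages: np.ndarray
    samples: list[str]
    snps: pd.DataFrame

    @property
    def n(self) -> int:
        return self.dosages.shape[0]

    @property
    def m(self) -> int:
        return self.dosages.shape[1]

    @property
    def has_missing(self) -> bool:
        return bool((self.dosages == MISSING).any())

    def validate(self) -> None:
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if len(self.samples) != self.n:
            raise ValueError("sample list does not match dosage rows")
        if len(self.snps) != self.m:
            raise ValueError("SNP table does not match dosage columns")
        ok = np.isin(self.dosages, (0, 1, 2, MISSING))
        if not ok.all():
            raise ValueError("dosage entries must be 0, 1, 2 or missing")
        if self.snps["id"].duplicated().any():
            dup = self.snps.loc[self.snps["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate SNP identifier: {dup}")

    def subset_snps(self, index) -> "GenotypeMatrix":
        """Return a copy restricted to the given SNP (column) indexer."""
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return GenotypeMatrix(
            dosages=self.dosages[:, index].copy(),
            samples=list(self.samples),
            snps=self.snps.iloc[index].reset_index(drop=True),
        )


@dataclass
class AlleleFrequency:
    """Per-SNP frequency of the counted allele, its complement, and the MAF."""

    p: np.ndarray
    q: np.ndarray
    maf: np.ndarray
    monomorphic: np.ndarray  # boolean mask, p in {0, 1}


@dataclass
class StandardizedMatrix:
    """Centered and scaled dosages x~ = (x - 2p) / sqrt(2(1+F)pq).

    Column means are zero (to rounding) whenever the frequencies were
    estimated from the same data.  Sample/SNP metadata ride along so that
    chromosome partitions and base-pair regions can be resolved downstream.
    """

    values: np.ndarray
    inbreeding_f: float
    freqs: AlleleFrequency
    samples: list[str] = field(default_factory=list)
    snps: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def m(self) -> int:
        return self.values.shape[1]

    def subset(self, index) -> "StandardizedMatrix":
        index = np.asarray(index)
        if index.dtype == bool:
            index = np.flatnonzero(index)
        return StandardizedMatrix(
            values=self.values[:, index],
            inbreeding_f=self.inbreeding_f,
            freqs=AlleleFrequency(
                p=self.freqs.p[index],
                q=self.freqs.q[index],
                maf=self.freqs.maf[index],
                monomorphic=self.freqs.monomorphic[index],
            ),
            samples=self.samples,
            snps=self.snps.iloc[index].reset_index(drop=True),
        )


def read_plink(prefix) -> GenotypeMatrix:
    """Read a PLINK v1 binary fileset (``prefix``.bed/.bim/.fam).

    The .bed must be SNP-major (magic ``6C 1B 01``).  Raises
    :class:`PlinkFormatError` on bad magic bytes or a truncated .bed body.
    """
    prefix = Path(prefix)
    bed_path = prefix.with_suffix(".bed")
    bim_path = prefix.with_suffix(".bim")
    fam_path = prefix.with_suffix(".fam")
    for p in (bed_path, bim_path, fam_path):
        if not p.exists():
            raise FileNotFoundError(p)

    snps = pd.read_csv(bim_path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                       dtype={"chrom": int, "id": str, "a1": str, "a2": str})
    fam = pd.read_csv(fam_path, sep=r"\s+", header=None,
                      names=["fid", "iid", "father", "mother", "sex", "pheno"],
                      dtype={"iid": str})
    samples = fam["iid"].tolist()
    n, m = len(samples), len(snps)

    raw = np.fromfile(bed_path, dtype=np.uint8)
    if raw[:2].tobytes() != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes")
    if raw[2:3].tobytes() != _SNP_MAJOR:
        raise PlinkFormatError(f"{bed_path}: not SNP-major")
    bytes_per_snp = (n + 3) // 4
    body = raw[3:]
    if body.size != bytes_per_snp * m:
        raise PlinkFormatError(
            f"{bed_path}: expected {bytes_per_snp * m} body bytes, got {body.size}")

    blocks = body.reshape(m, bytes_per_snp)
    # unpack 4 two-bit codes per byte, lowest bits first
    codes = (blocks[:, :, None] >> np.array([0, 2, 4, 6], dtype=np.uint8)) & 3
    codes = codes.reshape(m, bytes_per_snp * 4)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()  # n x m

    G = GenotypeMatrix(dosages=dosages, samples=samples, snps=snps)
    G.validate()
    return G


def write_plink(G: GenotypeMatrix, prefix) -> None:
    """Write ``G`` as a PLINK v1 SNP-major binary fileset."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    n, m = G.n, G.m
    bytes_per_snp = (n + 3) // 4

    code = np.empty((m, bytes_per_snp * 4), dtype=np.uint8)
    code[:] = 0
    lut = np.zeros(4, dtype=np.uint8)
    for dosage, c in _DOSAGE_TO_CODE.items():
        lut[dosage % 4] = c  # MISSING=-1 maps to index 3
    code[:, :n] = lut[G.dosages.T % 4]
    packed = (code[:, 0::4]
              | (code[:, 1::4] << 2)
              | (code[:, 2::4] << 4)
              | (code[:, 3::4] << 6)).astype(np.uint8)

    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC + _SNP_MAJOR)
        fh.write(packed.tobytes())
    G.snps[BIM_COLUMNS].to_csv(prefix.with_suffix(".bim"), sep="\t",
                               header=False, index=False)
    fam = pd.DataFrame({
        "fid": G.samples, "iid": G.samples,
        "father": 0, "mother": 0, "sex": 0, "pheno": -9,
    })
    fam.to_csv(prefix.with_suffix(".fam"), sep="\t", header=False, index=False)


def _missing_rate(G: GenotypeMatrix) -> np.ndarray:
    return (G.dosages == MISSING).mean(axis=0)


def _maf_from_calls(G: GenotypeMatrix) -> np.ndarray:
    """MAF per SNP from non-missing calls only."""
    d = np.ma.masked_equal(G.dosages, MISSING)
    p = d.mean(axis=0).filled(np.nan) / 2.0
    return np.minimum(p, 1.0 - p)


def apply_qc(G: GenotypeMatrix, maf_min: float = 0.05, miss_max: float = 0.2,
             autosomes_only: bool = True) -> GenotypeMatrix:
    """SNP-level quality control.

    Keeps autosomal SNPs (chromosome codes 1-22) whose missing-call rate is
    at most ``miss_max`` and whose minor allele frequency exceeds
    ``maf_min``.  Monomorphic SNPs are always removed.  SNP order is
    preserved and the operation is idempotent.
    """
    if not (0 <= maf_min < 0.5):
        raise ValueError("maf_min must lie in [0, 0.5)")
    if not (0 <= miss_max <= 1):
        raise ValueError("miss_max must lie in [0, 1]")
    keep = np.ones(G.m, dtype=bool)
    if autosomes_only:
        keep &= G.snps["chrom"].between(1, 22).to_numpy()
    keep &= _missing_rate(G) <= miss_max
    maf = _maf_from_calls(G)
    with np.errstate(invalid="ignore"):
        keep &= (maf > maf_min) & (maf > 0)
    if not keep.any():
        raise ValueError("quality control removed every SNP")
    return G.subset_snps(keep)


def impute_missing_hwe(G: GenotypeMatrix, seed: int) -> GenotypeMatrix:
    """Impute missing calls by sampling genotypes under Hardy-Weinberg.

    Each missing entry at a SNP with counted-allele frequency ``p`` (from
    that SNP's non-missing calls) is drawn from {0, 1, 2} with probabilities
    (q^2, 2pq, p^2).  Non-missing entries are untouched; identical seeds give
    bit-identical output.
    """
    if not G.has_missing:
        return G
    rng = np.random.default_rng(seed)
    dosages = G.dosages.copy()
    miss = dosages == MISSING
    counts = (~miss).sum(axis=0)
    if (counts == 0).any():
        snp = G.snps.loc[int(np.argmax(counts == 0)), "id"]
        raise ValueError(f"SNP {snp} has no non-missing genotype to impute from")
    d = np.ma.masked_equal(G.dosages, MISSING)
    p = (d.mean(axis=0) / 2.0).filled(0.0)
    for j in np.flatnonzero(miss.any(axis=0)):
        rows = np.flatnonzero(miss[:, j])
        pj, qj = p[j], 1.0 - p[j]
        draws = rng.choice(3, size=rows.size, p=(qj * qj, 2 * pj * qj, pj * pj))
        dosages[rows, j] = draws.astype(np.int8)
    return replace(G, dosages=dosages)


def allele_frequencies(G: GenotypeMatrix) -> AlleleFrequency:
    """Counted-allele frequencies p = mean(dosage)/2 on a complete panel."""
    if G.has_missing:
        raise ValueError("allele_frequencies requires a complete (imputed) panel")
    p = G.dosages.mean(axis=0) / 2.0
    q = 1.0 - p
    return AlleleFrequency(p=p, q=q, maf=np.minimum(p, q),
                           monomorphic=(p == 0.0) | (p == 1.0))


def standardize(G: GenotypeMatrix, F: float = 0.0,
                freqs: AlleleFrequency | None = None) -> StandardizedMatrix:
    """Standardize dosages to x~ = (x - 2p) / sqrt(2 (1+F) p q).

    ``F`` is the inbreeding coefficient: 0 for a random-mating population,
    1 for a fully inbred one.  Frequencies default to the panel's own
    (so columns are exactly mean-zero).  Monomorphic SNPs make the scale
    zero and are rejected by name.
    """
    if not (0.0 <= F <= 1.0):
        raise ValueError("inbreeding coefficient F must lie in [0, 1]")
    if G.has_missing:
        raise ValueError("standardize requires a complete (imputed) panel")
    if freqs is None:
        freqs = allele_frequencies(G)
    if freqs.monomorphic.any():
        snp = G.snps.loc[int(np.argmax(freqs.monomorphic)), "id"]
        raise ValueError(f"SNP {snp} is monomorphic; cannot standardize")
    scale = np.sqrt(2.0 * (1.0 + F) * freqs.p * freqs.q)
    values = (G.dosages.astype(np.float64) - 2.0 * freqs.p) / scale
    return StandardizedMatrix(values=values, inbreeding_f=float(F), freqs=freqs,
                              samples=list(G.samples), snps=G.snps.copy())
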