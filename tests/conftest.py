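import numpy as np
import pandas as pd
import pytest

from ldgrid import (ChromosomeSpec, GenotypeMatrix, SimulationConfig,
                    simulate_panel, standardize)


def make_genotypes(dosages, chroms=None, bps=None):
    """Build a GenotypeMatrix from a raw dosage array (−1 = missing)."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n, m = dosages.shape
    if chroms is None:
        chroms = [1] * m
    if bps is None:
        bps = list(range(1000, 1000 * (m + 1), 1000))
    snps = pd.DataFrame({
        "chrom": chroms,
        "id": [f"snp{j}" for j in range(m)],
        "cm": 0.0,
        "bp": bps,
        "a1": "A",
        "a2": "B",
    })
    return GenotypeMatrix(dosages=dosages, samples=[f"s{i}" for i in range(n)],
                          snps=snps)


@pytest.fixture(scope="session")
def blocky_panel():
    """60 samples, two chromosomes with strong 10-SNP LD blocks."""
    cfg = SimulationConfig(
        n=60,
        chromosomes=[ChromosomeSpec(m=80, block_size=10, within_r=0.7),
                     ChromosomeSpec(m=60, block_size=10, within_r=0.4)],
        maf_range=(0.1, 0.5), seed=11)
    return simulate_panel(cfg)


@pytest.fixture(scope="session")
def blocky_standardized(blocky_panel):
    return standardize(blocky_panel)
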