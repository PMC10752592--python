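"""Mean-LD estimators: intra, inter, scaled, genome decomposition, summaries."""

import numpy as np
import pytest

from ldgrid import (ChromosomeSpec, GRM, SimulationConfig, build_grm,
                    combine_genome_ld, genome_ld, grm_moments, inter_ld,
                    intra_fraction_summary, intra_ld, ld_partition,
                    plink_mean_r2, scaled_inter_ld, self_adjusted_ld,
                    simulate_panel, standardize, true_ld_summary)

from conftest import make_genotypes


class TestIntraLD:
    def test_two_sample_value(self):
        est = intra_ld(GRM(np.array([[1.0, 0.5], [0.5, 1.0]]), snp_count=2))
        assert est.value == pytest.approx(0.25)
        assert est.se >= 0

    def test_independent_panel_near_self_pair_floor(self):
        # no LD: l ~ 1/m, within 3 analytic SEs
        cfg = SimulationConfig(n=500, chromosomes=[ChromosomeSpec(m=200, block_size=10)],
                               maf_range=(0.05, 0.5), seed=17)
        Z = standardize(simulate_panel(cfg))
        est = intra_ld(build_grm(Z))
        assert abs(est.value - 1 / 200) <= 3 * est.se

    def test_value_is_nonnegative(self, blocky_standardized):
        for c in (1, 2):
            mask = (blocky_standardized.snps["chrom"] == c).to_numpy()
            assert intra_ld(build_grm(blocky_standardized, mask)).value >= 0


class TestInterLD:
    def test_self_pair_reduces_to_intra(self, blocky_standardized):
        K = build_grm(blocky_standardized)
        est = inter_ld(K, K, n_boot=0)
        assert est.value == pytest.approx(intra_ld(K).value, abs=1e-15)

    def test_independent_chromosomes_near_zero(self):
        cfg = SimulationConfig(
            n=300, chromosomes=[ChromosomeSpec(m=150, block_size=15, within_r=0.5)] * 2,
            maf_range=(0.1, 0.5), seed=23)
        Z = standardize(simulate_panel(cfg))
        K1 = build_grm(Z, (Z.snps["chrom"] == 1).to_numpy())
        K2 = build_grm(Z, (Z.snps["chrom"] == 2).to_numpy())
        est = inter_ld(K1, K2, n_boot=200, seed=1)
        assert abs(est.value) <= 3 * est.se

    def test_bootstrap_is_seeded(self, blocky_standardized):
        Z = blocky_standardized
        K1 = build_grm(Z, (Z.snps["chrom"] == 1).to_numpy())
        K2 = build_grm(Z, (Z.snps["chrom"] == 2).to_numpy())
        a = inter_ld(K1, K2, n_boot=50, seed=3)
        b = inter_ld(K1, K2, n_boot=50, seed=3)
        assert a.se == b.se


class TestScaling:
    def test_self_adjustment_points(self):
        assert self_adjusted_ld(1.0, 10) == pytest.approx(1.0)   # fixed point
        assert self_adjusted_ld(0.5, 2) == pytest.approx(0.0)    # pure self-pairs
        assert self_adjusted_ld(1.1e-3, 136_000) == pytest.approx(1.0927e-3, rel=1e-3)
        with pytest.raises(ValueError):
            self_adjusted_ld(0.5, 1)

    def test_scaled_inter_unit_point(self):
        mo = grm_moments(GRM(np.array([[1.0, 0.1], [0.1, 1.0]]), 2))
        v, var = scaled_inter_ld(2e-3, 2e-3, 2e-3, n=100,
                                 moments_i=mo, moments_j=mo)
        assert v == pytest.approx(1.0)

    def test_scaled_inter_cohort_magnitude(self):
        # components at homogeneous-European scale give a ratio near 0.1
        mo = grm_moments(GRM(np.eye(2), 2))
        v, _ = scaled_inter_ld(1.0e-4, 1.1e-3, 1.1e-3, n=99,
                               moments_i=mo, moments_j=mo)
        assert v == pytest.approx(1.0e-4 / 1.1e-3, rel=1e-12)
        assert v == pytest.approx(0.10, abs=0.01)

    def test_variance_vanishes_at_degenerate_point(self):
        # var(kio) var(kjo) == cov^2 makes the bracket collapse
        n = 50
        cov = 3e-3 - 1.0 / (n - 1) ** 2
        mo = grm_moments(GRM(np.eye(2), 2))
        mo.var_off = cov  # construct the degenerate configuration
        _, var = scaled_inter_ld(3e-3, 2e-3, 2e-3, n=n,
                                 moments_i=mo, moments_j=mo)
        assert var == pytest.approx(0.0, abs=1e-18)

    def test_nonpositive_adjusted_ld_rejected(self):
        mo = grm_moments(GRM(np.eye(2), 2))
        with pytest.raises(ValueError):
            scaled_inter_ld(1e-4, 0.0, 1e-3, 10, mo, mo)


class TestGenomeDecomposition:
    def test_single_chromosome_is_identity(self, blocky_standardized):
        mask = (blocky_standardized.snps["chrom"] == 1).to_numpy()
        Z1 = blocky_standardized.subset(mask)
        part = ld_partition(Z1, n_boot=0)
        assert part.genome.value == pytest.approx(part.intra[1].value, abs=1e-15)

    def test_two_chromosome_arithmetic(self):
        val = combine_genome_ld({1: 0.01, 2: 0.01}, {(1, 2): 0.001},
                                {1: 50, 2: 50})
        assert val == pytest.approx(0.0055)

    def test_decomposition_equals_whole_genome_grm(self, blocky_standardized):
        part = ld_partition(blocky_standardized, n_boot=0)
        whole = intra_ld(build_grm(blocky_standardized))
        assert genome_ld(part).value == pytest.approx(whole.value, rel=1e-10)

    def test_partition_bookkeeping(self, blocky_standardized):
        part = ld_partition(blocky_standardized, n_boot=0)
        assert part.C == 2
        assert len(part.inter) == 1
        assert part.m == blocky_standardized.m
        assert set(part.scaled_inter) == set(part.inter)


class TestSummaries:
    def test_trivial_limits(self):
        assert intra_fraction_summary(1e-3, 0.0, 22) == 1.0
        assert true_ld_summary(1e-3, 0.0) == 1.0
        with pytest.raises(ValueError):
            intra_fraction_summary(0.0, 0.0, 22)
        with pytest.raises(ValueError):
            true_ld_summary(0.0, 0.0)

    def test_inter_component_lowers_the_fraction(self):
        a = intra_fraction_summary(1e-3, 1e-4, 22)
        b = intra_fraction_summary(1e-3, 5e-4, 22)
        assert 0 < b < a < 1


class TestPlinkReference:
    def test_duplicated_snp_has_unit_r2(self):
        d = np.array([[0, 0], [1, 1], [2, 2], [1, 1]], dtype=np.int8)
        G = make_genotypes(d)
        assert plink_mean_r2(G, [0], [1]) == pytest.approx(1.0)

    def test_three_snp_mean_matches_explicit_pearson(self):
        rng = np.random.default_rng(12)
        d = rng.integers(0, 3, (30, 3)).astype(np.int8)
        G = make_genotypes(d)
        r2s = []
        for a in range(3):
            for b in range(a + 1, 3):
                r = np.corrcoef(d[:, a], d[:, b])[0, 1]
                r2s.append(r * r)
        assert plink_mean_r2(G, np.arange(3)) == pytest.approx(
            np.mean(r2s), abs=1e-12)

    def test_include_self_adds_unit_diagonal(self):
        rng = np.random.default_rng(13)
        d = rng.integers(0, 3, (40, 4)).astype(np.int8)
        G = make_genotypes(d)
        without = plink_mean_r2(G, np.arange(4))
        with_self = plink_mean_r2(G, np.arange(4), include_self=True)
        assert with_self == pytest.approx((without * 12 + 4) / 16, abs=1e-12)

    def test_zero_variance_column_rejected(self):
        d = np.array([[0, 1], [0, 2], [0, 1]], dtype=np.int8)
        with pytest.raises(ValueError, match="zero variance"):
            plink_mean_r2(make_genotypes(d), [0, 1])
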