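# Methods

## Model

For biallelic loci `l₁, l₂` with counted-allele frequencies `p`, LD is the
squared Pearson correlation `ρ²_{l₁l₂} = D²_{l₁l₂}/(p_{l₁}q_{l₁}p_{l₂}q_{l₂})`
of allele dosages. All mean-LD quantities are averages of `ρ²` over a grid of
SNP pairs: `ℓᵢ` over the `mᵢ²` ordered pairs within SNP set *i* (self-pairs
included, each contributing 1), `ℓᵢ.ⱼ` over the `mᵢmⱼ` cross pairs, `ℓ_g`
over the whole genome, and `ℓᵤ`/`ℓᵤᵥ` over B-SNP bins of a single
chromosome. Because genotypic (unphased) dosages are used throughout, the
estimated quantity is composite r² — the same measure PLINK's `--r2`
reports on dosages.

The estimator standardizes dosages as `x̃ = (x − 2p̂)/√(2(1+F)p̂q̂)` with
`p̂` the post-imputation sample frequency (denominator `2n`, no
pseudo-counts) and `F` the inbreeding coefficient (default 0, a
random-mating population; 1 for fully inbred). With `Kᵢ = X̃ᵢX̃ᵢᵀ/mᵢ` and
`k_io` the off-diagonal entries of `Kᵢ`, Isserlis's fourth-moment identity
for unrelated individuals (pairwise relatedness θ = 0) gives

    E(k_io²) = ℓᵢ,    E(k_io k_jo) = ℓᵢ.ⱼ,

so every grid mean costs `O(n²)` once the block GRMs (`O(n²m)` total) are
built. The genomic decomposition
`ℓ_g = Σ(mᵢ/m)²ℓᵢ + Σ_{i≠j}(mᵢmⱼ/m²)ℓᵢ.ⱼ` is implemented as an exact
algebraic identity: the whole-genome GRM is assembled as the SNP-weighted
average `K_g = Σ(mᵢ/m)Kᵢ`, so the identity holds to machine precision and is
asserted at 1e-10 in tests. Related samples (θ ≠ 0) are out of scope; the
GRM records the assumption explicitly.

Sampling variances come from the delta method:
`var(ℓᵢ) = 4 var(k_io)²/(n(n−1))` with the empirical off-diagonal variance
substituted; the scaled inter statistic `ℓ̃ᵢ.ⱼ = ℓᵢ.ⱼ/√(ℓ̃ᵢℓ̃ⱼ)` (with
`ℓ̃ᵢ = (mᵢℓᵢ−1)/(mᵢ−1)` removing self-pairs) carries
`var = (2ℓ̃ᵢ.ⱼ²/(n(n−1)))·[v + 1/v − 2]`, `v = var(k_io)var(k_jo)/cov²`,
`cov = ℓᵢ.ⱼ − 1/(n−1)²`. No closed form exists for the raw `ℓᵢ.ⱼ`, whose SE
is a seeded sample bootstrap (default 200 resamples). These variances are
delta-method approximations under idealized moments; Monte-Carlo calibration
(a factor-2 agreement band) is part of the acceptance suite, and the band is
genuinely needed — under strong block LD the off-diagonal entries are
heavily dependent and the formula can be optimistic.

Two cohort-level summaries condense a partition: the intra-chromosomal
fraction `Cℓ̄ᵢ/(Cℓ̄ᵢ + C(C−1)ℓ̄ᵢ.ⱼ)` (a lower bound on the share of genomic
LD that is intra-chromosomal; both pair orderings counted) and the true-LD
share `ℓ̄ᵢ/(ℓ̄ᵢ + b̂₀)` which discounts the long-range floor estimated by
the decay regression.

## Finite-sample behaviour of the moment estimator

With known frequencies the estimator is unbiased. With plug-in `p̂` (the
only practical choice) it carries a small finite-sample bias of order
`ℓ/n`: measured at n = 500, m = 200 on independent-SNP panels the mean
estimate is low by ≈ 1.8e-5 against the self-pair floor 1/m = 5e-3
(relative ≈ −2/n; the sign flips when m/n is large). Standardizing by true
frequencies removes it, confirming the plug-in mechanism. This is
negligible against the sampling SE of any single estimate (the single-panel
check "within 3 analytic SEs of 1/m" passes comfortably) but is resolvable
by averaging hundreds of replicate panels, where a 3-Monte-Carlo-SE
unbiasedness band at 200 replicates is exceeded — the corresponding
acceptance check documents this honestly rather than hiding it. No
correction is applied: the estimator is kept exactly as derived.

The brute-force sample-r² reference behaves differently: under no LD its
cross-pair mean sits near `1/(n−1)`, so PLINK-style means exceed the
GRM-moment estimate by ≈ 1/n. Regressing one on the other across panels
reproduces `y = 1/n + x` (slope 1, intercept 1/n), which the acceptance
suite verifies at desk scale.

## Quality control and imputation

Pipeline order: autosome restriction (chromosome codes 1–22) and
missing-rate filter (drop SNPs with missingness > 0.2) → Hardy–Weinberg
imputation → MAF filter (keep minor allele frequency > 0.05) → monomorphic
drop. MAF is thereby computed on complete data, which keeps the filter and
the standardization consistent. Imputation draws each missing genotype from
(q̂², 2p̂q̂, p̂²) using that SNP's non-missing calls, seeded and
bit-reproducible; it is deliberately naive, and heavily missing panels
should be imputed with a dedicated tool first. Dosage counts the second
.bim allele (PLINK A2); all statistics are squared correlations and are
invariant to which allele is counted.

## Grids, regions, decay

Chromosome bins are defined on SNP counts in file order: `β = ⌈mᵢ/B⌉`
consecutive bins (default B = 250), the last possibly short. Each bin's GRM
is built once and combined pairwise; a byte-budgeted LRU cache bounds
memory, and results are bit-identical across budgets. The chromosome mean
reassembles exactly from its grid with `mᵤmᵥ` weights. Region analyses
(e.g. an HLA cluster or a centromere) take 1-based inclusive base-pair
intervals; knockouts recompute the chromosome without the region. Grid TSVs
store raw values; the optional heatmap applies −log10 with a 1e-6 floor.

The decay regression `ℓ = b₀ + b₁x + e`, `xᵢ = 1/mᵢ`, uses
population-moment (divide-by-C) covariances — identical to OLS — and is
unweighted by default (a weighted variant exists but is off, matching the
plain-regression convention). Under a segment-exchangeable genome,
`E(b₁) = [E(ℓᵤ)−E(ℓᵤᵥ)]·m_seg ≈ E(ℓᵤ)·m_seg` and `E(b₀) = E(ℓᵤᵥ)`;
`recover_segment_parameters` inverts this. Pearson's R of `(x, ℓ)` is
reported signed; leave-one-chromosome-out refits flag chromosomes (such as
centromere-inflated ones) that distort the linear norm.

## Simulator

Haplotypes come from a latent-Gaussian copula: within an s-SNP block the
latent variables follow AR(1) (correlation r between neighbours) or an
exchangeable model (r between all pairs); blocks are independent; an
optional genome-wide background factor adds a uniform latent correlation
across all SNPs (the long-range/inter-chromosomal LD knob). An allele is
the indicator `latent < Φ⁻¹(p)`; a genotype sums two independent
haplotypes, so each SNP is binomial(2, p) under Hardy–Weinberg and the
simulated r² is composite, matching what both estimation routes measure. At
maf 0.5 the dosage correlation follows the arcsine law `(2/π)·asin(ρ_lat)`
exactly, which the calibrated studies exploit and a test verifies.
Structure draws subpopulation frequencies from the Balding–Nichols Beta
model around the ancestral frequency; admixture replaces hard assignment
with Beta-distributed individual ancestries. Panels are bit-deterministic
given the config seed.

What the simulator does *not* emulate: coalescent genealogy, recombination
maps and distance-dependent decay within blocks, phased haplotype D′,
mutation-frequency coupling, and missingness mechanisms other than
completely-at-random. Passing tests therefore demonstrate correctness of
the estimators under block-structured composite LD and Beta-model
structure, not realism of any particular human cohort.

## Study designs fixed in the validation suite

* Oracle equivalence: 20 panels (n = 50, four 50-SNP chromosomes); every
  intra, inter and grid value against explicit-loop GRM moments at 1e-10.
* Reconciliation: 50 panels (n = 100, m = 500, 25-SNP AR(1) blocks,
  within-block correlation swept 0→0.9), spanning mean r² ≈ 2e-3–6e-3 — the
  magnitude of real chromosomal values — so the slope is identified while
  staying in the no/low-LD regime.
* No-LD limit: 200 independent-SNP panels at n = 500, m = 200 (see the
  finite-sample note above).
* SE calibration: 200 replicate panels from one fixed population
  (n = 200, m = 300, 10-SNP blocks, r = 0.5, maf 0.5).
* Decay recovery: 22 chromosomes of 5–40 AR(1) segments of 100 SNPs,
  n = 400, maf 0.5; the AR(1) coefficient is solved numerically so the
  within-segment off-pair mean ρ² is exactly (0.1·s² − s)/(s² − s) and the
  background factor set so cross-segment mean ρ² = 0.001. AR(1) rather than
  exchangeable segments: with a single shared factor per segment the
  realized segment LD fluctuates like one meta-pair and the intercept
  recovery is needlessly noisy, whereas AR(1)'s local dependence
  self-averages.
* Structure: paired seeds at Fst = 0.1 versus homogeneous (n = 150, two
  200-SNP chromosomes); eigenvalue calibration at Fst = 0.05, n = 200,
  m = 5000.

Problem sizes were chosen as the smallest at which each property is cleanly
resolved; all run on a single CPU in a few minutes.

## Numerical conventions and edge cases

Off-diagonal moments use the population-variance convention over the
`n(n−1)` ordered pairs (symmetric matrices make ordered and unordered means
coincide). Column centering makes `mean(k_io) = −trace(K)/(n(n−1))`
exactly; it equals `−1/(n−1)` only to O(1/n) because the binomial-scaled
diagonal is near, not exactly, 1. GRMs are accumulated in double precision
over SNP chunks (results chunk-invariant). The top eigenvalue uses a full
symmetric solve for n ≤ 4000 and otherwise power iteration (fixed start
vector, tolerance 1e-8, ≤ 1000 iterations). Degenerate inputs fail loudly
and by name: monomorphic SNPs at standardization, all-missing SNPs at
imputation, empty SNP subsets, regions with fewer than two SNPs, bins of
fewer than two SNPs, zero-variance columns in the r² reference, non-finite
GRM entries. The scaled-inter variance returns infinity when the moment
bracket degenerates (zero covariance or zero variance product). The
brute-force oracle refuses more than 1e7 pairs.

## Applying the pipeline to sequencing cohorts

The default QC (autosomes; missingness ≤ 0.2 then HWE imputation; MAF
> 0.05) matches the standard recipe for 1000-Genomes-style cohort panels;
for multi-cohort comparisons, restrict to the consensus SNPs present in
every cohort before running `ldgrid ld`. Region coordinates for the usual
suspects on GRCh38-era panels: HLA cluster chr6:28,477,797–33,448,354;
chr11 centromere 46,061,947–59,413,484. Cohort-scale results depend on the
exact consensus-panel construction and are not reproduced at desk scale;
the synthetic acceptance test exercises the identical code path end to end.

## Known limitations

O(n²m) is still quadratic in n: fine for cohort panels of a few hundred to
a few thousand samples, slow at biobank scale (no Mailman-algorithm or
randomized acceleration is implemented). Related samples violate the θ = 0
assumption and are not corrected for. The delta-method variances degrade
under strong dependence (hence the factor-2 calibration band). The plug-in
frequency bias of order ℓ/n, while immaterial for any single estimate, is
detectable in large replicate averages. Bootstrap SEs for `ℓᵢ.ⱼ` resample
samples, not SNPs, and so capture sampling-of-individuals uncertainty only.
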