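# Methods

`haplomerge` evaluates how the way two genotyping-array cohorts are merged
*before* haplotype phasing affects downstream imputation accuracy, batch
artifacts, and polygenic scores. Everything runs on a synthetic biobank, so
all truth — haplotypes, transmitted gametes, causal effects — is known and
every metric is scored against it.

## The synthetic biobank

**Haplotype panel.** A single chromosome of `n_sites` biallelic SNPs with
strictly increasing bp positions and a genetic map of `map_length_cm`
centimorgans (default 2,000 sites over 200 cM, so ~0.1 cM between adjacent
markers). Variation starts from a founder bottleneck: `n_founders` (default
96) haplotypes are drawn site-independently from Balding–Nichols
per-population allele frequencies (`fst` per population around a shared
ancestral frequency ~ Uniform(0.05, 0.95)). The population then expands
immediately to a pool of `n_haplotypes` (default 12,000) and recombines for
`n_generations` (default 16): each new haplotype is a mosaic of two
same-population haplotypes of the previous generation, with crossover count
Poisson in the map length in Morgans and crossover positions uniform on the
genetic map, plus a symmetric per-site mutation flip (3×10⁻⁴ per
generation).

Why this shape: linkage disequilibrium in this model comes from
founder-block sharing, and pairwise r² between nearby sites scales like
1/(number of founders), while close relatedness among final haplotypes
scales like generations/(pool size). A small founder pool recombined inside
a much larger pool therefore gives array-like LD (adjacent-site r² a few
percent, long shared segments that a copying HMM can exploit, masked-site
imputation r² ≈ 0.8 from truth scaffolds) while keeping the spread of the
kinship proxy small enough that relatedness pruning leaves a usable sample.
These two quantities cannot be decoupled further on one desk-scale
chromosome: LD *is* segment sharing. Founders are split evenly across
populations — a small modern population is not less diverse, merely less
represented — which is what makes a reference panel skewed toward the
majority population genuinely worse for the minority.

**Populations.** Two populations (F_ST 0 and 0.1 against the ancestral
frequencies), mixed 85/15 in the pool. Cohort samples are drawn 80%
majority (pop0), 12% minority (pop1), 8% admixed; an admixed individual
carries one gamete from each population (one parent from each). Diploids
pair two dedicated pool haplotypes, so truth phase is known exactly; a
`HapPool` hands out pool rows without reuse so reference, cohorts and trio
parents never share haplotypes.

**Arrays, cohorts, waves.** Two array manifests of 840 and 1,510 panel
sites with 400 shared (the ~1:1.8 size ratio and ~28% overlap of the arrays
the study design emulates). Cohort A: 600 samples on array A; cohort B: 400
on array B; six genotyping waves each with per-wave missingness 1% and a
symmetric per-allele genotyping error of 10⁻³. The reference panel holds
400 panel haplotypes, 90% from pop0 — deliberately skewed.

**Trios.** 40 father–mother–offspring trios, parents drawn from pop0,
offspring gametes recombinant with Poisson crossovers; both transmitted
gametes are stored, so trio-resolved phase is exact. Trios are genotyped
error-free on both arrays and kept disjoint from the cohorts.

**Phenotype.** y = g + e with g = Z β over the masked markers
(column-standardized genotypes, β ~ N(0,1)) and e scaled so
var(g)/var(y) = 0.5 in expectation (h² = 0.5). Per-alt-allele effects
β/sd(genotype) are stored so oracle scoring works on raw dosages.

## QC battery

Site filters run in order, each on the survivors of the previous one:
per-wave and merged missingness (exclude if > 5% in any wave or overall;
strict ">"), case/control differential missingness (2×2 Pearson chi-square
without continuity correction, BH-FDR ≤ 0.2 excluded), Hardy–Weinberg in
pop0 controls (1-df chi-square, monomorphic sites get p = 1, BH-FDR ≤ 0.2),
the minimum-p batch-artifact scan, and MAF censoring (< 0.001, strict "<").

The batch-artifact scan runs a one-vs-rest allele-count chi-square per wave
per site and takes the per-site minimum p. Because the minimum of m
uniforms is not uniform, its null CDF is 1−(1−p)^m; the FDR-style adjusted
value divides the expected count of minima below p under that null,
n_snps·(1−(1−p)^m), by the observed count, and sites with adjusted value
≤ 0.1 are excluded. The two "m"s are deliberately distinct parameters —
batch count in the exponent, SNP count in the multiplier — since only that
reading makes the ratio an expected/observed FDR. Theoretical quantiles
1−(1−i/n)^(1/m) are emitted for QQ diagnostics.

Sample filters: overall missingness > 5%; abnormal heterozygosity (observed
het regressed on PC1–4, their squares and all pairwise products; a sample
is flagged only if observed het, adjusted het and the residuals of both on
runs of homozygosity all sit > 4 SD from their means — the conjunctive
reading; ROH is the total length of homozygous runs ≥ 25 consecutive sites,
a desk-scale stand-in for physical-length callers, and the ROH regressions
are skipped when no run qualifies). A homogeneous subset is selected by
squared Mahalanobis distance of the first 10 PCs to the pop0-anchored
centroid, keeping samples whose chi-square(10) upper-tail probability is
≥ 5.73×10⁻⁷. Duplicates (kinship proxy > 0.45) keep the lower-missingness
copy, preferring cases; the GWAS/PGS subset additionally drops one member
of every pair with kinship ≥ 0.0825.

The kinship proxy is half the standardized-genotype covariance (identical
pair ≈ 0.5, parent–offspring ≈ 0.25). It is computed blockwise —
within-cohort pairs on the cohort's full QC'd site set, cross-cohort pairs
on the shared sites — to use all available markers per pair. On one
desk-scale chromosome its sampling spread (~0.025, inflated by LD) makes
the 0.0825 third-degree cutoff conservative: roughly 60–70% of samples are
pruned, a known cost of estimating kinship from few, correlated markers.
The experiment runs on whatever subset survives.

## Integration protocols

Masking comes first: `mask_k` (default 100) markers shared by both QC'd
cohorts are held out before any protocol is built, so all protocols are
scored on the identical site set. Then:

* **separate** — each cohort keeps its own markers; trio offspring are
  appended to both cohorts.
* **intersection** — both cohorts merged at the shared markers; each
  dual-genotyped offspring enters once, with the array version chosen by a
  seeded half/half split.
* **union** — merged at the markers on either array; a sample is missing
  wherever its array lacks a marker (structural missingness ~50% at the
  default geometry).
* **two-stage** — the separately phased cohorts are imputed to the union
  markers, hard-called (posterior-mode genotype; observed calls never
  overwritten), merged with zero missingness, re-phased jointly, split back
  to their genotyped markers, and only then imputed to the full reference.

## The haplotype-copying engine

One Li–Stephens engine with a conditioning-set-size knob replaces the
production phasing/imputation tools; settings `small` (40 states) and
`large` (80) preserve the default-vs-high-resolution contrast those tools
expose. Transitions per interval are 1−exp(−4·Ne·Δcm/100/K) (Ne = 100),
emissions allow a symmetric per-allele copying error (10⁻³), and forward
values are rescaled per site (no log-space needed at these rates).

**Phasing** is iterative conditional decoding. The first sweep conditions
each sample on its K Hamming-closest reference haplotypes; later sweeps
draw candidates from the reference plus all other samples' current
estimates (snapshotted per sweep). Decoding must confront a structural
fact: under genotype emissions the diploid copying HMM is exactly
label-symmetric, so per-site posterior marginals carry no phase information
at all. The decoder therefore stores a backward table under symmetric
emissions (exact, since future genotypes are orientation-free) and walks
forward choosing each heterozygous site's orientation from its posterior
given all previous *chosen* orientations and all data, folding the chosen
ordered emission into the running forward vector. Missing genotypes are
filled with the sequential posterior-mode genotype, flagged, and never fold
into the decode. Two sweeps are the default; phase quality saturates after
the reference-conditioned sweep at desk scale.

**Imputation** runs each phased haplotype through the haploid copying HMM
against its K nearest reference haplotypes, combines the two alt-allele
posteriors into genotype probabilities, and reports DS = p(RA) + 2·p(AA).
Observed genotype calls pass through as DS. Per-site quality (DR2) is the
MaCH-Rsq form var(DS)/(2p̂(1−p̂)) with p̂ = mean(DS)/2, clipped to [0,1];
it is undefined (0) for a single sample or constant dosages. A brute-force
path-enumeration oracle (≤ ~6 sites × ≤ ~4 reference haplotypes) verifies
the forward–backward posteriors exactly and lives only in the tests.

**Consensus voting** across ≥ 3 phasing runs walks het sites in order; each
estimate votes switch/no-switch per inter-het interval and the majority
wins (ties keep the phase; the first het anchors orientation).

## Evaluation

**SER.** Trio phase is resolved by Mendelian transmission (forced when a
parent is homozygous; triple-het sites unresolvable; inconsistent sites
dropped with a count). SER counts adjacent resolvable-het pairs whose
relative orientation disagrees with the truth, divided by the possible
switches Σ(k−1); it is invariant to a global label swap. A per-block
breakdown over equal-cM windows exposes the SNP-density/SER relationship
on the single simulated chromosome.

**Imputation r².** Pooled (sample, site) squared Pearson correlation
between dosages and held-out truth per reference-MAF bin — bins (0,0.005],
(0.005,0.01], (0.01,0.05], (0.05,0.1], (0.1,0.2], (0.2,0.5] — overall and
by ancestry group. Pooling is the default because per-SNP r² is unstable in
rare bins; a per-SNP mode exists. Zero-variance cells are reported missing,
never 0.

**λ_GC.** Cohort-membership association scans on unrelated homogeneous
controls, using the 1-df allele-dosage trend chi-square (n·r²);
λ = median χ²/0.4549. The genotyped-vs-imputed arms run at array-exclusive
markers (genotyped on one array, necessarily imputed in the other cohort) —
at desk scale that is where cross-array artifacts express; at the masked
markers, joint phasing correlates the two cohorts' dosage errors and
deflates rather than inflates the mixed signal. The imputed-vs-imputed arm
runs at the masked markers. DR2 thresholds (0, 0.5, 0.9) filter each arm's
imputed side(s). The deviation from the masked-site-only design is
deliberate and documented: the production tools' pre-phasing fills carry
array-specific biases that this engine's posterior fills largely avoid, so
the masked-site mixed arms alone understate the phenomenon here.

**PGS.** The trait is simulated once over both cohorts (one shared genetic
architecture). For each discovery→scoring direction and protocol, three
arms: truth/truth (reference), GWAS on dosages + scoring on truth
(imputed-discovery), GWAS on truth + scoring on dosages (imputed-scoring).
GWAS is per-site OLS with age, sex and 10 PCs as covariates (residualized
form, identical to the joint fit); scores are Σᵢ βᵢ Xᵢⱼ over the masked
markers. Variance explained defaults to the nested contrast
R²(covariates+PGS) − R²(covariates), which is nonnegative by construction;
the literal two-model contrast (PGS-only vs PGS+covariates) is available
via `mode="two_model"` since as literally described it can go negative.
Rank concordance assigns percentiles by stable rank and reports the
100×100 joint-occupancy matrix and the top-5% overlap.

## Problem sizes and numerical choices

The default configuration (2,000 sites, cohorts 600+400, arrays 840/1,510
with 400 shared, 100 masked sites, 40 trios, K = 40) runs end to end in a
few minutes on one CPU. Repeated-seed studies use
`RunConfig.compact()` — identical marker density, array-size ratios and
population structure at half the chromosome (1,000 sites, arrays 420/755,
200 shared, 60 masked, K = 24); cohort sizes stay at 600+400 for
seed-replication work because the PGS top-5% overlap needs ~200 scored
samples per cohort to be estimable at all. All randomness derives from one
master seed through per-stage name-hashed streams, so adding a stage never
perturbs earlier stages and full runs are byte-reproducible. Tolerances:
forward–backward vs enumeration agrees to ~1e-10 (double precision with
per-site rescaling); BH adjustment matches the textbook step-up to 1e-12;
degenerate cases (monomorphic sites, constant dosages, empty DR2 strata,
all-zero ROH) are defined explicitly rather than left to NaN propagation.

## What the generator does and does not emulate

It reproduces: partial marker overlap between two arrays, wave-structured
missingness, genotyping error, population structure with a skewed reference
panel, admixture, trios with exact transmitted gametes, and a fully
polygenic trait on held-out markers. It does not reproduce: real human
demographic history or recombination hotspots, strand ambiguity (alleles
are fixed A/G), intensity-level genotyping artifacts, sex chromosomes,
indels/CNVs/multi-allelics, or genome-scale marker counts. Consequences to
keep in mind when reading results: absolute SER and r² sit well below
genome-scale values because one short chromosome offers far fewer markers
per centimorgan; DR2 ≥ 0.9 is a much harsher filter here than at
production scale (few desk-scale sites reach that estimated quality); and
relatedness pruning is far more aggressive than with genome-wide kinship
estimates. The *orderings* between protocols, populations and PGS arms are
the meaningful outputs, not the absolute levels.
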