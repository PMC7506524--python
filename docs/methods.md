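# Methods

## Scope and data model

The pipeline starts from four inputs: discovery GWAS summary statistics
(SNP, chromosome, 1-based position, effect allele A1, other allele A2,
log-odds effect, P), target-sample allele dosages in [0, 2] (TSV, or VCF
with a `DS` FORMAT field via cyvcf2; dosages are written back only as TSV),
a per-subject phenotype/covariate table, and per-subject 90-region BOLD
time-series matrices in AAL order together with per-axis maximum-motion
summaries. Voxel-level spatial preprocessing (realignment, normalization,
smoothing) and genotype imputation are upstream of this package; the
region-wise series and the imputed dosages are where it begins.

## Genotype QC and ancestry components

Variant filters: minor allele frequency (mean dosage / 2, folded) < 1%,
call rate < 95%, Hardy–Weinberg equilibrium P < 10⁻⁵. HWE uses the 1-df
chi-square goodness-of-fit of hard-called genotype counts (dosage rounded
to the nearest integer) against the p², 2pq, q² expectations; the exact
test would be a natural extension but the chi-square is standard for array
QC at these sample sizes. A monomorphic site returns P = 1. Sample
filters: missingness > 5%, a caller-supplied sex-mismatch flag (the data
model carries no X chromosome, so heterozygosity-based checking is out of
scope), and pairwise relatedness PI_HAT > 0.90. PI_HAT is the
method-of-moments estimator P(IBD=1)/2 + P(IBD=2) from identity-by-state
counts with their expectations at sample allele frequencies — the
asymptotic per-SNP probabilities without the finite-sample bias
correction, which is negligible at the SNP counts involved. In a flagged
pair the member with higher missingness is removed; at a tie the
lexicographically smaller id (the published protocols are silent on the
tie). Ancestry PCs come from the SVD of the dosage matrix standardized
per SNP by √(2p(1−p)) (population-genetics convention; the choice affects
component scale only, not covariate adjustment), missing values
mean-imputed, signs fixed so each component's largest-magnitude SNP
loading is positive.

## PRS construction

Clumping is greedy and P-informed: SNPs visited by ascending P (ties:
position, then id); each unclaimed SNP becomes an index SNP and claims all
unclaimed same-chromosome SNPs within ±250 kb whose squared dosage
correlation exceeds 0.1. LD is computed from the target-sample dosages —
the realistic choice when no external reference panel is assumed. One
clumping pass on the primary-disorder statistics is reused for every
threshold and for the partition (PRSice behaviour); a comparison-disorder
PRS is clumped independently on its own statistics.

The threshold grid is the 100 multiples of 0.005 in (0, 0.5] plus 10⁻⁵,
10⁻⁴ and 10⁻³ — 103 values. A threshold of exactly zero selects no SNPs
and is excluded; this is the only reading under which the grid's stated
count holds.

Scoring sums aligned dosage × β over retained SNPs with p ≤ P_T. Allele
alignment: if target A1/A2 match the statistics' A1/A2 the dosage is used
as-is; if swapped, 2 − dosage; strand-ambiguous A/T and C/G SNPs are
dropped (with a logged count) rather than frequency-resolved —
unambiguous and reproducible; any other allele pair is dropped and logged.
Missing dosages take the SNP's mean. Scores are raw weighted sums, not
per-SNP averages; all downstream association statistics are invariant to
that scale choice.

The case–control scan fits, per threshold, a logistic regression of status
on score plus covariates; the association P is the score coefficient's
Wald test and Nagelkerke's pseudo-R²,
R² = (1 − exp(2(ll₀ − ll₁)/n)) / (1 − exp(2·ll₀/n)),
compares the full fit against the covariates-only fit. Non-converged or
separated thresholds are flagged and excluded from top-k selection (ties
select the smaller threshold). Covariates are included in the selection
regressions.

"Shared with the comparison disorder" means present in its summary
statistics with p ≤ the same P_T (the criterion the source protocols leave
undefined); a presence-at-any-p alternative sits behind
`scz_criterion="any"`. The shared and specific subsets tile the selection,
so subset scores add exactly to the full score.

## ALFF

Motion screening keeps a subject iff every translation ≤ 3 mm and every
rotation ≤ 3° (the exclusion criterion is the strict "> 3" reading, so
exactly 3.0 is kept). Nuisance regression residualizes each region on an
intercept, a linear trend and the supplied nuisance signals in one least-
squares pass; the order regress-then-spectral-ALFF is fixed and documented
because upstream tool chains leave it unstated.

ALFF is computed spectrally rather than by time-domain band-pass
filtering: the definition — mean square root of power over the 0.01–0.08
Hz window — is directly a periodogram statistic, and the two routes differ
only by filter leakage. The amplitude at Fourier bin k is 2|X_k|/N, so a
pure in-band sinusoid of amplitude A at an exact Fourier frequency
contributes √power = A at its bin and A/n_band_bins to the region's ALFF
(with N = 200, TR = 2 s the band holds bins k = 4..32, i.e. 29 bins). Band
endpoints are inclusive (a closed interval); the DC bin never counts; the
Nyquist bin's factor-of-two subtlety is ignored since the band sits well
below Nyquist at any realistic TR. Per subject, raw ALFF is normalized by
the mean over the 90 regions — the region-wise stand-in for "within-brain
mean" in a pipeline that carries no voxel data. Readers of raw scans drop
the conventional first ten volumes; synthetic series are generated
post-discard.

## Association statistics

Each outcome is regressed (OLS) on the score plus age, sex, education,
disease status and four ancestry PCs, complete cases per outcome. The
reported correlation is the signed partial correlation r = t/√(t² + df)
of the score coefficient — by the Frisch–Waugh theorem identical to the
plain correlation of the two covariate-residualized vectors (tested to
1e-10). Bonferroni families: 90 for the region-wise ALFF analysis, 4 for
the emotion scores; thresholds are not counted in the family (the family
sizes reproduce published corrected/uncorrected P pairs exactly), and both
are overridable. Interaction with disease status is the two-sided P of the
score × status product term with main effects and covariates in the model;
it is invariant to affine recoding of status. Group comparisons use the
pooled-variance two-sample t (df = n₁+n₂−2) and the Pearson chi-square
without continuity correction on 2×k tables (df = k−1) — the variants that
reproduce published cohort-description tables from their printed summaries.

## Over-representation

SNPs map to genes by position against user-supplied intervals (BED input
converted to 1-based inclusive; no flank by default, `--flank-kb`
available). Each gene set, intersected with the background (default: all
genes in the interval table), is tested with the one-sided Fisher exact
test on the in-query × in-set table; the EASE variant subtracts one
overlap gene before testing (margins held fixed, i.e. the hypergeometric
tail from k−1), is conservative by construction, and is off by default
since published analyses rarely state which statistic they used. Adjusted
P is Bonferroni over the sets actually tested; reproduction of any
specific annotation database's term lists is out of scope.

## Synthetic-data generator

The generator's defaults are the validated study conditions: 328 subjects
(116 cases, 212 controls), 800 SNPs in 40 LD blocks, 225 timepoints at
TR = 2 s.

*Genotypes.* Within a block, latent Gaussians share an equicorrelation
`block_r2` (default 0.8); the latent value is mapped through its CDF and
thresholded at the Hardy–Weinberg split of a per-SNP allele frequency
drawn uniform in [0.05, 0.5]. Thresholding attenuates the dosage-scale
correlation: at latent 0.8 the measured mean within-block dosage r is
about 0.60. Any generator with controllable block r² would do; this one is
simple, seed-stable and analytically transparent. Blocks are placed so no
250-kb clumping window spans two blocks. Alleles are drawn from
non-ambiguous pairs only, so no synthetic SNP is strand-dropped.

*Summary statistics.* 10% of SNPs are causal for the primary disorder with
true log-odds effects N(0, (4·se)²), where se = effect_sd/√n_discovery
uses the discovery sample sizes of the two source GWAS (46,350 and
65,967); observed effects add N(0, se²) noise and P is the two-sided
z-test. Half of the causal SNPs (overlap_fraction = 0.5) are pleiotropic:
the same standardized effect is planted for the comparison disorder. With
causal_fraction = 0 the P values are uniform.

*Phenotypes.* The true score is the standardized dosage-weighted sum of
planted effects. The planted region's series is white noise plus a 0.04 Hz
sinusoid of amplitude max(0, 1 + planted_beta · score); all other regions
are pure noise. The negative-emotion score is round(12.8 −
emotion_beta · score + N(0, 2)) clipped to [0, 20] (20 items per category,
a stand-in where instruments do not publish item counts); positive and
neutral are unaffected, and the total is the exact sum of the three.
Covariates shift in the directions real schizophrenia cohorts show
(controls older and more educated), exercising covariate confounding.

*Planted effect size.* `planted_beta = 0.095` and `emotion_beta = 0.52`
are calibrated — once, then frozen — so the end-to-end measured partial
correlation of the pipeline PRS with planted-region ALFF and with the
negative-emotion score averages ≈ 0.2 at n = 328, the scale of reported
imaging-genetics effects. At that size the planted region attains the
minimum uncorrected P among 90 regions in roughly 80% of cohorts — the
effect sits deliberately at the detection boundary rather than being an
easy giveaway.

What the generator does *not* emulate: realistic haplotype/coalescent LD,
imputation uncertainty, spatial autocorrelation between regions,
physiological noise spectra, or genotype–covariate confounding beyond the
planted shifts. Passing tests therefore demonstrate that the machinery
recovers effects with the assumed structure, not that any particular real
dataset would yield them.

## Validation problem sizes and numerics

The recovery and familywise-calibration checks run 100 simulated cohorts
each at the default conditions, scoring one representative threshold
(P_T = 0.1) rather than repeating the 103-threshold logistic scan per
cohort — case status is independent of the planted brain effects by
design, so scan-selected thresholds would be arbitrary for recovery, and a
single fixed threshold keeps the simulation honest and fast. Sample-level
relatedness screening (O(n²)) is likewise exercised in its own tests
rather than inside every simulated cohort, which is clean by construction.
Scan power and some calibration examples are tested at reduced replicate
counts and sample sizes with correspondingly verified bounds.

Numerical conventions worth knowing: dosage correlations in clumping are
Pearson on mean-imputed columns; OLS/logistic fits go through statsmodels
(non-convergence and separation in the scan are caught and flagged, never
silently selected); Fisher P values come from scipy and match a
hypergeometric tail sum to 1e-10; band-bin selection uses a 1e-12
tolerance at the closed band endpoints so exact Fourier frequencies are
never dropped by float error. All generator randomness flows from a single
integer seed through independent named streams, making every cohort
byte-reproducible.

## Known limitations

No shrinkage or continuous-weight PRS methods; no reference-panel LD; no
X/Y chromosome handling; no exact HWE test; no mixed models or FDR
alternatives; no fALFF or voxel-level maps; enrichment performs no GO
graph propagation. The pooled-variance t test and uncorrected chi-square
are intentional (they match how cohort-description tables are
conventionally computed) but Welch/Yates variants may be preferable for
new analyses with unequal variances or small cells.
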