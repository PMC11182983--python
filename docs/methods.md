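# Methods

## Problem and scope

A trophectoderm (TE) biopsy taken for preimplantation genetic testing
carries both nuclear and mitochondrial template, so a low-pass sequencing
library quantifies relative mitochondrial abundance for free: the **mtDNA
ratio** is the mitochondrial read count divided by the read count of a
stable autosomal reference interval. This package implements that
quantification and the three analyses built on it — within-blastocyst
concordance of ratios across biopsy sites, a linear model of the ratio on
blastocyst morphokinetics, and logistic models of early-pregnancy
endpoints — together with synthetic-data generators that stand in for
clinical inputs.

## NGS quantification

**Read QC.** A read is retained iff it is mapped, not duplicate-flagged,
not secondary/supplementary, has MAPQ ≥ `min_mapq` (default 20) and
edit-distance fraction NM/aligned-length ≤ `max_mismatch_frac` (default
0.1). Filters are applied in the fixed order unmapped → duplicate →
secondary → low-MAPQ → poor-alignment, and each removed read is attributed
to the first filter it fails, so the per-filter removal counts are
well-defined and conserve the input count. The thresholds are conventional
for read-count applications; both are configuration, not science.
"Poor alignment" is operationalised as the NM fraction because the edit
distance is the only alignment-fidelity field guaranteed in minimal SAM;
an alignment-score variant can be swapped in via configuration.

**Counting.** Retained reads are assigned to the unique fixed-width bin
(default 1 Mb for full-size genomes, 100 kb for the scaled test genome)
containing their leftmost coordinate; mitochondrial-contig reads (contig
named `MT`, `chrM` or `chrMT`) accumulate separately. Coordinates are
0-based half-open throughout; SAM's 1-based positions are converted on
read.

**Normalization-interval screening.** For every run of `window_bins`
(default 10) consecutive bins on one autosome, the per-sample fraction of
total autosomal counts is computed over a reference panel of ≥ 2
presumed-euploid samples; the window's stability score is the coefficient
of variation of that fraction across samples. Candidates are restricted to
the chromosome(s) with the lowest population aneuploidy frequency, and the
minimum-CV window wins (ties broken by genome order, then start
coordinate). Sex chromosomes and the mitochondrial contig are excluded
from both the candidate set and the denominator totals, so sex-chromosome
dosage and mitochondrial load cannot leak into the stability measure. The
shipped per-chromosome aneuploidy-frequency table is a synthetic stand-in
with chromosome 6 minimal — matching that chromosome's reputation as the
least aneuploid somatic chromosome — and should be replaced with a
literature-derived table for real analyses.

**Ratio.** `value = scale × mt_reads / interval_reads`. The ratio is
invariant to uniform rescaling of counts (hence to sequencing depth in
expectation). A zero denominator yields an undefined flag, never an
exception; a configurable `min_mt_reads` threshold flags samples whose
mitochondrial evidence is too thin to count as a valid detection, because
near-zero ratios (e.g. spent culture media) are reportable but not
"detections". `scale` defaults to 1; published pipelines apply an
unspecified internal multiplier, so the absolute scale of printed ratios
is not recoverable and is exposed as a single knob.

## qPCR quantification

Two mitochondrial genes are paired with two single-copy nuclear genes
(ND1/BECN1, ND6/NEB). Per pair, ΔCt = mean Ct(nuclear) − mean Ct(mito);
the ratio is the mean of 2^ΔCt over the two pairs. The ΔCt direction is
fixed so abundant mtDNA (lower mitochondrial Ct) gives a ratio above 1,
which is the assay's purpose; the sign is one configuration constant.
Replicates are averaged per gene *before* exponentiation because wells are
not paired across genes by the plate layout. Ct values at the cycle
ceiling (default 40) are treated as non-detections by default. The ratio
is invariant under adding a constant to all Cts and strictly monotone in
each gene's Ct, both enforced by tests.

## Concordance analyses

Each blastocyst contributes up to three sites (close TE, distant TE, ICM).
Agreement is summarised per site pair by Spearman's ρ on
pairwise-complete data: a biopsy whose amplification failed is deleted
from exactly the pairs it belongs to, never imputed, and the matched-pair
count is reported next to every ρ. Spearman's ρ is the Pearson correlation
of mid-ranks; its two-sided p-value is exact (full permutation
enumeration) for tie-free samples of n ≤ 9 and t-distributed with n − 2
degrees of freedom otherwise. The biopsy-vs-media comparison uses the
Mann-Whitney U test with mid-ranks; the two-sided p-value is exact via the
classic null-distribution recurrence when the smaller group has ≤ 10
observations and no ties (forceable at larger n), otherwise a normal
approximation with tie and continuity corrections. Exact small-sample
p-values are disabled in the presence of ties, where the permutation
distribution is no longer distribution-free.

## Regression models

**Design.** An intercept is always included. Binary factors are coded 0/1
(male = 1, donor oocyte = 1), Gardner grades A/B/C as 3/2/1, day of
expanded-blastocyst formation and expansion score as integers; interaction
columns are elementwise products of coded main effects. All codings are
configuration with these defaults, and effects are per unit of the coding.
Missing data are complete-case per model with the used n reported.
Rank-deficient designs raise an error naming the collinear columns.

**Linear stage.** OLS with SEs from the unbiased residual variance and
t-based 95% CIs (df = n − p). An exactly-fitting response is flagged
degenerate with zero SEs. The fit is checked against the normal-equation
closed form and statsmodels to 1e-10 relative.

**Logistic stage.** Maximum likelihood via iteratively reweighted least
squares (Newton-Raphson) with step-halving, which makes the deviance
monotone non-increasing — a tested invariant. Convergence requires a
maximum absolute coefficient change below 1e-8 within 100 iterations.
Wald SEs come from the inverse observed information; odds ratios and
their 95% CIs are exponentiated Wald, matching the symmetric presentation
convention of clinical tables. Complete or quasi-complete separation
(coefficients escaping |β| > 30 while still moving) is flagged
non-converged and its estimates marked untrustworthy. Each of the four
endpoints (HCG, gestational sac, fetal heartbeat, ongoing pregnancy at 14
weeks) gets the same covariate set; a failed endpoint records its error
without aborting the others. No multiple-testing adjustment is applied
across endpoints by default (a Bonferroni option exists), matching common
reporting practice for co-primary clinical endpoints.

**Interactions.** Uncentred products such as day-of-formation × tEB are
near-collinear with their main effects and would inflate the main-effect
SEs beyond use; since published tables report main effects and
interactions side by side without stating the model structure, this
package fits the main-effects model as primary and assesses the
configured interaction pairs (TE grade × gender for HCG; maternal age ×
TE grade for gestational sac; the three pairwise interactions of day,
gender and tEB in the linear stage) in a separate augmented fit. All
qualitative conclusions are read from the primary fits.

**Feature screening.** An all-pairs Spearman matrix over the nine timing
features and the ratio; a feature passes when |ρ| with the ratio reaches a
configurable threshold (default 0.1 — weak correlations in the 0.1–0.2
range are the expected scale for single-biopsy ratios) or when flagged
timeline-relevant (tEB, the biopsy time point, by default). Subset filters
(day-5, expansion-5, male-only) are applied before screening when
configured.

## Synthetic-data generators

All generators are deterministic given their seed; the pipeline spawns
per-stage substreams from one global seed so stages can be re-run in
isolation.

**Reads.** A biopsy of `n_cells` cells contributes nuclear template ∝ copy
number × bin length and mitochondrial template ∝ `mt_copies_per_cell` ×
16,569 bp. Per-bin counts are Poisson; given the per-bin nuclear coverage
the expected mitochondrial count is `coverage × mt_copies × mt_length /
(2 × bin_width)` — the cell number cancels from the ratio, as in the
assay. With ~1,000 mtDNA copies per blastocyst cell, 1 Mb bins and a
10-bin interval this lands ratios in the 0.5–3 range that the assay
reports. Four contamination classes (duplicate, unmapped, low-MAPQ, NM
fraction 0.3) are injected as configured fractions of the stream,
positioned independently of class, which is exactly why QC filtering
leaves the ratio unbiased. Default contamination (5% duplicates, 3%
unmapped, 5% low-MAPQ, 2% poor alignment) is typical of low-pass WGA
libraries. Reads carry positions, flags, MAPQ and NM only — base-level
sequence, error profiles and amplification bias are out of scope. The
default genome scales GRCh38 contigs by 1/100 (full-length MT) so tests
run in seconds; full-size naming is one constructor argument.

**Multi-biopsy sets.** Each embryo has a latent log-ratio with
between-embryo sd 0.50; sites observe it with within-embryo sd 0.15, ICM
biopsies get a +0.26 log shift (ICM runs higher than TE) and extra
ICM-only dispersion 0.35 (the ICM lineage tracks the embryo latent less
tightly, which is what puts TE–TE concordance above TE–ICM). Ratios are
exponentiated, keeping them positive while preserving ranks, so Spearman
analyses see exactly the Gaussian latent structure, for which the pairwise
rank correlation follows σ²_b/(σ²_b + σ²_w). Published summaries do not
identify these variance components; the values were fixed once for clear
test signal and plausible concordance (TE–TE ≈ 0.85, TE–ICM ≈ 0.6–0.8)
and are not tuned thereafter.

**Time-lapse cohorts.** Timing vectors (tPNf…tEB, hours post
insemination) are multivariate Gaussian with means 23–111 h, sds 3–7 h and
an AR(1)-style correlation 0.6^|i−j|; draws violating the developmental
order tPNf < t2 < … < tEB are rejected and resampled (the resample count
is logged), which preserves the target correlation approximately while
honouring biology. Day of expanded-blastocyst formation is derived from
tEB by 24-hour windows (day 5 = 96–120 h). The ratio is generated as
intercept + 2.58·day + 0.98·male − 0.125·tEB + N(0, 2.0²), with the
intercept centred to give a mean ratio of 2.7; the three coefficients are
the reported point estimates of the corresponding clinical model, the
residual sd is not published and was fixed once at a value consistent
with the printed ratio range.

**Transfer cohorts.** Covariates come from realistic marginals (donor
fraction 0.15, maternal age N(36, 4.5²) clipped to 21–47, EM thickness
N(10.5, 1.8²), mostly day-5/day-6 blastocysts, Gardner grades mostly B,
mtDNA ratio N(2.7, 1.8²) left-censored at 0.05 — a mild-skew marginal on
the assay's reported scale; a heavier-tailed lognormal alternative makes
Wald intervals visibly anticonservative at n = 2,000 and was rejected for
the default). The four endpoints are drawn as a nested clinical
progression: HCG first, each later endpoint only among successes at the
previous one, with per-stage conditional odds ratios applied to centred
covariates on the conditional logit. With all odds ratios at 1 the
marginal prevalences equal `baseline_rates` exactly (default 0.66 / 0.57
/ 0.53 / 0.50, typical for euploid single-embryo transfer). Default
odds-ratio columns are the reported per-endpoint estimates, interpreted
as conditional per-stage effects.

**What the generators do not emulate.** Real libraries have GC- and
mappability-driven bin biases, WGA dropout structure and batch effects;
real cohorts have patient-level clustering (several embryos per couple),
informative missingness and measurement error in morphokinetic
annotation. Passing tests therefore demonstrate correctness of the
computational chain under its stated model, not robustness to those
real-data pathologies.

## Numerical choices and degenerate inputs

- Spearman exact p-values enumerate all n! permutations (cached per n,
  feasible to n = 9); rho of constant vectors is undefined and flagged.
- The U null distribution uses the two-group count recurrence with exact
  integer arithmetic; "exact" with ties raises rather than silently
  approximating. All values tied across both groups gives p = 1, flagged
  degenerate.
- IRLS floors the working weights at 1e-10 and clips fitted probabilities
  away from 0/1 when evaluating the deviance.
- Screening treats an all-zero window (CV undefined) as infinitely
  unstable; samples with zero autosomal totals are rejected up front.
- CV uses the sample standard deviation (ddof = 1), hence the ≥ 2 sample
  requirement.

## Problem sizes

Simulated studies default to the clinical design sizes: 29 embryos × 3
sites, 14 biopsy/media pairs, 307 time-lapse embryos, 2,283 transfer
cycles. Read-level checks use the 1/100-scale genome at 100 kb bins; ratio
recovery is exercised at ~10⁶ reads per library over 20 seeds and four
true ratios, calibration at 150–200 replicates of n = 2,000, and the
end-to-end sign pattern at 50 seeds. These sizes give each check clear
statistical resolution while keeping the full suite fast.

## Known limitations

- Flat models only: no mixed effects for embryos clustered within
  patients, no intraclass-correlation analysis of the multi-biopsy design.
- No aneuploidy calling, GC correction, heteroplasmy/variant analysis, or
  amplification-efficiency calibration for qPCR.
- The absolute scale of the NGS ratio is conventional (one multiplier);
  only relative comparisons are meaningful across pipelines.
- Exact rank-test p-values require tie-free data; heavily tied inputs fall
  back to corrected approximations.
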