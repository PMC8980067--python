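# Methods

## The analysis model

The pipeline quantifies genetic and environmental contributions to
structural brain measures in a case cohort using molecular scores in place
of (and alongside) clinical proxies.

**Polygenic risk score.** PRS_i = Σ_j w_j d_ij, where d_ij is subject i's
dosage of the GWAS effect allele at SNP j and w_j the external log-odds
weight. SNPs enter after variant QC, LD clumping (greedy, most significant
SNP kept per LD neighbourhood), and allele alignment; a GWAS p-value
threshold p_T selects the scored set. Because the informative p_T is not
known a priori, the package scans p_T ∈ {0.01, 0.02, …, 0.50}, fits
`family_history ~ PRS(p_T)` by logistic regression at each, and keeps the
p_T with the smallest two-sided Wald p on the PRS coefficient (ties go to
the smaller p_T; non-convergent or separated fits are recorded and excluded
from selection). The scan statistic is a design choice — any monotone
measure of group separation would do — and the full scan table is retained
in the output for inspection.

**Methylation profile score.** With no well-powered external epigenome-wide
reference to supply weights, the probe panel and weights are estimated
internally: L1-penalised logistic regression of case status on probe
M-values (M = log2 β/(1−β)) over a descending λ path anchored at the
data-derived λ_max, with λ chosen by 5-fold stratified cross-validated
binomial deviance and the one-standard-error rule (the sparsest model
within one SE of the minimum — the conventional guard against overfitting
the CV curve). MPS_i = Σ_k w_k x_ik over the selected probes, no intercept;
weights are reported on the M-value scale. Probes reach the fit only after
QC (detection failures in >1% of samples; bead count <3 in ≥5% of samples;
SNP at the interrogation/extension site) and BMIQ normalisation.

**BMIQ.** Illumina-style arrays mix two probe chemistries; type II betas
are compressed toward 0.5. Per sample, a three-state beta mixture
(unmethylated / hemi-methylated / methylated) is fitted by EM separately to
type I and type II probes; type II probes classified into an outer state
are mapped through that state's fitted CDF into the matching type I state
quantile, and hemi-methylated probes are linearly dilated so their range
endpoints land where the outer-state maps would send them. Type I probes
are never altered. The EM uses weighted method-of-moments updates for the
beta parameters (fast and stable near the boundaries), tolerance 1e-5 on
the relative log-likelihood, 200 iterations maximum; a sample whose EM
fails to converge is left unadjusted and counted in a warning.

**Association stage.** Analysis is restricted to the case group (the
comparison group exists to define the MPS) and to subjects with brain
measures. Measures are z-scored (n−1 denominator). For each factor
(PRS, MPS, family history, trauma scale) and measure, OLS of
`measure ~ factor + age + age² + gender + race + smoking`, complete-case.
Effect size is the partial R² = 1 − SSR_full/SSR_cov, clipped to [0, 1]
(the clip is logged; for nested OLS on a common sample it cannot trigger).
Interaction models add the factor pair and its product:
`measure ~ G + E + G:E + covariates`, with partial R² for the three-term
block. Clinical vs molecular pairs are compared by resampling subjects with
replacement (default 2000 draws), refitting both interaction models, and
recording Δ = partialR²_molecular − partialR²_clinical; the one-sided
bootstrap p is P(Δ < 0) with exact ties counted half (the mid-p convention;
it only matters in degenerate self-comparisons). A resample that loses a
rare categorical level entirely simply drops the constant dummy column
(it is absorbed by the intercept); genuinely rank-deficient resamples are
redrawn and counted.

**Multiplicity.** Storey q-values: π₀ estimated from #{p>λ}/(m(1−λ)) on
λ = 0.05…0.95 (step 0.05), extrapolated to λ→1 with a cubic smoothing
spline and clipped into (0, 1]; q is the usual step-up minimum of
π₀·m·p/rank. With fewer than 10 p-values π₀ is fixed at 1, which reduces
exactly to Benjamini–Hochberg (and the π₀=1 special case is tested against
an independent BH implementation). By default q-values are computed per
factor across measures, mirroring how per-factor FDR is usually reported;
a single pooled family across all factor×measure tests is available
(`qvalue_family="pooled"`), and is what the calibration tests use — see
*Known limitations*.

## Key parameters

| parameter | default | notes |
|---|---|---|
| variant QC | call rate ≥0.95, MAF ≥0.01, HWE exact p ≥1e-6, per-call quality ≥0.2 | standard array QC; quality filter only when a score matrix is supplied |
| clumping | r² ≥ 0.1 within 250 kb | PRS-convention defaults; configurable |
| IBD pruning | r² ≥ 0.2, window 50, step 5 | approximate marker independence for π̂ |
| p_T grid | 0.01–0.50, step 0.01 | threshold scan domain |
| probe QC | detection p ≥0.01 in >1% of samples; beads <3 in ≥5%; SNP overlap | the detection rule's failure fraction is configurable |
| LASSO | 25 λ values to λ_max·1e-3, 5-fold stratified CV, one-SE rule | liblinear with pinned random_state for reproducibility |
| M-values | base 2 | field convention |
| n_boot | 2000 | bootstrap comparison (0 skips the stage) |
| FDR level | 0.1 | discovery threshold on q |

Missing dosages in the PRS are imputed as 2× the effect-allele frequency
(mean imputation). Strand-ambiguous SNPs (A/T, C/G) are dropped during
alignment — without reference allele frequencies they cannot be oriented
safely. Betas are clamped into [1e-6, 1−1e-6] on load so the logit is
always defined.

## The synthetic cohort generator

The generator's defaults mirror the target study design: 119 subjects, 55
in the case-spectrum group, 8 of them without brain measures (subjects who
were never scanned), 44 measures, a 0–11 trauma count missing for ~3% of
subjects. Scales that would be genome-wide in real data are desk-sized
(600 SNPs, 800 probes) — enough to exercise every code path.

- **Genotypes**: per block of 5 adjacent SNPs, a shared latent Gaussian
  with pairwise correlation ld_rho (default 0.3) is thresholded at the
  Hardy–Weinberg quantiles of a MAF drawn from (0.05, 0.5); this controls
  MAF and LD independently and yields HWE in expectation. Missingness is
  MCAR at a configurable rate (default 0).
- **GWAS weights**: 25 causal SNPs (one per LD block) with log-odds weights
  ~ ±|N(0.2, 0.06)| and p ∈ [1e-8, 1e-4]; null SNPs get N(0, 0.02) weights
  and uniform p.
- **Methylation**: probe baselines from a three-state mixture; a continuous
  per-subject exposure latent (case mean 1, comparison mean 0, within-group
  SD 0.5) moves each signal probe by delta × direction × exposure, so the
  expected case-vs-comparison beta difference equals the configured delta
  (default 0.1) while the exposure still varies within groups — without
  within-group variation the case-only association stage would see nothing
  but probe noise. 84% of probes are labelled type II and compressed toward
  0.5 by a factor 0.8 to exercise BMIQ.
- **Clinical proxies**: family history is Bernoulli with log-odds
  increasing in the true genetic score (and higher in the case group); the
  trauma count is tied to the exposure latent through a Gaussian copula
  (correlation 0.3). These joint distributions are modelling assumptions,
  not estimates from data.
- **Brain measures**: y = β_G·G + β_E·E + β_G×E·G·E + covariate terms
  (standardised age, age², gender, race, smoking; effects 0.2/0.1/0.2/0.2/0.2)
  + N(0, 1), with G and E standardised true scores. Defaults
  β_G = 0.25, β_E = 0.45, β_G×E = 0.40 put partial R² in the 0.1–0.35 range
  at the 47-subject analysis size.

What the generator does **not** emulate: genome-wide scale and realistic LD
decay, array intensity artefacts (idat-level effects, batch/plate
structure), cell-type composition, population stratification within a
cohort (two-population fixtures are built in tests by concatenating
generators), pedigree structure beyond Mendelian offspring construction,
and any real coupling between methylation and genotype (the meQTL scan's
planted effects are made ad hoc in tests). Passing tests therefore
demonstrate correctness and calibration of the statistics, not robustness
to those real-data complications.

## Numerical choices

- OLS uses a QR decomposition with an explicit rank check that names the
  collinear columns; p-values from the t distribution on n−k df. The
  statsmodels fits serve as independent oracles in the tests, never as the
  implementation.
- The HWE exact test works in log-space with the support enumerated by het
  count parity; the "probability ≤ observed" rule uses a 1+1e-12 relative
  slack so equal-probability tables are included regardless of rounding
  direction. Verified against an exact-integer enumeration for every table
  with n ≤ 50.
- Clumping and the threshold scan break ties deterministically
  (chromosome, then position; smaller p_T).
- IBD: method-of-moments with the textbook expected-IBS-given-IBD terms,
  per-pair estimates clipped to [0,1] and renormalised; pairs with <50
  informative markers are flagged rather than dropped.
- The bootstrap seed stream derives from the analysis seed plus the measure
  index, so per-measure results are independent of the measure order in
  which they are computed — and byte-reproducible.

## Known limitations

- **Storey π₀ at small m.** With 44 tests per family the smoothed π₀
  estimator is strongly anti-conservative under the global null
  (mean π̂₀ ≈ 0.77; the per-family probability of any q < 0.1 is ≈ 0.19
  instead of the nominal 0.10). This is a property of the q-value method at
  small test counts, not of this implementation — BH (π₀ = 1) attains the
  nominal level exactly, and the estimator converges toward it as the
  family grows (≈ 0.12 at m = 176). The per-factor family remains the
  default because that is how per-factor FDR is conventionally reported,
  but calibration-sensitive work at a few dozen tests should use
  `qvalue_family="pooled"` or π₀ = 1. The end-to-end FDR calibration test
  uses the pooled family for this reason.
- The LASSO deliberately returns sparse panels; when several informative
  probes are driven by one latent exposure it keeps a subset and the panel
  should not be read as exhaustive.
- The threshold-scan p-value is used for selection only; it is not a valid
  test of the PRS–family-history association (winner's curse).
- Monte-Carlo test sizes (500 FDR replicates at 67 subjects × 44 measures,
  1000 type-I replicates at n = 300, 50 LASSO seeds at 200 × 500) were
  chosen to make the statistical assertions sharp at desk scale; they are
  package choices, and larger runs only tighten the same bands.
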