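# Methods

`methylgxe` re-implements, as a tested pipeline over synthetic data, an
epigenome-wide gene-environment analysis of 450K-style DNA methylation: the
question is whether prenatal pesticide exposure leaves a methylation
signature specifically in children carrying the PON1 192R allele, and
whether specific methylation marks lie on the causal path from exposure to
cardio-metabolic outcomes (leptin, body-fat measures, BMI-Z trajectories).

## Study design and data model

Samples occupy a 2x2 design: exposure (prenatal pesticide exposure, yes/no)
by PON1-192 carrier status (QQ vs QR/RR pooled). Default cell sizes are
11/13/12/12 (unexposed-QQ / exposed-QQ / unexposed-carrier /
exposed-carrier), n = 48. Methylation is carried as beta values
(methylated fraction, in (0,1)); all linear modelling happens on M-values,
M = log2(beta/(1-beta)), with betas clamped to [1e-6, 1-1e-6] before the
logit. Group means for interpretation and for the extreme-group filter use
the beta scale (an interpretability choice: a 0.15 methylation-fraction
difference means the same thing at every baseline level).

## Synthetic data generator

The generator's defaults define the study conditions; every downstream
stage is validated against its planted ground truth.

* **Probe baselines.** Per-probe means are drawn from a 3-component mixture
  (Beta(1.5,8), Beta(8,1.5), Beta(5,5) with weights 0.35/0.35/0.30),
  reproducing the bimodal, boundary-heavy 450K histogram.
* **Noise.** Sample-level betas are Beta(m*phi, (1-m)*phi) with
  phi = 100 (beta-scale SD ~0.05 at m = 0.5). The per-group variance of
  real probes is not published; phi is a calibration choice made once, at
  which the exposure-in-carriers test is correctly calibrated at the 1e-3
  threshold (verified by the null-calibration test).
* **Cell mixtures.** Six reference methylomes (granulocyte, CD4+ T, CD8+ T,
  B, monocyte, NK) share the probe baseline except at ~600 disjoint marker
  probes per type shifted by ~0.38 (so each type carries >= 500 probes with
  a between-type difference >= 0.3, scaled down automatically on small
  simulations). True proportions are Dirichlet(6,1,1,1,1,1) — a
  granulocyte-dominant composition typical of child whole blood — and each
  sample's probe means are the convex combination of the references.
* **Planted effects.** Interaction DMPs (default 50) shift the
  exposed-carrier cell by +-0.15 beta; planted DMRs (default 8 runs of 6
  adjacent probes) shift coherently; planted features are placed on blocks
  re-levelled to a shared mid-range baseline (a coherent region), and a
  configuration whose shift would push any mean outside (0,1) is rejected.
* **Genomic layout.** One synthetic chromosome per 10,000 probes; 1-based
  positions spaced probe_spacing_bp = 500 +-20% jitter. A small fraction of
  probes is flagged SNP-adjacent (2%), non-CpG (1%), sex-chromosomal (1%)
  or detection-poor (0.1%) to exercise the filters; planted features avoid
  all of these.
* **PON1 promoter cluster.** Nine adjacent probes assigned to the PON1
  gene; a biallelic promoter SNP (T-allele frequency 0.5, Hardy-Weinberg)
  shifts them additively by 0.05 beta per T allele. Paraoxonase activity is
  generated as 28 + 30*carrier - 10*(cluster mean M, centred) + N(0,4):
  genotype dominates, promoter methylation has a smaller but clearly
  negative effect.
* **Mediation structure.** Three paths (mark -> ln-leptin, delta BMI Z,
  body fat) with M-scale path coefficients a = +-1.5, outcome-scale b and
  direct effects c'. Marks are the centre probes of the first planted DMRs
  (so they qualify for the DMP-and-DMR screen); the a-shift is applied in
  the exposed-carrier cell, which makes `mark = a*exposure + noise` hold
  exactly within the carrier subset the screen uses. Marks additionally
  receive inter-individual M-scale variability (SD 0.6): without
  biological variance beyond the technical beta noise, the mark is nearly
  collinear with exposure at n = 24 and the mark -> outcome path is
  unidentifiable. BMI Z carries no planted path.
* **Batch.** Round-robin assignment (a confounded mode exists for testing
  the diagnostics); when batch_shift > 0, an M-scale offset with per-probe
  loading U(0.5, 1.5) is added. Sex is assigned in blocks within each
  design cell (female counts 5/7/6/6) so that sex remains orthogonal to
  the alternating batch factor.
* **Determinism.** One master seed; all sub-streams are spawned from it in
  a fixed order, so equal configurations produce byte-identical output.

What the generator does **not** emulate: Infinium I/II chemistry
differences, realistic LD around the promoter SNP, spatially varying CpG
density, annotation-correlated effect placement (planted DMPs land
uniformly, so annotation enrichment is null by construction), or
confounding between cell composition and exposure. Passing tests therefore
demonstrate correctness of the statistical machinery under the stated
model, not robustness to every artefact of real arrays.

## Preprocessing

Pre-normalization filters (in order, one reason per probe, priority
SNP > greedycut > missing): SNP within 3 bp of the CpG; an iterative
greedy detection-p prune (repeatedly drop the probe *or* sample with the
highest fraction of detection p > 0.01, ties probe-before-sample then
lexical); probes missing in any sample. Post-normalization: non-CpG (ch/rs)
probes and sex chromosomes, with the alias map {X, chrX, 23} / {Y, chrY,
24}, case-insensitive. Within-array normalization is a pass-through by
default (a rank-based quantile option exists); beta-mixture quantile
machinery is published elsewhere and the bespoke content of this pipeline
lies downstream.

Batch diagnostics: PCA of centred M-values; for each of the first eight
PCs and each covariate, Kruskal-Wallis (> 2 levels) or two-sided Wilcoxon
rank-sum (2 levels). Batch adjustment is location-only on the M scale:
per probe, the batch-level mean of residuals (after projecting out the
protected covariates exposure, carrier, sex) is subtracted. Plain
subtraction would perturb batch-effect-free data by the sampling noise of
a 24-sample mean (up to ~0.3 M on noisy probes), so the estimates are
shrunk: if the across-probe mean squared deviation exceeds twice its
sampling variance the means are equalized exactly (clear batch effect),
otherwise a moment-based factor tau2/(tau2 + s2/n_b) shrinks them toward
zero. This evidence gating is the same reason the standard empirical-Bayes
corrector shrinks; the protected covariates default is a choice (the
original workflow does not state what ComBat protected).

## Cell-type deconvolution

Signature selection is two-pass: the 100,000 most variable probes in the
mixture data (variance of beta), then the top 500 by between-type
dispersion of the reference betas. The reference carries one methylome per
type, so a literal one-way F statistic (which needs within-type replicates)
is not computable; the between-type variance is its numerator and induces
the same ranking. "Top 500" is read as one overall ranked list, not 500
per type. Both counts cap automatically at the probe count on small data.

Proportions solve min ||beta_s - R w||^2, w >= 0, sum(w) = 1 per sample:
non-negative least squares with a sum-to-one row weighted 1e3, then
renormalization — numerically equivalent to the constrained projection of
reference-based deconvolution. A rank-deficient reference on the signature
probes raises an error naming the collinear types. Estimated proportions
are reported and tested against exposure/genotype (one-way ANOVA) and
against outcomes (simple regression), but are never entered as model
covariates (n = 48 is too small, and composition is independent of the
design by construction).

## Single-CpG analysis (DMPs)

Two OLS models per probe on M-values, sex-adjusted, fitted by shared-design
matrix algebra across all probes at once:

* Model A: `M ~ exposure + carrier + exposure:carrier + sex`. Criteria:
  interaction p <= 0.1 AND exposure-effect-in-carriers p <= 0.001, where
  the carrier-stratum exposure effect is the linear contrast
  (beta_exposure + beta_interaction) tested with the full-model residual
  variance (t, df = n-5). A stratified alternative (`M ~ exposure + sex`
  on carriers only) is available behind a flag; the two agree within ~10%
  relative p on variance-homogeneous probes but differ in residual df.
* Model B: `M ~ exposure + carrier + sex`. Criteria: exposure p <= 0.001
  AND genotype p <= 0.1.

Both require the extreme-group filter: the exposed-carrier beta-scale mean
strictly the maximum (hyper) or minimum (hypo) of the four cells; exact
ties fail. Raw-p thresholds, no multiplicity correction at this stage —
the region-level analysis supplies the confirmation. Zero-variance probes
are flagged `invariant_probe` and excluded.

## Region analysis (DMRs)

For each contrast of exposed carriers against one other cell: pooled-
variance two-sample t per probe on M-values; squared t smoothed along each
chromosome with a Gaussian kernel (bandwidth sigma = lambda/C, truncated
at lambda; defaults lambda = 1000 bp, C = 2); the smoothed score referred
to a scaled chi-square with Satterthwaite moment matching (each null t^2
is F(1, df); the weighted mean's first two moments fix the scale g and
df k, p = chi2.sf(score/g, k)); BH adjustment genome-wide; probes with
P_adj < 0.05 grouped when consecutive significant probes are <= lambda
apart; regions need >= 2 CpGs, take P_adj = min over members, and must
pass the extreme-group filter on region-mean betas. The three contrasts
are scanned separately and the union reported with per-contrast
provenance. This is a deliberately simplified re-implementation of the
kernel-smoothing region-caller family (no moderated variance, no exact
Satterthwaite of the original); an isolated probe's score degenerates to
its own t^2. Regions export to BED (0-based half-open,
score = -10 log10 P_adj capped at 1000).

## Integration and enrichment

A DMP overlaps a DMR when its position lies in the closed interval
[start, end] on the same chromosome; the overlap percentage is reported
rounded to one decimal. The high-confidence gene list is the unique
non-empty nearest-gene symbols of overlapping DMPs (multi-gene annotations
split on ';').

All enrichment runs through one engine: two-sided Fisher exact test (the
sum-of-tables-with-probability-<=-observed convention), computed on the
disjoint 2x2 (hits in/out of category vs the rest of the background); the
reported c/d columns are the full-background counts, the convention of
"compared with all probes" plots. The background is the analyzed
(post-filter) probe set. Genomic-annotation categories use no multiplicity
adjustment (the p < 0.05 convention of those figures); TFBS tests use
Bonferroni across the sets tested; gene-set enrichment ranks by
-log10 p against a stated gene universe; disease mapping keeps
associations with score strictly > 0.1.

## Mediation

Baron-Kenny four-model screen of exposure -> mark (M-value) -> outcome,
restricted to marks in the DMP-and-DMR overlap and run on R-allele
carriers by default (the gene-environment framing; an all-samples mode
exists). Models: (1) outcome ~ exposure, (2) mark ~ exposure,
(3) outcome ~ mark, (4) outcome ~ exposure + mark; sex-adjusted for
ln-leptin and body fat, not for the BMI-Z-based outcomes (already
sex-standardized). Leptin is ln-transformed once, upstream, with a
non-positivity guard. Partial mediation: models 1-3 significant (p < 0.05),
mark significant in model 4, and |direct effect| < |total effect|; full
mediation additionally requires the model-4 exposure term non-significant
("drops to zero" operationalized as a test, since none is stated).

The ACME (indirect effect) is the a*b product: a from model 2, b from the
model-4 conditional mark coefficient — the point estimate equals that
product exactly. Significance comes from a nonparametric case-resampling
bootstrap (percentile 95% CI; two-sided p = 2*min(frac <= 0, frac >= 0)
floored at 2/n_boot; degenerate resamples with single-level exposure are
redrawn, capped retries). This replaces the quasi-Bayesian algorithm of
the R mediation package as a documented stand-in; under the a = b = 0 null
the interval is mildly conservative (~99% coverage at n = 24, inside the
binomial tolerance of the coverage test), a known property of
product-of-coefficients bootstraps at small n.

## Targeted models

Promoter-cluster ANOVA treats the -108 genotype categorically (CC/CT/TT);
the trend column is sign(mean_TT - mean_CC); with two groups F = t^2.
The activity model is OLS `activity ~ M + 192-genotype + sex` on complete
cases (>= 10), with a collinearity flag at |r| > 0.99. Pyrosequencing
validation divides percentages by 100 and reports per-probe Pearson r with
two-sided p; zero-variance probes are flagged, not tested.

## Problem sizes and numerical choices

Validation experiments run at 20,000 probes x 48 samples — large enough
for stable tail calibration (binomial SD of the 1e-3 rate is ~2.2e-4)
while keeping the full suite in minutes; 20 seeds for region-level
recovery and null counts; 50 seeds for mediation classification; 200
replicates x 200 bootstrap draws for null coverage. Fisher-oracle
equivalence is checked exhaustively for all 2x2 tables with n <= 40 plus a
seeded sweep up to n = 200 (the exhaustive space beyond that is ~10^7
tables for no additional information). Logit clamp 1e-6; NNLS sum-weight
1e3; exact ties fail the extreme-group filter; BH via the standard
step-up implementation.

## Known limitations

Planted-effect recovery rates are upper bounds for real data: planted
effects are homoscedastic shifts at mid-range baselines. The location-only
batch adjustment cannot remove scale (variance) batch effects. The DMR
caller inherits the smoothing leakage of its family: a strong single CpG
promotes its immediate neighbours, so called regions typically extend one
probe beyond a planted boundary. The mediation screen tests one mark at a
time; correlated marks within one region yield correlated (not
independent) discoveries.
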