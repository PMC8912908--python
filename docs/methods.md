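# Methods

This note documents the models, numerical choices and synthetic-data
assumptions behind cardiosplice, and what the passing test battery does and
does not establish about real data.

## Preprocessing

Genes are "expressed" at TPM ≥ 1 in at least ⌈0.1·n⌉ samples (inclusive
threshold); isoforms at usage strictly > 0.10 in at least ⌈0.1·n⌉ samples,
and a gene must retain at least two expressed isoforms to enter isoform
analyses. Usage with a zero gene-level denominator is set to 0 and flagged,
keeping matrices dense with "not expressed" semantics. Gene filtering runs
before isoform filtering.

Normalization is a per-feature rank inverse-normal transform,
Φ⁻¹((rank − 0.5)/n) with average ranks for ties; it realizes the stated
goal of the usual quantile-normalization composite (per-feature mean 0,
spread determined only by n) while being rank-invariant and exactly
reproducible. Constant features map to zero and are flagged.

The read-length blacklist runs a paired t-test per feature between
full-length and trimmed quantifications (Bonferroni < 0.05); a gene is
blacklisted if it or any of its isoforms is significant, which requires the
annotation's isoform→gene map — hence the optional annotation argument.

## Differential expression and usage

Pairwise tissue contrasts are per-feature OLS on the normalized values with
four technical covariates: sex, z-scored library size, fraction of
autosomal reads, fraction of mitochondrial reads. p-values come from the
single-coefficient t-test (identical to the one-coefficient F-test);
Bonferroni is applied per contrast over all tested features. Specificity
adds |log₂ ratio| > 2 (strict) on the original scale with pseudocounts of
1 TPM for genes and 0.01 usage for isoforms — chosen so ">4-fold" keeps its
meaning for well-expressed features while zero means stay finite.

### Ridge regression with cell-type proportions

Six mixture proportions sum to one and are collinear with the intercept, so
contrasts adjusting for composition use ridge. All predictors are
standardized and Y centered; the penalty is chosen per feature by
generalized cross-validation on a 25-point log grid 10⁻⁴..10⁴ (boundary
selections warn). Standard errors use the linear-smoother sandwich
σ̂²(XᵀX+λI)⁻¹XᵀX(XᵀX+λI)⁻¹ with σ̂² = RSS/(n − tr H − 1); the −1 counts the
implicit intercept so that λ = 0 reproduces OLS (β̂, SE) exactly, which is
tested to 1e-8. p-values are two-sided normal. This is a deliberate
approximation to debiased-projection ridge inference; effects are reported
on the standardized-predictor scale, so they are not numerically
commensurable with the OLS effects.

### Gene-set procedures

Stage enrichment is a Welch t-test of in-set vs out-of-set effect sizes per
gene set, BH-corrected. Genes with specific isoforms vs genes with no DE
isoform are compared per set with a 2×2 Fisher test (genes with DE but not
specific isoforms are excluded from both groups). All exact 2×2 tests in
the package report the conditional-MLE odds ratio of the noncentral
hypergeometric model; a hand-written enumeration oracle checks both the OR
and the exact p on every table with total ≤ 12.

## Deconvolution

Markers: one-vs-rest Wilcoxon on log-normalized counts (counts per 10,000,
log1p), requiring a positive shift, detection in ≥ 20% of in-type cells,
log₂ fold change ≥ 0.1 and Bonferroni p < 0.1. The signature matrix is the
per-type mean of depth-normalized (un-logged) expression over markers.
Mixtures are estimated per sample after z-scoring the signature (by its
overall mean/sd) and the mixture vector (by its own): ν-SVR with a linear
kernel over ν ∈ {0.25, 0.5, 0.75}, keeping the lowest-RMSE fit, truncating
negative coefficients and renormalizing to the simplex; NNLS (with a signed
intercept via a ±1 column pair) is the deterministic fallback. No quantile
mapping is applied anywhere. ν-SVR is the default because its
ε-insensitive loss is robust to marker genes perturbed by stage effects —
on the default synthetic cohort least squares degrades visibly on the
fetal-like samples while ν-SVR does not.

## Exon sequence analyses

Stage-specific exons come from genes with specific isoforms on *both*
sides of a contrast: side-1 exons are those present in tissue-1-specific
isoforms and absent from tissue-2-specific isoforms, and symmetrically.
Coordinates are 0-based half-open throughout; overlap tests (domains,
peaks) are strand-blind, sequence windows are always reported 5′→3′ on the
transcribed strand. Acceptor windows are the 100 nt upstream of the exon
start in transcription orientation (positions −100..−1), donor windows the
100 nt downstream of the exon end (+1..+100); windows truncated at
chromosome edges drop positions rather than being zero-padded.

Positional composition tests are Fisher 2×2 per (position, nucleotide),
BH-corrected across positions within each (side, nucleotide) family — FDR
rather than Bonferroni, matching the convention for positional screens.
A fast path (`ci=False`) skips the exact confidence intervals in large
simulation sweeps; p-values are identical.

Motif enrichment replaces an external known-motif scanner with a defined,
testable procedure: a window "contains" a motif when its best sense-strand
log-odds score (uniform background) reaches 0.8 of the maximum attainable
score; per motif, one-sided Fisher tests run in both directions with BH
over motifs per direction, keeping the direction with the smaller q and
signing the log₂ containment ratio accordingly (positive = first set).
Scanning is sense-only because the motifs describe RNA binding. First
exons of every isoform are excluded from the motif analysis only.

The eCLIP sweep tests, at each of 13 log₂-ratio cutoffs (0..6 by 0.5),
whether genes owning at least one significant isoform passing the cutoff
(per direction; each gene assigned the direction of its largest-|ratio|
isoform) overlap peaks more often than genes with no DE isoform at all;
genes with DE isoforms failing the cutoff are excluded from both sides.

## Heart failure

The RBP-panel geometry uses joint PCA of all samples on z-scored
log₂(TPM+1) of the panel (constant or absent RBPs dropped), with component
signs fixed by the largest-|loading| RBP. This deliberately replaces
reference-based integration with a deterministic equivalent of the same
geometric question; absolute distances and their p-values are therefore
not comparable to an anchor-integrated analysis, only the relative
pre/post contrast is. Distances are means over each healthy group in
top-10 PC space; pre-vs-post differences are paired t-tests by subject.

The reversion statistic classifies every isoform of the shared universe by
(heart-failure DE at FDR < 0.05) × (fetal-program column: iPSC-DE at FDR
< 0.05 AND sign(β_HF) = sign(β_iPSC)). The sign condition applies in both
rows — using the estimated heart-failure effect whether or not significant
— so the table is a genuine independence test with odds ratio 1 under a
null of unrelated programs, monotone in the planted reversion fraction.
The Pearson correlation of the two effect vectors is reported alongside.

## The synthetic cohort

Defaults: 40 fetal-like, 40 adult-heart, 30 adult-arteria samples and 8
pre/post-LVAD pairs; 2,000 genes, half with 2–4 isoforms; 6 cell types with
per-tissue Dirichlet mixtures (the fetal-like tissue carries almost no
fibroblast/immune mass); 300 stage-DE genes with |log₂FC| ~ U(2.5, 4),
one third drawn from a 120-gene RBP panel with an 85% fetal-up bias; 250
switch pairs with usage shift Δ ~ U(0.3, 0.6), 40% of them "strong"
(> 4-fold usage ratios on both sides, the source of stage-specific exons);
multiplicative lognormal noise σ = 0.25 on the log₂ scale; logistic-normal
per-sample usage jitter (sd 0.25). Gene TPM is mixture × stage effect ×
noise; isoform TPMs partition gene TPM exactly through the per-sample
usage simplex. Mitochondrial read fraction tracks cardiac-muscle content
(slope 0.1, noise sd 0.03) so the covariates are correlated with, but not
proxies for, tissue.

Heart failure: pre-LVAD samples reactivate half of the RBP stage effect at
the gene level; a fraction ρ (default 0.5) of switch pairs moves 80% of
the way back to fetal usage pre-LVAD, and 60 additional "private" pairs
shift pre-LVAD only, independent of the fetal program — failing hearts
have disease-specific changes too, and without them the reversion table
would be empty at ρ = 0. Post-LVAD samples match adult heart.

The genome is fabricated (one chromosome per 100 genes) so annotation,
windows, peaks and domains are internally consistent; GT/AG dinucleotides
mark every intron boundary, strong-switch exon flanks are drawn from
canonical splice-site profiles with a stronger polypyrimidine tract on the
fetal side (T fraction 0.55 vs 0.30 at −20..−5 — a deliberately strong
contrast, since desk-scale exon sets of ~125/side would not resolve the
subtler differences a cohort-scale comparison can), one PWM's consensus is
planted into 60%/20% of strong fetal/adult acceptor windows, eCLIP-style
peaks land in switch genes at 0.6 vs 0.3 background, and domains overlap
fetal alternative exons at 0.55 vs 0.35. Single-cell counts are negative
binomial (dispersion 0.5, 200 cells/type) from the same signatures; 6% of
genes per type are planted markers (2–4 log₂FC), with only 0.05 sd of
residual type variation elsewhere so the planted markers are the
recoverable type-specific structure. An `equal_composition` switch draws
every tissue's mixture from one Dirichlet — the controlled condition used
by the null-calibration and recovery studies, where the planted fold
change must equal the realized group-mean ratio.

One integer seed drives a single generator; identical seeds give
bit-identical cohorts, and the pipeline's outputs are byte-identical
across reruns.

### What the synthetic data does not emulate

No read-level simulation, mapping bias, batch structure between data
sources, gene–gene correlation beyond the mixture, isoform structure
beyond one distinctive exon per isoform, or realistic genome composition.
Passing recovery tests therefore demonstrates correctness of the
statistical machinery under the stated generative assumptions, not
performance on real cohorts; in particular the deconvolution accuracy and
the reversion odds ratios here are not predictions of real-data effect
sizes.

## Problem sizes and numerics

The validation battery uses 100-seed calibrations for the null type-I
error and splice positional tests, 50 null seeds for positional
calibration, 20 seeds per reversion fraction, and the full default cohort
elsewhere; these sizes give Monte-Carlo standard errors comfortably inside
the asserted bands. Exact tests fall back to OR = NaN, p = 1 on zero
margins; degenerate one-sample t-tests (zero variance, nonzero mean)
report p below machine epsilon with a flag; GCV boundary selections and
dropped constant predictors warn rather than fail. Feature output order is
lexicographic everywhere.
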