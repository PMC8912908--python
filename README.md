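# cardiosplice

Developmental-stage-specific isoform programs in cardiovascular bulk
RNA-seq: a tested, reusable pipeline for detecting stage-specific genes,
isoforms and exons between fetal-like cardiac tissue (iPSC-derived
cardiovascular progenitors, iPSC-CVPC) and adult heart/arteria,
characterizing their splice-site and RNA-binding-protein (RBP) properties,
deconvoluting cell-type composition, and quantifying how far failing-heart
transcriptomes revert toward the fetal isoform program.

The cohorts such analyses are usually run on are controlled-access, so the
package ships a first-class synthetic-data module that generates cohorts
with the same statistical structure — tissue groups, cell-type mixtures,
planted stage effects and isoform switches, paired pre/post-LVAD heart
failure samples — together with the ground truth, so every stage of the
pipeline has a recovery test.

## The statistics at the core

* **Isoform usage.** For isoform *i* of gene *g* in sample *s*,
  usage *u*(*i*,*s*) = TPM(*i*,*s*) / Σ_{j∈g} TPM(*j*,*s*) — length-free and
  comparable across samples. Genes need ≥ 2 expressed isoforms
  (usage > 10% in ≥ 10% of samples); genes are "expressed" at TPM ≥ 1 in
  ≥ 10% of samples.
* **Differential expression / usage.** Per feature, OLS of rank
  inverse-normal values on tissue plus four technical covariates (sex,
  z-scored library size, autosomal and mitochondrial read fractions):
  *Y*ᵢ = β*T*ᵢ + Σₚ γₚ*C*ᵢₚ + εᵢ, Bonferroni-corrected. A feature is
  *tissue-specific* when additionally |log₂ ratio of group means| > 2 on
  the original scale.
* **Ridge DE with cell-type proportions.** Because six mixture proportions
  sum to one, contrasts that adjust for composition use ridge regression,
  β̂ = (XᵀX + λI)⁻¹XᵀY with λ by generalized cross-validation, and
  linear-smoother sandwich standard errors.
* **Deconvolution.** Marker genes from labeled single-cell counts
  (one-vs-rest Wilcoxon), a signature matrix of per-type mean expression,
  and per-sample ν-SVR (linear kernel, ν ∈ {0.25, 0.5, 0.75}, negative
  coefficients truncated, renormalized to the simplex); NNLS as a
  deterministic fallback.
* **Exon sequence analyses.** Stage-specific exons (set differences of
  exons between specific isoforms of the same genes), Fisher tests for
  protein-domain overlap, per-position nucleotide composition of 100-bp
  splice-site flanks (polypyrimidine tract included), a PWM-scan Fisher
  procedure for motif enrichment in acceptor-side windows, and a
  13-threshold eCLIP peak-overlap enrichment sweep.
* **Fetal reversion in heart failure.** PCA on the RBP panel with paired
  pre/post-LVAD distance tests, and a 2×2 exact test asking whether
  isoforms differentially used in heart failure are enriched for the
  fetal–adult switch set *with matching direction* (conditional-MLE odds
  ratio).

## Worked example

Run the numbered analyses (each is a thin driver over the library; all
take an optional seed argument):

```bash
python analysis/01_simulate_cohort.py 0 results/cohort
python analysis/02_differential_expression.py 0
python analysis/06_heart_failure.py 0
```

Output of the differential stage (seed 0):

```
iPSC-CVPC_vs_adult_heart: 317 tissue-specific isoforms
iPSC-CVPC_vs_adult_arteria: 315 tissue-specific isoforms
adult_heart_vs_adult_arteria: 0 tissue-specific isoforms
top enriched gene set for the stage contrast: RNA_BINDING (t = 6.6, q = 2.34e-08)
```

Isoform switching separates developmental stages, not the two adult
tissues, and the RBP gene set tops the stage enrichment — the generator
concentrates fetal overexpression there, and the pipeline recovers it.
The heart-failure stage prints:

```
distance to iPSC-CVPC: closer pre-LVAD (pre-post = -10.05, p = 1.37e-12)
distance to adult_heart: closer post-LVAD (pre-post = +7.73, p = 7.82e-10)
RBP effect sizes (pre-LVAD vs adult heart): mean +0.132, p = 8.49e-10
reversion: 122 of 275 HF-DE isoforms match the fetal trend; OR = 10.92 (p = 3.62e-56), effect-size r = 0.34
```

Failing hearts sit closer to the fetal-like group before mechanical
unloading and move toward the adult group after it; isoforms
differentially used in heart failure are strongly enriched for the planted
fetal switch program (half of the switch pairs revert in this
configuration, so the odds ratio is far above 1).

The same stages are available as a CLI
(`cardiosplice simulate|preprocess|de|deconvolute|exons|eclip|heartfailure|run-all`),
driven by `--seed`, `--outdir` and an optional YAML config.

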