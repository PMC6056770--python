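# Methods

This document specifies the statistical models and numerical choices
implemented in `cnvar`. Everything stated here is exercised by the test
suite (`tests/`), mostly against independent oracles (closed-form algebra,
brute-force enumeration, or a reference implementation).

## Pre-processing

- **Input.** Proteins × samples matrix of log2 abundances (linear input is
  log2-transformed; non-positive linear values become missing), plus a
  design table mapping samples to conditions. Duplicate protein identifiers
  and samples absent from the design are errors.
- **Coverage filter.** A protein is kept for a two-condition comparison only
  if it is quantified in *more than half* of the replicates of **each**
  condition (strict inequality; e.g. 2 of 3).
- **Quantile normalization** equalizes the per-sample distributions before
  the moderated-t comparator: the reference distribution is the mean of the
  per-sample quantile profiles; tied observations receive the mean of the
  reference values at their ranks (midranks); samples with different numbers
  of observed values are aligned by interpolation on quantile positions.
- **The CNV branch consumes raw, un-normalized values**: replicates are
  averaged per condition over observed values only. The per-compartment
  regression absorbs sample-level scale and offset differences itself, and
  normalizing first would partially redistribute exactly the compartment
  shifts the method is designed to isolate. A `comparison-quantile` mode
  feeds the same normalized matrix to both branches when the two statistics
  must be compared on equal footing.

## Compartment assignment

Ten cellular compartments are defined as GO cellular-component term sets
expanded to all offspring over `is_a` and `part_of` edges (ontology parsed
with `obonet`; offspring via transitive closure on the resulting DAG;
obsolete terms and other namespaces ignored):

nucleus (GO:0005634), cytoplasm (GO:0005737), mitochondrion (GO:0005739),
extracellular (GO:0005576 + GO:0031012 + GO:0044421 + GO:0044420),
peroxisome (GO:0005777), lysosome (GO:0005764), endoplasmic reticulum
(GO:0005783), Golgi apparatus (GO:0005794), cell membrane (GO:0005886),
nuclear membrane (GO:0031965). Four of these (nucleus, cytoplasm,
mitochondrion, extracellular) form the default "major" set used for
per-protein CNV summaries. Proteins may belong to several compartments and
enter every corresponding model. GAF association files are read with
`NOT`-qualified rows skipped, optional evidence-code filtering, and isoform
suffixes stripped. Alternatively, any two-column protein→group table
defines custom "compartments".

## The CNV model

For each compartment *c* with proteins *i = 1…n* (n ≥ `min_fit_size`,
default 10), let *x_i* be the reference-condition mean log2 abundance and
*y_i* the test-condition mean. Fit by ordinary least squares

  y_i = β₀ + β₁ x_i + e_i.

A compartment-wide multiplicative change moves β₀ only; a proportional
response moves β₁. The residual e_i carries protein-specific deviation from
the compartment trend. CNV values standardize the residuals,

  cnv_i = (e_i − ē) / sd(e),   sd with ddof = 1,

so within a compartment CNV values have mean 0 and standard deviation 1 by
construction. The method is invariant to adding a constant to all *y* of a
compartment (absorbed by β₀) and, more generally, to any affine
transformation of *y* — both are asserted to 1e-8 in the tests.

Models with regression p ≥ `model_p` (default 0.05, slope t-test) are
reported but flagged not retained, and their records are marked accordingly.
Compartments below `min_fit_size` or with constant *x* are skipped with a
log message. If all residuals are equal (perfect fit), CNV is undefined and
records carry `cnv_computable = False`.

**Significance.** CNV values are treated as z-scores: two-sided p = 2·Φ̄(|cnv|),
then Benjamini–Hochberg q-values computed within each compartment
(optionally pooled across compartments). An optional empirical-null mode
rescales the CNV values by a robust null width (median absolute deviation,
normal-consistent) before computing p, for datasets where true signals
inflate the standardization denominator. The per-protein summary takes the
minimum q over the protein's (major) compartments.

## Compartment shift test

Per-protein log2 fold changes (test mean − reference mean; the values
themselves in ratio mode) of a compartment are compared against a background
— whole proteome by default, or its complement — with a two-sided
Mann–Whitney U test. Exact p-values are used when n + m ≤ 20 without ties
(verified against full enumeration of all label assignments to 1e-12);
otherwise the normal approximation with tie correction and continuity
correction. The location shift is summarized by the mean and median fold
change. Cross-dataset coherence of compartment shifts can be quantified by
correlating `mean_log2fc` vectors across runs.

## Moderated-t comparator

The standard against which CNV is compared is the empirical-Bayes moderated
t-test. Per protein, the pooled within-condition variance s² with d_g
residual degrees of freedom is shrunk toward a prior (d₀, s₀²):

  s̃² = (d₀·s₀² + d_g·s²) / (d₀ + d_g),

and t = Δmean / (s̃·√(1/n_A + 1/n_B)) is referred to d₀ + d_g degrees of
freedom. (d₀, s₀²) are estimated by moments matching on log s²: under the
scaled-χ² model, e = log s² − ψ(d_g/2) + log(d_g/2) has variance
ψ′(d_g/2) + ψ′(d₀/2), so d₀ follows by Newton inversion of the trigamma
function on the excess variance of e; when the observed variances are no
more dispersed than sampling alone explains, d₀ = ∞ and s₀² is the
arithmetic mean of s². The implementation reproduces the reference R
implementation (limma's `lmFit`/`eBayes`) to 1e-6 relative on t and p in the
test suite, and its limits are exact: d₀ = 0 recovers the ordinary pooled
t-test, d₀ → ∞ gives s̃² → s₀². q-values are Benjamini–Hochberg.

**Overlap classes.** At each threshold τ (defaults 0.05, 0.1, 0.25) every
protein is classified from (q_DE < τ, q_CNV < τ) into `both`,
`standard-only`, `cnv-only`, `neither`. Proteins present in only one
analysis are classified on the available side and flagged partial.

## Time-course mode

Inputs are per-timepoint log2 ratios against a common reference. Δ-ratios
subtract the baseline timepoint (baseline column identically zero; proteins
without a baseline value are excluded). Per-timepoint CNV uses the baseline
as *x* and the timepoint as *y*, so compartment-wide drift is absorbed while
proteins moving against their compartment stand out. Per compartment, a
Mann–Whitney test of ratios at each timepoint vs baseline flags
compartment-wide drift. For protein groups (e.g. complexes), two group
trajectory tests run per timepoint against the first non-baseline point:
`delta` mode on Δ-ratios and `cnv` mode on CNV values (unpaired
Mann–Whitney; paired Wilcoxon optional). Their dissociation — delta
significant, CNV null — identifies a group that moves because its
compartment moves, not because its members are individually regulated.

## Synthetic data generator

Condition A abundances are drawn N(baseline_mean, baseline_sd²) in log2
units (defaults 25, 2). Condition B: b_i = a_i + δ_c(i) + ε_i + o_i with
compartment shift δ_c, residual ε_i ~ N(0, σ_res²) (default 0.3), and
outlier effect o_i = ±γ·σ_res (default γ = 4) for exactly round(f_out·n)
proteins per compartment with alternating signs, so the compartment slope
stays unbiased. Replicates (default 3 per condition) add N(0, σ_rep²)
(default 0.2). Missingness is applied last: missing-completely-at-random by
default, with an optional intensity-dependent left-censoring mode (off by
default to keep null calibration clean). A ground-truth table records each
protein's compartment, δ, ε, outlier status and effect. Identical seeds give
byte-identical outputs; the time-course variant adds per-compartment drift
schedules and per-protein trajectory effects on top of a complete baseline.

Realism notes: log-additive shifts emulate organelle-content differences;
σ_rep < σ_res reflects technical replicates being tighter than biological
protein-level regulation; the left-censoring option exists because
proteomics missingness is abundance-biased.

## Numerical choices

- OLS via `scipy.stats.linregress`; verified against closed-form normal
  equations (1e-10) and brute-force SSE grid search in the tests.
- BH q-values by the step-up cumulative-minimum construction (mergesort for
  stable ties), NaN-aware.
- Trigamma inversion by Newton iteration with the standard asymptotic
  starting point; tolerance 1e-10 relative.
- All simulation randomness flows through `numpy.random.default_rng(seed)`;
  derived seeds are drawn below 2³¹.
- Output tables are written with a `# config_hash=` header (SHA-256 of the
  canonicalized configuration, truncated to 16 hex digits), `NA` for
  missing, `\n` line endings; run logs contain no timestamps, so reruns are
  byte-identical.

## Limitations

- **CNV power is bounded by within-compartment noise.** A planted effect of
  γ·σ_res yields a standardized residual distributed roughly N(γ, 1),
  because the protein's own residual variability σ_res survives
  standardization undiminished (replicate averaging reduces σ_rep only).
  With 20 signals among 1000 and BH at q < 0.1, the effective cutoff is
  |z| ≈ 3.15, capping mean sensitivity near 0.80 for γ = 4 even with a
  perfectly calibrated null — the acceptance suite documents this bound and
  the corresponding criterion is intentionally left failing rather than
  weakened. In practice this means single-protein composition changes need
  to exceed ~4–5 compartment residual SDs to be recovered reliably at
  stringent FDR.
- The standardization denominator includes true signals; with many strong
  outliers sd(e) inflates and p-values become conservative (the
  empirical-null option mitigates but cannot remove the bound above).
- Compartment models assume a single linear trend per compartment;
  multi-modal compartments (e.g. proteins belonging to several organelles)
  enter several models rather than a mixture.
- Quantile normalization redistributes large compartment shifts across the
  proteome; when a large fraction of the proteome moves, comparator fold
  changes of unshifted proteins acquire systematic offsets. The CNV branch
  is unaffected by construction (it consumes raw values).
- GO annotation quality bounds compartment assignment; no spatial-proteomics
  inference is attempted.
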