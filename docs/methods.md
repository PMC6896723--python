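# Methods

## The design and the generative model

The package analyzes a replicated matched design: `C` tumors ("cancers"),
each measured under a fresh-frozen reference condition (FF) and under one
condition per FFPE RNA-extraction kit, with `r` technical replicates inside
every (tumor, condition) cell. All modeling is on the (reference-normalized)
log2 scale. The synthetic generator draws

    Y_gckt = mu_g + a_gc + beta_gk + b_gck + eps_gckt

* `mu_g` — per-gene baseline, uniform on a configurable log2 range
  (default −10 … 5) so that the high/low stratification cutoff at −7.5 is
  exercised on both sides; reference-panel genes draw from a high range
  (2 … 6) as housekeeping genes do.
* `a_gc ~ N(0, σ_a²)` — tumor effect, shared by every condition and
  replicate of that tumor.
* `beta_gk` — fixed kit bias, zero for FF. Per-gene biases are
  `N(kit_bias, kit_bias_sd²)` with a correlation `rho` between kits
  (default 0.9): matched FFPE kits deviate from FF in largely the same
  per-gene way, which is what makes per-gene concordance values strongly
  rank-correlated between kits and the high-concordance overlap large.
* `b_gck ~ N(0, tau_gk²)` — per-tumor slope of the kit bias, zero for FF.
* `eps ~ N(0, sigma_e_k²)` — replicate noise, configurable per condition.
* optionally a cell intercept `u ~ N(0, sigma_u²)` (default 0, see below)
  and a negative-binomial count layer with mean `2^(Y + count_scale)`
  (default off; the analysis models log2 values).

Default parameter values (12 tumors, conditions FF/N/Q/R, duplicates
everywhere, σ_a = 0.7, kit_bias = 0.25, kit_bias_sd = 0.6, τ = 0.35,
σ_e = 0.14/0.14/0.19/0.22 by condition) were chosen once so that the
synthetic study lands in the ranges a matched FFPE/frozen breast-tumor
series exhibits — per-gene median CCC in the 0.6–0.75 band driven mostly by
the accuracy term rather than correlation, per-gene r near 0.86–0.9,
mixed-model bias medians near 0.2–0.3 with slope variance near 0.12, and
median replicate differences of 0.13–0.22 log2 units ordered N < Q < R.
RNA-quality metrics are drawn around per-condition medians (FF RIN 7.2 vs
FFPE ≈ 2.5, DV200 88 vs 73–83, median TIN 75.8 vs ≈ 81.3) and clipped to
their valid ranges.

What the generator deliberately does **not** emulate: gene–gene correlation
(tumor effects are independent across genes), library-size or GC effects,
count overdispersion structure beyond a single NB dispersion, and any
sequence-level artifacts. Two consequences matter for interpreting tests.
First, signature scores average many informative genes, so the independent
`a_gc` terms shrink by √(panel size) while the kit-shared bias does not —
synthetic signature-level CCC is therefore pessimistic relative to real
signatures whose genes share tumor biology. Second, passing recovery tests
shows the estimators are correct under the declared model, not that real
FFPE noise follows it.

## Preprocessing

* **Expression filter.** A gene is kept iff its count exceeds a threshold
  (default 0) in *every* sample of *every* condition group — a single
  shared gene list (global intersection), not per-kit lists. Applied on raw
  counts before replicate averaging.
* **Normalization.** log2 (counts get a pseudo-count, default 1), then per
  sample the mean log2 of the reference-gene panel is subtracted; reference
  genes are normalized identically and retained. The operation is exactly
  shift-invariant per sample. Mean (not median) panel summary, matching
  common reference-panel practice; both are exposed.
* **Replicate averaging.** Arithmetic mean per (tumor, condition) cell,
  columns named `cancer_condition`. Concordance, differential analysis and
  signature concordance run on the averaged matrix; the mixed model and
  replicate-difference statistics require the replicate-level matrix.
* **Stratification.** `high` iff mean normalized expression across samples
  is strictly greater than −7.5 (a gene exactly at the cutoff is `low`).
  The mean-across-samples summary is a documented choice; median is
  available.

## Concordance statistics

Lin's CCC uses population (1/n) moments, the original estimator; sample-
moment variants differ noticeably at n = 12. The accuracy term is computed
directly as `C_b = 2 s_x s_y / (s_x² + s_y² + d²)` so `CCC = r · C_b` holds
identically. Zero variance in either arm flags the statistic as undefined
(NaN) — degenerate genes are never reported as "agreement 0" and are
excluded from medians. Tumors missing from either arm are dropped pairwise
with the retained count reported.

Replicate difference is the median across tumors of |rep1 − rep2| per gene
and condition (mean pairwise absolute difference for > 2 replicates); with
Gaussian noise the per-gene statistic concentrates at
σ_e·√2·Φ⁻¹(3/4) ≈ 1.349·σ_e·0.707, which the calibration tests check. The
across-gene spread is summarized by the raw median absolute deviation
(no 1.4826 consistency factor) — a documented choice, exposed as a scale
argument.

The high-concordance overlap selects, per kit, genes with mean expression
(average of the two arm means) above −7.5 and CCC above 0.5, both strictly;
"percent shared" uses the union of the per-kit sets as denominator, since
the natural alternative (per-kit list sizes) is not uniquely defined for
three kits.

## The reliability mixed model

Per unit (gene or signature score):

    Y = Kit + (Kit | Cancer) + (1 | RepWcancer)

fixed effects: intercept (FF level) + one bias per kit. Random structure,
`diagonal` default: per-cancer intercept variance σ_a² plus independent
per-kit slope variances τ_k². A full (K+1)×(K+1) slope covariance
(Cholesky-parameterized) is available via `structure="full"`, but with ~12
cancers its off-diagonals are poorly identified, so it is not the default.
The cell intercept (1 | RepWcancer) is off by default: with duplicate
extractions it is exactly aliased with the slope variance inside each
cancer×kit cell (and with residual noise in the FF arm), so the default
reports σ_u² = 0; it can be enabled.

Estimation is REML. The restricted criterion (including its constant) is

    −2ℓ_R = log|V| + log|XᵀV⁻¹X| + yᵀPy + (n − p)·log 2π

evaluated block-wise per cancer (one shared Cholesky per evaluation in
balanced designs). Variances are optimized on the log scale by L-BFGS-B
from a method-of-moments start, with a Nelder-Mead polish when the line
search ends abnormally on flat surfaces; the fit never reports a point
worse than its start (descent guarantee). Variance estimates below 1e-8
are reported as boundary ties, not jittered. When the fixed effects fit the
data exactly (zero-noise inputs) the GLS solution reduces to OLS and all
variances are reported at the floor directly.

The balanced closed form used for starts (and as an independent oracle in
tests): σ̂_e² is the pooled within-cell variance (= half the mean squared
replicate difference for duplicates); β̂_k the mean (kit − FF) cell-mean
contrast; τ̂_k² the between-tumor variance of those contrasts minus the
replicate-noise contribution, floored at 0.

## Differential analysis

The genome-wide differential step is a per-gene OLS on
`value = Cancer + Kit` over the replicate-averaged, reference-normalized
log2 matrix — a deliberately transparent fixed-effects substitute for
count-based negative-binomial machinery, preserving the paired design
matrix. In a balanced design the kit coefficient is exactly the mean
within-tumor log2 difference. Kit-vs-kit contrasts reuse the single joint
fit rather than refitting per pair. BH adjustment is applied within each
contrast across genes; genes with zero residual variance are flagged
(`boundary` with p = 0 for a nonzero effect, `undefined` otherwise), never
silently given a p-value. Significance defaults to FDR < 0.05.

Mann–Whitney U uses midranks; for tie-free samples with n + m ≤ 12 the
two-sided p is exact by enumeration (fraction of labelings with
|U − nm/2| at least the observed), otherwise a normal approximation with
tie and continuity corrections. The continuity correction is clamped so a
perfectly central U reports p = 1.

## Signatures and the random null

Scores are unweighted mean differences (informative minus reference panel,
log2 scale); the commercial coefficient sets of EndoPredict and the
Recurrence Score are proprietary, so the bundled definitions carry gene
lists only and per-gene weights are user-suppliable. Replicate
reproducibility is reported as percent of the score's dynamic range (max −
min of replicate-averaged scores across all cells) — the denominator is a
documented choice.

The random-signature null asks whether the observed score's FF-vs-kit CCC
beats chance for gene sets of the same size and expression range. "Same
expression range" is operationalized as quantile-bin matching (default 10
bins on mean expression): each draw replaces every informative gene with a
distinct random gene from the same bin (bins may return the original
genes, which keeps the construction exchangeable and the percentiles
uniform under the null — a property the acceptance suite verifies by a
Kolmogorov–Smirnov test over 200 trials). The true reference panel is kept
in every draw. Draws are without replacement within a draw and independent
across draws; a bin that contains no gene beyond the signature's own
occupants aborts with a suggestion to use fewer bins. The percentile is
100 × the fraction of draws strictly below the observed statistic, and is
invariant under any strictly monotone transformation applied to both.

## Numerical and interface choices

* Single text dialect everywhere: TSV, UTF-8, '.' decimal; matrices are
  gene × sample with the gene id in the first column. All outputs are
  re-readable by the package's own readers.
* Convergence tolerance 1e-8 on the REML gradient, 1e-13 relative on the
  criterion; variance floor 1e-12 on the log-parameterized scale.
* All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; quality metrics use an independent child
  stream so expression and quality draws do not interact. Fixed-seed
  pipeline runs produce byte-identical report bundles (the run log records
  seed, a config hash that ignores the output location, and the package
  version — no timestamps).
* Problem sizes in the test and acceptance workloads (2,000 genes for
  calibration checks, 500 genes for mixed-model recovery, 200 trials ×
  500 draws for null calibration) are chosen so the statistical tolerances
  quoted above are meaningful at a few minutes of single-CPU compute.

## Known limitations

* The differential step models normalized log2 values, not counts; genes
  near the detection limit are better served by count models.
* With 12 tumors the slope variances τ_k² are estimated with large
  sampling error (the recovery tolerance is 15% on the median over
  hundreds of genes, not per gene), and the full slope covariance is
  provided but rarely identified.
* Signature-level results on synthetic data understate real-data
  concordance because the generator draws tumor effects independently per
  gene (see above).
* The generator does not model batch, library-size or positional effects;
  quality metrics are drawn around medians and are not linked to the
  expression noise level of the same sample.
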