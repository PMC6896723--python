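# ffpe-concordance

Reliability analysis of bulk RNA-seq gene expression measured from
formalin-fixed paraffin-embedded (FFPE) tumor tissue versus matched
fresh-frozen (FF) samples, across RNA-extraction kits.

FFPE is the routine clinical preservation method, but fixation degrades and
chemically modifies RNA. Before a diagnostic gene-expression assay can be
trusted on FFPE material, one has to quantify, gene by gene, how well FFPE
measurements agree with the fresh-frozen gold standard — and how much of the
disagreement is a systematic kit bias, how much is tumor-to-tumor variability
of that bias, and how much is plain technical-replicate noise. This package
implements that analysis for a replicated matched design (each tumor measured
in an FF arm and in one arm per FFPE extraction kit, with duplicate
extractions per cell), together with a synthetic-data generator that
reproduces the design's statistical structure with full ground truth.

It is aimed at transcriptomics methodologists and assay developers who need
the estimators (and their calibration story) rather than a wet-lab protocol.

## What it computes

**Per-gene concordance.** Agreement between the FF arm and each kit is Lin's
concordance correlation coefficient over tumors, with population (1/n)
moments:

    CCC = 2 s_xy / (s_x² + s_y² + (x̄ − ȳ)²) = r · C_b

where r is the Pearson correlation (precision) and C_b ∈ (0, 1] the accuracy
term penalizing location/scale shifts. Genes are stratified at a normalized
log2 expression of −7.5, and the high-expression, high-CCC (> 0.5) gene sets
are intersected across kits.

**Mixed-model bias/variance decomposition.** For each gene (or signature
score) the model

    Y = Kit + (Kit | Cancer) + (1 | RepWcancer)

is fitted by REML: a fixed kit bias β_k per FFPE kit (FF is the reference
level), a per-cancer random intercept σ_a² with independent per-kit random
slopes τ_k² (the across-tumor variability of the bias), an optional
replicate-cell intercept, and residual replicate noise σ_e². Variances are
optimized on the log scale from a method-of-moments start; a balanced
closed-form estimator is provided as well.

**Differential analysis.** Per-gene OLS on the paired two-factor model
`Expression = Cancer + Kit` after replicate averaging, Benjamini–Hochberg
FDR, and DEG counts at |log2FC| thresholds 0 / 0.5 / 1 / 2. Quality indices
(RIN, DV200, median TIN) go through the same paired model. Mann–Whitney U
with exact small-sample p-values and Bland–Altman limits of agreement cover
the remaining comparisons.

**Signature scoring.** Two-set signatures (mean of informative genes minus
mean of a reference panel, per sample, on the log2 scale) with bundled gene
lists for EndoPredict (8+3), the 21-gene Recurrence Score (16+5) and the
SET ER/PR index (18+10); FF-vs-kit score concordance; replicate
reproducibility as a percent of the score's dynamic range; and an
expression-matched random-signature null (default 10,000 draws, quantile-bin
matching on mean expression) that places the observed score CCC on a
percentile scale.

## Worked example

```python
from ffpe_concordance import (
    SimulationConfig, simulate_study, log_and_normalize, average_replicates,
    concordance_table, fit_lme_single,
)

config = SimulationConfig(n_genes=1000, n_reference_genes=10, seed=7)
matrix, design, truth = simulate_study(config)
normalized = log_and_normalize(matrix, truth.reference_genes)
averaged, avg_design = average_replicates(normalized, design)

for kit in design.kits:
    table = concordance_table(averaged, avg_design, kit)
    print(f"kit {kit}: median CCC {table['ccc'].median():.3f}, "
          f"median r {table['pearson_r'].median():.3f}, "
          f"median C_b {table['bias_term'].median():.3f}")

gene = normalized.genes[0]
res = fit_lme_single(normalized.values.loc[gene], design, unit_id=gene)
print(f"{gene}: bias", {k: round(v, 3) for k, v in res.bias.items()},
      f"tau2 {res.slope_var['N']:.3f} sigma_e2 {res.sigma_e2:.4f}")
print("truth:", {k: round(truth.beta(k).loc[gene], 3) for k in design.kits})
```

prints

```
kit N: median CCC 0.711, median r 0.895, median C_b 0.827
kit Q: median CCC 0.719, median r 0.890, median C_b 0.827
kit R: median CCC 0.689, median r 0.882, median C_b 0.807
gene00001: bias {'N': 0.635, 'Q': 0.68, 'R': 0.741} tau2 0.113 sigma_e2 0.0325
truth: {'N': 0.609, 'Q': 0.695, 'R': 0.601}
```

The median CCC around 0.7 with r near 0.89 says most disagreement between
FFPE and FF comes from per-gene expression shifts (the accuracy term), not
from poor correlation — and the fitted per-gene kit biases track the
generator's true biases.

The same analysis is available from the shell:

```
ffpe-concordance simulate --seed 7 --n-genes 1000 --out sim/
ffpe-concordance run --seed 7 --out results/
```

`run` executes filter → normalize → average → {concordance, mixed model,
differential, signatures} and writes per-stage TSVs plus `summary.json`.

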