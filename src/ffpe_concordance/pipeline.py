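"""End-to-end analysis pipeline: filter, normalize, average, analyze, report.

The report bundle mirrors the headline tables of a matched FFPE-vs-frozen
kit comparison: per-kit concordance medians (CCC, r, accuracy term),
mixed-model bias and variance medians, replicate-difference medians, DEG
counts on a |log2FC| grid, and signature-level concordance with an
expression-matched random null.  Every per-stage table is written as TSV
and every summary as JSON; with a fixed seed the bundle is reproducible
bit for bit.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from . import __version__
from .concordance import (
    concordance_table,
    high_concordant_overlap,
    mad,
    replicate_difference,
    summarize_replicate_difference,
)
from .differential import count_degs, paired_linear_fit, quality_index_effects
from .io import (
    read_design,
    read_expression_matrix,
    read_quality,
    read_signature,
    write_design,
    write_expression_matrix,
    write_json,
    write_quality,
)
from .lme import fit_lme_all
from .matrix import ExpressionMatrix
from .preprocess import average_replicates, filter_expressed, log_and_normalize, stratify_by_expression
from .signatures import (
    GeneSignature,
    median_percent_difference,
    random_signature_null,
    replicate_percent_difference,
    score_signature,
    signature_concordance,
)
from .synthetic import SimulationConfig, simulate_quality, simulate_study


@dataclass
class PipelineConfig:
    """Configuration of one pipeline run.

    Exactly one input source is active: a simulation block (``simulation``)
    or file paths (``expression_path`` + ``design_path``).  Thresholds
    default to the study's analysis constants: expression cutoff -7.5
    (normalized log2), CCC cutoff 0.5, FDR 0.05, |log2FC| grid 0/0.5/1/2,
    10,000 null draws.
    """

    simulation: SimulationConfig | None = None
    expression_path: str | None = None
    expression_scale: str = "counts"
    design_path: str | None = None
    quality_path: str | None = None
    signature_paths: tuple[str, ...] = ()
    reference_genes: tuple[str, ...] = ()
    reference: str = "FF"
    expr_threshold: float = -7.5
    ccc_threshold: float = 0.5
    fdr_alpha: float = 0.05
    lfc_grid: tuple[float, ...] = (0.0, 0.5, 1.0, 2.0)
    null_draws: int = 10_000
    null_bins: int = 10
    run_null: bool = True
    lme_structure: str = "diagonal"
    lme_include_cell: bool = False
    out_dir: str = "results"
    seed: int = 0

    def __post_init__(self) -> None:
        has_sim = self.simulation is not None
        has_files = self.expression_path is not None
        if has_sim == has_files:
            raise ValueError("exactly one of simulation block or expression_path must be set")
        if has_files and self.design_path is None:
            raise ValueError("design_path required with expression_path")
        if not 0 < self.fdr_alpha < 1:
            raise ValueError("fdr_alpha must be in (0, 1)")
        if not -1 <= self.ccc_threshold <= 1:
            raise ValueError("ccc_threshold must be in [-1, 1]")
        if self.null_draws < 1 or self.null_bins < 1:
            raise ValueError("null_draws and null_bins must be >= 1")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _config_hash(config: PipelineConfig) -> str:
    # out_dir is provenance-irrelevant: the same analysis in two locations
    # must hash identically
    payload = {
        k: v for k, v in vars(config).items() if k not in ("simulation", "out_dir")
    }
    if config.simulation is not None:
        payload["simulation"] = config.simulation.to_dict()
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _load_inputs(config: PipelineConfig, out: Path):
    if config.simulation is not None:
        sim = config.simulation
        matrix, design, truth = simulate_study(sim)
        quality = simulate_quality(sim)
        reference_genes = list(truth.reference_genes)
        truth.genes.to_csv(out / "truth.tsv", sep="\t", float_format="%.10g")
    else:
        matrix = read_expression_matrix(config.expression_path, scale=config.expression_scale)
        design = read_design(config.design_path, reference=config.reference)
        quality = read_quality(config.quality_path) if config.quality_path else None
        truth = None
        reference_genes = list(config.reference_genes)
    signatures = [read_signature(p) for p in config.signature_paths]
    if not reference_genes and signatures:
        reference_genes = signatures[0].reference
    return matrix, design, quality, truth, reference_genes, signatures


def _synthetic_signature(matrix: ExpressionMatrix, truth, n_informative: int = 18) -> GeneSignature:
    """Build a signature from the generator's own genes for simulated runs."""
    informative_pool = truth.genes.index[~truth.genes["is_reference"]]
    means = matrix.values.loc[informative_pool].mean(axis=1)
    top = means.sort_values(ascending=False).index[:n_informative].tolist()
    return GeneSignature(
        name="synthetic_top_expressed",
        informative=top,
        reference=list(truth.reference_genes),
    )


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute the full analysis and write the report bundle to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {}

    stage = "load"
    try:
        matrix, design, quality, truth, reference_genes, signatures = _load_inputs(config, out)
        write_design(design, out / "design.tsv")
        if quality is not None:
            write_quality(quality, out / "quality.tsv")

        stage = "preprocess"
        if matrix.scale == "counts":
            matrix = filter_expressed(matrix, design)
        if reference_genes:
            present_refs = [g for g in reference_genes if g in set(matrix.genes)]
            normalized = log_and_normalize(matrix, present_refs)
        elif matrix.scale == "counts":
            raise ValueError("counts input requires a reference-gene panel for normalization")
        else:
            normalized = matrix.with_scale("normalized-log2")
        write_expression_matrix(normalized, out / "normalized.tsv")
        averaged, avg_design = average_replicates(normalized, design)
        write_expression_matrix(averaged, out / "averaged.tsv")
        strata = stratify_by_expression(normalized, threshold=config.expr_threshold)
        report["n_genes"] = normalized.n_genes
        report["n_high_expression"] = int((strata == "high").sum())

        stage = "concordance"
        tables = {}
        conc_summary = {}
        for kit in design.kits:
            table = concordance_table(averaged, avg_design, kit)
            table.to_csv(out / f"concordance_{kit}.tsv", sep="\t", float_format="%.8g")
            tables[kit] = table
            defined = table[table["defined"]]
            conc_summary[kit] = {
                "median_ccc": float(defined["ccc"].median()),
                "mad_ccc": mad(defined["ccc"]),
                "median_r": float(defined["pearson_r"].median()),
                "mad_r": mad(defined["pearson_r"]),
                "median_bias_term": float(defined["bias_term"].median()),
                "mad_bias_term": mad(defined["bias_term"]),
                "n_defined": int(len(defined)),
            }
        overlap = high_concordant_overlap(
            tables, expr_threshold=config.expr_threshold, ccc_threshold=config.ccc_threshold
        )
        rep_diff = replicate_difference(normalized, design)
        rep_diff.to_csv(out / "replicate_difference.tsv", sep="\t", float_format="%.8g")
        rep_summary = summarize_replicate_difference(rep_diff)
        report["concordance"] = conc_summary
        report["high_concordant_percent_shared"] = overlap["percent_shared"]
        report["replicate_difference"] = {
            cond: {
                "median": row["median_difference"],
                "mad": row["mad_difference"],
            }
            for cond, row in rep_summary.iterrows()
        }

        stage = "lme"
        lme_table, lme_summary = fit_lme_all(
            normalized,
            design,
            structure=config.lme_structure,
            include_cell=config.lme_include_cell,
        )
        lme_table.to_csv(out / "lme.tsv", sep="\t", float_format="%.8g")
        report["lme"] = lme_summary

        stage = "differential"
        de = paired_linear_fit(averaged, avg_design, alpha=config.fdr_alpha)
        de.to_csv(out / "differential.tsv", sep="\t", index=False, float_format="%.8g")
        degs = count_degs(de, lfc_thresholds=config.lfc_grid, alpha=config.fdr_alpha)
        degs.to_csv(out / "deg_counts.tsv", sep="\t", index=False)
        report["deg_counts"] = {
            contrast: {
                str(row["lfc_threshold"]): int(row["n_deg"])
                for _, row in grp.iterrows()
            }
            for contrast, grp in degs.groupby("contrast", sort=False)
        }
        if quality is not None:
            qe = quality_index_effects(quality, design)
            qe.to_csv(out / "quality_effects.tsv", sep="\t", index=False, float_format="%.8g")
            report["quality_effects"] = {
                f"{row['metric']}:{row['contrast']}": {
                    "effect": float(row["effect"]),
                    "fdr": float(row["fdr"]) if pd.notna(row["fdr"]) else None,
                }
                for _, row in qe.iterrows()
            }

        stage = "signatures"
        if not signatures and truth is not None:
            signatures = [_synthetic_signature(normalized, truth)]
        sig_report: dict[str, Any] = {}
        for sig in signatures:
            scores = score_signature(normalized, sig)
            entry: dict[str, Any] = {}
            conc = signature_concordance(scores, design)
            entry["ccc"] = {kit: res.ccc for kit, res in conc.items()}
            per_cell = replicate_percent_difference(scores, design)
            entry["median_replicate_percent_difference"] = {
                cond: float(v) for cond, v in median_percent_difference(per_cell).items()
            }
            if config.run_null:
                entry["null_percentile"] = {}
                for i, kit in enumerate(design.kits):
                    null = random_signature_null(
                        normalized,
                        design,
                        sig,
                        kit,
                        B=config.null_draws,
                        n_bins=config.null_bins,
                        seed=config.seed + 1000 + i,
                    )
                    entry["null_percentile"][kit] = null.percentile
            sig_report[sig.name] = entry
        report["signatures"] = sig_report
    except Exception as exc:
        raise StageError(stage, exc) from exc

    report["run_log"] = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "package_version": __version__,
    }
    write_json(report, out / "summary.json")
    return report
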