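"""Expression filtering, reference-panel normalization and replicate handling.

The processing chain mirrors a matched-design RNA-seq comparison:

1. drop genes that are not detected in every sample of every condition
   group (``filter_expressed``),
2. log2-transform and normalize each sample against the mean of a
   reference-gene panel (``log_and_normalize``),
3. average technical replicates within each (cancer, condition) cell
   (``average_replicates``),
4. stratify genes into high/low expression at a normalized-log2 cutoff
   (``stratify_by_expression``).
"""

from __future__ import annotations

from typing import Iterable

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, MatrixError, StudyDesign


class EmptyMatrixError(MatrixError):
    """Filtering removed every gene; carries per-condition diagnostics."""

    def __init__(self, per_condition_expressed: dict[str, int]):
        self.per_condition_expressed = per_condition_expressed
        detail = ", ".join(f"{c}: {n}" for c, n in per_condition_expressed.items())
        super().__init__(
            "no gene is expressed in all samples of every condition "
            f"(genes expressed everywhere per condition: {detail})"
        )


def filter_expressed(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    min_count: float = 0.0,
) -> ExpressionMatrix:
    """Keep genes detected in every sample of every condition group.

    A gene is "expressed" in a sample when its count exceeds ``min_count``
    (strictly; the default 0 keeps genes with at least one read in every
    sample).  The retained set is the intersection of the per-condition
    "expressed in all samples" sets, so one shared gene list applies to all
    downstream comparisons.  Gene order is preserved.
    """
    if matrix.scale != "counts":
        raise MatrixError(f"filter_expressed expects counts, got scale {matrix.scale!r}")
    design.align(matrix)
    keep = pd.Series(True, index=matrix.genes)
    per_condition: dict[str, int] = {}
    for cond in design.conditions:
        cols = design.samples_for(condition=cond)
        expressed = (matrix.values[cols] > min_count).all(axis=1)
        per_condition[cond] = int(expressed.sum())
        keep &= expressed
    if not keep.any():
        raise EmptyMatrixError(per_condition)
    return ExpressionMatrix(matrix.values.loc[keep], scale="counts")


def log_and_normalize(
    matrix: ExpressionMatrix,
    reference_genes: Iterable[str],
    pseudo: float = 1.0,
    center: str = "mean",
) -> ExpressionMatrix:
    """Log2-transform and normalize each sample by its reference-panel level.

    Counts receive ``log2(x + pseudo)``; log2 input passes through
    unchanged.  Then, per sample, the ``center`` (mean by default, median
    optionally) of the reference genes' log2 values is subtracted from
    every gene, reference genes included.  The result is shift-invariant
    per sample: adding a constant to all log2 values of one sample leaves
    its normalized values unchanged.
    """
    reference_genes = list(reference_genes)
    missing = [g for g in reference_genes if g not in matrix.genes]
    if missing:
        raise MatrixError(f"reference genes absent from matrix: {missing}")
    if not reference_genes:
        raise MatrixError("reference gene panel is empty")
    if matrix.scale == "counts":
        logged = np.log2(matrix.values + pseudo)
    elif matrix.scale in ("log2", "normalized-log2"):
        logged = matrix.values.astype(float)
    else:  # pragma: no cover - scale validated at construction
        raise MatrixError(f"cannot normalize scale {matrix.scale!r}")
    ref_block = logged.loc[reference_genes]
    offset = ref_block.mean(axis=0) if center == "mean" else ref_block.median(axis=0)
    normalized = logged.sub(offset, axis=1)
    return ExpressionMatrix(normalized, scale="normalized-log2")


def average_replicates(matrix: ExpressionMatrix, design: StudyDesign) -> tuple[
    ExpressionMatrix, StudyDesign
]:
    """Average technical replicates to one column per (cancer, condition).

    Returns the averaged matrix (columns named ``cancer_condition``) and a
    matching single-replicate design.  Single-replicate cells pass through.
    """
    if matrix.scale == "counts":
        raise MatrixError("average replicates on the log2 scale, after transformation")
    design.align(matrix)
    cols: dict[str, pd.Series] = {}
    rows = []
    for (cancer, cond), grp in design.table.groupby(["cancer_id", "condition"], sort=True):
        label = design.cell_label(str(cancer), str(cond))
        cols[label] = matrix.values[grp["sample_id"].tolist()].mean(axis=1)
        rows.append(
            {"sample_id": label, "cancer_id": cancer, "condition": cond, "replicate": 1}
        )
    averaged = ExpressionMatrix(pd.DataFrame(cols), scale=matrix.scale)
    return averaged, StudyDesign(pd.DataFrame(rows), reference=design.reference)


def stratify_by_expression(
    matrix: ExpressionMatrix,
    threshold: float = -7.5,
    summary: str = "mean",
) -> pd.Series:
    """Label genes ``high`` or ``low`` by average normalized expression.

    A gene is ``high`` when its per-gene ``summary`` (mean by default)
    across all samples is strictly greater than ``threshold``; a gene
    sitting exactly at the threshold is ``low``.
    """
    if matrix.scale != "normalized-log2":
        raise MatrixError(f"stratification expects normalized-log2, got {matrix.scale!r}")
    stat = matrix.values.mean(axis=1) if summary == "mean" else matrix.values.median(axis=1)
    labels = pd.Series(np.where(stat > threshold, "high", "low"), index=matrix.genes)
    labels.name = "expression_stratum"
    return labels
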