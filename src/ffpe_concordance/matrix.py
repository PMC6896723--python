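"""Core data containers: expression matrices and replicated study designs.

The study layout mirrors a matched-sample RNA-extraction comparison: each
tumor ("cancer") is measured under several conditions (a fresh-frozen
reference arm plus one arm per FFPE extraction kit), with technical
replicates nested inside each (cancer, condition) cell.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

Scale = Literal["counts", "log2", "normalized-log2"]

VALID_SCALES: tuple[str, ...] = ("counts", "log2", "normalized-log2")


class DesignError(ValueError):
    """Raised for structurally invalid study designs."""


class MatrixError(ValueError):
    """Raised for structurally invalid expression matrices."""


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with a declared scale.

    Parameters
    ----------
    values
        DataFrame indexed by gene id with one column per sample id.
    scale
        One of ``counts`` (non-negative raw counts), ``log2`` (log2
        expression) or ``normalized-log2`` (log2 expression after
        reference-panel normalization).
    """

    values: pd.DataFrame
    scale: Scale = "log2"

    def __post_init__(self) -> None:
        if self.scale not in VALID_SCALES:
            raise MatrixError(f"unknown scale {self.scale!r}; expected one of {VALID_SCALES}")
        idx = self.values.index
        cols = self.values.columns
        if idx.duplicated().any():
            dupes = sorted(idx[idx.duplicated()].unique().tolist())
            raise MatrixError(f"duplicate gene ids: {dupes[:10]}")
        if cols.duplicated().any():
            dupes = sorted(cols[cols.duplicated()].unique().tolist())
            raise MatrixError(f"duplicate sample ids: {dupes[:10]}")
        arr = self.values.to_numpy()
        if arr.size and not np.issubdtype(arr.dtype, np.number):
            raise MatrixError("expression values must be numeric")
        if arr.size and np.isnan(arr.astype(float)).any():
            n_missing = int(np.isnan(arr.astype(float)).sum())
            raise MatrixError(f"expression matrix contains {n_missing} missing values")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        gene_ids = list(gene_ids)
        missing = [g for g in gene_ids if g not in self.values.index]
        if missing:
            raise MatrixError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values.loc[gene_ids], scale=self.scale)

    def with_scale(self, scale: Scale) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values, scale=scale)

    def copy(self) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.copy(), scale=self.scale)


DESIGN_COLUMNS = ("sample_id", "cancer_id", "condition", "replicate")


@dataclass
class StudyDesign:
    """Sample sheet mapping sample ids to (cancer, condition, replicate).

    ``reference`` names the gold-standard arm (fresh-frozen, ``FF`` by
    default) against which every other condition is compared.
    """

    table: pd.DataFrame
    reference: str = "FF"

    def __post_init__(self) -> None:
        missing = [c for c in DESIGN_COLUMNS if c not in self.table.columns]
        if missing:
            raise DesignError(f"design table missing columns: {missing}")
        self.table = self.table.loc[:, list(DESIGN_COLUMNS)].reset_index(drop=True)
        self.table["replicate"] = self.table["replicate"].astype(int)
        if self.table["sample_id"].duplicated().any():
            dupes = self.table.loc[self.table["sample_id"].duplicated(), "sample_id"]
            raise DesignError(f"duplicate sample ids: {sorted(dupes.unique().tolist())[:10]}")
        key = self.table[["cancer_id", "condition", "replicate"]]
        if key.duplicated().any():
            dupes = key[key.duplicated()].to_records(index=False).tolist()
            raise DesignError(f"duplicate (cancer, condition, replicate) rows: {dupes[:10]}")
        if self.reference not in set(self.table["condition"]):
            raise DesignError(
                f"reference condition {self.reference!r} absent from design "
                f"(found {sorted(set(self.table['condition']))})"
            )
        if not self.is_balanced():
            warnings.warn(
                "study design is unbalanced: not every cancer appears in every condition",
                stacklevel=2,
            )

    @property
    def cancers(self) -> list[str]:
        return sorted(self.table["cancer_id"].unique().tolist())

    @property
    def conditions(self) -> list[str]:
        """Condition labels with the reference first, others in sorted order."""
        others = sorted(c for c in self.table["condition"].unique() if c != self.reference)
        return [self.reference] + others

    @property
    def kits(self) -> list[str]:
        """Non-reference conditions (the FFPE extraction kits)."""
        return [c for c in self.conditions if c != self.reference]

    def is_balanced(self) -> bool:
        counts = self.table.groupby(["cancer_id", "condition"], sort=False).size()
        grid = counts.unstack(fill_value=0)
        if grid.shape[1] != self.table["condition"].nunique():
            return False
        return bool((grid.to_numpy() > 0).all()) and all(
            grid[c].nunique() == 1 for c in grid.columns
        )

    def samples_for(self, condition: str | None = None, cancer: str | None = None) -> list[str]:
        mask = pd.Series(True, index=self.table.index)
        if condition is not None:
            mask &= self.table["condition"] == condition
        if cancer is not None:
            mask &= self.table["cancer_id"] == cancer
        return self.table.loc[mask, "sample_id"].tolist()

    def replicates_per_condition(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for cond, grp in self.table.groupby("condition"):
            out[str(cond)] = int(grp.groupby("cancer_id").size().max())
        return out

    def cell_label(self, cancer: str, condition: str) -> str:
        return f"{cancer}_{condition}"

    def align(self, matrix: ExpressionMatrix) -> None:
        """Check that matrix columns and design samples coincide."""
        design_samples = set(self.table["sample_id"])
        matrix_samples = set(matrix.samples)
        if design_samples != matrix_samples:
            only_design = sorted(design_samples - matrix_samples)[:5]
            only_matrix = sorted(matrix_samples - design_samples)[:5]
            raise DesignError(
                "matrix columns and design samples differ: "
                f"design-only {only_design}, matrix-only {only_matrix}"
            )


def make_design(
    cancers: Sequence[str],
    conditions: Sequence[str],
    replicates: dict[str, int],
    reference: str = "FF",
) -> StudyDesign:
    """Build a fully crossed, balanced design table."""
    rows = []
    for cancer in cancers:
        for cond in conditions:
            n_rep = replicates[cond]
            if n_rep < 1:
                raise DesignError(f"replicate count for condition {cond!r} must be >= 1")
            for rep in range(1, n_rep + 1):
                rows.append(
                    {
                        "sample_id": f"{cancer}_{cond}_r{rep}",
                        "cancer_id": cancer,
                        "condition": cond,
                        "replicate": rep,
                    }
                )
    return StudyDesign(pd.DataFrame(rows), reference=reference)
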