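"""Readers and writers for the package's plain-text artifact formats.

Single dialect throughout: tab-separated UTF-8 text with '.' as the
decimal mark.  Expression matrices are gene x sample (first column gene
id, header row of sample ids); designs carry the four columns
(sample_id, cancer_id, condition, replicate); signatures are two-column
(gene_id, role) files, or one gene id per line for an informative-only
list.  Every writer's output is readable by the matching reader.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .matrix import DesignError, ExpressionMatrix, MatrixError, Scale, StudyDesign
from .signatures import GeneSignature
from .synthetic import QUALITY_RANGES


def read_expression_matrix(path: str | Path, scale: Scale = "log2") -> ExpressionMatrix:
    """Read a gene x sample TSV into a validated ExpressionMatrix."""
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype_backend="numpy_nullable")
    except Exception as exc:  # pandas raises various parse errors
        raise MatrixError(f"cannot parse {path}: {exc}") from exc
    if df.isna().any().any():
        rows = df.index[df.isna().any(axis=1)][:3].tolist()
        cols = df.columns[df.isna().any(axis=0)][:3].tolist()
        raise MatrixError(f"{path}: missing cells near rows {rows}, columns {cols}")
    try:
        values = df.astype(float)
    except (TypeError, ValueError) as exc:
        raise MatrixError(f"{path}: non-numeric cells ({exc})") from exc
    values.index = values.index.astype(str)
    values.index.name = "gene_id"
    values.columns = values.columns.astype(str)
    return ExpressionMatrix(values, scale=scale)


def write_expression_matrix(matrix: ExpressionMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t", float_format="%.10g")


def read_design(path: str | Path, reference: str = "FF") -> StudyDesign:
    """Read a sample sheet TSV into a validated StudyDesign."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "cancer_id": str, "condition": str})
    try:
        design = StudyDesign(df, reference=reference)
    except (DesignError, KeyError) as exc:
        raise DesignError(f"{path}: {exc}") from exc
    return design


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, sep="\t", index=False)


def read_signature(path: str | Path, name: str | None = None) -> GeneSignature:
    """Read a signature file: two-column (gene_id, role) or one id per line.

    Roles are restricted to ``informative`` and ``reference``; a bare gene
    list is treated as all-informative.
    """
    path = Path(path)
    informative: list[str] = []
    reference: list[str] = []
    for lineno, line in enumerate(path.read_text().strip().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 1:
            informative.append(parts[0].strip())
        elif len(parts) == 2:
            gene, role = parts[0].strip(), parts[1].strip()
            if role == "informative":
                informative.append(gene)
            elif role == "reference":
                reference.append(gene)
            else:
                raise ValueError(
                    f"{path}:{lineno}: role must be 'informative' or 'reference', got {role!r}"
                )
        else:
            raise ValueError(f"{path}:{lineno}: expected 1 or 2 tab-separated columns")
    return GeneSignature(name=name or path.stem, informative=informative, reference=reference)


def write_signature(sig: GeneSignature, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene in sig.informative:
            fh.write(f"{gene}\tinformative\n")
        for gene in sig.reference:
            fh.write(f"{gene}\treference\n")


def read_quality(path: str | Path) -> pd.DataFrame:
    """Read a per-sample quality table and enforce metric ranges."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: quality table needs a sample_id column")
    for metric, (lo, hi) in QUALITY_RANGES.items():
        if metric in df.columns:
            bad = df[(df[metric] < lo) | (df[metric] > hi)]
            if not bad.empty:
                raise ValueError(
                    f"{path}: {metric} outside [{lo}, {hi}] for samples "
                    f"{bad['sample_id'].tolist()[:5]}"
                )
    return df


def write_quality(quality: pd.DataFrame, path: str | Path) -> None:
    quality.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_json(obj: Mapping, path: str | Path) -> None:
    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, set):
            return sorted(o)
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_default)
        fh.write("\n")


def read_config(path: str | Path) -> dict:
    """Read a YAML (or JSON, a YAML subset) pipeline configuration."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg


def write_config(cfg: Mapping, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dict(cfg), fh, sort_keys=True)
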