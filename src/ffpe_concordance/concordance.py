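"""Agreement statistics between the fresh-frozen arm and each FFPE kit.

Lin's concordance correlation coefficient (CCC) measures agreement with the
identity line and factors into a precision term (Pearson r) and an accuracy
term C_b in (0, 1] that penalizes location and scale shifts:

    CCC = 2 s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) = r * C_b

with population (1/n) moments, following Lin's original estimator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix, StudyDesign


@dataclass(frozen=True)
class CCCResult:
    ccc: float
    pearson_r: float
    bias_term: float

    @property
    def defined(self) -> bool:
        return not math.isnan(self.ccc)

    def __iter__(self):
        return iter((self.ccc, self.pearson_r, self.bias_term))


def lin_ccc(x: Sequence[float], y: Sequence[float]) -> CCCResult:
    """Lin's concordance correlation coefficient with its decomposition.

    Uses population (1/n) moments.  If either vector has zero variance the
    statistic is undefined and all fields are NaN (``defined`` is False) —
    a degenerate input is flagged, never reported as agreement 0.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError(f"need at least 3 pairs, got {x.size}")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    mx, my = x.mean(), y.mean()
    dx, dy = x - mx, y - my
    sx2 = float(dx @ dx) / x.size
    sy2 = float(dy @ dy) / y.size
    sxy = float(dx @ dy) / x.size
    if sx2 == 0.0 or sy2 == 0.0:
        return CCCResult(math.nan, math.nan, math.nan)
    d2 = (mx - my) ** 2
    denom = sx2 + sy2 + d2
    ccc = 2.0 * sxy / denom
    r = sxy / math.sqrt(sx2 * sy2)
    cb = 2.0 * math.sqrt(sx2 * sy2) / denom
    return CCCResult(ccc, r, cb)


def concordance_table(
    avg_matrix: ExpressionMatrix,
    design: StudyDesign,
    kit: str,
) -> pd.DataFrame:
    """Per-gene CCC between the reference arm and one kit, across cancers.

    Expects the replicate-averaged matrix (one column per cancer x
    condition cell).  Cancers missing in either arm are dropped pairwise;
    the retained pair count is reported per gene in ``n_pairs``.  Genes
    with zero variance in either arm carry NaN statistics with
    ``defined = False``.
    """
    if kit == design.reference:
        raise ValueError("kit must differ from the reference condition")
    if kit not in design.conditions:
        raise ValueError(f"unknown condition {kit!r}")
    ref_rows = design.table[design.table["condition"] == design.reference]
    kit_rows = design.table[design.table["condition"] == kit]
    ref_by_cancer = dict(zip(ref_rows["cancer_id"], ref_rows["sample_id"]))
    kit_by_cancer = dict(zip(kit_rows["cancer_id"], kit_rows["sample_id"]))
    shared = [c for c in design.cancers if c in ref_by_cancer and c in kit_by_cancer]
    if len(shared) < 3:
        raise ValueError(f"need >= 3 cancers present in both arms, got {len(shared)}")

    X = avg_matrix.values[[ref_by_cancer[c] for c in shared]].to_numpy(dtype=float)
    Y = avg_matrix.values[[kit_by_cancer[c] for c in shared]].to_numpy(dtype=float)
    n = X.shape[1]
    mx = X.mean(axis=1)
    my = Y.mean(axis=1)
    dx = X - mx[:, None]
    dy = Y - my[:, None]
    sx2 = (dx * dx).sum(axis=1) / n
    sy2 = (dy * dy).sum(axis=1) / n
    sxy = (dx * dy).sum(axis=1) / n
    defined = (sx2 > 0) & (sy2 > 0)
    denom = sx2 + sy2 + (mx - my) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        ccc = np.where(defined, 2.0 * sxy / denom, np.nan)
        r = np.where(defined, sxy / np.sqrt(sx2 * sy2), np.nan)
        cb = np.where(defined, 2.0 * np.sqrt(sx2 * sy2) / denom, np.nan)
    return pd.DataFrame(
        {
            "ccc": ccc,
            "pearson_r": r,
            "bias_term": cb,
            "mean_ff": mx,
            "mean_kit": my,
            "n_pairs": n,
            "defined": defined,
        },
        index=avg_matrix.genes,
    )


def replicate_difference(matrix: ExpressionMatrix, design: StudyDesign) -> pd.DataFrame:
    """Median across cancers of the absolute replicate difference, per gene.

    For each gene and condition, |replicate_1 - replicate_2| is computed
    within every cancer (the mean pairwise absolute difference when a cell
    has more than two replicates) and the median across cancers is
    returned.  Conditions with a single replicate yield a NaN column.
    """
    design.align(matrix)
    out = {}
    for cond in design.conditions:
        rows = design.table[design.table["condition"] == cond]
        per_cancer = []
        for _, grp in rows.groupby("cancer_id"):
            cols = grp["sample_id"].tolist()
            if len(cols) < 2:
                continue
            vals = matrix.values[cols].to_numpy(dtype=float)
            if len(cols) == 2:
                diffs = np.abs(vals[:, 0] - vals[:, 1])
            else:
                i, j = np.triu_indices(len(cols), k=1)
                diffs = np.abs(vals[:, i] - vals[:, j]).mean(axis=1)
            per_cancer.append(diffs)
        if per_cancer:
            out[cond] = np.median(np.column_stack(per_cancer), axis=1)
        else:
            out[cond] = np.full(matrix.n_genes, np.nan)
    return pd.DataFrame(out, index=matrix.genes)


def mad(values: np.ndarray | pd.Series, scale: float = 1.0) -> float:
    """Median absolute deviation from the median (raw by default)."""
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size == 0:
        return math.nan
    return float(np.median(np.abs(v - np.median(v))) * scale)


def summarize_replicate_difference(per_gene: pd.DataFrame) -> pd.DataFrame:
    """Median and MAD across genes of the per-gene replicate difference."""
    rows = []
    for cond in per_gene.columns:
        v = per_gene[cond].to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        rows.append(
            {
                "condition": cond,
                "median_difference": float(np.median(finite)) if finite.size else math.nan,
                "mad_difference": mad(finite),
                "n_genes": int(finite.size),
            }
        )
    return pd.DataFrame(rows).set_index("condition")


def high_concordant_overlap(
    tables: Mapping[str, pd.DataFrame],
    expr_threshold: float = -7.5,
    ccc_threshold: float = 0.5,
) -> dict:
    """Overlap of high-expression, high-concordance genes across kits.

    Per kit, selects genes whose mean expression over the two arms exceeds
    ``expr_threshold`` and whose CCC exceeds ``ccc_threshold`` (both
    strictly).  ``percent_shared`` is 100 x |intersection| / |union| over
    all kits; an empty union is reported as NaN, never as 0.
    """
    sets: dict[str, set[str]] = {}
    for kit, table in tables.items():
        expr = (table["mean_ff"] + table["mean_kit"]) / 2.0
        mask = (expr > expr_threshold) & (table["ccc"] > ccc_threshold) & table["defined"]
        sets[kit] = set(table.index[mask])
    union: set[str] = set().union(*sets.values()) if sets else set()
    inter = set.intersection(*sets.values()) if sets else set()
    percent = 100.0 * len(inter) / len(union) if union else math.nan
    return {
        "per_kit": sets,
        "intersection": inter,
        "union": union,
        "percent_shared": percent,
    }


def summarize_by_group(
    table: pd.DataFrame,
    groups: Mapping[str, str],
    column: str = "ccc",
) -> pd.DataFrame:
    """Median and MAD of a concordance statistic per gene group.

    ``groups`` maps gene id -> label (e.g. chromosome or expression
    stratum).  Mapping entries for genes absent from the table are ignored
    and counted; table genes without a label are reported in
    ``n_ungrouped`` (as a DataFrame attribute).
    """
    labels = pd.Series({g: groups[g] for g in table.index if g in groups})
    if labels.empty:
        raise ValueError("groups cover no gene in the table")
    values = table.loc[labels.index, column]
    rows = []
    for label, idx in labels.groupby(labels).groups.items():
        v = values.loc[idx].to_numpy(dtype=float)
        finite = v[np.isfinite(v)]
        rows.append(
            {
                "group": label,
                "median": float(np.median(finite)) if finite.size else math.nan,
                "mad": mad(finite),
                "n": int(finite.size),
            }
        )
    out = pd.DataFrame(rows).set_index("group")
    out.attrs["n_ungrouped"] = int(len(table.index) - len(labels))
    out.attrs["n_unknown_ids"] = int(len([g for g in groups if g not in table.index]))
    return out


def bland_altman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement for paired scores.

    Differences are ``y - x``; bias is their mean and the limits are
    bias +/- 1.96 sd with the sample (n-1) standard deviation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors with at least 2 pairs")
    d = y - x
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd
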