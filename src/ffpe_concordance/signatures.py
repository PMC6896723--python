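"""Two-set gene-signature scoring and its expression-matched random null.

A signature score is the (optionally weighted) mean log2 expression of the
informative genes minus that of the reference genes, per sample — the
generic form of two-set breast-cancer indices such as EndoPredict, the
21-gene Recurrence Score and the SET ER/PR index.  Scores here are
unweighted by default: the proprietary coefficient sets of the commercial
assays are not public, so the bundled definitions carry gene lists only
and per-gene weights can be supplied by the user.

The random-signature null asks whether a signature's frozen-vs-FFPE
concordance is better than chance for gene sets of its size and expression
range: each of B draws replaces every informative gene with a random gene
from the same mean-expression quantile bin (sampling without replacement
within a draw, keeping the true reference panel), scores samples, averages
replicates and computes the same CCC statistic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np
import pandas as pd

from .concordance import CCCResult, lin_ccc
from .matrix import ExpressionMatrix, MatrixError, StudyDesign
from .preprocess import average_replicates

BUNDLED_SIGNATURES = ("endopredict", "recurrence_score", "set_erpr")


@dataclass
class GeneSignature:
    """Named two-set signature: informative genes scored against a reference panel."""

    name: str
    informative: list[str]
    reference: list[str]
    weights: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.informative:
            raise ValueError(f"signature {self.name!r} has no informative genes")
        overlap = set(self.informative) & set(self.reference)
        if overlap:
            raise ValueError(
                f"signature {self.name!r}: genes in both roles: {sorted(overlap)}"
            )
        if len(set(self.informative)) != len(self.informative):
            raise ValueError(f"signature {self.name!r} has duplicate informative genes")
        if len(set(self.reference)) != len(self.reference):
            raise ValueError(f"signature {self.name!r} has duplicate reference genes")

    @property
    def genes(self) -> list[str]:
        return list(self.informative) + list(self.reference)


def load_bundled_signature(name: str) -> GeneSignature:
    """Load one of the bundled breast-cancer signature definitions."""
    if name not in BUNDLED_SIGNATURES:
        raise ValueError(f"unknown bundled signature {name!r}; choose from {BUNDLED_SIGNATURES}")
    path = resources.files("ffpe_concordance.data.signatures").joinpath(f"{name}.tsv")
    informative, reference = [], []
    for line in path.read_text().strip().splitlines():
        gene, role = line.split("\t")
        if role == "informative":
            informative.append(gene)
        elif role == "reference":
            reference.append(gene)
        else:
            raise ValueError(f"bad role {role!r} in bundled signature {name}")
    return GeneSignature(name=name, informative=informative, reference=reference)


def _weighted_mean(block: pd.DataFrame, weights: Mapping[str, float] | None) -> pd.Series:
    if weights is None:
        return block.mean(axis=0)
    w = np.array([float(weights.get(g, 1.0)) for g in block.index])
    total = w.sum()
    if total == 0:
        raise ValueError("signature weights sum to zero")
    return pd.Series(block.to_numpy().T @ w / total, index=block.columns)


def score_signature(
    matrix: ExpressionMatrix,
    sig: GeneSignature,
    on_missing: str = "error",
) -> pd.Series:
    """Per-sample signature score on the log2 scale.

    score = mean(informative log2) - mean(reference log2), optionally
    weighted.  Missing genes raise by default (``on_missing="error"``) or
    are dropped with the remaining set (``on_missing="drop"``); dropping
    every informative gene is always an error.
    """
    if matrix.scale == "counts":
        raise MatrixError("score signatures on the log2 scale")
    present = set(matrix.genes)
    missing = [g for g in sig.genes if g not in present]
    if missing and on_missing == "error":
        raise MatrixError(f"signature {sig.name!r}: genes absent from matrix: {missing}")
    informative = [g for g in sig.informative if g in present]
    reference = [g for g in sig.reference if g in present]
    if not informative:
        raise MatrixError(f"signature {sig.name!r}: no informative genes left after dropping")
    score = _weighted_mean(matrix.values.loc[informative], sig.weights)
    if reference:
        score = score - _weighted_mean(matrix.values.loc[reference], sig.weights)
    score.name = sig.name
    return score


def signature_concordance(
    scores: pd.Series,
    design: StudyDesign,
) -> dict[str, CCCResult]:
    """FF-vs-kit concordance of a per-sample score, per kit.

    Replicate scores are averaged per (cancer, condition) cell first; the
    CCC is computed across cancers against the reference arm.
    """
    merged = design.table.assign(score=scores.loc[design.table["sample_id"]].to_numpy())
    cell = merged.groupby(["cancer_id", "condition"])["score"].mean().unstack()
    out: dict[str, CCCResult] = {}
    for kit in design.kits:
        pair = cell[[design.reference, kit]].dropna()
        out[kit] = lin_ccc(pair[design.reference], pair[kit])
    return out


@dataclass
class RandomSignatureNull:
    """Observed concordance statistic against its expression-matched null."""

    observed: float
    null: np.ndarray
    percentile: float
    B: int
    seed: int
    n_bins: int
    kit: str
    bin_sizes: dict[int, int] = field(default_factory=dict)


def _cell_arrays(
    matrix: ExpressionMatrix, design: StudyDesign
) -> tuple[np.ndarray, list[str], dict[str, list[int]]]:
    """Replicate-averaged value array plus per-condition cell columns."""
    avg, avg_design = average_replicates(matrix, design)
    cond_cols: dict[str, list[int]] = {}
    col_pos = {s: i for i, s in enumerate(avg.samples)}
    for cond in design.conditions:
        rows = avg_design.table[avg_design.table["condition"] == cond].sort_values("cancer_id")
        cond_cols[cond] = [col_pos[s] for s in rows["sample_id"]]
    return avg.values.to_numpy(dtype=float), list(avg.samples), cond_cols


def _ccc_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Lin CCC between matched (draws x cancers) matrices."""
    n = X.shape[1]
    mx = X.mean(axis=1)
    my = Y.mean(axis=1)
    dx = X - mx[:, None]
    dy = Y - my[:, None]
    sx2 = (dx * dx).sum(axis=1) / n
    sy2 = (dy * dy).sum(axis=1) / n
    sxy = (dx * dy).sum(axis=1) / n
    denom = sx2 + sy2 + (mx - my) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where((sx2 > 0) & (sy2 > 0), 2.0 * sxy / denom, np.nan)


def random_signature_null(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    sig: GeneSignature,
    kit: str,
    B: int = 10_000,
    n_bins: int = 10,
    seed: int = 0,
) -> RandomSignatureNull:
    """Expression-matched random-signature null for FF-vs-kit concordance.

    Genes are binned into ``n_bins`` quantile bins of mean expression; each
    draw replaces every informative gene with a distinct random gene from
    the same bin (the true reference panel is kept), scores samples,
    averages replicates and computes the FF-vs-``kit`` CCC across cancers.
    ``percentile`` is 100 x the fraction of null draws strictly below the
    observed CCC.  Deterministic given ``seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    if kit not in design.kits:
        raise ValueError(f"unknown kit {kit!r}; design kits: {design.kits}")
    if matrix.scale == "counts":
        raise MatrixError("run the null on the log2 scale")
    missing = [g for g in sig.genes if g not in set(matrix.genes)]
    if missing:
        raise MatrixError(f"signature {sig.name!r}: genes absent from matrix: {missing}")

    mean_expr = matrix.values.mean(axis=1)
    bins = pd.qcut(mean_expr, q=n_bins, labels=False, duplicates="drop")
    gene_pos = {g: i for i, g in enumerate(matrix.genes)}
    sig_bins = bins.loc[sig.informative]
    bin_needs = sig_bins.value_counts().to_dict()
    bin_members: dict[int, np.ndarray] = {}
    for b, need in bin_needs.items():
        members = np.array([gene_pos[g] for g in bins.index[bins == b]])
        # a bin holding only the signature's own genes yields a degenerate null
        if len(members) < need + 1:
            raise ValueError(
                f"expression bin {b} holds {len(members)} genes but the signature needs "
                f"{need}; use fewer bins"
            )
        bin_members[int(b)] = members

    V, _, cond_cols = _cell_arrays(matrix, design)
    ref_cols = cond_cols[design.reference]
    kit_cols = cond_cols[kit]
    ref_panel_rows = [gene_pos[g] for g in sig.reference]
    ref_panel_mean = V[ref_panel_rows].mean(axis=0) if ref_panel_rows else 0.0

    observed_rows = [gene_pos[g] for g in sig.informative]
    observed_score = V[observed_rows].mean(axis=0) - ref_panel_mean
    observed = float(
        _ccc_rows(observed_score[None, ref_cols], observed_score[None, kit_cols])[0]
    )

    rng = np.random.default_rng(seed)
    # per bin: B independent without-replacement draws via random-key argpartition
    draw_rows = np.empty((B, len(sig.informative)), dtype=int)
    col = 0
    for b, need in sorted(bin_needs.items()):
        members = bin_members[int(b)]
        keys = rng.random((B, len(members)))
        picked = np.argpartition(keys, need - 1, axis=1)[:, :need]
        draw_rows[:, col : col + need] = members[picked]
        col += need

    null = np.empty(B)
    chunk = max(1, min(B, 2000))
    for start in range(0, B, chunk):
        idx = draw_rows[start : start + chunk]
        scores = V[idx].mean(axis=1) - ref_panel_mean  # draws x cells
        null[start : start + chunk] = _ccc_rows(scores[:, ref_cols], scores[:, kit_cols])

    percentile = 100.0 * float(np.sum(null < observed)) / B
    return RandomSignatureNull(
        observed=observed,
        null=null,
        percentile=percentile,
        B=B,
        seed=seed,
        n_bins=n_bins,
        kit=kit,
        bin_sizes={int(b): len(m) for b, m in bin_members.items()},
    )


def replicate_percent_difference(
    scores: pd.Series,
    design: StudyDesign,
) -> pd.DataFrame:
    """Replicate disagreement of a score, as percent of its dynamic range.

    Per (cancer, condition) cell with at least two replicates:
    ``100 |score_rep1 - score_rep2| / range`` where the range is the spread
    (max - min) of replicate-averaged scores over all cells; the mean
    pairwise absolute difference is used for more than two replicates.  A
    zero score range makes the statistic undefined (all NaN).
    """
    merged = design.table.assign(score=scores.loc[design.table["sample_id"]].to_numpy())
    cell_means = merged.groupby(["cancer_id", "condition"])["score"].mean()
    score_range = float(cell_means.max() - cell_means.min())
    rows = []
    for (cancer, cond), grp in merged.groupby(["cancer_id", "condition"]):
        v = grp["score"].to_numpy(dtype=float)
        if v.size < 2:
            continue
        if v.size == 2:
            diff = abs(v[0] - v[1])
        else:
            i, j = np.triu_indices(v.size, k=1)
            diff = float(np.abs(v[i] - v[j]).mean())
        pct = 100.0 * diff / score_range if score_range > 0 else math.nan
        rows.append(
            {"cancer_id": cancer, "condition": cond, "abs_difference": diff, "percent": pct}
        )
    return pd.DataFrame(rows)


def median_percent_difference(per_cell: pd.DataFrame) -> pd.Series:
    """Median replicate percent difference per condition."""
    return per_cell.groupby("condition")["percent"].median()
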