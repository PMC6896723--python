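"""Paired differential analysis between conditions and related tests.

Expression differences between the fresh-frozen arm and each kit are
modeled per gene by ordinary least squares on the two-factor design

    value = Cancer + Kit

with the tumor as a blocking factor, after technical replicates have been
averaged.  The kit coefficient is the log2 fold change; kit-vs-kit
contrasts come from the same joint fit.  P-values are Benjamini-Hochberg
adjusted per contrast across genes.  This is a deliberately transparent
fixed-effects substitute for count-based negative-binomial machinery: on
reference-normalized log2 values with a balanced paired design the kit
coefficient is exactly the mean within-tumor log2 difference.
"""

from __future__ import annotations

import itertools
import math
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import DesignError, ExpressionMatrix, StudyDesign

_RESID_TOL = 1e-12


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    Sorted p-values ``p_(i)`` map to ``min_{j >= i} m p_(j) / j`` capped at
    1.  NaN entries propagate and do not count toward ``m``.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("p-values must be 1-D")
    finite = ~np.isnan(p)
    if ((p[finite] < 0) | (p[finite] > 1)).any():
        bad = p[finite][(p[finite] < 0) | (p[finite] > 1)][:5]
        raise ValueError(f"p-values outside [0, 1]: {bad}")
    out = np.full_like(p, np.nan)
    pv = p[finite]
    m = pv.size
    if m == 0:
        return out
    order = np.argsort(pv, kind="mergesort")
    ranked = pv[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    result = np.empty(m)
    result[order] = np.minimum(adjusted, 1.0)
    out[finite] = result
    return out


def _ols_design(design: StudyDesign) -> tuple[np.ndarray, list[str], dict[str, int]]:
    """Intercept + cancer dummies (first cancer dropped) + kit dummies."""
    table = design.table
    cancers = design.cancers
    kits = design.kits
    n = len(table)
    p = 1 + (len(cancers) - 1) + len(kits)
    D = np.zeros((n, p))
    D[:, 0] = 1.0
    cancer_pos = {c: i for i, c in enumerate(cancers)}
    for row_i, (_, row) in enumerate(table.iterrows()):
        ci = cancer_pos[row["cancer_id"]]
        if ci > 0:
            D[row_i, ci] = 1.0
        if row["condition"] != design.reference:
            D[row_i, len(cancers) + kits.index(row["condition"])] = 1.0
    kit_cols = {kit: len(cancers) + j for j, kit in enumerate(kits)}
    return D, table["sample_id"].tolist(), kit_cols


def paired_linear_fit(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    reference: str | None = None,
    alpha: float = 0.05,
    kit_contrasts: bool = True,
) -> pd.DataFrame:
    """Per-gene two-factor OLS (value = Cancer + Kit) with BH correction.

    Expects the replicate-averaged matrix.  Returns one row per gene per
    contrast with ``lfc``, ``p``, ``fdr`` and a ``significant`` flag at
    ``fdr < alpha``.  Genes with zero residual variance are flagged in the
    ``flag`` column: ``boundary`` (nonzero effect, p reported as 0) or
    ``undefined`` (no residual information).
    """
    if reference is not None and reference != design.reference:
        raise DesignError(
            f"reference {reference!r} does not match the design reference {design.reference!r}"
        )
    if len(design.cancers) < 2:
        raise DesignError("need at least 2 cancers for the paired fit")
    design.align(matrix)
    if (design.table.groupby(["cancer_id", "condition"]).size() > 1).any():
        raise DesignError("average technical replicates before the differential fit")

    D, sample_order, kit_cols = _ols_design(design)
    Y = matrix.values[sample_order].to_numpy(dtype=float)  # genes x samples
    n, p = D.shape
    dof = n - p
    DtD_inv = np.linalg.pinv(D.T @ D)
    H = DtD_inv @ D.T
    B = Y @ H.T  # genes x p
    resid = Y - B @ D.T
    rss = (resid**2).sum(axis=1)

    contrasts: list[tuple[str, np.ndarray]] = []
    for kit in design.kits:
        c = np.zeros(p)
        c[kit_cols[kit]] = 1.0
        contrasts.append((f"{kit}_vs_{design.reference}", c))
    if kit_contrasts:
        for k1, k2 in itertools.combinations(design.kits, 2):
            c = np.zeros(p)
            c[kit_cols[k2]] = 1.0
            c[kit_cols[k1]] = -1.0
            contrasts.append((f"{k2}_vs_{k1}", c))

    frames = []
    for name, c in contrasts:
        lfc = B @ c
        cvar = float(c @ DtD_inv @ c)
        if dof > 0:
            s2 = rss / dof
            se = np.sqrt(np.maximum(s2 * cvar, 0.0))
            with np.errstate(divide="ignore", invalid="ignore"):
                t = lfc / se
            pvals = 2.0 * stats.t.sf(np.abs(t), dof)
            flags = np.array([""] * len(lfc), dtype=object)
            degenerate = s2 <= _RESID_TOL
            boundary = degenerate & (np.abs(lfc) > 1e-10)
            undefined = degenerate & ~boundary
            pvals[boundary] = 0.0
            pvals[undefined] = np.nan
            flags[boundary] = "boundary"
            flags[undefined] = "undefined"
        else:
            pvals = np.full(len(lfc), np.nan)
            flags = np.array(["undefined"] * len(lfc), dtype=object)
        fdr = bh_adjust(pvals)
        frames.append(
            pd.DataFrame(
                {
                    "gene_id": matrix.genes,
                    "contrast": name,
                    "lfc": lfc,
                    "p": pvals,
                    "fdr": fdr,
                    "significant": fdr < alpha,
                    "flag": flags,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def count_degs(
    results: pd.DataFrame,
    lfc_thresholds: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Count significant genes per contrast at |LFC| thresholds.

    A gene counts toward threshold ``t`` when ``fdr < alpha`` and
    ``|lfc| > t``; up/down splits use the sign of the fold change.
    """
    rows = []
    for contrast, grp in results.groupby("contrast", sort=False):
        sig = grp[(grp["fdr"] < alpha) & grp["fdr"].notna()]
        for t in lfc_thresholds:
            hits = sig[sig["lfc"].abs() > t]
            rows.append(
                {
                    "contrast": contrast,
                    "lfc_threshold": t,
                    "n_deg": len(hits),
                    "n_up": int((hits["lfc"] > 0).sum()),
                    "n_down": int((hits["lfc"] < 0).sum()),
                }
            )
    return pd.DataFrame(rows)


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U with a small-sample exact two-sided p-value.

    ``U`` counts pairs where x exceeds y (midranks for ties).  For tie-free
    samples with ``n + m <= 12`` the two-sided p is exact by enumeration of
    all labelings (fraction with ``|U - mn/2|`` at least as large as
    observed); otherwise the normal approximation with tie and continuity
    corrections is used.  Identical samples give p = 1.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be non-empty")
    n, m = x.size, y.size
    pooled = np.concatenate([x, y])
    ranks = stats.rankdata(pooled)
    r_x = float(ranks[:n].sum())
    u = r_x - n * (n + 1) / 2.0
    has_ties = np.unique(pooled).size < pooled.size
    center = n * m / 2.0

    if not has_ties and n + m <= 12:
        observed_dev = abs(u - center)
        positions = np.arange(1, n + m + 1, dtype=float)
        count = 0
        total = 0
        for combo in itertools.combinations(range(n + m), n):
            u_perm = positions[list(combo)].sum() - n * (n + 1) / 2.0
            if abs(u_perm - center) >= observed_dev - 1e-12:
                count += 1
            total += 1
        return u, count / total

    N = n + m
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts).sum())) / (N * (N - 1)) if N > 1 else 0.0
    var_u = n * m / 12.0 * ((N + 1) - tie_term)
    if var_u <= 0:
        return u, 1.0
    dev = max(abs(u - center) - 0.5, 0.0)  # continuity correction
    z = dev / math.sqrt(var_u)
    return u, min(2.0 * stats.norm.sf(z), 1.0)


def quality_index_effects(
    quality: pd.DataFrame,
    design: StudyDesign,
    metrics: Sequence[str] = ("RIN", "DV200", "medTIN"),
) -> pd.DataFrame:
    """Kit effects on RNA-quality indices via the paired two-factor model.

    Replicate metrics are averaged per (cancer, condition) cell, then each
    index is fitted with ``value = Cancer + Kit`` and the kit coefficients
    are tested; BH adjustment is applied within each index across kits.
    A constant index yields flagged, undefined tests.
    """
    missing = [m for m in metrics if m not in quality.columns]
    if missing:
        raise ValueError(f"quality table missing metrics: {missing}")
    merged = design.table.merge(quality, on="sample_id", validate="one_to_one")
    cell = merged.groupby(["cancer_id", "condition"], as_index=False)[list(metrics)].mean()
    cell["sample_id"] = cell["cancer_id"] + "_" + cell["condition"]
    cell["replicate"] = 1
    cell_design = StudyDesign(
        cell[["sample_id", "cancer_id", "condition", "replicate"]].copy(),
        reference=design.reference,
    )
    rows = []
    for metric in metrics:
        values = pd.DataFrame(
            [cell.set_index("sample_id")[metric]], index=pd.Index([metric], name="metric")
        )
        em = ExpressionMatrix(values, scale="log2")  # linear model on the metric scale
        res = paired_linear_fit(em, cell_design, kit_contrasts=False)
        res = res.rename(columns={"gene_id": "metric", "lfc": "effect"})
        res["fdr"] = bh_adjust(res["p"].to_numpy())
        res["significant"] = res["fdr"] < 0.05
        rows.append(res)
    return pd.concat(rows, ignore_index=True)
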