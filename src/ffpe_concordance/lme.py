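"""REML estimation of the per-gene reliability mixed model.

For each gene (or signature score) the model is

    Y = Kit + (Kit | Cancer) + (1 | RepWcancer)

on the normalized log2 scale: a fixed kit effect (fresh-frozen arm as the
reference level, so the kit coefficients are the systematic FFPE-vs-frozen
biases), a per-cancer random intercept with per-kit random slopes (the
across-tumor variability of each kit's bias), an optional per-cell
intercept grouping the technical replicates of one tumor x kit cell, and
replicate noise.

The default random-slope covariance is diagonal: independent per-kit slope
variances tau_k^2 on top of a shared cancer intercept variance sigma_a^2.
A full (K+1) x (K+1) covariance over intercept and slopes is available via
``structure="full"`` but is hard to estimate stably from ~12 cancers.  The
cell intercept is weakly identified with duplicate extractions (it is
aliased with the slope variance within each cancer) and is off by default.

Variances are optimized on the log scale with L-BFGS-B from a
method-of-moments start; the restricted likelihood includes its constant
term, so reported ``minus2_reml`` values are comparable across
implementations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize

from .matrix import DesignError, ExpressionMatrix, StudyDesign

LOG2PI = math.log(2.0 * math.pi)
_VAR_FLOOR = 1e-12
_BOUNDARY_TOL = 1e-8


@dataclass
class LMEResult:
    """Fitted variance decomposition for one gene or signature score."""

    unit_id: str
    intercept: float
    bias: dict[str, float]  # kit -> fixed bias vs the reference arm
    slope_var: dict[str, float]  # kit -> tau_k^2
    sigma_a2: float
    sigma_e2: float
    sigma_u2: float
    minus2_reml: float
    converged: bool
    n_obs: int
    boundary: list[str] = field(default_factory=list)
    message: str = ""


class _DesignInfo:
    """Pre-computed per-cancer block structure for repeated fits."""

    def __init__(self, design: StudyDesign, include_slopes: bool = True, include_cell: bool = False):
        self.design = design
        self.kits = design.kits
        self.include_slopes = include_slopes
        self.include_cell = include_cell
        table = design.table.copy()
        cond_order = {c: i for i, c in enumerate(design.conditions)}
        table["_cond_ord"] = table["condition"].map(cond_order)
        table = table.sort_values(["cancer_id", "_cond_ord", "replicate"]).reset_index(drop=True)
        self.sample_order = table["sample_id"].tolist()
        self.groups: list[np.ndarray] = []  # row slices into sample_order per cancer
        self.block_X: list[np.ndarray] = []
        self.block_Zslope: list[np.ndarray] = []
        self.block_Zcell: list[np.ndarray] = []
        keys = []
        pos = 0
        for cancer, grp in table.groupby("cancer_id", sort=True):
            n_c = len(grp)
            idx = np.arange(pos, pos + n_c)
            pos += n_c
            conds = grp["condition"].tolist()
            X = np.ones((n_c, 1 + len(self.kits)))
            for j, kit in enumerate(self.kits):
                X[:, 1 + j] = [1.0 if c == kit else 0.0 for c in conds]
            Zs = X[:, 1:].copy()  # slope design = kit indicators
            cells = grp.groupby(["condition"], sort=False).ngroup().to_numpy()
            Zc = np.zeros((n_c, cells.max() + 1))
            Zc[np.arange(n_c), cells] = 1.0
            self.groups.append(idx)
            self.block_X.append(X)
            self.block_Zslope.append(Zs)
            self.block_Zcell.append(Zc)
            keys.append(tuple(zip(conds, grp["replicate"].tolist())))
        self.n_obs = pos
        self.p = 1 + len(self.kits)
        self.identical_blocks = len(set(keys)) == 1
        self.n_groups = len(self.groups)

    def reorder(self, y: pd.Series | np.ndarray, sample_ids: Sequence[str] | None = None) -> np.ndarray:
        if isinstance(y, pd.Series):
            return y.loc[self.sample_order].to_numpy(dtype=float)
        if sample_ids is None:
            raise ValueError("sample_ids required for a bare array")
        lookup = {s: i for i, s in enumerate(sample_ids)}
        return np.asarray(y, dtype=float)[[lookup[s] for s in self.sample_order]]

    # -- covariance assembly ------------------------------------------------

    def n_var_params(self, structure: str) -> int:
        k = len(self.kits)
        if structure == "diagonal":
            base = 1 + (k if self.include_slopes else 0)
        elif structure == "full":
            q = 1 + (k if self.include_slopes else 0)
            base = q * (q + 1) // 2
        else:
            raise ValueError(f"unknown structure {structure!r}")
        return base + 1 + (1 if self.include_cell else 0)  # + sigma_e2 (+ sigma_u2)

    def block_cov(self, g: int, params: np.ndarray, structure: str) -> np.ndarray:
        """Marginal covariance of one cancer's observations."""
        X = self.block_X[g]
        Zs = self.block_Zslope[g]
        n_c = X.shape[0]
        k = len(self.kits)
        ones = np.ones((n_c, 1))
        if structure == "diagonal":
            sigma_a2 = params[0]
            taus = params[1 : 1 + k] if self.include_slopes else np.zeros(k)
            off = (1 + k) if self.include_slopes else 1
            V = sigma_a2 * (ones @ ones.T)
            for j in range(k):
                V += taus[j] * np.outer(Zs[:, j], Zs[:, j])
        else:  # full: params hold a lower-triangular Cholesky of G
            q = 1 + (k if self.include_slopes else 0)
            L = np.zeros((q, q))
            tri = np.tril_indices(q)
            L[tri] = params[: q * (q + 1) // 2]
            G = L @ L.T
            Z = np.hstack([ones, Zs[:, : q - 1]])
            V = Z @ G @ Z.T
            off = q * (q + 1) // 2
        sigma_e2 = params[off]
        V = V + sigma_e2 * np.eye(n_c)
        if self.include_cell:
            sigma_u2 = params[off + 1]
            Zc = self.block_Zcell[g]
            V = V + sigma_u2 * (Zc @ Zc.T)
        return V


def _pack_theta(params: np.ndarray, structure: str, info: _DesignInfo) -> np.ndarray:
    """Map raw variance-scale parameters to the unconstrained optimizer scale."""
    if structure == "diagonal":
        return np.log(np.maximum(params, _VAR_FLOOR))
    # full: diagonal Cholesky entries on the log scale, off-diagonals free
    k = len(info.kits) if info.include_slopes else 0
    q = 1 + k
    m = q * (q + 1) // 2
    theta = params.copy()
    tri = np.tril_indices(q)
    diag_positions = [i for i, (r, c) in enumerate(zip(*tri)) if r == c]
    for i in diag_positions:
        theta[i] = math.log(max(theta[i], math.sqrt(_VAR_FLOOR)))
    theta[m:] = np.log(np.maximum(theta[m:], _VAR_FLOOR))
    return theta


def _unpack_theta(theta: np.ndarray, structure: str, info: _DesignInfo) -> np.ndarray:
    if structure == "diagonal":
        return np.exp(theta)
    k = len(info.kits) if info.include_slopes else 0
    q = 1 + k
    m = q * (q + 1) // 2
    params = theta.copy()
    tri = np.tril_indices(q)
    diag_positions = [i for i, (r, c) in enumerate(zip(*tri)) if r == c]
    for i in diag_positions:
        params[i] = math.exp(theta[i])
    params[m:] = np.exp(theta[m:])
    return params


def minus2_reml(
    params: np.ndarray,
    y: np.ndarray,
    info: _DesignInfo,
    structure: str = "diagonal",
) -> float:
    """-2 x restricted log-likelihood at the given variance parameters.

    ``y`` must already be in the block order of ``info``; fixed effects are
    profiled out by GLS and the restricted criterion includes its constant
    term ``(n - p) log 2 pi``.
    """
    p = info.p
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    ytViy = 0.0
    logdetV = 0.0
    if info.identical_blocks and structure == "diagonal":
        V0 = info.block_cov(0, params, structure)
        try:
            L = linalg.cholesky(V0, lower=True)
        except linalg.LinAlgError:
            return math.inf
        A = linalg.solve_triangular(L, info.block_X[0], lower=True)
        logdetV = 2.0 * info.n_groups * float(np.log(np.diag(L)).sum())
        XtViX = info.n_groups * (A.T @ A)
        n_c = V0.shape[0]
        Y = y.reshape(info.n_groups, n_c).T  # columns are cancers
        W = linalg.solve_triangular(L, Y, lower=True)
        ytViy = float((W * W).sum())
        XtViy = A.T @ W.sum(axis=1)
    else:
        for g, idx in enumerate(info.groups):
            V = info.block_cov(g, params, structure)
            try:
                L = linalg.cholesky(V, lower=True)
            except linalg.LinAlgError:
                return math.inf
            A = linalg.solve_triangular(L, info.block_X[g], lower=True)
            w = linalg.solve_triangular(L, y[idx], lower=True)
            logdetV += 2.0 * float(np.log(np.diag(L)).sum())
            XtViX += A.T @ A
            XtViy += A.T @ w
            ytViy += float(w @ w)
    sign, logdet_xvx = np.linalg.slogdet(XtViX)
    if sign <= 0:
        return math.inf
    try:
        beta = np.linalg.solve(XtViX, XtViy)
    except np.linalg.LinAlgError:
        return math.inf
    quad = ytViy - float(XtViy @ beta)
    n = info.n_obs
    return logdetV + logdet_xvx + quad + (n - p) * LOG2PI


def _gls_beta(params: np.ndarray, y: np.ndarray, info: _DesignInfo, structure: str) -> np.ndarray:
    p = info.p
    XtViX = np.zeros((p, p))
    XtViy = np.zeros(p)
    for g, idx in enumerate(info.groups):
        V = info.block_cov(g, params, structure)
        L = linalg.cholesky(V, lower=True)
        A = linalg.solve_triangular(L, info.block_X[g], lower=True)
        w = linalg.solve_triangular(L, y[idx], lower=True)
        XtViX += A.T @ A
        XtViy += A.T @ w
    return np.linalg.solve(XtViX, XtViy)


def balanced_closed_form(
    y: pd.Series | np.ndarray,
    design: StudyDesign,
    sample_ids: Sequence[str] | None = None,
) -> dict:
    """Method-of-moments estimates for a balanced replicated design.

    Residual variance is half the mean squared replicate difference (the
    pooled within-cell variance); kit biases are mean cell-mean contrasts
    against the reference arm; each slope variance is the between-cancer
    variance of the (kit - reference) cell differences minus the
    replicate-noise contribution, floored at zero.
    """
    if not design.is_balanced():
        raise DesignError("design is unbalanced; use fit_lme_single for REML estimation")
    if isinstance(y, pd.Series):
        series = y
    else:
        if sample_ids is None:
            raise ValueError("sample_ids required for a bare array")
        series = pd.Series(np.asarray(y, dtype=float), index=list(sample_ids))
    table = design.table
    values = series.loc[table["sample_id"]].to_numpy(dtype=float)
    df = table.assign(value=values)

    cell = df.groupby(["cancer_id", "condition"])["value"]
    cell_means = cell.mean().unstack()  # cancers x conditions
    reps = design.replicates_per_condition()

    # pooled within-cell variance = sigma_e^2
    sse = 0.0
    dof = 0
    for _, grp in df.groupby(["cancer_id", "condition"]):
        v = grp["value"].to_numpy()
        if v.size >= 2:
            sse += float(((v - v.mean()) ** 2).sum())
            dof += v.size - 1
    sigma_e2 = sse / dof if dof else 0.0

    ref = design.reference
    bias: dict[str, float] = {}
    slope_var: dict[str, float] = {}
    for kit in design.kits:
        d = cell_means[kit] - cell_means[ref]
        bias[kit] = float(d.mean())
        noise = sigma_e2 * (1.0 / reps[kit] + 1.0 / reps[ref])
        raw = float(d.var(ddof=1)) - noise if len(d) > 1 else 0.0
        slope_var[kit] = max(raw, 0.0)
    sigma_a2 = max(float(cell_means[ref].var(ddof=1)) - sigma_e2 / reps[ref], 0.0)
    return {
        "intercept": float(cell_means[ref].mean()),
        "bias": bias,
        "slope_var": slope_var,
        "sigma_a2": sigma_a2,
        "sigma_e2": sigma_e2,
    }


def fit_lme_single(
    y: pd.Series | np.ndarray,
    design: StudyDesign,
    structure: str = "diagonal",
    include_cell: bool = False,
    include_slopes: bool = True,
    sample_ids: Sequence[str] | None = None,
    unit_id: str = "",
    tol: float = 1e-8,
    _info: _DesignInfo | None = None,
) -> LMEResult:
    """REML fit of the reliability model for one response vector.

    ``y`` is one observation per design row (a pandas Series indexed by
    sample id, or an array with ``sample_ids``).  Returns fixed kit biases,
    variance components and the -2 restricted log-likelihood; variance
    estimates pinned at the zero boundary are listed in ``boundary``.
    """
    if len(design.conditions) < 2:
        raise DesignError("need at least 2 conditions")
    if len(design.cancers) < 2:
        raise DesignError("need at least 2 cancers")
    info = _info or _DesignInfo(design, include_slopes=include_slopes, include_cell=include_cell)
    yy = info.reorder(y, sample_ids)
    if not np.isfinite(yy).all():
        raise ValueError("response contains non-finite values")

    k = len(info.kits)
    # degenerate exact-fit case: the fixed effects explain y perfectly, so
    # every variance sits at the boundary and GLS reduces to OLS
    X_full = np.vstack(info.block_X)
    y_scale = max(float(np.max(np.abs(yy))), 1.0)
    beta_ols, *_ = np.linalg.lstsq(X_full, yy, rcond=None)
    if float(np.max(np.abs(yy - X_full @ beta_ols))) < 1e-10 * y_scale:
        floor_params = np.full(info.n_var_params(structure if structure == "diagonal" else "diagonal"), _VAR_FLOOR)
        crit = minus2_reml(floor_params, yy, info, "diagonal")
        return LMEResult(
            unit_id=unit_id,
            intercept=float(beta_ols[0]),
            bias={kit: float(b) for kit, b in zip(info.kits, beta_ols[1:])},
            slope_var={kit: _VAR_FLOOR for kit in info.kits},
            sigma_a2=_VAR_FLOOR,
            sigma_e2=_VAR_FLOOR,
            sigma_u2=_VAR_FLOOR if include_cell else 0.0,
            minus2_reml=crit,
            converged=True,
            n_obs=info.n_obs,
            boundary=["sigma_a2"] + [f"tau2_{kit}" for kit in info.kits] + ["sigma_e2"],
            message="exact fixed-effect fit; variances at the zero boundary",
        )
    # method-of-moments start (fall back to simple pooled moments if unbalanced)
    try:
        mom = balanced_closed_form(y, design, sample_ids)
        start_sa = mom["sigma_a2"]
        start_tau = np.array([mom["slope_var"][kit] for kit in info.kits])
        start_se = mom["sigma_e2"]
    except DesignError:
        v = float(np.var(yy)) or 1.0
        start_sa, start_tau, start_se = v / 3, np.full(k, v / 3), v / 3
    scale = max(float(np.var(yy)), 1e-6)
    floor0 = 1e-4 * scale

    if structure == "diagonal":
        params0 = [max(start_sa, floor0)]
        if include_slopes:
            params0 += [max(t, floor0) for t in start_tau]
        params0.append(max(start_se, floor0))
        if include_cell:
            params0.append(floor0)
        params0 = np.asarray(params0)
    elif structure == "full":
        q = 1 + (k if include_slopes else 0)
        G0 = np.diag(
            [max(start_sa, floor0)] + ([max(t, floor0) for t in start_tau] if include_slopes else [])
        )
        L0 = np.linalg.cholesky(G0)
        tri = np.tril_indices(q)
        params0 = list(L0[tri]) + [max(start_se, floor0)]
        if include_cell:
            params0.append(floor0)
        params0 = np.asarray(params0)
    else:
        raise ValueError(f"unknown structure {structure!r}")

    theta0 = _pack_theta(params0, structure, info)
    f0 = minus2_reml(_unpack_theta(theta0, structure, info), yy, info, structure)

    def objective(theta: np.ndarray) -> float:
        val = minus2_reml(_unpack_theta(theta, structure, info), yy, info, structure)
        # finite surrogate keeps the quasi-Newton line search stable
        return val if math.isfinite(val) else 1e30

    lo, hi = math.log(_VAR_FLOOR), math.log(1e6)
    if structure == "diagonal":
        bounds = [(lo, hi)] * theta0.size
    else:
        q = 1 + (k if include_slopes else 0)
        m = q * (q + 1) // 2
        tri = np.tril_indices(q)
        bounds = []
        for i, (r, c) in enumerate(zip(*tri)):
            bounds.append((lo / 2, hi / 2) if r == c else (-1e3, 1e3))
        bounds += [(lo, hi)] * (theta0.size - m)

    res = optimize.minimize(
        objective,
        theta0,
        method="L-BFGS-B",
        bounds=bounds,
        options={"ftol": 1e-13, "gtol": tol, "maxiter": 500},
    )
    theta_hat, f_hat = res.x, float(res.fun)
    converged = bool(res.success)
    message = str(res.message)
    if not converged:
        # line searches on nearly flat REML surfaces end abnormally; a
        # derivative-free polish from the same point settles the optimum
        polish = optimize.minimize(
            objective,
            np.clip(theta_hat, [b[0] for b in bounds], [b[1] for b in bounds]),
            method="Nelder-Mead",
            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 2000},
        )
        if float(polish.fun) <= f_hat + 1e-12:
            theta_hat, f_hat = polish.x, float(polish.fun)
            converged = bool(polish.success)
            message = str(polish.message)
    if not math.isfinite(f_hat) or f_hat > f0 + 1e-10:
        # descent guarantee: never report a point worse than the start
        theta_hat, f_hat = theta0, f0
        converged = False
        message = f"optimizer failed to improve on the moment start ({message})"
    params_hat = _unpack_theta(theta_hat, structure, info)
    beta = _gls_beta(params_hat, yy, info, structure)

    if structure == "diagonal":
        sigma_a2 = float(params_hat[0])
        taus = params_hat[1 : 1 + k] if include_slopes else np.zeros(k)
        off = (1 + k) if include_slopes else 1
    else:
        q = 1 + (k if include_slopes else 0)
        m = q * (q + 1) // 2
        Lhat = np.zeros((q, q))
        Lhat[np.tril_indices(q)] = params_hat[:m]
        G = Lhat @ Lhat.T
        sigma_a2 = float(G[0, 0])
        taus = np.diag(G)[1:] if include_slopes else np.zeros(k)
        off = m
    sigma_e2 = float(params_hat[off])
    sigma_u2 = float(params_hat[off + 1]) if include_cell else 0.0

    boundary = []
    if sigma_a2 <= _BOUNDARY_TOL:
        boundary.append("sigma_a2")
    for kit, t in zip(info.kits, taus):
        if include_slopes and t <= _BOUNDARY_TOL:
            boundary.append(f"tau2_{kit}")
    if sigma_e2 <= _BOUNDARY_TOL:
        boundary.append("sigma_e2")
    if include_cell and sigma_u2 <= _BOUNDARY_TOL:
        boundary.append("sigma_u2")

    return LMEResult(
        unit_id=unit_id,
        intercept=float(beta[0]),
        bias={kit: float(b) for kit, b in zip(info.kits, beta[1:])},
        slope_var={kit: float(t) for kit, t in zip(info.kits, taus)},
        sigma_a2=sigma_a2,
        sigma_e2=sigma_e2,
        sigma_u2=sigma_u2,
        minus2_reml=f_hat,
        converged=converged,
        n_obs=info.n_obs,
        boundary=boundary,
        message=message,
    )


def fit_lme_all(
    matrix: ExpressionMatrix,
    design: StudyDesign,
    structure: str = "diagonal",
    include_cell: bool = False,
    max_nonconverged_frac: float = 0.5,
) -> tuple[pd.DataFrame, dict]:
    """Fit the reliability model to every gene of a replicated matrix.

    Returns a per-gene table (bias and slope variance per kit, shared
    variance components, -2 REML, convergence flag) and a summary with the
    per-kit medians and MADs of the bias magnitude and slope variance plus
    the convergence rate.  Aborts if more than ``max_nonconverged_frac`` of
    genes fail to converge.
    """
    if matrix.scale == "counts":
        raise ValueError("fit the model on (normalized) log2 values, not raw counts")
    design.align(matrix)
    info = _DesignInfo(design, include_slopes=True, include_cell=include_cell)
    sample_ids = list(matrix.samples)
    values = matrix.values.to_numpy(dtype=float)
    rows = []
    n_bad = 0
    for i, gene in enumerate(matrix.genes):
        res = fit_lme_single(
            values[i],
            design,
            structure=structure,
            include_cell=include_cell,
            sample_ids=sample_ids,
            unit_id=str(gene),
            _info=info,
        )
        if not res.converged:
            n_bad += 1
        row = {
            "gene_id": gene,
            "sigma_a2": res.sigma_a2,
            "sigma_e2": res.sigma_e2,
            "sigma_u2": res.sigma_u2,
            "minus2_reml": res.minus2_reml,
            "converged": res.converged,
        }
        for kit in design.kits:
            row[f"bias_{kit}"] = res.bias[kit]
            row[f"tau2_{kit}"] = res.slope_var[kit]
        rows.append(row)
    table = pd.DataFrame(rows).set_index("gene_id")
    frac_bad = n_bad / max(len(rows), 1)
    if frac_bad > max_nonconverged_frac:
        raise RuntimeError(
            f"{frac_bad:.0%} of gene fits failed to converge "
            f"(limit {max_nonconverged_frac:.0%})"
        )
    from .concordance import mad  # local import to avoid cycle at module load

    summary: dict = {"convergence_rate": 1.0 - frac_bad, "n_genes": len(rows)}
    for kit in design.kits:
        b = table[f"bias_{kit}"].to_numpy()
        t = table[f"tau2_{kit}"].to_numpy()
        summary[kit] = {
            "median_bias": float(np.median(b)),
            "mad_bias": mad(b),
            "median_abs_bias": float(np.median(np.abs(b))),
            "median_variance": float(np.median(t)),
            "mad_variance": mad(t),
        }
    summary["median_sigma_e2"] = float(np.median(table["sigma_e2"]))
    return table, summary
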