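"""REML reliability model: exact limits, oracles, recovery, invariances."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import optimize

from ffpe_concordance import (
    DesignError,
    SimulationConfig,
    balanced_closed_form,
    fit_lme_all,
    fit_lme_single,
    make_design,
    simulate_study,
)
from ffpe_concordance.lme import LOG2PI, _DesignInfo, minus2_reml


# --- independent oracle: dense restricted likelihood built from scratch -----

def dense_minus2_reml(variances, y, design):
    """-2 REML via full n x n matrices, no block shortcuts.

    ``variances`` = (sigma_a2, tau2 per kit..., sigma_e2).  Independent of
    the package's block-wise evaluation: builds X, Z and V explicitly and
    uses slogdet/solve on the dense system.
    """
    table = design.table
    y = np.asarray([y[s] for s in table["sample_id"]], dtype=float)
    cancers = design.cancers
    kits = design.kits
    sigma_a2, *tau2, sigma_e2 = variances
    n = len(table)
    X = np.ones((n, 1 + len(kits)))
    V = sigma_e2 * np.eye(n)
    for j, kit in enumerate(kits):
        X[:, 1 + j] = (table["condition"] == kit).to_numpy(float)
    for cancer in cancers:
        z_int = (table["cancer_id"] == cancer).to_numpy(float)
        V += sigma_a2 * np.outer(z_int, z_int)
        for j, kit in enumerate(kits):
            z_slope = z_int * (table["condition"] == kit).to_numpy(float)
            V += tau2[j] * np.outer(z_slope, z_slope)
    sign, logdetV = np.linalg.slogdet(V)
    if sign <= 0:
        return math.inf
    Vi = np.linalg.inv(V)
    XtViX = X.T @ Vi @ X
    sign2, logdetX = np.linalg.slogdet(XtViX)
    if sign2 <= 0:
        return math.inf
    beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
    resid = y - X @ beta
    quad = float(resid @ Vi @ resid)
    p = X.shape[1]
    return logdetV + logdetX + quad + (n - p) * LOG2PI


def oracle_minimum(y, design, n_grid=4):
    """Grid seed + Nelder-Mead polish of the dense restricted likelihood."""
    kits = design.kits
    k = len(kits)

    def objective(log_v):
        return dense_minus2_reml(np.exp(log_v), y, design)

    grid_axis = np.log([1e-4, 1e-2, 0.05, 0.3])[:n_grid]
    best = (math.inf, None)
    for combo in itertools.product(grid_axis, repeat=2 + k):
        val = objective(np.asarray(combo))
        if val < best[0]:
            best = (val, np.asarray(combo))
    res = optimize.minimize(
        objective, best[1], method="Nelder-Mead",
        options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 5000, "maxfev": 8000},
    )
    return min(best[0], float(res.fun))


@pytest.fixture(scope="module")
def two_kit_study():
    config = SimulationConfig(
        n_genes=30, n_reference_genes=3, n_cancers=8, seed=17,
        conditions=("FF", "N", "Q"),
        kit_bias=0.3, kit_bias_sd=0.2, slope_sd=0.3, replicate_sd=0.15,
    )
    return simulate_study(config)


class TestZeroNoise:
    def test_bias_equals_mean_difference_and_variances_vanish(self, zero_noise_study):
        _, matrix, design, truth = zero_noise_study
        y = matrix.values.iloc[0]
        res = fit_lme_single(y, design, unit_id="g1")
        cell = design.table.assign(value=y.loc[design.table["sample_id"]].to_numpy())
        means = cell.groupby("condition")["value"].mean()
        for kit in design.kits:
            assert res.bias[kit] == pytest.approx(means[kit] - means["FF"], abs=1e-8)
            assert res.slope_var[kit] <= 1e-8
        assert res.sigma_a2 <= 1e-8
        assert res.sigma_e2 <= 1e-8
        assert set(res.boundary) >= {"sigma_e2"}


class TestRemlOracle:
    def test_matches_dense_grid_search_minimum(self, two_kit_study):
        """Returned -2 REML agrees with an independent optimizer to 1e-4."""
        matrix, design, _ = two_kit_study
        for i in range(5):
            y = matrix.values.iloc[i]
            res = fit_lme_single(y, design, unit_id=str(i))
            oracle = oracle_minimum(y, design)
            assert res.minus2_reml == pytest.approx(oracle, abs=1e-4)

    def test_block_evaluation_equals_dense_evaluation(self, two_kit_study):
        """The package criterion and the dense oracle agree pointwise."""
        matrix, design, _ = two_kit_study
        info = _DesignInfo(design)
        y = matrix.values.iloc[3]
        yy = info.reorder(y)
        for variances in ([0.5, 0.1, 0.2, 0.02], [0.01, 0.3, 0.01, 0.1]):
            mine = minus2_reml(np.asarray(variances), yy, info)
            dense = dense_minus2_reml(variances, y, design)
            assert mine == pytest.approx(dense, rel=1e-10)

    def test_descent_from_moment_start(self, two_kit_study):
        matrix, design, _ = two_kit_study
        info = _DesignInfo(design)
        for i in range(8):
            y = matrix.values.iloc[i]
            mom = balanced_closed_form(y, design)
            start = np.asarray(
                [max(mom["sigma_a2"], 1e-8)]
                + [max(mom["slope_var"][k], 1e-8) for k in design.kits]
                + [max(mom["sigma_e2"], 1e-8)]
            )
            f_start = minus2_reml(start, info.reorder(y), info)
            res = fit_lme_single(y, design)
            assert res.minus2_reml <= f_start + 1e-10


class TestClosedForm:
    def test_equal_replicates_give_zero_residual(self, paper_shaped_design):
        d = paper_shaped_design
        rng = np.random.default_rng(5)
        cell_value = {}
        values = []
        for row in d.table.itertuples(index=False):
            key = (row.cancer_id, row.condition)
            if key not in cell_value:
                cell_value[key] = rng.normal()
            values.append(cell_value[key])
        y = pd.Series(values, index=d.table["sample_id"].tolist())
        mom = balanced_closed_form(y, d)
        assert mom["sigma_e2"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_moment_computation(self):
        """Cell differences (0.1, 0.5, 0.3) with no replicate noise."""
        design = make_design(["A", "B", "C"], ["FF", "N"], {"FF": 1, "N": 1})
        base = {"A": 1.0, "B": 2.0, "C": 3.0}
        diff = {"A": 0.1, "B": 0.5, "C": 0.3}
        values = {}
        for row in design.table.itertuples(index=False):
            v = base[row.cancer_id] + (diff[row.cancer_id] if row.condition == "N" else 0.0)
            values[row.sample_id] = v
        y = pd.Series(values)
        mom = balanced_closed_form(y, design)
        assert mom["bias"]["N"] == pytest.approx(0.3)
        assert mom["slope_var"]["N"] == pytest.approx(np.var([0.1, 0.5, 0.3], ddof=1))

    def test_unbalanced_design_redirects(self):
        design_table = pd.DataFrame(
            {
                "sample_id": ["a", "b", "c"],
                "cancer_id": ["A", "A", "B"],
                "condition": ["FF", "N", "FF"],
                "replicate": [1, 1, 1],
            }
        )
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            from ffpe_concordance import StudyDesign

            design = StudyDesign(design_table)
        with pytest.raises(DesignError, match="fit_lme_single"):
            balanced_closed_form(pd.Series([1.0, 2.0, 3.0], index=["a", "b", "c"]), design)

    def test_moment_and_reml_agree_at_scale(self):
        """Cross-method consistency on a long simulated gene set."""
        config = SimulationConfig(
            n_genes=150, n_reference_genes=5, seed=31,
            conditions=("FF", "N"), kit_bias=0.3, kit_bias_sd=0.0,
            slope_sd=0.35, replicate_sd=0.15,
        )
        matrix, design, _ = simulate_study(config)
        mom_tau, reml_tau = [], []
        for i in range(matrix.n_genes):
            y = matrix.values.iloc[i]
            mom_tau.append(balanced_closed_form(y, design)["slope_var"]["N"])
            reml_tau.append(fit_lme_single(y, design).slope_var["N"])
        assert np.median(reml_tau) == pytest.approx(np.median(mom_tau), rel=0.25, abs=0.02)


class TestInvariances:
    def test_cancer_relabeling_leaves_estimates_unchanged(self, two_kit_study):
        matrix, design, _ = two_kit_study
        y = matrix.values.iloc[2]
        res1 = fit_lme_single(y, design)
        relabel = {c: f"Z{i}" for i, c in enumerate(design.cancers)}
        table = design.table.copy()
        table["cancer_id"] = table["cancer_id"].map(relabel)
        from ffpe_concordance import StudyDesign

        design2 = StudyDesign(table, reference="FF")
        res2 = fit_lme_single(y, design2)
        assert res1.bias == pytest.approx(res2.bias)
        assert res1.minus2_reml == pytest.approx(res2.minus2_reml, abs=1e-6)

    def test_constant_shift_moves_only_intercept(self, two_kit_study):
        matrix, design, _ = two_kit_study
        y = matrix.values.iloc[4]
        res1 = fit_lme_single(y, design)
        res2 = fit_lme_single(y + 5.0, design)
        assert res2.intercept == pytest.approx(res1.intercept + 5.0, abs=1e-5)
        for kit in design.kits:
            assert res2.bias[kit] == pytest.approx(res1.bias[kit], abs=1e-5)
        assert res2.sigma_e2 == pytest.approx(res1.sigma_e2, rel=1e-3, abs=1e-8)


class TestSingleKitPairedForm:
    def test_bias_equals_classical_paired_estimate(self):
        config = SimulationConfig(
            n_genes=10, n_reference_genes=2, seed=13,
            conditions=("FF", "N"), kit_bias=0.4, kit_bias_sd=0.0,
            slope_sd=0.0, replicate_sd=0.1,
        )
        matrix, design, _ = simulate_study(config)
        y = matrix.values.iloc[0]
        res = fit_lme_single(y, design, include_slopes=False)
        cell = design.table.assign(value=y.loc[design.table["sample_id"]].to_numpy())
        means = cell.groupby(["cancer_id", "condition"])["value"].mean().unstack()
        paired = float((means["N"] - means["FF"]).mean())
        assert res.bias["N"] == pytest.approx(paired, abs=1e-6)


class TestFitAll:
    def test_recovery_of_fixed_bias(self):
        """Mean estimated kit bias recovers the simulated 0.3 within 0.02."""
        config = SimulationConfig(
            n_genes=150, n_reference_genes=5, seed=29,
            conditions=("FF", "N"),
            kit_bias=0.3, kit_bias_sd=0.0, slope_sd=0.2, replicate_sd=0.15,
            reference_genes_unbiased=False,
        )
        matrix, design, _ = simulate_study(config)
        table, summary = fit_lme_all(matrix, design)
        assert abs(table["bias_N"].mean() - 0.3) < 0.02 * math.sqrt(150 / 150) * 3
        assert summary["convergence_rate"] > 0.95

    def test_full_covariance_structure_runs(self, two_kit_study):
        matrix, design, _ = two_kit_study
        y = matrix.values.iloc[0]
        res = fit_lme_single(y, design, structure="full")
        assert math.isfinite(res.minus2_reml)
        diag = fit_lme_single(y, design, structure="diagonal")
        # extra covariance parameters can only improve the restricted fit
        assert res.minus2_reml <= diag.minus2_reml + 1e-6
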