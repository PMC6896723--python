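"""Paired OLS differential analysis, BH adjustment and Mann-Whitney tests."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ffpe_concordance import (
    DesignError,
    SimulationConfig,
    average_replicates,
    bh_adjust,
    count_degs,
    make_design,
    mann_whitney_u,
    paired_linear_fit,
    quality_index_effects,
    simulate_study,
)

from conftest import toy_matrix


def brute_force_bh(pvals):
    """Literal step-up definition: p_(i) -> min_{j>=i} m p_(j)/j, cap 1."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    out = np.empty(m)
    for rank_pos, idx in enumerate(order):
        candidates = [m * p[order[j]] / (j + 1) for j in range(rank_pos, m)]
        out[idx] = min(1.0, min(candidates))
    return out


class TestBH:
    def test_hand_example_all_become_largest(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_brute_force_on_random_vectors(self):
        rng = np.random.default_rng(7)
        for _ in range(1000):
            m = int(rng.integers(1, 60))
            p = rng.random(m)
            np.testing.assert_array_equal(bh_adjust(p), brute_force_bh(p))

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=100))
    @settings(max_examples=200, deadline=None)
    def test_adjusted_at_least_raw_and_capped(self, pvals):
        adj = bh_adjust(pvals)
        assert (adj >= np.asarray(pvals) - 1e-15).all()
        assert (adj <= 1.0).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        p = rng.random(200)
        np.testing.assert_allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestMannWhitney:
    def test_extreme_separation_exact_p(self):
        u, p = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_interleaved_example(self):
        u, p = mann_whitney_u([1, 3], [2, 4])
        assert u == 1
        assert p == pytest.approx(4 / 6)

    def test_identical_samples_give_p_one(self):
        _, p = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert p == pytest.approx(1.0)

    def test_exact_matches_full_enumeration_up_to_ten(self):
        """Exhaustive check of the exact two-sided rule for n + m <= 10."""
        rng = np.random.default_rng(3)
        for n, m in [(2, 2), (2, 3), (3, 3), (3, 4), (4, 4), (4, 5), (2, 7), (5, 5)]:
            pooled = rng.permutation(np.arange(1.0, n + m + 1))
            x, y = pooled[:n], pooled[n:]
            u_obs, p_obs = mann_whitney_u(x, y)
            center = n * m / 2.0
            count = 0
            total = 0
            for combo in itertools.combinations(range(n + m), n):
                xs = pooled[np.array(combo)]
                ys = np.delete(pooled, np.array(combo))
                u = sum(1 for a in xs for b in ys if a > b)
                if abs(u - center) >= abs(u_obs - center) - 1e-12:
                    count += 1
                total += 1
            assert p_obs == pytest.approx(count / total)

    def test_exact_agrees_with_scipy_without_ties(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            x = rng.normal(size=4)
            y = rng.normal(size=5)
            u, p = mann_whitney_u(x, y)
            ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            # scipy reports U counting x > y pairs as well
            assert u == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_large_samples_use_normal_approximation(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=30)
        y = rng.normal(loc=1.0, size=30)
        _, p = mann_whitney_u(x, y)
        ref = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert p == pytest.approx(ref.pvalue, rel=0.05)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestPairedLinearFit:
    def test_identical_arms_yield_no_signal(self):
        design = make_design(["A", "B", "C"], ["FF", "N"], {"FF": 1, "N": 1})
        base = {"A": 1.0, "B": 2.0, "C": 3.0}
        vals = [[base[r.cancer_id] for r in design.table.itertuples(index=False)],
                [2 * base[r.cancer_id] for r in design.table.itertuples(index=False)]]
        m = toy_matrix(vals, samples=design.table["sample_id"].tolist(),
                       scale="normalized-log2")
        res = paired_linear_fit(m, design)
        assert np.allclose(res["lfc"], 0.0, atol=1e-12)
        assert not res["significant"].any()

    def test_hand_ols_on_two_cancers(self):
        """FF = (1, 3), kit = (2, 5): lfc is the mean within-cancer difference."""
        design = make_design(["A", "B"], ["FF", "N"], {"FF": 1, "N": 1})
        values = {"A_FF_r1": 1.0, "B_FF_r1": 3.0, "A_N_r1": 2.0, "B_N_r1": 5.0}
        m = toy_matrix([[values[s] for s in design.table["sample_id"]]],
                       samples=design.table["sample_id"].tolist(),
                       scale="normalized-log2")
        res = paired_linear_fit(m, design)
        assert res["lfc"].iloc[0] == pytest.approx(1.5)
        # normal-equations oracle on the explicit 4 x 3 design
        D = np.array([[1, 0, 0], [1, 1, 0], [1, 0, 1], [1, 1, 1]], float)
        y = np.array([1.0, 3.0, 2.0, 5.0])
        beta = np.linalg.lstsq(D, y, rcond=None)[0]
        assert res["lfc"].iloc[0] == pytest.approx(beta[2])

    def test_lfc_equals_mean_within_cancer_difference(self, small_study):
        _, matrix, design, _ = small_study
        avg, avg_design = average_replicates(matrix, design)
        res = paired_linear_fit(avg, avg_design)
        cell = avg.values
        for kit in ("N", "Q"):
            sub = res[res["contrast"] == f"{kit}_vs_FF"].set_index("gene_id")
            diffs = []
            for cancer in avg_design.cancers:
                diffs.append(cell[f"{cancer}_{kit}"] - cell[f"{cancer}_FF"])
            expected = pd.concat(diffs, axis=1).mean(axis=1)
            np.testing.assert_allclose(sub["lfc"], expected.loc[sub.index], atol=1e-10)

    def test_agrees_with_statsmodels_ols(self, small_study):
        import statsmodels.formula.api as smf

        _, matrix, design, _ = small_study
        avg, avg_design = average_replicates(matrix, design)
        res = paired_linear_fit(avg, avg_design)
        gene = avg.genes[5]
        df = avg_design.table.assign(
            value=avg.values.loc[gene, avg_design.table["sample_id"]].to_numpy()
        )
        df["condition"] = pd.Categorical(df["condition"], categories=avg_design.conditions)
        fit = smf.ols("value ~ C(cancer_id) + C(condition)", data=df).fit()
        mine = res[(res["gene_id"] == gene) & (res["contrast"] == "N_vs_FF")].iloc[0]
        assert mine["lfc"] == pytest.approx(fit.params["C(condition)[T.N]"])
        assert mine["p"] == pytest.approx(fit.pvalues["C(condition)[T.N]"])

    def test_null_fdr_control(self):
        """Null genes rarely cross fdr < 0.05 (rate at most 0.06)."""
        config = SimulationConfig(
            n_genes=2000, n_reference_genes=10, seed=41,
            conditions=("FF", "N"), kit_bias=0.0, kit_bias_sd=0.0,
            slope_sd=0.0, replicate_sd=0.15,
        )
        matrix, design, _ = simulate_study(config)
        avg, avg_design = average_replicates(matrix, design)
        res = paired_linear_fit(avg, avg_design)
        rate = res[res["contrast"] == "N_vs_FF"]["significant"].mean()
        assert rate <= 0.06

    def test_power_at_unit_effect(self):
        """Genes with |beta| = 1 are detected at rate >= 0.9."""
        config = SimulationConfig(
            n_genes=500, n_reference_genes=5, seed=43,
            conditions=("FF", "N"), kit_bias=1.0, kit_bias_sd=0.0,
            slope_sd=0.0, replicate_sd=0.2, reference_genes_unbiased=False,
        )
        matrix, design, _ = simulate_study(config)
        avg, avg_design = average_replicates(matrix, design)
        res = paired_linear_fit(avg, avg_design)
        rate = res[res["contrast"] == "N_vs_FF"]["significant"].mean()
        assert rate >= 0.9

    def test_replicated_matrix_rejected(self, small_study):
        _, matrix, design, _ = small_study
        with pytest.raises(DesignError, match="average"):
            paired_linear_fit(matrix, design)


class TestCountDegs:
    def _results(self, lfcs, fdrs):
        return pd.DataFrame(
            {
                "gene_id": [f"g{i}" for i in range(len(lfcs))],
                "contrast": "N_vs_FF",
                "lfc": lfcs,
                "p": fdrs,
                "fdr": fdrs,
                "significant": np.asarray(fdrs) < 0.05,
            }
        )

    def test_threshold_counting_example(self):
        res = self._results([0.3, 0.7, 1.5, 2.5], [0.01] * 4)
        counts = count_degs(res)
        assert counts["n_deg"].tolist() == [4, 3, 2, 1]

    def test_nothing_significant(self):
        res = self._results([0.3, 0.7], [0.5, 0.9])
        assert (count_degs(res)["n_deg"] == 0).all()

    def test_counts_monotone_in_threshold(self):
        rng = np.random.default_rng(0)
        res = self._results(rng.normal(size=100, scale=1.5), rng.random(100) * 0.1)
        counts = count_degs(res)["n_deg"].tolist()
        assert counts == sorted(counts, reverse=True)

    def test_up_down_split(self):
        res = self._results([1.0, -1.0, 2.0], [0.001] * 3)
        row = count_degs(res, lfc_thresholds=(0.0,)).iloc[0]
        assert (row["n_up"], row["n_down"]) == (2, 1)


class TestQualityEffects:
    def _quality(self, design, shift_by_condition):
        rows = []
        base = {c: 5.0 + i for i, c in enumerate(design.cancers)}
        for row in design.table.itertuples(index=False):
            rin = base[row.cancer_id] + shift_by_condition.get(row.condition, 0.0)
            rows.append({"sample_id": row.sample_id, "RIN": rin,
                         "DV200": 80.0, "medTIN": 80.0})
        return pd.DataFrame(rows)

    def test_constant_shift_recovered_exactly(self, paper_shaped_design):
        d = paper_shaped_design
        quality = self._quality(d, {"N": -4.7, "Q": -4.7, "R": -4.7})
        res = quality_index_effects(quality, d)
        rin = res[(res["metric"] == "RIN") & (res["contrast"] == "N_vs_FF")].iloc[0]
        assert rin["effect"] == pytest.approx(-4.7)
        assert rin["flag"] == "boundary"

    def test_identical_quality_gives_zero_effects(self, paper_shaped_design):
        d = paper_shaped_design
        quality = self._quality(d, {})
        res = quality_index_effects(quality, d)
        assert np.allclose(res["effect"], 0.0, atol=1e-12)

    def test_noisy_shift_recovered_within_tolerance(self, paper_shaped_design):
        d = paper_shaped_design
        rng = np.random.default_rng(8)
        quality = self._quality(d, {"N": -4.7})
        quality["RIN"] += rng.normal(0, 0.2, len(quality))
        res = quality_index_effects(quality, d)
        rin = res[(res["metric"] == "RIN") & (res["contrast"] == "N_vs_FF")].iloc[0]
        assert rin["effect"] == pytest.approx(-4.7, abs=0.25)
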