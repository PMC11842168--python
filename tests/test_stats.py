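"""Statistics: GLM odds ratios, likelihood-ratio tests, chi-squared,
Kruskal-Wallis/Dunn/Holm, and simulation-vs-telemetry comparison."""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest
import scipy.integrate
import scipy.stats

from lakewalk import (
    chisq_success,
    compare_to_telemetry,
    fit_success_glm,
    generate_telemetry,
    holm_adjust,
    kruskal_dunn,
    lrt,
    paths_frame,
    summarize_cell,
)
from lakewalk.stats import backward_select

from test_experiments import _fake_paths


def two_group_frame(k1, n1, k2, n2):
    return pd.DataFrame(
        {
            "group": ["a"] * n1 + ["b"] * n2,
            "success": [1] * k1 + [0] * (n1 - k1) + [1] * k2 + [0] * (n2 - k2),
        }
    )


class TestGlm:
    def test_two_by_two_odds_ratio_matches_closed_form(self):
        # group a: 30/100, group b: 60/100 -> OR(b vs a) closed form
        df = two_group_frame(30, 100, 60, 100)
        fit = fit_success_glm(df, "success ~ group")
        closed = (60 / 40) / (30 / 70)
        (term,) = [i for i in fit.odds_ratios.index if "group" in i]
        assert fit.odds_ratios.loc[term, "odds_ratio"] == pytest.approx(
            closed, abs=1e-6
        )
        assert fit.odds_ratios.loc[term, "ci_lo"] < closed < fit.odds_ratios.loc[term, "ci_hi"]

    def test_constant_response_gives_uninformative_slope(self):
        df = pd.DataFrame({"x": np.linspace(0, 1, 80), "success": 1})
        fit = fit_success_glm(df, "success ~ x")
        # no information about the slope: either flagged as separation or
        # clearly non-significant
        assert fit.separation or fit.odds_ratios.loc["x", "p_value"] > 0.05

    def test_sigma_effect_direction_recovered_from_simulations(self, smoke_grid):
        # on grids simulated by the walk engine the fitted turning-angle-sd
        # main effect must reduce the odds of success (odds ratio < 1)
        _, _, paths = smoke_grid
        records = paths_frame(paths)
        fit = fit_success_glm(
            records, "success ~ basin + step_length_m + turn_sd_deg"
        )
        assert fit.odds_ratios.loc["turn_sd_deg", "odds_ratio"] < 1.0
        assert not fit.separation

    def test_ci_level_975_option(self):
        df = two_group_frame(30, 100, 60, 100)
        narrow = fit_success_glm(df, "success ~ group", ci_level=0.95)
        wide = fit_success_glm(df, "success ~ group", ci_level=0.975)
        (term,) = [i for i in wide.odds_ratios.index if "group" in i]
        assert wide.odds_ratios.loc[term, "ci_lo"] < narrow.odds_ratios.loc[term, "ci_lo"]
        assert wide.odds_ratios.loc[term, "ci_hi"] > narrow.odds_ratios.loc[term, "ci_hi"]


class TestLrt:
    def test_identical_models_give_zero(self):
        df = two_group_frame(30, 100, 60, 100)
        fit = fit_success_glm(df, "success ~ group")
        res = lrt(fit, fit)
        assert res.statistic == pytest.approx(0.0, abs=1e-9)
        assert res.p_value == 1.0

    def test_chi2_tail_reference_values(self):
        # 2dLL = 9.13 on 3 df -> p ~= 0.028; 3.841 on 1 df -> p ~= 0.05
        assert scipy.stats.chi2.sf(9.13, 3) == pytest.approx(0.0276, abs=5e-4)
        assert scipy.stats.chi2.sf(3.841, 1) == pytest.approx(0.05, abs=5e-4)

    def test_tail_matches_independent_density_integration(self):
        # integrate the chi-squared density directly as an independent check
        for stat, df in ((9.13, 3), (3.841, 1), (31.414, 1)):
            dens = lambda x: x ** (df / 2 - 1) * math.exp(-x / 2) / (
                2 ** (df / 2) * math.gamma(df / 2)
            )
            tail, _ = scipy.integrate.quad(dens, stat, np.inf)
            assert scipy.stats.chi2.sf(stat, df) == pytest.approx(tail, abs=1e-9)

    def test_lrt_on_nested_fits(self, smoke_grid):
        _, _, paths = smoke_grid
        records = paths_frame(paths)
        full = fit_success_glm(records, "success ~ basin + turn_sd_deg")
        nested = fit_success_glm(records, "success ~ basin")
        res = lrt(nested, full)
        assert res.df == 1
        assert res.statistic > 0
        assert res.p_value < 0.001  # the sigma effect is strong by design

    def test_swapped_models_rejected(self):
        df = two_group_frame(30, 100, 60, 100)
        full = fit_success_glm(df, "success ~ group")
        nested = fit_success_glm(df, "success ~ 1")
        with pytest.raises(ValueError):
            lrt(full, nested)

    def test_backward_selection_keeps_strong_terms(self, smoke_grid):
        _, _, paths = smoke_grid
        records = paths_frame(paths)
        fit, dropped = backward_select(
            records,
            "success ~ basin + step_length_m + turn_sd_deg",
            ["basin", "step_length_m", "turn_sd_deg"],
        )
        kept = fit.formula.split("~")[1]
        assert "turn_sd_deg" in kept and "basin" in kept


class TestChisq:
    def test_identical_proportions_give_zero(self):
        res = chisq_success([[50, 50], [50, 50]])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_hand_computed_two_by_two(self):
        res = chisq_success([[10, 90], [90, 10]])
        assert res.statistic == pytest.approx(128.0)
        assert res.df == 1

    def test_matches_formula_recomputation_three_groups(self):
        table = np.array([[120, 80], [60, 140], [95, 105]], dtype=float)
        res = chisq_success(table)
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row @ col / table.sum()
        manual = float(((table - expected) ** 2 / expected).sum())
        assert res.statistic == pytest.approx(manual, abs=1e-9)
        assert res.df == 2

    def test_degenerate_table_rejected(self):
        with pytest.raises(ValueError):
            chisq_success([[0, 0], [10, 10]])
        with pytest.raises(ValueError):
            chisq_success([[5, 5]])


class TestKruskalDunn:
    def test_identical_groups_give_null_results(self):
        same = np.full(20, 3.7)
        omnibus, pairs = kruskal_dunn({"a": same, "b": same.copy(), "c": same.copy()})
        assert omnibus.statistic == 0.0
        assert all(p.statistic == 0.0 for p in pairs)
        assert all(p.adjusted_p == 1.0 for p in pairs)

    def test_holm_step_down_definition(self):
        adj = holm_adjust([0.01, 0.04])
        assert adj[0] == pytest.approx(0.02)
        assert adj[1] == pytest.approx(0.04)

    def test_holm_monotone_never_below_raw(self):
        rng = np.random.default_rng(5)
        raw = rng.uniform(0, 1, 12)
        adj = holm_adjust(list(raw))
        assert np.all(adj >= raw - 1e-15)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_shifted_group_detected(self):
        rng = np.random.default_rng(6)
        a = rng.normal(10, 1, 50)
        b = rng.normal(10, 1, 50)
        c = rng.normal(10, 1, 50) + 13.0  # ~10x IQR shift
        omnibus, pairs = kruskal_dunn({"a": a, "b": b, "c": c})
        assert omnibus.p_value < 0.001
        for p in pairs:
            if "c" in p.groups:
                assert p.adjusted_p < 0.001
            else:
                assert p.adjusted_p > 0.05

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            kruskal_dunn({"a": np.array([1.0]), "b": np.array([])})


class TestCompareToTelemetry:
    def _cell(self, k, n, lake="Lomond"):
        return summarize_cell(
            _fake_paths(k, n), basin=lake, step_length=100.0, turn_sd=5.0
        )

    def _records(self, n, p, seed=0):
        return generate_telemetry("Lomond", n, p, 5.2, 4.2, seed=seed)

    def test_matching_rates_flagged_within_interval(self):
        cell = self._cell(70, 200)
        recs = self._records(10_000, 0.35, seed=1)
        report = compare_to_telemetry([cell], recs)
        assert bool(report.loc[0, "rate_within_ci"])

    def test_disjoint_rates_flagged_outside(self):
        cell = self._cell(200, 200)
        recs = self._records(100, 0.31, seed=2)
        report = compare_to_telemetry([cell], recs)
        assert not bool(report.loc[0, "rate_within_ci"])
        assert report.loc[0, "binom_p"] < 1e-6

    def test_coverage_of_matching_generator(self):
        # telemetry generated at exactly the cell's success probability lies
        # inside the cell's 95% interval in almost every replicate
        hits = 0
        for seed in range(10):
            cell = self._cell(70, 200)
            recs = self._records(10_000, 0.35, seed=seed)
            report = compare_to_telemetry([cell], recs)
            hits += bool(report.loc[0, "rate_within_ci"])
        assert hits >= 9

    def test_requires_single_lake_and_records(self):
        cell = self._cell(70, 200)
        with pytest.raises(ValueError):
            compare_to_telemetry([cell], [])
        mixed = self._records(5, 0.5) + generate_telemetry(
            "Meig", 5, 0.5, 14.9, 17.5, seed=3
        )
        with pytest.raises(ValueError):
            compare_to_telemetry([cell], mixed)
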