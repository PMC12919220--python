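"""Statistical layer: long tables, LME, HMP, Mann-Whitney, reports."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import rankdata

from geotax import geostats as gs


def wide_table(genotypes, n_reps, times, fn, rng=None):
    rows = {}
    for g in genotypes:
        for r in range(1, n_reps + 1):
            label = f"{g}_rep{r}"
            rows[label] = [fn(g, r, t, rng) for t in times]
    return pd.DataFrame(rows, index=list(times)).T


class TestBuildLongTable:
    times = [0.5 * k for k in range(26)]

    def test_row_count_is_genotypes_by_reps_by_times(self):
        table = wide_table(["c", "m"], 3, self.times, lambda g, r, t, _: t)
        spec = gs.LMESpec("c", ("m",), tmax=99.0)
        long = gs.build_long_table(table, spec)
        assert len(long) == 2 * 3 * 26
        assert set(long.columns) == {"Genotype", "Replicate", "Time",
                                     "Measurement", "Subject"}
        assert (long["Subject"] == long["Genotype"] + "_rep"
                + long["Replicate"]).all()

    def test_tmax_below_all_times_is_an_error(self):
        table = wide_table(["c", "m"], 2, [1.0, 2.0], lambda g, r, t, _: t)
        with pytest.raises(ValueError, match="tmax"):
            gs.build_long_table(table, gs.LMESpec("c", ("m",), tmax=0.5))

    def test_unselected_genotype_never_appears(self):
        table = wide_table(["c", "m", "other"], 2, [0.0, 1.0],
                           lambda g, r, t, _: t)
        long = gs.build_long_table(table, gs.LMESpec("c", ("m",), tmax=9.0))
        assert set(long["Genotype"]) == {"c", "m"}

    def test_missing_control_is_an_error(self):
        table = wide_table(["m"], 2, [0.0, 1.0], lambda g, r, t, _: t)
        with pytest.raises(ValueError, match="control"):
            gs.build_long_table(table, gs.LMESpec("c", ("m",), tmax=9.0))

    def test_control_equal_to_comparison_rejected(self):
        with pytest.raises(ValueError):
            gs.LMESpec("c", ("c",), tmax=1.0)


class TestStars:
    @pytest.mark.parametrize(
        "p,expected",
        [(0.0005, "***"), (0.001, "***"), (0.005, "**"), (0.01, "**"),
         (0.03, "*"), (0.05, "*"), (0.05000001, "NS"), (1.0, "NS")],
    )
    def test_inclusive_thresholds(self, p, expected):
        assert gs.star_annotation(p) == expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            gs.star_annotation(1.5)

    def test_monotone_step_function(self):
        order = {"***": 0, "**": 1, "*": 2, "NS": 3}
        ps = np.linspace(0, 1, 101)
        ranks = [order[gs.star_annotation(p)] for p in ps]
        assert ranks == sorted(ranks)


class TestHarmonicMeanP:
    def test_equal_pvalues_return_that_p(self):
        assert gs.harmonic_mean_p([0.05, 0.05, 0.05]) == pytest.approx(
            0.05, abs=1e-9
        )

    def test_single_certain_p(self):
        assert gs.harmonic_mean_p([1.0]) == pytest.approx(1.0, abs=1e-9)

    def test_direct_evaluation(self):
        # 3 / (1/0.01 + 1/0.04 + 1/0.20) = 3 / 130
        assert gs.harmonic_mean_p([0.01, 0.04, 0.20]) == pytest.approx(
            3 / 130, rel=1e-6
        )

    def test_zero_p_guarded_by_epsilon(self):
        assert gs.harmonic_mean_p([0.0, 1.0]) > 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            gs.harmonic_mean_p([])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=8))
    def test_bounds(self, ps):
        h = gs.harmonic_mean_p(ps)
        assert min(ps) - 1e-9 <= h <= 1.0


def brute_force_mwu_p(a, b):
    """Exact two-sided p by enumerating all group assignments of the ranks."""
    combined = np.asarray(list(a) + list(b), dtype=float)
    ranks = rankdata(combined)
    n1 = len(a)
    idx = range(len(combined))

    def u_of(subset):
        r1 = ranks[list(subset)].sum()
        return r1 - n1 * (n1 + 1) / 2

    u_obs = u_of(range(n1))
    us = [u_of(c) for c in combinations(idx, n1)]
    us = np.asarray(us)
    # two-sided: double the smaller tail, capped at 1
    lo = np.mean(us <= u_obs)
    hi = np.mean(us >= u_obs)
    return min(1.0, 2 * min(lo, hi))


class TestMannWhitney:
    def test_fully_separated_triples_have_exact_p_point_one(self):
        assert gs.mann_whitney_p([1, 2, 3], [10, 11, 12]) == pytest.approx(0.1)

    def test_identical_groups_return_one(self):
        assert gs.mann_whitney_p([5, 5, 5], [5, 5, 5]) == 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_exact_mode_matches_brute_force_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        n1 = int(rng.integers(2, 6))
        n2 = int(rng.integers(2, 11 - n1))
        vals = rng.permutation(np.arange(1.0, n1 + n2 + 1))  # tie-free
        a, b = vals[:n1], vals[n1:]
        assert gs.mann_whitney_p(a, b) == pytest.approx(
            brute_force_mwu_p(a, b), rel=1e-9
        )

    def test_large_or_tied_samples_use_tie_corrected_normal(self):
        rng = np.random.default_rng(1)
        a = rng.integers(0, 5, 30).astype(float)
        b = rng.integers(1, 6, 30).astype(float)
        p = gs.mann_whitney_p(a, b)
        assert 0.0 < p <= 1.0

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            gs.mann_whitney_p([], [1.0])


class TestMWUGridAndPeaks:
    def test_identical_groups_grid_is_flat_zero(self):
        table = wide_table(["c", "m"], 3, [0.0, 0.5], lambda g, r, t, _: 1.0)
        grid = gs.mwu_timepoints(table, "c", "m")
        assert np.allclose(grid["p"], 1.0)
        assert np.allclose(grid["neglog10p"], 0.0)

    def test_neglog10_of_p_001_is_3(self):
        assert -np.log10(0.001) == pytest.approx(3.0)
        table = wide_table(
            ["c", "m"], 7, [0.0],
            lambda g, r, t, _: float(r) + (100.0 if g == "m" else 0.0),
        )
        grid = gs.mwu_timepoints(table, "c", "m")
        assert grid["neglog10p"].iloc[0] > 3.0  # fully separated n=7,7

    def test_peak_of_monotone_series_is_last_value(self):
        table = wide_table(["c"], 1, [0.0, 0.5, 1.0], lambda g, r, t, _: t)
        peaks = gs.peak_metrics(table)
        assert peaks["c_rep1"] == 1.0

    def test_peak_respects_tmax_window(self):
        table = wide_table(["c"], 1, [0.0, 5.0, 10.0], lambda g, r, t, _: t)
        assert gs.peak_metrics(table, tmax=6.0)["c_rep1"] == 5.0

    def test_identical_peak_sets_not_significant(self):
        table = wide_table(["c", "m"], 3, [0.0], lambda g, r, t, _: float(r))
        peaks = gs.peak_metrics(table)
        assert gs.mwu_peaks(peaks, "c", "m") == 1.0

    def test_shifted_peaks_exact_p(self):
        table = wide_table(
            ["c", "m"], 3, [0.0],
            lambda g, r, t, _: float(r) + (10.0 if g == "m" else 0.0),
        )
        peaks = gs.peak_metrics(table)
        assert gs.mwu_peaks(peaks, "c", "m") == pytest.approx(0.1)


class TestFitLME:
    def test_parameter_recovery_within_two_standard_errors(self):
        # simulate from the model equation and check coverage of the
        # genotype offset across seeded runs
        rng = np.random.default_rng(99)
        hits = 0
        runs = 40
        for _ in range(runs):
            long = gs.simulate_lme_dataset(
                rng, n_subjects_per_genotype=30, n_timepoints=3,
                beta0=2.0, genotype_offset=1.0, sigma_b=0.5, sigma_e=0.3,
            )
            res = gs.fit_lme(long, "ctrl")
            fe = res.fixed_effects.set_index("term")
            term = [t for t in fe.index if "[T.mut]" in t and ":" not in t][0]
            est, se = fe.loc[term, "estimate"], fe.loc[term, "se"]
            if abs(est - 1.0) <= 2 * se:
                hits += 1
        assert hits / runs >= 0.90

    def test_insufficient_subjects_rejected(self):
        rng = np.random.default_rng(0)
        long = gs.simulate_lme_dataset(rng, n_subjects_per_genotype=1)
        with pytest.raises(ValueError, match="subjects"):
            gs.fit_lme(long, "ctrl")

    def test_single_time_point_rejected(self):
        rng = np.random.default_rng(0)
        long = gs.simulate_lme_dataset(rng, n_subjects_per_genotype=3,
                                       n_timepoints=1)
        with pytest.raises(ValueError, match="time points"):
            gs.fit_lme(long, "ctrl")

    def test_result_carries_hmp_over_main_and_interactions(self):
        rng = np.random.default_rng(5)
        long = gs.simulate_lme_dataset(rng, n_subjects_per_genotype=8,
                                       n_timepoints=4)
        res = gs.fit_lme(long, "ctrl")
        comp = res.comparisons["mut"]
        assert len(comp.interaction_ps) == 3  # one per non-reference time
        ps = [comp.main_p, *comp.interaction_ps.values()]
        assert comp.hmp == pytest.approx(gs.harmonic_mean_p(ps), rel=1e-9)
        assert comp.stars in {"***", "**", "*", "NS"}
        assert "HMP" in res.summary()


class TestComparisonReport:
    def test_identical_genotypes_are_ns_everywhere(self):
        rng = np.random.default_rng(0)
        times = [0.5 * k for k in range(10)]

        def fn(g, r, t, rng):
            return 5.0 + 0.5 * t + rng.normal(0, 0.5)

        tables = {
            m: wide_table(["c", "m"], 6, times, fn, rng)
            for m in gs.MODALITIES
        }
        spec = gs.LMESpec("c", ("m",), tmax=10.0)
        report = gs.comparison_report(spec, tables)
        col = "c vs m"
        assert report.cells.shape == (10, 1)
        for row in report.cells.index:
            assert report.cells.loc[row, col].endswith("(NS)")

    def test_missing_modality_leaves_flagged_gap(self):
        times = [0.0, 0.5, 1.0]
        tables = {"position": wide_table(["c", "m"], 3, times,
                                         lambda g, r, t, _: t + r)}
        spec = gs.LMESpec("c", ("m",), tmax=10.0)
        report = gs.comparison_report(spec, tables)
        assert "velocity" in report.gaps
        assert report.cells.loc["velocity_LME", "c vs m"] == ""
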