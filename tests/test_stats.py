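"""Group-comparison tests and sample-size calculators."""

import itertools

import numpy as np
import pytest

from cpinet import (
    SampleSizeSpec,
    Status,
    ann_sample_heuristic,
    chi_squared,
    compare_groups,
    mann_whitney_u,
    paired_mean_change_n,
)


class TestMannWhitney:
    def test_identical_samples(self):
        a = [1.0, 2.0, 3.0, 4.0]
        res = mann_whitney_u(a, a)
        assert res.statistic == pytest.approx(len(a) ** 2 / 2)
        assert res.p_value > 0.95

    def test_fully_separated_small_samples_exact(self):
        res = mann_whitney_u([1, 2, 3], [4, 5, 6])
        assert res.statistic == 0.0
        # enumeration: 2 of C(6,3)=20 assignments are as extreme (two-sided)
        assert res.p_value == pytest.approx(2 / 20, abs=1e-12)

    def test_exact_p_matches_enumeration(self):
        a, b = [0.3, 1.7, 2.2], [0.9, 2.8, 3.1, 1.1]
        res = mann_whitney_u(a, b)
        pooled = np.array(a + b)
        n1 = len(a)
        u_obs = res.statistic

        def u_of(idx):
            x = pooled[list(idx)]
            yv = pooled[[i for i in range(len(pooled)) if i not in idx]]
            return sum((xi > yj) + 0.5 * (xi == yj) for xi in x for yj in yv)

        us = [u_of(idx) for idx in itertools.combinations(range(len(pooled)), n1)]
        mu = n1 * (len(pooled) - n1) / 2
        p = np.mean([abs(u - mu) >= abs(u_obs - mu) - 1e-12 for u in us])
        assert res.p_value == pytest.approx(p, abs=1e-12)

    def test_large_sample_shift_detected(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0.0, 1.0, 200)
        b = rng.normal(1.0, 1.0, 200)
        assert mann_whitney_u(a, b).p_value < 0.001

    def test_empty_sample_error(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestChiSquared:
    def test_polypharmacy_table_from_study(self):
        res = chi_squared([[80, 439], [40, 125]])
        assert res.statistic == pytest.approx(6.745, abs=0.002)
        assert round(res.p_value, 3) == 0.009

    def test_matches_expected_count_definition(self):
        table = np.array([[13.0, 27.0, 8.0], [22.0, 14.0, 19.0]])
        res = chi_squared(table)
        total = table.sum()
        stat = 0.0
        for i in range(2):
            for j in range(3):
                expected = table[i].sum() * table[:, j].sum() / total
                stat += (table[i, j] - expected) ** 2 / expected
        assert res.statistic == pytest.approx(stat, abs=1e-12)

    def test_proportional_table_is_null(self):
        res = chi_squared([[10, 20, 30], [20, 40, 60]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_pharmacist_success_2x3(self):
        res = chi_squared([[147, 452, 824], [109, 23, 139]])
        assert res.p_value < 0.001

    def test_zero_marginal_rejected(self):
        with pytest.raises(ValueError, match="marginal"):
            chi_squared([[0, 5], [0, 7]])


class TestPairedSampleSize:
    def test_study_z_and_t_solutions(self):
        spec = SampleSizeSpec(alpha=0.05, power=0.80, sd_change=1.05, effect=0.125)
        assert paired_mean_change_n(spec) == 554
        assert paired_mean_change_n(
            SampleSizeSpec(alpha=0.05, power=0.80, sd_change=1.05, effect=0.125,
                           statistic="t")) == 556

    def test_unit_ratio_z(self):
        spec = SampleSizeSpec(sd_change=1.0, effect=1.0, statistic="z")
        assert paired_mean_change_n(spec) == 8  # ceil((1.95996+0.84162)^2)

    def test_monotonicity_grid(self):
        grid_alpha = [0.01, 0.05, 0.1]
        grid_power = [0.7, 0.8, 0.9]
        grid_sd = [0.5, 1.05, 2.0]
        grid_eff = [0.1, 0.125, 0.5]
        for stat in ("z", "t"):
            for a, p, s, e in itertools.product(grid_alpha, grid_power, grid_sd, grid_eff):
                n = paired_mean_change_n(SampleSizeSpec(a, p, s, e, stat))
                n_easier_eff = paired_mean_change_n(SampleSizeSpec(a, p, s, e * 2, stat))
                n_easier_alpha = paired_mean_change_n(SampleSizeSpec(min(a * 2, 0.99), p, s, e, stat))
                n_harder_power = paired_mean_change_n(SampleSizeSpec(a, min(p + 0.05, 0.99), s, e, stat))
                n_harder_sd = paired_mean_change_n(SampleSizeSpec(a, p, s * 1.5, e, stat))
                assert n_easier_eff <= n
                assert n_easier_alpha <= n
                assert n_harder_power >= n
                assert n_harder_sd >= n

    def test_t_at_least_z(self):
        for s, e in [(1.05, 0.125), (1.0, 0.25), (2.0, 0.3)]:
            z = paired_mean_change_n(SampleSizeSpec(sd_change=s, effect=e, statistic="z"))
            t = paired_mean_change_n(SampleSizeSpec(sd_change=s, effect=e, statistic="t"))
            assert t >= z

    def test_invalid_spec(self):
        with pytest.raises(ValueError):
            SampleSizeSpec(alpha=0.0)
        with pytest.raises(ValueError):
            SampleSizeSpec(effect=-1.0)


class TestHeuristic:
    @pytest.mark.parametrize("inputs,expected", [(19, 380), (54, 1080), (1, 20)])
    def test_values(self, inputs, expected):
        assert ann_sample_heuristic(inputs, 2) == expected

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            ann_sample_heuristic(0, 2)


class TestCompareGroups:
    def test_table_structure_and_routing(self, small_consolidated):
        table = compare_groups(small_consolidated)
        assert len(table) == 54 + 7  # inputs + outcomes
        assert (table.loc["age_years", "method"] == "mann_whitney_u")
        assert (table.loc["score_rejection", "method"] == "mann_whitney_u")
        assert (table.loc["risk_renal", "method"] == "chi_squared")
        assert table.loc["risk_renal", "accepted"].startswith("Yes: ")
        assert "(" in table.loc["losta", "accepted"]

    def test_rejection_score_separates_groups(self, small_consolidated):
        table = compare_groups(small_consolidated)
        assert table.loc["score_rejection", "p_value"] < 0.001

    def test_display_p_suppressed_at_010(self, small_consolidated):
        table = compare_groups(small_consolidated)
        shown = table[table.display_p != ""]
        assert (shown.p_value < 0.10).all()

    def test_single_status_dataset_rejected(self, small_consolidated):
        only_accepted = [r for r in small_consolidated if r.status is Status.ACCEPTED]
        with pytest.raises(ValueError):
            compare_groups(only_accepted)
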