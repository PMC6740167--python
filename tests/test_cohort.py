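"""Utilization collapsing and the between/within-group statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ohcengage import cohort


def _rec(**over):
    base = dict(gp="never", nurse="1-3", outpatient="4-6", ae=">6", hospital_days=0)
    base.update(over)
    return cohort.UtilizationRecord(**base)


class TestCollapsing:
    @pytest.mark.parametrize(
        "raw,collapsed",
        [("never", "never"), ("1-3", "1-3"), ("4-6", "4+"), (">6", "4+")],
    )
    def test_visit_categories(self, raw, collapsed):
        out = cohort.collapse_visit_categories(_rec(gp=raw))
        assert out.gp == collapsed

    def test_unknown_token_rejected(self):
        with pytest.raises(cohort.DataError, match="sometimes"):
            cohort.collapse_visit_categories(_rec(gp="sometimes"))

    @pytest.mark.parametrize("cat,expected", [("never", False), ("1-3", True), ("4-6", True)])
    def test_binarize_any_visit(self, cat, expected):
        assert cohort.binarize_any_visit(_rec(nurse=cat))["nurse"] is expected

    def test_hospital_binarized_on_days(self):
        assert not cohort.binarize_any_visit(_rec(hospital_days=0))["hospital"]
        assert cohort.binarize_any_visit(_rec(hospital_days=1))["hospital"]

    @pytest.mark.parametrize(
        "days,cat", [(0, "none"), (1, "1-5"), (5, "1-5"), (6, "6-10"), (7, "6-10"), (10, "6-10"), (11, ">10")]
    )
    def test_hospital_day_bins(self, days, cat):
        assert cohort.categorize_hospital_days(days) == cat

    def test_negative_days_rejected(self):
        with pytest.raises(cohort.DataError):
            cohort.categorize_hospital_days(-1)

    @given(st.sampled_from(["never", "1-3", "4-6", ">6"]))
    @settings(max_examples=10, deadline=None)
    def test_binarize_commutes_with_collapse(self, cat):
        rec = _rec(ae=cat)
        assert (
            cohort.binarize_any_visit(cohort.collapse_visit_categories(rec))["ae"]
            == cohort.binarize_any_visit(rec)["ae"]
        )


class TestPairedT:
    def test_identical_vectors_degenerate(self):
        out = cohort.paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert out["mean_diff"] == 0.0 and out["p_value"] == 1.0 and out["degenerate"]

    def test_hand_computed_differences(self):
        out = cohort.paired_t([0.0, 0.0, 0.0, 0.0], [1.0, 2.0, 3.0, 4.0])
        assert out["mean_diff"] == pytest.approx(2.5)
        assert out["sd_diff"] == pytest.approx(1.29, abs=0.005)

    def test_rejects_unequal_lengths(self):
        with pytest.raises(ValueError):
            cohort.paired_t([1.0], [1.0, 2.0])

    def test_power_against_monte_carlo_rejection_rate(self):
        rng = np.random.default_rng(17)
        n, reps = 300, 500
        rejections = 0
        for _ in range(reps):
            diff = rng.normal(3.0, 8.4, size=n)
            if cohort.paired_t(np.zeros(n), diff)["p_value"] < 0.05:
                rejections += 1
        assert rejections / reps >= 0.9


class TestPower:
    def test_design_power_reaches_90_percent(self):
        assert cohort.power_paired_t(300, 3.0, 8.4) >= 0.90

    def test_null_power_equals_alpha(self):
        assert cohort.power_paired_t(300, 0.0, 8.4, alpha=0.05) == pytest.approx(0.05, abs=1e-6)

    def test_monotone_in_n_delta_and_sd(self):
        assert cohort.power_paired_t(400, 3, 8.4) > cohort.power_paired_t(200, 3, 8.4)
        assert cohort.power_paired_t(300, 4, 8.4) > cohort.power_paired_t(300, 2, 8.4)
        assert cohort.power_paired_t(300, 3, 6.0) > cohort.power_paired_t(300, 3, 10.0)


class TestChiSquare:
    def test_identical_rows_zero_statistic(self):
        out = cohort.chi_square_table([[10, 10], [20, 20]])
        assert out["statistic"] == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_2x2(self):
        out = cohort.chi_square_table([[10, 20], [20, 10]])
        assert out["statistic"] == pytest.approx(6.667, abs=0.001)
        assert out["df"] == 1

    def test_zero_margin_identified(self):
        with pytest.raises(ValueError, match="column 1"):
            cohort.chi_square_table([[5, 0], [7, 0]])

    def test_low_expected_count_flagged(self):
        out = cohort.chi_square_table([[1, 30], [2, 40]])
        assert out["low_expected_warning"]

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=40, deadline=None)
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        r, c = rng.integers(2, 6, size=2)
        table = rng.integers(1, 30, size=(r, c)).astype(float)
        out = cohort.chi_square_table(table)
        rows = table.sum(axis=1, keepdims=True)
        cols = table.sum(axis=0, keepdims=True)
        expected = rows @ cols / table.sum()
        brute = ((table - expected) ** 2 / expected).sum()
        assert out["statistic"] == pytest.approx(brute, rel=1e-12)
        assert out["p_value"] == pytest.approx(
            stats.chi2.sf(brute, (r - 1) * (c - 1)), rel=1e-10
        )


class TestKruskalWallis:
    def test_identical_groups_zero(self):
        out = cohort.kruskal_wallis([1.0, 1.0], [1.0, 1.0])
        assert out["statistic"] == 0.0 and out["p_value"] == 1.0

    def test_hand_computed_h(self):
        out = cohort.kruskal_wallis([1, 2, 3], [4, 5, 6])
        assert out["statistic"] == pytest.approx(3.857, abs=0.001)

    def test_shift_invariance(self):
        a, b = [1.0, 5.0, 2.0], [7.0, 3.0, 9.0]
        h1 = cohort.kruskal_wallis(a, b)["statistic"]
        h2 = cohort.kruskal_wallis([x + 100 for x in a], [x + 100 for x in b])["statistic"]
        assert h1 == pytest.approx(h2)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            cohort.kruskal_wallis([1.0], [])


class TestBuildTables:
    @staticmethod
    def _fixture_frames():
        """143 very-high users with 28 baseline / 10 follow-up emergency visits."""
        n = 143
        users = [f"u{i}" for i in range(n)]
        surveys = pd.DataFrame({"user_id": users})
        for i in range(1, 14):
            surveys[f"pam{i}_b"] = 3
            surveys[f"pam{i}_f"] = 3
        surveys["ae_b"] = ["1-3"] * 28 + ["never"] * (n - 28)
        surveys["ae_f"] = ["1-3"] * 10 + ["never"] * (n - 10)
        assignments = pd.DataFrame({"user_id": users, "cluster": 3})
        return surveys, assignments

    def test_single_cluster_percentages(self):
        surveys, assignments = self._fixture_frames()
        tables = cohort.build_tables(surveys, assignments)
        assert tables["clusters"]["percent"].iloc[0] == 100.0

    def test_fixture_counts_reproduced(self):
        surveys, assignments = self._fixture_frames()
        util = cohort.build_tables(surveys, assignments)["utilization"]
        ae = util[util["service"] == "ae"].set_index("time_point")
        assert ae.loc["baseline", "cluster_3_n"] == 28
        assert ae.loc["follow-up", "cluster_3_n"] == 10

    def test_emergency_visit_reduction_is_12_6_points(self):
        surveys, assignments = self._fixture_frames()
        util = cohort.build_tables(surveys, assignments)["utilization"]
        ae = util[util["service"] == "ae"].set_index("time_point")
        drop = ae.loc["baseline", "cluster_3_pct"] - ae.loc["follow-up", "cluster_3_pct"]
        assert drop == pytest.approx(12.6)
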