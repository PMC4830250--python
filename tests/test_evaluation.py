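import numpy as np
import pytest

from hemvol.estimators import CaseRecord
from hemvol.evaluation import (
    bland_altman,
    closest_value_counts,
    compare_means,
    deviation_bins,
    percentage_deviation,
    summarize_cohort,
)
from hemvol.synthetic import fixture_dataframe, load_study_fixture


class TestPercentageDeviation:
    def test_simple(self):
        assert percentage_deviation(11, 10) == pytest.approx(10.0)

    def test_exact_match_is_zero(self):
        # fixture case 1: variation 2' equals planimetry (9.85 mL)
        assert percentage_deviation(9.85, 9.85) == 0.0

    def test_absolute(self):
        assert percentage_deviation(9, 10) == pytest.approx(10.0)

    def test_scale_invariant(self):
        assert percentage_deviation(8.0, 10.0) == pytest.approx(
            percentage_deviation(8.0e3, 10.0e3)
        )

    def test_non_positive_reference_raises(self):
        with pytest.raises(ValueError):
            percentage_deviation(1.0, 0.0)

    def test_fixture_variation_2p_mean(self):
        df = fixture_dataframe()
        dev = [
            percentage_deviation(e, r)
            for e, r in zip(df["v2p"], df["planimetry_mL"])
        ]
        assert np.mean(dev) == pytest.approx(7.28, abs=0.1)


class TestClosestValueCounts:
    def test_simple_winner(self):
        got = closest_value_counts({"v1": [12.0], "v2": [10.5]}, [10.0])
        assert got.per_variation_count == {"v1": 0, "v2": 1}

    def test_tie_earlier_policy_default(self):
        got = closest_value_counts({"v1": [8.0], "v2": [12.0]}, [10.0])
        assert got.per_variation_count == {"v1": 1, "v2": 0}

    def test_tie_later_policy(self):
        got = closest_value_counts({"v1": [8.0], "v2": [12.0]}, [10.0], tie_policy="later")
        assert got.per_variation_count == {"v1": 0, "v2": 1}

    def test_counts_sum_to_n_any_policy(self):
        rng = np.random.default_rng(2)
        ref = rng.uniform(5, 50, 40)
        cols = {f"v{k}": ref + rng.normal(0, 3, 40) for k in range(5)}
        for policy in ("earlier", "later"):
            got = closest_value_counts(cols, ref, tie_policy=policy)
            assert sum(got.per_variation_count.values()) == 40

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            closest_value_counts({}, [1.0])
        with pytest.raises(ValueError):
            closest_value_counts({"v": []}, [])

    def test_fixture_overall_counts(self):
        df = fixture_dataframe()
        cols = {n: df[f"v{n}"].to_numpy() for n in ("1", "2", "3", "4", "1p", "2p", "3p", "4p")}
        got = closest_value_counts(cols, df["planimetry_mL"].to_numpy())
        assert got.per_variation_count["4p"] == 18
        assert got.per_variation_count["2p"] == 18
        assert got.per_variation_count["4"] == 0
        assert got.per_variation_count["2"] == 2


class TestDeviationBins:
    def test_one_each(self):
        assert deviation_bins([5, 15, 25]) == (1, 1, 1)

    def test_boundaries_go_to_middle_bin(self):
        assert deviation_bins([10.0, 20.0]) == (0, 2, 0)

    def test_negative_raises(self):
        with pytest.raises(ValueError):
            deviation_bins([-1.0])

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            deviation_bins([])

    def test_fixture_variation_4p_first_bin(self):
        df = fixture_dataframe()
        dev = np.abs(df["v4p"] - df["planimetry_mL"]) / df["planimetry_mL"] * 100
        bins = deviation_bins(dev.to_numpy())
        assert bins[0] / 53 * 100 == pytest.approx(84.91, abs=0.1)

    def test_order_independent(self):
        rng = np.random.default_rng(0)
        dev = rng.uniform(0, 40, 30)
        assert deviation_bins(dev) == deviation_bins(dev[::-1])


class TestCompareMeans:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        levene_p, t_p, variant = compare_means(x, x)
        assert t_p == pytest.approx(1.0)
        assert variant == "student"

    def test_separated_means(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 0.01, 20)
        b = rng.normal(10, 0.01, 20)
        _, t_p, _ = compare_means(a, b)
        assert t_p < 1e-10

    def test_degenerate_constant_pair_raises(self):
        with pytest.raises(ValueError):
            compare_means([5.0, 5.0], [5.0, 5.0])

    def test_welch_gate(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 0.1, 50)
        b = rng.normal(0, 30.0, 50)
        levene_p, _, variant = compare_means(a, b)
        assert levene_p < 0.05
        assert variant == "welch"

    def test_fixture_variation_2p_vs_planimetry(self):
        df = fixture_dataframe()
        levene_p, t_p, variant = compare_means(
            df["v2p"].to_numpy(), df["planimetry_mL"].to_numpy()
        )
        assert t_p == pytest.approx(0.99, abs=0.01)
        assert variant == "student"


class TestBlandAltman:
    def test_identical_columns(self):
        got = bland_altman([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert got.mean_difference_mL == 0.0
        assert got.loa_low_mL == got.loa_high_mL == 0.0

    def test_constant_offset(self):
        got = bland_altman([6.0, 7.0, 8.0], [1.0, 2.0, 3.0])
        assert got.mean_difference_mL == pytest.approx(5.0)
        assert got.sd_difference_mL == pytest.approx(0.0)

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])

    def test_limits_ordering(self):
        rng = np.random.default_rng(8)
        e = rng.normal(10, 3, 50)
        r = rng.normal(10, 3, 50)
        got = bland_altman(e, r)
        assert got.loa_low_mL <= got.mean_difference_mL <= got.loa_high_mL

    def test_gaussian_coverage_near_95_percent(self):
        rng = np.random.default_rng(123)
        d = rng.normal(0.0, 1.0, 100_000)
        got = bland_altman(d, np.zeros_like(d))
        assert got.proportion_within_loa == pytest.approx(0.95, abs=0.005)

    def test_fixture_variation_2p(self):
        df = fixture_dataframe()
        got = bland_altman(df["v2p"].to_numpy(), df["planimetry_mL"].to_numpy())
        expected_mean = df["v2p"].mean() - df["planimetry_mL"].mean()
        assert got.mean_difference_mL == pytest.approx(expected_mean)
        assert got.proportion_within_loa >= 0.90


@pytest.fixture(scope="module")
def summary():
    return summarize_cohort(load_study_fixture())


class TestSummarizeCohort:
    def test_reference_mean(self, summary):
        assert summary.reference_mean_mL == pytest.approx(31.72, abs=0.01)
        assert summary.reference_sd_mL == pytest.approx(39.24, abs=0.01)

    def test_intra_group_closest_variation_2(self, summary):
        assert summary.rows["2"].closest_intra == 30

    def test_intra_group_closest_all(self, summary):
        intra = {n: summary.rows[n].closest_intra for n in summary.rows}
        assert intra == {
            "1": 6, "2": 30, "3": 7, "4": 10,
            "1p": 5, "2p": 19, "3p": 10, "4p": 19,
        }

    def test_overall_closest_all(self, summary):
        overall = {n: summary.rows[n].closest_overall for n in summary.rows}
        assert overall == {
            "1": 1, "2": 2, "3": 1, "4": 0,
            "1p": 3, "2p": 18, "3p": 10, "4p": 18,
        }

    def test_estimated_means_match_printed_table(self, summary):
        printed = {
            "1": (43.49, 52.34), "2": (25.19, 30.13),
            "3": (40.51, 49.73), "4": (24.61, 30.23),
            "1p": (31.43, 38.73), "2p": (31.71, 39.17),
            "3p": (31.56, 38.79), "4p": (31.82, 39.30),
        }
        for name, (mean, sd) in printed.items():
            assert summary.rows[name].mean_mL == pytest.approx(mean, abs=0.015)
            assert summary.rows[name].sd_mL == pytest.approx(sd, abs=0.015)

    def test_two_case_toy_table_by_hand(self):
        # two variations, three cases, all numbers recomputed by hand
        records = [
            CaseRecord("a", 10.0, {}, {"x": 11.0, "y": 8.0}),
            CaseRecord("b", 20.0, {}, {"x": 24.0, "y": 19.0}),
            CaseRecord("c", 40.0, {}, {"x": 42.0, "y": 50.0}),
        ]
        from hemvol.estimators import VariationSpec

        registry = {
            "x": VariationSpec("x", 0.5, 0.0, "largest", "C0"),
            "y": VariationSpec("y", 0.5, 0.0, "largest", "C1"),
        }
        summary = summarize_cohort(records, registry=registry, groups={"g": ("x", "y")})
        row_x = summary.rows["x"]
        # deviations: 10%, 20%, 5%; boundary values land in the middle bin
        assert row_x.deviations.per_case_deviation_pct == pytest.approx((10.0, 20.0, 5.0))
        assert row_x.deviations.bin_counts == (1, 2, 0)
        # closest: case a -> x (1 vs 2), case b -> y (4 vs 1), case c -> x (2 vs 10)
        assert row_x.closest_overall == 2
        assert summary.rows["y"].closest_overall == 1
        assert row_x.mean_mL == pytest.approx((11 + 24 + 42) / 3)

    def test_requires_three_cases(self):
        with pytest.raises(ValueError):
            summarize_cohort(load_study_fixture()[:2])

    def test_permuting_cases_leaves_summary_unchanged(self):
        records = load_study_fixture()
        rng = np.random.default_rng(0)
        shuffled = [records[i] for i in rng.permutation(len(records))]
        a = summarize_cohort(records)
        b = summarize_cohort(shuffled)
        for name in a.rows:
            assert a.rows[name].deviations.bin_counts == b.rows[name].deviations.bin_counts
            assert a.rows[name].closest_overall == b.rows[name].closest_overall
            assert a.rows[name].mean_mL == pytest.approx(b.rows[name].mean_mL)
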