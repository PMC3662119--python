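import numpy as np
import pytest

from mammodensity.agreement import (
    RaterPanel,
    bland_altman,
    category_distribution_summary,
    evaluate,
    icc_interpretation,
    icc_two_way,
    pearson_rho,
    quadratic_weighted_kappa,
    reference_standard,
    within_one_birads,
)
from mammodensity.errors import UndefinedStatisticError
from mammodensity.phantom import RaterModel, simulate_rater_panel, snap_to_grid


def icc_anova_oracle(x):
    """ICC(2,1) from hand-expanded ANOVA sums, all in explicit loops."""
    n, k = len(x), len(x[0])
    grand = sum(sum(row) for row in x) / (n * k)
    row_means = [sum(row) / k for row in x]
    col_means = [sum(x[i][j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((m - grand) ** 2 for m in row_means)
    ss_cols = n * sum((m - grand) ** 2 for m in col_means)
    ss_total = sum((x[i][j] - grand) ** 2
                   for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


class TestReferenceStandard:
    def test_odd_count_median_robust_to_outlier(self):
        panel = RaterPanel(ratings=[[10, 20, 20, 30, 100]])
        assert reference_standard(panel)[0] == 20

    def test_identical_raters(self):
        panel = RaterPanel(ratings=[[35, 35, 35]])
        assert reference_standard(panel)[0] == 35

    def test_even_count_uses_mean_of_central_pair(self):
        panel = RaterPanel(ratings=[[10, 20, 30, 40]])
        assert reference_standard(panel)[0] == 25

    def test_empty_panel_errors(self):
        with pytest.raises(ValueError):
            RaterPanel(ratings=np.empty((0, 0)))


class TestICC:
    def test_identical_raters_give_one(self):
        x = np.column_stack([np.arange(10.0), np.arange(10.0)])
        icc, lo, hi = icc_two_way(x)
        assert icc == 1.0 and lo == 1.0 and hi == 1.0

    def test_matches_hand_expanded_anova_on_6x3(self):
        x = [[9.0, 2.0, 5.0],
             [6.0, 1.0, 3.0],
             [8.0, 4.0, 6.0],
             [7.0, 1.0, 2.0],
             [10.0, 5.0, 6.0],
             [6.0, 2.0, 4.0]]
        icc, _, _ = icc_two_way(np.array(x))
        assert abs(icc - icc_anova_oracle(x)) < 1e-10

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(5)
        x = rng.normal(50, 15, (20, 4)) + rng.normal(0, 5, (20, 4))
        frame = pd.DataFrame({
            "subject": np.repeat(np.arange(20), 4),
            "rater": np.tile(np.arange(4), 20),
            "score": x.ravel(),
        })
        table = pingouin.intraclass_corr(frame, targets="subject",
                                         raters="rater", ratings="score")
        mask = table["Type"].isin(["ICC2", "ICC(A,1)"])
        row = table[mask].iloc[0]
        ci_col = "CI95%" if "CI95%" in table.columns else "CI95"
        icc, lo, hi = icc_two_way(x)
        assert icc == pytest.approx(row["ICC"], abs=1e-10)
        assert lo == pytest.approx(row[ci_col][0], abs=0.011)
        assert hi == pytest.approx(row[ci_col][1], abs=0.011)

    def test_parameter_recovery(self):
        rng = np.random.default_rng(7)
        sigma_s, sigma_e = 20.0, 8.0
        x = rng.normal(50, sigma_s, 1000)[:, None] \
            + rng.normal(0, sigma_e, (1000, 5))
        icc, _, _ = icc_two_way(x)
        expected = sigma_s ** 2 / (sigma_s ** 2 + sigma_e ** 2)
        assert abs(icc - expected) <= 0.03

    def test_rater_offset_lowers_icc_but_not_rho(self):
        x = np.linspace(0, 80, 30)
        shifted = np.column_stack([x, x + 15])
        icc, _, _ = icc_two_way(shifted)
        assert icc < 1.0
        assert pearson_rho(x, x + 15) == pytest.approx(1.0)

    def test_no_variance_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            icc_two_way(np.full((5, 3), 7.0))

    def test_too_small_matrix_rejected(self):
        with pytest.raises(ValueError):
            icc_two_way(np.array([[1.0, 2.0]]))


class TestInterpretation:
    @pytest.mark.parametrize("icc,label", [
        (0.884, "excellent"),
        (0.862, "excellent"),
        (0.841, "excellent"),
        (0.20, "poor"), (0.21, "fair"),
        (0.40, "fair"), (0.41, "moderate"),
        (0.60, "moderate"), (0.61, "substantial"),
        (0.80, "substantial"), (0.81, "excellent"),
        (1.0, "excellent"), (-0.3, "poor"), (0.0, "poor"),
    ])
    def test_scale(self, icc, label):
        assert icc_interpretation(icc) == label

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            icc_interpretation(1.5)


class TestWeightedKappa:
    def test_identical_vectors_give_one(self):
        v = np.array([0, 5, 10, 50, 100, 25, 75], dtype=float)
        assert quadratic_weighted_kappa(v, v) == pytest.approx(1.0)

    def test_near_equivalence_with_icc_on_snapped_panels(self):
        rng = np.random.default_rng(11)
        truth = rng.uniform(0, 100, 500)
        a = snap_to_grid(np.clip(truth + rng.normal(0, 8, 500), 0, 100))
        b = snap_to_grid(np.clip(truth + rng.normal(0, 8, 500), 0, 100))
        kappa = quadratic_weighted_kappa(a, b)
        icc, _, _ = icc_two_way(np.column_stack([a, b]))
        assert abs(kappa - icc) <= 0.02

    def test_independent_ratings_near_zero(self):
        rng = np.random.default_rng(13)
        a = snap_to_grid(rng.uniform(0, 100, 4000))
        b = snap_to_grid(rng.uniform(0, 100, 4000))
        assert abs(quadratic_weighted_kappa(a, b)) <= 0.05

    def test_constant_ratings_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            quadratic_weighted_kappa([50.0] * 10, [50.0] * 10)


class TestPearson:
    def test_linear_transform_gives_one_while_icc_does_not(self):
        x = np.linspace(0, 40, 20)
        y = 2 * x + 5
        assert pearson_rho(x, y) == pytest.approx(1.0)
        icc, _, _ = icc_two_way(np.column_stack([x, y]))
        assert icc < 1.0

    def test_identity(self):
        x = np.array([1.0, 4.0, 9.0, 16.0])
        assert pearson_rho(x, x) == pytest.approx(1.0)

    def test_matches_longhand_formula(self):
        x = [2.0, 4.0, 5.0, 7.0, 9.0]
        y = [3.0, 5.0, 4.0, 8.0, 10.0]
        n = len(x)
        mx, my = sum(x) / n, sum(y) / n
        num = sum((a - mx) * (b - my) for a, b in zip(x, y))
        den = (sum((a - mx) ** 2 for a in x)
               * sum((b - my) ** 2 for b in y)) ** 0.5
        assert pearson_rho(x, y) == pytest.approx(num / den, abs=1e-12)

    def test_zero_variance_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            pearson_rho([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_hand_case(self):
        result = bland_altman([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert result.bias == pytest.approx(2.0)
        assert result.loa_low == pytest.approx(0.04)
        assert result.loa_high == pytest.approx(3.96)

    def test_identical_vectors(self):
        result = bland_altman([1.0, 2.0], [1.0, 2.0])
        assert result.bias == 0.0
        assert result.loa_low == 0.0 and result.loa_high == 0.0

    def test_swap_negates_bias_exactly(self):
        rng = np.random.default_rng(17)
        a, b = rng.uniform(0, 100, 40), rng.uniform(0, 100, 40)
        fwd, rev = bland_altman(a, b), bland_altman(b, a)
        assert fwd.bias == -rev.bias
        assert fwd.loa_low == pytest.approx(-rev.loa_high)

    def test_bias_inside_limits_and_gaussian_coverage(self):
        rng = np.random.default_rng(19)
        d = rng.normal(1.5, 3.0, 10_000)
        result = bland_altman(d, np.zeros_like(d))
        assert result.loa_low <= result.bias <= result.loa_high
        covered = np.mean((d >= result.loa_low) & (d <= result.loa_high))
        assert 0.93 <= covered <= 0.97

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bland_altman([1.0, 2.0], [1.0])


class TestWithinOneBirads:
    def test_identical_vectors(self):
        v = np.array([10.0, 30.0, 60.0, 90.0])
        assert within_one_birads(v, v) == 1.0

    def test_three_category_gap_scores_zero(self):
        assert within_one_birads([10.0] * 4, [90.0] * 4) == 0.0

    def test_enumerated_ten_pair_fixture(self):
        # eight concordant-or-adjacent pairs, two 2-category discordances
        reference = [10.0, 30.0, 55.0, 80.0, 20.0, 60.0, 90.0, 40.0,
                     10.0, 90.0]
        algorithm = [10.0, 40.0, 60.0, 90.0, 30.0, 50.0, 80.0, 30.0,
                     60.0, 30.0]
        assert within_one_birads(reference, algorithm) == pytest.approx(0.8)


class TestCategorySummary:
    def test_single_occupied_category(self):
        summaries = category_distribution_summary(
            [10.0, 12.0, 15.0], [1, 1, 1])
        assert summaries[1] is not None
        assert summaries[2] is None and summaries[3] is None \
            and summaries[4] is None

    def test_documented_quartile_convention(self):
        summaries = category_distribution_summary(
            [0.0, 10.0, 20.0, 30.0, 40.0], [1] * 5)
        box = summaries[1]
        assert box["median"] == 20.0
        assert box["q1"] == 10.0 and box["q3"] == 30.0

    def test_box_against_percentile_oracle(self):
        rng = np.random.default_rng(23)
        values = rng.uniform(0, 100, 200)
        cats = rng.integers(1, 5, 200)
        summaries = category_distribution_summary(values, cats)
        for cat in (1, 2, 3, 4):
            sub = np.sort(values[cats == cat])
            box = summaries[cat]
            # longhand linear-interpolation percentile
            for q, key in ((0.25, "q1"), (0.5, "median"), (0.75, "q3")):
                pos = q * (len(sub) - 1)
                lo, frac = int(np.floor(pos)), pos - np.floor(pos)
                expected = sub[lo] * (1 - frac) + sub[min(lo + 1,
                                                          len(sub) - 1)] * frac
                assert box[key] == pytest.approx(expected, abs=1e-9)
            assert box["whisker_low"] >= box["q1"] - 1.5 * (box["q3"]
                                                            - box["q1"])


class TestEvaluate:
    def test_algorithm_equal_to_reference_is_perfect(self):
        truths = np.linspace(0.05, 0.95, 20)
        panel = simulate_rater_panel(
            truths, RaterModel(n_raters=5, noise_sd=0.0, seed=0))
        reference = reference_standard(panel)
        report = evaluate(panel, reference)
        assert report.icc == 1.0
        assert report.bias == 0.0
        assert report.within_one_birads == 1.0
        assert report.promising is True

    def test_end_to_end_synthetic_report_invariants(self):
        rng = np.random.default_rng(29)
        truths = rng.uniform(0, 1, 80)
        panel = simulate_rater_panel(
            truths, RaterModel(n_raters=5, noise_sd=5.0, seed=30))
        algorithm = np.clip(100 * truths + rng.normal(0, 6, 80), 0, 100)
        report = evaluate(panel, algorithm)
        report.validate()
        assert report.icc_ci_low <= report.icc <= report.icc_ci_high
        assert report.loa_low <= report.bias <= report.loa_high
        assert report.n_subjects == 80
        assert report.icc_label in ("poor", "fair", "moderate",
                                    "substantial", "excellent")
        assert set(report.category_summaries) == {1, 2, 3, 4}
        payload = report.to_dict()
        assert payload["promising"] in (True, False)

    def test_misaligned_algorithm_rejected(self):
        panel = simulate_rater_panel([0.2, 0.4], RaterModel(seed=1))
        with pytest.raises(ValueError):
            evaluate(panel, np.array([20.0]))
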