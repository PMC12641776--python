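"""Descriptive tables, inter-rater agreement, correlations, age trends."""

import numpy as np
import pandas as pd
import pytest

from oracles import icc3k_anova_table, pearson_formula
from retimosaic import (
    age_trend,
    generate_rater_matrix,
    icc3k,
    normalized_range,
    pearson_matrix,
    summarize,
    within_range_check,
)


class TestSummarize:
    def test_constant_vector(self):
        t = summarize([5.0] * 8)
        row = t[t.stratum == "total"].iloc[0]
        assert row["mean"] == row["median"] == row.p25 == row.p75 == 5.0
        assert row["std"] == 0.0

    def test_linear_interpolation_quartiles(self):
        t = summarize([1, 2, 3, 4, 5])
        row = t.iloc[-1]
        assert row["median"] == 3.0
        assert row.p25 == 2.0 and row.p75 == 4.0

    def test_pooled_total_is_weighted_combination(self):
        vals = np.array([1.0, 2.0, 3.0, 10.0, 20.0])
        strata = np.array(["f", "f", "f", "m", "m"])
        t = summarize(vals, strata).set_index("stratum")
        pooled = (t.loc["f", "mean"] * 3 + t.loc["m", "mean"] * 2) / 5
        assert t.loc["total", "mean"] == pytest.approx(pooled)

    def test_empty_stratum_warns(self):
        with pytest.warns(UserWarning):
            summarize(np.array([1.0, np.nan]), np.array(["a", "b"]))


class TestICC3k:
    def test_perfect_agreement(self):
        x = np.tile(np.array([[10.0], [20.0], [30.0]]), (1, 4))
        icc, (lo, hi) = icc3k(x)
        assert icc == 1.0 and lo == 1.0 and hi == 1.0

    def test_rater_offsets_do_not_matter(self):
        base = np.array([10.0, 14.0, 19.0, 23.0, 31.0])
        x = np.column_stack([base, base + 3, base - 7])
        icc, _ = icc3k(x)
        assert icc == pytest.approx(1.0)

    def test_hand_built_matrix_matches_anova_oracle(self):
        x = np.array(
            [
                [9, 2, 5],
                [6, 1, 3],
                [8, 4, 6],
                [7, 1, 2],
                [10, 5, 6],
                [6, 2, 4],
            ],
            dtype=float,
        )
        icc, _ = icc3k(x)
        assert icc == pytest.approx(icc3k_anova_table(x), abs=1e-12)

    def test_matches_pingouin(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(8)
        x = rng.normal(50, 10, size=(12, 4)) + rng.normal(0, 4, size=(12, 1))
        n, k = x.shape
        long = pd.DataFrame(
            {
                "targets": np.repeat(np.arange(n), k),
                "raters": np.tile(np.arange(k), n),
                "score": x.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="targets", raters="raters", ratings="score"
        ).set_index("Type")
        icc, (lo, hi) = icc3k(x)
        # pingouin labels the two-way mixed consistency average as ICC(C,k)
        assert icc == pytest.approx(ref.loc["ICC(C,k)", "ICC"], abs=1e-9)
        ref_lo, ref_hi = ref.loc["ICC(C,k)", "CI95"]
        assert lo == pytest.approx(ref_lo, abs=0.005)
        assert hi == pytest.approx(ref_hi, abs=0.005)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        x = rng.normal(100, 20, size=(10, 5))
        a, _ = icc3k(x)
        b, _ = icc3k(3.7 * x)
        assert a == pytest.approx(b, abs=1e-12)

    def test_zero_between_target_variance_rejected(self):
        with pytest.raises(ValueError):
            icc3k(np.full((5, 3), 7.0))

    def test_good_raters_give_high_icc(self):
        rng = np.random.default_rng(10)
        truth = rng.integers(150, 600, size=90)
        df = generate_rater_matrix(truth, k=5, miss_rate=0.05, extra_rate=0.05, seed=4)
        icc, _ = icc3k(df.drop(columns="patch_id").to_numpy(dtype=float))
        assert icc > 0.7


class TestNormalizedRange:
    @pytest.mark.parametrize(
        "counts,expected",
        [([5, 5, 5], 0.0), ([4, 5, 6], 0.4), ([8, 10, 12, 10, 10], 0.4)],
    )
    def test_hand_arithmetic(self, counts, expected):
        assert normalized_range(counts) == pytest.approx(expected)

    def test_scale_invariance(self):
        assert normalized_range([8, 12, 10]) == pytest.approx(
            normalized_range([80, 120, 100])
        )

    def test_zero_mean_rejected(self):
        with pytest.raises(ValueError):
            normalized_range([0, 0, 0])


class TestWithinRangeCheck:
    def test_plain_interval_when_fully_unmasked(self):
        assert within_range_check(50, [48, 52, 55], 1.0)
        assert not within_range_check(60, [48, 52, 55], 1.0)

    def test_mask_adjustment(self):
        # 25 raw counts on a half-unmasked patch project to 50
        assert within_range_check(25, [48, 52, 55], 0.5)

    def test_adjusted_above_max_fails(self):
        assert not within_range_check(30, [48, 52, 55], 0.5)

    def test_zero_unmasked_fraction_rejected(self):
        with pytest.raises(ValueError):
            within_range_check(10, [5, 15], 0.0)


class TestPearsonMatrix:
    def test_exact_linear_relations(self):
        x = np.arange(10.0)
        df = pd.DataFrame({"x": x, "up": 2 * x + 1, "down": -x})
        m = pearson_matrix(df)
        assert m["r"].loc["x", "up"] == pytest.approx(1.0)
        assert m["r"].loc["x", "down"] == pytest.approx(-1.0)
        assert np.allclose(np.diag(m["r"]), 1.0)

    def test_fixture_matches_formula_oracle(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=10)
        y = 0.5 * x + rng.normal(scale=0.8, size=10)
        m = pearson_matrix(pd.DataFrame({"x": x, "y": y}))
        r_ref, p_ref = pearson_formula(x, y)
        assert m["r"].loc["x", "y"] == pytest.approx(r_ref, abs=1e-12)
        assert m["p"].loc["x", "y"] == pytest.approx(p_ref, rel=1e-9)

    def test_symmetry_and_flag(self):
        rng = np.random.default_rng(12)
        df = pd.DataFrame(rng.normal(size=(50, 3)), columns=list("abc"))
        df["d"] = df["a"] * 3 + 0.01 * rng.normal(size=50)
        m = pearson_matrix(df)
        assert np.allclose(m["r"].to_numpy(), m["r"].to_numpy().T)
        assert m["flag"].loc["a", "d"]  # near-perfect relation: p << 0.001
        assert not m["flag"].loc["a", "b"]

    def test_zero_variance_column_reported_missing(self):
        df = pd.DataFrame({"x": np.arange(5.0), "c": np.ones(5)})
        m = pearson_matrix(df)
        assert np.isnan(m["r"].loc["x", "c"])

    def test_affine_invariance(self):
        rng = np.random.default_rng(13)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = pearson_matrix(pd.DataFrame({"x": x, "y": y}))["r"].loc["x", "y"]
        b = pearson_matrix(pd.DataFrame({"x": 5 * x + 2, "y": 0.1 * y - 9}))["r"].loc["x", "y"]
        assert a == pytest.approx(b)


class TestAgeTrend:
    def test_exact_linear_recovery(self):
        age = np.array([25.0, 40.0, 55.0, 70.0])
        dens = 7000 - 12.5 * age
        fit = age_trend(dens, age)
        assert fit.slope == pytest.approx(-12.5)
        assert fit.rvalue == pytest.approx(-1.0)

    def test_noisy_negative_slope_detected(self):
        rng = np.random.default_rng(14)
        age = rng.uniform(23, 80, 40)
        dens = 7300 - 20 * age + rng.normal(0, 300, 40)
        fit = age_trend(dens, age)
        assert fit.slope < 0 and fit.pvalue < 0.05

    def test_flat_cohort_slope_ci_covers_zero(self):
        rng = np.random.default_rng(15)
        age = rng.uniform(23, 80, 40)
        dens = 10200 + rng.normal(0, 400, 40)
        fit = age_trend(dens, age)
        assert abs(fit.slope) < 2 * fit.stderr or fit.pvalue > 0.05

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            age_trend([1, 2, 3], [50, 50, 50])
        with pytest.raises(ValueError):
            age_trend([1, 2], [40, 50])
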