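"""Regression, AICc ranking, ANOVA/Tukey, and correlation operations."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from phloemetrics.trait_stats import (
    StatsError,
    aicc,
    correlation_matrix,
    multiple_linreg,
    rank_models,
    simple_linreg,
    tukey_hsd,
    two_way_anova,
)


class TestSimpleRegression:
    def test_exact_line(self):
        x = np.arange(10.0)
        res = simple_linreg(x, 2 * x + 1)
        assert res.coefficients["slope"] == pytest.approx(2.0)
        assert res.coefficients["intercept"] == pytest.approx(1.0)
        assert res.r2 == pytest.approx(1.0)

    def test_constant_response_convention(self):
        res = simple_linreg(np.arange(10.0), np.full(10, 3.0))
        assert res.r2 == 0.0
        assert res.coefficients["slope"] == pytest.approx(0.0, abs=1e-12)

    def test_constant_x_rejected(self):
        with pytest.raises(StatsError, match="degenerate"):
            simple_linreg(np.full(10, 2.0), np.arange(10.0))

    def test_normal_equations_oracle(self, rng):
        x = rng.normal(0, 2, 40)
        y = 1.5 * x - 0.7 + rng.normal(0, 0.5, 40)
        res = simple_linreg(x, y)
        design = np.column_stack([np.ones(40), x])
        beta = np.linalg.solve(design.T @ design, design.T @ y)
        assert res.coefficients["intercept"] == pytest.approx(beta[0], abs=1e-10)
        assert res.coefficients["slope"] == pytest.approx(beta[1], abs=1e-10)
        # r² equals the squared Pearson correlation
        assert res.r2 == pytest.approx(stats.pearsonr(x, y).statistic ** 2, rel=1e-10)

    def test_residual_orthogonality(self, rng):
        x = rng.normal(0, 1, 30)
        y = x + rng.normal(0, 1, 30)
        res = simple_linreg(x, y)
        fitted = res.coefficients["intercept"] + res.coefficients["slope"] * x
        resid = y - fitted
        assert abs(resid.sum()) < 1e-8
        assert abs((resid * x).sum()) < 1e-8


class TestMultipleRegression:
    def test_orthogonal_predictors_match_univariate(self):
        n = 16
        x1 = np.tile([1.0, -1.0], n // 2)
        x2 = np.repeat([1.0, -1.0], n // 2)
        y = 3 * x1 - 2 * x2 + 5
        res = multiple_linreg(pd.DataFrame({"x1": x1, "x2": x2}), y)
        s1 = simple_linreg(x1, y).coefficients["slope"]
        s2 = simple_linreg(x2, y).coefficients["slope"]
        assert res.coefficients["x1"] == pytest.approx(s1)
        assert res.coefficients["x2"] == pytest.approx(s2)

    def test_duplicate_predictor_detected(self, rng):
        x = rng.normal(0, 1, 20)
        X = pd.DataFrame({"a": x, "b": x})
        with pytest.raises(StatsError, match="collinear"):
            multiple_linreg(X, rng.normal(0, 1, 20))

    def test_pseudo_inverse_oracle(self, rng):
        X = pd.DataFrame(rng.normal(0, 1, (30, 3)), columns=["a", "b", "c"])
        y = rng.normal(0, 1, 30)
        res = multiple_linreg(X, y)
        design = np.column_stack([np.ones(30), X.to_numpy()])
        beta = np.linalg.pinv(design) @ y
        assert np.allclose(res.coefficients.to_numpy(), beta, atol=1e-10)


class TestAicc:
    def test_penalty_monotonicity(self):
        assert aicc(10.0, 20, 3) < aicc(10.0, 20, 4)

    def test_hand_computed_example(self):
        # 3 predictors + intercept: k_params=4, k=5, n=14, rss=2.5
        n, rss, k = 14, 2.5, 5
        expected = n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)
        assert aicc(rss, n, 4) == pytest.approx(expected)

    def test_converges_to_aic(self):
        n = 10**6
        k = 3  # k_params 2 -> k=3
        aic = n * math.log(5.0 / n) + 2 * k
        assert aicc(5.0, n, 2) == pytest.approx(aic, abs=1e-3)

    def test_small_sample_undefined(self):
        with pytest.raises(StatsError, match="undefined"):
            aicc(1.0, 5, 4)


class TestRankModels:
    def test_single_candidate(self, rng):
        data = pd.DataFrame({"x": rng.normal(0, 1, 15)})
        data["y"] = 2 * data["x"] + rng.normal(0, 0.3, 15)
        out = rank_models([("only", ["x"])], data, "y")
        assert len(out) == 1
        assert out.loc[0, "significant"]

    def test_nested_equal_fit_ranks_by_penalty(self, rng):
        x1 = rng.normal(0, 1, 24)
        x2 = rng.normal(0, 1, 24)  # irrelevant
        y = 2 * x1 + rng.normal(0, 0.01, 24)
        data = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        out = rank_models([("small", ["x1"]), ("big", ["x1", "x2"])], data, "y")
        assert out.loc[0, "model_label"] == "small"

    def test_synthetic_panel_favors_pedicel_model(self):
        """A panel built with a pedicel-area effect ranks the pedicel model
        above physiology-only models."""
        from phloemetrics.pipeline import run_all
        from phloemetrics.synthetic import SyntheticConfig

        report = run_all(SyntheticConfig(seed=11, n_cultivars=18))
        ledger = pd.DataFrame(report["model_ledger"])
        pos = {row.model_label: i for i, row in ledger.iterrows()}
        assert pos["pedicel"] < pos["physiology"]
        assert pos["pedicel"] < pos["photosynthesis"]
        assert pos["pedicel"] < pos["water potential"]

    def test_ordering_invariant_to_predictor_rescaling(self, rng):
        x1 = rng.normal(0, 1, 20)
        x2 = rng.normal(0, 1, 20)
        y = x1 + 0.5 * x2 + rng.normal(0, 0.4, 20)
        cands = [("m1", ["x1"]), ("m2", ["x2"]), ("m12", ["x1", "x2"])]
        d1 = pd.DataFrame({"x1": x1, "x2": x2, "y": y})
        d2 = pd.DataFrame({"x1": 1e4 * x1 + 7, "x2": x2 / 1e3, "y": y})
        order1 = rank_models(cands, d1, "y")["model_label"].tolist()
        order2 = rank_models(cands, d2, "y")["model_label"].tolist()
        assert order1 == order2


class TestAnova:
    def test_equal_group_means_not_significant(self):
        # identical within-group patterns => all F = 0, p = 1
        pattern = [0.3, -0.7, 1.1, 0.2]
        df = pd.DataFrame(
            {
                "y": pattern * 4,
                "a": ["a1"] * 8 + ["a2"] * 8,
                "b": (["b1"] * 4 + ["b2"] * 4) * 2,
            }
        )
        res = two_way_anova(df, "y", "a", "b")
        assert res.table.loc["a", "PR(>F)"] == pytest.approx(1.0)
        assert res.table.loc["b", "PR(>F)"] == pytest.approx(1.0)

    def test_one_way_equals_squared_t(self, rng):
        y = np.r_[rng.normal(0, 1, 8), rng.normal(1, 1, 8)]
        df = pd.DataFrame({"y": y, "g": ["a"] * 8 + ["b"] * 8})
        res = two_way_anova(df, "y", "g")
        t = stats.ttest_ind(y[:8], y[8:])
        assert res.table.loc["g", "F"] == pytest.approx(t.statistic**2, rel=1e-10)
        assert res.table.loc["g", "PR(>F)"] == pytest.approx(t.pvalue, rel=1e-10)

    def test_balanced_2x2_hand_decomposition(self):
        # textbook balanced 2x2 with 2 replicates per cell
        cells = {("a1", "b1"): [10.0, 12.0], ("a1", "b2"): [14.0, 16.0],
                 ("a2", "b1"): [20.0, 22.0], ("a2", "b2"): [24.0, 28.0]}
        rows = [(y, a, b) for (a, b), ys in cells.items() for y in ys]
        df = pd.DataFrame(rows, columns=["y", "a", "b"])
        y = df["y"].to_numpy()
        grand = y.mean()
        ss_a = sum(
            4 * (df[df.a == lvl]["y"].mean() - grand) ** 2 for lvl in ("a1", "a2")
        )
        ss_b = sum(
            4 * (df[df.b == lvl]["y"].mean() - grand) ** 2 for lvl in ("b1", "b2")
        )
        res = two_way_anova(df, "y", "a", "b")
        assert res.table.loc["a", "sum_sq"] == pytest.approx(ss_a)
        assert res.table.loc["b", "sum_sq"] == pytest.approx(ss_b)

    def test_empty_cell_interaction_rejected(self):
        df = pd.DataFrame(
            {"y": [1.0, 2, 3, 4, 5, 6],
             "a": ["a1", "a1", "a1", "a2", "a2", "a2"],
             "b": ["b1", "b1", "b2", "b1", "b1", "b1"]}
        )
        df = df[~((df.a == "a2") & (df.b == "b2"))]
        with pytest.raises(StatsError, match="empty"):
            two_way_anova(df, "y", "a", "b", interaction=True)

    def test_single_level_factor_rejected(self):
        df = pd.DataFrame({"y": [1.0, 2, 3], "a": ["x"] * 3})
        with pytest.raises(StatsError, match="levels"):
            two_way_anova(df, "y", "a")


class TestTukey:
    def test_two_groups_match_unadjusted_t(self, rng):
        y = np.r_[rng.normal(0, 1, 7), rng.normal(0.8, 1, 9)]
        g = np.array(["a"] * 7 + ["b"] * 9)
        out = tukey_hsd(y, g)
        t = stats.ttest_ind(y[:7], y[7:])
        assert out.loc[0, "p_adj"] == pytest.approx(t.pvalue, rel=1e-9)

    def test_identical_groups_share_letter(self):
        y = np.tile([1.0, 2.0, 3.0], 3)
        g = np.repeat(["a", "b", "c"], 3)
        out = tukey_hsd(y[np.argsort(g)], np.sort(g))
        assert (out["p_adj"] > 0.99).all()
        letters = out.attrs["letters"]
        assert len(set(letters.values())) == 1

    def test_shifted_group_gets_own_letter(self, rng):
        y = np.r_[rng.normal(0, 0.3, 6), rng.normal(0.1, 0.3, 6), rng.normal(10, 0.3, 6)]
        g = np.repeat(["a", "b", "c"], 6)
        out = tukey_hsd(y, g)
        letters = out.attrs["letters"]
        assert letters["a"] == letters["b"]
        assert letters["c"] != letters["a"]

    def test_single_observation_group_rejected(self):
        with pytest.raises(StatsError, match="single"):
            tukey_hsd([1.0, 2.0, 3.0], ["a", "a", "b"])


class TestCorrelationMatrix:
    def test_self_and_exact_negative(self):
        x = np.arange(10.0)
        r, p = correlation_matrix(pd.DataFrame({"x": x, "neg": -x}))
        assert r.loc["x", "x"] == 1.0
        assert r.loc["x", "neg"] == pytest.approx(-1.0)

    def test_matches_direct_covariance(self, rng):
        table = pd.DataFrame(rng.normal(0, 1, (25, 3)), columns=list("abc"))
        r, p = correlation_matrix(table)
        for c1, c2 in [("a", "b"), ("a", "c"), ("b", "c")]:
            direct = np.corrcoef(table[c1], table[c2])[0, 1]
            assert r.loc[c1, c2] == pytest.approx(direct, rel=1e-10)

    def test_insufficient_pairs_flagged(self):
        table = pd.DataFrame(
            {"a": [1.0, 2.0, np.nan, np.nan], "b": [np.nan, 1.0, 2.0, 3.0],
             "c": [1.0, 2.0, 3.0, 4.0]}
        )
        r, p = correlation_matrix(table, min_pairs=3)
        assert np.isnan(r.loc["a", "b"])  # only one complete pair
        assert not np.isnan(r.loc["b", "c"])
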