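"""OLS, backward elimination, median-split encoding, pattern ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from glycowear import inference as inf
from glycowear.inference import (
    RankDeficientError,
    backward_eliminate,
    fit_ols,
    median_split_encode,
    pattern_anova,
)


class TestFitOLS:
    def test_near_noiseless_slope_recovered(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=50)
        df = pd.DataFrame({"x": x, "y": 2.0 * x + rng.normal(0, 1e-8, 50)})
        fit = fit_ols(df, "y", ["x"])
        assert fit.table.loc["x", "coef"] == pytest.approx(2.0, abs=1e-6)
        assert fit.table.loc["x", "p"] < 1e-20

    def test_matches_normal_equations_on_hand_table(self):
        df = pd.DataFrame(
            {"x1": [1.0, 2.0, 3.0, 4.0, 5.0],
             "x2": [2.0, 1.0, 4.0, 3.0, 7.0],
             "y": [3.0, 5.0, 4.0, 8.0, 9.0]}
        )
        fit = fit_ols(df, "y", ["x1", "x2"])
        X = np.column_stack([np.ones(5), df["x1"], df["x2"]])
        beta = np.linalg.solve(X.T @ X, X.T @ df["y"].to_numpy())
        assert np.allclose(fit.table["coef"].to_numpy(), beta, atol=1e-10)

    def test_complete_case_deletion_counted(self):
        df = pd.DataFrame({"x": [1, 2, 3, 4, 5, np.nan], "y": [1, 2, 3, 4, np.nan, 6.0]})
        fit = fit_ols(df, "y", ["x"])
        assert fit.n_used == 4 and fit.n_dropped == 2

    def test_pvalues_uniform_under_null(self):
        rng = np.random.default_rng(1)
        ps = []
        for _ in range(500):
            df = pd.DataFrame({"x": rng.normal(size=200), "y": rng.normal(size=200)})
            ps.append(fit_ols(df, "y", ["x"]).table.loc["x", "p"])
        frac = np.mean(np.array(ps) < 0.05)
        assert abs(frac - 0.05) <= 3 * np.sqrt(0.05 * 0.95 / 500)

    def test_rank_deficiency_names_collinear_columns(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=30)
        df = pd.DataFrame({"a": x, "b": 2 * x, "c": rng.normal(size=30), "y": rng.normal(size=30)})
        with pytest.raises(RankDeficientError, match="a|b"):
            fit_ols(df, "y", ["a", "b", "c"])

    def test_too_few_rows_fatal(self):
        df = pd.DataFrame({"x": [1.0, 2.0], "y": [1.0, 2.0]})
        with pytest.raises(ValueError, match="complete rows"):
            fit_ols(df, "y", ["x"])


class TestBackwardEliminate:
    def test_single_strong_predictor_retained(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=100)
        df = pd.DataFrame({"x": x, "y": 10.0 * x + rng.normal(size=100)})
        res = backward_eliminate(df, "y", ["x"])
        assert res.retained_predictors == ["x"] and res.removed_trace == []

    def test_noise_predictors_eliminated_strong_kept(self):
        rng = np.random.default_rng(4)
        n = 200
        df = pd.DataFrame(rng.normal(size=(n, 9)), columns=[f"n{i}" for i in range(9)])
        df["s"] = rng.normal(size=n)
        df["y"] = 0.5 * df["s"] + rng.normal(size=n)
        res = backward_eliminate(df, "y", ["s", *[f"n{i}" for i in range(9)]])
        assert "s" in res.retained_predictors
        assert all(res.retained.loc[p, "p"] < 0.20 for p in res.retained_predictors)

    def test_trace_records_running_maximum_p(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(120, 6)), columns=[f"n{i}" for i in range(6)])
        df["y"] = rng.normal(size=120)
        res = backward_eliminate(df, "y", [f"n{i}" for i in range(6)])
        # audit: replay the elimination and verify each removal was the max p
        remaining = [f"n{i}" for i in range(6)]
        for name, p_at_removal in res.removed_trace:
            fit = fit_ols(df, "y", remaining)
            ps = {c: fit.pvalue(c) for c in remaining}
            assert p_at_removal == pytest.approx(max(ps.values()), abs=1e-12)
            assert ps[name] == pytest.approx(p_at_removal, abs=1e-12)
            assert p_at_removal >= 0.20
            remaining.remove(name)
        assert remaining == res.retained_predictors

    def test_final_model_reproducible_by_direct_refit(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(150, 5)), columns=list("abcde"))
        df["y"] = 0.8 * df["a"] - 0.6 * df["b"] + rng.normal(size=150)
        res = backward_eliminate(df, "y", list("abcde"))
        refit = fit_ols(df, "y", res.retained_predictors)
        assert np.array_equal(refit.table["coef"].to_numpy(), res.retained["coef"].to_numpy())

    def test_forced_covariate_never_removed(self):
        rng = np.random.default_rng(7)
        df = pd.DataFrame({"sex": rng.integers(0, 2, 100).astype(float),
                           "x": rng.normal(size=100)})
        df["y"] = rng.normal(size=100)  # sex is pure noise but forced
        res = backward_eliminate(df, "y", ["x"], forced=["sex"])
        assert "sex" in res.retained.index
        assert all(name != "sex" for name, _ in res.removed_trace)

    def test_sex_adjustment_changes_only_forced_column(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame({"x": rng.normal(size=200), "sex": rng.integers(0, 2, 200).astype(float)})
        df["y"] = 1.0 * df["x"] + rng.normal(size=200)
        plain = backward_eliminate(df, "y", ["x"])
        adjusted = backward_eliminate(df, "y", ["x"], forced=["sex"])
        assert set(adjusted.retained.index) - set(plain.retained.index) == {"sex"}

    def test_noise_candidate_retained_near_alpha_rate(self):
        # a single pure-noise candidate survives with probability ~ alpha
        rng = np.random.default_rng(9)
        kept = 0
        for _ in range(300):
            df = pd.DataFrame({"x": rng.normal(size=60)})
            df["y"] = rng.normal(size=60)
            res = backward_eliminate(df, "y", ["x"], alpha=0.20)
            kept += res.retained_predictors == ["x"]
        assert abs(kept / 300 - 0.20) <= 3 * np.sqrt(0.2 * 0.8 / 300)


class TestMedianSplitEncode:
    def test_four_values_split_at_midpoint(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0, 4.0]})
        pt = median_split_encode(df, ["v"])
        assert list(pt.data["pattern"]) == ["0", "0", "1", "1"]
        assert pt.medians["v"] == 2.5

    def test_value_at_median_coded_zero(self):
        df = pd.DataFrame({"v": [1.0, 2.0, 3.0]})
        pt = median_split_encode(df, ["v"])
        assert list(pt.data["pattern"]) == ["0", "0", "1"]

    def test_codes_match_per_variable_recomputation(self):
        rng = np.random.default_rng(10)
        df = pd.DataFrame(rng.normal(size=(16, 4)), columns=list("wxyz"))
        pt = median_split_encode(df, list("wxyz"))
        for i, (_, row) in enumerate(df.iterrows()):
            expected = "".join(
                "1" if row[v] > df[v].median() else "0" for v in "wxyz"
            )
            assert pt.data["pattern"].iloc[i] == expected

    def test_rows_with_missing_variable_excluded_and_counted(self):
        df = pd.DataFrame({"v": [1.0, np.nan, 3.0, 4.0], "w": [1.0, 2.0, 3.0, np.nan]})
        pt = median_split_encode(df, ["v", "w"])
        assert pt.n_excluded == 2 and len(pt.data) == 2

    def test_reencoding_with_fixed_medians_is_noop(self):
        rng = np.random.default_rng(11)
        df = pd.DataFrame(rng.normal(size=(20, 2)), columns=["a", "b"])
        pt = median_split_encode(df, ["a", "b"])
        again = median_split_encode(pt.data, ["a", "b"], medians=pt.medians)
        assert list(again.data["pattern"]) == list(pt.data["pattern"])

    def test_constant_variable_fatal(self):
        df = pd.DataFrame({"v": [2.0, 2.0, 2.0, 2.0]})
        with pytest.raises(ValueError, match="constant"):
            median_split_encode(df, ["v"])


def _pattern_table(groups: dict[str, list[float]], nvars: int = 1) -> inf.PatternTable:
    rows = []
    for code, vals in groups.items():
        for v in vals:
            rows.append({"pattern": code, "y": v})
    return inf.PatternTable(
        variables=[f"v{i}" for i in range(nvars)],
        medians={},
        data=pd.DataFrame(rows),
        n_excluded=0,
    )


class TestPatternAnova:
    def test_two_group_f_equals_t_squared(self):
        rng = np.random.default_rng(12)
        pt = _pattern_table({"0": list(rng.normal(0, 1, 12)), "1": list(rng.normal(0.5, 1, 9))})
        res = pattern_anova(pt, "y", min_group_n=2)
        t, _ = stats.ttest_ind(
            pt.data.loc[pt.data.pattern == "1", "y"],
            pt.data.loc[pt.data.pattern == "0", "y"],
            equal_var=True,
        )
        assert res.f == pytest.approx(t**2, abs=1e-10)

    def test_identical_groups_give_zero_f(self):
        pt = _pattern_table({"0": [1.0, 2.0, 3.0], "1": [1.0, 2.0, 3.0]})
        res = pattern_anova(pt, "y", min_group_n=2)
        assert res.f == pytest.approx(0.0)
        assert res.groups["mean"].nunique() == 1

    def test_three_balanced_groups_textbook_f(self):
        groups = {"00": [1.0, 2.0, 3.0], "01": [2.0, 3.0, 4.0], "10": [4.0, 5.0, 6.0]}
        pt = _pattern_table(groups, nvars=2)
        res = pattern_anova(pt, "y", min_group_n=2)
        all_vals = np.concatenate([np.array(v) for v in groups.values()])
        grand = all_vals.mean()
        ss_between = sum(len(v) * (np.mean(v) - grand) ** 2 for v in groups.values())
        ss_within = sum(((np.array(v) - np.mean(v)) ** 2).sum() for v in groups.values())
        f_oracle = (ss_between / 2) / (ss_within / 6)
        assert res.f == pytest.approx(f_oracle, abs=1e-10)
        assert res.df_between == 2 and res.df_within == 6

    def test_shifted_groups_contrast_within_2se_of_shift(self):
        rng = np.random.default_rng(13)
        delta = 1.5
        pt = _pattern_table({"0": list(rng.normal(0, 1, 60)), "1": list(rng.normal(delta, 1, 60))})
        res = pattern_anova(pt, "y", min_group_n=5)
        diff = res.contrasts.set_index("pattern").loc["1", "diff"]
        se = np.sqrt(2 / 60)  # known unit variance
        assert abs(diff - delta) <= 2 * se

    def test_small_groups_dropped_matches_size_count(self):
        rng = np.random.default_rng(14)
        groups = {"00": list(rng.normal(size=10)), "01": list(rng.normal(size=3)),
                  "10": list(rng.normal(size=7)), "11": list(rng.normal(size=4))}
        pt = _pattern_table(groups, nvars=2)
        res = pattern_anova(pt, "y", min_group_n=5)
        expected_dropped = sorted(c for c, v in groups.items() if len(v) < 5)
        assert res.dropped_groups == expected_dropped
        assert sorted(res.groups["pattern"]) == sorted(
            c for c, v in groups.items() if len(v) >= 5
        )

    def test_group_means_reproduce_from_raw_data(self):
        rng = np.random.default_rng(15)
        groups = {"0": list(rng.normal(size=8)), "1": list(rng.normal(size=8))}
        pt = _pattern_table(groups)
        res = pattern_anova(pt, "y", min_group_n=2)
        for code, vals in groups.items():
            got = res.groups.set_index("pattern").loc[code, "mean"]
            assert got == pytest.approx(np.mean(vals), abs=1e-12)

    def test_dropped_reference_group_fatal(self):
        pt = _pattern_table({"0": [1.0, 2.0], "1": list(np.arange(8.0))})
        with pytest.raises(ValueError, match="min_group_n"):
            pattern_anova(pt, "y", min_group_n=5)

    def test_bonferroni_option_inflates_p(self):
        rng = np.random.default_rng(16)
        groups = {"00": list(rng.normal(size=10)), "01": list(rng.normal(size=10)),
                  "11": list(rng.normal(size=10))}
        pt = _pattern_table(groups, nvars=2)
        plain = pattern_anova(pt, "y", min_group_n=5)
        adj = pattern_anova(pt, "y", min_group_n=5, bonferroni=True)
        assert (adj.contrasts["p"] >= plain.contrasts["p"] - 1e-15).all()


class TestRegressionCandidates:
    def test_rise_mean_model_excludes_af_includes_nutrients(self, design_table):
        cand = inf.regression_candidates(design_table.columns, "rise_slope", "mean")
        assert "TEMP_mean" in cand and "carbohydrate" in cand
        assert not any("_af_" in c for c in cand)

    def test_fall_model_includes_af(self, design_table):
        cand = inf.regression_candidates(design_table.columns, "fall_slope", "sd")
        assert "HR_af_sd" in cand
        assert "carbohydrate" not in cand  # sd models are physiology-only
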