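"""Outcome classification, median split, chi-square, rANCOVA, partial r."""

import numpy as np
import pandas as pd
import pingouin as pg
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from erpmarkers import clinstats
from erpmarkers.clinstats import (ClinicalRecord, classify_outcomes,
                                  contingency, gg_adjusted_dfs,
                                  mauchly_and_epsilon, median_split,
                                  ancova_at_week, partial_corr, pearson_chi2,
                                  rm_ancova)


def _rec(h0, h8, sid="S1"):
    return ClinicalRecord(subject_id=sid, age=40.0, sex="female",
                          medication="vortioxetine", hamd={0: h0, 2: h0, 4: h8, 8: h8})


class TestOutcomes:
    @pytest.mark.parametrize("h0,h8,remission,response", [
        (26, 7, True, True),     # 7 <= 7 and 19/26 >= 0.5
        (20, 10, False, True),   # exactly 50% decrease
        (26, 8, False, True),    # 8 > 7 but 18/26 >= 0.5
        (20, 11, False, False),
        (14, 7, True, True),
    ])
    def test_boundaries(self, h0, h8, remission, response):
        f = classify_outcomes(_rec(h0, h8))
        assert f.remission is remission
        assert f.response is response

    def test_zero_baseline_undefined(self):
        with pytest.raises(ValueError, match="undefined"):
            classify_outcomes(_rec(0, 0))

    def test_missing_week_errors(self):
        r = _rec(20, 5)
        r.hamd.pop(8)
        with pytest.raises(ValueError, match="week"):
            classify_outcomes(r)


class TestMedianSplit:
    def test_even_cohort_equal_groups(self):
        values = {f"S{i}": float(i) for i in range(1, 53)}
        split = median_split(values, "faa")
        assert len(split.subjects("low")) == 26
        assert len(split.subjects("high")) == 26

    def test_four_values(self):
        split = median_split({"a": 1, "b": 2, "c": 3, "d": 4})
        assert split.groups == {"a": "low", "b": "low", "c": "high", "d": "high"}

    def test_ties_at_median_go_low(self):
        split = median_split({"a": 1, "b": 2, "c": 2, "d": 3})
        assert split.groups == {"a": "low", "b": "low", "c": "low", "d": "high"}

    def test_all_identical_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            median_split({"a": 2, "b": 2, "c": 2, "d": 2})

    def test_too_few_values(self):
        with pytest.raises(ValueError, match="4"):
            median_split({"a": 1, "b": 2, "c": 3})


class TestContingencyAndChi2:
    def test_remission_reconstruction(self):
        # 20/26 low-group remitters, 32 remitters of 52 overall
        groups = {f"L{i}": "low" for i in range(26)}
        groups.update({f"H{i}": "high" for i in range(26)})
        flags = {f"L{i}": i < 20 for i in range(26)}
        flags.update({f"H{i}": i < 12 for i in range(26)})
        split = clinstats.SplitAssignment("faa", 0.0, groups)
        table = contingency(split, flags)
        assert table.tolist() == [[20, 6], [12, 14]]
        res = pearson_chi2(table)
        assert res.statistic == pytest.approx(5.20, abs=0.005)
        assert res.df == 1
        assert res.p == pytest.approx(0.023, abs=0.0005)

    def test_response_reconstruction(self):
        res = pearson_chi2(np.array([[23, 3], [17, 9]]))
        assert res.statistic == pytest.approx(3.90, abs=0.005)
        assert res.p == pytest.approx(0.048, abs=0.0005)

    def test_independence_gives_zero(self):
        assert pearson_chi2(np.array([[10, 10], [10, 10]])).statistic == 0.0

    def test_margins_sum_to_n(self):
        values = {f"S{i}": float(i % 7) + (0.01 * i) for i in range(20)}
        split = median_split(values)
        flags = {s: (i % 3 == 0) for i, s in enumerate(values)}
        table = contingency(split, flags)
        assert table.sum() == 20

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError, match="margin"):
            pearson_chi2(np.array([[0, 0], [5, 5]]))

    @given(a=st.integers(1, 40), b=st.integers(1, 40),
           c=st.integers(1, 40), d=st.integers(1, 40))
    @settings(deadline=None, max_examples=100)
    def test_matches_closed_form(self, a, b, c, d):
        n = a + b + c + d
        closed = n * (a * d - b * c) ** 2 / (
            (a + b) * (c + d) * (a + c) * (b + d))
        res = pearson_chi2(np.array([[a, b], [c, d]]))
        assert res.statistic == pytest.approx(closed, rel=1e-12)


def _wide_from_cov(rng, n, cov, means=(20, 15, 10, 5)):
    L = np.linalg.cholesky(cov)
    return np.asarray(means) + rng.standard_normal((n, 4)) @ L.T


class TestSphericity:
    def test_compound_symmetry_epsilon_near_one(self):
        rng = np.random.default_rng(0)
        cov = 9.0 * np.eye(4) + 4.0  # compound symmetric
        Y = _wide_from_cov(rng, 400, cov)
        s = mauchly_and_epsilon(Y)
        assert s.epsilon > 0.95
        assert s.mauchly_p > 0.05

    def test_autoregressive_epsilon_below_one(self):
        rng = np.random.default_rng(1)
        cov = 9.0 * 0.85 ** np.abs(np.subtract.outer(range(4), range(4)))
        Y = _wide_from_cov(rng, 200, cov)
        s = mauchly_and_epsilon(Y)
        assert s.epsilon < 0.9
        assert s.mauchly_p < 0.05

    def test_lower_bound_k4(self):
        rng = np.random.default_rng(2)
        # extreme violation: one dominant component
        Y = np.outer(rng.standard_normal(50), [1.0, 2.0, 4.0, 8.0])
        Y += 0.01 * rng.standard_normal(Y.shape)
        s = mauchly_and_epsilon(Y)
        assert 1.0 / 3.0 <= s.epsilon <= 1.0

    def test_matches_pingouin_intercept_only(self):
        rng = np.random.default_rng(3)
        cov = 9.0 * 0.6 ** np.abs(np.subtract.outer(range(4), range(4)))
        Y = _wide_from_cov(rng, 40, cov)
        long = pd.DataFrame({
            "subject_id": np.repeat(np.arange(40), 4),
            "week": np.tile([0, 2, 4, 8], 40),
            "hamd": Y.ravel()})
        s = mauchly_and_epsilon(Y)
        eps_pg = pg.epsilon(long, dv="hamd", within="week",
                            subject="subject_id", correction="gg")
        sph_pg = pg.sphericity(long, dv="hamd", within="week",
                               subject="subject_id")
        assert s.epsilon == pytest.approx(float(eps_pg), abs=1e-6)
        assert s.mauchly_w == pytest.approx(float(sph_pg.W), abs=1e-6)

    def test_singular_covariance_errors(self):
        Y = np.tile([1.0, 2.0, 3.0, 4.0], (30, 1))
        with pytest.raises(ValueError, match="singular"):
            mauchly_and_epsilon(Y)


def _cohort_long(seed=11, n=30, group_effect=0.3):
    from erpmarkers import pipeline, io
    from erpmarkers.synthgen import SimulationConfig

    sim = SimulationConfig(seed=seed, n_subjects=n, group_effect=group_effect)
    feats, records, _ = pipeline.simulate_study(sim, extract=False)
    clin = io.clinical_to_frame(records)
    df = feats.merge(clin, on="subject_id")
    split = median_split(df.set_index("subject_id")["faa_f5f6"], "faa")
    return pipeline._long_hamd(df, split, list(clinstats.COVARIATES))


class TestRmAncova:
    def test_interaction_f_matches_pingouin_without_covariates(self):
        long = _cohort_long()
        mine = rm_ancova(long, covariates=())
        aov = pg.mixed_anova(data=long, dv="hamd", within="week",
                             subject="subject_id", between="group")
        f_pg = float(aov.loc[aov["Source"] == "Interaction", "F"].iloc[0])
        assert mine.F == pytest.approx(f_pg, rel=1e-9)

    def test_gg_df_algebra_exact(self):
        long = _cohort_long()
        res = rm_ancova(long)
        n = long["subject_id"].nunique()
        k = long["week"].nunique()
        # p between-subject parameters: intercept + group + 4 covariates
        p = 2 + 4
        assert res.df1_unadjusted == k - 1
        assert res.df2_unadjusted == (k - 1) * (n - p)
        if not res.sphericity_assumed:
            assert res.df1 == pytest.approx(res.epsilon * (k - 1), abs=1e-12)
            assert res.df2 == pytest.approx(res.epsilon * (k - 1) * (n - p),
                                            abs=1e-9)

    def test_printed_df_shape(self):
        df1, df2 = gg_adjusted_dfs(0.85333, k=4, n=52)
        assert df1 == pytest.approx(2.560, abs=5e-4)
        assert df2 == pytest.approx(117.76, abs=0.05)

    def test_power_against_injected_interaction(self):
        hits = 0
        for seed in range(20):
            long = _cohort_long(seed=100 + seed, n=52, group_effect=0.27)
            if rm_ancova(long).p < 0.05:
                hits += 1
        assert hits / 20 > 0.5

    def test_too_few_per_group_errors(self):
        long = _cohort_long(n=10)
        one_group = long[long["group"] == "low"].copy()
        one_group.loc[one_group.index[:4], "group"] = "high"
        sub = one_group[one_group["subject_id"].isin(
            one_group["subject_id"].unique()[:3])]
        with pytest.raises(ValueError):
            rm_ancova(sub)


class TestAncovaAtWeek:
    def test_identical_groups_f_near_zero(self):
        rng = np.random.default_rng(5)
        n = 40
        y = rng.normal(15, 3, n // 2)
        long = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "week": 8, "hamd": np.tile(y, 2),
            "group": ["low"] * (n // 2) + ["high"] * (n // 2),
            "age": np.tile(rng.normal(45, 10, n // 2), 2),
            "sex": ["female"] * n,
            "hamd_w0": np.tile(rng.normal(26, 5, n // 2), 2),
            "medication": ["vortioxetine", "escitalopram"] * (n // 2)})
        res = ancova_at_week(long, 8)
        assert res.F == pytest.approx(0.0, abs=1e-9)

    def test_large_difference_detected(self):
        long = _cohort_long(seed=21, n=52, group_effect=0.5)
        res = ancova_at_week(long, 8)
        assert res.p < 0.05
        assert res.group_means["low"][0] < res.group_means["high"][0]

    def test_covariate_absorbs_confounded_difference(self):
        rng = np.random.default_rng(6)
        n = 60
        age = np.r_[rng.normal(35, 3, n // 2), rng.normal(55, 3, n // 2)]
        y = 0.5 * age + rng.normal(0, 1.0, n)  # difference fully age-driven
        long = pd.DataFrame({
            "subject_id": [f"S{i}" for i in range(n)],
            "week": 8, "hamd": y,
            "group": ["low"] * (n // 2) + ["high"] * (n // 2),
            "age": age, "sex": ["female", "male"] * (n // 2),
            "hamd_w0": rng.normal(26, 5, n),
            "medication": ["vortioxetine", "escitalopram"] * (n // 2)})
        adjusted = ancova_at_week(long, 8)
        unadjusted = ancova_at_week(long, 8, covariates=("hamd_w0",))
        assert adjusted.F < unadjusted.F


class TestPartialCorr:
    def test_no_covariates_reduces_to_pearson(self):
        rng = np.random.default_rng(7)
        x, y = rng.standard_normal(30), rng.standard_normal(30)
        from scipy import stats
        res = partial_corr(x, y)
        r, p = stats.pearsonr(x, y)
        assert res.r == pytest.approx(r, abs=1e-12)
        assert res.p == pytest.approx(p, abs=1e-12)
        assert res.df == 28

    def test_first_order_closed_form_six_points(self):
        # fixed 6-point dataset; r_xy.z from the textbook formula
        x = np.array([2.0, 4.0, 5.0, 7.0, 8.0, 11.0])
        y = np.array([1.0, 3.0, 2.0, 6.0, 9.0, 8.0])
        z = np.array([0.5, 1.0, 2.5, 3.0, 4.5, 5.0])
        rxy = np.corrcoef(x, y)[0, 1]
        rxz = np.corrcoef(x, z)[0, 1]
        ryz = np.corrcoef(y, z)[0, 1]
        closed = (rxy - rxz * ryz) / np.sqrt((1 - rxz ** 2) * (1 - ryz ** 2))
        res = partial_corr(x, y, z[:, None])
        assert res.r == pytest.approx(closed, abs=1e-10)
        assert res.df == 6 - 2 - 1

    def test_orthogonal_covariates_leave_r_unchanged(self):
        rng = np.random.default_rng(8)
        n = 64
        x = np.tile([1.0, -1.0], n // 2)
        y = x + 0.5 * np.tile([1.0, 1.0, -1.0, -1.0], n // 4)
        z = np.tile([1.0, -1.0, -1.0, 1.0], n // 4)  # orthogonal to x and y
        r0 = np.corrcoef(x, y)[0, 1]
        res = partial_corr(x, y, z[:, None])
        assert res.r == pytest.approx(r0, abs=1e-10)

    def test_matches_pingouin(self):
        rng = np.random.default_rng(9)
        df = pd.DataFrame(rng.standard_normal((40, 4)),
                          columns=["x", "y", "c1", "c2"])
        res = partial_corr(df["x"], df["y"], df[["c1", "c2"]])
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2"])
        assert res.r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-9)
        assert res.p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-9)

    def test_constant_after_residualization_errors(self):
        z = np.arange(10.0)
        with pytest.raises(ValueError, match="constant"):
            partial_corr(2 * z + 1, np.random.default_rng(0).standard_normal(10),
                         z[:, None])

    def test_too_few_observations(self):
        with pytest.raises(ValueError, match="need n"):
            partial_corr([1, 2, 3], [2, 3, 4], np.ones((3, 1)))
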