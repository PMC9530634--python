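"""Statistical layer: t-tests, chi-squared, split-plot ANOVA, FDR, GLM."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from rsnet.stats import (
    bh_fdr,
    chi_squared_2x2,
    correlation_trend_glm,
    fisher_z_compare,
    fisher_z_compare_dependent,
    local_metric_screen,
    global_metric_screen,
    mixed_anova_2x2,
    paired_t,
    pooled_t,
    welch_t,
)


class TestTwoSampleT:
    def test_printed_age_summaries(self):
        """The demographic age comparison: 23.18 (2.04) n=28 vs 23.75 (2.64) n=24."""
        res = welch_t(23.18, 2.04, 28, 23.75, 2.64, 24)
        assert round(res.t, 2) == -0.86

    def test_equal_summaries_give_zero(self):
        res = welch_t(5.0, 1.0, 10, 5.0, 1.0, 10)
        assert res.t == 0 and res.p == pytest.approx(1.0)

    @pytest.mark.parametrize("equal_var", [True, False])
    def test_matches_raw_data_t_test(self, rng, equal_var):
        """Summary-statistic t equals scipy's raw-data t on matching samples."""
        x = rng.normal(2, 1.5, 18)
        y = rng.normal(1.2, 0.8, 13)
        fn = pooled_t if equal_var else welch_t
        res = fn(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y))
        ref = sps.ttest_ind(x, y, equal_var=equal_var)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            welch_t(0, 1, 1, 0, 1, 10)
        with pytest.raises(ValueError):
            welch_t(0, 0, 5, 0, 1, 10)


class TestChiSquared:
    def test_printed_gender_table(self):
        """10/18 vs 10/14 females/males with Yates correction."""
        chi2, df, p = chi_squared_2x2(10, 18, 10, 14, yates=True)
        assert round(chi2, 2) == 0.02
        assert df == 1
        assert round(p, 3) == 0.878

    def test_identical_proportions_zero(self):
        chi2, _, p = chi_squared_2x2(5, 5, 10, 10, yates=False)
        assert chi2 == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    @pytest.mark.parametrize("yates", [True, False])
    def test_matches_direct_formula(self, rng, yates):
        for _ in range(20):
            a, b, c, d = rng.integers(1, 20, size=4)
            obs = np.array([[a, b], [c, d]], dtype=float)
            row = obs.sum(1, keepdims=True)
            col = obs.sum(0, keepdims=True)
            exp = row @ col / obs.sum()
            dev = np.abs(obs - exp)
            if yates:
                dev = np.maximum(dev - 0.5, 0)
            expected = float((dev**2 / exp).sum())
            chi2, _, _ = chi_squared_2x2(a, b, c, d, yates=yates)
            assert chi2 == pytest.approx(expected, abs=1e-10)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_squared_2x2(0, 0, 3, 4)


def simulate_long(rng, n1=10, n2=12, effect=0.0):
    rows = []
    for i in range(n1 + n2):
        group = "control" if i < n1 else "experimental"
        base = rng.normal(0, 1)
        boost = effect if group == "experimental" else 0.0
        rows.append(dict(subject=f"s{i}", group=group, time="baseline", y=base + rng.normal(0, 0.5)))
        rows.append(dict(subject=f"s{i}", group=group, time="followup", y=base + boost + rng.normal(0, 0.5)))
    return pd.DataFrame(rows)


class TestMixedAnova:
    def test_identical_trajectories_give_zero_f(self):
        rows = []
        for i in range(8):
            group = "control" if i < 4 else "experimental"
            rows.append(dict(subject=f"s{i}", group=group, time="baseline", y=1.0))
            rows.append(dict(subject=f"s{i}", group=group, time="followup", y=2.0))
        res = mixed_anova_2x2(pd.DataFrame(rows))
        assert res.F_group == 0 and res.F_interaction == 0

    @pytest.mark.parametrize("seed", range(20))
    def test_interaction_f_equals_squared_pooled_t_on_diffs(self, seed):
        """Algebraic identity of the 2x2 split-plot design."""
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(4, 15)), int(rng.integers(4, 15))
        df = simulate_long(rng, n1, n2, effect=rng.normal())
        res = mixed_anova_2x2(df)
        wide = df.pivot(index="subject", columns="time", values="y")
        diffs = wide["followup"] - wide["baseline"]
        grp = df.drop_duplicates("subject").set_index("subject")["group"]
        d1 = diffs[grp == "control"]
        d2 = diffs[grp == "experimental"]
        t = sps.ttest_ind(d1, d2, equal_var=True).statistic
        assert res.F_interaction == pytest.approx(t**2, abs=1e-8)
        assert res.df1 == 1 and res.df2 == n1 + n2 - 2

    def test_df2_matches_completer_count(self, rng):
        df = simulate_long(rng, 20, 21)
        res = mixed_anova_2x2(df)
        assert res.df2 == 39

    def test_matches_pingouin(self, rng):
        pingouin = pytest.importorskip("pingouin")
        df = simulate_long(rng, 9, 9, effect=0.8)
        res = mixed_anova_2x2(df)
        ref = pingouin.mixed_anova(
            data=df, dv="y", within="time", subject="subject", between="group"
        ).set_index("Source")
        assert res.F_group == pytest.approx(ref.loc["group", "F"], rel=1e-6)
        assert res.F_time == pytest.approx(ref.loc["time", "F"], rel=1e-6)
        assert res.F_interaction == pytest.approx(ref.loc["Interaction", "F"], rel=1e-6)

    def test_incomplete_subject_rejected(self, rng):
        df = simulate_long(rng).iloc[:-1]
        with pytest.raises(ValueError, match="two sessions"):
            mixed_anova_2x2(df)


class TestPairedT:
    def test_zero_diffs(self):
        res = paired_t(np.zeros(8))
        assert res.t == 0 and res.p_two_sided == 1.0

    def test_constant_nonzero_diffs_coded_infinite(self):
        res = paired_t(np.full(6, 2.5))
        assert np.isinf(res.t) and res.t > 0 and res.p_two_sided == 0.0

    def test_matches_scipy(self, rng):
        d = rng.normal(0.4, 1.0, 15)
        res = paired_t(d)
        ref = sps.ttest_1samp(d, 0.0)
        assert res.t == pytest.approx(ref.statistic, abs=1e-10)
        assert res.p_two_sided == pytest.approx(ref.pvalue, abs=1e-10)
        assert res.df == 14

    def test_too_few(self):
        with pytest.raises(ValueError):
            paired_t([1.0])


class TestBhFdr:
    def test_step_up_by_hand(self):
        np.testing.assert_allclose(
            bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)
        np.testing.assert_allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_manual_step_up_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=12)
        adj = bh_fdr(p)
        order = np.argsort(p)
        m = len(p)
        manual = np.empty(m)
        running = 1.0
        for rank in range(m - 1, -1, -1):
            running = min(running, m * p[order[rank]] / (rank + 1))
            manual[order[rank]] = running
        np.testing.assert_allclose(adj, manual, atol=1e-12)
        assert np.all(adj >= p - 1e-15)
        assert np.all(np.diff(adj[order]) >= -1e-15)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])


def make_glm_data(rng, n_per_cell=15, delta=0.0, base_slope=1.0, noise=1.0):
    rows = []
    for g in (0, 1):
        for t in (0, 1):
            slope = base_slope + (delta if (g == 1 and t == 1) else 0.0)
            s = rng.normal(0, 1, n_per_cell)
            y = 2.0 + slope * s + rng.normal(0, noise, n_per_cell)
            for si, yi in zip(s, y):
                rows.append((yi, si, g, t))
    arr = np.array(rows)
    return arr[:, 0], arr[:, 1], arr[:, 2], arr[:, 3]


class TestCorrelationTrendGlm:
    def test_matches_normal_equations(self, rng):
        y, s, g, t = make_glm_data(rng, delta=1.5)
        res = correlation_trend_glm(y, s, g, t)
        x = np.column_stack([np.ones_like(y), s, g, t, s * g, s * t, g * t, s * g * t])
        beta = np.linalg.solve(x.T @ x, x.T @ y)
        np.testing.assert_allclose(res.params, beta, atol=1e-10)

    def test_recovers_planted_slope_change(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            y, s, g, t = make_glm_data(rng, n_per_cell=25, delta=2.0)
            res = correlation_trend_glm(y, s, g, t)
            if abs(res.beta_interaction3 - 2.0) <= 2 * res.se_interaction3:
                hits += 1
        assert hits >= 36  # ~95% nominal coverage of the 2-SE interval

    def test_null_term_is_small(self, rng):
        y, s, g, t = make_glm_data(rng, n_per_cell=200, delta=0.0)
        res = correlation_trend_glm(y, s, g, t)
        assert abs(res.beta_interaction3) < 4 * res.se_interaction3

    def test_degenerates_to_simple_regression(self, rng):
        """Identical data in all four cells: interactions vanish and the
        score coefficient equals the simple-regression slope r * sy/sx."""
        s0 = rng.normal(0, 2, 30)
        y0 = 1.0 + 0.7 * s0 + rng.normal(0, 1, 30)
        y = np.tile(y0, 4)
        s = np.tile(s0, 4)
        g = np.repeat([0.0, 0.0, 1.0, 1.0], 30)
        t = np.repeat([0.0, 1.0, 0.0, 1.0], 30)
        res = correlation_trend_glm(y, s, g, t)
        r = np.corrcoef(s0, y0)[0, 1]
        beta1 = r * y0.std(ddof=1) / s0.std(ddof=1)
        assert res.params[1] == pytest.approx(beta1, abs=1e-10)
        np.testing.assert_allclose(res.params[4:], 0.0, atol=1e-10)

    def test_rank_deficient_design_rejected(self):
        y = np.arange(20.0)
        s = np.ones(20)
        g = np.r_[np.zeros(10), np.ones(10)]
        t = np.tile([0.0, 1.0], 10)
        with pytest.raises(ValueError, match="rank"):
            correlation_trend_glm(y, s, g, t)


class TestFisherZ:
    def test_equal_correlations(self):
        z, p = fisher_z_compare(0.4, 20, 0.4, 25)
        assert z == 0 and p == pytest.approx(1.0)

    def test_closed_form(self):
        z, _ = fisher_z_compare(0.5, 20, 0.0, 20)
        assert z == pytest.approx(np.arctanh(0.5) / np.sqrt(2 / 17))

    def test_antisymmetry(self):
        z1, p1 = fisher_z_compare(0.6, 30, 0.2, 25)
        z2, p2 = fisher_z_compare(0.2, 25, 0.6, 30)
        assert z1 == pytest.approx(-z2)
        assert p1 == pytest.approx(p2)

    def test_preconditions(self):
        with pytest.raises(ValueError):
            fisher_z_compare(1.0, 20, 0.5, 20)
        with pytest.raises(ValueError):
            fisher_z_compare(0.5, 3, 0.5, 20)

    def test_dependent_variant_reduces_to_independent(self):
        """With zero cross-session correlations the dependent z equals the
        independent formula at n1 = n2 = n."""
        c = np.eye(4)
        c[0, 1] = c[1, 0] = 0.5
        c[2, 3] = c[3, 2] = 0.1
        z_dep, _ = fisher_z_compare_dependent(c, 20)
        z_ind = (np.arctanh(0.5) - np.arctanh(0.1)) * np.sqrt(17 / 2)
        assert z_dep == pytest.approx(z_ind, abs=1e-12)

    def test_dependent_variant_null_calibration(self):
        """Equal population correlations across dependent sessions: the z
        statistic is approximately standard normal."""
        rng = np.random.default_rng(1)
        S = np.eye(4)
        S[0, 1] = S[1, 0] = S[2, 3] = S[3, 2] = 0.4
        S[0, 2] = S[2, 0] = S[1, 3] = S[3, 1] = 0.6
        S[0, 3] = S[3, 0] = S[1, 2] = S[2, 1] = 0.25
        L = np.linalg.cholesky(S)
        zs = []
        for _ in range(600):
            x = rng.standard_normal((40, 4)) @ L.T
            zs.append(fisher_z_compare_dependent(np.corrcoef(x, rowvar=False), 40)[0])
        zs = np.asarray(zs)
        assert 0.85 < zs.std() < 1.15
        assert sps.kstest(zs, "norm").pvalue > 0.001


def tiny_cohort_tables(rng, n1=6, n2=6, regions=("R01_L", "R01_R", "R02_L"), effect=0.0):
    """Hand-built manifest + long metric table with an optional planted
    interaction effect on the first region's degree."""
    manifest_rows, metric_rows = [], []
    for i in range(n1 + n2):
        group = "control" if i < n1 else "experimental"
        sid = f"s{i:02d}"
        for session in ("baseline", "followup"):
            manifest_rows.append(
                dict(
                    subject_id=sid, group=group, session=session, file="x.tsv",
                    age=23.0, gender="F", LSAS=rng.normal(70, 10),
                    BFNE=rng.normal(44, 7), SIAS=rng.normal(42, 10),
                    RSES=16.0, HADS_A=8.0, HADS_D=8.0, completer=True,
                )
            )
            for r_i, region in enumerate(regions):
                boost = effect if (group == "experimental" and session == "followup" and r_i == 0) else 0.0
                for th in ("0.1", "0.2", "AUC"):
                    metric_rows.append(
                        dict(
                            subject_id=sid, session=session, region=region,
                            metric="degree", threshold=th,
                            value=rng.normal(5, 1) + boost,
                        )
                    )
            for metric in ("global_efficiency", "char_path_length"):
                for th in ("0.1", "0.2", "AUC"):
                    metric_rows.append(
                        dict(
                            subject_id=sid, session=session, region="GLOBAL",
                            metric=metric, threshold=th, value=rng.normal(0.5, 0.05),
                        )
                    )
    return pd.DataFrame(manifest_rows), pd.DataFrame(metric_rows)


class TestScreens:
    def test_local_screen_schema_and_rows(self, rng):
        manifest, table = tiny_cohort_tables(rng)
        out = local_metric_screen(table, manifest)
        assert list(out.columns) == [
            "region", "side", "metric", "threshold", "F", "df1", "df2",
            "p", "p_fdr", "t_posthoc", "df_posthoc", "p_posthoc",
            "p_posthoc_one_sided",
        ]
        # regions x metrics x (thresholds + AUC)
        assert len(out) == 3 * 1 * 3
        assert set(out["side"]) == {"Left", "Right"}
        assert (out["p_fdr"] >= out["p"] - 1e-12).all()
        assert out["df2"].eq(10).all()

    def test_local_screen_finds_planted_effect(self, rng):
        manifest, table = tiny_cohort_tables(rng, n1=15, n2=15, effect=4.0)
        out = local_metric_screen(table, manifest)
        hit = out[(out["region"] == "R01_L") & (out["threshold"] == "AUC")]
        rest = out[(out["region"] != "R01_L")]
        assert hit["p_fdr"].iloc[0] < 0.05
        assert hit["F"].iloc[0] > rest["F"].max()

    def test_fdr_family_choices_differ(self, rng):
        manifest, table = tiny_cohort_tables(rng, effect=2.0)
        per = local_metric_screen(table, manifest, family="per-threshold")
        joint = local_metric_screen(table, manifest, family="joint")
        assert len(per) == len(joint)
        with pytest.raises(ValueError):
            local_metric_screen(table, manifest, family="bogus")

    def test_missing_values_drop_from_family(self, rng):
        manifest, table = tiny_cohort_tables(rng)
        table = table.copy()
        idx = table[(table["region"] == "R01_L") & (table["threshold"] == "0.1")].index[:1]
        table.loc[idx, "value"] = np.nan
        out = local_metric_screen(table, manifest)
        nan_row = out[(out["region"] == "R01_L") & (out["threshold"] == "0.1")]
        assert np.isnan(nan_row["F"].iloc[0]) and np.isnan(nan_row["p_fdr"].iloc[0])

    def test_global_screen_tables(self, rng):
        manifest, table = tiny_cohort_tables(rng)
        out = global_metric_screen(table, manifest)
        assert set(out) == {"anova", "glm", "fisher_z"}
        assert set(out["anova"]["metric"]) == {"global_efficiency", "char_path_length"}
        # 2 metrics x 3 scores
        assert len(out["glm"]) == 6 and len(out["fisher_z"]) == 6
        assert {"beta", "se", "t", "p"} <= set(out["glm"].columns)
        assert {"r_baseline", "r_followup", "z", "p"} <= set(out["fisher_z"].columns)
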