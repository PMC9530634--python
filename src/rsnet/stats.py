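"""Group x time inference layer.

Implements the statistical battery applied to a two-group (control /
experimental), two-session (baseline / follow-up) design:

* demographic checks — Welch / pooled two-sample t from summary statistics,
  Pearson chi-squared (optionally Yates-corrected) on a 2x2 gender table;
* 2x2 mixed-design (split-plot) ANOVA with the group-by-time interaction as
  the treatment-effect test, computed in closed form (for a 2x2 design the
  interaction F equals the squared pooled t on per-subject difference
  scores, which doubles as an internal consistency check);
* Benjamini-Hochberg FDR screening of local metrics across regions;
* post-hoc paired t within the experimental group;
* an OLS "correlation trend" GLM whose score x group x time coefficient
  measures the change, attributable to the intervention, of the slope
  between a symptom scale and a network metric;
* Fisher r-to-z comparison of two correlation coefficients.

The screening drivers consume the tidy long-format metric table produced by
the metrics stage together with the cohort manifest, and emit result tables
shaped like the familiar per-region / per-threshold significance listings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TTestResult",
    "AnovaResult",
    "PairedTResult",
    "GlmResult",
    "welch_t",
    "pooled_t",
    "chi_squared_2x2",
    "mixed_anova_2x2",
    "paired_t",
    "bh_fdr",
    "correlation_trend_glm",
    "fisher_z_compare",
    "fisher_z_compare_dependent",
    "local_metric_screen",
    "global_metric_screen",
]

GROUPS = ("control", "experimental")
SESSIONS = ("baseline", "followup")


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


@dataclass
class AnovaResult:
    """2x2 split-plot ANOVA: between-subject group, within-subject time."""

    F_group: float
    F_time: float
    F_interaction: float
    df1: int
    df2: int
    p_group: float
    p_time: float
    p_interaction: float


@dataclass
class PairedTResult:
    t: float
    df: int
    p_two_sided: float
    p_one_sided: float


@dataclass
class GlmResult:
    """OLS fit of the full score x group x time factorial design.

    Columns of the design matrix: intercept, score, group, time,
    score*group, score*time, group*time, score*group*time.  The three-way
    coefficient (index 7) is the correlation-trend-change statistic.
    """

    params: np.ndarray
    bse: np.ndarray
    tvalues: np.ndarray
    pvalues: np.ndarray
    df_resid: int

    TERMS = (
        "intercept",
        "score",
        "group",
        "time",
        "score:group",
        "score:time",
        "group:time",
        "score:group:time",
    )

    @property
    def beta_interaction3(self) -> float:
        return float(self.params[7])

    @property
    def se_interaction3(self) -> float:
        return float(self.bse[7])

    @property
    def t_interaction3(self) -> float:
        return float(self.tvalues[7])

    @property
    def p_interaction3(self) -> float:
        return float(self.pvalues[7])


def welch_t(mean1, sd1, n1, mean2, sd2, n2) -> TTestResult:
    """Welch two-sample t from summary statistics (Satterthwaite df)."""
    return _two_sample_t(mean1, sd1, n1, mean2, sd2, n2, pooled=False)


def pooled_t(mean1, sd1, n1, mean2, sd2, n2) -> TTestResult:
    """Equal-variance two-sample t from summary statistics."""
    return _two_sample_t(mean1, sd1, n1, mean2, sd2, n2, pooled=True)


def _two_sample_t(mean1, sd1, n1, mean2, sd2, n2, pooled: bool) -> TTestResult:
    for label, n, sd in (("1", n1, sd1), ("2", n2, sd2)):
        if n < 2:
            raise ValueError(f"group {label}: need n >= 2, got {n}")
        if sd <= 0:
            raise ValueError(f"group {label}: need sd > 0, got {sd}")
    v1, v2 = sd1**2 / n1, sd2**2 / n2
    if pooled:
        df = n1 + n2 - 2
        sp2 = ((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / df
        se = np.sqrt(sp2 * (1 / n1 + 1 / n2))
    else:
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        se = np.sqrt(v1 + v2)
    t = (mean1 - mean2) / se
    p = 2 * sps.t.sf(abs(t), df)
    return TTestResult(t=float(t), df=float(df), p=float(p))


def chi_squared_2x2(a, b, c, d, yates: bool = True):
    """Pearson chi-squared on the 2x2 table [[a, b], [c, d]].

    ``yates`` applies the continuity correction (the usual convention for the
    small 2x2 gender table).  Returns ``(chi2, df, p)`` with df = 1.
    """
    table = np.array([[a, b], [c, d]], dtype=float)
    if np.any(table < 0):
        raise ValueError("cell counts must be nonnegative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("2x2 table has a zero margin")
    chi2, p, df, _ = sps.chi2_contingency(table, correction=yates)
    return float(chi2), int(df), float(p)


def _split_plot_f(y_base: np.ndarray, y_follow: np.ndarray, group: np.ndarray):
    """Vectorized 2x2 split-plot ANOVA over columns of (n_subjects, m) arrays.

    ``group`` is a boolean/0-1 vector (1 = experimental).  Returns arrays of
    F statistics (group, time, interaction) plus the common dfs.  Effects
    with zero sums of squares yield F = 0; zero error variance with a
    nonzero effect yields F = inf (coded, not raised, so screens complete).
    """
    y_base = np.atleast_2d(np.asarray(y_base, dtype=float).T).T
    y_follow = np.atleast_2d(np.asarray(y_follow, dtype=float).T).T
    g = np.asarray(group).astype(bool)
    n1 = int((~g).sum())
    n2 = int(g.sum())
    n = n1 + n2
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least 2 subjects per group")

    diff = y_follow - y_base
    mean = (y_follow + y_base) / 2.0

    d1 = diff[~g].mean(axis=0)
    d2 = diff[g].mean(axis=0)
    dbar = diff.mean(axis=0)
    fitted_d = np.where(g[:, None], d2[None, :], d1[None, :])
    sse_d = ((diff - fitted_d) ** 2).sum(axis=0)

    ss_time = n * dbar**2 / 2.0
    ss_inter = (n1 * (d1 - dbar) ** 2 + n2 * (d2 - dbar) ** 2) / 2.0
    ms_err_w = sse_d / (2.0 * (n - 2))

    m1 = mean[~g].mean(axis=0)
    m2 = mean[g].mean(axis=0)
    mbar = mean.mean(axis=0)
    fitted_m = np.where(g[:, None], m2[None, :], m1[None, :])
    ss_group = 2.0 * (n1 * (m1 - mbar) ** 2 + n2 * (m2 - mbar) ** 2)
    ms_err_b = 2.0 * ((mean - fitted_m) ** 2).sum(axis=0) / (n - 2)

    def _f(ss, ms):
        with np.errstate(divide="ignore", invalid="ignore"):
            f = np.where(ss <= 0, 0.0, np.where(ms > 0, ss / ms, np.inf))
        return f

    return _f(ss_group, ms_err_b), _f(ss_time, ms_err_w), _f(ss_inter, ms_err_w), 1, n - 2


def mixed_anova_2x2(data: pd.DataFrame, dv: str = "y") -> AnovaResult:
    """2x2 mixed-design ANOVA on a tidy long table.

    ``data`` needs columns ``subject``, ``group``, ``time`` and the outcome
    ``dv``; every subject must contribute exactly the two sessions
    ("completers only").  Group is between-subjects, time within-subjects;
    all three F tests share df = (1, n_subjects - 2).
    """
    required = {"subject", "group", "time", dv}
    missing = required - set(data.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    counts = data.groupby("subject")["time"].nunique()
    rows = data.groupby("subject").size()
    bad = sorted(counts.index[(counts != 2) | (rows != 2)])
    if bad:
        raise ValueError(f"subjects without exactly two sessions: {bad}")
    if not np.all(np.isfinite(data[dv].to_numpy(dtype=float))):
        raise ValueError("outcome contains non-finite values")

    wide = data.pivot(index="subject", columns="time", values=dv)
    grp = data.drop_duplicates("subject").set_index("subject")["group"]
    grp = grp.reindex(wide.index)
    g = (grp.to_numpy() == GROUPS[1]).astype(bool)
    yb = wide[SESSIONS[0]].to_numpy()[:, None]
    yf = wide[SESSIONS[1]].to_numpy()[:, None]
    f_g, f_t, f_i, df1, df2 = _split_plot_f(yb, yf, g)
    return AnovaResult(
        F_group=float(f_g[0]),
        F_time=float(f_t[0]),
        F_interaction=float(f_i[0]),
        df1=df1,
        df2=df2,
        p_group=float(sps.f.sf(f_g[0], df1, df2)),
        p_time=float(sps.f.sf(f_t[0], df1, df2)),
        p_interaction=float(sps.f.sf(f_i[0], df1, df2)),
    )


def paired_t(diffs) -> PairedTResult:
    """One-sample t on paired differences (df = n - 1).

    Zero-variance nonzero differences are coded as infinite t rather than an
    exception so batch screens run to completion.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 paired differences")
    n = d.size
    sd = d.std(ddof=1)
    m = d.mean()
    if sd == 0:
        t = 0.0 if m == 0 else np.inf * np.sign(m)
        p2 = 1.0 if m == 0 else 0.0
    else:
        t = m / (sd / np.sqrt(n))
        p2 = 2 * sps.t.sf(abs(t), n - 1)
    p1 = sps.t.sf(t, n - 1)  # one-sided: H1 mean(diff) > 0
    return PairedTResult(t=float(t), df=n - 1, p_two_sided=float(p2), p_one_sided=float(p1))


def bh_fdr(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order-preserving)."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def correlation_trend_glm(outcome, score, group, time) -> GlmResult:
    """OLS of ``outcome`` on the full score x group x time factorial design.

    ``group`` and ``time`` are 0/1 indicators (experimental = 1,
    follow-up = 1).  The score:group:time coefficient is the change in the
    score-outcome slope specific to the experimental group at follow-up —
    the "correlation trend" statistic.  Raises on a rank-deficient design.
    """
    y = np.asarray(outcome, dtype=float)
    s = np.asarray(score, dtype=float)
    g = np.asarray(group, dtype=float)
    t = np.asarray(time, dtype=float)
    if not (y.shape == s.shape == g.shape == t.shape):
        raise ValueError("outcome, score, group, time must have equal length")
    x = np.column_stack(
        [np.ones_like(y), s, g, t, s * g, s * t, g * t, s * g * t]
    )
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("rank-deficient design matrix")
    if y.size <= x.shape[1]:
        raise ValueError("no residual degrees of freedom")
    fit = sm.OLS(y, x).fit()
    return GlmResult(
        params=np.asarray(fit.params),
        bse=np.asarray(fit.bse),
        tvalues=np.asarray(fit.tvalues),
        pvalues=np.asarray(fit.pvalues),
        df_resid=int(fit.df_resid),
    )


def fisher_z_compare(r1, n1, r2, n2):
    """z-test for the difference of two independent correlations.

    z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3)), two-sided normal p.
    """
    for label, r, n in (("1", r1, n1), ("2", r2, n2)):
        if abs(r) >= 1:
            raise ValueError(f"correlation {label} must satisfy |r| < 1")
        if n <= 3:
            raise ValueError(f"sample {label} needs n > 3")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1 / (n1 - 3) + 1 / (n2 - 3))
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


def fisher_z_compare_dependent(corr4: np.ndarray, n: int):
    """z-test for r(1,2) vs r(3,4) measured on the *same* n subjects.

    ``corr4`` is the 4x4 sample correlation matrix of the variables
    (score_baseline, metric_baseline, score_followup, metric_followup).
    The comparison of two nonoverlapping dependent correlations follows the
    Pearson-Filon statistic on Fisher-z scale (Raghunathan-Rosenthal-Rubin):
    the covariance of z12 and z34 is estimated from the remaining four
    correlations, shrinking the denominator relative to the independent
    test.  With all cross-correlations zero it reduces to the independent
    formula at n1 = n2 = n.
    """
    c = np.asarray(corr4, dtype=float)
    if c.shape != (4, 4):
        raise ValueError("corr4 must be the 4x4 correlation matrix")
    if n <= 3:
        raise ValueError("need n > 3")
    r12, r34 = c[0, 1], c[2, 3]
    r13, r14, r23, r24 = c[0, 2], c[0, 3], c[1, 2], c[1, 3]
    if abs(r12) >= 1 or abs(r34) >= 1:
        raise ValueError("compared correlations must satisfy |r| < 1")
    psi = 0.5 * (
        (r13 - r23 * r12) * (r24 - r23 * r34)
        + (r14 - r13 * r34) * (r23 - r13 * r12)
        + (r13 - r14 * r34) * (r24 - r14 * r12)
        + (r14 - r12 * r24) * (r23 - r34 * r24)
    )
    cov_z = psi / ((1 - r12**2) * (1 - r34**2))
    denom = 2.0 - 2.0 * cov_z
    if denom <= 0:
        raise ValueError("degenerate correlation structure")
    z = (np.arctanh(r12) - np.arctanh(r34)) * np.sqrt((n - 3) / denom)
    p = 2 * sps.norm.sf(abs(z))
    return float(z), float(p)


# ---------------------------------------------------------------------------
# screening drivers
# ---------------------------------------------------------------------------

LOCAL_FAMILIES = ("per-threshold", "joint")


def _side_of(label: str) -> str:
    up = label.upper()
    if up.endswith(("_L", ".L", "-L")):
        return "Left"
    if up.endswith(("_R", ".R", "-R")):
        return "Right"
    return ""


def _completer_layout(manifest: pd.DataFrame):
    """Completer subject order and their 0/1 group vector."""
    comp = manifest[manifest["completer"].astype(bool)]
    subj = comp.drop_duplicates("subject_id").sort_values("subject_id")
    subjects = subj["subject_id"].tolist()
    group = (subj["group"].to_numpy() == GROUPS[1]).astype(bool)
    if (~group).sum() < 2 or group.sum() < 2:
        raise ValueError("need at least 2 completers per group")
    return subjects, group


def _pivot_sessions(table: pd.DataFrame, subjects, value="value"):
    """(n_subjects x n_items) baseline / follow-up value arrays.

    Columns are the distinct (region, threshold) items of ``table``; rows
    follow ``subjects``.  Missing cells become NaN.
    """
    piv = table.pivot_table(
        index="subject_id",
        columns=["region", "threshold", "session"],
        values=value,
        aggfunc="first",
    )
    piv = piv.reindex(subjects)
    items = sorted({(r, th) for r, th, _ in piv.columns})
    yb = np.full((len(subjects), len(items)), np.nan)
    yf = np.full((len(subjects), len(items)), np.nan)
    for j, (r, th) in enumerate(items):
        if (r, th, SESSIONS[0]) in piv.columns:
            yb[:, j] = piv[(r, th, SESSIONS[0])].to_numpy()
        if (r, th, SESSIONS[1]) in piv.columns:
            yf[:, j] = piv[(r, th, SESSIONS[1])].to_numpy()
    return items, yb, yf


def local_metric_screen(
    metric_table: pd.DataFrame,
    manifest: pd.DataFrame,
    q: float = 0.05,
    family: str = "per-threshold",
) -> pd.DataFrame:
    """Region x metric x threshold interaction screen with BH-FDR.

    For every local metric, region, and threshold (individual densities plus
    the AUC aggregate) the 2x2 mixed-ANOVA group-by-time interaction is
    computed over completers; BH-FDR is applied across regions within each
    metric x threshold family (``family="joint"`` pools thresholds within a
    metric instead), and a post-hoc paired t (follow-up minus baseline,
    experimental group) accompanies each row.  Rows whose outcome is missing
    for any completer carry NaN statistics and are excluded from the FDR
    family.
    """
    if family not in LOCAL_FAMILIES:
        raise ValueError(f"family must be one of {LOCAL_FAMILIES}")
    subjects, group = _completer_layout(manifest)
    local = metric_table[metric_table["region"] != "GLOBAL"]
    rows = []
    for metric in sorted(local["metric"].unique()):
        sub = local[local["metric"] == metric]
        items, yb, yf = _pivot_sessions(sub, subjects)
        ok = np.isfinite(yb).all(axis=0) & np.isfinite(yf).all(axis=0)
        f_int = np.full(len(items), np.nan)
        p_int = np.full(len(items), np.nan)
        t_ph = np.full(len(items), np.nan)
        p_ph2 = np.full(len(items), np.nan)
        p_ph1 = np.full(len(items), np.nan)
        df2 = len(subjects) - 2
        if ok.any():
            _, _, fi, _, _ = _split_plot_f(yb[:, ok], yf[:, ok], group)
            f_int[ok] = fi
            p_int[ok] = sps.f.sf(fi, 1, df2)
            d_exp = (yf - yb)[group][:, ok]
            n_exp = int(group.sum())
            m = d_exp.mean(axis=0)
            sd = d_exp.std(axis=0, ddof=1)
            with np.errstate(divide="ignore", invalid="ignore"):
                t = np.where(
                    sd > 0, m / (sd / np.sqrt(n_exp)), np.where(m == 0, 0.0, np.inf) * np.sign(m + (m == 0))
                )
            t_ph[ok] = t
            p_ph2[ok] = 2 * sps.t.sf(np.abs(t), n_exp - 1)
            p_ph1[ok] = sps.t.sf(t, n_exp - 1)
        for j, (region, th) in enumerate(items):
            rows.append(
                {
                    "region": region,
                    "side": _side_of(region),
                    "metric": metric,
                    "threshold": th,
                    "F": f_int[j],
                    "df1": 1,
                    "df2": df2,
                    "p": p_int[j],
                    "t_posthoc": t_ph[j],
                    "df_posthoc": int(group.sum()) - 1,
                    "p_posthoc": p_ph2[j],
                    "p_posthoc_one_sided": p_ph1[j],
                }
            )
    out = pd.DataFrame(rows)
    out["p_fdr"] = np.nan
    if len(out):
        keys = ["metric"] if family == "joint" else ["metric", "threshold"]
        for _, idx in out.groupby(keys).groups.items():
            pv = out.loc[idx, "p"]
            fin = pv.notna()
            if fin.any():
                out.loc[pv.index[fin], "p_fdr"] = bh_fdr(pv[fin].to_numpy())
    cols = [
        "region", "side", "metric", "threshold", "F", "df1", "df2",
        "p", "p_fdr", "t_posthoc", "df_posthoc", "p_posthoc",
        "p_posthoc_one_sided",
    ]
    return out[cols].sort_values(["metric", "region", "threshold"]).reset_index(drop=True)


def global_metric_screen(
    metric_table: pd.DataFrame,
    manifest: pd.DataFrame,
    scores: tuple[str, ...] = ("LSAS", "BFNE", "SIAS"),
    glm_outcome: str = "score",
) -> dict[str, pd.DataFrame]:
    """Global-metric battery: ANOVA per threshold, trend GLM, Fisher z.

    Returns three tables: ``"anova"`` (mixed ANOVA + post-hoc paired t per
    global metric and threshold/AUC), ``"glm"`` (correlation-trend OLS per
    metric x social-anxiety score, reporting the three-way interaction term)
    and ``"fisher_z"`` (baseline versus follow-up score-metric correlation
    within the experimental group).

    ``glm_outcome`` selects the regression direction: ``"score"`` (default)
    regresses the scale score on the AUC-aggregated metric, so the three-way
    coefficient is the intervention-specific change in the score-per-metric
    slope; ``"metric"`` regresses the metric on the score instead.
    """
    if glm_outcome not in ("score", "metric"):
        raise ValueError("glm_outcome must be 'score' or 'metric'")
    subjects, group = _completer_layout(manifest)
    glob = metric_table[metric_table["region"] == "GLOBAL"]
    anova_rows = []
    for metric in sorted(glob["metric"].unique()):
        sub = glob[glob["metric"] == metric]
        items, yb, yf = _pivot_sessions(sub, subjects)
        for j, (_, th) in enumerate(items):
            col_b, col_f = yb[:, j], yf[:, j]
            if not (np.isfinite(col_b).all() and np.isfinite(col_f).all()):
                anova_rows.append(
                    {"metric": metric, "threshold": th, "F": np.nan, "df1": 1,
                     "df2": len(subjects) - 2, "p": np.nan, "t_posthoc": np.nan,
                     "df_posthoc": int(group.sum()) - 1, "p_posthoc": np.nan,
                     "p_posthoc_one_sided": np.nan}
                )
                continue
            _, _, fi, df1, df2 = _split_plot_f(col_b[:, None], col_f[:, None], group)
            ph = paired_t((col_f - col_b)[group])
            anova_rows.append(
                {
                    "metric": metric,
                    "threshold": th,
                    "F": float(fi[0]),
                    "df1": df1,
                    "df2": df2,
                    "p": float(sps.f.sf(fi[0], df1, df2)),
                    "t_posthoc": ph.t,
                    "df_posthoc": ph.df,
                    "p_posthoc": ph.p_two_sided,
                    "p_posthoc_one_sided": ph.p_one_sided,
                }
            )
    anova = pd.DataFrame(anova_rows)

    # score-metric correlation-trend GLM and Fisher z on AUC aggregates
    comp = manifest[manifest["completer"].astype(bool)].copy()
    comp = comp[comp["subject_id"].isin(subjects)]
    auc = glob[glob["threshold"] == "AUC"]
    glm_rows = []
    fisher_rows = []
    for metric in sorted(auc["metric"].unique()):
        vals = auc[auc["metric"] == metric][["subject_id", "session", "value"]]
        merged = comp.merge(vals, on=["subject_id", "session"], how="inner")
        if merged["value"].isna().any() or len(merged) < len(subjects) * 2:
            continue
        gvec = (merged["group"] == GROUPS[1]).astype(float).to_numpy()
        tvec = (merged["session"] == SESSIONS[1]).astype(float).to_numpy()
        for score in scores:
            svec = merged[score].to_numpy(dtype=float)
            mvec = merged["value"].to_numpy(dtype=float)
            if glm_outcome == "score":
                res = correlation_trend_glm(svec, mvec, gvec, tvec)
            else:
                res = correlation_trend_glm(mvec, svec, gvec, tvec)
            glm_rows.append(
                {
                    "metric": metric,
                    "score": score,
                    "beta": res.beta_interaction3,
                    "se": res.se_interaction3,
                    "t": res.t_interaction3,
                    "p": res.p_interaction3,
                    "df_resid": res.df_resid,
                }
            )
            exp = merged[(gvec == 1)]
            eb = exp[exp["session"] == SESSIONS[0]]
            ef = exp[exp["session"] == SESSIONS[1]]
            r_b = float(np.corrcoef(eb[score], eb["value"])[0, 1])
            r_f = float(np.corrcoef(ef[score], ef["value"])[0, 1])
            z, pz = fisher_z_compare(r_b, len(eb), r_f, len(ef))
            fisher_rows.append(
                {
                    "metric": metric,
                    "score": score,
                    "r_baseline": r_b,
                    "r_followup": r_f,
                    "z": z,
                    "p": pz,
                }
            )
    return {
        "anova": anova,
        "glm": pd.DataFrame(glm_rows),
        "fisher_z": pd.DataFrame(fisher_rows),
    }
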