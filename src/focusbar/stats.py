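"""The study's statistical decision tree and analyses.

Test selection for a paired contrast follows the published procedure
exactly: Shapiro–Wilk on each side and Levene's test (median-centered)
across sides at alpha = 0.05. If nothing is significant, a paired t-test;
if Levene is significant with both sides normal, a Welch t-test; if either
side is non-normal, the Wilcoxon signed-rank test (non-normality takes
precedence over variance heterogeneity, since Welch still assumes
normality). Effect sizes are Cohen's d — mean difference over the SD of
differences for paired designs, pooled-SD for independent groups — with the
convention recorded alongside every result.

Also here: the one-way repeated-measures ANOVA over sessions, OLS of
concentration on mean input level, and ``analyze_study`` tying the whole
report together (baseline vs VR, feedback vs no feedback, completers vs
non-completers, RM-ANOVA per scale, band-time summary).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .engine import FeedbackTrace, band_time_fractions

ALPHA_DEFAULT = 0.05

PAIRED_T = "paired_t"
WELCH_T = "welch_t"
WILCOXON = "wilcoxon_signed_rank"
INDEPENDENT_T = "independent_t"


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class TestResult:
    test: str
    statistic: float
    df: Optional[float]
    p: float
    d: Optional[float]
    d_convention: Optional[str]
    n: int

    def to_dict(self) -> dict:
        return asdict(self)


def _as_1d(x) -> np.ndarray:
    a = np.asarray(x, dtype=float).ravel()
    if np.isnan(a).any():
        raise StatsError("NaN values are not allowed")
    return a


def select_test(x, y, alpha: float = ALPHA_DEFAULT) -> str:
    """Choose the paired test per the study's decision tree."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) != len(y):
        raise StatsError("paired samples must have equal length")
    if len(x) < 3:
        raise StatsError("need n >= 3 (Shapiro-Wilk undefined below)")
    normal_x = _shapiro_p(x) >= alpha
    normal_y = _shapiro_p(y) >= alpha
    if not (normal_x and normal_y):
        return WILCOXON
    levene_p = sps.levene(x, y, center="median").pvalue
    if levene_p < alpha:
        return WELCH_T
    return PAIRED_T


def _shapiro_p(x: np.ndarray) -> float:
    if np.ptp(x) == 0:
        return 0.0  # constant data: treat as non-normal
    return float(sps.shapiro(x).pvalue)


def cohen_d(x, y, design: str = "paired") -> float:
    """Cohen's d under the stated design convention.

    paired: mean(x - y) / SD(x - y); independent: (mean x - mean y) / pooled
    SD. Sample (ddof=1) standard deviations throughout.
    """
    x, y = _as_1d(x), _as_1d(y)
    if design == "paired":
        if len(x) != len(y):
            raise StatsError("paired design requires equal lengths")
        if len(x) < 2:
            raise StatsError("need n >= 2")
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            raise StatsError("zero SD of paired differences: d undefined")
        return float(d.mean() / sd)
    if design == "independent":
        if len(x) < 2 or len(y) < 2:
            raise StatsError("need n >= 2 per group")
        n1, n2 = len(x), len(y)
        pooled = math.sqrt(
            ((n1 - 1) * x.var(ddof=1) + (n2 - 1) * y.var(ddof=1)) / (n1 + n2 - 2)
        )
        if pooled == 0:
            raise StatsError("zero pooled SD: d undefined")
        return float((x.mean() - y.mean()) / pooled)
    raise StatsError(f"unknown design {design!r}")


def paired_compare(x, y, test_id: Optional[str] = None) -> TestResult:
    """Run the named (or auto-selected) two-sided paired comparison."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) != len(y):
        raise StatsError("paired samples must have equal length")
    if test_id is None:
        test_id = select_test(x, y)
    n = len(x)

    if test_id == PAIRED_T:
        d = x - y
        sd = d.std(ddof=1)
        if sd == 0:
            if np.all(d == 0):
                return TestResult(PAIRED_T, 0.0, float(n - 1), 1.0, None, None, n)
            raise StatsError(
                "constant nonzero paired difference: t statistic undefined"
            )
        res = sps.ttest_rel(x, y)
        return TestResult(
            PAIRED_T, float(res.statistic), float(n - 1), float(res.pvalue),
            cohen_d(x, y, "paired"), "paired_diff_sd", n,
        )

    if test_id == WELCH_T:
        res = sps.ttest_ind(x, y, equal_var=False)
        return TestResult(
            WELCH_T, float(res.statistic), float(res.df), float(res.pvalue),
            cohen_d(x, y, "paired"), "paired_diff_sd", n,
        )

    if test_id == WILCOXON:
        d = x - y
        d = d[d != 0]  # wilcox convention: drop zero differences
        if len(d) == 0:
            raise StatsError("all paired differences are zero: no nonzero ranks")
        n_eff = len(d)
        if n_eff <= 12:
            stat, p = _wilcoxon_exact(d)
        else:
            res = sps.wilcoxon(d, method="approx", correction=True)
            stat, p = float(res.statistic), float(res.pvalue)
        eff = None
        try:
            eff = cohen_d(x, y, "paired")
        except StatsError:
            pass
        return TestResult(WILCOXON, stat, None, p, eff, "paired_diff_sd", n)

    raise StatsError(f"unknown paired test id {test_id!r}")


def _wilcoxon_exact(d: np.ndarray) -> tuple[float, float]:
    """Exact signed-rank test by full enumeration of the 2^n sign
    assignments (tie-aware via midranks; feasible for n <= 12).

    Statistic is min(W+, W-); the two-sided p is the null probability of a
    min-sum no larger than the observed one.
    """
    n = len(d)
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    w_obs = min(w_plus, w_minus)
    total = ranks.sum()
    signs = ((np.arange(2**n)[:, None] >> np.arange(n)) & 1).astype(float)
    sums = signs @ ranks
    p = float(np.mean(np.minimum(sums, total - sums) <= w_obs + 1e-12))
    return w_obs, p


def independent_compare(x, y) -> TestResult:
    """Two-sided independent-samples t-test (equal variances), pooled-SD d."""
    x, y = _as_1d(x), _as_1d(y)
    if len(x) < 2 or len(y) < 2:
        raise StatsError("need n >= 2 per group")
    res = sps.ttest_ind(x, y, equal_var=True)
    df = len(x) + len(y) - 2
    try:
        d = cohen_d(x, y, "independent")
        conv = "pooled_sd"
    except StatsError:
        d, conv = None, None
    return TestResult(
        INDEPENDENT_T, float(res.statistic), float(df), float(res.pvalue),
        d, conv, len(x) + len(y),
    )


# ---------------------------------------------------------------------------
# Repeated-measures ANOVA
# ---------------------------------------------------------------------------


def rm_anova(
    scores, greenhouse_geisser: bool = False
) -> dict:
    """One-way within-subjects ANOVA over a participants x sessions matrix.

    Rows with any missing session are dropped (listwise deletion). Returns
    F with (k-1, (k-1)(n-1)) degrees of freedom; if the between-session sum
    of squares is zero the session factor explains nothing and F = 0, p = 1.
    Greenhouse–Geisser correction (epsilon-scaled dfs) is optional and off
    by default.
    """
    a = np.asarray(scores, dtype=float)
    if a.ndim != 2:
        raise StatsError("scores must be a 2-D participants x sessions matrix")
    a = a[~np.isnan(a).any(axis=1)]
    n, k = a.shape
    if n < 2:
        raise StatsError("need >= 2 complete participants")
    if k < 2:
        raise StatsError("need >= 2 sessions")

    grand = a.mean()
    ss_sessions = n * ((a.mean(axis=0) - grand) ** 2).sum()
    ss_subjects = k * ((a.mean(axis=1) - grand) ** 2).sum()
    ss_total = ((a - grand) ** 2).sum()
    ss_error = ss_total - ss_sessions - ss_subjects
    df1, df2 = k - 1, (k - 1) * (n - 1)

    eps = 1.0
    if greenhouse_geisser:
        eps = _gg_epsilon(a)
    tol = 1e-12 * max(1.0, ss_total)
    if ss_sessions <= tol:
        f, p = 0.0, 1.0
    elif ss_error <= tol:
        f, p = float("inf"), 0.0
    else:
        f = (ss_sessions / df1) / (ss_error / df2)
        p = float(sps.f.sf(f, df1 * eps, df2 * eps))
    return {
        "F": float(f),
        "df1": df1,
        "df2": df2,
        "p": float(p),
        "n": n,
        "k": k,
        "epsilon": float(eps),
        "sphericity_correction": "greenhouse_geisser" if greenhouse_geisser else None,
    }


def _gg_epsilon(a: np.ndarray) -> float:
    """Greenhouse–Geisser epsilon from the double-centered covariance."""
    k = a.shape[1]
    s = np.cov(a, rowvar=False, ddof=1)
    s = s - s.mean(axis=0, keepdims=True) - s.mean(axis=1, keepdims=True) + s.mean()
    num = np.trace(s) ** 2
    den = (k - 1) * (s**2).sum()
    if den == 0:
        return 1.0
    return float(min(1.0, max(1.0 / (k - 1), num / den)))


# ---------------------------------------------------------------------------
# Regression
# ---------------------------------------------------------------------------


def regress_concentration_on_input(mean_levels, concentration_scores) -> dict:
    """OLS of session concentration score on session mean input level."""
    x, y = _as_1d(mean_levels), _as_1d(concentration_scores)
    if len(x) != len(y):
        raise StatsError("predictor and response must have equal length")
    if len(x) < 3:
        raise StatsError("need >= 3 sessions")
    if np.ptp(x) == 0:
        raise StatsError("zero variance in predictor")
    res = sps.linregress(x, y)
    return {
        "slope": float(res.slope),
        "intercept": float(res.intercept),
        "r_squared": float(res.rvalue**2),
        "p": float(res.pvalue),
        "n": len(x),
    }


# ---------------------------------------------------------------------------
# Full study report
# ---------------------------------------------------------------------------

_REPORT_SCALES = ("concentration", "motivation", "effort")


def analyze_study(
    scored: pd.DataFrame,
    traces: Optional[Sequence[FeedbackTrace]] = None,
    alpha: float = ALPHA_DEFAULT,
    max_sessions: int = 12,
) -> dict:
    """Run every contrast of the study over a scored table.

    ``scored`` has one row per administration with columns participant_id,
    session (0 = baseline), condition, feedback, concentration, motivation,
    effort and optionally sus. Contrasts:

    * baseline vs VR (per scale, paired on participants with a baseline and
      a session-1 administration; VR value = participant's mean over all VR
      sessions, and separately session 1 alone);
    * feedback vs no-feedback VR sessions (per scale plus SUS, paired on
      participants with at least two feedback sessions);
    * completers (all ``max_sessions`` sessions) vs non-completers,
      independent t on per-participant mean VR scores;
    * RM-ANOVA across sessions 1..``max_sessions`` (complete cases);
    * band-time fractions pooled over any supplied feedback traces.

    A contrast that is empty after inclusion filtering is reported with an
    ``error`` entry instead of raising.
    """
    required = {"participant_id", "session", "condition", "feedback"}
    if not required <= set(scored.columns):
        raise StatsError(f"scored table missing columns {sorted(required - set(scored.columns))}")
    has_sus = "sus" in scored.columns
    report: dict = {"alpha": alpha}

    base = scored[scored["session"] == 0].set_index("participant_id")
    vr = scored[scored["session"] > 0]

    # --- baseline vs VR -------------------------------------------------
    s1_pids = set(vr.loc[vr["session"] == 1, "participant_id"])
    eligible = [p for p in base.index if p in s1_pids]
    report["baseline_vs_vr"] = {}
    report["baseline_vs_vr_session1"] = {}
    for scale in _REPORT_SCALES:
        x = base.loc[eligible, scale].to_numpy(dtype=float)
        vr_means = (
            vr[vr["participant_id"].isin(eligible)]
            .groupby("participant_id")[scale]
            .mean()
            .reindex(eligible)
            .to_numpy(dtype=float)
        )
        report["baseline_vs_vr"][scale] = _safe_contrast(x, vr_means)
        s1 = (
            vr[vr["session"] == 1]
            .set_index("participant_id")[scale]
            .reindex(eligible)
            .to_numpy(dtype=float)
        )
        report["baseline_vs_vr_session1"][scale] = _safe_contrast(x, s1)

    # --- feedback vs no feedback ----------------------------------------
    fb_counts = vr[vr["feedback"]].groupby("participant_id").size()
    fb_eligible = sorted(fb_counts[fb_counts >= 2].index)
    report["feedback_vs_no_feedback"] = {"n_included": len(fb_eligible)}
    fb_scales = _REPORT_SCALES + (("sus",) if has_sus else ())
    for scale in fb_scales:
        sub = vr[vr["participant_id"].isin(fb_eligible)]
        on = sub[sub["feedback"]].groupby("participant_id")[scale].mean()
        off = sub[~sub["feedback"]].groupby("participant_id")[scale].mean()
        common = sorted(set(on.index) & set(off.index))
        x = on.reindex(common).to_numpy(dtype=float)
        y = off.reindex(common).to_numpy(dtype=float)
        report["feedback_vs_no_feedback"][scale] = _safe_contrast(x, y)

    # --- completers vs non-completers -----------------------------------
    n_sess = vr.groupby("participant_id")["session"].max()
    completers = sorted(n_sess[n_sess >= max_sessions].index)
    dropouts = sorted(n_sess[n_sess < max_sessions].index)
    report["completers_vs_noncompleters"] = {
        "n_completers": len(completers),
        "n_noncompleters": len(dropouts),
    }
    comp_scales = _REPORT_SCALES + (("sus",) if has_sus else ())
    for scale in comp_scales:
        means = vr.groupby("participant_id")[scale].mean()
        x = means.reindex(completers).dropna().to_numpy(dtype=float)
        y = means.reindex(dropouts).dropna().to_numpy(dtype=float)
        if len(x) < 2 or len(y) < 2:
            report["completers_vs_noncompleters"][scale] = {
                "error": "fewer than 2 participants in a group"
            }
        else:
            report["completers_vs_noncompleters"][scale] = independent_compare(
                x, y
            ).to_dict()

    # --- RM-ANOVA across sessions ----------------------------------------
    report["rm_anova"] = {}
    for scale in _REPORT_SCALES:
        wide = vr.pivot_table(
            index="participant_id", columns="session", values=scale, aggfunc="mean"
        ).reindex(columns=range(1, max_sessions + 1))
        try:
            report["rm_anova"][scale] = rm_anova(wide.to_numpy(dtype=float))
        except StatsError as exc:
            report["rm_anova"][scale] = {"error": str(exc)}

    # --- band-time summary ------------------------------------------------
    if traces:
        enabled = [t for t in traces if t.feedback_enabled]
        if enabled:
            pooled = {"green": 0, "yellow": 0, "red": 0}
            total = 0
            for t in enabled:
                fr = band_time_fractions(t)
                m = len(t.records)
                total += m
                for c in pooled:
                    pooled[c] += fr[c] * m
            report["band_time"] = {
                c: pooled[c] / total for c in ("green", "yellow", "red")
            }
            report["band_time"]["n_minutes"] = total
    return report


def _safe_contrast(x: np.ndarray, y: np.ndarray) -> dict:
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3:
        return {"error": f"only {len(x)} complete pairs after inclusion filtering"}
    try:
        return paired_compare(x, y).to_dict()
    except StatsError as exc:
        return {"error": str(exc)}


def summary_table(scored: pd.DataFrame) -> pd.DataFrame:
    """Means ± SD per scale and condition, mirroring the study's layout.

    Columns: baseline, vr_all, vr_session1, vr_feedback, vr_no_feedback;
    cells formatted "m (±sd)". Per-participant averaging is applied within
    each column before pooling, matching the per-participant analyses.
    """
    vr = scored[scored["session"] > 0]
    groups = {
        "baseline": scored[scored["session"] == 0],
        "vr_all": vr,
        "vr_session1": vr[vr["session"] == 1],
        "vr_feedback": vr[vr["feedback"]],
        "vr_no_feedback": vr[~vr["feedback"]],
    }
    rows = {}
    for scale in _REPORT_SCALES:
        row = {}
        for name, g in groups.items():
            per_p = g.groupby("participant_id")[scale].mean().dropna()
            if len(per_p) == 0:
                row[name] = "-"
            else:
                row[name] = f"{per_p.mean():.2f} (±{per_p.std(ddof=1):.2f})"
        rows[scale] = row
    return pd.DataFrame(rows).T
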