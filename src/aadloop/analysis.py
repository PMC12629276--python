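"""Session-level statistics: contrasts, effect sizes, hypothesis verdicts.

The statistical unit is the trial, nested in listeners. Session-half and
feedback/no-feedback contrasts of the per-trial decoder metrics are tested
with a two-factor ANOVA in which the contrast factor is fixed and the
participant is a random effect; with a balanced design this is the classical
repeated-measures F-test on listener x level cell means (implemented via
statsmodels AnovaRM), whose error term is the factor x participant
interaction. Effect sizes are pooled-SD Cohen's d on the per-listener cell
means — one independent unit per listener per level — with two 95% intervals
reported: the raw mean-difference CI from the t-distribution of the paired
per-listener differences, and the same interval on the standardized scale.

Three candidate neural bases of improved attention are scored from the
contrasts: H1, enhanced attended-talker tracking (attended metrics rise);
H2, suppressed unattended-talker tracking (unattended metrics fall);
H3, both at once — so H3 can hold only if H1 and H2 do.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.anova import AnovaRM

__all__ = [
    "ContrastReport",
    "PearsonReport",
    "HypothesisVerdict",
    "trial_metrics_table",
    "half_session_contrast",
    "mode_contrast",
    "cohens_d_with_ci",
    "calibration_vs_test_correlation",
    "classify_hypotheses",
]

METRIC_COLUMNS = (
    "acc_att", "acc_una", "corr_diff_att", "corr_diff_una",
    "alpha_deg", "comprehension_correct",
)


def trial_metrics_table(results) -> pd.DataFrame:
    """Flat per-trial metrics table for a list of session results.

    One row per trial with listener id, trial index, phase, mode, session
    half (neurofeedback-phase trials 1-25 vs 26-50), the four decoder
    metrics, the attenuation integral and the comprehension flag.
    """
    rows = []
    for res in results:
        half_n = res.config.n_feedback_phase_trials // 2
        for rec in res.trials:
            phase_idx = rec.plan.index - res.config.n_training_trials
            half = (
                "none" if rec.plan.phase != "neurofeedback"
                else ("first" if phase_idx < half_n else "second")
            )
            rows.append({
                "listener": res.listener_seed,
                "trial": rec.plan.index,
                "phase": rec.plan.phase,
                "mode": rec.plan.mode,
                "session_half": half,
                "acc_att": rec.summary_att.accuracy_pct if rec.summary_att else np.nan,
                "acc_una": rec.summary_una.accuracy_pct if rec.summary_una else np.nan,
                "corr_diff_att": rec.summary_att.mean_corr_diff if rec.summary_att else np.nan,
                "corr_diff_una": rec.summary_una.mean_corr_diff if rec.summary_una else np.nan,
                "alpha_deg": rec.attenuation.alpha_deg if rec.attenuation else np.nan,
                "comprehension_correct": (
                    float(rec.comprehension_correct)
                    if rec.comprehension_correct is not None else np.nan
                ),
            })
    return pd.DataFrame(rows)


@dataclass
class ContrastReport:
    """Result of one fixed-factor contrast with participant random effect."""

    factor: str
    metric: str
    levels: tuple[str, str]
    group_means: tuple[float, float]
    mean_difference: float            # second level minus first
    p_value: float
    cohens_d: float
    d_ci_95: tuple[float, float]
    raw_diff_ci_95: tuple[float, float]
    n_per_group: tuple[int, int]
    n_listeners: int
    degenerate: bool = False
    note: str = ""

    @property
    def significant(self) -> bool:
        return (not self.degenerate) and self.p_value < 0.05


def _pooled_sd(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = a.size, b.size
    return float(np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    ))


def cohens_d_with_ci(
    group_a, group_b, confidence: float = 0.95
) -> tuple[float, tuple[float, float]]:
    """Pooled-SD Cohen's d of a minus b with a t-distribution CI.

    The interval uses the standard-error approximation
    se = sqrt((na+nb)/(na*nb) + d^2 / (2 (na+nb-2))) with a central-t
    quantile at na+nb-2 degrees of freedom (noncentral-t-free; accurate to
    well under the reporting precision at the cohort sizes used here).
    Swapping the groups negates d and mirrors the CI. Zero pooled SD raises.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    sp = _pooled_sd(a, b)
    if sp == 0:
        raise ValueError("zero pooled standard deviation: d is undefined")
    d = float((a.mean() - b.mean()) / sp)
    na, nb = a.size, b.size
    se = np.sqrt((na + nb) / (na * nb) + d**2 / (2 * (na + nb - 2)))
    tq = stats.t.ppf(0.5 + confidence / 2, na + nb - 2)
    return d, (d - tq * se, d + tq * se)


def _contrast(
    table: pd.DataFrame,
    metric: str,
    factor_col: str,
    levels: tuple[str, str],
    factor_name: str,
) -> ContrastReport:
    data = table.dropna(subset=[metric])
    a = data[data[factor_col] == levels[0]]
    b = data[data[factor_col] == levels[1]]
    if len(a) == 0 or len(b) == 0:
        raise ValueError(f"empty group for {factor_name} contrast on {metric}")
    listeners = sorted(set(a["listener"]) & set(b["listener"]))
    note = ""
    if len(listeners) >= 2:
        sub = data[data["listener"].isin(listeners)]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            aov = AnovaRM(
                sub, depvar=metric, subject="listener",
                within=[factor_col], aggregate_func="mean",
            ).fit()
        p = float(aov.anova_table["Pr > F"].iloc[0])
        cm = sub.groupby(["listener", factor_col], observed=True)[metric].mean()
        m1 = cm.xs(levels[0], level=factor_col).reindex(listeners).to_numpy()
        m2 = cm.xs(levels[1], level=factor_col).reindex(listeners).to_numpy()
        diffs = m2 - m1
        sp = _pooled_sd(m2, m1)
        degenerate = sp == 0
        d = float(diffs.mean() / sp) if not degenerate else np.nan
        n = diffs.size
        if n >= 2 and diffs.std(ddof=1) > 0:
            tq = stats.t.ppf(0.975, n - 1)
            half = tq * diffs.std(ddof=1) / np.sqrt(n)
            raw_ci = (float(diffs.mean() - half), float(diffs.mean() + half))
        else:
            raw_ci = (float(diffs.mean()), float(diffs.mean()))
        d_ci = (
            (raw_ci[0] / sp, raw_ci[1] / sp) if not degenerate else (np.nan, np.nan)
        )
        means = (float(m1.mean()), float(m2.mean()))
        mean_diff = float(diffs.mean())
    else:
        # single listener: no random effect to model; plain Welch contrast
        note = "single listener: Welch t-test fallback, no random effect"
        warnings.warn(note, stacklevel=3)
        x1 = a[metric].to_numpy(float)
        x2 = b[metric].to_numpy(float)
        if min(x1.size, x2.size) < 2:
            raise ValueError(
                f"{factor_name} contrast on {metric}: need >= 2 trials per group"
            )
        degenerate = _pooled_sd(x2, x1) == 0
        if degenerate:
            p, d, d_ci = np.nan, np.nan, (np.nan, np.nan)
            raw_ci = (np.nan, np.nan)
        else:
            p = float(stats.ttest_ind(x2, x1, equal_var=False).pvalue)
            d, d_ci = cohens_d_with_ci(x2, x1)
            se = np.sqrt(x1.var(ddof=1) / x1.size + x2.var(ddof=1) / x2.size)
            tq = stats.t.ppf(0.975, min(x1.size, x2.size) - 1)
            mid = x2.mean() - x1.mean()
            raw_ci = (float(mid - tq * se), float(mid + tq * se))
        means = (float(x1.mean()), float(x2.mean()))
        mean_diff = means[1] - means[0]
    return ContrastReport(
        factor=factor_name,
        metric=metric,
        levels=levels,
        group_means=means,
        mean_difference=mean_diff,
        p_value=p,
        cohens_d=d,
        d_ci_95=tuple(d_ci),
        raw_diff_ci_95=tuple(raw_ci),
        n_per_group=(len(a), len(b)),
        n_listeners=max(len(listeners), 1),
        degenerate=degenerate,
        note=note,
    )


def half_session_contrast(
    table: pd.DataFrame, metric: str, mode_filter: str | None = "feedback_on"
) -> ContrastReport:
    """First vs second session half on neurofeedback-phase trials.

    ``mode_filter`` restricts to one trial mode (the session-half effect is
    examined separately within feedback-on and fixed-gain trials); None
    pools both modes.
    """
    data = table[table["phase"] == "neurofeedback"]
    if mode_filter is not None:
        data = data[data["mode"] == mode_filter]
    return _contrast(data, metric, "session_half", ("first", "second"), "session_half")


def mode_contrast(table: pd.DataFrame, metric: str) -> ContrastReport:
    """Feedback-on vs fixed-gain trials within the neurofeedback phase."""
    data = table[table["phase"] == "neurofeedback"]
    return _contrast(data, metric, "mode", ("feedback_on", "fixed_gain"), "mode")


@dataclass
class PearsonReport:
    r: float
    p_value: float
    ci_95: tuple[float, float]
    n: int


def calibration_vs_test_correlation(
    cv_accuracy, test_accuracy, confidence: float = 0.95
) -> PearsonReport:
    """Pearson correlation of per-listener calibration vs test accuracy.

    Two-sided p-value; CI by Fisher z-transform. Requires n >= 4 (the CI is
    undefined below that) and non-constant inputs.
    """
    x = np.asarray(cv_accuracy, dtype=float)
    y = np.asarray(test_accuracy, dtype=float)
    if x.size != y.size:
        raise ValueError("inputs differ in length")
    if x.size < 4:
        raise ValueError("need at least 4 listeners")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("constant input: correlation undefined")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    z = np.arctanh(np.clip(r, -1 + 1e-15, 1 - 1e-15))
    se = 1.0 / np.sqrt(x.size - 3)
    zq = stats.norm.ppf(0.5 + confidence / 2)
    lo, hi = np.tanh(z - zq * se), np.tanh(z + zq * se)
    return PearsonReport(r, float(res.pvalue), (float(lo), float(hi)), x.size)


@dataclass
class HypothesisVerdict:
    """Which neural bases of improved attention the contrasts support."""

    h1_supported: bool
    h2_supported: bool
    h3_supported: bool
    criteria: dict = field(default_factory=dict)


def classify_hypotheses(
    att_report: ContrastReport,
    una_report: ContrastReport,
    alpha: float = 0.05,
) -> HypothesisVerdict:
    """Score H1/H2/H3 from the feedback-trial session-half contrasts.

    H1 needs a significant *increase* of the attended metric, H2 a
    significant *decrease* of the unattended metric, H3 both. Direction is
    taken from the sign of the second-minus-first mean difference.
    """
    for rep in (att_report, una_report):
        if rep.degenerate or not np.isfinite(rep.p_value):
            raise ValueError(f"contrast on {rep.metric} is degenerate")
    h1 = att_report.p_value < alpha and att_report.mean_difference > 0
    h2 = una_report.p_value < alpha and una_report.mean_difference < 0
    h3 = h1 and h2
    return HypothesisVerdict(
        h1, h2, h3,
        criteria={
            "alpha": alpha,
            "attended": {
                "metric": att_report.metric,
                "p": att_report.p_value,
                "mean_difference": att_report.mean_difference,
                "d": att_report.cohens_d,
            },
            "unattended": {
                "metric": una_report.metric,
                "p": una_report.p_value,
                "mean_difference": una_report.mean_difference,
                "d": una_report.cohens_d,
            },
        },
    )
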