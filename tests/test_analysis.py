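"""Contrast statistics, effect sizes, and hypothesis classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from aadloop.analysis import (
    ContrastReport,
    calibration_vs_test_correlation,
    classify_hypotheses,
    cohens_d_with_ci,
    half_session_contrast,
    mode_contrast,
)


def _null_table(rng, n_listeners=8, n_per_half=10, listener_sd=5.0, noise_sd=8.0,
                shift=0.0, metric="acc_una"):
    """Synthetic neurofeedback-phase metric table with random listener
    intercepts and optional second-half shift."""
    rows = []
    for lid in range(n_listeners):
        mu = 60.0 + rng.normal(0, listener_sd)
        for half in ("first", "second"):
            for t in range(n_per_half):
                val = mu + rng.normal(0, noise_sd) + (shift if half == "second" else 0)
                rows.append({
                    "listener": lid, "trial": t, "phase": "neurofeedback",
                    "mode": "feedback_on", "session_half": half, metric: val,
                })
    return pd.DataFrame(rows)


class TestCohensD:
    def test_identical_groups_give_zero(self):
        d, ci = cohens_d_with_ci([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert d == 0.0
        assert ci[0] < 0 < ci[1]

    def test_hand_computed_example(self):
        d, _ = cohens_d_with_ci([0.0, 1.0], [1.0, 2.0])
        assert d == pytest.approx(-np.sqrt(2))

    def test_antisymmetry_reflects_interval(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 10)
        d1, ci1 = cohens_d_with_ci(a, b)
        d2, ci2 = cohens_d_with_ci(b, a)
        assert d1 == pytest.approx(-d2)
        assert ci1[0] == pytest.approx(-ci2[1])
        assert ci1[1] == pytest.approx(-ci2[0])

    @given(st.floats(-50, 50), st.floats(0.1, 20))
    @settings(deadline=None, max_examples=25)
    def test_location_scale_invariance(self, loc, scale):
        rng = np.random.default_rng(1)
        a, b = rng.normal(0, 1, 12), rng.normal(0.8, 1, 12)
        d0, _ = cohens_d_with_ci(a, b)
        d1, _ = cohens_d_with_ci(a * scale + loc, b * scale + loc)
        assert d1 == pytest.approx(d0, rel=1e-9)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValueError, match="pooled"):
            cohens_d_with_ci([1.0, 1.0, 1.0], [2.0, 2.0, 2.0])

    def test_tiny_groups_rejected(self):
        with pytest.raises(ValueError, match="at least 2"):
            cohens_d_with_ci([1.0], [1.0, 2.0])


class TestHalfSessionContrast:
    def test_identical_halves_give_null_result(self, rng):
        table = _null_table(rng, shift=0.0)
        rep = half_session_contrast(table, "acc_una")
        assert rep.p_value > 0.05 or abs(rep.cohens_d) < 0.8
        assert rep.d_ci_95[0] < 0 < rep.d_ci_95[1] or abs(rep.cohens_d) < 0.8

    def test_injected_shift_detected_with_correct_sign(self, rng):
        table = _null_table(rng, shift=-8.0)
        rep = half_session_contrast(table, "acc_una")
        assert rep.p_value < 0.05
        assert rep.cohens_d < 0
        assert rep.mean_difference < 0
        assert rep.d_ci_95[1] < 0

    def test_anova_p_equals_paired_t_on_cell_means(self, rng):
        # balanced repeated-measures ANOVA with one 2-level factor reduces
        # to the paired t-test on listener cell means
        table = _null_table(rng, shift=-4.0)
        rep = half_session_contrast(table, "acc_una")
        cm = table.groupby(["listener", "session_half"])["acc_una"].mean().unstack()
        t = stats.ttest_rel(cm["second"], cm["first"])
        assert rep.p_value == pytest.approx(t.pvalue, rel=1e-6)

    def test_single_listener_falls_back_to_welch(self, rng):
        table = _null_table(rng, n_listeners=1, shift=-10.0)
        with pytest.warns(UserWarning, match="single listener"):
            rep = half_session_contrast(table, "acc_una")
        assert "Welch" in rep.note

    def test_empty_group_rejected(self, rng):
        table = _null_table(rng)
        with pytest.raises(ValueError, match="empty group"):
            half_session_contrast(table[table.session_half == "first"], "acc_una")

    def test_type_one_error_calibrated(self):
        # null cohorts: the contrast should reject at ~ the nominal rate
        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            table = _null_table(np.random.default_rng(seed + 10_000))
            rejections += half_session_contrast(table, "acc_una").p_value < 0.05
        assert stats.binomtest(rejections, n_rep, 0.05).pvalue > 0.01


class TestModeContrast:
    def _table_with_modes(self, rng):
        rows = []
        for lid in range(6):
            for mode, n in (("feedback_on", 8), ("fixed_gain", 2)):
                for t in range(n):
                    alpha = 0.5 if mode == "fixed_gain" else rng.uniform(0.2, 0.9)
                    rows.append({
                        "listener": lid, "trial": t, "phase": "neurofeedback",
                        "mode": mode, "session_half": "first",
                        "alpha_deg": alpha,
                    })
        return pd.DataFrame(rows)

    def test_fixed_gain_alpha_deg_is_exactly_half(self, rng):
        rep = mode_contrast(self._table_with_modes(rng), "alpha_deg")
        assert rep.group_means[1] == pytest.approx(0.5)

    def test_one_trial_per_group_rejected(self):
        rows = [
            {"listener": 0, "trial": 0, "phase": "neurofeedback",
             "mode": m, "session_half": "first", "acc_att": v}
            for m, v in (("feedback_on", 60.0), ("fixed_gain", 55.0))
        ]
        with pytest.warns(UserWarning):
            with pytest.raises(ValueError, match="2 trials"):
                mode_contrast(pd.DataFrame(rows), "acc_att")


class TestCalibrationCorrelation:
    def test_perfect_relationship(self):
        x = np.arange(10, dtype=float)
        rep = calibration_vs_test_correlation(x, x)
        assert rep.r == pytest.approx(1.0)
        assert rep.p_value < 1e-6

    def test_independent_inputs_average_to_zero(self):
        rs = []
        for seed in range(60):
            rng = np.random.default_rng(seed)
            rep = calibration_vs_test_correlation(
                rng.normal(60, 7, 22), rng.normal(60, 7, 22)
            )
            rs.append(rep.r)
        assert abs(np.mean(rs)) < 0.08

    def test_ci_contains_r(self, rng):
        rep = calibration_vs_test_correlation(
            rng.normal(0, 1, 22), rng.normal(0, 1, 22)
        )
        assert rep.ci_95[0] <= rep.r <= rep.ci_95[1]

    def test_small_n_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            calibration_vs_test_correlation([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            calibration_vs_test_correlation([1.0] * 5, [1.0, 2.0, 3.0, 4.0, 5.0])


def _report(metric, p, diff):
    return ContrastReport(
        factor="session_half", metric=metric, levels=("first", "second"),
        group_means=(60.0, 60.0 + diff), mean_difference=diff, p_value=p,
        cohens_d=np.sign(diff) * 1.0, d_ci_95=(-2.0, 2.0),
        raw_diff_ci_95=(diff - 1, diff + 1), n_per_group=(20, 20), n_listeners=22,
    )


class TestClassifyHypotheses:
    def test_unattended_suppression_only_supports_h2(self):
        v = classify_hypotheses(_report("acc_att", 0.4, 1.0),
                                _report("acc_una", 0.01, -5.0))
        assert (v.h1_supported, v.h2_supported, v.h3_supported) == (False, True, False)

    def test_both_directions_support_all_three(self):
        v = classify_hypotheses(_report("acc_att", 0.01, 4.0),
                                _report("acc_una", 0.01, -5.0))
        assert (v.h1_supported, v.h2_supported, v.h3_supported) == (True, True, True)

    def test_nothing_significant_supports_none(self):
        v = classify_hypotheses(_report("acc_att", 0.5, 1.0),
                                _report("acc_una", 0.5, -1.0))
        assert not (v.h1_supported or v.h2_supported or v.h3_supported)

    def test_h3_implies_h1_and_h2(self):
        for p_att in (0.01, 0.5):
            for p_una in (0.01, 0.5):
                v = classify_hypotheses(_report("acc_att", p_att, 2.0),
                                        _report("acc_una", p_una, -2.0))
                assert not v.h3_supported or (v.h1_supported and v.h2_supported)

    def test_wrong_direction_not_supported(self):
        v = classify_hypotheses(_report("acc_att", 0.01, -4.0),
                                _report("acc_una", 0.01, 5.0))
        assert not v.h1_supported and not v.h2_supported
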