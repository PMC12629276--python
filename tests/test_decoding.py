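"""Ridge decoder training, prediction, window correlations, CV."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from aadloop.decoding import (
    DecodingTrial,
    EnvelopeSignal,
    TrainingSet,
    decoding_accuracy,
    leave_one_trial_out_cv,
    predict_envelope,
    train_decoder,
    train_decoder_from_trials,
    windowed_correlations,
)
from aadloop.listener import ListenerModel
from aadloop.preprocessing import LaggedDesignMatrix

from helpers import make_trials


def _training_set(design, target, n_channels=None, n_lags=None):
    design = np.asarray(design, dtype=float)
    n_channels = n_channels or design.shape[1]
    n_lags = n_lags or 1
    return TrainingSet(design, target, n_channels, n_lags,
                       1000.0 * n_lags / 64.0, 64.0)


class TestTrainDecoder:
    def test_identity_design_returns_target(self):
        dec = train_decoder(_training_set(np.eye(3), [1.0, 2.0, 3.0]), 0.0)
        np.testing.assert_allclose(dec.weights, [1, 2, 3])

    def test_identity_design_with_unit_ridge_halves_weights(self):
        dec = train_decoder(_training_set(np.eye(2), [1.0, 1.0]), 1.0)
        np.testing.assert_allclose(dec.weights, [0.5, 0.5])

    def test_matches_normal_equations_oracle(self, rng):
        for _ in range(20):
            n, p = rng.integers(15, 50), rng.integers(2, 10)
            design = rng.standard_normal((n, p))
            target = rng.standard_normal(n)
            lam = float(rng.uniform(0.1, 100))
            dec = train_decoder(_training_set(design, target), lam)
            oracle = np.linalg.inv(design.T @ design + lam * np.eye(p)) @ design.T @ target
            np.testing.assert_allclose(dec.weights, oracle, rtol=1e-8)

    def test_singular_unregularized_system_names_rank(self):
        design = np.ones((4, 3))  # rank 1
        with pytest.raises(ValueError, match="rank 1"):
            train_decoder(_training_set(design, np.ones(4)), 0.0)

    def test_weight_norm_shrinks_monotonically_with_lambda(self, rng):
        design = rng.standard_normal((40, 6))
        target = rng.standard_normal(40)
        norms = [
            np.linalg.norm(train_decoder(_training_set(design, target), lam).weights)
            for lam in (0.0, 1.0, 10.0, 100.0, 1e4)
        ]
        assert all(a > b for a, b in zip(norms, norms[1:]))

    def test_rejects_negative_lambda(self):
        with pytest.raises(ValueError, match="non-negative"):
            train_decoder(_training_set(np.eye(2), [1.0, 1.0]), -1.0)

    def test_unbalanced_training_set_rejected(self, clean_listener):
        trials = make_trials(clean_listener, n_trials=2, duration_s=10.0)
        trials[1].attended_side = "left"  # both left now
        trials[1].design = LaggedDesignMatrix(
            trials[1].design.data[:100], 24, 32, 500.0, 64.0
        )
        with pytest.raises(ValueError, match="unbalanced"):
            TrainingSet.from_trials(trials)


class TestLabelInversion:
    def test_unattended_decoder_equals_swapped_attended_decoder(self, clean_listener):
        trials = make_trials(clean_listener, n_trials=4, duration_s=15.0)
        dec_una = train_decoder_from_trials(trials, 10.0, role="unattended")
        swapped = [
            DecodingTrial(t.design, t.env_una, t.env_att,
                          attended_side="right" if t.attended_side == "left" else "left")
            for t in trials
        ]
        dec_att = train_decoder_from_trials(swapped, 10.0, role="attended")
        np.testing.assert_array_equal(dec_una.weights, dec_att.weights)


class TestPredictEnvelope:
    def test_zero_weights_give_zero_prediction(self, rng):
        design = LaggedDesignMatrix(rng.standard_normal((10, 4)), 2, 2, 31.25, 64.0)
        dec = train_decoder(_training_set(np.eye(4), np.zeros(4), 2, 2), 1.0)
        pred = predict_envelope(dec, design)
        assert pred.role == "predicted"
        np.testing.assert_allclose(pred.samples, 0.0)

    def test_identity_design_returns_weights(self):
        dec = train_decoder(_training_set(np.eye(4), [1.0, -2.0, 3.0, -4.0], 2, 2), 0.0)
        design = LaggedDesignMatrix(np.eye(4), 2, 2, 31.25, 64.0)
        np.testing.assert_allclose(predict_envelope(dec, design).samples, dec.weights)

    def test_rejects_dimension_mismatch(self, rng):
        dec = train_decoder(_training_set(np.eye(4), np.ones(4), 2, 2), 1.0)
        design = LaggedDesignMatrix(rng.standard_normal((5, 6)), 3, 2, 31.25, 64.0)
        with pytest.raises(ValueError, match="columns"):
            predict_envelope(dec, design)

    def test_noiseless_reconstruction_is_near_perfect(self, clean_listener):
        # linear forward model inside the decoder's lag span: the backward
        # model should reconstruct the attended envelope almost exactly
        trial = make_trials(clean_listener, n_trials=1, duration_s=60.0)[0]
        dec = train_decoder_from_trials([trial], 1e-6)
        pred = predict_envelope(dec, trial.design)
        r = np.corrcoef(pred.samples, trial.env_att.samples[: pred.n_samples])[0, 1]
        assert r > 0.95


class TestWindowedCorrelations:
    def test_self_correlation_is_one(self, rng):
        x = rng.standard_normal(64 * 30)
        pred = EnvelopeSignal(x, 64.0, role="predicted")
        env_att = EnvelopeSignal(x - x.min(), 64.0)  # affine copy: r = 1 exactly
        env_una = EnvelopeSignal(np.abs(rng.standard_normal(x.size)), 64.0, role="unattended")
        series = windowed_correlations(pred, env_att, env_una, 10.0, 0.5)
        np.testing.assert_allclose(series.corr_xa, 1.0, atol=1e-12)
        assert np.all(series.corr_diff > 0)

    def test_sign_flip_gives_minus_one(self, rng):
        x = np.abs(rng.standard_normal(64 * 20)) + 0.1
        pred = EnvelopeSignal(-x, 64.0, role="predicted")
        env_att = EnvelopeSignal(x, 64.0)
        env_una = EnvelopeSignal(np.abs(rng.standard_normal(x.size)), 64.0, role="unattended")
        series = windowed_correlations(pred, env_att, env_una, 10.0, 0.5)
        np.testing.assert_allclose(series.corr_xa, -1.0, atol=1e-12)

    def test_window_count_for_sixty_seconds(self, rng):
        n = 64 * 60
        sig = lambda: EnvelopeSignal(np.abs(rng.standard_normal(n)), 64.0)
        series = windowed_correlations(
            EnvelopeSignal(rng.standard_normal(n), 64.0, role="predicted"),
            sig(), EnvelopeSignal(np.abs(rng.standard_normal(n)), 64.0, role="unattended"),
            10.0, 0.5,
        )
        assert series.n_windows == 101

    def test_zero_variance_window_is_nan(self, rng):
        n = 64 * 10
        flat = EnvelopeSignal(np.ones(n), 64.0)
        series = windowed_correlations(
            EnvelopeSignal(rng.standard_normal(n), 64.0, role="predicted"),
            flat, EnvelopeSignal(np.abs(rng.standard_normal(n)), 64.0, role="unattended"),
            10.0, 0.5,
        )
        assert np.isnan(series.corr_xa).all()

    def test_unattended_role_flips_decision_sign(self, rng):
        n = 64 * 20
        pred = EnvelopeSignal(rng.standard_normal(n), 64.0, role="predicted")
        ea = EnvelopeSignal(np.abs(rng.standard_normal(n)), 64.0)
        eu = EnvelopeSignal(np.abs(rng.standard_normal(n)), 64.0, role="unattended")
        s_att = windowed_correlations(pred, ea, eu, 10.0, 0.5, decoder_role="attended")
        s_una = windowed_correlations(pred, ea, eu, 10.0, 0.5, decoder_role="unattended")
        np.testing.assert_allclose(s_att.corr_diff, -s_una.corr_diff)


class TestDecodingAccuracy:
    def _series(self, diffs):
        diffs = np.asarray(diffs, dtype=float)
        from aadloop.decoding import CorrelationWindowSeries
        return CorrelationWindowSeries(
            np.arange(diffs.size) * 0.5, 10.0, 0.5, diffs, np.zeros(diffs.size)
        )

    def test_two_of_three_positive(self):
        assert decoding_accuracy(self._series([0.1, -0.2, 0.3])).accuracy_pct == pytest.approx(200 / 3)

    def test_all_positive_is_hundred(self):
        assert decoding_accuracy(self._series([0.1, 0.2])).accuracy_pct == 100.0

    def test_exact_zero_counts_as_incorrect(self):
        assert decoding_accuracy(self._series([0.0, 0.1, 0.2, 0.3])).accuracy_pct == 75.0

    def test_nan_windows_excluded(self):
        summary = decoding_accuracy(self._series([np.nan, 0.1, -0.1]))
        assert summary.n_windows == 2
        assert summary.accuracy_pct == 50.0

    def test_all_nan_rejected(self):
        with pytest.raises(ValueError, match="no window"):
            decoding_accuracy(self._series([np.nan, np.nan]))

    @given(st.floats(min_value=0.01, max_value=100.0))
    @settings(deadline=None, max_examples=20)
    def test_accuracy_invariant_to_positive_prediction_scaling(self, scale):
        rng = np.random.default_rng(42)
        n = 64 * 20
        pred = rng.standard_normal(n)
        ea = np.abs(rng.standard_normal(n))
        eu = np.abs(rng.standard_normal(n))
        accs = []
        for s in (1.0, scale):
            series = windowed_correlations(
                EnvelopeSignal(pred * s, 64.0, role="predicted"),
                EnvelopeSignal(ea, 64.0),
                EnvelopeSignal(eu, 64.0, role="unattended"),
                5.0, 0.5,
            )
            accs.append(decoding_accuracy(series).accuracy_pct)
        assert accs[0] == accs[1]


class TestLeaveOneTrialOutCV:
    def test_two_trial_degenerate_case_returns_two_folds(self, clean_listener):
        trials = make_trials(clean_listener, n_trials=2, duration_s=15.0)
        report = leave_one_trial_out_cv(trials, window_s=5.0)
        assert report.n_folds == 2

    def test_single_trial_rejected(self, clean_listener):
        trials = make_trials(clean_listener, n_trials=1, duration_s=15.0)
        with pytest.raises(ValueError, match="2 trials"):
            leave_one_trial_out_cv(trials)

    def test_fold_solution_equals_fresh_retraining(self, noisy_listener):
        # the Gram-difference shortcut must equal training from scratch on
        # the remaining trials
        trials = make_trials(noisy_listener, n_trials=3, duration_s=15.0)
        report = leave_one_trial_out_cv(trials, 100.0, window_s=5.0)
        dec = train_decoder_from_trials(trials[1:], 100.0)
        pred = predict_envelope(dec, trials[0].design)
        series = windowed_correlations(
            pred, trials[0].env_att, trials[0].env_una, 5.0, 0.5
        )
        assert decoding_accuracy(series).accuracy_pct == pytest.approx(
            report.fold_accuracy_pct[0]
        )
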