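"""Neurofeedback mapping: decoded attention -> unattended-talker attenuation.

The real-time attention signal is the running (cumulative within-trial)
attended-decoder accuracy, smoothed with a causal exponential moving average.
Accuracy in [0, 100] maps linearly and inversely onto the unattended talker's
presentation gain in [0, -10] dB: better decoding attenuates the distractor
more, raising the attended talker's SNR. The attended stream is never
modified.

Per trial, the attenuation actually delivered is summarized by alpha_deg:
the time-integral of alpha(t) normalized by the maximal possible attenuation
(the floor, -10 dB, held for the whole trial), so alpha_deg is 0 with no
attenuation and 1 at permanent maximum attenuation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .decoding import CorrelationWindowSeries
from .preprocessing import RawAudio

__all__ = [
    "AttentionSignal",
    "GainTrace",
    "AttenuationSummary",
    "ATTENUATION_FLOOR_DB",
    "running_accuracy",
    "smooth_attention",
    "accuracy_to_gain",
    "db_to_linear",
    "apply_gain",
    "attenuation_summary",
]

#: maximal unattended-talker attenuation (dB); feedback range is [floor, 0]
ATTENUATION_FLOOR_DB = -10.0
#: gain update period (s) of the real-time loop
UPDATE_PERIOD_S = 0.5
#: default half-life (s) of the causal attention smoother
SMOOTHER_HALF_LIFE_S = 5.0


@dataclass
class AttentionSignal:
    """Real-time decoded attention accuracy on the update grid, in [0,100].

    Values exist only from the first completed correlation window onward;
    before that the feedback loop holds its initial (0 dB) gain.
    """

    times_s: np.ndarray
    accuracy_pct: np.ndarray
    smoothed: bool = False

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.accuracy_pct = np.asarray(self.accuracy_pct, dtype=float)
        if self.times_s.shape != self.accuracy_pct.shape:
            raise ValueError("times and accuracies differ in length")
        finite = self.accuracy_pct[np.isfinite(self.accuracy_pct)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("accuracy outside [0, 100]")


@dataclass
class GainTrace:
    """Piecewise-constant unattended-talker gain alpha(t) in dB <= 0."""

    times_s: np.ndarray
    alpha_db: np.ndarray
    update_period_s: float = UPDATE_PERIOD_S
    floor_db: float = ATTENUATION_FLOOR_DB

    def __post_init__(self) -> None:
        self.times_s = np.asarray(self.times_s, dtype=float)
        self.alpha_db = np.asarray(self.alpha_db, dtype=float)
        if self.times_s.shape != self.alpha_db.shape:
            raise ValueError("times and gains differ in length")
        if self.alpha_db.size and (
            self.alpha_db.min() < self.floor_db - 1e-9 or self.alpha_db.max() > 1e-9
        ):
            raise ValueError(f"gain outside [{self.floor_db}, 0] dB")


@dataclass
class AttenuationSummary:
    """Trial-level attenuation integrals.

    ``alpha_max`` is the (negative) maximal attenuation integral, the floor
    held across every sample of the trial (dB * samples); ``alpha_deg`` in
    [0, 1] is the delivered integral normalized by it.
    """

    alpha_max: float
    alpha_deg: float


def running_accuracy(series: CorrelationWindowSeries) -> AttentionSignal:
    """Cumulative causal decoding accuracy over the windows seen so far.

    At the k-th window decision the value is 100 x (number of windows so far
    with corrDiff > 0) / (number of decidable windows so far); undefined
    (zero-variance) windows are excluded from both counts, holding the
    previous value. Times are the instants the decisions become available
    (window end).
    """
    d = series.corr_diff
    defined = np.isfinite(d)
    hits = np.cumsum(defined & (d > 0))
    n = np.cumsum(defined)
    acc = np.where(n > 0, 100.0 * hits / np.maximum(n, 1), np.nan)
    times = series.window_starts_s + series.window_s
    return AttentionSignal(times, acc, smoothed=False)


def ema_coefficient(step_s: float, half_life_s: float) -> float:
    """Per-step EMA weight such that the step response reaches 1/2 after
    one half-life."""
    if half_life_s < 0:
        raise ValueError("half-life must be non-negative")
    if half_life_s == 0:
        return 1.0
    return 1.0 - 2.0 ** (-step_s / half_life_s)


def smooth_attention(
    signal: AttentionSignal,
    half_life_s: float = SMOOTHER_HALF_LIFE_S,
    initial: float | None = None,
) -> AttentionSignal:
    """Causal exponential moving average of the raw attention signal.

    ``initial`` seeds the EMA state before the first value (e.g. 0 for a
    step-response analysis); by default the first defined raw value is used.
    A convex combination of inputs, so the output stays in [0, 100].
    """
    if half_life_s <= 0:
        raise ValueError("half-life must be positive")
    step = float(np.median(np.diff(signal.times_s))) if signal.times_s.size > 1 else 1.0
    a = ema_coefficient(step, half_life_s)
    out = np.full_like(signal.accuracy_pct, np.nan)
    state = initial
    for i, x in enumerate(signal.accuracy_pct):
        if not np.isfinite(x):
            out[i] = state if state is not None else np.nan
            continue
        state = x if state is None else state + a * (x - state)
        out[i] = state
    return AttentionSignal(signal.times_s, out, smoothed=True)


def accuracy_to_gain(
    accuracy_pct, floor_db: float = ATTENUATION_FLOOR_DB
):
    """Linear inverse map from decoded accuracy to unattended gain.

    0 -> 0 dB (no attenuation), 100 -> floor (default -10 dB), 50 -> the
    midpoint (-5 dB). Inputs outside [0, 100] are clipped with a warning.
    """
    acc = np.asarray(accuracy_pct, dtype=float)
    if np.any(acc < 0) or np.any(acc > 100):
        warnings.warn("accuracy outside [0, 100]; clipping", stacklevel=2)
        acc = np.clip(acc, 0.0, 100.0)
    gain = floor_db * acc / 100.0 + 0.0  # +0.0 avoids negative zero
    return float(gain) if np.isscalar(accuracy_pct) else gain


def db_to_linear(db) -> float | np.ndarray:
    return 10.0 ** (np.asarray(db, dtype=float) / 20.0)


def apply_gain(
    audio: RawAudio, trace: GainTrace, ramp_s: float = 0.05
) -> RawAudio:
    """Apply the piecewise-constant gain trace to an audio stream.

    The gain is held constant within each update period; ``ramp_s`` crossfades
    linearly (in amplitude) into each new gain value to avoid audible clicks
    at update boundaries. The trace must cover the audio duration.
    """
    n = audio.samples.size
    if trace.times_s.size == 0:
        raise ValueError("empty gain trace")
    covered = trace.times_s[-1] + trace.update_period_s
    if covered + 1e-9 < n / audio.rate:
        raise ValueError(
            f"gain trace covers {covered:.3f} s, audio lasts {n / audio.rate:.3f} s"
        )
    # per-sample linear gain, then optional linear crossfade at boundaries
    idx = np.minimum(
        (np.arange(n) / audio.rate // trace.update_period_s).astype(int),
        trace.alpha_db.size - 1,
    )
    lin = db_to_linear(trace.alpha_db)[idx]
    ramp_n = int(round(ramp_s * audio.rate))
    if ramp_n > 1:
        kernel = np.ones(ramp_n) / ramp_n
        # causal moving average: smooths each step over ramp_s
        state = np.full(ramp_n - 1, lin[0])
        lin = np.convolve(np.concatenate([state, lin]), kernel, mode="valid")
    return RawAudio(audio.samples * lin, audio.rate, talker_id=audio.talker_id)


def attenuation_summary(trace: GainTrace) -> AttenuationSummary:
    """Discrete attenuation integrals over the trial's gain samples.

    alpha_max = sum over samples of the floor (-10 dB); alpha_deg =
    sum(alpha) / alpha_max, i.e. the time-average of alpha normalized by the
    floor, in [0, 1].
    """
    if trace.alpha_db.size == 0:
        raise ValueError("empty gain trace")
    alpha_max = trace.floor_db * trace.alpha_db.size
    alpha_deg = float(trace.alpha_db.sum() / alpha_max + 0.0)
    return AttenuationSummary(alpha_max, alpha_deg)
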