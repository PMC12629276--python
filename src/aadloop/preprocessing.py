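"""Causal signal conditioning for real-time auditory attention decoding.

Raw audio is reduced to a slow amplitude envelope and raw EEG is band-limited
to the cortical envelope-tracking band, both delivered at a common decode
rate. Every filter here is a strictly causal linear-phase FIR so that the
group delay is a single, exactly known constant that can be budgeted against
the real-time latency requirement: the output at time t depends only on
inputs at times <= t, and processing a prefix of a signal yields the
identical prefix of the full output.

The time-lagged design matrix used by the backward (stimulus-reconstruction)
model is also built here: row t stacks all channels at lags 0..L-1 samples
*after* stimulus time t, the convention for decoding a stimulus from the
neural response that follows it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from scipy import signal

__all__ = [
    "RawAudio",
    "RawEEG",
    "EnvelopeSignal",
    "LaggedDesignMatrix",
    "LatencyBudget",
    "extract_envelope",
    "preprocess_eeg",
    "build_lag_matrix",
    "unbuild_lag_matrix",
    "latency_budget",
    "n_lags_for_span",
]

#: default cut-off (Hz) of the causal audio-envelope low-pass
ENVELOPE_LOWPASS_HZ = 8.0
#: default EEG analysis band (Hz): cortical speech-envelope tracking band
EEG_BAND_HZ = (1.0, 8.0)
#: default group delay (s) of the causal EEG band-pass; sets the FIR order
EEG_FILTER_DELAY_S = 1.1
#: default group delay (s) of the causal envelope low-pass
ENVELOPE_FILTER_DELAY_S = 0.25
#: default rate (Hz) at which decoding operates
DEFAULT_DECODE_RATE = 64.0


@dataclass
class RawAudio:
    """Single-talker audio waveform.

    samples are amplitudes in [-1, 1] (arbitrary units), ``talker_id``
    labels the spatial stream (``"left"`` or ``"right"``).
    """

    samples: np.ndarray
    rate: float
    talker_id: str = "left"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("audio rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("audio contains non-finite samples")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class RawEEG:
    """Multichannel EEG, channels x time, in microvolts.

    ``group_delay_s`` records the accumulated causal-filter delay of any
    preprocessing already applied (0 for freshly acquired data).
    """

    samples: np.ndarray
    rate: float
    channel_labels: list[str] = field(default_factory=list)
    group_delay_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.atleast_2d(np.asarray(self.samples, dtype=float))
        if self.rate <= 0:
            raise ValueError("EEG rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("EEG contains non-finite samples")
        if not self.channel_labels:
            self.channel_labels = [f"ch{i:02d}" for i in range(self.n_channels)]
        if len(self.channel_labels) != self.n_channels:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.n_channels} channels"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]


@dataclass
class EnvelopeSignal:
    """A talker's amplitude envelope at the decode rate.

    ``role`` is ``"attended"``/``"unattended"`` for true stimulus envelopes
    (non-negative by construction) or ``"predicted"`` for decoder output,
    which is a least-squares reconstruction and may take either sign.
    """

    samples: np.ndarray
    rate: float
    role: str = "attended"
    group_delay_s: float = 0.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float).ravel()
        if self.rate <= 0:
            raise ValueError("envelope rate must be positive")
        if self.role not in ("attended", "unattended", "predicted"):
            raise ValueError(f"unknown envelope role {self.role!r}")
        if self.role != "predicted" and self.samples.size and self.samples.min() < 0:
            raise ValueError("stimulus envelope must be non-negative")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.rate


@dataclass
class LaggedDesignMatrix:
    """Time-lagged EEG design matrix for the backward model.

    ``data`` has one row per decodable stimulus sample; row t contains, for
    each channel in turn, the EEG samples at times t .. t+n_lags-1
    (channel-major column order). Trailing rows without full lag coverage
    are dropped, so ``data.shape[0] == n_samples - n_lags + 1``.
    """

    data: np.ndarray
    n_channels: int
    n_lags: int
    lag_span_ms: float
    rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("design matrix must be 2-D")
        if self.data.shape[1] != self.n_channels * self.n_lags:
            raise ValueError(
                f"design has {self.data.shape[1]} columns, expected "
                f"{self.n_channels} channels x {self.n_lags} lags"
            )

    @property
    def n_rows(self) -> int:
        return self.data.shape[0]


@dataclass
class LatencyBudget:
    """Decomposition of the closed-loop reaction delay.

    ``window_decision_delay_s`` attributes a sliding-window decision to the
    window's center, i.e. half the correlation-window length.
    """

    preprocess_delay_s: float
    window_decision_delay_s: float

    @property
    def total_s(self) -> float:
        return self.preprocess_delay_s + self.window_decision_delay_s


def _odd_taps_for_delay(delay_s: float, fs: float) -> int:
    """Number of taps of a linear-phase FIR with group delay ``delay_s``."""
    return 2 * int(round(delay_s * fs)) + 1


def _causal_decimate(x: np.ndarray, fs_in: float, fs_out: float) -> np.ndarray:
    """Sample a causally low-passed signal down to ``fs_out``.

    The anti-alias filtering is the caller's responsibility (the envelope
    low-pass / EEG band-pass already confine energy far below the output
    Nyquist). For integer ratios this is a pure stride; otherwise samples
    are taken at the nearest input index of each output instant, which is
    exact to within half an input sample and adds no delay.
    """
    ratio = Fraction(fs_in / fs_out).limit_denominator(10**6)
    n_out = int(np.floor(x.shape[-1] * fs_out / fs_in))
    if ratio.denominator == 1:
        return x[..., :: ratio.numerator][..., :n_out]
    idx = np.floor(np.arange(n_out) * fs_in / fs_out).astype(int)
    return x[..., idx]


def extract_envelope(
    audio: RawAudio,
    decode_rate: float = DEFAULT_DECODE_RATE,
    cutoff_hz: float = ENVELOPE_LOWPASS_HZ,
    filter_delay_s: float = ENVELOPE_FILTER_DELAY_S,
    role: str = "attended",
) -> EnvelopeSignal:
    """Compute a talker's amplitude envelope with a strictly causal chain.

    Full-wave rectification -> causal linear-phase FIR low-pass at
    ``cutoff_hz`` -> decimation to ``decode_rate``. The chain's group delay
    (``filter_delay_s``, exact for a linear-phase FIR) is reported on the
    returned signal so downstream alignment can compensate for it.
    """
    if decode_rate > audio.rate:
        raise ValueError(
            f"decode rate {decode_rate} Hz exceeds audio rate {audio.rate} Hz"
        )
    rectified = np.abs(audio.samples)
    numtaps = _odd_taps_for_delay(filter_delay_s, audio.rate)
    h = signal.firwin(numtaps, cutoff_hz, fs=audio.rate)
    low = signal.lfilter(h, 1.0, rectified)
    env = np.clip(_causal_decimate(low, audio.rate, decode_rate), 0.0, None)
    delay = (numtaps - 1) / 2 / audio.rate
    return EnvelopeSignal(env, decode_rate, role=role, group_delay_s=delay)


def preprocess_eeg(
    eeg: RawEEG,
    decode_rate: float = DEFAULT_DECODE_RATE,
    band_hz: tuple[float, float] = EEG_BAND_HZ,
    filter_delay_s: float = EEG_FILTER_DELAY_S,
    expected_channels: int | None = None,
    delay_budget_s: float | None = None,
) -> RawEEG:
    """Causally band-pass EEG to the envelope-tracking band and decimate.

    The band-pass is a linear-phase FIR whose order is set by
    ``filter_delay_s`` (group delay = (ntaps-1)/2/fs exactly). If
    ``delay_budget_s`` is given and the realized delay exceeds it, a
    ValueError is raised — the budget is the contract a real-time loop
    depends on.
    """
    if expected_channels is not None and eeg.n_channels != expected_channels:
        raise ValueError(
            f"EEG has {eeg.n_channels} channels, expected {expected_channels}"
        )
    if decode_rate > eeg.rate:
        raise ValueError("decode rate exceeds EEG rate")
    numtaps = _odd_taps_for_delay(filter_delay_s, eeg.rate)
    delay = (numtaps - 1) / 2 / eeg.rate
    if delay_budget_s is not None and delay > delay_budget_s + 1e-12:
        raise ValueError(
            f"filter group delay {delay:.3f} s exceeds budget {delay_budget_s:.3f} s"
        )
    h = signal.firwin(numtaps, band_hz, pass_zero=False, fs=eeg.rate)
    filtered = signal.lfilter(h, 1.0, eeg.samples, axis=1)
    out = _causal_decimate(filtered, eeg.rate, decode_rate)
    return RawEEG(
        out,
        decode_rate,
        channel_labels=list(eeg.channel_labels),
        group_delay_s=eeg.group_delay_s + delay,
    )


def n_lags_for_span(lag_span_ms: float, rate: float) -> int:
    return int(round(lag_span_ms / 1000.0 * rate))


def build_lag_matrix(eeg: RawEEG, lag_span_ms: float = 500.0) -> LaggedDesignMatrix:
    """Stack channels x lags into the backward-model design matrix.

    Row t holds EEG at times t .. t+n_lags-1 (the neural response *follows*
    the stimulus sample it decodes). Rows without complete lag coverage at
    the end are dropped: output rows = n_samples - n_lags + 1.
    """
    n_lags = n_lags_for_span(lag_span_ms, eeg.rate)
    if n_lags < 1:
        raise ValueError("lag span shorter than one sample")
    if eeg.n_samples < n_lags:
        raise ValueError(
            f"EEG length {eeg.n_samples} shorter than {n_lags} lags"
        )
    # (channels, rows, lags) -> (rows, channels*lags), channel-major columns
    windows = sliding_window_view(eeg.samples, n_lags, axis=1)
    data = np.ascontiguousarray(windows.transpose(1, 0, 2)).reshape(
        eeg.n_samples - n_lags + 1, eeg.n_channels * n_lags
    )
    return LaggedDesignMatrix(data, eeg.n_channels, n_lags, lag_span_ms, eeg.rate)


def unbuild_lag_matrix(design: LaggedDesignMatrix) -> np.ndarray:
    """Recover the original channels x time EEG array (lossless inverse)."""
    rows = design.data.reshape(design.n_rows, design.n_channels, design.n_lags)
    first = rows[:, :, 0]                      # times 0 .. n_rows-1
    tail = rows[-1, :, 1:]                     # times n_rows .. n_rows+n_lags-2
    return np.concatenate([first.T, tail], axis=1)


def latency_budget(
    window_s: float = 10.0,
    preprocess_delay_s: float = EEG_FILTER_DELAY_S,
) -> LatencyBudget:
    """Total reaction delay of the closed loop.

    A decision from a sliding correlation window of length ``window_s`` is
    attributed to the window center, contributing ``window_s / 2``; causal
    preprocessing contributes its group delay. With the defaults (1.1 s
    preprocessing, 10 s window) the total is 6.1 s.
    """
    if window_s < 0:
        raise ValueError("window length must be non-negative")
    return LatencyBudget(preprocess_delay_s, window_s / 2.0)
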