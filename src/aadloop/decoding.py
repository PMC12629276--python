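"""Linear stimulus-reconstruction (backward TRF) attention decoding.

A ridge-regression decoder W maps time-lagged multichannel EEG N to a talker
envelope:

    W = (N' N + lambda I)^-1 N' env        (training, closed form)
    env_hat = N_test W                     (prediction)

Attention is classified per sliding window by Pearson-correlating the
reconstruction with both candidate talker envelopes: the window is assigned
to whichever envelope correlates more strongly. For the attended decoder the
decision statistic is corrDiff = r(env_hat, env_att) - r(env_hat, env_una);
the unattended decoder (trained on the same data with the attended/unattended
labels inverted) uses its own target minus the other, so in both cases a
positive corrDiff means the decoder identified its target talker and
accuracy is the fraction of windows with corrDiff > 0.

The training set is balanced: equal amounts of data with the listener
attending each of the two talkers, so the decoder learns the attentional
role rather than one talker's acoustics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import linalg

from .preprocessing import EnvelopeSignal, LaggedDesignMatrix

__all__ = [
    "RidgeDecoder",
    "DecodingTrial",
    "TrainingSet",
    "CorrelationWindowSeries",
    "DecodingSummary",
    "CVReport",
    "DEFAULT_LAMBDA",
    "train_decoder",
    "train_decoder_from_trials",
    "predict_envelope",
    "windowed_correlations",
    "decoding_accuracy",
    "leave_one_trial_out_cv",
    "zscore",
]

#: default ridge regularization, applied to the unnormalized N'N
DEFAULT_LAMBDA = 1e2


def zscore(x: np.ndarray) -> np.ndarray:
    """Zero-mean, unit-variance copy; zero-variance input is only centered."""
    x = np.asarray(x, dtype=float)
    sd = x.std()
    return (x - x.mean()) / sd if sd > 0 else x - x.mean()


@dataclass
class RidgeDecoder:
    """Backward-model weight vector with its geometry and regularization."""

    weights: np.ndarray
    lambda_reg: float
    role: str  # attended | unattended
    n_channels: int
    n_lags: int
    lag_span_ms: float
    rate: float
    channel_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float).ravel()
        if self.weights.size != self.n_channels * self.n_lags:
            raise ValueError(
                f"{self.weights.size} weights for "
                f"{self.n_channels} channels x {self.n_lags} lags"
            )
        if self.lambda_reg < 0:
            raise ValueError("lambda must be non-negative")
        if self.role not in ("attended", "unattended"):
            raise ValueError(f"unknown decoder role {self.role!r}")


@dataclass
class DecodingTrial:
    """One trial's design matrix plus both candidate talker envelopes.

    Envelope lengths may exceed the design row count (the last lag-span of
    stimulus samples has no complete EEG coverage); they are truncated to
    the decodable range on use.
    """

    design: LaggedDesignMatrix
    env_att: EnvelopeSignal
    env_una: EnvelopeSignal
    attended_side: str = "left"

    def __post_init__(self) -> None:
        for env in (self.env_att, self.env_una):
            if env.n_samples < self.design.n_rows:
                raise ValueError("envelope shorter than design matrix rows")

    def target(self, role: str) -> np.ndarray:
        """Training target for a decoder of the given role (z-scored).

        ``role="unattended"`` inverts the attention labels: the decoder is
        trained toward the envelope the listener ignored.
        """
        env = self.env_att if role == "attended" else self.env_una
        return zscore(env.samples[: self.design.n_rows])


@dataclass
class TrainingSet:
    """Concatenated design + target over trials, with the balance record."""

    design: np.ndarray
    target: np.ndarray
    n_channels: int
    n_lags: int
    lag_span_ms: float
    rate: float
    balance_record: list[tuple[str, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.design = np.asarray(self.design, dtype=float)
        self.target = np.asarray(self.target, dtype=float).ravel()
        if self.design.shape[0] != self.target.size:
            raise ValueError("design rows and target length differ")
        if len(self.balance_record) >= 2:
            # single-trial sets are tolerated (diagnostic use); any larger
            # set must balance attended-left and attended-right data
            counts = {"left": 0, "right": 0}
            for side, n in self.balance_record:
                counts[side] = counts.get(side, 0) + n
            if counts["left"] != counts["right"]:
                raise ValueError(
                    f"unbalanced training set: {counts} samples per attended side"
                )

    @classmethod
    def from_trials(cls, trials: list[DecodingTrial], role: str = "attended"):
        if not trials:
            raise ValueError("no trials")
        d0 = trials[0].design
        design = np.concatenate([t.design.data for t in trials], axis=0)
        target = np.concatenate([t.target(role) for t in trials])
        record = [(t.attended_side, t.design.n_rows) for t in trials]
        return cls(
            design, target, d0.n_channels, d0.n_lags, d0.lag_span_ms, d0.rate,
            balance_record=record,
        )


def _ridge_solve(gram: np.ndarray, xty: np.ndarray, lam: float) -> np.ndarray:
    n = gram.shape[0]
    a = gram + lam * np.eye(n)
    if lam > 0:
        return linalg.solve(a, xty, assume_a="pos")
    try:
        c, low = linalg.cho_factor(a)
        return linalg.cho_solve((c, low), xty)
    except linalg.LinAlgError as exc:
        rank = np.linalg.matrix_rank(gram)
        raise ValueError(
            f"normal equations singular with lambda=0: design rank {rank} < {n}; "
            "use a positive regularization"
        ) from exc


def train_decoder(
    train: TrainingSet,
    lambda_reg: float = DEFAULT_LAMBDA,
    role: str = "attended",
) -> RidgeDecoder:
    """Closed-form L2-regularized least squares, W = (N'N + lam I)^-1 N'y.

    lambda acts on the raw (unnormalized) Gram matrix N'N, matching the
    closed form literally; reported default 1e2 assumes that convention.
    """
    if lambda_reg < 0:
        raise ValueError("lambda must be non-negative")
    gram = train.design.T @ train.design
    xty = train.design.T @ train.target
    w = _ridge_solve(gram, xty, lambda_reg)
    return RidgeDecoder(
        w, lambda_reg, role, train.n_channels, train.n_lags,
        train.lag_span_ms, train.rate,
    )


def train_decoder_from_trials(
    trials: list[DecodingTrial],
    lambda_reg: float = DEFAULT_LAMBDA,
    role: str = "attended",
) -> RidgeDecoder:
    """Train on concatenated trials; ``role="unattended"`` inverts labels."""
    return train_decoder(TrainingSet.from_trials(trials, role), lambda_reg, role)


def predict_envelope(
    decoder: RidgeDecoder, test: LaggedDesignMatrix
) -> EnvelopeSignal:
    """Reconstruct the decoder's target envelope: env_hat = N_test W."""
    if test.data.shape[1] != decoder.weights.size:
        raise ValueError(
            f"design has {test.data.shape[1]} columns, decoder expects "
            f"{decoder.weights.size}"
        )
    return EnvelopeSignal(test.data @ decoder.weights, test.rate, role="predicted")


@dataclass
class CorrelationWindowSeries:
    """Per-window correlations of a reconstruction with both envelopes.

    ``corr_xa``/``corr_xu`` are Pearson r against the attended / unattended
    envelope. ``corr_diff`` is the decoder's own-target correlation minus
    the other (corr_xa - corr_xu for the attended decoder, corr_xu - corr_xa
    for the unattended decoder), so corr_diff > 0 always means "target
    identified". Zero-variance windows carry NaN.
    """

    window_starts_s: np.ndarray
    window_s: float
    hop_s: float
    corr_xa: np.ndarray
    corr_xu: np.ndarray
    decoder_role: str = "attended"

    @property
    def corr_diff(self) -> np.ndarray:
        d = self.corr_xa - self.corr_xu
        return d if self.decoder_role == "attended" else -d

    @property
    def n_windows(self) -> int:
        return self.window_starts_s.size


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    den = np.sqrt(a @ a) * np.sqrt(b @ b)
    if den == 0:
        return np.nan
    return float(np.clip((a @ b) / den, -1.0, 1.0))


def windowed_correlations(
    pred: EnvelopeSignal,
    env_att: EnvelopeSignal,
    env_una: EnvelopeSignal,
    window_s: float = 10.0,
    hop_s: float = 0.5,
    decoder_role: str = "attended",
) -> CorrelationWindowSeries:
    """Sliding-window Pearson correlations of env_hat with both envelopes.

    Windows are half-open, placed every ``hop_s`` from the start of the
    common length of the three signals; a trailing partial window is not
    emitted. Signal count: floor((T - window) / hop) + 1.
    """
    if not (pred.rate == env_att.rate == env_una.rate):
        raise ValueError("signals have different rates")
    n = min(pred.n_samples, env_att.n_samples, env_una.n_samples)
    win = int(round(window_s * pred.rate))
    hop = int(round(hop_s * pred.rate))
    if win < 2 or hop < 1:
        raise ValueError("window must span >=2 samples and hop >=1")
    if win > n:
        raise ValueError("window longer than signal")
    starts = np.arange(0, n - win + 1, hop)
    xa = np.empty(starts.size)
    xu = np.empty(starts.size)
    p, ea, eu = pred.samples[:n], env_att.samples[:n], env_una.samples[:n]
    for i, s in enumerate(starts):
        seg = slice(s, s + win)
        xa[i] = _pearson(p[seg], ea[seg])
        xu[i] = _pearson(p[seg], eu[seg])
    return CorrelationWindowSeries(
        starts / pred.rate, window_s, hop_s, xa, xu, decoder_role=decoder_role
    )


@dataclass
class DecodingSummary:
    """Window-level decoding accuracy (percent of windows with corrDiff>0)."""

    accuracy_pct: float
    n_windows: int
    mean_corr_diff: float
    per_trial: list[float] | None = None


def decoding_accuracy(series: CorrelationWindowSeries) -> DecodingSummary:
    """Fraction of windows with strictly positive corrDiff, as a percent.

    Ties (corrDiff exactly 0) count as incorrect; NaN (zero-variance)
    windows are excluded from numerator and denominator.
    """
    d = series.corr_diff
    valid = d[np.isfinite(d)]
    if valid.size == 0:
        raise ValueError("no window with defined correlations")
    acc = 100.0 * float(np.count_nonzero(valid > 0)) / valid.size
    return DecodingSummary(acc, valid.size, float(valid.mean()))


@dataclass
class CVReport:
    """Leave-one-trial-out cross-validation accuracies."""

    fold_accuracy_pct: list[float]

    @property
    def mean_accuracy_pct(self) -> float:
        return float(np.mean(self.fold_accuracy_pct))

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracy_pct)


def leave_one_trial_out_cv(
    trials: list[DecodingTrial],
    lambda_reg: float = DEFAULT_LAMBDA,
    role: str = "attended",
    window_s: float = 10.0,
    hop_s: float = 0.5,
) -> CVReport:
    """Hold out each trial, train on the rest, score window accuracy on it.

    The per-trial Gram matrices are computed once and fold solutions reuse
    them (sum minus held-out term), which is exactly equivalent to
    retraining from scratch per fold.
    """
    if len(trials) < 2:
        raise ValueError("cross-validation needs at least 2 trials")
    grams = [t.design.data.T @ t.design.data for t in trials]
    xtys = [t.design.data.T @ t.target(role) for t in trials]
    gram_tot = np.sum(grams, axis=0)
    xty_tot = np.sum(xtys, axis=0)
    d0 = trials[0].design
    accs = []
    for i, trial in enumerate(trials):
        w = _ridge_solve(gram_tot - grams[i], xty_tot - xtys[i], lambda_reg)
        dec = RidgeDecoder(
            w, lambda_reg, role, d0.n_channels, d0.n_lags, d0.lag_span_ms, d0.rate
        )
        pred = predict_envelope(dec, trial.design)
        series = windowed_correlations(
            pred, trial.env_att, trial.env_una, window_s, hop_s, decoder_role=role
        )
        accs.append(decoding_accuracy(series).accuracy_pct)
    return CVReport(accs)
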