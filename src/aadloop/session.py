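"""Two-phase closed-loop session orchestration.

A session is 10 one-minute training trials (attended side alternating, 5
left / 5 right) followed by 50 neurofeedback-phase trials on a single
attended side. The attended-talker decoder is trained between trials 10 and
11 on the balanced 10-minute calibration set and then frozen. In the
neurofeedback phase, every fifth trial is an open-loop control with the
unattended talker held at a fixed -5 dB; all other trials run the closed
loop: every 0.5 s the newest EEG enters the causal pipeline, the 10 s
correlation window is re-evaluated, the running accuracy is smoothed and
mapped to the unattended talker's gain, and that gain shapes the *next*
stimulus chunk — the gain applied at step k depends only on data from steps
before k. The unattended decoder is trained offline at session end on the
same calibration data with inverted attention labels, and both decoders'
window metrics are computed offline for every neurofeedback trial.

Real time is simulated step-by-step on a 0.5 s grid; the contract is causal
ordering, not wall-clock timing.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .decoding import (
    CorrelationWindowSeries,
    CVReport,
    DecodingSummary,
    DecodingTrial,
    RidgeDecoder,
    _pearson,
    decoding_accuracy,
    leave_one_trial_out_cv,
    predict_envelope,
    train_decoder_from_trials,
    windowed_correlations,
)
from .feedback import (
    AttentionSignal,
    AttenuationSummary,
    GainTrace,
    accuracy_to_gain,
    attenuation_summary,
    db_to_linear,
    ema_coefficient,
)
from .listener import ListenerModel, StreamingEEG, generate_speech_envelope, simulate_eeg
from .preprocessing import EnvelopeSignal, RawEEG, build_lag_matrix, n_lags_for_span

__all__ = [
    "SessionConfig",
    "TrialPlan",
    "TrialRecord",
    "SessionResult",
    "build_schedule",
    "run_training_phase",
    "run_feedback_trial",
    "run_session",
    "run_cohort",
]


@dataclass
class SessionConfig:
    """Protocol and decoding parameters of one session."""

    n_training_trials: int = 10
    n_feedback_phase_trials: int = 50
    trial_length_s: float = 60.0
    fixed_gain_period: int = 5       # every fifth neurofeedback trial is open loop
    fixed_gain_db: float = -5.0      # midpoint of the feedback range
    lambda_reg: float = 1e2
    window_s: float = 10.0
    hop_s: float = 0.5               # correlation hop == gain update period
    lag_span_ms: float = 500.0
    n_channels: int = 24
    decode_rate: float = 64.0
    attended_side: str = "left"
    attenuation_floor_db: float = -10.0
    smoother_half_life_s: float = 5.0
    n_comprehension_choices: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_training_trials, self.n_feedback_phase_trials) < 0:
            raise ValueError("trial counts must be non-negative")
        if self.fixed_gain_period < 1:
            raise ValueError("fixed_gain_period must be >= 1")
        if not (self.attenuation_floor_db <= self.fixed_gain_db <= 0):
            raise ValueError("fixed gain outside the attenuation range")
        if self.n_training_trials % 2:
            raise ValueError("training trials must be even for side balance")

    @property
    def n_trials(self) -> int:
        return self.n_training_trials + self.n_feedback_phase_trials

    @property
    def samples_per_trial(self) -> int:
        return int(round(self.trial_length_s * self.decode_rate))

    @property
    def chance_comprehension_pct(self) -> float:
        return 100.0 / self.n_comprehension_choices


@dataclass
class TrialPlan:
    index: int            # 0-based across the whole session
    phase: str            # training | neurofeedback
    mode: str             # training | feedback_on | fixed_gain
    attended_side: str


def build_schedule(config: SessionConfig) -> list[TrialPlan]:
    """The fixed trial plan: mode depends only on trial index.

    Training trials alternate attended side (balanced). Within the
    neurofeedback phase trials are numbered from 1; multiples of
    ``fixed_gain_period`` are open-loop fixed-gain trials, so with the
    default period of 5 exactly 80% of the phase is feedback-on.
    """
    plans = []
    sides = ("left", "right")
    for i in range(config.n_training_trials):
        plans.append(TrialPlan(i, "training", "training", sides[i % 2]))
    for j in range(1, config.n_feedback_phase_trials + 1):
        mode = "fixed_gain" if j % config.fixed_gain_period == 0 else "feedback_on"
        plans.append(
            TrialPlan(
                config.n_training_trials + j - 1,
                "neurofeedback",
                mode,
                config.attended_side,
            )
        )
    return plans


@dataclass
class TrialRecord:
    """Everything recorded about one trial."""

    plan: TrialPlan
    env_att: EnvelopeSignal | None = None
    env_una: EnvelopeSignal | None = None          # as generated (pre-gain)
    env_una_presented: np.ndarray | None = None    # after attenuation
    eeg: RawEEG | None = None
    gain_trace: GainTrace | None = None            # None for training trials
    attention_raw: AttentionSignal | None = None
    attention_smoothed: AttentionSignal | None = None
    series_att: CorrelationWindowSeries | None = None
    series_una: CorrelationWindowSeries | None = None
    summary_att: DecodingSummary | None = None
    summary_una: DecodingSummary | None = None
    attenuation: AttenuationSummary | None = None
    comprehension_correct: bool | None = None

    def drop_signals(self) -> None:
        """Free the raw arrays, keeping metrics (cohort-scale memory)."""
        self.env_att = self.env_una = None
        self.env_una_presented = None
        self.eeg = None
        self.series_att = self.series_una = None
        self.attention_raw = self.attention_smoothed = None


@dataclass
class SessionResult:
    config: SessionConfig
    listener_seed: int
    trials: list[TrialRecord]
    decoder_att: RidgeDecoder
    decoder_una: RidgeDecoder
    cv_report: CVReport

    @property
    def neurofeedback_trials(self) -> list[TrialRecord]:
        return [t for t in self.trials if t.plan.phase == "neurofeedback"]

    @property
    def test_accuracy_pct(self) -> float:
        """Mean attended-decoder accuracy over the 50 evaluation trials."""
        return float(
            np.mean([t.summary_att.accuracy_pct for t in self.neurofeedback_trials])
        )


def _spawn_stateless(ss: np.random.SeedSequence, n: int) -> list:
    """Like SeedSequence.spawn but idempotent: repeated calls on the same
    parent yield the same children (spawn() mutates its counter, which would
    break replaying a trial from its seed)."""
    return [
        np.random.SeedSequence(entropy=ss.entropy, spawn_key=ss.spawn_key + (i,))
        for i in range(n)
    ]


def _trial_seeds(config: SessionConfig, listener: ListenerModel):
    """Independent seed streams per trial: (env_left, env_right, noise, misc)."""
    ss = np.random.SeedSequence([config.seed, listener.seed])
    children = _spawn_stateless(ss, config.n_trials + 1)
    return children[: config.n_trials], children[-1]


def _gen_trial_envs(seedseq, config: SessionConfig, side: str):
    c_left, c_right, c_noise, c_misc = _spawn_stateless(seedseq, 4)
    env_left = generate_speech_envelope(
        config.trial_length_s, config.decode_rate, np.random.default_rng(c_left)
    )
    env_right = generate_speech_envelope(
        config.trial_length_s, config.decode_rate, np.random.default_rng(c_right)
    )
    if side == "left":
        att, una = env_left, env_right
    else:
        att, una = env_right, env_left
    att = replace(att, role="attended")
    una = replace(una, role="unattended")
    return att, una, c_noise, c_misc


def _comprehension(seedseq, p: float) -> bool:
    return bool(np.random.default_rng(seedseq).random() < p)


def run_training_phase(
    listener: ListenerModel,
    config: SessionConfig,
    trial_seedseqs=None,
) -> tuple[list[TrialRecord], RidgeDecoder, CVReport]:
    """Collect the calibration trials and train the attended decoder.

    Both talkers are presented at full level (no feedback). The decoder is
    trained on the concatenated, side-balanced set; leave-one-trial-out CV
    over the same trials estimates calibration accuracy.
    """
    if trial_seedseqs is None:
        trial_seedseqs, _ = _trial_seeds(config, listener)
    plans = [p for p in build_schedule(config) if p.phase == "training"]
    records, dtrials = [], []
    for plan in plans:
        env_att, env_una, c_noise, c_misc = _gen_trial_envs(
            trial_seedseqs[plan.index], config, plan.attended_side
        )
        eeg, presented = simulate_eeg(
            listener, env_att, env_una, seed=c_noise, trial_index=plan.index
        )
        dtrials.append(
            DecodingTrial(
                build_lag_matrix(eeg, config.lag_span_ms),
                env_att, env_una, attended_side=plan.attended_side,
            )
        )
        records.append(
            TrialRecord(
                plan, env_att=env_att, env_una=env_una,
                env_una_presented=presented, eeg=eeg,
                comprehension_correct=_comprehension(c_misc, listener.comprehension_p),
            )
        )
    decoder = train_decoder_from_trials(dtrials, config.lambda_reg, role="attended")
    cv = leave_one_trial_out_cv(
        dtrials, config.lambda_reg, "attended", config.window_s, config.hop_s
    )
    return records, decoder, cv


def run_feedback_trial(
    listener: ListenerModel,
    decoder: RidgeDecoder,
    config: SessionConfig,
    plan: TrialPlan,
    trial_seedseq,
    n_steps: int | None = None,
) -> TrialRecord:
    """Simulate one neurofeedback-phase trial step by step.

    Feedback-on trials close the loop at every ``hop_s`` tick; fixed-gain
    trials hold the configured constant attenuation (open loop) regardless
    of decoding. ``n_steps`` truncates the trial for causality audits: the
    truncated run reproduces the identical prefix of every trace.
    """
    if decoder.rate != config.decode_rate:
        raise ValueError("decoder rate differs from session decode rate")
    env_att, env_una, c_noise, c_misc = _gen_trial_envs(
        trial_seedseq, config, plan.attended_side
    )
    rate = config.decode_rate
    chunk_n = int(round(config.hop_s * rate))
    total_steps = config.samples_per_trial // chunk_n
    steps = total_steps if n_steps is None else min(n_steps, total_steps)
    n_lags = n_lags_for_span(config.lag_span_ms, rate)
    win_n = int(round(config.window_s * rate))
    n_ch = listener.n_channels
    T = steps * chunk_n

    stream = StreamingEEG(listener, env_att, env_una, c_noise, trial_index=plan.index)
    eeg = np.empty((n_ch, T))
    presented = np.empty(T)
    pred = np.empty(max(T - n_lags + 1, 0))
    alphas = np.empty(steps)
    dec_times, raw_accs, smooth_accs = [], [], []
    n_pos = n_dec = 0
    ema = None
    a_coef = ema_coefficient(config.hop_s, config.smoother_half_life_s)
    alpha = config.fixed_gain_db if plan.mode == "fixed_gain" else 0.0
    rows_done = 0

    for k in range(steps):
        alphas[k] = alpha
        lo = k * chunk_n
        chunk, pres = stream.next_chunk(chunk_n, alpha)
        eeg[:, lo : lo + chunk_n] = chunk
        presented[lo : lo + chunk_n] = pres
        n_avail = lo + chunk_n
        nrows = n_avail - n_lags + 1
        if nrows > rows_done:
            seg = eeg[:, rows_done:n_avail]
            w = sliding_window_view(seg, n_lags, axis=1)
            rows = w.transpose(1, 0, 2).reshape(-1, n_ch * n_lags)
            pred[rows_done:nrows] = rows @ decoder.weights
            rows_done = nrows
        if plan.mode == "feedback_on" and nrows >= win_n:
            w0 = nrows - win_n
            ra = _pearson(pred[w0:nrows], env_att.samples[w0:nrows])
            ru = _pearson(pred[w0:nrows], presented[w0:nrows])
            d = (ra - ru) if np.isfinite(ra) and np.isfinite(ru) else np.nan
            if np.isfinite(d):
                n_dec += 1
                n_pos += d > 0
            if n_dec:
                raw = 100.0 * n_pos / n_dec
                ema = raw if ema is None else ema + a_coef * (raw - ema)
                alpha = accuracy_to_gain(ema, config.attenuation_floor_db)
            dec_times.append((k + 1) * config.hop_s)
            raw_accs.append(100.0 * n_pos / n_dec if n_dec else np.nan)
            smooth_accs.append(ema if ema is not None else np.nan)

    trace = GainTrace(
        np.arange(steps) * config.hop_s, alphas,
        update_period_s=config.hop_s, floor_db=config.attenuation_floor_db,
    )
    att_raw = att_smooth = None
    if plan.mode == "feedback_on":
        att_raw = AttentionSignal(np.asarray(dec_times), np.asarray(raw_accs))
        att_smooth = AttentionSignal(
            np.asarray(dec_times), np.asarray(smooth_accs), smoothed=True
        )
    return TrialRecord(
        plan,
        env_att=env_att,
        env_una=replace(env_una, samples=env_una.samples[:T]),
        env_una_presented=presented,
        eeg=RawEEG(eeg, rate),
        gain_trace=trace,
        attention_raw=att_raw,
        attention_smoothed=att_smooth,
        attenuation=attenuation_summary(trace),
        comprehension_correct=_comprehension(c_misc, listener.comprehension_p),
    )


def _offline_metrics(
    record: TrialRecord,
    decoder_att: RidgeDecoder,
    decoder_una: RidgeDecoder,
    config: SessionConfig,
) -> None:
    """Both decoders' window metrics for one recorded trial (in place)."""
    design = build_lag_matrix(record.eeg, config.lag_span_ms)
    env_una_pres = EnvelopeSignal(
        record.env_una_presented, config.decode_rate, role="unattended"
    )
    for decoder, attr_s, attr_a in (
        (decoder_att, "series_att", "summary_att"),
        (decoder_una, "series_una", "summary_una"),
    ):
        pred = predict_envelope(decoder, design)
        series = windowed_correlations(
            pred, record.env_att, env_una_pres,
            config.window_s, config.hop_s, decoder_role=decoder.role,
        )
        setattr(record, attr_s, series)
        setattr(record, attr_a, decoding_accuracy(series))


def run_session(
    listener: ListenerModel,
    config: SessionConfig | None = None,
    keep_signals: bool = True,
) -> SessionResult:
    """Run the full two-phase protocol for one listener.

    Deterministic given (config.seed, listener.seed). With
    ``keep_signals=False`` raw waveforms are dropped after metrics are
    computed, keeping cohort runs within desk-scale memory.
    """
    config = config or SessionConfig()
    if listener.n_channels != config.n_channels:
        raise ValueError(
            f"listener has {listener.n_channels} channels, config expects "
            f"{config.n_channels}"
        )
    trial_seedseqs, _ = _trial_seeds(config, listener)
    records, decoder_att, cv = run_training_phase(listener, config, trial_seedseqs)
    plans = build_schedule(config)
    for plan in plans[config.n_training_trials :]:
        rec = run_feedback_trial(
            listener, decoder_att, config, plan, trial_seedseqs[plan.index]
        )
        records.append(rec)
    # unattended decoder: same calibration data, inverted labels, offline
    train_trials = [
        DecodingTrial(
            build_lag_matrix(r.eeg, config.lag_span_ms),
            r.env_att, r.env_una, attended_side=r.plan.attended_side,
        )
        for r in records[: config.n_training_trials]
    ]
    decoder_una = train_decoder_from_trials(
        train_trials, config.lambda_reg, role="unattended"
    )
    for rec in records[config.n_training_trials :]:
        _offline_metrics(rec, decoder_att, decoder_una, config)
        if not keep_signals:
            rec.drop_signals()
    if not keep_signals:
        for rec in records[: config.n_training_trials]:
            rec.drop_signals()
    return SessionResult(
        config, listener.seed, records, decoder_att, decoder_una, cv
    )


def run_cohort(
    listeners: list[ListenerModel],
    config: SessionConfig | None = None,
    balance_sides: bool = True,
    keep_signals: bool = False,
    progress: bool = False,
) -> list[SessionResult]:
    """Run one session per listener.

    ``balance_sides`` alternates the neurofeedback-phase attended side
    across listeners, mirroring a counterbalanced cohort design.
    """
    config = config or SessionConfig()
    results = []
    for i, listener in enumerate(listeners):
        cfg = config
        if balance_sides:
            cfg = replace(config, attended_side="left" if i % 2 == 0 else "right")
        results.append(run_session(listener, cfg, keep_signals=keep_signals))
        if progress:
            print(f"listener {i + 1}/{len(listeners)} done", flush=True)
    return results
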