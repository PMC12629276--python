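"""Shared test utilities: compact synthetic decoding trials."""

from __future__ import annotations

import numpy as np

from aadloop.decoding import DecodingTrial
from aadloop.listener import ListenerModel, generate_speech_envelope, simulate_eeg
from aadloop.preprocessing import build_lag_matrix


def make_trials(
    listener: ListenerModel,
    n_trials: int = 10,
    duration_s: float = 60.0,
    master: int = 777,
    una_gain_lin: float = 1.0,
) -> list[DecodingTrial]:
    """Open-loop trials with fresh envelopes and EEG from the listener."""
    ss = np.random.SeedSequence([listener.seed, master])
    trials = []
    for i, cs in enumerate(ss.spawn(n_trials)):
        a, b, c = cs.spawn(3)
        env_att = generate_speech_envelope(
            duration_s, listener.rate, seed=np.random.default_rng(a)
        )
        env_una = generate_speech_envelope(
            duration_s, listener.rate, seed=np.random.default_rng(b), role="unattended"
        )
        eeg, _ = simulate_eeg(listener, env_att, env_una, seed=c,
                              una_gain_lin=una_gain_lin)
        trials.append(
            DecodingTrial(
                build_lag_matrix(eeg), env_att, env_una,
                attended_side="left" if i % 2 == 0 else "right",
            )
        )
    return trials
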