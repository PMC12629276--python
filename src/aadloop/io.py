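"""Serialization: decoders (JSON), sessions (HDF5), metrics (CSV), WAV audio.

The decoder file is self-describing: weights plus the geometry (channels,
lags, span, rate), regularization and role needed to apply it. The session
container stores the configuration, decoders, cross-validation report and
per-trial metrics, and — when the session was run with ``keep_signals`` —
the raw traces (EEG, envelopes, gain) as well.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import h5py
import numpy as np
from scipy.io import wavfile

from .decoding import CVReport, RidgeDecoder
from .feedback import GainTrace
from .preprocessing import RawAudio
from .session import SessionConfig, SessionResult, TrialPlan, TrialRecord

__all__ = [
    "save_decoder",
    "load_decoder",
    "save_session",
    "load_session",
    "read_wav",
    "write_wav",
]


def save_decoder(decoder: RidgeDecoder, path) -> None:
    payload = {
        "format": "aadloop-decoder-v1",
        "role": decoder.role,
        "lambda_reg": decoder.lambda_reg,
        "n_channels": decoder.n_channels,
        "n_lags": decoder.n_lags,
        "lag_span_ms": decoder.lag_span_ms,
        "rate": decoder.rate,
        "channel_labels": decoder.channel_labels,
        "weights": decoder.weights.tolist(),
    }
    Path(path).write_text(json.dumps(payload))


def load_decoder(path) -> RidgeDecoder:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "aadloop-decoder-v1":
        raise ValueError(f"{path} is not an aadloop decoder file")
    return RidgeDecoder(
        np.asarray(payload["weights"]),
        payload["lambda_reg"],
        payload["role"],
        payload["n_channels"],
        payload["n_lags"],
        payload["lag_span_ms"],
        payload["rate"],
        channel_labels=payload.get("channel_labels", []),
    )


def _write_decoder_group(g: h5py.Group, decoder: RidgeDecoder) -> None:
    g.create_dataset("weights", data=decoder.weights)
    g.attrs.update({
        "role": decoder.role, "lambda_reg": decoder.lambda_reg,
        "n_channels": decoder.n_channels, "n_lags": decoder.n_lags,
        "lag_span_ms": decoder.lag_span_ms, "rate": decoder.rate,
    })


def _read_decoder_group(g: h5py.Group) -> RidgeDecoder:
    a = g.attrs
    return RidgeDecoder(
        g["weights"][()], float(a["lambda_reg"]), str(a["role"]),
        int(a["n_channels"]), int(a["n_lags"]),
        float(a["lag_span_ms"]), float(a["rate"]),
    )


def save_session(result: SessionResult, path) -> None:
    """Write a session result to an HDF5 container."""
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "aadloop-session-v1"
        f.attrs["config_json"] = json.dumps(dataclasses.asdict(result.config))
        f.attrs["listener_seed"] = result.listener_seed
        f.create_dataset("cv_fold_accuracy_pct", data=result.cv_report.fold_accuracy_pct)
        _write_decoder_group(f.create_group("decoder_att"), result.decoder_att)
        _write_decoder_group(f.create_group("decoder_una"), result.decoder_una)
        for rec in result.trials:
            g = f.create_group(f"trials/{rec.plan.index:03d}")
            g.attrs.update({
                "phase": rec.plan.phase, "mode": rec.plan.mode,
                "attended_side": rec.plan.attended_side,
            })
            if rec.comprehension_correct is not None:
                g.attrs["comprehension_correct"] = bool(rec.comprehension_correct)
            for name, summary in (("att", rec.summary_att), ("una", rec.summary_una)):
                if summary is not None:
                    g.attrs[f"acc_{name}_pct"] = summary.accuracy_pct
                    g.attrs[f"mean_corr_diff_{name}"] = summary.mean_corr_diff
                    g.attrs[f"n_windows_{name}"] = summary.n_windows
            if rec.attenuation is not None:
                g.attrs["alpha_deg"] = rec.attenuation.alpha_deg
                g.attrs["alpha_max"] = rec.attenuation.alpha_max
            if rec.gain_trace is not None:
                g.create_dataset("gain_alpha_db", data=rec.gain_trace.alpha_db)
                g.attrs["gain_update_period_s"] = rec.gain_trace.update_period_s
                g.attrs["gain_floor_db"] = rec.gain_trace.floor_db
            if rec.eeg is not None:
                g.create_dataset("eeg", data=rec.eeg.samples)
                g.create_dataset("env_att", data=rec.env_att.samples)
                g.create_dataset("env_una", data=rec.env_una.samples)
                g.create_dataset("env_una_presented", data=rec.env_una_presented)


def load_session(path) -> SessionResult:
    """Read a session container back (metrics always; signals if stored)."""
    from .decoding import DecodingSummary
    from .feedback import AttenuationSummary
    from .preprocessing import EnvelopeSignal, RawEEG

    with h5py.File(path, "r") as f:
        if f.attrs.get("format") != "aadloop-session-v1":
            raise ValueError(f"{path} is not an aadloop session file")
        config = SessionConfig(**json.loads(f.attrs["config_json"]))
        cv = CVReport(list(np.asarray(f["cv_fold_accuracy_pct"])))
        dec_att = _read_decoder_group(f["decoder_att"])
        dec_una = _read_decoder_group(f["decoder_una"])
        trials = []
        for key in sorted(f["trials"]):
            g = f[f"trials/{key}"]
            a = g.attrs
            plan = TrialPlan(
                int(key), str(a["phase"]), str(a["mode"]), str(a["attended_side"])
            )
            rec = TrialRecord(plan)
            if "comprehension_correct" in a:
                rec.comprehension_correct = bool(a["comprehension_correct"])
            for name in ("att", "una"):
                if f"acc_{name}_pct" in a:
                    setattr(rec, f"summary_{name}", DecodingSummary(
                        float(a[f"acc_{name}_pct"]),
                        int(a[f"n_windows_{name}"]),
                        float(a[f"mean_corr_diff_{name}"]),
                    ))
            if "alpha_deg" in a:
                rec.attenuation = AttenuationSummary(
                    float(a["alpha_max"]), float(a["alpha_deg"])
                )
            if "gain_alpha_db" in g:
                alpha = g["gain_alpha_db"][()]
                period = float(a["gain_update_period_s"])
                rec.gain_trace = GainTrace(
                    np.arange(alpha.size) * period, alpha,
                    update_period_s=period, floor_db=float(a["gain_floor_db"]),
                )
            if "eeg" in g:
                rec.eeg = RawEEG(g["eeg"][()], config.decode_rate)
                rec.env_att = EnvelopeSignal(
                    g["env_att"][()], config.decode_rate, role="attended"
                )
                rec.env_una = EnvelopeSignal(
                    g["env_una"][()], config.decode_rate, role="unattended"
                )
                rec.env_una_presented = g["env_una_presented"][()]
            trials.append(rec)
        return SessionResult(
            config, int(f.attrs["listener_seed"]), trials, dec_att, dec_una, cv
        )


def read_wav(path, talker_id: str = "left") -> RawAudio:
    """Read a PCM or float WAV into a [-1, 1] waveform (first channel)."""
    rate, data = wavfile.read(path)
    data = np.asarray(data)
    if data.ndim > 1:
        data = data[:, 0]
    if np.issubdtype(data.dtype, np.integer):
        data = data.astype(float) / float(np.iinfo(data.dtype).max)
    return RawAudio(data.astype(float), float(rate), talker_id=talker_id)


def write_wav(audio: RawAudio, path) -> None:
    wavfile.write(path, int(round(audio.rate)), audio.samples.astype(np.float32))
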