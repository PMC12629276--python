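# aadloop

Closed-loop auditory attention decoding (AAD) neurofeedback, as a tested
Python library and CLI.

In a two-talker "cocktail party", cortical activity tracks the slow
amplitude envelopes of both speech streams, with the attended talker's
envelope represented more robustly. A **backward (stimulus-reconstruction)
model** exploits this: a ridge-regression decoder maps time-lagged
multichannel EEG `N` to the attended envelope,

```
W_att   = (NᵀN + λI)⁻¹ Nᵀ env_att        (training, λ = 1e2)
env̂_att = N_test · W_att                  (prediction)
```

and attention is classified per 10 s sliding window (0.5 s hop) by Pearson
correlation: `corrDiff = r(env̂, env_att) − r(env̂, env_una)`, with window
accuracy `acc = 100 × mean(corrDiff > 0)`. An unattended decoder is trained
on the same data with inverted attention labels.

The package implements the full closed-loop paradigm around that core, for
researchers prototyping AAD neurofeedback systems and brain-controlled
hearing-aid control signals:

- **Causal preprocessing** (`aadloop.preprocessing`) — linear-phase FIR
  chains for audio envelopes and 1–8 Hz EEG with exactly accounted group
  delay (1.1 s preprocessing + 5 s window-decision delay = 6.1 s loop
  latency), and the lagged design matrix (24 channels × 32 lags at 64 Hz).
- **Decoding** (`aadloop.decoding`) — closed-form ridge training,
  prediction, windowed correlations, accuracy, leave-one-trial-out CV.
- **Neurofeedback** (`aadloop.feedback`) — cumulative running accuracy,
  causal EMA smoothing, the inverse linear map from accuracy [0, 100] to
  unattended-talker attenuation [0, −10] dB, gain application with
  click-free ramps, and the per-trial attenuation integral α_deg.
- **Synthetic listener** (`aadloop.listener`) — a seeded forward model
  (per-channel damped-oscillation kernels, pink-noise background,
  attention-dependent gains) standing in for human participants.
- **Session engine** (`aadloop.session`) — the two-phase protocol: 10
  balanced one-minute training trials, decoder training "between trials 10
  and 11", then 50 trials with the closed loop simulated at 0.5 s ticks and
  every fifth trial an open-loop control at a fixed −5 dB.
- **Analysis** (`aadloop.analysis`) — session-half and feedback/no-feedback
  contrasts (repeated-measures ANOVA with participant as random effect),
  pooled-SD Cohen's d with t-based CIs, calibration-vs-test Pearson
  correlation with Fisher-z CI, and the H1/H2/H3 verdict (enhanced attended
  tracking / suppressed unattended tracking / both).

## Worked example

Simulate one listener through the full 60-trial protocol and export the
per-trial metrics:

```bash
$ aadloop run-session --listener-seed 3 --out session.h5
session saved to session.h5: CV 59.8%, test 63.1%

$ aadloop evaluate --session session.h5 --out metrics.csv
$ aadloop latency
preprocessing 1.10 s + window decision 5.00 s = 6.10 s
```

`CV 59.8%` is the leave-one-trial-out cross-validation accuracy of the
attended decoder over the 10 calibration trials — the fraction of 10 s
windows in which the reconstruction correlated more with the attended than
the unattended envelope (chance 50%). `test 63.1%` is the same decoder's
mean window accuracy over the 50 subsequent neurofeedback-phase trials.
`metrics.csv` holds one row per trial: both decoders' accuracies, mean
corrDiff values, the attenuation integral `alpha_deg` (0.5 on every
fixed-gain trial, by construction), and a comprehension flag.

The same from Python:

```python
from aadloop import ListenerModel, SessionConfig, run_session

listener = ListenerModel.create(seed=3)
result = run_session(listener, SessionConfig())
print(result.cv_report.mean_accuracy_pct)   # 59.8
print(result.test_accuracy_pct)             # 63.1
```

Cohort-level experiments go through `simulate-cohort`/`analyze`, which
inject a configurable second-half suppression of the unattended encoding
gain and test which hypothesis the decoder metrics support.

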