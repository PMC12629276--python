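# Methods

## Model and procedure

`aadloop` implements correlation-based linear auditory attention decoding
(AAD) inside a closed neurofeedback loop. The decoding core is a backward
temporal-response-function model: a weight vector `W` over channels × time
lags maps EEG to a reconstruction of a talker's amplitude envelope,

    W = (NᵀN + λI)⁻¹ Nᵀ env,      env̂ = N_test W,

where row *t* of the lagged design matrix `N` stacks all channels at lags
0…500 ms *after* stimulus time *t* (the neural response follows the
stimulus; trailing rows without complete lag coverage are dropped rather
than zero-padded, avoiding edge bias in short windows). λ acts on the raw,
unnormalized Gram matrix, exactly as the closed form is written; the default
λ = 1e2 assumes that convention. Envelope targets are z-scored per trial —
window-level Pearson statistics are scale-invariant, so this affects only
numerical conditioning.

Attention is classified per sliding window (default 10 s, 0.5 s hop) by
comparing the reconstruction's Pearson correlation with the two candidate
envelopes. The decision statistic is the decoder's own-target correlation
minus the other: `corrDiff_att = r(env̂, env_att) − r(env̂, env_una)` for the
attended decoder and `corrDiff_una = r(env̂, env_una) − r(env̂, env_att)` for
the unattended decoder (trained on the same calibration data with inverted
attention labels). Under this one sign convention, accuracy is uniformly the
percentage of windows with strictly positive corrDiff; exact ties count as
incorrect and zero-variance windows are excluded from both numerator and
denominator rather than imputed (Pearson r is undefined there).

The session protocol is two-phase: 10 one-minute calibration trials with
the attended side alternating (5 left / 5 right, so the decoder learns the
attentional role, not one talker's acoustics), decoder training between
trials 10 and 11, then 50 one-minute trials on a single attended side. In
the neurofeedback phase, every fifth trial (1-based within the phase) is an
open-loop control with the unattended talker fixed at −5 dB — the midpoint
of the feedback range — leaving 80% of trials with active feedback. The
closed loop runs on a 0.5 s grid: new EEG extends the reconstruction, the
trailing 10 s window is re-correlated, the cumulative within-trial accuracy
is smoothed by a causal exponential moving average (half-life 5 s), and the
result maps linearly from accuracy [0, 100] onto unattended-talker gain
[0, −10] dB applied to the *next* stimulus chunk. Before the first window
completes (10.5 s into a trial), the gain holds at 0 dB. The attended
stream's level is never modified. Per trial, delivered attenuation is
summarized as `alpha_deg = Σα(t) / Σ(−10 dB) ∈ [0, 1]` (discrete sums for
the integrals).

Real time is simulated step-by-step rather than wall-clock threaded: the
contract, enforced by replay tests, is causal ordering — the gain at step
*k* is a function only of data from steps before *k*, and truncating a
trial reproduces the identical prefix of every trace.

## Preprocessing and latency

All filters are strictly causal linear-phase FIRs, so each stage's group
delay is the constant (ntaps−1)/2/fs and the loop's reaction time is
auditable. Defaults: audio envelope = full-wave rectification → 8 Hz
low-pass (0.25 s delay) → decimation to 64 Hz; EEG = 1–8 Hz band-pass
(1.1 s delay, the budget the real-time loop assumes) → decimation to 64 Hz.
Cortical envelope tracking concentrates below ~8 Hz, which fixes the band;
the 64 Hz decode rate gives 32 lags per channel (768 weights with 24
channels). A sliding-window decision is attributed to the window's center,
so the 10 s window contributes 5 s and the total loop delay is ≈6.1 s.
Windows are half-open `[start, end)` and never cross trial boundaries; all
indexing is 0-based.

## The synthetic listener

The test bed replaces human participants with a seeded linear forward
model: each channel is the sum of the two envelopes convolved with
per-channel causal impulse responses (randomized damped oscillations, unit
norm, ~100–200 ms latency, 400 ms span — inside the decoder's lag span)
weighted by encoding gains `g_att`, `g_una`, plus background noise. The
attended and unattended streams use distinct kernel banks, reflecting
distinct spatiotemporal response patterns; this is what makes an unattended
decoder meaningful. A `shared_kernels` mode gives both streams identical
kernels so attention is expressed purely as gain — in that configuration,
and only there, equal gains make decoding sit exactly at chance, and the
package's chance-calibration properties are tested in it.

Two choices depart from the simplest construction, both calibrated once and
frozen:

- **Noise is pink (1/f), scaled ~115× the unit-gain attended component's
  RMS.** Independent white noise is almost irrelevant to a 768-weight
  decoder averaging over 10 s windows — accuracy stays at 100% even at
  extreme scales — whereas a 1/f background occupying the same 1–8 Hz band
  as the signal is both what scalp EEG looks like and what produces the
  realistic mid-60s% cross-validation regime with 10 minutes of training
  data. The default 22-listener cohort lands at mean CV ≈ 65–68% (SD ≈ 6–9
  across listeners, driven by per-listener gain and noise draws).
- **Presented level couples into encoding compressively**, as
  gain^0.25: a −10 dB attenuation scales the encoded distractor drive by
  only ~0.75. Cortical envelope tracking is approximately level-invariant
  over moderate ranges; proportional coupling would make the −5 dB control
  trials themselves halve the unattended encoding, an acoustic artifact the
  open-loop trials of the paradigm are designed to exclude.

Session-level effects are injected through per-trial gain schedules: a
cohort's `suppression_profile` lowers `g_una` by a given fraction in
second-half neurofeedback-phase trials, feedback-on trials only (fixed-gain
trials exempt unless requested), emulating feedback-driven suppression of
distractor tracking. Everything — kernels, envelopes, noise, cohort draws,
comprehension flags — derives from integer seeds, and sessions are
bit-reproducible.

What the generator does *not* emulate: volume conduction and spatially
correlated noise, alpha rhythms and artifacts, kernel nonstationarity,
behavioral lapses of attention within trials. Passing tests therefore show
that the pipeline is correct and well-calibrated for linearly encoded,
stationary signals; they do not certify performance on real EEG.

## Statistics

Contrasts of per-trial metrics (first vs second session half; feedback vs
fixed-gain mode) use a two-factor ANOVA with the contrast as fixed factor
and participant as a random effect. With a balanced design this is the
classical repeated-measures F-test on listener × level cell means
(statsmodels `AnovaRM`), whose error term is the factor × participant
interaction — equivalently a paired t-test on cell means, exact under
normality (verified: type-I rate 0.0499 over 10,000 null replicates). With
a single listener the fallback is a Welch t-test, labelled as such in the
report. Effect sizes are pooled-SD Cohen's d on the per-listener cell means
(one independent unit per listener per level). Two 95% intervals are
reported because the raw and standardized scales answer different
questions: the t-interval of the paired per-listener differences on the
metric scale, and the same interval divided by the pooled SD on the d
scale. The generic two-group `cohens_d_with_ci` uses the central-t
approximation `se = sqrt((na+nb)/(na·nb) + d²/(2(na+nb−2)))` — noncentral-t
machinery changes nothing at the reporting precision used here.
Calibration-vs-test association is a Pearson correlation with a Fisher-z
interval (requires n ≥ 4). The significance threshold is 0.05 two-sided
throughout; no multiple-testing correction is applied, and all raw p-values
are printed so users can correct.

The hypothesis verdict scores three candidate neural bases of improved
attention from the feedback-trial session-half contrasts: H1 = significant
*increase* in the attended metric, H2 = significant *decrease* in the
unattended metric, H3 = both (so H3 ⇒ H1 ∧ H2).

## Numerical choices and degenerate inputs

- Ridge solves use Cholesky factorization; λ = 0 on a rank-deficient system
  raises an error naming the deficient rank instead of silently
  pseudo-inverting.
- Leave-one-trial-out CV caches per-trial Gram matrices and solves each
  fold from the totals minus the held-out terms — algebraically identical
  to retraining, and tested as such.
- The real-time accuracy is cumulative within trial (matching the smooth
  feedback traces the paradigm describes) rather than a recent-window
  fraction; this is an assumption, configurable at the smoothing stage.
- The EMA smoother seeds its state with the first defined raw value;
  undefined (zero-variance) windows hold the previous state.
- Gain application crossfades linearly over a 50 ms ramp by default to
  avoid audible clicks; the paradigm itself is silent on ramping.
- `SeedSequence` children are derived with explicit spawn keys, so
  replaying any trial from its seed is idempotent.

## Problem sizes

The shipped tests exercise the protocol at its native scale where the
claim depends on it — the suppression-recovery check runs the full
22-listener × 60-trial closed-loop cohort (≈2 minutes) and noiseless /
chance calibrations use 10 one-minute trials — while orchestration unit
tests use scaled-down sessions (4 training + 10 feedback trials of 30 s).
The type-I calibration uses 400 synthetic null cohorts drawn at the
metrics-table level; simulating EEG for hundreds of full cohorts would add
nothing, since the contrast operates on the metrics table.

## Known limitations

- The synthetic listener's linearity makes decoding *easier* and more
  stationary than real EEG; absolute accuracies should not be read as
  predictions for human cohorts.
- In a linear forward model, suppressing the unattended stream necessarily
  also reduces the competitor-correlation variance seen by the attended
  decoder, producing a small (drifting, typically non-significant) positive
  attended-accuracy effect that real cohorts may not show.
- The mixed-model ANOVA is implemented for the balanced, two-level designs
  of this protocol; unbalanced multi-factor designs are out of scope.
- WAV I/O covers PCM and float mono/stereo-first-channel files; no other
  audio containers.
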