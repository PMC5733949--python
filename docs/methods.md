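# Methods

This note documents the models, conventions and design choices behind
`attnbci`, in the spirit of a toolbox methods appendix: what each stage
computes, which knobs matter, what the synthetic data do and do not
emulate, and where the genuinely open choices were made.

## Data model and timing conventions

A `ContinuousRecording` is a `channels × samples` float64 array in µV with
a sampling rate and a start time; per-sample timestamps are derived as
`start_time + i/fs` and are authoritative everywhere.  Event markers are
`(label, time)` pairs.  The marker-to-sample rule is causal and fixed:
**the onset sample of a marker is the first sample whose timestamp is ≥
the marker time** (with a 1 ns guard so grid-aligned times do not round
up).  Epoch windows `(t_min, t_max)` are half-open on the right and
contain exactly `round((t_max − t_min)·fs)` samples; the default
(−0.5, 3.5) s window at 250 Hz is 1000 samples.

The stream buffer applies the same rule to live data: a trial is emitted
exactly once, when and only when every sample of `[marker+t_min,
marker+t_max)` has been buffered, regardless of whether the marker arrives
before or after its window's data.  Buffer capacity defaults to 10 s and
must exceed the window span; a marker whose window precedes the retained
history raises an explicit "window unrecoverable" error rather than
silently emitting a short trial.  Because trials are selected purely by
timestamp, replaying a recording in chunks of any size reproduces the
batch epochs sample-exactly — this is asserted, not assumed, by the tests.

A shared clock between data and markers is assumed throughout; clock
drift between devices is out of scope.

## Preprocessing

Pipeline order is fixed: **extract → baseline → filter → rereference**.
Baseline correction subtracts the whole-epoch mean per trial and channel
(idempotent, linear).  Rereferencing forms a single bipolar channel
`channel − reference` (default Cz−TP9); since both operations are linear
they commute, and the order is convention, not constraint.

The bandpass is a Butterworth design, default band 1–11 Hz at 250 Hz.
"4th order" is interpreted as the **analog prototype order**, so the
bandpass transfer function has order 8 — the common toolbox convention;
`interpret="overall"` requests the alternative reading.  Filtering is a
single causal forward pass (`scipy.signal.lfilter`, a Direct Form II
Transposed realization) with zero initial state per trial, because an
online system cannot run a zero-phase second pass.  With the passband
edge at 1 Hz the poles sit close to the unit circle; float64
transfer-function filtering is then accurate to roughly 1e−7 relative,
which is the tolerance the linearity test uses.  The design is verified
against a closed-form oracle: the analog Butterworth bandpass magnitude
evaluated at the bilinear-prewarped frequency, computed independently of
the design routine.

Joint-probability epoch rejection is a simplified, self-contained variant
of the classic artifact screen: per channel, a 32-bin histogram over all
trials' pooled samples estimates the amplitude density (with a
one-count-per-bin floor so empty bins stay finite); a trial's score is
the mean negative log-density of its samples, averaged over channels;
trials scoring above `mean + 2·SD` of the scores are rejected, and the
criterion is applied once more to the survivors (two passes total).
Parity with any external toolbox routine is explicitly a non-goal — the
behaviour is fully specified here and tested on constructed artifacts.

## Classification

Templates are plain per-class trial averages on the derived channel.  The
per-lag score is the **Pearson correlation of the overlapping segment**
(no zero padding — padding biases the score toward zero asymmetrically at
larger lags); a raw mean-cross-product mode exists behind
`normalized=False` since third-party cross-correlation conventions vary.
The lag range is symmetric, ±32 ms (±8 samples at 250 Hz).  Tie-breaks
are fixed and documented: on the per-lag score, smaller |lag| wins, then
the negative lag; on the class decision, an exact tie labels "left".  A
constant (zero-variance) overlap scores 0.  Normalization makes the
decision invariant to positive scaling and offsets of the trial, which
the property tests assert.

Leave-one-out cross-validation rebuilds templates from all trials but one
and classifies the held-out trial, per candidate (channel, reference)
pair; accuracy is the exact fraction correct, and the best channel is the
argmax with ties broken by candidate order.

The empirical chance level is exact binomial: the threshold is
`100·k*/n` % where `k*` is the smallest count with
`BinomCDF(k*; n, 1/c) ≥ 1−α` — no normal approximation.  For (n=120,
c=2, α=.05) this yields 57.5 %, for n=40 it yields 62.5 %; the threshold
is non-increasing in n and approaches 100/c from above.

## Timing audit

"Amplitude" is rectified (absolute) amplitude, so square waves of either
polarity are handled; the half-maximum threshold comes from the
**trial-averaged** rectified response and is applied per single trial.
Trials that never cross are reported missing and excluded from summaries.
Both mean and median lag are reported (they answer different questions
when the lag distribution is skewed); jitter uses the n−1 denominator;
outliers use the 1.5·IQR rule.  The threshold is relative, so the audit
is gain-invariant, and every latency is an integer multiple of 1/fs —
the audit's resolution is one sample period (4 ms at 250 Hz) by
construction.  The default search window is 0–200 ms after the marker;
passing a negative lower edge (e.g. −40 ms) finds sound onsets that
precede their marker, which real stimulus stacks occasionally produce.

## ERP statistics

The N100 is the single most negative sample of the trial average at the
vertex within the 100–250 ms search window — no trough fitting; the
window is wider than a classic N100 because slowly ramping complex sounds
push the peak late (~150–200 ms), and it is configurable.  The FRN is the
mean amplitude 250–300 ms (half-open window) over the Fz/FC1/FC2/Cz ROI,
reported per condition and as the incorrect − correct difference.  Window
masks carry a 1 ns epsilon so grid-aligned edges are unambiguous under
float summation.  Group statistics take **one value per subject** and use
`t = mean/(sd/√n)` with n−1 degrees of freedom (two-sided p), verified
against an independent implementation; a zero-variance sample is refused
as degenerate.

## Synthetic data: what it emulates, what it does not

The generators define the study conditions; their defaults are not tuning
knobs.

* **Attention sessions** (`gen_recording`): 24 channels (standard 10/20
  montage), 250 Hz, one onset marker per trial, inter-trial interval
  6.5 s (the trial structure of a cue + 3 s playback + break paradigm).
  Class templates default to two Hann-burst envelopes spanning the 3 s
  playback — 4 bursts vs 5 bursts, echoing competing melody streams with
  different tone counts — at 5 µV peak, scaled by a fixed frontocentral
  topography (maximal at Cz, near-zero at the mastoids so the bipolar
  derivation keeps the signal).  Background noise is 1/f ("pink") noise
  made by spectral shaping of white Gaussian noise, renormalised per
  channel; default 10 µV SD.  The spectral content and envelope shapes
  are explicit stand-ins for plausible EEG, not claims about any real
  dataset.
* **ERP cohorts** (`gen_erp_cohort`): per subject, sound-onset trials
  carry a P1–N100–P200 complex built from compactly supported Hann bumps
  (P1 +1.2 µV at 60 ms, N100 at −2.6 µV / 177 ms by default, P200
  +1.5 µV at 280 ms); the N100 latency is quantized to the sample grid
  (177 ms → 176 ms at 250 Hz), and compact support guarantees the
  injected trough is recovered *exactly* at zero noise.  Feedback trials
  share a P300-like positivity; the incorrect condition adds a constant
  (boxcar) shift, default −2 µV, over exactly the 250–300 ms ROI window,
  so the measured condition difference equals the injected shift by
  construction.  Cohort noise defaults to 5 µV — enough that per-subject
  estimates scatter realistically while the group t-test retains high
  power (a property the suite checks over seeded replicates).
* **Timing fixtures** (`gen_timing_fixture`): single channel; after each
  marker a 100 ms, 25 Hz square burst starts at a lag drawn from
  Normal(12.67 ms, 2.87 ms²) **before** quantization, then floored to
  the sample grid; the ground truth stores the post-quantization lags.
  Floor quantization biases the recovered *mean* low by about half a
  sample (~2 ms), which is documented here precisely so the recovery
  tolerance (one sample period) is predictable; the median sits on the
  grid at 12 ms.  200 trials per session is the standard audit size.

What the synthetic data deliberately *lack*: eye/muscle/cardiac
artifacts, inter-channel correlated noise, amplitude non-stationarity,
electrode drift, real auditory stream statistics, and any transport
(Bluetooth/network) modelling.  Passing tests therefore demonstrate the
*algorithmic* correctness of the chain — buffering, filtering,
template matching, statistics — not the decoding accuracy to expect on
real recordings, which is dominated by exactly the nuisance structure the
generator omits.

## Problem sizes and determinism

The test suite and the acceptance script run on deliberately small
sessions (e.g. 2–10 trials per class for exact-identity checks, the full
120-trial feedback block where the statistic itself depends on n, 200
trials for timing audits, 3–9 subjects for cohorts), chosen so the whole
pipeline exercises end-to-end in seconds while every assertion still
tests the same code paths a full-size session would.  All randomness
flows through `numpy.random.default_rng` seeds surfaced in configs and
ground-truth records; identical configuration and seed give bit-identical
recordings, reports and files.  The simple text format writes floats with
`repr`, so write→read round-trips are bit-exact and repeated writes are
byte-identical.

## Known limitations

* XDF/LSL input is not implemented; the simple columnar CSV format is the
  canonical interchange, and real recordings must be converted to it.
* The joint-probability rejection is a documented simplification, not a
  re-implementation of any specific toolbox routine.
* No ICA or component-based artifact attenuation; the offline cleaning
  stage of a real study is out of scope.
* Single-channel (bipolar) decoding only — by design, matching the
  minimal-hardware use case; no spatial filtering or machine-learning
  classifiers.
* The stream model assumes a shared clock and contiguous chunks; dropped
  samples or clock drift raise errors rather than being corrected.
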