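# Methods

This note documents the signal model behind the synthetic sessions, the
analysis pipeline's numerical choices, and the design decisions that were
genuinely open — in that order. Nothing here states an empirical result;
the numbers the package produces come from `tests/` and
`scripts/acceptance.py`.

## Synthetic session model

A session is rendered on one timeline at 250 Hz with channels Front,
Over, Back (around the left ear), Cz and one EMG channel, all in μV.
The default schedule is 4 blocks × 25 trials per movement condition
(hand, tongue), each trial preparation (2 s) → movement (2 s) → relax
(4 s), with the cue at the start of the movement phase; conditions
alternate every two blocks, blocks are separated by a 10 s gap, and the
session opens with a 5 s lead-in so every trial's pre-cue window has
full support. Idle activity is a separate background-only recording,
3 × 180 s by default.

Each EEG channel is a sum of independent tracks:

* **Background**: 1/f noise (PSD ∝ f^−1, shaped in the frequency domain
  from white noise, clamped below 0.1 Hz, 4 μV RMS), white noise
  (1 μV RMS) and a 50 Hz line sinusoid (2 μV peak, random phase).
* **Oscillation**: per band (α 8–13 Hz, β 13–30 Hz) a band-limited
  Gaussian carrier at 5 μV RMS baseline, multiplied by a movement-locked
  ERD/ERS envelope: amplitude factor (1 − g·erd_depth) in the ERD window
  (−1 s, 1 s) around the true onset, (1 + g·(ers_gain − 1)) in the ERS
  window (1 s, 2.5 s), cosine ramps of 0.25 s, where g is a per-channel
  gain. Defaults: erd_depth 0.4, ers_gain 1.3. A pure-sinusoid carrier
  mode exists for deterministic oracle tests.
* **MRCP**: raised-cosine descent from zero at −2 s to the negative peak
  (−10 μV at unit gain) at +0.1 s, then an exponentially decaying
  rebound multiplied by a cosine taper so the waveform reaches exactly
  zero at the end of the 1 s rebound window (a pure exponential never
  reaches zero, which would break the compact-support contract the
  epoch-level tests rely on).
* **Artifacts**: square pulses of ±150 μV and 0.2 s, injected on all EEG
  channels in a seeded, exact fraction of trials (default 2%), placed
  1.5–0.5 s before the onset so they land inside both epoch windows.

Per-channel gains project the MRCP and the ERD modulation onto the
montage. Hand default: ear gains 0.3, Cz 1.0 — a clear vertex response,
heavily attenuated at the ear, which is what makes ear-channel detection
hard but possible. Tongue default: vertex MRCP slightly weaker (8 μV,
gain 0.8) and ear ERD gains 0.6, encoding the expectation that the
tongue's motor representation lies closer to the ear electrodes. These
ear-channel amplitudes are calibrated choices, not measurements; no
quantitative ear-level MRCP/ERD amplitudes are available to fit.

The EMG channel is 20–100 Hz noise at 1 μV RMS baseline; each hand trial
adds a burst (20 μV RMS plateau, 50 ms cosine rise, 2 s hold) starting
at the true onset = cue + U(−0.5, 0.5) s. Tongue trials get no wrist
burst but their MRCP/ERD still lock to a jittered true onset. All
randomness for one recording flows from a single seeded generator;
`(schedule, model, seed)` determines the output bitwise.

**What the generator does not emulate** — single-trial amplitude and
latency variability of the MRCP/ERD, eye blinks and EOG, glossokinetic
potentials, volume conduction, electrode impedance drift, non-stationary
background. Synthetic subjects are therefore cleaner than real ones and
classification accuracies on them run higher than on recorded data;
passing tests demonstrate that the pipeline recovers what the model
contains, not field performance.

## Preprocessing

EEG: zero-phase 5th-order Butterworth band-pass 0.1–30 Hz, then a
zero-phase 50 Hz notch of quality 30. EMG: zero-phase 6th-order
Butterworth 20–100 Hz, the same notch, then the magnitude of the
analytic (Hilbert) signal as envelope. Stated orders are design orders;
forward–backward application doubles the effective order. Filters are
designed at the recording rate (no resampling) and applied per stream
independently.

Edge handling matters at a 0.1 Hz corner: the slowest pole pair rings
for seconds, and default-length padding leaks visible transients into
the record. Padding is therefore odd-symmetric with length
max(3·fs/low_cutoff, filter state length) samples — 30 s for the EEG
band-pass — and signals shorter than the pad are rejected with the
required length in the message. The first and last 0.5 s are logged as
edge-contaminated.

The envelope is the magnitude of the analytic signal. An `envelope
method="real"` switch preserves the literal "real part of the analytic
signal" reading for audit; the real part is the unmodified signal and is
not usable as an envelope.

## EMG onset detection

Per cue, the onset is the earliest sample in (−1 s, 1 s) around the cue
where the first difference (scaled to units/s) of the envelope strictly
exceeds the block's threshold; if nothing crosses, the cue itself
becomes the onset and a fallback flag is set. Thresholds set by hand per
block are not portable, so the default is automatic: mean + 3 SD of the
envelope derivative over the block's baseline segments (the preparation
second from −2 s to −1 s before each cue); a scalar or per-block manual
override is accepted.

Two robustness measures wrap the bare rule, both exposed as parameters:

* the envelope is smoothed with a 0.1 s *trailing* moving average before
  differencing — the raw analytic envelope of 20–100 Hz activity
  flutters at the band's own timescale and its raw derivative crosses
  any baseline-derived threshold constantly; the trailing (causal)
  window avoids anticipating the burst (`smooth_s=0` restores the
  literal rule);
* a crossing only counts if the smoothed envelope rises above its
  baseline mean + 6 SD within the following 0.2 s. This is the
  automated stand-in for the visual inspection of detected onsets that a
  human operator would perform: it discards derivative flutter not
  followed by an actual burst while costing nothing against real bursts,
  which sit an order of magnitude above baseline (`confirm_s=0`
  disables it).

## Epoching and rejection

Windows are half-open `[t0+start, t0+end)` with t0 snapped to the
nearest sample: ⟨−2 s; 1 s⟩ (750 samples) for control, ⟨−2 s; 0 s⟩
(500 samples) for rehabilitation. A t0 whose window lacks full support
is excluded and logged, never raised. Idle epochs start at seeded random
points of the idle recording, sorted, pairwise ≥ 1 s apart (epochs may
overlap); the request is rejected — with the maximum feasible count —
when `(n−1)·gap` does not fit strictly inside the available range, since
the boundary case has zero sampling measure. An epoch is rejected when
any sample of any *checked* channel falls strictly outside ±100 μV
("went outside" the range; exactly ±100 μV is kept). Checked channels
default to the EEG channels entering the current analysis (the ear set
or Cz), not the EMG; both the boundary rule and the channel set are
configurable. Grand averages are pointwise means with the negative-peak
latency per channel (argmin) reported relative to t0. No baseline
correction is applied anywhere.

## Features

Per channel: means of non-overlapping 0.5 s intervals (6 for control
epochs, 4 for rehabilitation); the zero-lag correlation with a template;
and Welch band power in δ (0.5–4), θ (4–8), α (8–13) and β (13–30 Hz).
The template is the pointwise mean of the *training folds'* movement
epochs only. The correlation is normalized, Σe·t / √(Σe²·Σt²), chosen
for amplitude invariance since nothing fixes the scale convention; the
raw inner product is available via `normalized=False`, and a zero-energy
epoch or template defines the value as 0 rather than 0/0. Welch uses
1 s Hann segments with 50% overlap (5 segments per control epoch, 3 per
rehabilitation epoch); frequency bins belong to the band whose half-open
[lo, hi) interval contains their center. The "temporal" subset comprises
interval means plus the template correlation (the template is a
time-domain object); "spectral" the band powers; "all" both — giving
d = 33/21/12 for the three-channel ear set in the control window and 5
for Cz-temporal in rehabilitation.

## Classification

Idle epochs are down-sampled (seeded) to the movement count once per
scenario and electrode set, before fold planning, so every classifier
and feature subset sees identical data. Folds are stratified, shuffled,
seeded, and reused across the classifier/feature grid. Per fold, the
template and the feature standardization (z-score) are fit on training
epochs only; standardization is applied for all four classifiers because
SVM and KNN are scale-sensitive and band powers dwarf temporal means —
whether the original analysis standardized is unknown, so this is
flagged in run logs. KNN uses K = round(√n_train) (nearest integer,
minimum 1, recomputed per fold) with Euclidean distance on the z-scored
features. The Random Forest (128 trees) is the only stochastic
classifier; fixing its seed makes the whole pipeline deterministic. The
reported accuracy is the median over the five folds. The chance level is
the exact binomial quantile: the smallest k with CDF_Binom(n_test, 0.5)(k)
≥ 0.95, divided by n_test; a normal approximation is available for
comparison via `scipy.stats` directly.

## Pipeline and seeding

Stage seeds derive from one master seed by hashing (master, stage-name),
so adding a stage never perturbs existing streams and every derived seed
stays below 2³¹. Reports carry accuracies in percent with 2 decimals;
across synthetic subjects, cells are summarized by the median and a
2.5–97.5 percentile bootstrap range of the median (10,000 resamples,
seeded), which collapses to the point for one subject. Recordings are
written as TSV (time column + labelled channel columns, μV) with events
and ground truth as TSV sidecars; EDF files can be read when `mne` is
installed, but recordings are not written as EDF (no EDF writer among
the package's dependencies).

## Problem sizes

The default grid (one subject, 100 trials per condition, 540 s idle,
3 scenarios × 2 electrode sets × 3 feature subsets × 4 classifiers) runs
in well under a minute on one core. Monotonicity and permutation-null
checks in the test suite use reduced sessions (2 blocks × 25 trials,
180 s idle, LDA only) averaged over 10 seeds — enough for the 0.05
tolerance those checks use while keeping the suite quick.

## Known limitations

* The synthetic subjects lack trial-to-trial variability (above), so
  absolute accuracies are optimistic; only orderings and invariances —
  monotonicity in effect size, chance-level behavior of null data,
  leakage safety — transfer.
* Onset detection assumes one burst per cue window; overlapping
  movements are out of scope.
* Rejection checks only the analysis channels; whether an excluded
  channel should veto an epoch is configurable but unknowable from the
  available description.
* No re-referencing, spatial filtering, ICA, baseline correction, or
  online/asynchronous operation.
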