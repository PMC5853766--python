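# Methods

This note documents the models, the numerical choices, and the limits of
what the synthetic experiments demonstrate.

## Synthetic phonocardiogram model

The simulator emulates ~10 s chest-wall recordings (default sample rate
4 kHz, minimum 2 kHz) built from a small number of physiologically placed
components:

| component | model | defaults |
|---|---|---|
| S1 | Gaussian-windowed sinusoid (σ = dur/6) | 35 Hz, 110 ms, amplitude 1.0 |
| S2 | same | 60 Hz, 90 ms, amplitude 0.8 |
| S3 | same, 120–180 ms after S2 | 28 Hz, 70 ms, amplitude 0.15 |
| S4 | same, 70–100 ms before next S1 | 30 Hz, 70 ms, amplitude 0.15 |
| systolic murmur | 40–100 Hz Gaussian noise, diamond envelope over systole | peak std = 0.35 × intensity |
| diastolic murmur | same noise, decrescendo over first 70% of diastole | same scale |

Systole occupies a fixed 35% of each RR interval, so the interval rule
(systole < diastole) holds at every legal heart rate (30–200 bpm). All
tone centers sit inside the 20–100 Hz band where chest-wall heart sounds
concentrate, and ≥ 90% of synthesized energy lies below 150 Hz. S3/S4
amplitudes (0.15 of S1) reflect that gallop sounds are faint,
low-frequency events; the murmur scale is chosen so that even an intense
murmur's Shannon-energy peak stays below the S1/S2 peaks (see the
segmentation section for why this matters). Event times in annotations
mark the *center* of each transient.

Regular rhythm uses constant RR = 60/HR. Atrial fibrillation draws RR
i.i.d. from a gamma distribution with the configured coefficient of
variation (default 0.2), clipped to [0.25, 2.5] s; a configuration with
both AF and S4 is rejected because AF abolishes the atrial kick that
produces S4.

Additive noise is a weighted mix of white, pink (PSD ∝ 1/f, −3 dB/octave)
and 50 Hz mains-hum components, scaled to an exact requested global SNR.
If the noisy waveform would clip, signal and noise are rescaled together
(SNR unchanged; the factor is recorded in the recording metadata).

What the simulator does **not** model: realistic valve timbre and
split sounds, respiration and lung sounds, sensor coupling/motion
artifacts, murmur radiation patterns, or patient non-cooperation.
Consequently a passing synthetic benchmark shows algorithmic correctness
under the stated timing/band assumptions, not clinical performance.

## Denoising

Band-pass: 4th-order Butterworth, 20–100 Hz, applied forward–backward so
the zero-phase response preserves S1/S2 timing for segmentation.

Spectral subtraction: 256 ms Hann frames at 50% hop; the noise magnitude
spectrum is the per-bin mean over the lowest-energy 25% of frames; each
bin keeps `max(|X| − α|N̂|, β|X|)` with over-subtraction α = 1 and
spectral floor β = 0.05; inverse STFT with the original phase. The
quietest-*quartile* estimate is used rather than an extreme decile: the
decile is biased low by selection on frame energy (leaving ~21% residual
energy on pure stationary noise), while the quartile is still safely
noise-only for heart sounds, which occupy well under half of all frames.
Measured behavior: ~15% residual energy on pure noise, ≈ +8 dB SNR gain
on a 6 dB-SNR recording, < 0.01 dB RMS change on an already-clean signal.

Interpretability gate: a recording is flagged uninterpretable when its
peak amplitude is below 0.01 full scale (LOW_AMPLITUDE) or when a blind
SNR estimate — the ratio of the 98th to the 20th percentile of the 50 ms
smoothed instantaneous power, exploiting the impulsive on/off structure
of heart sounds — falls below 5 dB (HIGH_NOISE). The gate is advisory;
the pipeline excludes flagged recordings from metric denominators by
default but can retain them (`include_uninterpretable`).

## Segmentation

The envelogram is the windowed average Shannon energy −x² ln x² (0 ln 0
:= 0) of the peak-normalized signal, computed at a 1 kHz working rate
with 20 ms windows and 10 ms hop, then z-scored. Shannon energy is
maximal at |x| = e^−1/2 and vanishes at 0 and 1, which suppresses both
the noise floor and full-scale spikes relative to mid-amplitude
transients. A side effect matters for design: amplitude ordering is not
preserved (an 0.8-amplitude S2 maps *above* a 1.0-amplitude S1), so no
stage of the detector relies on "S1 is tallest".

Candidate events are envelope maxima above +0.5 standardized units with a
120 ms refractory gap (shorter than any physiologic systole); gaps longer
than 1.5× the median inter-event interval are re-scanned at half
threshold.

S1/S2 assignment evaluates competing hypotheses and keeps the best:

* **Phase clustering.** With the beat period T estimated from the
  envelope autocorrelation (searched over 0.3–2 s lags), events are
  clustered by t mod T with a 0.07 T tolerance — tight enough that the
  two closest genuine trains (S2 and an early-diastolic murmur peak,
  ~0.1 T apart) never merge. Every pair among the four most populated
  clusters is a hypothesis, oriented by the interval rule: the shorter of
  the two alternating intervals is systole, so it runs S1 → S2.
* **Strict alternation**, phase chosen so systole < diastole — the
  fallback that handles irregular rhythm (AF), where phases smear.

Each hypothesis is scored by its yield of plausible cycles (count ×
fraction plausible, where a cycle is plausible when its S1–S1 span
contains exactly one S2 at 15–60% of the span), with the summed envelope
amplitude of the assigned events as tie-break — S1 and S2 are the
strongest periodic trains, which rejects murmur-peak or S3/S4 trains that
would otherwise tie. The trailing S2 of the final (incomplete) cycle is
recovered from the winning S2 train. Fewer than four events, or no
plausible cycle, raises a typed segmentation failure that the pipeline
records per recording instead of crashing.

Measured on 100-recording seeded batches (all five classes, HR 50–110,
SNR 10–30 dB, after band-passing): S1+S2 recall and precision ≈ 0.99 at
±30 ms, with occasional hard failures (~2–4% of murmur recordings) where
an intense murmur train still wins a tie.

## Features

Each cycle (S1 onset to next S1 onset, minimum 200 ms) is peak-normalized
(gain invariance), resampled to a canonical 800 ms at 1 kHz, transformed
with a 64 ms Hann STFT at 75% overlap (256-point FFT), log-compressed
(log(1+|X|)), cropped to 10–200 Hz, bilinearly resized to exactly 40×40
(time × frequency) and min–max normalized per matrix (all-zero input maps
to an all-zero matrix). Note that resampling to the canonical duration
scales frequencies by (cycle length)/0.8 s — the network sees
cycle-normalized time *and* correspondingly warped frequency, which is
intrinsic to fixed-size cycle alignment.

## Classifier

Architecture (fixed 40×40 input): conv 5×5 ×8 → ReLU → max-pool 2×2 →
conv 5×5 ×16 → ReLU → max-pool 2×2 → dense 128 ReLU → dense 5 → softmax;
valid convolutions give the spatial path 40→36→18→14→7 (784 flat
features; ~104k parameters). Training: softmax cross-entropy, Adam at
learning rate 10⁻³ (β₁ = 0.9, β₂ = 0.999), batch size 32, 30 epochs,
He initialization, optional stratified 20% validation split for the
per-epoch log. The implementation is pure NumPy (float32) with explicit
im2col-based forward/backward passes, verified against central finite
differences in the test suite, and is bit-deterministic given
`random_state` on a fixed platform.

Recording-level diagnosis: the mean of per-cycle probability vectors; a
diagnosis is correct when the true class receives ≥ 50% aggregate
probability (the boundary counts as correct). The mean is the simplest
order-invariant cycle→recording rule.

In the end-to-end experiment (train on 400 balanced synthetic recordings
using ground-truth cycle bounds — mirroring training on curated,
annotated material — then evaluate 100 held-out recordings through the
full band-pass → denoise → segment → featurize path), recording-level
5-class accuracy is 100% under the ≥50% rule; the synthetic classes are
cleanly separable, so this is a parameter-recovery check, not a clinical
estimate.

## Evaluation statistics

Labels are dichotomized normal vs abnormal (S3, S4 and both murmurs are
positive). The five proportions — diagnostic accuracy, sensitivity,
specificity, PPV, NPV — are computed exactly from confusion counts, and
each carries an exact two-sided Clopper–Pearson CI on its
(numerator, denominator) pair via Beta quantiles:
lower = B⁻¹(α/2; k, n−k+1) (0 when k = 0),
upper = B⁻¹(1−α/2; k+1, n−k) (1 when k = n).
The exact method was chosen because it reproduces, at whole-percent
rounding, every published interval of this kind we use as a worked
example for k < n; the test suite cross-checks it against brute-force
bisection of the binomial CDF to 10⁻⁶ for all n ≤ 50. A metric whose
denominator is zero is reported as undefined ("—"), never as 0 or 100%.
Whole-percent renderings accompany full-precision proportions; the 5×5
confusion matrix is also available.

Known boundary caveat: for k = n cells some published tables print
intervals that are *not* Clopper–Pearson (e.g. a 14/14 specificity shown
as 68–100% where Clopper–Pearson gives 77–100%); such boundary cells are
outside what this package tries to match, and no attempt is made to force
agreement there.

## Pipeline and problem sizes

The pipeline stages are sklearn-style estimators (`BandpassFilter`,
`SpectralSubtractor`, `ShannonSegmenter`, `CycleSpectrogramExtractor`,
`HeartSoundCNN` with `fit`/`predict_proba`/`get_params`), composed by
`run_pipeline`, which is deterministic given the config seed and records
every per-recording failure rather than aborting. Test and acceptance
workloads use 10 s recordings at 4 kHz; the segmentation benchmark uses
100 recordings, and the end-to-end experiment 400 training plus 100
held-out recordings (~5,000 training cycles), sizes at which the whole
suite completes in minutes on a single CPU while every statistical bar
retains comfortable margin.
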