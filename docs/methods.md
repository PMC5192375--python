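# Methods

## The detector

`terma` detects recurring events in a single-channel, quasi-periodic
biomedical signal (ECG beats, PPG systolic waves, APG a–e waves, heart
sounds) using two event-related moving averages. The pipeline for a
record `x[n]` sampled at `fs` Hz, with parameters `(F1, F2, W1, W2, β)`:

1. **Band-pass filter.** Third-order Butterworth with passband `F1–F2` Hz,
   applied forward and backward (`sosfiltfilt`) so the output has zero
   phase lag. `F1 = 0` selects a pure low-pass of the same order, since a
   band-pass with a zero low edge is ill-defined. An `F2` at or above
   Nyquist is clipped to `0.99·fs/2` with a logged warning, so presets
   written in Hz remain usable at low sampling rates.
2. **Enhancement.** Point-wise squaring: `y[n] = x_f[n]²`.
3. **Two moving averages.** Centered means of `y` with windows `W1`
   (event duration) and `W2` (cycle duration), both given in
   milliseconds and converted per record to the nearest odd sample count
   (minimum 1; an exactly even sample count rounds up). Windows in
   milliseconds — never samples — keep one parameter set valid across
   sampling rates.
4. **Offset threshold.** `THR1[n] = MA_cycle[n] + α` with
   `α = β · mean(y)`, the mean taken over the whole record (batch
   operation, no running mean). Because the offset scales with the
   signal, detections are invariant to any positive rescaling of the
   input.
5. **Blocks of interest.** Maximal runs where `MA_event[n] > THR1[n]`
   (strict comparison, so an all-zero record yields no blocks), as
   half-open `[onset, offset)` intervals; runs touching a record
   boundary are kept.
6. **Width rejection.** Blocks narrower than `W1` samples (`THR2 = W1`)
   are discarded as noise; a block exactly `W1` wide is kept.
7. **Peak localisation.** One peak per surviving block: the index of the
   maximum absolute value of the filtered signal (ties to the earliest
   index). The search signal is configurable (`filtered`, `raw`,
   `squared`); the default is the filtered signal because squaring
   destroys the polarity the absolute-value rule needs.

**Edge handling.** The centered means are undefined within `(W−1)/2`
samples of the record edges; we extend the signal symmetrically
(edge-repeating, `numpy.pad(mode="symmetric")`). Constant padding (e.g.
zeros) would create artificial threshold crossings at the boundaries.

**Window-ratio rule.** The two windows couple — i.e. actually generate
blocks — when `2·W1 ≤ W2 ≤ 8·W1` (inclusive). The rule is empirical, so
`detect` logs a warning on violation rather than raising.

## Parameters and presets

The five decision variables, with the shipped presets (found by
brute-force multi-objective optimisation on annotated training
databases; β is stored as a fraction):

| preset        | event            | F1 (Hz) | F2 (Hz) | W1 (ms) | W2 (ms) | β    |
|---------------|------------------|---------|---------|---------|---------|------|
| ecg-qrs       | QRS complex      | 8       | 20      | 97      | 611     | 0.08 |
| ecg-twave     | T wave           | 0.5     | 10      | 70      | 140     | 0    |
| ppg-systolic  | systolic wave    | 0.5     | 8       | 111     | 667     | 0.02 |
| apg-ab        | a, b waves       | 0.5     | 15      | 175     | 1000    | 0    |
| apg-cde       | c, d, e waves    | 0.5     | 7       | 5       | 15      | 0    |
| heart-sounds  | S1, S2           | 0       | 60      | 130     | 270     | 0.03 |

All six satisfy the window-ratio rule.

## Evaluation

Detections are matched to reference annotations greedily in increasing
time: each reference event takes the nearest unmatched detection within
`±tolerance`, equidistant ties going to the earlier detection. The
matching is one-to-one, so `TP + FN = |reference|` and
`TP + FP = |detected|` hold identically. Sensitivity `SE = TP/(TP+FN)`,
positive predictivity `+P = TP/(TP+FP)`, overall accuracy
`J = (SE + +P)/2`; a zero denominator yields NaN (the convention that
marks a *non-coupling* detector, one that produced no blocks at all).

The matching tolerance is not part of the method and materially affects
the statistics, so every result records the tolerance used. The default
is ±75 ms, the long-standing QRS-matching convention (roughly half a
typical event cycle margin); callers override it per run.

## Optimisation

`grid_search` evaluates every admissible combination (`F1 < F2`,
`W1 < W2`) of explicit value lists — the caller owns discretization —
pooling TP/FP/FN across training records (micro-averaging) before
computing pooled SE/+P/J, and ranks by J descending with NaN last.
Tie-break at equal J: higher SE, then smaller W2, smaller W1, lower β,
lower F1 — preferring the cheaper, faster-responding detector — fixed so
rankings are exactly reproducible. `coupling_scan` sweeps `W2/W1` ratios
(and optionally β) at fixed W1 and classifies each cell: *coupling*
(J > 0.5), *non_coupling* (J = NaN), *intermediate* otherwise.

## Synthetic data

The generator places pulse centers at `(k + ½)·cycle_ms` plus Gaussian
jitter of standard deviation `cycle_jitter_frac·cycle_ms`, drops pulses
whose support would cross a record boundary, and adds a baseline-wander
sinusoid and white Gaussian noise. Shapes: `gaussian` (smooth unimodal,
PPG-like), `biphasic` (derivative of Gaussian, QRS-like), `burst`
(Gaussian-enveloped 40 Hz cosine with the carrier peak at the envelope
center, heart-sound-like). The pulse's ±3σ span equals the nominal
event width. Each annotation is the exact sample of the pulse extremum
(maximum absolute amplitude, earliest tie), matching the detector's peak
definition. Everything is determined by the seed.

The standard three-shape suite uses 20 s records: biphasic at 360 Hz
(1000 ms cycle, 80 ms events), Gaussian at 200 Hz (900 ms, 110 ms), and
burst at 1000 Hz (500 ms, 100 ms), with 3 % cycle jitter — durations and
rates typical of resting adult recordings, and sizes small enough that
the whole battery runs in seconds.

These are stylizations, not physiological simulators: no P/T morphology
around the QRS-like pulse, no dicrotic notch, no S1/S2 pairing within a
cardiac cycle, no pathological beats, and purely white (not muscle- or
electrode-artifact-like) noise. Passing tests therefore demonstrate the
detector's contract — event-scale averaging, thresholding, block logic,
scale invariance, graceful degradation with SNR — not clinical-grade
accuracy on real recordings.

**Window-recovery training set.** Recovering the event window by grid
search needs conditions where the window is identifiable: with sparse
events and mild noise, an over-wide window is never punished (it only
smooths noise better), so any window ≥ the true one ties or wins. The
recovery set (`recovery_training_specs`) therefore emulates a noisy
high-rate recording — 80 ms biphasic events at 150 beats/min, 10 % cycle
jitter, white noise at 0.6× the event amplitude, three 20 s records
pooled. There, an under-sized window (40 ms) admits noise blocks that
survive the width threshold (false positives), and an over-sized window
(160 ms) merges closely spaced beats and rejects narrowed blocks (false
negatives), so the true 80 ms window maximises pooled J.

## Numerical choices and degenerate inputs

- Strict `>` in block generation: an identically zero signal produces
  zero blocks and zero peaks, not one giant block.
- Records shorter than the zero-phase filter's padding requirement raise
  a dedicated `SignalTooShortError`; windows longer than the record
  raise an error naming the offending window.
- 0-based sample indices and half-open intervals everywhere, including
  output files; times are written with six decimals.
- Moving averages use exact convolution (not a running sum), keeping
  agreement with a per-index loop within 1e-9.

## Known limitations

- Batch-only: the record is processed at once (the offset uses the
  whole-record mean); no streaming variant.
- The minimal WFDB reader covers single-segment headers and signal
  formats 16 and 212 with gain/baseline conversion, plus standard
  annotation files — enough for the common PhysioNet layout, not the
  full format zoo.
- Synthetic fidelity limits above apply: results on real clinical data
  depend on morphology and noise structure the generator does not model.
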