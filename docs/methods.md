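# Methods

This note documents the models, estimators, and synthetic-data generator
implemented in `ecochg`, the conventions and defaults they use, and the
design decisions taken where more than one reasonable choice existed.

## The average cycle

Round-window electrocochleography (ECochG) to a tone burst is analyzed
through its *average cycle*: the pointwise mean of all steady-state stimulus
cycles, equivalent to a period histogram. `signal_core` extracts cycles from
a sweep by cutting the burst at exact (generally fractional) cycle
boundaries with cubic-spline interpolation, excluding 2 onset and 1 offset
cycles by default — onset cycles carry the compound action potential and the
response build-up; the count is configurable via `SteadyStateWindow`.

Responses to condensation and rarefaction stimulus polarity are combined
into the *difference* `(C − R)/2` (hair-cell dominated: the cochlear
microphonic inverts with polarity) and *alternating* `(C + R)/2` (neural
dominated: the rectified neurophonic does not invert) waveforms. The
transform is an exact linear bijection: `C = alt + diff`, `R = alt − diff`.

Canonical normalized form: each cycle is resampled to `n_points = 100` with
a periodic cubic spline, scaled so half the peak-to-peak amplitude is 1, and
circularly shifted so sample 0 sits at the positive-going zero crossing of
the fundamental (first-harmonic Fourier phase zero). Using the fundamental's
phase rather than the raw zero crossing makes the alignment robust to
harmonic distortion; a cycle whose fundamental carries less than 1e−12 of
the total power is rejected as degenerate.

For the four-channel quadruple fed to the classifier, one shift — derived
from the condensation fundamental — is applied to all four channels so that
their relative timing (which carries the discriminative information) is
preserved; amplitude is normalized per channel, and a numerically silent
channel (e.g. the alternating waveform of a noiseless linear CM-only
record) is stored as zeros rather than blown up to full scale.

## Forward model

**Cochlear microphonic (CM).** A sinusoidal drive `sin(θ + φ)` passed
through a two-sided saturating nonlinearity with independent asymptotes,

    g(x) = s_p (1 − e^(−x/s_p))   for x ≥ 0
    g(x) = −s_t (1 − e^(x/s_t))   for x < 0,

which has unit slope at the origin, is monotone, and is bounded in
`(−s_t, s_p)`. Large asymptotes recover a pure sinusoid; `s_p ≠ s_t`
produces the asymmetric flattening characteristic of the hair-cell
operating point. The emitted waveform is rescaled so its half peak-to-peak
equals the amplitude parameter `A_cm` (μV) exactly. Because the asymmetry
is a property of the transducer, not the stimulus, the response to inverted
polarity is `g(−x)`, *not* `−g(x)`: at high levels the saturated CM leaks
even harmonics into the alternating waveform, which is a real confound for
neural-response detection and is deliberately reproduced.

**Auditory nerve neurophonic (ANN).** The cycle histogram of phase-locked
firing is the half-wave-rectified drive `max(sin(θ + φ), 0)`, optionally
broadened by a wrapped-Gaussian blur of SD σ radians (the "spread of
excitation" accounting for phase dispersion across fibers). This histogram
is circularly convolved with a *unit potential* — the far-field action
potential shape, modeled as a biphasic pair of Gaussian lobes (negative
leading) with default FWHMs 0.25 ms and 0.5 ms, lobe separation 0.5 ms,
amplitude ratio −1 : +0.5, mean removed. The unit potential is defined in
time, so its phase footprint scales with stimulus frequency: at 250 Hz it
occupies an eighth of the cycle and the ANN is sharply non-sinusoidal; by
1 kHz it spans most of the cycle and washes the harmonics out. This is the
mechanism behind the 1 kHz detection rolloff, and it is why 1 kHz records
are excluded from training and from proportion summaries.

The ANN is **phase-locked to the CM drive**: both components arise from the
same basilar-membrane motion, so the rectified drive uses the same phase φ
as the CM (the ANN has no free phase of its own, in synthesis or fitting).
Flipping stimulus polarity shifts the rectified drive by half a cycle, so
the rarefaction ANN is the condensation ANN rotated by π; summing the two
phases interleaves the rectified responses and leaves only even harmonics
(2 f₀ dominant) in the alternating waveform.

**Noise.** Additive white Gaussian noise, independent between polarity
buffers, scaled to a stated SNR (dB) relative to the noiseless condensation
RMS. This stands in for the residual noise of a sweep average; the
generator does not model correlated physiological noise or artifacts.

## Synthetic cohorts

`simulate_cohort` generates labeled populations over the standard stimulus
grid (250–4000 Hz × 30–90 dB in 10 dB steps), 25 dB SNR, with per-subject
random effects. Normal-hearing (NH) conditions:

- CM amplitude grows ~linearly in level, `A_cm ≈ 3.5 μV/dB × (L − 10)`
  with log-normal subject gain (SD 0.3) and mild frequency weighting —
  hundreds of μV at 90 dB, the gerbil round-window scale. The human-like
  preset scales amplitudes by 0.1.
- Saturation deepens with level: `log10 s_p = 1.5 − 0.035 (L − 30) ± 0.15`,
  with the trough saturating 2–4× less than the peak.
- The true ANN proportion declines with level from ≈0.5 at 30 dB by
  0.006/dB (subject-jittered), clipped to [0.10, 0.60]; at 1 kHz the ANN
  amplitude is reduced to 40%; above 1 kHz it is zero. Spread grows with
  level: `σ = 0.3 + 0.005 (L − 30) ± 0.1` rad.

Lesion presets modify the NH laws:

- **KA (kainic acid)**: ANN amplitude multiplied by an apex-to-base survival
  gradient (0.45 at 250 Hz down to 0.10 at 1 kHz, subject-jittered) —
  round-window diffusion spares apical fibers.
- **HF-NIHL**: CM scaled down per frequency (basal hair-cell loss) and its
  level growth plateaued above a 60 dB onset (only 10% of the NH growth
  rate above onset), with earlier saturation; the ANN keeps following the
  *unlesioned* drive, so the realized ANN proportion rises at high levels —
  reproducing the characteristic contrast with NH animals.
- **HUMAN_LIKE**: 10× smaller amplitudes and a synaptopathy mixture (30% of
  subjects with no ANN, the rest with survival uniform on [0.2, 1]).

The generator encodes the *consequences* of basal spread of excitation and
traveling-wave phase interference phenomenologically (amplitude laws,
plateaus); it does not simulate cochlear place mechanics, the summating
potential, onset CAPs, or artifact contamination. Passing tests therefore
demonstrate correctness of the estimators under this generative family, not
performance on real recordings.

## Presence classifier

Two bidirectional LSTM layers (50 recurrent units each, the first returning
full sequences), followed by a single sigmoid unit on the concatenated
final hidden states of both directions; binary cross-entropy loss, Adam.
The network is implemented directly on NumPy (`_rnn.py`) with explicit
backpropagation through time — gate order i|f|g|o, Glorot input kernels,
orthogonal recurrent kernels, unit forget-gate bias — and its gradients are
verified against finite differences in the test suite. Training is
bit-reproducible from a single seed (initialization, stratified split, and
batch shuffling all derive from it), and weights round-trip through an
`.npz` + JSON sidecar.

Inputs are the four normalized channels in the fixed order (condensation,
rarefaction, difference, alternating); because amplitude and starting phase
are normalized away, classification depends only on waveform shape, and
predictions are invariant to rescaling the raw μV record.

Training labels come from frequency band alone (self-labeling on NH-like
cohorts): ≤750 Hz ⇒ ANN present, ≥2 kHz ⇒ absent, 1 kHz excluded. The
70/30 split is stratified by class and frequency. Defaults: ≤100 epochs
with an early stop when the epoch training loss falls below 1e−3, learning
rate 2e−3, batch size 32. The decision threshold on the sigmoid output is
0.5.

## Analytic decomposition

`fit_cycle` fits the condensation-phase average cycle (100 points, raw μV)
with the same forward model used for synthesis: free parameters are CM
amplitude, phase, peak and trough saturation (optimized as log10), and —
when the classifier allows an ANN — ANN amplitude and spread. The objective
is the unweighted sum of squared residuals, minimized by bounded
trust-region least squares (`scipy.optimize.least_squares`, tolerances
1e−10) from 8 starts crossing initial phase {0, π/2, π, 3π/2} × initial ANN
share {0.1, 0.4}. Bounds: amplitudes in [0, 10× the data half peak-to-peak],
saturations in [0.05, 1e6], spread in [0, π].

The model is over-determined: with residuals at the noise floor, competing
optima can attribute very different amplitudes to the ANN, because a
heavily blurred cycle histogram degenerates toward a sinusoid and mimics an
unsaturated CM. Among starts whose objective is within 5% of the best, the
fit therefore selects the smallest ANN amplitude (parsimony). The 5%
tolerance was calibrated on SNR-20 dB recovery simulations; without the
tie-break the fit systematically inflates the ANN (it can always spend the
extra component on fitting noise), and aggregate recovery degrades several-
fold. Per-record parameter uniqueness is *not* claimed; the estimator's
contract is aggregate (RMSE of recovered proportion ≤ 0.08 at SNR 20 dB,
exact recovery noiseless).

The headline statistic is the ANN proportion `A_ann / (A_cm + A_ann)`, both
amplitudes in μV. In the gated pipeline (`decompose_pipeline`), records the
classifier judges ANN-absent are refit without the ANN component and report
a proportion of exactly 0 — never an epsilon — and 1 kHz records are
flagged for exclusion from proportion summaries.

## Validation metrics

**Residual similarity.** Each low-frequency cycle (normalized) is regressed
against every member of a CM-only high-frequency library over integer
circular lag (FFT cross-correlation) and free scale (least squares); the
reported residual RMS of the best-matching member is normalized by the
query RMS, making the metric invariant to query scale and circular shift.
Small residuals mean the cycle is explainable as hair-cell-only; across a
population the residual should track the fitted ANN proportion, providing a
validation of the decomposition that makes no assumption about component
shapes.

**Total Response (TR).** Harmonic magnitudes (f₀, 2f₀, 3f₀) are read from
the discrete Fourier transform of the average cycle (amplitude `2|X_k|/N`);
a peak is significant if it reaches the 0.02 μV floor (−34 dB re 1 μV, the
single-response significance threshold under good recording conditions) and
stands ≥3× above the median non-harmonic bin magnitude. TR is the sum of
significant magnitudes in μV across the six standard frequencies, summed
before dB conversion (`20 log10(total/1 μV)`).

**Thresholds.** From a single high-level response: threshold = level −
(response dB − floor dB), i.e. linear extrapolation at 1 dB response drop
per dB of level down to the 0.02 μV floor. From a descending 10 dB level
series: linear interpolation, in (level, response-dB) coordinates, between
the last significant and first non-significant response; all-significant
and none-significant series are reported as bounds. A zero response, which
has no dB value, enters the interpolation as floor − 20 dB (a documented
stand-in). Saturated high-level responses make the single-level
extrapolation pessimistic relative to a measured series, and the tests
check that directional relationship.

## Problem sizes and runtime choices

The standard evaluation protocols (`protocols.py`) use a 43-subject NH
cohort (1,806 cycles: 903 ANN-present, 602 CM-only, 301 at the excluded
1 kHz band), a 200-cycle decomposition population with proportions uniform
on [0.05, 0.6] at 20 dB SNR, and a 100-cycle CM-only library. In the
population studies the stimulus level is derived from the cohort's
proportion-vs-level law (low proportions occur at high levels), so that
saturation and spread co-vary with proportion exactly as in the cohort.
These sizes keep a full end-to-end run (training plus ~300 multi-start
fits) in the tens of minutes on one CPU core while leaving class counts
large enough for percent-level rates.

## Known limitations

- At 750 Hz and high levels the generator produces records whose ANN is
  near the 0.10 proportion floor, heavily blurred, and masked by the CM's
  own even-harmonic leakage into the alternating waveform; these are
  intrinsically ambiguous, and detector sensitivity saturates just below
  paper-level performance under the default 100-epoch budget (longer
  training recovers part of the gap). See the per-frequency rates reported
  by the acceptance protocol.
- The analytic model's parameters are not identifiable per record; only
  aggregate recovery is claimed.
- The generator's lesion profiles (KA survival gradient, HF-NIHL plateau)
  are phenomenological; no claim is made about mechanistic cochlear
  modeling, and none of the cohort-level numbers here are estimates of real
  animal or human values.
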