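# Methods

## Problem and model

Intraoperative depth-of-anesthesia monitors record two frontal EEG
channels a few centimetres apart against a shared reference, sampled at
128 samples/s/channel with 0.05 uV per 16-bit count. Surgical tools,
cautery, movement and physiological artifacts contaminate the two
channels *asymmetrically*: at any given second one electrode is usually
hit harder than the other. Averaging the channels would smear one
channel's noise into the other, so `eegswitch` instead picks, second by
second, the channel carrying fewer spurious components and splices those
seconds into a single "combinational" stream — halving the data
dimension (2 x 128 to 1 x 128 samples/s) without inventing or altering
a single sample.

The decision statistic works on a level-4 db4 discrete wavelet
decomposition of each one-second frame, whose dyadic sub-bands coincide
with the clinical rhythms at this rate (ca4 = delta 0-4 Hz, cd4 = theta
4-8, cd3 = alpha 8-16, cd2 = beta 16-32, cd1 = gamma 32-64). Four
criteria per sub-band — mean, energy, Shannon entropy, population
standard deviation — all grow in magnitude when noise is present, so
each (band, criterion) comparison is won by the channel with the
*smaller absolute value*; each criterion votes by its 5-band majority,
and the epoch goes to the channel favoured by the majority of the four
criteria.

## Pipeline stages and parameters

1. **Epoching and error handling.** One-second frames of 128 samples.
   An *error sample* is |amplitude| > 400 uV or ADC saturation —
   physiological scalp EEG stays well under +/-200 uV, so the limit only
   triggers on recorder faults and violent artifacts. Up to 5 error
   samples per second per channel are repaired by previous-sample hold
   (linear interpolation optional); more constitutes a *burst* and the
   whole second is removed from both channels (the underlying EEG is
   unrecoverable, and removing both keeps the time axes aligned).
2. **Conventional filters.** Zero-phase IIR notch at the mains frequency
   (default 50 Hz, Q = 30) and a zero-phase Butterworth band-pass,
   realized as a 4th-order high-pass at 0.1 Hz plus a 4th-order low-pass
   at 63.5 Hz. The nominal 64 Hz upper edge equals Nyquist and is not
   realizable; the low-pass is skipped entirely if the configured edge
   reaches Nyquist. All filters are applied forward-backward, so the
   switching stage never has to compensate phase.
3. **Wavelet denoising.** db4, level 4, universal threshold
   `sigma * sqrt(2 ln n)` with `sigma = MAD(finest details)/0.6745`,
   **hard** mode: detail coefficients below the threshold are reset to
   zero, survivors and the approximation are untouched. Two deliberate
   choices here:
   * *Hard, not soft.* Soft shrinkage subtracts the threshold from
     every surviving coefficient and therefore biases genuine EEG
     amplitudes downward by ~4 sigma; hard thresholding only deletes
     noise-level coefficients.
   * *One threshold for both channels*, with sigma pooled from both
     channels' finest details. The recorder noise floor is common to
     the electrode pair, and a per-channel threshold would shrink the
     more contaminated channel harder — making it look spuriously
     "cleaner" in uncontaminated sub-bands and corrupting the vote.
     This effect was observed directly on synthetic runs.

   Universal-threshold denoising presumes the signal is sparse in the
   wavelet basis. Transients and piecewise-smooth structure are; a
   long stationary oscillation is not (its energy spreads over many
   moderate coefficients), and for a pure sinusoid in white noise the
   universal threshold removes as much signal as noise. The tests
   therefore verify RMSE reduction on a sparse transient signal and
   noise-band suppression for tones, not RMSE reduction on tones.
4. **Savitzky-Golay smoothing.** Polynomial order N = 17, frame
   M = 33 samples (interpreted as the full odd window, since N < M is
   required). The textbook monomial formulation is numerically
   degenerate at this order (scipy's `savgol_coeffs(33, 17)` returns a
   kernel summing to ~1e-12), so the kernel is built from a
   QR-orthogonalized Legendre basis on [-1, 1]; it reproduces
   polynomials of degree <= 17 to machine precision and has unit gain
   below ~16 Hz, -16 dB at 40 Hz. Edge half-windows evaluate the
   polynomial fit of the first/last full frame.

The continuous filters (2-4) run on the concatenation of the retained
epochs per channel; boundary seconds adjacent to removed epochs inherit
small filter transients, which affect both channels alike.

## Wavelet transform details

The db4 filter pair is constructed at import time by spectral
factorization of the Daubechies half-band polynomial (minimum-phase
root selection, taps normalized to sum to sqrt(2)) and cross-checked
against the textbook coefficients in the tests.

Frame decomposition uses **periodized** boundary extension: on a
128-sample frame the level-4 transform is then exactly orthogonal
(64 + 32 + 16 + 8 + 8 coefficients), giving perfect reconstruction and
exact Parseval energy conservation — properties the per-band energy and
entropy criteria rely on. Half-point **symmetric** extension is also
implemented (redundant boundary coefficients, perfect reconstruction via
length bookkeeping) and is used for denoising arbitrary-length series,
where wrap-around leakage would be worse than boundary redundancy.

## Decision rule and ties

Band comparison uses strict inequality on absolute values; an exact tie
contributes to neither channel. A criterion whose five bands split
evenly votes "tie" and is excluded from the final majority. If the four
criteria split 2-2 (or all tie), the previous epoch's decision is
carried forward — a continuity rule that avoids chattering switches on
indistinguishable channels — and a first-epoch tie defaults to
Channel 1. Identical channels therefore yield an all-Channel-1 series.

## Evaluation instruments

* **Per-second PSD**: each second is mean-removed, FFT'd and scaled to
  one-sided power density `|X|^2 / (N Fs)` (interior bins doubled), so
  summed power times the 1 Hz bin width equals the second's variance.
* **CCF side difference**: the cross-correlation over lags
  -(n-1)..(n-1), normalized correlation-coefficient style
  (`1/(n sx sy)`), split at lag 0; the statistic is
  `|mean(left) - mean(right)|`. It is exactly zero for any
  self-comparison (autocorrelation is even) and grows with the share of
  seconds the combinational signal did *not* take from that channel;
  the normalization keeps values on a comparable ~1e-3 scale across
  recordings.
* **Wavelet coherence**: analytic Morlet (omega0 = 6) CWT computed
  scale-by-scale in the frequency domain; cross- and auto-spectra are
  smoothed by a scale-proportional boxcar in time (~2 scales wide) and
  a 3-point window across scales before forming
  `|S(Wx Wy*)|^2 / (S|Wx|^2 S|Wy|^2)`, which Cauchy-Schwarz bounds to
  [0, 1]. Phase is the argument of the smoothed cross-spectrum.
  32 logarithmic scales spanning 1 Hz to 0.9 x Nyquist by default.

## Synthetic data generator

Clean activity per band is Gaussian noise spectrally masked to the band
interval and scaled so that ~3 sigma matches an amplitude drawn
uniformly from the clinical range (delta 20-200 uV, theta 20-100,
alpha 20-60, beta 2-20, gamma 3-5). Both channels share this source
plus an independent broadband jitter floor at 10% relative RMS —
mimicking a frontal pair, which is strongly correlated but not
identical. Defaults: 60 s, artifacts on half the seconds, one channel
per event, artifact energy 10x the clean energy of that second, seed 0.

Contamination archetypes: `emg_burst` (20-64 Hz noise), `spike` (three
isolated deflections), `drift` (sub-0.5 Hz oscillation plus ramp),
`device_pulses` (8/s pulse train), `error_burst` (10-64 saturated
samples, which the burst rule should remove rather than vote on).

What the generator does *not* emulate: nonstationary anesthesia
dynamics (burst suppression, spectral drift with drug levels),
electrode impedance drift, and correlated two-channel artifacts. A
green recovery test therefore establishes that asymmetric, strong
(10x) contamination is attributed to the right channel — not clinical
performance on real recordings.

## Known limitations

* **Single-band contamination dilutes the vote.** A drift artifact
  lives almost entirely in the delta band; the other four bands then
  compare only the channels' independent jitter, and each criterion's
  5-band majority needs two of those four coin flips. Across seeds the
  recovery score on drift-heavy schedules occasionally dips to ~0.85-
  0.93 while wideband artifacts (EMG, pulses) recover at ~1.0. This is
  a property of the equal-weight band majority, not of the
  implementation.
* Saturating artifacts (spikes at 10x energy) frequently trip the
  error-burst rule, so those seconds are removed rather than decided;
  the recovery score excludes them since no selection exists.
* The combinational signal concatenates retained seconds; removed
  epochs are recorded in the source map but not gap-marked in the
  sample stream.
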