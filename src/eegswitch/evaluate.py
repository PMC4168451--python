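"""Assessment instruments for the combinational signal.

Three complementary views are used to check that the switched output
stays faithful to the channel it was drawn from:

* **Per-second PSD** — each second is mean-removed and Fourier
  transformed; a clean switch leaves the per-second power distribution
  of the winning channel intact.
* **Double-sided CCF side difference** — the normalized cross-
  correlation over lags ``-(n-1) .. n-1`` is split at lag 0; for a
  signal against itself the two sides average to exactly the same
  value, so the absolute difference of the side means measures how far
  a pair is from the self-correlated ideal.
* **Wavelet coherence** — a Morlet continuous-wavelet cross-spectrum,
  smoothed in time and scale, giving a (scale, time) map of coherence
  modulus in [0, 1] and relative phase.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as sps

from eegswitch.switch import CombinationalSignal


# --- per-second power spectral density -------------------------------------

def psd_per_second(series: np.ndarray, sampling_rate: float = 128.0):
    """One-sided PSD of every full second of ``series``.

    Each second is normalized by subtracting its own mean, then the FFT
    is taken and scaled to power density (1 / (N * Fs), one-sided with
    interior bins doubled).  Returns ``(freqs, psd)`` where ``psd`` has
    one row per full second; a trailing partial second is dropped.
    """
    x = np.asarray(series, dtype=float)
    n = int(sampling_rate)
    n_epochs = x.size // n
    if n_epochs == 0:
        raise ValueError("need at least one full second of signal")
    frames = x[: n_epochs * n].reshape(n_epochs, n)
    frames = frames - frames.mean(axis=1, keepdims=True)
    spec = np.fft.rfft(frames, axis=1)
    psd = (np.abs(spec) ** 2) / (n * sampling_rate)
    psd[:, 1:-1] *= 2.0  # one-sided: fold negative frequencies
    if n % 2:  # odd frame length: no bin exactly at Nyquist
        psd[:, -1] *= 2.0
    freqs = np.fft.rfftfreq(n, d=1.0 / sampling_rate)
    return freqs, psd


# --- double-sided cross-correlation ----------------------------------------

@dataclass
class CcfResult:
    """Normalized double-sided cross-correlation and its side statistic."""

    lags: np.ndarray
    values: np.ndarray
    side_difference: float

    @property
    def zero_lag(self) -> float:
        return float(self.values[self.lags == 0][0])


def ccf_double_sided(x: np.ndarray, y: np.ndarray) -> CcfResult:
    """Correlation-coefficient-normalized CCF over lags ``-(n-1)..(n-1)``.

    ``r[k] = sum_t (x_t - mx)(y_{t+k} - my) / (n * sx * sy)`` so that a
    signal against itself has ``r[0] = 1``.  The side difference is
    ``|mean(r[k<0]) - mean(r[k>0])|`` (lag 0 excluded), which is exactly
    zero for any self-comparison because the autocorrelation is even.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length (truncate first)")
    if x.size < 2:
        raise ValueError("need at least two samples")
    n = x.size
    xc = x - x.mean()
    yc = y - y.mean()
    sx = xc.std(ddof=0)
    sy = yc.std(ddof=0)
    denom = n * sx * sy
    if denom == 0:
        raise ValueError("zero-variance series has no normalized CCF")
    # correlate(yc, xc) index k holds sum_t xc[t] * yc[t + k - (n-1)]
    values = sps.correlate(yc, xc, mode="full", method="auto") / denom
    lags = np.arange(-(n - 1), n)
    left = values[lags < 0].mean()
    right = values[lags > 0].mean()
    return CcfResult(lags=lags, values=values,
                     side_difference=float(abs(left - right)))


def ccf_report(ch1: np.ndarray, ch2: np.ndarray,
               comb: CombinationalSignal) -> pd.DataFrame:
    """One-row summary table for a processed recording.

    Columns: per-channel counts of seconds used in the combinational
    signal, and the CCF side difference of each input channel against
    the combinational output.  Channel series longer than the output
    (e.g. removed epochs were skipped) are truncated to the compared
    length.
    """
    out = np.asarray(comb.samples, dtype=float)
    n = out.size
    rows = {
        "ch1_seconds": int((comb.source_channels == 1).sum()),
        "ch2_seconds": int((comb.source_channels == 2).sum()),
        "ccf_side_diff_ch1": ccf_double_sided(
            np.asarray(ch1, dtype=float)[:n], out).side_difference,
        "ccf_side_diff_ch2": ccf_double_sided(
            np.asarray(ch2, dtype=float)[:n], out).side_difference,
    }
    return pd.DataFrame([rows])


# --- wavelet coherence ------------------------------------------------------

@dataclass
class CoherenceMap:
    """Magnitude-squared wavelet coherence and relative phase over
    (scale, time).  ``frequencies`` gives the pseudo-frequency of each
    scale row."""

    scales: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    modulus: np.ndarray  # (n_scales, n_times), in [0, 1]
    phase: np.ndarray  # radians, (-pi, pi]


def _morlet_cwt(x: np.ndarray, scales: np.ndarray, dt: float,
                omega0: float = 6.0) -> np.ndarray:
    """Continuous wavelet transform with the analytic Morlet wavelet,
    evaluated scale-by-scale in the frequency domain."""
    n = x.size
    npad = int(2 ** np.ceil(np.log2(n)))  # zero-pad to soften wrap-around
    xh = np.fft.fft(x, npad)
    ang = 2.0 * np.pi * np.fft.fftfreq(npad, d=dt)
    out = np.empty((scales.size, n), dtype=complex)
    norm_const = np.pi ** -0.25
    for i, s in enumerate(scales):
        # analytic Morlet in the frequency domain, positive freqs only
        arg = s * ang - omega0
        psi_hat = norm_const * np.sqrt(2.0 * np.pi * s / dt) * \
            np.exp(-0.5 * arg ** 2) * (ang > 0)
        out[i] = np.fft.ifft(xh * psi_hat)[:n]
    return out


def _smooth_time(w: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    """Boxcar smoothing along time with window length proportional to
    scale (the decorrelation length of the Morlet wavelet)."""
    out = np.empty_like(w)
    for i, s in enumerate(scales):
        m = max(1, int(round(2 * s / dt)) | 1)  # odd window ~ 2 scales wide
        kern = np.ones(m) / m
        out[i] = np.convolve(w[i], kern, mode="same")
    return out


def _smooth_scale(w: np.ndarray) -> np.ndarray:
    """3-point moving average across adjacent scales."""
    if w.shape[0] < 3:
        return w.copy()
    out = w.copy()
    out[1:-1] = (w[:-2] + w[1:-1] + w[2:]) / 3.0
    return out


def _smooth(w: np.ndarray, scales: np.ndarray, dt: float) -> np.ndarray:
    return _smooth_scale(_smooth_time(w, scales, dt))


def wavelet_coherence(x: np.ndarray, y: np.ndarray,
                      sampling_rate: float = 128.0,
                      omega0: float = 6.0,
                      n_scales: int = 32,
                      f_min: float = 1.0,
                      f_max: float | None = None) -> CoherenceMap:
    """Morlet wavelet coherence between two equal-length series.

    The cross-spectrum ``Wx * conj(Wy)`` and both auto-spectra are
    smoothed over time (scale-proportional boxcar) and scale (3-point);
    modulus is the smoothed magnitude-squared coherence, bounded in
    [0, 1] by Cauchy-Schwarz, and phase is the argument of the smoothed
    cross-spectrum.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("series must have equal length")
    if x.size < 128:
        raise ValueError("need at least 128 samples")
    dt = 1.0 / sampling_rate
    if f_max is None:
        f_max = sampling_rate / 2.0 * 0.9
    # Morlet scale <-> pseudo-frequency: f = (omega0 + sqrt(2+omega0^2)) / (4 pi s)
    fourier_factor = (4.0 * np.pi) / (omega0 + np.sqrt(2.0 + omega0 ** 2))
    freqs = np.geomspace(f_max, f_min, n_scales)
    scales = 1.0 / (fourier_factor * freqs)
    wx = _morlet_cwt(x - x.mean(), scales, dt, omega0)
    wy = _morlet_cwt(y - y.mean(), scales, dt, omega0)
    inv_s = (1.0 / scales)[:, None]
    sxy = _smooth(wx * np.conj(wy) * inv_s, scales, dt)
    sxx = _smooth((np.abs(wx) ** 2) * inv_s, scales, dt).real
    syy = _smooth((np.abs(wy) ** 2) * inv_s, scales, dt).real
    denom = sxx * syy
    with np.errstate(invalid="ignore", divide="ignore"):
        modulus = np.where(denom > 0, (np.abs(sxy) ** 2) / denom, 0.0)
    modulus = np.clip(modulus, 0.0, 1.0)
    phase = np.angle(sxy)
    times = np.arange(x.size) * dt
    return CoherenceMap(scales=scales, frequencies=freqs, times=times,
                        modulus=modulus, phase=phase)


def coherence_at_frequency(cmap: CoherenceMap, freq: float):
    """Rows of the modulus/phase maps at the scale closest to ``freq``."""
    i = int(np.argmin(np.abs(cmap.frequencies - freq)))
    return cmap.modulus[i], cmap.phase[i]
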