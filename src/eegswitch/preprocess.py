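"""The filtering stage: error correction, mains notch + band-pass,
wavelet denoising and Savitzky-Golay smoothing.

The recording is first cut into non-overlapping one-second epochs (128
samples at the recorder's rate).  Error samples — amplitudes no scalp
EEG can produce, or ADC saturation — are counted per epoch and channel:
a few sporadic errors are repaired by previous-sample hold, while a
burst (more than ``error_burst_count`` in a second) removes the whole
epoch from both channels, since the underlying EEG is unrecoverable.
The retained samples then pass, per channel, through a zero-phase mains
notch, a zero-phase Butterworth band-pass, db4 wavelet denoising with
the universal threshold, and a Savitzky-Golay polynomial smoother.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy import signal

from eegswitch.decompose import WaveletSpec, wavedec, waverec
from eegswitch.rawio import RawRecording, to_microvolts, INT16_MIN, INT16_MAX


@dataclass
class FilterConfig:
    """Parameters of the four filtering sub-stages.

    Notes on defaults: physiological scalp EEG stays well below
    +/-200 uV, so ``error_abs_limit=400`` uV flags only non-physiologic
    excursions; ``sg_order=17`` / ``sg_frame=33`` balance smoothing
    against waveform fidelity; the band-pass upper edge is capped just
    below the 64 Hz Nyquist frequency of the 128 samples/s recorder.
    """

    mains_freq: float = 50.0
    notch_q: float = 30.0
    bp_low: float = 0.1
    bp_high: float = 63.5
    bp_order: int = 4
    sg_order: int = 17
    sg_frame: int = 33
    denoise_wavelet: str = "db4"
    denoise_level: int = 4
    denoise_threshold_rule: str = "universal"
    # "hard" zeroes sub-threshold coefficients and leaves the rest
    # untouched; "soft" additionally shrinks survivors, which biases
    # genuine EEG amplitudes downward
    denoise_mode: str = "hard"
    error_abs_limit: float = 400.0  # uV
    error_burst_count: int = 5  # errors/second tolerated before removal
    error_correction: str = "hold"  # or "interpolate"

    def __post_init__(self) -> None:
        if self.sg_order >= self.sg_frame:
            raise ValueError("sg_order must be strictly less than sg_frame")
        if self.sg_frame % 2 == 0:
            raise ValueError("sg_frame must be odd")
        if not 0 < self.bp_low < self.bp_high:
            raise ValueError("need 0 < bp_low < bp_high")
        if self.denoise_mode not in ("soft", "hard"):
            raise ValueError("denoise_mode must be 'soft' or 'hard'")
        if self.denoise_threshold_rule != "universal":
            raise ValueError("only the universal threshold rule is supported")
        if self.error_correction not in ("hold", "interpolate"):
            raise ValueError("error_correction must be 'hold' or 'interpolate'")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "FilterConfig":
        return cls(**d)


@dataclass
class EpochGrid:
    """A recording cut into one-second frames, channels kept aligned.

    ``data`` has shape (n_epochs, 2, epoch_length); ``removed`` marks
    epochs dropped by the burst rule (removal always applies to both
    channels so the time axes stay synchronized).
    """

    data: np.ndarray
    removed: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.removed = np.asarray(self.removed, dtype=bool)
        if self.data.ndim != 3 or self.data.shape[1] != 2:
            raise ValueError("data must have shape (n_epochs, 2, epoch_length)")
        if self.removed.shape != (self.data.shape[0],):
            raise ValueError("removed flags must match epoch count")

    @property
    def n_epochs(self) -> int:
        return int(self.data.shape[0])

    @property
    def epoch_length(self) -> int:
        return int(self.data.shape[2])

    @property
    def retained_indices(self) -> np.ndarray:
        return np.flatnonzero(~self.removed)

    @property
    def n_retained(self) -> int:
        return int((~self.removed).sum())

    def retained_data(self) -> np.ndarray:
        """(n_retained, 2, epoch_length) view of the surviving epochs."""
        return self.data[~self.removed]

    def channel_series(self, channel: int) -> np.ndarray:
        """Retained epochs of one channel concatenated in time order."""
        return self.retained_data()[:, channel, :].reshape(-1)


def make_epoch_grid(rec: RawRecording) -> EpochGrid:
    """Cut a recording into one-second epochs of microvolt samples.

    A trailing partial second is dropped.
    """
    ch1, ch2 = to_microvolts(rec)
    n_len = int(rec.sampling_rate)
    n_epochs = ch1.size // n_len
    data = np.stack(
        [
            ch1[: n_epochs * n_len].reshape(n_epochs, n_len),
            ch2[: n_epochs * n_len].reshape(n_epochs, n_len),
        ],
        axis=1,
    )
    return EpochGrid(
        data=data,
        removed=np.zeros(n_epochs, dtype=bool),
        sampling_rate=rec.sampling_rate,
    )


def _error_mask(frame: np.ndarray, cfg: FilterConfig,
                lsb_microvolts: float) -> np.ndarray:
    sat_hi = INT16_MAX * lsb_microvolts
    sat_lo = INT16_MIN * lsb_microvolts
    return (np.abs(frame) > cfg.error_abs_limit) | (frame >= sat_hi) | (frame <= sat_lo)


def correct_errors(grid: EpochGrid, cfg: FilterConfig,
                   lsb_microvolts: float = 0.05) -> EpochGrid:
    """Repair sporadic error samples, remove error-burst epochs.

    An error sample is one whose magnitude exceeds ``error_abs_limit``
    or sits at ADC saturation.  Up to ``error_burst_count`` errors per
    epoch per channel are replaced from the preceding good samples
    (previous-sample hold by default, linear interpolation optionally);
    more than that removes the full one-second epoch from both channels.
    """
    data = grid.data.copy()
    removed = grid.removed.copy()
    for e in range(grid.n_epochs):
        if removed[e]:
            continue
        masks = [_error_mask(data[e, c], cfg, lsb_microvolts) for c in (0, 1)]
        if any(int(mk.sum()) > cfg.error_burst_count for mk in masks):
            removed[e] = True
            continue
        for c, mk in enumerate(masks):
            if mk.any():
                data[e, c] = _repair(data[e, c], mk, cfg.error_correction)
    return EpochGrid(data=data, removed=removed, sampling_rate=grid.sampling_rate)


def _repair(frame: np.ndarray, mask: np.ndarray, method: str) -> np.ndarray:
    out = frame.copy()
    good = np.flatnonzero(~mask)
    bad = np.flatnonzero(mask)
    if good.size == 0:
        return np.zeros_like(frame)
    if method == "interpolate":
        out[bad] = np.interp(bad, good, frame[good])
        return out
    for i in bad:  # previous-sample hold; leading errors take first good value
        prev = good[good < i]
        out[i] = out[prev[-1]] if prev.size else frame[good[0]]
    return out


def notch_filter(series: np.ndarray, cfg: FilterConfig,
                 sampling_rate: float = 128.0) -> np.ndarray:
    """Zero-phase IIR notch at the mains frequency."""
    if cfg.mains_freq >= sampling_rate / 2:
        raise ValueError("mains frequency must be below Nyquist")
    b, a = signal.iirnotch(cfg.mains_freq, cfg.notch_q, fs=sampling_rate)
    return signal.filtfilt(b, a, np.asarray(series, dtype=float))


def bandpass_filter(series: np.ndarray, cfg: FilterConfig,
                    sampling_rate: float = 128.0) -> np.ndarray:
    """Zero-phase Butterworth band-pass confining the signal to the EEG band.

    Realized as a high-pass at ``bp_low`` cascaded with a low-pass at
    ``bp_high`` (skipped when ``bp_high`` reaches Nyquist), which is
    numerically safer than a single band-pass with a corner almost at
    Nyquist.
    """
    nyq = sampling_rate / 2
    if not 0 < cfg.bp_low < min(cfg.bp_high, nyq + 1e-12):
        raise ValueError("invalid band edges")
    x = np.asarray(series, dtype=float)
    sos_hp = signal.butter(cfg.bp_order, cfg.bp_low, "highpass",
                           fs=sampling_rate, output="sos")
    y = signal.sosfiltfilt(sos_hp, x)
    if cfg.bp_high < nyq:
        sos_lp = signal.butter(cfg.bp_order, cfg.bp_high, "lowpass",
                               fs=sampling_rate, output="sos")
        y = signal.sosfiltfilt(sos_lp, y)
    return y


def universal_threshold(detail: np.ndarray, n: int) -> float:
    """Donoho-Johnstone universal threshold ``sigma * sqrt(2 ln n)`` with
    sigma estimated as MAD(finest details) / 0.6745."""
    sigma = float(np.median(np.abs(detail))) / 0.6745 if detail.size else 0.0
    return sigma * np.sqrt(2.0 * np.log(n)) if n > 1 else 0.0


def wavelet_denoise(series: np.ndarray, cfg: FilterConfig,
                    threshold: float | None = None) -> np.ndarray:
    """db4 wavelet shrinkage: decompose, zero/shrink small detail
    coefficients, reconstruct.

    The threshold follows the universal rule with the noise scale taken
    from the finest detail level (or is supplied explicitly via
    ``threshold``, e.g. a value pooled across channels so both channels
    of a recording are shrunk identically); approximation coefficients
    are left untouched.  Output length equals input length.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 2 ** cfg.denoise_level:
        raise ValueError("series shorter than one decomposition support")
    order = int(cfg.denoise_wavelet[2:])
    spec = WaveletSpec(mother=f"db{order}", level=cfg.denoise_level,
                       mode="symmetric")
    coeffs, lengths = wavedec(x, spec)
    thr = (universal_threshold(coeffs[-1], x.size)
           if threshold is None else float(threshold))
    new = [coeffs[0]]
    for d in coeffs[1:]:
        if cfg.denoise_mode == "soft":
            new.append(np.sign(d) * np.maximum(np.abs(d) - thr, 0.0))
        else:
            new.append(np.where(np.abs(d) > thr, d, 0.0))
    return waverec(new, spec, lengths)


def _sg_kernel(frame: int, order: int) -> np.ndarray:
    """Savitzky-Golay convolution kernel via an orthogonal-basis
    least-squares projection.

    The textbook monomial formulation (and scipy's ``savgol_coeffs``)
    breaks down numerically for high polynomial orders — at order 17,
    window 33 the monomial Vandermonde is so ill-conditioned the
    returned kernel is effectively zero.  Building the projection from
    a QR-orthogonalized Legendre basis on [-1, 1] is exact in the same
    least-squares sense and stays well-conditioned.
    """
    xs = np.linspace(-1.0, 1.0, frame)
    v = np.polynomial.legendre.legvander(xs, order)
    q, _ = np.linalg.qr(v)
    return q @ q[frame // 2]  # center row of the projection matrix


def sg_smooth(series: np.ndarray, cfg: FilterConfig) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoothing.

    Interior samples are the moving polynomial fit evaluated at the
    window center; the first and last half-windows evaluate the fit to
    the first/last full frame (the same convention scipy uses), so a
    global polynomial of degree <= ``sg_order`` passes through
    unchanged everywhere.
    """
    x = np.asarray(series, dtype=float)
    frame, order = cfg.sg_frame, cfg.sg_order
    if x.size < frame:
        raise ValueError("series shorter than the smoothing frame")
    w = _sg_kernel(frame, order)
    half = frame // 2
    y = np.convolve(x, w[::-1], mode="same")
    xs = np.linspace(-1.0, 1.0, frame)
    v = np.polynomial.legendre.legvander(xs, order)
    coef_head, *_ = np.linalg.lstsq(v, x[:frame], rcond=None)
    y[:half] = v[:half] @ coef_head
    coef_tail, *_ = np.linalg.lstsq(v, x[-frame:], rcond=None)
    y[-half:] = v[half + 1:] @ coef_tail
    return y


def run_filter_chain(rec: RawRecording,
                     cfg: FilterConfig | None = None) -> EpochGrid:
    """Apply the full filtering stage and return the filtered epoch grid.

    Order: epoching -> error correction / burst removal -> mains notch +
    band-pass -> wavelet denoising -> Savitzky-Golay smoothing.  The
    continuous filters run on the retained samples of each channel as
    one series, then the result is re-cut into the surviving epochs.

    The denoising threshold is pooled across the two channels (noise
    scale from the concatenated finest-detail coefficients): the
    recorder noise floor is common to both electrodes, and a shared
    threshold shrinks both channels identically so the downstream
    minimum-absolute-value comparison stays unbiased.
    """
    if cfg is None:
        cfg = FilterConfig()
    grid = make_epoch_grid(rec)
    grid = correct_errors(grid, cfg, lsb_microvolts=rec.lsb_microvolts)
    if grid.n_retained == 0:
        return grid
    keep = ~grid.removed
    out = grid.data.copy()
    filtered = []
    for c in (0, 1):
        series = grid.data[keep, c, :].reshape(-1)
        series = notch_filter(series, cfg, rec.sampling_rate)
        series = bandpass_filter(series, cfg, rec.sampling_rate)
        filtered.append(series)
    thr = _pooled_threshold(filtered, cfg)
    for c in (0, 1):
        series = wavelet_denoise(filtered[c], cfg, threshold=thr)
        if series.size >= cfg.sg_frame:
            series = sg_smooth(series, cfg)
        out[keep, c, :] = series.reshape(-1, grid.epoch_length)
    return EpochGrid(data=out, removed=grid.removed,
                     sampling_rate=grid.sampling_rate)


def _pooled_threshold(channels: list[np.ndarray], cfg: FilterConfig) -> float:
    order = int(cfg.denoise_wavelet[2:])
    spec = WaveletSpec(mother=f"db{order}", level=cfg.denoise_level,
                       mode="symmetric")
    finest = np.concatenate([wavedec(ch, spec)[0][-1] for ch in channels])
    n = max(ch.size for ch in channels)
    return universal_threshold(finest, n)
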