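"""Level-4 db4 discrete wavelet decomposition of one-second EEG frames.

Each 128-sample frame is split by the classic two-channel filter-bank
cascade (low-pass -> approximation, high-pass -> detail, downsample by 2
at every level) into five coefficient sets whose dyadic frequency
intervals line up with the clinical EEG rhythms at 128 samples/s:

====== ======= ===============
band   rhythm  interval (Hz)
====== ======= ===============
ca4    delta   0 - 4
cd4    theta   4 - 8
cd3    alpha   8 - 16
cd2    beta    16 - 32
cd1    gamma   32 - 64
====== ======= ===============

Two boundary-extension modes are provided.  ``"periodization"`` (the
default for frame analysis) treats the frame as circular: the transform
is then exactly orthogonal, so reconstruction is perfect and coefficient
energy equals frame energy to machine precision.  ``"symmetric"``
(half-point reflection) avoids wrap-around leakage for non-periodic
series at the price of redundant boundary coefficients; it is the mode
used for wavelet denoising of long series.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import comb

BAND_ORDER = ("ca4", "cd4", "cd3", "cd2", "cd1")
BAND_RHYTHMS = {
    "ca4": "Delta",
    "cd4": "Theta",
    "cd3": "Alpha",
    "cd2": "Beta",
    "cd1": "Gamma",
}


@lru_cache(maxsize=None)
def daubechies_scaling_filter(order: int) -> np.ndarray:
    """Orthonormal Daubechies scaling (low-pass) filter with ``order``
    vanishing moments (``order=4`` is the db4 filter, 8 taps).

    Built by spectral factorization of the Daubechies half-band
    polynomial: the binomial polynomial ``P(y) = sum C(p-1+k, k) y^k``
    is factored and, for each root, the stable zero (inside the unit
    circle) of ``z^2 - (2 - 4y)z + 1`` is kept, yielding the
    minimum-phase factor.  Normalized so the taps sum to ``sqrt(2)``.
    """
    p = int(order)
    if p < 1:
        raise ValueError("order must be >= 1")
    if p == 1:  # Haar
        return np.array([1.0, 1.0]) / np.sqrt(2.0)
    k = np.arange(p)
    bino = comb(p - 1 + k, k)  # coefficients of y^k, ascending
    yroots = np.roots(bino[::-1])
    poly = np.array([1.0 + 0j])
    for _ in range(p):  # ((1 + z) / 2)^p factor
        poly = np.convolve(poly, [0.5, 0.5])
    for y in yroots:
        zpair = np.roots([1.0, -(2.0 - 4.0 * y), 1.0])
        z = zpair[np.argmin(np.abs(zpair))]
        poly = np.convolve(poly, [1.0, -z]) / (1.0 - z)
    h = np.real(poly)
    return h * (np.sqrt(2.0) / h.sum())


def quadrature_mirror(h: np.ndarray) -> np.ndarray:
    """High-pass filter paired with scaling filter ``h`` (alternating-sign
    reversal), completing the orthogonal two-channel bank."""
    g = h[::-1].copy()
    g[1::2] *= -1.0
    return g


@dataclass(frozen=True)
class WaveletSpec:
    """Mother wavelet and decomposition depth.

    ``mother`` accepts ``"dbN"`` names; ``level`` is the number of
    cascade stages (each one halves the analysed band).
    """

    mother: str = "db4"
    level: int = 4
    mode: str = "periodization"

    def __post_init__(self) -> None:
        if not self.mother.startswith("db"):
            raise ValueError(f"unsupported mother wavelet: {self.mother!r}")
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.mode not in ("periodization", "symmetric"):
            raise ValueError(f"unknown extension mode: {self.mode!r}")

    @property
    def order(self) -> int:
        return int(self.mother[2:])

    @property
    def lowpass(self) -> np.ndarray:
        return daubechies_scaling_filter(self.order)

    @property
    def highpass(self) -> np.ndarray:
        return quadrature_mirror(self.lowpass)


@dataclass
class SubbandSet:
    """Coefficients of one decomposed frame: approximation ``ca`` at the
    deepest level plus details ``cd`` ordered deepest-first
    (cd4, cd3, cd2, cd1 for a level-4 transform)."""

    ca: np.ndarray
    cd: list[np.ndarray]
    level: int
    frame_length: int
    mode: str = "periodization"

    def band(self, label: str) -> np.ndarray:
        """Coefficients for a band label such as ``"ca4"`` or ``"cd2"``."""
        kind, j = label[:2], int(label[2:])
        if kind == "ca":
            if j != self.level:
                raise KeyError(label)
            return self.ca
        if kind == "cd" and 1 <= j <= self.level:
            return self.cd[self.level - j]
        raise KeyError(label)

    @property
    def band_labels(self) -> tuple[str, ...]:
        return (f"ca{self.level}",) + tuple(
            f"cd{j}" for j in range(self.level, 0, -1)
        )

    def band_energy(self, label: str) -> float:
        c = self.band(label)
        return float(np.dot(c, c))


# --- single-level analysis / synthesis -------------------------------------

def _dwt_per(x: np.ndarray, h: np.ndarray, g: np.ndarray):
    n = x.size
    if n % 2:
        raise ValueError("periodized transform needs an even length")
    L = h.size
    idx = (np.arange(L)[None, :] + 2 * np.arange(n // 2)[:, None]) % n
    xw = x[idx]
    return xw @ h, xw @ g


def _idwt_per(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray):
    n = 2 * a.size
    L = h.size
    idx = (np.arange(L)[None, :] + 2 * np.arange(n // 2)[:, None]) % n
    x = np.zeros(n)
    np.add.at(x, idx, np.outer(a, h) + np.outer(d, g))
    return x


def _extend_sym(x: np.ndarray, p: int) -> np.ndarray:
    # half-point symmetric: ... x1 x0 | x0 x1 ... xn-1 | xn-1 xn-2 ...
    if p > x.size:  # tile reflections for very short inputs
        reps = int(np.ceil(p / x.size)) + 1
        tiles = [x if i % 2 == 0 else x[::-1] for i in range(reps)]
        left = np.concatenate([t for t in reversed(tiles)])[-p:]
        right = np.concatenate([t[::-1] for t in tiles])[:p]
        return np.concatenate([left, x, right])
    return np.concatenate([x[:p][::-1], x, x[-p:][::-1]])


def _dwt_sym(x: np.ndarray, h: np.ndarray, g: np.ndarray):
    L = h.size
    xe = _extend_sym(x, L - 1)
    a = np.convolve(xe, h[::-1], mode="valid")[1::2]
    d = np.convolve(xe, g[::-1], mode="valid")[1::2]
    return a, d


def _idwt_sym(a: np.ndarray, d: np.ndarray, h: np.ndarray, g: np.ndarray,
              out_len: int):
    L = h.size
    up_a = np.zeros(2 * a.size)
    up_a[::2] = a
    up_d = np.zeros(2 * d.size)
    up_d[::2] = d
    x = np.convolve(up_a, h, mode="full") + np.convolve(up_d, g, mode="full")
    start = L - 2
    return x[start:start + out_len]


def dwt_single(x: np.ndarray, spec: WaveletSpec):
    """One analysis stage: returns (approximation, detail)."""
    h, g = spec.lowpass, spec.highpass
    if spec.mode == "periodization":
        return _dwt_per(x, h, g)
    return _dwt_sym(x, h, g)


def idwt_single(a: np.ndarray, d: np.ndarray, spec: WaveletSpec,
                out_len: int | None = None):
    """One synthesis stage, inverse of :func:`dwt_single`."""
    h, g = spec.lowpass, spec.highpass
    if spec.mode == "periodization":
        return _idwt_per(a, d, h, g)
    if out_len is None:
        out_len = 2 * a.size - h.size + 2
    return _idwt_sym(a, d, h, g, out_len)


# --- multi-level ------------------------------------------------------------

def wavedec(x: np.ndarray, spec: WaveletSpec):
    """Multilevel analysis.  Returns ``[ca_N, cd_N, ..., cd_1]`` plus the
    per-level input lengths needed to invert a symmetric-mode transform."""
    x = np.asarray(x, dtype=float)
    if 2 ** spec.level > x.size:
        raise ValueError(
            f"series of length {x.size} too short for level {spec.level}"
        )
    details: list[np.ndarray] = []
    lengths: list[int] = []
    a = x
    for _ in range(spec.level):
        lengths.append(a.size)
        if spec.mode == "periodization" and a.size % 2:
            raise ValueError("periodization needs even length at every level")
        a, d = dwt_single(a, spec)
        details.append(d)
    return [a] + details[::-1], lengths


def waverec(coeffs: list[np.ndarray], spec: WaveletSpec,
            lengths: list[int] | None = None) -> np.ndarray:
    """Invert :func:`wavedec`."""
    a = coeffs[0]
    n_levels = len(coeffs) - 1
    for i, d in enumerate(coeffs[1:]):
        out_len = None
        if lengths is not None:
            out_len = lengths[n_levels - 1 - i]
        if a.size != d.size:  # defensive: symmetric-mode off-by-one
            m = min(a.size, d.size)
            a, d = a[:m], d[:m]
        a = idwt_single(a, d, spec, out_len=out_len)
    return a


def dwt_frame(frame: np.ndarray, spec: WaveletSpec | None = None) -> SubbandSet:
    """Decompose one one-second frame into its five sub-bands.

    The frame length must be a multiple of ``2**level`` (128 samples at
    the default level 4).
    """
    if spec is None:
        spec = WaveletSpec()
    frame = np.asarray(frame, dtype=float)
    if frame.ndim != 1:
        raise ValueError("frame must be 1-D")
    if spec.mode == "periodization" and frame.size % (2 ** spec.level):
        raise ValueError(
            f"frame length {frame.size} is not a multiple of 2^{spec.level}"
        )
    coeffs, _ = wavedec(frame, spec)
    return SubbandSet(
        ca=coeffs[0],
        cd=coeffs[1:],
        level=spec.level,
        frame_length=frame.size,
        mode=spec.mode,
    )


def idwt_frame(bands: SubbandSet, spec: WaveletSpec | None = None) -> np.ndarray:
    """Reconstruct a frame from its sub-band coefficients."""
    if spec is None:
        spec = WaveletSpec(mode=bands.mode)
    if spec.level != bands.level:
        raise ValueError("spec level does not match coefficient set")
    sizes = [c.size for c in bands.cd]
    if spec.mode == "periodization":
        expected = [bands.frame_length // 2 ** j
                    for j in range(bands.level, 0, -1)]
        if bands.ca.size != expected[0] or sizes != expected:
            raise ValueError("coefficient shapes inconsistent with frame length")
    lengths = None
    if spec.mode == "symmetric":
        L = spec.lowpass.size
        lengths = []
        n = bands.frame_length
        for _ in range(spec.level):
            lengths.append(n)
            n = (n + L - 1) // 2
    return waverec([bands.ca] + list(bands.cd), spec, lengths=lengths)


def subband_frequency_map(sampling_rate: float = 128.0,
                          level: int = 4) -> dict[str, tuple[float, float]]:
    """Dyadic frequency interval of each sub-band.

    The approximation covers ``(0, Fs / 2**(N+1))``; detail ``j`` covers
    ``(Fs / 2**(j+1), Fs / 2**j)``.
    """
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    if level < 1:
        raise ValueError("level must be >= 1")
    out = {f"ca{level}": (0.0, sampling_rate / 2 ** (level + 1))}
    for j in range(level, 0, -1):
        out[f"cd{j}"] = (sampling_rate / 2 ** (j + 1), sampling_rate / 2 ** j)
    return out
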