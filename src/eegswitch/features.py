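"""Per-sub-band criteria: mean, energy, Shannon entropy, standard deviation.

Every retained one-second epoch of each channel is decomposed into its
five wavelet sub-bands, and each coefficient vector is summarised by the
four criteria.  A noisy channel inflates the magnitude of all four, so
the downstream comparison always favours the channel whose criterion has
the smaller absolute value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eegswitch.decompose import BAND_ORDER, WaveletSpec, dwt_frame
from eegswitch.preprocess import EpochGrid

CRITERIA = ("mean", "energy", "entropy", "std")


def crit_mean(coeffs: np.ndarray) -> float:
    """Arithmetic mean of the coefficients."""
    c = _as_vector(coeffs)
    return float(c.mean())


def crit_energy(coeffs: np.ndarray) -> float:
    """Sum of squared coefficients."""
    c = _as_vector(coeffs)
    return float(np.dot(c, c))


def crit_entropy(coeffs: np.ndarray, variant: str = "nonnorm") -> float:
    """Shannon entropy of the squared coefficients.

    ``"nonnorm"`` (default) is the un-normalized wavelet-entropy
    ``-sum c_i^2 ln(c_i^2)`` with the ``0 ln 0 := 0`` convention;
    ``"normalized"`` uses the energy distribution ``p_i = c_i^2 / E``
    and returns ``-sum p_i ln p_i``.
    """
    c = _as_vector(coeffs)
    c2 = c * c
    if variant == "nonnorm":
        nz = c2[c2 > 0]
        return float(-(nz * np.log(nz)).sum())
    if variant == "normalized":
        total = c2.sum()
        if total == 0:
            return 0.0
        p = c2[c2 > 0] / total
        return float(-(p * np.log(p)).sum())
    raise ValueError(f"unknown entropy variant: {variant!r}")


def crit_std(coeffs: np.ndarray) -> float:
    """Population standard deviation (divide by n) of the coefficients."""
    c = _as_vector(coeffs)
    return float(c.std(ddof=0))


def _as_vector(coeffs: np.ndarray) -> np.ndarray:
    c = np.asarray(coeffs, dtype=float)
    if c.size == 0:
        raise ValueError("empty coefficient vector")
    return c.ravel()


_CRIT_FUNCS = {
    "mean": crit_mean,
    "energy": crit_energy,
    "entropy": crit_entropy,
    "std": crit_std,
}


@dataclass
class SubbandFeatureTable:
    """Criterion values indexed by (epoch, channel, band, criterion).

    ``values`` has shape (n_epochs, 2, 5, 4) with bands in
    :data:`~eegswitch.decompose.BAND_ORDER` and criteria in
    :data:`CRITERIA`; ``epoch_indices`` maps rows back to original epoch
    positions (removed epochs are absent).
    """

    values: np.ndarray
    epoch_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.epoch_indices = np.asarray(self.epoch_indices, dtype=int)
        if self.values.ndim != 4 or self.values.shape[1:] != (2, 5, 4):
            raise ValueError("values must have shape (n_epochs, 2, 5, 4)")
        if self.epoch_indices.shape != (self.values.shape[0],):
            raise ValueError("epoch_indices must match epoch count")

    @property
    def n_epochs(self) -> int:
        return int(self.values.shape[0])

    def value(self, epoch: int, channel: int, band: str, criterion: str) -> float:
        return float(
            self.values[epoch, channel,
                        BAND_ORDER.index(band), CRITERIA.index(criterion)]
        )

    def to_frame(self) -> pd.DataFrame:
        """Tidy export: one row per (epoch, channel, band, criterion)."""
        e, c, b, k = np.meshgrid(
            np.arange(self.n_epochs), [1, 2], np.arange(5), np.arange(4),
            indexing="ij",
        )
        return pd.DataFrame(
            {
                "epoch": self.epoch_indices[e.ravel()],
                "channel": c.ravel(),
                "band": np.array(BAND_ORDER)[b.ravel()],
                "criterion": np.array(CRITERIA)[k.ravel()],
                "value": self.values.ravel(),
            }
        )


def frame_features(frame: np.ndarray, spec: WaveletSpec | None = None,
                   entropy_variant: str = "nonnorm") -> np.ndarray:
    """(5, 4) criterion matrix for one frame."""
    bands = dwt_frame(frame, spec)
    out = np.empty((5, 4))
    for bi, label in enumerate(BAND_ORDER):
        c = bands.band(label)
        for ki, crit in enumerate(CRITERIA):
            if crit == "entropy":
                out[bi, ki] = crit_entropy(c, entropy_variant)
            else:
                out[bi, ki] = _CRIT_FUNCS[crit](c)
    return out


def build_feature_table(grid: EpochGrid, spec: WaveletSpec | None = None,
                        entropy_variant: str = "nonnorm") -> SubbandFeatureTable:
    """Compute the full criterion table for every retained epoch of both
    channels."""
    if spec is None:
        spec = WaveletSpec()
    retained = grid.retained_indices
    values = np.empty((retained.size, 2, 5, 4))
    for row, e in enumerate(retained):
        for c in (0, 1):
            values[row, c] = frame_features(grid.data[e, c], spec,
                                            entropy_variant)
    return SubbandFeatureTable(values=values, epoch_indices=retained)
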