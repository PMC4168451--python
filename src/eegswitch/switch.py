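"""Switching stage: assemble the single-channel combinational signal.

Each retained second of the output is a verbatim copy of that second
from whichever channel won the epoch vote — no crossfade, no resampling,
no invented samples — so the spectral and correlation structure of the
chosen channel is preserved exactly.  Removed epochs are skipped and the
surviving seconds concatenated; their original indices stay available in
the source map.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eegswitch.preprocess import EpochGrid
from eegswitch.select import DecisionSeries


@dataclass
class CombinationalSignal:
    """The assembled one-channel output.

    ``samples`` holds 128 x n_retained microvolt values; ``source_map``
    records, per output second, the original epoch index and the source
    channel (1 or 2).
    """

    samples: np.ndarray
    source_epochs: np.ndarray
    source_channels: np.ndarray  # 1 or 2
    sampling_rate: float

    @property
    def n_epochs(self) -> int:
        return int(self.source_epochs.size)

    def epoch_samples(self, k: int) -> np.ndarray:
        n = int(self.sampling_rate)
        return self.samples[k * n:(k + 1) * n]

    def source_map(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"epoch": self.source_epochs, "source_channel": self.source_channels}
        )

    def boundary_jumps(self) -> np.ndarray:
        """|last sample of second k - first sample of second k+1| — a
        diagnostic for switching discontinuities."""
        n = int(self.sampling_rate)
        ends = self.samples[n - 1::n][:-1]
        starts = self.samples[n::n]
        return np.abs(ends - starts)


def build_combinational(grid: EpochGrid,
                        decisions: DecisionSeries) -> CombinationalSignal:
    """Concatenate, per retained epoch, the samples of the winning channel."""
    retained = grid.retained_indices
    if decisions.n_epochs != retained.size or not np.array_equal(
            decisions.epoch_indices, retained):
        raise ValueError("decision series does not cover the retained epochs")
    ch_idx = decisions.winner_channel_index()
    data = grid.retained_data()  # (n_retained, 2, epoch_length)
    samples = data[np.arange(retained.size), ch_idx, :].reshape(-1)
    return CombinationalSignal(
        samples=samples,
        source_epochs=retained.copy(),
        source_channels=ch_idx + 1,
        sampling_rate=grid.sampling_rate,
    )
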