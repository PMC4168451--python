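"""Per-epoch channel decision: minimum-absolute-value band comparison
followed by a cross-criterion majority vote.

For each epoch, every (band, criterion) pair is compared between the two
channels; the channel with the strictly smaller absolute value takes the
band.  Each criterion then votes for the channel that won more of the
five bands, and the epoch is assigned to the channel favoured by the
majority of the four criteria.  Ties at the final stage carry the
previous epoch's decision forward (a continuity rule that avoids
chattering switches); a tie on the very first epoch defaults to
Channel 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from eegswitch.decompose import BAND_ORDER
from eegswitch.features import CRITERIA, SubbandFeatureTable

CH1, CH2, TIE = "ch1", "ch2", "tie"


def band_winner(v1: float, v2: float) -> str:
    """Channel whose criterion value has the strictly smaller magnitude."""
    if not (np.isfinite(v1) and np.isfinite(v2)):
        raise ValueError("criterion values must be finite")
    a1, a2 = abs(v1), abs(v2)
    if a1 < a2:
        return CH1
    if a2 < a1:
        return CH2
    return TIE


def criterion_winner(band_results: list[str]) -> str:
    """Majority over the five per-band results for one criterion."""
    if len(band_results) != len(BAND_ORDER):
        raise ValueError(f"expected {len(BAND_ORDER)} band results")
    n1 = band_results.count(CH1)
    n2 = band_results.count(CH2)
    if n1 > n2:
        return CH1
    if n2 > n1:
        return CH2
    return TIE


def epoch_decision(criterion_winners: list[str],
                   prev: str | None = None) -> tuple[str, str]:
    """Final per-epoch decision from the four criterion votes.

    Returns ``(winner, tie_resolved_by)`` where ``tie_resolved_by`` is
    ``"none"`` for a clear majority, ``"carry_forward"`` when the
    previous epoch's decision broke the tie, and ``"default"`` when a
    first-epoch tie fell back to Channel 1.
    """
    if len(criterion_winners) != len(CRITERIA):
        raise ValueError(f"expected {len(CRITERIA)} criterion results")
    n1 = criterion_winners.count(CH1)
    n2 = criterion_winners.count(CH2)
    if n1 > n2:
        return CH1, "none"
    if n2 > n1:
        return CH2, "none"
    if prev in (CH1, CH2):
        return prev, "carry_forward"
    return CH1, "default"


@dataclass
class DecisionSeries:
    """Per-epoch winners with the full vote breakdown.

    All arrays are aligned with the feature table's retained epochs;
    ``epoch_indices`` maps back to positions in the original recording.
    """

    epoch_indices: np.ndarray
    winner: np.ndarray  # "ch1" | "ch2"
    criterion_winners: np.ndarray  # (n, 4) of "ch1" | "ch2" | "tie"
    band_tallies: np.ndarray  # (n, 4, 2) band wins per criterion per channel
    tie_resolved_by: np.ndarray  # "none" | "carry_forward" | "default"

    @property
    def n_epochs(self) -> int:
        return int(self.winner.size)

    def winner_channel_index(self) -> np.ndarray:
        """0 for Channel 1, 1 for Channel 2."""
        return (self.winner == CH2).astype(int)

    def counts(self) -> dict[str, int]:
        return {
            CH1: int((self.winner == CH1).sum()),
            CH2: int((self.winner == CH2).sum()),
        }

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": self.epoch_indices,
                "winner": self.winner,
                **{
                    f"{crit}_winner": self.criterion_winners[:, k]
                    for k, crit in enumerate(CRITERIA)
                },
                "tie_resolved_by": self.tie_resolved_by,
            }
        )


def decide_series(table: SubbandFeatureTable) -> DecisionSeries:
    """Run the band comparison and criterion majority over a whole table."""
    n = table.n_epochs
    winners = np.empty(n, dtype=object)
    crit_w = np.empty((n, len(CRITERIA)), dtype=object)
    tallies = np.zeros((n, len(CRITERIA), 2), dtype=int)
    tie_by = np.empty(n, dtype=object)
    prev: str | None = None
    for e in range(n):
        cw: list[str] = []
        for k in range(len(CRITERIA)):
            results = [
                band_winner(table.values[e, 0, b, k], table.values[e, 1, b, k])
                for b in range(len(BAND_ORDER))
            ]
            tallies[e, k, 0] = results.count(CH1)
            tallies[e, k, 1] = results.count(CH2)
            cw.append(criterion_winner(results))
        crit_w[e] = cw
        winners[e], tie_by[e] = epoch_decision(cw, prev)
        prev = winners[e]
    return DecisionSeries(
        epoch_indices=table.epoch_indices.copy(),
        winner=winners.astype(str),
        criterion_winners=crit_w.astype(str),
        band_tallies=tallies,
        tie_resolved_by=tie_by.astype(str),
    )
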