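"""Synthetic two-channel anesthesia-EEG with ground-truth channel quality.

The generator emulates what the selection pipeline actually faces in the
operating room: two frontal-montage channels that share the same
underlying cortical rhythms (they sit centimetres apart and reference
the same electrode) but are contaminated *asymmetrically* — surgical
tools, cautery and movement hit one electrode harder than the other at
any given moment.

Clean activity is a sum of five band-limited random-phase processes
with the standard clinical rhythm ranges: delta 0.1-4 Hz at 20-200 uV,
theta 4-8 Hz at 20-100 uV, alpha 8-16 Hz at 20-60 uV, beta 16-32 Hz at
2-20 uV and gamma 32-64 Hz at 3-5 uV.  Both channels take the shared
source plus a small independent jitter floor.  Contamination is then
injected second-by-second into exactly one scheduled channel, from five
archetypes: EMG bursts (20-64 Hz noise), isolated spikes, slow drift,
periodic device pulses and recorder error bursts (ADC saturation).  The
schedule is emitted as ground truth so decisions can be scored.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from eegswitch.rawio import (
    INT16_MAX,
    INT16_MIN,
    DEFAULT_LSB_MICROVOLTS,
    DEFAULT_SAMPLING_RATE,
    RawRecording,
)
from eegswitch.select import CH1, CH2

#: (low Hz, high Hz, min uV, max uV) for each clinical rhythm
DEFAULT_BANDS: dict[str, tuple[float, float, float, float]] = {
    "delta": (0.1, 4.0, 20.0, 200.0),
    "theta": (4.0, 8.0, 20.0, 100.0),
    "alpha": (8.0, 16.0, 20.0, 60.0),
    "beta": (16.0, 32.0, 2.0, 20.0),
    "gamma": (32.0, 64.0, 3.0, 5.0),
}

CONTAMINATION_KINDS = ("emg_burst", "spike", "drift", "device_pulses",
                      "error_burst")
BOTH = "both"


@dataclass(frozen=True)
class ContaminationEvent:
    """One scheduled second of contamination on one channel."""

    epoch: int
    channel: str  # "ch1" | "ch2" — the channel that takes the hit
    kind: str
    energy_ratio: float = 10.0  # artifact energy / clean EEG energy


@dataclass
class SynthConfig:
    """Stated world of the generator.

    ``channel_jitter`` is the RMS of each channel's independent noise
    floor relative to the shared source RMS (small, so the channels stay
    strongly correlated like a real frontal pair).  ``energy_ratio`` is
    the default artifact-to-EEG energy ratio for scheduled events —
    intraoperative artifacts bury the EEG, hence the 10x default.
    """

    duration_s: int = 60
    sampling_rate: int = DEFAULT_SAMPLING_RATE
    lsb_microvolts: float = DEFAULT_LSB_MICROVOLTS
    bands: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BANDS))
    channel_jitter: float = 0.1
    energy_ratio: float = 10.0
    contamination_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 1:
            raise ValueError("duration_s must be >= 1")
        if not 0 <= self.contamination_fraction <= 1:
            raise ValueError("contamination_fraction must be in [0, 1]")


@dataclass
class SynthGroundTruth:
    """Per-epoch label of the designed clean channel.

    ``clean_channel[k]`` is ``"both"`` for an uncontaminated second,
    otherwise the channel that did *not* receive the artifact.
    """

    clean_channel: np.ndarray  # "ch1" | "ch2" | "both"
    kind: np.ndarray  # "none" or a CONTAMINATION_KINDS entry
    energy_ratio: np.ndarray

    @property
    def n_epochs(self) -> int:
        return int(self.clean_channel.size)

    @property
    def contaminated_epochs(self) -> np.ndarray:
        return np.flatnonzero(self.clean_channel != BOTH)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "epoch": np.arange(self.n_epochs),
                "clean_channel": self.clean_channel,
                "contamination": self.kind,
                "energy_ratio": self.energy_ratio,
            }
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "SynthGroundTruth":
        df = df.sort_values("epoch")
        return cls(
            clean_channel=df["clean_channel"].to_numpy(dtype=str),
            kind=df["contamination"].to_numpy(dtype=str),
            energy_ratio=df["energy_ratio"].to_numpy(dtype=float),
        )


def _bandlimited_noise(n: int, fs: float, f_lo: float, f_hi: float,
                       rms: float, rng: np.random.Generator) -> np.ndarray:
    """Gaussian noise confined to [f_lo, f_hi] with the requested RMS,
    built by masking the spectrum of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(freqs < f_lo) | (freqs > f_hi)] = 0.0
    x = np.fft.irfft(spec, n)
    s = x.std()
    return x * (rms / s) if s > 0 else x


def generate_clean(cfg: SynthConfig,
                   rng: np.random.Generator | None = None) -> RawRecording:
    """Two channels sharing band-structured rhythms plus independent jitter.

    Per band, the amplitude (peak-to-mean envelope, approximated as
    3 sigma of the band-limited Gaussian process) is drawn uniformly in
    the configured range; all bands share phase structure between the
    channels through a common source.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    n = cfg.duration_s * cfg.sampling_rate
    fs = float(cfg.sampling_rate)
    nyq = fs / 2.0
    common = np.zeros(n)
    for f_lo, f_hi, a_lo, a_hi in cfg.bands.values():
        amp = rng.uniform(a_lo, a_hi)
        common += _bandlimited_noise(n, fs, f_lo, min(f_hi, nyq),
                                     rms=amp / 3.0, rng=rng)
    src_rms = common.std()
    channels = []
    for _ in range(2):
        jitter = _bandlimited_noise(n, fs, 0.5, min(45.0, nyq),
                                    rms=cfg.channel_jitter * src_rms, rng=rng)
        channels.append(common + jitter)
    counts = [
        np.clip(np.round(ch / cfg.lsb_microvolts), INT16_MIN, INT16_MAX)
        for ch in channels
    ]
    return RawRecording(channel1=counts[0], channel2=counts[1],
                        sampling_rate=cfg.sampling_rate,
                        lsb_microvolts=cfg.lsb_microvolts)


def make_schedule(cfg: SynthConfig,
                  rng: np.random.Generator | None = None,
                  kinds: tuple[str, ...] = ("emg_burst", "spike", "drift",
                                            "device_pulses"),
                  ) -> list[ContaminationEvent]:
    """Random per-second schedule: a ``contamination_fraction`` share of
    the seconds gets one event, on a uniformly chosen channel, of a
    uniformly chosen kind."""
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 1)
    for k in kinds:
        if k not in CONTAMINATION_KINDS:
            raise ValueError(f"unknown contamination kind: {k!r}")
    n_events = int(round(cfg.contamination_fraction * cfg.duration_s))
    epochs = rng.choice(cfg.duration_s, size=n_events, replace=False)
    return [
        ContaminationEvent(
            epoch=int(e),
            channel=CH1 if rng.random() < 0.5 else CH2,
            kind=str(rng.choice(list(kinds))),
            energy_ratio=cfg.energy_ratio,
        )
        for e in sorted(epochs)
    ]


def _artifact(kind: str, n: int, fs: float, target_energy: float,
              rng: np.random.Generator) -> np.ndarray:
    """One second of artifact with the requested total energy."""
    t = np.arange(n) / fs
    if kind == "emg_burst":
        x = _bandlimited_noise(n, fs, 20.0, min(64.0, fs / 2), rms=1.0, rng=rng)
    elif kind == "spike":
        x = np.zeros(n)
        for i in rng.choice(np.arange(4, n - 4), size=3, replace=False):
            width = int(rng.integers(2, 5))
            x[i - width:i + width] += np.hanning(2 * width) * rng.choice([-1, 1])
    elif kind == "drift":
        f = rng.uniform(0.1, 0.45)
        x = np.sin(2 * np.pi * f * t + rng.uniform(0, 2 * np.pi)) + t
    elif kind == "device_pulses":
        period = int(fs // 8)  # 8 pulses per second
        x = np.zeros(n)
        for start in range(0, n, period):
            x[start:start + 4] = [1.0, -1.0, 1.0, -1.0]
    else:
        raise ValueError(f"unknown artifact kind: {kind!r}")
    e = float(np.dot(x, x))
    return x * np.sqrt(target_energy / e) if e > 0 else x


def inject_contamination(
    rec: RawRecording,
    schedule: list[ContaminationEvent],
    cfg: SynthConfig | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[RawRecording, SynthGroundTruth]:
    """Apply the schedule to a clean recording, one channel per event.

    Artifact energy is set relative to the clean energy of the targeted
    second; ``error_burst`` instead saturates a run of samples (which
    the filtering stage is expected to remove wholesale).
    """
    if cfg is None:
        cfg = SynthConfig(duration_s=rec.n_samples // int(rec.sampling_rate),
                          sampling_rate=int(rec.sampling_rate),
                          lsb_microvolts=rec.lsb_microvolts)
    if rng is None:
        rng = np.random.default_rng(cfg.seed + 2)
    n = int(rec.sampling_rate)
    n_epochs = rec.n_samples // n
    counts = [rec.channel1.astype(float).copy(),
              rec.channel2.astype(float).copy()]
    clean = np.full(n_epochs, BOTH, dtype=object)
    kind_arr = np.full(n_epochs, "none", dtype=object)
    ratio_arr = np.zeros(n_epochs)
    for ev in schedule:
        if not 0 <= ev.epoch < n_epochs:
            raise ValueError(f"event epoch {ev.epoch} outside recording")
        ci = 0 if ev.channel == CH1 else 1
        sl = slice(ev.epoch * n, (ev.epoch + 1) * n)
        if ev.kind == "error_burst":
            n_bad = int(rng.integers(10, n // 2))
            pos = rng.choice(n, size=n_bad, replace=False)
            seg = counts[ci][sl]
            seg[pos] = rng.choice([INT16_MIN, INT16_MAX], size=n_bad)
            counts[ci][sl] = seg
        else:
            seg_uv = counts[ci][sl] * rec.lsb_microvolts
            clean_energy = float(np.dot(seg_uv, seg_uv))
            art = _artifact(ev.kind, n, float(rec.sampling_rate),
                            ev.energy_ratio * clean_energy, rng)
            counts[ci][sl] = np.clip(
                counts[ci][sl] + np.round(art / rec.lsb_microvolts),
                INT16_MIN, INT16_MAX)
        clean[ev.epoch] = CH2 if ci == 0 else CH1
        kind_arr[ev.epoch] = ev.kind
        ratio_arr[ev.epoch] = ev.energy_ratio
    out = RawRecording(channel1=counts[0], channel2=counts[1],
                       sampling_rate=rec.sampling_rate,
                       lsb_microvolts=rec.lsb_microvolts)
    truth = SynthGroundTruth(clean_channel=clean.astype(str),
                             kind=kind_arr.astype(str),
                             energy_ratio=ratio_arr)
    return out, truth


def generate_recording(
    cfg: SynthConfig | None = None,
    schedule: list[ContaminationEvent] | None = None,
) -> tuple[RawRecording, SynthGroundTruth]:
    """Convenience: clean generation plus scheduled contamination."""
    if cfg is None:
        cfg = SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    rec = generate_clean(cfg, rng)
    if schedule is None:
        schedule = make_schedule(cfg, rng)
    return inject_contamination(rec, schedule, cfg, rng)


def recovery_score(truth: SynthGroundTruth, decisions) -> float:
    """Fraction of contaminated epochs whose decision names the designed
    clean channel.

    Epochs labelled ``both`` are excluded (either answer is right);
    contaminated epochs absent from the decision series (removed by the
    burst rule) are also excluded, since no selection was made for them.
    """
    contaminated = set(truth.contaminated_epochs.tolist())
    if not contaminated:
        raise ValueError("no contaminated epochs to score")
    hits = 0
    total = 0
    for row, epoch in enumerate(decisions.epoch_indices):
        if int(epoch) in contaminated:
            total += 1
            if decisions.winner[row] == truth.clean_channel[int(epoch)]:
                hits += 1
    if total == 0:
        raise ValueError("all contaminated epochs were removed upstream")
    return hits / total
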