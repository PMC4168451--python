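"""Reader/writer for the recorder's raw binary dialect.

The depth-of-anesthesia monitor exports a headerless binary stream of
16-bit signed integers, interleaved per sample: Channel 1, Channel 2,
Channel 1, ... at 128 samples/s/channel, one count = 0.05 uV.  A plain
two-column delimited text dialect is supported as a readable fallback,
and single-channel output (the combinational signal) is written without
interleaving.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

INT16_MIN = -32768
INT16_MAX = 32767

DEFAULT_SAMPLING_RATE = 128
DEFAULT_LSB_MICROVOLTS = 0.05


class RawFormatError(ValueError):
    """Raised when a raw file violates the recorder's dialect."""


@dataclass
class RawRecording:
    """Two synchronized integer sample sequences plus scaling metadata.

    Parameters
    ----------
    channel1, channel2
        Sample counts as recorded (16-bit signed integer range).
    sampling_rate
        Samples per second per channel.
    lsb_microvolts
        Microvolts represented by one integer count.
    """

    channel1: np.ndarray
    channel2: np.ndarray
    sampling_rate: float = DEFAULT_SAMPLING_RATE
    lsb_microvolts: float = DEFAULT_LSB_MICROVOLTS

    def __post_init__(self) -> None:
        self.channel1 = np.asarray(self.channel1, dtype=np.int64)
        self.channel2 = np.asarray(self.channel2, dtype=np.int64)
        if self.channel1.shape != self.channel2.shape or self.channel1.ndim != 1:
            raise ValueError("channel1 and channel2 must be 1-D and equal length")
        for name, ch in (("channel1", self.channel1), ("channel2", self.channel2)):
            if ch.size and (ch.min() < INT16_MIN or ch.max() > INT16_MAX):
                raise ValueError(f"{name} contains samples outside int16 range")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.lsb_microvolts <= 0:
            raise ValueError("lsb_microvolts must be positive")

    @property
    def n_samples(self) -> int:
        return int(self.channel1.size)

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate


def to_microvolts(rec: RawRecording) -> tuple[np.ndarray, np.ndarray]:
    """Convert both channels from integer counts to microvolts."""
    scale = rec.lsb_microvolts
    return (rec.channel1.astype(float) * scale, rec.channel2.astype(float) * scale)


def read_raw(
    path: str | Path,
    dialect: str = "binary",
    *,
    sampling_rate: float = DEFAULT_SAMPLING_RATE,
    lsb_microvolts: float = DEFAULT_LSB_MICROVOLTS,
    byteorder: str = "little",
) -> RawRecording:
    """Read a two-channel raw recording.

    ``dialect`` is ``"binary"`` (interleaved int16 pairs, headerless) or
    ``"text"`` (two delimited integer columns, comma or whitespace,
    optional header line).
    """
    path = Path(path)
    if dialect == "binary":
        data = path.read_bytes()
        if len(data) == 0:
            raise RawFormatError(f"{path}: empty file")
        if len(data) % 2:
            raise RawFormatError(
                f"{path}: truncated sample at byte offset {len(data) - 1}"
            )
        dtype = "<i2" if byteorder == "little" else ">i2"
        samples = np.frombuffer(data, dtype=dtype)
        if samples.size % 2:
            raise RawFormatError(
                f"{path}: truncated channel pair at byte offset {(samples.size - 1) * 2}"
            )
        ch1 = samples[0::2]
        ch2 = samples[1::2]
    elif dialect == "text":
        ch1, ch2 = _read_text(path)
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return RawRecording(
        channel1=ch1,
        channel2=ch2,
        sampling_rate=sampling_rate,
        lsb_microvolts=lsb_microvolts,
    )


def _read_text(path: Path) -> tuple[np.ndarray, np.ndarray]:
    rows: list[tuple[int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            parts = line.replace(",", " ").split()
            if len(parts) != 2:
                raise RawFormatError(f"{path}:{lineno}: expected two columns")
            try:
                rows.append((int(parts[0]), int(parts[1])))
            except ValueError:
                if lineno == 1:  # optional header
                    continue
                raise RawFormatError(f"{path}:{lineno}: non-integer sample") from None
    if not rows:
        raise RawFormatError(f"{path}: no samples")
    arr = np.asarray(rows, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def write_raw(
    rec: RawRecording,
    path: str | Path,
    dialect: str = "binary",
    *,
    byteorder: str = "little",
) -> Path:
    """Write a recording; byte-exact inverse of :func:`read_raw` for binary."""
    path = Path(path)
    if dialect == "binary":
        dtype = "<i2" if byteorder == "little" else ">i2"
        interleaved = np.empty(rec.n_samples * 2, dtype=dtype)
        interleaved[0::2] = rec.channel1
        interleaved[1::2] = rec.channel2
        path.write_bytes(interleaved.tobytes())
    elif dialect == "text":
        with open(path, "w") as fh:
            for a, b in zip(rec.channel1, rec.channel2):
                fh.write(f"{a}\t{b}\n")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return path


def write_single_channel(
    samples_uv: np.ndarray,
    path: str | Path,
    dialect: str = "binary",
    *,
    lsb_microvolts: float = DEFAULT_LSB_MICROVOLTS,
    byteorder: str = "little",
) -> Path:
    """Write a single real-valued channel (microvolts), quantized to counts.

    Used for the combinational output: one channel, no interleaving, so a
    binary file of n samples is exactly 2n bytes.
    """
    path = Path(path)
    counts = np.clip(np.round(np.asarray(samples_uv, dtype=float) / lsb_microvolts),
                     INT16_MIN, INT16_MAX).astype(np.int64)
    if dialect == "binary":
        dtype = "<i2" if byteorder == "little" else ">i2"
        path.write_bytes(counts.astype(dtype).tobytes())
    elif dialect == "text":
        with open(path, "w") as fh:
            for c in counts:
                fh.write(f"{c}\n")
    else:
        raise ValueError(f"unknown dialect: {dialect!r}")
    return path
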