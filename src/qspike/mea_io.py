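"""Reading, writing and demultiplexing of multiplexed raw MEA recordings.

The on-disk dialect is deliberately open: a ``<stem>.raw`` file of
little-endian signed 16-bit samples, frame-major interleaved (one frame = one
sample per channel), plus a JSON sidecar ``<stem>.meta.json`` carrying the
acquisition parameters and the electrode layout (:class:`RecordingMeta`).
Demultiplexing splits the stream into one contiguous float64 file per channel
(``<stem>.chNN.f64``), scaled to volts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import FormatError, TruncationError

__all__ = [
    "RecordingMeta",
    "MultiplexedRecording",
    "ChannelTrace",
    "standard_8x8_layout",
    "grid_layout",
    "read_multiplexed",
    "write_multiplexed",
    "demultiplex",
    "interleave",
    "channel_trace",
    "load_channel",
    "channel_filename",
    "estimate_raw_size",
]

SAMPLE_DTYPE = np.dtype("<i2")  # 16-bit A/D counts, little-endian


def standard_8x8_layout() -> tuple[list[str], list[tuple[int, int]]]:
    """Labels and (row, col) positions of a 60-electrode 8x8 grid.

    The four corner positions of the 8x8 grid carry no electrode, which is
    the standard layout of commercial planar MEAs.  Labels follow the
    column-row naming convention (e.g. "12" = column 1, row 2).
    """
    labels: list[str] = []
    layout: list[tuple[int, int]] = []
    for col in range(1, 9):
        for row in range(1, 9):
            if (col, row) in {(1, 1), (1, 8), (8, 1), (8, 8)}:
                continue
            labels.append(f"{col}{row}")
            layout.append((row - 1, col - 1))
    return labels, layout


def grid_layout(n_channels: int) -> tuple[list[str], list[tuple[int, int]]]:
    """Generic labels/positions for arbitrary channel counts (test rigs)."""
    if n_channels == 60:
        return standard_8x8_layout()
    side = math.ceil(math.sqrt(n_channels))
    labels = [f"ch{i:02d}" for i in range(n_channels)]
    layout = [(i // side, i % side) for i in range(n_channels)]
    return labels, layout


@dataclass
class RecordingMeta:
    """Acquisition parameters and electrode layout of one recording."""

    n_channels: int
    sampling_rate_hz: float
    duration_s: float
    adc_bits: int = 16
    volts_per_count: float = 1.25e-7
    channel_labels: list[str] = field(default_factory=list)
    layout: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.channel_labels:
            self.channel_labels, self.layout = grid_layout(self.n_channels)
        self.layout = [tuple(p) for p in self.layout]
        self.validate()

    def validate(self) -> None:
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")
        n = self.duration_s * self.sampling_rate_hz
        if abs(n - round(n)) > 1e-6:
            raise ValueError(
                f"duration_s * sampling_rate_hz = {n} is not an integer sample count"
            )
        if len(self.channel_labels) != self.n_channels:
            raise ValueError("one label per channel required")
        if len(set(self.channel_labels)) != self.n_channels:
            raise ValueError("channel labels must be unique")
        if len(self.layout) != self.n_channels:
            raise ValueError("one layout position per channel required")
        if len(set(self.layout)) != self.n_channels:
            raise ValueError("layout positions must be unique")

    @property
    def n_samples_per_channel(self) -> int:
        return round(self.duration_s * self.sampling_rate_hz)

    def to_dict(self) -> dict:
        return {
            "n_channels": self.n_channels,
            "sampling_rate_hz": self.sampling_rate_hz,
            "duration_s": self.duration_s,
            "adc_bits": self.adc_bits,
            "volts_per_count": self.volts_per_count,
            "channel_labels": list(self.channel_labels),
            "layout": [list(p) for p in self.layout],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "RecordingMeta":
        return cls(
            n_channels=int(d["n_channels"]),
            sampling_rate_hz=float(d["sampling_rate_hz"]),
            duration_s=float(d["duration_s"]),
            adc_bits=int(d.get("adc_bits", 16)),
            volts_per_count=float(d.get("volts_per_count", 1.25e-7)),
            channel_labels=list(d.get("channel_labels", [])),
            layout=[tuple(p) for p in d.get("layout", [])],
        )


@dataclass
class MultiplexedRecording:
    """A raw recording still in interleaved A/D counts.

    ``samples`` has shape (n_samples_per_channel, n_channels); row-major
    memory order makes each row one interleaved frame, so ``samples.ravel()``
    is exactly the on-disk sample stream.
    """

    meta: RecordingMeta
    samples: np.ndarray

    def __post_init__(self) -> None:
        self.samples = np.ascontiguousarray(self.samples, dtype=SAMPLE_DTYPE)
        if self.samples.ndim != 2 or self.samples.shape[1] != self.meta.n_channels:
            raise ValueError("samples must have shape (n_samples, n_channels)")
        if self.samples.shape[0] != self.meta.n_samples_per_channel:
            raise ValueError(
                f"sample count {self.samples.shape[0]} does not match metadata "
                f"({self.meta.n_samples_per_channel})"
            )


@dataclass
class ChannelTrace:
    """One electrode's voltage trace, scaled to physical units."""

    channel_id: int
    label: str
    samples: np.ndarray  # volts (or microvolts downstream; see pipeline)
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("trace contains non-finite values")

    @property
    def n_samples(self) -> int:
        return self.samples.size

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate_hz

    def with_samples(self, samples: np.ndarray) -> "ChannelTrace":
        return ChannelTrace(self.channel_id, self.label, samples, self.sampling_rate_hz)


def _sidecar_path(stem: Path) -> Path:
    return stem.with_name(stem.name + ".meta.json")


def _raw_path(stem: Path) -> Path:
    return stem.with_name(stem.name + ".raw")


def write_multiplexed(rec: MultiplexedRecording, stem: Path) -> Path:
    """Write ``<stem>.raw`` + ``<stem>.meta.json``; returns the raw path."""
    stem = Path(stem)
    raw = _raw_path(stem)
    rec.samples.astype(SAMPLE_DTYPE).tofile(raw)
    _sidecar_path(stem).write_text(json.dumps(rec.meta.to_dict(), indent=1))
    return raw


def read_multiplexed(path: Path) -> MultiplexedRecording:
    """Read a multiplexed recording from ``<stem>.raw`` (+ JSON sidecar).

    ``path`` may be the stem or the ``.raw`` file itself.  Raw counts are NOT
    scaled to volts here; scaling happens at demultiplex time.
    """
    path = Path(path)
    stem = path.with_suffix("") if path.suffix == ".raw" else path
    raw, sidecar = _raw_path(stem), _sidecar_path(stem)
    if not raw.exists():
        raise FormatError(f"raw binary not found: {raw}")
    if not sidecar.exists():
        raise FormatError(f"sidecar metadata not found: {sidecar}")
    meta = RecordingMeta.from_dict(json.loads(sidecar.read_text()))
    frame_bytes = meta.n_channels * SAMPLE_DTYPE.itemsize
    size = raw.stat().st_size
    if size % frame_bytes != 0:
        raise TruncationError(
            f"{raw}: size {size} B is not a whole number of "
            f"{frame_bytes}-byte frames ({meta.n_channels} channels)"
        )
    n_frames = size // frame_bytes
    if n_frames != meta.n_samples_per_channel:
        raise FormatError(
            f"{raw}: {n_frames} frames on disk but sidecar declares "
            f"{meta.n_samples_per_channel} "
            f"({meta.duration_s} s at {meta.sampling_rate_hz} Hz)"
        )
    data = np.fromfile(raw, dtype=SAMPLE_DTYPE).reshape(n_frames, meta.n_channels)
    return MultiplexedRecording(meta=meta, samples=data)


def channel_filename(stem: str, channel_id: int) -> str:
    return f"{stem}.ch{channel_id:02d}.f64"


def channel_trace(rec: MultiplexedRecording, channel_id: int) -> ChannelTrace:
    """In-memory demultiplex of one channel, scaled to volts."""
    volts = rec.samples[:, channel_id].astype(np.float64) * rec.meta.volts_per_count
    return ChannelTrace(
        channel_id=channel_id,
        label=rec.meta.channel_labels[channel_id],
        samples=volts,
        sampling_rate_hz=rec.meta.sampling_rate_hz,
    )


def demultiplex(rec: MultiplexedRecording, out_dir: Path, stem: str = "recording") -> list[Path]:
    """Split a recording into per-channel float64 files in volts.

    File ``out_dir/<stem>.chNN.f64`` holds channel NN's samples contiguously,
    equal to the NN-th element of every frame times volts_per_count.  Naming
    is deterministic in the channel index, so re-runs overwrite in place.
    """
    out_dir = Path(out_dir)
    try:
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for c in range(rec.meta.n_channels):
            p = out_dir / channel_filename(stem, c)
            channel_trace(rec, c).samples.tofile(p)
            paths.append(p)
    except OSError as exc:  # unwritable destination
        raise OSError(f"cannot write per-channel files under {out_dir}: {exc}") from exc
    return paths


def load_channel(path: Path, meta: RecordingMeta, channel_id: int) -> ChannelTrace:
    """Load one demultiplexed channel file back into a trace (volts)."""
    samples = np.fromfile(Path(path), dtype=np.float64)
    if samples.size != meta.n_samples_per_channel:
        raise FormatError(
            f"{path}: {samples.size} samples, expected {meta.n_samples_per_channel}"
        )
    return ChannelTrace(
        channel_id=channel_id,
        label=meta.channel_labels[channel_id],
        samples=samples,
        sampling_rate_hz=meta.sampling_rate_hz,
    )


def interleave(traces: list[ChannelTrace], meta: RecordingMeta) -> MultiplexedRecording:
    """Inverse of :func:`demultiplex`: volts back to interleaved counts.

    Exact inverse: scaling by volts_per_count is a single float64 multiply,
    so dividing and rounding recovers the original 16-bit counts bitwise.
    """
    if len(traces) != meta.n_channels:
        raise ValueError("one trace per channel required")
    counts = np.empty((meta.n_samples_per_channel, meta.n_channels), dtype=SAMPLE_DTYPE)
    for t in sorted(traces, key=lambda t: t.channel_id):
        counts[:, t.channel_id] = np.rint(t.samples / meta.volts_per_count).astype(SAMPLE_DTYPE)
    return MultiplexedRecording(meta=meta, samples=counts)


def estimate_raw_size(n_channels: int, sample_bytes: int, rate_hz: float, duration_s: float) -> int:
    """Uncompressed raw data volume in bytes: channels x bytes x rate x time.

    E.g. 60 channels at 16-bit, 20 kHz, one hour -> 8.64e9 B (~8 GiB), the
    scale that motivates batch preprocessing in the first place.
    """
    for name, v in [("n_channels", n_channels), ("sample_bytes", sample_bytes),
                    ("rate_hz", rate_hz), ("duration_s", duration_s)]:
        if v <= 0:
            raise ValueError(f"{name} must be positive, got {v}")
    return round(n_channels * sample_bytes * rate_hz * duration_s)
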