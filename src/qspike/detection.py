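"""Multi-unit spike detection and elementary polarity sorting.

The noise level of a band-passed extracellular trace is estimated robustly as
sigma = median(|x|) / 0.6745 — the median absolute deviation scaled to the
standard deviation of a Gaussian — which is insensitive to the spikes
themselves.  Events are local extrema whose absolute value exceeds
k * sigma; a refractory dead time merges multi-lobed waveforms into a single
event, keeping the largest extremum.  "Elementary sorting" classifies events
only by the sign of the threshold crossing.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import ConsolidationError, DegenerateTraceError
from .mea_io import ChannelTrace

__all__ = [
    "DetectionConfig",
    "SpikeEvent",
    "SpikeTrain",
    "PolarityClass",
    "PolaritySummary",
    "estimate_threshold",
    "detect_peaks",
    "extract_waveforms",
    "sort_by_polarity",
    "consolidate_trains",
]

logger = logging.getLogger(__name__)

MAD_TO_SIGMA = 0.6745  # median(|Z|) of a standard normal


@dataclass
class DetectionConfig:
    """Detector knobs.

    k_threshold multiplies the robust sigma estimate; 5 is the conventional
    choice for multi-unit work.  dead_time_ms suppresses further events after
    an accepted one; the waveform window spans wave_pre_ms before to
    wave_post_ms after the peak.
    """

    k_threshold: float = 5.0
    dead_time_ms: float = 1.0
    wave_pre_ms: float = 1.0
    wave_post_ms: float = 2.0
    polarity_mode: str = "both"  # both | positive_only | negative_only

    def validate(self) -> None:
        if self.k_threshold <= 0:
            raise ValueError("k_threshold must be positive")
        if self.dead_time_ms < 0:
            raise ValueError("dead_time_ms must be non-negative")
        if self.wave_pre_ms <= 0 or self.wave_post_ms <= 0:
            raise ValueError("waveform window must span >= 1 sample each side")
        if self.polarity_mode not in ("both", "positive_only", "negative_only"):
            raise ValueError(f"unknown polarity_mode {self.polarity_mode!r}")


@dataclass
class SpikeEvent:
    channel_id: int
    time_s: float
    polarity: int  # +1 / -1
    peak_amplitude: float  # signed, units of the trace
    waveform: np.ndarray


@dataclass
class SpikeTrain:
    """Timestamped detections of one channel (strictly increasing times)."""

    channel_id: int
    label: str
    timestamps_s: np.ndarray
    polarities: np.ndarray
    amplitudes: np.ndarray  # signed peak values, units of the trace
    threshold: float
    sampling_rate_hz: float

    def __post_init__(self) -> None:
        self.timestamps_s = np.asarray(self.timestamps_s, dtype=float)
        self.polarities = np.asarray(self.polarities, dtype=np.int8)
        self.amplitudes = np.asarray(self.amplitudes, dtype=float)
        if not (self.timestamps_s.size == self.polarities.size == self.amplitudes.size):
            raise ValueError("timestamps, polarities and amplitudes must align")
        if self.timestamps_s.size > 1 and not np.all(np.diff(self.timestamps_s) > 0):
            raise ValueError("timestamps must be strictly increasing")

    @property
    def n_events(self) -> int:
        return self.timestamps_s.size


def estimate_threshold(trace: ChannelTrace, cfg: DetectionConfig) -> float:
    """k * median(|x|) / 0.6745 on the (filtered) trace.

    For pure Gaussian noise this converges to k * sigma; unlike the sample SD
    it barely moves when spikes are present.  A flat trace has no noise scale
    and detection refuses to run on it.
    """
    cfg.validate()
    x = trace.samples
    if x.size == 0 or np.ptp(x) == 0:
        raise DegenerateTraceError(
            f"channel {trace.channel_id} ({trace.label}): trace has no amplitude "
            "variation; threshold undefined"
        )
    thr = cfg.k_threshold * float(np.median(np.abs(x))) / MAD_TO_SIGMA
    if thr == 0.0:
        raise DegenerateTraceError(
            f"channel {trace.channel_id} ({trace.label}): median(|x|) = 0"
        )
    return thr


def _candidate_extrema(x: np.ndarray, thr: float, mode: str) -> tuple[np.ndarray, np.ndarray]:
    idx_parts = []
    if mode in ("both", "positive_only"):
        pos, _ = sps.find_peaks(x, height=thr)
        idx_parts.append(pos)
    if mode in ("both", "negative_only"):
        neg, _ = sps.find_peaks(-x, height=thr)
        idx_parts.append(neg)
    idx = np.sort(np.concatenate(idx_parts)) if idx_parts else np.empty(0, dtype=int)
    return idx, x[idx] if idx.size else np.empty(0)


def detect_peaks(trace: ChannelTrace, cfg: DetectionConfig) -> SpikeTrain:
    """Detect supra-threshold local extrema with a refractory dead time.

    Candidates are all local extrema with |value| > threshold (respecting
    polarity_mode).  The dead time is enforced amplitude-first: candidates are
    accepted in decreasing |amplitude| (ties: earlier first) provided no
    already-accepted event lies within dead_time_ms, so when two lobes of one
    waveform both cross threshold the larger one wins.
    """
    thr = estimate_threshold(trace, cfg)
    idx, vals = _candidate_extrema(trace.samples, thr, cfg.polarity_mode)
    dead = int(round(cfg.dead_time_ms * 1e-3 * trace.sampling_rate_hz))

    if idx.size and dead > 0:
        order = np.argsort(-np.abs(vals), kind="stable")  # idx pre-sorted by time
        accepted: list[int] = []
        for j in order:
            i = int(idx[j])
            p = bisect.bisect_left(accepted, i)
            if p > 0 and i - accepted[p - 1] < dead:
                continue
            if p < len(accepted) and accepted[p] - i < dead:
                continue
            accepted.insert(p, i)
        sel = np.searchsorted(idx, np.asarray(accepted, dtype=int))
        idx, vals = idx[sel], vals[sel]

    return SpikeTrain(
        channel_id=trace.channel_id,
        label=trace.label,
        timestamps_s=idx / trace.sampling_rate_hz,
        polarities=np.sign(vals).astype(np.int8) if vals.size else np.empty(0, dtype=np.int8),
        amplitudes=vals,
        threshold=thr,
        sampling_rate_hz=trace.sampling_rate_hz,
    )


def extract_waveforms(trace: ChannelTrace, train: SpikeTrain, cfg: DetectionConfig) -> list[SpikeEvent]:
    """Cut the [peak - wave_pre, peak + wave_post] window around each event.

    Events whose window would cross the recording bounds are dropped (and
    logged); all surviving waveforms share one length, pre + post + 1 samples.
    """
    cfg.validate()
    rate = trace.sampling_rate_hz
    pre = max(int(round(cfg.wave_pre_ms * 1e-3 * rate)), 1)
    post = max(int(round(cfg.wave_post_ms * 1e-3 * rate)), 1)
    events: list[SpikeEvent] = []
    n = trace.n_samples
    dropped = 0
    for t, pol, amp in zip(train.timestamps_s, train.polarities, train.amplitudes):
        i = int(round(t * rate))
        if i - pre < 0 or i + post >= n:
            dropped += 1
            continue
        events.append(
            SpikeEvent(
                channel_id=trace.channel_id,
                time_s=float(t),
                polarity=int(pol),
                peak_amplitude=float(amp),
                waveform=trace.samples[i - pre:i + post + 1].copy(),
            )
        )
    if dropped:
        logger.info(
            "channel %d: dropped %d event(s) with out-of-bounds waveform window",
            trace.channel_id, dropped,
        )
    return events


@dataclass
class PolarityClass:
    events: list[SpikeEvent]
    mean_waveform: np.ndarray | None
    sd_waveform: np.ndarray | None

    @property
    def count(self) -> int:
        return len(self.events)


@dataclass
class PolaritySummary:
    positive: PolarityClass
    negative: PolarityClass


def sort_by_polarity(events: Iterable[SpikeEvent]) -> PolaritySummary:
    """Partition events by crossing sign; per-class mean and SD waveforms.

    The partition is exhaustive and disjoint; an empty class reports count 0
    with undefined (None) mean/SD.  SD is the point-wise sample standard
    deviation (n-1 denominator; None also when a class has a single event).
    """
    pos = [e for e in events if e.polarity > 0]
    neg = [e for e in events if e.polarity < 0]

    def stats(cls: list[SpikeEvent]) -> PolarityClass:
        if not cls:
            return PolarityClass(cls, None, None)
        w = np.stack([e.waveform for e in cls])
        mean = w.mean(axis=0)
        sd = w.std(axis=0, ddof=1) if len(cls) > 1 else None
        return PolarityClass(cls, mean, sd)

    return PolaritySummary(positive=stats(pos), negative=stats(neg))


def consolidate_trains(
    trains: Mapping[int, SpikeTrain] | Sequence[SpikeTrain],
    expected_channels: Sequence[int] | None = None,
    labels: Mapping[int, str] | None = None,
) -> pd.DataFrame:
    """Merge all channels' trains into one table, sorted by time then channel.

    This is the dependency barrier of the pipeline: if ``expected_channels``
    is given and any is missing, consolidation refuses and names them.
    Columns: channel, label, time_s, polarity (+1/-1), amplitude.
    """
    if not isinstance(trains, Mapping):
        trains = {t.channel_id: t for t in trains}
    if expected_channels is not None:
        missing = sorted(set(expected_channels) - set(trains))
        if missing:
            raise ConsolidationError(
                f"cannot consolidate: missing spike trains for channel(s) {missing}"
            )
    frames = []
    for c in sorted(trains):
        t = trains[c]
        frames.append(
            pd.DataFrame(
                {
                    "channel": np.full(t.n_events, c, dtype=int),
                    "label": (labels or {}).get(c, t.label),
                    "time_s": t.timestamps_s,
                    "polarity": t.polarities.astype(int),
                    "amplitude": t.amplitudes,
                }
            )
        )
    if not frames:
        table = pd.DataFrame(columns=["channel", "label", "time_s", "polarity", "amplitude"])
    else:
        table = pd.concat(frames, ignore_index=True)
    table = table.sort_values(["time_s", "channel"], kind="stable").reset_index(drop=True)
    return table
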