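"""Spike-train statistics and network-burst analysis.

Works on the consolidated spike table (one row per detected event across all
electrodes).  Network bursts — the transient MEA-wide synchronizations that
dominate the activity of mature cultures — are found by binning the merged
spike train (default 25 ms bins), thresholding the per-bin network spike
count, merging nearby supra-threshold runs, and requiring participation of a
minimum number of distinct electrodes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .detection import SpikeTrain

__all__ = [
    "BurstConfig",
    "NetworkBurst",
    "AnalysisSummary",
    "firing_rate",
    "active_electrodes",
    "pooled_isi",
    "isi_log_bins",
    "network_spike_count",
    "detect_network_bursts",
    "burst_statistics",
    "largest_burst",
    "discharge_probability_profile",
]

DEFAULT_MIN_RATE_HZ = 0.02  # minimal occurrence frequency for an "active" electrode


@dataclass
class BurstConfig:
    """Network-burst detector parameters.

    ``count_threshold`` and ``min_channels`` default to fractions of the
    active-electrode count (resolved at run time): a bin enters a burst when
    it holds at least 0.25 x n_active network spikes (never fewer than 2),
    and a burst must recruit at least max(2, 0.2 x n_active) distinct
    electrodes.  Runs closer than ``merge_gap_ms`` are merged.
    """

    bin_ms: float = 25.0
    count_threshold: float | None = None
    min_channels: int | None = None
    merge_gap_ms: float = 100.0

    def validate(self) -> None:
        if self.bin_ms <= 0:
            raise ValueError("bin_ms must be positive")
        if self.count_threshold is not None and self.count_threshold < 1:
            raise ValueError("count_threshold must be >= 1")
        if self.min_channels is not None and self.min_channels < 1:
            raise ValueError("min_channels must be >= 1")

    def resolved(self, n_active: int) -> "BurstConfig":
        """Fill rate-dependent defaults from the active-electrode count."""
        thr = self.count_threshold if self.count_threshold is not None else max(2.0, 0.25 * n_active)
        mc = self.min_channels if self.min_channels is not None else max(2, round(0.2 * n_active))
        out = BurstConfig(self.bin_ms, float(thr), int(mc), self.merge_gap_ms)
        out.validate()
        return out


@dataclass
class NetworkBurst:
    """One MEA-wide synchronized epoch."""

    onset_s: float
    offset_s: float
    n_spikes: int
    n_channels: int
    peak_bin_count: int

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class AnalysisSummary:
    """The quantitative digest printed in the end-of-run report."""

    recording_duration_s: float
    total_samples: int
    sampling_rate_hz: float
    n_active_electrodes: int
    n_spikes: int
    n_bursts: int
    mean_burst_duration_s: float | None
    sd_burst_duration_s: float | None
    mean_ibi_s: float | None
    sd_ibi_s: float | None
    burst_threshold_used: float

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}


def firing_rate(train: SpikeTrain | np.ndarray, duration_s: float) -> float:
    """Mean rate = event count / recording duration (Hz)."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    n = train.n_events if isinstance(train, SpikeTrain) else len(train)
    return n / duration_s


def active_electrodes(
    trains: Iterable[SpikeTrain],
    duration_s: float,
    min_rate_hz: float = DEFAULT_MIN_RATE_HZ,
) -> tuple[list[int], dict[int, float]]:
    """Channels whose rate is strictly above the minimal occurrence frequency.

    Returns (active channel ids, per-channel rate map); the rates feed the
    active-electrode histogram of the report.  The boundary is strict: a
    channel at exactly min_rate_hz is not active.
    """
    rates = {t.channel_id: firing_rate(t, duration_s) for t in trains}
    active = sorted(c for c, r in rates.items() if r > min_rate_hz)
    return active, rates


def isi_log_bins(n_bins: int = 50, lo_s: float = 1e-3, hi_s: float = 100.0) -> np.ndarray:
    return np.logspace(math.log10(lo_s), math.log10(hi_s), n_bins + 1)


def pooled_isi(trains: Iterable[SpikeTrain]) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """MEA-wide interspike-interval sample and its log-spaced histogram.

    ISIs are computed within each channel, then pooled across channels (the
    merged-train alternative would conflate electrodes).  Returns
    (isis, counts, bin_edges); all empty when no channel has two spikes.
    A bimodal histogram — a fast intra-burst peak and a slow between-burst
    peak — is the signature of a bursting culture.
    """
    parts = [np.diff(t.timestamps_s) for t in trains if t.n_events >= 2]
    isis = np.concatenate(parts) if parts else np.empty(0)
    edges = isi_log_bins()
    counts, _ = np.histogram(isis, bins=edges)
    return isis, counts, edges


def network_spike_count(
    table: pd.DataFrame, bin_ms: float, duration_s: float | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """Merged spike count per time bin, half-open bins [i*bin, (i+1)*bin).

    Returns (counts, bin_edges_s); the sum of counts equals the table's row
    count (a spike exactly on an edge lands in the later bin).
    """
    if bin_ms <= 0:
        raise ValueError("bin_ms must be positive")
    bin_s = bin_ms * 1e-3
    times = table["time_s"].to_numpy(dtype=float)
    if duration_s is None:
        duration_s = float(times.max()) + bin_s if times.size else bin_s
    n_bins = max(int(math.ceil(duration_s / bin_s)), 1)
    idx = np.floor(times / bin_s).astype(int)
    idx = np.clip(idx, 0, n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    edges = np.arange(n_bins + 1) * bin_s
    return counts, edges


def detect_network_bursts(
    counts: np.ndarray,
    cfg: BurstConfig,
    table: pd.DataFrame,
) -> list[NetworkBurst]:
    """Threshold-and-merge burst detection on the network spike-count series.

    Maximal runs of bins with count >= count_threshold are merged when the
    gap between them is shorter than merge_gap_ms, then kept only if at least
    min_channels distinct electrodes fire inside the run.  Onset/offset sit
    on bin edges.  cfg must already be resolved (no None fields).
    """
    cfg.validate()
    if cfg.count_threshold is None or cfg.min_channels is None:
        raise ValueError("BurstConfig must be resolved before burst detection")
    bin_s = cfg.bin_ms * 1e-3
    hot = np.asarray(counts) >= cfg.count_threshold
    if not hot.any():
        return []
    # maximal supra-threshold runs as [start_bin, end_bin) pairs
    d = np.diff(hot.astype(np.int8), prepend=0, append=0)
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    runs: list[list[int]] = []
    gap_bins = cfg.merge_gap_ms * 1e-3 / bin_s
    for s, e in zip(starts, ends):
        if runs and (s - runs[-1][1]) < gap_bins:
            runs[-1][1] = e
        else:
            runs.append([s, e])

    times = table["time_s"].to_numpy(dtype=float)
    chans = table["channel"].to_numpy()
    order = np.argsort(times, kind="stable")
    times, chans = times[order], chans[order]

    bursts: list[NetworkBurst] = []
    for s, e in runs:
        onset, offset = s * bin_s, e * bin_s
        i0, i1 = np.searchsorted(times, [onset, offset])
        if len(np.unique(chans[i0:i1])) < cfg.min_channels:
            continue
        bursts.append(
            NetworkBurst(
                onset_s=float(onset),
                offset_s=float(offset),
                n_spikes=int(i1 - i0),
                n_channels=int(len(np.unique(chans[i0:i1]))),
                peak_bin_count=int(np.max(counts[s:e])),
            )
        )
    return bursts


def _mean_sd(x: np.ndarray) -> tuple[float | None, float | None]:
    if x.size == 0:
        return None, None
    mean = float(np.mean(x))
    sd = float(np.std(x, ddof=1)) if x.size >= 2 else None
    return mean, sd


def burst_statistics(bursts: Sequence[NetworkBurst], duration_s: float) -> dict:
    """Durations and inter-burst intervals (offset_i -> onset_{i+1}).

    Sample statistics use the n-1 denominator; with fewer than two bursts the
    SDs (and IBIs) are undefined and reported as None.
    """
    durations = np.array([b.duration_s for b in bursts])
    ibis = np.array(
        [bursts[i + 1].onset_s - bursts[i].offset_s for i in range(len(bursts) - 1)]
    )
    mean_dur, sd_dur = _mean_sd(durations)
    mean_ibi, sd_ibi = _mean_sd(ibis)
    return {
        "n_bursts": len(bursts),
        "burst_rate_hz": len(bursts) / duration_s if duration_s > 0 else None,
        "mean_burst_duration_s": mean_dur,
        "sd_burst_duration_s": sd_dur,
        "mean_ibi_s": mean_ibi,
        "sd_ibi_s": sd_ibi,
        "ibis_s": ibis,
    }


def largest_burst(
    bursts: Sequence[NetworkBurst],
    table: pd.DataFrame,
    zoom_spans_s: Sequence[float] = (20.0, 4.0, 1.0),
) -> tuple[NetworkBurst, list[tuple[float, float]]]:
    """The burst with the most spikes (ties -> earliest) plus zoom windows.

    The windows are nested intervals centered on the burst midpoint, used by
    the report to display the event at increasing temporal resolution.
    """
    if not bursts:
        raise ValueError("no bursts available")
    best = max(bursts, key=lambda b: (b.n_spikes, -b.onset_s))
    mid = 0.5 * (best.onset_s + best.offset_s)
    t_max = float(table["time_s"].max()) if len(table) else best.offset_s
    windows = []
    for span in sorted(zoom_spans_s, reverse=True):
        half = max(span, best.duration_s * 1.2) / 2.0
        windows.append((max(mid - half, 0.0), min(mid + half, t_max)))
    return best, windows


def discharge_probability_profile(
    bursts: Sequence[NetworkBurst],
    table: pd.DataFrame,
    profile_bin_ms: float = 5.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Intra-burst discharge probability vs time from burst onset.

    Spikes inside each burst are re-referenced to that burst's onset and
    histogrammed; per-burst histograms are averaged and the profile is
    normalized to sum to 1 (probability per bin).  Returns (profile, edges_s).
    """
    if not bursts:
        raise ValueError("no bursts available")
    bin_s = profile_bin_ms * 1e-3
    span = max(b.duration_s for b in bursts)
    n_bins = max(int(math.ceil(span / bin_s)), 1)
    edges = np.arange(n_bins + 1) * bin_s
    times = np.sort(table["time_s"].to_numpy(dtype=float))
    acc = np.zeros(n_bins)
    for b in bursts:
        i0, i1 = np.searchsorted(times, [b.onset_s, b.offset_s])
        h, _ = np.histogram(times[i0:i1] - b.onset_s, bins=edges)
        acc += h
    profile = acc / len(bursts)
    total = profile.sum()
    if total > 0:
        profile = profile / total
    return profile, edges
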