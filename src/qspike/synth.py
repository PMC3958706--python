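"""Synthetic MEA recordings with known ground truth.

Emulates the stereotypical spontaneous activity of a mature cortical culture
on a planar MEA: Gaussian background noise on every electrode, tonic Poisson
multi-unit spikes, and network-wide synchronized burst epochs shared across
channels.  Spike waveforms are mono-, bi- or triphasic templates scaled to a
requested peak signal-to-noise ratio.  Every draw comes from a seeded
generator, so a fixed seed reproduces the recording bitwise — which is what
makes every downstream stage testable against the returned ground truth.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mea_io import MultiplexedRecording, RecordingMeta, write_multiplexed

__all__ = [
    "SpikeTemplate",
    "GroundTruth",
    "BurstSpec",
    "make_template",
    "synthesize_mea_recording",
    "write_fixture",
]

logger = logging.getLogger(__name__)

SHAPE_KINDS = ("monophasic", "biphasic", "triphasic")


@dataclass
class SpikeTemplate:
    """A normalized extracellular spike waveform (peak |amplitude| = 1)."""

    shape_kind: str
    duration_ms: float
    samples: np.ndarray
    peak_index: int  # sample index of the dominant extremum

    @property
    def polarity(self) -> int:
        return 1 if self.samples[self.peak_index] > 0 else -1


def make_template(shape_kind: str, duration_ms: float = 1.2, rate_hz: float = 25000.0) -> SpikeTemplate:
    """Build a unit-peak spike template.

    monophasic: a single (negative) lobe.  biphasic: a dominant negative lobe
    followed by a positive rebound.  triphasic: a small leading positive lobe,
    the dominant negative lobe, then a positive rebound.  All lobes sit within
    ~0.4 ms of the dominant extremum so a 1 ms detector dead time absorbs the
    secondary lobes of one event.
    """
    if shape_kind not in SHAPE_KINDS:
        raise ValueError(f"unknown shape_kind {shape_kind!r}; expected one of {SHAPE_KINDS}")
    if not (0.5 <= duration_ms <= 3.0):
        raise ValueError("duration_ms must lie in [0.5, 3.0]")
    n = max(int(round(duration_ms * 1e-3 * rate_hz)), 7)
    t = np.linspace(0.0, 1.0, n)  # normalized time within the template
    width = 0.09

    def lobe(center: float) -> np.ndarray:
        return np.exp(-0.5 * ((t - center) / width) ** 2)

    if shape_kind == "monophasic":
        w = -lobe(0.5)
    elif shape_kind == "biphasic":
        w = -lobe(0.42) + 0.55 * lobe(0.68)
    else:  # triphasic
        w = 0.30 * lobe(0.22) - lobe(0.48) + 0.50 * lobe(0.74)
    w = w / np.max(np.abs(w))
    return SpikeTemplate(
        shape_kind=shape_kind,
        duration_ms=duration_ms,
        samples=w,
        peak_index=int(np.argmax(np.abs(w))),
    )


@dataclass
class BurstSpec:
    """Network-burst plan: how many, how long, how dense."""

    count: int = 3
    duration_s: float = 0.5
    rate_hz: float = 25.0  # per-channel event rate inside a burst


@dataclass
class GroundTruth:
    """True spike/burst times of a synthetic recording (the test oracle)."""

    spike_times_s: list[np.ndarray]   # per channel, sorted
    spike_polarities: list[np.ndarray]  # per spike, +1/-1
    burst_windows_s: list[tuple[float, float]]
    noise_sigma_uv: float
    seed: int
    n_dropped: int = 0  # spikes discarded because of placement collisions

    @property
    def n_spikes(self) -> int:
        return sum(len(t) for t in self.spike_times_s)

    def to_dict(self) -> dict:
        return {
            "spike_times_s": [t.tolist() for t in self.spike_times_s],
            "spike_polarities": [p.tolist() for p in self.spike_polarities],
            "burst_windows_s": [list(w) for w in self.burst_windows_s],
            "noise_sigma_uv": self.noise_sigma_uv,
            "seed": self.seed,
            "n_dropped": self.n_dropped,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            spike_times_s=[np.asarray(t, dtype=float) for t in d["spike_times_s"]],
            spike_polarities=[np.asarray(p, dtype=int) for p in d["spike_polarities"]],
            burst_windows_s=[tuple(w) for w in d["burst_windows_s"]],
            noise_sigma_uv=float(d["noise_sigma_uv"]),
            seed=int(d["seed"]),
            n_dropped=int(d.get("n_dropped", 0)),
        )


def _draw_burst_windows(rng: np.random.Generator, spec: BurstSpec, duration_s: float,
                        min_gap_s: float = 1.0, margin_s: float = 1.0) -> list[tuple[float, float]]:
    """Non-overlapping burst windows with >= min_gap_s separation."""
    if spec.count == 0:
        return []
    need = spec.count * spec.duration_s + (spec.count - 1) * min_gap_s + 2 * margin_s
    if need > duration_s:
        raise ValueError(
            f"cannot place {spec.count} bursts of {spec.duration_s}s in {duration_s}s"
        )
    # place onsets on the free line after removing burst+gap footprints
    slack = duration_s - need
    cuts = np.sort(rng.uniform(0.0, slack, size=spec.count))
    onsets = margin_s + cuts + np.arange(spec.count) * (spec.duration_s + min_gap_s)
    return [(float(o), float(o + spec.duration_s)) for o in onsets]


def synthesize_mea_recording(
    meta: RecordingMeta,
    rates_hz: np.ndarray | float,
    burst_spec: BurstSpec | None = None,
    noise_sigma_uv: float = 10.0,
    snr: float = 8.0,
    seed: int = 0,
) -> tuple[MultiplexedRecording, GroundTruth]:
    """Simulate a multiplexed recording plus its ground truth.

    Parameters
    ----------
    rates_hz : scalar or per-channel array of tonic (outside-burst) Poisson
        firing rates.
    burst_spec : network bursts; events inside each window are added to every
        channel as Poisson events at ``burst_spec.rate_hz``.
    noise_sigma_uv : standard deviation of the white Gaussian background.
    snr : spike peak amplitude expressed in units of the noise sigma.

    Spikes closer together than one template duration collide; the later one
    is dropped (and counted in the ground truth), mirroring the refractory
    dead time of the detector.
    """
    if snr <= 0:
        raise ValueError("snr must be positive")
    rates = np.broadcast_to(np.asarray(rates_hz, dtype=float), (meta.n_channels,))
    if np.any(rates < 0):
        raise ValueError("rates must be non-negative")
    burst_spec = burst_spec or BurstSpec(count=0)

    n = meta.n_samples_per_channel
    rate = meta.sampling_rate_hz
    dur = meta.duration_s
    ss = np.random.SeedSequence(seed)
    global_rng = np.random.default_rng(ss.spawn(1)[0])
    channel_seeds = ss.spawn(meta.n_channels)

    windows = _draw_burst_windows(global_rng, burst_spec, dur)

    counts = np.empty((n, meta.n_channels), dtype=np.int16)
    all_times: list[np.ndarray] = []
    all_pols: list[np.ndarray] = []
    n_dropped = 0
    peak_uv = snr * noise_sigma_uv
    full_scale = 2 ** (meta.adc_bits - 1) - 1

    for c in range(meta.n_channels):
        rng = np.random.default_rng(channel_seeds[c])
        # each channel records one dominant multi-unit shape and polarity
        kind = rng.choice(SHAPE_KINDS)
        sign = -1 if rng.random() < 0.7 else 1
        tpl = make_template(kind, rate_hz=rate)
        tpl_dur_s = tpl.samples.size / rate

        signal = rng.normal(0.0, noise_sigma_uv, size=n)

        times = []
        lo, hi = tpl_dur_s, dur - tpl_dur_s
        if rates[c] > 0 and hi > lo:
            n_tonic = rng.poisson(rates[c] * dur)
            times.append(rng.uniform(lo, hi, size=n_tonic))
        for (on, off) in windows:
            n_b = rng.poisson(burst_spec.rate_hz * (off - on))
            times.append(rng.uniform(max(on, lo), min(off, hi), size=n_b))
        t_all = np.sort(np.concatenate(times)) if times else np.empty(0)

        # collision rule: drop the later of two spikes closer than the template
        kept = []
        last = -np.inf
        for t in t_all:
            if t - last < tpl_dur_s:
                n_dropped += 1
                continue
            kept.append(t)
            last = t
        kept = np.asarray(kept)

        wf = sign * peak_uv * tpl.samples
        for t in kept:
            i0 = int(round(t * rate)) - tpl.peak_index
            signal[i0:i0 + tpl.samples.size] += wf
        all_times.append(kept)
        pol = int(np.sign(sign * tpl.samples[tpl.peak_index]))
        all_pols.append(np.full(kept.size, pol, dtype=int))

        ch_counts = np.rint(signal * 1e-6 / meta.volts_per_count)
        if np.max(np.abs(ch_counts)) > full_scale:
            raise ValueError("synthetic signal exceeds A/D full scale; lower snr or sigma")
        counts[:, c] = ch_counts.astype(np.int16)

    if n_dropped:
        logger.info("dropped %d colliding synthetic spikes", n_dropped)

    rec = MultiplexedRecording(meta=meta, samples=counts)
    truth = GroundTruth(
        spike_times_s=all_times,
        spike_polarities=all_pols,
        burst_windows_s=windows,
        noise_sigma_uv=noise_sigma_uv,
        seed=seed,
        n_dropped=n_dropped,
    )
    return rec, truth


def write_fixture(rec: MultiplexedRecording, truth: GroundTruth, stem: Path) -> Path:
    """Write the recording dialect plus ``<stem>.truth.json``."""
    stem = Path(stem)
    raw = write_multiplexed(rec, stem)
    stem.with_name(stem.name + ".truth.json").write_text(json.dumps(truth.to_dict()))
    return raw
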