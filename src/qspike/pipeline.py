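"""End-to-end orchestration: raw recording in, report + archive out.

Stages: demultiplex the interleaved binary, then per channel (in parallel on
the worker pool) blank stimulation artifacts, band-pass filter, detect and
polarity-sort spikes, store timestamps and waveforms; barrier; consolidate
all channels into one spike table; run the network-level analyses; render
figures and the HTML report; pack the results archive.

All per-channel work is a pure function of that channel's samples and the
configuration, so results are bitwise independent of the worker count.
Traces are converted to microvolts after demultiplexing, so thresholds and
amplitudes are reported in µV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import analysis as ana
from . import mea_io
from .batch import ExecutionLog, plan_jobs, run_batch
from .detection import DetectionConfig, SpikeTrain, consolidate_trains, detect_peaks, \
    extract_waveforms, sort_by_polarity
from .preprocess import ArtifactSpec, FilterSpec, remove_stimulation_artifacts, \
    zero_phase_filter
from .reporting import ReportBundle, execution_digest, package_archive, \
    render_active_hist, render_isi_hist, render_largest_burst_zoom, render_raster_and_count, \
    render_report, render_waveform_grid, save_figure

__all__ = ["PipelineConfig", "RunResult", "run_pipeline", "load_config"]


@dataclass
class PipelineConfig:
    """All tunables of one run, one nesting level per stage."""

    filter: FilterSpec = field(default_factory=FilterSpec)
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    burst: ana.BurstConfig = field(default_factory=ana.BurstConfig)
    artifact_pre_ms: float = 0.5
    artifact_post_ms: float = 2.0
    blank_before_filter: bool = True
    min_rate_hz: float = ana.DEFAULT_MIN_RATE_HZ
    raster_window_s: float = 300.0


def load_config(path: Path) -> PipelineConfig:
    """Read a nested-key YAML configuration (missing keys keep defaults)."""
    d = yaml.safe_load(Path(path).read_text()) or {}
    cfg = PipelineConfig()
    if "filter" in d:
        f = d["filter"]
        cfg.filter = FilterSpec(
            order=f.get("order", 4),
            low_hz=f.get("low_hz", 400.0),
            high_hz=f.get("high_hz", 3000.0),
            passband_ripple_db=f.get("rp_db", 0.1),
            stopband_atten_db=f.get("rs_db", 40.0),
        )
    if "detection" in d:
        det = d["detection"]
        cfg.detection = DetectionConfig(
            k_threshold=det.get("k_threshold", 5.0),
            dead_time_ms=det.get("dead_time_ms", 1.0),
            wave_pre_ms=det.get("wave_pre_ms", 1.0),
            wave_post_ms=det.get("wave_post_ms", 2.0),
            polarity_mode=det.get("polarity_mode", "both"),
        )
    if "burst" in d:
        b = d["burst"]
        cfg.burst = ana.BurstConfig(
            bin_ms=b.get("bin_ms", 25.0),
            count_threshold=b.get("count_threshold"),
            min_channels=b.get("min_channels"),
            merge_gap_ms=b.get("merge_gap_ms", 100.0),
        )
    if "artifact" in d:
        cfg.artifact_pre_ms = d["artifact"].get("pre_ms", 0.5)
        cfg.artifact_post_ms = d["artifact"].get("post_ms", 2.0)
    if "analysis" in d:
        cfg.min_rate_hz = d["analysis"].get("min_rate_hz", ana.DEFAULT_MIN_RATE_HZ)
    if "pipeline" in d:
        cfg.blank_before_filter = d["pipeline"].get("blank_before_filter", True)
    return cfg


@dataclass
class ChannelJobSpec:
    """Everything one per-channel job needs (picklable, self-contained)."""

    channel_id: int
    label: str
    trace_path: str
    sampling_rate_hz: float
    n_samples: int
    out_dir: str
    filter_spec: FilterSpec
    detection: DetectionConfig
    stim_times_s: list[float]
    artifact_pre_ms: float
    artifact_post_ms: float
    blank_before_filter: bool


def _polarity_label(p: int) -> str:
    return "positive" if p > 0 else "negative"


def channel_job(spec: ChannelJobSpec) -> dict:
    """Preprocess and detect on one channel; writes its own output files.

    Pure in its channel input; prints nothing (stdout/stderr land in the
    per-job log).  Returns the spike train plus polarity-class waveform
    statistics for the report figures.
    """
    meta_like = mea_io.RecordingMeta(
        n_channels=1, sampling_rate_hz=spec.sampling_rate_hz,
        duration_s=spec.n_samples / spec.sampling_rate_hz,
    )
    trace = mea_io.load_channel(Path(spec.trace_path), meta_like, 0)
    trace = mea_io.ChannelTrace(
        spec.channel_id, spec.label, trace.samples * 1e6, spec.sampling_rate_hz
    )  # volts -> microvolts

    art = ArtifactSpec(spec.stim_times_s, spec.artifact_pre_ms, spec.artifact_post_ms)
    if spec.stim_times_s and spec.blank_before_filter:
        trace = remove_stimulation_artifacts(trace, art)
    trace = zero_phase_filter(trace, spec.filter_spec)
    if spec.stim_times_s and not spec.blank_before_filter:
        trace = remove_stimulation_artifacts(trace, art)

    train = detect_peaks(trace, spec.detection)
    events = extract_waveforms(trace, train, spec.detection)
    classes = sort_by_polarity(events)

    out = Path(spec.out_dir)
    spikes_dir = out / "spikes"
    wf_dir = out / "waveforms"
    spikes_dir.mkdir(parents=True, exist_ok=True)
    wf_dir.mkdir(parents=True, exist_ok=True)

    with open(spikes_dir / f"ch{spec.channel_id:02d}.spikes.tsv", "w") as fh:
        for t, p, a in zip(train.timestamps_s, train.polarities, train.amplitudes):
            fh.write(f"{t:.9e}\t{_polarity_label(int(p))}\t{a:.9e}\n")

    wf = np.stack([e.waveform for e in events]) if events else np.empty((0, 0))
    np.savez(
        wf_dir / f"ch{spec.channel_id:02d}.npz",
        waveforms=wf,
        times=np.array([e.time_s for e in events]),
        polarities=np.array([e.polarity for e in events], dtype=np.int8),
    )

    def cls_stats(cls):
        return {
            "mean": cls.mean_waveform,
            "sd": cls.sd_waveform,
            "count": cls.count,
        }

    return {
        "channel_id": spec.channel_id,
        "label": spec.label,
        "timestamps_s": train.timestamps_s,
        "polarities": train.polarities,
        "amplitudes": train.amplitudes,
        "threshold_uv": train.threshold,
        "positive": cls_stats(classes.positive),
        "negative": cls_stats(classes.negative),
    }


@dataclass
class RunResult:
    """Outcome of one pipeline run."""

    status: str  # done | failed
    out_dir: Path
    meta: mea_io.RecordingMeta
    log: ExecutionLog
    summary: ana.AnalysisSummary | None = None
    table: pd.DataFrame | None = None
    bursts: list[ana.NetworkBurst] = field(default_factory=list)
    report_path: Path | None = None
    archive_path: Path | None = None
    channel_results: dict[int, dict] = field(default_factory=dict)


def _write_logs(log: ExecutionLog, out_dir: Path) -> None:
    log_dir = out_dir / "logs"
    log_dir.mkdir(parents=True, exist_ok=True)
    for j in log.jobs:
        (log_dir / f"ch{j.job_id:02d}.out").write_text(j.stdout)
        (log_dir / f"ch{j.job_id:02d}.err").write_text(j.stderr)
    (log_dir / "run.json").write_text(json.dumps(log.to_dict(), indent=1))


def _load_stim_times(stem: Path) -> list[float]:
    p = stem.with_name(stem.name + ".stim.txt")
    if not p.exists():
        return []
    return [float(line) for line in p.read_text().split() if line.strip()]


def run_pipeline(
    input_stem: Path,
    out_dir: Path,
    n_workers: int = 1,
    config: PipelineConfig | None = None,
    queue_name: str = "default",
    make_figures: bool = True,
    make_archive: bool = True,
) -> RunResult:
    """Run the full workflow on one recording.

    ``input_stem`` names the ``<stem>.raw`` + ``<stem>.meta.json`` pair (an
    optional ``<stem>.stim.txt`` provides stimulation times, one per line, in
    seconds).  A failing channel job marks the run failed; the surviving
    channels' outputs and all logs are still written, but consolidation and
    analysis are withheld.
    """
    cfg = config or PipelineConfig()
    input_stem = Path(input_stem)
    if input_stem.suffix == ".raw":
        input_stem = input_stem.with_suffix("")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rec = mea_io.read_multiplexed(input_stem)
    meta = rec.meta
    ch_paths = mea_io.demultiplex(rec, out_dir / "channels", stem=input_stem.name)
    stim_times = _load_stim_times(input_stem)

    plan = plan_jobs(meta.n_channels, n_workers)
    args = [
        ChannelJobSpec(
            channel_id=c,
            label=meta.channel_labels[c],
            trace_path=str(ch_paths[c]),
            sampling_rate_hz=meta.sampling_rate_hz,
            n_samples=meta.n_samples_per_channel,
            out_dir=str(out_dir),
            filter_spec=cfg.filter,
            detection=cfg.detection,
            stim_times_s=stim_times,
            artifact_pre_ms=cfg.artifact_pre_ms,
            artifact_post_ms=cfg.artifact_post_ms,
            blank_before_filter=cfg.blank_before_filter,
        )
        for c in range(meta.n_channels)
    ]
    results, log = run_batch(plan, channel_job, args, queue_name=queue_name)
    _write_logs(log, out_dir)
    if log.status != "done":
        return RunResult(status="failed", out_dir=out_dir, meta=meta, log=log,
                         channel_results=results)

    trains = {
        c: SpikeTrain(
            channel_id=c,
            label=r["label"],
            timestamps_s=r["timestamps_s"],
            polarities=r["polarities"],
            amplitudes=r["amplitudes"],
            threshold=r["threshold_uv"],
            sampling_rate_hz=meta.sampling_rate_hz,
        )
        for c, r in results.items()
    }
    table = consolidate_trains(trains, expected_channels=range(meta.n_channels))
    table.to_csv(out_dir / "consolidated.tsv", sep="\t", index=False,
                 float_format="%.9e")

    active, rates = ana.active_electrodes(trains.values(), meta.duration_s, cfg.min_rate_hz)
    isis, isi_counts, isi_edges = ana.pooled_isi([trains[c] for c in active])
    counts, edges = ana.network_spike_count(table, cfg.burst.bin_ms, meta.duration_s)
    burst_cfg = cfg.burst.resolved(len(active))
    bursts = ana.detect_network_bursts(counts, burst_cfg, table)
    bstats = ana.burst_statistics(bursts, meta.duration_s)

    summary = ana.AnalysisSummary(
        recording_duration_s=meta.duration_s,
        total_samples=meta.n_samples_per_channel * meta.n_channels,
        sampling_rate_hz=meta.sampling_rate_hz,
        n_active_electrodes=len(active),
        n_spikes=int(len(table)),
        n_bursts=bstats["n_bursts"],
        mean_burst_duration_s=bstats["mean_burst_duration_s"],
        sd_burst_duration_s=bstats["sd_burst_duration_s"],
        mean_ibi_s=bstats["mean_ibi_s"],
        sd_ibi_s=bstats["sd_ibi_s"],
        burst_threshold_used=burst_cfg.count_threshold,
    )
    (out_dir / "summary.json").write_text(json.dumps(summary.to_dict(), indent=1))
    with open(out_dir / "bursts.tsv", "w") as fh:
        fh.write("onset_s\toffset_s\tduration_s\tn_spikes\tn_channels\n")
        for b in bursts:
            fh.write(f"{b.onset_s:.6f}\t{b.offset_s:.6f}\t{b.duration_s:.6f}"
                     f"\t{b.n_spikes}\t{b.n_channels}\n")
    if bursts:
        profile, p_edges = ana.discharge_probability_profile(bursts, table)
        pd.DataFrame({"t_from_onset_s": p_edges[:-1], "probability": profile}).to_csv(
            out_dir / "discharge_profile.tsv", sep="\t", index=False)

    figures: dict[str, Path] = {}
    absent: dict[str, str] = {}
    if make_figures:
        fig_dir = out_dir / "figures"
        for pol in ("positive", "negative"):
            stats = {c: (r[pol]["mean"], r[pol]["sd"], r[pol]["count"])
                     for c, r in results.items()}
            fig = render_waveform_grid(stats, meta.layout, meta.channel_labels, pol,
                                       meta.sampling_rate_hz)
            figures[f"waveform_grid_{'pos' if pol == 'positive' else 'neg'}"] = \
                save_figure(fig, fig_dir / f"waveform_grid_{pol}")
        figures["active_hist"] = save_figure(
            render_active_hist(rates, cfg.min_rate_hz), fig_dir / "active_hist")
        figures["isi_hist"] = save_figure(
            render_isi_hist(isi_counts, isi_edges), fig_dir / "isi_hist")
        fig = render_raster_and_count(table, counts, edges, cfg.raster_window_s)
        figures["raster"] = save_figure(fig, fig_dir / "raster")
        fig = render_raster_and_count(table, counts, edges, meta.duration_s)
        figures["network_count"] = save_figure(fig, fig_dir / "network_count")
        if bursts:
            best, windows = ana.largest_burst(bursts, table)
            fig = render_largest_burst_zoom(best, windows, table, counts, edges)
            figures["largest_burst_zoom"] = save_figure(fig, fig_dir / "largest_burst_zoom")
        else:
            absent["largest_burst_zoom"] = "no network bursts detected"
    else:
        (out_dir / "figures").mkdir(exist_ok=True)
        absent = {fid: "figure rendering disabled" for fid in
                  ("waveform_grid_pos", "waveform_grid_neg", "active_hist", "isi_hist",
                   "raster", "network_count", "largest_burst_zoom")}

    bundle = ReportBundle(
        summary=summary,
        execution=execution_digest(log),
        figures=figures,
        figure_absent_reasons=absent,
    )
    report_path = render_report(bundle, out_dir / "report.html")

    archive_path = None
    if make_archive:
        archive_path = package_archive(out_dir)

    return RunResult(
        status="done",
        out_dir=out_dir,
        meta=meta,
        log=log,
        summary=summary,
        table=table,
        bursts=bursts,
        report_path=report_path,
        archive_path=archive_path,
        channel_results=results,
    )
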