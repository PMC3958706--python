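"""End-of-run reporting: figures, HTML summary, results archive.

The report carries the execution digest (queue, start/end, total time) and
the activity summary (duration, samples, rate, active electrodes, spikes,
bursts and their statistics, burst threshold), plus the standard figure set:
polarity-split waveform grids on the electrode layout, active-electrode rate
histogram, pooled ISI histogram, raster + network spike count, and the
largest-burst zoom.  Rendering is deterministic: every number comes from the
machine-readable analysis outputs, never from the wall clock, so identical
inputs produce byte-identical HTML.
"""

from __future__ import annotations

import string
import tarfile
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import matplotlib

matplotlib.use("Agg", force=False)
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .analysis import AnalysisSummary, NetworkBurst  # noqa: E402
from .batch import ExecutionLog  # noqa: E402

__all__ = [
    "FIGURE_IDS",
    "REPORT_FIELDS",
    "ReportBundle",
    "execution_digest",
    "report_fields",
    "render_waveform_grid",
    "render_active_hist",
    "render_isi_hist",
    "render_raster_and_count",
    "render_largest_burst_zoom",
    "render_report",
    "package_archive",
    "ARCHIVE_ARTIFACT_CLASSES",
]

FIGURE_IDS = (
    "waveform_grid_pos",
    "waveform_grid_neg",
    "active_hist",
    "isi_hist",
    "raster",
    "network_count",
    "largest_burst_zoom",
)

# The canonical report items; "start and end time of the processes" is a
# single item rendered as a start -> end pair.
REPORT_FIELDS = (
    "queue_name",
    "process_start_end",
    "total_execution_time_s",
    "recording_duration_s",
    "total_samples",
    "sampling_rate_hz",
    "n_active_electrodes",
    "n_spikes",
    "n_bursts",
    "mean_burst_duration_s",
    "sd_burst_duration_s",
    "mean_ibi_s",
    "sd_ibi_s",
    "burst_detection_threshold",
)


@dataclass
class ReportBundle:
    """Everything the report renderer needs, already computed."""

    summary: AnalysisSummary
    execution: dict  # digest from execution_digest()
    figures: dict[str, Path | None] = field(default_factory=dict)
    figure_absent_reasons: dict[str, str] = field(default_factory=dict)
    archive_path: Path | None = None

    def __post_init__(self) -> None:
        for fid in FIGURE_IDS:
            if fid not in self.figures and fid not in self.figure_absent_reasons:
                raise ValueError(f"figure {fid!r} neither present nor marked absent")


def _iso(ts: float) -> str:
    return datetime.fromtimestamp(ts, tz=timezone.utc).strftime("%Y-%m-%d %H:%M:%S UTC")


def execution_digest(log: ExecutionLog) -> dict:
    return {
        "queue_name": log.queue_name,
        "n_workers": log.n_workers,
        "start": _iso(log.start),
        "end": _iso(log.end),
        "total_execution_time_s": round(log.total_time_s, 3),
        "status": log.status,
    }


def _fmt(v, unit: str = "", nd: int = 4) -> str:
    if v is None:
        return "n/a (fewer than 2 bursts)"
    if isinstance(v, float):
        return f"{v:.{nd}g}{unit}"
    return f"{v}{unit}"


def report_fields(summary: AnalysisSummary, execution: dict) -> dict[str, str]:
    """The 14 canonical report items as rendered strings."""
    return {
        "queue_name": str(execution["queue_name"]),
        "process_start_end": f"{execution['start']} → {execution['end']}",
        "total_execution_time_s": _fmt(float(execution["total_execution_time_s"]), " s"),
        "recording_duration_s": _fmt(summary.recording_duration_s, " s"),
        "total_samples": _fmt(summary.total_samples),
        "sampling_rate_hz": _fmt(summary.sampling_rate_hz, " Hz"),
        "n_active_electrodes": _fmt(summary.n_active_electrodes),
        "n_spikes": _fmt(summary.n_spikes),
        "n_bursts": _fmt(summary.n_bursts),
        "mean_burst_duration_s": _fmt(summary.mean_burst_duration_s, " s"),
        "sd_burst_duration_s": _fmt(summary.sd_burst_duration_s, " s"),
        "mean_ibi_s": _fmt(summary.mean_ibi_s, " s"),
        "sd_ibi_s": _fmt(summary.sd_ibi_s, " s"),
        "burst_detection_threshold": _fmt(summary.burst_threshold_used, " spikes/bin"),
    }


_FIELD_TITLES = {
    "queue_name": "Queue name",
    "process_start_end": "Start and end time of the processes",
    "total_execution_time_s": "Total execution time",
    "recording_duration_s": "Total recording duration",
    "total_samples": "Total number of samples",
    "sampling_rate_hz": "Sampling rate",
    "n_active_electrodes": "Number of active electrodes",
    "n_spikes": "Number of spikes",
    "n_bursts": "Number of bursts",
    "mean_burst_duration_s": "Mean burst duration",
    "sd_burst_duration_s": "Standard deviation of burst duration",
    "mean_ibi_s": "Mean inter-burst interval",
    "sd_ibi_s": "Standard deviation of inter-burst intervals",
    "burst_detection_threshold": "Burst detection threshold",
}


def save_figure(fig, base: Path) -> Path:
    """Save as both raster (PNG) and vector (SVG); returns the PNG path."""
    base = Path(base)
    base.parent.mkdir(parents=True, exist_ok=True)
    png = base.with_suffix(".png")
    fig.savefig(png, dpi=110)
    fig.savefig(base.with_suffix(".svg"))
    plt.close(fig)
    return png


def render_waveform_grid(
    channel_stats: Mapping[int, tuple[np.ndarray | None, np.ndarray | None, int]],
    layout: Sequence[tuple[int, int]],
    labels: Sequence[str],
    polarity: str,
    sampling_rate_hz: float,
):
    """Mean waveform +/- SD per electrode, laid out on the physical grid.

    ``channel_stats[c] = (mean, sd, count)``; electrodes with no events of
    this polarity get an empty labeled subplot annotated "(0)".
    """
    n_rows = max(r for r, _ in layout) + 1
    n_cols = max(c for _, c in layout) + 1
    fig, axes = plt.subplots(n_rows, n_cols, figsize=(1.6 * n_cols, 1.2 * n_rows), squeeze=False)
    for ax_row in axes:
        for ax in ax_row:
            ax.set_axis_off()
    for ch, (row, col) in enumerate(layout):
        ax = axes[row][col]
        ax.set_axis_on()
        ax.set_xticks([])
        ax.set_yticks([])
        mean, sd, count = channel_stats.get(ch, (None, None, 0))
        if mean is not None:
            t_ms = np.arange(mean.size) / sampling_rate_hz * 1e3
            if sd is not None:
                ax.fill_between(t_ms, mean - sd, mean + sd, color="0.7")
            ax.plot(t_ms, mean, "k-", lw=1.2)
        ax.set_title(f"{labels[ch]} ({count})", fontsize=6, pad=1)
    sign = "positive" if polarity == "positive" else "negative"
    fig.suptitle(f"Average waveforms, {sign} threshold crossings (count in brackets)")
    return fig


def render_active_hist(rates_hz: Mapping[int, float], min_rate_hz: float):
    """Histogram of per-electrode firing rates with the activity cutoff."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    vals = np.array(list(rates_hz.values()))
    if vals.size:
        ax.hist(vals, bins=30, color="0.4")
    ax.axvline(min_rate_hz, color="r", ls="--", label=f"{min_rate_hz} Hz cutoff")
    ax.set_xlabel("firing rate (Hz)")
    ax.set_ylabel("electrodes")
    ax.legend(fontsize=7)
    fig.tight_layout()
    return fig


def render_isi_hist(counts: np.ndarray, edges_s: np.ndarray):
    """Pooled ISI distribution on logarithmic bins."""
    fig, ax = plt.subplots(figsize=(5, 3.2))
    centers = np.sqrt(edges_s[:-1] * edges_s[1:])
    ax.step(centers * 1e3, counts, where="mid", color="k")
    ax.set_xscale("log")
    ax.set_xlabel("interspike interval (ms)")
    ax.set_ylabel("count")
    fig.tight_layout()
    return fig


def render_raster_and_count(
    table: pd.DataFrame,
    counts: np.ndarray,
    edges_s: np.ndarray,
    window_s: float = 300.0,
):
    """Raster over the first 5 min (or full recording if shorter) + counts."""
    t_end = min(window_s, edges_s[-1])
    fig, (ax1, ax2) = plt.subplots(2, 1, figsize=(7, 4.5), sharex=True,
                                   height_ratios=[3, 1])
    sub = table[table["time_s"] < t_end]
    ax1.plot(sub["time_s"], sub["channel"], "|", ms=2, color="k")
    ax1.set_ylabel("electrode")
    keep = edges_s[:-1] < t_end
    ax2.step(edges_s[:-1][keep], counts[keep], where="post", color="k")
    ax2.set_xlabel("time (s)")
    ax2.set_ylabel("network\nspikes/bin")
    ax1.set_xlim(0, t_end)
    fig.tight_layout()
    return fig


def render_largest_burst_zoom(
    burst: NetworkBurst,
    windows: Sequence[tuple[float, float]],
    table: pd.DataFrame,
    counts: np.ndarray,
    edges_s: np.ndarray,
):
    """The largest network burst at increasing temporal resolution."""
    n = len(windows)
    fig, axes = plt.subplots(2, n, figsize=(3.2 * n, 4.5), squeeze=False,
                             height_ratios=[1, 2])
    for k, (t0, t1) in enumerate(windows):
        keep = (edges_s[:-1] >= t0) & (edges_s[:-1] < t1)
        axes[0][k].step(edges_s[:-1][keep], counts[keep], where="post", color="k")
        axes[0][k].axvspan(burst.onset_s, burst.offset_s, color="r", alpha=0.15)
        sub = table[(table["time_s"] >= t0) & (table["time_s"] < t1)]
        axes[1][k].plot(sub["time_s"], sub["channel"], "|", ms=2, color="k")
        axes[1][k].set_xlim(t0, t1)
        axes[0][k].set_xlim(t0, t1)
        axes[1][k].set_xlabel("time (s)")
    axes[1][0].set_ylabel("electrode")
    axes[0][0].set_ylabel("spikes/bin")
    fig.suptitle(f"Largest network burst: {burst.n_spikes} spikes, "
                 f"{burst.n_channels} electrodes")
    fig.tight_layout()
    return fig


_HTML_TEMPLATE = string.Template(
    """<!DOCTYPE html>
<html><head><meta charset="utf-8"><title>Recording analysis report</title>
<style>
body { font-family: sans-serif; margin: 2em; max-width: 60em; }
table { border-collapse: collapse; }
td, th { border: 1px solid #999; padding: 4px 10px; text-align: left; }
.warn { color: #a00; }
img { max-width: 100%; margin: 0.8em 0; }
</style></head>
<body>
<h1>Recording analysis report</h1>
<h2>Execution log</h2>
<table>$execution_rows</table>
<h2>Activity summary</h2>
<table>$summary_rows</table>
<h2>Figures</h2>
$figures
</body></html>
"""
)


def render_report(bundle: ReportBundle, out_path: Path) -> Path:
    """Write ``report.html`` (PDF only when a converter is available).

    Every canonical report item appears verbatim; absent statistics render as
    "n/a (reason)"; missing figure files produce a placeholder plus warning
    rather than a failure.  No wall-clock access: byte-identical output for
    identical inputs.
    """
    out_path = Path(out_path)
    fields = report_fields(bundle.summary, bundle.execution)
    exec_keys = ("queue_name", "process_start_end", "total_execution_time_s")
    rows_exec = "\n".join(
        f"<tr><th>{_FIELD_TITLES[k]}</th><td>{fields[k]}</td></tr>" for k in exec_keys
    )
    rows_sum = "\n".join(
        f"<tr><th>{_FIELD_TITLES[k]}</th><td>{fields[k]}</td></tr>"
        for k in REPORT_FIELDS
        if k not in exec_keys
    )
    fig_html = []
    for fid in FIGURE_IDS:
        path = bundle.figures.get(fid)
        if path is not None and Path(path).exists():
            rel = Path(path).name
            fig_html.append(f'<h3>{fid}</h3><img src="figures/{rel}" alt="{fid}">')
        else:
            reason = bundle.figure_absent_reasons.get(fid, "figure file missing")
            fig_html.append(f'<h3>{fid}</h3><p class="warn">not rendered: {reason}</p>')
    html = _HTML_TEMPLATE.substitute(
        execution_rows=rows_exec, summary_rows=rows_sum, figures="\n".join(fig_html)
    )
    out_path.write_text(html)
    return out_path


# artifact classes a complete results archive must contain
ARCHIVE_ARTIFACT_CLASSES = {
    "report": "report.html",
    "figures": "figures",
    "consolidated": "consolidated.tsv",
    "timestamps": "spikes",
    "waveforms": "waveforms",
    "summary": "summary.json",
    "logs": "logs",
}


def package_archive(out_dir: Path, archive_path: Path | None = None,
                    allow_partial: bool = False) -> Path:
    """Pack one run's results directory into a gzip tar archive.

    A complete archive holds all seven artifact classes (report, figures,
    consolidated table, per-channel timestamps, waveforms, summary JSON,
    logs); a partial run is refused unless ``allow_partial``.
    """
    out_dir = Path(out_dir)
    missing = [k for k, rel in ARCHIVE_ARTIFACT_CLASSES.items()
               if not (out_dir / rel).exists()]
    if missing and not allow_partial:
        raise FileNotFoundError(
            f"run incomplete, artifact class(es) missing: {missing}; "
            "pass allow_partial=True to archive anyway"
        )
    archive_path = Path(archive_path or out_dir.with_suffix(".tar.gz"))
    with tarfile.open(archive_path, "w:gz") as tar:
        for p in sorted(out_dir.rglob("*")):
            if p.suffix in (".raw", ".f64"):
                continue  # bulk intermediates stay outside the archive
            tar.add(p, arcname=p.relative_to(out_dir))
    return archive_path
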