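# Methods

## Scope and data model

`qspike` turns a multiplexed raw extracellular recording from a planar
micro-electrode array (MEA) into multi-unit spike trains, polarity-sorted
average waveforms, network-burst statistics, and an HTML report with a
results archive. The unit of work is one electrode: every CPU-intensive step
(filtering, detection, waveform extraction) is a pure function of a single
channel's samples and the configuration, which makes the workload
embarrassingly parallel and — more importantly — makes the scientific output
provably independent of how many workers execute it.

The input dialect is deliberately open: `<stem>.raw` holds little-endian
signed 16-bit samples, frame-major interleaved (one frame = one sample per
channel), and `<stem>.meta.json` carries channel count, sampling rate,
duration, volts-per-count scale, electrode labels and the (row, col) grid
layout. Proprietary acquisition formats are out of scope; converting to this
dialect is a one-off copy at 2 bytes/sample. Demultiplexed per-channel files
(`<stem>.chNN.f64`) store float64 **volts**; inside the pipeline traces are
handled in microvolts so thresholds and amplitudes are reported in µV. At
the reference acquisition settings (60 channels, 16-bit, 20 kHz) one hour of
raw data is 60 × 2 × 20 000 × 3600 ≈ 8.6 GB, which is why batch rather than
interactive processing is the design center.

## Preprocessing

**Band-pass filtering.** An elliptic band-pass, design order 4 (requested as
order 2 of the prototype; band-pass design doubles it), 400–3000 Hz, 0.1 dB
passband ripple, 40 dB stopband attenuation, applied forward–backward
(`sosfiltfilt`). The two passes square the magnitude response (so effective
stopband suppression is ≥ 80 dB) and cancel the phase, leaving spike peaks
unshifted in time. Startup transients are flushed by mirror (even) padding
of 3 × (order + 1) samples; traces shorter than that are rejected rather
than silently filtered. All defaults are configurable (`filter.*` keys).

**Stimulation-artifact blanking.** When a `<stem>.stim.txt` file provides
stimulation times, samples in [t − 0.5 ms, t + 2 ms] around each are
replaced by the straight line joining the samples just outside the window.
Linear interpolation, not zeroing: a step discontinuity would ring through
the band-pass and masquerade as spikes. The operation is idempotent, and
windows reaching past the recording are clipped with a warning. Blanking
runs before filtering by default (configurable) so the filter never sees the
raw artifact; either ordering is defensible and the choice is exposed rather
than asserted.

## Spike detection and elementary sorting

The noise scale of the **filtered** trace is estimated as
σ̂ = median(|x|) / 0.6745 — the median absolute deviation calibrated to a
Gaussian — and the detection threshold is k · σ̂ with k = 5 by default. The
median-based estimate is the standard choice for extracellular work because
it barely moves when spikes are present (the tests inject 1% contamination
and check the estimate stays within 3%). A completely flat trace has no
noise scale; detection refuses to run on it instead of returning a zero
threshold.

Candidate events are local extrema with |value| above threshold
(positive-only / negative-only / both, configurable). A refractory **dead
time** (default 1 ms) then thins candidates, amplitude-first: candidates are
accepted in decreasing |amplitude| (ties: earlier first) provided no
already-accepted event lies within the dead time. This rule makes the
detector keep the dominant lobe when several lobes of one waveform cross
threshold, and it leaves timestamps invariant under positive rescaling of
the trace (the threshold scales with the signal) and equivariant under time
shifts.

Waveforms span 1 ms before to 2 ms after the peak (configurable); events
whose window would cross the recording bounds are dropped and logged.
"Elementary sorting" partitions events by crossing sign only — no
clustering — and reports per-class point-wise mean and sample SD (n − 1)
waveforms plus counts, which is what the report's waveform grids draw.

Per-channel timestamps are written as text (`time_s TAB polarity TAB
amplitude_uv`); once **all** channels have finished (the batch barrier) they
are consolidated into a single table sorted by time then channel. Row count
conservation and permutation invariance of the consolidation are tested.

## Spike-train and network-burst analysis

*Firing rate* is count/duration. An electrode is **active** when its rate is
strictly above 0.02 Hz (the boundary is strict: 24 spikes in 1200 s is out,
25 is in). The **pooled ISI** distribution computes intervals within each
channel and pools the samples across channels — merged-train intervals would
conflate electrodes — and is histogrammed on 50 logarithmic bins from 1 ms
to 100 s; bimodality (fast intra-burst mode plus slow between-burst mode) is
the signature of a bursting culture and is checked with a two-peak-with-dip
criterion on the lightly smoothed histogram.

**Network bursts** are detected on the merged spike-count series (25 ms
half-open bins; bin sums conserve the spike total): maximal runs of bins
with count ≥ threshold are merged when separated by < 100 ms, and kept when
at least `min_channels` distinct electrodes fire inside the run. The
threshold defaults to max(2, 0.25 × n_active) network spikes/bin and
`min_channels` to max(2, 0.2 × n_active); both scale with array activity
because an absolute count means nothing across cultures of different
activity levels. All four knobs are configurable and the threshold actually
used is a report field. Burst onset/offset land on bin edges, so planted
0.5 s bursts are recovered with up to one bin width of edge error.

Burst statistics use sample moments (n − 1): durations, and inter-burst
intervals defined as offset_i → onset_{i+1}. With fewer than two bursts the
SDs (and IBIs) are undefined and the report prints "n/a" with the reason.
The **largest burst** is the one with the most spikes (ties → earliest) and
is rendered at nested zoom windows (20/4/1 s around its midpoint). The
**discharge-probability profile** re-references intra-burst spikes to burst
onset, averages per-burst histograms (5 ms bins) and normalizes the profile
to sum to 1 — probability per bin rather than a rate, so profiles are
comparable across recordings of different burst counts.

## Batch engine

`plan_jobs` assigns one job per channel; load per worker is
⌈n_jobs / n_workers⌉ (60 channels on 12 workers → 5 jobs each). `run_batch`
executes jobs on a `concurrent.futures` process pool (in-process when
n_workers = 1), captures each job's stdout/stderr and wall-clock interval,
attributes it to a worker PID, and returns only when every job is terminal —
the barrier consolidation requires. A failing job marks the run failed with
its traceback in the job log; the other jobs still complete and their
outputs remain on disk. Because jobs are pure per-channel functions,
consolidated outputs are bitwise identical for any worker count; the tests
compare table checksums across 1/2/4/8 workers. Parallel efficiency is the
pure ratio E = T_max/ΔT × 100% relative to the slowest single-worker run; no
wall-clock performance is asserted anywhere, since observed speedups are
properties of the host, not of the code.

## Reporting

The HTML report (stdlib templating; PDF only if an external converter is
attached, otherwise reported absent) renders an execution digest and the
canonical 14-item summary: queue name; process start→end; total execution
time; recording duration; total samples; sampling rate; active electrodes;
spikes; bursts; mean and SD of burst duration; mean and SD of inter-burst
interval; burst detection threshold. Every number is taken from the
machine-readable outputs (`summary.json`, `logs/run.json`), never recomputed
at render time and never read from the wall clock, so identical inputs give
byte-identical HTML. Figures (waveform grids on the 8×8 layout, active-rate
histogram, pooled ISI histogram, 5-min raster + network count, largest-burst
zoom) are saved as PNG and SVG; a missing figure degrades to a placeholder
with a warning. A complete run is packed into one gzip tar archive per input
recording containing report, figures, consolidated table, per-channel
timestamps, waveforms (`.npz`), summary JSON and logs; packing a partial run
requires `allow_partial`.

## Synthetic fixtures

The generator emulates spontaneous activity of a mature dissociated culture:
white Gaussian noise (σ = 10 µV default) on every electrode, per-channel
tonic Poisson spikes, and non-overlapping network-burst windows (≥ 1 s
apart) during which every channel receives additional Poisson events at the
within-burst rate. Each channel carries one template — monophasic, biphasic
(negative lobe then positive rebound) or triphasic (small leading positive
lobe) — with dominant polarity negative in 70% of channels and peak
amplitude snr × σ. Spikes closer than one template duration collide; the
later one is dropped and counted. Seeding uses one `SeedSequence` spawned
per channel, so output is bitwise reproducible and independent of channel
iteration order.

What the generator does **not** emulate — 1/f and line noise (a pink-noise
option exists in spirit but white is the default because the MAD threshold
calibration assumes an approximately Gaussian background), electrode-to-
electrode amplitude heterogeneity, overlapping spikes from multiple units on
one electrode, slow drift, and real burst substructure. Passing tests
therefore demonstrate correctness of the machinery at a realistic SNR, not
detector performance on arbitrary real recordings.

Study-condition defaults, chosen once: 60 electrodes on the 8×8 layout,
25 kHz sampling, 60 s duration, volts_per_count = 1.25e-7 (±4.096 mV input
range at 16 bits, typical of commercial MEA amplifiers), tonic 0.3 Hz,
three 0.5 s bursts at 25 Hz within-burst rate, SNR 8. The quick unit-test
rig is a 12-channel, 30 s scaled-down version of the same conditions.

## Numerical choices and limitations

- Threshold constant 0.6745 = median(|Z|) of the standard normal; k = 5 and
  the 1 ms dead time are declared defaults, configurable.
- Detection works at sample resolution; timestamps are extremum index /
  rate. Sub-sample interpolation is out of scope.
- The monophasic template loses part of its energy below 400 Hz, so its
  extracted mean waveform correlates ≈ 0.98 (not ≥ 0.99) with the injected
  shape; the bi/triphasic templates sit fully in band.
- Worker-count determinism relies on every per-channel stage being
  deterministic; any future randomized stage must take an explicit seed.
- Joint multi-electrode (tetrode-style) sorting is deliberately excluded:
  it breaks the per-channel independence the whole execution model is built
  on.
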