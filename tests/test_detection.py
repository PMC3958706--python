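import numpy as np
import pytest

from qspike.detection import (
    DetectionConfig,
    SpikeEvent,
    consolidate_trains,
    detect_peaks,
    estimate_threshold,
    extract_waveforms,
    sort_by_polarity,
)
from qspike.errors import ConsolidationError, DegenerateTraceError
from qspike.mea_io import ChannelTrace
from qspike.preprocess import FilterSpec, zero_phase_filter
from qspike.synth import make_template

RATE = 25000.0


def inject(template, times_s, sign=1.0, amp=8.0, noise_sigma=1.0, duration_s=5.0, seed=0):
    """Gaussian noise with template instances at known times; returns trace."""
    rng = np.random.default_rng(seed)
    x = rng.normal(0.0, noise_sigma, int(duration_s * RATE))
    for t in times_s:
        i0 = int(round(t * RATE)) - template.peak_index
        x[i0:i0 + template.samples.size] += sign * amp * template.samples
    return ChannelTrace(0, "t", x, RATE)


class TestThreshold:
    def test_gaussian_noise_converges_to_k_sigma(self):
        rng = np.random.default_rng(123)
        tr = ChannelTrace(0, "g", rng.normal(size=1_000_000), RATE)
        thr = estimate_threshold(tr, DetectionConfig(k_threshold=5.0))
        assert thr == pytest.approx(5.0, rel=0.02)

    def test_homogeneous_in_signal_scale(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100_000)
        cfg = DetectionConfig()
        t1 = estimate_threshold(ChannelTrace(0, "a", x, RATE), cfg)
        t2 = estimate_threshold(ChannelTrace(0, "a", 7.5 * x, RATE), cfg)
        assert t2 == pytest.approx(7.5 * t1, rel=1e-12)

    @pytest.mark.parametrize("value", [0.0, 3.14])
    def test_flat_trace_degenerate(self, value):
        tr = ChannelTrace(0, "c", np.full(10000, value), RATE)
        with pytest.raises(DegenerateTraceError):
            estimate_threshold(tr, DetectionConfig())

    def test_robust_to_spikes(self):
        # the median-based estimate barely moves when 1% of samples are spikes
        rng = np.random.default_rng(2)
        x = rng.normal(size=200_000)
        x[::100] += 20.0
        thr = estimate_threshold(ChannelTrace(0, "s", x, RATE), DetectionConfig())
        assert thr == pytest.approx(5.0, rel=0.03)


class TestDetectPeaks:
    def test_subthreshold_noise_yields_empty_train(self, noise_trace):
        train = detect_peaks(noise_trace, DetectionConfig())
        assert train.n_events == 0

    def test_injected_spikes_recovered_within_half_ms(self):
        tpl = make_template("biphasic", rate_hz=RATE)
        times = 0.3 + np.arange(10) * 0.45
        tr = zero_phase_filter(inject(tpl, times, seed=5), FilterSpec())
        train = detect_peaks(tr, DetectionConfig())
        assert train.n_events == 10
        assert np.max(np.abs(train.timestamps_s - times)) <= 0.5e-3

    def test_dead_time_keeps_larger_extremum(self, noise_trace):
        x = noise_trace.samples.copy()
        i = 100_000
        gap = int(0.4e-3 * RATE)
        x[i] = 8.0
        x[i + gap] = -10.0
        train = detect_peaks(ChannelTrace(0, "d", x, RATE), DetectionConfig(dead_time_ms=1.0))
        assert train.n_events == 1
        assert train.timestamps_s[0] == pytest.approx((i + gap) / RATE)
        assert train.polarities[0] == -1

    def test_consecutive_gaps_respect_dead_time(self):
        tpl = make_template("triphasic", rate_hz=RATE)
        tr = zero_phase_filter(inject(tpl, 0.2 + np.arange(20) * 0.2, seed=7), FilterSpec())
        cfg = DetectionConfig(dead_time_ms=1.0)
        train = detect_peaks(tr, cfg)
        if train.n_events > 1:
            assert np.min(np.diff(train.timestamps_s)) >= cfg.dead_time_ms * 1e-3

    def test_scale_invariant_timestamps(self, noise_trace):
        x = noise_trace.samples.copy()
        x[50_000] = 9.0
        x[120_000] = -7.5
        cfg = DetectionConfig()
        t1 = detect_peaks(ChannelTrace(0, "a", x, RATE), cfg)
        t2 = detect_peaks(ChannelTrace(0, "a", 250.0 * x, RATE), cfg)
        np.testing.assert_array_equal(t1.timestamps_s, t2.timestamps_s)
        np.testing.assert_array_equal(t1.polarities, t2.polarities)

    def test_translation_equivariant(self, noise_trace):
        x = noise_trace.samples.copy()
        x[50_000] = 9.0
        m = 1000
        cfg = DetectionConfig()
        t1 = detect_peaks(ChannelTrace(0, "a", x, RATE), cfg)
        t2 = detect_peaks(ChannelTrace(0, "a", np.roll(x, m), RATE), cfg)
        np.testing.assert_allclose(t2.timestamps_s, t1.timestamps_s + m / RATE)

    def test_polarity_mode_filters_sign(self, noise_trace):
        x = noise_trace.samples.copy()
        x[50_000] = 9.0
        x[120_000] = -9.0
        tr = ChannelTrace(0, "p", x, RATE)
        pos = detect_peaks(tr, DetectionConfig(polarity_mode="positive_only"))
        neg = detect_peaks(tr, DetectionConfig(polarity_mode="negative_only"))
        assert np.all(pos.polarities == 1) and pos.n_events == 1
        assert np.all(neg.polarities == -1) and neg.n_events == 1


class TestWaveforms:
    def test_boundary_event_dropped(self, noise_trace):
        x = noise_trace.samples.copy()
        x[2] = 9.0  # peak closer to the start than wave_pre
        tr = ChannelTrace(0, "b", x, RATE)
        cfg = DetectionConfig()
        train = detect_peaks(tr, cfg)
        events = extract_waveforms(tr, train, cfg)
        assert train.n_events == 1 and len(events) == 0

    def test_interior_events_all_extracted(self, noise_trace):
        x = noise_trace.samples.copy()
        for i in (50_000, 100_000, 150_000):
            x[i] = 9.0
        tr = ChannelTrace(0, "i", x, RATE)
        cfg = DetectionConfig()
        train = detect_peaks(tr, cfg)
        events = extract_waveforms(tr, train, cfg)
        assert len(events) == train.n_events == 3
        expected_len = int(round(cfg.wave_pre_ms * 1e-3 * RATE)) + \
            int(round(cfg.wave_post_ms * 1e-3 * RATE)) + 1
        assert all(e.waveform.size == expected_len for e in events)

    def test_mean_waveform_recovers_template(self):
        tpl = make_template("biphasic", rate_hz=RATE)
        times = 0.3 + np.arange(100) * 0.045
        tr = zero_phase_filter(inject(tpl, times, duration_s=5.0, seed=9), FilterSpec())
        cfg = DetectionConfig()
        train = detect_peaks(tr, cfg)
        events = extract_waveforms(tr, train, cfg)
        mean = np.stack([e.waveform for e in events]).mean(axis=0)
        pre = int(round(cfg.wave_pre_ms * 1e-3 * RATE))
        raw = np.zeros(mean.size)
        raw[pre - tpl.peak_index:pre - tpl.peak_index + tpl.samples.size] = 8.0 * tpl.samples
        corr = np.corrcoef(mean, raw)[0, 1]
        assert corr >= 0.99


class TestPolaritySorting:
    def make_event(self, pol, wf):
        return SpikeEvent(0, 0.1, pol, float(pol) * np.max(np.abs(wf)), np.asarray(wf, float))

    def test_all_negative_leaves_positive_empty(self):
        ev = [self.make_event(-1, [-1, -2, -1]) for _ in range(3)]
        s = sort_by_polarity(ev)
        assert s.positive.count == 0 and s.positive.mean_waveform is None
        assert s.negative.count == 3

    def test_single_event_mean_is_waveform(self):
        ev = [self.make_event(1, [1.0, 2.0, 1.0]), self.make_event(-1, [-3.0, -4.0, -1.0])]
        s = sort_by_polarity(ev)
        np.testing.assert_array_equal(s.positive.mean_waveform, [1.0, 2.0, 1.0])
        np.testing.assert_array_equal(s.negative.mean_waveform, [-3.0, -4.0, -1.0])
        assert s.positive.sd_waveform is None  # undefined for n=1

    def test_partition_exhaustive_and_disjoint(self):
        ev = [self.make_event(p, [p * 1.0, p * 2.0]) for p in (1, -1, 1, -1, -1)]
        s = sort_by_polarity(ev)
        assert s.positive.count + s.negative.count == len(ev)

    def test_two_opposite_templates_recovered(self):
        tpl = make_template("biphasic", rate_hz=RATE)
        rng = np.random.default_rng(3)
        mk = lambda sign: [
            SpikeEvent(0, 0.0, int(sign), sign * 8.0,
                       sign * 8.0 * tpl.samples + rng.normal(0, 0.5, tpl.samples.size))
            for _ in range(50)
        ]
        s = sort_by_polarity(mk(1) + mk(-1))
        assert np.corrcoef(s.positive.mean_waveform, 8.0 * tpl.samples)[0, 1] >= 0.99
        assert np.corrcoef(s.negative.mean_waveform, -8.0 * tpl.samples)[0, 1] >= 0.99
        # point-wise SD tracks the injected noise level
        assert np.median(s.positive.sd_waveform) == pytest.approx(0.5, rel=0.3)


def make_train(channel_id, times, pols=None):
    from qspike.detection import SpikeTrain

    times = np.asarray(times, dtype=float)
    pols = np.asarray(pols if pols is not None else np.ones_like(times), dtype=int)
    return SpikeTrain(channel_id, f"ch{channel_id:02d}", times, pols,
                      np.where(pols > 0, 10.0, -10.0), 5.0, RATE)


class TestConsolidation:
    def test_empty_trains_give_empty_table(self):
        trains = [make_train(c, []) for c in range(60)]
        table = consolidate_trains(trains, expected_channels=range(60))
        assert len(table) == 0

    def test_row_count_conservation(self):
        trains = [make_train(0, [0.1, 0.2, 0.3]), make_train(1, [0.15] + [0.5, 0.6, 0.7, 0.8]),
                  make_train(2, [])]
        table = consolidate_trains(trains)
        assert len(table) == 3 + 5 + 0

    def test_sorted_by_time_then_channel(self):
        trains = [make_train(1, [0.1, 0.3]), make_train(0, [0.1, 0.2])]
        table = consolidate_trains(trains)
        assert table["time_s"].is_monotonic_increasing
        first_two = table[table["time_s"] == 0.1]["channel"].tolist()
        assert first_two == [0, 1]

    def test_input_order_irrelevant(self):
        rng = np.random.default_rng(0)
        trains = [make_train(c, np.sort(rng.uniform(0, 10, 20))) for c in range(6)]
        a = consolidate_trains(trains)
        b = consolidate_trains(list(reversed(trains)))
        assert a.equals(b)

    def test_missing_channel_named(self):
        trains = [make_train(0, [0.1]), make_train(2, [0.2])]
        with pytest.raises(ConsolidationError, match=r"\[1, 3\]"):
            consolidate_trains(trains, expected_channels=range(4))
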