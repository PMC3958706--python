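import numpy as np
import pandas as pd
import pytest
from scipy.optimize import curve_fit

from qspike.analysis import (
    BurstConfig,
    NetworkBurst,
    active_electrodes,
    burst_statistics,
    detect_network_bursts,
    discharge_probability_profile,
    firing_rate,
    largest_burst,
    network_spike_count,
    pooled_isi,
)
from qspike.detection import SpikeTrain

RATE = 20000.0


def make_train(channel_id, times):
    times = np.asarray(times, dtype=float)
    return SpikeTrain(channel_id, f"ch{channel_id:02d}", times,
                      np.full(times.size, -1), np.full(times.size, -10.0), 5.0, RATE)


def make_table(rows):
    """rows: iterable of (channel, time_s)."""
    df = pd.DataFrame(rows, columns=["channel", "time_s"])
    df["label"] = df["channel"].map("ch{:02d}".format)
    df["polarity"] = -1
    df["amplitude"] = -10.0
    return df.sort_values(["time_s", "channel"]).reset_index(drop=True)


class TestRatesAndActivity:
    def test_empty_train_zero_rate(self):
        assert firing_rate(make_train(0, []), 60.0) == 0.0

    def test_rate_arithmetic(self):
        assert firing_rate(make_train(0, np.linspace(1, 1199, 24)), 1200.0) == pytest.approx(0.02)

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError, match="duration"):
            firing_rate(make_train(0, []), 0.0)

    def test_poisson_rate_recovery(self):
        rng = np.random.default_rng(0)
        times = np.sort(rng.uniform(0, 600, rng.poisson(5.0 * 600)))
        est = firing_rate(make_train(0, times), 600.0)
        assert abs(est - 5.0) <= 3 * np.sqrt(5.0 / 600)

    def test_activity_boundary_is_strict(self):
        at_cut = make_train(0, np.linspace(1, 1199, 24))    # exactly 0.02 Hz
        above = make_train(1, np.linspace(1, 1199, 25))     # 0.0208 Hz
        active, rates = active_electrodes([at_cut, above], 1200.0)
        assert active == [1]
        assert rates[0] == pytest.approx(0.02)

    def test_silent_channels_not_active(self):
        rng = np.random.default_rng(1)
        trains = [make_train(c, np.sort(rng.uniform(0, 60, 60))) for c in range(40)]
        trains += [make_train(40 + c, []) for c in range(20)]
        active, _ = active_electrodes(trains, 60.0)
        assert active == list(range(40))


class TestPooledIsi:
    def test_single_channel_isis(self):
        isis, _, _ = pooled_isi([make_train(0, [1.0, 2.0, 4.0])])
        assert sorted(isis.tolist()) == [1.0, 2.0]

    def test_one_spike_channels_give_empty(self):
        isis, counts, _ = pooled_isi([make_train(0, [1.0]), make_train(1, [2.0])])
        assert isis.size == 0 and counts.sum() == 0

    def test_pooling_is_within_channel(self):
        # near-coincident spikes on different channels must NOT create a tiny ISI
        isis, _, _ = pooled_isi([make_train(0, [1.0, 3.0]), make_train(1, [1.001, 3.001])])
        assert np.min(isis) == pytest.approx(2.0)


class TestNetworkSpikeCount:
    def test_empty_table_all_zero(self):
        counts, edges = network_spike_count(make_table([]), 25.0, duration_s=1.0)
        assert counts.sum() == 0 and counts.size == 40

    def test_conservation(self):
        table = make_table([(0, 0.01), (1, 0.02), (0, 0.5), (2, 0.51),
                            (1, 0.7), (0, 0.71), (2, 0.72), (1, 0.99)])
        counts, _ = network_spike_count(table, 25.0, duration_s=1.0)
        assert counts.sum() == len(table) == 8

    def test_edge_spike_lands_in_later_bin(self):
        table = make_table([(0, 0.025)])
        counts, edges = network_spike_count(table, 25.0, duration_s=0.1)
        assert counts[1] == 1 and counts[0] == 0


def cfg(threshold, min_channels=1, bin_ms=25.0, merge_gap_ms=100.0):
    return BurstConfig(bin_ms=bin_ms, count_threshold=threshold,
                       min_channels=min_channels, merge_gap_ms=merge_gap_ms)


class TestBurstDetection:
    def test_no_spikes_no_bursts(self):
        table = make_table([])
        counts, _ = network_spike_count(table, 25.0, duration_s=1.0)
        assert detect_network_bursts(counts, cfg(2), table) == []

    def test_single_channel_blocked_by_min_channels(self):
        table = make_table([(0, 0.100 + 0.002 * k) for k in range(50)])
        counts, _ = network_spike_count(table, 25.0, duration_s=1.0)
        assert detect_network_bursts(counts, cfg(2, min_channels=5), table) == []

    def test_burst_onset_offset_on_bin_edges(self):
        rows = [(c, 0.210 + 0.003 * k) for c in range(4) for k in range(20)]
        table = make_table(rows)
        counts, _ = network_spike_count(table, 25.0, duration_s=1.0)
        bursts = detect_network_bursts(counts, cfg(4, min_channels=3), table)
        assert len(bursts) == 1
        b = bursts[0]
        assert b.onset_s == pytest.approx(0.200) and b.offset_s == pytest.approx(0.275)
        assert b.n_channels == 4 and b.n_spikes == 80

    def test_nearby_runs_merge(self):
        rows = [(c, t + 0.001 * c) for c in range(3)
                for t in list(np.arange(0.2, 0.25, 0.005)) + list(np.arange(0.30, 0.35, 0.005))]
        table = make_table(rows)
        counts, _ = network_spike_count(table, 25.0, duration_s=1.0)
        merged = detect_network_bursts(counts, cfg(3, merge_gap_ms=100.0), table)
        split = detect_network_bursts(counts, cfg(3, merge_gap_ms=10.0), table)
        assert len(merged) == 1 and len(split) == 2

    def test_channel_relabeling_invariant(self):
        rng = np.random.default_rng(2)
        rows = [(int(c), float(t)) for c, t in
                zip(rng.integers(0, 8, 400), rng.uniform(0.2, 0.4, 400))]
        table = make_table(rows)
        counts, _ = network_spike_count(table, 25.0, duration_s=1.0)
        a = detect_network_bursts(counts, cfg(5, min_channels=3), table)
        perm = rng.permutation(8)
        table2 = table.assign(channel=perm[table["channel"].to_numpy()])
        b = detect_network_bursts(counts, cfg(5, min_channels=3), table2)
        assert [(x.onset_s, x.offset_s, x.n_spikes, x.n_channels) for x in a] == \
               [(x.onset_s, x.offset_s, x.n_spikes, x.n_channels) for x in b]

    def test_unresolved_config_rejected(self):
        table = make_table([])
        counts, _ = network_spike_count(table, 25.0, duration_s=1.0)
        with pytest.raises(ValueError, match="resolved"):
            detect_network_bursts(counts, BurstConfig(), table)

    def test_resolved_defaults_scale_with_active_count(self):
        r = BurstConfig().resolved(40)
        assert r.count_threshold == 10.0 and r.min_channels == 8
        r2 = BurstConfig().resolved(4)
        assert r2.count_threshold == 2.0 and r2.min_channels == 2


class TestBurstStatistics:
    def burst(self, on, off, n=10, ch=5):
        return NetworkBurst(on, off, n, ch, n)

    def test_two_burst_arithmetic(self):
        stats = burst_statistics([self.burst(1.0, 1.2), self.burst(2.0, 2.3)], 10.0)
        assert stats["mean_burst_duration_s"] == pytest.approx(0.25)
        assert stats["sd_burst_duration_s"] == pytest.approx(np.std([0.2, 0.3], ddof=1))
        assert stats["mean_ibi_s"] == pytest.approx(0.8)
        assert stats["sd_ibi_s"] is None  # single IBI

    def test_no_bursts_all_absent(self):
        stats = burst_statistics([], 10.0)
        assert stats["n_bursts"] == 0
        assert stats["mean_burst_duration_s"] is None
        assert stats["mean_ibi_s"] is None

    def test_largest_burst_tie_breaks_earlier(self):
        bursts = [self.burst(1, 1.1, n=10), self.burst(2, 2.1, n=40), self.burst(3, 3.1, n=40)]
        best, windows = largest_burst(bursts, make_table([(0, 2.05)]))
        assert best.onset_s == 2
        assert len(windows) == 3
        spans = [w[1] - w[0] for w in windows]
        assert spans == sorted(spans, reverse=True)

    def test_single_burst_selected(self):
        b = self.burst(1, 1.5)
        best, _ = largest_burst([b], make_table([(0, 1.2)]))
        assert best is b


class TestDischargeProfile:
    def test_profile_sums_to_one(self):
        rng = np.random.default_rng(3)
        rows = [(int(c), float(t)) for c, t in
                zip(rng.integers(0, 6, 500), rng.uniform(1.0, 1.5, 500))]
        table = make_table(rows)
        profile, _ = discharge_probability_profile(
            [NetworkBurst(1.0, 1.5, 500, 6, 50)], table)
        assert profile.sum() == pytest.approx(1.0)

    def test_uniform_spikes_flat_profile(self):
        times = np.linspace(1.0, 1.5, 1000, endpoint=False)
        table = make_table([(0, float(t)) for t in times])
        profile, _ = discharge_probability_profile(
            [NetworkBurst(1.0, 1.5, 1000, 1, 10)], table, profile_bin_ms=50.0)
        assert np.max(np.abs(profile - 1.0 / profile.size)) < 0.1 / profile.size

    def test_exponential_decay_constant_recovered(self):
        # spikes inside each burst drawn from a truncated exponential, tau=0.1 s
        tau, dur = 0.1, 0.5
        rng = np.random.default_rng(4)
        bursts = [NetworkBurst(float(k), float(k) + dur, 0, 4, 10) for k in range(1, 7)]
        rows = []
        for b in bursts:
            u = rng.uniform(0, 1, 2000)
            offs = -tau * np.log(1 - u * (1 - np.exp(-dur / tau)))
            rows += [(int(c), b.onset_s + float(t))
                     for c, t in zip(rng.integers(0, 8, offs.size), offs)]
        table = make_table(rows)
        profile, edges = discharge_probability_profile(bursts, table, profile_bin_ms=10.0)
        centers = 0.5 * (edges[:-1] + edges[1:])
        popt, _ = curve_fit(lambda t, a, tt: a * np.exp(-t / tt), centers, profile,
                            p0=(profile[0], 0.05))
        assert popt[1] == pytest.approx(tau, rel=0.2)

    def test_no_bursts_rejected(self):
        with pytest.raises(ValueError, match="no bursts"):
            discharge_probability_profile([], make_table([]))
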