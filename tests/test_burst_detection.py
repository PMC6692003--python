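"""Synchronous-burst detector: per-electrode stage, participation, SBPM."""

import numpy as np
import pytest

from synchroburst import (
    DetectorParams,
    ElectrodeChannel,
    compute_sbpm,
    detect_electrode_bursts,
    detect_network_bursts,
    participation_trace,
    run_detector,
)

from conftest import make_recording


def chan(eid, times):
    return ElectrodeChannel(eid, np.asarray(times, dtype=float))


class TestElectrodeBursts:
    def test_long_isis_give_no_burst(self):
        assert detect_electrode_bursts(chan("12", [0.0, 1.0, 2.0])) == []

    def test_five_spikes_at_50hz_one_burst(self):
        events = detect_electrode_bursts(
            chan("12", [10.00, 10.02, 10.04, 10.06, 10.08])
        )
        assert len(events) == 1
        ev = events[0]
        assert (ev.t_start_s, ev.t_end_s, ev.n_spikes) == (10.00, 10.08, 5)

    def test_two_runs_split_by_gap(self):
        t = [1.0, 1.02, 1.04, 1.06, 1.08, 2.08, 2.10, 2.12, 2.14, 2.16]
        events = detect_electrode_bursts(chan("12", t))
        assert len(events) == 2
        assert events[0].t_end_s < events[1].t_start_s

    def test_short_runs_below_min_spikes_dropped(self):
        events = detect_electrode_bursts(chan("12", [1.0, 1.05, 1.10, 1.15]))
        assert events == []  # 4 spikes < min_spikes=5

    def test_isi_exactly_at_threshold_is_in_burst(self):
        t = [0.0, 0.1, 0.2, 0.3, 0.4]
        events = detect_electrode_bursts(chan("12", t))
        assert len(events) == 1 and events[0].n_spikes == 5


class TestParticipationTrace:
    def test_no_bursts_all_zero(self):
        rec = make_recording({"12": [1.0, 5.0]}, duration_s=10.0)
        trace = participation_trace(rec, {"12": []})
        assert trace.counts.sum() == 0
        assert len(trace.counts) == 400  # 10 s / 25 ms

    def test_single_burst_covers_expected_bins(self):
        # oracle: closed-interval overlap of [1.0, 1.1] with 25 ms bins
        rec = make_recording({"12": list(np.linspace(1.0, 1.1, 9))},
                             duration_s=10.0)
        bursts = {"12": detect_electrode_bursts(rec.channel("12"))}
        assert len(bursts["12"]) == 1
        trace = participation_trace(rec, bursts)
        edges = trace.bin_edges_s
        expected = np.array([
            1 if (edges[b] <= 1.1 and edges[b + 1] >= 1.0) else 0
            for b in range(len(trace.counts))
        ])
        np.testing.assert_array_equal(trace.counts, expected)
        assert trace.counts.sum() == expected.sum() > 0

    def test_counts_bounded_by_channel_count(self, rng):
        spikes = {
            eid: np.sort(rng.uniform(0, 10, 200))
            for eid in ("12", "13", "14")
        }
        rec = make_recording({k: list(v) for k, v in spikes.items()},
                             duration_s=10.0)
        bursts = {
            ch.electrode_id: detect_electrode_bursts(ch) for ch in rec.channels
        }
        trace = participation_trace(rec, bursts)
        assert trace.counts.max() <= 3

    def test_inactive_electrodes_do_not_count(self):
        # an electrode with one 5-spike burst in 600 s is below 0.1 Hz
        rec = make_recording({"12": [1.0, 1.02, 1.04, 1.06, 1.08]})
        bursts = {"12": detect_electrode_bursts(rec.channel("12"))}
        trace = participation_trace(rec, bursts)
        assert trace.counts.sum() == 0


class TestNetworkBursts:
    def co_burst(self, eids, intervals, duration=60.0, rate_hz=100):
        spikes = {}
        for eid in eids:
            t = []
            for (a, b) in intervals:
                t.extend(np.arange(a, b, 1.0 / rate_hz))
            # keep electrodes active enough for the rate filter
            spikes[eid] = sorted(t)
        return make_recording(spikes, duration_s=duration)

    def test_all_zero_trace_no_bursts(self):
        rec = make_recording({"12": []}, duration_s=10.0)
        trace = participation_trace(rec, {"12": []})
        assert detect_network_bursts(trace, rec, {"12": []}) == []

    def test_three_electrodes_below_participation_min(self):
        eids = ["12", "13", "14"]
        rec = self.co_burst(eids, [(5.0, 5.8)])
        assert run_detector(rec).n_bursts == 0

    def test_merge_rule_hand_trace(self):
        eids = [f"1{c}" for c in range(2, 8)] + ["21", "22", "23", "24"]
        rec = self.co_burst(eids, [(5.0, 5.8), (5.95, 6.5)])
        result = run_detector(rec)
        assert result.n_bursts == 1
        nb = result.network_bursts[0]
        assert nb.t_start_s <= 5.0 and nb.t_end_s >= 6.5
        assert nb.peak_participation == 10
        assert nb.participating_electrodes == frozenset(eids)

    def test_distant_bursts_not_merged(self):
        eids = [f"1{c}" for c in range(2, 8)]
        rec = self.co_burst(eids, [(5.0, 5.8), (10.0, 10.8)])
        assert run_detector(rec).n_bursts == 2


class TestSbpm:
    def test_zero_bursts(self):
        res = compute_sbpm([], 600.0)
        assert res.sbpm == 0.0 and res.n_bursts == 0

    @pytest.mark.parametrize("n,duration,expected", [(3, 600, 0.3), (41, 600, 4.1)])
    def test_rate_arithmetic(self, n, duration, expected):
        from synchroburst import NetworkBurst

        bursts = [
            NetworkBurst(float(i), i + 0.5, frozenset({"12", "13"}), 5)
            for i in range(n)
        ]
        res = compute_sbpm(bursts, duration)
        assert res.sbpm == pytest.approx(expected)
        # exact integer identity
        assert res.sbpm * res.duration_min == res.n_bursts

    def test_nonpositive_duration_rejected(self):
        with pytest.raises(ValueError):
            compute_sbpm([], 0.0)


class TestDetectorProperties:
    def random_recording(self, rng, duration=120.0):
        spikes = {}
        for eid in ("12", "13", "14", "15", "16", "21", "22", "23"):
            bg = rng.uniform(0, duration, rng.poisson(0.5 * duration))
            t = [bg]
            for _ in range(rng.poisson(4)):
                onset = rng.uniform(0, duration - 1)
                t.append(onset + np.sort(rng.uniform(0, 0.8, 60)))
            spikes[eid] = np.sort(np.concatenate(t))
        return make_recording({k: list(v) for k, v in spikes.items()},
                              duration_s=duration)

    def test_determinism(self, rng):
        rec = self.random_recording(rng)
        r1, r2 = run_detector(rec), run_detector(rec)
        assert r1 == r2

    def test_lowering_participation_min_never_decreases_bursts(self, rng):
        for _ in range(5):
            rec = self.random_recording(rng)
            counts = [
                run_detector(rec, DetectorParams(participation_min=k)).n_bursts
                for k in (8, 6, 4, 2)
            ]
            assert all(a <= b for a, b in zip(counts, counts[1:]))

    def test_empty_recording_zero_sbpm(self):
        rec = make_recording({}, duration_s=600.0)
        assert run_detector(rec).sbpm == 0.0


class TestParams:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"isi_max_s": 0.0},
            {"min_spikes": 1},
            {"participation_min": 1},
            {"bin_s": -0.1},
        ],
    )
    def test_invalid_params_rejected(self, kwargs):
        with pytest.raises(ValueError):
            DetectorParams(**kwargs)
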