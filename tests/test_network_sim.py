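"""Network model: connectivity, membrane, synapse/metabolism, integration."""

import math

import numpy as np
import pytest

from synchroburst import (
    ConnectivityConfig,
    MembraneConfig,
    MetabolismConfig,
    NetworkConfig,
    NoiseConfig,
    SynapseConfig,
    build_lattice_connectivity,
    effective_recovery_rate,
    hh_derivatives,
    on_presynaptic_spike,
    result_to_recording,
    simulate_network,
)
from synchroburst.network_sim import (
    expected_edge_count,
    resting_fixed_point,
)

SILENT = NoiseConfig(nu_ext_hz=0.0, g_ext=0.0)


class TestConnectivity:
    def test_p_max_zero_gives_no_edges(self):
        cfg = NetworkConfig(connectivity=ConnectivityConfig(p_max=0.0))
        assert build_lattice_connectivity(cfg).n_edges == 0

    def test_p_max_one_infinite_range_fully_connected(self):
        cfg = NetworkConfig(
            grid=(5, 5),
            connectivity=ConnectivityConfig(p_max=1.0, lambda_d=1e9),
            seed=4,
        )
        assert build_lattice_connectivity(cfg).n_edges == 25 * 24

    def test_edge_count_matches_brute_force_expectation(self):
        cfg = NetworkConfig(seed=12)
        mu = expected_edge_count(cfg)  # direct summation over all pairs
        graph = build_lattice_connectivity(cfg)
        sd = math.sqrt(mu)  # Poisson-binomial SD is below sqrt(mean)
        assert abs(graph.n_edges - mu) < 4 * sd

    def test_no_self_edges_and_reproducible(self):
        cfg = NetworkConfig(grid=(6, 6), seed=9)
        g1 = build_lattice_connectivity(cfg)
        g2 = build_lattice_connectivity(cfg)
        np.testing.assert_array_equal(g1.indices, g2.indices)
        for j in range(36):
            targets = g1.indices[g1.indptr[j]:g1.indptr[j + 1]]
            assert j not in targets

    def test_invalid_p_max_rejected(self):
        with pytest.raises(ValueError):
            ConnectivityConfig(p_max=1.5)


class TestMembrane:
    def test_resting_fixed_point_has_zero_derivatives(self):
        mem = MembraneConfig()
        V, n0, h0 = resting_fixed_point(mem)
        dV, dn, dh = hh_derivatives(V, n0, h0, 0.0, 0.0, mem)
        assert abs(dV) < 1e-6 and abs(dn) < 1e-9 and abs(dh) < 1e-9

    def test_h_zero_kills_sodium_current(self):
        mem = MembraneConfig(g_K=0.0, g_L=0.0)
        dV, _, _ = hh_derivatives(0.0, 0.0, 0.0, 0.0, 0.0, mem)
        assert dV == 0.0  # only Na term could contribute and h=0 removes it

    def test_leak_reversal_is_equilibrium_without_gates(self):
        mem = MembraneConfig()
        dV, _, _ = hh_derivatives(mem.E_L, 0.0, 0.0, 0.0, 0.0, mem)
        assert dV == pytest.approx(0.0, abs=1e-12)


class TestSynapseAndMetabolism:
    SYN = SynapseConfig()
    MET = MetabolismConfig()

    def test_release_arithmetic(self):
        syn = SynapseConfig(U=0.5)
        released, D, _A = on_presynaptic_spike(1.0, 1.0, syn, self.MET)
        assert released == 0.5 and D == 0.5

    def test_empty_pool_releases_nothing(self):
        released, D, A = on_presynaptic_spike(0.0, 0.7, self.SYN, self.MET)
        assert released == 0.0 and D == 0.0 and A == 0.7

    def test_two_spikes_geometric_depletion(self):
        syn = SynapseConfig(U=0.5)
        r1, D, A = on_presynaptic_spike(1.0, 1.0, syn, self.MET)
        r2, D, A = on_presynaptic_spike(D, A, syn, self.MET)
        assert r1 + r2 == pytest.approx(0.75)

    def test_cumulative_release_never_exceeds_initial_pool(self):
        D, A, total = 1.0, 1.0, 0.0
        for _ in range(200):
            r, D, A = on_presynaptic_spike(D, A, self.SYN, self.MET)
            total += r
        assert total <= 1.0 + 1e-12

    def test_recovery_rate_zero_at_empty_store(self):
        assert effective_recovery_rate(0.0, self.SYN, self.MET) == 0.0

    def test_recovery_rate_half_saturation(self):
        met = MetabolismConfig(K_A=0.2)
        assert effective_recovery_rate(0.2, self.SYN, met) == pytest.approx(
            self.SYN.k_rec0 / 2
        )

    def test_recovery_rate_strictly_increasing_in_A(self):
        grid = np.linspace(0.0, 1.0, 100)
        vals = [effective_recovery_rate(a, self.SYN, self.MET) for a in grid]
        assert all(b > a for a, b in zip(vals, vals[1:]))


class TestSimulation:
    def test_no_drive_no_spikes(self):
        cfg = NetworkConfig(
            grid=(4, 4), duration_s=2.0, noise=SILENT,
            synapse=SynapseConfig(g_max=0.0), seed=0,
        )
        assert simulate_network(cfg).n_spikes == 0

    def test_sodium_block_silences_network(self):
        # TTX analog: zero Na conductance, default external drive
        cfg = NetworkConfig(
            grid=(6, 6), duration_s=20.0, seed=2,
            membrane=MembraneConfig(g_Na=0.0),
        )
        assert simulate_network(cfg).n_spikes == 0

    def test_raster_deterministic_and_sorted(self):
        cfg = NetworkConfig(grid=(6, 6), duration_s=10.0, seed=5)
        s1 = simulate_network(cfg)
        s2 = simulate_network(cfg)
        np.testing.assert_array_equal(s1.spike_times_s, s2.spike_times_s)
        np.testing.assert_array_equal(s1.neuron_index, s2.neuron_index)
        assert np.all(np.diff(s1.spike_times_s) >= 0)

    def test_refractory_enforced_per_neuron(self):
        cfg = NetworkConfig(grid=(6, 6), duration_s=20.0, seed=5)
        sim = simulate_network(cfg)
        for i in np.unique(sim.neuron_index):
            t = sim.spikes_of(i)
            if t.size > 1:
                assert np.min(np.diff(t)) >= cfg.refractory_ms * 1e-3 - 1e-12

    def test_vesicle_and_energy_stay_in_unit_interval(self, rng):
        for _ in range(15):
            cfg = NetworkConfig(
                grid=(int(rng.integers(3, 7)), int(rng.integers(3, 7))),
                duration_s=3.0,
                seed=int(rng.integers(0, 2**31)),
                synapse=SynapseConfig(
                    g_max=float(rng.uniform(0, 0.3)),
                    U=float(rng.uniform(0.05, 1.0)),
                    k_rec0=float(rng.uniform(0.1, 5.0)),
                ),
                metabolism=MetabolismConfig(
                    G=float(rng.uniform(0, 1)),
                    c_A=float(rng.uniform(0, 1)),
                    K_A=float(rng.uniform(0.01, 1.0)),
                    k_gen_max=float(rng.uniform(0, 2)),
                ),
                noise=NoiseConfig(nu_ext_hz=float(rng.uniform(0, 3)), g_ext=0.1),
            )
            b = simulate_network(cfg).state_bounds
            assert 0.0 <= b["D_min"] <= b["D_max"] <= 1.0
            assert 0.0 <= b["A_min"] <= b["A_max"] <= 1.0

    def test_traces_sampled_for_requested_neurons(self):
        cfg = NetworkConfig(grid=(4, 4), duration_s=1.0, seed=3,
                            trace_neurons=(0, 5), trace_every_ms=1.0)
        sim = simulate_network(cfg)
        assert sim.trace_V.shape == (1000, 2)
        assert np.all(np.isfinite(sim.trace_V))
        assert sim.trace_D.min() >= 0.0 and sim.trace_D.max() <= 1.0

    def test_python_gate_path_matches_default_gate(self):
        """The pluggable-recovery path reproduces the compiled kernel's
        raster when given the same Michaelis-Menten gate.  The two paths
        differ only in micro-optimisations (rest-state freeze, strided
        vesicle updates), so spike counts and times agree closely."""
        cfg = NetworkConfig(grid=(4, 4), duration_s=3.0, seed=8)
        met = cfg.metabolism
        sim_fast = simulate_network(cfg)
        sim_py = simulate_network(
            cfg, recovery_gate=lambda a: a / (a + met.K_A)
        )
        assert sim_py.n_spikes > 0
        assert abs(sim_fast.n_spikes - sim_py.n_spikes) <= max(
            2, 0.05 * sim_py.n_spikes
        )
        k = min(10, sim_fast.n_spikes, sim_py.n_spikes)
        np.testing.assert_allclose(
            sim_fast.spike_times_s[:k], sim_py.spike_times_s[:k], atol=2e-3
        )


class TestElectrodeMapping:
    def test_empty_raster_gives_60_empty_channels(self):
        cfg = NetworkConfig(grid=(20, 20), duration_s=1.0, noise=SILENT,
                            synapse=SynapseConfig(g_max=0.0), seed=0)
        rec = result_to_recording(simulate_network(cfg))
        assert len(rec.channels) == 60
        assert rec.n_spikes == 0

    def test_single_neuron_maps_to_single_channel(self):
        from synchroburst.network_sim import SimulationResult

        cfg = NetworkConfig(grid=(20, 20), duration_s=5.0)
        sim = SimulationResult(
            neuron_index=np.array([105, 105, 105]),
            spike_times_s=np.array([1.0, 2.0, 3.0]),
            config=cfg, seed=0,
        )
        rec = result_to_recording(sim)
        occupied = [ch for ch in rec.channels if ch.n_spikes]
        assert len(occupied) == 1
        np.testing.assert_array_equal(occupied[0].spike_times_s, [1.0, 2.0, 3.0])

    def test_spike_count_conserved_outside_corner_tiles(self, rng):
        cfg = NetworkConfig(grid=(20, 20), duration_s=5.0)
        idx = rng.integers(0, 400, 500)
        from synchroburst.network_sim import SimulationResult

        sim = SimulationResult(
            neuron_index=idx,
            spike_times_s=np.sort(rng.uniform(0, 5, 500)),
            config=cfg, seed=0,
        )
        # corner tiles of the 8x8 overlay hold no electrode
        r, c = idx // 20, idx % 20
        tr, tc = np.minimum(r * 8 // 20, 7) + 1, np.minimum(c * 8 // 20, 7) + 1
        in_corner = np.isin(tr * 10 + tc, [11, 18, 81, 88])
        rec = result_to_recording(sim)
        assert rec.n_spikes == int((~in_corner).sum())


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"dt_ms": 0.0},
            {"duration_s": -1.0},
            {"grid": (0, 5)},
            {"D_init": 1.5},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            NetworkConfig(**kwargs)

    def test_invalid_release_fraction_rejected(self):
        with pytest.raises(ValueError):
            SynapseConfig(U=0.0)

    def test_glucose_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            MetabolismConfig(G=2.0)
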