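"""Metabolically-coupled excitatory spiking-network model.

400 neurons on a 20x20 lattice, connected by random, sparse excitatory
synapses whose probability decays exponentially with Euclidean lattice
distance.  Each neuron is a reduced Hodgkin–Huxley model (dynamic ``n`` and
``h`` gates, instantaneous ``m = m_inf(V)``, classic squid-axon rates and
conductances).  Synapses are AMPA-like conductances (reversal 0 mV,
exponential decay) subject to short-term depression through a single
docked-vesicle pool: a presynaptic spike releases the fraction ``U`` of the
docked pool ``D``, and ``D`` recovers toward 1 at rate ``k_rec`` between
spikes.

The metabolic coupling makes ``k_rec`` energy-dependent.  Each presynaptic
terminal carries a dimensionless energy store ``A`` in [0, 1]: every release
costs ``c_A * U * D`` of it, regeneration proceeds at ``k_gen_max * G *
(1 - A)`` where ``G`` in [0, 1] is extracellular glucose availability, and
the recovery rate is Michaelis–Menten-gated,

    k_rec(A) = k_rec0 * A / (A + K_A).

When glucose is plentiful (G ~ 1) the store stays charged, vesicle recovery
is fast, and recurrent excitation plus depression produces the familiar
self-terminating network-wide bursts.  When glucose is scarce the energy
store drains faster than it refills during bursting, recovery stalls, the
docked pool stays depleted, and synchronous bursting slows or stops — while
spontaneous spiking driven by external Poisson kicks persists.  Zeroing the
synaptic conductance reproduces AMPA-receptor blockade (CNQX); zeroing the
sodium conductance reproduces TTX silencing.

Integration is fixed-step Heun (RK2) for (V, n, h) with analytic
exponential decay of conductances, event-driven conductance increments with
a fixed axonal+synaptic delay, and external Poisson drive; everything is
reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np
from numba import njit

from .spike_data import ElectrodeChannel, Recording

__all__ = [
    "ConnectivityConfig",
    "MembraneConfig",
    "SynapseConfig",
    "MetabolismConfig",
    "NoiseConfig",
    "NetworkConfig",
    "ConnectivityGraph",
    "SimulationResult",
    "build_lattice_connectivity",
    "hh_derivatives",
    "on_presynaptic_spike",
    "effective_recovery_rate",
    "simulate_network",
    "result_to_recording",
]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ConnectivityConfig:
    """Distance-decaying random connectivity on the lattice.

    An ordered pair (j -> i), j != i, is connected with probability
    ``p_max * exp(-d_ij / lambda_d)`` with ``d_ij`` the Euclidean distance in
    lattice units; boundaries are open (no torus).
    """

    p_max: float = 0.6
    lambda_d: float = 2.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_max <= 1.0):
            raise ValueError("p_max must be in [0, 1]")
        if self.lambda_d <= 0:
            raise ValueError("lambda_d must be positive")


@dataclass(frozen=True)
class MembraneConfig:
    """Reduced-HH membrane parameters, classic squid-axon values.

    Units: C_m in uF/cm^2, conductances in mS/cm^2, potentials in mV,
    i_app in uA/cm^2 (constant injected current, 0 by default).
    """

    C_m: float = 1.0
    g_Na: float = 120.0
    E_Na: float = 50.0
    g_K: float = 36.0
    E_K: float = -77.0
    g_L: float = 0.3
    E_L: float = -54.4
    V_init: float = -65.0
    i_app: float = 0.0

    def __post_init__(self) -> None:
        for name in ("C_m", "g_Na", "g_K", "g_L"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.C_m == 0:
            raise ValueError("C_m must be positive")


@dataclass(frozen=True)
class SynapseConfig:
    """Depressing AMPA-like synapse with a single docked-vesicle pool.

    ``g_max`` is the conductance increment a target receives per unit of
    released vesicle fraction; each presynaptic spike releases ``U * D``.
    ``k_rec0`` is the baseline (energy-unconstrained) vesicle recovery rate;
    its reciprocal is the depression recovery time constant.
    """

    g_max: float = 0.1
    tau_syn_ms: float = 3.0
    E_syn: float = 0.0
    U: float = 0.4
    k_rec0: float = 1.0

    def __post_init__(self) -> None:
        if self.g_max < 0 or self.k_rec0 < 0:
            raise ValueError("g_max and k_rec0 must be non-negative")
        if not (0.0 < self.U <= 1.0):
            raise ValueError("U must be in (0, 1]")
        if self.tau_syn_ms <= 0:
            raise ValueError("tau_syn_ms must be positive")


@dataclass(frozen=True)
class MetabolismConfig:
    """Presynaptic energy store gating vesicle recovery.

    ``G`` is dimensionless glucose availability (1 ~ glucose-rich culture
    media, 0.1 ~ depleted); ``k_gen_max * G * (1 - A)`` regenerates the
    store, each release event costs ``c_A * U * D``, and recovery is gated
    as ``k_rec0 * A / (A + K_A)``.
    """

    G: float = 1.0
    k_gen_max: float = 0.5
    K_A: float = 0.5
    c_A: float = 0.3
    A_init: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.G <= 1.0):
            raise ValueError("G must be in [0, 1]")
        for name in ("k_gen_max", "K_A", "c_A"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0.0 <= self.A_init <= 1.0):
            raise ValueError("A_init must be in [0, 1]")


@dataclass(frozen=True)
class NoiseConfig:
    """External Poisson conductance kicks per neuron (spontaneous drive)."""

    nu_ext_hz: float = 0.5
    g_ext: float = 0.1

    def __post_init__(self) -> None:
        if self.nu_ext_hz < 0 or self.g_ext < 0:
            raise ValueError("noise rates/conductances must be non-negative")


@dataclass(frozen=True)
class NetworkConfig:
    """Complete, reproducible specification of one network simulation."""

    grid: tuple[int, int] = (20, 20)
    seed: int = 0
    dt_ms: float = 0.05
    duration_s: float = 60.0
    connectivity: ConnectivityConfig = field(default_factory=ConnectivityConfig)
    membrane: MembraneConfig = field(default_factory=MembraneConfig)
    synapse: SynapseConfig = field(default_factory=SynapseConfig)
    metabolism: MetabolismConfig = field(default_factory=MetabolismConfig)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    spike_threshold_mV: float = -20.0
    refractory_ms: float = 2.0
    delay_ms: float = 1.5
    D_init: float = 1.0
    trace_neurons: tuple[int, ...] = ()
    trace_every_ms: float = 1.0

    def __post_init__(self) -> None:
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        rows, cols = self.grid
        if rows < 1 or cols < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not (0.0 <= self.D_init <= 1.0):
            raise ValueError("D_init must be in [0, 1]")
        if self.delay_ms < self.dt_ms:
            raise ValueError("delay_ms must be at least one time step")

    @property
    def n_neurons(self) -> int:
        return self.grid[0] * self.grid[1]


@dataclass(frozen=True)
class ConnectivityGraph:
    """Directed adjacency in CSR form: presynaptic j -> indices[indptr[j]:indptr[j+1]]."""

    n_neurons: int
    indptr: np.ndarray
    indices: np.ndarray
    weights: np.ndarray

    @property
    def n_edges(self) -> int:
        return int(self.indices.size)


@dataclass
class SimulationResult:
    """Spike raster plus optional sampled state traces."""

    neuron_index: np.ndarray  # int, per spike
    spike_times_s: np.ndarray  # float, per spike, sorted
    config: NetworkConfig
    seed: int
    trace_times_s: Optional[np.ndarray] = None
    trace_V: Optional[np.ndarray] = None  # (n_samples, n_trace_neurons)
    trace_D: Optional[np.ndarray] = None
    trace_A: Optional[np.ndarray] = None
    #: running extrema of D and A over all neurons and steps, for invariant
    #: checks: keys D_min, D_max, A_min, A_max (None on the python path)
    state_bounds: Optional[dict] = None

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def spikes_of(self, neuron: int) -> np.ndarray:
        return self.spike_times_s[self.neuron_index == neuron]


# ---------------------------------------------------------------------------
# Connectivity
# ---------------------------------------------------------------------------

def lattice_positions(grid: tuple[int, int]) -> np.ndarray:
    """(n_neurons, 2) array of (row, col) lattice coordinates."""
    rows, cols = grid
    rr, cc = np.meshgrid(np.arange(rows), np.arange(cols), indexing="ij")
    return np.column_stack([rr.ravel(), cc.ravel()]).astype(np.float64)


def expected_edge_count(config: NetworkConfig) -> float:
    """Exact expectation of the edge count by direct summation over pairs."""
    pos = lattice_positions(config.grid)
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    p = config.connectivity.p_max * np.exp(-d / config.connectivity.lambda_d)
    np.fill_diagonal(p, 0.0)
    return float(p.sum())


def build_lattice_connectivity(config: NetworkConfig) -> ConnectivityGraph:
    """Draw the random distance-decaying connectivity graph.

    Independent Bernoulli draws per ordered pair with success probability
    ``p_max * exp(-d / lambda_d)``; no self-edges; reproducible from
    (config, seed).
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x5EED]))
    pos = lattice_positions(config.grid)
    n = pos.shape[0]
    d = np.sqrt(((pos[:, None, :] - pos[None, :, :]) ** 2).sum(-1))
    p = config.connectivity.p_max * np.exp(-d / config.connectivity.lambda_d)
    np.fill_diagonal(p, 0.0)
    adj = rng.random((n, n)) < p
    indptr = np.zeros(n + 1, dtype=np.int64)
    indptr[1:] = np.cumsum(adj.sum(axis=1))
    indices = np.flatnonzero(adj.ravel()) % n
    # row-major flatnonzero orders targets within each presynaptic row
    weights = np.ones(indices.size, dtype=np.float64)
    return ConnectivityGraph(n, indptr, indices.astype(np.int64), weights)


# ---------------------------------------------------------------------------
# Single-step physiology (pure-python reference forms, used by tests and by
# the numba kernel below via identical formulas)
# ---------------------------------------------------------------------------

def _vtrap(x: float, y: float) -> float:
    """x / (1 - exp(-x/y)) with the removable singularity at x=0 filled."""
    if abs(x / y) < 1e-6:
        return y * (1.0 + x / (2.0 * y))
    return x / (1.0 - math.exp(-x / y))


def alpha_n(V: float) -> float:
    return 0.01 * _vtrap(V + 55.0, 10.0)


def beta_n(V: float) -> float:
    return 0.125 * math.exp(-(V + 65.0) / 80.0)


def alpha_h(V: float) -> float:
    return 0.07 * math.exp(-(V + 65.0) / 20.0)


def beta_h(V: float) -> float:
    return 1.0 / (1.0 + math.exp(-(V + 35.0) / 10.0))


def alpha_m(V: float) -> float:
    return 0.1 * _vtrap(V + 40.0, 10.0)


def beta_m(V: float) -> float:
    return 4.0 * math.exp(-(V + 65.0) / 18.0)


def m_inf(V: float) -> float:
    am, bm = alpha_m(V), beta_m(V)
    return am / (am + bm)


def hh_derivatives(
    V: float,
    n: float,
    h: float,
    g_syn: float,
    g_ext: float,
    mem: MembraneConfig,
    E_syn: float = 0.0,
) -> tuple[float, float, float]:
    """Time derivatives (dV/dt, dn/dt, dh/dt) of the reduced HH model.

    Sodium activation is instantaneous (``m = m_inf(V)``); ``n`` and ``h``
    follow first-order kinetics with the standard rate functions.  Synaptic
    and external conductances appear as a single ohmic term toward E_syn.
    Units: mV, ms, mS/cm^2, uA/cm^2.
    """
    m = m_inf(V)
    i_Na = mem.g_Na * m * m * m * h * (V - mem.E_Na)
    i_K = mem.g_K * n ** 4 * (V - mem.E_K)
    i_L = mem.g_L * (V - mem.E_L)
    i_syn = (g_syn + g_ext) * (V - E_syn)
    dV = (-i_Na - i_K - i_L - i_syn + mem.i_app) / mem.C_m
    dn = alpha_n(V) * (1.0 - n) - beta_n(V) * n
    dh = alpha_h(V) * (1.0 - h) - beta_h(V) * h
    return dV, dn, dh


def resting_state(mem: MembraneConfig) -> tuple[float, float, float]:
    """Gating variables at their steady state for V = V_init."""
    V = mem.V_init
    n0 = alpha_n(V) / (alpha_n(V) + beta_n(V))
    h0 = alpha_h(V) / (alpha_h(V) + beta_h(V))
    return V, n0, h0


def resting_fixed_point(mem: MembraneConfig) -> tuple[float, float, float]:
    """The true resting fixed point (V*, n*, h*) of the input-free membrane.

    Solves dV/dt = 0 with gates at their voltage steady states by
    bisection; used both as an oracle in tests and to anchor the kernel's
    quiescence optimisation (neurons settled at rest with no synaptic
    input skip integration until input arrives).
    """
    from scipy.optimize import brentq

    def f(V: float) -> float:
        n0 = alpha_n(V) / (alpha_n(V) + beta_n(V))
        h0 = alpha_h(V) / (alpha_h(V) + beta_h(V))
        dV, _, _ = hh_derivatives(V, n0, h0, 0.0, 0.0, mem)
        return dV

    V_star = float(brentq(f, -90.0, -30.0, xtol=1e-12))
    n_star = alpha_n(V_star) / (alpha_n(V_star) + beta_n(V_star))
    h_star = alpha_h(V_star) / (alpha_h(V_star) + beta_h(V_star))
    return V_star, n_star, h_star


def on_presynaptic_spike(
    D: float, A: float, syn: SynapseConfig, met: MetabolismConfig
) -> tuple[float, float, float]:
    """Vesicle release and energy cost of one presynaptic spike.

    Returns ``(released, D_new, A_new)``: the spike releases the fraction
    ``U * D`` of the docked pool, leaving ``D * (1 - U)``, and debits the
    energy store by ``c_A * U * D`` (floored at 0).  Each postsynaptic
    target then receives a conductance increment ``g_max * released * w``.
    """
    released = syn.U * D
    D_new = D * (1.0 - syn.U)
    A_new = max(0.0, A - met.c_A * released)
    return released, D_new, A_new


def effective_recovery_rate(A: float, syn: SynapseConfig, met: MetabolismConfig) -> float:
    """Energy-gated vesicle recovery rate k_rec0 * A / (A + K_A) (1/s)."""
    if met.K_A == 0.0:
        return syn.k_rec0 if A > 0 else 0.0
    return syn.k_rec0 * A / (A + met.K_A)


# ---------------------------------------------------------------------------
# The integration kernel
# ---------------------------------------------------------------------------

@njit(cache=True, fastmath=True, inline="always")
def _hh_rhs(v, ni, hi, gtot, C_m, g_Na, E_Na, g_K, E_K, g_L, E_L, i_app, E_syn):
    """Reduced-HH right-hand side; identical formulas to hh_derivatives."""
    x = v + 40.0
    if x > 1e-4 or x < -1e-4:
        am = 0.1 * x / (1.0 - math.exp(-x / 10.0))
    else:
        am = 1.0 * (1.0 + x / 20.0)
    bm = 4.0 * math.exp(-(v + 65.0) / 18.0)
    m = am / (am + bm)
    x = v + 55.0
    if x > 1e-4 or x < -1e-4:
        an = 0.01 * x / (1.0 - math.exp(-x / 10.0))
    else:
        an = 0.1 * (1.0 + x / 20.0)
    bn = 0.125 * math.exp(-(v + 65.0) / 80.0)
    ah = 0.07 * math.exp(-(v + 65.0) / 20.0)
    bh = 1.0 / (1.0 + math.exp(-(v + 35.0) / 10.0))
    dv = (
        -g_Na * m * m * m * hi * (v - E_Na)
        - g_K * ni * ni * ni * ni * (v - E_K)
        - g_L * (v - E_L)
        - gtot * (v - E_syn)
        + i_app
    ) / C_m
    dn = an * (1.0 - ni) - bn * ni
    dh = ah * (1.0 - hi) - bh * hi
    return dv, dn, dh


@njit(cache=True, fastmath=True)
def _kernel(  # noqa: C901 - monolithic for speed
    n_neurons: int,
    n_steps: int,
    dt: float,  # ms
    # membrane
    C_m: float, g_Na: float, E_Na: float, g_K: float, E_K: float,
    g_L: float, E_L: float, i_app: float,
    # synapse
    E_syn: float, g_syn_decay: float, U: float, k_rec0: float, g_max: float,
    # metabolism
    G: float, k_gen_max: float, K_A: float, c_A: float,
    # spiking
    v_thresh: float, refr_steps: int, delay_steps: int,
    # quiescence: true resting fixed point for the freeze optimisation
    freeze_ok: bool, V_rest: float, n_rest: float, h_rest: float,
    # connectivity (CSR)
    indptr: np.ndarray, indices: np.ndarray, weights: np.ndarray,
    # external drive: events sorted by (step, neuron)
    ext_steps: np.ndarray, ext_neurons: np.ndarray, g_ext_inc: float,
    # state (modified in place)
    V: np.ndarray, n: np.ndarray, h: np.ndarray,
    g_syn: np.ndarray, g_ext: np.ndarray,
    D: np.ndarray, A: np.ndarray,
    # outputs
    spike_neuron: np.ndarray, spike_step: np.ndarray,
    trace_idx: np.ndarray, trace_every: int,
    trace_V: np.ndarray, trace_D: np.ndarray, trace_A: np.ndarray,
    dminmax: np.ndarray,  # [D_min, D_max, A_min, A_max] running extrema
):
    """Fixed-step Heun integration of the full network.  Returns
    (n_spikes, error_neuron, error_step); error_neuron >= 0 flags divergence,
    error_neuron == -2 flags spike-buffer overflow."""
    dt_s = dt * 1.0e-3
    buf = np.zeros((delay_steps + 1, n_neurons))
    refr = np.zeros(n_neurons, dtype=np.int64)
    frozen = np.zeros(n_neurons, dtype=np.uint8)
    n_spikes = 0
    ev = 0
    n_ev = ext_steps.size
    n_trace = trace_idx.size
    cap = spike_neuron.size
    # The vesicle pool D and energy store A evolve on ~1 s scales, so they
    # are advanced in 1 ms sweeps rather than every membrane step.
    da_every = max(1, int(round(1.0 / dt)))
    dt_da = da_every * dt_s

    for step in range(n_steps):
        slot = step % (delay_steps + 1)
        while ev < n_ev and ext_steps[ev] == step:
            g_ext[ext_neurons[ev]] += g_ext_inc
            ev += 1

        if step % da_every == 0:
            for i in range(n_neurons):
                a = A[i]
                k_rec = k_rec0 * a / (a + K_A) if (a + K_A) > 0.0 else 0.0
                d_ = D[i] + dt_da * k_rec * (1.0 - D[i])
                a = a + dt_da * k_gen_max * G * (1.0 - a)
                if d_ > 1.0:
                    d_ = 1.0
                if a > 1.0:
                    a = 1.0
                D[i] = d_
                A[i] = a
                if d_ < dminmax[0]:
                    dminmax[0] = d_
                if d_ > dminmax[1]:
                    dminmax[1] = d_
                if a < dminmax[2]:
                    dminmax[2] = a
                if a > dminmax[3]:
                    dminmax[3] = a

        # Heun (RK2) step for V, n, h with conductances frozen over the
        # step.  Depolarized or strongly driven neurons are subcycled:
        # the spike upstroke with instantaneous m_inf(V) is stiff at
        # dt = 0.05 ms, and subcycling keeps the scheme stable and the
        # spike shape accurate while resting neurons pay a single step.
        # Neurons settled exactly at the resting fixed point with no
        # synaptic drive are frozen and skipped until input arrives.
        for i in range(n_neurons):
            inc = buf[slot, i]
            buf[slot, i] = 0.0
            if frozen[i] == 1:
                if inc == 0.0 and g_ext[i] == 0.0:
                    continue
                frozen[i] = 0
            g_s = g_syn[i] + inc
            g_e = g_ext[i]
            gtot = g_s + g_e
            v0 = V[i]
            v = v0
            ni = n[i]
            hi = h[i]

            if v > -50.0 or gtot > 6.0:
                nsub = 16 + 8 * int(gtot / 12.0)
            elif v > -60.0 or gtot > 1.5:
                nsub = 4
            else:
                nsub = 1
            hdt = dt / nsub
            for _ in range(nsub):
                dv1, dn1, dh1 = _hh_rhs(
                    v, ni, hi, gtot, C_m, g_Na, E_Na, g_K, E_K, g_L, E_L,
                    i_app, E_syn,
                )
                vp = v + hdt * dv1
                np_ = ni + hdt * dn1
                hp = hi + hdt * dh1
                dv2, dn2, dh2 = _hh_rhs(
                    vp, np_, hp, gtot, C_m, g_Na, E_Na, g_K, E_K, g_L, E_L,
                    i_app, E_syn,
                )
                v = v + 0.5 * hdt * (dv1 + dv2)
                ni = ni + 0.5 * hdt * (dn1 + dn2)
                hi = hi + 0.5 * hdt * (dh1 + dh2)
                if ni < 0.0:
                    ni = 0.0
                elif ni > 1.0:
                    ni = 1.0
                if hi < 0.0:
                    hi = 0.0
                elif hi > 1.0:
                    hi = 1.0
            v_new = v
            n[i] = ni
            h[i] = hi

            if v_new > 500.0 or v_new < -500.0 or v_new != v_new:
                return n_spikes, i, step

            # threshold crossing outside refractory registers a spike
            if refr[i] > 0:
                refr[i] -= 1
            elif v0 < v_thresh and v_new >= v_thresh:
                if n_spikes >= cap:
                    return n_spikes, -2, step
                spike_neuron[n_spikes] = i
                spike_step[n_spikes] = step
                n_spikes += 1
                refr[i] = refr_steps
                released = U * D[i]
                a = max(0.0, A[i] - c_A * released)
                d_ = D[i] * (1.0 - U)
                D[i] = d_
                A[i] = a
                if d_ < dminmax[0]:
                    dminmax[0] = d_
                if a < dminmax[2]:
                    dminmax[2] = a
                if g_max > 0.0 and released > 0.0:
                    dslot = (step + delay_steps) % (delay_steps + 1)
                    for k in range(indptr[i], indptr[i + 1]):
                        buf[dslot, indices[k]] += g_max * released * weights[k]

            V[i] = v_new
            # analytic conductance decay over the step
            g_syn[i] = g_s * g_syn_decay
            g_ext[i] = g_e * g_syn_decay

            # freeze once fully relaxed: snap to the fixed point so the
            # state is exactly stationary until the next input
            if (
                freeze_ok
                and refr[i] == 0
                and gtot < 1e-7
                and -1e-2 < v_new - V_rest < 1e-2
                and -1e-4 < ni - n_rest < 1e-4
                and -1e-4 < hi - h_rest < 1e-4
            ):
                V[i] = V_rest
                n[i] = n_rest
                h[i] = h_rest
                g_syn[i] = 0.0
                g_ext[i] = 0.0
                frozen[i] = 1

        # state traces
        if n_trace > 0 and step % trace_every == 0:
            row = step // trace_every
            for j in range(n_trace):
                idx = trace_idx[j]
                trace_V[row, j] = V[idx]
                trace_D[row, j] = D[idx]
                trace_A[row, j] = A[idx]

    return n_spikes, -1, n_steps


def _external_events(
    config: NetworkConfig, rng: np.random.Generator, n_steps: int
) -> tuple[np.ndarray, np.ndarray]:
    """Pre-draw external Poisson kick times, sorted by (step, neuron)."""
    nu = config.noise.nu_ext_hz
    if nu <= 0 or config.noise.g_ext <= 0:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    n = config.n_neurons
    counts = rng.poisson(nu * config.duration_s, size=n)
    total = int(counts.sum())
    neurons = np.repeat(np.arange(n, dtype=np.int64), counts)
    times = rng.uniform(0.0, config.duration_s, size=total)
    steps = np.minimum(
        (times / (config.dt_ms * 1e-3)).astype(np.int64), n_steps - 1
    )
    order = np.lexsort((neurons, steps))
    return steps[order], neurons[order]


def simulate_network(
    config: NetworkConfig,
    graph: Optional[ConnectivityGraph] = None,
    recovery_gate: Optional[Callable[[float], float]] = None,
) -> SimulationResult:
    """Run one network simulation.

    Parameters
    ----------
    config
        Full parameter set; ``config.seed`` drives connectivity and noise.
    graph
        Pre-built connectivity; built from the config when omitted.
    recovery_gate
        Optional replacement for the default Michaelis–Menten energy gate;
        maps A in [0,1] to a multiplier in [0,1] on ``k_rec0``.  Supplying a
        gate routes integration through a slower non-compiled path, so it is
        intended for small exploratory runs.

    Returns
    -------
    SimulationResult
        The spike raster (sorted by time, ties in neuron-index order) and,
        if ``config.trace_neurons`` is non-empty, sampled V/D/A traces.

    Raises
    ------
    FloatingPointError
        If any membrane potential leaves [-500, 500] mV.
    """
    if graph is None:
        graph = build_lattice_connectivity(config)
    if recovery_gate is not None:
        return _simulate_pygate(config, graph, recovery_gate)

    n = config.n_neurons
    n_steps = int(round(config.duration_s / (config.dt_ms * 1e-3)))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x015E]))
    ext_steps, ext_neurons = _external_events(config, rng, n_steps)

    V0, n0, h0 = resting_state(config.membrane)
    V = np.full(n, V0)
    gate_n = np.full(n, n0)
    gate_h = np.full(n, h0)
    g_syn = np.zeros(n)
    g_ext = np.zeros(n)
    D = np.full(n, config.D_init)
    A = np.full(n, config.metabolism.A_init)

    cap = max(10_000, int(n * config.duration_s * 30))
    spike_neuron = np.empty(cap, dtype=np.int64)
    spike_step = np.empty(cap, dtype=np.int64)

    trace_idx = np.asarray(config.trace_neurons, dtype=np.int64)
    trace_every = max(1, int(round(config.trace_every_ms / config.dt_ms)))
    n_rows = (n_steps + trace_every - 1) // trace_every if trace_idx.size else 0
    trace_V = np.zeros((n_rows, trace_idx.size))
    trace_D = np.zeros((n_rows, trace_idx.size))
    trace_A = np.zeros((n_rows, trace_idx.size))
    dminmax = np.array([np.inf, -np.inf, np.inf, -np.inf])

    decay = math.exp(-config.dt_ms / config.synapse.tau_syn_ms)
    n_spk, err_neuron, err_step = _kernel(
        n, n_steps, config.dt_ms,
        config.membrane.C_m, config.membrane.g_Na, config.membrane.E_Na,
        config.membrane.g_K, config.membrane.E_K, config.membrane.g_L,
        config.membrane.E_L, config.membrane.i_app,
        config.synapse.E_syn, decay, config.synapse.U, config.synapse.k_rec0,
        config.synapse.g_max,
        config.metabolism.G, config.metabolism.k_gen_max,
        config.metabolism.K_A, config.metabolism.c_A,
        config.spike_threshold_mV,
        int(round(config.refractory_ms / config.dt_ms)),
        max(1, int(round(config.delay_ms / config.dt_ms))),
        config.membrane.i_app == 0.0, *resting_fixed_point(config.membrane),
        graph.indptr, graph.indices, graph.weights,
        ext_steps, ext_neurons, config.noise.g_ext,
        V, gate_n, gate_h, g_syn, g_ext, D, A,
        spike_neuron, spike_step,
        trace_idx, trace_every, trace_V, trace_D, trace_A, dminmax,
    )
    if err_neuron == -2:
        raise RuntimeError(
            f"spike buffer overflow at t={err_step * config.dt_ms * 1e-3:.3f} s; "
            "the network is firing pathologically fast for these parameters"
        )
    if err_neuron >= 0:
        raise FloatingPointError(
            f"membrane potential diverged on neuron {err_neuron} at "
            f"t={err_step * config.dt_ms * 1e-3:.4f} s"
        )

    times = spike_step[:n_spk] * (config.dt_ms * 1e-3)
    result = SimulationResult(
        neuron_index=spike_neuron[:n_spk].copy(),
        spike_times_s=times,
        config=config,
        seed=config.seed,
    )
    result.state_bounds = {
        "D_min": float(dminmax[0]), "D_max": float(dminmax[1]),
        "A_min": float(dminmax[2]), "A_max": float(dminmax[3]),
    }
    if trace_idx.size:
        result.trace_times_s = (
            np.arange(n_rows) * trace_every * config.dt_ms * 1e-3
        )
        result.trace_V = trace_V
        result.trace_D = trace_D
        result.trace_A = trace_A
    return result


def _simulate_pygate(
    config: NetworkConfig,
    graph: ConnectivityGraph,
    recovery_gate: Callable[[float], float],
) -> SimulationResult:
    """Pure-python integration path accepting an arbitrary recovery gate.

    Same scheme as the compiled kernel (Heun for V/n/h, analytic conductance
    decay, delayed event delivery); used for pluggable-metabolism
    experiments at small scale.
    """
    mem, syn, met = config.membrane, config.synapse, config.metabolism
    n = config.n_neurons
    dt = config.dt_ms
    dt_s = dt * 1e-3
    n_steps = int(round(config.duration_s / dt_s))
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0x015E]))
    ext_steps, ext_neurons = _external_events(config, rng, n_steps)

    V0, n0, h0 = resting_state(mem)
    V = np.full(n, V0)
    gn = np.full(n, n0)
    gh = np.full(n, h0)
    g_syn = np.zeros(n)
    g_ext = np.zeros(n)
    D = np.full(n, config.D_init)
    A = np.full(n, met.A_init)
    refr = np.zeros(n, dtype=int)
    delay_steps = max(1, int(round(config.delay_ms / dt)))
    refr_steps = int(round(config.refractory_ms / dt))
    buf = np.zeros((delay_steps + 1, n))
    decay = math.exp(-dt / syn.tau_syn_ms)
    ev = 0
    out_n, out_t = [], []

    for step in range(n_steps):
        slot = step % (delay_steps + 1)
        g_syn += buf[slot]
        buf[slot] = 0.0
        while ev < ext_steps.size and ext_steps[ev] == step:
            g_ext[ext_neurons[ev]] += config.noise.g_ext
            ev += 1
        for i in range(n):
            gtot = g_syn[i] + g_ext[i]
            if V[i] > -50.0 or gtot > 6.0:
                nsub = 16 + 8 * int(gtot / 12.0)
            elif V[i] > -60.0 or gtot > 1.5:
                nsub = 4
            else:
                nsub = 1
            hdt = dt / nsub
            v, ni_, hi_ = V[i], gn[i], gh[i]
            for _ in range(nsub):
                dv1, dn1, dh1 = hh_derivatives(v, ni_, hi_, gtot, 0.0, mem, syn.E_syn)
                vp, npr, hp = v + hdt * dv1, ni_ + hdt * dn1, hi_ + hdt * dh1
                dv2, dn2, dh2 = hh_derivatives(vp, npr, hp, gtot, 0.0, mem, syn.E_syn)
                v = v + 0.5 * hdt * (dv1 + dv2)
                ni_ = min(1.0, max(0.0, ni_ + 0.5 * hdt * (dn1 + dn2)))
                hi_ = min(1.0, max(0.0, hi_ + 0.5 * hdt * (dh1 + dh2)))
            v_new, gn[i], gh[i] = v, ni_, hi_
            if abs(v_new) > 500.0 or v_new != v_new:
                raise FloatingPointError(
                    f"membrane potential diverged on neuron {i} at "
                    f"t={step * dt_s:.4f} s"
                )
            k_rec = syn.k_rec0 * recovery_gate(A[i])
            D[i] = min(1.0, D[i] + dt_s * k_rec * (1.0 - D[i]))
            A[i] = min(1.0, A[i] + dt_s * met.k_gen_max * met.G * (1.0 - A[i]))
            if refr[i] > 0:
                refr[i] -= 1
            elif V[i] < config.spike_threshold_mV <= v_new:
                out_n.append(i)
                out_t.append(step * dt_s)
                refr[i] = refr_steps
                released, D[i], A[i] = on_presynaptic_spike(D[i], A[i], syn, met)
                if syn.g_max > 0 and released > 0:
                    dslot = (step + delay_steps) % (delay_steps + 1)
                    lo, hi = graph.indptr[i], graph.indptr[i + 1]
                    buf[dslot, graph.indices[lo:hi]] += (
                        syn.g_max * released * graph.weights[lo:hi]
                    )
            V[i] = v_new
        g_syn *= decay
        g_ext *= decay

    return SimulationResult(
        neuron_index=np.asarray(out_n, dtype=np.int64),
        spike_times_s=np.asarray(out_t, dtype=np.float64),
        config=config,
        seed=config.seed,
    )


# ---------------------------------------------------------------------------
# Electrode mapping
# ---------------------------------------------------------------------------

def result_to_recording(
    sim: SimulationResult,
    layout: str = "mea60",
    recording_id: Optional[str] = None,
    condition: Optional[str] = None,
) -> Recording:
    """Pool the lattice raster onto a 60-electrode MEA layout.

    The default layout overlays an 8x8 grid of equal tiles on the lattice
    and drops the four corner tiles, mirroring the 60-electrode device;
    spikes of neurons in a tile are merged, time-sorted, into one channel.
    All 60 channels are present even when empty.
    """
    if layout != "mea60":
        raise ValueError(f"unknown layout {layout!r}")
    from .spike_data import ELECTRODE_LABELS

    rows, cols = sim.config.grid
    corner_labels = {"11", "18", "81", "88"}
    pools: dict[str, list[float]] = {eid: [] for eid in ELECTRODE_LABELS}
    if sim.n_spikes:
        r = sim.neuron_index // cols
        c = sim.neuron_index % cols
        tr = np.minimum((r * 8) // rows, 7) + 1
        tc = np.minimum((c * 8) // cols, 7) + 1
        for label, t in zip(
            (tr * 10 + tc).astype(np.int64), sim.spike_times_s
        ):
            key = str(label)
            if key not in corner_labels:
                pools[key].append(float(t))
    channels = [
        ElectrodeChannel(eid, np.sort(np.asarray(ts)))
        for eid, ts in pools.items()
    ]
    return Recording(
        recording_id=recording_id or f"sim-seed{sim.seed}",
        duration_s=sim.config.duration_s,
        channels=channels,
        condition=condition,
    )
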