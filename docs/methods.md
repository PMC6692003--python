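# Methods

This note documents the models and procedures implemented in
`synchroburst`, the assumptions behind them, the parameters that matter,
and the numerical choices — at the level of detail a user needs to judge
what results obtained with the package do and do not show.

## Background and scope

Cultured excitatory networks (human induced neurons co-cultured with
astrocytes) on 60-electrode MEAs develop network-wide *synchronous bursts*:
roughly second-long, high-frequency spike trains with onsets synchronized
across most electrodes, recurring a few times per minute once the culture
matures. The frequency of these events — SBPM, synchronous bursts per
minute — is the single quantitative readout this package computes,
simulates, and summarizes. Synchronous bursting in such cultures depends
on excitatory synaptic transmission (abolished by AMPA-receptor block,
while spontaneous spikes persist), on spiking itself (abolished by sodium
channel block), and on presynaptic energetics: the rate of synaptic
vesicle recovery, and hence the glucose available to power it, sets how
often the network can burst.

The package starts from spike times. Spike detection from raw voltage,
LFP processing, and spike sorting are out of scope, as are compound-burst
and higher-order burst-organization analyses.

## Synchronous-burst detector

Two stages, all thresholds in `DetectorParams`:

1. *Per-electrode bursts* (max-interval rule). A maximal run of at least
   `min_spikes` (default 5) spikes whose consecutive inter-spike intervals
   are all ≤ `isi_max_s` (default 0.1 s) is one electrode burst spanning
   its first to last spike. The 0.1 s / 5-spike defaults separate the
   ~10 ms ISIs inside burst trains from seconds-scale spontaneous firing.
2. *Network synchrony*. Time is tiled in `bin_s` = 25 ms bins; each bin
   counts electrodes whose burst overlaps it (closed intervals; a burst
   endpoint on a bin edge counts in both bins). Runs of bins with count ≥
   `participation_min` (default 5 electrodes) are candidate network
   bursts; candidates separated by ≤ `merge_gap_s` (default 0.5 s) merge.
   Only electrodes with mean rate ≥ `active_rate_min_hz` (default 0.1 Hz)
   participate, so dead channels cannot dilute the synchrony measure.
   `participation_min` is an absolute count, not a fraction, so behaviour
   is stable while activity spreads across a developing network.

SBPM is the network-burst count divided by recording minutes, exactly.
The detector is a pure, deterministic function of (recording, parameters).

The per-electrode/participation/threshold/merge structure is this
package's own concrete design; its thresholds were fixed a priori at the
values above and validated by planted-burst recovery (below), not by
matching any external implementation. Lowering `participation_min` can
only add bursts (tested as a property).

## Network model

400 reduced Hodgkin–Huxley neurons on a 20×20 lattice.

**Membrane.** Classic squid-axon HH with dynamic `n`, `h` and
instantaneous sodium activation `m = m∞(V)`; C_m = 1 µF/cm²,
g_Na = 120, g_K = 36, g_L = 0.3 mS/cm², E_Na = 50, E_K = −77,
E_L = −54.4 mV. A spike is registered on an upward crossing of −20 mV
outside a 2 ms refractory window. The instantaneous-m reduction keeps the
model three-dimensional per neuron; it fires tonically above rheobase and
its resting fixed point (V* ≈ −65 mV) is computed by root-finding and
verified in tests.

**Connectivity.** Directed Bernoulli edges with probability
p_max·exp(−d/λ_d), d the Euclidean lattice distance, open boundaries;
defaults p_max = 0.6, λ_d = 2 give sparse, local connectivity with mean
out-degree ≈ 11. Edge weights are uniform (1); transmission delay is a
fixed 1.5 ms.

**Synapses and depression.** AMPA-like conductance (E_syn = 0 mV,
exponential decay τ_syn = 3 ms) with a single docked-vesicle pool D per
presynaptic neuron. A spike releases U·D (U = 0.4), leaving D·(1−U);
between spikes dD/dt = k_rec·(1−D) with baseline k_rec0 = 1 s⁻¹. Each
unit of released fraction increments every postsynaptic target's
conductance by g_max.

**Metabolic coupling.** Each terminal carries a dimensionless energy
store A ∈ [0,1]. Release costs c_A·U·D of it; regeneration is
dA/dt = k_gen_max·G·(1−A) with glucose availability G ∈ [0,1]
(1 ≈ glucose-rich media, 0.1 ≈ depleted; availability, not a
concentration model — no transporter kinetics); and recovery is
Michaelis–Menten-gated, k_rec = k_rec0·A/(A+K_A). Defaults
k_gen_max = 0.5 s⁻¹, K_A = 0.5, c_A = 0.3. The functional form is a
deliberate minimal choice — the mechanism ("recovery slows as recent
energy consumption outpaces glucose-fuelled regeneration") is what is
modelled, not a specific biochemical pathway — and is pluggable via
`simulate_network(..., recovery_gate=...)`.

**Spontaneous drive.** Independent external Poisson conductance kicks per
neuron, ν_ext = 0.5 Hz with g_ext = 0.1 mS/cm². The threshold kick from
rest is ≈ 0.05 mS/cm², so each kick reliably fires its neuron and the
spontaneous rate is ≈ 0.5 Hz per neuron — in the range seen between
bursts in mature cultures, and persisting when synapses are blocked.

**Why these numbers.** g_max = 0.1 makes a single full-pool EPSP
(g_max·U ≈ 0.04) just *sub*threshold, so network bursts require
coincident input and ignite from chance coincidences of spontaneous
spikes; depression then terminates them and k_rec sets the inter-burst
interval. This puts default SBPM at roughly 7–11 per minute at G = 1 —
the scale reported for mature cultures — and makes bursting collapse by
one to two orders of magnitude at G = 0.1, the behaviour the glucose
experiments show. c_A and K_A were sized so that sustained bursting at
G = 0.1 drains A (consumption ≫ regeneration at 10% availability) while
at G = 1 the store stays charged. With weaker coupling (c_A ~ 0.02) the
energy store is inert and glucose has no effect; with single-EPSP-
suprathreshold g_max (~0.5) the network locks into continuous firing.

**Pharmacology analogs.** AMPA block (CNQX): g_max = 0. Sodium-channel
block (TTX): g_Na = 0. v-ATPase inhibition (CMA): k_rec0 scaled down.
Glucose depletion: G lowered.

**Electrode mapping.** `result_to_recording` overlays an 8×8 grid of
equal tiles on the lattice, drops the four corner tiles (the 60-electrode
device geometry), and pools each tile's spikes into one channel. Whether
the original study mapped model neurons to electrodes is unknown; this
mapping exists so one detector serves simulated and synthetic data alike.

## Numerics

Fixed-step Heun (RK2) at dt = 0.05 ms for (V, n, h), with conductances
held over the step and decayed analytically; event-driven conductance
increments through a delay ring buffer; spikes tie-broken in neuron-index
order. Three documented refinements:

* *State-dependent subcycling.* With instantaneous m∞(V) the upstroke is
  stiff at 0.05 ms: pure RK2 overshoots spike peaks by >100 mV and
  diverges under sustained conductance ≳15 mS/cm². Depolarized
  (V > −50 mV) or strongly driven neurons take 16 RK2 substeps (plus more
  under extreme conductance), mildly depolarized ones 4, resting ones 1.
  The rule is a deterministic function of state, so rasters remain
  bit-reproducible. It also fixes accuracy: the single-neuron convergence
  oracle (10 s of tonic firing at i_app = 10 µA/cm²) matches a 10× finer
  reference to identical spike counts and <1 ms per-spike deviation.
* *Rest-state freeze.* A neuron whose conductances have fully decayed and
  whose state lies within (10⁻² mV, 10⁻⁴) of the resting fixed point is
  snapped to it exactly and skipped until input arrives. The snap error
  is below the freeze tolerance and applies only to isolated resting
  neurons.
* *Strided vesicle/energy updates.* D and A evolve on ~1 s timescales and
  are advanced by Euler steps every 1 ms (releases are applied exactly at
  spike times). Both are clamped to [0,1]; a fuzz suite verifies the
  bounds over randomized configurations.

Membrane potentials outside ±500 mV raise an integration error naming
neuron and time. Simulations are bit-reproducible from (config, seed);
external Poisson event times are pre-drawn from a seeded generator.

## Synthetic MEA generator

Stands in for raw recordings, with ground truth. Burst onsets are a
Poisson process at `burst_rate_per_min` (default 4/min, the mature-culture
scale) thinned to enforce a 1 s refractory gap; durations are lognormal
(median 0.8 s, σ = 0.4); each burst recruits ⌈0.8·60⌉ random electrodes
firing independent 80 Hz Poisson trains over the burst, onsets jittered
by 10 ms per electrode; background is 0.5 Hz Poisson per electrode
throughout. Deterministic given the seed.

What it does *not* emulate: within-burst envelope structure (bursts are
homogeneous Poisson inside), per-electrode rate heterogeneity (unreported
for the source cultures; a rate-multiplier hook exists but defaults are
uniform), jittered burst *ends* (all participants share the end), LFP
waveforms, and developmental emergence (time courses are emulated by a
user-specified rate-versus-day protocol). Detector validation against
this generator therefore shows that the detector recovers bursts of the
stated morphology — not that it is robust to every failure mode of real
electrodes.

## Condition analysis

Per-condition mean ± SEM (sample SD, n−1, over √n; undefined and flagged
for n = 1) and two-sided Student's t-tests between condition pairs:
pooled-variance for independent samples, difference scores for paired
designs (both provided; the repeated-measures protocols suggest pairing
but the choice is the user's). Degenerate inputs (zero variance
everywhere) report t = 0, p = 1 with a flag rather than erroring. Raw P
values only — no multiple-testing correction, matching how such
experiments are conventionally reported — and the normality assumption
of the t-test is inherited, not checked. Two-way ANOVA is out of scope.

## Validation suite and problem sizes

The slow end-to-end checks run at desk scale, chosen to keep the full
suite and the acceptance script each in the tens of minutes on one CPU:

* CNQX analog: 5 seeds × 300 s simulations — zero SBPM on every seed,
  spikes persisting.
* Glucose effect: 5 seeds × 120 s at G = 1 vs G = 0.1 — mean SBPM
  strictly higher at G = 1.
* Recovery-rate monotonicity: k_rec0 × {1, 0.5, 0.25, 0.1, 0.01}, 3 seeds
  × 120 s — seed-averaged SBPM non-increasing.
* TTX analog: 60 s — empty raster.
* Detector round trip: 20 seeds × 600 s synthetic recordings at 4
  bursts/min — burst-level precision and recall ≥ 0.9, mean detected SBPM
  within 3 Poisson standard errors of the planted rate; 20 burst-free
  seeds — zero detections in ≥ 19.
* Numerical oracle and state-bounds fuzz as described above.

The experimental SBPM values reported for live cultures (e.g. 6.23 ± 2.00
under glucose + pyruvate, 0.30 ± 0.12 after 20 min without substrate)
arise from biology no desk-scale simulation reproduces de novo; they set
the *scale* of the generator defaults and the *direction* of the ordering
checks, nothing more.

## Known limitations

* The simulator is excitatory-only: no inhibition (consistent with the
  GABA-block insensitivity of these cultures), no NMDA kinetics, no
  facilitation, no multi-pool vesicle cycling, no astrocyte compartment.
* Glucose enters only as a scalar availability gating one rate constant;
  the model cannot distinguish glycolytic from oxidative ATP supply.
* The detector's defaults assume burst trains well above the spontaneous
  rate; extremely bursty background (≫1 Hz with clustered spikes) would
  need re-tuned thresholds.
* SBPM in the simulator depends jointly on g_max, connectivity, ν_ext and
  k_rec0; the defaults form one calibrated operating point, not a fit to
  any particular culture.
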