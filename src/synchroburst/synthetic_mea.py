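"""Synthetic MEA recordings with planted ground truth.

Real recordings from these cultures show two superposed processes: sparse
spontaneous action potentials on each electrode, and network-wide
synchronous bursts — roughly second-long, high-frequency (tens of Hz) spike
trains with onsets synchronized across most electrodes, recurring a few
times per minute in mature networks.  This module generates recordings with
exactly that phenomenology and a known :class:`GroundTruth` (the planted
burst intervals and their participants), so the synchronous-burst detector
can be validated by round trip: plant bursts at rate lambda, detect, and
compare event-by-event.

Burst onsets follow a Poisson process at ``burst_rate_per_min`` thinned to
enforce a refractory gap between bursts; burst durations are lognormal;
each burst recruits a random subset of electrodes that fire independent
Poisson trains at ``within_burst_rate_hz`` for the burst's duration, with a
small electrode-specific onset jitter.  Background spiking is independent
Poisson on every electrode throughout.  Everything is deterministic given
the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np

from .spike_data import ELECTRODE_LABELS, ElectrodeChannel, Recording

__all__ = [
    "GeneratorParams",
    "GroundTruth",
    "generate_recording",
    "generate_condition_series",
]


@dataclass(frozen=True)
class GeneratorParams:
    """Parameters of the synthetic recording generator.

    Defaults emulate a mature culture on a 60-electrode MEA: 600 s
    recordings, 0.5 Hz spontaneous firing per electrode, bursts at 4 per
    minute lasting ~0.8 s (lognormal, sigma 0.4) during which 80 % of
    electrodes fire at 80 Hz, with 10 ms onset jitter across electrodes and
    at least 1 s between bursts.
    """

    n_electrodes: int = 60
    duration_s: float = 600.0
    background_rate_hz: float = 0.5
    burst_rate_per_min: float = 4.0
    burst_duration_median_s: float = 0.8
    burst_duration_sigma: float = 0.4
    within_burst_rate_hz: float = 80.0
    participation_fraction: float = 0.8
    onset_jitter_s: float = 0.01
    refractory_gap_s: float = 1.0
    #: optional per-electrode multiplier on background_rate_hz (length
    #: n_electrodes); uniform when None — real heterogeneity is unreported.
    rate_multipliers: Optional[tuple[float, ...]] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (1 <= self.n_electrodes <= 60):
            raise ValueError("n_electrodes must be in 1..60")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        for name in ("background_rate_hz", "burst_rate_per_min",
                     "within_burst_rate_hz", "onset_jitter_s",
                     "refractory_gap_s"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not (0 < self.participation_fraction <= 1):
            raise ValueError("participation_fraction must be in (0, 1]")
        if self.burst_rate_per_min * self.refractory_gap_s > 60.0:
            raise ValueError(
                "burst_rate_per_min * refractory_gap_s exceeds 60 s/min: the "
                "refractory gap cannot be satisfied in expectation"
            )
        if self.rate_multipliers is not None and len(
            self.rate_multipliers
        ) != self.n_electrodes:
            raise ValueError("rate_multipliers length must equal n_electrodes")


@dataclass(frozen=True)
class GroundTruth:
    """Planted burst intervals and rates for round-trip validation."""

    burst_intervals_s: tuple[tuple[float, float], ...]
    participants: tuple[frozenset[str], ...]
    burst_rate_per_min: float
    background_rate_hz: float

    @property
    def n_bursts(self) -> int:
        return len(self.burst_intervals_s)


def _poisson_train(rng: np.random.Generator, rate_hz: float, t0: float,
                   t1: float) -> np.ndarray:
    """Homogeneous Poisson spike times on [t0, t1)."""
    if rate_hz <= 0 or t1 <= t0:
        return np.empty(0)
    n = rng.poisson(rate_hz * (t1 - t0))
    return np.sort(rng.uniform(t0, t1, size=n))


def _plant_bursts(
    rng: np.random.Generator, params: GeneratorParams
) -> list[tuple[float, float]]:
    """Poisson onsets thinned to the refractory gap, lognormal durations."""
    lam_hz = params.burst_rate_per_min / 60.0
    onsets = _poisson_train(rng, lam_hz, 0.0, params.duration_s)
    mu = math.log(params.burst_duration_median_s)
    intervals: list[tuple[float, float]] = []
    prev_end = -math.inf
    for onset in onsets:
        if onset < prev_end + params.refractory_gap_s:
            continue  # thinned: too close to the previous kept burst
        dur = float(rng.lognormal(mu, params.burst_duration_sigma))
        end = min(onset + dur, params.duration_s)
        if end <= onset:
            continue
        intervals.append((float(onset), end))
        prev_end = end
    return intervals


def generate_recording(
    params: GeneratorParams = GeneratorParams(),
) -> tuple[Recording, GroundTruth]:
    """Generate one synthetic MEA recording and its ground truth.

    Returns the recording (channels on the standard 60-electrode grid
    labels) and the planted burst intervals with per-burst participant sets.
    """
    rng = np.random.default_rng(params.seed)
    electrode_ids = ELECTRODE_LABELS[: params.n_electrodes]
    intervals = _plant_bursts(rng, params)

    n_part = math.ceil(params.participation_fraction * params.n_electrodes)
    participants: list[frozenset[str]] = []
    spikes: dict[str, list[np.ndarray]] = {eid: [] for eid in electrode_ids}

    for (t0, t1) in intervals:
        chosen = rng.choice(params.n_electrodes, size=n_part, replace=False)
        chosen_ids = frozenset(electrode_ids[i] for i in sorted(chosen))
        participants.append(chosen_ids)
        for i in sorted(chosen):
            jitter = rng.normal(0.0, params.onset_jitter_s)
            start = min(max(t0 + jitter, 0.0), params.duration_s)
            train = _poisson_train(
                rng, params.within_burst_rate_hz, start, min(t1, params.duration_s)
            )
            if train.size:
                spikes[electrode_ids[i]].append(train)

    mults = params.rate_multipliers or (1.0,) * params.n_electrodes
    for eid, m in zip(electrode_ids, mults):
        bg = _poisson_train(
            rng, params.background_rate_hz * m, 0.0, params.duration_s
        )
        if bg.size:
            spikes[eid].append(bg)

    channels = [
        ElectrodeChannel(
            eid,
            np.sort(np.concatenate(spikes[eid])) if spikes[eid] else np.empty(0),
        )
        for eid in electrode_ids
    ]
    rec = Recording(
        recording_id=f"synthetic-seed{params.seed}",
        duration_s=params.duration_s,
        channels=channels,
    )
    truth = GroundTruth(
        burst_intervals_s=tuple(intervals),
        participants=tuple(participants),
        burst_rate_per_min=params.burst_rate_per_min,
        background_rate_hz=params.background_rate_hz,
    )
    return rec, truth


def generate_condition_series(
    protocol: Sequence[tuple[str, float, int]],
    base_seed: int = 0,
    params: GeneratorParams = GeneratorParams(),
) -> list[tuple[Recording, GroundTruth]]:
    """Generate a multi-condition, multi-replicate recording series.

    ``protocol`` lists ``(condition_label, burst_rate_per_min, n_replicates)``
    triples — the shape of a depletion–repletion experiment, where each
    epoch's media composition sets a different underlying burst rate.  Seeds
    are derived deterministically as ``base_seed*10000 + 100*condition_index
    + replicate_index`` and recorded in each Recording's id; condition labels
    go into the metadata.
    """
    out: list[tuple[Recording, GroundTruth]] = []
    for ci, (label, lam, n_rep) in enumerate(protocol):
        for ri in range(n_rep):
            seed = base_seed * 10_000 + 100 * ci + ri
            p = replace(params, burst_rate_per_min=lam, seed=seed)
            rec, truth = generate_recording(p)
            rec = replace(
                rec,
                recording_id=f"{label}-rep{ri}-seed{seed}",
                condition=label,
                replicate_id=f"rep{ri}",
            )
            out.append((rec, truth))
    return out
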