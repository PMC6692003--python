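"""Synchronous network-burst detection and the SBPM statistic.

Network-wide synchronous bursts — intervals in which many electrodes of an
MEA simultaneously exhibit high-frequency spike trains with synchronized
onsets — are the defining feature of mature excitatory cultures, and their
frequency, SBPM (synchronous bursts per minute), is the headline statistic
of every analysis in this package.

The detector is a two-stage design:

1. **Per-electrode bursts** (max-interval rule): on each electrode, every
   maximal run of at least ``min_spikes`` spikes whose consecutive
   inter-spike intervals are all at most ``isi_max_s`` becomes one
   :class:`BurstEvent`.
2. **Network synchrony**: time is tiled into ``bin_s`` bins and each bin
   counts the electrodes whose burst spans it (the
   :class:`ParticipationTrace`, i.e. the number of electrodes bursting at
   each time point).  Maximal runs of bins with participation of at least
   ``participation_min`` electrodes become candidate network bursts;
   candidates separated by at most ``merge_gap_s`` are merged.  Only
   electrodes whose mean firing rate reaches ``active_rate_min_hz`` count
   toward participation, so dead channels never dilute the synchrony
   measure.

All thresholds are exposed in :class:`DetectorParams`; the detector is a pure
deterministic function of (recording, parameters).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .spike_data import ElectrodeChannel, Recording

__all__ = [
    "DetectorParams",
    "BurstEvent",
    "ParticipationTrace",
    "NetworkBurst",
    "SBPMResult",
    "detect_electrode_bursts",
    "participation_trace",
    "detect_network_bursts",
    "compute_sbpm",
    "run_detector",
]


@dataclass(frozen=True)
class DetectorParams:
    """Tunable thresholds of the synchronous-burst detector.

    Attributes
    ----------
    isi_max_s
        Maximum in-burst inter-spike interval on a single electrode.  The
        0.1 s default separates the ~10 ms ISIs inside high-frequency burst
        trains from seconds-scale spontaneous firing.
    min_spikes
        Minimum spikes per per-electrode burst (>= 2).
    bin_s
        Width of the participation time bins.
    participation_min
        Minimum number of simultaneously bursting electrodes for a network
        burst; an absolute count rather than a fraction so behaviour is
        stable while activity spreads across a developing network.
    active_rate_min_hz
        Minimum mean firing rate for an electrode to count as active.
    merge_gap_s
        Candidate network bursts separated by at most this gap are merged.
    """

    isi_max_s: float = 0.1
    min_spikes: int = 5
    bin_s: float = 0.025
    participation_min: int = 5
    active_rate_min_hz: float = 0.1
    merge_gap_s: float = 0.5

    def __post_init__(self) -> None:
        for name in ("isi_max_s", "bin_s", "merge_gap_s", "active_rate_min_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spikes < 2:
            raise ValueError("min_spikes must be >= 2")
        if self.participation_min < 2:
            raise ValueError("participation_min must be >= 2")


@dataclass(frozen=True)
class BurstEvent:
    """A high-frequency spike train on one electrode."""

    electrode_id: str
    t_start_s: float
    t_end_s: float
    n_spikes: int


@dataclass(frozen=True)
class ParticipationTrace:
    """Per-bin count of electrodes bursting across the MEA."""

    bin_edges_s: np.ndarray  # length n_bins + 1, uniform width
    counts: np.ndarray  # length n_bins, int

    @property
    def bin_s(self) -> float:
        return float(self.bin_edges_s[1] - self.bin_edges_s[0])


@dataclass(frozen=True)
class NetworkBurst:
    """A detected network-wide synchronous burst interval."""

    t_start_s: float
    t_end_s: float
    participating_electrodes: frozenset[str]
    peak_participation: int


@dataclass(frozen=True)
class SBPMResult:
    """Synchronous bursts per minute plus the bursts themselves."""

    sbpm: float
    n_bursts: int
    duration_min: float
    network_bursts: tuple[NetworkBurst, ...] = field(default_factory=tuple)


def detect_electrode_bursts(
    channel: ElectrodeChannel, params: DetectorParams = DetectorParams()
) -> list[BurstEvent]:
    """Find per-electrode bursts with the max-interval rule.

    Every maximal run of >= ``min_spikes`` spikes whose consecutive ISIs are
    all <= ``isi_max_s`` becomes one :class:`BurstEvent` spanning its first
    and last spike.
    """
    t = np.asarray(channel.spike_times_s, dtype=np.float64)
    if t.size < params.min_spikes:
        return []
    # Runs of spikes chained by short ISIs: break where ISI > isi_max_s
    # (tolerance absorbs float noise so threshold-equal ISIs stay in-burst).
    breaks = np.flatnonzero(np.diff(t) > params.isi_max_s * (1 + 1e-9))
    starts = np.concatenate(([0], breaks + 1))
    ends = np.concatenate((breaks, [t.size - 1]))  # inclusive
    bursts = []
    for s, e in zip(starts, ends):
        n = int(e - s + 1)
        if n >= params.min_spikes:
            bursts.append(
                BurstEvent(channel.electrode_id, float(t[s]), float(t[e]), n)
            )
    return bursts


def _snap(x: float, tol: float = 1e-9) -> float:
    """Round to the nearest integer when within tol, absorbing float noise
    at bin boundaries."""
    r = round(x)
    return float(r) if abs(x - r) < tol else x


def _active_electrodes(rec: Recording, params: DetectorParams) -> set[str]:
    return {
        ch.electrode_id
        for ch in rec.channels
        if ch.mean_rate_hz(rec.duration_s) >= params.active_rate_min_hz
    }


def participation_trace(
    rec: Recording,
    bursts: dict[str, Sequence[BurstEvent]],
    params: DetectorParams = DetectorParams(),
) -> ParticipationTrace:
    """Count, per time bin, how many electrodes are bursting.

    Bins of width ``bin_s`` tile ``[0, duration_s]``; an electrode counts in
    bin ``b`` if any of its bursts overlaps ``b`` (intervals and bins treated
    as closed, so a burst touching a bin edge counts in both bins).  Only
    electrodes passing the active-rate filter contribute.
    """
    n_bins = int(np.ceil(rec.duration_s / params.bin_s))
    edges = np.arange(n_bins + 1, dtype=np.float64) * params.bin_s
    counts = np.zeros(n_bins, dtype=np.int64)
    active = _active_electrodes(rec, params)
    for eid, events in bursts.items():
        if eid not in active:
            continue
        covered = np.zeros(n_bins, dtype=bool)
        for ev in events:
            # Closed-interval overlap: bins b with edge[b] <= t_end and
            # edge[b+1] >= t_start; a burst endpoint landing exactly on an
            # edge counts in both adjoining bins.
            x0 = _snap(ev.t_start_s / params.bin_s)
            x1 = _snap(ev.t_end_s / params.bin_s)
            lo = int(np.floor(x0)) - 1 if x0 == int(x0) else int(np.floor(x0))
            hi = int(np.floor(x1))
            lo = max(lo, 0)
            hi = min(hi, n_bins - 1)
            covered[lo : hi + 1] = True
        counts += covered
    return ParticipationTrace(bin_edges_s=edges, counts=counts)


def detect_network_bursts(
    trace: ParticipationTrace,
    rec: Recording,
    bursts: dict[str, Sequence[BurstEvent]],
    params: DetectorParams = DetectorParams(),
) -> list[NetworkBurst]:
    """Threshold the participation trace and merge nearby candidates.

    Maximal runs of bins with participation >= ``participation_min`` become
    candidate bursts spanning the outer bin edges of the run; candidates
    whose gap is <= ``merge_gap_s`` are merged into one network burst.
    """
    counts = trace.counts
    above = counts >= params.participation_min
    if not above.any():
        return []
    d = np.diff(above.astype(np.int8))
    run_starts = np.flatnonzero(d == 1) + 1
    run_ends = np.flatnonzero(d == -1)  # inclusive bin index
    if above[0]:
        run_starts = np.concatenate(([0], run_starts))
    if above[-1]:
        run_ends = np.concatenate((run_ends, [above.size - 1]))

    edges = trace.bin_edges_s
    intervals = [
        [float(edges[s]), float(edges[e + 1]), int(counts[s : e + 1].max())]
        for s, e in zip(run_starts, run_ends)
    ]
    # Merge candidates separated by <= merge_gap_s.
    merged = [intervals[0]]
    for start, end, peak in intervals[1:]:
        if start - merged[-1][1] <= params.merge_gap_s:
            merged[-1][1] = end
            merged[-1][2] = max(merged[-1][2], peak)
        else:
            merged.append([start, end, peak])

    active = _active_electrodes(rec, params)
    out = []
    for start, end, peak in merged:
        participants = frozenset(
            eid
            for eid, events in bursts.items()
            if eid in active
            and any(ev.t_start_s <= end and ev.t_end_s >= start for ev in events)
        )
        out.append(NetworkBurst(start, end, participants, peak))
    return out


def compute_sbpm(
    network_bursts: Sequence[NetworkBurst], duration_s: float
) -> SBPMResult:
    """Synchronous bursts per minute: burst count over recording minutes."""
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    duration_min = duration_s / 60.0
    n = len(network_bursts)
    return SBPMResult(
        sbpm=n / duration_min,
        n_bursts=n,
        duration_min=duration_min,
        network_bursts=tuple(network_bursts),
    )


def run_detector(
    rec: Recording, params: DetectorParams = DetectorParams()
) -> SBPMResult:
    """Full detector: per-electrode bursts -> participation -> SBPM.

    Pure and deterministic: identical input yields an identical result.
    """
    bursts = {
        ch.electrode_id: detect_electrode_bursts(ch, params) for ch in rec.channels
    }
    trace = participation_trace(rec, bursts, params)
    network = detect_network_bursts(trace, rec, bursts, params)
    return compute_sbpm(network, rec.duration_s)
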