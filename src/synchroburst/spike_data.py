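"""Spike-train recordings from multi-electrode arrays (MEAs) and their file I/O.

The shared data model for every downstream stage: a :class:`Recording` is a set
of per-electrode spike-time lists with duration and condition metadata, the
common currency between the network simulator, the synthetic-recording
generator, and the synchronous-burst detector.

Electrode identifiers follow the Multichannel-Systems-style row/column labels
of a standard 8x8 MEA: ``"rc"`` with row ``r`` and column ``c`` in 1..8.  The
four corner positions (11, 18, 81, 88) carry no electrode and are rejected,
leaving the 60-electrode layout of the devices these cultures grow on.

Two on-disk dialects are supported:

* CSV — header ``electrode_id,spike_time_s``, one row per spike, with
  recording-level metadata in a JSON sidecar sharing the file's stem
  (``rec.csv`` + ``rec.meta.json``).  Diff-able, fixture-friendly.
* HDF5 — one dataset per electrode under ``/spikes/<electrode_id>`` with
  recording-level metadata as root attributes.

Spike times are stored in seconds as floats; the nominal 25 kHz acquisition
rate is metadata only, since all analysis here starts from detected spikes,
never from voltage traces.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd

__all__ = [
    "ELECTRODE_LABELS",
    "ElectrodeChannel",
    "Recording",
    "ValidationReport",
    "read_spike_table",
    "write_spike_table",
    "validate_recording",
]

_CORNERS = frozenset({"11", "18", "81", "88"})

#: The 60 valid electrode labels of the 8x8-minus-corners MEA grid, sorted.
ELECTRODE_LABELS: tuple[str, ...] = tuple(
    f"{r}{c}" for r in range(1, 9) for c in range(1, 9) if f"{r}{c}" not in _CORNERS
)

_LABEL_RE = re.compile(r"^[1-8][1-8]$")


def _check_electrode_id(electrode_id: str) -> str:
    eid = str(electrode_id)
    if not _LABEL_RE.match(eid):
        raise ValueError(
            f"electrode_id {eid!r} is not a row-column label in 1..8 x 1..8"
        )
    if eid in _CORNERS:
        raise ValueError(
            f"electrode_id {eid!r} is a corner position; the 8x8 MEA has no "
            "corner electrodes"
        )
    return eid


@dataclass
class ElectrodeChannel:
    """Spike times (seconds, sorted ascending) recorded on one electrode."""

    electrode_id: str
    spike_times_s: np.ndarray

    def __post_init__(self) -> None:
        self.electrode_id = _check_electrode_id(self.electrode_id)
        self.spike_times_s = np.asarray(self.spike_times_s, dtype=np.float64)
        if self.spike_times_s.ndim != 1:
            raise ValueError("spike_times_s must be one-dimensional")

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times_s.size)

    def mean_rate_hz(self, duration_s: float) -> float:
        """Mean firing rate over the recording duration."""
        return self.n_spikes / float(duration_s)


@dataclass
class Recording:
    """One MEA recording: up to 60 electrode channels plus metadata.

    Parameters
    ----------
    recording_id
        Free-text identifier.
    duration_s
        Recording length in seconds (the sessions these emulate last 600 s).
    channels
        Electrode channels; electrode ids must be unique.
    condition
        Biological condition label (e.g. ``"glucose+pyruvate"``, ``"CNQX"``).
    day_from_induction
        Days since neuronal induction, for developmental time courses.
    replicate_id
        Culture / biological replicate identifier.
    nominal_sample_rate_hz
        Acquisition rate of the original voltage data; metadata only.
    """

    recording_id: str
    duration_s: float = 600.0
    channels: list[ElectrodeChannel] = field(default_factory=list)
    condition: Optional[str] = None
    day_from_induction: Optional[int] = None
    replicate_id: Optional[str] = None
    nominal_sample_rate_hz: float = 25_000.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if len(self.channels) > 60:
            raise ValueError("a 60-electrode MEA cannot have more than 60 channels")

    @property
    def electrode_ids(self) -> list[str]:
        return [ch.electrode_id for ch in self.channels]

    @property
    def n_spikes(self) -> int:
        return sum(ch.n_spikes for ch in self.channels)

    @property
    def duration_min(self) -> float:
        return self.duration_s / 60.0

    def channel(self, electrode_id: str) -> ElectrodeChannel:
        for ch in self.channels:
            if ch.electrode_id == electrode_id:
                return ch
        raise KeyError(electrode_id)

    def with_channels(self, channels: Iterable[ElectrodeChannel]) -> "Recording":
        return replace(self, channels=list(channels))


@dataclass
class ValidationReport:
    """Outcome of :func:`validate_recording`: ok iff no issues were found."""

    ok: bool
    issues: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.ok != (len(self.issues) == 0):
            raise ValueError("ok must be true exactly when issues is empty")


def validate_recording(rec: Recording) -> ValidationReport:
    """Check a recording's invariants, reporting rather than raising.

    Flags, per electrode: unsorted spike times, times outside
    ``[0, duration_s]``, and duplicated electrode ids.
    """
    issues: list[tuple[str, str]] = []
    seen: set[str] = set()
    for ch in rec.channels:
        eid = ch.electrode_id
        if eid in seen:
            issues.append((eid, f"duplicate electrode_id {eid!r}"))
        seen.add(eid)
        t = ch.spike_times_s
        if t.size and np.any(np.diff(t) < 0):
            issues.append((eid, "spike times are not sorted ascending"))
        if t.size and (t.min() < 0 or t.max() > rec.duration_s):
            issues.append(
                (eid, f"spike times outside [0, {rec.duration_s}] s")
            )
    return ValidationReport(ok=not issues, issues=issues)


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

_META_FIELDS = (
    "recording_id",
    "duration_s",
    "nominal_sample_rate_hz",
    "condition",
    "day_from_induction",
    "replicate_id",
)


def _infer_dialect(path: Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        if dialect not in ("csv", "hdf5"):
            raise ValueError(f"unknown dialect {dialect!r}; expected 'csv' or 'hdf5'")
        return dialect
    suffix = path.suffix.lower()
    if suffix in (".csv", ".txt"):
        return "csv"
    if suffix in (".h5", ".hdf5", ".hdf"):
        return "hdf5"
    raise ValueError(f"cannot infer dialect from suffix {suffix!r}; pass dialect=")


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".meta.json")


def _finalize_channels(
    raw: dict[str, np.ndarray], duration_s: float, source: str
) -> list[ElectrodeChannel]:
    """Sort spike times (the only repair performed) and range-check them."""
    channels = []
    for eid in sorted(raw):
        times = np.sort(np.asarray(raw[eid], dtype=np.float64))
        if times.size and (times[0] < 0 or times[-1] > duration_s):
            bad = times[0] if times[0] < 0 else times[-1]
            raise ValueError(
                f"{source}: electrode {eid!r} has spike time {bad} s outside "
                f"[0, {duration_s}] s"
            )
        channels.append(ElectrodeChannel(eid, times))
    return channels


def read_spike_table(
    source: str | Path, dialect: Optional[str] = None
) -> Recording:
    """Read a recording from a CSV or HDF5 spike table.

    Channels are returned sorted by electrode id and spike times sorted
    ascending (unsorted input is repaired by sorting; out-of-range times
    raise).  For CSV, recording metadata is read from the JSON sidecar
    ``<stem>.meta.json`` when present, else defaults apply.
    """
    path = Path(source)
    dialect = _infer_dialect(path, dialect)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "csv":
        return _read_csv(path)
    return _read_hdf5(path)


def _read_csv(path: Path) -> Recording:
    try:
        df = pd.read_csv(path, dtype={"electrode_id": str})
    except Exception as exc:  # pragma: no cover - pandas error text varies
        raise ValueError(f"{path}: malformed CSV spike table: {exc}") from exc
    expected = ["electrode_id", "spike_time_s"]
    if list(df.columns) != expected:
        raise ValueError(
            f"{path}: expected columns {expected}, found {list(df.columns)}"
        )
    if df["spike_time_s"].isna().any():
        row = int(df.index[df["spike_time_s"].isna()][0]) + 2  # 1-based + header
        raise ValueError(f"{path}: missing spike_time_s at line {row}")

    meta: dict = {}
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    recording_id = meta.get("recording_id", path.stem)
    duration_s = float(meta.get("duration_s", 600.0))

    raw: dict[str, np.ndarray] = {
        str(eid): grp["spike_time_s"].to_numpy(dtype=np.float64)
        for eid, grp in df.groupby("electrode_id", sort=True)
    }
    for eid in meta.get("electrode_ids", []):
        raw.setdefault(str(eid), np.empty(0))
    channels = _finalize_channels(raw, duration_s, str(path))
    day = meta.get("day_from_induction")
    return Recording(
        recording_id=recording_id,
        duration_s=duration_s,
        channels=channels,
        condition=meta.get("condition"),
        day_from_induction=None if day is None else int(day),
        replicate_id=meta.get("replicate_id"),
        nominal_sample_rate_hz=float(meta.get("nominal_sample_rate_hz", 25_000.0)),
    )


def _read_hdf5(path: Path) -> Recording:
    import h5py

    with h5py.File(path, "r") as f:
        if "spikes" not in f:
            raise ValueError(f"{path}: missing /spikes group")
        attrs = dict(f.attrs)
        raw = {
            eid: np.asarray(ds[()], dtype=np.float64)
            for eid, ds in f["spikes"].items()
        }

    def _opt(key):
        v = attrs.get(key)
        if v is None:
            return None
        if isinstance(v, bytes):
            v = v.decode()
        return v

    duration_s = float(attrs.get("duration_s", 600.0))
    channels = _finalize_channels(raw, duration_s, str(path))
    day = _opt("day_from_induction")
    return Recording(
        recording_id=str(_opt("recording_id") or path.stem),
        duration_s=duration_s,
        channels=channels,
        condition=_opt("condition"),
        day_from_induction=None if day is None else int(day),
        replicate_id=_opt("replicate_id"),
        nominal_sample_rate_hz=float(attrs.get("nominal_sample_rate_hz", 25_000.0)),
    )


def write_spike_table(
    rec: Recording, dest: str | Path, dialect: Optional[str] = None
) -> None:
    """Write a recording; lossless at microsecond time precision.

    CSV output carries metadata in a ``<stem>.meta.json`` sidecar so that a
    round trip through :func:`read_spike_table` reproduces every field.
    """
    path = Path(dest)
    dialect = _infer_dialect(path, dialect)
    if dialect == "csv":
        _write_csv(rec, path)
    else:
        _write_hdf5(rec, path)


def _write_csv(rec: Recording, path: Path) -> None:
    rows = [
        (ch.electrode_id, f"{t:.6f}")
        for ch in sorted(rec.channels, key=lambda c: c.electrode_id)
        for t in ch.spike_times_s
    ]
    df = pd.DataFrame(rows, columns=["electrode_id", "spike_time_s"])
    df.to_csv(path, index=False)
    meta = {k: getattr(rec, k) for k in _META_FIELDS}
    # channel list survives the round trip even for spike-free electrodes
    meta["electrode_ids"] = sorted(rec.electrode_ids)
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")


def _write_hdf5(rec: Recording, path: Path) -> None:
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["recording_id"] = rec.recording_id
        f.attrs["duration_s"] = float(rec.duration_s)
        f.attrs["nominal_sample_rate_hz"] = float(rec.nominal_sample_rate_hz)
        if rec.condition is not None:
            f.attrs["condition"] = rec.condition
        if rec.day_from_induction is not None:
            f.attrs["day_from_induction"] = int(rec.day_from_induction)
        if rec.replicate_id is not None:
            f.attrs["replicate_id"] = rec.replicate_id
        g = f.create_group("spikes")
        for ch in rec.channels:
            g.create_dataset(ch.electrode_id, data=ch.spike_times_s)
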