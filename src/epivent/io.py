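"""Signal containers and file I/O.

The package's substrate is the :class:`TimeSeries`: one uniformly sampled
channel with a sampling rate and a recording-relative start time.  All times
anywhere in the package are 0-based seconds from recording start, and all
intervals are half-open ``[start, end)``; sample ``i`` of a channel covers
``[start + i/rate, start + (i+1)/rate)``.

Two container formats are supported:

* EDF (European Data Format, 16-bit): read and written by a minimal
  self-contained codec (:func:`write_edf` / :func:`read_edf`).  Physical
  dimension fields are carried but not interpreted; amplitudes are arbitrary
  units throughout, consistent with within-animal normalization downstream.
* CSV: one header row, a ``time_s`` column plus one column per channel, at a
  single common sampling rate.

Event tables (apneas, sighs, seizures, ...) round-trip through a common CSV
schema (``type, start_s, end_s, duration_s`` + per-type value fields) via
:func:`write_events_csv` / :func:`read_events_csv`.
"""

from __future__ import annotations

import dataclasses
import math
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ChannelMissingError, SignalIOError

__all__ = [
    "TimeSeries",
    "Interval",
    "MovementMask",
    "read_recording",
    "write_recording",
    "read_edf",
    "write_edf",
    "write_events_csv",
    "read_events_csv",
    "register_event_type",
]

#: canonical channel labels used by the synthetic generator and the readers
EEG_LABEL = "EEG"
EMG_LABEL = "DiaEMG"


@dataclass
class TimeSeries:
    """One uniformly sampled signal channel.

    Parameters
    ----------
    label : str
        Channel name (e.g. ``"EEG"``, ``"DiaEMG"``).
    rate : float
        Sampling rate in Hz; must be positive.
    samples : ndarray
        Ordered real samples in channel units (arbitrary units throughout).
    start : float
        Recording-relative start time of the first sample, seconds.
    units : str
        Physical-dimension tag, carried but never interpreted.
    """

    label: str
    rate: float
    samples: np.ndarray
    start: float = 0.0
    units: str = "a.u."

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise SignalIOError(f"sampling rate must be > 0, got {self.rate}")
        if self.samples.ndim != 1:
            raise SignalIOError("samples must be one-dimensional")
        if self.samples.size and not np.all(np.isfinite(self.samples)):
            raise SignalIOError(f"channel {self.label!r} contains non-finite samples")

    @property
    def n(self) -> int:
        return self.samples.size

    @property
    def duration(self) -> float:
        """Signal duration in seconds (``n / rate``)."""
        return self.samples.size / self.rate

    @property
    def end(self) -> float:
        return self.start + self.duration

    def times(self) -> np.ndarray:
        """Sample times (left edge of each sample's interval), seconds."""
        return self.start + np.arange(self.samples.size) / self.rate

    def index_at(self, t: float) -> int:
        """Index of the sample whose half-open interval contains time ``t``."""
        i = int(math.floor((t - self.start) * self.rate + 1e-9))
        return min(max(i, 0), self.samples.size - 1)

    def slice(self, start: float, end: float) -> "TimeSeries":
        """Sub-series covering ``[start, end)`` (clipped to the recording)."""
        i0 = max(0, int(math.ceil((start - self.start) * self.rate - 1e-9)))
        i1 = min(self.samples.size, int(math.ceil((end - self.start) * self.rate - 1e-9)))
        i1 = max(i1, i0)
        return TimeSeries(
            label=self.label,
            rate=self.rate,
            samples=self.samples[i0:i1].copy(),
            start=self.start + i0 / self.rate,
            units=self.units,
        )

    def copy_with(self, samples: np.ndarray, label: str | None = None) -> "TimeSeries":
        return TimeSeries(
            label=self.label if label is None else label,
            rate=self.rate,
            samples=samples,
            start=self.start,
            units=self.units,
        )


@dataclass(frozen=True, order=True)
class Interval:
    """Half-open time interval ``[start, end)`` in recording seconds."""

    start: float
    end: float

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise SignalIOError(f"interval end {self.end} < start {self.start}")

    @property
    def length(self) -> float:
        return self.end - self.start

    def contains(self, t: float) -> bool:
        return self.start <= t < self.end

    def overlaps(self, other: "Interval") -> bool:
        return self.start < other.end and other.start < self.end


@dataclass
class MovementMask:
    """Sorted, non-overlapping intervals during which the animal is moving."""

    intervals: list[Interval] = field(default_factory=list)

    def __post_init__(self) -> None:
        iv = sorted(self.intervals)
        for a, b in zip(iv, iv[1:]):
            if b.start < a.end:
                raise SignalIOError("movement intervals overlap")
        self.intervals = iv

    def is_moving(self, t: float) -> bool:
        for iv in self.intervals:
            if iv.contains(t):
                return True
            if iv.start > t:
                break
        return False

    def overlaps(self, interval: Interval) -> bool:
        return any(iv.overlaps(interval) for iv in self.intervals)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"start_s": [iv.start for iv in self.intervals],
             "end_s": [iv.end for iv in self.intervals]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "MovementMask":
        return cls([Interval(float(r.start_s), float(r.end_s)) for r in df.itertuples()])


# ---------------------------------------------------------------------------
# EDF codec
# ---------------------------------------------------------------------------

_EDF_RECORD_S = 1.0  # data-record duration; channel rates must be integral per record


def _edf_str(value: str, width: int) -> bytes:
    b = value.encode("ascii", "replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(path: str | os.PathLike, channels: Sequence[TimeSeries]) -> None:
    """Write channels to a minimal EDF file (16-bit, 1 s data records).

    Channels may have different rates but must share ``start`` and have whole
    seconds of data (EDF stores fixed-size data records); amplitudes are scaled
    to the int16 range per channel, so round-trip precision is
    ``(max - min) / 65534`` of each channel.
    """
    if not channels:
        raise SignalIOError("no channels to write")
    starts = {c.start for c in channels}
    if len(starts) > 1:
        raise SignalIOError("EDF channels must share a start time")
    n_records = channels[0].duration / _EDF_RECORD_S
    for c in channels:
        if abs(c.duration - n_records * _EDF_RECORD_S) > 1e-9:
            raise SignalIOError("EDF channels must cover the same whole number of seconds")
        if abs(c.rate * _EDF_RECORD_S - round(c.rate * _EDF_RECORD_S)) > 1e-9:
            raise SignalIOError(f"rate {c.rate} is not integral per {_EDF_RECORD_S} s record")
    if abs(n_records - round(n_records)) > 1e-9:
        raise SignalIOError("EDF requires a whole number of 1 s data records")
    n_records = int(round(n_records))

    ns = len(channels)
    header = b"".join(
        [
            _edf_str("0", 8),
            _edf_str("epivent recording", 80),
            _edf_str("synthetic/unspecified", 80),
            _edf_str("01.01.00", 8),
            _edf_str("00.00.00", 8),
            _edf_str(str(256 * (1 + ns)), 8),
            _edf_str("", 44),
            _edf_str(str(n_records), 8),
            _edf_str(f"{_EDF_RECORD_S:g}", 8),
            _edf_str(str(ns), 4),
        ]
    )
    phys_min, phys_max, scaled = [], [], []
    for c in channels:
        lo = float(np.min(c.samples)) if c.n else -1.0
        hi = float(np.max(c.samples)) if c.n else 1.0
        if hi <= lo:
            hi = lo + 1.0
        phys_min.append(lo)
        phys_max.append(hi)
        dig = np.round((c.samples - lo) / (hi - lo) * 65534.0 - 32767.0)
        scaled.append(dig.astype("<i2"))

    fields_ = [
        b"".join(_edf_str(c.label, 16) for c in channels),
        b"".join(_edf_str("", 80) for _ in channels),
        b"".join(_edf_str(c.units, 8) for c in channels),
        b"".join(_edf_str(f"{lo:.8g}"[:8], 8) for lo in phys_min),
        b"".join(_edf_str(f"{hi:.8g}"[:8], 8) for hi in phys_max),
        b"".join(_edf_str("-32767", 8) for _ in channels),
        b"".join(_edf_str("32767", 8) for _ in channels),
        b"".join(_edf_str("", 80) for _ in channels),
        b"".join(_edf_str(str(int(round(c.rate * _EDF_RECORD_S))), 8) for c in channels),
        b"".join(_edf_str("", 32) for _ in channels),
    ]
    with open(path, "wb") as fh:
        fh.write(header)
        for blk in fields_:
            fh.write(blk)
        spr = [int(round(c.rate * _EDF_RECORD_S)) for c in channels]
        for rec in range(n_records):
            for c_i, c in enumerate(channels):
                seg = scaled[c_i][rec * spr[c_i]: (rec + 1) * spr[c_i]]
                fh.write(seg.tobytes())


def read_edf(path: str | os.PathLike) -> list[TimeSeries]:
    """Read all channels of an EDF file written by :func:`write_edf` (or any
    plain 16-bit EDF without annotations)."""
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise SignalIOError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_s = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise SignalIOError(f"{path}: corrupted EDF header") from exc
        if ns <= 0 or n_records < 0 or record_s <= 0:
            raise SignalIOError(f"{path}: corrupted EDF header")
        sig_head = fh.read(256 * ns)
        if len(sig_head) < 256 * ns:
            raise SignalIOError(f"{path}: truncated EDF signal header")

        def col(width: int, offset: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width: base + (i + 1) * width].decode("ascii").strip()
                for i in range(ns)
            ]

        labels = col(16, 0)
        units = [
            sig_head[ns * 96 + i * 8: ns * 96 + (i + 1) * 8].decode("ascii").strip()
            for i in range(ns)
        ]
        off = ns * 104
        try:
            pmin = [float(sig_head[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
            off += ns * 8
            pmax = [float(sig_head[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
            off += ns * 8
            dmin = [float(sig_head[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
            off += ns * 8
            dmax = [float(sig_head[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
            off += ns * 8 + ns * 80
            spr = [int(sig_head[off + i * 8: off + (i + 1) * 8]) for i in range(ns)]
        except ValueError as exc:
            raise SignalIOError(f"{path}: corrupted EDF signal header") from exc

        raw: list[list[np.ndarray]] = [[] for _ in range(ns)]
        for _ in range(n_records):
            for i in range(ns):
                buf = fh.read(2 * spr[i])
                if len(buf) < 2 * spr[i]:
                    raise SignalIOError(f"{path}: truncated EDF data record")
                raw[i].append(np.frombuffer(buf, dtype="<i2").astype(float))

    out = []
    for i in range(ns):
        dig = np.concatenate(raw[i]) if raw[i] else np.empty(0)
        gain = (pmax[i] - pmin[i]) / (dmax[i] - dmin[i])
        phys = (dig - dmin[i]) * gain + pmin[i]
        out.append(TimeSeries(labels[i], spr[i] / record_s, phys, start=0.0, units=units[i]))
    return out


# ---------------------------------------------------------------------------
# Recording-level read/write
# ---------------------------------------------------------------------------

def _movement_sidecar(path: str) -> str:
    return str(path) + ".movement.csv"


def write_recording(
    path: str | os.PathLike,
    eeg: TimeSeries,
    emg: TimeSeries,
    movement: MovementMask | None = None,
    format: str | None = None,
) -> None:
    """Write EEG + EMG (and an optional movement-mask sidecar CSV).

    ``format`` is inferred from the extension when omitted.  CSV requires both
    channels to share one sampling rate; EDF accepts mixed rates.
    """
    fmt = format or ("csv" if str(path).endswith(".csv") else "edf")
    if fmt == "edf":
        write_edf(path, [eeg, emg])
    elif fmt == "csv":
        if abs(eeg.rate - emg.rate) > 1e-9 or eeg.n != emg.n:
            raise SignalIOError("CSV recordings need a single common rate; use EDF")
        df = pd.DataFrame(
            {"time_s": eeg.times(), eeg.label: eeg.samples, emg.label: emg.samples}
        )
        df.to_csv(path, index=False, float_format="%.9g")
    else:
        raise SignalIOError(f"unknown format {fmt!r}")
    if movement is not None and movement.intervals:
        movement.to_frame().to_csv(_movement_sidecar(str(path)), index=False)


def read_recording(
    path: str | os.PathLike,
    format: str | None = None,
    eeg_label: str = EEG_LABEL,
    emg_label: str = EMG_LABEL,
) -> tuple[TimeSeries, TimeSeries, MovementMask | None]:
    """Read a two-channel recording; returns ``(eeg, emg, movement-or-None)``.

    A movement mask is loaded from the ``<path>.movement.csv`` sidecar when
    present.  CSV files must have a uniform ``time_s`` column (tolerance
    1e-6 s on the sampling interval).
    """
    if not os.path.exists(path):
        raise SignalIOError(f"no such file: {path}")
    fmt = format or ("csv" if str(path).endswith(".csv") else "edf")
    if fmt == "edf":
        channels = read_edf(path)
        by_label = {c.label: c for c in channels}
    elif fmt == "csv":
        try:
            df = pd.read_csv(path)
        except Exception as exc:  # malformed header/body
            raise SignalIOError(f"{path}: unreadable CSV: {exc}") from exc
        if "time_s" not in df.columns or len(df.columns) < 2:
            raise SignalIOError(f"{path}: CSV needs a time_s column plus channels")
        t = df["time_s"].to_numpy(dtype=float)
        if t.size < 2:
            raise SignalIOError(f"{path}: need at least two samples")
        dt = np.diff(t)
        if np.any(np.abs(dt - dt[0]) > 1e-6) or dt[0] <= 0:
            raise SignalIOError(f"{path}: non-uniform time_s column")
        rate = 1.0 / dt[0]
        by_label = {
            c: TimeSeries(c, rate, df[c].to_numpy(dtype=float), start=float(t[0]))
            for c in df.columns
            if c != "time_s"
        }
    else:
        raise SignalIOError(f"unknown format {fmt!r}")

    missing = [lab for lab in (eeg_label, emg_label) if lab not in by_label]
    if missing:
        raise ChannelMissingError(
            f"{path}: missing channel(s) {missing}; found {sorted(by_label)}"
        )
    movement = None
    side = _movement_sidecar(str(path))
    if os.path.exists(side):
        movement = MovementMask.from_frame(pd.read_csv(side))
    return by_label[eeg_label], by_label[emg_label], movement


# ---------------------------------------------------------------------------
# Event tables
# ---------------------------------------------------------------------------

_EVENT_REGISTRY: dict[str, type] = {}


def register_event_type(name: str):
    """Class decorator registering an event dataclass for CSV round-trip."""

    def deco(cls):
        cls.event_type = name
        _EVENT_REGISTRY[name] = cls
        return cls

    return deco


_CORE_COLS = ["type", "start_s", "end_s", "duration_s"]


_START_ALIASES = ("start", "time", "onset", "seizure_end")
_END_ALIASES = ("end", "offset")


def _event_row(ev) -> dict:
    d = dataclasses.asdict(ev)
    row = {"type": ev.event_type, "start_s": None, "end_s": None, "duration_s": None}
    for a in _START_ALIASES:
        if a in d:
            row["start_s"] = d.pop(a)
            break
    for a in _END_ALIASES:
        if a in d:
            row["end_s"] = d.pop(a)
            break
    if "duration" in d:
        row["duration_s"] = d.pop("duration")
    for k, v in d.items():
        row[k] = v
    return row


def write_events_csv(events: Iterable, path: str | os.PathLike) -> None:
    """Write a heterogeneous, start-sorted event list to CSV.

    One row per event with columns ``type, start_s, end_s, duration_s`` plus
    the union of per-type value fields; times round-trip at 1e-6 s.
    """
    events = list(events)
    rows = [_event_row(ev) for ev in events]
    starts = [r["start_s"] for r in rows]
    if any(s is None for s in starts):
        raise SignalIOError("event without a start time")
    if any(b < a for a, b in zip(starts, starts[1:])):
        raise SignalIOError("events must be sorted by start time")
    cols = list(_CORE_COLS)
    for r in rows:
        for k in r:
            if k not in cols:
                cols.append(k)
    df = pd.DataFrame(rows, columns=cols)
    df.to_csv(path, index=False, float_format="%.9f")


def read_events_csv(path: str | os.PathLike) -> list:
    """Reconstruct the typed event list written by :func:`write_events_csv`."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        name = row["type"]
        cls = _EVENT_REGISTRY.get(name)
        if cls is None:
            raise SignalIOError(f"unknown event type {name!r}")
        fields_ = {f.name: f for f in dataclasses.fields(cls)}
        start_name = next((a for a in _START_ALIASES if a in fields_), None)
        end_name = next((a for a in _END_ALIASES if a in fields_), None)
        kwargs = {}
        for fname in fields_:
            if fname == start_name:
                kwargs[fname] = float(row["start_s"])
            elif fname == end_name:
                kwargs[fname] = float(row["end_s"])
            elif fname == "duration":
                v = row["duration_s"]
                kwargs[fname] = None if pd.isna(v) else float(v)
            elif fname in row.index:
                v = row[fname]
                if pd.isna(v):
                    kwargs[fname] = None
                else:
                    ftype = str(fields_[fname].type)
                    if "bool" in ftype:
                        kwargs[fname] = v in (True, "True", 1, 1.0)
                    elif "str" in ftype:
                        kwargs[fname] = str(v)
                    else:
                        kwargs[fname] = float(v)
        out.append(cls(**kwargs))
    return out
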