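"""Core data model and file I/O for multi-beam fly activity records.

A multi-beam activity monitor holds flies in individual glass tubes, each
tube spanned by a row of infrared beams.  Every second the monitor reports,
per tube, the number of beam interruptions ("counts") and the beam index at
which the fly was last detected.  This module defines the in-memory types
(:class:`BeamGeometry`, :class:`ActivityTrace`, :class:`StimulusLog`) and a
bit-exact reader/writer pair for the toolkit's plain-text CSV dialect.

The activity dialect::

    #photobeam-activity v1
    #t0=2022-01-01T08:00:00
    #zt0=0.0
    #geometry=16x17
    #flies=tube01,tube02,...
    0,<tube01_count>,<tube01_pos>,...,<tubeNN_count>,<tubeNN_pos>
    1,...

and the stimulus-log dialect::

    #photobeam-stim v1
    <time_ms>,<tubes>,<color>,<intensity>

where ``tubes`` is a compressed range list such as ``1-16`` or ``1,3,5-7``.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass, field
from datetime import datetime
from typing import Iterable, NamedTuple, Sequence, TextIO, Union

import numpy as np

__all__ = [
    "Color",
    "BeamGeometry",
    "DEFAULT_GEOMETRY",
    "ActivityTrace",
    "StimulusEvent",
    "StimulusLog",
    "FormatError",
    "IntegrityError",
    "UsageError",
    "ValidationError",
    "zt_hours",
    "read_activity_csv",
    "write_activity_csv",
    "read_stimulus_log",
    "write_stimulus_log",
]


class FormatError(ValueError):
    """A file does not conform to the expected dialect."""


class IntegrityError(ValueError):
    """A file parses but violates an ordering/consistency contract."""


class UsageError(ValueError):
    """An operation was called with inconsistent arguments."""


class ValidationError(ValueError):
    """A domain object violates one of its invariants."""


class Color(str, enum.Enum):
    """LED illumination state of a tube."""

    WHITE = "white"
    BLUE = "blue"
    GREEN = "green"
    OFF = "off"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Integer codes used when illumination is stored in dense arrays.
COLOR_CODE = {Color.OFF: 0, Color.WHITE: 1, Color.BLUE: 2, Color.GREEN: 3}
CODE_COLOR = {v: k for k, v in COLOR_CODE.items()}


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BeamGeometry:
    """Physical layout of a multi-tube, multi-beam monitor.

    Parameters
    ----------
    n_tubes:
        Number of tube slots in the monitor.
    n_beams:
        Number of infrared beams per tube (1-based indices downstream).
    tube_length:
        Physical tube length in mm.
    beam_positions:
        Strictly increasing beam coordinates in mm, all inside
        ``(0, tube_length)``.  Defaults to evenly spaced beams with equal
        margins at both walls.
    """

    n_tubes: int = 16
    n_beams: int = 17
    tube_length: float = 90.0
    beam_positions: tuple = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.n_tubes < 1:
            raise ValidationError("n_tubes must be >= 1")
        if self.n_beams < 3:
            raise ValidationError("n_beams must be >= 3")
        if self.tube_length <= 0:
            raise ValidationError("tube_length must be positive")
        if self.beam_positions is None:
            spacing = self.tube_length / (self.n_beams + 1)
            pos = tuple(spacing * (i + 1) for i in range(self.n_beams))
            object.__setattr__(self, "beam_positions", pos)
        else:
            pos = tuple(float(p) for p in self.beam_positions)
            object.__setattr__(self, "beam_positions", pos)
        pos = self.beam_positions
        if len(pos) != self.n_beams:
            raise ValidationError("beam_positions length must equal n_beams")
        arr = np.asarray(pos)
        if not np.all(np.diff(arr) > 0):
            raise ValidationError("beam_positions must be strictly increasing")
        if arr[0] <= 0 or arr[-1] >= self.tube_length:
            raise ValidationError("beam_positions must lie inside (0, tube_length)")

    @property
    def spacing(self) -> float:
        """Mean distance between adjacent beams, mm (beam-width unit)."""
        return float(np.mean(np.diff(self.beam_positions)))

    def beam_x(self, index: int) -> float:
        """Coordinate (mm) of the 1-based beam ``index``."""
        return self.beam_positions[index - 1]

    def nearest_beam(self, x):
        """1-based index of the beam nearest to coordinate ``x`` (mm)."""
        arr = np.asarray(self.beam_positions)
        idx = np.argmin(np.abs(np.subtract.outer(np.atleast_1d(x), arr)), axis=1) + 1
        return idx if np.ndim(x) else int(idx[0])


DEFAULT_GEOMETRY = BeamGeometry()


# ---------------------------------------------------------------------------
# Zeitgeber time
# ---------------------------------------------------------------------------


def zt_hours(t_s, zt0: float):
    """Convert session time (s) to Zeitgeber time (hours, ZT0 = lights-on).

    ``zt0`` is the ZT hour of the session start; the result wraps modulo 24.
    """
    return (np.asarray(t_s, dtype=float) / 3600.0 + zt0) % 24.0


# ---------------------------------------------------------------------------
# ActivityTrace
# ---------------------------------------------------------------------------


@dataclass
class ActivityTrace:
    """Per-second beam-crossing counts and beam position for one fly.

    ``counts[k]`` is the number of beam interruptions during second ``k`` of
    the session; ``position[k]`` is the 1-based index of the beam at which
    the fly was detected at the end of that second.  Because a fly must cross
    every beam separating two reported positions, every trace satisfies the
    displacement invariant ``counts[k] >= |position[k] - position[k-1]|``.
    """

    fly_id: str
    t0: datetime
    zt0: float
    counts: np.ndarray
    position: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.position = np.asarray(self.position, dtype=np.int64)
        if self.counts.ndim != 1 or self.position.ndim != 1:
            raise ValidationError("counts and position must be 1-D")
        if len(self.counts) != len(self.position):
            raise ValidationError("counts and position must have equal length")
        if np.any(self.counts < 0):
            raise ValidationError("counts must be non-negative")
        if len(self.position) and np.any(self.position < 1):
            raise ValidationError("position indices are 1-based (>= 1)")

    @property
    def duration(self) -> int:
        """Session length in seconds."""
        return len(self.counts)

    def displacement_violations(self) -> np.ndarray:
        """Indices k where ``counts[k] < |position[k] - position[k-1]|``.

        Empty for any physically consistent trace; real hardware can glitch.
        """
        if self.duration < 2:
            return np.empty(0, dtype=np.int64)
        dpos = np.abs(np.diff(self.position))
        bad = np.nonzero(self.counts[1:] < dpos)[0] + 1
        return bad

    def zt_at(self, t_s) -> np.ndarray:
        """Zeitgeber time (hours) of session second(s) ``t_s``."""
        return zt_hours(t_s, self.zt0)


# ---------------------------------------------------------------------------
# StimulusLog
# ---------------------------------------------------------------------------


class StimulusEvent(NamedTuple):
    """One LED state change: at ``time_ms`` the listed tubes switch to
    ``color`` at ``intensity`` (fraction of full output, 0 for OFF)."""

    time_ms: int
    tubes: frozenset
    color: Color
    intensity: float = 1.0


@dataclass
class StimulusLog:
    """Ordered record of every LED state change during a session.

    Events are sorted by time; per tube, consecutive events must change the
    illumination (no duplicate no-op entries).
    """

    events: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [
            StimulusEvent(int(e.time_ms), frozenset(int(t) for t in e.tubes),
                          Color(e.color), float(e.intensity))
            for e in self.events
        ]
        times = [e.time_ms for e in self.events]
        if any(b < a for a, b in zip(times, times[1:])):
            raise IntegrityError("stimulus events must be sorted by time_ms")
        last: dict = {}
        for i, ev in enumerate(self.events):
            for tube in ev.tubes:
                state = (ev.color, ev.intensity)
                if last.get(tube) == state:
                    raise IntegrityError(
                        f"event {i} (t={ev.time_ms} ms) repeats the state of "
                        f"tube {tube} (no-op entry)"
                    )
                last[tube] = state

    def __len__(self) -> int:
        return len(self.events)

    def __iter__(self):
        return iter(self.events)

    def color_codes(self, tube: int, n_seconds: int,
                    initial: Color = Color.OFF) -> np.ndarray:
        """Per-second illumination of ``tube`` as integer color codes.

        The color of second ``t`` is the LED state in effect at time
        ``t * 1000`` ms (events are applied at or before the start of the
        second).
        """
        out = np.full(n_seconds, COLOR_CODE[initial], dtype=np.int8)
        changes = [(e.time_ms, COLOR_CODE[e.color]) for e in self.events
                   if tube in e.tubes]
        for t_ms, code in changes:
            sec = max(0, -(-t_ms // 1000))  # first second with start >= t_ms
            if sec < n_seconds:
                out[sec:] = code
        return out

    def uniform_across(self, tubes: Iterable[int]) -> bool:
        """True if every event addresses all of ``tubes`` identically."""
        want = frozenset(int(t) for t in tubes)
        return all(e.tubes >= want for e in self.events)


# ---------------------------------------------------------------------------
# Tube-set range serialization ("1-16", "1,3,5-7")
# ---------------------------------------------------------------------------


def _format_tubes(tubes: frozenset) -> str:
    ids = sorted(tubes)
    if not ids:
        return ""
    parts = []
    start = prev = ids[0]
    for t in ids[1:]:
        if t == prev + 1:
            prev = t
            continue
        parts.append(f"{start}-{prev}" if prev > start else f"{start}")
        start = prev = t
    parts.append(f"{start}-{prev}" if prev > start else f"{start}")
    return ",".join(parts)


def _parse_tubes(text: str) -> frozenset:
    ids = set()
    for part in text.split(","):
        part = part.strip()
        if not part:
            continue
        if "-" in part:
            a, b = part.split("-", 1)
            ids.update(range(int(a), int(b) + 1))
        else:
            ids.add(int(part))
    return frozenset(ids)


# ---------------------------------------------------------------------------
# Activity CSV reader / writer
# ---------------------------------------------------------------------------

_ACTIVITY_MAGIC = "#photobeam-activity v1"
_STIM_MAGIC = "#photobeam-stim v1"

PathOrFile = Union[str, TextIO]


def _open(path_or_file: PathOrFile, mode: str):
    if hasattr(path_or_file, "read") or hasattr(path_or_file, "write"):
        return path_or_file, False
    return open(path_or_file, mode), True


def write_activity_csv(traces: Sequence[ActivityTrace],
                       path: PathOrFile) -> None:
    """Write ``traces`` (one tube column-group each) in the activity dialect.

    All traces must share the same duration, ``t0`` and ``zt0``; the output
    round-trips bit-exactly through :func:`read_activity_csv`.
    """
    traces = list(traces)
    if not traces:
        raise UsageError("cannot write an empty trace collection")
    d0, t0, zt0 = traces[0].duration, traces[0].t0, traces[0].zt0
    for tr in traces[1:]:
        if tr.duration != d0:
            raise UsageError("all traces must have the same duration")
        if tr.t0 != t0 or tr.zt0 != zt0:
            raise UsageError("all traces must share t0 and zt0")
    fh, close = _open(path, "w")
    try:
        fh.write(_ACTIVITY_MAGIC + "\n")
        fh.write(f"#t0={t0.isoformat()}\n")
        fh.write(f"#zt0={zt0!r}\n")
        fh.write(f"#geometry={len(traces)}x{DEFAULT_GEOMETRY.n_beams}\n")
        fh.write("#flies=" + ",".join(tr.fly_id for tr in traces) + "\n")
        cols = np.empty((d0, 1 + 2 * len(traces)), dtype=np.int64)
        cols[:, 0] = np.arange(d0)
        for i, tr in enumerate(traces):
            cols[:, 1 + 2 * i] = tr.counts
            cols[:, 2 + 2 * i] = tr.position
        lines = "\n".join(",".join(map(str, row)) for row in cols.tolist())
        if d0:
            fh.write(lines + "\n")
    finally:
        if close:
            fh.close()


def read_activity_csv(path: PathOrFile) -> list:
    """Parse an activity CSV into one :class:`ActivityTrace` per tube.

    Raises :class:`FormatError` (naming the offending line) on malformed
    headers, :class:`IntegrityError` on non-monotonic timestamps, and warns
    (with the row index) when a row violates the displacement invariant —
    tolerated because real hardware can glitch.
    """
    fh, close = _open(path, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    if not lines or lines[0] != _ACTIVITY_MAGIC:
        raise FormatError(f"line 1: expected magic header {_ACTIVITY_MAGIC!r}")
    header: dict = {}
    data_start = None
    for ln, line in enumerate(lines[1:], start=2):
        if line.startswith("#"):
            if "=" not in line:
                raise FormatError(f"line {ln}: malformed header {line!r}")
            key, val = line[1:].split("=", 1)
            header[key] = val
        else:
            data_start = ln - 1  # 0-based index of the first data row
            break
    for key in ("t0", "zt0", "geometry"):
        if key not in header:
            raise FormatError(f"missing required header '#{key}='")
    try:
        t0 = datetime.fromisoformat(header["t0"])
    except ValueError as exc:
        raise FormatError(f"bad #t0 header: {exc}") from exc
    zt0 = float(header["zt0"])
    try:
        n_tubes, _n_beams = (int(v) for v in header["geometry"].split("x"))
    except ValueError as exc:
        raise FormatError(f"bad #geometry header: {exc}") from exc
    fly_ids = (header["flies"].split(",") if "flies" in header
               else [f"tube{i + 1:02d}" for i in range(n_tubes)])
    if len(fly_ids) != n_tubes:
        raise FormatError("#flies count does not match #geometry n_tubes")

    rows = lines[data_start:] if data_start is not None else []
    n_cols = 1 + 2 * n_tubes
    data = np.empty((len(rows), n_cols), dtype=np.int64)
    for i, row in enumerate(rows):
        parts = row.split(",")
        lineno = data_start + i + 1
        if len(parts) != n_cols:
            raise FormatError(
                f"line {lineno}: expected {n_cols} fields, got {len(parts)}")
        try:
            data[i] = [int(p) for p in parts]
        except ValueError as exc:
            raise FormatError(f"line {lineno}: {exc}") from exc
    if len(rows) and np.any(np.diff(data[:, 0]) <= 0):
        raise IntegrityError("non-monotonic timestamps in activity file")

    traces = []
    for i in range(n_tubes):
        tr = ActivityTrace(fly_id=fly_ids[i], t0=t0, zt0=zt0,
                           counts=data[:, 1 + 2 * i], position=data[:, 2 + 2 * i])
        bad = tr.displacement_violations()
        if len(bad):
            warnings.warn(
                f"trace {tr.fly_id}: counts below net beam displacement at "
                f"row(s) {bad[:5].tolist()}{'...' if len(bad) > 5 else ''}",
                stacklevel=2,
            )
        traces.append(tr)
    return traces


# ---------------------------------------------------------------------------
# Stimulus log reader / writer
# ---------------------------------------------------------------------------


def write_stimulus_log(log: StimulusLog, path: PathOrFile) -> None:
    """Write a stimulus log; round-trips losslessly through
    :func:`read_stimulus_log`."""
    fh, close = _open(path, "w")
    try:
        fh.write(_STIM_MAGIC + "\n")
        for ev in log.events:
            fh.write(f"{ev.time_ms},{_format_tubes(ev.tubes)},"
                     f"{ev.color.value},{ev.intensity!r}\n")
    finally:
        if close:
            fh.close()


def read_stimulus_log(path: PathOrFile) -> StimulusLog:
    """Parse a stimulus-log file; unsorted input raises IntegrityError."""
    fh, close = _open(path, "r")
    try:
        lines = fh.read().splitlines()
    finally:
        if close:
            fh.close()
    if not lines or lines[0] != _STIM_MAGIC:
        raise FormatError(f"line 1: expected magic header {_STIM_MAGIC!r}")
    events = []
    for ln, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split(",")
        if len(parts) < 4:
            raise FormatError(f"line {ln}: expected 4 fields, got {len(parts)}")
        time_ms, color, intensity = parts[0], parts[-2], parts[-1]
        tubes = ",".join(parts[1:-2])
        try:
            events.append(StimulusEvent(int(time_ms), _parse_tubes(tubes),
                                        Color(color), float(intensity)))
        except ValueError as exc:
            raise FormatError(f"line {ln}: {exc}") from exc
    return StimulusLog(events)
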