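"""Containers and I/O for four-limb IMU session recordings.

The training system straps one 9-axis inertial sensor (gyroscope,
accelerometer, magnetometer, nominally sampled at 26 Hz) to each of an
infant's four limbs.  A training *session* is three minutes of stimulus
playback with the four streams recorded throughout.  This module holds the
array-backed data model (:class:`SensorStream`, :class:`SessionRecord`),
plain-text readers/writers (per-sensor CSV and a JSON-lines session log),
and the stream-quality rules used downstream:

* *completeness* — a session is complete when no stream was interrupted and
  every stream contains a gap-free run of at least the planned duration;
  only complete sessions enter any analysis.
* *connectivity* — a per-limb flag that is false when a sensor dropped
  samples (coverage below ``min_coverage``) or showed a gap longer than
  ``max_gap_s`` anywhere in the session; the side-difference analysis
  additionally excludes sessions failing this check.

Timestamps are seconds from session start.  Each sample is taken to cover
one nominal sampling interval, so a stream of ``n`` samples at 26 Hz spans
``n / 26`` seconds (4680 samples == 180 s).  Gyroscope units are deg/s
throughout; data recorded in rad/s must be converted at ingest.
"""

from __future__ import annotations

import csv
import json
import math
import os
from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np

from .errors import EmptyInputError, ParseError, SchemaError

__all__ = [
    "LIMBS",
    "LEFT_LIMBS",
    "RIGHT_LIMBS",
    "CSV_COLUMNS",
    "NOMINAL_RATE_HZ",
    "DEFAULT_SESSION_S",
    "DEFAULT_MAX_GAP_S",
    "DEFAULT_MIN_COVERAGE",
    "ImuSample",
    "SensorStream",
    "PlaybackTrace",
    "SessionRecord",
    "LimbQuality",
    "StreamQualityReport",
    "read_sensor_csv",
    "write_sensor_csv",
    "read_session_log",
    "write_session_log",
    "validate_stream_quality",
    "is_complete_session",
]

LIMBS = ("left_hand", "right_hand", "left_foot", "right_foot")
LEFT_LIMBS = ("left_hand", "left_foot")
RIGHT_LIMBS = ("right_hand", "right_foot")

CSV_COLUMNS = ("t", "gx", "gy", "gz", "ax", "ay", "az", "mx", "my", "mz")
NOMINAL_RATE_HZ = 26.0
DEFAULT_SESSION_S = 180.0
DEFAULT_MAX_GAP_S = 1.0
DEFAULT_MIN_COVERAGE = 0.95


@dataclass(frozen=True)
class ImuSample:
    """One timestamped 9-axis reading.

    ``t`` is seconds since session start; ``gyro`` is deg/s, ``accel`` is g,
    ``mag`` is the magnetic field in arbitrary units (µT-scale).
    """

    t: float
    gyro: tuple[float, float, float]
    accel: tuple[float, float, float]
    mag: tuple[float, float, float]

    def __post_init__(self) -> None:
        vals = (self.t, *self.gyro, *self.accel, *self.mag)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("ImuSample components must be finite")
        if self.t < 0:
            raise ValueError("ImuSample timestamp must be >= 0")


@dataclass
class SensorStream:
    """The recording of one limb sensor, stored as NumPy arrays.

    ``t`` has shape ``(n,)`` and must be strictly increasing; ``gyro``,
    ``accel`` and ``mag`` have shape ``(n, 3)``.
    """

    limb: str
    t: np.ndarray
    gyro: np.ndarray
    accel: np.ndarray
    mag: np.ndarray
    sample_rate_hz: float = NOMINAL_RATE_HZ

    def __post_init__(self) -> None:
        if self.limb not in LIMBS:
            raise ValueError(f"unknown limb {self.limb!r}; expected one of {LIMBS}")
        self.t = np.asarray(self.t, dtype=float)
        for name in ("gyro", "accel", "mag"):
            arr = np.asarray(getattr(self, name), dtype=float)
            if arr.shape != (self.t.size, 3):
                raise ValueError(f"{name} must have shape (n, 3) matching t")
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite values")
            setattr(self, name, arr)
        if self.t.size and (not np.all(np.isfinite(self.t)) or self.t[0] < 0):
            raise ValueError("timestamps must be finite and >= 0")
        if self.t.size > 1 and not np.all(np.diff(self.t) > 0):
            bad = int(np.flatnonzero(np.diff(self.t) <= 0)[0]) + 2
            raise ParseError(f"timestamps not strictly increasing at sample {bad}")

    def __len__(self) -> int:
        return int(self.t.size)

    def __getitem__(self, i: int) -> ImuSample:
        return ImuSample(
            float(self.t[i]),
            tuple(self.gyro[i]),
            tuple(self.accel[i]),
            tuple(self.mag[i]),
        )

    @property
    def duration_s(self) -> float:
        """Observed span, counting one nominal interval per sample."""
        if not len(self):
            return 0.0
        return float(self.t[-1] - self.t[0] + 1.0 / self.sample_rate_hz)

    def gaps(self) -> np.ndarray:
        """Inter-sample intervals, prefixed with the lead-in gap from t=0."""
        if not len(self):
            return np.array([])
        return np.concatenate([[self.t[0]], np.diff(self.t)])

    def longest_consecutive_s(self, max_gap_s: float = DEFAULT_MAX_GAP_S) -> float:
        """Duration of the longest run with no inter-sample gap above ``max_gap_s``."""
        if not len(self):
            return 0.0
        breaks = np.flatnonzero(np.diff(self.t) > max_gap_s)
        starts = np.concatenate([[0], breaks + 1])
        ends = np.concatenate([breaks, [len(self) - 1]])
        spans = self.t[ends] - self.t[starts] + 1.0 / self.sample_rate_hz
        return float(spans.max())


@dataclass
class PlaybackTrace:
    """Scalar stimulus playback level over time, clamped to [0, 1]."""

    t: np.ndarray
    level: np.ndarray

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.level = np.asarray(self.level, dtype=float)
        if self.t.shape != self.level.shape:
            raise ValueError("t and level must have the same shape")
        if self.level.size and (self.level.min() < 0 or self.level.max() > 1):
            raise ValueError("playback level must lie in [0, 1]")


@dataclass
class SessionRecord:
    """One three-minute training session.

    ``mode`` is ``"active"`` (stimulus driven by the infant's movement) or
    ``"passive"`` (catch trial: stimulus plays regardless).
    ``controlling_limbs`` is meaningful only for active sessions.  ``day``
    is an optional training-day label used by the daily-ratio analysis.
    """

    session_id: str
    mode: str
    streams: dict[str, SensorStream]
    controlling_limbs: tuple[str, ...] = LIMBS
    planned_duration_s: float = DEFAULT_SESSION_S
    interrupted: bool = False
    playback_trace: PlaybackTrace | None = None
    day: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("active", "passive"):
            raise ValueError(f"mode must be 'active' or 'passive', got {self.mode!r}")
        self.controlling_limbs = tuple(self.controlling_limbs)
        if not self.controlling_limbs:
            raise ValueError("controlling_limbs must be nonempty")
        for limb in self.controlling_limbs:
            if limb not in LIMBS:
                raise ValueError(f"unknown controlling limb {limb!r}")
        for limb, stream in self.streams.items():
            if stream.limb != limb:
                raise ValueError(f"stream under key {limb!r} is labelled {stream.limb!r}")


@dataclass(frozen=True)
class LimbQuality:
    """Coverage and gap statistics for one limb within a session."""

    limb: str
    expected_count: int
    observed_count: int
    largest_gap_s: float
    connectivity_ok: bool


@dataclass(frozen=True)
class StreamQualityReport:
    """Per-limb connectivity verdicts; ``session_ok`` iff every limb passed."""

    session_id: str
    limbs: Mapping[str, LimbQuality]

    @property
    def session_ok(self) -> bool:
        return all(q.connectivity_ok for q in self.limbs.values())


# ---------------------------------------------------------------------------
# CSV reader / writer


def read_sensor_csv(path: str | os.PathLike, limb: str) -> SensorStream:
    """Read one sensor's recording from CSV (header ``t,gx,...,mz``).

    Raises :class:`SchemaError` for a wrong header, :class:`EmptyInputError`
    for a file with no data rows, and :class:`ParseError` (naming the row)
    for non-numeric cells or non-monotone timestamps.
    """
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise EmptyInputError(f"{path}: file is empty") from None
        if tuple(h.strip() for h in header) != CSV_COLUMNS:
            missing = set(CSV_COLUMNS) - {h.strip() for h in header}
            raise SchemaError(
                f"{path}: header {header!r} does not match {','.join(CSV_COLUMNS)}"
                + (f" (missing {sorted(missing)})" if missing else "")
            )
        rows: list[list[float]] = []
        for lineno, row in enumerate(reader, start=2):
            if not row:
                continue
            if len(row) != len(CSV_COLUMNS):
                raise ParseError(f"{path}: row {lineno}: expected {len(CSV_COLUMNS)} fields")
            try:
                vals = [float(c) for c in row]
            except ValueError:
                raise ParseError(f"{path}: row {lineno}: non-numeric cell") from None
            if rows and vals[0] <= rows[-1][0]:
                raise ParseError(f"{path}: row {lineno}: timestamp not increasing")
            rows.append(vals)
    if not rows:
        raise EmptyInputError(f"{path}: no data rows")
    arr = np.asarray(rows, dtype=float)
    return SensorStream(limb=limb, t=arr[:, 0], gyro=arr[:, 1:4], accel=arr[:, 4:7], mag=arr[:, 7:10])


def write_sensor_csv(stream: SensorStream, path: str | os.PathLike) -> None:
    """Write a stream to CSV; floats use ``repr`` so reads round-trip exactly."""
    data = np.column_stack([stream.t, stream.gyro, stream.accel, stream.mag])
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for row in data:
            writer.writerow([repr(float(v)) for v in row])


# ---------------------------------------------------------------------------
# JSON-lines session log


def _stream_to_obj(stream: SensorStream) -> dict:
    return {
        "t": stream.t.tolist(),
        "gyro": stream.gyro.tolist(),
        "accel": stream.accel.tolist(),
        "mag": stream.mag.tolist(),
        "sample_rate_hz": stream.sample_rate_hz,
    }


def _stream_from_obj(limb: str, obj, base_dir: str) -> SensorStream:
    if isinstance(obj, str):  # relative CSV path
        return read_sensor_csv(os.path.join(base_dir, obj), limb)
    return SensorStream(
        limb=limb,
        t=np.asarray(obj["t"], dtype=float),
        gyro=np.asarray(obj["gyro"], dtype=float),
        accel=np.asarray(obj["accel"], dtype=float),
        mag=np.asarray(obj["mag"], dtype=float),
        sample_rate_hz=float(obj.get("sample_rate_hz", NOMINAL_RATE_HZ)),
    )


def read_session_log(path: str | os.PathLike) -> list[SessionRecord]:
    """Read a JSON-lines session log (one session object per line).

    Sessions flagged interrupted are kept — the completeness filter is the
    analysis stage's job.  A malformed line raises :class:`ParseError` with
    the line number; a duplicate ``session_id`` raises :class:`SchemaError`.
    """
    records: list[SessionRecord] = []
    seen: set[str] = set()
    base_dir = os.path.dirname(os.fspath(path))
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            try:
                obj = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: line {lineno}: invalid JSON ({exc.msg})") from None
            try:
                rec = _record_from_obj(obj, base_dir)
            except KeyError as exc:
                raise SchemaError(f"{path}: line {lineno}: missing key {exc}") from None
            if rec.session_id in seen:
                raise SchemaError(f"{path}: line {lineno}: duplicate session_id {rec.session_id!r}")
            seen.add(rec.session_id)
            records.append(rec)
    return records


def _record_from_obj(obj: dict, base_dir: str) -> SessionRecord:
    streams = {
        limb: _stream_from_obj(limb, sobj, base_dir)
        for limb, sobj in obj["streams"].items()
    }
    trace = None
    if obj.get("playback_trace") is not None:
        tobj = obj["playback_trace"]
        trace = PlaybackTrace(np.asarray(tobj["t"], float), np.asarray(tobj["level"], float))
    return SessionRecord(
        session_id=str(obj["session_id"]),
        mode=obj["mode"],
        streams=streams,
        controlling_limbs=tuple(obj.get("controlling_limbs", LIMBS)),
        planned_duration_s=float(obj.get("planned_duration_s", DEFAULT_SESSION_S)),
        interrupted=bool(obj.get("interrupted", False)),
        playback_trace=trace,
        day=obj.get("day"),
    )


def write_session_log(records: Iterable[SessionRecord], path: str | os.PathLike) -> None:
    """Write sessions as JSON-lines with streams inlined (exact float round-trip)."""
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            obj = {
                "session_id": rec.session_id,
                "mode": rec.mode,
                "controlling_limbs": list(rec.controlling_limbs),
                "planned_duration_s": rec.planned_duration_s,
                "interrupted": rec.interrupted,
                "day": rec.day,
                "streams": {limb: _stream_to_obj(s) for limb, s in rec.streams.items()},
                "playback_trace": (
                    None
                    if rec.playback_trace is None
                    else {"t": rec.playback_trace.t.tolist(), "level": rec.playback_trace.level.tolist()}
                ),
            }
            fh.write(json.dumps(obj) + "\n")


# ---------------------------------------------------------------------------
# Quality rules


def validate_stream_quality(
    session: SessionRecord,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
) -> StreamQualityReport:
    """Flag per-limb connectivity problems (dropped samples or long gaps).

    A limb fails when its observed/expected sample coverage over the planned
    duration falls below ``min_coverage`` or any gap (including the lead-in
    from t=0) exceeds ``max_gap_s``.  A missing limb stream fails rather than
    raising.
    """
    limbs: dict[str, LimbQuality] = {}
    for limb in LIMBS:
        stream = session.streams.get(limb)
        if stream is None or not len(stream):
            expected = int(round(session.planned_duration_s * NOMINAL_RATE_HZ))
            limbs[limb] = LimbQuality(limb, expected, 0, float("inf"), False)
            continue
        expected = int(round(session.planned_duration_s * stream.sample_rate_hz))
        observed = len(stream)
        largest_gap = float(stream.gaps().max())
        ok = (observed / expected) >= min_coverage and largest_gap <= max_gap_s
        limbs[limb] = LimbQuality(limb, expected, observed, largest_gap, ok)
    return StreamQualityReport(session_id=session.session_id, limbs=limbs)


def is_complete_session(
    session: SessionRecord,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> bool:
    """True iff the session yields three minutes of consecutive data.

    Requires the session not to be interrupted and every limb stream to
    contain a gap-free run (no inter-sample gap above ``max_gap_s``) at least
    ``planned_duration_s`` long, with overall sample coverage of at least
    ``min_coverage`` of the expected count.  Small float tolerance absorbs
    the discrete sampling grid.
    """
    if session.interrupted:
        return False
    tol = 1e-6
    for limb in LIMBS:
        stream = session.streams.get(limb)
        if stream is None or not len(stream):
            return False
        if stream.longest_consecutive_s(max_gap_s) < session.planned_duration_s - tol:
            return False
        expected = int(round(session.planned_duration_s * stream.sample_rate_hz))
        if len(stream) / expected < min_coverage:
            return False
    return True
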