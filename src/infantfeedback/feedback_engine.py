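"""Movement-contingent stimulus controller.

The training app turns limb movement into graded audiovisual playback.  The
activity signal is the magnitude of the angular velocity, ``s(t) = |gyro|``
in deg/s.  Each controlling limb maintains its own adaptive threshold over
the trailing five seconds,

    tau(t0) = w_max * max(s on [t0-5, t0]) + w_mean * mean(s on [t0-5, t0]) + eps,

with equal default weights w_max = w_mean = 0.5 and a fixed background
offset ``eps`` (the gyroscope magnitude of a still sensor).  Whenever any
controlling limb's activity reaches its threshold, the playback level ramps
up linearly; otherwise it ramps down, always clamped to [0, 1] — the
stimulus starts and stops gradually rather than abruptly.  Passive (catch
trial) sessions play the stimulus at full level regardless of movement and
serve as the within-infant movement baseline.

Two threshold implementations are provided: an O(1)-per-sample streaming
one (:class:`SlidingWindowThreshold`, used by the session runner) and a
direct full-window recomputation (:func:`threshold_trace_reference`) kept
as an independent check of the streaming bookkeeping.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from collections import deque
from typing import Mapping, Sequence

import numpy as np

from .errors import AnalysisError, EmptyInputError, SchemaError
from .imu_io import (
    LIMBS,
    NOMINAL_RATE_HZ,
    PlaybackTrace,
    SensorStream,
    SessionRecord,
)

__all__ = [
    "ActivitySignal",
    "ThresholdConfig",
    "FeedbackConfig",
    "FeedbackState",
    "SessionPlan",
    "compute_activity",
    "adaptive_threshold",
    "SlidingWindowThreshold",
    "threshold_trace",
    "threshold_trace_reference",
    "controller_step",
    "run_feedback_session",
    "schedule_training_day",
]


@dataclass
class ActivitySignal:
    """Angular-velocity magnitude of one limb, deg/s; values are >= 0."""

    limb: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape:
            raise ValueError("times and values must have equal shape")
        if self.values.size and self.values.min() < 0:
            raise ValueError("activity values must be >= 0")


@dataclass(frozen=True)
class ThresholdConfig:
    """Adaptive-threshold parameters.

    ``window_s`` — trailing window length (s).  ``w_max``/``w_mean`` —
    unitless weights on the window maximum and mean; the defaults implement
    the equally weighted sum.  ``epsilon`` — background offset in deg/s; the
    default stands in for a per-device still-sensor calibration.
    """

    window_s: float = 5.0
    w_max: float = 0.5
    w_mean: float = 0.5
    epsilon: float = 0.8

    def __post_init__(self) -> None:
        if self.window_s <= 0:
            raise ValueError("window_s must be > 0")
        if self.w_max < 0 or self.w_mean < 0 or self.epsilon < 0:
            raise ValueError("weights and epsilon must be >= 0")


@dataclass(frozen=True)
class FeedbackConfig:
    """Threshold parameters plus the playback ramp times (linear ramps)."""

    threshold: ThresholdConfig = field(default_factory=ThresholdConfig)
    ramp_up_s: float = 1.0
    ramp_down_s: float = 2.0

    def __post_init__(self) -> None:
        if self.ramp_up_s <= 0 or self.ramp_down_s <= 0:
            raise ValueError("ramp times must be > 0")


@dataclass(frozen=True)
class FeedbackState:
    """Controller state after a step: playback level and current thresholds."""

    playback_level: float = 0.0
    tau: Mapping[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class SessionPlan:
    """Ordered (mode, controlling_limbs) entries for one training day."""

    entries: tuple[tuple[str, tuple[str, ...]], ...]
    p_active: float
    seed: int | None = None


def compute_activity(stream: SensorStream) -> ActivitySignal:
    """Euclidean norm of the 3-axis gyroscope vector at each sample."""
    if not len(stream):
        raise EmptyInputError(f"stream for {stream.limb} is empty")
    values = np.linalg.norm(stream.gyro, axis=1)
    return ActivitySignal(limb=stream.limb, times=stream.t.copy(), values=values)


def adaptive_threshold(window_values: Sequence[float] | np.ndarray, config: ThresholdConfig) -> float:
    """Threshold for one trailing window: w_max*max + w_mean*mean + epsilon."""
    values = np.asarray(window_values, dtype=float)
    if values.size == 0:
        raise EmptyInputError("threshold window is empty")
    if values.min() < 0:
        raise ValueError("activity is a magnitude; window values must be >= 0")
    return float(config.w_max * values.max() + config.w_mean * values.mean() + config.epsilon)


class SlidingWindowThreshold:
    """Streaming trailing-window threshold with O(1) amortised updates.

    Keeps a running sum for the window mean and a monotonically decreasing
    deque for the window maximum.  A sample at time ``t`` belongs to the
    window of ``t0`` iff ``t >= t0 - window_s`` — the same predicate the
    reference recomputation uses, so both see identical windows.  During the
    first ``window_s`` of a session the window is simply all samples so far.
    """

    def __init__(self, config: ThresholdConfig) -> None:
        self.config = config
        self._window: deque[tuple[float, float]] = deque()  # (t, value)
        self._maxq: deque[tuple[float, float]] = deque()
        self._sum = 0.0

    def push(self, t: float, value: float) -> float:
        """Ingest one sample and return tau at its time."""
        if value < 0:
            raise ValueError("activity must be >= 0")
        cutoff = t - self.config.window_s
        while self._window and self._window[0][0] < cutoff:
            _, old = self._window.popleft()
            self._sum -= old
        while self._maxq and self._maxq[0][0] < cutoff:
            self._maxq.popleft()
        self._window.append((t, value))
        self._sum += value
        while self._maxq and self._maxq[-1][1] <= value:
            self._maxq.pop()
        self._maxq.append((t, value))
        cfg = self.config
        mean = self._sum / len(self._window)
        return cfg.w_max * self._maxq[0][1] + cfg.w_mean * mean + cfg.epsilon


def threshold_trace(signal: ActivitySignal, config: ThresholdConfig) -> np.ndarray:
    """Per-sample threshold trace via the streaming implementation."""
    tracker = SlidingWindowThreshold(config)
    return np.array([tracker.push(t, v) for t, v in zip(signal.times, signal.values)])


def threshold_trace_reference(signal: ActivitySignal, config: ThresholdConfig) -> np.ndarray:
    """Per-sample threshold by brute-force recomputation of every window.

    Recomputes max and mean over the full trailing window at each sample;
    used to validate :func:`threshold_trace`.
    """
    t, v = signal.times, signal.values
    out = np.empty_like(v)
    for i in range(v.size):
        lo = int(np.searchsorted(t, t[i] - config.window_s, side="left"))
        w = v[lo : i + 1]
        out[i] = config.w_max * w.max() + config.w_mean * w.mean() + config.epsilon
    return out


def controller_step(
    state: FeedbackState,
    activity_now: Mapping[str, float],
    tau: Mapping[str, float],
    dt: float,
    config: FeedbackConfig,
) -> FeedbackState:
    """Advance the playback level by one sample interval.

    The drive condition is permissive across limbs: playback ramps up if
    *any* controlling limb's activity reaches its threshold (activity - tau
    >= 0), otherwise it ramps down; the level is clamped to [0, 1].
    """
    if dt <= 0:
        raise ValueError("dt must be > 0")
    drive = any(activity_now[limb] - tau[limb] >= 0 for limb in activity_now)
    level = state.playback_level + (dt / config.ramp_up_s if drive else -dt / config.ramp_down_s)
    return FeedbackState(playback_level=min(1.0, max(0.0, level)), tau=dict(tau))


def run_feedback_session(
    streams: Mapping[str, SensorStream],
    mode: str,
    controlling_limbs: Sequence[str] = LIMBS,
    config: FeedbackConfig | None = None,
    session_id: str = "session",
    day: int | None = None,
    planned_duration_s: float | None = None,
) -> SessionRecord:
    """Replay a session through the controller and record the playback trace.

    Active mode: each controlling limb's threshold is recomputed at every
    sample from its trailing window, and the shared playback level follows
    the drive condition.  Passive mode: the trace is identically 1 and never
    consults the movement data.
    """
    config = config or FeedbackConfig()
    controlling = tuple(controlling_limbs)
    ref_limb = controlling[0] if mode == "active" else next(iter(streams))
    if mode == "active":
        missing = [l for l in controlling if l not in streams]
        if missing:
            raise SchemaError(f"missing streams for controlling limbs {missing}")
    times = streams[ref_limb].t
    if mode == "passive":
        trace = PlaybackTrace(t=times.copy(), level=np.ones_like(times))
    else:
        signals = {l: compute_activity(streams[l]) for l in controlling}
        n = times.size
        for l in controlling:
            if signals[l].times.size != n:
                raise AnalysisError("controlling limb streams must share one clock")
        trackers = {l: SlidingWindowThreshold(config.threshold) for l in controlling}
        dt_nominal = 1.0 / streams[ref_limb].sample_rate_hz
        level = np.empty(n)
        state = FeedbackState()
        for i in range(n):
            tau = {l: trackers[l].push(times[i], signals[l].values[i]) for l in controlling}
            act = {l: signals[l].values[i] for l in controlling}
            dt = times[i] - times[i - 1] if i else dt_nominal
            state = controller_step(state, act, tau, dt, config)
            level[i] = state.playback_level
        trace = PlaybackTrace(t=times.copy(), level=level)
    planned = planned_duration_s
    if planned is None:
        planned = min(s.duration_s for s in streams.values())
    return SessionRecord(
        session_id=session_id,
        mode=mode,
        streams=dict(streams),
        controlling_limbs=controlling,
        planned_duration_s=planned,
        playback_trace=trace,
        day=day,
    )


def schedule_training_day(
    n_sessions: int = 5,
    p_active: float = 0.68,
    controlling_limbs: Sequence[str] = LIMBS,
    seed: int | None = None,
) -> SessionPlan:
    """Randomize the day's sessions: i.i.d. Bernoulli(p_active) active/passive.

    One seeded generator drives the whole plan, so an identical seed gives
    an identical plan.  The controller can be set to one limb, two, or all
    four via ``controlling_limbs``.
    """
    if not 0 <= p_active <= 1:
        raise ValueError("p_active must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    limbs = tuple(controlling_limbs)
    entries = tuple(
        ("active" if rng.random() < p_active else "passive", limbs) for _ in range(n_sessions)
    )
    return SessionPlan(entries=entries, p_active=p_active, seed=seed)
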