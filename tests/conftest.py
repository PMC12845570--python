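"""Shared fixtures: constructed sensor streams and sessions.

All fixtures are generated programmatically; constructed streams use
constant gyro vectors so pooled medians are known by hand.
"""

from __future__ import annotations

import numpy as np
import pytest

from infantfeedback.imu_io import (
    LIMBS,
    NOMINAL_RATE_HZ,
    SensorStream,
    SessionRecord,
)

DT = 1.0 / NOMINAL_RATE_HZ


def make_stream(
    limb: str,
    duration_s: float = 180.0,
    gyro_vec=(3.0, 4.0, 0.0),
    t: np.ndarray | None = None,
) -> SensorStream:
    """Constant-gyro stream; pass an explicit ``t`` to inject gaps."""
    if t is None:
        n = int(round(duration_s * NOMINAL_RATE_HZ))
        t = np.arange(n) * DT
    n = t.size
    gyro = np.tile(np.asarray(gyro_vec, float), (n, 1))
    zeros = np.zeros((n, 3))
    return SensorStream(limb=limb, t=t, gyro=gyro, accel=zeros, mag=zeros)


def make_session(
    session_id: str = "s1",
    mode: str = "passive",
    duration_s: float = 180.0,
    left_mag: float = 5.0,
    right_mag: float = 5.0,
    interrupted: bool = False,
    day: int | None = None,
    stream_overrides: dict | None = None,
) -> SessionRecord:
    """Four constant streams; left limbs at |gyro| = left_mag, right at right_mag."""
    streams = {}
    for limb in LIMBS:
        mag = left_mag if limb.startswith("left") else right_mag
        streams[limb] = make_stream(limb, duration_s, gyro_vec=(mag, 0.0, 0.0))
    if stream_overrides:
        streams.update(stream_overrides)
    return SessionRecord(
        session_id=session_id,
        mode=mode,
        streams=streams,
        interrupted=interrupted,
        day=day,
    )


def times_with_dropout(total_s: float, gap_start: float, gap_end: float) -> np.ndarray:
    """Uniform 26-Hz timestamps over [0, total_s) minus one dropout window."""
    n = int(round(total_s * NOMINAL_RATE_HZ))
    t = np.arange(n) * DT
    return t[(t < gap_start) | (t > gap_end)]


@pytest.fixture
def full_session() -> SessionRecord:
    return make_session()


@pytest.fixture
def mixed_quality_log() -> list[SessionRecord]:
    """Ten sessions: 6 clean, 2 interrupted, 1 short, 1 one-sensor dropout.

    The dropout session carries 186 s of data on one sensor with a ~4.4-s
    hole after the 181-s mark: still three minutes of consecutive data
    (complete) but a connectivity failure for the side analysis.
    """
    sessions = [
        make_session(f"good-{i}", mode="active" if i % 2 else "passive", day=1 + i // 2)
        for i in range(6)
    ]
    sessions.append(make_session("interrupted-1", duration_s=90.0, interrupted=True, day=4))
    sessions.append(make_session("interrupted-2", duration_s=45.0, interrupted=True, day=4))
    sessions.append(make_session("short-1", duration_s=120.0, day=5))
    dropout_t = times_with_dropout(186.0, gap_start=181.0, gap_end=185.4)
    dropout = make_session(
        "dropout-1",
        day=5,
        stream_overrides={
            "left_hand": make_stream("left_hand", gyro_vec=(5.0, 0.0, 0.0), t=dropout_t)
        },
    )
    # other three limbs also span 186 s so stream lengths differ only in the hole
    for limb in ("right_hand", "left_foot", "right_foot"):
        dropout.streams[limb] = make_stream(limb, duration_s=186.0, gyro_vec=(5.0, 0.0, 0.0))
    sessions.append(dropout)
    return sessions
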