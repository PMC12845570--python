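"""Offline analysis of recorded training sessions.

The analyses mirror how the training data are evaluated after an
intervention:

* **Session activity** — the median of the angular-velocity magnitude over
  the session, pooling all samples from the four sensors.  Only complete
  sessions (three minutes of consecutive data) are analysed.
* **Active/passive contrast** — per training day, the ratio of mean active
  to mean passive session activity; per infant, a paired t-test on mean
  active vs. mean passive activity (values above 1 mean the infant moved
  more when the stimulus was movement-contingent).
* **Side-difference index** — (R - L) / (R + L) on pooled left vs. right
  (hand and foot combined) median activity; positive values indicate a
  right-dominant side.  Sessions with connectivity problems on any sensor
  are additionally excluded here to keep the two sides comparable.
* **Clinical correlation** — ordinary least-squares regression of one
  per-infant score on another (e.g. sensor-derived laterality vs. a hand
  assessment), reported as r², two-sided p, slope and intercept.
* **Compliance** — minutes per training day and the share of infants
  reaching at least 50% of the recommended dose (4 days/week over roughly
  six months, 104 days by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AnalysisError, EmptyInputError
from .feedback_engine import compute_activity
from .imu_io import (
    DEFAULT_MAX_GAP_S,
    DEFAULT_MIN_COVERAGE,
    LEFT_LIMBS,
    LIMBS,
    RIGHT_LIMBS,
    SessionRecord,
    is_complete_session,
    validate_stream_quality,
)

__all__ = [
    "DEFAULT_RECOMMENDED_DAYS",
    "SessionActivity",
    "FilterDecision",
    "PairedTestResult",
    "AsymmetryResult",
    "RegressionResult",
    "ComplianceSummary",
    "session_activity",
    "filter_sessions",
    "activity_table",
    "daily_ratios",
    "active_passive_test",
    "side_asymmetry_index",
    "clinical_correlation",
    "compliance_metrics",
    "analyze_sessions",
    "plot_daily_ratios",
]

DEFAULT_RECOMMENDED_DAYS = 104  # 4 days/week x ~26 weeks


@dataclass(frozen=True)
class SessionActivity:
    """Median pooled |gyro| of one complete session, deg/s."""

    session_id: str
    mode: str
    activity: float
    n_samples: int
    day: int | None = None


@dataclass(frozen=True)
class FilterDecision:
    """Why a session was kept or dropped by a given analysis stage."""

    session_id: str
    included: bool
    reason: str


@dataclass(frozen=True)
class PairedTestResult:
    """Paired t-test on per-infant mean active vs. passive activity."""

    t: float
    p: float
    df: int
    n: int
    mean_diff: float
    mean_ratio: float
    sd_ratio: float
    degenerate: bool = False


@dataclass(frozen=True)
class AsymmetryResult:
    """Side-difference index over the included sessions."""

    index: float
    left: float
    right: float
    n_sessions_used: int
    excluded: tuple[FilterDecision, ...] = ()


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r2: float
    p: float
    n: int


@dataclass
class ComplianceSummary:
    """Per-infant dose metrics and the group-level compliance numbers.

    ``mean_minutes_per_day``/``sd_minutes_per_day`` summarise the infants
    meeting the >=50% criterion (descriptive SD over that group, ddof=0);
    ``pct_meeting`` counts every participant in the denominator.
    """

    per_infant: pd.DataFrame
    mean_minutes_per_day: float
    sd_minutes_per_day: float
    n_meeting: int
    n_total: int
    pct_meeting: float
    recommended_days: int


# ---------------------------------------------------------------------------


def session_activity(session: SessionRecord, *, _checked: bool = False) -> SessionActivity:
    """Median of the pooled four-sensor angular-velocity magnitudes.

    All samples from all four sensors form one collection whose median is
    the session's activity — so the result is invariant to sensor order.
    Calling this directly on an incomplete session raises
    :class:`AnalysisError`; the pipeline filters such sessions out instead.
    """
    if not _checked and not is_complete_session(session):
        raise AnalysisError(
            f"session {session.session_id!r} is not complete (three minutes of consecutive data)"
        )
    pooled = np.concatenate(
        [compute_activity(session.streams[limb]).values for limb in LIMBS if limb in session.streams]
    )
    return SessionActivity(
        session_id=session.session_id,
        mode=session.mode,
        activity=float(np.median(pooled)),
        n_samples=int(pooled.size),
        day=session.day,
    )


def filter_sessions(
    sessions: list[SessionRecord],
    require_connectivity: bool = False,
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[list[SessionRecord], list[FilterDecision]]:
    """Apply the complete-session filter (and optionally the connectivity rule).

    Returns the kept sessions and an itemized decision per input session.
    """
    kept: list[SessionRecord] = []
    decisions: list[FilterDecision] = []
    for s in sessions:
        if s.interrupted:
            decisions.append(FilterDecision(s.session_id, False, "interrupted"))
            continue
        if not is_complete_session(s, max_gap_s=max_gap_s, min_coverage=min_coverage):
            decisions.append(
                FilterDecision(s.session_id, False, "incomplete: lacks three minutes of consecutive data")
            )
            continue
        if require_connectivity:
            report = validate_stream_quality(s, min_coverage=min_coverage, max_gap_s=max_gap_s)
            if not report.session_ok:
                bad = [l for l, q in report.limbs.items() if not q.connectivity_ok]
                decisions.append(
                    FilterDecision(s.session_id, False, f"connectivity problems: {', '.join(bad)}")
                )
                continue
        decisions.append(FilterDecision(s.session_id, True, "complete"))
        kept.append(s)
    return kept, decisions


def activity_table(
    sessions: list[SessionRecord],
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> tuple[pd.DataFrame, list[FilterDecision]]:
    """Per-session activity for every complete session, plus filter decisions."""
    kept, decisions = filter_sessions(sessions, max_gap_s=max_gap_s, min_coverage=min_coverage)
    rows = [session_activity(s, _checked=True) for s in kept]
    df = pd.DataFrame(
        [
            {
                "session_id": r.session_id,
                "day": r.day,
                "mode": r.mode,
                "activity": r.activity,
                "n_samples": r.n_samples,
            }
            for r in rows
        ],
        columns=["session_id", "day", "mode", "activity", "n_samples"],
    )
    return df, decisions


def daily_ratios(activities: pd.DataFrame) -> pd.DataFrame:
    """Mean active / mean passive activity per training day.

    Days lacking either mode (or with zero passive mean) get ``ratio`` NaN
    and an explanatory ``note``; callers report rather than silently drop
    them.
    """
    if "day" not in activities or activities["day"].isna().all():
        raise AnalysisError("sessions carry no day labels; daily ratios undefined")
    rows = []
    for day, grp in activities.groupby("day"):
        act = grp.loc[grp["mode"] == "active", "activity"]
        pas = grp.loc[grp["mode"] == "passive", "activity"]
        note = ""
        ratio = np.nan
        if act.empty or pas.empty:
            note = "missing active sessions" if act.empty else "missing passive sessions"
        elif pas.mean() == 0:
            note = "passive mean is zero; ratio undefined"
        else:
            ratio = float(act.mean() / pas.mean())
        rows.append(
            {
                "day": day,
                "n_active": len(act),
                "n_passive": len(pas),
                "mean_active": float(act.mean()) if len(act) else np.nan,
                "mean_passive": float(pas.mean()) if len(pas) else np.nan,
                "ratio": ratio,
                "note": note,
            }
        )
    return pd.DataFrame(rows)


def active_passive_test(active_means, passive_means) -> PairedTestResult:
    """Classical paired t-test on per-infant (active - passive) mean activity.

    With all differences zero the test returns t = 0, p = 1.  With nonzero
    but constant differences the SD of differences is zero and t diverges;
    the result is flagged degenerate and p reported at the floating-point
    floor with a warning.
    """
    a = np.asarray(active_means, dtype=float)
    p = np.asarray(passive_means, dtype=float)
    if a.shape != p.shape or a.ndim != 1:
        raise AnalysisError("active and passive means must be paired 1-d arrays")
    n = a.size
    if n < 2:
        raise AnalysisError("paired t-test needs at least 2 infants")
    d = a - p
    ratios = a / p
    mean_ratio = float(ratios.mean())
    sd_ratio = float(ratios.std(ddof=1))
    if np.allclose(d.std(ddof=1), 0.0):
        if np.allclose(d, 0.0):
            return PairedTestResult(0.0, 1.0, n - 1, n, 0.0, mean_ratio, sd_ratio)
        warnings.warn(
            "zero variance of paired differences; t undefined, p reported at machine floor",
            stacklevel=2,
        )
        tstat = float(np.inf if d.mean() > 0 else -np.inf)
        return PairedTestResult(
            tstat, float(np.finfo(float).tiny), n - 1, n, float(d.mean()), mean_ratio, sd_ratio, True
        )
    res = stats.ttest_rel(a, p)
    return PairedTestResult(
        float(res.statistic), float(res.pvalue), n - 1, n, float(d.mean()), mean_ratio, sd_ratio
    )


def side_asymmetry_index(
    sessions: list[SessionRecord],
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> AsymmetryResult:
    """Laterality of movement: (R - L) / (R + L) of pooled side medians.

    L pools every gyro-magnitude sample of the left hand and foot across the
    included sessions (complete AND connectivity-ok) and takes the median; R
    likewise for the right side.  The index lies in [-1, 1]; positive means
    right-dominant.
    """
    kept, decisions = filter_sessions(
        sessions, require_connectivity=True, max_gap_s=max_gap_s, min_coverage=min_coverage
    )
    excluded = tuple(d for d in decisions if not d.included)
    if not kept:
        reasons = "; ".join(f"{d.session_id}: {d.reason}" for d in excluded) or "no sessions supplied"
        raise AnalysisError(f"no sessions eligible for side analysis ({reasons})")
    left = np.concatenate(
        [compute_activity(s.streams[l]).values for s in kept for l in LEFT_LIMBS]
    )
    right = np.concatenate(
        [compute_activity(s.streams[l]).values for s in kept for l in RIGHT_LIMBS]
    )
    L = float(np.median(left))
    R = float(np.median(right))
    if L == 0.0 and R == 0.0:
        raise AnalysisError("both sides have zero median activity; index undefined")
    return AsymmetryResult(
        index=(R - L) / (R + L), left=L, right=R, n_sessions_used=len(kept), excluded=excluded
    )


def clinical_correlation(x, y) -> RegressionResult:
    """OLS of y on x across infants: slope, intercept, r², two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise AnalysisError("x and y must be paired 1-d arrays")
    if x.size < 3:
        raise AnalysisError("regression needs at least 3 paired observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise AnalysisError("regression inputs must be finite")
    if np.allclose(x, x[0]):
        raise AnalysisError("predictor is constant; regression undefined")
    if np.allclose(y, y[0]):
        # flat response: zero slope explains everything there is to explain
        return RegressionResult(slope=0.0, intercept=float(y.mean()), r2=0.0, p=1.0, n=x.size)
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r2=float(res.rvalue) ** 2,
        p=float(res.pvalue),
        n=x.size,
    )


def compliance_metrics(
    journal: pd.DataFrame, recommended_days: int = DEFAULT_RECOMMENDED_DAYS
) -> ComplianceSummary:
    """Training-dose metrics from the parent journal.

    ``journal`` needs columns ``infant_id, days_trained, hours_trained``.
    Minutes/day is computed for every infant with at least one trained day;
    the group mean and SD cover the infants meeting the >=50% criterion
    (days_trained >= recommended_days / 2), while the %-meeting figure keeps
    all participants in the denominator.
    """
    required = {"infant_id", "days_trained", "hours_trained"}
    if journal.empty:
        raise EmptyInputError("compliance journal is empty")
    if not required.issubset(journal.columns):
        raise AnalysisError(f"journal must have columns {sorted(required)}")
    df = journal.copy()
    if (df["days_trained"] < 0).any() or (df["hours_trained"] < 0).any():
        raise AnalysisError("days and hours trained must be >= 0")
    df["minutes_per_day"] = np.where(
        df["days_trained"] > 0, 60.0 * df["hours_trained"] / df["days_trained"], np.nan
    )
    df["pct_of_recommended"] = 100.0 * df["days_trained"] / recommended_days
    df["met_50pct"] = df["days_trained"] >= 0.5 * recommended_days
    included = df.loc[df["met_50pct"] & df["days_trained"].gt(0), "minutes_per_day"]
    mean_mpd = float(included.mean()) if len(included) else float("nan")
    sd_mpd = float(included.std(ddof=0)) if len(included) else float("nan")
    n_meet = int(df["met_50pct"].sum())
    n_total = len(df)
    return ComplianceSummary(
        per_infant=df,
        mean_minutes_per_day=mean_mpd,
        sd_minutes_per_day=sd_mpd,
        n_meeting=n_meet,
        n_total=n_total,
        pct_meeting=100.0 * n_meet / n_total,
        recommended_days=recommended_days,
    )


# ---------------------------------------------------------------------------


def analyze_sessions(
    sessions: list[SessionRecord],
    max_gap_s: float = DEFAULT_MAX_GAP_S,
    min_coverage: float = DEFAULT_MIN_COVERAGE,
) -> dict:
    """Full activity report for one session log: per-session activity, daily
    ratios where day labels exist, and the itemized filter decisions."""
    table, decisions = activity_table(sessions, max_gap_s=max_gap_s, min_coverage=min_coverage)
    report: dict = {
        "n_sessions": len(sessions),
        "n_complete": int(len(table)),
        "filter_decisions": [
            {"session_id": d.session_id, "included": d.included, "reason": d.reason}
            for d in decisions
        ],
        "sessions": table.to_dict(orient="records"),
    }
    if len(table) and table["day"].notna().any():
        ratios = daily_ratios(table)
        report["daily_ratios"] = [
            {k: (None if isinstance(v, float) and np.isnan(v) else v) for k, v in row.items()}
            for row in ratios.to_dict(orient="records")
        ]
        valid = ratios["ratio"].dropna()
        report["mean_daily_ratio"] = float(valid.mean()) if len(valid) else None
    by_mode = table.groupby("mode")["activity"].mean() if len(table) else pd.Series(dtype=float)
    report["mean_activity_by_mode"] = {k: float(v) for k, v in by_mode.items()}
    return report


def plot_daily_ratios(ratios: pd.DataFrame, path: str) -> None:
    """Basic active/passive daily-ratio scatter with the unity line."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots()
    ax.scatter(ratios["day"], ratios["ratio"])
    ax.axhline(1.0, color="red", lw=1)
    ax.set_xlabel("training day")
    ax.set_ylabel("active / passive activity ratio")
    fig.savefig(path)
    plt.close(fig)
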