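"""Detection and summarisation of visits to permanent water points.

Because an hourly fix rarely lands exactly on a water point, the visit
circle for each point is sized from the animals' own travel speed nearby:
the mean distance travelled per hour over "passing series" (runs of at
least three consecutive fixes whose interior fixes pass within 50 m of the
point) is halved and rounded up to the nearest 10 m.  Any fix - or run of
consecutive fixes - inside that circle counts as one visit, timed at the
fix closest to the point.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .trajectory import AnalysisWindow, Trajectory, hour_of_day

__all__ = [
    "WaterPoint",
    "Visit",
    "passing_series",
    "visit_radius",
    "detect_visits",
    "visit_stats",
]


@dataclass
class WaterPoint:
    label: str
    x: float
    y: float
    pass_threshold_m: float = 50.0
    visit_radius_m: float | None = None

    def __post_init__(self) -> None:
        if self.pass_threshold_m <= 0:
            raise ValueError("pass threshold must be positive")
        if self.visit_radius_m is not None and self.visit_radius_m <= 0:
            raise ValueError("visit radius must be positive")


@dataclass(frozen=True)
class Visit:
    animal_id: str
    water_label: str
    visit_time: pd.Timestamp
    n_fixes: int
    min_distance_m: float


@dataclass
class PassingSeries:
    start_index: int
    stop_index: int  # inclusive
    step_lengths_m: np.ndarray = field(repr=False, default=None)

    @property
    def n_fixes(self) -> int:
        return self.stop_index - self.start_index + 1


def _distances(traj: Trajectory, wp: WaterPoint) -> np.ndarray:
    return np.hypot(traj.x - wp.x, traj.y - wp.y)


def passing_series(traj: Trajectory, wp: WaterPoint):
    """Passing series near a water point and the mean hourly distance.

    A passing series is a maximal run of >= 3 consecutive fixes whose
    interior fixes (all but the first and last) lie strictly within the
    50-m pass threshold.  Step lengths of all 1-h steps inside all series
    are pooled into the mean hourly distance (with SE), the basis of the
    visit radius.

    Returns (list of PassingSeries, mean_m, se_m); mean and SE are NaN when
    no series qualifies.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    d = _distances(traj, wp)
    inner = d < wp.pass_threshold_m
    # maximal inner runs extended by one fix on each side, merged on overlap
    spans: list[list[int]] = []
    i = 0
    n = len(traj)
    while i < n:
        if inner[i]:
            j = i
            while j + 1 < n and inner[j + 1]:
                j += 1
            lo = max(i - 1, 0)
            hi = min(j + 1, n - 1)
            if spans and lo <= spans[-1][1]:
                spans[-1][1] = hi
            else:
                spans.append([lo, hi])
            i = j + 1
        else:
            i += 1
    spans = [s for s in spans if s[1] - s[0] + 1 >= 3]

    series = []
    all_steps = []
    dt_h = np.diff(traj.times.asi8) / 3.6e12 if n > 1 else np.array([])
    step_len = np.hypot(np.diff(traj.x), np.diff(traj.y)) if n > 1 else np.array([])
    for lo, hi in spans:
        idx = np.arange(lo, hi)
        ok = np.abs(dt_h[idx] - 1.0) <= 5.0 / 60.0
        lens = step_len[idx][ok]
        series.append(PassingSeries(lo, hi, lens))
        all_steps.append(lens)
    if not series:
        warnings.warn(f"no passing series near water point {wp.label!r}")
        return [], float("nan"), float("nan")
    pooled = np.concatenate(all_steps)
    mean = float(pooled.mean()) if pooled.size else float("nan")
    se = float(pooled.std(ddof=1) / math.sqrt(pooled.size)) if pooled.size > 1 else float("nan")
    return series, mean, se


def visit_radius(mean_hourly_distance_m: float) -> float:
    """Visit-circle radius: half the mean hourly distance, rounded up to the
    next multiple of 10 m (879 -> 440, 408 -> 210, 1633 -> 820)."""
    if not mean_hourly_distance_m > 0:
        raise ValueError("mean hourly distance must be positive")
    return 10.0 * math.ceil(mean_hourly_distance_m / 20.0)


def detect_visits(
    traj: Trajectory, wp: WaterPoint, bridge_gaps: bool = True
) -> list[Visit]:
    """Visits: maximal runs of consecutive fixes within the visit radius
    (closed disc).  The visit time is the time of the run's closest fix
    (earliest on ties).  A cadence gap flanked by in-radius fixes does not
    split a visit unless ``bridge_gaps`` is False.
    """
    if wp.visit_radius_m is None:
        raise ValueError(f"water point {wp.label!r} has no visit radius set")
    n = len(traj)
    if n == 0:
        return []
    d = _distances(traj, wp)
    inside = d <= wp.visit_radius_m
    dt_h = np.diff(traj.times.asi8) / 3.6e12 if n > 1 else np.array([])

    visits = []
    run: list[int] = []
    for i in range(n):
        if inside[i]:
            if run and not bridge_gaps and dt_h[i - 1] > 1.0 + 5.0 / 60.0:
                visits.append(_make_visit(traj, wp, run, d))
                run = []
            run.append(i)
        elif run:
            visits.append(_make_visit(traj, wp, run, d))
            run = []
    if run:
        visits.append(_make_visit(traj, wp, run, d))
    return visits


def _make_visit(traj, wp, run, d) -> Visit:
    sub = d[run]
    best = run[int(np.argmin(sub))]  # argmin returns the earliest tie
    return Visit(
        animal_id=traj.animal_id,
        water_label=wp.label,
        visit_time=traj.times[best],
        n_fixes=len(run),
        min_distance_m=float(d[best]),
    )


def visit_stats(visits, window: AnalysisWindow):
    """Per-day visit rate and a 24-bin histogram of visit hours."""
    if window.days <= 0:
        raise ValueError("zero-length window")
    rate = len(visits) / window.days
    hist = np.zeros(24, dtype=int)
    for v in visits:
        hist[hour_of_day(v.visit_time)] += 1
    return float(rate), hist


def visits_frame(visits) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "animal": v.animal_id,
                "water": v.water_label,
                "time": v.visit_time,
                "hour": hour_of_day(v.visit_time),
                "n_fixes": v.n_fixes,
                "min_dist_m": v.min_distance_m,
            }
            for v in visits
        ],
        columns=["animal", "water", "time", "hour", "n_fixes", "min_dist_m"],
    )
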