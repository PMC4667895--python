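"""Trajectory data model: hourly GPS fix sequences on a planar grid.

A trajectory is a per-animal, time-ordered sequence of fixes recorded at a
nominal 1-h cadence inside a fixed analysis window (e.g. a 50-day season).
Gaps (missed fix attempts) are recorded, never interpolated; downstream
analyses decide how to treat them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "AnalysisWindow",
    "Fix",
    "Trajectory",
    "parse_fix_table",
    "step_series",
    "hour_of_day",
    "DEFAULT_CADENCE_TOL_MIN",
]

#: Tolerance (minutes) around the nominal hourly cadence for snapping and
#: for declaring a step "valid" (exactly one cadence interval long).
DEFAULT_CADENCE_TOL_MIN = 5.0


@dataclass(frozen=True)
class AnalysisWindow:
    """A fixed observation period, nominally 50 days, with a season label."""

    start: pd.Timestamp
    end: pd.Timestamp
    season_label: str = ""

    def __post_init__(self) -> None:
        for name in ("start", "end"):
            ts = getattr(self, name)
            if not isinstance(ts, pd.Timestamp) or ts.tzinfo is None:
                raise ValueError(f"window {name} must be a tz-aware Timestamp")
        if self.end <= self.start:
            raise ValueError("window end must be after start")

    @classmethod
    def from_start(cls, start, days: float = 50.0, season_label: str = "") -> "AnalysisWindow":
        start = pd.Timestamp(start)
        if start.tzinfo is None:
            start = start.tz_localize("UTC")
        return cls(start, start + pd.Timedelta(days=days), season_label)

    @property
    def days(self) -> float:
        return (self.end - self.start) / pd.Timedelta(days=1)

    @property
    def hours(self) -> float:
        return (self.end - self.start) / pd.Timedelta(hours=1)


@dataclass(frozen=True)
class Fix:
    animal_id: str
    timestamp: pd.Timestamp
    x: float
    y: float

    def __post_init__(self) -> None:
        if self.timestamp.tzinfo is None:
            raise ValueError("fix timestamp must be tz-aware")
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("fix coordinates must be finite")


@dataclass
class Trajectory:
    """Time-ordered fixes of one animal within one analysis window."""

    animal_id: str
    times: pd.DatetimeIndex
    x: np.ndarray
    y: np.ndarray
    window: AnalysisWindow
    gaps: list[tuple[pd.Timestamp, pd.Timestamp, float]] = field(default_factory=list)
    n_dropped_outside_window: int = 0

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if not (len(self.times) == len(self.x) == len(self.y)):
            raise ValueError("times, x and y must have equal length")
        if self.times.tz is None:
            raise ValueError("trajectory timestamps must be tz-aware")
        if len(self.times) > 1 and not self.times.is_monotonic_increasing:
            raise ValueError("timestamps must be increasing")
        if len(self.times) != len(set(self.times)):
            raise ValueError("duplicate timestamps in trajectory")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise ValueError("coordinates must be finite")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def n_fixes(self) -> int:
        return len(self.times)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "id": self.animal_id,
                "timestamp": self.times,
                "x": self.x,
                "y": self.y,
            }
        )

    def to_geojson(self) -> dict:
        """Fixes as a GeoJSON FeatureCollection of points (for inspection)."""
        feats = [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [float(xi), float(yi)]},
                "properties": {"id": self.animal_id, "timestamp": ti.isoformat()},
            }
            for ti, xi, yi in zip(self.times, self.x, self.y)
        ]
        return {"type": "FeatureCollection", "features": feats}

    def write_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _looks_geographic(x: np.ndarray, y: np.ndarray) -> bool:
    # Planar metre coordinates are required; lon/lat sneaks in as small numbers.
    return bool(np.all(np.abs(x) <= 180.0) and np.all(np.abs(y) <= 90.0))


def _find_gaps(times: pd.DatetimeIndex, cadence_h: float, tol_min: float):
    gaps = []
    if len(times) < 2:
        return gaps
    diffs_h = np.diff(times.asi8) / 3.6e12
    tol_h = tol_min / 60.0
    for i, dh in enumerate(diffs_h):
        if dh > cadence_h + tol_h:
            gaps.append((times[i], times[i + 1], float(dh)))
    return gaps


def parse_fix_table(
    source,
    window: AnalysisWindow,
    cadence_tol_min: float = DEFAULT_CADENCE_TOL_MIN,
    tz: str | None = None,
) -> dict[str, Trajectory]:
    """Parse a delimited fix table into one :class:`Trajectory` per animal.

    Parameters
    ----------
    source
        Path / file handle of a CSV with columns ``id,timestamp,x,y``
        (ISO-8601 timestamps), or an equivalent DataFrame.
    window
        Fixes outside ``[window.start, window.end)`` are dropped; the count
        of dropped rows is recorded on each trajectory.
    tz
        Timezone to localise naive timestamps to.  Naive timestamps without
        ``tz`` are an error.

    Returns
    -------
    dict mapping animal id to Trajectory (fixes sorted, gaps recorded).
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        df = pd.read_csv(source)
    required = {"id", "timestamp", "x", "y"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"fix table missing column(s): {sorted(missing)}")

    try:
        ts = pd.to_datetime(df["timestamp"], format="ISO8601", utc=False)
    except (ValueError, TypeError) as exc:
        raise ValueError(f"unparseable timestamp in fix table: {exc}") from exc
    if getattr(ts.dt, "tz", None) is None:
        if tz is None:
            raise ValueError("naive timestamps in fix table; pass tz= to localise")
        ts = ts.dt.tz_localize(tz)
    df = df.assign(timestamp=ts)

    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(vals.index[vals.isna()][0])
            raise ValueError(f"non-numeric {col!r} at row {row}")
        df[col] = vals.astype(float)

    dup = df.duplicated(subset=["id", "timestamp"])
    if dup.any():
        row = int(df.index[dup][0])
        raise ValueError(f"duplicate (id, timestamp) at row {row}")

    if len(df) and _looks_geographic(df["x"].to_numpy(), df["y"].to_numpy()):
        raise ValueError(
            "coordinates look like lon/lat degrees; project to planar metres "
            "before ingest"
        )

    out: dict[str, Trajectory] = {}
    for animal_id, sub in df.groupby("id", sort=True):
        sub = sub.sort_values("timestamp")
        inside = (sub["timestamp"] >= window.start) & (sub["timestamp"] < window.end)
        dropped = int((~inside).sum())
        sub = sub[inside]
        times = pd.DatetimeIndex(sub["timestamp"])
        traj = Trajectory(
            animal_id=str(animal_id),
            times=times,
            x=sub["x"].to_numpy(),
            y=sub["y"].to_numpy(),
            window=window,
            gaps=_find_gaps(times, 1.0, cadence_tol_min),
            n_dropped_outside_window=dropped,
        )
        out[str(animal_id)] = traj
    return out


def step_series(
    traj: Trajectory, cadence_tol_min: float = DEFAULT_CADENCE_TOL_MIN
) -> pd.DataFrame:
    """Consecutive-fix steps: start time, duration (h), Euclidean length (m).

    Steps whose duration differs from the 1-h cadence by more than the
    tolerance are flagged ``valid=False`` and excluded from hourly statistics
    downstream.  Fewer than two fixes yields an empty frame.
    """
    cols = ["start_time", "hour", "duration_h", "distance_m", "valid"]
    if len(traj) < 2:
        return pd.DataFrame(columns=cols)
    dt_h = np.diff(traj.times.asi8) / 3.6e12
    dist = np.hypot(np.diff(traj.x), np.diff(traj.y))
    tol_h = cadence_tol_min / 60.0
    valid = np.abs(dt_h - 1.0) <= tol_h
    starts = traj.times[:-1]
    hours = np.array([hour_of_day(t, cadence_tol_min) for t in starts])
    return pd.DataFrame(
        {
            "start_time": starts,
            "hour": hours,
            "duration_h": dt_h,
            "distance_m": dist,
            "valid": valid,
        }
    )


def hour_of_day(timestamp: pd.Timestamp, cadence_tol_min: float = DEFAULT_CADENCE_TOL_MIN) -> int:
    """Local clock hour (0-23) of a fix, snapping GPS jitter to the hour.

    Timestamps within the cadence tolerance of a whole hour are assigned to
    that hour (13:58 with a 5-min tolerance is hour 14); anything further off
    the hour falls in the hour bin it lies in.
    """
    ts = pd.Timestamp(timestamp)
    if ts.tzinfo is None:
        raise ValueError("hour_of_day requires a tz-aware timestamp")
    offset_min = ts.minute + ts.second / 60.0 + ts.microsecond / 6e7
    if offset_min >= 60.0 - cadence_tol_min:
        return (ts.hour + 1) % 24
    return ts.hour


def write_fixes_geojson(trajectories, path) -> None:
    feats: list[dict] = []
    for traj in trajectories:
        feats.extend(traj.to_geojson()["features"])
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)
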