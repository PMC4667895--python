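"""Hourly displacement statistics and the activity-distance correlation.

Each valid 1-h step is assigned to the clock-hour bin of its starting fix
(configurable to the end fix).  Cross-animal summaries always use the
two-stage scheme: per-individual means first, then mean +/- SE of those
means.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trajectory import Trajectory, hour_of_day, step_series

__all__ = [
    "HourlyDistanceProfile",
    "hourly_mean_distance",
    "period_mean_distance",
    "activity_distance_correlation",
    "profiles_frame",
]


@dataclass
class HourlyDistanceProfile:
    animal_id: str
    season_label: str
    n: np.ndarray  # steps per hour bin, length 24
    mean_m: np.ndarray  # NaN where n == 0
    se_m: np.ndarray  # NaN where n < 2

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "animal": self.animal_id,
                "season": self.season_label,
                "hour": np.arange(24),
                "n": self.n,
                "mean_m": self.mean_m,
                "se_m": self.se_m,
            }
        )


def hourly_mean_distance(
    traj: Trajectory, bin_by: str = "start"
) -> HourlyDistanceProfile:
    """Mean (and SE) of step distances per hour of day.

    Only valid 1-h steps count; steps flagged as spanning a gap are
    excluded.  ``bin_by`` chooses whether a step falls in its start- or
    end-fix hour bin.
    """
    if bin_by not in ("start", "end"):
        raise ValueError("bin_by must be 'start' or 'end'")
    steps = step_series(traj)
    n = np.zeros(24, dtype=int)
    mean = np.full(24, np.nan)
    se = np.full(24, np.nan)
    valid = steps[steps["valid"]] if len(steps) else steps
    if len(valid) == 0:
        warnings.warn(f"no valid 1-h steps for animal {traj.animal_id!r}")
    else:
        hours = (
            valid["hour"].to_numpy()
            if bin_by == "start"
            else (valid["hour"].to_numpy() + 1) % 24
        )
        dist = valid["distance_m"].to_numpy()
        for h in range(24):
            sel = dist[hours == h]
            n[h] = sel.size
            if sel.size:
                mean[h] = sel.mean()
            if sel.size >= 2:
                se[h] = sel.std(ddof=1) / math.sqrt(sel.size)
    return HourlyDistanceProfile(
        animal_id=traj.animal_id,
        season_label=traj.window.season_label,
        n=n,
        mean_m=mean,
        se_m=se,
    )


def period_mean_distance(profiles, hours) -> tuple[float, float]:
    """Mean +/- SE over animals of the per-animal mean over the hour bins.

    E.g. the daylight period 8:00-16:00 is ``hours=range(8, 17)``.  SE is
    NaN with a single animal.
    """
    hours = sorted(set(int(h) for h in hours))
    if not hours:
        raise ValueError("empty hour set")
    if any(h < 0 or h > 23 for h in hours):
        raise ValueError("hours must be within 0-23")
    per_animal = []
    for p in profiles:
        vals = p.mean_m[hours]
        vals = vals[np.isfinite(vals)]
        if vals.size:
            per_animal.append(vals.mean())
    if not per_animal:
        raise ValueError("no animal has data in the requested hours")
    arr = np.asarray(per_animal)
    mean = float(arr.mean())
    se = float(arr.std(ddof=1) / math.sqrt(arr.size)) if arr.size > 1 else float("nan")
    return mean, se


def activity_distance_correlation(
    activity_props, mean_distances, hours
) -> tuple[float, int]:
    """Spearman rank correlation (average ranks on ties) between the hourly
    proportion of active scans and the hourly mean distance travelled.

    ``activity_props`` and ``mean_distances`` map hour -> value (dict,
    Series, or length-24 arrays); ``hours`` selects the hour bins compared.
    Returns (rho, n).
    """
    hours = [int(h) for h in hours]
    if len(hours) < 3:
        raise ValueError("need at least 3 hour bins for a rank correlation")

    def pick(series, h):
        if isinstance(series, dict):
            return series[h]
        if isinstance(series, pd.Series):
            return series.loc[h]
        return np.asarray(series, dtype=float)[h]

    a = np.array([pick(activity_props, h) for h in hours], dtype=float)
    d = np.array([pick(mean_distances, h) for h in hours], dtype=float)
    if np.any(~np.isfinite(a)) or np.any(~np.isfinite(d)):
        raise ValueError("non-finite values in correlated series")
    rho = stats.spearmanr(a, d).statistic
    return float(rho), len(hours)


def profiles_frame(profiles) -> pd.DataFrame:
    """Tidy CSV-ready frame (animal, season, hour, n, mean_m, se_m)."""
    if not profiles:
        return pd.DataFrame(columns=["animal", "season", "hour", "n", "mean_m", "se_m"])
    return pd.concat([p.to_frame() for p in profiles], ignore_index=True)
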