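import numpy as np
import pandas as pd
import pytest

from khulan import AnalysisWindow, Trajectory


@pytest.fixture
def window48() -> AnalysisWindow:
    return AnalysisWindow.from_start("2013-08-12T00:00:00+00:00", days=2.0, season_label="summer")


@pytest.fixture
def window50d() -> AnalysisWindow:
    return AnalysisWindow.from_start("2013-08-12T00:00:00+00:00", days=50.0, season_label="summer")


def make_traj(xy, window, animal="A1", start=None, hours=None):
    """Trajectory from a list of (x, y), hourly cadence by default.

    ``hours`` optionally gives the integer hour offsets of each fix
    (allows gaps).
    """
    xy = np.asarray(xy, dtype=float)
    start = pd.Timestamp(start) if start is not None else window.start
    if hours is None:
        hours = np.arange(len(xy))
    times = pd.DatetimeIndex([start + pd.Timedelta(hours=int(h)) for h in hours])
    return Trajectory(
        animal_id=animal, times=times, x=xy[:, 0], y=xy[:, 1], window=window
    )


def bruteforce_recursion_record(traj, focal_index, radius=200.0):
    """Independent O(window) rescan of residence/recursion/visits for one
    focal fix, on the full hourly timeline (gap-bridging semantics)."""
    d = np.hypot(traj.x - traj.x[focal_index], traj.y - traj.y[focal_index])
    inside = d <= radius
    hours = np.rint(
        (traj.times.asi8 - traj.window.start.value) / 3.6e12
    ).astype(int)
    total = int(traj.window.hours)
    status = np.zeros(total, dtype=int)  # 0 unknown, 1 in, -1 out
    for h, i in zip(hours, inside):
        status[h] = 1 if i else -1
    runs = []
    cur = None
    for h in range(total):
        if status[h] == 1:
            if cur is None:
                cur = [h, h]
            else:
                cur[1] = h
        elif status[h] == -1 and cur is not None:
            runs.append(tuple(cur))
            cur = None
    if cur is not None:
        runs.append(tuple(cur))
    focal_h = hours[focal_index]
    ri = [i for i, (s, e) in enumerate(runs) if s <= focal_h <= e][0]
    s, e = runs[ri]
    if ri + 1 < len(runs):
        rec, cens = runs[ri + 1][0] - e - 1, False
    else:
        rec, cens = (total - 1) - e, True
    return e - s + 1, rec, cens, len(runs)


@pytest.fixture
def traj_factory(window48):
    def _make(xy, window=None, **kw):
        return make_traj(xy, window or window48, **kw)

    return _make
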