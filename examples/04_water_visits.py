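"""Water-point visit detection: passing series, radius rule, visit rate.

The visit circle around a water point is sized from the animals' own
travel speed nearby: half the mean hourly distance over passing series,
rounded up to the nearest 10 m.
"""

from dataclasses import replace

import numpy as np

from khulan import (
    SimConfig,
    detect_visits,
    generate_landscape,
    passing_series,
    simulate_trajectory,
    visit_radius,
    visit_stats,
)

cfg = SimConfig(nrows=150, ncols=150, window_days=50, water_visit_prob=1.0)
land = generate_landscape(cfg, seed=1)
traj = simulate_trajectory(cfg, land, seed=1, animal_id="A1")

for wp in land.water_points:
    series, mean_m, se_m = passing_series(traj, wp)
    if not np.isfinite(mean_m):
        print(f"{wp.label}: never approached within 50 m")
        continue
    radius = visit_radius(mean_m)
    wp = replace(wp, visit_radius_m=radius)
    visits = detect_visits(traj, wp)
    rate, hist = visit_stats(visits, traj.window)
    peak = int(hist.argmax())
    print(
        f"{wp.label}: {len(series)} passing series, "
        f"mean hourly distance {mean_m:.0f} +/- {se_m:.0f} m "
        f"-> visit radius {radius:.0f} m"
    )
    print(
        f"  {len(visits)} visits = {rate:.2f}/day; "
        f"busiest hour {peak}:00 ({hist[peak]} visits)"
    )
print(
    "-> with daily water trips steered to the evening, the visit histogram\n"
    "   peaks at dusk and the rate is about one visit per day."
)
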