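"""Recursion metrics, censored survival and the 24-h periodicity scan.

For every fix of a simulated animal, computes residence time, recursion
time (right-censored) and the number of visits to its 200-m circle; then
estimates the median recursion time by Kaplan-Meier and scans the periodic
Poisson family for a 24-h rhythm in the pooled recursion durations.
"""

import numpy as np

from khulan import (
    RecursionConfig,
    SimConfig,
    fit_poisson_periodicity,
    generate_landscape,
    km_curve,
    recursion_table,
    simulate_trajectory,
)

cfg = SimConfig(nrows=150, ncols=150, window_days=50)
land = generate_landscape(cfg, seed=1)

durations, censored = [], []
for i in range(1, 4):
    traj = simulate_trajectory(cfg, land, seed=1, animal_id=f"A{i}")
    tab = recursion_table(traj)
    km = km_curve(tab["recursion_h"], tab["censored"])
    print(
        f"A{i}: n-tilde (mean visits/location) {tab['n_visits'].mean():.1f}; "
        f"mean residence {tab['residence_h'].mean():.1f} h; "
        f"median recursion {km.median_h:.0f} h "
        f"({100 * tab['censored'].mean():.0f}% censored)"
    )
    keep = ~tab["censored"] & (tab["recursion_h"] >= 1)
    durations.append(tab.loc[keep, "recursion_h"].to_numpy())

pooled = np.concatenate(durations)
fits, best = fit_poisson_periodicity(pooled, RecursionConfig())
by_id = {}
for f in fits:
    if f.model_id not in by_id or f.aic < by_id[f.model_id].aic:
        by_id[f.model_id] = f
print("\nmodel  df    AIC   (best k)")
for mid in ("M1", "M2", "M3", "M4", "M5"):
    f = by_id[mid]
    k = "-" if f.k is None else f.k
    print(f"{mid:5s} {f.df:3d} {f.aic:8.1f}   {k}")
print(
    f"\nbest model: {best.label} -> recursion-time peaks every 24 h minus "
    f"{best.k} h,\ni.e. the animals return to the same places at about the "
    "same time of day."
)
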