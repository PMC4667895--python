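"""End-to-end orchestration: simulate or ingest, analyse, export.

``run_pipeline`` executes every stage in order (ingest/simulate ->
displacement -> home ranges -> selection coefficients -> water visits ->
recursion table -> Kaplan-Meier + periodicity fits -> visits-vs-home-range
models -> recursion sites) and writes each module's tidy CSV / ASCII-grid /
GeoJSON outputs plus a JSON manifest (resolved config, seed, versions,
per-stage counters).  Runs are idempotent for a fixed seed.
"""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .displacement import hourly_mean_distance, profiles_frame
from .homerange import UDParams, isopleth_mask, movement_kernel_ud, sc_profile, sample_habitat, HABITAT_VARIABLES, grid_nodes
from .raster import write_ascii_grid, Raster
from .recursion import (
    RecursionConfig,
    fit_poisson_periodicity,
    fit_visits_vs_hr,
    km_curve,
    periodicity_table,
    recursion_table,
    visits_hr_table,
)
from .sites import SiteConfig, find_recursion_sites, sites_frame, sites_geojson
from .synthetic import (
    LandscapeStack,
    SimConfig,
    generate_landscape,
    simulate_trajectory,
    summer_config,
    winter_config,
)
from .trajectory import AnalysisWindow, hour_of_day, parse_fix_table
from .water import detect_visits, passing_series, visit_radius, visit_stats, visits_frame

__all__ = ["RunConfig", "run_pipeline", "summarize"]


@dataclass
class RunConfig:
    """Pipeline configuration.

    In synthetic mode the seasons listed in ``seasons`` are generated with
    the corresponding presets; in files mode ``fix_table`` and
    ``landscape_dir`` must point at existing inputs.
    """

    mode: str = "synthetic"  # synthetic | files
    outdir: str = "khulan_run"
    seed: int = 0
    n_individuals: int = 5
    window_days: float = 50.0
    seasons: tuple[str, ...] = ("summer", "winter")
    sim_overrides: dict = field(default_factory=dict)
    fix_table: str | None = None
    landscape_dir: str | None = None
    window_start: str | None = None
    season_label: str = "field"
    ud_params: UDParams = field(default_factory=UDParams)
    recursion: RecursionConfig = field(default_factory=RecursionConfig)
    sites: SiteConfig = field(default_factory=SiteConfig)
    write_rasters: bool = False

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ValueError("mode must be 'synthetic' or 'files'")
        if self.mode == "files":
            for name in ("fix_table", "landscape_dir", "window_start"):
                if getattr(self, name) is None:
                    raise ValueError(f"files mode requires {name}")
            for p in (self.fix_table, self.landscape_dir):
                if not Path(p).exists():
                    raise FileNotFoundError(p)


def _season_config(label: str, cfg: RunConfig) -> SimConfig:
    base = summer_config() if label == "summer" else winter_config()
    base = replace(
        base,
        season_label=label,
        n_individuals=cfg.n_individuals,
        window_days=cfg.window_days,
    )
    if cfg.sim_overrides:
        base = replace(base, **cfg.sim_overrides)
    return base


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all stages; returns the manifest (also written to manifest.json)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    counters: dict = {}

    # --- stage: ingest or simulate -------------------------------------
    trajectories: dict[tuple[str, str], object] = {}  # (animal, season) -> Trajectory
    land_by_season: dict[str, LandscapeStack] = {}
    if cfg.mode == "synthetic":
        sim_cfgs = {label: _season_config(label, cfg) for label in cfg.seasons}
        for label, sc in sim_cfgs.items():
            # same seed => same terrain, streams and water; only NDVI differs
            land_by_season[label] = generate_landscape(sc, cfg.seed)
            for i in range(sc.n_individuals):
                animal = f"A{i + 1}"
                traj = simulate_trajectory(
                    sc, land_by_season[label], cfg.seed, f"{animal}-{label}"
                )
                traj.animal_id = animal
                trajectories[(animal, label)] = traj
    else:
        if not (Path(cfg.landscape_dir) / "elevation.asc").exists():
            raise FileNotFoundError(
                f"landscape is missing the elevation layer: "
                f"{Path(cfg.landscape_dir) / 'elevation.asc'}"
            )
        field_land = LandscapeStack.read(cfg.landscape_dir)
        land_by_season[cfg.season_label] = field_land
        window = AnalysisWindow.from_start(
            cfg.window_start, cfg.window_days, cfg.season_label
        )
        for animal, traj in parse_fix_table(cfg.fix_table, window, tz="UTC").items():
            trajectories[(animal, cfg.season_label)] = traj

    def season_land(season: str) -> LandscapeStack:
        return land_by_season[season]

    fix_rows = []
    for (animal, season), traj in trajectories.items():
        df = traj.to_frame()
        df.insert(1, "season", season)
        fix_rows.append(df)
    all_fixes = pd.concat(fix_rows, ignore_index=True)
    all_fixes.to_csv(out / "fixes.csv", index=False)
    counters["n_fixes"] = int(len(all_fixes))
    counters["n_gaps"] = int(sum(len(t.gaps) for t in trajectories.values()))

    # --- stage: displacement --------------------------------------------
    profiles = [hourly_mean_distance(t) for t in trajectories.values()]
    profiles_frame(profiles).to_csv(out / "displacement_profiles.csv", index=False)

    # --- stage: home ranges & habitat selection -------------------------
    hr_rows, sc_frames = [], []
    hr95: dict[tuple[str, str], object] = {}
    hr_means: dict[str, dict] = {}
    for (animal, season), traj in trajectories.items():
        land = season_land(season)
        ud = movement_kernel_ud(traj, cfg.ud_params, land.grid)
        h95 = isopleth_mask(ud, 0.95)
        h50 = isopleth_mask(ud, 0.50)
        hr95[(animal, season)] = h95
        hr_rows.append(
            {
                "animal": animal,
                "season": season,
                "area95_km2": h95.area_km2,
                "area50_km2": h50.area_km2,
            }
        )
        if cfg.write_rasters:
            write_ascii_grid(
                Raster(land.grid, h95.mask.astype(float)),
                out / f"hr95_{animal}_{season}.asc",
            )
        sc_frames.append(sc_profile(traj, land, h95))
        nodes = grid_nodes(h95)
        hr_means[f"{animal}:{season}"] = {
            v: float(np.mean(sample_habitat(nodes, land, v))) for v in HABITAT_VARIABLES
        }
    hr_table = pd.DataFrame(hr_rows)
    hr_table.to_csv(out / "home_ranges.csv", index=False)
    sc_all = pd.concat(sc_frames, ignore_index=True)
    sc_all.to_csv(out / "selection_coefficients.csv", index=False)
    counters["n_undefined_sc"] = int(sc_all["sc"].isna().sum())

    # --- stage: water visits --------------------------------------------
    visit_rows, rate_rows = [], []
    for (animal, season), traj in trajectories.items():
        for wp in season_land(season).water_points:
            if wp.visit_radius_m is None:
                _, mean_m, _ = passing_series(traj, wp)
                radius = visit_radius(mean_m) if np.isfinite(mean_m) else 440.0
                wp = replace_wp(wp, radius)
            visits = detect_visits(traj, wp)
            rate, hist = visit_stats(visits, traj.window)
            vf = visits_frame(visits)
            vf.insert(1, "season", season)
            visit_rows.append(vf)
            rate_rows.append(
                {
                    "animal": animal,
                    "season": season,
                    "water": wp.label,
                    "visit_radius_m": wp.visit_radius_m,
                    "rate_per_day": rate,
                    **{f"h{h:02d}": int(c) for h, c in enumerate(hist)},
                }
            )
    nonempty_visits = [v for v in visit_rows if not v.empty]
    if nonempty_visits:
        visits_all = pd.concat(nonempty_visits, ignore_index=True)
    else:
        visits_all = visits_frame([])
        visits_all.insert(1, "season", pd.Series(dtype=str))
    visits_all.to_csv(out / "water_visits.csv", index=False)
    pd.DataFrame(rate_rows).to_csv(out / "water_visit_rates.csv", index=False)

    # --- stage: recursion table, KM, periodicity ------------------------
    rec_frames = {}
    km_rows = []
    for (animal, season), traj in trajectories.items():
        rec = recursion_table(traj, cfg.recursion)
        rec_frames[(animal, season)] = rec
        km = km_curve(rec["recursion_h"], rec["censored"])
        km_rows.append(
            {
                "animal": animal,
                "season": season,
                "n_tilde": float(rec["n_visits"].mean()),
                "median_recursion_h": km.median_h,
                "mean_residence_h": float(rec["residence_h"].mean()),
                "prop_censored": float(rec["censored"].mean()),
            }
        )
    all_rec = pd.concat(rec_frames.values(), ignore_index=True)
    all_rec.to_csv(out / "recursion_records.csv", index=False)
    km_table = pd.DataFrame(km_rows)
    km_table.to_csv(out / "recursion_summary.csv", index=False)
    counters["n_recursion_records"] = int(len(all_rec))
    counters["n_censored"] = int(all_rec["censored"].sum())

    fit_frames = []
    best_by_season = {}
    for season in sorted({s for (_, s) in trajectories}):
        pooled = all_rec[(all_rec["season"] == season) & (~all_rec["censored"])][
            "recursion_h"
        ].to_numpy()
        pooled = pooled[pooled >= 1]
        if pooled.size >= cfg.recursion.min_durations:
            fits, best = fit_poisson_periodicity(pooled, cfg.recursion)
            tab = periodicity_table(fits)
            tab.insert(0, "season", season)
            fit_frames.append(tab)
            best_by_season[season] = best.label
    if fit_frames:
        pd.concat(fit_frames, ignore_index=True).to_csv(
            out / "periodicity_models.csv", index=False
        )

    # --- stage: visits vs home-range size -------------------------------
    rows = km_table.merge(hr_table, on=["animal", "season"])
    visits_models = {}
    if len(rows) >= 4:
        for level, col in (("95", "area95_km2"), ("50", "area50_km2")):
            fits, best = fit_visits_vs_hr(
                rows.rename(columns={col: "area_km2"}), "area_km2"
            )
            tab = visits_hr_table(fits)
            tab.insert(0, "hr_level", level)
            visits_models[level] = (tab, best.model_id)
        pd.concat([t for t, _ in visits_models.values()], ignore_index=True).to_csv(
            out / "visits_hr_models.csv", index=False
        )

    # --- stage: recursion sites -----------------------------------------
    site_frames = []
    all_sites_geo = []
    for season in sorted({s for (_, s) in trajectories}):
        records_by_animal = {}
        for (animal, s), rec in rec_frames.items():
            if s != season:
                continue
            traj = trajectories[(animal, s)]
            records_by_animal[animal] = pd.DataFrame(
                {
                    "animal": animal,
                    "x": traj.x,
                    "y": traj.y,
                    "hour": [hour_of_day(t) for t in traj.times],
                    "n_visits": rec["n_visits"].to_numpy(),
                }
            )
        hrm = {
            a: hr_means[f"{a}:{season}"]
            for a in records_by_animal
            if f"{a}:{season}" in hr_means
        }
        season_sites = find_recursion_sites(
            records_by_animal, season_land(season), cfg.sites, hrm
        )
        sf = sites_frame(season_sites)
        if not sf.empty:
            sf.insert(0, "season", season)
        site_frames.append(sf)
        geo = sites_geojson(season_sites)
        for f in geo["features"]:
            f["properties"]["season"] = season
        all_sites_geo.extend(geo["features"])
    sites_table = (
        pd.concat(site_frames, ignore_index=True) if site_frames else pd.DataFrame()
    )
    sites_table.to_csv(out / "recursion_sites.csv", index=False)
    with open(out / "recursion_sites.geojson", "w") as fh:
        json.dump({"type": "FeatureCollection", "features": all_sites_geo}, fh)
    counters["n_sites"] = int(len(sites_table))

    manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "seed": cfg.seed,
        "mode": cfg.mode,
        "config": _config_echo(cfg),
        "counters": counters,
        "best_periodicity_model": best_by_season,
        "best_visits_hr_model": {k: v for k, (_, v) in visits_models.items()},
        "artifacts": sorted(p.name for p in out.iterdir() if p.is_file()),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest


def replace_wp(wp, radius):
    from dataclasses import replace as _replace

    return _replace(wp, visit_radius_m=radius)


def _config_echo(cfg: RunConfig) -> dict:
    d = asdict(cfg)
    d["ud_params"] = asdict(cfg.ud_params)
    d["recursion"] = asdict(cfg.recursion)
    d["sites"] = asdict(cfg.sites)
    return d


def summarize(outdir) -> str:
    """One-page per-animal-season text summary built from the run's CSVs."""
    out = Path(outdir)
    missing = [
        name
        for name in ("home_ranges.csv", "recursion_summary.csv", "manifest.json")
        if not (out / name).exists()
    ]
    if missing:
        raise FileNotFoundError(f"incomplete bundle, missing: {missing}")
    with open(out / "manifest.json") as fh:
        manifest = json.load(fh)
    hr = pd.read_csv(out / "home_ranges.csv")
    km = pd.read_csv(out / "recursion_summary.csv")
    rates_path = out / "water_visit_rates.csv"
    rates = pd.read_csv(rates_path) if rates_path.exists() else pd.DataFrame()
    sites_path = out / "recursion_sites.csv"
    sites = pd.read_csv(sites_path) if sites_path.exists() and sites_path.stat().st_size > 1 else pd.DataFrame()

    lines = [
        f"khulan run summary (seed {manifest['seed']}, mode {manifest['mode']})",
        "=" * 64,
    ]
    merged = km.merge(hr, on=["animal", "season"])
    for _, r in merged.iterrows():
        animal, season = r["animal"], r["season"]
        rate = 0.0
        if not rates.empty:
            sel = rates[(rates["animal"] == animal) & (rates["season"] == season)]
            rate = float(sel["rate_per_day"].sum()) if len(sel) else 0.0
        n_sites = 0
        if not sites.empty and "animals" in sites:
            n_sites = int(
                sites[
                    (sites["season"] == season)
                    & sites["animals"].astype(str).str.contains(str(animal))
                ].shape[0]
            )
        best = manifest.get("best_periodicity_model", {}).get(season, "-")
        lines.append(
            f"{animal} {season}: HR95 {r['area95_km2']:.2f} km2, "
            f"HR50 {r['area50_km2']:.2f} km2, n-tilde {r['n_tilde']:.2f}, "
            f"median recursion {r['median_recursion_h']:.0f} h, "
            f"best periodicity {best}, water visits/day {rate:.2f}, "
            f"main sites {n_sites}"
        )
    return "\n".join(lines)
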