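"""Synthetic desert landscapes and wild-ass-like GPS trajectories.

The generator emulates the statistical structure the downstream analyses
assume: a hilly elevation field with drainage lines (thalwegs) carrying
elevated vegetation (NDVI), one to three water points on the drainage
network, and hourly trajectories from a biased correlated random walk whose
habitat attraction switches over the diel cycle - high ground during the
day, vegetated thalwegs at night - with near-daily steered excursions to a
water point in the summer configuration.

Every stage draws from a named substream of a single seed, so landscapes
and individual walks can be regenerated independently and reproducibly.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage
from shapely.geometry import LineString, mapping, shape

from .homerange import buffer_thalweg
from .raster import Grid, Raster, read_ascii_grid, write_ascii_grid
from .recursion import PeriodicModelSpec, model_lambda
from .trajectory import AnalysisWindow, Trajectory
from .water import WaterPoint

__all__ = [
    "LandscapeStack",
    "SimConfig",
    "default_schedule",
    "summer_config",
    "winter_config",
    "generate_landscape",
    "derive_terrain",
    "simulate_trajectory",
    "sample_recursion_durations",
    "substream",
]


def substream(seed: int, *names) -> np.random.Generator:
    """Named, platform-stable substream of a master seed."""
    key = tuple(zlib.crc32(str(n).encode()) for n in names)
    return np.random.default_rng(np.random.SeedSequence(int(seed), spawn_key=key))


@dataclass
class LandscapeStack:
    """Co-registered habitat rasters plus vector water/stream features."""

    grid: Grid
    elevation: Raster
    slope: Raster
    aspect: Raster
    ndvi: Raster
    thalweg: Raster
    stream_network: list = field(default_factory=list)
    water_points: list[WaterPoint] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("elevation", "slope", "aspect", "ndvi", "thalweg"):
            r: Raster = getattr(self, name)
            if r.grid != self.grid:
                raise ValueError(f"raster {name!r} is not on the shared grid")
        if np.any((self.slope.values < 0) | (self.slope.values > 90)):
            raise ValueError("slope out of [0, 90]")
        if np.any((self.aspect.values < 0) | (self.aspect.values >= 360)):
            raise ValueError("aspect out of [0, 360)")
        if not np.all(np.isin(self.thalweg.values, (0.0, 1.0))):
            raise ValueError("thalweg raster must be binary")

    def write(self, outdir) -> None:
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in ("elevation", "slope", "aspect", "ndvi", "thalweg"):
            write_ascii_grid(getattr(self, name), outdir / f"{name}.asc")
        feats = [
            {
                "type": "Feature",
                "geometry": mapping(line),
                "properties": {"kind": "stream"},
            }
            for line in self.stream_network
        ]
        for wp in self.water_points:
            feats.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Point", "coordinates": [wp.x, wp.y]},
                    "properties": {
                        "kind": "water_point",
                        "label": wp.label,
                        "pass_threshold_m": wp.pass_threshold_m,
                        "visit_radius_m": wp.visit_radius_m,
                    },
                }
            )
        with open(outdir / "features.geojson", "w") as fh:
            json.dump({"type": "FeatureCollection", "features": feats}, fh)

    @classmethod
    def read(cls, indir) -> "LandscapeStack":
        from pathlib import Path

        indir = Path(indir)
        rasters = {
            name: read_ascii_grid(indir / f"{name}.asc")
            for name in ("elevation", "slope", "aspect", "ndvi", "thalweg")
        }
        streams, wps = [], []
        fpath = indir / "features.geojson"
        if fpath.exists():
            with open(fpath) as fh:
                fc = json.load(fh)
            for feat in fc["features"]:
                props = feat.get("properties") or {}
                if props.get("kind") == "water_point":
                    x, y = feat["geometry"]["coordinates"]
                    wps.append(
                        WaterPoint(
                            label=props.get("label", "W"),
                            x=x,
                            y=y,
                            pass_threshold_m=props.get("pass_threshold_m", 50.0),
                            visit_radius_m=props.get("visit_radius_m"),
                        )
                    )
                else:
                    streams.append(shape(feat["geometry"]))
        return cls(grid=rasters["elevation"].grid, stream_network=streams,
                   water_points=wps, **rasters)


def default_step_multiplier() -> dict[int, float]:
    """Diel modulation of step length: crepuscular travel peaks, long
    night-time feeding/drinking moves, short midday resting steps."""
    mult = {h: 1.0 for h in range(24)}
    for h in (5, 6, 18, 19):
        mult[h] = 2.0  # dawn and dusk peaks
    for h in (20, 21, 22, 23, 0, 1, 2, 3, 4):
        mult[h] = 1.4
    for h in range(9, 17):
        mult[h] = 0.55
    return mult


def default_schedule() -> dict[int, dict[str, float]]:
    """Diel habitat-attraction weights: high ground by day (08-16 h),
    vegetated thalwegs by night (20-04 h)."""
    sched = {
        h: {"elevation": 0.0, "ndvi": 0.0, "thalweg": 0.0, "water": 0.0}
        for h in range(24)
    }
    for h in range(8, 17):
        sched[h]["elevation"] = 2.5
    for h in (20, 21, 22, 23, 0, 1, 2, 3, 4):
        sched[h]["ndvi"] = 2.0
        sched[h]["thalweg"] = 2.0
    return sched


@dataclass
class SimConfig:
    """Generator configuration; defaults emulate the summer study conditions
    (five animals, 50-day window, hourly cadence, near-daily water visits)."""

    nrows: int = 200
    ncols: int = 200
    cell_m: float = 30.0
    x0: float = 0.0
    y0: float = 0.0
    elev_range_m: tuple[float, float] = (600.0, 1000.0)
    elev_smooth_cells: float = 10.0
    n_streams: int = 3
    thalweg_buffer_m: float = 25.0
    ndvi_base: float = 0.10
    ndvi_contrast: float = 0.08
    ndvi_noise: float = 0.015
    n_water_points: int = 2

    n_individuals: int = 5
    window_days: float = 50.0
    start_time: str = "2013-08-12T00:00:00+00:00"
    season_label: str = "summer"

    step_scale_m: float = 250.0  # gamma scale; shape 1.5 -> mean ~375 m/h
    step_shape: float = 1.5
    turn_sd_rad: float = 0.8
    n_candidates: int = 24
    schedule: dict = field(default_factory=default_schedule)
    diel_step_multiplier: dict = field(default_factory=default_step_multiplier)
    water_visit_prob: float = 1.0  # daily Bernoulli
    water_hours: tuple[int, ...] = (19, 20, 21, 22, 23)
    water_arrival_m: float = 50.0
    territory_radius_m: float = 2500.0
    territory_centre: tuple[float, float] | None = None
    fix_loss_prob: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.water_visit_prob <= 1:
            raise ValueError("water_visit_prob must be in [0, 1]")
        if not 0 <= self.fix_loss_prob < 1:
            raise ValueError("fix_loss_prob must be in [0, 1)")
        if not self.schedule:
            raise ValueError("empty attraction schedule")
        for h, w in self.schedule.items():
            if not all(np.isfinite(list(w.values()))):
                raise ValueError(f"non-finite schedule weight at hour {h}")

    @property
    def grid(self) -> Grid:
        return Grid(self.x0, self.y0, self.cell_m, self.nrows, self.ncols)

    def window(self) -> AnalysisWindow:
        return AnalysisWindow.from_start(
            pd.Timestamp(self.start_time), self.window_days, self.season_label
        )


def summer_config(**overrides) -> SimConfig:
    """Summer preset: sparse vegetation concentrated along thalwegs,
    near-daily water visits, occasional missed fixes."""
    cfg = SimConfig(fix_loss_prob=0.02)
    return replace(cfg, **overrides)


def winter_config(**overrides) -> SimConfig:
    """Winter preset: more uniform vegetation, rare water visits."""
    cfg = SimConfig(
        season_label="winter",
        start_time="2013-12-12T00:00:00+00:00",
        ndvi_base=0.13,
        ndvi_contrast=0.03,
        water_visit_prob=0.08,
        step_scale_m=200.0,
        fix_loss_prob=0.02,
    )
    return replace(cfg, **overrides)


# ---------------------------------------------------------------------------
# Terrain
# ---------------------------------------------------------------------------

def derive_terrain(elevation: Raster) -> tuple[Raster, Raster, np.ndarray]:
    """Slope (degrees), aspect (degrees clockwise from north) and a flat-cell
    flag, from Horn 3x3 finite differences.

    Aspect is the azimuth the slope *faces* (direction of steepest descent);
    flat cells get aspect 0 and are flagged.  Border cells use replicated
    edge values (half-width differences).
    """
    z = elevation.values
    if z.shape[0] < 3 or z.shape[1] < 3:
        raise ValueError("elevation raster must be at least 3x3")
    if not np.all(np.isfinite(z)):
        raise ValueError("elevation must be finite")
    cell = elevation.grid.cell
    P = np.pad(z, 1, mode="edge")
    # row index grows northwards; compass points on the padded array:
    N = P[2:, 1:-1]
    S = P[:-2, 1:-1]
    E = P[1:-1, 2:]
    W = P[1:-1, :-2]
    NE = P[2:, 2:]
    NW = P[2:, :-2]
    SE = P[:-2, 2:]
    SW = P[:-2, :-2]
    dzdx = ((NE + 2 * E + SE) - (NW + 2 * W + SW)) / (8 * cell)
    dzdy = ((NE + 2 * N + NW) - (SE + 2 * S + SW)) / (8 * cell)
    grad = np.hypot(dzdx, dzdy)
    slope = np.degrees(np.arctan(grad))
    flat = grad < 1e-12
    aspect = np.degrees(np.arctan2(-dzdx, -dzdy)) % 360.0
    aspect[flat] = 0.0
    aspect[aspect >= 360.0] = 0.0
    return (
        Raster(elevation.grid, slope),
        Raster(elevation.grid, aspect),
        flat,
    )


# ---------------------------------------------------------------------------
# Landscape
# ---------------------------------------------------------------------------

def _trace_stream(z: np.ndarray, start: tuple[int, int]) -> list[tuple[int, int]]:
    """Steepest-descent path over the 8-neighbourhood until a local minimum
    or the raster edge."""
    nrows, ncols = z.shape
    path = [start]
    r, c = start
    visited = {start}
    while True:
        best = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                rr, cc = r + dr, c + dc
                if (dr or dc) and 0 <= rr < nrows and 0 <= cc < ncols:
                    if z[rr, cc] < z[r, c] and (best is None or z[rr, cc] < z[best]):
                        best = (rr, cc)
        if best is None or best in visited:
            break
        path.append(best)
        visited.add(best)
        r, c = best
        if r in (0, nrows - 1) or c in (0, ncols - 1):
            break
    return path


def generate_landscape(cfg: SimConfig, seed: int) -> LandscapeStack:
    """Generate a co-registered landscape stack, reproducibly per seed.

    Elevation is smoothed Gaussian noise rescaled to the configured range;
    streams are steepest-descent traces from high ground; the thalweg mask
    is the 25-m buffer of the stream network; NDVI is elevated inside
    thalwegs by ``ndvi_contrast``; water points sit on the network.
    """
    grid = cfg.grid
    if grid.nrows < 50 or grid.ncols < 50:
        raise ValueError("landscape grid must be at least 50x50 cells")
    rng = substream(seed, "landscape")
    noise = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=cfg.elev_smooth_cells, mode="reflect")
    lo, hi = cfg.elev_range_m
    rngspan = smooth.max() - smooth.min()
    elev = lo + (smooth - smooth.min()) / rngspan * (hi - lo)
    elevation = Raster(grid, elev)
    slope, aspect, _flat = derive_terrain(elevation)

    xs, ys = grid.cell_centres()
    # streams: trace downhill from randomly chosen high cells
    order = np.argsort(elev.ravel())
    top = order[-int(0.1 * elev.size):]
    starts = rng.choice(top, size=cfg.n_streams, replace=False)
    network = []
    for flat_idx in starts:
        r, c = np.unravel_index(int(flat_idx), elev.shape)
        path = _trace_stream(elev, (r, c))
        if len(path) >= 2:
            coords = [(xs[cc], ys[rr]) for rr, cc in path]
            network.append(LineString(coords))
    thalweg = buffer_thalweg(network, grid, cfg.thalweg_buffer_m)

    ndvi_noise = ndimage.gaussian_filter(rng.standard_normal(grid.shape), 3.0)
    sd = ndvi_noise.std()
    if sd > 0:
        ndvi_noise /= sd
    ndvi_vals = cfg.ndvi_base + cfg.ndvi_contrast * thalweg.values + cfg.ndvi_noise * ndvi_noise
    ndvi = Raster(grid, np.clip(ndvi_vals, 0.0, 0.6))

    # water points sit on the network; central vertices are preferred
    # (ranges contract around permanent water, so water must be reachable)
    water_points: list[WaterPoint] = []
    vertices = [coord for line in network for coord in line.coords]
    if vertices and cfg.n_water_points > 0:
        verts = np.asarray(vertices)
        cx = (grid.extent[0] + grid.extent[2]) / 2.0
        cy = (grid.extent[1] + grid.extent[3]) / 2.0
        order_c = np.argsort(np.hypot(verts[:, 0] - cx, verts[:, 1] - cy))
        chosen: list[np.ndarray] = []
        for i in order_c:
            v = verts[i]
            if all(np.hypot(*(v - c)) > 1500.0 for c in chosen):
                chosen.append(v)
            if len(chosen) == cfg.n_water_points:
                break
        for j, v in enumerate(chosen):
            water_points.append(WaterPoint(label=f"W{j + 1}", x=float(v[0]), y=float(v[1])))

    return LandscapeStack(
        grid=grid,
        elevation=elevation,
        slope=slope,
        aspect=aspect,
        ndvi=ndvi,
        thalweg=thalweg,
        stream_network=network,
        water_points=water_points,
    )


# ---------------------------------------------------------------------------
# Trajectories
# ---------------------------------------------------------------------------

def _zscore(values: np.ndarray) -> np.ndarray:
    sd = values.std()
    return (values - values.mean()) / sd if sd > 0 else np.zeros_like(values)


def simulate_trajectory(
    cfg: SimConfig, land: LandscapeStack, seed: int, animal_id: str
) -> Trajectory:
    """Hourly biased correlated random walk on the landscape.

    At each hour a small set of candidate headings is drawn around the
    previous heading (wrapped-normal turns, gamma step lengths) and one is
    chosen by softmax over the hour's habitat-attraction score at the
    candidate endpoints (z-scored elevation and NDVI, binary thalweg), plus
    a soft territorial pull beyond the territory radius.  On "water days"
    (daily Bernoulli draw) the walk is steered straight to the nearest
    water point during the designated evening hours until it passes within
    the arrival distance.  Reproducible per (seed, animal id).
    """
    if not cfg.schedule:
        raise ValueError("empty attraction schedule")
    rng = substream(seed, "walk", animal_id)
    water_rng = substream(seed, "water_days", animal_id)
    loss_rng = substream(seed, "fix_loss", animal_id)
    grid = land.grid
    window = cfg.window()
    n_hours = int(round(window.hours))
    times = window.start + pd.to_timedelta(np.arange(n_hours), unit="h")

    z_elev = _zscore(land.elevation.values)
    z_ndvi = _zscore(land.ndvi.values)
    thal = land.thalweg.values

    xmin, ymin, xmax, ymax = grid.extent
    margin = grid.cell
    centre = (
        np.array(cfg.territory_centre, dtype=float)
        if cfg.territory_centre is not None
        else np.array([(xmin + xmax) / 2.0, (ymin + ymax) / 2.0])
    )
    n_days = int(np.ceil(cfg.window_days))
    water_days = water_rng.random(n_days) < cfg.water_visit_prob

    if land.water_points:
        wxy = np.array([[wp.x, wp.y] for wp in land.water_points])
    else:
        wxy = None

    pos = centre + rng.normal(scale=300.0, size=2)
    pos[0] = np.clip(pos[0], xmin + margin, xmax - margin)
    pos[1] = np.clip(pos[1], ymin + margin, ymax - margin)
    heading = rng.uniform(0, 2 * np.pi)

    xs = np.empty(n_hours)
    ys = np.empty(n_hours)
    visited_today = False
    day_idx = -1
    for i in range(n_hours):
        hour = times[i].hour
        day = i // 24
        if day != day_idx:
            day_idx = day
            visited_today = False
        steer = (
            wxy is not None
            and day < n_days
            and water_days[day]
            and hour in cfg.water_hours
            and not visited_today
        )
        if steer:
            dists = np.hypot(wxy[:, 0] - pos[0], wxy[:, 1] - pos[1])
            j = int(np.argmin(dists))
            dist = dists[j]
            draw = rng.gamma(cfg.step_shape, cfg.step_scale_m)
            step = min(dist, max(draw, 1500.0))  # trips to water are fast
            direction = np.arctan2(wxy[j, 1] - pos[1], wxy[j, 0] - pos[0])
            pos = pos + step * np.array([np.cos(direction), np.sin(direction)])
            heading = direction
            if np.hypot(wxy[j, 0] - pos[0], wxy[j, 1] - pos[1]) <= cfg.water_arrival_m:
                visited_today = True
        else:
            w = cfg.schedule.get(hour, {"elevation": 0, "ndvi": 0, "thalweg": 0, "water": 0})
            turns = rng.normal(0.0, cfg.turn_sd_rad, size=cfg.n_candidates)
            scale = cfg.step_scale_m * cfg.diel_step_multiplier.get(hour, 1.0)
            lengths = rng.gamma(cfg.step_shape, scale, size=cfg.n_candidates)
            angles = heading + turns
            cx = np.clip(pos[0] + lengths * np.cos(angles), xmin + margin, xmax - margin)
            cy = np.clip(pos[1] + lengths * np.sin(angles), ymin + margin, ymax - margin)
            r, c = grid.index_of(cx, cy, clip=True)
            score = (
                w.get("elevation", 0.0) * z_elev[r, c]
                + w.get("ndvi", 0.0) * z_ndvi[r, c]
                + w.get("thalweg", 0.0) * thal[r, c]
            )
            if w.get("water", 0.0) and wxy is not None:
                dmin = np.min(
                    np.hypot(wxy[:, 0][:, None] - cx, wxy[:, 1][:, None] - cy), axis=0
                )
                score += w["water"] * (-dmin / 1000.0)
            dcen = np.hypot(cx - centre[0], cy - centre[1])
            score -= (np.maximum(0.0, dcen - cfg.territory_radius_m) / 250.0) ** 2
            p = np.exp(score - score.max())
            p /= p.sum()
            pick = rng.choice(cfg.n_candidates, p=p)
            newpos = np.array([cx[pick], cy[pick]])
            if np.any(newpos != pos):
                heading = np.arctan2(newpos[1] - pos[1], newpos[0] - pos[0])
            pos = newpos
        xs[i] = pos[0]
        ys[i] = pos[1]

    keep = loss_rng.random(n_hours) >= cfg.fix_loss_prob
    keep[0] = True  # anchor the series
    times_kept = pd.DatetimeIndex(times[keep])
    from .trajectory import _find_gaps  # gap bookkeeping shared with the parser

    return Trajectory(
        animal_id=animal_id,
        times=times_kept,
        x=xs[keep],
        y=ys[keep],
        window=window,
        gaps=_find_gaps(times_kept, 1.0, 5.0),
    )


# ---------------------------------------------------------------------------
# Recursion-duration sampler
# ---------------------------------------------------------------------------

def sample_recursion_durations(
    spec: PeriodicModelSpec,
    t_range=range(1, 169),
    n: int | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Sample a multiset of integer recursion durations from a periodic
    Poisson model.

    For each hour t in ``t_range`` a Poisson count with the model's
    lambda(t) is drawn and expanded into duration values.  When ``n`` is
    given, the intercept is shifted so the expected total count is n.
    """
    t = np.asarray(list(t_range), dtype=float)
    lam = model_lambda(spec, t)
    if n is not None:
        lam = lam * (n / lam.sum())
    if np.any(lam > 1e12):
        bad = t[int(np.argmax(lam))]
        raise OverflowError(f"lambda overflows at t={bad:g}")
    rng = substream(seed, "durations")
    counts = rng.poisson(lam)
    return np.repeat(t.astype(int), counts)
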