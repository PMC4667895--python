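"""Utilization distributions, isopleth home ranges and habitat selection.

The home-range estimator is a simplified movement-based kernel: each valid
step is densified by interpolating points at a fixed time interval ``tau``
along the straight segment, and an isotropic Gaussian kernel of bandwidth
``h_min`` is placed at every observed and interpolated point.  This captures
the serial correlation between successive locations that motivates
movement-based (rather than point) kernel estimators, while keeping the
bandwidth fixed (the time-dependent variance growth of the full
movement-based estimator, parameter ``b``, is not modelled here and the
parameter is retained in the configuration for provenance only).

Habitat selection is quantified by the standardized use-availability
contrast

    SC = (mean over used locations - mean over availability nodes)
         / SD over availability nodes,

with availability taken at the nodes of a square grid covering the 95%
home range.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from scipy import ndimage

from .raster import Grid, Raster
from .trajectory import Trajectory, hour_of_day, step_series

__all__ = [
    "UDParams",
    "UDRaster",
    "HomeRange",
    "movement_kernel_ud",
    "isopleth_mask",
    "northern_exposure",
    "buffer_thalweg",
    "grid_nodes",
    "sample_habitat",
    "selection_coefficient",
    "sc_profile",
    "HABITAT_VARIABLES",
]

HABITAT_VARIABLES = ("thalweg", "ndvi", "elevation", "slope", "northern_exposure")


@dataclass(frozen=True)
class UDParams:
    """Movement-kernel parameters (hours and metres).

    t_max: steps longer than this duration are treated as gaps and
        contribute endpoint kernels only.
    tau: interpolation time step along each bridged segment.
    l_min: steps shorter than this length contribute endpoints only.
    h_min: Gaussian kernel bandwidth (SD).
    b: retained for provenance; variance growth along steps is not modelled.
    """

    t_max: float = 2.5
    tau: float = 0.1
    l_min: float = 50.0
    h_min: float = 100.0
    b: float = 0.0

    def __post_init__(self) -> None:
        if min(self.t_max, self.tau, self.l_min, self.h_min) <= 0:
            raise ValueError("UD parameters must be positive")
        if self.tau >= self.t_max:
            raise ValueError("tau must be smaller than t_max")


@dataclass
class UDRaster:
    grid: Grid
    density: np.ndarray  # probability density per m^2; integrates to 1

    def __post_init__(self) -> None:
        self.density = np.asarray(self.density, dtype=float)
        if self.density.shape != self.grid.shape:
            raise ValueError("density shape does not match grid")
        total = float(self.density.sum() * self.grid.cell_area_m2)
        if not math.isclose(total, 1.0, abs_tol=1e-6):
            raise ValueError(f"UD does not integrate to 1 (got {total})")


@dataclass
class HomeRange:
    level: float
    grid: Grid
    mask: np.ndarray  # boolean

    @property
    def area_km2(self) -> float:
        return float(self.mask.sum() * self.grid.cell_area_m2 / 1e6)

    def outline_geojson(self) -> dict:
        """Mask cells as a GeoJSON MultiPolygon of cell squares (dissolved)."""
        cells = []
        rows, cols = np.nonzero(self.mask)
        g = self.grid
        for r, c in zip(rows, cols):
            x = g.x0 + c * g.cell
            y = g.y0 + r * g.cell
            cells.append(shapely.box(x, y, x + g.cell, y + g.cell))
        geom = shapely.union_all(cells) if cells else shapely.Polygon()
        return {
            "type": "Feature",
            "geometry": shapely.geometry.mapping(geom),
            "properties": {"level": self.level, "area_km2": self.area_km2},
        }


def _kernel_points(traj: Trajectory, params: UDParams) -> tuple[np.ndarray, np.ndarray]:
    """Observed fixes plus tau-spaced interpolated points along bridged steps."""
    xs = [traj.x]
    ys = [traj.y]
    steps = step_series(traj)
    durs = steps["duration_h"].to_numpy()
    dists = steps["distance_m"].to_numpy()
    for i in range(len(steps)):
        dur, dist = durs[i], dists[i]
        if dur > params.t_max or dist < params.l_min:
            continue  # endpoints only (already included)
        frac = (np.arange(1, int(np.floor(dur / params.tau)) + 1) * params.tau) / dur
        frac = frac[frac < 1.0]
        if frac.size == 0:
            continue
        x0, y0 = traj.x[i], traj.y[i]
        x1, y1 = traj.x[i + 1], traj.y[i + 1]
        xs.append(x0 + frac * (x1 - x0))
        ys.append(y0 + frac * (y1 - y0))
    return np.concatenate(xs), np.concatenate(ys)


def movement_kernel_ud(traj: Trajectory, params: UDParams, grid: Grid) -> UDRaster:
    """Movement-kernel utilization distribution on ``grid``.

    Points are deposited onto the grid with bilinear weights and smoothed
    with a Gaussian of SD ``h_min``; the result is normalized to integrate
    to exactly 1 over the grid (mass smoothed beyond the border is folded
    back by the normalization).
    """
    if len(traj) < 2:
        raise ValueError("movement_kernel_ud needs at least two fixes")
    px, py = _kernel_points(traj, params)

    acc = np.zeros(grid.shape)
    # bilinear splat onto cell centres
    gx = (px - grid.x0) / grid.cell - 0.5
    gy = (py - grid.y0) / grid.cell - 0.5
    c0 = np.floor(gx).astype(int)
    r0 = np.floor(gy).astype(int)
    fx = gx - c0
    fy = gy - r0
    for dr, dc, w in (
        (0, 0, (1 - fx) * (1 - fy)),
        (0, 1, fx * (1 - fy)),
        (1, 0, (1 - fx) * fy),
        (1, 1, fx * fy),
    ):
        r = np.clip(r0 + dr, 0, grid.nrows - 1)
        c = np.clip(c0 + dc, 0, grid.ncols - 1)
        np.add.at(acc, (r, c), w)

    sigma_cells = params.h_min / grid.cell
    dens = ndimage.gaussian_filter(acc, sigma=sigma_cells, mode="constant")
    total = dens.sum() * grid.cell_area_m2
    if total <= 0:
        raise ValueError("empty utilization distribution")
    return UDRaster(grid, dens / total)


def isopleth_mask(ud: UDRaster, level: float) -> HomeRange:
    """Smallest-area cell set holding ``level`` of the UD mass.

    Cells are included in descending density order (ties broken row-major)
    until the cumulative probability reaches ``level``.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("isopleth level must be in (0, 1)")
    flat = ud.density.ravel()
    order = np.argsort(-flat, kind="stable")  # stable => row-major tie-break
    csum = np.cumsum(flat[order]) * ud.grid.cell_area_m2
    n_in = int(np.searchsorted(csum, level) + 1)
    n_in = min(n_in, flat.size)
    mask = np.zeros(flat.size, dtype=bool)
    mask[order[:n_in]] = True
    return HomeRange(level=level, grid=ud.grid, mask=mask.reshape(ud.grid.shape))


def northern_exposure(slope_deg, aspect_deg):
    """Northern exposure E_N = sin(slope) * cos(aspect).

    The orthogonal projection of the terrain unit normal onto the
    south-north axis: -1 for a south-facing vertical slope, +1 for a
    north-facing vertical slope, 0 on flat ground.  Aspect is the slope
    azimuth in degrees clockwise from north.
    """
    slope = np.asarray(slope_deg, dtype=float)
    aspect = np.asarray(aspect_deg, dtype=float)
    if np.any((slope < 0) | (slope > 90)):
        raise ValueError("slope must be within [0, 90] degrees")
    if np.any((aspect < 0) | (aspect >= 360)):
        raise ValueError("aspect must be within [0, 360) degrees")
    out = np.sin(np.radians(slope)) * np.cos(np.radians(aspect))
    return float(out) if out.ndim == 0 else out


def buffer_thalweg(stream_network, grid: Grid, buffer_m: float = 25.0) -> Raster:
    """Binary raster: 1 where the cell centre is within ``buffer_m`` of the
    drainage network (closed boundary), 0 elsewhere."""
    lines = [g for g in np.atleast_1d(np.asarray(stream_network, dtype=object)) if g is not None]
    vals = np.zeros(grid.shape)
    if not lines or all(shapely.is_empty(g) for g in lines):
        import warnings

        warnings.warn("empty stream network: thalweg raster is all zero")
        return Raster(grid, vals)
    network = shapely.union_all(list(lines))
    xm, ym = grid.centre_mesh()
    pts = shapely.points(xm.ravel(), ym.ravel())
    inside = shapely.dwithin(pts, network, buffer_m)
    return Raster(grid, inside.reshape(grid.shape).astype(float))


def grid_nodes(hr: HomeRange, spacing_m: float = 30.0) -> np.ndarray:
    """Availability nodes: square lattice over the home range.

    The lattice is anchored at the minimum corner of the mask's bounding
    box; nodes whose containing raster cell belongs to the mask are kept.
    Returns an (n, 2) array of x, y coordinates.
    """
    if spacing_m <= 0:
        raise ValueError("spacing must be positive")
    if not hr.mask.any():
        raise ValueError("empty home-range mask")
    rows, cols = np.nonzero(hr.mask)
    g = hr.grid
    xmin = g.x0 + cols.min() * g.cell
    ymin = g.y0 + rows.min() * g.cell
    xmax = g.x0 + (cols.max() + 1) * g.cell
    ymax = g.y0 + (rows.max() + 1) * g.cell
    nx = np.arange(xmin, xmax + 1e-9, spacing_m)
    ny = np.arange(ymin, ymax + 1e-9, spacing_m)
    xm, ym = np.meshgrid(nx, ny)
    xs = xm.ravel()
    ys = ym.ravel()
    c = np.floor((xs - g.x0) / g.cell).astype(int)
    r = np.floor((ys - g.y0) / g.cell).astype(int)
    # nodes exactly on the bbox's upper edges belong to the closed bbox
    c[np.isclose(xs, xmax)] -= 1
    r[np.isclose(ys, ymax)] -= 1
    ok = (r >= 0) & (r < g.nrows) & (c >= 0) & (c < g.ncols)
    keep = np.zeros(xs.shape, dtype=bool)
    keep[ok] = hr.mask[r[ok], c[ok]]
    return np.column_stack([xs[keep], ys[keep]])


def sample_habitat(points, land, variable: str) -> np.ndarray:
    """Nearest-cell habitat values at planar points.

    ``variable`` is one of elevation, slope, aspect, ndvi, thalweg, or
    northern_exposure (computed on the fly from slope and aspect).
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    xs, ys = pts[:, 0], pts[:, 1]
    if variable == "northern_exposure":
        return northern_exposure(land.slope.sample(xs, ys), land.aspect.sample(xs, ys))
    try:
        raster: Raster = getattr(land, variable)
    except AttributeError as exc:
        raise ValueError(f"unknown habitat variable {variable!r}") from exc
    return raster.sample(xs, ys)


def selection_coefficient(use_values, avail_values, ddof: int = 1) -> float:
    """Standardized selection coefficient.

    SC = (mean(use) - mean(availability)) / SD(availability), with the
    sample (n-1) SD by default.  Zero availability SD yields NaN (an
    undefined-SC marker), never an exception.
    """
    use = np.asarray(use_values, dtype=float)
    avail = np.asarray(avail_values, dtype=float)
    if use.size == 0:
        raise ValueError("use sample is empty")
    sd = float(np.std(avail, ddof=ddof))
    # guard against float residue on constant availability
    scale = float(np.max(np.abs(avail))) if avail.size else 0.0
    if not np.isfinite(sd) or sd <= 1e-12 * max(scale, 1.0):
        return float("nan")
    return float((use.mean() - avail.mean()) / sd)


def sc_profile(
    traj: Trajectory,
    land,
    hr: HomeRange,
    variables=HABITAT_VARIABLES,
    node_spacing_m: float = 30.0,
) -> pd.DataFrame:
    """Hourly selection coefficients for each habitat variable.

    Use = habitat values at the animal's fixes that fall inside the home
    range, grouped by clock hour; availability = values at the lattice
    nodes covering the range.  Hours with no in-range fixes get NaN.
    Returns a tidy frame (animal, season, variable, hour, n, sc).
    """
    nodes = grid_nodes(hr, node_spacing_m)
    r, c = hr.grid.index_of(traj.x, traj.y, clip=True)
    in_mask = hr.mask[r, c] & hr.grid.contains(traj.x, traj.y)
    hours = np.array([hour_of_day(t) for t in traj.times])

    records = []
    for var in variables:
        avail = sample_habitat(nodes, land, var)
        use_all = sample_habitat(np.column_stack([traj.x, traj.y]), land, var)
        for h in range(24):
            sel = in_mask & (hours == h)
            n = int(sel.sum())
            sc = selection_coefficient(use_all[sel], avail) if n else float("nan")
            records.append(
                {
                    "animal": traj.animal_id,
                    "season": traj.window.season_label,
                    "variable": var,
                    "hour": h,
                    "n": n,
                    "sc": sc,
                }
            )
    return pd.DataFrame(records)
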