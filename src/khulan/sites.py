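"""Identification and characterization of main recursion sites.

For each animal-season, the 20% most-revisited locations are selected
(ties at the cutoff included) and clustered: two selected locations belong
to the same cluster when their 200-m circles overlap (centre distance at
most twice the radius, closed at tangency), taking the transitive closure.
Clusters of at least 15 locations are "main recursion sites"; sites drawn
from a pooled multi-animal selection that span several animals are flagged
common.  Each site is characterized by the mean and SD of the habitat
variables over its member locations (thalweg as a proportion) and by the
diel histogram of its member fix hours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .homerange import HABITAT_VARIABLES, sample_habitat

__all__ = [
    "SiteConfig",
    "RecursionSite",
    "top_visited",
    "cluster_overlapping",
    "characterize_site",
    "find_recursion_sites",
    "sites_frame",
]


@dataclass(frozen=True)
class SiteConfig:
    top_fraction: float = 0.20
    link_radius_m: float = 200.0
    min_cluster_size: int = 15

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction < 1:
            raise ValueError("top_fraction must be in (0, 1)")
        if self.min_cluster_size < 1:
            raise ValueError("min_cluster_size must be >= 1")


@dataclass
class RecursionSite:
    site_id: str
    animal_ids: tuple[str, ...]
    members: pd.DataFrame = field(repr=False)  # animal, x, y, hour, n_visits
    common: bool = False
    habitat_mean: dict = field(default_factory=dict)
    habitat_sd: dict = field(default_factory=dict)
    hour_histogram: np.ndarray | None = None
    exceeds_hr_mean: dict = field(default_factory=dict)

    @property
    def n_locations(self) -> int:
        return len(self.members)

    @property
    def n_visits(self) -> int:
        return int(self.members["n_visits"].sum())

    @property
    def centroid(self) -> tuple[float, float]:
        return (float(self.members["x"].mean()), float(self.members["y"].mean()))


def top_visited(records: pd.DataFrame, cfg: SiteConfig = SiteConfig()) -> pd.DataFrame:
    """Select the top fraction of locations by visit count.

    ``records`` needs columns x, y, n_visits (plus animal, hour for later
    stages).  The top ceil(fraction * n) rows by ``n_visits`` are selected
    and every row tied with the cutoff count is included, so the selection
    can slightly exceed the nominal fraction.
    """
    if records.empty:
        raise ValueError("no records to select from")
    m = math.ceil(cfg.top_fraction * len(records))
    ranked = records.sort_values("n_visits", ascending=False, kind="stable")
    cutoff = ranked["n_visits"].iloc[m - 1]
    return records[records["n_visits"] >= cutoff].copy()


def cluster_overlapping(
    selected: pd.DataFrame, cfg: SiteConfig = SiteConfig()
) -> list[RecursionSite]:
    """Connected components of the circle-overlap graph, as bare sites.

    Locations are linked when their centres are within 2 * link_radius
    (closed: tangent circles overlap); components of at least
    ``min_cluster_size`` members are returned, ordered by size descending
    then centroid (x, y), so the output is permutation-invariant.
    """
    if selected.empty:
        return []
    pts = selected[["x", "y"]].to_numpy(dtype=float)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=2.0 * cfg.link_radius_m, output_type="ndarray")
    n = len(pts)
    if len(pairs):
        ij = np.vstack([pairs, pairs[:, ::-1]])
        adj = csr_matrix(
            (np.ones(len(ij)), (ij[:, 0], ij[:, 1])), shape=(n, n)
        )
    else:
        adj = csr_matrix((n, n))
    n_comp, labels = connected_components(adj, directed=False)

    sites = []
    for comp in range(n_comp):
        idx = np.nonzero(labels == comp)[0]
        if idx.size < cfg.min_cluster_size:
            continue
        members = selected.iloc[idx].copy()
        animals = tuple(sorted(members["animal"].astype(str).unique())) if "animal" in members else ()
        sites.append(
            RecursionSite(
                site_id="",
                animal_ids=animals,
                members=members,
                common=len(animals) > 1,
            )
        )
    sites.sort(key=lambda s: (-s.n_locations, s.centroid))
    for i, s in enumerate(sites):
        s.site_id = f"S{i + 1}"
    return sites


def characterize_site(
    site: RecursionSite,
    land,
    hr_means: dict | None = None,
    variables=HABITAT_VARIABLES,
) -> RecursionSite:
    """Fill in habitat means/SDs, the diel histogram, and (when the
    animal's 95% home-range means are supplied) flags marking variables
    whose site mean exceeds the home-range mean."""
    pts = site.members[["x", "y"]].to_numpy(dtype=float)
    for var in variables:
        vals = sample_habitat(pts, land, var)
        site.habitat_mean[var] = float(np.mean(vals))
        if len(vals) > 1 and np.ptp(vals) > 0:
            site.habitat_sd[var] = float(np.std(vals, ddof=1))
        else:
            site.habitat_sd[var] = 0.0
        if hr_means is not None and var in hr_means:
            site.exceeds_hr_mean[var] = bool(site.habitat_mean[var] > hr_means[var])
    hist = np.zeros(24, dtype=int)
    if "hour" in site.members:
        for h in site.members["hour"].astype(int):
            hist[h % 24] += 1
    site.hour_histogram = hist
    return site


def find_recursion_sites(
    records_by_animal: dict[str, pd.DataFrame],
    land,
    cfg: SiteConfig = SiteConfig(),
    hr_means_by_animal: dict[str, dict] | None = None,
) -> list[RecursionSite]:
    """Per-animal top-visited selection, then per-animal clustering plus a
    second pooled pass over the union of all animals' selections to find
    sites common to several individuals.

    Per-animal sites that reappear (same member set) inside a common site
    are reported once, flagged common.
    """
    selections = {}
    for animal, rec in records_by_animal.items():
        if rec.empty:
            continue
        selections[animal] = top_visited(rec, cfg)

    sites: list[RecursionSite] = []
    for animal in sorted(selections):
        for s in cluster_overlapping(selections[animal], cfg):
            sites.append(s)

    if len(selections) > 1:
        pooled = pd.concat(selections.values(), ignore_index=True)
        for s in cluster_overlapping(pooled, cfg):
            if s.common:
                sites.append(s)
        # drop per-animal sites fully contained in a common site
        common = [s for s in sites if s.common]
        def absorbed(s):
            key = set(map(tuple, s.members[["x", "y"]].to_numpy()))
            for c in common:
                ckey = set(map(tuple, c.members[["x", "y"]].to_numpy()))
                if key <= ckey:
                    return True
            return False
        sites = common + [s for s in sites if not s.common and not absorbed(s)]

    sites.sort(key=lambda s: (-s.n_locations, s.centroid))
    for i, s in enumerate(sites):
        s.site_id = ("C" if s.common else "S") + str(i + 1)
        if hr_means_by_animal is not None:
            means = [hr_means_by_animal.get(a) for a in s.animal_ids]
            means = [m for m in means if m]
            if means:
                pooled_means = {
                    v: float(np.mean([m[v] for m in means])) for v in means[0]
                }
                characterize_site(s, land, pooled_means)
                continue
        characterize_site(s, land)
    return sites


def sites_frame(sites) -> pd.DataFrame:
    """Table-3-style layout: one row per site with per-variable mean (SD)."""
    rows = []
    for s in sites:
        row = {
            "site": s.site_id,
            "animals": ",".join(s.animal_ids),
            "common": s.common,
            "n_locations": s.n_locations,
            "n_visits": s.n_visits,
        }
        for var in s.habitat_mean:
            if var == "thalweg":
                row["thalweg_prop"] = s.habitat_mean[var]
            else:
                row[f"{var}_mean"] = s.habitat_mean[var]
                row[f"{var}_sd"] = s.habitat_sd[var]
            if var in s.exceeds_hr_mean:
                row[f"{var}_exceeds_hr"] = s.exceeds_hr_mean[var]
        rows.append(row)
    return pd.DataFrame(rows)


def sites_geojson(sites) -> dict:
    import shapely
    from shapely.geometry import mapping

    feats = []
    for s in sites:
        pts = shapely.points(s.members["x"].to_numpy(), s.members["y"].to_numpy())
        hull = shapely.convex_hull(shapely.union_all(pts))
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(hull),
                "properties": {
                    "site": s.site_id,
                    "common": s.common,
                    "n_locations": s.n_locations,
                    "n_visits": s.n_visits,
                },
            }
        )
    return {"type": "FeatureCollection", "features": feats}
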