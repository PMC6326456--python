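"""Spatial exposure construction: conflict intensity, partition, windows.

Conflict events (battles, killings) are treated as manifestations of a
latent spatial point process.  For a reference month the events of the
preceding 12 completed months are smoothed with an isotropic Gaussian
kernel (in locally projected km), each event weighted by its
best-estimate fatalities, and the density is integrated over the cells
of a regular lon/lat grid so that a cell value reads as *expected deaths
in that cell over the window*.  A child's exposure is the value of the
cell containing its (displaced) cluster location for the 12 months
preceding its interview; the default 30 km bandwidth exceeds the <=20 km
cluster displacement so a displaced location still sits under the mass
of nearby events.

The module also builds the survey-constrained partition: a Voronoi
tessellation seeded at cluster locations whose cells are merged into the
maximum number of contiguous areas such that every area contains
clusters from both survey rounds, and computes retrospective
flood/drought window extrema from monthly series.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial import Voronoi
from scipy.special import ndtr
from shapely.geometry import MultiPoint, Point, Polygon, box, mapping
from shapely.ops import unary_union

from maternut.data_model_io import (ChildRecord, ConflictEvent, GeoPoint,
                                    SurveyCluster)

EARTH_RADIUS_KM = 6371.0

DEFAULT_BANDWIDTH_KM = 30.0
DEFAULT_CELL_DEG = 0.1
DEFAULT_WINDOW_MONTHS = 12


@dataclass(frozen=True)
class GridSpec:
    """Regular lon/lat grid: half-open cells of ``cell_deg`` degrees."""

    lon_min: float
    lat_min: float
    lon_max: float
    lat_max: float
    cell_deg: float = DEFAULT_CELL_DEG

    def __post_init__(self) -> None:
        if self.lon_max <= self.lon_min or self.lat_max <= self.lat_min:
            raise ValueError("empty grid spec")
        if self.cell_deg <= 0:
            raise ValueError("cell_deg must be positive")

    @property
    def n_lon(self) -> int:
        return max(1, math.ceil((self.lon_max - self.lon_min) / self.cell_deg
                                - 1e-9))

    @property
    def n_lat(self) -> int:
        return max(1, math.ceil((self.lat_max - self.lat_min) / self.cell_deg
                                - 1e-9))


@dataclass
class IntensityGrid:
    """Expected conflict deaths per cell over a retrospective window.

    ``values[iy, ix]`` covers the half-open cell
    ``[lon_min + ix*d, lon_min + (ix+1)*d) x [lat_min + iy*d, ...)``.
    """

    spec: GridSpec
    month: int
    window_months: int
    values: np.ndarray

    def to_long_csv(self, path: str | Path) -> None:
        """Export as long-format CSV (lon, lat, value) of cell centres."""
        d = self.spec.cell_deg
        with open(path, "w", encoding="utf-8", newline="") as fh:
            fh.write("lon,lat,value\n")
            for iy in range(self.values.shape[0]):
                lat = self.spec.lat_min + (iy + 0.5) * d
                for ix in range(self.values.shape[1]):
                    lon = self.spec.lon_min + (ix + 0.5) * d
                    fh.write(f"{lon!r},{lat!r},{float(self.values[iy, ix])!r}\n")


@dataclass
class MonthlySeries:
    """Month-indexed environmental series for one location key.

    Values may be NaN (missing month); months must be strictly
    increasing.
    """

    key: str
    months: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.months = np.asarray(self.months, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.months.shape != self.values.shape:
            raise ValueError("months and values must align")
        if len(self.months) > 1 and not np.all(np.diff(self.months) > 0):
            raise ValueError("months must be strictly increasing")


def _project_km(lon: np.ndarray, lat: np.ndarray,
                lat0: float) -> tuple[np.ndarray, np.ndarray]:
    """Equirectangular projection to km about reference latitude lat0."""
    x = EARTH_RADIUS_KM * math.cos(math.radians(lat0)) * np.radians(lon)
    y = EARTH_RADIUS_KM * np.radians(lat)
    return x, y


def events_in_window(events: Iterable[ConflictEvent], ref_month: int,
                     window_months: int = DEFAULT_WINDOW_MONTHS
                     ) -> list[ConflictEvent]:
    """Events in the ``window_months`` completed months strictly before
    ``ref_month`` (closed interval [ref - w, ref - 1])."""
    lo, hi = ref_month - window_months, ref_month - 1
    return [e for e in events if lo <= e.month <= hi]


def estimate_intensity(events: Iterable[ConflictEvent], ref_month: int,
                       window_months: int = DEFAULT_WINDOW_MONTHS,
                       spec: GridSpec | None = None,
                       bandwidth_km: float = DEFAULT_BANDWIDTH_KM
                       ) -> IntensityGrid:
    """Kernel-smoothed conflict-intensity surface for one reference month.

    The Gaussian kernel is separable, so the per-cell integral is exact:
    a product of 1-D normal CDF differences across the cell edges.  The
    surface is rescaled so total mass equals total window deaths (mass
    conservation; kernel tails falling outside the box are folded back
    proportionally).
    """
    if spec is None:
        raise ValueError("a GridSpec is required")
    if window_months < 1:
        raise ValueError("window_months must be >= 1")
    windowed = events_in_window(events, ref_month, window_months)
    values = np.zeros((spec.n_lat, spec.n_lon))
    grid = IntensityGrid(spec=spec, month=ref_month,
                         window_months=window_months, values=values)
    if not windowed:
        return grid
    lon_edges = spec.lon_min + spec.cell_deg * np.arange(spec.n_lon + 1)
    lat_edges = spec.lat_min + spec.cell_deg * np.arange(spec.n_lat + 1)
    lat0 = 0.5 * (spec.lat_min + spec.lat_max)
    x_edges, y_edges = _project_km(lon_edges, lat_edges, lat0)
    ev_lon = np.array([e.location.lon for e in windowed])
    ev_lat = np.array([e.location.lat for e in windowed])
    deaths = np.array([e.deaths for e in windowed], dtype=float)
    ex, ey = _project_km(ev_lon, ev_lat, lat0)
    h = bandwidth_km
    # (n_events, n_edges) CDF evaluations -> per-cell differences
    cdf_x = ndtr((x_edges[None, :] - ex[:, None]) / h)
    cdf_y = ndtr((y_edges[None, :] - ey[:, None]) / h)
    dx = np.diff(cdf_x, axis=1)          # (n_events, n_lon)
    dy = np.diff(cdf_y, axis=1)          # (n_events, n_lat)
    values[:] = (deaths[:, None] * dy).T @ dx
    total_deaths = float(deaths.sum())
    mass = float(values.sum())
    if mass > 1e-12 * max(total_deaths, 1.0):
        values *= total_deaths / mass
    # far tails carry no meaningful mass on the expected-deaths scale;
    # flooring them keeps "zero exposure" an exact statement
    values[values < 1e-9] = 0.0
    return grid


def lookup_intensity(grid: IntensityGrid, p: GeoPoint) -> float:
    """Value of the half-open cell containing ``p`` (east/north on ties)."""
    spec = grid.spec
    ix = math.floor((p.lon - spec.lon_min) / spec.cell_deg + 1e-12)
    iy = math.floor((p.lat - spec.lat_min) / spec.cell_deg + 1e-12)
    if not (0 <= ix < spec.n_lon and 0 <= iy < spec.n_lat):
        raise ValueError(f"point ({p.lon}, {p.lat}) outside grid box")
    return float(grid.values[iy, ix])


def assign_child_intensity(child: ChildRecord,
                           events: Iterable[ConflictEvent],
                           window_months: int = DEFAULT_WINDOW_MONTHS,
                           spec: GridSpec | None = None,
                           bandwidth_km: float = DEFAULT_BANDWIDTH_KM
                           ) -> float:
    """Conflict exposure of one child: 12 completed months before interview."""
    grid = estimate_intensity(events, child.interview_month, window_months,
                              spec, bandwidth_km)
    return lookup_intensity(grid, child.location)


def assign_intensities(children: Sequence[ChildRecord],
                       events: Iterable[ConflictEvent],
                       window_months: int = DEFAULT_WINDOW_MONTHS,
                       spec: GridSpec | None = None,
                       bandwidth_km: float = DEFAULT_BANDWIDTH_KM
                       ) -> np.ndarray:
    """Vectorised exposure assignment, one surface per interview month."""
    events = list(events)
    months = sorted({c.interview_month for c in children})
    grids = {m: estimate_intensity(events, m, window_months, spec,
                                   bandwidth_km) for m in months}
    return np.array([lookup_intensity(grids[c.interview_month], c.location)
                     for c in children])


def window_extremum(series: MonthlySeries, ref_month: int,
                    window_months: int = DEFAULT_WINDOW_MONTHS,
                    mode: str = "max") -> float:
    """Max (flood / surface runoff) or min (drought index) over the
    ``window_months`` completed months strictly before ``ref_month``."""
    if mode not in ("max", "min"):
        raise ValueError(f"mode must be 'max' or 'min', got {mode!r}")
    lo, hi = ref_month - window_months, ref_month - 1
    mask = (series.months >= lo) & (series.months <= hi)
    vals = series.values[mask]
    vals = vals[~np.isnan(vals)]
    if vals.size == 0:
        raise ValueError(
            f"no non-missing values in window [{lo}, {hi}] for {series.key}")
    return float(vals.max() if mode == "max" else vals.min())


@dataclass
class PartitionArea:
    area_id: str
    polygon: Polygon | None
    cluster_ids: list[str]


@dataclass
class Partition:
    """Contiguous areas, each containing clusters from both rounds."""

    areas: list[PartitionArea]

    def cluster_to_area(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for area in self.areas:
            for cid in area.cluster_ids:
                out[cid] = area.area_id
        return out

    def to_geojson(self, path: str | Path) -> None:
        features = []
        for area in self.areas:
            features.append({
                "type": "Feature",
                "geometry": (mapping(area.polygon)
                             if area.polygon is not None else None),
                "properties": {"area_id": area.area_id,
                               "cluster_ids": area.cluster_ids},
            })
        with open(path, "w", encoding="utf-8") as fh:
            json.dump({"type": "FeatureCollection", "features": features}, fh)


def _voronoi_cells(points: np.ndarray,
                   boundary: Polygon) -> tuple[list[Polygon], list[set[int]]]:
    """Boundary-clipped Voronoi cell per seed plus seed adjacency sets.

    Unbounded cells are closed by extending ridges far beyond the
    boundary before clipping (standard finite-polygon reconstruction).
    """
    n = len(points)
    adjacency: list[set[int]] = [set() for _ in range(n)]
    if n == 1:
        return [boundary], adjacency
    if n <= 3 or np.linalg.matrix_rank(points - points.mean(axis=0)) < 2:
        # too few / collinear seeds for a proper tessellation: nearest-seed
        # cells via brute force on the boundary are overkill here, treat
        # every pair as adjacent and give each seed an equal claim
        for i in range(n):
            adjacency[i] = set(range(n)) - {i}
        return [None] * n, adjacency  # type: ignore[list-item]
    vor = Voronoi(points)
    for (p, q) in vor.ridge_points:
        adjacency[p].add(q)
        adjacency[q].add(p)
    span = max(boundary.bounds[2] - boundary.bounds[0],
               boundary.bounds[3] - boundary.bounds[1])
    radius = 100.0 * max(span, 1.0)
    center = points.mean(axis=0)
    cells: list[Polygon] = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 not in region:
            poly = Polygon(vor.vertices[region])
        else:
            # rebuild the open cell: collect finite vertices plus far
            # points along the unbounded ridge directions
            pts = [vor.vertices[v] for v in region if v != -1]
            for (p, q), ridge in zip(vor.ridge_points, vor.ridge_vertices):
                if i not in (p, q) or -1 not in ridge:
                    continue
                finite = vor.vertices[[v for v in ridge if v != -1][0]]
                other = points[q] if p == i else points[p]
                tangent = points[i] - other
                tangent = tangent / np.linalg.norm(tangent)
                normal = np.array([-tangent[1], tangent[0]])
                midpoint = 0.5 * (points[i] + other)
                direction = normal if np.dot(normal, midpoint - center) > 0 \
                    else -normal
                pts.append(finite + direction * radius)
                pts.append(points[i] + (points[i] - center) * 0
                           + direction * radius)
            poly = MultiPoint(pts).convex_hull
        clipped = poly.intersection(boundary)
        if clipped.is_empty:
            clipped = Point(points[i]).buffer(1e-9).intersection(boundary)
        cells.append(clipped)
    return cells, adjacency


def build_partition(clusters: Sequence[SurveyCluster],
                    boundary: Polygon | None = None) -> Partition:
    """Voronoi tessellation merged until every area spans both rounds.

    The number of areas is maximised exactly: every contiguous area that
    contains both rounds must contain at least one *adjacent* mixed-round
    cluster pair (walk any within-area path from a 2008 cluster to a 2013
    cluster; the rounds switch at some edge), so the achievable area
    count is bounded by the maximum bipartite matching over mixed-round
    adjacent pairs — and seeding one area per matched pair, then
    attaching every unmatched cell to an adjacent area, attains the
    bound.  Leftover attachment is deterministic: lowest-index cell
    first, joining the smallest adjacent area (ties to the lowest id).
    """
    if not clusters:
        raise ValueError("no clusters")
    rounds = {c.survey_round for c in clusters}
    if len(rounds) < 2:
        raise ValueError(
            f"all clusters belong to round {rounds.pop()}; a partition with "
            "both rounds in every area is infeasible")
    points = np.array([[c.location.lon, c.location.lat] for c in clusters])
    if boundary is None:
        lon_min, lat_min = points.min(axis=0) - 0.5
        lon_max, lat_max = points.max(axis=0) + 0.5
        boundary = box(lon_min, lat_min, lon_max, lat_max)
    cells, adjacency = _voronoi_cells(points, boundary)

    n = len(clusters)
    side_a = [i for i in range(n) if clusters[i].survey_round ==
              min(rounds)]
    side_b = [i for i in range(n) if clusters[i].survey_round !=
              min(rounds)]
    bi = np.zeros((len(side_a), len(side_b)), dtype=np.int8)
    b_pos = {idx: k for k, idx in enumerate(side_b)}
    for k, i in enumerate(side_a):
        for j in adjacency[i]:
            if j in b_pos:
                bi[k, b_pos[j]] = 1
    from scipy.sparse import csr_matrix
    from scipy.sparse.csgraph import maximum_bipartite_matching
    match = maximum_bipartite_matching(csr_matrix(bi), perm_type="column")
    groups: dict[int, set[int]] = {}
    assigned = np.full(n, -1, dtype=int)
    gid = 0
    for k, i in enumerate(side_a):
        if match[k] >= 0:
            j = side_b[match[k]]
            groups[gid] = {i, j}
            assigned[i] = gid
            assigned[j] = gid
            gid += 1
    # attach leftovers to adjacent areas until everything is assigned
    while True:
        leftovers = [i for i in range(n) if assigned[i] < 0]
        if not leftovers:
            break
        progressed = False
        for i in leftovers:
            adj_groups = sorted({int(assigned[j]) for j in adjacency[i]
                                 if assigned[j] >= 0})
            if not adj_groups:
                continue
            target = min(adj_groups,
                         key=lambda g: (len(groups[g]), g))
            groups[target].add(i)
            assigned[i] = target
            progressed = True
            break
        if not progressed:
            raise ValueError("disconnected cluster cannot join any area")

    areas = []
    for rank, gid in enumerate(sorted(groups)):
        members = sorted(groups[gid])
        polys = [cells[i] for i in members if cells[i] is not None]
        polygon = unary_union(polys) if polys else boundary
        areas.append(PartitionArea(
            area_id=f"A{rank:03d}",
            polygon=polygon,
            cluster_ids=[clusters[i].cluster_id for i in members]))
    return Partition(areas=areas)
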