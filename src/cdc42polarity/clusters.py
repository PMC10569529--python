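"""Voronoi-tessellation cluster detection and cluster-dynamics statistics.

A cluster of active Cdc42 is a connected group of adjacent Voronoi polygons
whose individual areas fall below a data-driven size threshold.  The
threshold is calibrated per dataset as the intersection between the polygon
-area density of the analyzed snapshots and that of uniform negative
controls (50 realizations at matched N and geometry).  Candidate groups are
then filtered by total area (default <= 0.785 um^2, the footprint of a
~1-um-diameter polarity site) and by molecule count (default >= 20; the
count filter value is a package default, not a published number).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial import SphericalVoronoi, Voronoi

from .fixtures import uniform_pattern
from .params import Geometry

#: Maximum total polygon area of a cluster, um^2 (1-um-diameter site).
CLUSTER_AREA_MAX = 0.785

#: Minimum number of molecules in a cluster (package default).
CLUSTER_COUNT_MIN = 20


class ThresholdError(RuntimeError):
    """Raised when control and sample polygon-size densities do not intersect."""


@dataclass
class VoronoiThreshold:
    size_threshold: float
    bin_edges: np.ndarray
    control_density: np.ndarray
    sample_density: np.ndarray
    n_controls: int


@dataclass
class Cluster:
    member_ids: np.ndarray
    polygon_area_sum: float
    n_molecules: int
    centroid: np.ndarray


@dataclass
class ClusterStateSeries:
    times: np.ndarray
    n_clusters: np.ndarray
    sampling_interval: float

    @property
    def states(self) -> np.ndarray:
        """Per-time label 0, 1 or 2 (2 meaning '2 or more clusters')."""
        return np.minimum(self.n_clusters, 2)


# ---------------------------------------------------------------------------
# tessellation

def _shoelace(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def voronoi_areas_2d(points, L: float, margin: float | None = None):
    """Voronoi polygon areas and adjacency on the periodic square.

    Periodicity is handled by tiling ghost images of points within ``margin``
    of the tile borders and keeping the central-tile cells.  The default
    margin (4x the mean point spacing, at least 0.5 um) is wide enough that
    every central cell is closed by its true periodic neighbours.
    """
    pts = np.mod(np.asarray(points, float), L)
    n = len(pts)
    if n < 3:
        raise ValueError("tessellation needs at least 3 points")
    if margin is None:
        margin = max(4.0 * math.sqrt(L * L / n), 0.5)
    margin = min(margin, L)
    ghosts, owner = [pts], [np.arange(n)]
    for dx in (-L, 0.0, L):
        for dy in (-L, 0.0, L):
            if dx == 0.0 and dy == 0.0:
                continue
            g = pts + (dx, dy)
            m = (
                (g[:, 0] > -margin) & (g[:, 0] < L + margin)
                & (g[:, 1] > -margin) & (g[:, 1] < L + margin)
            )
            ghosts.append(g[m])
            owner.append(np.flatnonzero(m))
    allpts = np.vstack(ghosts)
    owner = np.concatenate(owner)
    vor = Voronoi(allpts)
    areas = np.empty(n)
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) == 0:
            raise RuntimeError("open Voronoi cell in central tile; enlarge margin")
        areas[i] = _shoelace(vor.vertices[region])
    edges = set()
    for (a, b) in vor.ridge_points:
        if a < n or b < n:
            ia, ib = owner[a], owner[b]
            if ia != ib:
                edges.add((min(ia, ib), max(ia, ib)))
    return areas, edges


def voronoi_areas_sphere(points, R: float):
    """Spherical Voronoi cell areas and adjacency (shared-arc neighbours)."""
    pts = np.asarray(points, float)
    n = len(pts)
    if n < 4:
        raise ValueError("spherical tessellation needs at least 4 points")
    sv = SphericalVoronoi(pts, radius=R, threshold=1e-9)
    sv.sort_vertices_of_regions()
    areas = sv.calculate_areas()
    vert_to_pts: dict[int, list[int]] = {}
    for i, region in enumerate(sv.regions):
        for v in region:
            vert_to_pts.setdefault(v, []).append(i)
    pair_count: dict[tuple[int, int], int] = {}
    for members in vert_to_pts.values():
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                key = (min(members[a], members[b]), max(members[a], members[b]))
                pair_count[key] = pair_count.get(key, 0) + 1
    edges = {k for k, c in pair_count.items() if c >= 2}
    return areas, edges


def polygon_areas(points, geometry: Geometry):
    if geometry.mode == "plane2d":
        return voronoi_areas_2d(points, geometry.L)
    return voronoi_areas_sphere(points, geometry.R)


# ---------------------------------------------------------------------------
# threshold calibration

def calibrate_threshold(
    snapshots,
    geometry: Geometry,
    n_controls: int = 50,
    seed=0,
    nbins: int | None = None,
) -> VoronoiThreshold:
    """Polygon-size threshold from uniform negative controls.

    Pools Voronoi polygon areas over the given snapshots, builds matched
    uniform controls (same N, same geometry), histograms both on common
    Freedman-Diaconis bins and returns the abscissa where the sample's
    small-polygon mode hands over to the control mode (first bin at which
    the control density reaches the sample density).
    """
    snapshots = [np.asarray(s) for s in snapshots]
    if not snapshots or any(len(s) < 3 for s in snapshots):
        raise ValueError("need non-empty snapshots with at least 3 points each")
    rng = np.random.default_rng(seed)
    sample = np.concatenate([polygon_areas(s, geometry)[0] for s in snapshots])
    control = np.concatenate(
        [
            polygon_areas(uniform_pattern(len(s), geometry, rng), geometry)[0]
            for s in snapshots
            for _ in range(max(1, n_controls // len(snapshots)))
        ]
    )
    pooled = np.concatenate([sample, control])
    if nbins is None:
        iqr = np.subtract(*np.percentile(pooled, [75, 25]))
        width = 2 * iqr / len(pooled) ** (1 / 3) if iqr > 0 else None
        nbins = int(np.clip((pooled.max() - pooled.min()) / width, 20, 400)) if width else 100
    edges = np.linspace(0.0, pooled.max(), nbins + 1)
    hs, _ = np.histogram(sample, bins=edges, density=True)
    hc, _ = np.histogram(control, bins=edges, density=True)

    first = np.flatnonzero(hs > 0)
    if first.size == 0:
        raise ThresholdError("sample polygon-size density is empty")
    i0 = first[0]
    crossing = None
    for i in range(i0, nbins):
        if hc[i] >= hs[i]:
            crossing = i
            break
    if crossing is None:
        raise ThresholdError(
            "control and sample polygon-size densities do not intersect; "
            "cannot define a cluster threshold"
        )
    thr = 0.5 * (edges[crossing] + edges[crossing + 1])
    return VoronoiThreshold(float(thr), edges, hc, hs, n_controls)


# ---------------------------------------------------------------------------
# detection

def _centroid(points, geometry: Geometry) -> np.ndarray:
    pts = np.asarray(points, float)
    if geometry.mode == "sphere3d":
        m = pts.mean(axis=0)
        nrm = np.linalg.norm(m)
        return geometry.R * m / nrm if nrm > 0 else pts[0]
    # circular mean per axis under periodicity
    L = geometry.L
    ang = 2 * np.pi * pts / L
    mean = np.arctan2(np.sin(ang).mean(axis=0), np.cos(ang).mean(axis=0))
    return np.mod(mean * L / (2 * np.pi), L)


def detect_clusters(
    points,
    geometry: Geometry,
    threshold: VoronoiThreshold | float,
    area_max: float = CLUSTER_AREA_MAX,
    count_min: int = CLUSTER_COUNT_MIN,
    area_filter: str = "max",
) -> list[Cluster]:
    """Clusters = adjacent Voronoi polygons below the size threshold.

    ``area_filter="max"`` keeps groups whose total polygon area is at most
    ``area_max`` (the default reading: a polarity site is about 1 um across);
    ``"min"`` inverts the rule for sensitivity analysis.
    """
    pts = np.asarray(points, float)
    if len(pts) < 3:
        warnings.warn("fewer than 3 points; no tessellation, no clusters")
        return []
    thr = threshold.size_threshold if isinstance(threshold, VoronoiThreshold) else float(threshold)
    areas, edges = polygon_areas(pts, geometry)
    keep = areas < thr
    # union-find over adjacency restricted to kept polygons
    parent = np.arange(len(pts))

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in edges:
        if keep[a] and keep[b]:
            ra, rb = find(a), find(b)
            if ra != rb:
                parent[rb] = ra
    groups: dict[int, list[int]] = {}
    for i in np.flatnonzero(keep):
        groups.setdefault(find(i), []).append(i)
    out = []
    for members in groups.values():
        ids = np.array(sorted(members))
        area = float(areas[ids].sum())
        ok_area = area <= area_max if area_filter == "max" else area >= area_max
        if ok_area and len(ids) >= count_min:
            out.append(Cluster(ids, area, len(ids), _centroid(pts[ids], geometry)))
    out.sort(key=lambda c: -c.n_molecules)
    return out


def count_series(
    snapshots,
    times,
    geometry: Geometry,
    threshold: VoronoiThreshold | float,
    area_max: float = CLUSTER_AREA_MAX,
    count_min: int = CLUSTER_COUNT_MIN,
) -> ClusterStateSeries:
    """Detected cluster counts over a sequence of snapshots."""
    times = np.asarray(times, float)
    counts = np.array(
        [
            len(detect_clusters(s, geometry, threshold, area_max, count_min))
            if len(s) >= 3 else 0
            for s in snapshots
        ]
    )
    dt = float(times[1] - times[0]) if len(times) > 1 else 0.0
    return ClusterStateSeries(times, counts, dt)


# ---------------------------------------------------------------------------
# state statistics

@dataclass
class StateStatistics:
    occupancy: np.ndarray  # fraction of samples in states 0, 1, 2+
    transition_matrix: np.ndarray  # row-stochastic over observed exits
    dwell_times: dict  # state -> array of dwell durations (s)
    n_samples: int


def state_statistics(series: ClusterStateSeries, resample_interval: float | None = None) -> StateStatistics:
    """Occupancy fractions, transition matrix and dwell times of 0/1/2+ states.

    ``resample_interval`` (e.g. 120 s) subsamples the series to the coarser
    experimental scoring interval before computing statistics.
    """
    states = series.states
    times = series.times
    if len(states) < 2:
        raise ValueError("series must contain at least two samples")
    if resample_interval is not None:
        if series.sampling_interval <= 0 or resample_interval < series.sampling_interval:
            raise ValueError("resample interval must exceed the native interval")
        stride = int(round(resample_interval / series.sampling_interval))
        states = states[::stride]
        times = times[::stride]
    occ = np.array([np.mean(states == s) for s in (0, 1, 2)])
    trans = np.zeros((3, 3))
    for a, b in zip(states[:-1], states[1:]):
        trans[a, b] += 1
    rows = trans.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        tm = np.where(rows > 0, trans / rows, np.nan)
    interval = float(times[1] - times[0]) if len(times) > 1 else 0.0
    dwell: dict[int, list[float]] = {0: [], 1: [], 2: []}
    run_state, run_len = states[0], 1
    for s in states[1:]:
        if s == run_state:
            run_len += 1
        else:
            dwell[int(run_state)].append(run_len * interval)
            run_state, run_len = s, 1
    dwell[int(run_state)].append(run_len * interval)
    return StateStatistics(occ, tm, {k: np.asarray(v) for k, v in dwell.items()}, len(states))
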