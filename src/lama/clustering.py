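"""Second-order statistics and density clustering for localization patterns.

Ripley's K, L and H functions characterize clustering at *all* length
scales at once: under complete spatial randomness (CSR) K(r) = πr², so
L(r) = sqrt(K/π) = r and H(r) = L(r) − r ≈ 0; positive H indicates
aggregation and the H peak sits near the characteristic cluster radius.

DBSCAN and OPTICS sort the localizations into density-connected clusters
plus noise; the per-cluster convex-hull morphology (area, perimeter,
circularity, diameter, localization count) then quantifies individual
cluster size and copy numbers.

Determinism
-----------
DBSCAN here uses a fixed, order-independent convention: a point is a core
point when at least ``min_pts`` points (itself included) lie within
``eps``; clusters are the connected components of the core-point eps-graph,
numbered by their lowest member row index; a border point joins the cluster
of its *nearest* core neighbor (ties broken by lowest row index).  The same
convention is used by the OPTICS eps-cut, so both algorithms produce
identical partitions at equal parameters.
"""

from __future__ import annotations

import heapq
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from shapely.geometry import MultiPoint

from .locdata import LocalizationTable

NOISE = -1


# ---------------------------------------------------------------------------
# Ripley functions
# ---------------------------------------------------------------------------

@dataclass
class RipleyCurve:
    """K/L/H values over a radius grid.

    ``K`` has units of area [nm²]; ``L = sqrt(K/π)`` and ``H = L − r`` are
    lengths [nm].  ``edge_correction`` records whether the translation
    correction for a rectangular window was applied.
    """

    radii: np.ndarray
    K: np.ndarray
    edge_correction: str
    n_points: int
    region_area: float
    L: np.ndarray = field(init=False)
    H: np.ndarray = field(init=False)

    def __post_init__(self):
        self.radii = np.asarray(self.radii, dtype=float)
        self.K = np.asarray(self.K, dtype=float)
        self.L = np.sqrt(self.K / np.pi)
        self.H = self.L - self.radii


def ripley(table: LocalizationTable, radii, edge_correction: str = "translation") -> RipleyCurve:
    """Ripley K/L/H estimate of a localization pattern.

    K̂(r) = (A / (n(n−1))) · Σ_{i≠j} e_ij · 1(d_ij ≤ r), with e_ij = 1 for
    ``edge_correction="none"`` and the translation correction
    e_ij = A / ((w−|Δx|)(h−|Δy|)) for a rectangular w×h observation window.

    ``radii`` must be strictly increasing; radii beyond half the shorter
    region side only trigger a warning (the translation correction degrades
    there).
    """
    radii = np.asarray(radii, dtype=float)
    if radii.ndim != 1 or len(radii) == 0 or np.any(np.diff(radii) <= 0):
        raise ValueError("radii must be a strictly increasing 1-D grid")
    n = len(table)
    if n < 2:
        raise ValueError("Ripley statistics need at least 2 points")
    if edge_correction not in ("none", "translation"):
        raise ValueError(f"unknown edge correction {edge_correction!r}")
    w, h = table.region_size
    area = table.region_area
    if radii[-1] > min(w, h) / 2.0:
        warnings.warn("radii exceed half the shorter region side; "
                      "edge-corrected estimates become unreliable there")

    xy = table.coordinates
    tree = cKDTree(xy)
    pairs = tree.query_pairs(float(radii[-1]), output_type="ndarray")
    if len(pairs):
        diff = xy[pairs[:, 0]] - xy[pairs[:, 1]]
        dist = np.hypot(diff[:, 0], diff[:, 1])
        if edge_correction == "translation":
            wx = w - np.abs(diff[:, 0])
            hy = h - np.abs(diff[:, 1])
            weights = area / (wx * hy)
        else:
            weights = np.ones(len(pairs))
        order = np.argsort(dist)
        dist, weights = dist[order], weights[order]
        csum = np.concatenate([[0.0], np.cumsum(weights)])
        # each unordered pair contributes twice to the ordered-pair sum
        k = 2.0 * csum[np.searchsorted(dist, radii, side="right")]
    else:
        k = np.zeros_like(radii)
    k *= area / (n * (n - 1))
    return RipleyCurve(radii=radii, K=k, edge_correction=edge_correction,
                       n_points=n, region_area=area)


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

@dataclass
class ClusterResult:
    """Per-localization cluster labels (−1 = noise) plus parameters."""

    labels: np.ndarray
    n_clusters: int
    params: dict

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=int)

    def members(self, cluster_id: int) -> np.ndarray:
        return np.flatnonzero(self.labels == cluster_id)


def _canonical_labels(core_idx: np.ndarray, core_component: np.ndarray,
                      n: int) -> tuple[np.ndarray, int]:
    """Relabel components by their lowest core row index; return full label array."""
    labels = np.full(n, NOISE, dtype=int)
    if not len(core_idx):
        return labels, 0
    comp_min = {}
    for idx, comp in zip(core_idx, core_component):
        comp_min[comp] = min(comp_min.get(comp, idx), idx)
    order = sorted(comp_min, key=comp_min.get)
    remap = {comp: new for new, comp in enumerate(order)}
    labels[core_idx] = [remap[c] for c in core_component]
    return labels, len(order)


def _assign_borders(labels: np.ndarray, xy: np.ndarray, core_idx: np.ndarray,
                    eps: float) -> None:
    """Attach non-core points within eps of a core point to the nearest core's cluster."""
    if not len(core_idx):
        return
    non_core = np.flatnonzero(labels == NOISE)
    if not len(non_core):
        return
    core_tree = cKDTree(xy[core_idx])
    # k=2 so a tie between two equidistant cores resolves to the lower row index
    d, j = core_tree.query(xy[non_core], k=min(2, len(core_idx)),
                           distance_upper_bound=eps * (1 + 1e-12))
    d = np.atleast_2d(d.T).T if d.ndim == 1 else d
    j = np.atleast_2d(j.T).T if j.ndim == 1 else j
    for row, idx in enumerate(non_core):
        if not np.isfinite(d[row, 0]) or d[row, 0] > eps:
            continue
        best = j[row, 0]
        if (j.shape[1] > 1 and np.isfinite(d[row, 1])
                and d[row, 1] <= eps and np.isclose(d[row, 1], d[row, 0])):
            best = min(best, j[row, 1])
        labels[idx] = labels[core_idx[best]]


def dbscan(table: LocalizationTable, eps: float, min_pts: int) -> ClusterResult:
    """Density-based clustering with deterministic, order-independent labels.

    Core points have >= ``min_pts`` neighbors within ``eps`` *counting
    themselves*; clusters are connected components of the core-core
    eps-graph; border points join their nearest core point's cluster;
    everything else is noise (label −1).
    """
    if eps <= 0:
        raise ValueError("eps must be > 0")
    if min_pts < 1:
        raise ValueError("min_pts must be >= 1")
    xy = table.coordinates
    n = len(xy)
    if n == 0:
        return ClusterResult(np.empty(0, dtype=int), 0,
                             {"eps": eps, "min_pts": min_pts})
    tree = cKDTree(xy)
    neighbors = tree.query_ball_point(xy, eps)
    counts = np.fromiter((len(nb) for nb in neighbors), dtype=int, count=n)
    is_core = counts >= min_pts
    core_idx = np.flatnonzero(is_core)

    # connected components over core points (BFS restricted to core-core edges)
    component = np.full(n, -1, dtype=int)
    comp = 0
    for start in core_idx:
        if component[start] != -1:
            continue
        stack = [start]
        component[start] = comp
        while stack:
            p = stack.pop()
            for q in neighbors[p]:
                if is_core[q] and component[q] == -1:
                    component[q] = comp
                    stack.append(q)
        comp += 1

    labels, n_clusters = _canonical_labels(core_idx, component[core_idx], n)
    _assign_borders(labels, xy, core_idx, eps)
    return ClusterResult(labels, n_clusters, {"eps": eps, "min_pts": min_pts})


# ---------------------------------------------------------------------------
# OPTICS
# ---------------------------------------------------------------------------

@dataclass
class OpticsResult:
    """OPTICS ordering with core and reachability distances.

    ``ordering[k]`` is the row index of the k-th processed point;
    ``reachability`` and ``core_distance`` are indexed by row (np.inf where
    undefined).  ``min_pts`` counts the point itself, matching
    :func:`dbscan`.
    """

    ordering: np.ndarray
    reachability: np.ndarray
    core_distance: np.ndarray
    min_pts: int
    max_eps: float
    _table: LocalizationTable


def optics(table: LocalizationTable, min_pts: int, max_eps: float = np.inf) -> OpticsResult:
    """OPTICS density ordering of a localization table.

    The reachability profile generalizes DBSCAN over all eps <= ``max_eps``;
    valleys correspond to clusters.  Use :func:`extract_dbscan` to cut the
    profile at a fixed eps.
    """
    if min_pts < 2:
        raise ValueError("min_pts must be >= 2")
    xy = table.coordinates
    n = len(xy)
    ordering = []
    reach = np.full(n, np.inf)
    core_dist = np.full(n, np.inf)
    if n == 0:
        return OpticsResult(np.empty(0, dtype=int), reach, core_dist,
                            min_pts, max_eps, table)
    tree = cKDTree(xy)
    k = min(min_pts, n)
    dists, _ = tree.query(xy, k=k)
    dists = np.atleast_2d(dists)
    if n >= min_pts:
        cd = dists[:, min_pts - 1]  # min_pts-th neighbor counting self
        core_dist = np.where(cd <= max_eps, cd, np.inf)

    processed = np.zeros(n, dtype=bool)
    eps_query = max_eps if np.isfinite(max_eps) else None

    def neighbors_of(p):
        if eps_query is None:
            return [q for q in range(n) if q != p]
        return tree.query_ball_point(xy[p], eps_query)

    for start in range(n):
        if processed[start]:
            continue
        processed[start] = True
        ordering.append(start)
        heap: list[tuple[float, int]] = []
        if np.isfinite(core_dist[start]):
            _optics_update(start, neighbors_of(start), xy, core_dist, reach,
                           processed, heap)
        while heap:
            r, p = heapq.heappop(heap)
            if processed[p] or r > reach[p]:
                continue
            processed[p] = True
            ordering.append(p)
            if np.isfinite(core_dist[p]):
                _optics_update(p, neighbors_of(p), xy, core_dist, reach,
                               processed, heap)
    return OpticsResult(np.asarray(ordering, dtype=int), reach, core_dist,
                        min_pts, max_eps, table)


def _optics_update(p, neighbor_idx, xy, core_dist, reach, processed, heap):
    for q in neighbor_idx:
        if processed[q] or q == p:
            continue
        new_reach = max(core_dist[p], float(np.hypot(*(xy[q] - xy[p]))))
        if new_reach < reach[q]:
            reach[q] = new_reach
            heapq.heappush(heap, (new_reach, q))


def extract_dbscan(result: OpticsResult, eps: float) -> ClusterResult:
    """Cut an OPTICS result at a fixed eps, reproducing :func:`dbscan`.

    Core points are those with core distance <= eps; walking the ordering
    groups them into the DBSCAN connected components; border points are then
    attached to their nearest core point's cluster — the identical
    convention used by :func:`dbscan`, so partitions coincide exactly for
    eps <= ``max_eps``.
    """
    if eps > result.max_eps:
        raise ValueError("extraction eps must be <= the max_eps of the ordering")
    xy = result._table.coordinates
    n = len(xy)
    is_core = result.core_distance <= eps
    component = np.full(n, -1, dtype=int)
    comp = -1
    for idx in result.ordering:
        if not is_core[idx]:
            continue
        if result.reachability[idx] > eps:
            comp += 1  # unreachable at this eps: starts a new cluster
        component[idx] = comp
    core_idx = np.flatnonzero(is_core)
    labels, n_clusters = _canonical_labels(core_idx, component[core_idx], n)
    _assign_borders(labels, xy, core_idx, eps)
    return ClusterResult(labels, n_clusters,
                         {"eps": eps, "min_pts": result.min_pts})


# ---------------------------------------------------------------------------
# morphology
# ---------------------------------------------------------------------------

@dataclass
class ClusterShape:
    """Convex-hull morphology of one cluster.

    ``circularity = 4πA/P²`` is 1 for a disc and decreases for elongated
    shapes; it is NaN for degenerate clusters (fewer than 3 non-collinear
    points, flagged by ``degenerate``).  ``n_localizations`` is the raw copy
    number proxy — conversion to molecule numbers belongs to the counting
    module.
    """

    cluster_id: int
    n_localizations: int
    hull_vertices: np.ndarray
    area: float
    perimeter: float
    circularity: float
    centroid: np.ndarray
    max_diameter: float
    degenerate: bool = False


def cluster_morphology(table: LocalizationTable, result: ClusterResult) -> list[ClusterShape]:
    """Convex-hull shape descriptors for every non-noise cluster."""
    if len(result.labels) != len(table):
        raise ValueError("cluster labels do not align with the table rows")
    xy = table.coordinates
    shapes = []
    for cid in range(result.n_clusters):
        members = xy[result.labels == cid]
        centroid = members.mean(axis=0)
        hull = MultiPoint(members).convex_hull
        if hull.geom_type == "Polygon":
            verts = np.asarray(hull.exterior.coords)[:-1]
            area = hull.area
            perimeter = hull.length
            circ = 4.0 * np.pi * area / perimeter ** 2 if perimeter > 0 else np.nan
            degenerate = False
        else:  # point or line: no interior
            verts = np.asarray(hull.coords) if hasattr(hull, "coords") else members
            area, perimeter, circ, degenerate = 0.0, float(hull.length), np.nan, True
        diff = members[:, None, :] - members[None, :, :]
        max_diam = float(np.sqrt((diff ** 2).sum(-1)).max()) if len(members) > 1 else 0.0
        shapes.append(ClusterShape(
            cluster_id=cid, n_localizations=len(members), hull_vertices=verts,
            area=float(area), perimeter=float(perimeter), circularity=float(circ),
            centroid=centroid, max_diameter=max_diam, degenerate=degenerate))
    return shapes
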