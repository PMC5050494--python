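"""Coordinate-based colocalization (CBC) between two localization channels.

For every localization A_i of species A, the local neighbor-density
gradients of species A and species B around A_i are compared over a radius
grid r_j = j·r_max/n_steps:

    D_{A_i,A}(r_j) = N_{A_i,A}(r_j) / N_{A_i,A}(r_max) · r_max² / r_j²
    D_{A_i,B}(r_j) = N_{A_i,B}(r_j) / N_{A_i,B}(r_max) · r_max² / r_j²

(the count around A_i excludes A_i itself in its own channel).  The
Spearman rank correlation S_{A_i} of the two D vectors measures whether
both species' densities rise and fall together around A_i, and is damped
by the distance E_{A_i} to the nearest B localization:

    C_{A_i} = S_{A_i} · exp(−E_{A_i} / r_max)  ∈ [−1, 1]

C ≈ +1 flags perfect colocalization, 0 no correlation, < 0 segregation.
C is undefined (reported as NaN and excluded from summaries) when A_i has
no neighbor of either species within r_max or a D vector is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from .clustering import ClusterResult, dbscan
from .locdata import LocalizationTable


@dataclass
class CBCResult:
    """Per-localization colocalization values for one direction (A→B).

    ``values`` aligns with the rows of the queried table (NaN = undefined);
    ``nn_dist`` holds the nearest-other-channel distances E [nm].
    """

    values: np.ndarray
    nn_dist: np.ndarray
    params: dict

    @property
    def defined(self) -> np.ndarray:
        return self.values[np.isfinite(self.values)]

    @property
    def n_undefined(self) -> int:
        return int(np.sum(~np.isfinite(self.values)))

    def summary(self) -> dict:
        d = self.defined
        return {
            "mean_C": float(np.mean(d)) if len(d) else float("nan"),
            "median_C": float(np.median(d)) if len(d) else float("nan"),
            "n_defined": int(len(d)),
            "n_undefined": self.n_undefined,
        }


def _spearman_rows(da: np.ndarray, db: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation with average-rank ties; NaN for constant rows."""
    ra = rankdata(da, axis=1)
    rb = rankdata(db, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    va = (ra ** 2).sum(axis=1)
    vb = (rb ** 2).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = (ra * rb).sum(axis=1) / np.sqrt(va * vb)
    s[(va <= 0) | (vb <= 0)] = np.nan
    return s


def cbc(table_a: LocalizationTable, table_b: LocalizationTable,
        r_max: float = 300.0, n_steps: int = 10,
        self_colocalization: bool = False) -> CBCResult:
    """Coordinate-based colocalization of channel A against channel B.

    Set ``self_colocalization=True`` when both arguments are the same
    physical table, so that each record's own coordinate is excluded from
    the B channel as well.  The returned values align with ``table_a``; run
    the function again with swapped arguments for the symmetric B→A
    direction.
    """
    if not len(table_a) or not len(table_b):
        raise ValueError("both channels must be non-empty")
    if n_steps < 3:
        raise ValueError("n_steps must be >= 3")
    if r_max <= 0:
        raise ValueError("r_max must be > 0")

    xy_a = table_a.coordinates
    xy_b = table_b.coordinates
    radii = r_max * np.arange(1, n_steps + 1) / n_steps
    tree_a = cKDTree(xy_a)
    tree_b = cKDTree(xy_b)

    n = len(xy_a)
    counts_a = np.zeros((n, n_steps))
    counts_b = np.zeros((n, n_steps))
    nn_dist = np.full(n, np.inf)

    neigh_a = tree_a.query_ball_point(xy_a, r_max)
    neigh_b = tree_b.query_ball_point(xy_a, r_max)
    for i in range(n):
        da = np.hypot(*(xy_a[neigh_a[i]] - xy_a[i]).T) if neigh_a[i] else np.empty(0)
        db = np.hypot(*(xy_b[neigh_b[i]] - xy_a[i]).T) if neigh_b[i] else np.empty(0)
        db_nn = db[db > 0] if self_colocalization else db
        nn_dist[i] = db_nn.min() if len(db_nn) else np.inf
        # a record is never its own neighbor: zero-distance coincidences are
        # excluded from the density counts (in E they count unless self mode)
        da, db = da[da > 0], db[db > 0]
        counts_a[i] = np.searchsorted(np.sort(da), radii, side="right")
        counts_b[i] = np.searchsorted(np.sort(db), radii, side="right")

    # fall back to a full NN query where no B point lies within r_max
    missing = ~np.isfinite(nn_dist)
    if missing.any():
        k = 2 if self_colocalization else 1
        d, _ = tree_b.query(xy_a[missing], k=k)
        nn_dist[missing] = np.atleast_2d(d.T).T[:, -1] if k > 1 else d

    with np.errstate(invalid="ignore", divide="ignore"):
        grad_a = counts_a / counts_a[:, -1:] * (r_max ** 2 / radii ** 2)
        grad_b = counts_b / counts_b[:, -1:] * (r_max ** 2 / radii ** 2)
    undefined = (counts_a[:, -1] == 0) | (counts_b[:, -1] == 0)

    s = _spearman_rows(np.nan_to_num(grad_a), np.nan_to_num(grad_b))
    values = s * np.exp(-nn_dist / r_max)
    values[undefined] = np.nan
    return CBCResult(values=values, nn_dist=nn_dist,
                     params={"r_max": r_max, "n_steps": n_steps,
                             "self_colocalization": self_colocalization})


def interaction_domains(table_a: LocalizationTable, cbc_result: CBCResult,
                        c_threshold: float, eps: float, min_pts: int) -> ClusterResult:
    """Clusters of colocalized localizations ("interaction domains").

    DBSCAN is run on the subset of A localizations whose colocalization
    value reaches ``c_threshold``; the returned labels align with the full
    ``table_a`` (records below threshold are noise).  An empty subset gives
    an empty result, not an error.
    """
    if len(cbc_result.values) != len(table_a):
        raise ValueError("CBC result does not align with the table")
    keep = np.isfinite(cbc_result.values) & (cbc_result.values >= c_threshold)
    labels = np.full(len(table_a), -1, dtype=int)
    if not keep.any():
        return ClusterResult(labels, 0, {"eps": eps, "min_pts": min_pts,
                                         "c_threshold": c_threshold})
    sub = table_a.with_data(table_a.data.loc[keep])
    sub_result = dbscan(sub, eps=eps, min_pts=min_pts)
    labels[np.flatnonzero(keep)] = sub_result.labels
    return ClusterResult(labels, sub_result.n_clusters,
                         {"eps": eps, "min_pts": min_pts, "c_threshold": c_threshold})
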