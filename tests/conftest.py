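"""Shared fixtures and independent brute-force oracles."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from lama import LocalizationTable

DATA_DIR = Path(__file__).parent / "data"


def table_from_xy(xy, frames=0, region=None, **extra) -> LocalizationTable:
    """Wrap an (n, 2) coordinate array as a localization table."""
    xy = np.atleast_2d(np.asarray(xy, dtype=float))
    frames = np.broadcast_to(np.asarray(frames), len(xy))
    data = pd.DataFrame({"x": xy[:, 0], "y": xy[:, 1], "frame": frames})
    for name, values in extra.items():
        data[name] = values
    return LocalizationTable(data, region=region)


@pytest.fixture
def three_row_table() -> LocalizationTable:
    """The minimal worked example: 3 records in 2 frames."""
    return table_from_xy([(100, 200), (110, 210), (500, 500)], frames=[0, 0, 1])


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive O(n²)/O(n³) implementations)
# ---------------------------------------------------------------------------

def dbscan_oracle(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """Brute-force DBSCAN reference.

    Core points = rows with >= min_pts rows (self included) within eps of
    them; clusters = connected components of the core eps-graph, numbered
    by lowest member index; border points join the nearest core point's
    cluster (ties to the lowest index).
    """
    n = len(xy)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    within = d <= eps
    core = within.sum(axis=1) >= min_pts
    comp = -np.ones(n, dtype=int)
    c = 0
    for i in range(n):
        if not core[i] or comp[i] >= 0:
            continue
        stack = [i]
        comp[i] = c
        while stack:
            p = stack.pop()
            for q in range(n):
                if core[q] and comp[q] < 0 and within[p, q]:
                    comp[q] = c
                    stack.append(q)
        c += 1
    labels = np.where(core, comp, -1)
    for i in range(n):
        if core[i]:
            continue
        cand = np.flatnonzero(core & within[i])
        if len(cand):
            labels[i] = comp[cand[np.argmin(d[i, cand])]]
    return labels


def mutual_nn_oracle(pa: np.ndarray, pb: np.ndarray, max_dist: float):
    """Exhaustive mutual-nearest-neighbor pairing."""
    d = np.sqrt(((pa[:, None, :] - pb[None, :, :]) ** 2).sum(-1))
    pairs = []
    for i in range(len(pa)):
        j = int(np.argmin(d[i]))
        if int(np.argmin(d[:, j])) == i and d[i, j] <= max_dist:
            pairs.append((i, j))
    return pairs


def hull_oracle(points: np.ndarray):
    """Convex-hull area and perimeter via scipy's qhull (independent of shapely)."""
    from scipy.spatial import ConvexHull

    hull = ConvexHull(points)
    return hull.volume, hull.area  # in 2-D: volume = area, area = perimeter
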