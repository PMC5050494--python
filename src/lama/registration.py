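"""Channel registration from matched fiducial markers.

Multi-color SMLM images are acquired sequentially or on separate camera
regions, so the color channels are related by a small geometric transform
(shift, slight rotation/scaling, residual affine distortion).  Bright,
persistent emitters (fiducial beads) visible in every channel provide
matched control points from which that transform is estimated by least
squares and then applied to whole localization tables.

The fiducial registration error (FRE) — the RMS residual distance of the
fiducial pairs after transformation — summarizes the registration quality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .exceptions import EstimationError, MatchingError
from .locdata import LocalizationTable

MODELS = ("translation", "similarity", "affine")


@dataclass(frozen=True)
class AffineTransform2D:
    """Mapping ``p -> matrix @ p + offset`` between channel coordinates (nm).

    ``model`` records which family the transform was estimated in:
    translation (matrix = identity), similarity (rotation × isotropic scale)
    or full affine.
    """

    matrix: np.ndarray
    offset: np.ndarray
    model: str = "affine"

    def __post_init__(self):
        m = np.asarray(self.matrix, dtype=float).reshape(2, 2)
        o = np.asarray(self.offset, dtype=float).reshape(2)
        if abs(np.linalg.det(m)) <= 1e-12:
            raise EstimationError("transform matrix is singular")
        if self.model == "translation" and not np.allclose(m, np.eye(2)):
            raise ValueError("translation model requires an identity matrix")
        object.__setattr__(self, "matrix", m)
        object.__setattr__(self, "offset", o)

    @classmethod
    def identity(cls) -> "AffineTransform2D":
        return cls(np.eye(2), np.zeros(2), model="translation")

    def __call__(self, points: np.ndarray) -> np.ndarray:
        points = np.asarray(points, dtype=float)
        return points @ self.matrix.T + self.offset

    def inverse(self) -> "AffineTransform2D":
        inv = np.linalg.inv(self.matrix)
        model = self.model if self.model == "translation" else "affine"
        return AffineTransform2D(inv, -inv @ self.offset, model=model)


@dataclass
class FiducialPairSet:
    """Matched fiducial coordinates: ``points_moving[i] ↔ points_fixed[i]`` (nm)."""

    points_moving: np.ndarray
    points_fixed: np.ndarray

    def __post_init__(self):
        self.points_moving = np.atleast_2d(np.asarray(self.points_moving, dtype=float))
        self.points_fixed = np.atleast_2d(np.asarray(self.points_fixed, dtype=float))
        if self.points_moving.shape != self.points_fixed.shape:
            raise ValueError("moving and fixed point sets must have equal shape")

    def __len__(self) -> int:
        return len(self.points_moving)


_MIN_PAIRS = {"translation": 1, "similarity": 2, "affine": 3}


def estimate_transform(pairs: FiducialPairSet, model: str = "similarity"):
    """Least-squares transform mapping moving onto fixed points.

    Returns ``(transform, fre)`` where *fre* is the RMS residual over the
    fiducials after applying the transform.

    * translation: mean displacement.
    * similarity: closed-form Procrustes solution (rotation + isotropic
      scale + shift); deterministic, no iterative optimizer.
    * affine: linear least squares; requires >= 3 non-collinear points.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    src = pairs.points_moving
    dst = pairs.points_fixed
    n = len(src)
    if n < _MIN_PAIRS[model]:
        raise EstimationError(
            f"{model} registration needs >= {_MIN_PAIRS[model]} pairs, got {n}")

    if model == "translation":
        t = AffineTransform2D(np.eye(2), (dst - src).mean(axis=0), model=model)
    elif model == "similarity":
        mu_s, mu_d = src.mean(axis=0), dst.mean(axis=0)
        sc, dc = src - mu_s, dst - mu_d
        var_s = (sc ** 2).sum() / n
        if var_s <= 0:
            raise EstimationError("all moving points coincide")
        cov = dc.T @ sc / n
        u, s, vt = np.linalg.svd(cov)
        d = np.sign(np.linalg.det(u @ vt)) or 1.0
        s_diag = np.diag([1.0, d])
        rot = u @ s_diag @ vt
        scale = np.trace(np.diag(s) @ s_diag) / var_s
        t = AffineTransform2D(scale * rot, mu_d - scale * rot @ mu_s, model=model)
    else:  # affine
        design = np.hstack([src, np.ones((n, 1))])
        if np.linalg.matrix_rank(design) < 3:
            raise EstimationError("affine registration needs non-collinear points")
        coef, *_ = np.linalg.lstsq(design, dst, rcond=None)
        t = AffineTransform2D(coef[:2].T, coef[2], model=model)

    residuals = t(src) - dst
    fre = float(np.sqrt((residuals ** 2).sum(axis=1).mean()))
    return t, fre


def apply_transform(table: LocalizationTable, t: AffineTransform2D) -> LocalizationTable:
    """Map the x/y coordinates of a table through a transform.

    All other fields are unchanged; the region becomes the bounding box of
    the four transformed region corners.
    """
    data = table.data.copy()
    xy = t(table.coordinates) if len(table) else np.empty((0, 2))
    data["x"], data["y"] = xy[:, 0], xy[:, 1]
    x0, y0, x1, y1 = table.region
    corners = t(np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]]))
    region = (corners[:, 0].min(), corners[:, 1].min(),
              corners[:, 0].max(), corners[:, 1].max())
    return table.with_data(data, region=region)


def match_fiducials(table_a: LocalizationTable, table_b: LocalizationTable,
                    max_dist: float) -> FiducialPairSet:
    """Mutual-nearest-neighbor fiducial pairing between two channels.

    A pair (a, b) is kept when b is a's nearest neighbor in B, a is b's
    nearest neighbor in A, and their distance is <= ``max_dist``; each point
    is used at most once.  Raises :class:`MatchingError` when no pair
    qualifies.
    """
    if not len(table_a) or not len(table_b):
        raise MatchingError("both tables must be non-empty")
    pa, pb = table_a.coordinates, table_b.coordinates
    d_ab, j_ab = cKDTree(pb).query(pa)        # nearest B for each A
    _, j_ba = cKDTree(pa).query(pb)           # nearest A for each B
    idx_a = np.arange(len(pa))
    mutual = (j_ba[j_ab] == idx_a) & (d_ab <= max_dist)
    if not mutual.any():
        raise MatchingError(f"no mutual-nearest pairs within {max_dist} nm")
    return FiducialPairSet(pa[mutual], pb[j_ab[mutual]])
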