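"""Fourier ring correlation (FRC) resolution estimation.

The localization list is split into two statistically independent halves,
each rendered as a 2-D count histogram.  The correlation of the two images
over rings of constant spatial frequency,

    FRC(q) = Re Σ_ring F1·conj(F2) / sqrt(Σ_ring |F1|² · Σ_ring |F2|²),

decays from ≈1 at low frequency to ≈0 where the two halves share no
reproducible structure; the resolution is 1/q* at the first crossing of
the fixed threshold 1/7.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .locdata import LocalizationTable


@dataclass
class FRCCurve:
    """FRC values over a spatial-frequency grid.

    ``spatial_frequency`` is in 1/nm (ring centers); ``resolution`` [nm] is
    None when the curve never crosses the threshold.  ``split_mode`` and
    ``seed`` record how the halves were formed.
    """

    spatial_frequency: np.ndarray
    frc: np.ndarray
    threshold: float
    resolution: float | None
    split_mode: str
    pixel_size_img: float
    seed: int | None


def render_histogram(table: LocalizationTable, pixel_size_img: float) -> np.ndarray:
    """2-D count image of the localizations over the table's region.

    Pixel (row, col) covers ``[y0 + row·p, y0 + (row+1)·p) × [x0 + col·p, …)``;
    the image sums to the number of localizations (records on the far edges
    are clipped into the last pixel so none is lost).
    """
    if pixel_size_img <= 0:
        raise ValueError("pixel_size_img must be > 0")
    x0, y0, x1, y1 = table.region
    nx = max(int(np.ceil((x1 - x0) / pixel_size_img)), 1)
    ny = max(int(np.ceil((y1 - y0) / pixel_size_img)), 1)
    if not len(table):
        return np.zeros((ny, nx))
    ix = np.clip(((table.data["x"] - x0) / pixel_size_img).astype(int), 0, nx - 1)
    iy = np.clip(((table.data["y"] - y0) / pixel_size_img).astype(int), 0, ny - 1)
    img = np.zeros((ny, nx))
    np.add.at(img, (iy, ix), 1.0)
    return img


def split_halves(table: LocalizationTable, mode: str = "random_halves",
                 seed: int | None = None, block_size: int = 50):
    """Split a table into two halves for FRC.

    ``random_halves`` assigns each record by an independent fair coin
    (seeded).  ``odd_even_blocks`` alternates blocks of ``block_size``
    frames, which keeps repeated localizations of one blinking emitter in
    the same half and avoids spuriously correlated halves.
    """
    if mode == "random_halves":
        rng = np.random.default_rng(seed)
        pick = rng.random(len(table)) < 0.5
    elif mode == "odd_even_blocks":
        pick = (table.frames // block_size) % 2 == 0
    else:
        raise ValueError(f"unknown split mode {mode!r}")
    a = table.with_data(table.data.loc[pick])
    b = table.with_data(table.data.loc[~pick])
    return a, b


def _ring_sums(values: np.ndarray, ring_index: np.ndarray, n_rings: int) -> np.ndarray:
    return np.bincount(ring_index.ravel(), weights=values.ravel(), minlength=n_rings)


def frc_from_images(img1: np.ndarray, img2: np.ndarray, pixel_size_img: float):
    """FRC curve of two equally shaped images; returns (q [1/nm], frc)."""
    if img1.shape != img2.shape:
        raise ValueError("images must have equal shape")
    size = 1 << int(np.ceil(np.log2(max(img1.shape + (2,)))))  # square power of two
    pad1 = np.zeros((size, size))
    pad2 = np.zeros((size, size))
    pad1[:img1.shape[0], :img1.shape[1]] = img1
    pad2[:img2.shape[0], :img2.shape[1]] = img2
    f1 = np.fft.fftshift(np.fft.fft2(pad1))
    f2 = np.fft.fftshift(np.fft.fft2(pad2))
    c = size // 2
    yy, xx = np.indices((size, size))
    ring = np.round(np.hypot(yy - c, xx - c)).astype(int)
    n_rings = size // 2
    valid = ring < n_rings
    ring = np.where(valid, ring, 0)
    cross = np.where(valid, (f1 * np.conj(f2)).real, 0.0)
    p1 = np.where(valid, np.abs(f1) ** 2, 0.0)
    p2 = np.where(valid, np.abs(f2) ** 2, 0.0)
    num = _ring_sums(cross, ring, n_rings)
    den = np.sqrt(_ring_sums(p1, ring, n_rings) * _ring_sums(p2, ring, n_rings))
    with np.errstate(invalid="ignore", divide="ignore"):
        frc = np.where(den > 0, num / den, 0.0)
    q = np.arange(n_rings) / (size * pixel_size_img)
    return q, frc


def _smooth(y: np.ndarray, width: int = 3) -> np.ndarray:
    kernel = np.ones(width) / width
    pad = width // 2
    padded = np.concatenate([y[:1].repeat(pad), y, y[-1:].repeat(pad)])
    return np.convolve(padded, kernel, mode="valid")


def _threshold_crossing(q: np.ndarray, frc: np.ndarray, threshold: float):
    """First downward crossing of the threshold, linearly interpolated in q."""
    below = frc < threshold
    idx = np.flatnonzero(below[1:] & ~below[:-1])
    if len(idx) == 0:
        return None
    i = idx[0]
    f0, f1 = frc[i], frc[i + 1]
    frac = (f0 - threshold) / (f0 - f1) if f1 != f0 else 0.0
    q_star = q[i] + frac * (q[i + 1] - q[i])
    return float(1.0 / q_star) if q_star > 0 else None


def frc_curve(table: LocalizationTable, pixel_size_img: float = 10.0,
              split_mode: str = "random_halves", seed: int | None = None,
              threshold: float = 1.0 / 7.0,
              _halves: tuple | None = None) -> FRCCurve:
    """FRC resolution estimate of a localization table.

    The table is split into halves (see :func:`split_halves`), rendered at
    ``pixel_size_img`` nm/pixel on the table's region, and correlated ring
    by ring; the curve is smoothed with a 3-ring moving average before the
    threshold crossing is located.  ``_halves`` is a test hook to bypass the
    split with two prepared tables.

    Raises ``ValueError`` for fewer than 2 localizations.
    """
    if len(table) < 2 and _halves is None:
        raise ValueError("FRC needs at least 2 localizations")
    if _halves is not None:
        half_a, half_b = _halves
    else:
        half_a, half_b = split_halves(table, mode=split_mode, seed=seed)
    region = table.region
    img1 = render_histogram(half_a.with_data(half_a.data, region=region), pixel_size_img)
    img2 = render_histogram(half_b.with_data(half_b.data, region=region), pixel_size_img)
    q, raw = frc_from_images(img1, img2, pixel_size_img)
    smoothed = _smooth(raw, 3)
    resolution = _threshold_crossing(q[1:], smoothed[1:], threshold)
    return FRCCurve(spatial_frequency=q, frc=smoothed, threshold=threshold,
                    resolution=resolution, split_mode=split_mode,
                    pixel_size_img=pixel_size_img, seed=seed)
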