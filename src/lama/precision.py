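"""Localization-precision estimation.

Two complementary routes are provided:

* **Photon statistics** — closed-form theoretical precision of a single
  fitted emitter from its photon count N, PSF width s, camera pixel size a
  and background noise b (Thompson-style error propagation and the
  Mortensen maximum-likelihood variant).

* **NeNA (nearest-neighbor analysis)** — experimental precision from the
  data themselves: a fluorophore that stays on across consecutive frames is
  localized repeatedly, so the distance between its frame-f and frame-f+1
  localizations follows a Rayleigh-type distribution whose scale is
  sqrt(2)·sigma_loc.  Fitting the pooled consecutive-frame nearest-neighbor
  distance histogram yields the effective localization precision of the
  whole measurement, drift and all.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit
from scipy.spatial import cKDTree

from .exceptions import EstimationError, FitError
from .locdata import LocalizationTable


@dataclass(frozen=True)
class PhotonModelInput:
    """Per-molecule quantities entering the closed-form precision formulas.

    photons
        Detected photon count N (> 0).
    psf_sigma
        Gaussian PSF standard deviation s [nm] (> 0).
    pixel_size
        Camera pixel size a [nm] (> 0).
    background
        Background noise standard deviation b [photons/pixel] (>= 0).
    """

    photons: float
    psf_sigma: float
    pixel_size: float
    background: float = 0.0

    def __post_init__(self):
        if not (self.photons > 0 and self.psf_sigma > 0 and self.pixel_size > 0):
            raise ValueError("photons, psf_sigma and pixel_size must be > 0")
        if self.background < 0:
            raise ValueError("background must be >= 0")


def precision_thompson(inp: PhotonModelInput) -> float:
    """Thompson–Larson–Webb localization precision [nm].

    sigma² = s²/N + a²/(12 N) + 8π s⁴ b² / (a² N²):
    photon shot noise, pixelation noise and background noise in quadrature.
    """
    n, s, a, b = inp.photons, inp.psf_sigma, inp.pixel_size, inp.background
    return float(np.sqrt(s * s / n + a * a / (12.0 * n)
                         + 8.0 * np.pi * s ** 4 * b * b / (a * a * n * n)))


def precision_mortensen(inp: PhotonModelInput) -> float:
    """Mortensen MLE localization precision [nm].

    With sa² = s² + a²/12:  sigma² = (sa²/N) · (16/9 + 8π sa² b² / (N a²)).
    The 16/9 factor is the excess variance of least-squares-equivalent
    estimation with pixelated, background-corrupted data; at b = 0 this is
    (4/3)·sqrt(sa²/N).
    """
    n, s, a, b = inp.photons, inp.psf_sigma, inp.pixel_size, inp.background
    sa2 = s * s + a * a / 12.0
    return float(np.sqrt(sa2 / n * (16.0 / 9.0 + 8.0 * np.pi * sa2 * b * b / (n * a * a))))


# ---------------------------------------------------------------------------
# NeNA
# ---------------------------------------------------------------------------

@dataclass
class NenaResult:
    """Outcome of the nearest-neighbor precision fit.

    sigma_loc
        Fitted localization precision [nm].
    fit_components
        Fitted model parameters: amplitude of the same-molecule term and the
        linear background coefficient.
    histogram
        ``(bin_centers [nm], densities)`` of the consecutive-frame NN
        distances the fit was run on.
    n_pairs
        Number of distances entering the histogram.
    """

    sigma_loc: float
    fit_components: dict
    histogram: tuple
    n_pairs: int


def _nena_same_molecule(d, sigma):
    """Distance density of two localizations of one molecule, unit amplitude.

    Each localization errs by an isotropic Gaussian of width sigma, so the
    separation d is Rayleigh with scale sqrt(2)·sigma:
    p(d) = d/(2 sigma²) · exp(−d²/(4 sigma²)); integrates to 1 on [0, ∞).
    """
    s2 = 2.0 * sigma * sigma
    return d / s2 * np.exp(-d * d / (2.0 * s2))


def _nena_model(d, sigma, amplitude, slope):
    # same-molecule peak + linear term for uncorrelated near neighbors
    return amplitude * _nena_same_molecule(d, sigma) + slope * d


def consecutive_frame_distances(table: LocalizationTable, max_dist: float = 500.0) -> np.ndarray:
    """Nearest-neighbor distance from every frame-f localization to frame f+1.

    Only distances <= ``max_dist`` are kept.  This is the raw material of
    the NeNA precision estimate.
    """
    frames = table.frames
    xy = table.coordinates
    order = np.unique(frames)
    by_frame = {f: xy[frames == f] for f in order}
    dists = []
    for f in order:
        nxt = by_frame.get(f + 1)
        if nxt is None or not len(nxt):
            continue
        d, _ = cKDTree(nxt).query(by_frame[f], distance_upper_bound=max_dist)
        dists.append(d[np.isfinite(d)])
    if not dists:
        return np.empty(0)
    return np.concatenate(dists)


def nena(table: LocalizationTable, max_dist: float = 500.0,
         bin_width: float = 5.0) -> NenaResult:
    """Experimental localization precision from consecutive-frame distances.

    The normalized distance histogram is fitted with
    ``A · d/(2σ²) · exp(−d²/(4σ²)) + c·d`` by nonlinear least squares;
    ``sigma_loc`` is the fitted σ.  Requires the table to span at least two
    frames; warns below 100 usable distances and raises
    :class:`EstimationError` when a fit is impossible.
    """
    if len(np.unique(table.frames)) < 2:
        raise EstimationError("NeNA needs localizations in at least two frames")
    d = consecutive_frame_distances(table, max_dist=max_dist)
    if len(d) < 10:
        raise EstimationError(
            f"only {len(d)} consecutive-frame distances within {max_dist} nm")
    if len(d) < 100:
        import warnings
        warnings.warn(f"NeNA fit on only {len(d)} distances; estimate may be unstable")

    edges = np.arange(0.0, max_dist + bin_width, bin_width)
    density, edges = np.histogram(d, bins=edges, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # initialize sigma from the histogram mode: Rayleigh mode = sqrt(2)·sigma
    sigma0 = max(centers[np.argmax(density)] / np.sqrt(2.0), bin_width / 2.0)
    p0 = (sigma0, 1.0, 0.0)
    bounds = ([1e-3, 0.0, 0.0], [max_dist / 2.0, np.inf, np.inf])
    try:
        popt, _ = curve_fit(_nena_model, centers, density, p0=p0, bounds=bounds,
                            maxfev=20000)
    except RuntimeError as err:
        raise FitError("NeNA fit did not converge", diagnostics=str(err)) from err
    sigma, amplitude, slope = popt
    return NenaResult(sigma_loc=float(sigma),
                      fit_components={"amplitude": float(amplitude),
                                      "background_slope": float(slope)},
                      histogram=(centers, density),
                      n_pairs=int(len(d)))
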