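"""Ground-truth SMLM data generation.

Synthetic localization tables with known ground truth back every analysis
in this package: CSR (complete spatial randomness) and Gaussian-cluster
point patterns, static emitters re-localized frame after frame (the NeNA
fixture), geometric blinking with incomplete labeling (the counting
fixture), and two-color samples with a known channel transform, fiducial
markers and a controllable colocalized fraction (registration and CBC
fixtures).

All generators are deterministic given their seed and expose the ground
truth they drew, so every analysis module has a recovery test.  Molecule
counts are fixed-n (binomial placement) rather than Poisson so tests are
exact on counts.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .locdata import LocalizationTable
from .registration import AffineTransform2D

DEFAULT_REGION = (0.0, 0.0, 2000.0, 2000.0)


@dataclass
class SimulationConfig:
    """Knobs of the ground-truth generator (lengths in nm).

    The defaults describe a typical dSTORM-scale experiment: a 2×2 µm
    field, 1000 molecules, 50-nm clusters, 10-nm localization precision,
    blinking probability 0.3 and full labeling.
    """

    region: tuple = DEFAULT_REGION
    n_molecules: int = 1000
    pattern: str = "csr"                 # csr | gaussian_clusters | segregated_halves | filament
    n_clusters: int = 5
    sigma_c: float = 50.0                # cluster spread
    sigma_loc: float = 10.0              # localization noise per axis
    frames: int = 1000
    q: float = 0.3                       # blinking probability
    dark_tolerance: int = 1
    p_label: float = 1.0
    colocalized_fraction: float = 0.5
    jitter: float = 10.0                 # A↔B colocalization jitter
    channel_transform: AffineTransform2D | None = None
    n_fiducials: int = 8
    fiducial_photons: float = 20000.0
    mean_photons: float = 1000.0
    seed: int = 0

    def __post_init__(self):
        x0, y0, x1, y1 = self.region
        if not (x1 > x0 and y1 > y0):
            raise ValueError("region must have positive width and height")
        if not (0 <= self.q < 1 and 0 < self.p_label <= 1
                and 0 <= self.colocalized_fraction <= 1):
            raise ValueError("probability parameters out of range")
        if self.sigma_loc < 0 or self.sigma_c <= 0 or self.jitter < 0:
            raise ValueError("lengths must be non-negative (sigma_c > 0)")


def _rng(config_or_seed) -> np.random.Generator:
    seed = getattr(config_or_seed, "seed", config_or_seed)
    return np.random.default_rng(seed)


def _uniform_points(rng, region, n):
    x0, y0, x1, y1 = region
    return np.column_stack([rng.uniform(x0, x1, n), rng.uniform(y0, y1, n)])


@dataclass
class GroundTruth:
    """True molecule positions plus pattern metadata."""

    positions: np.ndarray
    pattern: str
    cluster_centers: np.ndarray | None = None
    cluster_assignment: np.ndarray | None = None


def simulate_points(config: SimulationConfig, rng=None) -> GroundTruth:
    """Draw ground-truth molecule positions for the configured pattern.

    csr: fixed-n uniform over the region.  gaussian_clusters: centers
    uniform, members isotropic Gaussian(sigma_c) clipped to the region.
    segregated_halves: uniform over the left half (the matching right-half
    channel comes from :func:`simulate_two_color`).  filament: points
    spread along a diagonal sine curve with 5-nm transverse width.
    """
    rng = rng or _rng(config)
    region = config.region
    n = config.n_molecules
    x0, y0, x1, y1 = region

    if config.pattern == "csr":
        return GroundTruth(_uniform_points(rng, region, n), "csr")

    if config.pattern == "gaussian_clusters":
        centers = _uniform_points(rng, region, config.n_clusters)
        assignment = rng.integers(0, config.n_clusters, n)
        pts = centers[assignment] + rng.normal(0.0, config.sigma_c, (n, 2))
        pts[:, 0] = np.clip(pts[:, 0], x0, np.nextafter(x1, x0))
        pts[:, 1] = np.clip(pts[:, 1], y0, np.nextafter(y1, y0))
        return GroundTruth(pts, "gaussian_clusters", centers, assignment)

    if config.pattern == "segregated_halves":
        half = (x0, y0, (x0 + x1) / 2.0, y1)
        return GroundTruth(_uniform_points(rng, half, n), "segregated_halves")

    if config.pattern == "filament":
        t = rng.uniform(0.0, 1.0, n)
        w, h = x1 - x0, y1 - y0
        backbone = np.column_stack([
            x0 + t * w,
            y0 + h * (0.5 + 0.25 * np.sin(2 * np.pi * t)),
        ])
        pts = backbone + rng.normal(0.0, 5.0, (n, 2))
        return GroundTruth(pts, "filament")

    raise ValueError(f"unknown pattern {config.pattern!r}")


def _photons(rng, n, mean):
    # lognormal with sigma 0.3, median chosen so the mean matches
    sigma = 0.3
    return rng.lognormal(np.log(mean) - sigma ** 2 / 2.0, sigma, n)


def simulate_localizations(truth: GroundTruth, config: SimulationConfig,
                           rng=None) -> LocalizationTable:
    """Blinking localization table from ground-truth molecules.

    Each labeled molecule (labeling probability ``p_label``) produces
    1 + Geometric(q) on-events; every event is localized in one random
    frame with isotropic Gaussian coordinate noise ``sigma_loc`` per axis
    and a lognormal photon count.  Frames are drawn uniformly, so the table
    carries realistic frame structure for the event-merging step of the
    counting workflow (events closer than the dark tolerance in the same
    molecule can fuse, exactly as in real data).
    """
    rng = rng or _rng(config)
    pos = truth.positions
    labeled = rng.random(len(pos)) < config.p_label
    rows_xy, rows_frame, rows_mol = [], [], []
    for i in np.flatnonzero(labeled):
        # on-events = 1 + Geometric(q) re-activations; numpy's geometric(p)
        # counts trials to first success, which is exactly that with p = 1−q
        n_events = int(rng.geometric(1.0 - config.q))
        frames = np.sort(rng.choice(config.frames, size=min(n_events, config.frames),
                                    replace=False))
        for f in frames:
            rows_xy.append(pos[i] + rng.normal(0.0, config.sigma_loc, 2))
            rows_frame.append(f)
            rows_mol.append(i)
    if rows_xy:
        xy = np.asarray(rows_xy)
    else:
        xy = np.empty((0, 2))
    data = pd.DataFrame({
        "x": xy[:, 0] if len(xy) else [],
        "y": xy[:, 1] if len(xy) else [],
        "frame": np.asarray(rows_frame, dtype=int),
        "photons": _photons(rng, len(rows_frame), config.mean_photons),
        "molecule_id": np.asarray(rows_mol, dtype=int),
    })
    return LocalizationTable(data, region=config.region)


def simulate_static_emitters(n_emitters: int, n_frames: int, sigma_loc: float,
                             region=DEFAULT_REGION, seed: int = 0) -> LocalizationTable:
    """Emitters localized in *every* frame with fresh Gaussian noise.

    This is the NeNA fixture: each emitter contributes ``n_frames − 1``
    consecutive-frame distance samples whose true underlying precision is
    ``sigma_loc``.
    """
    rng = np.random.default_rng(seed)
    pos = _uniform_points(rng, region, n_emitters)
    reps = np.repeat(pos, n_frames, axis=0)
    noise = rng.normal(0.0, sigma_loc, reps.shape)
    frames = np.tile(np.arange(n_frames), n_emitters)
    data = pd.DataFrame({"x": reps[:, 0] + noise[:, 0],
                         "y": reps[:, 1] + noise[:, 1],
                         "frame": frames,
                         "molecule_id": np.repeat(np.arange(n_emitters), n_frames)})
    return LocalizationTable(data, region=region)


def simulate_blink_counts(n_molecules: int, m: int, q: float, p_label: float = 1.0,
                          seed: int = 0) -> np.ndarray:
    """Ground-truth blink counts of n m-mers: sum of geometric counts over
    the Binomial(m, p_label) active labels, conditioned on >= 1 label."""
    rng = np.random.default_rng(seed)
    counts = np.empty(n_molecules, dtype=int)
    for i in range(n_molecules):
        k = 0
        while k == 0:
            k = rng.binomial(m, p_label)
        counts[i] = (rng.geometric(1.0 - q, k) - 1).sum()
    return counts


@dataclass
class TwoColorSample:
    """Two-channel sample plus its ground truth.

    ``table_b`` is expressed in the distorted B-channel frame (the true
    transform maps B-channel coordinates onto the A frame, i.e. it is what
    registration should recover with B as the moving channel).
    """

    table_a: LocalizationTable
    table_b: LocalizationTable
    fiducials_a: np.ndarray
    fiducials_b: np.ndarray
    true_transform: AffineTransform2D
    colocalized_pairs: np.ndarray  # (index into A molecules, index into B molecules)
    positions_a: np.ndarray = field(repr=False, default=None)
    positions_b: np.ndarray = field(repr=False, default=None)


def simulate_two_color(config: SimulationConfig) -> TwoColorSample:
    """Two-color sample with fiducials, channel distortion and partial
    colocalization.

    A fraction ``colocalized_fraction`` of the B molecules sits at A
    molecule positions (plus isotropic ``jitter``); the rest are
    independent CSR.  Both molecule sets and the shared fiducial markers
    are localized with ``sigma_loc`` noise; B-channel coordinates are then
    pushed through the *inverse* of ``channel_transform`` so that applying
    ``channel_transform`` (or the estimate recovered from the fiducials)
    registers B back onto A.  Fiducials appear in each of ``frames`` frames
    with probability 0.95 and carry ``fiducial_photons`` photons, so a
    photon filter separates them from ordinary molecules.
    """
    rng = _rng(config)
    true_t = config.channel_transform or AffineTransform2D.identity()
    inv_t = true_t.inverse()
    x0, y0, x1, y1 = config.region

    truth_a = simulate_points(config, rng=rng)
    pos_a = truth_a.positions
    n_b = config.n_molecules
    n_coloc = int(round(config.colocalized_fraction * n_b))
    idx_a = rng.choice(len(pos_a), size=n_coloc, replace=False) if n_coloc else np.empty(0, int)
    coloc = pos_a[idx_a] + (rng.normal(0.0, config.jitter, (n_coloc, 2))
                            if config.jitter > 0 else 0.0)
    if config.pattern == "segregated_halves":
        right_half = ((x0 + x1) / 2.0, y0, x1, y1)
        indep = _uniform_points(rng, right_half, n_b - n_coloc)
    else:
        indep = _uniform_points(rng, config.region, n_b - n_coloc)
    pos_b = np.vstack([coloc, indep])
    pairs = np.column_stack([idx_a, np.arange(n_coloc)])

    fid = _uniform_points(rng, (x0 + 100, y0 + 100, x1 - 100, y1 - 100),
                          config.n_fiducials)

    def channel_table(mol_pos, fid_pos, to_channel):
        rows = []
        mol_noise = (rng.normal(0.0, config.sigma_loc, mol_pos.shape)
                     if config.sigma_loc > 0 else 0.0)
        mol_xy = mol_pos + mol_noise
        mol = pd.DataFrame({"x": mol_xy[:, 0], "y": mol_xy[:, 1],
                            "frame": rng.integers(0, config.frames, len(mol_pos)),
                            "photons": _photons(rng, len(mol_pos), config.mean_photons)})
        rows.append(mol)
        for p in fid_pos:
            present = rng.random(config.frames) < 0.95
            f = np.flatnonzero(present)
            noise = (rng.normal(0.0, config.sigma_loc / 3.0, (len(f), 2))
                     if config.sigma_loc > 0 else np.zeros((len(f), 2)))
            rows.append(pd.DataFrame({
                "x": p[0] + noise[:, 0], "y": p[1] + noise[:, 1], "frame": f,
                "photons": _photons(rng, len(f), config.fiducial_photons)}))
        df = pd.concat(rows, ignore_index=True)
        if to_channel is not None:
            xy = to_channel(df[["x", "y"]].to_numpy())
            df["x"], df["y"] = xy[:, 0], xy[:, 1]
        return df

    df_a = channel_table(pos_a, fid, None)
    df_b = channel_table(pos_b, fid, inv_t)
    corners = inv_t(np.array([[x0, y0], [x1, y0], [x0, y1], [x1, y1]]))
    region_b = (corners[:, 0].min(), corners[:, 1].min(),
                corners[:, 0].max(), corners[:, 1].max())
    return TwoColorSample(
        table_a=LocalizationTable(df_a, region=config.region),
        table_b=LocalizationTable(df_b, region=region_b),
        fiducials_a=fid, fiducials_b=inv_t(fid), true_transform=true_t,
        colocalized_pairs=pairs, positions_a=pos_a, positions_b=pos_b)
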