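# lama — quantitative analysis of single-molecule localization microscopy data

Single-molecule localization microscopy (SMLM: dSTORM, PALM and relatives)
reconstructs super-resolved images from lists of single-fluorophore
detections. The raw product of an SMLM experiment is therefore not an image
but a **localization table** — x/y positions (nanometers), frame indices,
photon counts and PSF widths — and the biologically interesting quantities
(cluster sizes, copy numbers, protein–protein colocalization, complex
stoichiometry, achieved resolution) are properties of this point pattern,
not of any rendered picture.

`lama` is a library + CLI for extracting those quantities. It consumes
localization tables as written by common localization software (rapidSTORM
space-separated `.txt`, ThunderSTORM `.csv`) and provides:

| module | what it computes |
|---|---|
| `lama.locdata` | table reading/writing, unit and frame-base normalization, ROI/frame/photon filtering |
| `lama.registration` | 2-D channel registration (translation / similarity / affine) from matched fiducial markers, with the fiducial registration error (FRE) |
| `lama.precision` | theoretical localization precision from photon statistics (Thompson, Mortensen) and experimental precision from the consecutive-frame nearest-neighbor distance distribution (NeNA) |
| `lama.clustering` | Ripley K/L/H second-order statistics with translation edge correction, deterministic DBSCAN and OPTICS, per-cluster convex-hull morphology |
| `lama.colocalization` | coordinate-based colocalization (CBC) and CBC×DBSCAN interaction domains |
| `lama.frc` | Fourier-ring-correlation resolution (1/7 threshold) |
| `lama.counting` | molecular stoichiometry from photoswitching kinetics (negative-binomial blink-count model) |
| `lama.simulate` | ground-truth generators (CSR, Gaussian clusters, filaments, blinking, two-color) backing every analysis with a recovery test |

## The statistics at the core

**Ripley functions.** For n points in a window of area A,
K̂(r) = A/(n(n−1)) · Σ_{i≠j} e_ij · 1(d_ij ≤ r), with translation edge
correction e_ij = A/((w−|Δx|)(h−|Δy|)) for a w×h rectangle. Under complete
spatial randomness K(r) = πr², so H(r) = √(K/π) − r ≈ 0; H peaks near the
characteristic cluster scale.

**DBSCAN (deterministic convention).** A point is *core* when ≥ `min_pts`
points (itself included) lie within `eps`; clusters are the connected
components of the core-point eps-graph, numbered by lowest member row;
border points join their *nearest* core point's cluster. The OPTICS eps-cut
uses the same convention, so both produce identical partitions.

**CBC.** For each localization A_i the rank correlation (Spearman) of the
distance-scaled neighbor-density curves of species A and B around A_i,
damped by the nearest-B distance: C_i = S_i · exp(−E_i/r_max) ∈ [−1, 1].

**NeNA.** Repeated localizations of one emitter in consecutive frames are
separated by a Rayleigh-distributed distance with scale √2·σ_loc; fitting
p(d) = A·d/(2σ²)·exp(−d²/(4σ²)) + c·d to the pooled distance histogram
gives the experimental precision σ_loc.

**Counting.** A fluorophore's number of re-activations is geometric with
blinking probability q; an m-mer's blink count is negative-binomial,
P(N|m,q) = C(N+m−1, N) q^N (1−q)^m. q is calibrated on a monomer standard
(q̂ = N̄/(1+N̄)) and m recovered by a likelihood scan, optionally with a
zero-truncated Binomial(m, p_label) mixture for incomplete labeling.

**FRC.** The localization list is split into two independent halves,
rendered as 2-D histograms, and correlated ring-by-ring in Fourier space;
the resolution is 1/q* where the smoothed curve first drops below 1/7.

## Worked example

```python
import numpy as np
from lama import *

cfg = SimulationConfig(seed=42, pattern="gaussian_clusters", n_molecules=2000,
                       n_clusters=8, sigma_c=40.0, sigma_loc=10.0, q=0.3)
table = simulate_localizations(simulate_points(cfg), cfg)
print("n localizations:", len(table))

curve = ripley(table, np.arange(10, 410, 10))
print("H peak at r =", curve.radii[np.argmax(curve.H)], "nm")

res = dbscan(table, eps=40.0, min_pts=8)
shapes = cluster_morphology(table, res)
big = max(shapes, key=lambda s: s.n_localizations)
print("clusters:", res.n_clusters,
      "| largest: n =", big.n_localizations,
      "area =", round(big.area), "nm2, circularity =", round(big.circularity, 3))
```

prints

```
n localizations: 2849
H peak at r = 120.0 nm
clusters: 7 | largest: n = 704 area = 78574 nm2, circularity = 0.857
```

2000 molecules in 8 clusters of σ_c = 40 nm produce 2849 localizations
(each molecule blinks a geometric number of times at q = 0.3). The H
function peaks at 120 nm — a small multiple of the cluster radius — and
DBSCAN recovers 7 of the 8 seeded clusters (two overlap), the largest
holding 704 localizations with near-circular shape (4πA/P² = 0.86).

Precision, from photon statistics and from the data themselves:

```python
inp = PhotonModelInput(photons=1500, psf_sigma=140, pixel_size=100, background=12)
precision_thompson(inp)   # 8.68 nm
precision_mortensen(inp)  # 9.56 nm

t = simulate_static_emitters(100, 101, 12.0, region=(0, 0, 10000, 10000), seed=4)
nena(t).sigma_loc         # 11.93 nm  (truth: 12 nm, from 10,000 NN pairs)
```

Stoichiometry from blinking statistics:

```python
mono = BlinkCountDistribution.from_events(simulate_blink_counts(2000, m=1, q=0.35, seed=9))
q_hat = calibrate_q(mono)                                    # 0.345
dimers = BlinkCountDistribution.from_events(simulate_blink_counts(2000, m=2, q=0.35, seed=3))
fit_oligomer(dimers, q=q_hat, m_candidates=range(1, 7)).m_hat  # 2
```

The same pipelines are available from the shell:

```bash
lama simulate --pattern clusters --n 2000 --seed 42 -o clusters.csv
lama ripley clusters.csv --rmax 400 --dr 10
lama cluster clusters.csv --algo dbscan --eps 40 --min-pts 8 --shapes shapes.csv
lama precision --mode thompson --photons 1500 --psf-sigma 140 --background 12
lama frc clusters.csv --pixel 10 --seed 1
```

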