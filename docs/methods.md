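# Methods

This note documents the models, conventions and numerical choices behind
each analysis, what the synthetic-data generators do and do not emulate,
and the known limitations.

## Data model and conventions

All coordinates are nanometers with the origin at the top-left of the
field, x rightward, y downward; frames are 0-based internally. rapidSTORM
files are already 0-based; ThunderSTORM counts frames from 1 and is shifted
on read. Pixel-unit coordinates are converted using the reader's
`pixel_size_nm`; a unit declared in the file header overrides the config
default. Unknown columns are carried through untouched.

The observation *region* defaults to the tight bounding box of the data.
Analyses that integrate over the window — Ripley edge correction, FRC
rendering — read the region from the table, so when the structure
under-fills the field the region should be widened explicitly (the
simulators always stamp the true generation window).

Rectangular ROI filtering uses the half-open convention [x0,x1)×[y0,y1) so
that adjacent tiles partition points uniquely; polygon ROIs (shapely) are
boundary-inclusive.

## Registration

Translation is the mean displacement; similarity is the closed-form
Procrustes/Umeyama solution (SVD of the cross-covariance, isotropic scale);
affine is linear least squares. All three are deterministic — no iterative
optimizer, nothing to tune. Minimum pair counts: 1 / 2 / 3 non-collinear.
Fiducial matching is mutual-nearest-neighbor with a distance cap: adequate
for sparse beads and exactly reproducible by exhaustive search, unlike
assignment-problem solvers whose optima can be non-unique. FRE is the RMS
residual over fiducials after transformation; for n pairs, k model
parameters and isotropic noise σ its expectation is ≈ σ·√(2 − k/n).

## Localization precision

Photon-statistics formulas, with N photons, PSF width s, pixel size a,
background standard deviation b:

* Thompson: σ² = s²/N + a²/(12N) + 8π s⁴ b²/(a²N²)
* Mortensen (MLE): σ² = (s² + a²/12)/N · (16/9 + 8π (s²+a²/12) b²/(N a²))

Both are strictly decreasing in N and increasing in b; Mortensen exceeds
Thompson at b = 0 by ≈ 4/3.

NeNA pools, for every localization in frame f, the distance to its nearest
neighbor in frame f+1 (cap 500 nm, histogram bin 5 nm) and fits

p(d) = A · d/(2σ²) · exp(−d²/(4σ²)) + c·d

by bounded nonlinear least squares (σ ∈ (0, max_dist/2], σ₀ = histogram
mode/√2, A₀ = 1, c₀ = 0). The first term is the exact distance density of
two independent isotropic Gaussian localizations of one molecule
(normalized to 1); the linear term absorbs uncorrelated near neighbors,
whose density grows ∝ d at short range. A fuller multi-term background
correction exists in the literature; the linear term is deliberately the
simplest model that is unbiased on sparse data, and the recovery tests
(σ ∈ {5,10,25,50} nm, 10⁴ pairs, within 5%) bound what it costs. Only
f → f+1 pairs are used; longer lags would mix in drift.

## Ripley statistics

K̂(r) = A/(n(n−1)) · Σ_{i≠j} e_ij 1(d_ij ≤ r). Translation correction
e_ij = A/((w−|Δx|)(h−|Δy|)) applies to rectangular regions only;
non-rectangular ROIs fall back to no correction with a warning. Pairs are
found with a kd-tree at the largest radius, sorted once, and accumulated by
binary search, so the curve costs O(p log p) in the pair count. Radii
beyond half the shorter region side trigger a warning: the correction's
variance explodes there. L = √(K/π) and H = L − r are derived exactly.

Validation note: for pure Gaussian-cluster patterns (every point in a
cluster, no background) the H peak sits at ~2–3× the cluster σ_c, not at
σ_c itself — the peak tracks the pairwise-distance mode, which for an
isotropic Gaussian cluster is near 2σ_c. The tests assert that
proportionality rather than a fixed window.

## DBSCAN and OPTICS

Both are implemented in-package around scipy kd-tree radius queries,
because the package guarantees a *deterministic, order-independent*
partition:

* core point: ≥ min_pts neighbors within eps, counting itself (ELKI
  convention);
* clusters: connected components of the core-core eps-graph, numbered by
  their lowest member row index;
* border points: attached to the cluster of the *nearest* core point
  within eps, ties to the lowest row index.

Nearest-core border attachment (rather than "first cluster to claim the
point during expansion") is what makes the result independent of traversal
order and exactly reproducible by an exhaustive-search oracle; it also lets
the OPTICS eps-cut coincide with DBSCAN bit-for-bit, where the textbook
extraction can differ on border points. OPTICS uses the standard
priority-queue ordering with core distance = distance to the min_pts-th
neighbor counting self; cluster extraction is eps-cut only (no
xi-steepness extraction in this version).

Morphology uses the convex hull (shapely): area, perimeter, circularity
4πA/P², centroid (mean of member coordinates), hull diameter and
localization count. Clusters with < 3 non-collinear points are flagged
degenerate with area 0 and undefined (NaN) circularity. An alpha-shape
would follow concave clusters more faithfully and is a noted extension;
the convex hull is exactly testable against an independent hull
implementation.

## Coordinate-based colocalization

Radius grid r_j = j·r_max/n_steps (default n_steps = 10). The scaled
density gradients D_{A_i,A}(r_j) and D_{A_i,B}(r_j) are rank-correlated
(Spearman, average-rank ties); C_i = S_i · exp(−E_i/r_max). Conventions:

* A record is never its own neighbor: zero-distance coincidences are
  excluded from both density counts. In the nearest-neighbor distance E a
  coincident cross-channel record *does* count (E = 0), unless the two
  channels are the same physical table (`self_colocalization=True`), in
  which case the self-record is excluded from E as well. With these rules
  two identical channels give C ≡ 1 exactly.
* If either D vector is constant, Spearman correlation is undefined and C
  is reported missing (NaN), not zero — silent zeros would bias channel
  means. Missing values are excluded from summaries and counted in
  `n_undefined`.

Under independent CSR channels the mean C is slightly positive (≈ +0.09 at
500 points per channel in a 2×2 µm field) rather than exactly zero: at low
density both D vectors begin with runs of zeros below the first-neighbor
distance, and those shared ties correlate positively. This is a property
of the estimator at finite density, not of the implementation; the null
band used in validation (|mean C| < 0.1) accounts for it.

Interaction domains: DBSCAN over the subset {A_i : C_i ≥ threshold};
labels are reported aligned to the full channel-A table. An empty subset
yields an empty result, not an error.

## Fourier ring correlation

Halves are formed either by a seeded fair coin per localization
(`random_halves`, default) or by alternating 50-frame blocks
(`odd_even_blocks`). The block mode exists because random splitting places
repeated localizations of one blinking emitter in *both* halves, which
correlates them and flatters the resolution; the caveat is documented
rather than corrected (no spurious-correlation term in this version).

Images are count histograms on the table's region (default 10 nm/pixel),
zero-padded to the next power-of-two square. Rings are one frequency pixel
wide; the curve is smoothed with a 3-ring moving average; the resolution is
1/q* at the first downward crossing of the fixed 1/7 threshold, linearly
interpolated between rings, and undefined when the curve never crosses.

## Molecular counting

The photoswitching Markov chain is reduced to its observable consequence:
with an absorbing bleach state, the number of re-activations N of one
fluorophore is Geometric(q) on {0, 1, ...}, so an m-mer's count is
negative-binomial, P(N|m,q) = C(N+m−1,N) q^N (1−q)^m (dwell-time fitting
of on/off lifetimes is out of scope). Blink counts are extracted by
spatial DBSCAN grouping; within a group, frame indices merge into
on-events when gaps are ≤ dark_tolerance frames (default 1, absorbing
events split by the localization software), and N = events − 1.

Calibration on a monomer standard has the closed form q̂ = N̄/(1+N̄) (the
geometric MLE). The oligomer fit scans a bounded candidate set (default
1..8) and maximizes the log-likelihood; with labeling efficiency
p_label < 1 the model is the mixture Σ_k Binom(k; m, p_label)·P(N|k,q)
renormalized over k ≥ 1, because a complex with zero active labels is never
observed. When q is free it is profiled per candidate by bounded scalar
maximization. Note the m = 1 column of the mixture is independent of
p_label, so q and p_label are not jointly identifiable from monomers alone
— p_label is always supplied, never fitted.

## Synthetic data: what it does and does not emulate

The generators draw fixed-n point patterns (CSR, uniform-center Gaussian
clusters, segregated halves, a sine filament), geometric blink counts,
per-event isotropic Gaussian localization noise, lognormal photon counts
(shape 0.3), Bernoulli labeling, and two-color samples with a known
affine channel distortion, partial colocalization (jitter 10 nm) and
fiducials present in 95% of frames at 20× molecule brightness. Defaults: a
2×2 µm region, 1000 molecules, σ_loc = 10 nm, q = 0.3 — a typical
dSTORM-scale experiment.

Not emulated: camera-frame (pixel image) formation and PSF fitting, EMCCD
noise, sample drift, z-dependence, dye-specific dark-state kinetics beyond
the geometric reduction, and chromatic aberration beyond a single affine
map. Passing recovery tests therefore demonstrates correctness of the
estimators *given* the localization-list model, not robustness to
upstream fitting artifacts; NeNA in particular sees no drift here and will
report drift as extra apparent precision loss on real data (by design — it
measures the effective precision).

Validation problem sizes (chosen to be decisive yet desk-scale): 200 CSR
replicates of n = 1000 for the Ripley calibration; 500 random instances
(n ≤ 200) for the clustering oracle; 100 replicate pairs of n = 500 for
the CBC null; 10⁴ nearest-neighbor pairs per NeNA fit; 25 replicates per
noise level × 4 levels for FRC monotonicity; 100 replicates each for q
(n = 2000) and oligomer recovery (n = 1000–2000).

## Numerical details

* Ripley uses exact pair enumeration (no approximation); K is exactly
  nondecreasing by construction.
* The NeNA fit is bounded so σ cannot escape to the background term;
  non-convergence raises a fit error with solver diagnostics rather than
  returning a boundary value.
* Negative-binomial pmfs come from scipy (`nbinom(m, 1−q)`); mixture
  weights are renormalized in double precision and log-likelihoods floor
  the pmf at 1e−300 to keep empty-bin terms finite.
* FRC returns exactly 1 on every ring when both halves are identical; rings
  with zero power are reported as 0 correlation.
* Degenerate geometry raises typed errors (`EstimationError`,
  `MatchingError`, `FitError`) rather than returning silent NaNs, except
  where the contract says otherwise (empty interaction-domain subset,
  undefined CBC values, FRC without a threshold crossing).

## Known limitations

No 3-D (z) support; no drift correction; no alpha-shape morphology; no
pair-correlation g(r); no kinetic rate-constant estimation; no non-rigid
registration. The internal TSV dialect (x_nm, y_nm, frame, photons,
psf_sigma_nm, background, precision_nm, channel) is this package's own
interchange format.
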