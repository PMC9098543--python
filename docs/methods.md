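# Methods

This note documents the models, the numerical choices, and the scope of
the synthetic validation, in the order the pipeline runs them.

## Synthetic phantom (what it emulates, and what it does not)

The generator reproduces the statistical structure of a single-shell
ex vivo HARDI acquisition of a small (quail-sized) brain:

- **Acquisition geometry.** 75 diffusion-encoding directions spread by
  electrostatic repulsion of antipodally identified charges, plus 5 b=0
  volumes, at b = 4500 s/mm². The optimizer is a projected-gradient
  descent with backtracking; energy is monotonically non-increasing and
  the result deterministic per seed (the reference 75-direction set
  reaches a ≈ 16° minimum inter-axis angle).
- **Grid.** 32³ voxels at 0.2 mm isotropic, voxel centers at
  (i + 0.5)·0.2 mm, half-open voxel ownership. The brain mask is an
  ellipsoid (radii 2.0 × 2.2 × 1.6 mm) enlarged to cover every planted
  streamline point.
- **Tissue.** Three ADC modes — GM 3.0×10⁻⁴, WM 2.3×10⁻⁴, CSF
  6.5×10⁻⁴ mm²/s — chosen on the 10⁻⁴ mm²/s scale so that b·D falls in
  the physically sensible ex vivo range 1.0–2.9; at 10⁻⁹ mm²/s the shell
  would carry no diffusion contrast at all. WM is an axially symmetric
  tensor with λ∥/λ⊥ = 5 at fixed trace 3·ADC, which produces the sharp
  single-lobe ODFs the tracking stage assumes. S0 = 1000 a.u.
- **Bundles.** Tubes around polyline centerlines; each tube rasterizes
  its tangent into the voxels it crosses (two distinct directions in a
  voxel make a crossing with equal volume fractions), and carries
  `fiber_count` ground-truth streamlines laid parallel to the
  centerline in a parallel-transported frame with seeded in-disk
  jitter. The default study has one tube per hemisphere and one in the
  cerebellar slab, well separated.
- **Signal.** Multi-tensor: S(g,b) = S0·Σᵢ fᵢ·exp(−b gᵀDᵢg); Rician
  noise |S + n₁ + i·n₂| with n₁,n₂ ~ N(0, S0/SNR); SNR is defined at
  b=0 and defaults to 30. Background (outside-mask) voxels carry pure
  noise, which is what the denoiser's σ estimator relies on.

Not emulated: segmented-EPI artifacts, susceptibility/eddy distortions
(absent in the multishot ex vivo acquisitions this pipeline targets),
partial-volume ramps at tissue interfaces, B1 bias, anatomically
realistic geometry, and inter-subject anatomical variability (the
synthetic cohort shares one geometry; subjects differ by noise and
seeds, and registration to a template is the identity). Passing tests
therefore demonstrate correctness of the algorithms under the model's
own assumptions, not robustness to real-world artifact structure.

## Denoising

Rician-adapted non-local means, each 3D volume independently. The
weight between voxels x and y is exp(−d²/h²) with d² the *mean* squared
intensity difference over a (2·1+1)³ patch; the estimate is computed on
squared magnitudes and bias-corrected: out = sqrt(max(E_w[x²] − 2σ², 0)).
Patch radius 1, search radius 3. σ is estimated from the MAD of the
background b=0 magnitudes (Rayleigh MAD→σ factor 0.4485) and h = 1.5σ;
with the patch-mean distance this h gives substantial averaging (RMSE
roughly halves at SNR 30) while h on an *unnormalized* patch SSD would
reduce the filter to its Rician bias correction. When the background is
noise-free the estimator returns σ = 0 and the data pass through
unchanged. Patch and search windows are clipped at the volume boundary:
terms involving out-of-bounds voxels are dropped from both numerator
and denominator (patch means keep the full-kernel denominator).

## Local models

- **DTI.** Log-linear least squares of ln S = ln S0 − b gᵀDg per masked
  voxel via a precomputed pseudoinverse; signals are clamped at
  1e−6·S0 before the log. Eigenvalues are sorted descending and
  negatives clamped to zero (count logged); FA = √(3/2)·‖λ−λ̄‖/‖λ‖.
- **Q-ball.** Real symmetric SH basis (even degrees, j(l,m) ordered by
  l then m ascending; m<0 → √2·Im Y_l^|m|, m=0 → Y_l⁰, m>0 → √2·Re
  Y_l^m), order 8 (45 coefficients, needing ≥ 45 directions),
  Laplace–Beltrami regularization λ = 0.006, analytic Funk–Radon by
  2π·P_l(0) scaling. Signals are normalized by the mean of the b=0
  volumes. Multi-shell input is rejected at scheme construction.
- **GFA.** ODFs are sampled on a 2562-vertex subdivided icosahedron,
  min-shifted to be non-negative (the FRT can produce small negative
  lobes), and GFA = sample std (ddof = 1) over rms — zero for flat
  ODFs, 1 for a one-hot ODF in the large-n limit.
- **Peaks.** Local maxima on the same tessellation (value ≥ all
  neighbors), relative threshold 0.25 of the per-voxel maximum, greedy
  non-max suppression at 25° minimum axis separation. The 2562-vertex
  mesh quantizes directions to ≈ 2.3° worst case, well inside the 5°
  recovery tolerance used in validation.
- **Percentile thresholds** use linear interpolation of the empirical
  CDF (numpy's default), both for the 98 % GFA threshold and the
  population fiber-length window.

## Tractography

The SRD tracker integrates both directions from each seed at 50 µm
steps, with trilinear interpolation of the *SH coefficients* (not of
peak directions), so the ODF field is continuous along the path. At
each step the candidate d_odf is the in-cone (30°, axial) local maximum
of the interpolated ODF closest to the previous direction, evaluated on
a 642-vertex icosphere with a weighted-neighbor refinement of the
winning vertex (weights value-above-neighborhood-minimum); if the
refined direction leaves the cone the raw vertex is used. The update is
d ∝ (1−w)·d_odf + w·d_prev with w = clamp(1 − GFA/θ, 0, 1). The first
step uses the global ODF maximum at the seed. Termination: leaving the
mask (or grid), or no in-cone peak. When w saturates (w ≥ 1−10⁻³,
i.e. GFA ≈ 0) the tracker propagates straight without consulting the
ODF — this reconciles the no-in-cone-peak stop rule with the defined
behavior in isotropic regions, where a flat ODF has no meaningful
peaks but regularization fully dominates anyway. Retained streamlines
have length in [0.1, 100] mm (boundaries at ±1e−9 for float safety);
dropped-seed counts are logged. The inner loop is a numba kernel;
results are bit-deterministic for fixed inputs and seed.

θ defaults to 0.12; the pipeline driver recomputes it as the cohort
mean of each subject's 98th GFA percentile (the synthetic cohort lands
at ≈ 0.19), mirroring how the published default was derived rather than
hard-coding it.

## Intra-subject clustering

Regions: a fiber touching both hemispheres is interhemispheric;
otherwise majority vote of its points' labels; points over unlabeled
voxels take the nearest labeled voxel (logged). Length window: pooled
2–98 % percentiles across the cohort, cut into 8 equal-width bins,
right-closed last bin. Density masks count distinct fibers per voxel
(threshold 5). Parcellation: k-means (k = round(n/27), seeded,
n_init = 4) on voxel-center coordinates. Parcel connectivity counts
co-visiting fibers; average-linkage clusters of D = 1 − M/max(M) are
cut at 0.9 (exposed in config; an all-zero matrix yields singletons).
Fibers join the parcel cluster holding the largest fraction of their
points if that fraction is ≥ 0.31, using the fiber's own points
(uniform 50 µm spacing makes resampling unnecessary); clusters below 5
members are dropped. The centroid is the member minimizing the mean
symmetric MCP distance to the other members, ties to the lower index.
For speed the pipeline computes these distances on 21-point resampled
copies, and clusters larger than 256 members average against a seeded
256-member reference subsample instead of all members; the operation
itself remains exact when called directly, and the subsample only
affects which member represents very large (typically background)
clusters. Table-style caps on density-mask size (6000/300 voxels per
clustering unit) exist in the configuration but are off by default;
the 27-voxel parcel target is the operative dimension-reduction knob.

## Inter-subject clustering

Centroids are resampled to 21 equidistant points. The raw pairwise
distance is the mean point-to-corresponding-point distance minimized
over the two orderings; the length correction d·nf/(nf + min_len)
(floored at 0.01 mm) implements the stated behavior — the constraint
relaxes as the shorter centroid lengthens, halving the raw distance
when min_len = nf — as this package's explicit form of the published
but unprinted correction. Affinities are exp(−d²/1600 mm²), zeroed
beyond CAMD = 2 mm. HDBSCAN (scikit-learn, precomputed metric) runs on
the corrected distances with zero-affinity pairs set to a sentinel
beyond CAMD; min_cluster_size = min_samples = max(2, ⌈0.5·n_subjects⌉).
"Maximum distance after exclusion" (0.4 mm) is implemented as a
post-pass pruning members farther than 0.4 mm from the cluster medoid
(disable-able). Clusters present in < 50 % of the cohort are dropped.
The (nf, CAMD) grid search reruns the whole stage on a 10 × 10 grid
over [1, 100] × [0.1, 4.0] mm and returns the argmax of the retained
cluster count (first grid point in row-major order on ties) together
with the full surface.

## Atlas and group comparison

A cluster joins a named bundle when its member centroids jointly reach
every include region (≥ 1 point each) and no point touches an exclude
region; selection per centroid trajectory on the template label volume.
Duplicate bundle names are an error; a centroid selected into two
bundles is logged. Fiber density is fibers per in-mask voxel of the
region (whole mask for interhemispheric fibers); line comparisons use
Welch's unequal-variance t-test, two-sided, α = 0.05 — "t test" admits
either pooled or Welch; Welch is the safer default under per-line
variance differences.

## Determinism and problem sizes

All randomness flows from a single root seed through SHA-256
stage-name hashing (seeds < 2³¹); k-means and HDBSCAN are seed-pinned
or deterministic, and the tracking kernel is pure arithmetic, so a rerun
reproduces the atlas and centroid coordinates bit-for-bit. The
validation suite works at desk scale by design: 32³ grids, tubes of
2–4.8 mm, cohorts of 6 subjects (2 for pure software-property checks),
≈ 30k streamlines per subject — sizes chosen so the full cohort run
completes in minutes on one CPU while every stage still operates in its
intended regime. Published cohort-scale figures (10⁵–10⁶ streamlines,
tens of anatomically named bundles) depend on real scans and are out of
scope here.

## Known limitations

- Single-shell, single- and two-fiber voxels only; no spherical
  deconvolution (deliberately, as the reference application lacks a
  corpus callosum to calibrate an impulse response), no multi-shell
  microstructure models, no probabilistic or global tracking.
- The SRD blending weight and the Guevara-style length correction are
  this package's explicit formulations of published-but-unprinted
  rules; both are documented contracts, exposed in configuration.
- Identity registration only: inter-subject clustering assumes
  centroids are already in a common space (true for the synthetic
  cohort); a per-subject affine can be applied by the caller.
- The tracking tessellation (642 vertices + refinement) bounds the
  per-step angular resolution at roughly 1–2°; curvature sharper than
  the aperture per step cannot be followed.
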