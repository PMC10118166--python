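# Methods

## Coordinate and geometry conventions

Volumes are 3D arrays in `(z, y, x)` index order. World coordinates in μm
are `origin + index × spacing`; every measurement is computed in world
coordinates, so anisotropic voxels are supported without resampling
(resampling would alter the topology of thin structures). NRRD headers are
authoritative for spacing; TIFF requires a `<name>.tif.meta.json` sidecar
with `"spacing_um": [z, y, x]` because TIFF tags carry no reliable
3D spacing. Intensities are never rescaled silently; statistics are
reported in native units.

## Tubule morphometry

**Skeleton.** The binary lumen (largest 26-connected component; others are
dropped with a warning) is thinned with `skimage.morphology.skeletonize`,
a 3D topology-preserving thinning that serves as the medial-axis
surrogate. Exact medial axes are not required: accuracy is assessed as
proximity to phantom ground-truth centerlines (within ~1 voxel on straight
tubes).

**Centerline.** Skeleton voxels become nodes of a 26-neighbor graph with
world-distance edge weights. Terminal twigs shorter than 10 voxels are
pruned (thinning spurs, not anatomy — the pronephric tubule is
unbranched). The centerline is the longest endpoint-to-endpoint geodesic
(Dijkstra from each endpoint); ties break toward the lexicographically
smallest endpoint coordinate for determinism. A closed-loop skeleton has
no endpoints and is rejected with a topology error. Two corrections
compensate known thinning artifacts:

- *Endpoint extension.* Thinning retreats ~2 voxels from rounded lumen
  ends. Each path end is advanced along its end tangent in quarter-voxel
  steps while the interpolated distance-to-boundary stays flat, stopping
  where it begins to fall toward the end surface. Straight-tube lengths
  are then recovered to ±1 μm.
- *Spine smoothing.* Voxel-jagged paths overestimate geodesic length by
  3–4%. The path is smoothed with a 5-point moving average (endpoints
  pinned) before parameterization; residual length bias is ≲0.5%.

**Parameterization.** The geodesic coordinate is the cumulative Euclidean
arc length by default. An Isomap mode (k-NN graph, k = 6 by default,
shortest-path distances, classical 1D metric embedding via
`sklearn.manifold.Isomap`) is provided and agrees with arc length to well
under 1% on simple curves; it exists for parity with workflows that derive
the 1D coordinate by manifold embedding.

**Turning point.** A manually supplied TP index always wins. The
automatic fallback takes the curvature of the smoothed centerline
(11-point window) and returns the middle of the contiguous region above
80% of the peak curvature — a plain curvature argmax is ill-posed on a
circular bend, where curvature is a plateau, and would land on the bend's
edge. Signed alignment puts the TP at *s* = 0 with the glomerulus side
negative; with `glomerulus_end="auto"` the shorter limb is taken as the
neck, matching the anatomy (neck-to-TP ≈ 100 μm, TP-to-cloaca ≈ 300 μm).

**Caliber.** Two conventions are computed per centerline point and both
are reported:

- `diameter_um` — inscribed-sphere diameter: twice the world-metric
  Euclidean distance transform sampled (trilinear) at the point. Points
  outside the lumen are snapped to the nearest lumen voxel with a warning.
- `area_um2` / `equiv_diameter_um` — cross-section area in the plane
  normal to the local tangent (central differences on the smoothed spine;
  one-sided at endpoints). The plane is sampled on a square grid of pitch
  = min(spacing)/2; lumen membership is looked up by trilinear
  interpolation and only the connected in-plane region containing the
  centerline point is counted, so another fold of the tubule crossing the
  plane does not inflate the area. The area is the *sum of interpolated
  values* over that region times the sample area — partial-volume
  integration, which is unbiased where thresholded pixel counting dilates
  the section by about half a voxel (≈ +12% on a 5 μm-radius tube).
  A region touching the sampling window's border sets a `saturated` flag
  (the value is then a lower bound). Accuracy on cylinders is ±3%
  regardless of orientation relative to the grid.

Length is the span of *s*; volume is foreground voxel count × voxel
volume.

## Regional analysis

Profiles are aligned on the signed coordinate and averaged in bins whose
edges are integer multiples of the bin width (default 25 μm — resolving
the −75…175 μm region of interest into 10 bins) covering the pooled *s*
range; the final right edge is inclusive. Per bin, control vs treated is
compared with Welch's unequal-variance two-tailed t-test (group sizes are
typically unequal, e.g. 4 vs 8, and no variance homogeneity is assumed);
bins with fewer than two specimens in either group are marked untestable.
Raw p-values are reported by default, matching per-position significance
profiling; Benjamini–Hochberg correction is available by flag. A region
(PCT/PST, split at *s* = 175 μm) is called significant when more than half
of its testable bins are. Whole-tubule metrics are summarized as fold
change versus the control-group mean, with five-number (box-plot)
summaries and Welch tests per metric. Multi-dose designs use one-way
ANOVA followed by Dunnett's many-to-one comparisons (`scipy.stats.dunnett`).

## Glomerulus metrics

The damage ratio is (Bowman's space + cellular) / cellular — the whole
glomerulus over its cellular compartment; it equals 1 for a space-free
glomerulus and rises as Bowman's space expands. This reading is the one
consistent with both published worked examples (volume fold 1.40 from
space 81 083 vs 25 379 μm³ with cellular 121 265 vs 131 994 μm³; area fold
1.2 from 3 524/2 565 vs 3 337/2 866 μm²). Group ratios in 2D use the
ratio-of-means convention (grand means, which reproduces the printed
folds); mean-of-ratios is reported alongside, and both raw compartments
are always emitted so any alternative ratio can be recomputed. Dilatation
scoring replaces an observer's qualitative call with an explicit rule —
dilated ⇔ lumen area > k × median(control), k = 2 by default — making the
percentage computable and auditable; k is the rule's single free
parameter.

## Fluorescence quantification

Z-stacks are reduced by maximum-intensity projection. The threshold is
either a number or Otsu's method computed on the pooled control-group
projections and then held fixed for the whole experiment (one shared
threshold, as all groups are acquired with identical settings). Mean SI
is taken over pixels *strictly above* the threshold (the whole-ROI mean is
available via `domain="roi"`); an empty suprathreshold set yields 0 with a
flag. Threshold-based glomerulus volume counts suprathreshold voxels in
the largest 26-connected component (a single structure is being measured)
times the voxel volume. Fold change divides by the arithmetic mean of the
control group, so control folds average exactly 1.

## Synthetic phantoms

The generators are pure functions of (spec, seed) and emit analytic ground
truth; the test suite treats that ground truth as the only oracle.

- **Tube.** A hairpin path — straight neck limb, half-circle bend (the TP
  at its apex), straight tail limb; defaults 100 μm neck, 300 μm tail,
  30 μm limb separation, gentle sinusoidal z-undulation — is interpolated
  through control points by a natural cubic spline, resampled at half-voxel
  arc steps, and rasterized: a voxel is lumen iff its center lies within
  the local radius of the nearest path sample (matching the
  distance-transform diameter estimator's geometry). The radius profile is
  piecewise linear on the signed coordinate (default constant 5 μm), times
  a global treated-vs-control scale, times an optional smooth jitter field
  (Gaussian factors at 40 μm knots, linearly interpolated) emulating
  biological caliber variation. Radii under one voxel are rejected to
  avoid aliased, disconnected lumina.
- **Glomerulus.** Concentric ellipsoids: cellular core inside a capsule,
  the shell being Bowman's space. The core scale is tuned by bisection on
  actual voxel counts, so the realized cellular fraction matches the
  request (within 2%, typically much closer) and the ground-truth counts
  are exact.
- **Fluorescence.** Blobs on zero background with additive Gaussian
  noise. The default profile is a uniformly bright ball — the appearance
  of a saturated reporter-filled glomerulus, and the shape for which the
  suprathreshold mean SI is exactly linear in the expression factor.
  Gaussian and flat-top profiles are available to emulate diffuse stains;
  their soft skirts make the suprathreshold domain itself
  intensity-dependent, which is precisely the regime where per-specimen
  suprathreshold means stop being linear.
- **Dilatation cohort.** A per-tubule area table: control areas scatter
  lognormally (σ = 8%) around π·25 μm²; a chosen fraction of treated
  tubules is scaled ×2.5.

What the phantoms deliberately omit: optics (PSF blur, phase-contrast
fringes), photon/detector noise beyond additive Gaussian, segmentation
error, and anatomical irregularity beyond smooth caliber jitter. Passing
the recovery tests therefore demonstrates the correctness of the
measurement chain on clean geometry, not robustness to real acquisition
artifacts — in particular, exact SI linearity degrades for soft-edged
real blobs, and manual-segmentation noise would widen all phantom
tolerances.

## Validation problem sizes

The validation experiments use 1 μm isotropic voxels (phantom volumes of
roughly 300 × 60 × 30 μm³, ~0.5 M voxels each): a 4-control / 8-treated
cohort with treated radius ×1.75 and 5% smooth jitter for fold-change
recovery (recovered diameter fold within ±0.05 of 1.75, length fold
within ±0.03 of 1), and the same design with the scaling confined to
*s* ∈ [−75, 175] μm for localization. These sizes keep a full validation
run around half a minute while leaving every effect far above the
estimator noise floor.

## Known limitations

- Thinning-based skeletons are not exact medial axes; sharp local bumps
  can shift the spine by up to a voxel.
- The skeletonization step treats voxels as isotropic; with strongly
  anisotropic spacing the extracted path remains valid as a graph but its
  geometric centering degrades. Measurements themselves are world-metric.
- Cross-section areas at a sharp bend can include part of the curved wall
  (the normal plane cuts the bend obliquely); both groups are affected
  equally, so fold changes are unaffected.
- The 2D histology analog consumes area tables; it does not segment
  glomeruli from stained images.
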