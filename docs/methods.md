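# Methods

This note records the models, parameter choices, and numerical conventions
behind `vesselkit`, and what the synthetic benchmark does and does not
establish about real microscopy data.

## Coordinate and intensity conventions

All geometry is in pixel units with the origin at the top-left corner,
x along columns, y along rows; physical units (µm, mm²) enter only in the
metrics module through the user-supplied µm/px calibration — pixel scale is
never read from file metadata. Images are floats in their native range;
multi-channel input collapses to the plain channel mean. Histogram
equalization is global (not adaptive) and maps each distinct value to its
empirical CDF, so output spans (0, 1], the transform is monotone in input
ranks, and 16-bit input is equalized over its observed range rather than the
nominal type range (confocal exports are often low-occupancy 16-bit).
A constant image is returned unchanged with a warning.

## Training-region construction

Square regions of side `box_size` are centered at arc-length positions
`0, stride, 2·stride, …` plus the final endpoint, so consecutive centers are
at most one stride apart and the region union covers the trace. Defaults
`box_size = 32 px`, `stride = box_size/2` (50 % overlap): dense enough that a
single traced vessel yields tens of regions and an image hundreds, which is
the point of training on regions rather than whole images. Regions are
axis-aligned squares regardless of local vessel direction (detection-model
inputs are axis-aligned); boxes extending past the border keep their nominal
center so arc sampling stays regular. All three annotation classes generate
regions of their own label.

## Reconstruction

* **Neighbor rule.** Edge iff center distance ≤ `radius_factor` × mean box
  diagonal, `radius_factor = 1.25`. The rule is scale-free in box size and
  guarantees that consecutive boxes sampled at ≤ 50 % overlap remain
  connected even across one or two missed detections, while bounding
  long-range false links. Coincident centers are left unconnected (a
  zero-length edge carries no length; the chain reconnects through the next
  box).
* **False-connection filter.** "Contour" evidence is operationalized as
  foreground support: mask = pixels strictly above the `support_quantile`
  (0.8) quantile of the equalized image; an edge needs `min_support` (0.7)
  of its 1-px straight-segment samples on the mask. This is a declared
  substitute for whatever contour detector the original desktop tool used —
  the choice is the minimal independently testable reading, and the mask
  source is pluggable. Filtering precedes cycle removal.
* **Cycle removal.** Exact per-component minimum spanning tree with edge
  weight = center distance; Kruskal over edges sorted by `(weight, u, v)` so
  weight ties break deterministically. Verified against exhaustive
  spanning-tree enumeration on small graphs.
* **Decomposition.** Trees split into maximal simple paths at nodes of
  degree ≥ 3. Total length is invariant to the decomposition choice; the
  split additionally yields a branch count for free. A single isolated box
  yields no polyline (a point has no extent).

## Measurement and comparison

Total vessel length sums vessel-labelled polylines only; `out_of_plane` and
`debris` are excluded by construction. Density is per projected image area
(µm/mm²). Sample density is the mean over a sample's images (a warning is
logged when the count differs from the conventional 4); group density is the
mean over samples with the n−1 sample SD. Percent error compares group-mean
densities — `|reference − measured|/reference × 100` — and accuracy is
`100 − error`, with an N/A sentinel (NaN) whenever error exceeds 100; N/A
propagates through aggregation together with a count of excluded groups.
A per-image error is available for diagnostics but is not part of the
group-level protocol.

The pixel-based comparison method is the classical chain: equalize →
quantile threshold (`threshold_quantile = 0.9`) → drop components outside
`[min_object_px, max_object_px] = [50, 50000]` → topological skeletonization
→ skeleton length with diagonal correction (orthogonal step 1, diagonal √2,
skipping staircase-corner diagonals that share an orthogonal neighbor). Raw
pixel counts would overestimate diagonal vessels by up to 41 %, hence the
step weighting. Thresholds are quantiles, not absolute intensities, because
inputs are equalized and quantiles are modality-portable; the exact values
in the original laboratory protocol are not public, so all are exposed as
parameters.

## Cross-validation design

Partitioning is at the sample (biological replicate) level so that images of
one construct can never straddle partitions — the leakage that image-level
splits invite. Partition sizes are `floor(fraction·n)` and every partition
must be non-empty. The holdout is drawn once and fixed across folds
(the stricter reading of a holdout "entirely segregated" from training);
a rotating holdout is available behind a flag. Fold/partition error is the
mean percent error over the partition's samples. A 200-plan sweep asserts
zero leakage and per-sample holdout frequency within 3 binomial SD of the
configured fraction.

## Synthetic scenes

The generator produces the qualitative obstacles of real angiogenesis
imagery, not a biophysical simulation:

* **Vessels**: branching correlated random walks — heading perturbed by
  `Normal(0, tortuosity_sd)` per `step_px` step, side branches at ±~45° with
  probability `branch_prob` per step (branches do not re-branch, so branch
  counts are binomial and testable). Ground truth is exact by construction
  and independent of rendering.
* **Rendering**: vessels as Gaussian-profile ridges (σ = width/2) with
  per-vessel lognormal brightness (CV = `intensity_cv`, emulating uneven
  lectin staining); debris as short thick bright dashes (elongated clumps —
  deliberately shaped so they pass size filters and skeletonize to nonzero
  length, the pixel method's real failure mode); out-of-plane objects as
  heavily blurred dim ridges excluded from true length; Gaussian read noise.
  Phase-contrast mode renders dark vessels with a bright halo on mid-gray.
* **Defaults** emulate a higher-magnification fluorescent field:
  512×512 px at 0.65 µm/px (0.111 mm²), 4 seed fragments × 50 steps of 4 px,
  `tortuosity_sd = 0.1`, width 4 px, `branch_prob = 0.015`, 6 debris,
  2 out-of-plane objects, noise SD 0.02 — giving true densities around
  3500–9000 µm/mm² across the benchmark's low/medium/high grid (seed counts
  2/4/8, the spread a multi-group experiment produces). The benchmark used
  by the acceptance checks is 3 density levels × 7 scenes.

What passing synthetic tests shows: the reconstruction's geometric behavior
(coverage, conservation, filter selectivity, noise tolerance) and the
qualitative debris contrast between measurement methods. What it does not
show: performance on real stain variability, real debris morphology, or real
annotator error — no claim about absolute accuracy on laboratory images
follows from these tests.

## Known limitations

* **Crossing undercount.** Where two bright vessels cross or run parallel
  within the neighbor radius, cross-links have full image support, the
  components merge, and the minimum spanning tree replaces along-vessel
  stride edges with shorter cross-links. Single isolated vessels recover to
  ~1 px; at the benchmark's medium/high densities the median noise-free
  deficit is tens of px on ~600–1600 px of truth (the noisy-detector median
  error stays under 10 %, ~4 %). This is intrinsic to distance-weighted
  spanning-tree reconstruction and mirrors the known loss of accuracy of
  polyline-over-detection measurement in dense, overlapping fields; the
  acceptance suite keeps the strict noise-free bound as a failing check
  rather than hiding the effect.
* The detector contract is desk-scale only: the oracle backend injects
  controlled error around ground truth, and the classical backend is
  threshold-based; no trained network ships, so detector-specific failure
  modes (class confusion, confidence miscalibration) are out of scope.
* 2-D projections only; no 3-D stack analysis beyond maximum projection.
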