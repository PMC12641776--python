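# Methods

## Scope and model

`retimosaic` quantifies two cellular mosaics visible in adaptive-optics
fundus images of the healthy macula: the retinal pigment epithelium (RPE),
which images as a honeycomb of dim cell centres with bright borders, and
the cone photoreceptor (PR) mosaic, which images as bright dots on a dark
background. Rods are below the resolution of the modality and are neither
analyzed nor simulated. The biological quantity of interest is the local
morphometry of these mosaics — density (cells/mm²), per-cell area and
perimeter, neighbor count — as a function of retinal eccentricity and
participant age.

The geometric model is deliberately simple. Each acquisition covers a
fixed angular field (default 6.7°, 2048 px square) whose centre is known in
degrees relative to a fixation target. The fixation target approximates
the fovea; no anatomical co-registration is attempted, and all coordinates
are reported as fixation-relative. Retinal magnification follows the
Bennett–Littmann linear model, `pixel size (µm) = 0.504·0.01306·(AL −
1.82)·6.5` for axial length AL in mm; axial lengths at or below 1.82 mm
are rejected as invalid biometry. Two conventions close the gaps the
coordinate definition leaves open, and are applied uniformly:

* the horizontal axis is mirrored between OD and OS inside
  `pixel_to_global_degrees` — and nowhere else — so that +x° is temporal
  for both eyes and all downstream code is side-agnostic; +y° is the
  superior retina, with raster rows increasing downward;
* signed eccentricity is `sign(x)·hypot(x, y)` with `sign(0) = +1`, so a
  third sign branch is avoided for the measure-zero vertical meridian.

Pixel `(r, c)` denotes the centre of that pixel; the frame is the square
`[-0.5, n-0.5]²` so that a 2048-grid has centre (1023.5, 1023.5) and the
four corners span exactly one field of view.

## Masking

Morphometry is restricted to retina where the mosaic is actually resolved.
Three boolean layers are computed per image, with `mosaic ⊆ quality ∧
¬vessel` by construction:

* **quality** — local variance of a high-pass response (Gaussian
  high-pass, σ = 4 px; 15-px window), thresholded at a fraction (default
  0.05) of the image's own 90th-percentile energy, so the decision is
  invariant to intensity scale. Defocused regions lose orders of magnitude
  of high-frequency energy and fall below any reasonable threshold.
* **vessel** — multi-scale Sato tubeness (σ = 8, 16, 32 px) of the
  inverted, texture-suppressed image, gated by a darkness criterion
  (smoothed intensity below 0.75 of the image median — vessels absorb
  light) and a minimum component size. No elongation test is applied: the
  darkness gate plus size filter proved far more robust on merged or
  branching ribbons.
* **mosaic** — the ratio of band-pass energy (difference of Gaussians at
  0.18× the expected cell spacing) to broadband high-frequency energy,
  both locally averaged over 0.75 spacing, thresholded at 0.02–0.03. A
  resolved mosaic concentrates ~8% of its high-frequency energy in the
  spacing band versus ~0.5% for structureless noise, a 13–25× margin.
  Because the local energy average smears mosaic energy about one spacing
  past the true boundary, the thresholded layer is eroded by one expected
  spacing; this makes the criterion conservative near transitions, which
  is the desired behavior for "regions where the target structure is
  clearly present".

All masking and detection thresholds are implementation tunables recorded
in the run configuration's `tuned` provenance block; none is a protocol
constant. They were fixed by measuring the separation between rendered
mosaic, defocus and noise on synthetic scenes and choosing values with at
least a factor-of-several margin on both sides.

## Detection

Centroids are local maxima of a difference-of-Gaussians response matched
to the expected spacing (inner σ = 0.15·s, outer 1.6×), where the expected
spacing s comes from the modality's nominal density via the hexagonal
relation `density = 2/(√3·s²)` (defaults 6313 cells/mm² for RPE, 10,207
for PR). RPE images are inverted first so honeycomb centres respond as
blobs. Non-maximum suppression uses a Euclidean disc of radius 0.4·s: at
the 0.15-spacing positional jitter typical of real mosaics, suppression at
0.5·s merges 3–4% of genuinely close pairs, while 0.4·s loses under 1.5%
with no measured loss of precision (precision 1.0, recall ≥ 0.987 on clean
synthetic scenes). Maxima below 5% of the strongest response are dropped,
and only maxima on mosaic-mask pixels are kept. Detection is fully
deterministic. The detector interface is modality + expected spacing, so a
learned detector could be substituted without touching downstream stages.

## Voronoi morphometry

Each cell is the Voronoi region of its centroid, clipped to the image
rectangle. Clipping is exact, not approximate: the centroid set is
augmented with its mirror reflections across the four frame edges before
tessellating. Inside the frame a reflected point can never beat its source
point, and a point's reflection across an edge places a Voronoi boundary
exactly on that edge, so the regions of the original points are bounded,
tile the frame exactly (area conservation holds to rounding), and equal
the rectangle-clipped regions of the plain diagram. Test suites verify
this against a brute-force half-plane-intersection oracle (areas and
perimeters to 1e-6 relative, neighbor graphs identical).

Areas scale with pixel-size²; perimeters with pixel-size. Neighbors are
regions sharing an edge longer than 1e-9 px. A cell is a **boundary cell**
when its region touches the frame or extends into non-mosaic raster area
(tested at the region's vertices); boundary cells are excluded from
area/perimeter/neighbor summaries — their geometry is a truncation
artifact — but still count toward density, which is a detection-count
quantity. Regions are clipped to the frame only, never to the mask
polygon: mask membership is decided by the centroid's raster position at
detection time, and degenerate (cocircular) configurations such as perfect
lattices are handled by the tessellation library's merged-vertex output,
with exact duplicates removed up front.

## Filtering and aggregation

The cascade, in order, with every constant a `protocol` configuration
value:

1. images with **strictly more than 90%** of their area masked are
   excluded;
2. the frame is split into **256 × 256 px** squares (64 per full frame);
   each cell belongs to exactly one square by centroid pixel; squares with
   **fewer than 200** detected cells (boundary-flagged cells included) or
   no mosaic-visible pixels are dropped;
3. **local density** of a retained square is cells / mosaic-visible area
   of the square, in cells/mm² — density is normalized by *visible* area,
   not square area, so partial masking does not bias it;
4. for PR only, records with eccentricity **strictly inside (−2.5°,
   2.5°)** are removed; endpoints are kept (the exclusion is read as an
   open interval; the choice is measure-zero);
5. retained summaries are averaged in **25 equal-width bins** over a
   configurable signed-eccentricity range (default ±10°); per-bin mean and
   SD are reported, empty bins appear with count 0. The unit of averaging
   is the grid square, consistent with the ≥200-cell filter; per-cell
   averaging is the documented alternative.

Heatmaps bin square centroids on the (x°, y°) plane at the grid-square
angular pitch (0.8375°) and smooth with a Gaussian of σ = one sampling
distance, normalized over the populated support only, so unsampled areas
stay missing rather than being interpolated. PR/RPE ratio profiles match
squares of the same eye one-to-one, nearest centroid first, within half a
grid-square width (0.42°) — half-pitch guarantees unambiguous pairing on
aligned grids — and unmatched squares are dropped.

## Validation statistics

* **ICC(3,k)** — two-way mixed, consistency, average of k raters:
  `(MS_targets − MS_error)/MS_targets` from the two-way ANOVA
  decomposition, with the 95% CI from the exact F bounds (Shrout–Fleiss).
  Consistency form: invariant to per-rater offsets and common rescaling;
  undefined (raised) when between-target variance is zero. Cross-checked
  in the tests against an independent ANOVA-table computation and against
  `pingouin`.
* **Normalized range** — (max − min)/mean of one patch's counts.
* **Within-range check** — the automatic count, divided by the patch's
  unmasked fraction to project it to a full-patch count, must fall within
  [min, max] of the manual counts. Scaling the manual counts down instead
  is algebraically equivalent.
* **Pearson matrix** — pairwise-complete Pearson r with the t-test
  p-value, flagged at p < 0.001, without multiple-testing correction
  (mirroring the conventional presentation; corrected values can be added
  downstream). Eyes and grid squares are treated as independent
  observations; within-participant correlation is not modelled.
* **Descriptive tables** — mean, median, sample SD, 25th/75th percentiles
  (linear interpolation), per gender stratum and pooled.
* **Age trend** — ordinary least squares of per-eye mean density on age;
  the slope sign is the quantity of interest.

## Synthetic scenes

The generator exists so that every stage has ground truth. Cell positions
are a hexagonal lattice whose local spacing follows a configured density
field through `density = 2/(√3 s²)`; the field is linear in absolute
eccentricity and in age, floored at a minimum. Within-row spacing is set
to `1/(density·row height)` point-by-point, so the realized point density
matches the field exactly even when it varies across the frame; positions
are then jittered by Gaussian noise of 0.15·s (default), the perturbation
level at which natural mosaics keep a mean neighbor count of ~6. RPE
scenes are rendered as the distance field to the nearest centroid (dim
centres, bright borders); PR scenes as Gaussian dots; both on a
margin-expanded canvas so border texture is correct. Vessels are smooth
random-walk ribbons (default width 60 µm) darkened to 15% of background;
defocus is a Gaussian-blurred elliptical patch whose area fraction grows
linearly with age (default 0.02 at age 23, +0.004/yr) — emulating the
observation that older eyes lose *visible* mosaic area, separately from
any true density decline; structureless "non-mosaic" patches are
noise-filled ellipses; sensor noise is additive Gaussian. Defaults encode
a normative cohort: RPE 6313 cells/mm² at fixation, flat over
eccentricity, −20 cells/mm²/yr around age 50; PR 11,500 cells/mm² at 2.5°
declining 400 cells/mm²/°, no age trend; ages 23–80; axial length
N(23.6, 0.8) mm; five acquisition zones (fixation and ±5° on both axes).
Every generator is a pure function of (config, seed).

What the generator does **not** emulate: the instrument's optical
point-spread and wavefront residuals, photoreceptor reflectance dynamics
(Stiles–Crawford, rod intrusion), true anatomical density topography near
the fovea, disease phenotypes, and fixational image registration error.
Passing tests therefore demonstrate that the pipeline measures what it
claims on images with the assumed structure — not that a clinical cohort
would yield the same numbers.

## Numerical choices and degenerate inputs

* Tessellation needs ≥ 4 distinct centroids; duplicates are removed with a
  warning; an empty mosaic mask yields an empty detection list, not an
  error.
* A zero-visible-area image makes the mosaic-area ratio undefined
  (raised); a zero-variance column makes its correlations missing (NaN).
* Neighbor edges shorter than 1e-9 px do not count (square-lattice corner
  contacts are not adjacency).
* Profile bins are right-open except the last, which absorbs its upper
  edge.
* Morphological closing and erosion pad with edge replication so frame
  borders are not spuriously masked.

## Problem sizes used in the checks

The bundled checks run at sizes chosen to exercise the full geometry while
remaining desk-scale: oracle comparisons on ≤ 50 points × 200
configurations; neighbor-topology and density-recovery experiments on full
2048-px frames (≈ 24k RPE / 38k PR cells per frame, 5 scenes per modality)
in the acceptance script, and reduced 512–1024-px variants (2 scenes, 40
synthetic eyes for age trends) in the test suite.

## Known limitations

* The fixation-based origin can be hundreds of µm from the true foveal
  centre; eccentricity profiles inherit that offset.
* The classical detector is tuned for clean, noise-calibrated synthetic
  scenes; clinical images with hypo-/hyper-reflective pathology would
  need the swappable detector interface.
* The grid-square unit of analysis quantizes eccentricity at ~0.84°; cell-
  level binning would sharpen profiles at the cost of weakening the
  ≥200-cell reliability filter.
* Five acquisition zones are a configuration default, not a constraint;
  protocols with six or more zones are supported by editing the zone list.
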