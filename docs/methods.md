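# Methods

`phalanxmap` re-implements, as a tested pipeline, the cortical-bone
morphometric workflow used to compare great-ape proximal phalanges:
cortical thickness mapping over the diaphysis, cross-sectional geometric
properties, included-angle longitudinal curvature, and the multivariate /
nonparametric statistics that compare taxa. Because the microCT scans
behind the original comparative study are not publicly deposited, the
pipeline is exercised end-to-end on parametric phantoms whose thickness
field, curvature and section properties are known in closed form. This
note documents the models, the parameters that matter, the numerical
choices, and what the phantom-based validation does and does not show.

## Coordinate convention

One fixed frame everywhere: proximodistal axis = +z (proximal at low z),
dorsal = +y, radial = +x. The circumferential angle φ is measured in
degrees from dorsal, increasing toward +x; palmar is φ = 180°.

## Phantom model (`phantom`)

A phantom is a pair of watertight triangulated surfaces swept along a
circular-arc centerline lying in the dorsopalmar (y–z) plane:

- **Centerline.** Total arc length = `length_mm`. The *shaft* portion
  (`shaft_start`–`shaft_end`, default 15–85%) subtends the included angle
  θ = `included_angle_deg`, so the arc radius is
  R = (shaft arc length)/θ[rad]; θ = 0 degenerates to a straight segment.
  θ is attached to the shaft, not the whole bone, because the
  included-angle measurement can only ever see the diaphyseal midline —
  the epiphyses are excluded by the ROI by definition.
- **Outer wall.** Radius profile = mid-shaft radius × a flare/taper factor
  (quadratic in shaft fraction; `taper` is the fractional mid-shaft
  reduction relative to the flared ends) × a dorsopalmar elliptical
  flattening (default 10%), plus outward Gaussian ridge bumps carrying
  half of the flexor-sheath-ridge (FSR) amplitude. Hemispheroidal caps
  close the bone outside the shaft; the proximal (base) cap is flared 18%
  wider than the distal (trochlea) cap so "larger end = proximal" holds by
  construction.
- **Thickness field.** t(s, φ) = t₀ + FSR bumps (Gaussian in φ at
  `fsr_angles_deg`, default 120°/240°, σ = 10°, windowed along the shaft
  with a Gaussian centred at `fsr_window_center`) + a distodorsal term
  (∝ s², Gaussian in φ about dorsal, σ = 40°). The endosteal wall sits at
  outer radius − t; the medullary cavity closes inside the caps, or
  earlier when `lumen_fill_distal_fraction` > 0 (emulating distally
  in-filled cortices). Positivity and non-collapse are validated at
  construction.
- **Noise.** Per-vertex radial Gaussian noise (clipped at 3 sd), seeded.
  Draws are dimensionless × `noise_sd`, so scaling every mm parameter by c
  scales the mesh by exactly c (similarity equivariance is bit-exact).
- **Taxon archetypes.** `taxon_preset` encodes only the comparative
  ordering reported for the four genera — *Pongo* strongly curved/thin,
  *Gorilla* straight/thick with prominent distally-shifted FSRs, *Pan*
  intermediate, *Homo* nearly straight, thinnest, distodorsally
  thickened. The magnitudes are this package's documented constants, not
  measurements. `cohort_specs` adds lognormal inter-individual variation
  (CVs ≈ 4–10%) around an archetype.

Phantoms emulate segmentation roughness and gross inter-taxon pattern;
they do **not** emulate trabecular bone, porosity, real epiphyseal
anatomy, or asymmetric ridges. Passing phantom tests therefore
demonstrates the correctness of the measurement chain, not biological
realism.

## Voxel path (`cortex`)

`voxelize` rasterizes a mesh pair slice-by-slice (mesh–plane sections →
point-in-polygon on voxel centres); masks are flagged `undersampled` when
the voxel exceeds ⅓ of the minimal design thickness. The extraction stage
is a deliberately simple, fully documented analogue of the
morphological-filter + ray-casting workflow used on segmented microCT:

1. `fill_bone`: closing (2-voxel ball) + per-slice and 3D hole filling;
   idempotent on solid masks.
2. `cast_inner_boundary`: per axial slice, a 1° ray fan from the slice
   centroid records the last non-bone voxel before the first cortex hit;
   the enclosed polygon becomes the medullary mask. A slice whose
   centroid is already bone **fails** — the same failure mode that forced
   exclusion of distally in-filled specimens in the original workflow.
3. `check_exclusion`: any failed slice inside the shaft ROI excludes the
   specimen (strict reading); failures in the epiphyses are tolerated.
4. `surfaces_from_masks`: marching cubes at the 0.5 level + Taubin
   smoothing (10 iterations; shrinkage-free to first order, so thickness
   is preserved).

Round-trip accuracy (mesh → voxels → surfaces → thickness map) is
voxel-limited: mean error ≈ 0.25 voxel, max < 2 voxels, decreasing
monotonically as voxels halve.

## Thickness mapping (`mapping`)

- **Orientation.** Principal axis of the periosteal vertices → +z; the
  larger end (by lateral spread of the end quartiles) → low z. Dorsal is
  recovered from planar-section cues: primarily the bow of the section
  centroid curve (the shaft apex bulges dorsally), secondarily the
  radial-excess direction of the outlines (ridges sit palmar). If both
  cues are negligible the ambiguity is flagged and an optional
  `dorsal_hint` is honoured. A negative enclosed volume flags mirrored
  input.
- **ROI.** The shaft runs between supplied fractions of the z-extent
  (phantoms self-declare theirs); the crop extends 2% **of the ROI span**
  beyond each end, so that all section levels from 2% to 98% fall inside
  cropped geometry.
- **Sections.** 97 planes ⊥ z at 1% increments from 2% to 98% of ROI
  length; the largest intersection loop per surface is kept. A missing
  endosteal loop raises the exclusion error.
- **Landmarks.** 50 equiangular rays from the centroid of the cortical
  ring area (outer minus inner region), the first ray dorsal. On each
  outline the landmark is the ray's *farthest* boundary crossing — the
  tie-break that stays stable when FSR ridges make outlines concave.
  Thickness = external − internal ray parameter, i.e. the length of the
  line between the paired landmarks. 97 × 50 = 4850 values per bone.
- **Scaling.** Maps are divided by bone length (z-extent of the oriented
  periosteal mesh) or, alternatively, by the geometric mean of length and
  three breadths (mid-shaft, base at 7.5%, trochlea at 92.5% of length).
- **Palmar/dorsal partition.** 13 rays centred on each of the dorsal and
  palmar midlines (26 of 50); the 12 medial + 12 lateral rays — where the
  FSRs live — are excluded, so the ratio compares ridge-free cortex.
  Sector size must be odd (centred) and non-overlapping.
- **Rendering.** Unrolled 2D map (rows = sections proximal→distal,
  columns = rays with dorsal centred), per-bone colour scale; CSV written
  with `%.17g` so the matrix round-trips bit-exactly.

Exact-annulus accuracy is limited only by polygon chords: for circular
sections of radii R (outer) and r (inner) sampled with n circumferential
vertices, the thickness error is bounded by (R + r)(1 − cos(π/n)); the
suite asserts with this bound, not a loose tolerance.

## Cross-sectional geometry (`csg`)

Shoelace (Green's theorem) area and second moments per polygon, winding
auto-corrected, self-intersection rejected via shapely. Ring properties
combine outer − inner with the parallel-axis theorem about the ring
centroid: CA (mm²), Ixx/Iyy (mm⁴, x = radioulnar, y = dorsopalmar),
J = Ixx + Iyy, and Z_pol = J / r_max with r_max measured from the ring
centroid to the periosteal outline (the centroid convention; bending-axis
section moduli are out of scope). Sampled at 35/50/65% of shaft length.
Convergence to the annulus closed forms is O(1/n²).

Length-scaling divides each property by the bone length raised to its
length dimension (CA/L², J/L⁴, Z_pol/L³) so scaled values are invariant
under isometry; a `power="linear"` option reproduces naive division by L
for sensitivity checks.

## Included-angle curvature (`curvature`)

The shaft midline is modelled as a circular arc; θ is the angle it
subtends. The estimator:

1. For each section, rays from the ring centroid along ±y locate the
   dorsal and palmar periosteal silhouette. For a shaft of locally
   constant radius a these profiles are *exact offset circles* (radii
   R ± a, same centre) of the centerline arc.
2. Each profile gets a **Taubin** algebraic circle fit. Taubin is
   closed-form and essentially unbiased on shallow arcs; the simpler Kasa
   fit was tried first and rejected because it invents curvature at the
   noise scale when the true sagitta is small (a noisy straight tube came
   back as θ ≈ 4° instead of 0; Taubin: 0.03°).
3. The two *signed curvatures* are averaged — a proximodistally varying
   radius (taper) perturbs the two profiles with opposite sign, so the
   mean cancels it; averaging radii does not. The finite offset is then
   corrected by inverting κ̄ = R/(R² − a²) with the measured half-gap a.
4. θ is the arc angle of that circle between the proximal and distal ROI
   boundary planes (extrapolating the 2–98% sample to the full shaft).
   Collinear/curvature-free profiles short-circuit to θ = 0 exactly.
5. Three replicates re-fit on seeded random 80% subsets of the sections,
   emulating repeated manual measurements; `theta_mean` is their average.

Validity limit: planar z-sections sample the palmar offset circle only
while a/R < 1 − sin(θ/2). The canonical curvature-validation phantoms are
therefore slender arc tubes (60 mm long, 2 mm radius, 0.5 mm wall,
taper 0), for which recovery is within 0.7° up to θ = 120° (and within
~1° at surface noise of 0.05 mm). On tapered, flattened, ridged presets
the residual bias is a few percent — adequate for ordering taxa, and an
honest reflection of the method's own documented imprecision.

## Statistics (`stats`)

- **PCA**: covariance form (column-centred, *not* unit-variance scaled —
  the 4850 variables share units and unit scaling would inflate
  low-signal rays); deterministic sign convention (largest-|loading|
  positive).
- **PERMANOVA**: pseudo-F from the squared Euclidean distance matrix of
  the first three PC scores,
  F = (SS_between/(g−1)) / (SS_within/(n−g)); p = (1 + #{F* ≥ F}) /
  (1 + n_perm) under seeded label permutation, or complete enumeration of
  distinct assignments for small n (`method="exact"`). Pairwise tests use
  Bonferroni (multiplier = number of pairs, capped at 1). Degenerate
  all-identical data returns F = 0, p = 1. skbio's implementation is used
  in the test suite as an independent oracle only.
- **Normality gate**: per-group Shapiro–Wilk at α = 0.05; any failure (or
  a group smaller than 3, or constant) routes to the nonparametric path.
- **Kruskal–Wallis + Dunn**: tie-corrected H (scipy) with χ² p; Dunn z
  from mean ranks with the tie-corrected variance, reporting both raw and
  Bonferroni-adjusted p (the adjustment choice is often unstated in
  applied work, so both are exposed).
- **Paired palmar vs dorsal t**: on (palmar − dorsal), so dorsal-dominant
  cortices give negative t.
- **Curvature–thickness regression**: OLS of mean scaled thickness on θ,
  digits pooled within taxon.

All permutation procedures are bit-reproducible for a given seed, and
p-values respect the 1/(n_perm+1) lower bound. Calibration loops use
999 permutations: the attainable level just below 0.05 is then 49/1000 =
0.049, closest to nominal (with 199 it is 0.045, which visibly biases a
500-replicate type-I estimate low).

## Pipeline (`pipeline`, `cli`)

`RunConfig` (YAML/JSON round-trippable) drives simulate → orient → map →
CSG → curvature → statistics. Every stochastic stage is seeded from the
config seed; re-running a config reproduces outputs bit-exactly, and the
manifest records all specs, settings, exclusions (with reasons — never
silent) and SHA-256 checksums of every output file. The `phalanxmap`
console script exposes `simulate`, `extract`, `map`, `csg`, `curvature`,
`stats` and `run`.

## Problem sizes used in validation

Default analysis phantoms use 160–200 axial × 96–256 circumferential
vertices; the discrimination cohort is 10 + 10 specimens at 160 × 96; the
voxel round-trip uses a 20 mm phantom at 0.15–0.6 mm voxels; calibration
uses 500 null replicates of n = 20 at 999 permutations. These sizes make
every oracle's error regime visible (chord bounds, voxel-limited
tolerances, binomial noise of rejection rates) while keeping a full run
in minutes on one CPU core.

## Known limitations

- Sections are planar and ⊥ z; for strongly curved shafts they cut the
  tube obliquely, which slightly inflates mapped thickness toward the
  ends (faithful to the mapped workflow, but worth remembering when
  comparing to the analytic field).
- The dorsal-direction cue needs either a visible shaft bow or palmar
  ridge mass; a perfectly straight, unridged bone is flagged ambiguous
  rather than guessed.
- Z_pol uses r_max from the ring centroid; principal-axis section moduli
  and Imax/Imin analyses are out of scope.
- The voxel ray-casting stage is a documented simplified analogue of the
  proprietary workflow it emulates; no bit-compatibility is claimed.
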