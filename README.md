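# phalanxmap

Cortical-bone morphometrics of proximal phalanges: diaphyseal thickness
mapping, cross-sectional geometry, longitudinal curvature, and the
statistical comparisons used to contrast locomotor groups — packaged as a
tested, reproducible pipeline with a parametric phantom generator for
ground-truth validation.

## Who this is for

Biological anthropologists and skeletal biologists who quantify how
cortical bone is distributed along the finger-bone shaft. Great apes load
their fingers very differently (knuckle-walking, suspensory hook grips,
manipulation), and those loading regimes are hypothesised to leave
signatures in where the diaphyseal cortex is thick, how rigid the
cross-sections are, and how curved the shaft is. The pipeline measures
all three from periosteal/endosteal surface pairs (or a segmented voxel
mask) and runs the comparative statistics.

## What it computes

For each bone, oriented into a canonical frame (+z proximodistal, +y
dorsal):

- **Thickness map** — the shaft region of interest (ROI, base to
  trochlea, cropped with a 2% buffer) is cut into **97 cross-sections**
  (1% increments, 2–98% of ROI length); each section receives **50 paired
  equiangular semi-landmarks** on the periosteal and endosteal outlines,
  rays starting at the centroid of the cortical ring; thickness is the
  ray-segment length between paired landmarks → a 97 × 50 matrix
  (**4850 measurements per bone**), raw (mm) or scaled by bone length.
- **Cross-sectional geometry** at 35/50/65% of shaft length — cortical
  area CA (axial strength), polar moment of area J = Ixx + Iyy (bending /
  torsional rigidity) and polar section modulus Z_pol = J / r_max
  (maximum bending strength), from exact polygon moments.
- **Included-angle curvature** θ — the shaft midline is modelled as a
  circular arc; θ is the arc angle between the proximal and distal ROI
  boundaries (0° = straight), measured with a three-replicate protocol.
- **Statistics** — covariance PCA over the 4850 thickness variables;
  omnibus + pairwise permutational MANOVA (Euclidean pseudo-F on PC1–3,
  Bonferroni-corrected); Shapiro–Wilk-gated Kruskal–Wallis + Dunn tests;
  paired palmar-vs-dorsal t-tests (dorsal-dominant ⇒ negative t);
  curvature–thickness OLS regression with digits pooled.

A `synthetic` phantom family with fully known thickness field, curvature
and section properties (four great-ape archetypes: `pongo`, `gorilla`,
`pan`, `homo`) provides end-to-end oracles, and a voxel path
(fill → 1° ray-cast of the medullary boundary → marching cubes) emulates
the segmented-microCT workflow, including the exclusion rule for shafts
whose medullary cavity is filled with bone distally.

## Worked example

```python
from phalanxmap import taxon_preset, generate_mesh_pair, mapping
from phalanxmap.csg import csg_at_levels
from phalanxmap.curvature import measure_ia

spec = taxon_preset("gorilla", seed=1)          # thick-walled, ridged archetype
pair = generate_mesh_pair(spec)                 # watertight surface pair
pair, info = mapping.standard_orientation(pair)
roi = mapping.define_roi_from_frame(pair)
tmap = mapping.compute_thickness_map(roi)
L = mapping.bone_length(pair)
smap = mapping.scale_map(tmap, L)
palmar, dorsal, ratio = mapping.palmar_dorsal_partition(smap)
ia = measure_ia(roi, seed=1)

print(f"sections x rays: {tmap.values.shape}, bone length {L:.2f} mm")
print(f"mean thickness {tmap.values.mean():.3f} mm (scaled {smap.values.mean():.4f})")
print(f"palmar/dorsal ratio {ratio:.3f}")
print(f"included angle {ia.theta_mean:.1f} deg, arc radius {ia.circle_radius:.1f} mm")
for p in csg_at_levels(roi):
    print(f"level {p.level:.0%}: CA {p.CA:.1f} mm^2, J {p.J:.0f} mm^4, Zpol {p.Zpol:.0f} mm^3")
```

prints

```
sections x rays: (97, 50), bone length 39.93 mm
mean thickness 1.644 mm (scaled 0.0412)
palmar/dorsal ratio 1.019
included angle 26.6 deg, arc radius 60.2 mm
level 35%: CA 48.8 mm^2, J 1167 mm^4, Zpol 189 mm^3
level 50%: CA 49.6 mm^2, J 1159 mm^4, Zpol 189 mm^3
level 65%: CA 50.8 mm^2, J 1223 mm^4, Zpol 194 mm^3
```

Reading the numbers: the gorilla-like archetype is a robust, mildly
curved shaft (θ ≈ 27° vs its 25° design, the residual being the planar-
sectioning bias discussed in `docs/methods.md`); its mean cortical
thickness of 1.64 mm is the thickest of the four archetypes; the
palmar/dorsal ratio near 1 reflects a shaft whose extra palmar bone sits
entirely on the flexor-sheath ridges, which the 13-ray dorsal/palmar
sectors deliberately exclude; and CA/J/Z_pol are nearly level-independent
because the archetype's taper is mild between 35% and 65%.

The same analysis runs from the shell:

```bash
phalanxmap simulate --preset gorilla --n 10 --seed 7 --out bones/
phalanxmap map --periosteal bones/gorilla_00_periosteal.ply \
               --endosteal  bones/gorilla_00_endosteal.ply --out maps/
phalanxmap run --config run.yaml     # full cohort pipeline with manifest
```

## Layout

| module | contents |
|---|---|
| `phalanxmap.phantom` | `PhalanxSpec`, phantom mesh/voxel generation, taxon presets, cohorts |
| `phalanxmap.cortex` | voxel mask → filled bone → ray-cast medullary region → surfaces, exclusion rule |
| `phalanxmap.mapping` | orientation, ROI, 97 sections, 50 paired landmarks, thickness maps, palmar/dorsal partition |
| `phalanxmap.csg` | polygon moments, ring properties (CA, Ixx, Iyy, J, Z_pol), length scaling |
| `phalanxmap.curvature` | silhouette circle fits, included angle, replicate protocol |
| `phalanxmap.stats` | PCA, PERMANOVA (+ exact enumeration), Shapiro gate, Kruskal–Wallis + Dunn, paired t, regression |
| `phalanxmap.pipeline` / `phalanxmap.cli` | seeded end-to-end runs, manifests, fixture suite, `phalanxmap` CLI |

`docs/methods.md` documents the models, parameter defaults, numerical
choices and known limitations in detail.
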