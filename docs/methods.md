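# Methods

## Problem and pipeline

Metopic suture closure produces a spectrum of orbitofrontal deformity:
from a benign midline ridge with near-normal orbits to trigonocephaly with
a keel-shaped forehead and retruded lateral orbital rims. `craniocurve`
quantifies that spectrum from head-surface triangle meshes in four stages:
(1) mesh ingestion and repair, (2) per-vertex signed mean curvature,
(3) landmark-anchored region means, (4) two-group k-means severity
classification with clinician-agreement scoring. The pipeline starts at
STL; DICOM ingestion, bone thresholding and surface reconstruction are
upstream and out of scope, as is automatic landmark detection. CT (bone)
and stereophotogrammetry (skin) surfaces are treated identically; no
cross-modality adjustment is applied.

## Mesh handling

STL carries no units; millimetres are assumed (the CT/3dMD convention) and
curvature is converted to m⁻¹ (× 1000). On load, duplicate vertices are
merged at 1e-6 mm — far below scanner precision, so this only removes STL
triangle-soup duplication — degenerate faces are dropped, and face
windings are made consistent. Outwardness is decided by signed volume for
closed meshes and by majority vote of face normals against centroid-to-face
vectors for open ones (stereophotogrammetry captures have boundaries, so
signed volume is undefined). Landmarks are snapped to the exact nearest
surface point; a snap beyond 10 mm raises an error, a bound generous for
annotation error but tight enough to catch coordinate-frame mismatches.

## Curvature estimation

The primary estimator is the cotangent Laplace–Beltrami operator with
mixed Voronoi vertex areas: the mean-curvature-normal vector at vertex i is
K_i = (1/2A_i) Σ_j (cot α_ij + cot β_ij)(v_i − v_j), and H = |K|/2 signed
by dot(K, outward normal). The sign convention makes a ridge positive and
a retruded (concave) orbit negative. The mixed-area rule clamps the
circumcentric split for obtuse triangles (half area to the obtuse corner,
quarter to each other), so vertex areas partition the surface exactly —
the tests assert Σ A_i equals the total area to 1e-9 relative.

Boundary vertices have incomplete one-rings and are excluded from all
downstream averages rather than extrapolated; a vertex whose mixed area
degenerates to zero is likewise flagged invalid with a warning.

An independent quadric-patch estimator (least-squares fit of
z = ax² + bxy + cy² over the 2-ring in the local normal frame, H = −(a+c)
on the outward-normal convention) ships as a cross-check. On sphere
fixtures both estimators agree with 1/r within 2%, and on generated heads
their median absolute disagreement stays below 5% of the field's
interquartile range; all region means and acceptance checks use the
cotangent estimator.

Optional umbrella smoothing (area-weighted one-ring averaging including
the centre vertex) is available for noisy scan data; the default is 0
iterations, since nothing is known about smoothing in the clinical
workflow this mirrors and the synthetic fixtures need none.

## Regions

A "rectangular" strip on a curved surface is realised without geodesic
machinery:

* **mid-forehead strip** — vertices within ±width/2 (default full width
  10 mm) of the midline plane through glabella, anterior fontanelle and
  the mesh centroid, restricted to the axial extent of the
  glabella→fontanelle segment. If the three points are near-collinear
  (antipodal anchors on a sphere fixture) any plane containing the axis is
  equivalent by symmetry and a deterministic perpendicular is used.
* **supraorbital strips** — vertices within `width` (default 10 mm) of the
  rim polyline, on the "above" side (positive component along an up-hint,
  which defaults to rim-centroid → anterior fontanelle), and projecting
  within the polyline's arc-length extent. The rim polyline's own extent
  defines the lateral-to-mid-orbit span; nothing is inferred beyond it.

The 10 mm figure is interpreted as full width about the midline plane for
the forehead strip and as band depth above the rim for the orbital strips;
both are configurable. Region means are area-weighted (mixed Voronoi
weights), making them invariant to tessellation density; unweighted vertex
averaging would drift with mesh refinement.

## Features and group statistics

Left/right orbital means are pooled per subject by simple averaging
(h_orb = (left + right)/2); per-side values are retained, and a
three-feature clustering mode (h_mid, h_orb_left, h_orb_right) exists.
Group summaries use the sample (n−1) standard deviation. Group comparison
defaults to Welch's unequal-variance t-test — the two groups differ in
size and spread — with Student's pooled test available. The t statistic is
oriented so the affected group (operative/surgical/severe under
conventional label pairs) is the minuend.

## Clustering

k is fixed at 2 (the BMR/MCS dichotomy); no model selection. Lloyd
iterations with k-means++ initialisation and 50 independent restarts
(scikit-learn backend), deterministic given the seed; rows are canonically
ordered before clustering so the result is invariant to subject order.
Features are clustered in raw m⁻¹ — their spreads are comparable (≈5–7 vs
≈5–6 m⁻¹) — with z-scoring available. The severe cluster is defined as the
one with the larger mid-forehead centroid, ties broken by the smaller
orbital centroid. Agreement maps severe ↔ operative, mild ↔ conservative
and reports the concordant fraction, discordant ids and the 2×2 table.

## Synthetic data

* **Fixtures** (sphere r=100 mm → H=+10 m⁻¹, open cylinder r=50 mm →
  +10 m⁻¹, plane → 0, dented sphere for sign checks) certify estimator
  accuracy, convergence and sign.
* **Parametric heads**: an ellipsoid (semi-axes 65 × 80 × 75 mm, roughly
  infant head scale) built from a mirror-symmetric subdivided octahedron,
  deformed along the surface normal by (a) a midline Gaussian ridge
  (sd 6 mm across the midline, amplitude 1 + 7·`ridge_sharpness` mm,
  windowed to the glabella→fontanelle arc) and (b) an inward supraorbital
  Gaussian trough (depth 7·`orb_retrusion` mm centred 6 mm above each
  rim). Landmarks are emitted at deformed mesh vertices, so they lie
  exactly on the generated surface and the landmark-derived midline plane
  coincides with the generator's true symmetry plane. Amplitude-driven
  dials make the strip means strictly monotone in the dials, and the
  deepest scoops turn h_orb negative — the qualitative signature of the
  severe phenotype. The generator certifies segmentation geometry,
  monotonicity and bilateral symmetry; it does **not** claim anatomically
  realistic absolute curvatures, so mesh-level tests validate geometry,
  not clinical values.
* **Cohorts**: per group, (h_mid, h_orb) is drawn from a bivariate normal
  at the packaged published group statistics (severe 38.6 ± 7.1 and
  −6.7 ± 4.7 m⁻¹, n=16; mild 28.0 ± 4.9 and 10.6 ± 5.5 m⁻¹, n=27; a
  treatment-group variant 39.0 ± 6.9 / −5.9 ± 5.7 vs 27.7 ± 4.6 /
  10.2 ± 6.3). The between-feature correlation is unreported clinically;
  the default is ρ = 0, configurable, and all shipped simulations state
  their ρ. Left/right orbital values are split h_orb ± δ, δ ~ N(0, 1 m⁻¹),
  preserving the pooled mean exactly. Cohort-level simulations exercise
  the statistics and clustering stages under the reported effect sizes;
  they inherit the normality assumption and cannot reveal non-Gaussian
  tails or measurement error present in real feature distributions.

## Numerical choices and problem sizes

Head meshes default to subdivision level 6 (16 386 vertices, ≈2.6 mm edge
length), which resolves the 6 mm ridge profile; fixture tests use levels
3–5 to demonstrate convergence. The clustering simulations use 200 cohorts
and the power simulations 500 replicates — enough for ≈0.3-point Monte
Carlo error on an agreement percentage — and the whole suite plus the
reproduction script runs in well under a minute of compute. Ties in the
severe-cluster rule, empty-cluster handling and degenerate one-rings are
all resolved deterministically as described above, and every generator is
bit-reproducible from its seed.

## Known limitations

* The strip construction is extrinsic (plane/polyline distance bands), not
  geodesic; on strongly curved foreheads the band can be slightly wider on
  the surface than its nominal width.
* The mid-forehead slab predicate is purely geometric; with pathological
  landmark placements (axis tilted far from the sagittal arc) it could
  admit vertices far from the forehead. With anchors at glabella and
  anterior fontanelle the axial extent excludes the posterior skull for
  head-like geometry.
* Welch power at the packaged treatment-group statistics is ≈0.84 for the
  mid-forehead feature at the p < 10⁻⁴ level (noncentrality ≈ 5.8,
  df ≈ 23), so a single simulated cohort will sometimes miss that
  significance threshold on h_mid even though the orbital feature is
  essentially always significant; the package reports exact p-values
  rather than thresholding.
* Severity clustering assumes exactly two phenotypes; subjects genuinely
  intermediate on the spectrum are forced to one side.
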