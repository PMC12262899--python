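# Methods

This note records the models, numerical choices and open-design decisions
behind `cardiotwin`, and what the synthetic tests do and do not demonstrate.

## Synthetic phantom

The phantom is an analytic biventricular geometry rasterized into the four
cine views through each view's own voxel-to-world affine, so every stage
consumes exactly the data layout a real study provides.

* **LV**: truncated prolate ellipsoid shell. Endocardial semi-axes default
  to 25/25/45 mm (cavity = half-ellipsoid below the base plane,
  EDV ≈ 58.9 mL); wall thickness 10 mm. Cavity semi-axes scale by
  `v(t)^(1/3)` so cavity volume is exactly `v(t)` times its ED value while
  the epicardium stays fixed (the wall thickens in systole).
* **RV**: the part of a laterally offset ellipsoid (default center +30 mm,
  semi-axes 28/28/48 mm) outside the LV epicardium — a crescent. Because
  the crescent empties superlinearly when the ellipsoid scales with the LV
  transient, the RV scale factor is damped (`v_rv = 1 − 0.6(1 − v)`),
  keeping phantom RV ejection fraction in the normal 50–65% range.
* **Atria and aorta** are geometric placeholders (half-ellipsoid caps above
  the base plane, a tube in the 3-chamber plane) — sufficient for the
  valve-plane and aortic landmark interfaces to exist, not anatomically
  detailed. Atria scale reciprocally (`va = 2 − v`), largest at ES.
* **Transient** `v(t)`: cosine dip from 1 at frame 0 to
  `es_volume_fraction` (default 0.4 ≈ 60% EF) at `es_frame` (default 18 of
  50) and back — smooth with a single minimum.
* **Acquisition**: 1.8×1.8×8 mm SAX stack (10 slices), 1.6×1.6×6 mm
  single-slice LAX planes, 50 frames. Breath-hold misalignment: seeded
  zero-mean in-plane shifts per SAX slice and per LAX view, constant over
  the cycle, labels resampled nearest-neighbor so they remain integral.

What the phantom does **not** emulate: image intensities, segmenter errors
(beyond misalignment), papillary muscles, trabeculation, valve anatomy,
through-plane motion, arrhythmic cycles. Tests passing on phantoms show
the geometry processing is correct under known ground truth; they do not
certify performance on real segmentations.

## Frame selection

ES = argmin over frames of the summed LV-cavity voxel count (LAX views +
five SAX mid-slices). "Five mid-slices" is centered at `floor(n/2)`
(`{m−2..m+2}`); the center convention for even counts was open and is
fixed here. Ties break to the earliest frame for determinism. Absent views
are dropped from the sum.

## Contours and landmarks

Per structure: largest 4-connected component, boundary traced as the
0.5-level iso-contour (sub-voxel), lifted through the affine. The RV
boundary splits into septum (within 2 px of the LV cavity∪myocardium
region, by distance transform) and free wall; the criterion was open and
this is the reference decision. Valve landmarks are the extremal points of
the 4-adjacent label-interface point set along its principal direction;
the 3-chamber mitral interface uses cavity-against-background (no atrial
label exists in that view), minus the aortic interface. Basal SAX slices
where the LV cavity touches the image border are excluded (truncation
guard). The apex is an exhaustive farthest-point search over the
epicardial contour — property-tested against a brute-force oracle.

## Surface fitting

The template is a synthetic idealized biventricular surface built from the
same analytic geometry (surfaces of revolution for the LV; stacked
crescent cross-section rings for the RV; fan lids closing the mitral,
aortic, tricuspid and pulmonary orifices and the epicardial base). It is
*not* a population atlas: fixed connectivity and regularized fitting are
the testable contract, and all fits are vertex-wise corresponded.

Deformation model: per-vertex displacement `d` from the landmark-aligned
template, minimizing data term (squared distance of each contour point to
its nearest same-region vertex) plus `λ‖L d‖²` with `L` the uniform graph
Laplacian — a deliberate simplification of diffeomorphic atlas fitting.
Alternating exact sparse solves with correspondence updates makes the
objective non-increasing (asserted in tests). λ follows a coarse-to-fine
schedule (1.0, 0.3, 0.08 for 10/10/25 iterations), calibrated once on
phantom self-fit fixtures; ED and ES are fitted independently.

Known bias: nearest-vertex (point-to-vertex) correspondences settle
vertices at the centroid of their matched boundary points, which lies
slightly inside a curved surface. Fitted LV cavity volumes therefore run
≈5–8% low against analytic truth (relative RMS ≈6% over 20 seeded
phantoms). The bias largely cancels between ED and ES, so ejection
fractions agree with segmentation-derived ones within ≈5 percentage
points — the same behavior that motivates the cohort QC rule.

Per-slice in-plane misalignment correction: each slice's contours are
translated by the in-plane projection of the mean closest-point residual
against the current surface (3 fixed-point iterations, shift capped at
10 mm).

RV epicardium: RV endocardial vertices offset 3 mm along area-weighted
outward vertex normals; offset self-intersections are detected and
flagged. On a hemi-ellipsoidal patch the mean offset-to-surface distance
measures 2.98 mm (slightly under 3 because the nearest surface point of a
convex offset is marginally closer than the normal foot).

## Volumetric meshing

Walls are meshed by extruding the matched endo/epi surface grids: each
surface triangle sweeps a stack of wedges (default 4 layers for fitted
meshes; 10 ~1 mm layers for the idealized LV fixture), each wedge split
into three tetrahedra with quad-face diagonals through the smallest global
node index — provably conformal across neighbors. Valve lids extrude
2 mm along the basal normal. Elements are tagged at construction with the
six regions; `label_regions` can re-derive tags generically by
point-in-region classification. A Delaunay-plus-carve fallback
tetrahedralizes generic closed surfaces behind the pluggable backend
interface (exact on convex polyhedra, ray-parity carving otherwise);
node ordering is normalized so all signed volumes are positive.

## Coordinates and fibers

Z and ρ are linear-FE Laplace solutions (assembled stiffness matrix,
direct sparse solve): Z from the apex node set (nodes within 2 mm of the
epicardial point farthest from the base centroid — the apex definition was
open) to the basal rim; ρ from endocardial to epicardial node sets, both
chambers in one solve. Φ is the angle about the base-centroid→apex axis
from a configurable reference direction (default: toward the RV centroid,
i.e. through the septum; the zero direction and sector edges were open),
with five equal 72° sectors.

Fibers: per element, transmural axis `ê_t = ∇ρ/|∇ρ|`, longitudinal axis
`ê_l` = ∇Z orthonormalized against `ê_t`, circumferential `ê_c = ê_l×ê_t`.
Fiber = `ê_c` rotated by α(ρ) about `ê_t`; sheet = the in-wall normal
rotated by β(ρ) about the fiber; α, β interpolate **linearly** in the
element-centroid ρ between 60°/−60° and −65°/25° ("from X to Y" leaves the
functional form open; linear is the rule-based standard). Elements with
degenerate gradients (mostly valve lids) copy the nearest valid triad.
Helix/sheet angle measurement functions invert the construction exactly;
regression of helix angle on ρ over the idealized LV mesh returns
intercept 60.0 and slope −120.0.

Note on band averages: a quantity like "mean helix angle over elements
with ρ < 0.05" evaluates the linear law at the mean selected centroid
(≈0.03), i.e. ≈56–57°, not the 60° endpoint itself; the endpoint is
recovered by the regression profile at ρ = 0. The acceptance script
reports the band means as measured.

## QC, binning, averaging

Relative difference uses the segmentation value as denominator (the
denominator was open); exclusion is strict `>` against Q3 + 1.5·IQR with
linear-interpolation quantiles. Duplicating a cohort shifts interpolated
quantiles only marginally (they are exactly invariant only in the large-n
limit); verdicts on the original members are stable. Superimposition is
rigid only — representative anatomies must preserve absolute size, and
bins are size-relevant (BMI) — with the reference loop initialized from
the first mesh in sorted-id order (deterministic stand-in for a random
pick) and iterated to a reference-to-mean Procrustes distance ≤ 1e-6
(centered vertex RMS normalized by reference centroid size; the metric was
open). Averaging is vertex-wise over bins with ≥3 members; representative
volumetric meshes are rebuilt from the averaged surfaces.

Atrial volumes (the method was open, flagged prominently): LA by biplane
area–length `V = (8/3π)·A₂·A₄/L` (2- and 4-chamber areas, shorter length),
RA by single-plane area–length from the 4-chamber view; length runs from
the valve-interface midpoint to the farthest atrial voxel.

## Problem sizes and determinism

Test and acceptance runs use: idealized LV fiber mesh ≈20k elements;
phantom cohorts of 6–20 subjects at the native 1.8 mm SAX resolution with
6–10 frames; the 100-phantom ES-selection sweep at a coarsened 3.6 mm
in-plane grid (frame selection consumes voxel counts, which the coarser
grid preserves). All randomness flows through explicit
`numpy.random.default_rng` seeds; two pipeline runs with the same seed and
configuration produce identical manifests (content hashes of surfaces,
meshes, fibers and phenotypes).

## Known limitations

* The template fit is a regularized ICP, not a diffeomorphic atlas: no
  fold-over guarantee (offset and surface self-intersections are detected
  and reported, mirroring the known RV septum/free-wall failure mode).
* Septal special-casing of full UVC constructions is omitted; Φ is a
  simple axial angle.
* The Delaunay-carve fallback does not enforce boundary-facet conformity
  on non-convex inputs; the extrusion mesher is the production path.
* Phantom realism limits are listed above; no claim is made about
  segmenter robustness on real images.
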