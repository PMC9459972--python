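# Methods

## Problem setting

A face-mesh detector applied to an RGB photograph yields an ordered set of
478 3D landmarks (468 facial + 10 iris) in unit-normalised image
coordinates; landmark indices are anatomically stable across captures, so
index *i* in two captures of the same person denotes the same skin point.
`facesym` quantifies facial-palsy progression from such landmark sets: a
registration stage places captures from different visits (or expressions)
into one frame, and three per-muscle statistics measure static and dynamic
left–right asymmetry.

## Registration

### Scale matching

Rigid registration cannot absorb the scale difference between captures
taken at different camera distances. Scale is therefore equalised first:
for a chosen landmark index *i*, the target cloud is multiplied by
`‖s_i − O‖ / ‖t_i − O‖` about the fixed landmark-coordinate origin
O = (0, 0, 0). No single index is trustworthy a priori — the landmark that
defines the scale may itself have moved with expression or palsy — so the
whole pipeline is swept over the index range (optionally strided) and the
transform with minimal inlier RMSE wins. The inlier RMSE is the
root-mean-square of the per-index residuals `‖T·s_i − t_i‖` over **all** n
landmarks; no residual cutoff is applied, because the index correspondence
makes every landmark a genuine measurement rather than a putative match
(a cutoff can still be imposed through the ICP correspondence gate, which
is a separate, internal threshold).

Origin-anchored scale matching is exact only for poses that preserve norms
about the origin (scale × rotation). Under a translation component the norm
ratio varies per index and no sweep candidate yields an exactly
rigid-compatible pair; registration then degrades gracefully (tested) but
noise-free recovery is no longer exact. This is an intrinsic property of
the origin-based scale factor, acceptable because face-mesh coordinates
place the head near a stable position in the unit image frame.

### Coarse alignment

Global registration is correspondence-free: simplified FPFH descriptors
(Darboux-frame angle histograms, 3 × 11 bins) are computed per landmark and
matched nearest-neighbour in descriptor space, then RANSAC over 3-point
correspondence samples (batched, edge-length prefilter, 99.9%-confidence
early exit, final refit on the inlier set) produces a rigid transform.
Two adaptations matter on sparse, noisy landmark clouds:

* descriptor neighbourhoods are an **annulus** (default 0.06–0.25 of the
  bounding-box diagonal, ≤ 60 neighbours): at realistic noise levels the
  direction to a very close neighbour is noise-dominated, while mid-range
  geometry is stable. Dropping the near field raised the fraction of
  approximately correct feature matches at σ = 0.01 from a few percent to
  ~30%, which RANSAC converts into reliable alignments;
* a scale-normalised distance-from-centroid channel is appended to each
  descriptor. It is rotation-invariant, cheap, and strongly discriminative
  on head-shaped clouds.

All descriptor channels are angle- or ratio-based, so descriptors are
scale-invariant and are computed once per cloud pair, outside the sweep.
Feature normals use a wider neighbourhood (k = 24) than the ICP normals
for stability.

### Refinement

Point-to-plane ICP: nearest-neighbour correspondences gated at 10% of the
target bounding-box diagonal, the linearised least-squares solve of
Σ [(R·s + t − t_c)·n_c]², the update applied as an exact Rodrigues rotation
(R stays orthonormal without a separate re-orthonormalisation step), and
convergence when the relative change of the correspondence RMSE drops below
1e−8 (or 100 iterations). Target normals come from k = 12 nearest-neighbour
PCA (smallest-eigenvalue direction), oriented camera-facing (+z);
degenerate neighbourhoods fall back to +z with a warning.

A point-to-point ICP (closed-form Kabsch update per iteration) and the
coarse global registration alone are provided as baselines. For the
method-comparison benchmark all methods run inside the same scale sweep
with the same min-RMSE selection, so only the registration core differs.
The ICP baselines are initialised with the identity rotation and the
centroid-difference translation Σ(s − t)/N, kept in exactly that printed
sign convention; for a pure translation this moves the source away from
rather than toward the target, but on origin-centred scale-matched clouds
the effect is small.

The stored result transform composes the winning rigid transform with the
inverse of its scale matching, i.e. it maps source landmarks directly into
the original target frame and can be applied to any capture of the source
session. Reported `inlier_rmse` and residuals refer to the scale-matched
frame in which the sweep selection happened; cross-method comparisons in
the benchmark re-evaluate every transform in the original target frame so
all methods and the oracle share one measuring stick.

### Oracle

The closed-form least-squares similarity fit (SVD of the cross-covariance,
with the standard reflection guard) exploits the same index correspondence
and serves as the lower-bound oracle in tests; it is never part of the
pipeline under test.

## Symmetry and movement metrics

The midsagittal plane passes through the midpoint of the left and right
central iris landmarks, with unit normal along the inter-iris vector
(oriented left → right). Which of the five per-eye iris landmarks is "the"
iris is configurable in the topology resource; the central one is the
default.

* **Distance symmetry**: each left landmark is reflected across the plane
  (`p − 2[(p − q)·n]n`) and the Euclidean distance to its right partner
  taken. 0 = perfect symmetry.
* **Angle symmetry**: cosine between the plane normal and the
  right-minus-left pair vector. With this orientation convention perfect
  symmetry scores +1. The per-muscle value averages per-pair cosines; a
  "flattened" variant (one cosine of the stacked group vectors) is exposed
  separately — note it is bounded below 1 whenever pair-vector magnitudes
  differ (Cauchy–Schwarz), which is why averaging is the reporting default.
* **Movement asymmetry**: after registering the smile capture onto the
  neutral capture (neutral is the rest frame), per-side displacement
  magnitudes m_L, m_R are compared per pair; the headline per-muscle value
  averages |m_L − m_R| (signed per-pair values are retained in the report —
  a signed mean would let opposing pairs cancel).

Both static metrics are intrinsic to one capture and rigid-invariant
(asserted to 1e−9 under random rigid motions; the plane is recomputed from
the moved irises). Distance symmetry scales linearly with isotropic scale,
angle symmetry is scale-invariant. Per-muscle aggregation averages over
pairs whose *both* members lie in a group, multiplies by 100 and rounds
(6 decimals for the static metrics, 3 for movement — the magnitude
conventions of the clinical reporting style the tables follow); groups
without internal pairs report an explicit empty marker.

## Face topology resource

Only per-group landmark *counts* are fixed by the clinical grouping
convention (17 groups; e.g. Orbicularis Oculi 59, Orbicularis Oris 44, Nose
Tip 32 in full mode); the actual index assignment is authored here, against
the package's own procedural template, honouring those counts exactly.
Odd-cardinality groups are realised either with a midline member (midline
muscles: Corrugator, Procerus) or with one left-side member whose mirror
partner is ungrouped (lateral muscles) — the published counts are
left/right-asymmetric, so the authored topology reproduces that asymmetry.
Left/right pairing, midline membership and the iris indices are exact by
construction of the mirrored template. The resource files are JSON,
regenerated by `scripts/build_topology_resources.py` and re-validated on
every load (pairing involution, full index coverage, group cardinalities,
iris pairing). The nose-tip group is not a muscle; its spatial extent is a
best-effort anatomical choice around the ridge, tip and alae.

## Synthetic data generator

The generator emulates the capture structure of a longitudinal palsy study
(neutral + smile per visit, several visits) in the unit-normalised
coordinates of a face-mesh detector:

* **Template**: ~0.85 × 1.0 model units, half-face built procedurally on an
  elliptical dome with a nose bump and mirrored across x = 0, so it is
  exactly mirror-symmetric in floating point. Geometry is fixed
  (seed-independent); randomness enters only through jitter/noise draws.
* **Smile**: a Gaussian displacement field centred on the mouth corners
  (s.d. 0.11 model units), direction outward/upward/slightly forward, peak
  amplitude g = 0.08 model units (≈ a 1.5 cm corner excursion on a real
  face). The field depends on |x| only, so symmetric faces stay exactly
  symmetric.
* **Palsy**: multiplicative attenuation α ∈ [0, 1] of the displacement on
  one side — the simplest mechanism that drives all three metrics
  monotonically — plus optional static structural jitter on that side
  (shared between the captures of a subject).
* **Noise and pose**: isotropic Gaussian landmark noise (independent
  between the neutral and smile captures of a session) and an optional
  similarity pose applied last. Ground-truth displacement fields and pose
  matrices are returned with every capture.

The registration benchmark fixes 20 cases: scale ~ U[0.8, 1.25] and a
rotation of U[5°, 25°] about a random axis, both about the origin
(translation-free — see the scale-matching note above), with noise σ
cycling over {0, 0.005, 0.01}; per-case substreams derive from one base
seed. At σ = 0.01 the noise is ~40% of the median landmark spacing, a
deliberately hard regime in which the point-to-plane optimum sits a few
percent above the least-squares oracle.

What the generator does **not** model: non-rigid shape change between
visits, detector-specific correlated errors, occlusion and pose-dependent
landmark drift, and real anatomical variation between subjects. Passing
tests therefore demonstrate correctness of the algorithms under controlled
conditions, not clinical accuracy on real patients; absolute metric
magnitudes on real data depend on the (detector-specific) coordinate
normalisation.

## Longitudinal reports

The first manifest session is the reference. Each later session's neutral
capture is registered onto the reference neutral and the recovered
similarity applied to both captures of that session (the two captures of
one visit share a camera setup), putting all sessions on the reference
scale. Static symmetry is evaluated on the aligned smile capture; movement
asymmetry registers the aligned smile onto the aligned neutral within each
session. With a single usable session only the symmetry tables are
produced. Unreadable sessions are skipped, logged, and surfaced as a
partial-failure exit code (3); usage errors exit 1, validation errors 2.
Identical manifest + configuration + seed give byte-identical CSVs.

Note that the within-session rigid fit absorbs part of a strongly
asymmetric deformation (the fit tilts toward the moving side), shrinking
movement-asymmetry magnitudes relative to their no-registration values;
the ordering across sessions is preserved on the full 478-point topology,
where the mouth region is a small fraction of the cloud. The sparse
68-point mode is too mouth-dominated for this to hold reliably and is kept
for static metrics and format compatibility.

## Numerical choices and problem sizes

* Registration defaults: normals k = 12 (ICP) / 24 (features), ICP ≤ 100
  iterations, relative convergence 1e−8, correspondence gate 10% of the
  target diagonal, RANSAC ≤ 100 000 iterations with 99.9%-confidence early
  exit, seed 0. Ties in nearest-neighbour correspondence resolve to the
  lowest target index (KD-tree order), keeping runs deterministic.
* The sweep default covers all indices; reports and tests use stride 10
  (48 candidates on the full topology), which keeps a full four-method,
  20-case benchmark under two minutes on one core while leaving the
  min-RMSE selection dense enough for scale resolution at the benchmark
  noise levels.
* Perfect-symmetry assertions use identity registration (the analytically
  forced fixed point, exact to well below 1e−9). When a real sweep
  registration is interposed on symmetric-motion data, the recovered
  transform is itself a rigid compromise between two different shapes and
  carries solver-tolerance-level asymmetry (~1e−4 model units in the
  per-pair movement differences); tests assert those two regimes
  separately.
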