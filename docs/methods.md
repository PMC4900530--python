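# Methods

## The data model

A retopologised shell mesh is an ordered stack of X aperture rings,
each a closed loop of Y vertices, stored row-major with ring 0 the
earliest post-protoconch aperture. Consecutive rings are stitched by
(X−1)·Y quads, so every interior vertex has exactly four neighbours.
Coordinates are millimetres throughout; no unit conversion is ever
applied. Validation enforces X ≥ 3, Y ≥ 4, the exact X·Y vertex count,
quads spanning consecutive rings only, finite coordinates and distinct
consecutive ring centroids.

Only ASCII PLY is read and written; binary PLY is rejected with an
explicit message, since the point of the format is that the raw vertex
list is readable without 3D software. The ring size Y is recorded in a
`comment aperturekit ring_size=<Y>` header line on export; on import it
is taken from that comment, from a caller hint, or inferred as the
unique divisor of the vertex count under which every quad has two
intra-ring edges joining cyclically adjacent vertices. Files that store
each grid quad as two triangles are accepted: under a known Y each grid
triangle has exactly one non-grid edge (the quad diagonal) and pairs
are merged back into quads.

## Shell volume

The tube is closed with a centroid-fan triangulation at each end ring,
face orientation is made globally consistent, and the volume is the
absolute signed-tetrahedra sum against the origin (divergence theorem);
the orientation fixing and volume sum are delegated to `trimesh` on the
capped triangulation. Centroid fans are orientation-stable for
star-shaped end rings; self-intersecting caps on strongly non-convex
final apertures are *not* detected — a known limitation. Volume is
translation/rotation invariant and scales as s³ under uniform scaling.

## Curvature and torsion of the ontogeny axis

The ontogeny axis is the trajectory of one marker vertex (default ring
index 0) through all X rings. At each point i a local polynomial
r(u) = a₀ + a₁u + … (3-vector coefficients, one independent weighted
least-squares fit per coordinate) is fitted over the window
{i−q, …, i+q}, truncated one-sidedly at the ends so the profile always
has X rows. The parameter u is signed cumulative chord length from
point i; since κ and τ are invariant under reparametrisation, the
chord-length parameter serves as the local arc-length approximation.
Weights are w(u) = (1 − (|u|/u_max)²)², with u_max set 5% beyond the
window span so the outermost samples keep a small nonzero weight
(a weight that is exactly zero at the edge would discard two samples
and under-determine the fit at small q); tricube and Gaussian kernels
are selectable. Then at u = 0:

κ = |r′×r″| / |r′|³  τ = det(r′, r″, r‴) / |r′×r″|²

with r′ = a₁, r″ = 2a₂, r‴ = 6a₃.

**Window size.** q counts points *per side* and defaults to
max(2, round(0.10·X)) — the 10% rule. Like any local estimator it has a
bias/variance trade-off; `convergence_scan` tabulates estimates over
several q so a converged window can be chosen, and the test suite
verifies that the error on an analytic helix falls with sampling
density and that noise variance falls with q.

**Fit degree.** The degree is configurable and defaults to 5. A cubic
is the minimum that carries a third derivative for torsion, but its
truncation bias grows with the fourth power of the window's turning
angle and reaches ~2% already when a half-window subtends ~0.6 rad of a
circular arc — i.e. at the default 10% window on realistically sampled
shells. The quintic keeps the same estimator structure while pushing
that bias two orders of magnitude down; degree 3 remains available for
very short or very noisy axes.

**Arc length.** Cumulative axis length integrates the fitted speed
|r′(u)| over each inter-point interval (5-point Gauss–Legendre),
falling back to the plain chord where no adequate fit exists. s₀ = 0
at the first aperture.

**Degenerate frames.** Where |r′×r″| vanishes (locally straight axis)
torsion is undefined; it is reported as 0 with a `degenerate_frame`
flag rather than NaN, so profiles remain usable downstream.

Estimator invariances verified by tests: rigid motions leave κ, τ and
arc length unchanged; reflections flip the sign of τ only; uniform
scaling by s multiplies arc length by s and divides κ and τ by s.

## Aperture size and shape

Size is the outline perimeter: the sum of Euclidean edge lengths
including the closing edge. Duplicate consecutive vertices contribute
zero length and trigger a warning.

Shape uses elliptic Fourier analysis extended to three coordinates:
x(t), y(t), z(t) are each expanded to n harmonics (default 5, giving
6n = 30 coefficients) in the cumulative chord-length parameter of the
closed polygon, with the closed-form integrals for a piecewise-linear
outline — hence no equal-spacing assumption, and robustness to uneven
vertex placement (verified to ~1e-4 on unevenly resampled circles).

Normalisation removes starting point, orientation and size in three
steps: (1) the parameter origin is phase-rotated so the first-harmonic
trace starts on its semi-major axis (the phase extremising the
first-harmonic radius, which also makes the two first-harmonic
semi-axes orthogonal); (2) the rigid rotation taking the semi-major
axis to +x, the semi-minor to +y and the first-harmonic ellipse normal
to +z is applied to every harmonic's coefficient vectors; (3) all
coefficients are divided by the semi-major axis length and the DC term
dropped. Two phases put the start on the major axis (opposite ends);
the candidate whose flattened coefficient vector is lexicographically
larger is chosen, making the result deterministic and invariant to the
input's placement, scale and starting vertex (property-tested over 100
random similarities and all cyclic reindexings). The frame is built
right-handed from the outline's own trace, so *reflections are not
normalised away*: coiling chirality is preserved in the coefficients.

Aperture shape scores are the projections of the normalised coefficient
vectors on the principal components of the *pooled* coefficient matrix
across all shells in an analysis (centred, covariance PCA — the
coefficients are dimensionless and commensurate after normalisation).
Components are retained up to >90% cumulative explained variance, and
loading signs are fixed deterministically (largest-magnitude loading
positive). Scores are context-dependent by construction: adding shells
to the pool changes the component basis, which is why profiles meant to
be compared must be scored against one shared model.

## Profile standardisation and comparison

Each profile variable is linearly interpolated in cumulative axis
length at the fractions i/50, i = 1…50, of the shell's own total axis
length — excluding 0% (the undefined pre-growth state) and including
100%. This removes absolute-length differences so PDC compares trends;
a two-fold length difference would otherwise bias the embedding.

PDC embeds each 50-point series in overlapping windows of m = 5
consecutive values (delay t = 1; 46 windows), records each window's
ordinal pattern (rank permutation; ties rank the earlier index lower —
a deterministic convention that matters only for exactly equal values),
and normalises pattern counts into a distribution over the 5! = 120
patterns. Distributions are compared with the symmetric α-divergence;
at the default α = 0.5 the closed form

D(p, q) = 2 Σᵢ (√pᵢ − √qᵢ)² = 4 (1 − Σᵢ √(pᵢqᵢ))

is used directly (stable with empty cells, bounded by 4, zero iff
p = q). Multivariate dissimilarity is the sum of per-variable
divergences (a `mean` option exists); the five standard runs are the
four variables combined and each variable alone. Shells are clustered
by single-linkage agglomeration (scipy), whose merge heights are
verified against a brute-force implementation; dendrograms serialise to
Newick with leaf branch lengths of half the absorbing merge height.

## The synthetic generator

The generator emulates an idealised helicospiral shell: axis
c(θ) = (R cos θ, ±R sin θ, z(θ)) with R = r₀e^{kθ} and
z = pitch·(e^{kθ}−1)/k (→ pitch·θ as k → 0, the circular-helix limit;
the exponential form keeps the shell self-similar). Rings are ellipses
in the axis's rotation-minimising normal plane (parallel transport by
the double-reflection method, avoiding the frame flips Frenet frames
suffer where curvature is small), scaled by a per-radian growth factor
defaulting to e^k. Vertex 0 of every ring is placed *exactly on* the
axis curve, so the marker-vertex trajectory is the analytic
helicospiral and estimator output can be compared with exact truth: κ
and τ from the closed-form derivatives of c, arc length integrated by
adaptive quadrature to 1e-12. An optional constriction — a Gaussian dip
in aperture size centred at a fraction of ontogeny, twice as deep on
the minor axis so aperture shape changes through it — mimics the
pre-apertural narrowing used taxonomically in the relevant land-snail
genera, and gives shape scores genuine within-shell variation.

Default parameters (r₀ = 1 mm, k = 0.06 rad⁻¹, pitch = 0.35 mm·rad⁻¹,
4.5 whorls, 90 apertures × 16 vertices, semi-axes 0.6 × 0.5 mm) give a
millimetre-scale shell of realistic proportion and match the sampling
regime of retopologised scans, which carry roughly 73–96 apertures of
16 vertices each. The eight-shell reference set comprises four bases
spanning regular to strongly distorted coiling plus a half-size copy
(0.5, 0.5, 0.5), an elongated (0.5, 0.5, 2) and a depressed
(1.5, 1.5, 0.5) variant, and a composite in which an enlarged copy of a
base continues growth from its final aperture (the copy's first ring is
identified with the base's last, 2X−1 rings in total).

What the generator does **not** emulate: ornamentation (ribs, spines),
shell thickness, scan noise beyond optional Gaussian vertex jitter,
irregular aperture spacing, or true whorl overlap. Passing tests
therefore demonstrate correctness of the geometry pipeline on smooth
ring grids, not robustness to segmentation artefacts of real scans.

## Numerical choices and degenerate inputs

- Torsion at locally straight points: 0 plus a flag (see above).
- Windows truncated at profile ends; fit degree reduced if a truncated
  window cannot support it (torsion then reported as 0, flagged).
- EFA on outlines with duplicate points: zero-length edges are dropped
  from the integrals; fewer than 4 distinct points is an error.
- A degenerate first harmonic (zero major axis) cannot be normalised
  and raises; a flat first-harmonic ellipse (collinear trace) falls
  back to an arbitrary-but-deterministic completion of the frame.
- PCA on identical outlines raises (zero variance, no shape axes).
- Problem sizes in the test suite: estimator oracles use a 400-point
  circular helix over 3 turns (r = 2, c = 1 mm, exact κ = 0.4,
  τ = 0.2 mm⁻¹); the end-to-end study runs the full eight-shell set at
  default sizes.

## Known limitations

- Cap self-intersection is not detected in volume computation.
- The composite construction aligns ring centroids; if base and copy
  apertures differ in shape at the junction the grid is valid but the
  junction ring is shared geometry, not a smooth weld.
- PDC with 46 windows over 120 patterns is sparse by construction; it
  is a trend comparison, not a density estimate, and short profiles
  (< (m−1)t + 1 points) are rejected rather than padded.
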