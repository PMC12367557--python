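# Methods

This note documents the models and procedures implemented in `mimicaxis`,
the choices made where the design was genuinely open, and what the
synthetic fixtures do and do not establish about real scan data.

## Meshes and conventions

All phenotypes are coloured triangle meshes (`ColouredMesh`): vertices in
millimetres, 0-based triangle indices, integer RGB (0–255) per vertex.
The anterior–posterior axis is +X and dorsal is +Z, so "body length" is
always the X extent of the body component.  Colour interpolation is done
in real arithmetic and rounded half-up only when a mesh is materialised.

OBJ has no canonical vertex colour.  On write we emit both a companion
MTL (one material per distinct colour, each face assigned the majority
colour of its vertices) and colours appended to the `v` lines, a widely
supported extension that makes the round trip exact.  On read, `v`-line
colours win; otherwise per-face material colours are broadcast to
incident vertices, with conflicts at shared vertices resolved by majority
vote and ties by the lowest material index.  Whether a given scan stores
colour per vertex or per material varies between toolchains, so both are
supported.  PLY I/O (uchar vertex colours) goes through `trimesh`.
UV-textured colour is out of scope.

## Pattern segmentation and morphing

Vertices are split into two colour segments by k-means (k = 2) on RGB.
To make segmentation a pure function of the mesh, the two centroids are
initialised at the pair of vertex colours with maximal mutual RGB
distance (ties by lowest vertex index) and Lloyd iterations run to a
1e−6 tolerance.  Each segment's colour is the per-channel *median* of its
members' original colours; the brighter median (larger R+G+B, ties to the
larger cluster) is segment 1 and carries positive sign in the distance
map.  Which segment is "positive" is an arbitrary but fixed convention;
any consistent choice gives the same morphs after segment alignment,
which pairs segments across endpoints by minimal summed RGB distance
(ties preserve index order).

The signed distance map assigns each vertex the minimum number of edges
separating it from a vertex of the opposite segment (multi-source BFS
over the vertex adjacency graph), signed by segment.  "Edge distance" is
read as an unweighted hop count: it is integer-valued, resolution-honest,
and admits an exact brute-force oracle, which the test suite runs on all
fixture meshes up to 500 vertices.  A Euclidean-edge-length variant was
considered and rejected as the default because hop counts are what the
interpolation thresholds and tests can verify exactly; the hop metric
does make distances (and hence the exact boundary placement of morphs)
depend on mesh resolution, which is a known limitation.

Interpolation takes `D_w(v) = (1−w)·D_A(v) + w·D_B(v)` and labels
positive vertices segment 1, negative segment 2; the measure-zero tie
`D_w = 0` goes to segment 1.  Since `D_w` is linear in `w`, each vertex
changes label at most once along any sweep, and the endpoints are
recovered bit-exactly at w = 0 and w = 1.  Segment colours interpolate
linearly per channel and clamp to [0, 255]; the clamp can only bind under
extrapolation.  Both endpoint fields must live on the shared
correspondence topology; colours are transferred onto it by
nearest-vertex sampling.

## Shape correspondence and interpolation

Template projection is iterative closest-surface-point projection with
Laplacian smoothing (weight `smoothing` per iteration, default 0.5,
50 iterations) and a final pure projection, leaving template topology
untouched.  Convergence requires every vertex within 1% of the target's
bounding-box diagonal.  The closest-point query is an exact point–triangle
projection over KD-tree-prefiltered candidate faces.

The default shape morph is per-vertex linear interpolation over the
correspondence.  This is a deliberate simplification of control-point
diffeomorphic (LDDMM-style) morphing: the correspondence plus
axis-interpolation contract is what the downstream stages consume, and
linear interpolation is the only variant for which extrapolation (needed
for the A150/V−50-type stimuli) is well defined.  A `kernel_flow` variant
is provided for qualitative parity: the A→B displacement is ridge-regressed
onto Gaussian kernels on a 5×5×5 control grid (kernel width 1.5× grid
spacing, ridge 1e−10) and each vertex travels the fraction `w` of its
fitted displacement in 10 equal steps.  It is restricted to w ∈ [0, 1],
recovers B at w = 1 only up to the regression residual (checked at 1e−3
of the bounding-box diagonal), and makes no diffeomorphism guarantee; its
kernel parameters are non-canonical defaults, not calibrated values.

Wing outlines are closed simple 2D loops, resampled to a fixed 200 points
by arc length from a common anchor (the point of minimum X, i.e. the wing
root) after normalising orientation to counter-clockwise, then
interpolated point-wise.  The fixed resampling count makes outline
interpolation deterministic and testable.

## Stimulus assembly

Appendages are standardised: legs are 0.6 mm diameter cylinders with four
articulated segments (coxa/femur/tibia/tarsus), antennae 0.8 mm cylinders
bent into a gentle bow with linearly interpolated axial length, wings
flat 0.4 mm extrusions in 50% grey (128,128,128).  A leg takes whichever
of the two body segment colours is nearer (Euclidean RGB) to a reference
colour measured from real specimens' legs.  Cylinder cross-sections use
16 sections, so the polygon width equals the nominal diameter exactly.

The assembly order mirrors the production pipeline: appendages are built
at nominal size, combined with the body, and the whole is *then* scaled
uniformly so the body X extent equals the interpolated body length.  The
published appendage dimensions are therefore treated as pre-scaling
nominal values; whether they were nominal or as-printed is ambiguous, so
the spec of each appendage is configurable.  The optional base (10 mm
disc, 1.5 mm post entering the ventral thorax at 35% of body length by
default) is added after scaling at its physical print size, since it is
mounting hardware rather than phenotype.  Anchor placement is supplied by
the caller or defaulted from the body bounding box.

## Axis orchestration

A stimulus code `M25/V75` names the endpoints by initial letter with
percentage weights summing to 100 (to 1e−9); the axis position `p` is the
second endpoint's weight and may leave [0, 100] for extrapolated stimuli
(`A150/V−50`).  Both the ASCII hyphen and the typographic minus U+2212
are accepted on input; output uses ASCII.  Per-trait weights default to
`p/100` and can be overridden independently; changing one trait's weight
leaves the other three components bit-identical.  Antennal length follows
the shape weight, since antenna geometry is a shape feature rather than a
whole-body scaling; body length follows the size weight.

Trait-level combinations enumerate {poor, good, perfect}⁴ with the
constraint that poor and good never co-occur, giving 2⁴ + 2⁴ − 1 = 31
maps (the all-perfect map — a perfect mimic of the unrewarded model — is
the overlap and is included, as is the all-poor map, identical to the
training fly).  Order is lexicographic over (shape, pattern, colour,
size) with poor < good < perfect, for reproducible batch output.

Distance to the nearest model is `min_m |p − m|` in percentage points;
"intermediate" means strictly between models at 0 and 100.

## Experiment designs

Layout generators reproduce the published dish counts exactly for every
seed; only placement (uniform over the 7×7 grid, no spatial balancing)
and seeded allocation choices vary.  The 19 mimic dishes of the
multiple-models testing phase are spread over 7 types by largest-remainder
rounding — every type gets 2 and a seeded draw picks the five types that
get a third — because the published design states "equal numbers (with
rounding)" without an allocation rule; the two deficit types are
re-randomised per seed rather than fixed.  Edge flags mark exactly the
grid perimeter.  Chick trials are 16 presentations (6 rewarded fly, 6
unrewarded wasp, 4 rewarded probes drawn without replacement from the 31
combinations); invertebrate tests alternate the five axis probes with
two-plus-two reinforcement presentations.

## Behavioural statistics

Protection: the r-th dish attacked gets rank r; unopened dishes are
placed "at the end" without internal ordering, implemented as each taking
the *mean* of the remaining ranks (deterministic and order-invariant,
where arbitrary distinct ranks would inject noise); x = (rank−1)/(n−1)
forces 0 and 1 at the ends.  The adjusted logit uses the 0.01 offset so 0
and 1 stay finite.

Curve fits use `scipy.optimize.least_squares` (trust-region reflective)
with relative-step tolerance 1e−10 and a 1500-evaluation cap.
Initialisation: sigmoid a = max(y), b = 1, c = median(t); asymptotic
a = mean of the last quartile of y, b = mean of the first quartile,
c = log(0.3).  The sigmoid's "zero at time zero" assumption holds only
approximately (f(0) = a/(1+e^{bc}) ≠ 0); the formula is fitted as printed,
unconstrained.  The stabilisation day is the smallest integer t ≥ 1 with
|f(t) − a| ≤ 0.1·|a| (closed form via the exponential decay), defined for
the asymptotic family with a ≠ 0 only.

Latency standardization maps each trial's *median* fly and wasp latencies
onto the 0.855 s and 1.28 s anchors, while the exclusion rule uses the
*mean* wasp−fly difference (< 0.1 s excluded).  Medians for the anchors
and means for the exclusion follow the two rules' respective definitions
literally; they intentionally differ, and a trial with equal medians is
excluded because the linear map is undefined.

AICc = −2ℓ + 2k + 2k(k+1)/(n−k−1), requiring n > k + 1.  Ranking treats
scores within 2 of the minimum as tied and picks the fewest parameters,
remaining ties by label order.  Mixed-model fitting itself (GLMMs, post
hoc tests) is routine external statistics and out of scope; the ranking
consumes user-supplied (ℓ, k, n) triples.

## Synthetic fixtures

Banded ellipsoids emulate two-tone banded insect bodies: a UV tessellation
with poles on the X axis (n_lat·n_lon + 2 vertices, 2·n_lat·n_lon faces)
coloured by an analytic stripe function of normalised X.  `band_phase` is
measured in stripe widths (half a two-tone period), making the
phase-to-shift map linear — the analytic pattern midway between two
phases is the pattern at the mean phase, which is the oracle used for the
mid-axis interpolation test — and keeping phases in [0, 1) away from the
degenerate complementary pattern.  Optional Gaussian colour noise (the
noisy tests use sd 8 per channel) perturbs vertex colours under a seed.
Fixture pairs share topology by construction, standing in for the
template-projection step.  What these fixtures do *not* emulate: ragged
real-scan topology, colour gradients within segments, asymmetric band
geometry, or patterns not expressible as a function of one body axis —
so passing tests establish algorithmic correctness, not robustness to
scan artefacts.

Simulated sessions draw attack orders from a Plackett–Luce scheme: each
dish's latent aversion is its stimulus type's true learning curve at
session t plus Gaussian noise (default sd 0.3) on the logit-protection
scale, and dishes are chosen sequentially with probability ∝
exp(−β·aversion) (realised with the Gumbel trick; β = 0 is uniform,
β = ∞ sorts by aversion).  A stopping rule leaves a fraction of dishes
(default 10%) unopened.  This is the simplest rank-choice model
consistent with rate-maximising foraging; it is a test harness, not a
model of bird cognition.  Curve-recovery checks fit on the per-session
mean latent aversion of a stimulus type (the scale the curves are defined
on, with 17 dishes of the focal type over 30 sessions in the default
composition); the rank-order transform itself is monotone but nonlinear,
so asymptote recovery through ranks alone is not expected and not
claimed.  Chick-latency simulation adds per-trait effects (scaled by the
poor/good/perfect fraction) and noise to a baseline, truncated at 0.05 s.

## Problem sizes and determinism

All randomness flows through integer seeds into
`numpy.random.default_rng`; layouts, fixtures and simulations are pure
functions of their parameters and seed.  Test and acceptance runs use
fixture meshes of 290–514 vertices, 100 layout seeds, and 200 simulated
feeders of 30 sessions for curve recovery — sizes at which the exact
oracles (per-vertex BFS, enumeration, closed forms) remain cheap while
still exercising every code path.

## Known limitations

* The hop-count distance metric ties pattern-boundary precision to mesh
  resolution; strongly anisotropic tessellations will bias boundaries.
* `kernel_flow` is not an LDDMM implementation: no momentum conservation,
  no diffeomorphism guarantee, endpoint recovery only to the regression
  residual.
* Template projection assumes the target is a closed, well-resolved
  surface; thin or self-intersecting geometry can trap vertices.
* Only two-segment (binary) patterns are supported; gradient patterns and
  k > 2 segmentations are out of scope.
* Ultraviolet reflectance is not modelled anywhere in the colour pipeline.
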