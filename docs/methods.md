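# Methods

## Coordinate model and conventions

All internal quantities are expressed in Å and radians; degrees appear
only at the I/O boundary (text Z-matrices, CLI output). Cartesian vectors
are flattened atom-major (index = 3·atom + axis, 0-based). Derivative
expansions carry order-k tensors with k leading source axes and, for
coordinate maps, one trailing target axis; property (scalar) expansions
omit the trailing axis. Every tensor is totally symmetric in its leading
axes by construction — symmetry is an invariant of the algebra, not a
post-hoc symmetrization.

The primitives are

- distance `r_ij = |x_i − x_j|`,
- angle `θ_ijk = atan2(|a×b|, a·b)` with `a = x_i − x_j`, `b = x_k − x_j`
  (range [0, π]),
- dihedral `τ_ijkl = atan2(|u₂|·det[u₁,u₂,u₃], n₁·n₂)` with
  `u₁ = x_j − x_i`, `u₂ = x_k − x_j`, `u₃ = x_l − x_k`, `n₁ = u₁×u₂`,
  `n₂ = u₂×u₃` (range (−π, π], sign right-handed in the normals, trans = π,
  cis = 0; the value flips sign under mirror reflection).

Composite coordinates are linear combinations (coefficient-weighted sums
whose dependence on the underlying coordinates is exhausted at first
order) or scalar functions with user-supplied jet-differentiable
expressions.

## The derivative engine

The order-m derivative of a composite is organized as a sum over the
integer partitions P(m), one term per partition p: the product of inner
derivative tensors of orders p₁..p_j contracted with the order-j outer
tensor, followed by the transposition set T(p). T(p) contains one
permutation per distinct assignment of the m axes to blocks of sizes p
(equal-size blocks unordered), m!/(∏ pᵢ!·∏ multⱼ!) in total; because each
factor is symmetric within its own block, this is the minimal set that
restores total symmetry and simultaneously supplies the full multinomial
weight of the classical higher-order chain rule. Partitions and
transpositions are enumerated in a fixed deterministic order
(lexicographically descending partitions; block anchors increasing), so
repeated runs contract in the same order and tensor archives are
reproducible bit-for-bit.

Primitive derivatives are produced by forward-mode jet arithmetic over
the participating atoms' reduced coordinate space (6, 9 or 12
dimensions): sums and products via the multivariate Leibniz rule (a sum
over distinct axis splits), vector norms via the partition recursion
applied to √(a·a) — whose terms are tensor products capped at second
order — and atan2 via the exact closed form of its mixed partials,
∂^a_c ∂^b_s atan2 = Im(i^b (−1)^{k−1}(k−1)!/(c+is)^k). This realizes the
first-order identity dθ = cosθ·d(sinθ) − sinθ·d(cosθ) and its
higher-order analogues without branch logic, and keeps every order exact
to machine rounding (the finite-difference oracle agrees to ~1e-11 at
fourth order). Tensors are stored densely on the involved-atom blocks and
scattered into the full 3N space on demand; whole-system stacks assemble
the per-coordinate results with the coordinate index on the trailing
axis.

Arcsine and arccosine (needed by the planar-dihedral branch and
angle-from-sides completion) are themselves expressed through atan2 and
the norm machinery, so no additional derivative rules exist to maintain.

### Planar dihedrals

At τ = 0 or ±π the |a×b|-style sine part of the arctangent has a
non-differentiable zero. The planar branch replaces the arctangent with
arcsin of the sine of the angle between the normals,
`sin τ = |u₂|·det/( |n₁||n₂| )`, which is smooth through the planar
point; near trans the branch value `π − arcsin(·)` continues smoothly
past π (it is reported un-wrapped to preserve continuity of the
derivatives). The half-width of the window in which the branch is
intended is a user parameter (default 0.01 rad); inside the overlap the
two branches agree to ~1e-8, which the tests check.

## Inversion and the Eckart frame

For an invertible map, differentiating ∇_R Q · ∇_Q R = I gives a
recursion: order m of the inverse is minus the sum over partitions of m
other than (m) of the symmetrized mixed terms, contracted with the
first-order inverse. The recursion reuses the same partition/contraction
code as the forward chain rule, and the composite of inverse and forward
expansions has identity first order and vanishing higher orders
identically (to rounding), which the tests verify together with an
independent oracle.

Cartesian→internal maps lose the six rigid-body directions. The Eckart
conditions (Σmᵢ dxᵢ = 0, Σmᵢ xᵢ×dxᵢ = 0) are orthogonality constraints
in mass-weighted coordinates, so the projection transports each Cartesian
gradient axis to mass-weighted axes, removes the span of six (five for a
linear reference, detected by a moment-of-inertia eigenvalue below
1e-8 amu·Å²) orthonormalized translation/rotation generators, and
transports back — an oblique but idempotent projection on raw axes that
leaves genuine internal-coordinate gradients untouched. The first-order
inverse is the Moore–Penrose pseudoinverse of the projected stack
(singular-value cutoff 1e-8 relative, shared with all rank decisions);
higher orders follow from the recursion. The independent oracle —
Gauss-Newton reconstruction of displaced internals followed by
mass-weighted Kabsch superposition onto the reference — agrees with the
inverse tensors to the finite-difference limit (~1e-9 at first order,
~1e-8 at second).

Whether masses enter the projection is switchable; mass-weighted is the
default, and the unweighted variant coincides with setting all masses
equal.

## Conversions between coordinate systems

Conversions chain four completion rules over the shared atom graph:
side-angle-side → third distance (law of cosines), three sides → angle
(inverse law of cosines), four-atom chain closure → the 1–4 distance
(from the exact canonical Cartesian embedding of the chain — the closure
expressed directly in the six chain coordinates), and dihedral magnitude
from the closure inverted for cos τ. Rules are applied to a fixed point
in priority order with lexicographic tie-breaking, so conversion output
is deterministic; values and derivatives propagate through the same jet
arithmetic, making the conversion differentiable to any order and
composable with Cartesian expansions (path independence through an
intermediate system holds to ~1e-15).

A dihedral recovered from distances is determined only up to sign (a
mirror image has identical distances); the sign is inherited from a
source dihedral on the same atom quadruple when one exists and taken
positive otherwise. The distance-from-angles rules are singular at
collinear or planar configurations (acos/asin endpoints), where the
conversion value remains correct but its derivatives diverge.

### Constructed coordinates

- Delocalized internals: orthonormal left singular vectors of the
  redundant first-order stack above the rank cutoff (3N−6 of them),
  signs fixed by making each vector's largest component positive.
- Relocalization: orthogonal Procrustes rotation of the delocalized
  coefficient rows toward the best-covered identity axes; protected
  combinations (e.g. a symmetric stretch, local CO stretches) are
  orthonormalized first and excluded from the rotation, so they appear as
  pure rows with mixing below 1e-10. Protected coordinates must lie in
  the delocalized span (checked to 1e-6 relative).
- Direct-mode coordinates: least-squares fit of the ∇_R X rows to a
  target displacement field, by default in mass-weighted coordinates;
  the residual norm of the fit is returned so nested fits expose how much
  of the motion each added coordinate captures.

## Vibrational analysis

G = B M⁻¹ Bᵀ with B the first-order stack and M the diagonal mass
matrix. Frequencies come from the symmetric similarity G^{1/2} F G^{1/2}
(pseudo-square-root over the retained eigenvalues for redundant sets);
eigenvalues in hartree/(amu·Å²) convert to cm⁻¹ through the centralized
constant √(E_h/(u·Å²))/(2πc) ≈ 2720.23, with imaginary modes reported as
negative numbers. Local frequencies are the 1×1 diagonal GF blocks,
sign·√|G_ii F_ii|, before any mixing. The pure-scaling transform
normalizes a set of local-mode columns in the G⁻¹ metric (normal modes
satisfy Qᵀ G⁻¹ Q = I), after which the scaled force matrix has
near-identity kinetic metric; its matrix square root gives local
frequencies on the diagonal and bilinear couplings off-diagonal, both in
cm⁻¹. This off-diagonal-of-the-frequency-matrix convention is one
reasonable normalization of a bilinear coupling; it reduces to the usual
2×2 coupled-oscillator w in the degenerate limit and is the documented
choice here. Mode-space projection zeroes a coordinate's row across the
mode columns and re-orthonormalizes, dropping exactly one dimension when
the coordinate lay in the span.

## Interpolation

Each frame linearly interpolates the internal values in system A and in
system B (dihedrals along the shorter arc), reconstructs Cartesians from
each by warm-started Gauss-Newton on the forward map (pseudoinverse step,
convergence 1e-10 Å on the step norm, 100 iterations maximum), embeds
both against the previous frame, and blends with the switching weight.
The sigmoidal weight is a logistic in the global path parameter t
(steepness 10, center 0.5 by default) affinely normalized to hit 0 and 1
at the endpoints, so each endpoint's geometry is exact in its own
coordinate system; the exponential weight (1−e^{−kt})/(1−e^{−k}), k = 2
by default, leaves the far regime more gradually and can borrow favorable
features of both coordinate systems mid-path. Both forms are monotone and
smooth, both parameters are user-settable, and the weight's argument is
the global t. Single-system interpolation is the same loop without
blending and supports redundant (e.g. distance-only) systems through the
least-squares reconstruction.

## Fixtures and what the tests show

The seeded generator provides ideal-geometry templates (water 0.9572 Å /
104.52°; pyramidal ammonia; linear acetylene; an HOOH-like skew chain; a
six-atom methanol-like skeleton; a five-membered-ring-plus-heavy-atom
toy) with optional Gaussian coordinate noise; scales up to ~0.05 Å keep
all coordinates nondegenerate. Random test geometries rejection-sample
clusters with minimum separation 0.7 Å and all triple sines above 0.2,
i.e. they deliberately avoid the degenerate configurations the package
detects and refuses. Passing tests therefore demonstrate correctness of
the calculus and transformations on well-conditioned geometries — they do
not exercise electronic-structure inputs, and quantities that require
external force fields (absolute frequencies of real molecules) appear
only through synthetic force constants whose Cartesian-route counterpart
is computed by the same tests.

Problem sizes in the test suite and acceptance script (20 random 4-atom
geometries for the derivative oracle, water/methanol-like fixtures for
inversion, 100-draw completion checks) were chosen as the smallest sets
that exercise every code path with comfortable statistical margin;
results are independent of these sizes beyond rounding.

## Numerical choices

- Degeneracy tolerances: difference vectors below 1e-10 Å and dihedral
  flanking-angle sines below 1e-10 raise a degenerate-geometry error
  naming the offending vectors; both are module constants.
- Rank and pseudoinverse cutoff: 1e-8 × largest singular value
  everywhere (delocalization, completeness checks, Eckart inversion, GF
  pseudo-square-root), configurable per call.
- Finite-difference oracles in the tests use Richardson 5-point stencils
  at h = 1e-4 (one-sided at branch points).
- Archives are npz containers written through a fixed-timestamp zip
  writer, so identical inputs give bit-identical files; `np.load` reads
  them unchanged. Arrays are written in sorted name order.

## Known limitations

- No dedicated linear-bend coordinates: at an exactly linear reference
  the valence-angle primitive is degenerate, so complete (3N−5) systems
  for linear molecules cannot be assembled from the in-scope primitive
  types (the rigid-body machinery still yields the correct 5-generator
  null space). Out-of-plane wags and in-plane rocks are likewise out of
  scope.
- Conversion covers primitive-coordinate targets reachable through the
  four completion rules; coordinate sets requiring general trilateration
  (e.g. a position fixed jointly by two angles about different axes) are
  reported as unreachable rather than solved iteratively.
- The interpolation is geometry-only; no energetic information is used to
  refine the path.
- Jet tensors are dense over the participating atoms, which is ideal for
  the ≤ 4-atom footprint of the primitives but would not scale to
  coordinates coupling many atoms at high order.
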