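# Methods

`retvasc` procedurally generates whole-retina vascular networks as spatial
graphs, solves one-dimensional blood flow and contrast transport on them,
and perturbs them with disease models.  This note records the model, its
assumptions, the parameters that matter, the numerical choices, and what
the reduced-scale study conditions do and do not demonstrate.

## Model overview

A retina is modelled as a planar disc (default radius 12.5 mm) with an
optic disc at the origin, a macula centred 4.5 mm temporally (region
diameter 5.5 mm) containing an avascular fovea (radius 0.3 mm), and an
optic-disc region of diameter 3.6 mm.  Generation proceeds in stages:

1. **Seeding.**  A central retinal artery (calibre sampled
   normal(135, 15) µm) and vein (normal(151, 15) µm) enter through the
   optic nerve head (out of plane), split once into a superior and an
   inferior in-plane arcade, then branch stochastically for five
   generations.  Each bifurcation draws an asymmetry ratio
   α = r_small/r_large ~ U(0.4, 0.9); daughter radii satisfy Murray's law
   r_p^γ = r_1^γ + r_2^γ with γ ~ normal(2.4, 0.11), and daughter
   deflection angles follow the optimal-branching relations

       cos θ1 = [(1+α³)^{4/3} + α⁴ − 1] / [2α²(1+α³)^{2/3}]
       cos θ2 = [(1+α³)^{4/3} + 1 − α⁴] / [2(1+α³)^{2/3}]

   with independent Gaussian noise (sd 5°) per angle.  Inter-bifurcation
   length is 18 ± 3 × the local calibre.  The larger daughter is steered
   toward the macula, producing the characteristic arcades; branches
   stopping at the retina edge or the (vessel-free) macula terminate.
   These angle relations are the Weber-point optimum of the cost
   Σ r² l, which is why the geometric optimiser (below) leaves an ideal
   bifurcation unmoved when run with ρ = 2.

2. **Leaf distribution and lattice growth.**  Leaf nodes at 3 mm spacing
   (square grid with circular jitter of spacing/4, guaranteeing a minimum
   pairwise distance of spacing/2) attach to the nearest tree; they are
   scaffolding and are removed after the first growth pass.  Square
   lattices with strides linearly spaced from 3000 µm down to 150 µm
   (5 levels, endpoints included) are then invaded: per sweep, every
   unoccupied site with an occupied 8-neighbour receives a candidate —
   a straight terminal segment from the nearest tree node within two
   strides — scored by the expected change of the network cost
   C = Σ_b r_b^ρ l_b^λ (ρ = λ = 1) including the Murray-consistent radius
   increments propagated to the root.  Candidates commit in ascending
   expected-cost order (ties: site index, then node id — determinism over
   elegance).  Because the radius increment (r^γ + r_t^γ)^{1/γ} − r is
   concave in the added load, the realised cost increase per sweep never
   exceeds the sum of the committed estimates, which the tests check as an
   accounting identity.

3. **Radii.**  Radii are maintained bottom-up: every leaf segment carries
   the terminal radius (default 8 µm); every parent satisfies
   r_p = (Σ_c r_c^γ)^{1/γ}.  After growth each tree is rescaled uniformly
   so the root segment matches its sampled calibre — the Murray relation
   is homogeneous, so it holds exactly at every bifurcation at all times.
   This is also why exponent recovery (below) is a sharp test: fitting
   r_p^x = r_1^x + r_2^x at any bifurcation returns the sampled γ.

4. **Optimisation.**  Geometric: coordinate-wise golden-section search per
   movable node, accepting only cost-reducing moves, sweeping until the
   relative improvement drops below 1e-4; leaf nodes move at most
   pinning-fraction (0.5) × leaf spacing from their anchor; frozen
   segments are untouched; no move may shorten a segment below 10 µm (the
   Weber point otherwise collapses segments onto their neighbours) or cut
   a vessel-free region.  Topological: bifurcations may shift their
   low-flow side one generation downstream, and inter-bifurcation branches
   shorter than 0.5 × (parent length × 2^{−1/3}) — the metabolic-scaling
   expectation — merge into higher-order splits; both moves are accepted
   only if the cost decreases, and re-attachment targets are never
   descendants of the moved subtree, preserving acyclicity.  Highly
   asymmetric bifurcations (α < 0.2) are trimmed and their territory
   regrown at the finest stride.

5. **Self-intersections.**  Same-tree in-plane crossings (chord distance
   below the sum of radii, shared nodes excluded) are removed by
   re-attaching the smaller branch's distal node to the nearest endpoint
   of the other segment — rewiring rather than detouring, so later growth
   cannot recreate the crossing.  The tree index is rebuilt before every
   rewire (stale parent maps can otherwise detach a cycle).  Crossings
   surviving five passes are deleted with their subtree and logged.

6. **Macula.**  The annulus between the fovea and the macula outer radius
   is filled with a radial lattice of leaf targets, alternating arteriole
   and venule, jittered uniformly in a disc so vessels do not align with
   the lattice, thinned i.i.d. with the sparsity probability (0.3), and
   processed rim-inward so the radial pattern develops; a hard branch-angle
   limit (90°) prevents doubling back, and no segment may cross the fovea.
   Target density self-calibrates: it equals the flow-density factor
   (sampled U(1.5, 2.0)) × the network's own measured peripheral terminal
   density.  Because radial chains absorb earlier targets as interior
   nodes, a top-up loop adds leaves below non-leaf parents until the
   annulus leaf density reaches the target — this is the mechanism by
   which the factor becomes a *flow* density ratio once capillary
   resistance dominates and per-leaf flows equalise.

7. **Tortuosity.**  Each branch is displaced normal to its axis by two
   superimposed sinusoids a0 sin(x/τ0 + δ0) + a1 sin(x/τ1 + δ1) of the
   arclength x, total amplitude U(1, 3.5)·r for arteries, U(1, 7.5)·r for
   veins (split randomly between modes), periods τ0 ∈ [15, 25]·r and
   τ1 ∈ [30, 50]·r.  Phases are realised by snapping each period so an
   integer number of half-waves fits the branch: both sines vanish at the
   branch nodes exactly, so bifurcation positions are preserved to
   rounding.  (Given these period ranges τ0 is the higher-frequency mode;
   the package speaks of periods, not frequency labels.)  Paths are
   re-densified at min(radius, 50 µm) spacing.

8. **Capillary bed.**  Default: Voronoi.  Seed points at 25 /mm² are
   sampled over the disc (fovea excluded); interior Voronoi edges become
   4 µm capillaries; dead-end vertices are pruned iteratively and only the
   largest connected component kept; every arterial and venous terminal
   connects to its nearest surviving vertex.  The network is then a single
   component with one inlet and one outlet.  A 2-D space-colonization
   grower (attraction 400 µm, kill 120 µm, step 100 µm) is available as
   the alternative construction and for regrowing interdigitations.
   Artery–vein crossings are separated out of plane: the violating
   interval of the artery lifts anteriorly and the vein's dips
   posteriorly by smooth trapezoids clearing the sum of radii; branch-node
   endpoints stay pinned (terminal endpoints may move, dragging their
   capillary link).  Both sides move because one-sided local bumps cannot
   clear extended near-parallel overlaps, and opposite directions keep
   independently lifted vessels from colliding.  Small-calibre crossings
   (both radii < 5 µm) can additionally be interdigitated by deleting the
   low-flow side.

9. **Eye surface.**  The planar network projects onto a hemisphere
   (diameter U(23, 25) mm) by the azimuthal-equidistant inverse — planar
   distance from the optic disc becomes arc length on the sphere — chosen
   because it preserves radial arc lengths exactly.  Azimuthal distances
   contract by sin(β)/β at polar angle β (≤ ~16% at the rim); projected
   segment lengths are therefore never longer than planar ones, which is
   what the tests assert.  Macula pit and optic-disc cup/rim are Gaussian
   radial relief; out-of-plane excursions become offsets along the local
   surface normal.  Topology is untouched.

## Flow and fluorescein

Each segment is a Poiseuille resistor R = ∫ 8µ/(π r⁴) dl along its path
(trapezoidal in 1/r⁴; near-zero-length paths are floored at a 1 µm
equivalent).  Viscosity is constant, µ = 3.5 mPa·s, by default — a
diameter-dependent law is left behind the boundary-condition enum but off,
for determinism.  Dirichlet pressures at the inlet (normal(56.2, 14.0)
mmHg) and outlet (normal(20.0, 10.0) mmHg, jointly resampled until
arterial > venous) close the linear system.  Numerics: conductances span
~5 orders of magnitude and pressure differences in remote capillaries sit
far below the pressure level, so the solver uses symmetric Jacobi scaling,
an LU factorisation, iterative refinement with residuals accumulated in
80-bit extended precision, and evaluates q = g·Δp from extended-precision
pressures.  Per-node mass balance then holds to ~1e-10 relative on full
mini retinas (and ≤1e-8 on the solver-contract networks in the tests);
nodes whose throughflow is at rounding level (< 1e-9 × the peak segment
flow) are excluded from the residual metric since their balance is
0 ≈ 0.

The fluorescein input is C(t) = s1 G(t; t1, σ1) + s2 G(t; t2, σ2) +
α H(t−t3) e^{−β(t−t3)} with s1 = 0.833, s2 = 0.336, α = 1.064,
t1 = 0.171 min, t2 = 0.364 min, t3 = 0.482 min, σ1 = 10 s, σ2 = 25 s,
β = 0.043 /min, renormalised to unit peak.  The printed source form of
this model is ambiguous (the washout exponent omits β; α collides with a
tortuosity symbol); the convention above — unit-peak Gaussians, washout
α e^{−β(t−t3)}, global renormalisation — is this package's documented
choice.  Note t = 0 is only ~1σ1 before the first pass under these
constants, so C(0) is not negligible (~0.3 after normalisation).

Transport is shift-and-scale advection, not convolution: each segment's
curve is the inlet curve delayed by the cumulative transit time Σ l/|v|
along the dominant-flow (max-|q|) path and scaled by the product of flow
fractions q_child/q_parent at the branch points passed — i.e. tracer
*amount* partitions with flow, so daughter amplitudes sum to the parent's
(a symmetric split halves each).  Merging nodes add incoming amounts and
inherit the dominant input's delay.  No dispersion, haematocrit phase
separation or compliance is modelled.  The arterio-venous delay is the
half-max time of the outlet-adjacent vein curve minus that of the inlet
curve.

## Pathology

RVO: vein segments in the top radius quartile with an artery within 2× the
sum of radii are candidates; one, chosen uniformly, is narrowed by 80%
(diameter), flow is re-solved, and the deficit summed over the vein
subtree draining through the occlusion.  DR: artery segments with radius
< 35 µm beyond a decreasing minimum distance from the macula centre
(default schedule 10, 7.5, 5, 2.5 mm; scaled down with reduced domains)
are fully occluded in batches of five; vessels whose flow falls below
1e-4 µL/min are pruned — up- and downstream alike — carving ischaemic
territories; pruning is idempotent, and under fixed pressure boundary
conditions any occlusion can only decrease total inlet flow.

## Analysis

Branches are inter-bifurcation segments.  Branching angle is measured
between the two largest daughters' direction vectors over their first
50 µm (the daughter-vs-parent convention is not used since the
inter-daughter angle is what image-based morphometry measures; radius ties
are broken by rounded radius then id so resampling cannot flip the
selection).  Tortuosity = path length / chord.  Branches belong to the
region — macula (5.5 mm disc on the fovea), optic disc (3.6 mm), otherwise
periphery, with the disc test taking precedence — of their midpoint.
Vessel volume is reported as true cylindrical Σ π r² dl (the per-branch
table also carries what a projected-area proxy would need).  The Murray
exponent is re-fitted per bifurcation by Brent root-finding on
r_p^x = r_1^x + r_2^x over x ∈ (0.5, 6), degenerate bifurcations
(r_p ≤ max daughter) skipped; the per-network median is reported.
Rasterisation renders each segment as a filled tube on a grid with 21 µm
lateral and 6.3 µm axial spacing by default (voxel-centre-in-tube test);
en-face images are axial maximum-intensity projections.  Dice of two empty
masks is defined as 1.0 (the formula is 0/0 there) and logged.

Perfusion density per region is the summed |flow| of arterial feeding
segments (artery segments with a capillary neighbour) per unit region
area, the macula measured over its annulus (fovea excluded).

## Study conditions and scale

Clinical-scale networks (12.5 mm radius, 150 µm final stride) take hours
each on one CPU; the package therefore ships two reduced presets used by
the examples, the tests and the reproduction script, chosen as the largest
domains that keep a full build in seconds: **mini** (5 mm retina, strides
1500→350 µm over 3 levels, 4 seed generations, scaled macula/disc regions,
8 capillary seeds/mm²) and **micro** (3.2 mm, 1000→400 µm over 2 levels,
3 generations).  All physiological sampling distributions are untouched by
the presets.  Consequences: scale-free quantities — the recovered Murray
exponent, calibre statistics, the macula/periphery perfusion ratio,
conservation laws, geometric invariants — transfer directly and are
asserted at their configured values.  Absolute whole-retina quantities —
total flow (~34 µL/min at clinical scale), the ~7 s arterio-venous delay,
the ~10 µL/min RVO deficit — scale with domain size and vessel counts, so
at desk scale they are asserted as conservation plus order-of-magnitude
properties, not point values.

## What the generator does not emulate

Single planar plexus (no superficial/deep capillary layering), no
choroidal or cilioretinal supply, no vessel-wall mechanics or flow
autoregulation, constant viscosity by default, no imaging physics (the
rasteriser produces geometry masks, not OCT-A speckle or fundus optics).
Passing tests therefore certify the geometry/flow model's internal
physics and its stated population statistics, not agreement with any
particular clinical image.

## Known limitations

- Greedy per-sweep candidate commitment approximates one-at-a-time
  globally minimal insertion; the difference is not characterised.
- The dominant-path delay model understates arrival-time spread at strong
  merges (no convolution of multiple paths).
- Unresolvable same-tree crossings (after five rewiring passes) are
  deleted rather than detoured; counts are logged in metadata.
- Per-node relative mass balance below ~1e-10 is limited by float
  representation of near-equal pressures, not by the solver.
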