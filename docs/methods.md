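# Methods

This note records the models implemented in `myofield`, the parameter
choices that matter, the numerical decisions taken where the design was
genuinely open, and what the synthetic test bed does and does not show.

## Coordinate and grid conventions

The muscle's principal axis is `e2 = (0, 1, 0)`; all orientation sign
conventions (the `h(V)` rule for voxel orientations, streamline orientation
for divergence counting, fibre-vector alignment) flip vectors so their `e2`
component is non-negative. Voxel grids use half-open membership
`[i, i+1)` in continuous index space with the voxel centre at `index + 0.5`;
the NIfTI affine written to disk converts to the centre-at-integer
convention. The default grid has 2.625 mm in-plane spacing and 6.25 mm
slices along the axis (clinical diffusion-imaging resolution), and is
aligned so the aponeurosis mid-plane runs through voxel centres — without
that alignment a 3 mm sheet straddles two voxel layers and every overlap
score degrades by construction, an artefact of grid placement rather than
of the detector.

## Track-derived voxel fields

* **FA.** The printed prefactor 1/2 is the default; the conventional
  `sqrt(1/2)` normalisation is available via the `prefactor` argument.
  Neither is asserted as "correct"; they differ by a constant factor only.
* **Track filtering** keeps tracks of 15–200 mm arc length whose per-step
  turning angle never exceeds 10° (default) and, when per-point FA samples
  are supplied, whose FA stays within [0.1, 0.5] (inclusive bounds).
* **Density K(V)** counts *distinct* tracks with at least one resampled
  point (0.5 mm arc-length resampling, guaranteeing no sphere is skipped)
  inside the sphere of diameter 2.625 mm embedded in the voxel. Re-entries
  of the same track do not recount.
* **Per-track, per-voxel orientation** is the unit chord between the
  track's first and last in-sphere sample (local tangent for a single
  sample) — robust to resampling density. The voxel mean is deliberately
  not re-normalised: its norm ≤ 1 measures intra-voxel coherence.
* **Discrete divergence** (endpoint mode, the detector default) orients
  each track so its end-to-end chord has non-negative `e2` component, then
  counts entering (+1) minus leaving (−1) per voxel; pass-throughs cancel,
  terminations contribute +1, originations −1. The global sum equals
  (#endpoints − #startpoints inside the grid) exactly. A central-difference
  mode (`fd`) on the orientation field is also exposed; its numerical scale
  differs, which is why the detection thresholds are fully configurable.

## Aponeurosis detection

Candidates are voxels inside the region of interest where divergence and
density *strictly* exceed their thresholds (defaults 3.0 and 600). The 600
was calibrated against a ~110k-track subject acquisition; for differently
sized track sets `density_threshold="auto"` keeps the same fraction of
tracks (600/109710 ≈ 0.55%). Components below 10 voxels are removed
(26-connectivity default, 6 exposed), survivors are ranked by size with
ties broken by smallest flat voxel index (deterministic), and the largest
component is the detection. Dice of two empty masks is defined as 1.0,
empty versus non-empty as 0.0 (limit consistency). The region of interest
is a user-supplied mask or an axis-aligned half-space; the anatomical
"exclude posterior voxels" rule is not quantifiable generically.

## Synthetic bipennate muscle

The generator replaces subject-specific imaging with a fully known
geometry: a solid of revolution (monotone spline radius profile, 160 mm
long, 15 mm belly radius, 6 mm tendon radius, flat tendon end discs of
20 mm length) whose cross-sections are a square-to-disc mapping of a
structured grid, Kuhn-subdivided into conforming tetrahedra. The
aponeurosis is a volumetric planar sheet (3 mm, exactly two element layers,
so mid-plane nodes exist for boundary conditions) from 35% of the length to
the distal muscle–tendon junction, spanning the anterior ~80% of the
cross-section so it attaches anteriorly and stays interior posteriorly.

The analytic fibre field tilts `e2` by the pennation angle (default 15°)
towards the sheet mid-plane, mirror-symmetrically; inside the sheet slab
the tilt decays linearly to zero at the mid-plane. The decay serves track
integration: with an abruptly axial field inside the slab, integrated
tracks would skim along the slab surface and terminate one voxel off the
sheet plane, which misrepresents fibres that anatomically insert *onto*
the aponeurosis.

Streamlines are generated insertion-first: insertion points are drawn
uniformly over the sheet (axial and anterior–posterior position, side,
0.3 mm standoff) and integrated *backwards* through the field to the
muscle surface; the reversed path is the track. Uniform insertion along
the aponeurosis is the anatomical feather pattern; seeding uniformly on
the outer surface instead would pile insertions up distally and at the
sheet's proximal edge, because every fibre drifts distally on its way in.
Per-step angular noise (Gaussian tangential perturbation, von-Mises-like
for small angles) models tractography dispersion; 0–5° covers the regime
used in the tests.

What the synthetic bed does **not** emulate: partial-volume and noise
structure of real DTI, fat infiltration, the posterior aponeurosis,
inter-subject shape variability, and tracks from neighbouring tissue.
Passing the recovery tests therefore demonstrates the detector's internal
consistency at realistic geometry/resolution ratios, not clinical
performance.

## Heat-flux fibre fields

Steady-state conduction `div(grad T) = 0` is discretised with P1 Galerkin
tetrahedra; Dirichlet rows are eliminated, the reduced SPD system is solved
directly up to 2·10⁵ nodes (diagonal-preconditioned CG beyond, tolerance
1e-10). κ = 1 throughout: only flux *directions* matter and temperatures
carry no physical units. Boundary data: inlet `T0 = 1`, outlet `T1`,
power-law ramps `T0·n^α1` on the lateral muscle surface and `T0·n^α2` on
the sheet's mid-plane strip, each surface normalised over its own axial
extent with `n = 1` at the proximal side so ramps join the inlet value
continuously. `0^0 := 1` so that α = 0 degenerates to a constant surface
temperature without a jump. Shared nodes take the precedence
inlet > outlet > aponeurosis > muscle.

Element fibre vectors are unit fluxes with one pass of volume-weighted
nodal recovery by default: the raw P0 gradient of P1 elements carries
10–20° inter-element jumps on the anisotropic tetrahedra produced by the
thin sheet layers, while the underlying flux field is smooth; lumped nodal
averaging removes most of that noise without biasing directions
(`smooth_passes=0` restores the raw gradients). Elements whose flux
magnitude is negligible against the global temperature spread per
characteristic element length are masked invalid — in particular a
constant field has no meaningful directions at all.

Mesh sensitivity is assessed on a ladder of four refinement levels
(element size divided by 1.5 per level, ~9k to ~260k elements): the mean
nearest-centroid angular difference between consecutive levels decreases
along the ladder and reaches ≈4.3° at the finest pair, with the
angle-to-axis histogram peak bin stable at every level. The coarser pairs
differ by more (≈9°), dominated by weak-gradient regions (the proximal
plateau where surface ramp and inlet temperature almost coincide) where
flux directions are intrinsically ill-conditioned.

## Boundary-condition identification

The design space is `T1 ∈ [−200, −1]`, `α1, α2 ∈ [0, 20]`, start
(−100, 5, 10), constraint `α2 − α1 ≥ 0` (it orients the flux towards the
aponeurosis). Designs are a maximin-improved Latin hypercube over the full
box — the constraint binds the optimiser only, so the metamodel is
informed on both sides of it. scipy's `LatinHypercube` has no maximin
option, so a seeded within-column swap hill-climb (which preserves the
stratification) raises the minimum pairwise distance above that of the
plain LHS.

The objective `ȳ` is the *arithmetic* mean of per-element cosine distances
over Ω̄ — the word "geometric" sometimes attached to this mean contradicts
its defining formula, and the formula wins. Ω̄ excludes muscle elements
within 3 mm of the exterior surface (exact point–triangle distances, KD-tree
pruned) and the distal 10% of the length.

The metamodel is an interpolating thin-plate-spline RBF on box-normalised
inputs with the ramp exponents additionally passed through `log(1+α)`:
the ramp `n^α` responds multiplicatively to α, so the objective varies
fastest at small exponents and the log map equalises the sampling density
where it matters. Accuracy is reported as R² on 20 held-out designs
(typically ≥ 0.95 with 200 training designs; individual design seeds can
dip lower when a held-out point lands in the steep small-α valley).

Optimisation: seeded simulated annealing (geometric cooling 0.95, Gaussian
proposals projected onto the feasible set, step adapted towards ~40%
acceptance, 5 restarts) on the metamodel, followed by a local polish of
the surrogate optimum *against the thermal solver* from several starts
(the surrogate optimum and the three best simulated designs) — the
objective has a narrow curved valley in which a single quasi-Newton descent
can stall on a secondary minimum. The polish runs Nelder–Mead then SLSQP in
box-normalised coordinates; in raw coordinates (T1 spans hundreds, the
exponents units) the conditioning is hopeless. With this loop the known
reference exponents are recovered essentially exactly; T1 is weakly
identified (sub-1% first-order Sobol share) and no accuracy is claimed for
it. Sensitivity uses pick-freeze first-order Sobol indices on the
metamodel — the variance-based choice is a stand-in for the unspecified
original analysis, not a claim of equivalence.

## Muscle mechanics

Stress (second Piola–Kirchhoff, MPa; lengths mm, forces N):

* isotropic: `S_iso = B1 I + B2 C + B3 C⁻¹ + k(J−1)J C⁻¹`, the exact
  C-derivative of `C1(Ī1−3) + C2(Ī2−3) + k/2(J−1)²`,
* passive fibre: `C3/Λ²(Λ^C4 − 1) M` for Λ ≥ 1, zero in compression,
* active fibre: `a·σ_max/Λ²·exp(−|(Λ/Λ_opt−1)/ΔW|^ν) M` with
  ascending/descending constants switching at Λ_opt (the switch is C¹ for
  ν > 1).

Defaults: muscle `C1 = 2e-3, C2 = 2e-4, k = 7.2, C3 = 5e-3, C4 = 6,
σ_max = 0.3 MPa, ΔW = 0.15/0.16, ν = 2/6, Λ_opt = 1.3`; tendon and
aponeurosis `C1 = 2e-2, C2 = 2e-3, C3 = 0.5, C4 = 25`, no active part.
The tabulated activation flag γ (0 for muscle, 1 for tendon) would, read
literally, disable muscle activation; the model uses an activation scaling
of 1 for muscle and 0 for tendon/aponeurosis and keeps the tabulated value
as `gamma_table` for reference.

Pre-stretch enters as an additive shift of the stretch in the fibre laws
only, `Λ = √I4 + (Λ_app − 1)`, applied to the muscle region — an internal
load that leaves the kinematics untouched. `Λ_app = 1` (no shift) is the
passive load case; with a shift the fibre stress is an internal-load model
rather than an energy derivative, so the energy-consistency guarantee
applies to the unshifted passive law.

Solver: total-Lagrangian P1 tetrahedra, full Newton with element tangents
by central finite differences of the element internal force (h = 1e-6),
backtracking line search, adaptive halving of load increments. Two
numerical safeguards were needed in practice and are on by default:

1. **Kink smoothing.** The passive law's slope jumps by ≈ C3·C4 at Λ = 1
   (12.5 MPa for tendon); with hundreds of elements hovering at the kink,
   Newton cycles indefinitely. The solver uses a C¹ Hermite blend over
   `[1, 1+0.01]` with zero value and slope at Λ = 1 — the reference state
   stays exactly stress-free and the law is exact outside the band. The
   constitutive API keeps the exact piecewise law by default.
2. **Energy descent rescue.** Under full activation the equilibrium path
   can pass near unstable states (local snap-through; the tangent becomes
   indefinite and Newton stalls at a saddle). For fixed activation and
   shift the model is conservative — every fibre-stress magnitude m(Λ)
   admits the pseudo-potential `A(Λ) − shift·B(Λ)` with `A = ∫ m t dt`,
   `B = ∫ m dt`, tabulated once per material — so the solver falls back to
   L-BFGS minimisation of the total potential (exact internal force as
   gradient) and then finishes with Newton, which converges quadratically
   in the recovered stable basin.

Load case 1 fixes the inlet disc and ramps equal nodal shares of an axial
force to 5 N at the outlet; reported output is the mean axial outlet
displacement per step. Load case 2 fixes both tendon ends, ramps the
pre-stretch shift (default to 1.25), then ramps activation 0→1; reported
output is the inlet reaction force versus activation. Linear tetrahedra
are accepted despite their locking risk (quasi-compressibility with finite
k mitigates it); with k = 7.2 MPa the volumetric deviation |det F − 1|
reaches ≈0.07 locally at 5 N on the synthetic mesh — logged by the tests
as a soft bound rather than enforced.

At desk scale the expected directions of effect hold strictly: a steeper
fibre field (10° vs 25° pennation on the same mesh) gives a smaller
passive end displacement (≈7.5 vs ≈11.1 mm at 5 N) and a larger isometric
reaction at full activation (≈25 vs ≈7.7 N at 1.25 pre-stretch).

## Fibre-field comparison metrics

The relative inclination `90° − angle(unit difference vector, e2)` is
computed after axis alignment; positive values mean the first field is
steeper. At identical vectors the construction is ill-conditioned, so
differences below 1e-9 are set to 0, flagged, and excluded from spread
statistics. In deformed configurations both vectors are pushed forward
with the element deformation gradient, re-normalised and re-aligned; the
construction is invariant to uniform scalings of F. Angles are reported in
degrees throughout (radians internally).

## Problem sizes and determinism

Default test/study sizes: 9216-element mesh (2.6k nodes) for detection,
recovery and field work; 4680 elements for mechanics; 3000 tracks with 5°
noise for detection; 200 + 20 designs for the metamodel loop; refinement
levels 3–4 (85k/262k elements) for mesh sensitivity. Every stochastic
stage takes an explicit integer seed and reproduces its outputs
bit-identically; mesh generation and the solvers are deterministic by
construction.

## Known limitations

Single anterior aponeurosis only; no contact with neighbouring structures;
homogeneous activation; linear tetrahedra; the synthetic generator's
thickness of the sheet scales mildly with the local radius (cross-section
mapping); the detector's absolute thresholds are meaningful only relative
to acquisition scale, hence the fractional "auto" mode; T1 is reported but
not identifiable from the fibre-direction objective.
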