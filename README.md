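# myofield

Reconstruction of a bipennate muscle's internal architecture for
continuum-mechanical simulation: aponeurosis detection from fibre
tractography, smooth fibre-orientation fields from steady-state heat
conduction with optimised boundary conditions, and a transversely isotropic
active/passive muscle finite-element solver to compare fibre architectures
mechanically.

## Who this is for

Researchers in musculoskeletal biomechanics who need, for a pennate muscle,
(i) a geometric representation of the internal aponeurosis, (ii) a smooth,
simulation-ready fibre orientation field consistent with tractography, and
(iii) a way to quantify how differences between fibre architectures
propagate into passive and active mechanical behaviour.

## The methods in brief

**Aponeurosis detection.** Muscle fibres of a bipennate muscle converge
onto and terminate at the internal aponeurosis, which therefore acts as a
sink of the oriented streamline field. Tracks are filtered by fractional
anisotropy FA = ½·√(Σᵢ<ⱼ(Λᵢ−Λⱼ)²)/√(ΣΛᵢ²), turning angle and length, then
rasterised: per voxel V a density K(V) (distinct tracks through a sphere
embedded in the voxel), a mean orientation â₀ᵛ = h(V)·(1/K)·Σₖ a₀ₖ sign-fixed
along the muscle axis e₂, and a discrete divergence D(V) (oriented tracks
entering minus leaving). Voxels with D and K jointly above thresholds,
inside a region of interest, are cleaned by connected-component filtering;
the largest component is the detected sheet, scored against a reference by
the Dice coefficient 2|A∩B|/(|A|+|B|).

**Heat-flux fibre fields.** On the tagged muscle–tendon–aponeurosis mesh
the steady-state heat equation ∇·(∇T)=0 is solved with Dirichlet data
T₀/T₁ at the tendon end faces and power-law ramps T₀·n^α₁ (lateral muscle
surface) and T₀·n^α₂ (aponeurosis midline strip), where n is the normalised
axial coordinate of each surface. Element-wise unit heat-flux directions
a₀ = −∇T/‖∇T‖ form the fibre field; end BCs alone give a fusiform field,
the ramps with α₂ ≥ α₁ bend the flux into the bipennate feather pattern.

**Boundary-condition identification.** s = (T₁, α₁, α₂) is found by
minimising the mean cosine distance ȳ = (1/K)·Σₖ(1 − cos θₖ) to a reference
field over a sub-region Ω̄ (muscle minus a 3 mm surface layer and the
distal end), using a 200-point maximin Latin-hypercube design, an
interpolating RBF metamodel, seeded simulated annealing under α₂ − α₁ ≥ 0,
and a local polish against the true objective.

**Mechanics.** Tissue is a quasi-compressible Mooney–Rivlin matrix plus a
transversely isotropic fibre reinforcement: passive tension-only stress
C₃/Λ²(Λ^C₄ − 1)·a₀⊗a₀ and an active stress σ_max/Λ²·exp(−|(Λ/Λ_opt − 1)/ΔW|^ν)
scaled by the activation level, with fibre stretch Λ = √(tr(a₀⊗a₀·C)) plus
an optional additive pre-stretch shift. A total-Lagrangian Newton solver on
linear tetrahedra runs passive stretch (axial force ramp at the distal
tendon) and isometric contraction (pre-stretch, then activation 0→1 with
both tendon ends fixed).

Because no subject imaging data ships with the package, a synthetic
generator provides the study geometry: a fusiform solid of revolution with
flat tendon end discs, a thin planar aponeurosis sheet reaching the distal
muscle–tendon junction, an analytic feather fibre field with configurable
pennation angle, and streamlines integrated through that field with angular
noise — all with known ground truth.

## Worked example

```python
import numpy as np
from myofield.synth import (BipennateSpec, synth_streamlines, default_grid,
                            true_sheet_mask)
from myofield.tract_fields import compute_voxel_fields
from myofield.aponeurosis import BinaryVoxelMask, detect_aponeurosis, dice

spec = BipennateSpec()                       # 160 mm muscle, 15 deg pennation
tracks = synth_streamlines(spec, n=3000, noise_deg=5.0, seed=42)
grid = default_grid(spec)                    # 2.625 mm in-plane, 6.25 mm slices
fields = compute_voxel_fields(tracks, grid)

idx = np.stack(np.meshgrid(*map(np.arange, grid.shape), indexing="ij"), -1)
anterior = grid.centres(idx.reshape(-1, 3))[:, 0] >= -12.0
roi = BinaryVoxelMask(grid, anterior.reshape(grid.shape), tag="roi")

mask, report = detect_aponeurosis(fields.divergence, fields.count, roi,
                                  density_threshold="auto",
                                  n_tracks=len(tracks))
print(report["n_detected_voxels"])           # 115
print(round(dice(mask, true_sheet_mask(spec, grid)), 3))   # 0.951
```

The detector finds a single 115-voxel component on the sheet mid-plane; its
Dice overlap with the known synthetic sheet is 0.951, i.e. the joint
divergence–density criterion localises the aponeurosis to about one voxel.

The same pipeline is scriptable from the shell:

```bash
myofield synth --seed 42 --n-streamlines 3000 --outdir run/synth
myofield tract-fields --streamlines run/synth/streamlines.trk --outdir run/fields
myofield detect-apo --fields run/fields --outdir run/apo
myofield optimise-bc --outdir run/bc
myofield simulate --load-case 1 --pennation 15 --outdir run/sim
```

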