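# Methods

## Problem and scope

An aneurysm sac deforms measurably when a catheter injects a known flow rate
against its wall. Given binary lumen segmentations of a baseline (C1) and a
stimulated (C2) acquisition, the pipeline measures the luminal volume change
of the delimited aneurysm region and inverts it for the constants (a, b) of
an isotropic incompressible Fung-type wall law, then reports the wall stress
state at the identified constants. The package deliberately replaces the
original tool chain's 3-D one-way fluid–structure finite-element solve with
a closed-form reduced-order model (below); full CFD/ALE coupling, non-rigid
registration, heterogeneous or anisotropic wall models, and any
rupture-probability model are out of scope.

## Forward model

**Constitutive law.** W = (a/b)·(exp(b/2·(I₁−3)) − 1), a in kPa, b
dimensionless, with incompressibility assumed. For the equibiaxial sphere
stretch λ: I₁ = 2λ² + λ⁻⁴, wall Cauchy stress σ = (λ/2)·dŴ/dλ =
2(λ²−λ⁻⁴)·dW/dI₁.

**Membrane equilibrium.** The sac is a sphere of reference radius R₀ (mm)
and uniform thickness H (default 430 μm, the literature mid-range for these
walls). Inflation solves the Laplace relation P = 2σ(λ)h/r with r = R₀λ and
h = Hλ⁻² by bracketed root finding on λ ∈ [1, 3]: a 2001-point vectorized
scan brackets the first crossing on the stable ascending branch and Brent's
method refines it to ~1e−15 relative. If the requested pressure exceeds the
membrane limit point (reachable in the weak-stiffening limit b → 0), the
solver raises a non-convergence error naming the limit pressure rather than
jumping to the unstable branch. At the default geometry H/R₀ ≈ 0.21, beyond
the usual thin-wall heuristic; the solver warns and the warning is expected.
The b → 0 limit reproduces the closed-form neo-Hookean membrane response
P = 2Ha(λ⁻¹−λ⁻⁷)/R₀, which the tests exercise.

**Reference configuration.** R₀ absorbs the baseline in vivo load: it is
either given directly (synthetic studies) or recovered per candidate (a, b)
from the measured C1 volume by solving 2σ(λ)Hλ⁻²/r_obs = P₁ for λ and
setting R₀ = r_obs/λ. The image-anchored mode mirrors the original
procedure, which built one baseline model per sampled couple.

**Load reduction.** The transmural pressure program is
P(t) = p_out(t) + ½ρ v_jet(t)², where p_out is the pulsatile outlet
pressure and v_jet is the stimulus flow rate divided by the catheter lumen
area (inner diameter 1.68 mm). The uniform stagnation-pressure term is this
package's stated approximation of how the jet loads the wall; the original
study does not specify the spatial load distribution inside its solver. The
catheter body is rigid and motionless; it enters the model only through its
lumen area (its occupied volume is not voxelized into the phantom masks, a
simplification that leaves the measured ΔV unaffected since the occupied
volume is identical in C1 and C2).

## Synthetic data

The phantom is a parent tube (radius 1.5 mm, length 12 mm) carrying a
spherical sac whose center is placed so the sphere crosses the tube-top
plane with a cross-section equal to the neck radius. The C1/C2 masks
voxelize this implicit solid (a voxel is lumen iff its center is inside;
0.25 mm isotropic voxels matching the imaging resolution) with the sac
radius taken from the membrane model at the acquisition-time pressures.
Optional noise flips a seeded random fraction of the voxels within one
voxel of the lumen boundary.

The cardiac waveform is a piecewise half-sine systolic peak over a
diastolic baseline. Defaults: heart rate 200 beats/min (plausible for an
anaesthetized New Zealand White rabbit, and chosen so the systolic upstroke
spans the whole 0–0.07 s acquisition-offset window — the baseline pressure
is then injective in the offset, making the scan well-posed); peak velocity
0.35 m/s; outlet pressure 5732–13865 Pa; systole occupying half the cycle
with its peak at the quarter cycle; 300 samples per cycle (the peak phase
falls on the sampling grid, so the configured extrema are attained
exactly). The stimulus is a trapezoidal pulse (default 3 s duration, 0.1 s
ramps) whose time integral equals flow rate × duration exactly. The default
C2 instant is the first systole peak at least 2 s after the stimulus
trigger, matching the acquisition protocol.

**What the phantom does not emulate:** X-ray physics, contrast transport,
partial-volume or reconstruction artefacts, non-spherical sac deformation,
and wall-motion amplitudes below the voxel size. That last point matters:
at 0.25 mm voxels a sub-voxel radial displacement quantizes the
mask-derived ΔV (the demo pipeline shows this faithfully), so closed-loop
identification accuracy is validated on forward-model-generated ΔV_exp,
while the mask branch is validated on volumes, overlays and region splits.
Passing tests therefore demonstrate correctness of the machinery, not
imaging-noise robustness.

## Volumetry

Marching cubes at level 0.5 on the (zero-padded) mask gives a watertight
luminal surface in world millimetres; fragmented lumina reduce to the
largest connected component with a logged warning. The wall is the inner
surface offset outward along vertex normals by the thickness; offsets that
self-intersect (volume non-increasing or watertightness lost) are
rejected. Rigid C1/C2 overlay maximizes a soft Dice of Gaussian-smoothed
masks restricted to the artery side of the cut plane (the deforming sac is
excluded so it cannot bias alignment), via centroid initialization and
Powell refinement over 3 translations + 3 rotations; the final
artery-restricted Dice must exceed 0.5. The cut plane is stored in world
frame and serialized so the identical region is extracted from C1, C2 and
the numerical branch. Volumes come from voxel counting (default, the
direct image-domain measurement) and from the mesh (plane-cut volumes use a
signed-tetrahedron sum with apex on the cut plane, which needs no cap
triangulation); their agreement within a few percent is the internal
control — which published volumes were mesh- or voxel-derived is unknown,
so both are exposed.

## Inverse identification

The sweep uses 51 couples by default on [85, 645] kPa × [14.4, 17.6]. The
"grid" layout is a 17 × 3 tensor lattice (any n is laid out as an exact
na × nb lattice with ≥ 3 levels per axis when possible; otherwise a
deterministic corners-first subset of the smallest such lattice, with a
full-rank check on the quadratic basis — note a true tensor grid with only
two levels on one axis is rank-deficient, since b² is then an affine
function of b). A seeded Latin-hypercube layout is also available.

Fitting happens in affine-normalized coordinates (a and b differ ~20× in
scale); the stored normalization makes surface evaluation bit-reproducible
against training, and the raw-coordinate coefficients α₁…α₆ are recovered
by exact expansion. Evaluation outside the fitted box is refused by default.

Minimization is multi-start (5 × 5) L-BFGS-B over the box followed by a
bounded Levenberg–Marquardt polish on the residuals — the squared cost is
quartically flat near a zero level set, where a plain quasi-Newton stop
leaves kPa-scale error. Per-load mode matches one flow rate; since a scalar
match generically admits a whole zero-level curve, ties (cost below
1e−9 mm³) are broken by the point of the level set closest, in normalized
coordinates, to the literature anchor (353.6 kPa, 16.7) via an
equality-constrained projection. Joint mode minimizes the sum of squared
costs over the three flow-rate surfaces — generically a unique interior
minimizer, and the default for synthetic validation.

**Metamodel bias and the polish step.** The true ΔV(a) response is close to
c/a over the 7.6-fold a-range, which a full quadratic cannot follow: the
fitted surfaces carry a relative residual of order 10 %, and the pure
surface minimizer inherits a comparable bias in a (the same order as the
published relative errors e ≈ 3–9 %). Joint identification therefore
finishes with a Gauss–Newton polish of (a, b) against the forward model
itself (residuals scaled by |ΔV_exp|), the standard surrogate-then-refine
practice; with noise-free synthetic data this recovers ground truth to
numerical precision. The unpolished estimate remains available
(`refine=False`), the per-Δt surface residual bound is reported alongside
every fit, and the identified cost minimum is never meaningful below that
bound.

**Acquisition-time scan.** The offset Δt between the unknown cardiac phases
of the two acquisitions shifts the baseline instant: t1 = t2 − Δt folded
into one cycle. For each candidate Δt ∈ {0.01, …, 0.07} s (the printed scan
range read as excluding zero; the grid is configurable) surfaces are fitted
and the cost minimized; the Δt with the lowest minimum wins, ties are
logged, and the forward model is re-run at the winner to produce
ΔV_num/mat and the relative errors e. In joint mode the correct offset is
the only one whose three volume changes are simultaneously matchable by a
single couple, which is what makes the scan discriminating.

## Reporting

The published study tables (luminal volumes, identified constants, relative
errors, stress-state summaries for subjects S1/S2) are embedded as input
fixtures; every derived column is recomputed from its sources on load.
Rounding conventions: ΔV to 2 decimals (mm³), ΔV% to 1 decimal, the D2→D3
stiffness decrease to the nearest integer percent, e to 2 decimals. The
baseline ⟨P_C1⟩, ⟨σ₁,C1⟩ references are not published; fixtures derived by
inverting the printed percentages are consistency checks only, never ground
truth. The rupture-criterion ratio ⟨σ₁⟩/⟨P⟩ is emitted per condition and
flagged provisional — the eventual combination of stress components is not
yet defined.

## Numerical choices and defaults

| quantity | default | note |
|---|---|---|
| wall thickness H | 430 μm | uniform; literature mid-range |
| wall/fluid density | 1050 kg/m³ | |
| dynamic viscosity | 0.0035 Pa·s | Newtonian (vessels ≫ 0.1 mm) |
| catheter lumen / outer | 1.68 / 1.87 mm | |
| outlet pressure | 5732–13865 Pa | pulsatile, phase-locked to velocity |
| heart rate | 200 beats/min | exposed as config (see above) |
| sweep | 51 couples, [85, 645] × [14.4, 17.6] | grid or Latin hypercube |
| Δt grid | 0.01 … 0.07 s, step 0.01 | configurable |
| membrane root | bracket + Brent, xtol 1e−14 | stable branch only |
| zero-level tie tolerance | 1e−9 mm³ | per-load anchor tie-break |
| registration metric | soft Dice, σ = 1 voxel smoothing | artery-restricted |

Problem sizes used in tests and in the acceptance study — 10 seeded ground
truths for closed-loop recovery, 7 offsets for the scan study, 500 × 500
brute-force cost grids, ~10⁵-voxel phantom masks — keep every stage
closed-form checkable while exercising the full pipeline.

## Known limitations

* The spherical-membrane reduction preserves ΔV(a, b, load) structurally
  but not the absolute stress level of a real, irregular, thick-necked sac;
  published subject-specific stress tables are not reproducible at desk
  scale and are treated as inputs, not targets.
* Sub-voxel wall displacement quantizes mask-derived ΔV at 0.25 mm
  resolution; identification from real masks inherits that noise floor.
* Per-load identification is fundamentally under-determined (one scalar,
  two constants); the anchor tie-break is a documented convention, not a
  statistical estimator. Joint mode is the identifiable path.
* The uniform stagnation-pressure jet load is an approximation; no
  uncertainty quantification is provided beyond the reported surface
  residual.
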