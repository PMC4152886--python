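# Methods

`pennatefem` simulates quasi-static isometric contraction of an idealized
unipennate muscle belly — two flat aponeurosis sheets sandwiching a
parallelogram of muscle tissue, styled on the human lateral gastrocnemius —
and reports the whole-muscle force vector, its center of force on the
tendon-side cross-section, and the emergent fiber architecture (pennation,
strain fields, belly shape changes, fiber trajectories).

## Model

**Geometry.** The muscle cross-section (in any width slice) is a
parallelogram: short sides of length `L_f` = 65 mm (the fiber length) at
the initial pennation angle θ₀ = 15° to the long sides, which are covered
by aponeurosis slabs 210 mm × 3 mm.  Width is 55 mm.  The two slabs are
staggered along the belly axis by `L_f cos θ₀` ≈ 62.8 mm, giving a total
length of ≈ 272.8 mm.  The far end of each aponeurosis is rigidly fixed;
every other surface is traction free.  There is no external tendon: the
belly as a whole is isometric, fiber shortening being taken up by
aponeurosis stretch and shape change.

**Tissue mechanics.**  Both tissues are nearly incompressible,
transversely isotropic and hyperelastic.  The strain energy splits into

* a volumetric penalty `W_vol = κ/4 (J² − 1 − 2 ln J)` with κ = 10⁶ Pa
  (muscle) and 10⁸ Pa (aponeurosis);
* an isotropic base part in the isochoric first invariant — a cubic
  (Yeoh) polynomial for muscle and an exponential (Humphrey) form for the
  aponeurosis;
* an along-fiber part defined through its Cauchy stress–stretch relation
  `λ ∂W/∂λ = σ(λ)`, acting as a rank-one tension `σ(λ)/J · a⊗a` along the
  deformed fiber direction.

Muscle fiber stress is Hill-type: `σ = σ₀ (α(X,t) · fl(λ) + p(λ))` with
maximum isometric stress σ₀ = 200 kPa, a trigonometric-polynomial active
force–length factor `fl` (ω = 4.957; clamped to zero outside
λ ∈ [0.561, 1.773], the interval on which the fit is non-negative), and an
exponential passive term `p` active only in tension (its printed fit
constants leave a 7.4 × 10⁻⁴ offset at λ = 1⁺, which is subtracted so the
curve is exactly continuous).  The force–velocity factor is unity: the
contractions are quasi-static and isometric.  Aponeurosis fiber stress is
a piecewise exponential/linear tension-only curve; its two branches meet
continuously at the printed breakpoint.

**Activation.**  α(X, t) ramps linearly over 0.4 s.  Four spatial
patterns: uniform (α_max = 0.1) and three half-volume patterns
(α_max = 0.2) split proximo-distally (by a length plane), as a midline
band in width, or medio-laterally (by a width plane), blended smoothly by
an arctan profile (default width 5 mm).  Region boundaries are calibrated
against the mesh quadrature so the whole-muscle mean activation is
exactly 10% at the end time in every condition; the medial-lateral
transition width is instead solved so the activity centroid sits at the
reported x = 32.1 mm (the mid-width boundary keeps its mean at 10% by
symmetry).  Which half is active in the proximal-distal pattern is
configurable; the default activates the half adjacent to the fixed deep
end.

**Discretization and solver.**  Structured sheared-hexahedral (affine)
cells conform exactly to the tissue interfaces; trilinear displacements
with 2×2×2 Gauss quadrature.  Near-incompressibility uses the three-field
displacement / pressure / dilation formulation with cell-wise constant
auxiliary fields, condensed cell-by-cell into a mean-dilatation
displacement-only system whose Newton tangent carries one rank-one
volumetric block per cell.  Activation is applied in 10 quasi-static load
steps, each solved by Newton–Raphson with a consistent analytic tangent.
Because the tissue curves stiffen exponentially, the line search uses the
potential energy (Armijo) rather than the residual norm, falls back to a
Levenberg-style diagonal damping when no energy-decreasing step exists,
and bisects the load increment recursively (depth ≤ 4) if a step still
fails.  Linear systems are solved with sparse LU by default; a
Jacobi-preconditioned conjugate-gradient option is available in config.
Convergence is declared at a relative residual of 10⁻⁸ (absolute
10⁻¹⁰ N), or at the precision achievable for the system's conditioning
(≤ 10⁻⁴ relative) when floating-point limits bind first.

## Parameter readings the published constants do not settle

Three printed constants are mutually inconsistent with the published
results at the 10×–100× level, and the package takes a documented position
on each (each remains overridable in `MaterialParams`):

1. **Yeoh coefficients (muscle base).**  As printed (`~10⁻² Pa`) the
   muscle has no isotropic stiffness at all; the discrete problem is then
   numerically singular (hourglass modes) and no solver progress is
   possible.  The default multiplies them by 3 × 10⁴ (shear modulus
   ≈ 0.4 kPa) — the smallest factor, on a 1–3–10 grid, for which Newton
   converges across all twelve study conditions, i.e. the closest
   tractable approximation of the printed near-zero stiffness.

2. **Humphrey exponent (aponeurosis base).**  As printed (579.6) the
   aponeurosis base material has a ≈ 100 MPa shear modulus: the sheets
   become quasi-rigid plates, suppress every reported shape change, and
   carry the tension through the base instead of the along-fiber curve.
   Exponents of this model are O(1–30) in its source literature; the
   default reads the mantissa at unit scale (5.796, base shear modulus
   ≈ 1 MPa).

3. **Aponeurosis stress–stretch curve.**  The stiffness variants are
   defined by reaching maximum strains of 10/5/2% when the muscle
   develops maximal isometric force.  With this geometry that force
   (σ₀ × physiological cross-section ≈ 598 N) loads the tendon-side
   aponeurosis section to 3.62 MPa — yet the printed curve needs 1.39 GPa
   to reach 5% strain.  The default calibration therefore rescales only
   the **strain axis** of the printed curve, per variant, so that it
   reaches its defining maximum strain exactly at 3.62 MPa; the stress
   values are kept verbatim.  This single anchoring reproduces the
   reported working-point aponeurosis stretch (≈ 1.5% for the compliant
   variant at 10% mean activation) with no further freedom.  The printed
   curve is available as `apo_calibration="printed"`.

## Outputs and conventions

* **Force and center of force.**  Cauchy tractions are integrated over
  the z = 0 cross-section of the deep aponeurosis (a material, fixed
  plane, so reference and deformed areas coincide).  The center of force
  is the normal-traction (σ_zz) weighted centroid — the standard
  center-of-pressure definition (the source study leaves its COF
  definition unstated).
* **Pennation** is the volume-weighted angle between the deformed fiber
  direction and the locally convected aponeurosis plane — the convention
  that returns exactly 15° in the reference state and is invariant under
  rigid rotations.  Means over the whole muscle and over the active
  region (activation-weighted) are both reported; the proximal-distal
  comparison value uses the active region, since the figure it comes from
  shows the actively contracting half.
* **Width change** is measured between the extremal deformed
  x-coordinates of the muscle surface at mid-length, mid-thickness;
  **thickness** is the y-distance between the two muscle–aponeurosis
  interfaces at matched physical z (the staggered interfaces are
  interpolated onto common z samples).
* **Fiber trajectories** are deformed images of straight reference fiber
  lines, sampled through the trilinear displacement field; curvature by
  finite differences along arclength, and the S-shape diagnostic counts
  sign changes of the signed deviation from the end-to-end chord.

## Problem sizes

Default production mesh: 8 × (2+6+2) × 48 cells (3840 hexahedra, ≈ 14.6 k
displacement unknowns).  The acceptance script uses 6 × (2+6+2) × 32
(1920 cells) and the test suite's desk-scale runs use 4 × (1+4+1) × 24
(576 cells): across these meshes the whole-muscle force changes by < 1%,
while pointwise strain maxima (which live at the sharp staggered ends of
the muscle sheet) grow slowly under refinement and are reported at the
stated resolutions.  Ten load steps reproduce the 20-step end state to
within the Newton tolerance (elastostatic path independence).

## Known limitations

* The three parameter readings above are design choices forced by
  internal inconsistencies in the published constants; with any single
  "verbatim" reading the model contradicts the published emergent
  behavior (pennation increase, mid-slab center of force, belly bulging).
* Even with those choices, the uniform-activation peak fiber strain and
  the belly width bulge remain below the reported 26% / 12% (the model
  reaches ≈ 11–25% and ≈ 7–8% depending on condition and mesh).  The
  reported values appear to require still softer base tissue than is
  numerically reachable with this element technology.
* Maximum-strain metrics sit at geometric stress concentrations (sharp
  muscle ends, clamped edges) and are therefore mesh-dependent;
  force-level and centroid metrics are mesh-converged.
* No external tendon, no force–velocity dependence, no viscoelasticity or
  damage, single fiber family, no fiber-type heterogeneity.
* The synthetic geometry is a regularized parallelepiped; none of the
  subject-specific curvature or tapering of a real gastrocnemius is
  represented, so quantitative agreement with imaging studies is not to
  be expected from these simulations.
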