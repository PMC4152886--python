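# pennatefem

3D finite-element simulation of an isometric, unipennate muscle belly —
muscle tissue sandwiched between two aponeurosis sheets, styled on the
human lateral gastrocnemius — under **regionalized activation** and
**variable aponeurosis stiffness**.

Skeletal muscles contain neuromuscular compartments that can be driven
relatively independently.  This package asks the question such
compartmentalization raises: if the *mean* activation of a muscle is held
fixed (10%), how do the magnitude, direction and point of application of
the whole-muscle force change when that activity is concentrated in one
half of the muscle rather than spread uniformly?  And how does the
stiffness of the aponeurosis — the in-series elastic sheet the fibers
insert into — reshape that answer?

## Model in brief

Both tissues are nearly incompressible, transversely isotropic
hyperelastic solids.  The strain energy per unit reference volume is

```
W = κ/4 (J² − 1 − 2 ln J)  +  W_base(Ī₁)  +  W_fib(λ),   λ ∂W_fib/∂λ = σ(λ)
```

with a Yeoh cubic (muscle) or Humphrey exponential (aponeurosis) base
material and an along-fiber Cauchy stress σ(λ) acting as a rank-one
tension along the deformed fiber direction.  Muscle fiber stress is
Hill-type, `σ = σ₀ (α(X,t)·fl(λ) + p(λ))` with σ₀ = 200 kPa, a
trigonometric force–length curve `fl` and a tension-only passive
exponential `p`; the aponeurosis uses a piecewise exponential/linear
tension curve whose strain axis defines the *compliant / normal / stiff*
variants (maximum working strains 10 / 5 / 2% at maximal isometric
force).  Activation α(X,t) ramps linearly over 0.4 s in one of four
spatial patterns (uniform, proximal–distal, midline, medial–lateral),
calibrated so the whole-muscle mean activation always reaches 10%.

The equilibrium problem is the stationary point of the three-field
potential (displacement u, pressure p̃, dilation J̃; Q1/P0/P0 hexahedra,
condensed to a mean-dilatation displacement form) solved by
Newton–Raphson with an energy line search over quasi-static load steps.
See `docs/methods.md` for the full account, including the positions taken
where the published material constants are mutually inconsistent.

## Worked example

```python
from pennatefem import RunSpec, run_single
from pennatefem.geometry import Resolution
from pennatefem.solver import SolverConfig

spec = RunSpec.for_condition(
    "proximal_distal", "compliant",
    resolution=Resolution(nx=4, ny_apo=1, ny_muscle=4, nz=24),
    solver=SolverConfig(n_load_steps=10))
res = run_single(spec)
for k in ("force_N", "delta_y", "delta_z", "COFx_mm", "COFy_mm",
          "pennation_active_deg", "max_fiber_strain_pct",
          "apo_strain_max_pct"):
    print(f"{k:24s} {res.summary[k]:.4g}")
```

prints (desk-scale mesh, ~40 s on one CPU):

```
force_N                  60.04
delta_y                  0.07221
delta_z                  0.9974
COFx_mm                  27.5
COFy_mm                  1.44
pennation_active_deg     16.13
max_fiber_strain_pct     25.25
apo_strain_max_pct       1.787
```

Reading: at 10% mean activation concentrated proximo-distally, the belly
transmits ≈ 60 N across the tendon-side plane, almost along the belly
axis (δz ≈ 0.998) with a small through-thickness component; the force
centroid sits on the mid-width line (COFx = 27.5 mm — the pattern is
mirror-symmetric) about half-way down the 3 mm aponeurosis thickness;
fibers in the active half have rotated from 15° to ≈ 16.1° pennation,
shortening locally by up to ≈ 25% while the aponeurosis stretches up to
≈ 1.8%.

The same grid is available from the shell:

```
pennatefem run --pattern medial_lateral --stiffness compliant --out out/
pennatefem matrix --resolution 4,1,4,24 --out matrix_out/   # all 12 conditions
pennatefem curves --out stress_stretch.csv
```

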