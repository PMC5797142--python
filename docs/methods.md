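# Methods

`ligmech` implements five constitutive representations of knee ligaments —
discrete tension-only springs, isotropic linear elasticity, compressible
neo-Hookean hyperelasticity, biphasic porohyperelasticity, and a
fibril-reinforced porohyperelastic (FRPHE) composite — together with the
numerical machinery needed to compare them at joint level: a small u-p
finite-element solver, a synthetic knee surrogate, and a rigid-body stance
pipeline. This note records the models, the defaults, and the design
decisions that were genuinely open.

## Constitutive models

**Spring.** A line element of stiffness `k_s` [N/mm] between the femoral
and tibial attachment points. With pre-strain `ε0` the force-free length
is `L_ref/(1+ε0)`; the force is `k_s·max(e, 0)` on the elongation `e` past
that slack length — the element buckles (carries nothing) in compression.

**Linear elastic.** Hooke's law `σ = C:ε` with isotropic `C(E, ν)`. At the
material point the infinitesimal strain `ε = sym(F) − I` is used. In the
finite-element setting the law is applied corotationally (Biot strain
`U − I` from the polar decomposition `F = RU`, stress rotated back by `R`)
so that the finite rigid rotations a ligament undergoes during stance do
not create spurious strain; this is the behavior of a linear material
inside a geometrically nonlinear solve, and it coincides with plain Hooke
at small strain.

**Neo-Hookean.** Cauchy stress
`σ = K_m ln(J)/J I + (G_m/J)(F·Fᵀ − J^{2/3} I)`.
Constants come either as `(K_m, G_m)` or in the `(C1, D)` convention with
`G_m = 2·C1` and `K_m = 2/D` — both pairs are kept on the parameter object
and the conversion is a single documented constructor. Note that the
tabulated `(E, ν)` of the linear model and `(C1, D)` of the hyperelastic
model share the same shear modulus and nearly the same uniaxial tangent,
but not the same bulk modulus; the laws are therefore equivalent in
tension-dominated states and differ volumetrically.

**Biphasic (porohyperelastic).** Total stress `σ_tot = σ_eff − p·I` with
the effective stress given by the neo-Hookean skeleton and the pore
pressure `p` governed by fluid continuity with Darcy flux `q = −k ∇p` and
the strain-dependent permeability

`k(J) = k0 [φ0 φ_f / ((1−φ0) φ_s)]² exp(M (J²−1)/2)`,

with current solid fraction `φ_s = φ0/J` and fluid fraction
`φ_f = 1 − φ0/J`. `k` is stored in 1e-15 m⁴/(N·s) and converted exactly
once at solver entry (1e-15 m⁴/(N·s) = 1e-3 mm⁴/(N·s) in the mm-N-MPa-s
unit system). The initial solid fraction `φ0` is not part of the reference
parameter table; the default 0.3 corresponds to ligament tissue at roughly
70% water content and only enters through the (weak) fraction bracket.

**FRPHE.** The solid skeleton splits into a tension-only collagen fibril
network and the neo-Hookean nonfibrillar ground matrix built from
`(E_m, ν_m)`: `σ_tot = σ_f + σ_nf − p·I`. Each fibril direction carries the
uniaxial law `σ_f = E_f·ε_f` for `ε_f > 0` and zero otherwise. One primary
direction per material point follows the tissue axis; a fixed reference
set of 13 secondary directions (3 axis-aligned + 10 quasi-uniform on the
half-sphere, Fibonacci lattice) represents the randomly oriented fibrils.
The primary-to-secondary stress ratio is the density ratio `C`.

Two conventions here were genuinely open:

* *Fibril strain measure.* Logarithmic strain of the direction stretch,
  `ε_f = ln|F·d|`, consistent with the finite-strain matrix law; the
  Green–Lagrange variant is available behind the same one-line function.
* *Direction-sum normalization.* The direction sum is density-weighted:
  the primary direction carries weight `ρ_z·C/(C·n_p + n_s)` and each
  secondary `ρ_z/(C·n_p + n_s)` (here `n_p = 1`, `n_s = 13`), so adding
  directions refines the angular distribution instead of stiffening the
  tissue, in the spirit of the fibril-reinforced cartilage formulations
  this model family descends from. With the tabulated `C = 12` for the
  cruciates an *unnormalized* sum would make the fibril term an order of
  magnitude stiffer than every other representation and invert all
  model-ordering observations; the raw convention remains available as
  `normalization="raw"`. A corollary of the weighting (and of the
  direction-count convention in general) is that `E_f` is a network
  modulus, not a tissue tensile modulus: the effective axial tangent of
  the composite is roughly `C/(C+13)·E_f` plus small secondary and matrix
  terms, e.g. ≈58 MPa for the adjusted ACL set (`E_f` = 100, `C` = 12,
  `E_m` = 1).

The relative collagen density `ρ_z` defaults to 1 and is absorbed into
`E_f`. Tension gating applies to the spring elements and the fibril
network only; the 3-D matrix laws are symmetric in tension and
compression, which is what produces the observed contrast between the
FRPHE ligament (no compressive axial stress) and the plain hyperelastic
one under late-stance bending.

## Finite elements

Equal-order linear displacement/pressure tetrahedra (the pore-pressure tet
family) in a total-Lagrangian setting; the deformation gradient is
constant per element, integration is single-point. The momentum residual
uses the first Piola transform of the total Cauchy stress; fluid
continuity `dJ/dt + Div(J F⁻¹ q) = 0` is integrated by backward Euler
(unconditionally stable for consolidation) with the permeability tensor
pulled back as `k J F⁻¹F⁻ᵀ`.

Equal-order pairs need pressure stabilization near the undrained/
incompressible limit: a Brezzi–Pitkäranta-type term
`τ ∇δp·∇(ṗ)` with `τ = c·h²/H_A` (element size `h`, aggregate modulus
`H_A`, default `c = 0.02`) damps the checkerboard mode without polluting
steady states (the term vanishes when `ṗ = 0`). The coefficient is covered
by the consolidation benchmark: with `c = 0.02` the pressure profiles match
the analytic series to <2% relative L2 on a 16-element column at three
sampled times, and the error decreases monotonically under refinement.
Remaining signature of the element pair: pointwise pressure oscillations
of order ±10% at unresolved early-time boundary layers (the interior mean
stays within 2‰ of the undrained value).

The element tangent is assembled by forward finite differences of the
element residual (step 1e-7), with all perturbed element copies evaluated
in one batched call. Newton iteration uses a backtracking line search on
the residual norm and a cached LU factorization that is rebuilt lazily
whenever the iteration stalls; failed increments are bisected (up to 5
levels). Convergence demands a residual below 1e-8 relative to the driving
force scale of the step (or 1e-9 absolute). Reactions are reported by
residual restriction at constrained dofs, which makes the "reactions
balance applied loads" identity exact to solver tolerance.

## Synthetic knee surrogate

The study geometry (subject MRI) and gait inputs are not distributable, so
the joint is a surrogate with every element chosen once and documented:

* **Ligament geometry.** Four bundles (ACL, PCL, MCL, LCL) as curved,
  optionally twisted tubes of tetrahedra between anatomically plausible
  attachment points in a joint frame (x anterior, y medial, z superior);
  fibers follow the centerline. Cross-section areas are derived from the
  consistency condition `E·A/L = k_s` between the tabulated linear modulus
  and the tabulated initial spring constant, which lands on realistic
  values (ACL ≈ 57 mm², MCL ≈ 32 mm²) and makes the spring and solid
  representations comparable by construction. Mesh resolution 1 gives
  ~600 tets for all four bundles; the disk template is area-corrected so
  mesh volumes stay within 2% of the analytic tube volume.
* **Pre-strain.** Reference-pose tensile pre-strains ACL 2%, MCL 2%,
  LCL 1.5%, PCL 1% (near-slack), in the range used by numerical knee
  models. Solid ligaments realize pre-strain by meshing the tube at its
  slack length and mounting the tibial end at the farther reference
  insertion. With *zero* pre-strain the (near-vertical) ligament columns
  are pushed into axial compression by the joint compression itself and
  the symmetric matrix laws then shield the contact — an artifact of the
  column-like surrogate geometry that inverts the expected model ordering;
  taut reference ligaments remove it. A fully slack configuration remains
  available (`pre_strains=0.0`).
* **Gait waveforms.** Each channel is a baseline plus Gaussian bumps in
  stance fraction, windowed by `sin(π·min(t,1−t))^0.4` so all loads vanish
  at heel strike and toe off; the axial channel is double-peaked (peaks
  near 25% and 75% of stance). Amplitudes are literature-plausible
  magnitudes for an 80 kg adult: axial 2.2/2.0 BW (total knee compressive
  force scale, i.e. external load plus lumped muscle action),
  internal-external moments 2–2.5 N·m and an adduction (varus) moment of
  8–9 N·m — the physiological frontal-plane direction, which loads the
  medial compartment and tensions the LCL, conservative in magnitude and
  sized to the moment capacity of a four-ligament joint without muscles —
  anterior-posterior shear ~0.15–0.18 BW, flexion 4–26°. The generator is
  pure and the time-reversed profile mirrors the waveform exactly.
* **Contact and capsule.** Tibiofemoral contact is lumped into one
  compression-only element per condyle at ±22 mm, normal stiffness
  6000 N/mm (cartilage scale), with a C1 one-sided quadratic smoothing
  over 0.02 mm. A tangential stiffness of 30 N/mm per condyle, engaged in
  proportion to the normal load, stands in for the horizontal/torsional
  stability that plateau conformity and menisci provide — without it the
  surrogate has essentially no internal-external rotation stiffness. A
  weak capsule restraint (2 N/mm, 500 N·mm/rad) keeps the unloaded joint
  well-posed; its share of the load budget is <1%.
* **Parameter sampling.** Ligament moduli are drawn from
  `Normal(base, RSD·base)` truncated below at 1% of the base value via the
  inverse-CDF method. Truncation raises the mean and shrinks the spread,
  so empirical sample RSDs are compared against the analytic
  truncated-normal RSD (`truncated_rsd`), which is the documented
  correction.

## Stance pipeline

Femur fixed; tibia rigid with flexion prescribed and the axial force,
shear forces and moments applied; the remaining five DOFs (three
translations, valgus-varus, internal-external) are solved from quasi-static
equilibrium at each of the stance samples (default 25 over a 0.6 s
stance). Solid ligaments enter through full FE sub-solves with end faces
rigidly coupled to the bones; a Powell hybrid solve (with explicit
1e-4-scale difference steps and a Levenberg–Marquardt polish for the
tension-gate kinks near unloaded poses) drives the 5-DOF residual below
1e-6 of the force scale. The first gait sample is approached through a
fully drained settling ramp, so heel strike starts from the relaxed
(p = 0) pre-tension state; during stance the biphasic ligaments evolve
with the real time step and their configured (sealed or free) drainage.
The reported joint reaction force is the total compressive contact force —
the quantity the ligament tensions modulate by pulling the tibia into the
femur.

The first peak is the earliest local maximum of the reaction trace in
(0, 50%] of stance; the peak-matching adjustment finds a uniform scalar on
the spring-constant or fibril-modulus set by bracketed root finding.

## Problem sizes and tolerances

Default analyses use mesh resolution 1 (~600 tets over four bundles,
well under the 2,000-tet envelope of the scaled joint) and 25 stance
samples; the fluid-sensitivity analysis runs the reference plus 12
variants (k0 ∈ {0.15, 2.9, 15}, M ∈ {1, 10}, sealed and free) in roughly
ten minutes on one core. The consolidation benchmark uses a 1×1×1 mm
column at 4/8/16 elements through the thickness and 160 geometric time
steps.

## What the surrogate does and does not show

Passing tests establish the *mechanistic* claims on the surrogate: the
constitutive laws are implemented exactly (closure identities to 1e-10,
frozen high-precision oracles); the solver reproduces closed-form
consolidation; the tension-only representations track each other and fall
below the symmetric solids when late-stance bending arrives; joint forces
respond to the fibril network modulus monotonically and to the
nonfibrillar matrix and fluid phase only marginally; and the elastic /
hyperelastic / porohyperelastic family is mutually equivalent within 5%
in its regime of validity (small strain, drained-slow loading for the
biphasic member — at stance rates a sealed biphasic ligament is
volumetrically rigid and genuinely ~7% stiffer in uniaxial terms).

The surrogate does **not** reproduce the subject-specific magnitudes:
absolute joint forces, translations and rotations depend on the real
geometry, cartilage contact and muscle forces and are out of scope.
Reaction forces land in the physiological 2–3 BW band by construction of
the axial input, not by validation. Anatomical realism of the attachment
sites, wrapping, and the patellofemoral mechanism are absent. The FRPHE
fibril recruitment is bilinear (no toe region), as in the source model
family.

## Known limitations

* Linear tetrahedra with equal-order pressure: early-time pressure
  oscillation at unresolved boundary layers; mild volumetric locking in
  bending near the undrained limit.
* The finite-difference tangent costs one batched residual sweep per
  assembly; acceptable at the shipped problem sizes, not intended for
  meshes beyond ~10⁴ elements.
* The rigid-contact surrogate has no rolling/sliding kinematics; flexion
  does not translate the contact point posteriorly.
* Spring ligaments are single lines, not fiber bundles; their wrap-around
  and twist behavior is absent.
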