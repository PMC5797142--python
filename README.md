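# ligmech

Constitutive representations of knee ligaments — from tension-only
springs to fibril-reinforced porohyperelastic (FRPHE) tissue — and a
reduced knee-joint pipeline that compares them over the stance phase of
gait. The package is aimed at computational biomechanics researchers who
want to study how much constitutive detail a ligament model needs: does
the compression-tension nonlinearity of collagenous tissue matter for
joint-level forces, and which constituents (fibril network, nonfibrillar
matrix, interstitial fluid) actually drive the response?

## Models

Five representations of the same ligament, with reference parameters
shipped for the ACL, PCL, MCL, LCL, patellar and quadriceps tendons:

| model | law |
|---|---|
| spring | F = k_s·e for elongation e > 0, else 0 |
| linear elastic | σ = **C**(E, ν) : ε |
| neo-Hookean | σ = K_m ln(J)/J **I** + (G_m/J)(**F·F**ᵀ − J^{2/3} **I**) |
| porohyperelastic | σ_tot = σ_eff − p**I**, k(J) = k0[φ0φ_f/((1−φ0)φ_s)]² exp(M(J²−1)/2) |
| FRPHE | σ_tot = σ_f + σ_nf − p**I**, σ_f = E_f ε_f for ε_f > 0 (tension-only fibrils) |

The FRPHE fibril network has one primary direction along the tissue axis
and 13 secondary directions, with primary:secondary stress ratio given by
the density ratio C.

Around the material laws: a quasi-static u-p finite-element solver on
linear pore-pressure tetrahedra (backward-Euler fluid continuity,
strain-dependent permeability, sealed or free-draining surfaces), a
synthetic knee surrogate (parametric ligament tube meshes, stance-phase
gait waveforms, truncated-Gaussian parameter sampling), and a rigid
femur-tibia joint with lumped condylar contact driven through stance.

## Worked example

```python
import numpy as np
from ligmech import joint_pipeline as jp
from ligmech.synthetic_knee import generate_gait

gait = generate_gait(n_steps=25)             # double-peaked stance loading
model = jp.build_surrogate_joint("frphe")    # 4 FRPHE bundles, Table 'adjusted'
res = jp.run_stance(model, gait)
print(np.round(res.reaction_BW[::4], 2))
print(round(res.per_ligament_force["PCL"].max(), 1), "N peak PCL force")
```

prints

```
[0.06 1.5  2.01 1.5  1.83 1.4  0.  ]
59.1 N peak PCL force
```

— the tibiofemoral reaction force in body weight at 0, 17, 33, …, 100% of
stance (two peaks just above 2 BW, in the physiological range), and the
peak force carried by the PCL bundle. Swapping `"frphe"` for `"spring"`,
`"linear"`, `"neohookean"` or `"poro"` runs the identical loading through
the other representations; `jp.compare_models` tabulates the pairwise
trace differences.

The numbered scripts under `analysis/` reproduce the full study line:

1. `01_material_point.py` — material-point stiffness/permeability tables
2. `02_verification.py` — consolidation benchmark, FRPHE bar asymmetry
3. `03_compare_models.py` — five-model stance comparison
4. `04_adjust_first_peak.py` — first-peak stiffness adjustment
5. `05_parameter_sweep.py` — fibrillar vs nonfibrillar modulus sweeps
6. `06_fluid_sensitivity.py` — permeability/drainage sensitivity
7. `07_sample_parameters.py` — probabilistic modulus sampling

Each writes CSV tables (and plots) under `results/`.

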