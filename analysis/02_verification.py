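#!/usr/bin/env python
"""Verify the poroelastic solver against closed-form benchmarks.

Runs (a) the confined-compression consolidation benchmark against the
analytic pressure series at three mesh resolutions and (b) the uniaxial
tension/compression response of a fibril-reinforced bar.  Writes
results/terzaghi.csv and results/uniaxial_frphe.csv and prints the error
summary.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from ligmech.constitutive import BiphasicParams, FibrilParams, FRPHEParams, NeoHookeanParams
from ligmech.poro_fem import (
    PERMEABILITY_UNIT,
    FEFRPHE,
    run_confined_compression,
    run_uniaxial_tension,
    terzaghi_pressure,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

nh = NeoHookeanParams.from_young_poisson(1.0, 0.4)
fluid = BiphasicParams(2.9, 0.0, 0.3)
lam = 1.0 * 0.4 / (1.4 * 0.2)
HA = lam + 2.0 / 2.8
tchar = 1.0 / (fluid.k0 * PERMEABILITY_UNIT * HA)
Ts = np.geomspace(5e-4, 0.45, 160)

rows = []
for nz in (4, 8, 16):
    mesh, res = run_confined_compression(nh, fluid, 0.002, Ts * tchar, height=1.0, nz=nz)
    for T_target in (0.05, 0.15, 0.35):
        i = int(np.argmin(np.abs(Ts - T_target)))
        pa = terzaghi_pressure(1.0 - mesh.nodes[:, 2], Ts[i])
        err = np.linalg.norm(res.pressure[i] / 0.002 - pa) / np.linalg.norm(pa)
        rows.append({"nz": nz, "T": round(Ts[i], 4), "rel_L2_error": round(err, 5)})
terz = pd.DataFrame(rows)
terz.to_csv(OUT / "terzaghi.csv", index=False)
print("Consolidation benchmark (relative L2 pressure error):")
print(terz.pivot(index="T", columns="nz", values="rel_L2_error").to_string())

params = FRPHEParams.from_matrix_moduli(1.0, 0.4, FibrilParams(100.0, 12.0), BiphasicParams(2.9, 7.98))
strains = np.array([-0.02, -0.01, -0.005, 0.005, 0.01, 0.02, 0.03])
rows = []
for e in strains:
    _, stress, _ = run_uniaxial_tension(FEFRPHE(params), [1.0 + e])
    rows.append({"strain": e, "nominal_stress_MPa": round(float(stress[0]), 5)})
uni = pd.DataFrame(rows)
uni.to_csv(OUT / "uniaxial_frphe.csv", index=False)
print("\nFRPHE bar, nominal stress vs strain (tension stiff, compression soft):")
print(uni.to_string(index=False))
ratio = (uni.nominal_stress_MPa.iloc[-1] / 0.03) / (-uni.nominal_stress_MPa.iloc[0] / 0.02)
print(f"\ntension:compression tangent ratio ~ {ratio:.0f}x (fibril gating)")
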