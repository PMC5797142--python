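#!/usr/bin/env python
"""Match the first reaction-force peak by rescaling spring stiffness.

Reproduces the adjustment procedure: starting from the literature-based
('initial') spring constants, find the uniform multiplier that matches
the first peak of a reference trace.  Demonstrated on the spring model
against (a) itself (fixed point at 1.0) and (b) a doubled-stiffness
variant (recovers 0.5).  Writes results/adjustment.csv.
"""

from pathlib import Path

import pandas as pd

import ligmech.joint_pipeline as jp
from ligmech.synthetic_knee import generate_gait
from ligmech.tables import load_reference_parameters

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

gait = generate_gait(n_steps=25)
base = jp.run_stance(jp.build_surrogate_joint("spring", "initial"), gait, t_max=0.55)
_, ref_peak = jp.find_first_peak(base.time, base.reaction_N)
print(f"reference first peak: {ref_peak:.1f} N")

springs = load_reference_parameters()["spring"]["initial"]
rows = []
for factor, label in ((1.0, "self"), (2.0, "doubled-stiffness")):
    adj = jp.adjust_to_first_peak(
        lambda m: jp.build_surrogate_joint("spring", "initial", spring_scale=factor * m),
        gait,
        ref_peak,
        base_values={k: factor * v for k, v in springs.items()},
        tol=2.0,
    )
    print(f"{label}: multiplier {adj.multiplier:.3f}, matched peak {adj.peak:.1f} N")
    for lig, val in adj.adjusted_values.items():
        rows.append({"scenario": label, "ligament": lig, "k_adjusted_N_per_mm": round(val, 1),
                     "multiplier": round(adj.multiplier, 4)})
pd.DataFrame(rows).to_csv(OUT / "adjustment.csv", index=False)
print("\nAdjusting away a doubled stiffness recovers the 50% reduction that "
      "first-peak matching applies to an overstiff spring set.")
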