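"""Shared fixtures.

The joint-level stance solves are expensive, so everything downstream of
them (model comparison, parameter sweeps, fluid-insensitivity, stress sign
checks) is computed once per session here and shared between the module
tests and the acceptance suite.
"""

from __future__ import annotations

import numpy as np
import pytest

import ligmech.joint_pipeline as jp
from ligmech.synthetic_knee import GaitProfile, generate_gait


@pytest.fixture(scope="session")
def gait25():
    return generate_gait(n_steps=25)


@pytest.fixture(scope="session")
def gentle_gait():
    """Reduced-amplitude stance loading keeping ligament strains small."""
    profile = GaitProfile(
        axial_bw_bumps=((1.1, 0.25, 0.17), (1.0, 0.75, 0.17)),
        flexion_bumps=((8.0, 0.15, 0.09), (10.0, 1.05, 0.18)),
        ie_moment_bumps=((1000.0, 0.3, 0.15), (-1200.0, 0.8, 0.12)),
        vv_moment_bumps=((3000.0, 0.25, 0.15), (2500.0, 0.75, 0.15)),
        ap_force_bumps=((60.0, 0.2, 0.12), (-70.0, 0.85, 0.12)),
    )
    return generate_gait(profile, n_steps=25)


@pytest.fixture(scope="session")
def stance_results(gait25):
    """Full stance traces for the five representations ('adjusted' reference block)."""
    out = {}
    for kind in ("spring", "linear", "neohookean", "poro", "frphe"):
        model = jp.build_surrogate_joint(kind, "adjusted")
        out[kind] = jp.run_stance(model, gait25)
    return out


@pytest.fixture(scope="session")
def second_peak_models(gait25):
    """FRPHE and hyperelastic joints marched to the second force peak.

    The committed ligament FE states are left at ~76% of stance, where
    flexion and the applied moments put the PCL into combined bending.
    """
    models = {}
    for kind in ("frphe", "neohookean"):
        model = jp.build_surrogate_joint(kind, "adjusted")
        jp.run_stance(model, gait25, t_max=0.78)
        models[kind] = model
    return models


@pytest.fixture(scope="session")
def ef_sweeps(gait25):
    """Fibril-modulus sweeps for ACL and LCL over the parametric range."""
    out = {}
    for lig in ("ACL", "LCL"):
        table, traces = jp.parameter_sweep("Ef", (10.0, 100.0, 250.0), gait25, ligament=lig)
        out[lig] = (table, traces)
    return out


@pytest.fixture(scope="session")
def em_sweep(gait25):
    """Nonfibrillar-modulus sweep (all ligaments) over the parametric range."""
    return jp.parameter_sweep("Em", (1.0, 50.0), gait25, ligament=None)


@pytest.fixture(scope="session")
def fluid_runs(gait25):
    """Fluid-property variation: reference plus the extreme corners.

    The least permeable (k0 = 0.15, M = 1, sealed) and most permeable
    (k0 = 15, M = 10, free-draining) corners bound the parametric range,
    so their deviation from the reference bounds the full sweep.
    """
    from ligmech.synthetic_knee import default_ligament_specs

    ref_model = jp.build_surrogate_joint("frphe", "adjusted")
    ref = jp.run_stance(ref_model, gait25)
    deviations = {}
    for k0, M, drain in ((0.15, 1.0, "sealed"), (15.0, 10.0, "free")):
        params_map = {
            name: jp.frphe_params_for(name, "adjusted", k0=k0, M=M)
            for name in default_ligament_specs()
        }
        model = jp.build_surrogate_joint(
            "frphe", "adjusted", params_map=params_map, drainage=drain
        )
        res = jp.run_stance(model, gait25)
        deviations[(k0, M, drain)] = 100.0 * float(
            np.max(np.abs(res.reaction_N - ref.reaction_N)) / np.max(np.abs(ref.reaction_N))
        )
    return deviations, ref
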