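"""Access to the shipped reference material-parameter tables.

``load_reference_parameters`` returns the raw per-ligament constants for
each constitutive model; ``build_material_params`` converts a ligament's
record into the typed parameter objects of :mod:`ligmech.constitutive`.
"""

from __future__ import annotations

import json
from importlib import resources
from typing import Any

from .constitutive import (
    BiphasicParams,
    FibrilParams,
    FRPHEParams,
    LinearElasticParams,
    NeoHookeanParams,
)

MODEL_KINDS = ("spring", "linear", "neohookean", "poro", "frphe")

_cache: dict[str, Any] = {}


def _load(name: str) -> dict:
    if name not in _cache:
        with resources.files("ligmech.data").joinpath(name).open() as fh:
            _cache[name] = json.load(fh)
    return _cache[name]


def load_reference_parameters() -> dict:
    """Per-ligament reference constants for the five constitutive models."""
    return _load("reference_materials.json")


def load_parameter_ranges() -> dict:
    """Ranges used in the FRPHE parametric analysis."""
    return _load("parametric_ranges.json")


def spring_reduction_percent(ligament: str = "PCL") -> float:
    """Percent reduction from the initial to the adjusted spring constant."""
    t = load_reference_parameters()["spring"]
    k_i, k_a = t["initial"][ligament], t["adjusted"][ligament]
    return 100.0 * (k_i - k_a) / k_i


def build_material_params(kind: str, ligament: str, block: str = "adjusted") -> Any:
    """Typed constitutive parameters for one ligament.

    ``block`` selects the 'initial' or 'adjusted' value set where the table
    distinguishes them (spring stiffness, FRPHE fibril modulus).
    """
    t = load_reference_parameters()
    if kind == "spring":
        return t["spring"][block][ligament]  # bare stiffness; geometry added by caller
    if kind == "linear":
        return LinearElasticParams(t["linear"]["E_MPa"][ligament], t["linear"]["nu"][ligament])
    if kind == "neohookean":
        b = t["neohookean"]
        return NeoHookeanParams.from_c1_d(b["C1_MPa"][ligament], b["D_per_MPa"][ligament])
    if kind == "poro":
        b = t["poro"]
        return (
            NeoHookeanParams.from_c1_d(b["C1_MPa"][ligament], b["D_per_MPa"][ligament]),
            BiphasicParams(b["k0_1e-15_m4_per_Ns"][ligament], b["M"][ligament]),
        )
    if kind == "frphe":
        b = t["frphe"]
        ef = b["Ef_MPa_initial" if block == "initial" else "Ef_MPa_adjusted"][ligament]
        return FRPHEParams.from_matrix_moduli(
            b["Em_MPa"][ligament],
            b["nu_m"][ligament],
            FibrilParams(ef, b["C"][ligament]),
            BiphasicParams(b["k0_1e-15_m4_per_Ns"][ligament], b["M"][ligament]),
        )
    raise ValueError(f"unknown model kind {kind!r}; expected one of {MODEL_KINDS}")
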