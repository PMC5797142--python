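"""Material-point constitutive laws for knee ligament tissue.

Five representations of increasing structural fidelity are implemented,
all evaluable at a single material point, independent of any mesh:

* discrete tension-only spring (``spring_force``),
* isotropic linear elasticity (``linear_elastic_stress``),
* compressible neo-Hookean hyperelasticity (``neo_hookean_stress``),
* biphasic (porohyperelastic) total stress with strain-dependent
  permeability (``biphasic_total_stress``, ``strain_dependent_permeability``),
* fibril-reinforced porohyperelastic (FRPHE) tissue, where the solid
  skeleton splits into a tension-only collagen fibril network and an
  isotropic nonfibrillar ground matrix (``frphe_total_stress``).

Sign conventions: tension positive, Cauchy stress in MPa, lengths in mm,
forces in N.  Pore pressure ``p`` enters the total stress as ``sigma_eff
- p*I``.  Permeability is carried in units of 1e-15 m^4/(N s) and converted
only at solver entry (see :mod:`ligmech.poro_fem`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

I3 = np.eye(3)

__all__ = [
    "ConstitutiveError",
    "InvertedElementError",
    "PoreCollapseError",
    "SpringParams",
    "LinearElasticParams",
    "NeoHookeanParams",
    "BiphasicParams",
    "FibrilParams",
    "FRPHEParams",
    "DeformationState",
    "StressDecomposition",
    "spring_force",
    "linear_elastic_stress",
    "neo_hookean_stress",
    "strain_dependent_permeability",
    "biphasic_total_stress",
    "fibril_stress",
    "fiber_strain",
    "fibril_network_stress",
    "frphe_total_stress",
    "default_secondary_directions",
    "effective_tensile_modulus",
]


class ConstitutiveError(ValueError):
    """Invalid parameter or deformation input to a material law."""


class InvertedElementError(ConstitutiveError):
    """Deformation gradient with non-positive determinant."""


class PoreCollapseError(ConstitutiveError):
    """Volumetric state in which the solid fraction would exceed unity."""


# ---------------------------------------------------------------------------
# parameter records
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpringParams:
    """Tension-only line spring: stiffness k_s [N/mm], slack geometry.

    ``pre_strain`` is the tensile strain imposed at the reference pose, so
    the force-free (slack) length is ``rest_length / (1 + pre_strain)``.
    """

    k_s: float
    rest_length: float
    pre_strain: float = 0.0

    def __post_init__(self) -> None:
        if self.k_s < 0:
            raise ConstitutiveError(f"spring constant must be >= 0, got {self.k_s}")
        if self.rest_length <= 0:
            raise ConstitutiveError("rest_length must be positive")

    @property
    def slack_length(self) -> float:
        return self.rest_length / (1.0 + self.pre_strain)


@dataclass(frozen=True)
class LinearElasticParams:
    """Isotropic Hookean solid: Young's modulus E [MPa], Poisson ratio nu."""

    E: float
    nu: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ConstitutiveError(f"Young's modulus must be positive, got {self.E}")
        if not (-1.0 < self.nu < 0.5):
            raise ConstitutiveError(f"Poisson ratio must lie in (-1, 0.5), got {self.nu}")

    def lame(self) -> tuple[float, float]:
        """Return Lame parameters (lambda, mu) in MPa."""
        lam = self.E * self.nu / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        mu = self.E / (2.0 * (1.0 + self.nu))
        return lam, mu


@dataclass(frozen=True)
class NeoHookeanParams:
    """Compressible neo-Hookean solid.

    Constructed from exactly one of the pairs ``(C1, D)`` (the Abaqus
    convention of material coefficient / compressibility coefficient) or
    ``(K_m, G_m)`` (bulk / shear modulus); the other pair is derived via
    ``G_m = 2 C1`` and ``K_m = 2 / D``.
    """

    K_m: float
    G_m: float
    C1: float
    D: float

    @classmethod
    def from_c1_d(cls, C1: float, D: float) -> "NeoHookeanParams":
        if C1 <= 0 or D <= 0:
            raise ConstitutiveError("C1 and D must be positive")
        return cls(K_m=2.0 / D, G_m=2.0 * C1, C1=C1, D=D)

    @classmethod
    def from_bulk_shear(cls, K_m: float, G_m: float) -> "NeoHookeanParams":
        if K_m <= 0 or G_m <= 0:
            raise ConstitutiveError("K_m and G_m must be positive")
        return cls(K_m=K_m, G_m=G_m, C1=G_m / 2.0, D=2.0 / K_m)

    @classmethod
    def from_young_poisson(cls, E: float, nu: float) -> "NeoHookeanParams":
        """Standard isotropic conversion K = E/3(1-2nu), G = E/2(1+nu)."""
        lep = LinearElasticParams(E, nu)
        K = lep.E / (3.0 * (1.0 - 2.0 * lep.nu))
        G = lep.E / (2.0 * (1.0 + lep.nu))
        return cls.from_bulk_shear(K, G)

    def __post_init__(self) -> None:
        if self.K_m <= 0 or self.G_m <= 0:
            raise ConstitutiveError("bulk and shear moduli must be positive")
        if not (np.isclose(self.G_m, 2.0 * self.C1) and np.isclose(self.K_m, 2.0 / self.D)):
            raise ConstitutiveError(
                "inconsistent neo-Hookean constants; use one of the classmethod "
                "constructors (from_c1_d / from_bulk_shear / from_young_poisson)"
            )


@dataclass(frozen=True)
class BiphasicParams:
    """Fluid-phase constants of a biphasic mixture.

    k0 : initial permeability, 1e-15 m^4/(N s)
    M_exp : dimensionless exponent of the strain-dependent permeability law
    phi0 : initial solid volume fraction
    """

    k0: float
    M_exp: float
    phi0: float = 0.3

    def __post_init__(self) -> None:
        if self.k0 <= 0:
            raise ConstitutiveError("initial permeability must be positive")
        if not (0.0 < self.phi0 < 1.0):
            raise ConstitutiveError("solid volume fraction must lie in (0, 1)")
        if self.M_exp < 0:
            raise ConstitutiveError("permeability exponent must be >= 0")


@dataclass(frozen=True)
class FibrilParams:
    """Collagen fibril network constants.

    Ef : fibril network modulus, MPa
    C_ratio : density ratio between primary and secondary fibrils (>= 1)
    rho_z : relative collagen density (default 1, absorbed into Ef)
    """

    Ef: float
    C_ratio: float = 1.0
    rho_z: float = 1.0

    def __post_init__(self) -> None:
        if self.Ef < 0:
            raise ConstitutiveError("fibril network modulus must be >= 0")
        if self.C_ratio < 1.0:
            raise ConstitutiveError("primary/secondary density ratio must be >= 1")
        if self.rho_z <= 0:
            raise ConstitutiveError("relative collagen density must be positive")


@dataclass(frozen=True)
class FRPHEParams:
    """Composite fibril-reinforced porohyperelastic material record."""

    nonfibrillar: NeoHookeanParams
    fibril: FibrilParams
    fluid: BiphasicParams

    @classmethod
    def from_matrix_moduli(
        cls,
        E_m: float,
        nu_m: float,
        fibril: FibrilParams,
        fluid: BiphasicParams,
    ) -> "FRPHEParams":
        return cls(NeoHookeanParams.from_young_poisson(E_m, nu_m), fibril, fluid)


# ---------------------------------------------------------------------------
# kinematic state
# ---------------------------------------------------------------------------


@dataclass
class DeformationState:
    """Deformation gradient F plus derived strain measures at a point.

    ``J = det F`` and the infinitesimal strain ``eps = sym(F) - I`` are
    computed on construction.  ``fiber_dir`` is the reference direction of
    the primary fibrils (unit vector).
    """

    F: np.ndarray
    fiber_dir: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        self.F = np.asarray(self.F, dtype=float)
        if self.F.shape != (3, 3):
            raise ConstitutiveError("F must be 3x3")
        self.fiber_dir = np.asarray(self.fiber_dir, dtype=float)
        n = np.linalg.norm(self.fiber_dir)
        if not np.isclose(n, 1.0, atol=1e-8):
            if n == 0:
                raise ConstitutiveError("fiber direction must be nonzero")
            self.fiber_dir = self.fiber_dir / n
        if self.J <= 0:
            raise InvertedElementError(f"det F = {self.J} <= 0")

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def eps(self) -> np.ndarray:
        """Infinitesimal strain tensor sym(F) - I (symmetric by construction)."""
        return 0.5 * (self.F + self.F.T) - I3

    @classmethod
    def identity(cls, fiber_dir=(0.0, 0.0, 1.0)) -> "DeformationState":
        return cls(I3.copy(), np.asarray(fiber_dir, dtype=float))

    @classmethod
    def uniaxial_stretch(
        cls,
        stretch: float,
        axis: int = 2,
        lateral: float | None = None,
        fiber_dir=None,
    ) -> "DeformationState":
        """Diagonal F with ``stretch`` along ``axis``.

        ``lateral`` defaults to 1 (constrained lateral faces); pass e.g.
        ``stretch**-0.5`` for an isochoric stretch.
        """
        lat = 1.0 if lateral is None else lateral
        diag = [lat, lat, lat]
        diag[axis] = stretch
        if fiber_dir is None:
            fiber_dir = np.zeros(3)
            fiber_dir[axis] = 1.0
        return cls(np.diag(diag), fiber_dir)


@dataclass
class StressDecomposition:
    """Total stress and its constituent parts (all Cauchy, MPa).

    Closure invariants: ``total = effective - pressure*I`` and, for FRPHE
    materials, ``effective = fibril + nonfibrillar``.
    """

    total: np.ndarray
    effective: np.ndarray
    fibril: np.ndarray
    nonfibrillar: np.ndarray
    pressure: float

    def __post_init__(self) -> None:
        for name in ("total", "effective", "fibril", "nonfibrillar"):
            t = np.asarray(getattr(self, name), dtype=float)
            if t.shape != (3, 3):
                raise ConstitutiveError(f"{name} stress must be 3x3")
            setattr(self, name, t)

    def closure_residuals(self) -> tuple[float, float]:
        """Relative residuals of the two decomposition identities."""
        r1 = np.linalg.norm(self.total - (self.effective - self.pressure * I3))
        r1 /= max(np.linalg.norm(self.total), 1e-300)
        r2 = np.linalg.norm(self.effective - (self.fibril + self.nonfibrillar))
        r2 /= max(np.linalg.norm(self.effective), 1e-300)
        return float(r1), float(r2)


# ---------------------------------------------------------------------------
# laws
# ---------------------------------------------------------------------------


def spring_force(params: SpringParams, current_length: float) -> float:
    """Tension-only spring force [N] at the given end-to-end length [mm].

    The spring carries load only when elongated past its slack length
    (``rest_length/(1+pre_strain)``); in compression it buckles and the
    force is identically zero.
    """
    if current_length <= 0:
        raise ConstitutiveError(f"current_length must be positive, got {current_length}")
    e = current_length - params.slack_length
    return params.k_s * e if e > 0 else 0.0


def linear_elastic_stress(params: LinearElasticParams, state: DeformationState) -> StressDecomposition:
    """Isotropic Hooke's law sigma = lambda tr(eps) I + 2 mu eps."""
    lam, mu = params.lame()
    eps = state.eps
    sig = lam * np.trace(eps) * I3 + 2.0 * mu * eps
    return StressDecomposition(
        total=sig, effective=sig, fibril=np.zeros((3, 3)), nonfibrillar=sig, pressure=0.0
    )


def neo_hookean_stress(params: NeoHookeanParams, state: DeformationState) -> StressDecomposition:
    """Compressible neo-Hookean Cauchy stress.

    sigma = K_m ln(J)/J I + (G_m/J) (F F^T - J^{2/3} I)
    """
    J = state.J
    if J <= 0:
        raise InvertedElementError(f"det F = {J} <= 0")
    F = state.F
    b = F @ F.T
    sig = params.K_m * np.log(J) / J * I3 + params.G_m / J * (b - J ** (2.0 / 3.0) * I3)
    return StressDecomposition(
        total=sig, effective=sig, fibril=np.zeros((3, 3)), nonfibrillar=sig, pressure=0.0
    )


def strain_dependent_permeability(params: BiphasicParams, J: float) -> float:
    """Permeability k(J) in 1e-15 m^4/(N s).

    k = k0 [phi0 phi_f / ((1-phi0) phi_s)]^2 exp(M (J^2-1)/2) with current
    volume fractions phi_s = phi0/J, phi_f = 1 - phi0/J.  Strictly
    increasing in J for M >= 0; equals k0 at J = 1.
    """
    if J <= params.phi0:
        raise PoreCollapseError(
            f"J = {J} <= phi0 = {params.phi0}: solid would exceed total volume"
        )
    phi_s = params.phi0 / J
    phi_f = 1.0 - phi_s
    bracket = params.phi0 * phi_f / ((1.0 - params.phi0) * phi_s)
    return params.k0 * bracket**2 * np.exp(params.M_exp * (J**2 - 1.0) / 2.0)


def biphasic_total_stress(effective: np.ndarray, p: float) -> StressDecomposition:
    """Total mixture stress sigma_tot = sigma_eff - p I."""
    effective = np.asarray(effective, dtype=float)
    if not np.allclose(effective, effective.T, atol=1e-9 * max(1.0, np.abs(effective).max())):
        raise ConstitutiveError("effective stress must be symmetric")
    total = effective - p * I3
    return StressDecomposition(
        total=total,
        effective=effective,
        fibril=np.zeros((3, 3)),
        nonfibrillar=effective,
        pressure=float(p),
    )


def fibril_stress(params: FibrilParams, eps_f: float) -> float:
    """Tension-only uniaxial fibril stress: Ef*eps_f for eps_f > 0, else 0."""
    return params.Ef * eps_f if eps_f > 0 else 0.0


def fiber_strain(F: np.ndarray, d: np.ndarray, measure: str = "log") -> float:
    """Fibril strain along reference direction ``d`` under gradient ``F``.

    The default measure is the logarithmic strain of the direction stretch,
    ``ln |F d|``, consistent with the finite-strain matrix law; ``"green"``
    selects the Green-Lagrange strain ``(|F d|^2 - 1)/2``.
    """
    lam = float(np.linalg.norm(F @ d))
    if measure == "log":
        return float(np.log(lam))
    if measure == "green":
        return 0.5 * (lam**2 - 1.0)
    raise ConstitutiveError(f"unknown fibril strain measure {measure!r}")


def default_secondary_directions(n_extra: int = 10) -> np.ndarray:
    """Reference directions of the secondary (randomly oriented) fibrils.

    Three axis-aligned directions plus ``n_extra`` quasi-uniform directions
    on the upper half-sphere (Fibonacci lattice).  Deterministic.
    """
    dirs = [np.eye(3)[i] for i in range(3)]
    golden = (1.0 + np.sqrt(5.0)) / 2.0
    for i in range(n_extra):
        z = (i + 0.5) / n_extra  # upper half sphere only
        r = np.sqrt(max(0.0, 1.0 - z * z))
        phi = 2.0 * np.pi * i / golden
        dirs.append(np.array([r * np.cos(phi), r * np.sin(phi), z]))
    return np.array(dirs)


def _fibril_weights(params: FibrilParams, n_secondary: int, normalization: str) -> tuple[float, float]:
    """Per-direction stress weights (primary, secondary).

    ``"density"`` (default) distributes the total fibril density over the
    direction set, weight rho_z*C/(C + n_s) for the single primary and
    rho_z/(C + n_s) per secondary, so the primary:secondary stress ratio is
    exactly C while the direction-sum stays bounded as directions are added.
    ``"raw"`` applies rho_z*C and rho_z with no normalization.
    """
    if normalization == "density":
        denom = params.C_ratio + n_secondary
        return params.rho_z * params.C_ratio / denom, params.rho_z / denom
    if normalization == "raw":
        return params.rho_z * params.C_ratio, params.rho_z
    raise ConstitutiveError(f"unknown normalization {normalization!r}")


def fibril_network_stress(
    params: FibrilParams,
    state: DeformationState,
    secondary_dirs: np.ndarray | None = None,
    measure: str = "log",
    normalization: str = "density",
) -> np.ndarray:
    """Cauchy stress tensor of the tension-only collagen fibril network.

    Each direction carries a uniaxial tension-only stress (primary along
    ``state.fiber_dir``, weighted by the density ratio C relative to each
    secondary direction); the tensor is assembled as the weighted sum of
    ``sigma * n (x) n`` over the *current* (pushed-forward) directions, and
    is therefore symmetric positive-semidefinite in tension-only states.
    """
    if secondary_dirs is None:
        secondary_dirs = default_secondary_directions()
    secondary_dirs = np.atleast_2d(np.asarray(secondary_dirs, dtype=float))
    if secondary_dirs.shape[0] == 0:
        raise ConstitutiveError("secondary direction set must be nonempty")
    norms = np.linalg.norm(secondary_dirs, axis=1)
    if np.any(norms < 1e-12):
        raise ConstitutiveError("zero-length secondary direction")
    secondary_dirs = secondary_dirs / norms[:, None]

    w_p, w_s = _fibril_weights(params, secondary_dirs.shape[0], normalization)
    F = state.F
    sig = np.zeros((3, 3))
    for d, w in [(state.fiber_dir, w_p)] + [(d, w_s) for d in secondary_dirs]:
        eps_f = fiber_strain(F, d, measure)
        s = fibril_stress(params, eps_f)
        if s > 0:
            v = F @ d
            n = v / np.linalg.norm(v)
            sig += w * s * np.outer(n, n)
    return sig


def frphe_total_stress(
    params: FRPHEParams,
    state: DeformationState,
    p: float = 0.0,
    secondary_dirs: np.ndarray | None = None,
    measure: str = "log",
    normalization: str = "density",
) -> StressDecomposition:
    """Fibril-reinforced porohyperelastic total stress.

    sigma_tot = sigma_f + sigma_nf - p I, with the nonfibrillar part given
    by the neo-Hookean ground matrix and the fibrillar part by the
    tension-only fibril network.
    """
    nf = neo_hookean_stress(params.nonfibrillar, state).total
    fib = fibril_network_stress(params.fibril, state, secondary_dirs, measure, normalization)
    eff = fib + nf
    return StressDecomposition(
        total=eff - p * I3, effective=eff, fibril=fib, nonfibrillar=nf, pressure=float(p)
    )


# ---------------------------------------------------------------------------
# derived quantities
# ---------------------------------------------------------------------------


def effective_tensile_modulus(
    params: FRPHEParams,
    strain: float = 0.01,
    secondary_dirs: np.ndarray | None = None,
    normalization: str = "density",
) -> float:
    """Small-strain tangent modulus [MPa] of the FRPHE solid in fiber-axis tension.

    Solves numerically for the transverse stretch that annuls the mean
    lateral stress under a drained uniaxial-stress state along the fiber
    axis (z), then returns sigma_zz / strain.  The secondary direction set
    is in general not transversely isotropic, so the single transverse
    stretch zeroes the lateral stresses only on average; the residual
    anisotropy is far below the quoted tolerance of its consumers.
    """
    from scipy.optimize import brentq

    lam_ax = 1.0 + strain

    def lateral_stress(lam_t: float) -> float:
        st = DeformationState(np.diag([lam_t, lam_t, lam_ax]), np.array([0.0, 0.0, 1.0]))
        sig = frphe_total_stress(params, st, 0.0, secondary_dirs, normalization=normalization).total
        return 0.5 * (sig[0, 0] + sig[1, 1])

    lam_t = brentq(lateral_stress, 0.5, 1.5, xtol=1e-12)
    st = DeformationState(np.diag([lam_t, lam_t, lam_ax]), np.array([0.0, 0.0, 1.0]))
    sig = frphe_total_stress(params, st, 0.0, secondary_dirs, normalization=normalization).total
    return float(sig[2, 2] / strain)
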