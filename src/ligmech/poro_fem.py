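"""Quasi-static displacement / pore-pressure (u-p) finite elements on linear tetrahedra.

A deliberately small solver, sized for single-ligament meshes (hundreds to
a few thousand elements), exercising the biphasic and fibril-reinforced
porohyperelastic laws of :mod:`ligmech.constitutive`:

* total-Lagrangian kinematics with a constant deformation gradient per
  linear tetrahedron (the pore-pressure tet element family);
* equal-order linear interpolation for displacement and pore pressure,
  with a small Brezzi-Pitkaranta-type pressure-gradient stabilization for
  the nearly undrained limit;
* backward-Euler integration of the fluid continuity equation
  ``dJ/dt + Div(q) = 0`` with Darcy flux ``q = -k(J) grad p`` and the
  strain-dependent permeability law;
* Newton iteration with a finite-difference element tangent and adaptive
  step halving.

Units: mm, N, MPa, s. Permeability values are carried in 1e-15 m^4/(N s)
and converted once here (``PERMEABILITY_UNIT``: 1e-15 m^4/(N s) =
1e-3 mm^4/(N s)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .constitutive import (
    BiphasicParams,
    ConstitutiveError,
    FRPHEParams,
    InvertedElementError,
    LinearElasticParams,
    NeoHookeanParams,
    PoreCollapseError,
    default_secondary_directions,
)

#: 1e-15 m^4/(N s) expressed in mm^4/(N s)
PERMEABILITY_UNIT = 1.0e-3

__all__ = [
    "PERMEABILITY_UNIT",
    "PoroMesh",
    "BoundarySpec",
    "SolverConfig",
    "FEState",
    "SolveResult",
    "FEMaterial",
    "FELinearElastic",
    "FENeoHookean",
    "FEFRPHE",
    "make_fe_material",
    "PoroFE",
    "solve_quasi_static",
    "box_mesh",
    "single_tet_mesh",
    "terzaghi_pressure",
    "run_confined_compression",
    "run_uniaxial_tension",
]


# ---------------------------------------------------------------------------
# mesh
# ---------------------------------------------------------------------------


@dataclass
class PoroMesh:
    """Tetrahedral mesh with per-element fiber directions.

    nodes : (N, 3) coordinates [mm]
    tets : (E, 4) connectivity, positively oriented
    fiber : (E, 3) unit primary-fibril direction per element
    material_id : (E,) integer tag
    node_sets : named node-id arrays (e.g. end faces of a ligament)
    """

    nodes: np.ndarray
    tets: np.ndarray
    fiber: np.ndarray | None = None
    material_id: np.ndarray | None = None
    node_sets: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.tets = np.asarray(self.tets, dtype=int)
        if self.fiber is None:
            self.fiber = np.tile([0.0, 0.0, 1.0], (len(self.tets), 1))
        self.fiber = np.asarray(self.fiber, dtype=float)
        if self.material_id is None:
            self.material_id = np.zeros(len(self.tets), dtype=int)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_elements(self) -> int:
        return len(self.tets)

    def volumes(self) -> np.ndarray:
        """Signed tet volumes [mm^3]; positive for a valid orientation."""
        x = self.nodes[self.tets]
        d = x[:, 1:] - x[:, :1]
        return np.linalg.det(d) / 6.0

    def validate(self) -> None:
        if self.tets.min() < 0 or self.tets.max() >= self.n_nodes:
            raise ValueError("tet connectivity references nodes out of range")
        v = self.volumes()
        if np.any(v <= 0):
            raise ValueError(f"{np.sum(v <= 0)} tets have non-positive volume")
        norms = np.linalg.norm(self.fiber, axis=1)
        if not np.allclose(norms, 1.0, atol=1e-8):
            raise ValueError("fiber directions must be unit vectors")

    def fix_orientation(self) -> None:
        """Swap two nodes of negatively oriented tets."""
        v = self.volumes()
        bad = v < 0
        self.tets[bad] = self.tets[bad][:, [0, 1, 3, 2]]

    def boundary_faces(self) -> np.ndarray:
        """(F, 3) exterior faces (each appears in exactly one tet), outward oriented."""
        t = self.tets
        # outward faces of a positively oriented tet (0,1,2,3)
        faces = np.concatenate(
            [t[:, [1, 2, 3]], t[:, [0, 3, 2]], t[:, [0, 1, 3]], t[:, [0, 2, 1]]]
        )
        key = np.sort(faces, axis=1)
        _, inv, counts = np.unique(key, axis=0, return_inverse=True, return_counts=True)
        return faces[counts[inv] == 1]


# ---------------------------------------------------------------------------
# FE materials (batched over elements)
# ---------------------------------------------------------------------------


class FEMaterial:
    """Batched effective-stress law; subclasses set ``fluid`` for biphasic tissue."""

    fluid: BiphasicParams | None = None

    def cauchy(self, F: np.ndarray, fiber: np.ndarray) -> np.ndarray:  # (E,3,3)
        raise NotImplementedError

    def stiffness_scale(self) -> float:
        """Aggregate-modulus-like scale [MPa] used for pressure stabilization."""
        raise NotImplementedError


def _det33(F: np.ndarray) -> np.ndarray:
    return np.linalg.det(F)


class FELinearElastic(FEMaterial):
    """Corotational isotropic Hooke law.

    Hooke's law is applied to the rotation-free Biot strain U - I from the
    polar decomposition F = R U and the stress is rotated back, so rigid
    rotations of a ligament produce no spurious strain (the behavior of a
    linear material inside a geometrically nonlinear solve); at small
    strain this coincides with plain Hooke on eps = sym(F) - I.
    """

    def __init__(self, params: LinearElasticParams, fluid: BiphasicParams | None = None):
        self.params = params
        self.lam, self.mu = params.lame()
        self.fluid = fluid

    def cauchy(self, F, fiber):
        W, S, Vt = np.linalg.svd(F)
        # proper rotation: absorb any reflection into the smallest singular value
        det = np.linalg.det(np.einsum("eij,ejk->eik", W, Vt))
        W = W.copy()
        W[det < 0, :, 2] *= -1.0
        S = S.copy()
        S[det < 0, 2] *= -1.0
        R = np.einsum("eij,ejk->eik", W, Vt)
        U = np.einsum("eji,ej,ejk->eik", Vt, S, Vt)  # V diag(S) V^T
        eps = U - np.eye(3)
        tr = np.trace(eps, axis1=1, axis2=2)
        sig = self.lam * tr[:, None, None] * np.eye(3) + 2.0 * self.mu * eps
        return np.einsum("eij,ejk,elk->eil", R, sig, R)

    def stiffness_scale(self):
        return self.lam + 2.0 * self.mu


class FENeoHookean(FEMaterial):
    """Compressible neo-Hookean effective stress (batched)."""

    def __init__(self, params: NeoHookeanParams, fluid: BiphasicParams | None = None):
        self.params = params
        self.fluid = fluid

    def cauchy(self, F, fiber):
        J = _det33(F)
        if np.any(J <= 0):
            raise InvertedElementError(f"inverted element(s): {np.nonzero(J <= 0)[0][:5]}")
        b = np.einsum("eik,ejk->eij", F, F)
        K, G = self.params.K_m, self.params.G_m
        return (
            K * (np.log(J) / J)[:, None, None] * np.eye(3)
            + (G / J)[:, None, None] * (b - (J ** (2.0 / 3.0))[:, None, None] * np.eye(3))
        )

    def stiffness_scale(self):
        return self.params.K_m + 4.0 * self.params.G_m / 3.0


class FEFRPHE(FEMaterial):
    """Fibril-reinforced porohyperelastic effective stress (batched).

    Nonfibrillar neo-Hookean matrix plus a tension-only fibril network with
    one primary direction per element and a shared reference set of
    secondary directions; density-weighted direction sum (the primary to
    secondary stress ratio is the density ratio C).
    """

    def __init__(
        self,
        params: FRPHEParams,
        secondary_dirs: np.ndarray | None = None,
        normalization: str = "density",
    ):
        self.params = params
        self.matrix = FENeoHookean(params.nonfibrillar)
        self.fluid = params.fluid
        dirs = default_secondary_directions() if secondary_dirs is None else np.asarray(secondary_dirs, float)
        self.secondary = dirs / np.linalg.norm(dirs, axis=1)[:, None]
        fib = params.fibril
        if normalization == "density":
            denom = fib.C_ratio + len(self.secondary)
            self.w_p = fib.rho_z * fib.C_ratio / denom
            self.w_s = fib.rho_z / denom
        elif normalization == "raw":
            self.w_p = fib.rho_z * fib.C_ratio
            self.w_s = fib.rho_z
        else:
            raise ConstitutiveError(f"unknown normalization {normalization!r}")

    def fibril_cauchy(self, F: np.ndarray, fiber: np.ndarray) -> np.ndarray:
        Ef = self.params.fibril.Ef
        sig = np.zeros_like(F)
        # primary
        v = np.einsum("eij,ej->ei", F, fiber)
        lam = np.linalg.norm(v, axis=1)
        eps = np.log(lam)
        s = Ef * np.where(eps > 0, eps, 0.0)
        n = v / lam[:, None]
        sig += self.w_p * s[:, None, None] * np.einsum("ei,ej->eij", n, n)
        # secondary
        V = np.einsum("eij,sj->esi", F, self.secondary)
        L = np.linalg.norm(V, axis=2)
        epsS = np.log(L)
        sS = Ef * np.where(epsS > 0, epsS, 0.0)
        N = V / L[..., None]
        sig += self.w_s * np.einsum("es,esi,esj->eij", sS, N, N)
        return sig

    def cauchy(self, F, fiber):
        return self.matrix.cauchy(F, fiber) + self.fibril_cauchy(F, fiber)

    def stiffness_scale(self):
        return self.matrix.stiffness_scale()


def drained_copy(material: FEMaterial) -> FEMaterial:
    """Shallow copy of a material with the fluid phase removed."""
    import copy

    m = copy.copy(material)
    m.fluid = None
    return m


def make_fe_material(kind: str, params, drained: bool = False) -> FEMaterial:
    """FE material from typed constitutive parameters.

    kind: 'linear' (LinearElasticParams), 'neohookean' (NeoHookeanParams),
    'poro' ((NeoHookeanParams, BiphasicParams)), 'frphe' (FRPHEParams).
    ``drained=True`` drops the fluid phase (pure solid solve).
    """
    if kind == "linear":
        return FELinearElastic(params)
    if kind == "neohookean":
        return FENeoHookean(params)
    if kind == "poro":
        nh, fluid = params
        return FENeoHookean(nh, fluid=None if drained else fluid)
    if kind == "frphe":
        mat = FEFRPHE(params)
        if drained:
            mat.fluid = None
        return mat
    raise ValueError(f"unknown FE material kind {kind!r}")


def _permeability_batch(params: BiphasicParams, J: np.ndarray) -> np.ndarray:
    """Strain-dependent permeability (vectorized), in 1e-15 m^4/(N s)."""
    if np.any(J <= params.phi0):
        raise PoreCollapseError("pore collapse: J <= phi0 in some element")
    phi_s = params.phi0 / J
    phi_f = 1.0 - phi_s
    bracket = params.phi0 * phi_f / ((1.0 - params.phi0) * phi_s)
    # clamp the exponent: wild trial iterates must not overflow before the
    # Newton safeguard rejects them
    expo = np.minimum(params.M_exp * (J**2 - 1.0) / 2.0, 60.0)
    return params.k0 * bracket**2 * np.exp(expo)


# ---------------------------------------------------------------------------
# boundary conditions, solver configuration and state
# ---------------------------------------------------------------------------


@dataclass
class BoundarySpec:
    """Dirichlet / traction / drainage data for a quasi-static solve.

    fixed_disp : list of (node, component, value) where value is a float or
        a callable of time returning mm.
    traction : list of (face node-triple, vector) with vector a (3,) array
        [MPa] or a callable of time; applied on the reference area.
    free_drain_nodes : node ids where p = 0 (free draining); all other
        exterior surface is sealed (natural, no-flux).
    point_forces : list of (node, (3,) force [N] or callable of time).
    """

    fixed_disp: list = field(default_factory=list)
    traction: list = field(default_factory=list)
    free_drain_nodes: Sequence[int] = field(default_factory=list)
    point_forces: list = field(default_factory=list)

    @staticmethod
    def _value(v, t):
        return v(t) if callable(v) else v

    def prescribed_u(self, t: float) -> dict[tuple[int, int], float]:
        return {(n, c): float(self._value(v, t)) for n, c, v in self.fixed_disp}

    def external_force(self, mesh: PoroMesh, t: float) -> np.ndarray:
        f = np.zeros((mesh.n_nodes, 3))
        for face, vec in self.traction:
            a, b, c = face
            xa, xb, xc = mesh.nodes[a], mesh.nodes[b], mesh.nodes[c]
            area = 0.5 * np.linalg.norm(np.cross(xb - xa, xc - xa))
            load = np.asarray(self._value(vec, t), dtype=float) * area / 3.0
            for n in face:
                f[n] += load
        for n, vec in self.point_forces:
            f[n] += np.asarray(self._value(vec, t), dtype=float)
        return f


@dataclass
class SolverConfig:
    """Newton and stabilization settings (defaults cover all shipped analyses)."""

    newton_tol: float = 1.0e-8
    newton_abs_tol: float = 1.0e-9
    max_iterations: int = 25
    max_halvings: int = 5
    stab_coeff: float = 0.02
    fd_step: float = 1.0e-7


@dataclass
class FEState:
    """Committed solution at one time: displacement, pressure, time."""

    u: np.ndarray
    p: np.ndarray
    t: float

    def copy(self) -> "FEState":
        return FEState(self.u.copy(), self.p.copy(), self.t)


@dataclass
class SolveResult:
    """Histories of a quasi-static solve."""

    times: np.ndarray
    displacement: np.ndarray  # (T, N, 3)
    pressure: np.ndarray  # (T, N)
    reaction: np.ndarray  # (T, 3) resultant on the constrained set
    converged: np.ndarray  # (T,) bool


# ---------------------------------------------------------------------------
# solver
# ---------------------------------------------------------------------------


class PoroFE:
    """Assembler/solver bound to one mesh and one material.

    The object holds no solution state; callers pass :class:`FEState`
    objects in and out, which makes speculative (perturbation) solves from
    a committed state cheap and side-effect free.
    """

    def __init__(self, mesh: PoroMesh, material: FEMaterial, config: SolverConfig | None = None):
        mesh.validate()
        self.mesh = mesh
        self.material = material
        self.config = config or SolverConfig()
        self.has_fluid = material.fluid is not None

        x = mesh.nodes[mesh.tets]  # (E,4,3)
        d = np.swapaxes(x[:, 1:] - x[:, :1], 1, 2)  # (E,3,3) columns = edge vectors
        self.V = np.linalg.det(d) / 6.0
        dinv = np.linalg.inv(d)  # rows: gradients of N1..N3 in edge basis
        grads = np.empty((mesh.n_elements, 4, 3))
        grads[:, 1:, :] = dinv
        grads[:, 0, :] = -dinv.sum(axis=1)
        self.B = grads  # B[e,a,:] = grad N_a

        self.n_u = 3 * mesh.n_nodes
        self.n_dof = self.n_u + (mesh.n_nodes if self.has_fluid else 0)
        self.ndof_e = 16 if self.has_fluid else 12

        # element dof maps and sparse scatter pattern
        t = mesh.tets
        udofs = (3 * t[:, :, None] + np.arange(3)[None, None, :]).reshape(len(t), 12)
        if self.has_fluid:
            self.edofs = np.concatenate([udofs, self.n_u + t], axis=1)
        else:
            self.edofs = udofs
        self._rows = np.repeat(self.edofs, self.ndof_e, axis=1).ravel()
        self._cols = np.tile(self.edofs, (1, self.ndof_e)).ravel()

        # stabilization coefficient tau_e = c * h_e^2 / H_A  [mm^2/MPa]
        h2 = (6.0 * self.V) ** (2.0 / 3.0)
        self.tau = self.config.stab_coeff * h2 / material.stiffness_scale() if self.has_fluid else None

        # tangent factorization cache: reused across speculative solves from
        # the same committed state (rebuilt whenever convergence stalls)
        self._lu_cache = None
        self._lu_key = None

    # -- element-level residual, batched ------------------------------------

    def _element_residual(self, ue, pe, Jn, pe_n, dt, V=None, B=None, fiber=None, tau=None):
        """Residuals (E, ndof_e) for element dof values ue (E,4,3), pe (E,4).

        The optional geometry arrays let the tangent evaluate all
        perturbed element copies in a single batched call.
        """
        V = self.V if V is None else V
        B = self.B if B is None else B
        fiber = self.mesh.fiber if fiber is None else fiber
        tau = self.tau if tau is None else tau
        F = np.eye(3) + np.einsum("eai,eaj->eij", ue, B)
        J = _det33(F)
        if np.any(J <= 0):
            raise InvertedElementError(f"inverted element(s): {np.nonzero(J <= 0)[0][:5]}")
        sig = self.material.cauchy(F, fiber)
        if self.has_fluid:
            pbar = pe.mean(axis=1)
            sig = sig - pbar[:, None, None] * np.eye(3)
        Finv = np.linalg.inv(F)
        P = J[:, None, None] * np.einsum("eik,ejk->eij", sig, Finv)
        ru = np.einsum("e,eij,eaj->eai", V, P, B).reshape(len(V), 12)
        if not self.has_fluid:
            return ru
        g = np.einsum("ea,eai->ei", pe, B)
        k = _permeability_batch(self.material.fluid, J) * PERMEABILITY_UNIT
        Kt = (k * J)[:, None, None] * np.einsum("eij,ekj->eik", Finv, Finv)
        q = np.einsum("eik,ek->ei", Kt, g)
        if tau is not None and dt > 0:
            g_n = np.einsum("ea,eai->ei", pe_n, B)
            q = q + tau[:, None] * (g - g_n) / dt
        rp = V[:, None] * (
            0.25 * ((J - Jn) / dt)[:, None] + np.einsum("eai,ei->ea", B, q)
        )
        return np.concatenate([ru, rp], axis=1)

    def _gather(self, x):
        t = self.mesh.tets
        u = x[: self.n_u].reshape(-1, 3)
        ue = u[t]
        pe = x[self.n_u :][t] if self.has_fluid else None
        return ue, pe

    def residual(self, x: np.ndarray, state_n: FEState, dt: float) -> np.ndarray:
        """Global residual (internal minus external terms are added by callers)."""
        ue, pe = self._gather(x)
        if self.has_fluid:
            Fn = np.eye(3) + np.einsum("eai,eaj->eij", state_n.u[self.mesh.tets], self.B)
            Jn = _det33(Fn)
            pe_n = state_n.p[self.mesh.tets]
        else:
            Jn, pe_n = None, None
        re = self._element_residual(ue, pe, Jn, pe_n, dt)
        R = np.zeros(self.n_dof)
        np.add.at(R, self.edofs.ravel(), re.ravel())
        return R

    def tangent(self, x: np.ndarray, state_n: FEState, dt: float) -> sp.csc_matrix:
        """Finite-difference element tangent, assembled sparse.

        All ``ndof_e`` perturbed element copies are evaluated in one
        batched residual call (elements stacked along the batch axis).
        """
        ue, pe = self._gather(x)
        if self.has_fluid:
            Fn = np.eye(3) + np.einsum("eai,eaj->eij", state_n.u[self.mesh.tets], self.B)
            Jn = _det33(Fn)
            pe_n = state_n.p[self.mesh.tets]
        else:
            Jn, pe_n = None, None
        E = self.mesh.n_elements
        m = self.ndof_e + 1  # base + one perturbation per element dof
        h = self.config.fd_step

        ue_big = np.broadcast_to(ue.reshape(E, 12), (m, E, 12)).copy()
        for j in range(12):
            ue_big[j + 1, :, j] += h
        if self.has_fluid:
            pe_big = np.broadcast_to(pe, (m, E, 4)).copy()
            for j in range(4):
                pe_big[13 + j, :, j] += h
            pe_flat = pe_big.reshape(m * E, 4)
            Jn_t = np.tile(Jn, m)
            pe_n_t = np.tile(pe_n, (m, 1))
        else:
            pe_flat, Jn_t, pe_n_t = None, None, None

        r_all = self._element_residual(
            ue_big.reshape(m * E, 4, 3),
            pe_flat,
            Jn_t,
            pe_n_t,
            dt,
            V=np.tile(self.V, m),
            B=np.tile(self.B, (m, 1, 1)),
            fiber=np.tile(self.mesh.fiber, (m, 1)),
            tau=np.tile(self.tau, m) if self.tau is not None else None,
        ).reshape(m, E, self.ndof_e)
        K = np.transpose((r_all[1:] - r_all[0]) / h, (1, 2, 0))
        A = sp.coo_matrix(
            (K.ravel(), (self._rows, self._cols)), shape=(self.n_dof, self.n_dof)
        )
        return A.tocsc()

    # -- Newton step ---------------------------------------------------------

    def _constrained_dofs(self, prescribed: dict, free_drain_nodes) -> tuple[np.ndarray, np.ndarray]:
        dofs = [3 * n + c for (n, c) in prescribed]
        vals = list(prescribed.values())
        if self.has_fluid:
            for n in free_drain_nodes:
                dofs.append(self.n_u + int(n))
                vals.append(0.0)
        return np.asarray(dofs, dtype=int), np.asarray(vals, dtype=float)

    def step(
        self,
        state_n: FEState,
        prescribed: dict[tuple[int, int], float],
        dt: float,
        f_ext: np.ndarray | None = None,
        free_drain_nodes: Sequence[int] = (),
        x0: np.ndarray | None = None,
    ):
        """Advance one backward-Euler step from ``state_n``.

        Returns ``(state, info)`` where ``info`` carries convergence flag,
        iteration count and the reaction forces at constrained u-dofs
        (force exerted *by* the constraints *on* the body).  Does not
        mutate ``state_n``; on Newton failure the interval is bisected
        internally (up to ``max_halvings`` levels).
        """
        cfg = self.config
        fe = np.zeros(self.n_dof)
        if f_ext is not None:
            fe[: self.n_u] = np.asarray(f_ext, dtype=float).ravel()

        cd, cv = self._constrained_dofs(prescribed, free_drain_nodes)
        free = np.setdiff1d(np.arange(self.n_dof), cd, assume_unique=False)

        lu_key = (len(free), int(free.sum()))  # same free-dof set => reusable LU

        def guarded_residual(x, state_from, dt_sub):
            try:
                return self.residual(x, state_from, dt_sub) - fe
            except ConstitutiveError:
                # inverted element / pore collapse on a trial iterate
                return None

        def attempt(state_from: FEState, cv_target: np.ndarray, dt_sub: float, xstart):
            """Damped quasi-Newton from ``xstart``; returns (x, ok, iters, R).

            The tangent factorization is cached across attempts (and across
            speculative solves from the same committed state) and rebuilt
            lazily when the iteration stalls; steps go through a
            backtracking line search on the residual norm.
            """
            x = xstart.copy()
            x[cd] = cv_target
            R = guarded_residual(x, state_from, dt_sub)
            if R is None:
                return x, False, 0, None
            rn = np.linalg.norm(R[free])
            # tolerance relative to the driving force scale of this step
            # (external load or incremental internal imbalance)
            scale = max(1.0, float(np.linalg.norm(fe)), rn)
            lu = self._lu_cache if self._lu_key == lu_key else None
            lu_fresh = False
            r_prev = np.inf

            def rebuild():
                A = self.tangent(x, state_from, dt_sub)
                f = spla.splu(A[free][:, free].tocsc())
                self._lu_cache, self._lu_key = f, lu_key
                return f

            for it in range(cfg.max_iterations):
                if rn <= cfg.newton_tol * scale or rn <= cfg.newton_abs_tol:
                    return x, True, it, R
                if lu is None or (rn > 0.5 * r_prev and not lu_fresh):
                    try:
                        lu = rebuild()
                        lu_fresh = True
                    except (ConstitutiveError, RuntimeError):
                        return x, False, it, None
                dx = lu.solve(-R[free])
                accepted = False
                alpha = 1.0
                for _ in range(6):
                    xt = x.copy()
                    xt[free] = x[free] + alpha * dx
                    Rt = guarded_residual(xt, state_from, dt_sub)
                    if Rt is not None:
                        rnt = np.linalg.norm(Rt[free])
                        if rnt < rn or rnt <= cfg.newton_tol * scale:
                            accepted = True
                            break
                    alpha *= 0.5
                if not accepted:
                    if not lu_fresh:
                        lu = None  # force a rebuild at the current point
                        continue
                    return x, False, it, R
                r_prev = rn
                x, R, rn = xt, Rt, rnt
                lu_fresh = False
            return x, rn <= cfg.newton_tol * scale, cfg.max_iterations, R

        def advance(state_from, cv_from, cv_to, dt_sub, depth, xstart):
            x, ok, its, R = attempt(state_from, cv_to, dt_sub, xstart)
            if ok:
                s = FEState(
                    x[: self.n_u].reshape(-1, 3).copy(),
                    x[self.n_u :].copy() if self.has_fluid else np.zeros(self.mesh.n_nodes),
                    state_from.t + dt_sub,
                )
                return s, x, R, True
            if depth >= cfg.max_halvings:
                if R is None:
                    x = xstart.copy()
                    R = np.zeros(self.n_dof)
                s = FEState(
                    x[: self.n_u].reshape(-1, 3).copy(),
                    x[self.n_u :].copy() if self.has_fluid else np.zeros(self.mesh.n_nodes),
                    state_from.t + dt_sub,
                )
                return s, x, R, False
            cv_mid = 0.5 * (cv_from + cv_to)
            s1, x1, R1, ok1 = advance(state_from, cv_from, cv_mid, dt_sub / 2, depth + 1, xstart)
            if not ok1:
                return s1, x1, R1, False
            return advance(s1, cv_mid, cv_to, dt_sub / 2, depth + 1, x1)

        if x0 is None:
            x0 = np.concatenate(
                [state_n.u.ravel(), state_n.p] if self.has_fluid else [state_n.u.ravel()]
            )
        cv_start = x0[cd] if len(cd) else cv
        state, x, R, ok = advance(state_n, cv_start, cv, dt, 0, x0)

        u_cd = cd[cd < self.n_u]
        reaction = np.zeros((self.mesh.n_nodes, 3))
        rflat = reaction.ravel()
        rflat[u_cd] = R[u_cd]
        info = {
            "converged": ok,
            "reaction": rflat.reshape(-1, 3),
            "x": x,
        }
        return state, info


def solve_quasi_static(
    mesh: PoroMesh,
    material: FEMaterial,
    bc: BoundarySpec,
    times: Sequence[float],
    config: SolverConfig | None = None,
    initial: FEState | None = None,
) -> SolveResult:
    """March a quasi-static history over ``times`` (strictly increasing).

    The reaction reported per step is the resultant of constraint forces on
    the fixed-displacement node set.
    """
    times = np.asarray(times, dtype=float)
    if np.any(np.diff(times) <= 0):
        raise ValueError("schedule must be strictly increasing")
    fe = PoroFE(mesh, material, config)
    state = initial or FEState(
        np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_nodes), times[0] if len(times) else 0.0
    )
    T = len(times)
    disp = np.zeros((T, mesh.n_nodes, 3))
    pres = np.zeros((T, mesh.n_nodes))
    reac = np.zeros((T, 3))
    conv = np.zeros(T, dtype=bool)
    t_prev = state.t
    x_prev = None
    for i, t in enumerate(times):
        dt = t - t_prev if i > 0 or t > t_prev else max(t, 1e-12)
        if dt <= 0:
            dt = 1e-12
        prescribed = bc.prescribed_u(t)
        f_ext = bc.external_force(mesh, t)
        state, info = fe.step(
            state, prescribed, dt, f_ext=f_ext, free_drain_nodes=bc.free_drain_nodes, x0=x_prev
        )
        x_prev = info["x"]
        disp[i] = state.u
        pres[i] = state.p
        reac[i] = info["reaction"].sum(axis=0)
        conv[i] = info["converged"]
        t_prev = t
    return SolveResult(times, disp, pres, reac, conv)


# ---------------------------------------------------------------------------
# structured meshes
# ---------------------------------------------------------------------------


def box_mesh(lx: float, ly: float, lz: float, nx: int, ny: int, nz: int) -> PoroMesh:
    """Structured box [0,lx]x[0,ly]x[0,lz], 6 tets per cell (Kuhn split).

    The identical split in every cell makes the triangulation conforming.
    Node sets 'bottom'/'top' tag the z = 0 and z = lz faces.
    """
    xs = np.linspace(0, lx, nx + 1)
    ys = np.linspace(0, ly, ny + 1)
    zs = np.linspace(0, lz, nz + 1)
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    nodes = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])

    def nid(i, j, k):
        return (i * (ny + 1) + j) * (nz + 1) + k

    perms = [(0, 1, 2), (0, 2, 1), (1, 0, 2), (1, 2, 0), (2, 0, 1), (2, 1, 0)]
    tets = []
    for i in range(nx):
        for j in range(ny):
            for k in range(nz):
                corner = np.array([i, j, k])
                for perm in perms:
                    path = [corner.copy()]
                    c = corner.copy()
                    for ax in perm:
                        c = c.copy()
                        c[ax] += 1
                        path.append(c)
                    tets.append([nid(*pt) for pt in path])
    mesh = PoroMesh(nodes, np.array(tets))
    mesh.fix_orientation()
    mesh.node_sets["bottom"] = np.nonzero(np.isclose(nodes[:, 2], 0.0))[0]
    mesh.node_sets["top"] = np.nonzero(np.isclose(nodes[:, 2], lz))[0]
    mesh.validate()
    return mesh


def single_tet_mesh() -> PoroMesh:
    """One positively oriented unit tetrahedron (verification fixture)."""
    nodes = np.array([[0, 0, 0], [1, 0, 0], [0, 1, 0], [0, 0, 1]], dtype=float)
    return PoroMesh(nodes, np.array([[0, 1, 2, 3]]))


# ---------------------------------------------------------------------------
# verification harnesses
# ---------------------------------------------------------------------------


def terzaghi_pressure(
    xi: np.ndarray, T: float, p0: float = 1.0, n_terms: int = 50
) -> np.ndarray:
    """One-dimensional linear consolidation pressure series.

    ``xi`` is depth below the drained surface normalized by the drainage
    height H (0 at the drained boundary, 1 at the sealed one); ``T`` is the
    dimensionless time c_v t / H^2 with consolidation coefficient
    ``c_v = k * H_A`` (permeability times aggregate modulus).
    """
    xi = np.asarray(xi, dtype=float)
    p = np.zeros_like(xi)
    for m in range(1, 2 * n_terms, 2):
        p += (4.0 / np.pi / m) * np.sin(0.5 * m * np.pi * xi) * np.exp(
            -(m**2) * np.pi**2 * T / 4.0
        )
    return p0 * p


def run_confined_compression(
    nh: NeoHookeanParams,
    fluid: BiphasicParams,
    applied_stress: float,
    times: Sequence[float],
    height: float = 1.0,
    nz: int = 16,
    sealed_top: bool = False,
    config: SolverConfig | None = None,
):
    """Confined compression of a 1 x 1 x ``height`` mm biphasic column.

    Lateral walls and bottom are rigid, impermeable rollers; the top face
    carries the applied axial compressive stress [MPa] and is free draining
    unless ``sealed_top``.  Returns ``(mesh, result)``; pressure profiles
    can be read from ``result.pressure`` at the returned node coordinates.
    """
    mesh = box_mesh(1.0, 1.0, height, 1, 1, nz)
    fixed = []
    for n in range(mesh.n_nodes):
        fixed.append((n, 0, 0.0))
        fixed.append((n, 1, 0.0))
    for n in mesh.node_sets["bottom"]:
        fixed.append((int(n), 2, 0.0))
    faces = mesh.boundary_faces()
    zc = mesh.nodes[faces].mean(axis=1)[:, 2]
    top_faces = faces[np.isclose(zc, height)]
    traction = [(tuple(f), np.array([0.0, 0.0, -applied_stress])) for f in top_faces]
    drain = [] if sealed_top else list(mesh.node_sets["top"])
    bc = BoundarySpec(fixed_disp=fixed, traction=traction, free_drain_nodes=drain)
    res = solve_quasi_static(mesh, FENeoHookean(nh, fluid=fluid), bc, times, config)
    return mesh, res


def run_uniaxial_tension(
    material: FEMaterial,
    stretch_history: Sequence[float],
    length: float = 4.0,
    width: float = 1.0,
    n: int = 2,
    config: SolverConfig | None = None,
):
    """Displacement-driven uniaxial bar test along z (fibers along z).

    Symmetry rollers on the x=0, y=0 and z=0 faces, prescribed axial
    displacement on the top face, lateral faces free (and free draining for
    biphasic materials).  Returns engineering strain and nominal axial
    stress arrays (reaction force / reference area).
    """
    mesh = box_mesh(width, width, length, n, n, max(2 * n, 2))
    nodes = mesh.nodes
    fixed = []
    for nd in np.nonzero(np.isclose(nodes[:, 0], 0.0))[0]:
        fixed.append((int(nd), 0, 0.0))
    for nd in np.nonzero(np.isclose(nodes[:, 1], 0.0))[0]:
        fixed.append((int(nd), 1, 0.0))
    for nd in mesh.node_sets["bottom"]:
        fixed.append((int(nd), 2, 0.0))

    stretches = np.asarray(stretch_history, dtype=float)
    times = np.arange(1, len(stretches) + 1, dtype=float)

    def top_disp(t):
        lam = np.interp(t, times, stretches)
        return (lam - 1.0) * length

    top = [int(nd) for nd in mesh.node_sets["top"]]
    for nd in top:
        fixed.append((nd, 2, top_disp))
    drain = list(range(mesh.n_nodes)) if material.fluid is not None else []
    bc = BoundarySpec(fixed_disp=fixed, free_drain_nodes=drain)

    # nominal stress from the reaction resultant on the top face
    fe = PoroFE(mesh, material, config)
    area = width * width
    stress = np.zeros(len(times))
    disp = np.zeros((len(times), mesh.n_nodes, 3))
    pres = np.zeros((len(times), mesh.n_nodes))
    conv = np.zeros(len(times), dtype=bool)
    state = FEState(np.zeros((mesh.n_nodes, 3)), np.zeros(mesh.n_nodes), 0.0)
    t_prev = 0.0
    x_prev = None
    for i, t in enumerate(times):
        dt = t - t_prev
        state, info = fe.step(
            state, bc.prescribed_u(t), dt, f_ext=bc.external_force(mesh, t),
            free_drain_nodes=bc.free_drain_nodes, x0=x_prev,
        )
        x_prev = info["x"]
        stress[i] = info["reaction"][top, 2].sum() / area
        disp[i], pres[i], conv[i] = state.u, state.p, info["converged"]
        t_prev = t
    res = SolveResult(times, disp, pres, np.zeros((len(times), 3)), conv)
    return stretches - 1.0, stress, res
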