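"""Reduced knee-joint analyses: model comparison, peak matching, parameter sweeps.

The joint is two rigid bodies — femur fixed, tibia free — connected by
the four main ligaments (ACL, PCL, MCL, LCL) under any of the five
constitutive representations, plus a lumped compression-only tibiofemoral
contact (one element per condyle, medial and lateral).  The stance phase
is driven the way gait inputs split in joint models of this kind:
flexion-extension rotation and the axial (distal-proximal) force are
prescribed, the remaining rigid DOFs (AP/ML translations, joint
distraction, valgus-varus and internal-external rotation) follow from
quasi-static equilibrium under the applied shear forces and moments.

Solid ligaments are full finite-element problems (``ligmech.poro_fem``)
whose end cross-sections are kinematically coupled to the rigid bodies;
spring ligaments use the closed-form tension-only force.  The reported
joint reaction force is the resultant compressive contact force, which is
what the ligament tensions modulate (they pull the tibia into the femur).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq, root

from .constitutive import (
    BiphasicParams,
    FibrilParams,
    FRPHEParams,
    SpringParams,
    spring_force,
)
from .poro_fem import FEState, PoroFE, SolverConfig, drained_copy, make_fe_material
from .synthetic_knee import (
    GaitWaveforms,
    LigamentSpec,
    build_ligament_mesh,
    default_ligament_specs,
)
from .tables import build_material_params, load_reference_parameters

GRAVITY = 9.81
ROT_SCALE = 50.0  # mm; lever arm used to balance rotation/translation scaling

__all__ = [
    "JointModel",
    "StanceResult",
    "build_surrogate_joint",
    "frphe_params_for",
    "run_stance",
    "find_first_peak",
    "adjust_to_first_peak",
    "compare_models",
    "parameter_sweep",
    "compare_drainage",
    "fluid_insensitivity",
    "AdjustResult",
    "ComparisonReport",
]


def _rot_x(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[1, 0, 0], [0, c, -s], [0, s, c]])


def _rot_y(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, 0, s], [0, 1, 0], [-s, 0, c]])


def _rot_z(a):
    c, s = np.cos(a), np.sin(a)
    return np.array([[c, -s, 0], [s, c, 0], [0, 0, 1]])


@dataclass
class TibiaPose:
    """Rigid pose of the tibia relative to the (fixed) femur frame."""

    R: np.ndarray
    t: np.ndarray

    @classmethod
    def from_dofs(cls, q: np.ndarray, flex_rad: float) -> "TibiaPose":
        """q = (tx, ty, tz, vv*ROT_SCALE, ie*ROT_SCALE); flexion about y prescribed."""
        vv = q[3] / ROT_SCALE
        ie = q[4] / ROT_SCALE
        R = _rot_z(ie) @ _rot_x(vv) @ _rot_y(flex_rad)
        return cls(R, np.asarray(q[:3], dtype=float))

    def apply(self, X: np.ndarray) -> np.ndarray:
        return X @ self.R.T + self.t


# ---------------------------------------------------------------------------
# ligament elements
# ---------------------------------------------------------------------------


class SpringLigament:
    """Closed-form tension-only line element between the attachment points."""

    kind = "spring"

    def __init__(self, spec: LigamentSpec, k_s: float):
        self.spec = spec
        self.params = SpringParams(
            k_s=k_s, rest_length=spec.chord_length, pre_strain=spec.pre_strain
        )
        self.origin = np.asarray(spec.origin, dtype=float)
        self.insertion = np.asarray(spec.insertion, dtype=float)

    def force_and_moment(self, pose: TibiaPose, dt: float):
        x_i = pose.apply(self.insertion)
        d = self.origin - x_i
        L = np.linalg.norm(d)
        f = spring_force(self.params, L)
        F = f * d / L
        return F, np.cross(x_i, F), None

    def commit(self, payload) -> None:
        pass

    def tension(self, pose: TibiaPose) -> float:
        return spring_force(self.params, np.linalg.norm(self.origin - pose.apply(self.insertion)))


class SolidLigament:
    """Finite-element ligament with end faces rigidly coupled to the bones."""

    kind = "solid"

    def __init__(
        self,
        spec: LigamentSpec,
        material,
        resolution: int = 1,
        drainage: str = "sealed",
        config: SolverConfig | None = None,
    ):
        self.spec = spec
        # pre-strain: the stress-free tube is meshed at its slack length and
        # its tibial end is mounted at the (farther) reference insertion, so
        # the reference pose carries the prescribed tensile pre-strain
        if spec.pre_strain != 0.0:
            o = np.asarray(spec.origin, dtype=float)
            ins = np.asarray(spec.insertion, dtype=float)
            ins_slack = o + (ins - o) / (1.0 + spec.pre_strain)
            mesh_spec = dataclasses.replace(spec, insertion=tuple(ins_slack))
            self.mount_offset = ins - ins_slack
        else:
            mesh_spec = spec
            self.mount_offset = np.zeros(3)
        self.mesh = build_ligament_mesh(mesh_spec, resolution)
        self.material = material
        self.fe = PoroFE(self.mesh, material, config)
        self.femur_nodes = self.mesh.node_sets["femur_end"]
        self.tibia_nodes = self.mesh.node_sets["tibia_end"]
        if drainage not in ("sealed", "free"):
            raise ValueError("drainage must be 'sealed' or 'free'")
        if drainage == "free" and material.fluid is not None:
            ends = set(self.femur_nodes) | set(self.tibia_nodes)
            surf = np.unique(self.mesh.boundary_faces())
            self.free_drain = [int(n) for n in surf if n not in ends]
        else:
            self.free_drain = []
        self.state = FEState(
            np.zeros((self.mesh.n_nodes, 3)), np.zeros(self.mesh.n_nodes), 0.0
        )
        self._x_warm = None
        # settling mode solves the drained (solid-only) problem so the
        # committed state entering stance is the relaxed p = 0 pre-tension
        self.settling = False
        self.fe_drained = (
            PoroFE(self.mesh, drained_copy(material), config)
            if material.fluid is not None
            else None
        )
        self._x_warm_drained = None

    def _prescribed(self, pose: TibiaPose) -> dict:
        pres = {}
        for n in self.femur_nodes:
            for c in range(3):
                pres[(int(n), c)] = 0.0
        X = self.mesh.nodes[self.tibia_nodes]
        u = pose.apply(X + self.mount_offset) - X
        for j, n in enumerate(self.tibia_nodes):
            for c in range(3):
                pres[(int(n), c)] = float(u[j, c])
        return pres

    def force_and_moment(self, pose: TibiaPose, dt: float):
        if self.settling and self.fe_drained is not None:
            start = FEState(self.state.u, np.zeros(self.mesh.n_nodes), self.state.t)
            new_state, info = self.fe_drained.step(
                start, self._prescribed(pose), dt, x0=self._x_warm_drained
            )
            # never reuse a diverged iterate as the next warm start
            self._x_warm_drained = info["x"] if info["converged"] else None
        else:
            new_state, info = self.fe.step(
                self.state,
                self._prescribed(pose),
                dt,
                free_drain_nodes=self.free_drain,
                x0=self._x_warm,
            )
            self._x_warm = info["x"] if info["converged"] else None
        # reaction = force by the rigid coupling on the ligament;
        # the ligament pulls back on the tibia with the opposite sign
        f_nodes = -info["reaction"][self.tibia_nodes]
        F = f_nodes.sum(axis=0)
        x_cur = self.mesh.nodes[self.tibia_nodes] + new_state.u[self.tibia_nodes]
        M = np.cross(x_cur, f_nodes).sum(axis=0)
        payload = (new_state, info["converged"])
        return F, M, payload

    def commit(self, payload) -> None:
        if payload is not None:
            self.state = payload[0]

    def tension(self, pose: TibiaPose) -> float:
        F, _, _ = self.force_and_moment(pose, dt=1e9)
        return float(np.linalg.norm(F))

    def axial_stress(self) -> dict[str, np.ndarray]:
        """Per-element fiber-axis stress [MPa] at the committed state.

        Returns the effective solid stress resolved along the current
        (pushed-forward) fiber direction, and its fibrillar part for FRPHE
        materials (None otherwise).  This is the quantity whose sign
        separates tension-only fibril-reinforced tissue from symmetric
        matrix laws under late-stance bending.
        """
        from .poro_fem import FEFRPHE

        ue = self.state.u[self.mesh.tets]
        F = np.eye(3) + np.einsum("eai,eaj->eij", ue, self.fe.B)
        fib_dir = self.mesh.fiber
        sig = self.material.cauchy(F, fib_dir)
        v = np.einsum("eij,ej->ei", F, fib_dir)
        n = v / np.linalg.norm(v, axis=1)[:, None]
        total_axial = np.einsum("ei,eij,ej->e", n, sig, n)
        fibril_axial = None
        if isinstance(self.material, FEFRPHE):
            sf = self.material.fibril_cauchy(F, fib_dir)
            fibril_axial = np.einsum("ei,eij,ej->e", n, sf, n)
        return {"total_axial": total_axial, "fibril_axial": fibril_axial}


# ---------------------------------------------------------------------------
# joint model
# ---------------------------------------------------------------------------


@dataclass
class JointModel:
    """Femur-tibia pair joined by ligament elements and condylar contacts."""

    ligaments: dict
    contact_points: np.ndarray = field(
        default_factory=lambda: np.array([[0.0, 22.0, 0.0], [0.0, -22.0, 0.0]])
    )
    contact_stiffness: float = 6000.0  # N/mm per condyle, normal direction
    contact_smoothing: float = 0.02  # mm
    contact_tangential_stiffness: float = 30.0  # N/mm per condyle when loaded
    contact_load_scale_N: float = 100.0  # normal force at half tangential engagement
    capsule_stiffness: float = 2.0  # N/mm, weak soft-tissue centering
    capsule_rot_stiffness: float = 500.0  # N mm/rad on the free rotations
    mass_kg: float = 80.0
    stance_duration_s: float = 0.6

    @property
    def body_weight_N(self) -> float:
        return self.mass_kg * GRAVITY

    def contact_forces(self, pose: TibiaPose) -> tuple[np.ndarray, np.ndarray, float]:
        """Per-condyle contact force on the tibia (compression-only, smoothed).

        Penetration is the upward displacement of a tibial condyle point
        past the femoral surface plane z = 0; the smoothed normal ramp is
        C1 and exactly zero once the gap exceeds the smoothing length.  A
        tangential stiffness, engaged in proportion to the normal load,
        lumps the horizontal/torsional stability that plateau and meniscus
        conformity provide in the intact joint; the reported resultant is
        the total compressive (normal) force.
        """
        x = pose.apply(self.contact_points)
        pen = x[:, 2]
        k, s = self.contact_stiffness, self.contact_smoothing
        # one-sided quadratic blend: exactly zero for pen <= 0, C1 throughout
        f = np.where(
            pen >= s, k * (pen - 0.5 * s), np.where(pen > 0, k * pen**2 / (2.0 * s), 0.0)
        )
        forces = np.zeros((len(x), 3))
        forces[:, 2] = -f
        if self.contact_tangential_stiffness > 0:
            w = f / (f + self.contact_load_scale_N)
            u_t = x[:, :2] - self.contact_points[:, :2]
            forces[:, :2] = -self.contact_tangential_stiffness * w[:, None] * u_t
        moment = np.cross(x, forces).sum(axis=0)
        return forces, moment, float(f.sum())

    def evaluate(self, q: np.ndarray, flex_rad: float, loads: dict, dt: float):
        """Rigid-body force/moment residual and per-ligament contributions."""
        pose = TibiaPose.from_dofs(q, flex_rad)
        F = np.array([loads["ap"], loads["ml"], loads["axial"]], dtype=float)
        M = np.array([loads["vv"], 0.0, loads["ie"]], dtype=float)
        lig_forces = {}
        payloads = {}
        for name, lig in self.ligaments.items():
            Fl, Ml, payload = lig.force_and_moment(pose, dt)
            F = F + Fl
            M = M + Ml
            lig_forces[name] = Fl
            payloads[name] = payload
        cf, cm, ctot = self.contact_forces(pose)
        F = F + cf.sum(axis=0)
        M = M + cm
        # weak capsule/soft-tissue restraint; keeps the unloaded joint
        # (heel strike, toe off) well-posed, negligible under load
        F = F - self.capsule_stiffness * pose.t
        M = M - self.capsule_rot_stiffness * np.array(
            [q[3] / ROT_SCALE, 0.0, q[4] / ROT_SCALE]
        )
        res = np.array([F[0], F[1], F[2], M[0] / ROT_SCALE, M[2] / ROT_SCALE])
        return res, {
            "pose": pose,
            "lig_forces": lig_forces,
            "payloads": payloads,
            "contact_total": ctot,
        }


def frphe_params_for(
    ligament: str,
    block: str = "adjusted",
    Ef: float | None = None,
    Em: float | None = None,
    k0: float | None = None,
    M: float | None = None,
) -> FRPHEParams:
    """Reference FRPHE parameters for one ligament with optional overrides."""
    t = load_reference_parameters()["frphe"]
    ef = Ef if Ef is not None else t["Ef_MPa_initial" if block == "initial" else "Ef_MPa_adjusted"][ligament]
    em = Em if Em is not None else t["Em_MPa"][ligament]
    return FRPHEParams.from_matrix_moduli(
        em,
        t["nu_m"][ligament],
        FibrilParams(ef, t["C"][ligament]),
        BiphasicParams(
            k0 if k0 is not None else t["k0_1e-15_m4_per_Ns"][ligament],
            M if M is not None else t["M"][ligament],
        ),
    )


def build_surrogate_joint(
    kind: str = "frphe",
    block: str = "adjusted",
    resolution: int = 1,
    specs: dict[str, LigamentSpec] | None = None,
    drainage: str = "sealed",
    params_map: dict | None = None,
    spring_scale: float = 1.0,
    config: SolverConfig | None = None,
    contact_stiffness: float = 6000.0,
) -> JointModel:
    """Assemble the four-bundle surrogate joint under one representation.

    ``params_map`` overrides the reference constitutive parameters per
    ligament (values as accepted by the FE material for ``kind``);
    ``spring_scale`` uniformly scales all spring constants (used by the
    first-peak adjustment).
    """
    specs = specs or default_ligament_specs()
    ligaments = {}
    for name, spec in specs.items():
        if kind == "spring":
            k = build_material_params("spring", name, block) * spring_scale
            ligaments[name] = SpringLigament(spec, k)
        else:
            if params_map and name in params_map:
                params = params_map[name]
            else:
                params = build_material_params(kind, name, block)
            mat = make_fe_material(kind, params)
            ligaments[name] = SolidLigament(
                spec, mat, resolution=resolution, drainage=drainage, config=config
            )
    return JointModel(ligaments=ligaments, contact_stiffness=contact_stiffness)


# ---------------------------------------------------------------------------
# stance solve
# ---------------------------------------------------------------------------


@dataclass
class StanceResult:
    """Joint-level time series over the stance phase."""

    time: np.ndarray  # stance fraction
    reaction_N: np.ndarray  # resultant compressive contact force
    translations: np.ndarray  # (T,3): AP (x), ML (y), IS (z) of the tibia, mm
    rotations: np.ndarray  # (T,3): flexion, valgus-varus, int-ext, degrees
    per_ligament_force: dict[str, np.ndarray]
    converged: np.ndarray
    residual_norm: np.ndarray
    mass_kg: float = 80.0

    @property
    def reaction_BW(self) -> np.ndarray:
        return self.reaction_N / (self.mass_kg * GRAVITY)


def _loads_at(gait: GaitWaveforms, i: int) -> dict:
    return {
        "axial": gait.axial_force[i],
        "ap": gait.ap_force[i],
        "ml": gait.ml_force[i],
        "vv": gait.valgus_varus_moment[i],
        "ie": gait.int_ext_moment[i],
    }


def run_stance(
    model: JointModel,
    gait: GaitWaveforms,
    t_max: float = 1.0,
    n_init_ramp: int = 4,
    xtol: float = 1e-10,
) -> StanceResult:
    """March the tibia through stance, solving rigid equilibrium per step.

    The first gait sample is approached through ``n_init_ramp`` pseudo-time
    substeps from the unloaded reference pose.  Each step solves the
    5-DOF equilibrium (Powell hybrid method) with the previous solution as
    the initial guess; nonconverged steps are flagged, not fatal.
    """
    mask = gait.time <= t_max + 1e-12
    times = gait.time[mask]
    T = len(times)
    q = np.zeros(5)
    reaction = np.zeros(T)
    trans = np.zeros((T, 3))
    rots = np.zeros((T, 3))
    lig_force = {name: np.zeros(T) for name in model.ligaments}
    conv = np.zeros(T, dtype=bool)
    resid = np.zeros(T)

    def solve_point(q0, flex_rad, loads, dt):
        fun = lambda x: model.evaluate(x, flex_rad, loads, dt)[0]
        # FD step ~1e-4 in the scaled DOFs: large enough that the FE-solver
        # tolerance does not pollute the difference quotients
        sol = root(
            fun, q0, method="hybr", options={"xtol": xtol, "maxfev": 400, "eps": 1e-8}
        )
        ok = sol.success
        if not ok:
            # tension-gating kinks can stall the Powell solver near unloaded
            # poses; a Levenberg-Marquardt polish handles the flat directions
            sol2 = root(fun, sol.x, method="lm", options={"maxiter": 40, "eps": 1e-8})
            if np.linalg.norm(sol2.fun) < np.linalg.norm(sol.fun):
                sol = sol2
            ok = np.linalg.norm(sol.fun) <= 1e-6 * max(1.0, abs(loads["axial"]))
        return sol.x, ok

    dt_phys = model.stance_duration_s / max(T - 1, 1)

    for i in range(T):
        flex_rad = np.deg2rad(gait.flexion[i])
        loads = _loads_at(gait, i)
        if i == 0:
            # ramp the reference pose into the first gait sample in fully
            # drained settling mode, so heel strike starts from the relaxed
            # (p = 0, steady-state) pre-tension
            for lig in model.ligaments.values():
                if hasattr(lig, "settling"):
                    lig.settling = True
            for j in range(1, n_init_ramp + 1):
                f = j / n_init_ramp
                sub_loads = {k: f * v for k, v in loads.items()}
                q, ok = solve_point(q, f * flex_rad, sub_loads, dt_phys)
            _, settled = model.evaluate(q, flex_rad, loads, dt_phys)
            for name, lig in model.ligaments.items():
                lig.commit(settled["payloads"][name])
                if hasattr(lig, "settling"):
                    lig.settling = False
        else:
            q_prev = q.copy()
            q, ok = solve_point(q, flex_rad, loads, dt_phys)
            if not ok:
                # load continuation: subdivide the gait increment, finer on
                # retry (tension gates switching near unloaded poses)
                prev = _loads_at(gait, i - 1)
                prev_flex = np.deg2rad(gait.flexion[i - 1])
                for n_sub in (4, 8):
                    qq, okk = q_prev.copy(), True
                    for f in np.linspace(1.0 / n_sub, 1.0, n_sub):
                        sub = {k: prev[k] + f * (loads[k] - prev[k]) for k in loads}
                        qq, okk = solve_point(
                            qq, prev_flex + f * (flex_rad - prev_flex), sub, dt_phys / n_sub
                        )
                    if okk:
                        break
                if okk or np.linalg.norm(
                    model.evaluate(qq, flex_rad, loads, dt_phys)[0]
                ) < np.linalg.norm(model.evaluate(q, flex_rad, loads, dt_phys)[0]):
                    q, ok = qq, okk
        res, data = model.evaluate(q, flex_rad, loads, dt_phys)

        def force_scale(d):
            return max(
                1.0,
                abs(loads["axial"]),
                sum(np.linalg.norm(f) for f in d["lig_forces"].values()),
            )

        if np.linalg.norm(res) > 1e-6 * force_scale(data):
            # a stray nonconverged FE sub-solve can spoil the recording even
            # when equilibrium was found; re-solve once with warmed caches
            q, ok = solve_point(q, flex_rad, loads, dt_phys)
            res, data = model.evaluate(q, flex_rad, loads, dt_phys)
        for name, lig in model.ligaments.items():
            lig.commit(data["payloads"][name])
            lig_force[name][i] = np.linalg.norm(data["lig_forces"][name])
        reaction[i] = data["contact_total"]
        trans[i] = q[:3]
        rots[i] = [gait.flexion[i], np.rad2deg(q[3] / ROT_SCALE), np.rad2deg(q[4] / ROT_SCALE)]
        resid[i] = np.linalg.norm(res)
        conv[i] = resid[i] <= 1e-6 * force_scale(data)
    return StanceResult(
        time=times,
        reaction_N=reaction,
        translations=trans,
        rotations=rots,
        per_ligament_force=lig_force,
        converged=conv,
        residual_norm=resid,
        mass_kg=model.mass_kg,
    )


# ---------------------------------------------------------------------------
# analyses
# ---------------------------------------------------------------------------


def find_first_peak(time: np.ndarray, series: np.ndarray) -> tuple[int, float]:
    """First local maximum with stance fraction in (0, 0.5]; earliest on ties."""
    s = np.asarray(series)
    for i in range(1, len(s) - 1):
        if time[i] > 0.5:
            break
        if s[i] > s[i - 1] and s[i] >= s[i + 1]:
            return i, float(s[i])
    raise ValueError("no first peak found in (0, 0.5] of stance")


def second_peak(time: np.ndarray, series: np.ndarray) -> float:
    """Largest value in the second half of stance."""
    mask = time > 0.5
    return float(np.max(series[mask])) if mask.any() else float("nan")


@dataclass
class AdjustResult:
    multiplier: float
    peak: float
    reference_peak: float
    adjusted_values: dict[str, float]


def adjust_to_first_peak(
    build: Callable[[float], JointModel],
    gait: GaitWaveforms,
    reference_peak: float,
    base_values: dict[str, float],
    tol: float = 1.0,
    bracket: tuple[float, float] = (0.25, 4.0),
) -> AdjustResult:
    """Scale a parameter set so the first reaction-force peak matches a reference.

    ``build(multiplier)`` must return a fresh joint with the target
    parameter set (spring constants or fibril moduli) scaled uniformly.
    Bracketed root finding on the multiplier; raises if the bracket does
    not straddle the reference peak.
    """

    def peak_of(m: float) -> float:
        res = run_stance(build(m), gait, t_max=0.55)
        return find_first_peak(res.time, res.reaction_N)[1]

    lo, hi = bracket
    f_lo = peak_of(lo) - reference_peak
    f_hi = peak_of(hi) - reference_peak
    if f_lo == 0:
        m = lo
    elif f_hi == 0:
        m = hi
    elif f_lo * f_hi > 0:
        raise ValueError(
            f"no bracketing interval: peaks at multipliers {bracket} are "
            f"{f_lo + reference_peak:.1f} and {f_hi + reference_peak:.1f} N "
            f"vs reference {reference_peak:.1f} N"
        )
    else:
        m = brentq(lambda x: peak_of(x) - reference_peak, lo, hi, xtol=1e-3)
    peak = peak_of(m)
    if abs(peak - reference_peak) > tol:
        raise ValueError(f"adjustment missed tolerance: |{peak} - {reference_peak}| > {tol}")
    return AdjustResult(
        multiplier=m,
        peak=peak,
        reference_peak=reference_peak,
        adjusted_values={k: v * m for k, v in base_values.items()},
    )


@dataclass
class ComparisonReport:
    results: dict[str, StanceResult]

    def table(self):
        import pandas as pd

        rows = []
        for name, res in self.results.items():
            for i, t in enumerate(res.time):
                rows.append(
                    {
                        "model": name,
                        "time_frac": t,
                        "reaction_N": res.reaction_N[i],
                        "reaction_BW": res.reaction_BW[i],
                        "ap_mm": res.translations[i, 0],
                        "ml_mm": res.translations[i, 1],
                        "is_mm": res.translations[i, 2],
                        "vv_deg": res.rotations[i, 1],
                        "ie_deg": res.rotations[i, 2],
                    }
                )
        return pd.DataFrame(rows)

    def pairwise_max_rel_diff(self):
        import pandas as pd

        names = list(self.results)
        out = pd.DataFrame(index=names, columns=names, dtype=float)
        for a in names:
            for b in names:
                fa, fb = self.results[a].reaction_N, self.results[b].reaction_N
                denom = max(np.max(np.abs(fa)), np.max(np.abs(fb)), 1e-12)
                out.loc[a, b] = float(np.max(np.abs(fa - fb)) / denom)
        return out

    def within_band(self, names: Sequence[str], band: float) -> bool:
        d = self.pairwise_max_rel_diff()
        return bool(all(d.loc[a, b] <= band for a in names for b in names))


def compare_models(models: dict[str, JointModel], gait: GaitWaveforms) -> ComparisonReport:
    """Run identical stance loading through several representations."""
    return ComparisonReport({name: run_stance(m, gait) for name, m in models.items()})


def parameter_sweep(
    parameter: str,
    values: Sequence[float],
    gait: GaitWaveforms,
    ligament: str | None = None,
    block: str = "adjusted",
    resolution: int = 1,
    config: SolverConfig | None = None,
):
    """Sweep one FRPHE constituent parameter and collect reaction traces.

    ``parameter`` is one of Ef, Em, k0, M; ``ligament`` limits the
    variation to one bundle (others stay at reference values), as in the
    fibril-modulus sweeps; ``None`` varies all four.
    """
    import pandas as pd

    if parameter not in ("Ef", "Em", "k0", "M"):
        raise ValueError("parameter must be one of Ef, Em, k0, M")
    rows = []
    traces = {}
    for v in values:
        params_map = {}
        for name in default_ligament_specs():
            kwargs = {}
            if ligament is None or name == ligament:
                kwargs[parameter] = v
            params_map[name] = frphe_params_for(name, block, **kwargs)
        model = build_surrogate_joint(
            "frphe", block, resolution=resolution, params_map=params_map, config=config
        )
        res = run_stance(model, gait)
        _, fp = find_first_peak(res.time, res.reaction_N)
        rows.append(
            {
                "value": v,
                "first_peak_N": fp,
                "second_peak_N": second_peak(res.time, res.reaction_N),
                "max_N": float(res.reaction_N.max()),
            }
        )
        traces[v] = res
    table = pd.DataFrame(rows)
    # nondecreasing up to 0.1% of the peak: a ligament that only engages in
    # part of stance moves one peak strongly and leaves the other at the
    # equilibrium-resolution level
    tol = 1e-3 * float(table["max_N"].max())
    table["peak_monotone_nondecreasing"] = bool(np.all(np.diff(table["max_N"]) >= -tol))
    table["second_peak_monotone_nondecreasing"] = bool(
        np.all(np.diff(table["second_peak_N"]) >= -tol)
    )
    return table, traces


def compare_drainage(
    gait: GaitWaveforms,
    kind: str = "frphe",
    block: str = "adjusted",
    resolution: int = 1,
    config: SolverConfig | None = None,
) -> dict:
    """Sealed vs free-draining external ligament surfaces: trace difference."""
    res = {}
    for mode in ("sealed", "free"):
        model = build_surrogate_joint(kind, block, resolution=resolution, drainage=mode, config=config)
        res[mode] = run_stance(model, gait)
    fa, fb = res["sealed"].reaction_N, res["free"].reaction_N
    rel = np.max(np.abs(fa - fb)) / max(np.max(np.abs(fa)), 1e-12)
    return {"results": res, "max_rel_diff": float(rel)}


def fluid_insensitivity(
    gait: GaitWaveforms,
    k0_values: Sequence[float] = (0.15, 2.9, 15.0),
    M_values: Sequence[float] = (1.0, 10.0),
    drainage_modes: Sequence[str] = ("sealed", "free"),
    block: str = "adjusted",
    resolution: int = 1,
    config: SolverConfig | None = None,
):
    """Maximum % change of the reaction trace over fluid-property variations.

    The reference run uses the tabulated values (k0 = 2.9e-15 m^4/Ns, M = 7.98,
    sealed surfaces); each variation run changes k0 and M in all ligaments
    and/or the drainage condition, and the reported number is
    ``100 * max over runs and steps |F - F_ref| / max |F_ref|``.
    """
    import pandas as pd

    ref_model = build_surrogate_joint("frphe", block, resolution=resolution, config=config)
    ref = run_stance(ref_model, gait)
    fref = ref.reaction_N
    denom = np.max(np.abs(fref))
    rows = []
    worst = 0.0
    for mode in drainage_modes:
        for k0 in k0_values:
            for M in M_values:
                params_map = {
                    name: frphe_params_for(name, block, k0=k0, M=M)
                    for name in default_ligament_specs()
                }
                model = build_surrogate_joint(
                    "frphe", block, resolution=resolution, params_map=params_map,
                    drainage=mode, config=config,
                )
                res = run_stance(model, gait)
                d = 100.0 * float(np.max(np.abs(res.reaction_N - fref)) / denom)
                rows.append({"drainage": mode, "k0": k0, "M": M, "max_rel_diff_pct": d})
                worst = max(worst, d)
    return worst, pd.DataFrame(rows), ref
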