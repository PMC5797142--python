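"""Synthetic surrogate for the subject-specific knee inputs.

The study this package emulates drove a subject-specific MRI knee with
measured gait; neither the geometry nor the gait numbers are distributed.
This module generates desk-scale stand-ins:

* parametric ligament geometries (curved, optionally twisted tubes meshed
  with tetrahedra, fibers along the centerline) for the four main knee
  ligaments (ACL, PCL, MCL, LCL),
* stance-phase gait-like loading waveforms (double-peaked axial force,
  flexion-extension rotation, internal-external and valgus-varus moments,
  anterior-posterior and medial-lateral forces), explicitly surrogate:
  amplitudes are literature-plausible magnitudes scaled by body weight
  (80 kg default), not a subject's measurements,
* probabilistic sampling of ligament moduli from truncated Gaussians with
  prescribed relative standard deviations.

All generators are deterministic given their inputs (sampling takes an
explicit seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial import Delaunay
from scipy.stats import truncnorm

from .poro_fem import PoroMesh
from .tables import load_reference_parameters

GRAVITY = 9.81  # m/s^2

__all__ = [
    "LigamentSpec",
    "GaitProfile",
    "GaitWaveforms",
    "ParameterSample",
    "default_ligament_specs",
    "build_ligament_mesh",
    "arc_length",
    "analytic_volume",
    "generate_gait",
    "reverse_profile",
    "sample_parameters",
    "truncated_rsd",
    "DEFAULT_RSD",
]

LIGAMENT_NAMES = ("ACL", "PCL", "MCL", "LCL", "PT", "QT", "MPFL", "LPFL")

#: relative standard deviations of literature modulus distributions
DEFAULT_RSD = {"ACL": 0.62, "PCL": 0.60, "LCL": 0.70, "MCL": 0.71, "PT": 0.52, "QT": 0.43}


# ---------------------------------------------------------------------------
# ligament geometry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class LigamentSpec:
    """Parametric geometry of one ligament bundle.

    origin / insertion : 3-D attachment points [mm] in the joint frame
        (x anterior, y medial, z superior, origin at the joint center);
        origin is the femoral attachment.
    cross_section_area : mm^2
    curvature : dimensionless sagitta / length of the bowed centerline
    twist : end-to-end twist of the cross-section frame, degrees
    pre_strain : tensile strain at the reference pose
    representation : 'spring' or 'solid'
    """

    name: str
    origin: tuple[float, float, float]
    insertion: tuple[float, float, float]
    cross_section_area: float
    curvature: float = 0.0
    twist: float = 0.0
    pre_strain: float = 0.0
    representation: str = "solid"

    def __post_init__(self) -> None:
        if np.allclose(self.origin, self.insertion):
            raise ValueError("origin and insertion must differ")
        if self.cross_section_area <= 0:
            raise ValueError("cross-section area must be positive")
        if abs(self.pre_strain) >= 0.2:
            raise ValueError("|pre_strain| must be < 0.2")

    @property
    def chord_length(self) -> float:
        return float(np.linalg.norm(np.subtract(self.insertion, self.origin)))


#: reference-pose (full extension) tensile pre-strains, in the range used
#: by numerical knee models; the PCL is near-slack at full extension
DEFAULT_PRE_STRAIN = {"ACL": 0.02, "PCL": 0.01, "MCL": 0.02, "LCL": 0.015}


def default_ligament_specs(
    pre_strains: dict[str, float] | float | None = None,
) -> dict[str, LigamentSpec]:
    """The four-bundle surrogate ligament set.

    Attachment points are anatomically plausible but synthetic.  Areas are
    chosen so a linear-elastic tube of the tabulated reference modulus E
    matches the tabulated initial spring stiffness (A = k_s L / E), making spring
    and solid representations comparable by construction.  ``pre_strains``
    overrides the default per-ligament reference-pose tension (pass 0.0
    for entirely slack reference ligaments).
    """
    t = load_reference_parameters()
    if pre_strains is None:
        pre_strains = DEFAULT_PRE_STRAIN
    if not isinstance(pre_strains, dict):
        pre_strains = {k: float(pre_strains) for k in DEFAULT_PRE_STRAIN}
    geometry = {
        # name: origin (femur), insertion (tibia), curvature, twist
        "ACL": ((-8.0, -6.0, 2.0), (8.0, 2.0, -28.0), 0.03, 30.0),
        "PCL": ((6.0, 8.0, 0.0), (-14.0, -2.0, -30.0), 0.04, 20.0),
        "MCL": ((-2.0, 42.0, 8.0), (0.0, 38.0, -55.0), 0.05, 0.0),
        "LCL": ((-4.0, -40.0, 8.0), (-8.0, -40.0, -48.0), 0.03, 0.0),
    }
    specs = {}
    for name, (o, i, curv, tw) in geometry.items():
        L = float(np.linalg.norm(np.subtract(i, o)))
        area = t["spring"]["initial"][name] * L / t["linear"]["E_MPa"][name]
        specs[name] = LigamentSpec(
            name, o, i, area, curvature=curv, twist=tw, pre_strain=pre_strains.get(name, 0.0)
        )
    return specs


def _centerline(spec: LigamentSpec, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Centerline points and unit tangents at fractions ``s`` in [0, 1]."""
    o = np.asarray(spec.origin, dtype=float)
    i = np.asarray(spec.insertion, dtype=float)
    axis = i - o
    L = np.linalg.norm(axis)
    t_hat = axis / L
    # bow direction: radially outward from the joint center, orthogonal to axis
    mid = 0.5 * (o + i)
    n = mid - (mid @ t_hat) * t_hat
    if np.linalg.norm(n) < 1e-9:
        n = np.cross(t_hat, [1.0, 0.0, 0.0])
        if np.linalg.norm(n) < 1e-9:
            n = np.cross(t_hat, [0.0, 1.0, 0.0])
    n = n / np.linalg.norm(n)
    sag = spec.curvature * L
    pts = o[None, :] + s[:, None] * axis[None, :] + sag * np.sin(np.pi * s)[:, None] * n[None, :]
    tans = axis[None, :] / L + sag * np.pi * np.cos(np.pi * s)[:, None] * n[None, :] / L
    tans = tans / np.linalg.norm(tans, axis=1)[:, None]
    return pts, tans


def arc_length(spec: LigamentSpec, n_quad: int = 2000) -> float:
    """Centerline arc length [mm] by fine quadrature."""
    s = np.linspace(0.0, 1.0, n_quad + 1)
    pts, _ = _centerline(spec, s)
    return float(np.sum(np.linalg.norm(np.diff(pts, axis=0), axis=1)))


def analytic_volume(spec: LigamentSpec) -> float:
    """Tube volume [mm^3]: cross-section area times centerline arc length."""
    return spec.cross_section_area * arc_length(spec)


def _disk_template(resolution: int) -> tuple[np.ndarray, np.ndarray]:
    """2-D unit-disk point layout (rings) and its triangulation.

    Ring radii are scaled so the triangulated polygon area equals the area
    of the unit circle, which keeps mesh volumes within a fraction of a
    percent of the analytic tube volume.
    """
    pts = [np.zeros(2)]
    for j in range(1, resolution + 1):
        r = j / resolution
        m = 6 * j
        ang = 2.0 * np.pi * np.arange(m) / m
        pts.extend(np.column_stack([r * np.cos(ang), r * np.sin(ang)]))
    pts = np.array(pts)
    tri = Delaunay(pts).simplices
    # area correction: scale so polygon area == pi (unit circle)
    a = pts[tri]
    area = 0.5 * np.abs(
        np.sum(
            (a[:, 1, 0] - a[:, 0, 0]) * (a[:, 2, 1] - a[:, 0, 1])
            - (a[:, 2, 0] - a[:, 0, 0]) * (a[:, 1, 1] - a[:, 0, 1])
        )
    )
    return pts * np.sqrt(np.pi / area), tri


_PRISM_ROTATIONS = [
    (0, 1, 2, 3, 4, 5),
    (1, 2, 0, 4, 5, 3),
    (2, 0, 1, 5, 3, 4),
    (3, 5, 4, 0, 2, 1),
    (4, 3, 5, 1, 0, 2),
    (5, 4, 3, 2, 1, 0),
]


def _split_prism(v: list[int]) -> list[tuple[int, int, int, int]]:
    """Split a triangular prism into 3 tets with face-consistent diagonals.

    Each quadrilateral face gets the diagonal through its smallest global
    node index, so neighboring prisms triangulate shared faces identically
    and the mesh stays conforming.
    """
    k = int(np.argmin(v))
    rot = next(r for r in _PRISM_ROTATIONS if r[0] == k)
    w = [v[i] for i in rot]
    if min(w[1], w[5]) < min(w[2], w[4]):
        tets = [(w[0], w[1], w[2], w[5]), (w[0], w[1], w[5], w[4]), (w[0], w[4], w[5], w[3])]
    else:
        tets = [(w[0], w[1], w[2], w[4]), (w[0], w[4], w[2], w[5]), (w[0], w[4], w[5], w[3])]
    return tets


def build_ligament_mesh(spec: LigamentSpec, resolution: int = 1, n_axial: int | None = None) -> PoroMesh:
    """Tetrahedral tube mesh of one ligament.

    A curved, optionally twisted tube of ``resolution`` element rings
    across the radius is extruded along the centerline; fiber directions
    follow the local tangent.  Node sets ``femur_end`` and ``tibia_end``
    tag the end cross-sections for kinematic coupling.
    """
    if resolution < 1:
        raise ValueError("resolution must be >= 1")
    L = spec.chord_length
    if L <= 0:
        raise ValueError("degenerate ligament spec: zero length")
    R = float(np.sqrt(spec.cross_section_area / np.pi))
    if n_axial is None:
        # twisted tubes need finer axial slabs to hold the prism volume
        n_axial = max(
            4, int(round(resolution * L / (2.0 * R))), int(np.ceil(abs(spec.twist) / 4.0))
        )

    disk, tris = _disk_template(resolution)
    n_sec = len(disk)
    s = np.linspace(0.0, 1.0, n_axial + 1)
    centers, tangents = _centerline(spec, s)

    # reference normal for the cross-section frame (non-parallel to the axis)
    axis = (np.asarray(spec.insertion) - np.asarray(spec.origin)) / L
    ref = np.array([1.0, 0.0, 0.0])
    if abs(axis @ ref) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])

    nodes = np.empty(((n_axial + 1) * n_sec, 3))
    for i, (c, t) in enumerate(zip(centers, tangents)):
        n1 = ref - (ref @ t) * t
        n1 = n1 / np.linalg.norm(n1)
        n2 = np.cross(t, n1)
        phi = np.deg2rad(spec.twist) * s[i]
        e1 = np.cos(phi) * n1 + np.sin(phi) * n2
        e2 = -np.sin(phi) * n1 + np.cos(phi) * n2
        nodes[i * n_sec : (i + 1) * n_sec] = (
            c[None, :] + R * (disk[:, :1] * e1[None, :] + disk[:, 1:] * e2[None, :])
        )

    tets, fiber = [], []
    for i in range(n_axial):
        base, top = i * n_sec, (i + 1) * n_sec
        # element fibers: tangent at the mid-height of the slab
        t_mid = 0.5 * (tangents[i] + tangents[i + 1])
        t_mid = t_mid / np.linalg.norm(t_mid)
        for a, b, c in tris:
            prism = [base + a, base + b, base + c, top + a, top + b, top + c]
            for tet in _split_prism(prism):
                tets.append(tet)
                fiber.append(t_mid)

    mesh = PoroMesh(nodes, np.array(tets), np.array(fiber))
    mesh.fix_orientation()
    mesh.node_sets["femur_end"] = np.arange(n_sec)
    mesh.node_sets["tibia_end"] = np.arange(n_axial * n_sec, (n_axial + 1) * n_sec)
    mesh.validate()
    return mesh


# ---------------------------------------------------------------------------
# gait waveforms
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GaitProfile:
    """Parameters of the surrogate stance-phase loading waveforms.

    Each channel is a baseline plus a sum of Gaussian bumps
    ``(amplitude, center, width)`` in stance fraction; the axial force is
    additionally windowed to vanish at heel strike and toe off.  Axial
    bump amplitudes are in units of body weight; moments in N mm, shear
    forces in N.
    """

    body_mass_kg: float = 80.0
    stance_duration_s: float = 0.6
    axial_bw_bumps: tuple = ((2.2, 0.25, 0.17), (2.0, 0.75, 0.17))
    flexion_base_deg: float = 4.0
    flexion_bumps: tuple = ((12.0, 0.15, 0.09), (22.0, 1.05, 0.18))
    ie_moment_bumps: tuple = ((2000.0, 0.3, 0.15), (-2500.0, 0.8, 0.12))
    # negative = adduction (varus), the canonical frontal-plane gait moment;
    # it loads the medial compartment and tensions the LCL
    vv_moment_bumps: tuple = ((-9000.0, 0.25, 0.15), (-8000.0, 0.75, 0.15))
    ap_force_bumps: tuple = ((120.0, 0.2, 0.12), (-140.0, 0.85, 0.12))
    ml_force_bumps: tuple = ((40.0, 0.5, 0.25),)

    @property
    def body_weight_N(self) -> float:
        return self.body_mass_kg * GRAVITY


def reverse_profile(profile: GaitProfile) -> GaitProfile:
    """Time-mirrored profile: every bump center c maps to 1 - c."""

    def rev(bumps):
        return tuple((a, 1.0 - c, w) for a, c, w in bumps)

    return replace(
        profile,
        axial_bw_bumps=rev(profile.axial_bw_bumps),
        flexion_bumps=rev(profile.flexion_bumps),
        ie_moment_bumps=rev(profile.ie_moment_bumps),
        vv_moment_bumps=rev(profile.vv_moment_bumps),
        ap_force_bumps=rev(profile.ap_force_bumps),
        ml_force_bumps=rev(profile.ml_force_bumps),
    )


@dataclass
class GaitWaveforms:
    """Stance-phase loading time series (arrays share one length)."""

    time: np.ndarray  # stance fraction, 0..1
    axial_force: np.ndarray  # N, >= 0, double peaked
    flexion: np.ndarray  # degrees
    int_ext_moment: np.ndarray  # N mm
    valgus_varus_moment: np.ndarray  # N mm
    ap_force: np.ndarray  # N
    ml_force: np.ndarray  # N
    profile: GaitProfile = field(default_factory=GaitProfile)

    def n_local_maxima(self, series: np.ndarray) -> int:
        s = np.asarray(series)
        return int(np.sum((s[1:-1] > s[:-2]) & (s[1:-1] > s[2:])))

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "time_frac": self.time,
                "Fz_N": self.axial_force,
                "flexion_deg": self.flexion,
                "Mie_Nmm": self.int_ext_moment,
                "Mvv_Nmm": self.valgus_varus_moment,
                "Fap_N": self.ap_force,
                "Fml_N": self.ml_force,
            }
        )


def _bumps(t: np.ndarray, bumps) -> np.ndarray:
    out = np.zeros_like(t)
    for a, c, w in bumps:
        out = out + a * np.exp(-((t - c) ** 2) / (2.0 * w**2))
    return out


def generate_gait(profile: GaitProfile | None = None, n_steps: int = 100) -> GaitWaveforms:
    """Deterministic surrogate stance waveforms on ``n_steps`` points.

    The axial force is a body-weight-scaled double bump windowed by
    ``sin(pi t)^0.4``; with the default profile it has exactly two local
    maxima, near 25% and 75% of stance.
    """
    if n_steps < 10:
        raise ValueError("n_steps must be >= 10")
    profile = profile or GaitProfile()
    for bumps in (profile.axial_bw_bumps,):
        if any(a < 0 for a, _, _ in bumps):
            raise ValueError("axial force bump amplitudes must be non-negative")
    t = np.linspace(0.0, 1.0, n_steps)
    # ground-contact window, evaluated on min(t, 1-t) so it is exactly
    # time-symmetric; all load channels vanish at heel strike and toe off
    envelope = np.sin(np.pi * np.minimum(t, 1.0 - t)) ** 0.4
    axial = profile.body_weight_N * envelope * _bumps(t, profile.axial_bw_bumps)
    return GaitWaveforms(
        time=t,
        axial_force=axial,
        flexion=profile.flexion_base_deg + _bumps(t, profile.flexion_bumps),
        int_ext_moment=envelope * _bumps(t, profile.ie_moment_bumps),
        valgus_varus_moment=envelope * _bumps(t, profile.vv_moment_bumps),
        ap_force=envelope * _bumps(t, profile.ap_force_bumps),
        ml_force=envelope * _bumps(t, profile.ml_force_bumps),
        profile=profile,
    )


# ---------------------------------------------------------------------------
# probabilistic material sampling
# ---------------------------------------------------------------------------


@dataclass
class ParameterSample:
    """Per-ligament modulus draws from truncated Gaussians."""

    draws: dict[str, np.ndarray]
    rsd_used: dict[str, float]
    seed: int
    floor_frac: float


def truncated_rsd(rsd: float, floor_frac: float = 0.01) -> float:
    """Analytic RSD of N(mu, (rsd*mu)^2) truncated below at floor_frac*mu.

    This is the truncation correction against which empirical sample RSDs
    are compared: truncating the lower tail raises the mean and shrinks
    the standard deviation, so the post-truncation RSD is below the
    requested one (noticeably so for RSD ~ 0.7).
    """
    a = (floor_frac - 1.0) / rsd
    mean, var = truncnorm.stats(a, np.inf, loc=1.0, scale=rsd, moments="mv")
    return float(np.sqrt(var) / mean)


def sample_parameters(
    base: dict[str, float],
    rsd: dict[str, float] | float | None = None,
    n: int = 1,
    seed: int = 0,
    floor_frac: float = 0.01,
) -> ParameterSample:
    """Draw ``n`` positive modulus values per ligament.

    Values follow Normal(base, rsd*base) truncated below at
    ``floor_frac * base`` (default 1% of the base value), sampled via the
    inverse-CDF of the truncated normal; reproducible given ``seed``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rsd is None:
        rsd = {k: DEFAULT_RSD[k] for k in base}
    if not isinstance(rsd, dict):
        rsd = {k: float(rsd) for k in base}
    rng = np.random.default_rng(seed)
    draws, used = {}, {}
    for name, mu in base.items():
        r = rsd[name]
        if r < 0:
            raise ValueError("rsd must be >= 0")
        if r == 0:
            draws[name] = np.full(n, float(mu))
        else:
            a = (floor_frac - 1.0) / r
            draws[name] = truncnorm.rvs(
                a, np.inf, loc=mu, scale=r * mu, size=n, random_state=rng
            )
        used[name] = r
    return ParameterSample(draws=draws, rsd_used=used, seed=seed, floor_frac=floor_frac)
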