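"""Parametric synthetic hips: watertight femur and acetabulum meshes.

The study emulated here measured impingement-limited motion on bone
models segmented from CT.  Patient scans are not available, so this
module builds their statistical stand-ins: a parametric proximal femur
(spherical head, cylindrical neck, bent shaft, optional cam bump at the
head-neck junction) and a hemispherical acetabular cup, both swept as
structured ring meshes that are watertight by construction, plus the
anatomical landmarks the reference-frame protocol needs.

Two one-dimensional calibrations tie the generator to the radiographic
module: the cam amplitude is solved so the *measured* alpha angle hits a
requested target, and the cup's lateral coverage is solved so the
*measured* CE angle does.  ``generate_cohort`` assembles seeded groups
whose alpha/CE targets are drawn from truncated normal distributions
(every case must satisfy its group's diagnostic window, mirroring the
study's inclusion criteria).

Conventions: millimetres and degrees; right-handed coordinates with
``+x`` lateral (simulated right side), ``+y`` anterior, ``+z`` superior;
the femoral head center of the neutral pose is the origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
import json

import numpy as np
import trimesh
from scipy.optimize import brentq

from .frames import _axis_angle_matrix, build_femoral_frame, fit_sphere
from .radiographic import GroupLabel, measure_alpha, measure_ce

__all__ = [
    "FemurParams",
    "PelvisParams",
    "LandmarkSet",
    "HipCase",
    "GroupSpec",
    "CohortSpec",
    "generate_femur",
    "generate_pelvis",
    "generate_hip_case",
    "generate_cohort",
    "default_cohort_spec",
    "save_case",
    "cohort_spec_to_yaml",
]

# distance from the head center to the knee joint line (landmarks only;
# the meshed shaft is truncated well proximal of this)
KNEE_DISTANCE = 380.0
EPICONDYLE_HALFSPAN = 40.0


@dataclass(frozen=True)
class FemurParams:
    """Proximal femur geometry (mm / degrees)."""

    head_radius: float = 24.0
    neck_radius: float = 16.5
    neck_length: float = 25.0
    neck_shaft_angle: float = 130.0
    femoral_anteversion: float = 15.0
    cam_amplitude: float = 0.0
    cam_center_angle: float = 32.0   # circumferential, 0 = anterior, + toward superolateral
    cam_angular_width: float = 30.0
    shaft_length: float = 90.0
    mesh_edge_length: float = 2.0

    def __post_init__(self) -> None:
        if not (self.head_radius > self.neck_radius > 0):
            raise ValueError("need head_radius > neck_radius > 0")
        if self.cam_amplitude < 0:
            raise ValueError("cam_amplitude must be >= 0")
        if self.mesh_edge_length <= 0 or self.neck_length <= 0 or self.shaft_length <= 0:
            raise ValueError("lengths must be positive")


@dataclass(frozen=True)
class PelvisParams:
    """Acetabular cup geometry (mm / degrees)."""

    cup_radius: float = 24.5          # head radius + clearance
    lateral_coverage_angle: float = 30.0  # polar angle of the lateral rim from vertical
    cup_anteversion: float = 15.0
    cup_inclination: float | None = None  # derived (90 - coverage) when None
    rim_thickness: float = 5.0
    mesh_edge_length: float = 2.0

    def __post_init__(self) -> None:
        if not (0 < self.lateral_coverage_angle < 90):
            raise ValueError("lateral_coverage_angle must be in (0, 90)")
        if self.cup_radius <= 0 or self.rim_thickness <= 0 or self.mesh_edge_length <= 0:
            raise ValueError("cup dimensions must be positive")


@dataclass(frozen=True)
class LandmarkSet:
    """Named anatomical points (mm, world coordinates)."""

    ASIS_left: np.ndarray
    ASIS_right: np.ndarray
    pubic_symphysis: np.ndarray
    medial_epicondyle: np.ndarray
    lateral_epicondyle: np.ndarray
    head_reference_points: np.ndarray  # (>=4, 3), on the head sphere surface

    def __post_init__(self) -> None:
        for name in ("ASIS_left", "ASIS_right", "pubic_symphysis",
                     "medial_epicondyle", "lateral_epicondyle"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
            if not np.all(np.isfinite(getattr(self, name))):
                raise ValueError(f"landmark {name} is not finite")
        pts = np.asarray(self.head_reference_points, dtype=float)
        if pts.ndim != 2 or pts.shape[0] < 4 or pts.shape[1] != 3:
            raise ValueError("need >= 4 head reference points")
        object.__setattr__(self, "head_reference_points", pts)
        if np.allclose(self.ASIS_left, self.ASIS_right):
            raise ValueError("ASIS points must be distinct")
        fit_sphere(pts)  # raises if coplanar

    def as_dict(self) -> dict:
        return {
            "ASIS_left": self.ASIS_left.tolist(),
            "ASIS_right": self.ASIS_right.tolist(),
            "pubic_symphysis": self.pubic_symphysis.tolist(),
            "medial_epicondyle": self.medial_epicondyle.tolist(),
            "lateral_epicondyle": self.lateral_epicondyle.tolist(),
            "head_reference_points": self.head_reference_points.tolist(),
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "LandmarkSet":
        d = json.loads(Path(path).read_text())
        return cls(**{k: np.asarray(v) for k, v in d.items()})


@dataclass(frozen=True)
class HipCase:
    """One simulated hip: meshes, landmarks, and generation provenance."""

    case_id: str
    pelvis_mesh: trimesh.Trimesh
    femur_mesh: trimesh.Trimesh
    landmarks: LandmarkSet
    femur_params: FemurParams
    pelvis_params: PelvisParams
    target_group: GroupLabel
    target_alpha: float
    target_ce: float
    seed: int


@dataclass(frozen=True)
class GroupSpec:
    n: int
    alpha_mean: float
    alpha_sd: float
    ce_mean: float
    ce_sd: float

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("group size must be >= 1")
        if self.alpha_sd < 0 or self.ce_sd < 0:
            raise ValueError("standard deviations must be >= 0")


@dataclass(frozen=True)
class CohortSpec:
    """Three diagnostic groups plus shared anatomy defaults."""

    groups: dict[GroupLabel, GroupSpec]
    master_seed: int = 0
    femur_defaults: FemurParams = field(default_factory=FemurParams)
    pelvis_defaults: PelvisParams = field(default_factory=PelvisParams)
    neck_shaft_angle_sd: float = 3.0
    femoral_anteversion_sd: float = 4.0
    cup_anteversion_sd: float = 4.0


# target windows implied by the diagnostic definitions; every sampled case
# must classify into its group (cases outside would have been excluded
# from the study, so they are resampled)
_GROUP_WINDOWS = {
    GroupLabel.cam_FAI: ((55.0, 84.0), (25.0, 40.0)),
    GroupLabel.DDH_with_cam: ((55.0, 84.0), (20.0, 24.9)),
    GroupLabel.DDH_without_cam: ((46.0, 54.9), (20.0, 24.9)),
}


def default_cohort_spec(master_seed: int = 0) -> CohortSpec:
    """The study's group structure: 15 cam-FAI, 11 borderline-DDH-with-cam
    and 12 borderline-DDH-without-cam hips, with the reported per-group
    alpha and CE angle means and SDs."""
    return CohortSpec(
        groups={
            GroupLabel.cam_FAI: GroupSpec(15, 65.7, 7.6, 32.3, 4.2),
            GroupLabel.DDH_with_cam: GroupSpec(11, 63.6, 6.1, 22.0, 1.5),
            GroupLabel.DDH_without_cam: GroupSpec(12, 49.5, 3.6, 21.7, 1.7),
        },
        master_seed=master_seed,
    )


# ---------------------------------------------------------------------------
# femur


def _neck_axis(params: FemurParams) -> np.ndarray:
    """Unit vector from the head center toward the neck/shaft (lateral,
    inferior, and posterior by the anteversion angle)."""
    delta = np.radians(180.0 - params.neck_shaft_angle)
    av = np.radians(params.femoral_anteversion)
    return np.array([np.sin(delta) * np.cos(av),
                     -np.sin(delta) * np.sin(av),
                     -np.cos(delta)])


def _circumferential_basis(axis: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(u, w): u = anterior projected off the axis, w = axis x u."""
    y = np.array([0.0, 1.0, 0.0])
    u = y - (y @ axis) * axis
    u = u / np.linalg.norm(u)
    return u, np.cross(axis, u)


def _ring_mesh(ring_centers, ring_frames, ring_radii, n_circ: int,
               cap_start: np.ndarray, cap_end: np.ndarray) -> trimesh.Trimesh:
    """Closed swept-tube mesh: start pole, rings, end pole.

    ``ring_frames`` holds per-ring (u, w) in-plane basis vectors; all
    rings share ``n_circ`` vertices, so the strip triangulation is
    manifold and the two pole fans close the surface.
    """
    phi = np.linspace(0, 2 * np.pi, n_circ, endpoint=False)
    cos_p, sin_p = np.cos(phi), np.sin(phi)
    verts = [np.asarray(cap_start, dtype=float)[None, :]]
    for c, (u, w), r in zip(ring_centers, ring_frames, ring_radii):
        ring = c + r * (np.outer(cos_p, u) + np.outer(sin_p, w))
        verts.append(ring)
    verts.append(np.asarray(cap_end, dtype=float)[None, :])
    V = np.vstack(verts)

    n_rings = len(ring_radii)
    faces = []
    first = 1
    for j in range(n_circ):  # start pole fan
        faces.append([0, first + j, first + (j + 1) % n_circ])
    for i in range(n_rings - 1):
        a = 1 + i * n_circ
        b = a + n_circ
        for j in range(n_circ):
            j2 = (j + 1) % n_circ
            faces.append([a + j, b + j, a + j2])
            faces.append([a + j2, b + j, b + j2])
    last = 1 + (n_rings - 1) * n_circ
    end = len(V) - 1
    for j in range(n_circ):  # end pole fan
        faces.append([end, last + (j + 1) % n_circ, last + j])
    mesh = trimesh.Trimesh(vertices=V, faces=np.asarray(faces), process=False)
    if mesh.volume < 0:
        mesh.invert()
    return mesh


def _femur_base_mesh(params: FemurParams):
    """Swept proximal femur (no cam displacement yet).

    Returns ``(mesh, info)`` where ``info`` carries the neck axis,
    circumferential basis, junction polar angle and the shaft foot point
    used for landmark placement.
    """
    R, rn = params.head_radius, params.neck_radius
    n_hat = _neck_axis(params)
    u, w = _circumferential_basis(n_hat)
    edge = params.mesh_edge_length
    n_circ = max(24, int(np.ceil(2 * np.pi * R / edge)))

    theta_j = np.degrees(np.arcsin(rn / R))  # junction polar angle from the neck axis

    centers, frames, radii = [], [], []

    # head: rings of the sphere, polar angle theta from +n_hat, walked from
    # the apex (theta near 180) toward the junction; finer near the junction
    # so the alpha-angle contour and the cam bump are well resolved
    coarse = np.degrees(edge / R)
    thetas = []
    t = 178.0
    while t > theta_j:
        thetas.append(t)
        t -= coarse if t > theta_j + 25.0 else 1.5
    thetas.append(theta_j)
    for th in thetas:
        tr = np.radians(th)
        centers.append(R * np.cos(tr) * n_hat)
        frames.append((u, w))
        radii.append(R * np.sin(tr))

    # neck cylinder: fine axial steps near the junction (cam / alpha zone)
    a_j = R * np.cos(np.radians(theta_j))
    a_end = a_j + params.neck_length
    a = a_j
    while a < a_end - 1e-9:
        a = min(a + (0.8 if a < a_j + 12.0 else edge), a_end)
        centers.append(a * n_hat)
        frames.append((u, w))
        radii.append(rn)

    # bend from the neck direction to the vertical shaft
    shaft_dir = np.array([0.0, 0.0, -1.0])
    omega = np.arccos(np.clip(n_hat @ shaft_dir, -1, 1))
    bend_axis = np.cross(n_hat, shaft_dir)
    bend_axis = bend_axis / np.linalg.norm(bend_axis)
    bend_len = 30.0
    r_bend = bend_len / omega
    m_hat = shaft_dir - (shaft_dir @ n_hat) * n_hat
    m_hat = m_hat / np.linalg.norm(m_hat)
    arc_center = a_end * n_hat + r_bend * m_hat
    shaft_radius = 1.15 * rn
    n_bend = 10
    for i in range(1, n_bend + 1):
        t = i / n_bend
        rot = _axis_angle_matrix(bend_axis, t * omega)
        centers.append(arc_center - r_bend * (rot @ m_hat))
        frames.append((rot @ u, rot @ w))
        s = t * t * (3 - 2 * t)  # smoothstep radius blend
        radii.append((1 - s) * rn + s * shaft_radius)

    # straight shaft, then a capped end
    rot_full = _axis_angle_matrix(bend_axis, omega)
    u_s, w_s = rot_full @ u, rot_full @ w
    shaft_top = centers[-1]
    n_shaft = max(2, int(params.shaft_length / (2 * edge)))
    for i in range(1, n_shaft + 1):
        centers.append(shaft_top + shaft_dir * (params.shaft_length * i / n_shaft))
        frames.append((u_s, w_s))
        radii.append(shaft_radius)

    apex = -R * n_hat
    end_pole = centers[-1] + shaft_dir * (0.6 * shaft_radius)
    mesh = _ring_mesh(centers, frames, radii, n_circ, apex, end_pole)
    info = {
        "neck_axis": n_hat, "u": u, "w": w, "theta_j": theta_j,
        "shaft_foot": shaft_top,
    }
    return mesh, info


def _apply_cam(mesh: trimesh.Trimesh, params: FemurParams, info: dict) -> trimesh.Trimesh:
    """Displace vertices radially (away from the neck axis) by a smooth
    Gaussian bump centered circumferentially at ``cam_center_angle`` and
    in the polar direction at the head-neck junction."""
    A = params.cam_amplitude
    if A <= 0:
        return mesh
    n_hat, u, w = info["neck_axis"], info["u"], info["w"]
    theta_j = info["theta_j"]
    V = mesh.vertices.copy()
    axial = V @ n_hat
    rad_vec = V - np.outer(axial, n_hat)
    rad = np.linalg.norm(rad_vec, axis=1)
    theta = np.degrees(np.arctan2(rad, axial))
    phi = np.degrees(np.arctan2(V @ w, V @ u))
    dphi = (phi - params.cam_center_angle + 180.0) % 360.0 - 180.0

    sigma_phi = params.cam_angular_width / 2.0
    # larger cams are broader: the polar falloff toward the head apex widens
    # with amplitude (a tall narrow spike is not a pistol-grip deformity),
    # which also makes the measured alpha strictly increasing in amplitude
    sigma_theta = np.where(theta >= theta_j, 7.0 + 1.3 * A, 8.0)
    g = (np.exp(-0.5 * ((theta - theta_j) / sigma_theta) ** 2)
         * np.exp(-0.5 * (dphi / sigma_phi) ** 2))
    # confine to the head-neck junction zone with smooth tapers so the bump
    # never reaches the apex (where the sphere-fit reference points live)
    # nor the shaft bend
    def smoothstep(x):
        x = np.clip(x, 0.0, 1.0)
        return x * x * (3 - 2 * x)

    g *= smoothstep((100.0 - theta) / 15.0) * smoothstep((theta - (theta_j - 25.0)) / 10.0)
    ok = rad > 1e-9
    V[ok] += (A * g[ok] / rad[ok])[:, None] * rad_vec[ok]
    out = trimesh.Trimesh(vertices=V, faces=mesh.faces, process=False)
    return out


def _femur_landmarks(params: FemurParams, info: dict) -> dict:
    """Epicondyles at the anatomical knee distance on the shaft line, and
    exact head-sphere reference points on the apex side (away from any
    cam) for the sphere fit."""
    foot = info["shaft_foot"]
    knee_mid = np.array([foot[0], foot[1], -KNEE_DISTANCE])
    med = knee_mid - np.array([EPICONDYLE_HALFSPAN, 0, 0])
    lat = knee_mid + np.array([EPICONDYLE_HALFSPAN, 0, 0])

    n_hat, u, w = info["neck_axis"], info["u"], info["w"]
    R = params.head_radius
    dirs = [-n_hat]
    for pol in (120.0, 150.0):
        for az in (0.0, 90.0, 180.0, 270.0):
            tr, az_r = np.radians(pol), np.radians(az)
            dirs.append(np.cos(tr) * n_hat
                        + np.sin(tr) * (np.cos(az_r) * u + np.sin(az_r) * w))
    head_pts = R * np.vstack(dirs)
    return {"medial_epicondyle": med, "lateral_epicondyle": lat,
            "head_reference_points": head_pts}


def generate_femur(params: FemurParams, target_alpha: float | None = None,
                   seed: int = 0):
    """Build a watertight proximal femur; optionally solve the cam
    amplitude so the measured alpha angle hits ``target_alpha``.

    Returns ``(mesh, femur_landmarks_dict, resolved_params)``.

    Raises
    ------
    ValueError
        If ``target_alpha`` is below the cam-free alpha of the same
        geometry, or the amplitude solve does not converge (the error
        names the achievable range).
    """
    base, info = _femur_base_mesh(params)
    lm = _femur_landmarks(params, info)

    if target_alpha is None:
        return _apply_cam(base, params, info), lm, params

    def measured(amplitude: float) -> float:
        p = replace(params, cam_amplitude=amplitude)
        m = _apply_cam(base, p, info)
        return _alpha_of(m, lm, params.head_radius)

    lo, hi = 0.0, 14.0
    f_lo = measured(lo) - target_alpha
    if f_lo > 0:
        raise ValueError(
            f"target alpha {target_alpha:.1f} deg is below the cam-free alpha "
            f"{f_lo + target_alpha:.1f} deg of this geometry")
    f_hi = measured(hi) - target_alpha
    if f_hi < 0:
        raise ValueError(
            f"cam amplitude solve failed: alpha {f_hi + target_alpha:.1f} deg at "
            f"amplitude {hi} mm is still below target {target_alpha:.1f} deg")
    amp = brentq(lambda a: measured(a) - target_alpha, lo, hi, xtol=5e-3)
    resolved = replace(params, cam_amplitude=float(amp))
    return _apply_cam(base, resolved, info), lm, resolved


def _alpha_of(mesh, lm: dict, head_radius: float) -> float:
    """Measured alpha of a generated femur, using its own landmarks."""
    frame = build_femoral_frame(np.zeros(3), lm["medial_epicondyle"],
                                lm["lateral_epicondyle"])
    fit = fit_sphere(lm["head_reference_points"])
    return measure_alpha(mesh, frame, fit)


# ---------------------------------------------------------------------------
# pelvis


def _cup_axis(params: PelvisParams) -> np.ndarray:
    """Unit pole axis of the cup (points into the covered hemisphere)."""
    incl = params.cup_inclination
    tau = np.radians(90.0 - params.lateral_coverage_angle if incl is None else incl)
    av = np.radians(params.cup_anteversion)
    return np.array([-np.sin(tau),
                     -np.cos(tau) * np.sin(av),
                     np.cos(tau) * np.cos(av)])


def _pelvis_mesh(params: PelvisParams, head_center: np.ndarray) -> trimesh.Trimesh:
    """Hemispherical cup shell: inner cap, flat rim annulus, outer cap."""
    Ri = params.cup_radius
    Ro = Ri + params.rim_thickness
    a_hat = _cup_axis(params)
    # in-plane basis of the opening plane
    ref = np.array([0.0, 0.0, 1.0])
    if abs(a_hat @ ref) > 0.95:
        ref = np.array([1.0, 0.0, 0.0])
    u = ref - (ref @ a_hat) * a_hat
    u = u / np.linalg.norm(u)
    w = np.cross(a_hat, u)

    edge = params.mesh_edge_length
    n_circ = max(24, int(np.ceil(2 * np.pi * Ro / edge)))

    centers, frames, radii = [], [], []

    def cap_rings(radius: float, chis_deg) -> None:
        for chi in chis_deg:
            cr = np.radians(chi)
            centers.append(head_center + radius * np.cos(cr) * a_hat)
            frames.append((u, w))
            radii.append(radius * np.sin(cr))

    coarse = np.degrees(edge / Ri)
    chis_in = list(np.arange(coarse, 75.0, coarse)) + list(np.arange(75.0, 90.0, 2.0)) + [90.0]
    cap_rings(Ri, chis_in)
    # rim annulus in the opening plane
    for r in (0.5 * (Ri + Ro), Ro):
        centers.append(head_center.copy())
        frames.append((u, w))
        radii.append(r)
    chis_out = list(np.arange(88.0, 0.0, -2 * coarse))
    cap_rings(Ro, chis_out)

    start_pole = head_center + Ri * a_hat
    end_pole = head_center + Ro * a_hat
    return _ring_mesh(centers, frames, radii, n_circ, start_pole, end_pole)


def _pelvis_landmarks(head_center: np.ndarray) -> dict:
    """Synthetic pelvic landmarks at adult-scale offsets from the hip
    center; all three share one anterior coordinate so the anterior
    pelvic plane of the supine pose is exactly vertical."""
    c = np.asarray(head_center, dtype=float)
    return {
        "ASIS_right": c + np.array([25.0, 60.0, 80.0]),
        "ASIS_left": c + np.array([-205.0, 60.0, 80.0]),
        "pubic_symphysis": c + np.array([-90.0, 60.0, -15.0]),
    }


def generate_pelvis(params: PelvisParams, target_ce: float | None = None,
                    head_center=(0.0, 0.0, 0.0), seed: int = 0):
    """Build a watertight cup shell; optionally solve the lateral
    coverage angle so the measured CE angle hits ``target_ce``.

    Returns ``(mesh, pelvic_landmarks_dict, resolved_params)``.
    """
    c = np.asarray(head_center, dtype=float)
    lm = _pelvis_landmarks(c)
    if target_ce is None:
        return _pelvis_mesh(params, c), lm, params
    if not (0.0 < target_ce < 45.0):
        raise ValueError(f"target CE {target_ce} deg outside the representable (0, 45)")

    def measured(cov: float) -> float:
        return measure_ce(_pelvis_mesh(replace(params, lateral_coverage_angle=cov), c), c)

    lo, hi = 3.0, 55.0
    f_lo, f_hi = measured(lo) - target_ce, measured(hi) - target_ce
    if f_lo > 0 or f_hi < 0:
        raise ValueError(f"target CE {target_ce:.1f} deg outside the coverage range "
                         f"[{f_lo + target_ce:.1f}, {f_hi + target_ce:.1f}]")
    cov = brentq(lambda x: measured(x) - target_ce, lo, hi, xtol=2e-2)
    resolved = replace(params, lateral_coverage_angle=float(cov))
    return _pelvis_mesh(resolved, c), lm, resolved


# ---------------------------------------------------------------------------
# cases and cohorts


def generate_hip_case(case_id: str, target_group: GroupLabel,
                      target_alpha: float, target_ce: float,
                      femur_params: FemurParams | None = None,
                      pelvis_params: PelvisParams | None = None,
                      seed: int = 0) -> HipCase:
    """One synthetic hip whose measured angles hit the given targets."""
    fp = femur_params or FemurParams()
    pp = pelvis_params or PelvisParams(cup_radius=fp.head_radius + 0.5)
    femur, f_lm, fp = generate_femur(fp, target_alpha=target_alpha, seed=seed)
    pelvis, p_lm, pp = generate_pelvis(pp, target_ce=target_ce, seed=seed)
    lm = LandmarkSet(**p_lm, **f_lm)
    return HipCase(case_id=case_id, pelvis_mesh=pelvis, femur_mesh=femur,
                   landmarks=lm, femur_params=fp, pelvis_params=pp,
                   target_group=target_group, target_alpha=float(target_alpha),
                   target_ce=float(target_ce), seed=seed)


def _truncated_normal(rng, mean: float, sd: float, window: tuple[float, float],
                      max_tries: int = 4000) -> float:
    lo, hi = window
    if sd == 0.0:
        if lo <= mean <= hi:
            return mean
        raise ValueError(f"unreachable truncation window [{lo}, {hi}] "
                         f"for a point mass at {mean}")
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise ValueError(f"unreachable truncation window [{lo}, {hi}] "
                     f"for N({mean}, {sd}^2)")


def generate_cohort(spec: CohortSpec) -> list[HipCase]:
    """Seeded cohort with exactly the per-group sizes of ``spec``.

    Per-case alpha/CE targets are truncated-normal draws inside each
    group's diagnostic window; neck-shaft angle and femoral/cup
    anteversion vary normally around the shared defaults.  The same
    master seed reproduces byte-identical meshes.
    """
    cases: list[HipCase] = []
    root = np.random.SeedSequence(spec.master_seed)
    group_seqs = root.spawn(len(spec.groups))
    for (group, gspec), gseq in zip(spec.groups.items(), group_seqs):
        a_win, c_win = _GROUP_WINDOWS[group]
        for i, cseq in enumerate(gseq.spawn(gspec.n)):
            rng = np.random.default_rng(cseq)
            alpha_t = _truncated_normal(rng, gspec.alpha_mean, gspec.alpha_sd, a_win)
            ce_t = _truncated_normal(rng, gspec.ce_mean, gspec.ce_sd, c_win)
            fp = replace(
                spec.femur_defaults,
                neck_shaft_angle=float(np.clip(
                    rng.normal(spec.femur_defaults.neck_shaft_angle,
                               spec.neck_shaft_angle_sd), 120, 142)),
                femoral_anteversion=float(np.clip(
                    rng.normal(spec.femur_defaults.femoral_anteversion,
                               spec.femoral_anteversion_sd), 2, 30)),
            )
            pp = replace(
                spec.pelvis_defaults,
                cup_radius=spec.femur_defaults.head_radius + 0.5,
                cup_anteversion=float(np.clip(
                    rng.normal(spec.pelvis_defaults.cup_anteversion,
                               spec.cup_anteversion_sd), 5, 35)),
            )
            case_seed = int(cseq.generate_state(1)[0] % (2**31))
            cases.append(generate_hip_case(
                case_id=f"{group.value}_{i:02d}", target_group=group,
                target_alpha=alpha_t, target_ce=ce_t,
                femur_params=fp, pelvis_params=pp, seed=case_seed))
    return cases


def save_case(case: HipCase, out_dir: str | Path, mesh_format: str = "stl") -> Path:
    """Write one case's meshes (binary STL or PLY), landmarks (JSON) and
    generation parameters (YAML) into ``out_dir``."""
    from dataclasses import asdict

    import yaml

    from .mesh_io import write_mesh

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    suffix = ".stl" if mesh_format == "stl" else ".ply"
    write_mesh(case.pelvis_mesh, out / f"{case.case_id}_pelvis{suffix}",
               file_format=mesh_format)
    write_mesh(case.femur_mesh, out / f"{case.case_id}_femur{suffix}",
               file_format=mesh_format)
    case.landmarks.to_json(out / f"{case.case_id}_landmarks.json")
    params = {
        "case_id": case.case_id,
        "target_group": case.target_group.value if case.target_group else None,
        "target_alpha": case.target_alpha,
        "target_ce": case.target_ce,
        "seed": case.seed,
        "femur_params": asdict(case.femur_params),
        "pelvis_params": asdict(case.pelvis_params),
    }
    (out / f"{case.case_id}_params.yaml").write_text(
        yaml.safe_dump(params, sort_keys=False))
    return out


def cohort_spec_to_yaml(spec: CohortSpec, path: str | Path) -> Path:
    """Serialize a cohort spec (group sizes and angle distributions) to a
    YAML config readable by the command-line ``cohort`` command."""
    from dataclasses import asdict

    import yaml

    payload = {
        "master_seed": spec.master_seed,
        "groups": {g.value: asdict(gs) for g, gs in spec.groups.items()},
    }
    path = Path(path)
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path
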