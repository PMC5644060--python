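"""Impingement-limited range of motion about the hip joint center.

The femur rotates about the fitted head center (ball joint, no
translation): flexion first, about the pelvic medio-lateral axis, then
internal rotation about the flexed femoral mechanical axis — the
clinical maneuver behind the study's primary outcome, maximum internal
rotation at 90 deg of flexion.  The motion limit is the largest angle at
which the bony surfaces remain separated by more than the contact
tolerance; it is found by bisection and validated one angular-resolution
step past the limit, where the first contact between the acetabular rim
and the femoral head-neck junction is recorded as the impingement point
(reported in neutral-pose femoral coordinates) and assigned to the
proximal or distal region of the junction.

Collision queries use a two-phase scheme: a cKDTree over the pelvis
vertices provides a conservative broad phase, and exact point-triangle
distances (signed by the local face normal, so interpenetration counts
as contact) decide the narrow phase.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import trimesh
from scipy.spatial import cKDTree

from .frames import Frame, SphereFit, _axis_angle_matrix

__all__ = [
    "Pose",
    "ROMResult",
    "CollisionConfig",
    "ContactChecker",
    "pose_femur",
    "pose_rotation",
    "detect_contact",
    "max_flexion",
    "max_internal_rotation_at_flexion",
    "sweep_limit",
    "check_exclusion",
    "classify_region",
]


@dataclass(frozen=True)
class Pose:
    """Hip pose in degrees (adduction/abduction fixed at zero)."""

    flexion: float = 0.0
    internal_rotation: float = 0.0

    def __post_init__(self) -> None:
        if not (np.isfinite(self.flexion) and np.isfinite(self.internal_rotation)):
            raise ValueError("pose angles must be finite")
        if not (0.0 <= self.flexion <= 150.0):
            raise ValueError("flexion out of [0, 150] deg")
        if not (-90.0 <= self.internal_rotation <= 90.0):
            raise ValueError("internal rotation out of [-90, 90] deg")


@dataclass(frozen=True)
class ROMResult:
    """A motion limit: angle (deg), impingement point and its region."""

    limit_angle: float
    contact_point: np.ndarray | None  # neutral-pose coordinates (mm)
    region: str  # "proximal" | "distal" | "none"
    reached_cap: bool

    def __post_init__(self) -> None:
        if (self.contact_point is None) == (not self.reached_cap):
            raise ValueError("contact point must be present iff the cap was not reached")


@dataclass(frozen=True)
class CollisionConfig:
    contact_tolerance: float = 0.1    # mm
    angular_resolution: float = 0.1   # deg, bisection stop
    flexion_cap: float = 150.0        # deg
    rotation_cap: float = 90.0        # deg

    def __post_init__(self) -> None:
        if min(self.contact_tolerance, self.angular_resolution,
               self.flexion_cap, self.rotation_cap) <= 0:
            raise ValueError("collision parameters must be positive")
        if self.angular_resolution > 0.1:
            raise ValueError("angular_resolution must be <= 0.1 deg")


def pose_rotation(pelvic_frame: Frame, femoral_frame: Frame, pose: Pose) -> np.ndarray:
    """Rotation matrix of the pose about the head center.

    Flexion rotates about the pelvic medio-lateral (+x lateral) axis so
    that the distal femur swings anteriorly; internal rotation then
    rotates about the *flexed* femoral long axis with the sign that
    swings the foot laterally (right-side convention).
    """
    r_flex = _axis_angle_matrix(pelvic_frame.x, np.radians(pose.flexion))
    distal = -femoral_frame.z
    axis = r_flex @ distal
    r_ir = _axis_angle_matrix(axis, -np.radians(pose.internal_rotation))
    return r_ir @ r_flex


def pose_femur(femur_mesh, pelvic_frame: Frame, femoral_frame: Frame,
               pose: Pose) -> trimesh.Trimesh:
    """Femur mesh transformed to ``pose`` (rotation about the head center)."""
    rot = pose_rotation(pelvic_frame, femoral_frame, pose)
    c = femoral_frame.origin
    v = (np.asarray(femur_mesh.vertices) - c) @ rot.T + c
    return trimesh.Trimesh(vertices=v, faces=femur_mesh.faces, process=False)


class ContactChecker:
    """Reusable collision oracle for one pelvis/femur pair.

    The pelvis is static; the femur rotates about ``center``.  Femur
    query points are pre-filtered to the spherical band (around the
    rotation center) that the pelvis occupies — exact under pure
    rotation, since vertex radii are invariant.
    """

    def __init__(self, pelvis_mesh, femur_mesh, center, config: CollisionConfig,
                 check_watertight: bool = True):
        self.config = config
        self.center = np.asarray(center, dtype=float)
        if check_watertight and not (pelvis_mesh.is_watertight and femur_mesh.is_watertight):
            warnings.warn("non-watertight input mesh: contact detection runs in "
                          "distance-only mode; interpenetration may be missed")

        pv = np.asarray(pelvis_mesh.vertices)
        self._pelvis_vtx_tree = cKDTree(pv)
        tris = pv[np.asarray(pelvis_mesh.faces)]
        self._tris = tris
        tri_centroids = tris.mean(axis=1)
        self._tri_tree = cKDTree(tri_centroids)
        # max distance from a triangle centroid to its vertices: broad-phase pad
        self._pad = float(np.linalg.norm(tris - tri_centroids[:, None, :],
                                         axis=2).max())
        self._face_normals = np.asarray(pelvis_mesh.face_normals)

        # exact radial band of the pelvis surface around the rotation center:
        # femur vertex radii are rotation-invariant, so only vertices inside
        # the band can ever touch the pelvis
        center_cp = trimesh.triangles.closest_point(
            tris, np.tile(self.center, (len(tris), 1)))
        surf_r = np.linalg.norm(center_cp - self.center, axis=1)
        vtx_r = np.linalg.norm(tris - self.center, axis=2)
        fv = np.asarray(femur_mesh.vertices)
        fr = np.linalg.norm(fv - self.center, axis=1)
        margin = config.contact_tolerance + 0.05
        sel = (fr >= surf_r.min() - margin) & (fr <= vtx_r.max() + margin)
        self._q = fv[sel]
        if len(self._q) == 0:
            raise ValueError("femur has no vertices within reach of the pelvis")
        # Lipschitz bound of the distance field under rotation (mm per radian)
        self.max_query_radius = float(np.linalg.norm(self._q - self.center,
                                                     axis=1).max())

    def signed_distance(self, rot: np.ndarray):
        """Minimum signed femur-vertex-to-pelvis-surface distance under
        rotation ``rot`` about the center, with the closest-pair witness
        midpoint in *posed* coordinates.  Negative = interpenetration."""
        w = (self._q - self.center) @ rot.T + self.center
        d_vv, _ = self._pelvis_vtx_tree.query(w, k=1)
        tol = self.config.contact_tolerance
        cutoff = tol + self._pad + 0.2
        cand = np.nonzero(d_vv <= cutoff)[0]
        if len(cand) == 0:
            i = int(np.argmin(d_vv))
            return float(d_vv[i] - self._pad), None  # conservative lower bound
        pts = w[cand]
        k = min(32, len(self._tris))
        _, tri_idx = self._tri_tree.query(pts, k=k,
                                          distance_upper_bound=cutoff + self._pad)
        tri_idx = np.atleast_2d(tri_idx)
        valid = tri_idx < len(self._tris)
        if not valid.any():
            i = int(np.argmin(d_vv))
            return float(d_vv[i] - self._pad), None
        flat_pts = np.repeat(pts, k, axis=0)[valid.ravel()]
        flat_tri = tri_idx.ravel()[valid.ravel()]
        cp = trimesh.triangles.closest_point(self._tris[flat_tri], flat_pts)
        d_flat = np.linalg.norm(cp - flat_pts, axis=1)
        dists = np.full((len(pts), k), np.inf)
        dists[valid] = d_flat
        row_best = dists.argmin(axis=1)
        rows = np.nonzero(np.isfinite(dists[np.arange(len(pts)), row_best]))[0]
        flat_of = np.full((len(pts), k), -1, dtype=np.int64)
        flat_of[valid] = np.arange(len(flat_tri))
        best_pair = flat_of[rows, row_best[rows]]
        d_best = d_flat[best_pair]
        n = self._face_normals[flat_tri[best_pair]]
        inside = np.einsum("ij,ij->i", flat_pts[best_pair] - cp[best_pair], n) < 0
        signed = np.where(inside, -d_best, d_best)
        j = int(np.argmin(signed))
        mid = 0.5 * (flat_pts[best_pair[j]] + cp[best_pair[j]])
        return float(signed[j]), mid

    def in_contact(self, rot: np.ndarray):
        """(bool, witness point in neutral femoral coordinates or None)."""
        d, mid = self.signed_distance(rot)
        if d > self.config.contact_tolerance or mid is None:
            return False, None
        neutral = (mid - self.center) @ rot + self.center
        return True, neutral


def detect_contact(pelvis_mesh, posed_femur_mesh,
                   config: CollisionConfig | None = None):
    """One-shot contact test between a pelvis and an already-posed femur.

    Returns ``(in_contact, witness_point | None)`` where the witness is
    the midpoint of the closest surface pair (the intersection locus
    when interpenetrating).  Non-watertight inputs trigger a warning and
    a distance-only check.
    """
    config = config or CollisionConfig()
    checker = ContactChecker.__new__(ContactChecker)
    checker.config = config
    checker.center = np.zeros(3)
    if not (pelvis_mesh.is_watertight and posed_femur_mesh.is_watertight):
        warnings.warn("non-watertight input mesh: contact detection runs in "
                      "distance-only mode; interpenetration may be missed")
    pv = np.asarray(pelvis_mesh.vertices)
    checker._pelvis_vtx_tree = cKDTree(pv)
    tris = pv[np.asarray(pelvis_mesh.faces)]
    checker._tris = tris
    cent = tris.mean(axis=1)
    checker._tri_tree = cKDTree(cent)
    checker._pad = float(np.linalg.norm(tris - cent[:, None, :], axis=2).max())
    checker._face_normals = np.asarray(pelvis_mesh.face_normals)
    checker._q = np.asarray(posed_femur_mesh.vertices)
    d, mid = checker.signed_distance(np.eye(3))
    if d > config.contact_tolerance or mid is None:
        return False, None
    return True, mid


def _search_limit(checker: ContactChecker, pelvic_frame: Frame,
                  femoral_frame: Frame, pose_of, cap: float,
                  config: CollisionConfig) -> ROMResult:
    """Bisection for the largest contact-free angle in [0, cap]."""
    tol = config.contact_tolerance
    d0, _ = checker.signed_distance(
        pose_rotation(pelvic_frame, femoral_frame, pose_of(0.0)))
    if d0 <= tol:
        raise ValueError("contact already present at the search start pose "
                         "(malformed case)")
    # conservative advancement: the signed distance changes by at most
    # max_query_radius mm per radian of rotation, so steps sized by the
    # current clearance can never tunnel through a thin structure
    lip = checker.max_query_radius
    a, d = 0.0, d0
    lo = hi = None
    while a < cap:
        step = max(config.angular_resolution,
                   np.degrees(0.95 * (d - tol) / lip))
        a_next = min(a + step, cap)
        d_next, _ = checker.signed_distance(
            pose_rotation(pelvic_frame, femoral_frame, pose_of(a_next)))
        if d_next <= tol:
            lo, hi = a, a_next
            break
        a, d = a_next, d_next
    if lo is None:
        return ROMResult(limit_angle=cap, contact_point=None, region="none",
                         reached_cap=True)
    while hi - lo > config.angular_resolution:
        mid = 0.5 * (lo + hi)
        hit, _ = checker.in_contact(
            pose_rotation(pelvic_frame, femoral_frame, pose_of(mid)))
        if hit:
            hi = mid
        else:
            lo = mid
    # validated contact one resolution step past the limit
    _, witness = checker.in_contact(
        pose_rotation(pelvic_frame, femoral_frame, pose_of(hi)))
    return ROMResult(limit_angle=lo, contact_point=witness, region="unassigned",
                     reached_cap=False)


def max_flexion(pelvis_mesh, femur_mesh, pelvic_frame: Frame,
                femoral_frame: Frame, config: CollisionConfig | None = None,
                checker: ContactChecker | None = None) -> ROMResult:
    """Largest contact-free flexion (internal rotation 0)."""
    config = config or CollisionConfig()
    checker = checker or ContactChecker(pelvis_mesh, femur_mesh,
                                        femoral_frame.origin, config)
    return _search_limit(checker, pelvic_frame, femoral_frame,
                         lambda a: Pose(flexion=a), config.flexion_cap, config)


def max_internal_rotation_at_flexion(pelvis_mesh, femur_mesh,
                                     pelvic_frame: Frame, femoral_frame: Frame,
                                     flexion: float = 90.0,
                                     config: CollisionConfig | None = None,
                                     checker: ContactChecker | None = None) -> ROMResult:
    """Largest contact-free internal rotation at fixed ``flexion``."""
    config = config or CollisionConfig()
    checker = checker or ContactChecker(pelvis_mesh, femur_mesh,
                                        femoral_frame.origin, config)
    return _search_limit(
        checker, pelvic_frame, femoral_frame,
        lambda a: Pose(flexion=flexion, internal_rotation=a),
        config.rotation_cap, config)


def sweep_limit(checker: ContactChecker, pelvic_frame: Frame,
                femoral_frame: Frame, mode: str, step: float = 0.05,
                flexion: float = 90.0,
                config: CollisionConfig | None = None) -> float:
    """Exhaustive ascending-sweep limit (validation oracle for the
    bisection search): the angle one step below the first contact."""
    config = config or checker.config
    cap = config.flexion_cap if mode == "flexion" else config.rotation_cap
    if mode == "flexion":
        pose_of = lambda a: Pose(flexion=a)
    elif mode == "internal_rotation":
        pose_of = lambda a: Pose(flexion=flexion, internal_rotation=a)
    else:
        raise ValueError(f"unknown sweep mode {mode!r}")
    angle = 0.0
    while angle <= cap:
        hit, _ = checker.in_contact(
            pose_rotation(pelvic_frame, femoral_frame, pose_of(angle)))
        if hit:
            return max(0.0, angle - step)
        angle += step
    return cap


def check_exclusion(flexion_result: ROMResult) -> bool:
    """True when the case must be excluded: impingement appears below
    90 deg of flexion (and the flexion cap was not the stop)."""
    return (not flexion_result.reached_cap) and flexion_result.limit_angle < 90.0


def classify_region(contact_point, head_fit: SphereFit, neck_axis,
                    neck_radius: float) -> str:
    """Proximal/distal split of the head-neck junction.

    The boundary is the plane perpendicular to the neck axis through the
    circle where the fitted head sphere blends into the neck (axial
    offset ``sqrt(R^2 - rn^2)`` from the head center).  Contacts on the
    head side are proximal; ties go proximal.
    """
    p = np.asarray(contact_point, dtype=float)
    axis = np.asarray(neck_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    rn = min(neck_radius, head_fit.radius - 1e-9)
    boundary = float(np.sqrt(head_fit.radius**2 - rn**2))
    axial = (p - head_fit.center) @ axis
    return "proximal" if axial <= boundary else "distal"
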