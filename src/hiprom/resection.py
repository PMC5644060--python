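"""Virtual osteochondroplasty of the femoral head-neck junction.

Two standardized resection models are carved around the impingement
point, mirroring burr recontouring at arthroscopy:

* **slight**: 4 mm deep, 8 mm wide;
* **sufficient**: 8 mm deep, 16 mm wide;

both 15 mm long along the femoral long axis.  The removed solid is a
half-ellipsoidal trough oriented by the local surface frame (depth along
the inward surface normal, width circumferential, length axial) whose
edge is tapered smoothly — the dimensions fix the trough's semi-axes,
the shape is the smoothest solid honoring them.

The carve is applied as a height-field vertex displacement along the
inward normal direction, clipped to the trough's depth profile.  This
preserves the mesh topology, so the post-operative femur is watertight
by construction, material is only ever removed, and every vertex outside
the modified region is bit-identical to the pre-operative mesh.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import trimesh

from .frames import Frame

__all__ = [
    "RESECTION_MODELS",
    "ResectionSpec",
    "ResectionOutcome",
    "make_resection_spec",
    "apply_resection",
    "compute_improvement",
    "jitter_center",
]

# model -> (depth, width, length) in mm
RESECTION_MODELS = {
    "slight": (4.0, 8.0, 15.0),
    "sufficient": (8.0, 16.0, 15.0),
}


@dataclass(frozen=True)
class ResectionSpec:
    """A placed, oriented resection trough."""

    model: str
    depth: float
    width: float
    length: float
    center: np.ndarray        # on the femoral surface (mm)
    normal: np.ndarray        # outward surface normal at the center
    width_dir: np.ndarray     # circumferential (horizontal-slice) direction
    length_dir: np.ndarray    # along the femoral long axis

    def __post_init__(self) -> None:
        expected = RESECTION_MODELS.get(self.model)
        if expected is None:
            raise ValueError(f"unknown resection model {self.model!r}")
        if (self.depth, self.width, self.length) != expected:
            raise ValueError(f"{self.model} resection must have "
                             f"(depth, width, length) = {expected}")
        for name in ("center", "normal", "width_dir", "length_dir"):
            object.__setattr__(self, name,
                               np.asarray(getattr(self, name), dtype=float))

    def as_dict(self) -> dict:
        return {"model": self.model, "depth": self.depth, "width": self.width,
                "length": self.length, "center": self.center.tolist(),
                "normal": self.normal.tolist(),
                "width_dir": self.width_dir.tolist(),
                "length_dir": self.length_dir.tolist()}


@dataclass(frozen=True)
class ResectionOutcome:
    post_mesh: trimesh.Trimesh
    removed_volume: float          # mm^3
    modified_region_radius: float  # mm; surface beyond this is untouched

    def __post_init__(self) -> None:
        if self.removed_volume < -1e-6:
            raise ValueError("removed volume must be non-negative")


def _nearest_surface_frame(femur_mesh, point, normal_radius: float = 4.0):
    """(surface point, outward normal, distance) near ``point``.

    The normal is the area-weighted average of face normals within
    ``normal_radius`` mm of the surface point — a burr is oriented
    against the smoothed local surface, not a single facet, and the
    averaging keeps the trough orientation stable under small
    re-placements of its center.
    """
    tris = np.asarray(femur_mesh.vertices)[np.asarray(femur_mesh.faces)]
    p = np.asarray(point, dtype=float)
    cp = trimesh.triangles.closest_point(tris, np.tile(p, (len(tris), 1)))
    d = np.linalg.norm(cp - p, axis=1)
    i = int(np.argmin(d))
    centroids = tris.mean(axis=1)
    near = np.linalg.norm(centroids - cp[i], axis=1) <= normal_radius
    weights = np.asarray(femur_mesh.area_faces)[near]
    normal = (np.asarray(femur_mesh.face_normals)[near] * weights[:, None]).sum(axis=0)
    nn = np.linalg.norm(normal)
    if nn < 1e-9:  # pathological cancellation: fall back to the facet normal
        return cp[i], np.asarray(femur_mesh.face_normals)[i], float(d[i])
    return cp[i], normal / nn, float(d[i])


def make_resection_spec(model: str, contact_point, femoral_frame: Frame,
                        femur_mesh) -> ResectionSpec:
    """Place a standardized resection at the impingement point.

    The center is the surface point nearest the contact point (which
    must lie within 1 mm of the surface); depth runs along the inward
    surface normal, length along the femoral long axis projected onto
    the tangent plane, width along their cross product (the
    circumferential, horizontal-slice direction).
    """
    if model not in RESECTION_MODELS:
        raise ValueError(f"unknown resection model {model!r}")
    depth, width, length = RESECTION_MODELS[model]
    center, normal, dist = _nearest_surface_frame(femur_mesh, contact_point)
    if dist > 1.0:
        raise ValueError(f"contact point is {dist:.2f} mm from the femoral "
                         "surface (limit 1 mm)")
    distal = -femoral_frame.z
    l_dir = distal - (distal @ normal) * normal
    nl = np.linalg.norm(l_dir)
    if nl < 1e-6:
        raise ValueError("femoral long axis is normal to the surface here")
    l_dir = l_dir / nl
    w_dir = np.cross(normal, l_dir)
    return ResectionSpec(model=model, depth=depth, width=width, length=length,
                         center=center, normal=normal, width_dir=w_dir,
                         length_dir=l_dir)


def apply_resection(femur_mesh, spec: ResectionSpec,
                    smooth_margin: float = 2.0) -> ResectionOutcome:
    """Carve the trough of ``spec`` out of the femur.

    Vertices whose footprint coordinates fall inside the elliptical
    outline are displaced along the inward normal down to the trough
    surface; the cut tapers smoothly to zero at the outline (the "edge
    trimmed smoothly" step), so the removed solid is contained in the
    half-ellipsoid with semi-axes (width/2, length/2, depth).
    """
    if not femur_mesh.is_watertight:
        raise ValueError("resection requires a watertight femur mesh")
    v = np.asarray(femur_mesh.vertices).copy()
    e = v - spec.center
    h = e @ spec.normal
    aw = e @ spec.width_dir
    al = e @ spec.length_dir
    q = (aw / (spec.width / 2.0)) ** 2 + (al / (spec.length / 2.0)) ** 2

    inside = (q < 1.0) & (h > -spec.depth) & (h < spec.depth)
    if inside.any():
        h_trough = -spec.depth * np.sqrt(1.0 - q[inside])
        # column removed at each vertex: from the trough surface up to the
        # original surface, but never above the tangent plane, so the
        # removed set stays inside the half-ellipsoid (a bump standing
        # above the plane is lowered by the full column depth instead)
        cut = np.maximum(0.0, np.minimum(h[inside], 0.0) - h_trough)
        # smooth edge taper over the outer 30% of the footprint
        t = np.clip((1.0 - q[inside]) / 0.3, 0.0, 1.0)
        cut *= t * t * (3 - 2 * t)
        v[inside] -= cut[:, None] * spec.normal

    post = trimesh.Trimesh(vertices=v, faces=femur_mesh.faces, process=False)
    removed = float(femur_mesh.volume - post.volume)
    radius = float(np.sqrt((spec.width / 2) ** 2 + (spec.length / 2) ** 2
                           + spec.depth ** 2) + smooth_margin)
    return ResectionOutcome(post_mesh=post, removed_volume=max(0.0, removed),
                            modified_region_radius=radius)


def compute_improvement(pre_angle: float, post_angle: float) -> float:
    """Improvement in a motion limit: post minus pre (degrees)."""
    if not (np.isfinite(pre_angle) and np.isfinite(post_angle)):
        raise ValueError("angles must be finite")
    return float(post_angle - pre_angle)


def jitter_center(contact_point, femur_mesh, sigma: float, rng) -> np.ndarray:
    """Perturb a resection center tangentially by a Gaussian of scale
    ``sigma`` mm and re-project onto the surface (models the
    investigator's placement variability for repeatability studies)."""
    center, normal, _ = _nearest_surface_frame(femur_mesh, contact_point)
    g = rng.normal(0.0, sigma, size=3)
    tangential = g - (g @ normal) * normal
    moved, _, _ = _nearest_surface_frame(femur_mesh, center + tangential)
    return moved
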