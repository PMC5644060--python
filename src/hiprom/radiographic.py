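"""Simulated radiographic measurements and diagnostic grouping.

Two plain-film angles drive the study design:

* the **alpha angle** (cam severity): on a lateral projection of the
  head-neck region, the angle at the femoral head center between the
  neck axis and the first point where the bone contour departs the
  circle fitted to the head;
* the **lateral center-edge (CE) angle** (acetabular coverage): on an
  antero-posterior projection, the angle between the longitudinal
  (superior) axis and the line from the head center to the lateral
  acetabular rim edge.

Both are computed directly from the 3-D surface meshes using
orthographic projections, which is the reproducible analogue of the
standardized plain-radiograph measurements.  ``classify_hip`` applies
the study's diagnostic thresholds: cam-type FAI is alpha >= 55 deg with
CE >= 25 deg, borderline dysplasia (DDH) is 20 <= CE < 25 deg, pincer
over-coverage (CE > 40 deg) and true dysplasia (CE < 20 deg) are
excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np

from .frames import Frame, SphereFit

__all__ = [
    "GroupLabel",
    "RadiographicMeasures",
    "estimate_neck_axis",
    "measure_alpha",
    "measure_ce",
    "classify_hip",
]


class GroupLabel(str, Enum):
    """Diagnostic group of one hip (exactly one label per hip)."""

    cam_FAI = "cam_FAI"
    DDH_with_cam = "DDH_with_cam"
    DDH_without_cam = "DDH_without_cam"
    excluded_pincer = "excluded_pincer"
    excluded_dysplasia = "excluded_dysplasia"
    excluded_other = "excluded_other"


STUDY_GROUPS = (GroupLabel.cam_FAI, GroupLabel.DDH_with_cam, GroupLabel.DDH_without_cam)


@dataclass(frozen=True)
class RadiographicMeasures:
    alpha_angle: float
    ce_angle: float
    projection_metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0 < self.alpha_angle < 180):
            raise ValueError(f"alpha angle {self.alpha_angle} out of (0, 180)")
        if not (-30 < self.ce_angle < 60):
            raise ValueError(f"CE angle {self.ce_angle} out of (-30, 60)")


def estimate_neck_axis(femur_mesh, head_fit: SphereFit,
                       band: tuple[float, float] = (1.35, 1.85)):
    """Estimate the femoral neck axis from the mesh.

    Vertices in a spherical shell ``band * head_radius`` around the head
    center lie on the neck cylinder (beyond the cam zone, before the
    shaft bend); the axis is the direction from the head center to their
    centroid, and the neck radius the minimum distance of those vertices
    from the axis.

    Returns ``(axis_unit_vector, neck_radius_estimate)``.
    """
    c = head_fit.center
    r = head_fit.radius
    v = np.asarray(femur_mesh.vertices) - c
    d = np.linalg.norm(v, axis=1)
    sel = (d >= band[0] * r) & (d <= band[1] * r)
    if sel.sum() < 10:
        raise ValueError("too few neck vertices to estimate the neck axis")
    axis = v[sel].mean(axis=0)
    axis = axis / np.linalg.norm(axis)
    axial = v[sel] @ axis
    radial = np.linalg.norm(v[sel] - np.outer(axial, axis), axis=1)
    return axis, float(np.median(np.sort(radial)[: max(8, sel.sum() // 10)]))


def measure_alpha(femur_mesh, femoral_frame: Frame, head_fit: SphereFit,
                  departure_threshold: float = 0.5,
                  max_distance_factor: float = 1.6,
                  n_sectors: int = 36,
                  detailed: bool = False):
    """Alpha angle from the head-neck contour (degrees).

    For each circumferential sector around the neck axis the radial
    profile ``r(theta)`` (distance from the fitted head center vs polar
    angle from the neck axis) is scanned for the largest angle at which
    the contour crosses outside the fitted circle by more than
    ``departure_threshold`` mm; the alpha angle is the maximum over
    sectors (the lateral projection shows whichever sector carries the
    cam).  For an ideally spherical head with a coaxial cylindrical
    neck of radius ``rn`` this returns ``arcsin(rn / (R + thr))``, the
    cam-free geometric minimum.

    Set ``detailed=True`` to also get the departure flag and the sector
    profile maxima.
    """
    c = head_fit.center
    radius = head_fit.radius
    axis, _ = estimate_neck_axis(femur_mesh, head_fit)

    v = np.asarray(femur_mesh.vertices) - c
    d = np.linalg.norm(v, axis=1)
    sel = (d > 0.2 * radius) & (d <= max_distance_factor * radius)
    e = v[sel]
    dist = d[sel]

    # circumferential basis: phi measured from the anterior direction
    anterior = femoral_frame.y
    u = anterior - (anterior @ axis) * axis
    u = u / np.linalg.norm(u)
    w = np.cross(axis, u)

    axial = e @ axis
    theta = np.degrees(np.arctan2(np.linalg.norm(e - np.outer(axial, axis), axis=1),
                                  axial))
    phi = np.degrees(np.arctan2(e @ w, e @ u))
    exceed = dist - (radius + departure_threshold)

    sector = ((phi + 180.0) / (360.0 / n_sectors)).astype(int) % n_sectors
    best = -np.inf
    departed = False
    for s in range(n_sectors):
        m = sector == s
        if m.sum() < 3:
            continue
        order = np.argsort(theta[m])
        th = theta[m][order]
        ex = exceed[m][order]
        above = ex > 0
        if not above.any():
            continue
        departed = True
        i = np.nonzero(above)[0][-1]  # highest-theta point outside the circle
        if i + 1 < len(th) and ex[i + 1] < 0 and th[i + 1] > th[i]:
            # interpolate the crossing toward the next (inside) point
            t_cross = th[i] + (th[i + 1] - th[i]) * ex[i] / (ex[i] - ex[i + 1])
        else:
            t_cross = th[i]
        best = max(best, t_cross)

    if not departed:
        # contour never leaves the circle in the scanned region: report the
        # cam-free geometric minimum for this head/neck pairing
        _, rn = estimate_neck_axis(femur_mesh, head_fit)
        best = np.degrees(np.arcsin(min(1.0, rn / (radius + departure_threshold))))

    if detailed:
        return float(best), {"departed": departed, "neck_axis": axis}
    return float(best)


def measure_ce(pelvis_mesh, head_center, pelvic_frame: Frame | None = None,
               coronal_slab_halfwidth: float = 6.0) -> float:
    """Lateral center-edge angle on a simulated A-P projection (degrees).

    The pelvis is projected along the anterior axis of ``pelvic_frame``
    (the canonical axes when omitted, so the measurement moves with the
    model under rigid motion); among rim points near the coronal plane
    through the head center (within ``coronal_slab_halfwidth`` mm, which
    keeps the anterior and posterior walls out of the sourcil
    measurement) the CE angle is the largest angle from the superior
    axis to a head-center-to-rim line on the lateral side.
    """
    c = np.asarray(head_center, dtype=float)
    v = np.asarray(pelvis_mesh.vertices) - c
    if pelvic_frame is not None:
        v = v @ pelvic_frame.axes.T
    lateral = v[:, 0]
    anterior = v[:, 1]
    superior = v[:, 2]
    sel = (lateral > 0) & (np.abs(anterior) <= coronal_slab_halfwidth)
    if not sel.any():
        raise ValueError("no acetabular rim lateral to the head center")
    angles = np.degrees(np.arctan2(lateral[sel], superior[sel]))
    return float(angles.max())


def classify_hip(alpha: float, ce: float) -> GroupLabel:
    """Assign the diagnostic group from the two angles.

    Thresholds (all in degrees): pincer over-coverage CE > 40 and true
    dysplasia CE < 20 are excluded before any cam assignment; cam-type
    FAI needs alpha >= 55 and CE >= 25; borderline DDH is 20 <= CE < 25,
    split by the cam criterion alpha >= 55.  Total function: every
    finite pair receives exactly one label.
    """
    if not (np.isfinite(alpha) and np.isfinite(ce)):
        raise ValueError("classify_hip requires finite angles")
    if ce > 40:
        return GroupLabel.excluded_pincer
    if ce < 20:
        return GroupLabel.excluded_dysplasia
    if ce >= 25:
        return GroupLabel.cam_FAI if alpha >= 55 else GroupLabel.excluded_other
    return GroupLabel.DDH_with_cam if alpha >= 55 else GroupLabel.DDH_without_cam
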