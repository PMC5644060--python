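"""Anatomical reference frames and the hip joint center.

The simulation protocol fixes two frames before any motion is applied:

* a **pelvic frame** built from the anterior pelvic plane (both anterior
  superior iliac spines and the pubic symphysis), taken as vertical for a
  supine functional position, with ``+x`` lateral toward the simulated
  side, ``+y`` anterior and ``+z`` superior;
* a **femoral frame** whose origin is the femoral head center (a
  least-squares sphere fit to reference points on the head surface) and
  whose long axis runs from the head center to the midpoint between the
  medial and lateral epicondyles.

All coordinates are millimetres; all frames are right-handed orthonormal
triads stored row-wise (rows = frame axes expressed in world coordinates).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

__all__ = [
    "Frame",
    "SphereFit",
    "fit_sphere",
    "build_pelvic_frame",
    "build_femoral_frame",
]

_ORTHO_TOL = 1e-9


@dataclass(frozen=True)
class Frame:
    """A right-handed orthonormal reference frame.

    Attributes
    ----------
    origin : (3,) ndarray
        Frame origin in world coordinates (mm).
    axes : (3, 3) ndarray
        Rows are the frame's x, y, z axes expressed in world coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        origin = np.asarray(self.origin, dtype=float)
        axes = np.asarray(self.axes, dtype=float)
        if origin.shape != (3,) or axes.shape != (3, 3):
            raise ValueError("Frame needs a 3-vector origin and 3x3 axes")
        if not np.all(np.isfinite(origin)) or not np.all(np.isfinite(axes)):
            raise ValueError("Frame contains non-finite values")
        if np.abs(axes @ axes.T - np.eye(3)).max() > 1e-8:
            raise ValueError("Frame axes are not orthonormal")
        if np.linalg.det(axes) < 0:
            raise ValueError("Frame is left-handed (det < 0)")
        object.__setattr__(self, "origin", origin)
        object.__setattr__(self, "axes", axes)

    @property
    def x(self) -> np.ndarray:
        return self.axes[0]

    @property
    def y(self) -> np.ndarray:
        return self.axes[1]

    @property
    def z(self) -> np.ndarray:
        return self.axes[2]

    def to_json(self, path: str | Path) -> None:
        payload = {"origin": self.origin.tolist(), "axes": self.axes.tolist()}
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "Frame":
        payload = json.loads(Path(path).read_text())
        return cls(np.asarray(payload["origin"]), np.asarray(payload["axes"]))


@dataclass(frozen=True)
class SphereFit:
    """Least-squares sphere: center (mm), radius (mm) and RMS residual (mm)."""

    center: np.ndarray
    radius: float
    rms_residual: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "center", np.asarray(self.center, dtype=float))
        if self.radius <= 0:
            raise ValueError("sphere radius must be positive")
        if self.rms_residual < 0:
            raise ValueError("rms residual must be non-negative")


def fit_sphere(points: np.ndarray) -> SphereFit:
    """Fit a sphere to ``points`` by linear least squares.

    Uses the algebraic formulation ``|p|^2 = 2 c.p + (r^2 - |c|^2)``,
    which is exact when the points lie exactly on a sphere.

    Parameters
    ----------
    points : (n, 3) array_like
        At least four non-coplanar points (mm).

    Raises
    ------
    ValueError
        For fewer than four points or a (near-)coplanar configuration.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 4:
        raise ValueError("fit_sphere needs at least 4 three-dimensional points")
    if not np.all(np.isfinite(pts)):
        raise ValueError("fit_sphere: non-finite input point")

    A = np.hstack([2.0 * pts, np.ones((len(pts), 1))])
    b = np.einsum("ij,ij->i", pts, pts)
    # Coplanar points make the 4-column system rank deficient.
    if np.linalg.matrix_rank(A, tol=1e-8 * max(1.0, np.abs(pts).max())) < 4:
        raise ValueError("fit_sphere: points are coplanar or degenerate")
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    r2 = sol[3] + center @ center
    if r2 <= 0:
        raise ValueError("fit_sphere: degenerate solution (non-positive radius)")
    radius = float(np.sqrt(r2))
    residuals = np.linalg.norm(pts - center, axis=1) - radius
    return SphereFit(center=center, radius=radius,
                     rms_residual=float(np.sqrt(np.mean(residuals**2))))


def _unit(v: np.ndarray, what: str) -> np.ndarray:
    n = np.linalg.norm(v)
    if n < 1e-9:
        raise ValueError(f"degenerate geometry: {what} has zero length")
    return v / n


def build_pelvic_frame(landmarks, side: str = "right",
                       sagittal_tilt_deg: float = 0.0) -> Frame:
    """Pelvic frame from the anterior pelvic plane.

    The plane through both ASIS points and the pubic symphysis is taken
    as vertical (supine functional position); an optional sagittal tilt
    about the medio-lateral axis models pelvic tilt.

    ``+x`` points laterally toward the simulated side, ``+z`` superiorly
    (from symphysis toward the ASIS midpoint, orthogonalized), and
    ``+y = z x x`` anteriorly.  Origin is the ASIS midpoint.
    """
    asis_r = np.asarray(landmarks.ASIS_right, dtype=float)
    asis_l = np.asarray(landmarks.ASIS_left, dtype=float)
    symph = np.asarray(landmarks.pubic_symphysis, dtype=float)
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")

    inter_asis = asis_l - asis_r
    x = _unit(inter_asis if side == "left" else -inter_asis, "inter-ASIS axis")
    mid_asis = 0.5 * (asis_r + asis_l)
    up = mid_asis - symph
    up_perp = up - (up @ x) * x
    z = _unit(up_perp, "symphysis-to-ASIS direction (collinear landmarks?)")
    y = np.cross(z, x)

    axes = np.vstack([x, y, z])
    if abs(sagittal_tilt_deg) > 0:
        t = np.radians(sagittal_tilt_deg)
        rot = _axis_angle_matrix(x, t)
        axes = np.vstack([x, rot @ y, rot @ z])
    return Frame(origin=mid_asis, axes=axes)


def build_femoral_frame(head_center, medial_epicondyle, lateral_epicondyle) -> Frame:
    """Femoral frame: origin at the head center, long axis toward the knee.

    The mechanical long axis runs from the head center to the midpoint
    between the epicondyles; the frame's ``z`` points proximally (back up
    that axis), ``x`` along the medial-to-lateral epicondylar direction
    orthogonalized against it, and ``y = z x x``.
    """
    c = np.asarray(head_center, dtype=float)
    med = np.asarray(medial_epicondyle, dtype=float)
    lat = np.asarray(lateral_epicondyle, dtype=float)
    mid = 0.5 * (med + lat)
    distal = _unit(mid - c, "head-center-to-knee axis")
    z = -distal
    epi = lat - med
    x = epi - (epi @ z) * z
    x = _unit(x, "epicondylar axis (epicondyles coincident or on the long axis)")
    y = np.cross(z, x)
    return Frame(origin=c, axes=np.vstack([x, y, z]))


def _axis_angle_matrix(axis: np.ndarray, angle_rad: float) -> np.ndarray:
    """Rotation matrix about a unit ``axis`` by ``angle_rad`` (Rodrigues)."""
    a = np.asarray(axis, dtype=float)
    a = a / np.linalg.norm(a)
    K = np.array([[0, -a[2], a[1]], [a[2], 0, -a[0]], [-a[1], a[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)
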