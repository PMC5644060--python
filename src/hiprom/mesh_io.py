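"""Mesh and landmark I/O with validation.

Real segmented bones can replace the synthetic generator anywhere in the
pipeline: meshes are read from STL (binary or ASCII) or PLY with
explicit units (STL files carry none, so the caller must declare them)
and an explicit anatomical side.  The simulation core uses one set of
sign conventions — a canonical right hip with ``+x`` lateral — so
left-side meshes are mirrored across ``x = 0`` at import and the flag
recorded.  Landmarks travel either as a JSON sidecar or as comment lines
embedded in an ASCII PLY header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = ["MeshDocument", "read_mesh", "write_mesh"]

log = logging.getLogger(__name__)

_UNIT_SCALE_TO_MM = {"mm": 1.0, "cm": 10.0, "m": 1000.0}
_FORMATS = {".stl": "stl", ".ply": "ply"}


@dataclass
class MeshDocument:
    """A validated triangle mesh in millimetres, canonical right side."""

    mesh: trimesh.Trimesh
    units: str = "mm"
    side: str = "right"
    source: str = "<memory>"
    mirrored: bool = False
    landmarks: dict = field(default_factory=dict)
    dropped_degenerate_faces: int = 0


def _mirror_x(mesh: trimesh.Trimesh) -> trimesh.Trimesh:
    v = np.asarray(mesh.vertices).copy()
    v[:, 0] *= -1.0
    f = np.asarray(mesh.faces)[:, ::-1]  # flip winding to keep outward normals
    return trimesh.Trimesh(vertices=v, faces=f, process=False)


def read_mesh(path: str | Path, declared_units: str = "mm",
              side: str = "right") -> MeshDocument:
    """Read and validate an STL or PLY mesh.

    Units are never inferred from file content; pass ``declared_units``
    ("mm", "cm" or "m" — scaled to mm).  ``side="left"`` mirrors the
    mesh to the canonical right-side frame.  Degenerate (zero-area)
    faces are dropped with a logged count; non-finite coordinates or an
    empty face list fail with diagnostics.
    """
    path = Path(path)
    if declared_units not in _UNIT_SCALE_TO_MM:
        raise ValueError(f"unknown units {declared_units!r}; use mm/cm/m")
    if side not in ("right", "left"):
        raise ValueError(f"side must be 'right' or 'left', got {side!r}")
    try:
        mesh = trimesh.load(path, file_type=_FORMATS.get(path.suffix.lower()),
                            process=False, force="mesh")
    except Exception as err:  # noqa: BLE001 - re-raise with the path named
        raise ValueError(f"unreadable mesh file {path}: {err}") from err

    v = np.asarray(mesh.vertices, dtype=float) * _UNIT_SCALE_TO_MM[declared_units]
    f = np.asarray(mesh.faces)
    if len(f) == 0:
        raise ValueError(f"{path}: mesh has zero faces")
    bad = ~np.isfinite(v).all(axis=1)
    if bad.any():
        raise ValueError(f"{path}: non-finite coordinates at vertex indices "
                         f"{np.nonzero(bad)[0][:10].tolist()}")

    tri = v[f]
    area2 = np.linalg.norm(np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0]),
                           axis=1)
    degenerate = (area2 <= 1e-12) | (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) \
        | (f[:, 0] == f[:, 2])
    n_dropped = int(degenerate.sum())
    if n_dropped:
        log.warning("%s: dropped %d degenerate faces", path, n_dropped)
        f = f[~degenerate]

    out = trimesh.Trimesh(vertices=v, faces=f, process=False)
    if path.suffix.lower() == ".stl":
        # STL stores three loose vertices per facet; weld exact duplicates
        # to recover the indexed (watertight) topology
        out.merge_vertices(merge_tex=True, merge_norm=True)
    mirrored = side == "left"
    if mirrored:
        out = _mirror_x(out)
    return MeshDocument(mesh=out, units="mm", side="right", source=str(path),
                        mirrored=mirrored, landmarks=_read_ply_landmarks(path),
                        dropped_degenerate_faces=n_dropped)


def _read_ply_landmarks(path: Path) -> dict:
    """Landmark comment lines from an ASCII PLY header, if any."""
    if path.suffix.lower() != ".ply":
        return {}
    landmarks: dict = {}
    try:
        with open(path, "rb") as fh:
            for raw in fh:
                line = raw.decode("ascii", errors="replace").strip()
                if line.startswith("comment landmark "):
                    parts = line.split()
                    if len(parts) == 6:
                        landmarks[parts[2]] = [float(x) for x in parts[3:6]]
                if line == "end_header":
                    break
    except OSError:
        return {}
    return landmarks


def write_mesh(doc: MeshDocument | trimesh.Trimesh, path: str | Path,
               file_format: str | None = None, landmarks: dict | None = None) -> Path:
    """Write a mesh as binary STL or PLY (deterministic bytes for a
    fixed input).

    For PLY, ``landmarks`` (name -> [x, y, z]) are embedded as ASCII
    header comments and recovered by :func:`read_mesh`; for STL they are
    written to a JSON sidecar ``<path>.landmarks.json``.
    """
    path = Path(path)
    mesh = doc.mesh if isinstance(doc, MeshDocument) else doc
    if landmarks is None and isinstance(doc, MeshDocument):
        landmarks = doc.landmarks or None
    fmt = file_format or _FORMATS.get(path.suffix.lower())
    if fmt not in ("stl", "ply"):
        raise ValueError(f"unsupported mesh format {fmt!r} (use stl or ply)")

    if fmt == "stl":
        path.write_bytes(trimesh.exchange.stl.export_stl(mesh))
        if landmarks:
            import json
            Path(f"{path}.landmarks.json").write_text(
                json.dumps({k: list(map(float, p)) for k, p in landmarks.items()},
                           indent=2))
        return path

    text = trimesh.exchange.ply.export_ply(mesh, encoding="ascii")
    if landmarks:
        lines = text.decode("ascii").splitlines()
        head = [f"comment landmark {name} {p[0]:.9g} {p[1]:.9g} {p[2]:.9g}"
                for name, p in landmarks.items()]
        insert_at = next(i for i, l in enumerate(lines) if l.startswith("element"))
        lines[insert_at:insert_at] = head
        text = ("\n".join(lines) + "\n").encode("ascii")
    path.write_bytes(text)
    return path
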