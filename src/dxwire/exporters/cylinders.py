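"""Cylinder-model export: one 2-nm-diameter cylinder per duplex axis.

Cylinders are written as closed triangulated prisms in a single ASCII PLY
file; per-cylinder metadata (edge, helix, diameter, length) is recorded in
header comments so downstream checks can read it without re-deriving
geometry.
"""

from __future__ import annotations

import numpy as np

from ..atomic_model import HelixFrame
from ..constants import CONSTANTS, DesignConstants
from ..geometry_core import ScaledMesh

__all__ = ["write_cylinder_model", "read_cylinder_metadata", "CIRCLE_SEGMENTS"]

CIRCLE_SEGMENTS = 16


def _cylinder_mesh(origin, direction, length, radius):
    z = np.asarray(direction, dtype=float)
    ref = np.array([1.0, 0.0, 0.0])
    if abs(np.dot(ref, z)) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    x = np.cross(z, ref)
    x /= np.linalg.norm(x)
    y = np.cross(z, x)
    angles = 2 * np.pi * np.arange(CIRCLE_SEGMENTS) / CIRCLE_SEGMENTS
    ring = radius * (np.outer(np.cos(angles), x) + np.outer(np.sin(angles), y))
    bottom = origin + ring
    top = origin + length * z + ring
    verts = [origin, origin + length * z] + list(bottom) + list(top)
    faces = []
    for i in range(CIRCLE_SEGMENTS):
        j = (i + 1) % CIRCLE_SEGMENTS
        b0, b1 = 2 + i, 2 + j
        t0, t1 = 2 + CIRCLE_SEGMENTS + i, 2 + CIRCLE_SEGMENTS + j
        faces.append([0, b1, b0])            # bottom cap fan
        faces.append([1, t0, t1])            # top cap fan
        faces.append([b0, b1, t1])
        faces.append([b0, t1, t0])
    return np.array(verts), faces


def write_cylinder_model(scaled: ScaledMesh, frames: dict[tuple[int, int], HelixFrame],
                         path, constants: DesignConstants = CONSTANTS,
                         provenance: list[str] | None = None) -> list[dict]:
    """Write the PLY cylinder model; returns per-cylinder metadata."""
    meta = []
    all_verts = []
    all_faces = []
    offset = 0
    for (ei, h) in sorted(frames):
        frame = frames[(ei, h)]
        length = scaled.edge_nm[ei]
        verts, faces = _cylinder_mesh(frame.origin, frame.direction, length,
                                      constants.duplex_diameter / 2.0)
        all_verts.append(verts)
        all_faces.extend([[i + offset for i in f] for f in faces])
        offset += len(verts)
        meta.append({
            "edge": ei,
            "helix": h,
            "diameter_nm": constants.duplex_diameter,
            "length_nm": round(length, 3),
        })
    verts = np.vstack(all_verts)
    with open(path, "w") as fh:
        fh.write("ply\nformat ascii 1.0\n")
        for line in provenance or []:
            fh.write(f"comment {line}\n")
        for m in meta:
            fh.write(
                "comment cylinder edge={edge} helix={helix} "
                "diameter_nm={diameter_nm} length_nm={length_nm}\n".format(**m)
            )
        fh.write(f"element vertex {len(verts)}\n")
        fh.write("property float x\nproperty float y\nproperty float z\n")
        fh.write(f"element face {len(all_faces)}\n")
        fh.write("property list uchar int vertex_indices\n")
        fh.write("end_header\n")
        for v in verts:
            fh.write(f"{v[0]:.4f} {v[1]:.4f} {v[2]:.4f}\n")
        for face in all_faces:
            fh.write(" ".join([str(len(face))] + [str(i) for i in face]) + "\n")
    return meta


def read_cylinder_metadata(path) -> list[dict]:
    """Parse the per-cylinder comment metadata back from a PLY file."""
    meta = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line == "end_header":
                break
            if line.startswith("comment cylinder "):
                fields = dict(kv.split("=") for kv in line.split()[2:])
                meta.append({
                    "edge": int(fields["edge"]),
                    "helix": int(fields["helix"]),
                    "diameter_nm": float(fields["diameter_nm"]),
                    "length_nm": float(fields["length_nm"]),
                })
    return meta
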