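"""Minimal Wavefront OBJ reader/writer for geometry-only meshes.

Only ``v`` and ``f`` records carry information here; texture coordinates,
normals, materials and groups are parsed past and discarded, since OBJ is
used purely as a geometry transfer format between the photogrammetry
pipeline and this toolkit. Faces with more than three vertices are
fan-triangulated from their first vertex.
"""

from __future__ import annotations

import os

import numpy as np

from .mesh import MeshError, TriMesh

__all__ = ["ObjFormatError", "read_obj", "write_obj"]


class ObjFormatError(MeshError):
    """Raised for malformed OBJ content."""


def _parse_face_token(token: str, n_vertices: int, lineno: int) -> int:
    # v, v/vt, v//vn and v/vt/vn forms; only the vertex index is kept.
    head = token.split("/", 1)[0]
    try:
        idx = int(head)
    except ValueError:
        raise ObjFormatError(f"line {lineno}: bad face token {token!r}") from None
    # OBJ indices are 1-based; negatives count back from the end.
    if idx > 0:
        idx -= 1
    elif idx < 0:
        idx += n_vertices
    else:
        raise ObjFormatError(f"line {lineno}: face index 0 is invalid")
    if not 0 <= idx < n_vertices:
        raise ObjFormatError(
            f"line {lineno}: face references vertex {head} "
            f"but only {n_vertices} vertices are defined"
        )
    return idx


def read_obj(path) -> TriMesh:
    """Read a triangulated mesh from a Wavefront OBJ file.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    ObjFormatError
        On malformed records, out-of-range face indices, or zero faces.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(f"OBJ file not found: {path}")
    vertices: list[list[float]] = []
    faces: list[tuple[int, int, int]] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            key = parts[0]
            if key == "v":
                if len(parts) < 4:
                    raise ObjFormatError(f"line {lineno}: vertex needs 3 coords")
                vertices.append([float(x) for x in parts[1:4]])
            elif key == "f":
                if len(parts) < 4:
                    raise ObjFormatError(f"line {lineno}: face needs >= 3 vertices")
                idx = [_parse_face_token(t, len(vertices), lineno)
                       for t in parts[1:]]
                for a, b in zip(idx[1:-1], idx[2:]):
                    faces.append((idx[0], a, b))
            # vt, vn, mtllib, usemtl, g, o, s ... silently ignored
    if not faces:
        raise ObjFormatError(f"{path}: no faces found")
    return TriMesh(np.array(vertices, dtype=float), np.array(faces), False)


def write_obj(mesh: TriMesh, path) -> None:
    """Write a mesh as OBJ with 9-significant-digit coordinates (lossless
    for desk-scale geometry)."""
    with open(path, "w") as fh:
        for v in mesh.vertices:
            fh.write(f"v {v[0]:.9g} {v[1]:.9g} {v[2]:.9g}\n")
        for f in mesh.faces:
            fh.write(f"f {f[0] + 1} {f[1] + 1} {f[2] + 1}\n")
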