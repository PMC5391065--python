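"""Triangulated quadrat meshes: containers, rigid transforms, scaling.

All coordinates are metres once ``TriMesh.units_scaled`` is set. The convention
throughout the package is right-handed, Z up: after orientation the quadrat
lies in the X-Y plane with one corner at the origin and edges along +X/+Y.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "MeshError",
    "TriMesh",
    "QuadratModel",
    "scale_to_reference",
    "orient_to_plane",
    "rotation_matrix",
    "point_to_point_distance",
]


class MeshError(ValueError):
    """Raised for invalid mesh structure or invalid geometric arguments."""


@dataclass(frozen=True)
class TriMesh:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex coordinates. Metres once ``units_scaled`` is True.
    faces : (m, 3) int array
        Vertex-index triples (0-based).
    units_scaled : bool
        Whether coordinates have been scaled to real-world metres.
    """

    vertices: np.ndarray
    faces: np.ndarray
    units_scaled: bool = False

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        f = np.asarray(self.faces, dtype=np.int64)
        if v.ndim != 2 or v.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {v.shape}")
        if f.ndim != 2 or f.shape[1] != 3:
            raise MeshError(f"faces must be (m, 3) triangles, got {f.shape}")
        if len(f) == 0:
            raise MeshError("mesh has no faces")
        if f.min() < 0 or f.max() >= len(v):
            raise MeshError(
                f"face index out of range: vertices 0..{len(v) - 1}, "
                f"face indices span {f.min()}..{f.max()}"
            )
        if (f[:, 0] == f[:, 1]).any() or (f[:, 1] == f[:, 2]).any() or (
            f[:, 0] == f[:, 2]
        ).any():
            raise MeshError("degenerate face: repeated vertex index")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def triangles(self) -> np.ndarray:
        """Face corner coordinates, shape (m, 3, 3)."""
        return self.vertices[self.faces]

    def area(self) -> float:
        """Total surface area (sum of triangle areas)."""
        t = self.triangles()
        cross = np.cross(t[:, 1] - t[:, 0], t[:, 2] - t[:, 0])
        return float(0.5 * np.linalg.norm(cross, axis=1).sum())

    def bounds(self) -> np.ndarray:
        """Axis-aligned bounding box, shape (2, 3): [min, max]."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


@dataclass(frozen=True)
class QuadratModel:
    """A scaled, oriented quadrat mesh ready for metric extraction.

    ``quadrat_side`` is the physical side length of the reference frame
    (2 m square by default). After orientation the quadrat interior is the
    square [0, side] x [0, side] in X-Y.
    """

    mesh: TriMesh
    quadrat_side: float = 2.0
    scale_factor: float = 1.0
    rotation_applied: str = "none"

    def __post_init__(self):
        if self.scale_factor <= 0:
            raise MeshError("scale_factor must be positive")
        if self.quadrat_side <= 0:
            raise MeshError("quadrat_side must be positive")

    def region(self) -> tuple[float, float, float, float]:
        """Full quadrat footprint (x0, y0, x1, y1)."""
        return (0.0, 0.0, self.quadrat_side, self.quadrat_side)


def scale_to_reference(mesh: TriMesh, measured_length: float,
                       true_length: float) -> TriMesh:
    """Uniformly scale so a measured reference length becomes its true length.

    The quadrat corner-to-corner span measured on the raw model and its known
    physical value (2·√2 m for a 2 m quadrat) determine a single isotropic
    factor; anisotropic scaling is refused by construction.
    """
    if not np.isfinite(measured_length) or measured_length <= 0:
        raise MeshError("measured_length must be positive and finite")
    if not np.isfinite(true_length) or true_length <= 0:
        raise MeshError("true_length must be positive and finite")
    factor = true_length / measured_length
    return replace(mesh, vertices=mesh.vertices * factor, units_scaled=True)


def rotation_matrix(axis, angle_rad: float) -> np.ndarray:
    """Rotation matrix about an arbitrary axis (Rodrigues' formula)."""
    axis = np.asarray(axis, dtype=float)
    n = np.linalg.norm(axis)
    if n == 0 or not np.isfinite(n):
        raise MeshError("rotation axis must be nonzero and finite")
    k = axis / n
    K = np.array([[0, -k[2], k[1]], [k[2], 0, -k[0]], [-k[1], k[0], 0]])
    return np.eye(3) + np.sin(angle_rad) * K + (1 - np.cos(angle_rad)) * (K @ K)


def orient_to_plane(mesh: TriMesh, axis=(0.0, 0.0, 1.0), angle_rad: float = 0.0,
                    translation=(0.0, 0.0, 0.0)) -> TriMesh:
    """Apply a rigid transform (rotate about ``axis`` then translate).

    Used to lay a tilted quadrat flat in the X-Y plane with a corner at the
    origin. Rigid: pairwise distances are preserved exactly up to roundoff.
    """
    R = rotation_matrix(axis, angle_rad)
    t = np.asarray(translation, dtype=float)
    return replace(mesh, vertices=mesh.vertices @ R.T + t)


def point_to_point_distance(p, q, split: bool = False):
    """Euclidean distance between two 3D points, in metres.

    With ``split=True`` returns ``(full, xy, dz)``: the 3D distance, the
    distance in the X-Y plane only, and |ΔZ| — the planar and vertical
    components are reported separately when comparing against known object
    dimensions measured horizontally or vertically.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != (3,) or q.shape != (3,):
        raise MeshError("points must be 3D")
    if not (np.isfinite(p).all() and np.isfinite(q).all()):
        raise MeshError("non-finite point coordinates")
    d = q - p
    full = float(np.linalg.norm(d))
    if not split:
        return full
    return full, float(np.hypot(d[0], d[1])), float(abs(d[2]))
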