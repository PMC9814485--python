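"""Triangulated surface meshes and their validation.

All surfaces used by the simulator are closed, consistently oriented
2-manifolds: every edge is shared by exactly two triangles and the triangle
winding is counter-clockwise as seen from outside (outward normals, positive
signed volume).  Coordinates are millimetres, right-handed, with the torso
z-axis pointing cranially.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import trimesh


class MeshError(ValueError):
    """Raised for invalid or inconsistent surface meshes."""


@dataclass
class TriSurface:
    """A triangulated surface.

    Parameters
    ----------
    vertices : (n, 3) float array
        Vertex positions in mm.
    triangles : (m, 3) int array
        Vertex index triples, counter-clockwise seen from outside.
    name : str
        Label ("torso", "lung_left", ...).
    """

    vertices: np.ndarray
    triangles: np.ndarray
    name: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=np.float64)
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"vertices must be (n, 3), got {self.vertices.shape}")
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise MeshError(f"triangles must be (m, 3), got {self.triangles.shape}")
        if len(self.triangles) and self.triangles.max() >= len(self.vertices):
            raise MeshError("triangle index out of range")

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_corners(self) -> np.ndarray:
        """(m, 3, 3) array of triangle corner positions."""
        return self.vertices[self.triangles]

    def triangle_areas(self) -> np.ndarray:
        c = self.triangle_corners()
        cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        return 0.5 * np.linalg.norm(cross, axis=1)

    def triangle_normals(self) -> np.ndarray:
        """Unit normals following the winding convention."""
        c = self.triangle_corners()
        cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])
        norm = np.linalg.norm(cross, axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        return cross / norm

    def triangle_centroids(self) -> np.ndarray:
        return self.triangle_corners().mean(axis=1)

    def vertex_normals(self) -> np.ndarray:
        """Area-weighted vertex normals (unit length)."""
        c = self.triangle_corners()
        cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])  # 2*area*normal
        vn = np.zeros_like(self.vertices)
        for k in range(3):
            np.add.at(vn, self.triangles[:, k], cross)
        norm = np.linalg.norm(vn, axis=1, keepdims=True)
        norm[norm == 0.0] = 1.0
        return vn / norm

    def signed_volume(self) -> float:
        """Signed enclosed volume (mm^3); positive for outward orientation."""
        c = self.triangle_corners()
        return float(np.einsum("ij,ij->i", c[:, 0], np.cross(c[:, 1], c[:, 2])).sum() / 6.0)

    def edge_array(self, directed: bool = False) -> np.ndarray:
        """Unique undirected edges (k, 2), or all 3m directed edges."""
        e = np.concatenate(
            [self.triangles[:, [0, 1]], self.triangles[:, [1, 2]], self.triangles[:, [2, 0]]]
        )
        if directed:
            return e
        return np.unique(np.sort(e, axis=1), axis=0)

    def flipped(self) -> "TriSurface":
        """Copy with reversed winding (normals negated)."""
        return replace(self, triangles=self.triangles[:, ::-1].copy())

    def copy(self) -> "TriSurface":
        return TriSurface(self.vertices.copy(), self.triangles.copy(), self.name)

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(
            vertices=self.vertices, faces=self.triangles, process=False
        )

    @classmethod
    def from_trimesh(cls, mesh: trimesh.Trimesh, name: str = "") -> "TriSurface":
        return cls(np.asarray(mesh.vertices), np.asarray(mesh.faces), name)


@dataclass
class SurfaceDiagnostics:
    """Result of :func:`validate_surface`."""

    closed: bool
    oriented: bool
    degenerate_triangles: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    offending_edges: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=int))
    signed_volume: float = 0.0

    @property
    def ok(self) -> bool:
        return self.closed and self.oriented and len(self.degenerate_triangles) == 0


def validate_surface(surface: TriSurface, degenerate_area_tol: float = 1e-9) -> SurfaceDiagnostics:
    """Check the closed-manifold, orientation and degeneracy invariants.

    Closedness requires every undirected edge to be shared by exactly two
    triangles.  Consistent outward orientation requires every undirected edge
    to be traversed once in each direction by its two triangles, and the total
    signed volume to be positive.  Triangles with area below
    ``degenerate_area_tol`` (mm^2) are reported as degenerate.

    The input is never mutated.
    """
    if surface.n_vertices < 4 or surface.n_triangles == 0:
        raise MeshError(f"surface {surface.name!r} is empty or too small to validate")

    directed = surface.edge_array(directed=True)
    undirected = np.sort(directed, axis=1)
    uniq, inverse, counts = np.unique(
        undirected, axis=0, return_inverse=True, return_counts=True
    )
    closed = bool(np.all(counts == 2))
    offending = uniq[counts != 2]

    oriented = closed
    if closed:
        # each undirected edge must appear once as (a,b) and once as (b,a)
        forward = directed[:, 0] < directed[:, 1]
        n_forward = np.zeros(len(uniq), dtype=int)
        np.add.at(n_forward, inverse, forward.astype(int))
        consistent = bool(np.all(n_forward == 1))
        oriented = consistent and surface.signed_volume() > 0.0

    degenerate = np.flatnonzero(surface.triangle_areas() < degenerate_area_tol)
    return SurfaceDiagnostics(
        closed=closed,
        oriented=oriented,
        degenerate_triangles=degenerate,
        offending_edges=offending,
        signed_volume=surface.signed_volume(),
    )


def icosphere(subdivisions: int = 3, radius: float = 1.0, name: str = "sphere") -> TriSurface:
    """Outward-oriented icosphere (convenience wrapper around trimesh)."""
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return TriSurface.from_trimesh(m, name=name)


def ellipsoid(
    semi_axes: tuple[float, float, float],
    center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    subdivisions: int = 3,
    name: str = "",
) -> TriSurface:
    """Ellipsoid mesh built by anisotropic scaling of an icosphere."""
    s = icosphere(subdivisions=subdivisions, radius=1.0, name=name)
    s.vertices = s.vertices * np.asarray(semi_axes, dtype=float) + np.asarray(center, dtype=float)
    return s


def merge_surfaces(parts: list[TriSurface], name: str = "") -> TriSurface:
    """Concatenate surfaces into one (disjoint vertex sets)."""
    verts, tris, offset = [], [], 0
    for p in parts:
        verts.append(p.vertices)
        tris.append(p.triangles + offset)
        offset += p.n_vertices
    return TriSurface(np.concatenate(verts), np.concatenate(tris), name)


def save_surface(surface: TriSurface, path: str) -> None:
    """Write a surface as OFF, PLY or STL (by file extension)."""
    surface.to_trimesh().export(path)


def load_surface(path: str, name: str = "") -> TriSurface:
    """Read a surface mesh (OFF, PLY, STL, ...)."""
    m = trimesh.load_mesh(path, process=False)
    return TriSurface.from_trimesh(m, name=name or str(path))
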