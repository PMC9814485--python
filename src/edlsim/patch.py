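"""Embedding of partially active diseased-myocardium patches.

A patch models a region of diseased, partially electrically active
myocardium as a separate closed dipole-layer component embedded mid-wall.
At the patch location the ventricular surface nodes are pushed inward along
their normals (a smooth cosine-tapered dent), creating a mid-myocardial
border between normal and diseased tissue while leaving the outer shape of
the ventricular model intact: the patch is a closed surface whose inner face
is an exact, winding-flipped copy of the dented nodes and triangles, and
whose outer face restores the original surface geometry.  Inner and outer
faces share the undisplaced rim vertices, so the patch closes without any
extra stitching strip and the union of the dented ventricle and the patch
outer face reproduces the original surface vertex-for-vertex.

Because coincident, oppositely wound triangles with equal source strength
cancel exactly, a fully connected patch whose activation equals the normal
one contributes nothing: the model degenerates to the unpatched ventricle.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .anatomy import VentricularModel
from .mesh import MeshError, TriSurface

__all__ = ["PatchSpec", "PatchSurface", "PatchedModel", "embed_patch"]

CONNECTION_TYPES = ("full_inner", "outer_ring_full", "outer_ring_latest_25pct")


class PatchGeometryError(MeshError):
    """Patch specification incompatible with the host surface."""


@dataclass
class PatchSpec:
    """Geometry and electrical description of one diseased-region patch.

    ``center`` is a position (mm) snapped to the nearest host-surface vertex.
    ``depth`` is the dent displacement at the patch centre and must stay
    below the local wall thickness.  ``health_fraction`` scales the patch's
    dipole-layer strength (fraction of electrically active tissue).
    """

    center: np.ndarray
    radius: float = 15.0
    depth: float = 3.0
    host: str = "epicardial"  # 'epicardial' | 'endocardial' | 'both'
    connection_type: str = "full_inner"
    health_fraction: float = 1.0

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if self.radius <= 0.0:
            raise PatchGeometryError(f"radius must be positive, got {self.radius}")
        if not 0.0 <= self.health_fraction <= 1.0:
            raise PatchGeometryError("health_fraction must lie in [0, 1]")
        if self.host not in ("epicardial", "endocardial", "both"):
            raise PatchGeometryError(f"unknown host surface {self.host!r}")
        if self.connection_type not in CONNECTION_TYPES:
            raise PatchGeometryError(f"unknown connection type {self.connection_type!r}")


@dataclass
class PatchSurface:
    """One closed patch component with its node bookkeeping.

    ``orig_vertex_id`` maps every patch-local vertex to the ventricular
    vertex it copies (in the *original*, unpatched indexing).  Displaced
    region vertices occur twice — an inner copy at the dented position and
    an outer copy at the original position; rim vertices occur once and are
    shared by both faces.
    """

    mesh: TriSurface
    orig_vertex_id: np.ndarray
    inner_ids: np.ndarray  # inner face vertices (region inner copies + rim)
    outer_ids: np.ndarray  # outer copies of the displaced region vertices
    ring_ids: np.ndarray  # undisplaced rim vertices (shared by both faces)
    displacement: np.ndarray  # per patch-local vertex, dent depth (mm)
    spec: PatchSpec = None
    host: str = "epicardial"

    @property
    def node_correspondence(self) -> np.ndarray:
        """(k, 2) pairs [patch-local inner id, ventricular vertex id]."""
        return np.column_stack([self.inner_ids, self.orig_vertex_id[self.inner_ids]])

    def thickness_edges(self) -> np.ndarray:
        """(d, 2) patch-local [inner copy, outer copy] pairs across the slab."""
        region = self.orig_vertex_id[self.outer_ids]
        inner_lookup = {int(self.orig_vertex_id[i]): int(i) for i in self.inner_ids}
        return np.array(
            [[inner_lookup[int(o)], int(j)] for o, j in zip(region, self.outer_ids)],
            dtype=int,
        ).reshape(-1, 2)


@dataclass
class PatchedModel:
    """Dented ventricular model plus its embedded patch components."""

    ventricles: VentricularModel  # dented geometry, original vertex indexing
    patches: list
    original: VentricularModel  # the unpatched model (distance-matrix reuse)
    metadata: dict = field(default_factory=dict)


def _single_patch(
    ventricles: VentricularModel, spec: PatchSpec, host: str
) -> tuple[np.ndarray, np.ndarray, PatchSurface]:
    surface = ventricles.surface
    pool = (
        ventricles.epi_vertex_ids if host == "epicardial" else ventricles.endo_vertex_ids
    )
    pos = surface.vertices
    center_vid = pool[np.argmin(np.linalg.norm(pos[pool] - spec.center, axis=1))]
    center = pos[center_vid]

    r = np.linalg.norm(pos[pool] - center, axis=1)
    region = pool[r < spec.radius]
    if len(region) < 3:
        raise PatchGeometryError(
            "patch region too small: fewer than 3 host vertices within the radius"
        )
    if len(region) == len(pool):
        raise PatchGeometryError("patch extends over the whole host surface")

    thickness = _local_thickness(ventricles, region, host)
    if spec.depth <= 0.0:
        raise PatchGeometryError("dent depth must be positive (a zero-depth patch is degenerate)")
    if spec.depth >= thickness.min():
        raise PatchGeometryError(
            f"dent depth {spec.depth} mm >= local wall thickness {thickness.min():.2f} mm"
        )

    # smooth cosine taper: depth at the centre, 0 at the rim
    w = np.zeros(surface.n_vertices)
    rr = np.linalg.norm(pos[region] - center, axis=1)
    w[region] = spec.depth * 0.5 * (1.0 + np.cos(np.pi * rr / spec.radius))
    normals = surface.vertex_normals()
    displaced = pos.copy()
    displaced[region] -= w[region, None] * normals[region]

    region_mask = np.zeros(surface.n_vertices, dtype=bool)
    region_mask[region] = True
    changed = np.any(region_mask[surface.triangles], axis=1)
    changed_tris = surface.triangles[changed]
    patch_verts = np.unique(changed_tris)
    ring = patch_verts[~region_mask[patch_verts]]
    if len(ring) == 0:
        raise PatchGeometryError("patch has no rim: region covers a whole component")

    # patch-local indexing: inner layer (all patch verts) then outer copies
    local = -np.ones(surface.n_vertices, dtype=int)
    local[patch_verts] = np.arange(len(patch_verts))
    n_inner = len(patch_verts)
    region_sorted = patch_verts[region_mask[patch_verts]]
    outer_local = {int(v): n_inner + j for j, v in enumerate(region_sorted)}

    verts = np.concatenate([displaced[patch_verts], pos[region_sorted]])
    inner_tris = local[changed_tris][:, ::-1]  # flipped winding
    outer_tris = np.array(
        [[outer_local.get(int(v), local[v]) for v in tri] for tri in changed_tris]
    )
    mesh = TriSurface(verts, np.concatenate([inner_tris, outer_tris]), name="patch")

    orig_id = np.concatenate([patch_verts, region_sorted])
    disp = np.concatenate([w[patch_verts], w[region_sorted]])
    patch = PatchSurface(
        mesh=mesh,
        orig_vertex_id=orig_id,
        inner_ids=np.arange(n_inner),
        outer_ids=np.arange(n_inner, n_inner + len(region_sorted)),
        ring_ids=local[ring],
        displacement=disp,
        spec=spec,
        host=host,
    )
    return region, displaced, patch


def _local_thickness(ventricles: VentricularModel, region: np.ndarray, host: str) -> np.ndarray:
    if host == "epicardial":
        epi_index = {int(v): i for i, v in enumerate(ventricles.epi_vertex_ids)}
        return ventricles.wall_thickness[[epi_index[int(v)] for v in region]]
    # endocardial: distance to the paired epicardial vertex
    pair = dict(map(tuple, ventricles.endo_epi_pairs))
    p = ventricles.surface.vertices
    return np.array([np.linalg.norm(p[pair[int(v)]] - p[int(v)]) for v in region])


def embed_patch(ventricles: VentricularModel, spec: PatchSpec) -> PatchedModel:
    """Embed one patch (or an endo/epi pair for ``host='both'``).

    Returns the dented ventricular model together with the closed patch
    surfaces.  Non-region vertices keep their original positions exactly and
    each patch's inner face duplicates the dented nodes bit-for-bit.
    """
    hosts = ["epicardial", "endocardial"] if spec.host == "both" else [spec.host]
    current = ventricles
    patches = []
    for host in hosts:
        region, displaced, patch = _single_patch(current, spec, host)
        dented_surface = replace(current.surface, vertices=displaced)
        current = replace(current, surface=dented_surface)
        patches.append(patch)
    return PatchedModel(
        ventricles=current,
        patches=patches,
        original=ventricles,
        metadata={"spec": spec},
    )
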