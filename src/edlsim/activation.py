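"""Fastest-route activation of the ventricles and of diseased patches.

Depolarization times are computed with the fastest-route algorithm:
multi-source shortest paths on a graph whose nodes are surface vertices and
whose edges carry traversal times length/velocity.  The ventricular graph
contains the surface edges of the biventricular mesh (default 0.85 m/s)
plus transmural edges between paired endocardial/epicardial vertices with a
2.5-fold slower velocity.  Normal activation starts from seven endocardial
foci (four left-ventricular, three right-ventricular).

Patch activation follows the distance-matrix-reuse principle: the
ventricular sequence is always computed on the unpatched geometry and
transferred to the dented model, and the patch graph uses the *original*
(undented) edge lengths.  Through-thickness edges between opposing
inner/outer patch nodes carry only the excess crossing time
``w * (1/v_patch - 1/v_normal)``: at the normal velocity the patch metric
degenerates to the unpatched metric, so a fully connected patch reproduces
the normal activation map exactly, while slower patch velocities produce
genuinely delayed outer-face activation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .anatomy import AnatomyModel, VentricularModel
from .patch import PatchedModel, PatchSurface

__all__ = [
    "Velocities",
    "FocusSet",
    "ActivationGraph",
    "ActivationMap",
    "build_ventricular_graph",
    "fastest_route",
    "default_foci",
    "ventricular_activation",
    "connection_set",
    "discontinuous_connection_set",
    "delayed_patch_activation",
    "dyssynchronous_patch_activation",
]

EDGE_CLASSES = ("surface", "transmural", "patch")


@dataclass
class Velocities:
    """Conduction velocities (m/s).  1 mm / (1 m/s) = 1 ms."""

    surface: float = 0.85
    transmural_factor: float = 2.5  # slowing perpendicular to the wall
    patch: float | None = None

    def of_class(self, cls: str) -> float:
        if cls == "surface":
            return self.surface
        if cls == "transmural":
            return self.surface / self.transmural_factor
        if cls == "patch":
            if self.patch is None:
                raise ValueError("patch velocity not set")
            return self.patch
        raise ValueError(f"unknown edge class {cls!r}")

    def validate(self) -> None:
        if self.surface <= 0 or self.transmural_factor <= 0:
            raise ValueError("velocities must be positive")
        if self.patch is not None and self.patch <= 0:
            raise ValueError("patch velocity must be positive")


@dataclass
class FocusSet:
    """Activation onset sites (vertex ids) with onset times (ms)."""

    nodes: np.ndarray
    onsets: np.ndarray
    labels: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.nodes = np.asarray(self.nodes, dtype=int)
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.onsets.shape != self.nodes.shape:
            raise ValueError("one onset time per focus node required")
        if np.any(self.onsets < 0):
            raise ValueError("onset times must be >= 0")


@dataclass
class ActivationGraph:
    """Undirected weighted graph for fastest-route computation."""

    n_nodes: int
    edges: np.ndarray  # (k, 2) vertex pairs
    lengths: np.ndarray  # mm
    classes: np.ndarray  # per-edge class name

    def __post_init__(self) -> None:
        if np.any(self.lengths <= 0):
            raise ValueError("edge lengths must be positive")

    def time_matrix(self, velocities: Velocities):
        """Sparse symmetric matrix of edge traversal times (ms)."""
        velocities.validate()
        v = np.array([velocities.of_class(c) for c in self.classes])
        t = self.lengths / v
        i, j = self.edges[:, 0], self.edges[:, 1]
        m = coo_matrix(
            (np.concatenate([t, t]), (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_nodes, self.n_nodes),
        )
        return m.tocsr()


@dataclass
class ActivationMap:
    """Per-node depolarization times (ms) of one source component."""

    times: np.ndarray
    component: str = "ventricles"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        finite = self.times[np.isfinite(self.times)]
        if len(finite) and finite.min() < -1e-9:
            raise ValueError("activation times must be >= 0")

    @property
    def unreachable(self) -> np.ndarray:
        return np.flatnonzero(~np.isfinite(self.times))

    @property
    def range_ms(self) -> float:
        finite = self.times[np.isfinite(self.times)]
        return float(finite.max() - finite.min()) if len(finite) else 0.0


def build_ventricular_graph(ventricles: VentricularModel) -> ActivationGraph:
    """Surface edges of the biventricular mesh plus transmural pair edges."""
    surf = ventricles.surface
    edges = surf.edge_array()
    lengths = np.linalg.norm(
        surf.vertices[edges[:, 0]] - surf.vertices[edges[:, 1]], axis=1
    )
    classes = np.full(len(edges), "surface", dtype=object)
    tm = ventricles.endo_epi_pairs
    tm_len = np.linalg.norm(surf.vertices[tm[:, 0]] - surf.vertices[tm[:, 1]], axis=1)
    edges = np.concatenate([edges, tm])
    lengths = np.concatenate([lengths, tm_len])
    classes = np.concatenate([classes, np.full(len(tm), "transmural", dtype=object)])
    return ActivationGraph(surf.n_vertices, edges, lengths, classes)


def _multi_source_shortest(times_matrix, seeds: np.ndarray, onsets: np.ndarray) -> np.ndarray:
    """min over seeds of (onset + shortest-path time), via a virtual source."""
    from scipy.sparse import vstack, hstack, csr_matrix

    n = times_matrix.shape[0]
    col = np.zeros((n, 1))
    virt_row = csr_matrix((onsets, (np.zeros(len(seeds), int), seeds)), shape=(1, n))
    m = vstack(
        [hstack([times_matrix, csr_matrix(col)]), hstack([virt_row, csr_matrix((1, 1))])]
    ).tocsr()
    dist = dijkstra(m, directed=True, indices=[n])
    return dist[0, :n]


def fastest_route(
    graph: ActivationGraph, foci: FocusSet, velocities: Velocities
) -> ActivationMap:
    """Depolarization map delta(n) = min over foci of onset + path time.

    Unreachable nodes are flagged with infinite delta.  Deterministic: the
    result depends only on the graph metric, not on tie-breaking.
    """
    if np.any(foci.nodes >= graph.n_nodes) or np.any(foci.nodes < 0):
        raise ValueError("focus node outside the graph")
    t = _multi_source_shortest(graph.time_matrix(velocities), foci.nodes, foci.onsets)
    return ActivationMap(
        t,
        component="ventricles",
        metadata={
            "foci": foci.nodes.tolist(),
            "onsets": foci.onsets.tolist(),
            "velocity_surface": velocities.surface,
            "transmural_factor": velocities.transmural_factor,
        },
    )


def default_foci(anatomy: AnatomyModel) -> FocusSet:
    """Seven endocardial foci: four LV, three RV, all with onset 0 ms.

    Sites follow the classic septal-dominant pattern of early human
    ventricular activation: LV mid-septal, anterior, posterior and apical;
    RV septal, apical and inferior.  The free walls activate by spread, not
    by direct Purkinje breakthrough, which keeps the free-wall epicardium
    dependent on lateral propagation.
    """
    v = anatomy.ventricles
    surf = v.surface
    directions = {
        "lv_septal": (0, np.array([-1.0, 0.0, 0.0])),
        "lv_anterior": (0, np.array([0.0, -1.0, -0.3])),
        "lv_posterior": (0, np.array([0.0, 1.0, -0.3])),
        "lv_apex": (0, np.array([0.0, 0.0, -1.0])),
        "rv_septal": (1, np.array([1.0, 0.0, 0.0])),
        "rv_apex": (1, np.array([0.0, 0.0, -1.0])),
        "rv_inferior": (1, np.array([0.0, 0.7, -0.7])),
    }
    nodes, labels = [], []
    for label, (comp, d) in directions.items():
        ids = v.endo_vertex_ids[v.endo_component == comp]
        pos = surf.vertices[ids]
        center = pos.mean(axis=0)
        score = (pos - center) @ (d / np.linalg.norm(d))
        nodes.append(int(ids[np.argmax(score)]))
        labels.append(label)
    return FocusSet(np.array(nodes), np.zeros(len(nodes)), labels)


def ventricular_activation(
    model: VentricularModel | PatchedModel,
    foci: FocusSet,
    velocities: Velocities | None = None,
) -> ActivationMap:
    """Normal ventricular activation (always on the unpatched geometry).

    For a :class:`PatchedModel` the map is computed on ``model.original``
    and transferred to the dented model by the shared vertex indexing
    (distance-matrix reuse: the dent does not alter ventricular timing).
    """
    velocities = velocities or Velocities()
    ventricles = model.original if isinstance(model, PatchedModel) else model
    return fastest_route(build_ventricular_graph(ventricles), foci, velocities)


# ---------------------------------------------------------------------------
# patch activation


def connection_set(patch: PatchSurface, ventricular_map: ActivationMap) -> np.ndarray:
    """Patch-local node ids electrically connected to the ventricles."""
    return discontinuous_connection_set(patch, patch.spec.connection_type, ventricular_map)


def discontinuous_connection_set(
    patch: PatchSurface, connection_type: str, ventricular_map: ActivationMap
) -> np.ndarray:
    """Connected node set for each connection type.

    ``full_inner``: the whole inner face (dent copies + rim).
    ``outer_ring_full``: the rim only (type-1 isolating layer).
    ``outer_ring_latest_25pct``: the quarter of rim nodes with the latest
    ventricular activation (type 2), pointwise by delta.
    """
    if connection_type == "full_inner":
        return patch.inner_ids.copy()
    ring = patch.ring_ids
    if len(ring) == 0:
        raise ValueError("patch rim not identifiable")
    if connection_type == "outer_ring_full":
        return ring.copy()
    if connection_type == "outer_ring_latest_25pct":
        delta = ventricular_map.times[patch.orig_vertex_id[ring]]
        k = int(np.ceil(0.25 * len(ring)))
        return ring[np.argsort(delta)[-k:]]
    raise ValueError(f"unknown connection type {connection_type!r}")


def _patch_time_graph(
    model: PatchedModel,
    patch: PatchSurface,
    patch_velocity: float,
    normal_velocity: float,
    thickness_mode: str,
):
    """Edge traversal times (ms) of the patch graph.

    Surface edges use the original (undented) vertex distances at the patch
    velocity.  ``thickness_mode``:

    - ``"excess"`` (default): inner/outer pair edges with the excess
      crossing time ``w * (1/v_p - 1/v_normal)`` — zero at normal velocity;
    - ``"physical"``: pair edges at ``w / v_p``;
    - ``"none"``: faces communicate through the rim only.
    """
    if not 0 < patch_velocity <= normal_velocity:
        raise ValueError(
            f"patch velocity must lie in (0, {normal_velocity}], got {patch_velocity}"
        )
    orig_pos = model.original.surface.vertices
    edges = patch.mesh.edge_array()
    lengths = np.linalg.norm(
        orig_pos[patch.orig_vertex_id[edges[:, 0]]]
        - orig_pos[patch.orig_vertex_id[edges[:, 1]]],
        axis=1,
    )
    # inner and outer copies of one original edge have identical length; a
    # copy degenerate in the original metric (none by construction) would
    # be dropped here
    keep = lengths > 0
    times = [lengths[keep] / patch_velocity]
    edge_list = [edges[keep]]
    if thickness_mode != "none":
        pairs = patch.thickness_edges()
        w = patch.displacement[pairs[:, 1]]
        if thickness_mode == "excess":
            tau = w * (1.0 / patch_velocity - 1.0 / normal_velocity)
        elif thickness_mode == "physical":
            tau = w / patch_velocity
        else:
            raise ValueError(f"unknown thickness mode {thickness_mode!r}")
        # sparse graphs treat zero entries as absent: floor the zero-excess
        # case (v_p = v_normal) at a time far below any physical resolution
        edge_list.append(pairs)
        times.append(np.maximum(tau, 1e-9))
    edges = np.concatenate(edge_list)
    t = np.concatenate(times)
    i, j = edges[:, 0], edges[:, 1]
    n = patch.mesh.n_vertices
    return coo_matrix(
        (np.concatenate([t, t]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n),
    ).tocsr()


def delayed_patch_activation(
    model: PatchedModel,
    ventricular_map: ActivationMap,
    patch_velocity: float,
    patch_index: int = 0,
    normal_velocity: float | None = None,
    thickness_mode: str = "excess",
) -> ActivationMap:
    """Homogeneously slowed patch activation.

    Connected nodes (per the patch's connection type) inherit the
    ventricular delta exactly; the remaining patch nodes receive
    fastest-route times from the connected set at ``patch_velocity``.
    """
    patch = model.patches[patch_index]
    if normal_velocity is None:
        normal_velocity = float(
            ventricular_map.metadata.get("velocity_surface", Velocities().surface)
        )
    connected = connection_set(patch, ventricular_map)
    if len(connected) == 0:
        raise ValueError("empty patch connection set")
    seed_times = ventricular_map.times[patch.orig_vertex_id[connected]]
    m = _patch_time_graph(model, patch, patch_velocity, normal_velocity, thickness_mode)
    t = _multi_source_shortest(m, connected, seed_times)
    t[connected] = seed_times  # connected nodes keep the ventricular timing
    return ActivationMap(
        t,
        component=f"patch_{patch_index}",
        metadata={
            "patch_velocity": patch_velocity,
            "normal_velocity": normal_velocity,
            "connection_type": patch.spec.connection_type,
            "thickness_mode": thickness_mode,
        },
    )


def dyssynchronous_patch_activation(
    model: PatchedModel,
    ventricular_map: ActivationMap,
    jitter_max: float,
    seed: int,
    patch_velocity: float = 0.45,
    patch_index: int = 0,
    jitter_distribution: str = "uniform",
    **kwargs,
) -> ActivationMap:
    """Inhomogeneous-substrate activation: delayed base plus timing jitter.

    The base map is the delayed activation at ``patch_velocity`` (default
    0.45 m/s); non-connected patch nodes receive independent additive
    offsets in ``[0, jitter_max]`` ms from a seeded generator (uniform by
    default; ``"truncnorm"`` draws from a normal with sigma = jitter_max/3
    truncated to the same range).  Connected nodes keep the ventricular
    timing.
    """
    if jitter_max < 0:
        raise ValueError("jitter_max must be >= 0")
    base = delayed_patch_activation(
        model, ventricular_map, patch_velocity, patch_index, **kwargs
    )
    patch = model.patches[patch_index]
    connected = connection_set(patch, ventricular_map)
    free = np.setdiff1d(np.arange(patch.mesh.n_vertices), connected)
    rng = np.random.default_rng(seed)
    if jitter_distribution == "uniform":
        offsets = rng.uniform(0.0, jitter_max, size=len(free))
    elif jitter_distribution == "truncnorm":
        offsets = np.clip(
            np.abs(rng.normal(0.0, jitter_max / 3.0, size=len(free))), 0.0, jitter_max
        )
    else:
        raise ValueError(f"unknown jitter distribution {jitter_distribution!r}")
    t = base.times.copy()
    t[free] += offsets
    meta = dict(base.metadata, jitter_max=jitter_max, jitter_seed=seed)
    return ActivationMap(t, component=base.component, metadata=meta)
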