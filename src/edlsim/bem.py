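"""Boundary-element volume conduction for equivalent-dipole-layer sources.

The potential generated by a dipole layer of strength ``s`` (mA/m) carried by
a triangulated surface, observed at ``y`` in an unbounded homogeneous medium
of conductivity ``sigma`` (S/m), is

    Phi_inf(y) = -(1 / (4 pi sigma)) * sum_triangles s_tri * Omega(y, tri)

with ``Omega`` the signed solid angle of the triangle seen from ``y``
(positive orientation: a closed outward-oriented surface subtends +4 pi from
interior points).  In these units (mV, mA/m, S/m) no length conversion is
needed: solid angles are scale-invariant and strength/conductivity is already
in mV.

The torso is modelled as a piecewise-homogeneous conductor (thorax, lungs,
blood cavities) bounded by closed interface meshes.  Interface potentials
satisfy the second-kind integral equation

    (sigma_in + sigma_out)/2 * Phi(y) =
        sigma_s * Phi_inf(y)
        + 1/(4 pi) * sum_interfaces (sigma_in - sigma_out) * PV int Phi domega

discretized by vertex collocation with the potential interpolated linearly
per triangle (each vertex receives Omega/3 of its incident triangles).  The
singular auto-solid-angle is fixed by closure: the principal-value row sum
over the observation point's own surface is forced to 2 pi.  The insulated
torso makes the operator singular (constant null space); the system is
deflated with a rank-one projector and the potential reference is fixed as
zero mean over the torso electrodes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .mesh import TriSurface, validate_surface

__all__ = [
    "SingularObservationError",
    "triangle_solid_angle",
    "solid_angle_matrix",
    "infinite_medium_potential",
    "TransferMatrix",
    "VolumeConductor",
    "assemble_transfer_matrix",
]


class SingularObservationError(ValueError):
    """Observation point lies on the source layer itself."""


def triangle_solid_angle(triangle: np.ndarray, point: np.ndarray) -> float:
    """Signed solid angle (sr) of a plane triangle seen from ``point``.

    Uses the analytic arctangent formula of van Oosterom & Strackee.  The
    sign follows the winding: a triangle whose normal points away from the
    observation point subtends a positive angle.  A point lying inside the
    triangle is a genuine singularity of the double-layer kernel and raises
    :class:`SingularObservationError`; the closure construction in
    :class:`VolumeConductor` handles that case instead.
    """
    tri = np.asarray(triangle, dtype=float)
    y = np.asarray(point, dtype=float)
    r = tri - y
    n = np.linalg.norm(r, axis=1)
    N = float(np.dot(r[0], np.cross(r[1], r[2])))
    D = float(
        n[0] * n[1] * n[2]
        + np.dot(r[0], r[1]) * n[2]
        + np.dot(r[0], r[2]) * n[1]
        + np.dot(r[1], r[2]) * n[0]
    )
    if N == 0.0 and D <= 0.0:
        # coplanar with the triangle, on or inside its edges
        raise SingularObservationError("observation point lies on the triangle")
    return float(2.0 * np.arctan2(N, D))


def solid_angle_matrix(
    surface: TriSurface, points: np.ndarray, chunk: int = 256
) -> np.ndarray:
    """Solid angles of every triangle of ``surface`` from every point.

    Returns an ``(n_points, n_triangles)`` array.  Points coincident with a
    triangle vertex yield 0 for that triangle (the formula's continuous
    limit), which is what the closure-based diagonal treatment expects.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    corners = surface.triangle_corners()  # (m, 3, 3)
    out = np.empty((len(pts), len(corners)))
    for lo in range(0, len(pts), chunk):
        p = pts[lo : lo + chunk]  # (k, 3)
        r = corners[None, :, :, :] - p[:, None, None, :]  # (k, m, 3, 3)
        n = np.linalg.norm(r, axis=3)  # (k, m, 3)
        r0, r1, r2 = r[:, :, 0], r[:, :, 1], r[:, :, 2]
        N = np.einsum("kmi,kmi->km", r0, np.cross(r1, r2))
        D = (
            n[:, :, 0] * n[:, :, 1] * n[:, :, 2]
            + np.einsum("kmi,kmi->km", r0, r1) * n[:, :, 2]
            + np.einsum("kmi,kmi->km", r0, r2) * n[:, :, 1]
            + np.einsum("kmi,kmi->km", r1, r2) * n[:, :, 0]
        )
        with np.errstate(invalid="ignore"):
            om = 2.0 * np.arctan2(N, D)
        om[np.isnan(om)] = 0.0  # point exactly on a vertex
        out[lo : lo + chunk] = om
    return out


def _node_weight_matrix(surface: TriSurface) -> np.ndarray:
    """(m_tris, n_nodes) matrix averaging node values onto triangles."""
    W = np.zeros((surface.n_triangles, surface.n_vertices))
    rows = np.repeat(np.arange(surface.n_triangles), 3)
    W[rows, surface.triangles.ravel()] = 1.0 / 3.0
    return W


def infinite_medium_potential(
    source: TriSurface,
    strengths: np.ndarray,
    sigma: float,
    points: np.ndarray,
) -> np.ndarray:
    """Potential (mV) of a dipole layer in an unbounded homogeneous medium.

    ``strengths`` are per-node dipole-layer strengths (mA/m), interpolated
    linearly per triangle (triangle strength = mean of its three nodes).
    """
    if sigma <= 0.0:
        raise ValueError(f"conductivity must be positive, got {sigma}")
    strengths = np.asarray(strengths, dtype=float)
    if strengths.shape != (source.n_vertices,):
        raise ValueError("need one strength per source node")
    om = solid_angle_matrix(source, points)  # (k, m)
    s_tri = strengths[source.triangles].mean(axis=1)
    phi = -(om @ s_tri) / (4.0 * np.pi * sigma)
    return phi if np.ndim(points) == 2 else float(phi[0])


@dataclass
class TransferMatrix:
    """Per-source-element gains at a set of observation points.

    ``triangle_gains`` maps per-triangle dipole-layer strength (mA/m) to
    potential (mV).  ``gains`` is the per-source-node equivalent under the
    linear interpolation (a node feeds 1/3 of each incident triangle).
    Potentials are referenced to zero mean over the torso electrodes.
    """

    triangle_gains: np.ndarray  # (n_obs, m_src_tris)
    source: TriSurface
    observation_id: str = ""
    metadata: dict = field(default_factory=dict)

    @property
    def gains(self) -> np.ndarray:
        return self.triangle_gains @ _node_weight_matrix(self.source)

    @property
    def n_observations(self) -> int:
        return self.triangle_gains.shape[0]

    def potentials(self, triangle_strengths: np.ndarray) -> np.ndarray:
        """Apply the matrix to per-triangle strengths (mA/m) -> mV."""
        return self.triangle_gains @ np.asarray(triangle_strengths, dtype=float)

    def save(self, path: str | Path) -> None:
        """Cache to ``<path>.npz`` + ``<path>.json`` (gains + provenance)."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), triangle_gains=self.triangle_gains)
        meta = dict(self.metadata)
        meta.update(
            observation_id=self.observation_id,
            source_name=self.source.name,
            source_hash=mesh_hash(self.source),
        )
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path, source: TriSurface) -> "TransferMatrix":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        if meta["source_hash"] != mesh_hash(source):
            raise ValueError("cached transfer matrix does not match this source mesh")
        gains = np.load(path.with_suffix(".npz"))["triangle_gains"]
        return cls(gains, source, meta.get("observation_id", ""), meta)


def mesh_hash(surface: TriSurface) -> str:
    import hashlib

    h = hashlib.sha256()
    h.update(np.ascontiguousarray(surface.vertices).tobytes())
    h.update(np.ascontiguousarray(surface.triangles).tobytes())
    return h.hexdigest()[:16]


class VolumeConductor:
    """BEM operator for one piecewise-homogeneous anatomy.

    Assembles the interface collocation system once (the expensive part,
    independent of the source) and exposes transfer-matrix computation for
    any number of source surfaces, which share the LU factorization.
    """

    def __init__(self, anatomy) -> None:
        self.anatomy = anatomy
        comps = anatomy.compartments
        for c in comps:
            diag = validate_surface(c.surface)
            if not diag.ok:
                raise ValueError(
                    f"interface surface {c.surface.name!r} is not a closed "
                    f"outward-oriented manifold"
                )
        self._surfaces = [c.surface for c in comps]
        self._sigma_in = np.array([c.sigma_in for c in comps])
        self._sigma_out = np.array([c.sigma_out for c in comps])
        self._offsets = np.cumsum([0] + [s.n_vertices for s in self._surfaces])
        self.n_nodes = int(self._offsets[-1])
        self.nodes = np.concatenate([s.vertices for s in self._surfaces])
        self._assemble()

    # -- assembly ---------------------------------------------------------
    def _double_layer_block(self, surface: TriSurface, points: np.ndarray) -> np.ndarray:
        """(n_points, n_surface_nodes) linear-interpolation double-layer matrix."""
        om = solid_angle_matrix(surface, points)
        D = np.zeros((len(points), surface.n_vertices))
        for k in range(3):
            np.add.at(D.T, surface.triangles[:, k], om.T / 3.0)
        return D

    def _assemble(self) -> None:
        n = self.n_nodes
        M = np.zeros((n, n))
        for ell, s_ell in enumerate(self._surfaces):
            dsig = self._sigma_in[ell] - self._sigma_out[ell]
            lo, hi = self._offsets[ell], self._offsets[ell + 1]
            D = self._double_layer_block(s_ell, self.nodes)  # (n, n_ell)
            # closure: PV row sum over own surface equals 2 pi
            rows = np.arange(lo, hi)
            own = D[rows]
            idx = np.arange(hi - lo)
            own[idx, idx] += 2.0 * np.pi - own.sum(axis=1)
            D[rows] = own
            M[:, lo:hi] -= dsig / (4.0 * np.pi) * D
            self._store_block(ell, D)
        centers = 0.5 * (self._sigma_in + self._sigma_out)
        diag_scale = np.concatenate(
            [np.full(s.n_vertices, c) for s, c in zip(self._surfaces, centers)]
        )
        M[np.arange(n), np.arange(n)] += diag_scale
        # deflation: the insulated-torso operator annihilates constants
        scale = float(np.mean(np.abs(np.diag(M))))
        Md = M + scale * np.ones((n, n)) / n
        self._lu = lu_factor(Md)

    def _store_block(self, ell: int, D: np.ndarray) -> None:
        if not hasattr(self, "_interface_blocks"):
            self._interface_blocks: dict[int, np.ndarray] = {}
        self._interface_blocks[ell] = D

    # -- solving ----------------------------------------------------------
    def source_sigma(self) -> float:
        return float(self.anatomy.sigma_myocardium)

    def solve_interface(self, phi_inf: np.ndarray) -> np.ndarray:
        """Interface potentials for infinite-medium term(s) at all nodes.

        ``phi_inf``: (n_nodes,) or (n_nodes, k) for k simultaneous sources.
        """
        rhs = self.source_sigma() * np.asarray(phi_inf, dtype=float)
        return lu_solve(self._lu, rhs)

    def _interior_composition(
        self, points: np.ndarray, phi_inf_pts: np.ndarray, phi_interfaces: np.ndarray
    ) -> np.ndarray:
        """Representation formula at interior (non-interface) points."""
        sig = self.anatomy.conductivity_at(points)
        if np.any(sig <= 0.0):
            raise ValueError("observation point outside the torso")
        acc = self.source_sigma() * phi_inf_pts
        for ell, s_ell in enumerate(self._surfaces):
            dsig = self._sigma_in[ell] - self._sigma_out[ell]
            if dsig == 0.0:
                continue
            lo, hi = self._offsets[ell], self._offsets[ell + 1]
            D = self._double_layer_block(s_ell, points)
            acc += dsig / (4.0 * np.pi) * (D @ phi_interfaces[lo:hi])
        return acc / sig[:, None] if acc.ndim == 2 else acc / sig

    def transfer_matrix(
        self,
        source: TriSurface,
        observation: str | np.ndarray = "electrodes",
    ) -> TransferMatrix:
        """Per-triangle gains from ``source`` to the observation set.

        ``observation`` is ``"electrodes"`` (the anatomy's torso electrodes)
        or an ``(k, 3)`` array of points strictly inside the torso (cardiac
        observation points).  All gains are referenced to zero mean over the
        torso electrodes.
        """
        sigma_s = self.source_sigma()
        # infinite-medium gain of each source triangle at interface nodes
        G_inf = -solid_angle_matrix(source, self.nodes) / (4.0 * np.pi * sigma_s)
        phi_if = self.solve_interface(G_inf)  # (n_nodes, m_tris)

        el_idx = self.anatomy.electrode_node_indices()  # torso surface nodes
        torso_off = self._offsets[self.anatomy.torso_index]
        A_el = phi_if[torso_off + el_idx]
        ref = A_el.mean(axis=0)

        if isinstance(observation, str) and observation == "electrodes":
            A = A_el - ref
            obs_id = "electrodes"
        else:
            pts = np.atleast_2d(np.asarray(observation, dtype=float))
            G_inf_pts = -solid_angle_matrix(source, pts) / (4.0 * np.pi * sigma_s)
            A = self._interior_composition(pts, G_inf_pts, phi_if) - ref
            obs_id = f"points[{len(pts)}]"
        if not np.all(np.isfinite(A)):
            raise FloatingPointError("non-finite transfer-matrix entries")
        return TransferMatrix(
            A,
            source,
            observation_id=obs_id,
            metadata={
                "conductivities": {
                    c.surface.name: (c.sigma_in, c.sigma_out)
                    for c in self.anatomy.compartments
                },
                "deflation": "rank-one mean projector",
                "reference": "zero mean over torso electrodes",
            },
        )


def assemble_transfer_matrix(
    anatomy, source: TriSurface, observation: str | np.ndarray = "electrodes"
) -> TransferMatrix:
    """One-shot transfer-matrix assembly (see :class:`VolumeConductor`)."""
    return VolumeConductor(anatomy).transfer_matrix(source, observation)
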