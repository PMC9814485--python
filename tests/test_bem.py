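"""Volume conductor: infinite-medium kernel and BEM transfer matrices."""

import numpy as np
import pytest

from edlsim.anatomy import Compartment, _ellipsoid_inside
from edlsim.bem import (
    TransferMatrix,
    VolumeConductor,
    infinite_medium_potential,
    solid_angle_matrix,
)
from edlsim.mesh import TriSurface, icosphere


def spherical_cap(radius=10.0, half_angle_deg=25.0, rings=6, segs=16):
    """Open spherical-cap mesh around +z (outward normals)."""
    thetas = np.linspace(0.0, np.deg2rad(half_angle_deg), rings + 1)
    verts = [np.array([0.0, 0.0, radius])]
    ring_start = [0]
    for th in thetas[1:]:
        phi = np.linspace(0, 2 * np.pi, segs, endpoint=False)
        ring_start.append(len(verts))
        for p in phi:
            verts.append(radius * np.array([np.sin(th) * np.cos(p), np.sin(th) * np.sin(p), np.cos(th)]))
    tris = []
    for s in range(segs):
        tris.append([0, 1 + s, 1 + (s + 1) % segs])
    for r in range(1, rings):
        a, b = ring_start[r], ring_start[r + 1]
        for s in range(segs):
            s2 = (s + 1) % segs
            tris.append([a + s, b + s, b + s2])
            tris.append([a + s, b + s2, a + s2])
    return TriSurface(np.asarray(verts), np.asarray(tris), "cap")


class TestInfiniteMedium:
    def test_uniform_closed_layer_exterior_zero(self):
        s = icosphere(2, 10.0)
        strengths = np.full(s.n_vertices, 8.0)
        phi = infinite_medium_potential(s, strengths, 0.2, np.array([[30.0, 0, 0], [0, 0, -15.0]]))
        assert np.abs(phi).max() < 1e-9

    def test_uniform_closed_layer_interior_full_step(self):
        s = icosphere(2, 10.0)
        M, sigma = 8.0, 0.2
        phi = infinite_medium_potential(s, np.full(s.n_vertices, M), sigma, np.array([[1.0, 2.0, 0.5]]))
        assert np.isclose(phi[0], -M / sigma, atol=1e-9)  # -40 mV

    def test_cap_against_quadrature_oracle(self):
        """Closed-form triangle solid angles vs direct surface quadrature."""
        cap = spherical_cap()
        y = np.array([25.0, 5.0, 4.0])
        M, sigma = 8.0, 0.2
        phi = infinite_medium_potential(cap, np.full(cap.n_vertices, M), sigma, y[None, :])[0]
        # oracle: centroid-rule quadrature of the dipole-layer integral on a
        # 16x-subdivided mesh, using the raw kernel (x-y).n / |x-y|^3
        sub = cap
        for _ in range(2):
            sub = _subdivide(sub)
        c = sub.triangle_corners()
        centroids = c.mean(axis=1)
        cross = np.cross(c[:, 1] - c[:, 0], c[:, 2] - c[:, 0])  # 2*area*n
        rvec = centroids - y
        r = np.linalg.norm(rvec, axis=1)
        domega = 0.5 * np.einsum("ij,ij->i", rvec, cross) / r**3
        phi_oracle = -M / (4 * np.pi * sigma) * domega.sum()
        assert abs(phi - phi_oracle) <= 1e-3 * abs(phi_oracle)

    def test_invalid_sigma(self):
        s = icosphere(1, 1.0)
        with pytest.raises(ValueError):
            infinite_medium_potential(s, np.ones(s.n_vertices), 0.0, np.array([[2.0, 0, 0]]))


def _subdivide(surface: TriSurface) -> TriSurface:
    import trimesh

    m = surface.to_trimesh().subdivide()
    return TriSurface(np.asarray(m.vertices), np.asarray(m.faces), surface.name)


class TestTransferMatrix:
    def test_uniform_closed_source_zero_at_electrodes(self, anatomy, conductor):
        A = conductor.transfer_matrix(anatomy.source_surface)
        phi = A.potentials(np.full(anatomy.source_surface.n_triangles, 8.0))
        assert np.abs(phi).max() < 1e-6

    def test_row_sums_near_zero(self, anatomy, conductor):
        A = conductor.transfer_matrix(anatomy.source_surface)
        assert np.abs(A.triangle_gains.sum(axis=1)).max() < 1e-6 / 8.0

    def test_interior_point_full_step(self, anatomy, conductor):
        # a point inside the myocardial wall sees the full potential step
        pt = np.array([[-38.0, -40.0, -10.0]])
        A = conductor.transfer_matrix(anatomy.source_surface, pt)
        phi = A.potentials(np.full(anatomy.source_surface.n_triangles, 8.0))
        assert np.isclose(phi[0], -40.0, atol=1e-6)

    def test_superposition_linearity(self, anatomy, conductor):
        A = conductor.transfer_matrix(anatomy.source_surface)
        rng = np.random.default_rng(0)
        s1 = rng.uniform(0, 8, anatomy.source_surface.n_triangles)
        s2 = rng.uniform(0, 8, anatomy.source_surface.n_triangles)
        assert np.allclose(A.potentials(s1 + s2), A.potentials(s1) + A.potentials(s2), atol=1e-12)

    def test_node_gains_shape(self, anatomy, conductor):
        A = conductor.transfer_matrix(anatomy.source_surface)
        assert A.gains.shape == (64, anatomy.source_surface.n_vertices)

    def test_cache_roundtrip(self, tmp_path, anatomy, conductor):
        A = conductor.transfer_matrix(anatomy.source_surface)
        A.save(tmp_path / "tm")
        B = TransferMatrix.load(tmp_path / "tm", anatomy.source_surface)
        assert np.array_equal(A.triangle_gains, B.triangle_gains)
        with pytest.raises(ValueError):
            TransferMatrix.load(tmp_path / "tm", anatomy.torso)


class TestOracles:
    def test_dipole_in_homogeneous_sphere(self, sphere_anatomy):
        """Small central EDL cap vs the analytic dipole-in-sphere potential."""
        an = sphere_anatomy
        a_r, n_seg = 3.0, 12
        ang = np.linspace(0, 2 * np.pi, n_seg, endpoint=False)
        verts = np.vstack(
            [[0, 0, 0], np.column_stack([a_r * np.cos(ang), a_r * np.sin(ang), np.zeros(n_seg)])]
        )
        tris = np.array([[0, 1 + i, 1 + (i + 1) % n_seg] for i in range(n_seg)])
        disk = TriSurface(verts, tris, "disk")
        M = 8.0
        A = VolumeConductor(an).transfer_matrix(disk)
        phi = A.potentials(np.full(disk.n_triangles, M))
        p = M * disk.triangle_areas().sum()  # dipole moment along +z
        sph = an.surface
        cos_t = sph.vertices[:, 2] / np.linalg.norm(sph.vertices, axis=1)
        phi_ref = 3 * p * cos_t / (4 * np.pi * an.sigma_myocardium * an.radius**2)
        phi_ref -= phi_ref.mean()
        assert np.abs(phi - phi_ref).max() <= 0.02 * np.abs(phi_ref).max()

    def test_homogeneous_limit_matches_infinite_medium(self):
        """Equal conductivities + far boundary reduce to the open medium."""
        sigma = 0.2
        big = icosphere(2, 400.0, "far_boundary")

        class FarAnatomy:
            compartments = [Compartment(big, sigma, 0.0, _ellipsoid_inside((0, 0, 0), (400.0,) * 3))]
            sigma_myocardium = sigma
            torso_index = 0

            def electrode_node_indices(self):
                return np.arange(big.n_vertices)

            def conductivity_at(self, pts):
                return self.compartments[0].contains(pts) * sigma

        src = icosphere(2, 10.0, "src")
        strengths = np.zeros(src.n_triangles)
        strengths[:40] = 8.0  # open cap pattern
        pts = np.array([[30.0, 0.0, 0.0], [0.0, -25.0, 10.0], [-20.0, 20.0, -20.0]])
        A = VolumeConductor(FarAnatomy()).transfer_matrix(src, pts)
        phi_bem = A.potentials(strengths)
        om = solid_angle_matrix(src, pts)
        phi_inf = -(om @ strengths) / (4 * np.pi * sigma)
        phi_inf -= (-(solid_angle_matrix(src, big.vertices) @ strengths) / (4 * np.pi * sigma)).mean()
        assert np.abs(phi_bem - phi_inf).max() <= 0.01 * np.abs(phi_inf).max()
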