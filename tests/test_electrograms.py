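"""Electrograms: bipolar voltages, LAT annotation, low-voltage patches."""

import numpy as np
import pytest

from edlsim.electrograms import (
    annotate_lat,
    bipolar_from_unipolar,
    cardiac_observation_points,
    fractionation_index,
)
from edlsim.mesh import icosphere
from edlsim.sources import PotentialTraces


@pytest.fixture(scope="module")
def small_surface():
    return icosphere(subdivisions=1, radius=10.0)  # 42 nodes


def traces_for(surface, values, dt=1.0):
    t = np.arange(values.shape[1]) * dt
    return PotentialTraces(t, values, labels=[f"n{i}" for i in range(len(values))])


class TestBipolar:
    def test_identical_traces_zero_voltage(self, small_surface):
        v = np.tile(np.sin(np.linspace(0, 3, 50)), (small_surface.n_vertices, 1))
        egms = bipolar_from_unipolar(traces_for(small_surface, v), small_surface)
        assert np.allclose(egms.bipolar_voltage, 0.0)
        assert len(egms.isolated) == 0

    def test_step_trace_dominates(self, small_surface):
        v = np.zeros((small_surface.n_vertices, 40))
        v[0, 20:] = 2.0  # 2 mV step at node 0, neighbours flat
        egms = bipolar_from_unipolar(traces_for(small_surface, v), small_surface)
        assert egms.bipolar_voltage[0] >= 2.0

    def test_against_exhaustive_maximum(self, small_surface):
        rng = np.random.default_rng(3)
        v = rng.normal(size=(small_surface.n_vertices, 60)).cumsum(axis=1) * 0.1
        egms = bipolar_from_unipolar(traces_for(small_surface, v), small_surface)
        edges = small_surface.edge_array()
        for i in range(small_surface.n_vertices):
            nbrs = np.concatenate(
                [edges[edges[:, 0] == i, 1], edges[edges[:, 1] == i, 0]]
            )
            oracle = max(np.abs(v[i] - v[j]).max() for j in nbrs)
            assert np.isclose(egms.bipolar_voltage[i], oracle)

    def test_self_bipolar_identically_zero(self, small_surface):
        v = np.random.default_rng(0).normal(size=(small_surface.n_vertices, 30))
        egms = bipolar_from_unipolar(traces_for(small_surface, v), small_surface)
        assert np.all(egms.bipolar_trace(5, 5) == 0.0)


class TestLAT:
    def test_simulated_mode_returns_delta(self, small_surface):
        delta = np.linspace(0, 80, small_surface.n_vertices)
        v = np.zeros((small_surface.n_vertices, 10))
        egms = bipolar_from_unipolar(traces_for(small_surface, v), small_surface)
        lat = annotate_lat(egms, mode="simulated", activation_times=delta)
        assert np.array_equal(lat, delta)

    def test_electrogram_mode_finds_step(self, small_surface):
        n = small_surface.n_vertices
        t_star = 25
        v = np.zeros((n, 60))
        v[0, t_star:] = -3.0  # sharp downstroke at node 0 only
        egms = bipolar_from_unipolar(traces_for(small_surface, v), small_surface)
        lat = annotate_lat(egms, mode="electrogram")
        assert abs(lat[0] - t_star) <= 1.0

    def test_downslope_variant_matches_refined_grid(self, small_surface):
        n = small_surface.n_vertices
        t = np.arange(0, 60.0, 1.0)
        t_star = 31.0
        v = np.tile(-2.0 / (1.0 + np.exp(-(t - t_star))), (n, 1))
        v += np.linspace(0, 0.1, n)[:, None]  # distinct offsets
        egms = bipolar_from_unipolar(
            PotentialTraces(t, v, labels=[f"n{i}" for i in range(n)]), small_surface
        )
        lat = annotate_lat(egms, mode="unipolar_downslope")
        # oracle: dense-grid argmin of dV/dt of the analytic waveform
        tf = np.arange(0, 60.0, 0.01)
        wf = -2.0 / (1.0 + np.exp(-(tf - t_star)))
        t_oracle = tf[np.argmin(np.gradient(wf, tf))]
        assert np.all(np.abs(lat - t_oracle) <= 1.0)

    def test_flat_trace_flagged(self, small_surface):
        v = np.zeros((small_surface.n_vertices, 30))
        egms = bipolar_from_unipolar(traces_for(small_surface, v), small_surface)
        lat = annotate_lat(egms, mode="electrogram")
        assert np.all(np.isnan(lat))


class TestSilentPatchVoltageMap:
    def test_silent_patch_region_has_lower_voltage(self, anatomy, conductor, patched, vmap):
        """An electrically silent patch depresses local bipolar voltage."""
        from edlsim.activation import delayed_patch_activation
        from edlsim.sources import SourceConfig, simulate_potentials

        # a mapping catheter touches the anatomical surface from outside;
        # over the diseased region the local source is the (silenced) patch
        surf = anatomy.ventricles.surface
        obs = cardiac_observation_points(surf, offset_mm=0.5, side="outside")
        A_v = conductor.transfer_matrix(patched.ventricles.surface, obs)
        A_p = conductor.transfer_matrix(patched.patches[0].mesh, obs)
        pmap = delayed_patch_activation(patched, vmap, 0.45)
        uni = simulate_potentials(
            {"ventricles": A_v, "patch_0": A_p},
            {"ventricles": vmap, "patch_0": pmap},
            SourceConfig(),
            strength_scales={"patch_0": 0.0},  # silent diseased region
            labels=[f"n{i}" for i in range(surf.n_vertices)],
        )
        egms = bipolar_from_unipolar(uni, surf)
        p = patched.patches[0]
        region = p.orig_vertex_id[p.outer_ids]
        epi = anatomy.ventricles.epi_vertex_ids
        outside = np.setdiff1d(epi, p.orig_vertex_id)
        assert np.median(egms.bipolar_voltage[region]) < np.median(
            egms.bipolar_voltage[outside]
        )


def test_observation_points_inside_wall(anatomy):
    surf = anatomy.source_surface
    obs = cardiac_observation_points(surf, offset_mm=0.5)
    d = np.linalg.norm(obs - surf.vertices, axis=1)
    assert np.allclose(d, 0.5, atol=1e-9)
    assert np.all(anatomy.conductivity_at(obs) > 0)


def test_fractionation_counts_deflections(small_surface):
    t = np.arange(0, 100.0)
    smooth = -1.0 / (1.0 + np.exp(-(t - 40)))
    wiggly = smooth + 0.8 * np.sin(t / 3.0) * np.exp(-((t - 50) ** 2) / 400)
    v = np.vstack([np.tile(smooth, (small_surface.n_vertices - 1, 1)), wiggly])
    egms = bipolar_from_unipolar(
        PotentialTraces(t, v, labels=[f"n{i}" for i in range(len(v))]), small_surface
    )
    counts = fractionation_index(egms)
    assert counts[-1] > counts[0]
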