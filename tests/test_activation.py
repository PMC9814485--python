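"""Fastest-route activation: oracles, patch activation semantics."""

import numpy as np
import pytest

from edlsim.activation import (
    ActivationGraph,
    FocusSet,
    Velocities,
    delayed_patch_activation,
    discontinuous_connection_set,
    dyssynchronous_patch_activation,
    fastest_route,
    ventricular_activation,
)


def chain_graph(n=11, spacing=1.0):
    edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return ActivationGraph(
        n, edges, np.full(n - 1, spacing), np.full(n - 1, "surface", dtype=object)
    )


def bellman_ford(n, edges, weights, sources, onsets):
    """Independent shortest-path oracle: repeated edge relaxation."""
    dist = np.full(n, np.inf)
    dist[sources] = onsets
    for _ in range(n):
        changed = False
        for (i, j), w in zip(edges, weights):
            if dist[i] + w < dist[j]:
                dist[j] = dist[i] + w
                changed = True
            if dist[j] + w < dist[i]:
                dist[i] = dist[j] + w
                changed = True
        if not changed:
            break
    return dist


class TestFastestRoute:
    def test_chain_closed_form(self):
        g = chain_graph()
        m = fastest_route(g, FocusSet([0], [0.0]), Velocities(surface=1.0))
        assert np.allclose(m.times, np.arange(11.0))  # 1 mm at 1 m/s = 1 ms

    def test_two_foci_min_property(self):
        g = chain_graph()
        v = Velocities(surface=1.0)
        left = fastest_route(g, FocusSet([0], [0.0]), v).times
        right = fastest_route(g, FocusSet([10], [0.0]), v).times
        both = fastest_route(g, FocusSet([0, 10], [0.0, 0.0]), v).times
        assert np.allclose(both, np.minimum(left, right))

    def test_onset_offsets_respected(self):
        g = chain_graph()
        m = fastest_route(g, FocusSet([0, 10], [0.0, 3.0]), Velocities(surface=1.0))
        assert np.allclose(m.times, np.minimum(np.arange(11.0), 3.0 + np.arange(10, -1, -1.0)))

    def test_random_graph_against_bellman_ford(self):
        rng = np.random.default_rng(42)
        n = 50
        edges = np.array([(i, j) for i in range(n) for j in range(i + 1, n) if rng.random() < 0.12])
        lengths = rng.uniform(0.5, 5.0, len(edges))
        g = ActivationGraph(n, edges, lengths, np.full(len(edges), "surface", dtype=object))
        foci = FocusSet([0, 17, 33], [0.0, 2.0, 5.0])
        v = Velocities(surface=0.85)
        m = fastest_route(g, foci, v)
        oracle = bellman_ford(n, edges, lengths / 0.85, foci.nodes, foci.onsets)
        finite = np.isfinite(oracle)
        assert np.allclose(m.times[finite], oracle[finite], atol=1e-9)
        assert np.array_equal(np.isfinite(m.times), finite)

    def test_transmural_crossing_time(self):
        """10 mm perpendicular at 0.85/2.5 = 0.34 m/s takes ~29.4 ms."""
        edges = np.array([[0, 1]])
        g = ActivationGraph(2, edges, np.array([10.0]), np.array(["transmural"], dtype=object))
        m = fastest_route(g, FocusSet([0], [0.0]), Velocities(surface=0.85, transmural_factor=2.5))
        assert np.isclose(m.times[1], 10.0 / 0.34, atol=0.05)  # 29.41 ms

    def test_unreachable_flagged(self):
        g = chain_graph(5)
        g2 = ActivationGraph(6, g.edges, g.lengths, g.classes)  # node 5 isolated
        m = fastest_route(g2, FocusSet([0], [0.0]), Velocities(surface=1.0))
        assert np.array_equal(m.unreachable, [5])

    def test_triangle_inequality(self, anatomy, vmap):
        """delta satisfies the graph-metric triangle inequality on edges."""
        from edlsim.activation import build_ventricular_graph

        g = build_ventricular_graph(anatomy.ventricles)
        v = Velocities()
        for (i, j), L, cls in zip(g.edges, g.lengths, g.classes):
            w = L / v.of_class(cls)
            assert vmap.times[j] <= vmap.times[i] + w + 1e-9
            assert vmap.times[i] <= vmap.times[j] + w + 1e-9


class TestPatchActivation:
    def test_normal_velocity_full_connection_reproduces_unpatched(self, patched, vmap):
        pmap = delayed_patch_activation(patched, vmap, 0.85)
        ref = vmap.times[patched.patches[0].orig_vertex_id]
        assert np.abs(pmap.times - ref).max() < 1e-6

    def test_connected_nodes_inherit_ventricular_delta(self, patched, vmap):
        p = patched.patches[0]
        pmap = delayed_patch_activation(patched, vmap, 0.4)
        assert np.array_equal(pmap.times[p.inner_ids], vmap.times[p.orig_vertex_id[p.inner_ids]])

    def test_patch_never_precedes_connected_set(self, patched, vmap):
        p = patched.patches[0]
        pmap = delayed_patch_activation(patched, vmap, 0.3)
        assert pmap.times.min() >= vmap.times[p.orig_vertex_id[p.inner_ids]].min() - 1e-9

    def test_slower_patch_strictly_larger_delays(self, patched, vmap):
        """Internal patch delays relative to normal grow as velocity drops."""
        ref = vmap.times[patched.patches[0].orig_vertex_id]
        d25 = delayed_patch_activation(patched, vmap, 0.25).times - ref
        d65 = delayed_patch_activation(patched, vmap, 0.65).times - ref
        assert d25.max() > d65.max() > 0.0
        assert np.all(d25 >= d65 - 1e-9)

    def test_halving_velocity_doubles_internal_delays(self, patched, vmap):
        """Pure surface propagation scales as 1/v (uniform-onset connected set)."""
        p = patched.patches[0]
        uniform = type(vmap)(np.full_like(vmap.times, 10.0), "ventricles", dict(vmap.metadata))
        t1 = delayed_patch_activation(patched, uniform, 0.5, thickness_mode="none").times
        t2 = delayed_patch_activation(patched, uniform, 0.25, thickness_mode="none").times
        free = np.setdiff1d(np.arange(p.mesh.n_vertices), p.inner_ids)
        assert np.allclose(t2[free] - 10.0, 2.0 * (t1[free] - 10.0), rtol=1e-9)

    def test_velocity_bounds_enforced(self, patched, vmap):
        with pytest.raises(ValueError):
            delayed_patch_activation(patched, vmap, 0.0)
        with pytest.raises(ValueError):
            delayed_patch_activation(patched, vmap, 1.2)


class TestDyssynchronous:
    def test_zero_jitter_equals_delayed(self, patched, vmap):
        base = delayed_patch_activation(patched, vmap, 0.45)
        dys = dyssynchronous_patch_activation(patched, vmap, 0.0, seed=1)
        assert np.allclose(dys.times, base.times)

    def test_seed_determinism(self, patched, vmap):
        a = dyssynchronous_patch_activation(patched, vmap, 60.0, seed=5)
        b = dyssynchronous_patch_activation(patched, vmap, 60.0, seed=5)
        c = dyssynchronous_patch_activation(patched, vmap, 60.0, seed=6)
        assert np.array_equal(a.times, b.times)
        assert not np.array_equal(a.times, c.times)

    def test_offsets_within_bounds(self, patched, vmap):
        p = patched.patches[0]
        base = delayed_patch_activation(patched, vmap, 0.45)
        for jit in (30.0, 90.0):
            dys = dyssynchronous_patch_activation(patched, vmap, jit, seed=2)
            off = dys.times - base.times
            assert off.min() >= 0.0 and off.max() <= jit
            assert np.allclose(off[p.inner_ids], 0.0)  # connected nodes keep delta


class TestConnectionSets:
    def test_full_inner_counts(self, patched, vmap):
        p = patched.patches[0]
        c = discontinuous_connection_set(p, "full_inner", vmap)
        assert len(c) == len(p.inner_ids)

    def test_ring_subset_relations(self, patched, vmap):
        p = patched.patches[0]
        full = set(discontinuous_connection_set(p, "full_inner", vmap))
        ring = set(discontinuous_connection_set(p, "outer_ring_full", vmap))
        latest = set(discontinuous_connection_set(p, "outer_ring_latest_25pct", vmap))
        assert ring <= full and latest <= ring

    def test_latest_quartile_definition(self, patched, vmap):
        p = patched.patches[0]
        ring = discontinuous_connection_set(p, "outer_ring_full", vmap)
        latest = discontinuous_connection_set(p, "outer_ring_latest_25pct", vmap)
        assert len(latest) == int(np.ceil(0.25 * len(ring)))
        delta = vmap.times[p.orig_vertex_id]
        excluded = np.setdiff1d(ring, latest)
        assert delta[latest].min() >= delta[excluded].max() - 1e-12

    def test_discontinuous_starts_at_edge(self, patched, vmap):
        """With a type-1 isolating layer, the patch activates from its rim."""
        p = patched.patches[0]
        p.spec.connection_type = "outer_ring_full"
        try:
            pmap = delayed_patch_activation(patched, vmap, 0.45)
        finally:
            p.spec.connection_type = "full_inner"
        ring_delta = pmap.times[p.ring_ids]
        inner_free = np.setdiff1d(p.inner_ids, p.ring_ids)
        assert pmap.times[inner_free].min() >= ring_delta.min()


def test_default_foci_layout(anatomy, foci):
    assert len(foci.nodes) == 7
    labels = set(foci.labels)
    assert sum(l.startswith("lv") for l in labels) == 4
    assert sum(l.startswith("rv") for l in labels) == 3
    assert np.all(np.isin(foci.nodes, anatomy.ventricles.endo_vertex_ids))
    assert np.all(foci.onsets == 0.0)


def test_ventricular_activation_reaches_everywhere(vmap):
    assert len(vmap.unreachable) == 0
    assert vmap.times.min() == 0.0
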