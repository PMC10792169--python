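"""Discrete shape operator, parallel transport and inclusion pair angles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dtsmem as d
from dtsmem.geometry import (euler_directional_curvatures, pair_angles,
                             parallel_transport, refresh_region)
from tests.conftest import sphere_radius


class TestCurvature:
    def test_sphere_principal_curvatures(self, icosphere3, geom_sphere3):
        r = sphere_radius(icosphere3)
        h = geom_sphere3.mean_curvature
        assert np.all(h > 0)  # convex, outward normals
        assert np.abs(h * r - 1.0).max() < 0.02
        # individual principal curvatures split around 1/R by the
        # discretization (the sphere is umbilic); the split stays small
        assert np.abs(geom_sphere3.c1 * r - 1.0).max() < 0.08
        assert np.abs(geom_sphere3.c2 * r - 1.0).max() < 0.08

    def test_flat_sheet_is_flat(self, flat88, geom_flat):
        assert np.abs(geom_flat.c1).max() < 1e-10
        assert np.abs(geom_flat.c2).max() < 1e-10
        assert np.allclose(geom_flat.normal, [0.0, 0.0, 1.0])

    def test_tube_curvatures_and_directions(self, tube1616):
        g = d.SurfaceGeometry(tube1616)
        center = tube1616.pos[:, :2].mean(axis=0)
        rho = float(np.linalg.norm(tube1616.pos[:, :2] - center,
                                   axis=1).mean())
        assert np.abs(g.c1 * rho - 1.0).max() < 0.03
        assert np.abs(g.c2 * rho).max() < 0.03
        # T1 circumferential within 5 degrees
        circ = np.cross([0.0, 0.0, 1.0], g.normal)
        circ /= np.linalg.norm(circ, axis=1)[:, None]
        cosang = np.abs(np.einsum("ij,ij->i", g.t1, circ))
        assert np.degrees(np.arccos(np.clip(cosang, 0, 1))).max() < 5.0

    def test_gauss_bonnet_sphere(self, icosphere3, geom_sphere3):
        total = float((geom_sphere3.gaussian_curvature
                       * geom_sphere3.area).sum())
        assert total == pytest.approx(4 * np.pi, rel=0.01)

    def test_gauss_bonnet_torus(self, torus_fine):
        g = d.SurfaceGeometry(torus_fine)
        total = float((g.gaussian_curvature * g.area).sum())
        assert abs(total) < 0.05 * 4 * np.pi

    def test_vertex_area_allocation_is_exact(self, icosphere3, geom_sphere3):
        # sum of barycentric vertex areas == sum of triangle areas
        assert geom_sphere3.area.sum() == pytest.approx(
            geom_sphere3.tri_area.sum(), rel=1e-12)

    def test_principal_frame_orthonormal(self, geom_sphere3):
        g = geom_sphere3
        assert np.allclose(np.einsum("ij,ij->i", g.t1, g.t2), 0, atol=1e-9)
        assert np.allclose(np.einsum("ij,ij->i", g.t1, g.normal), 0,
                           atol=1e-9)
        assert np.allclose(np.linalg.norm(g.t1, axis=1), 1, atol=1e-9)
        assert np.all(g.c1 >= g.c2 - 1e-12)


class TestRefreshRegion:
    def test_dependency_radius(self, flat88):
        g = d.SurfaceGeometry(flat88)
        out = refresh_region(flat88, g, [10])
        assert len(out) == 1 + int(flat88.deg[10])

    def test_incremental_matches_full(self, flat88, rng):
        m = flat88.copy()
        g = d.SurfaceGeometry(m)
        for _ in range(20):
            v = int(rng.integers(m.n_vertices))
            m.pos[v] += rng.normal(0, 0.05, 3)
            refresh_region(m, g, [v])
        full = d.SurfaceGeometry(m)
        for name in ("area", "normal", "c1", "c2", "t1", "t2"):
            np.testing.assert_allclose(getattr(g, name), getattr(full, name),
                                       atol=1e-12)

    def test_empty_set(self, flat88, geom_flat):
        assert refresh_region(flat88, geom_flat, []).size == 0


class TestEulerFormula:
    @given(c1=st.floats(-2, 2), c2=st.floats(-2, 2),
           theta=st.floats(0, 2 * math.pi))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_trace_invariance(self, c1, c2, theta):
        cp, cq = euler_directional_curvatures(c1, c2, theta)
        assert cp + cq == pytest.approx(c1 + c2, abs=1e-9)

    def test_axis_aligned_cases(self):
        assert euler_directional_curvatures(0.7, -0.2, 0.0) == \
            pytest.approx((0.7, -0.2))
        cp, cq = euler_directional_curvatures(0.7, -0.2, math.pi / 2)
        assert (cp, cq) == pytest.approx((-0.2, 0.7))


class TestParallelTransport:
    def test_identity_on_flat_sheet(self, flat88, geom_flat):
        v = 20
        u = int(flat88.neigh[v, 0])
        vec = np.array([1.0, 0.0, 0.0])
        out = parallel_transport(flat88, geom_flat, v, u, vec)
        np.testing.assert_allclose(out, vec, atol=1e-12)

    def test_norm_preserved_and_invertible(self, icosphere3, geom_sphere3):
        m, g = icosphere3, geom_sphere3
        v = 40
        u = int(m.neigh[v, 1])
        vec = 0.7 * g.t1[v] + 0.3 * g.t2[v]
        out = parallel_transport(m, g, v, u, vec)
        assert np.linalg.norm(out) == pytest.approx(np.linalg.norm(vec),
                                                    abs=1e-12)
        back = parallel_transport(m, g, u, v, out)
        np.testing.assert_allclose(back, vec, atol=1e-10)

    def test_flat_loop_has_zero_holonomy(self, flat88, geom_flat):
        m, g = flat88, geom_flat
        v0 = 27
        ring = [int(u) for u in m.neigh[v0, :int(m.deg[v0])]]
        vec = np.array([0.6, 0.8, 0.0])
        cur = vec.copy()
        path = [v0] + ring + [v0]
        for a, b in zip(path[:-1], path[1:]):
            cur = parallel_transport(m, g, a, b, cur)
        np.testing.assert_allclose(cur, vec, atol=1e-10)

    def test_sphere_octant_loop_holonomy(self):
        """Transport around a geodesic octant rotates by the enclosed solid
        angle (pi/2).  Oracle: the octant of a sphere subtends 4pi/8."""
        m = d.build_icosphere(4, radius=20.0, check_window=False)
        g = d.SurfaceGeometry(m)
        c = m.pos.mean(axis=0)

        def nearest(direction):
            return int(np.argmax((m.pos - c) @ direction))

        # walk along great-circle arcs x->y->z->x through nearest vertices
        def arc(a, b, steps=40):
            pa = m.pos[a] - c
            pb = m.pos[b] - c
            pts = []
            for t in np.linspace(0, 1, steps):
                q = (1 - t) * pa + t * pb
                pts.append(nearest(q / np.linalg.norm(q)))
            # deduplicate consecutive
            out = [pts[0]]
            for p in pts[1:]:
                if p != out[-1]:
                    out.append(p)
            return out

        vx = nearest(np.array([1.0, 0, 0]))
        vy = nearest(np.array([0, 1.0, 0]))
        vz = nearest(np.array([0, 0, 1.0]))
        loop = arc(vx, vy) + arc(vy, vz)[1:] + arc(vz, vx)[1:]
        # make consecutive vertices adjacent by local hops
        path = [loop[0]]
        for target in loop[1:]:
            while path[-1] != target:
                v = path[-1]
                nbrs = m.neigh[v, :int(m.deg[v])]
                tdir = m.pos[target] - m.pos[v]
                best = int(nbrs[np.argmax(
                    (m.pos[nbrs] - m.pos[v]) @ tdir)])
                path.append(best)
        vec = g.t1[path[0]].copy()
        cur = vec.copy()
        for a, b in zip(path[:-1], path[1:]):
            cur = parallel_transport(m, g, a, b, cur)
        cosang = float(np.clip(cur @ vec, -1, 1))
        angle = math.acos(cosang)
        assert angle == pytest.approx(math.pi / 2, abs=0.15)


class TestPairAngles:
    def _flat_pair(self):
        m = d.build_flat_grid(6, 6, 1.2)
        g = d.SurfaceGeometry(m)
        v = 14
        u = int(m.neigh[v, 0])
        r = m.min_image(m.pos[u] - m.pos[v])
        r /= np.linalg.norm(r)
        return m, g, v, u, r

    def test_parallel_directions_give_zero(self):
        m, g, v, u, r = self._flat_pair()
        th, ga = pair_angles(m, g, v, r, u, r)
        assert th == pytest.approx(0.0, abs=1e-12)
        assert ga == pytest.approx(0.0, abs=1e-12)

    def test_perpendicular_second_inclusion(self):
        m, g, v, u, r = self._flat_pair()
        perp = np.cross([0.0, 0.0, 1.0], r)
        th, _ = pair_angles(m, g, v, r, u, perp)
        assert abs(th) == pytest.approx(math.pi / 2, abs=1e-12)

    @pytest.mark.parametrize("fold,sign", [("ridge", 1.0), ("valley", -1.0)])
    def test_gamma_sign_follows_tip_rule(self, fold, sign):
        """Fold a flat sheet across an edge: a bump (surfaces folded away
        from each other, normal tips spreading) gives gamma > 0, a pit
        (folded toward each other) gives gamma < 0."""
        m = d.build_flat_grid(8, 8, 1.2)
        v = 27
        u = int(m.neigh[v, 0])
        m.pos[v, 2] += 0.4 * sign
        g = d.SurfaceGeometry(m)
        dvec = m.min_image(m.pos[u] - m.pos[v])
        dv_ = dvec - (dvec @ g.normal[v]) * g.normal[v]
        du_ = dvec - (dvec @ g.normal[u]) * g.normal[u]
        _, ga = pair_angles(m, g, v, dv_ / np.linalg.norm(dv_),
                            u, du_ / np.linalg.norm(du_))
        assert sign * ga > 0.05

    def test_rejects_non_adjacent_hosts(self, flat88, geom_flat):
        with pytest.raises(ValueError):
            pair_angles(flat88, geom_flat, 0, np.array([1.0, 0, 0]),
                        27, np.array([1.0, 0, 0]))
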