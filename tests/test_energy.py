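"""Membrane energy terms: analytic oracles and null cases."""

import math

import numpy as np
import pytest

import dtsmem as d
from dtsmem.energy import (area_coupling_energy, bending_energy,
                           enclosed_volume,
                           frame_tension_energy, global_curvature_energy,
                           osmotic_energy, volume_coupling_energy)
from tests.conftest import sphere_radius


class TestBending:
    def test_flat_sheet_zero(self, flat88, geom_flat):
        e = bending_energy(flat88, geom_flat, d.MembraneParams(20.0))
        assert abs(e) < 1e-12

    def test_sphere_helfrich_8pikappa(self, icosphere3, geom_sphere3):
        e = bending_energy(icosphere3, geom_sphere3, d.MembraneParams(20.0))
        assert e == pytest.approx(8 * math.pi * 20.0, rel=0.03)

    def test_matched_spontaneous_curvature(self, icosphere3, geom_sphere3):
        r = sphere_radius(icosphere3)
        e = bending_energy(icosphere3, geom_sphere3,
                           d.MembraneParams(20.0, cbar=2.0 / r))
        assert abs(e) < 0.02 * 8 * math.pi * 20.0

    def test_positive_gaussian_modulus_lowers_sphere_energy(
            self, icosphere3, geom_sphere3):
        kg = 5.0
        e0 = bending_energy(icosphere3, geom_sphere3, d.MembraneParams(20.0))
        e1 = bending_energy(icosphere3, geom_sphere3,
                            d.MembraneParams(20.0, kappa_g=kg))
        assert e1 - e0 == pytest.approx(-kg * 4 * math.pi, rel=0.01)

    def test_gaussian_term_topological_on_torus(self, torus_fine):
        g = d.SurfaceGeometry(torus_fine)
        e0 = bending_energy(torus_fine, g, d.MembraneParams(0.0))
        e1 = bending_energy(torus_fine, g, d.MembraneParams(0.0, kappa_g=7.0))
        # 2 pi chi = 0 for genus 1
        assert abs(e1 - e0) < 0.05 * 7.0 * 4 * math.pi


class TestCouplings:
    def test_area_coupling_null_and_direct(self, flat88, geom_flat):
        a = geom_flat.total_area
        assert area_coupling_energy(flat88, geom_flat, 100.0, a) == \
            pytest.approx(0.0, abs=1e-18)
        assert area_coupling_energy(flat88, geom_flat, 0.0, a / 2) == 0.0
        # A = 1.1 A0, K_A = 100: N_T * (K_A/2) * 0.1^2 = N_T * 0.5
        e = area_coupling_energy(flat88, geom_flat, 100.0, a / 1.1)
        assert e == pytest.approx(flat88.n_triangles * 0.5 * 100
                                  * (1.1 - 1.0) ** 2, rel=1e-9)

    def test_enclosed_volume_sphere(self, icosphere3, geom_sphere3):
        r = sphere_radius(icosphere3)
        v = enclosed_volume(icosphere3, geom_sphere3)
        assert v == pytest.approx(4.0 / 3.0 * math.pi * r ** 3, rel=0.01)

    def test_enclosed_volume_antisymmetric(self, icosphere2):
        m = icosphere2.copy()
        m.tris = m.tris[:, ::-1].copy()
        m._build_connectivity()
        v = enclosed_volume(m)
        assert v == pytest.approx(-enclosed_volume(icosphere2), rel=1e-12)

    def test_enclosed_volume_rejects_open_sheet(self, flat88):
        with pytest.raises(ValueError):
            enclosed_volume(flat88)

    def test_volume_coupling(self):
        assert volume_coupling_energy(3.0, 10.0, 0.0, 0.0, 1.0) == 0.0
        v0 = 8.0 ** 1.5 / (6 * math.sqrt(math.pi))
        assert volume_coupling_energy(v0, 8.0, 0.0, 500.0, 1.0) == \
            pytest.approx(0.0, abs=1e-12)
        # V = V0/2, v_t = 1, K = 1000: K/2 * (1/2 - 1)^2 = 125
        assert volume_coupling_energy(0.5 * v0, 8.0, 0.0, 1000.0, 1.0) == \
            pytest.approx(125.0, rel=1e-12)

    def test_osmotic_null_and_stationary_point(self):
        assert osmotic_energy(5.0, 1.0, 0.0, 0.0, 5.0) == 0.0
        assert osmotic_energy(5.0, 1.0, 2.0, 3.0, 5.0) == \
            pytest.approx(0.0, abs=1e-12)
        # stationary point where concentrations match: c_in V_ini / V = c_out
        rt, cin, cout, vini = 2.0, 3.0, 1.5, 4.0
        vstar = cin * vini / cout
        eps = 1e-5
        de = (osmotic_energy(vstar + eps, rt, cin, cout, vini)
              - osmotic_energy(vstar - eps, rt, cin, cout, vini)) / (2 * eps)
        assert abs(de) < 1e-6
        # and it is a minimum
        assert osmotic_energy(vstar * 1.1, rt, cin, cout, vini) > \
            osmotic_energy(vstar, rt, cin, cout, vini)

    def test_global_curvature(self, icosphere3, geom_sphere3, flat88,
                              geom_flat):
        r = sphere_radius(icosphere3)
        e = global_curvature_energy(icosphere3, geom_sphere3, 10.0, 2.0 / r)
        # M = (2/R) A on a sphere
        assert abs(e) < 0.01 * 10.0 * geom_sphere3.total_area / r ** 2
        assert global_curvature_energy(icosphere3, geom_sphere3, 0.0, 5.0) == 0
        a = geom_flat.total_area
        assert global_curvature_energy(flat88, geom_flat, 6.0, 0.0) == \
            pytest.approx(0.0, abs=1e-15)
        assert global_curvature_energy(flat88, geom_flat, 6.0, 0.3) == \
            pytest.approx(0.5 * 6.0 * a * 0.09, rel=1e-9)

    def test_frame_tension(self, flat88, icosphere2):
        assert frame_tension_energy(flat88.box, 0.0) == 0.0
        box = flat88.box.copy()
        box.lengths[:2] = 20.0
        assert frame_tension_energy(box, 2.0) == pytest.approx(-800.0)
        with pytest.raises(ValueError):
            frame_tension_energy(icosphere2.box, 1.0)

    def test_tension_monotone_in_projected_area(self, flat88):
        b1 = flat88.box.copy()
        b2 = flat88.box.copy()
        b2.lengths[0] *= 1.1
        assert frame_tension_energy(b2, 2.0) < frame_tension_energy(b1, 2.0)


class TestTotalEnergy:
    def test_all_couplings_off_flat_sheet(self, flat88):
        st = d.SimulationState(flat88.copy(),
                               membrane=d.MembraneParams(20.0), seed=1)
        assert st.total_energy() == pytest.approx(0.0, abs=1e-9)
        assert st.energy_running == pytest.approx(0.0, abs=1e-9)

    def test_energy_is_extensive(self, icosphere2):
        # two disjoint identical vesicles carry twice the energy of one
        m1 = icosphere2
        g1 = d.SurfaceGeometry(m1)
        e1 = bending_energy(m1, g1, d.MembraneParams(20.0))
        shift = m1.pos.max() + 20.0
        pos = np.vstack([m1.pos, m1.pos + np.array([shift, 0, 0])])
        tris = np.vstack([m1.tris, m1.tris + m1.n_vertices])
        box = d.Box(m1.box.lengths + np.array([shift + 40, 0, 0]),
                    m1.box.periodic)
        m2 = d.Mesh(pos, tris.astype(np.int32), box)
        e2 = bending_energy(m2, d.SurfaceGeometry(m2),
                            d.MembraneParams(20.0))
        assert e2 == pytest.approx(2 * e1, rel=1e-12)

    def test_incremental_tracks_full_recompute(self, flat88):
        st = d.SimulationState(
            flat88.copy(), membrane=d.MembraneParams(20.0, cbar=0.1),
            couplings=d.EnsembleCouplings(tension_on=True, tau=1.0,
                                          area_on=True, k_a=10.0,
                                          a0=1.05 * 110.0,
                                          global_curv_on=True, k_r=2.0,
                                          m0=0.05),
            seed=9)
        st.resync_every = 0  # disable periodic resync for this check
        st.mc_sweep(30)  # ~10^3 accepted moves
        full = st.total_energy()
        assert st.energy_running == pytest.approx(full, rel=1e-8, abs=1e-8)
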