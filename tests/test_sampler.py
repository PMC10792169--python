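"""Monte Carlo engine: determinism, constraints, frozen mode, consistency."""

import numpy as np
import pytest

import dtsmem as d
from dtsmem.inclusions import InclusionField, InclusionType, PairPotential
from dtsmem.sampler import zero_temperature_quench


def make_state(mesh, seed=3, frozen=False, coverage=0.0, couplings=None,
               force=None, kappa=20.0, delta=0.1):
    mesh = mesh.copy()
    geom = d.SurfaceGeometry(mesh)
    field = None
    if coverage:
        types = [InclusionType("p", 2, k1=5.0, c_par0=0.5)]
        field = InclusionField(mesh, types,
                               [PairPotential("p", "p", a=0.2, b=0.3)])
        field.place_random("p", coverage, geom,
                           np.random.default_rng(seed))
    return d.SimulationState(
        mesh, membrane=d.MembraneParams(kappa), couplings=couplings,
        inclusions=field, moves=d.MoveParams(delta=delta), force=force,
        frozen=frozen, seed=seed)


class TestDeterminism:
    def test_fixed_seed_reproduces_trajectory(self, flat88):
        s1 = make_state(flat88, seed=11, coverage=0.2)
        s2 = make_state(flat88, seed=11, coverage=0.2)
        s1.mc_sweep(40)
        s2.mc_sweep(40)
        assert np.array_equal(s1.mesh.pos, s2.mesh.pos)
        assert np.array_equal(s1.mesh.edges, s2.mesh.edges)
        assert np.array_equal(s1.inclusions.host, s2.inclusions.host)

    def test_restart_equals_uninterrupted(self, flat88):
        s1 = make_state(flat88, seed=4)
        s2 = make_state(flat88, seed=4)
        s1.mc_sweep(60)
        s2.mc_sweep(25)
        s2.mc_sweep(35)  # per-sweep seeding makes the split immaterial
        assert np.array_equal(s1.mesh.pos, s2.mesh.pos)
        assert s1.energy_running == pytest.approx(s2.energy_running,
                                                  rel=1e-12)

    def test_zero_sweeps_keep_initial_frame(self, flat88):
        s = make_state(flat88, seed=2)
        traj = s.run(0)
        assert len(traj.sweeps) >= 1
        assert traj.sweeps[0] == 0


class TestSweepComposition:
    def test_trial_counts_per_sweep(self, flat88):
        s = make_state(flat88, coverage=0.25)
        stats = s.mc_sweep(3)
        assert stats.attempted[0] == 3 * flat88.n_triangles
        assert stats.attempted[1] == 3 * flat88.n_vertices
        assert stats.attempted[2] == 3 * s.inclusions.n_inclusions
        assert stats.attempted[3] == 0  # no tension ensemble

    def test_box_trial_requires_tension(self, flat88):
        s = make_state(flat88, couplings=d.EnsembleCouplings(
            tension_on=True, tau=0.0))
        stats = s.mc_sweep(10)
        assert stats.attempted[3] == 10  # p_box = 1 per sweep

    def test_downhill_moves_always_accepted(self, flat88):
        # with every energy term off, any constraint-passing proposal has
        # dE = 0 and must be accepted: no Metropolis rejections at all
        s = make_state(flat88, kappa=0.0)
        stats = s.mc_sweep(20)
        metro_rejects = stats.attempted - stats.hard_rejected \
            - stats.accepted
        assert metro_rejects[1] == 0

    def test_hard_core_rejection_is_unconditional(self, flat88):
        # shrink the box margin: place two meshes? instead: tighten d_min
        # so that *every* displacement toward a neighbor violates it
        mesh = flat88.copy()
        st = d.SimulationState(mesh, membrane=d.MembraneParams(0.0),
                               constraints=d.Constraints(
                                   l_min=1.0, l_max=1.9, d_min=1.19),
                               moves=d.MoveParams(delta=0.02), seed=8)
        stats = st.mc_sweep(5)
        # lattice spacing 1.2: nearly any move violates d_min = 1.19
        assert stats.hard_rejected[1] > 0.8 * stats.attempted[1]
        assert st.audit() == 0


class TestFrozenMode:
    def test_coordinates_bit_identical(self, icosphere2):
        s = make_state(icosphere2, coverage=0.2, frozen=True)
        ref = s.mesh.pos.copy()
        tref = s.mesh.tris.copy()
        hosts0 = s.inclusions.host.copy()
        s.mc_sweep(50)
        assert np.array_equal(s.mesh.pos, ref)
        assert np.array_equal(s.mesh.tris, tref)
        assert not np.array_equal(s.inclusions.host, hosts0)  # they moved

    def test_shape_moves_raise(self, flat88):
        s = make_state(flat88, frozen=True, coverage=0.1)
        with pytest.raises(RuntimeError):
            s.attempt_vertex_move(0)


class TestEnergyBookkeeping:
    def test_incremental_matches_full_with_everything_on(self, icosphere2):
        s = make_state(icosphere2, coverage=0.2,
                       couplings=d.EnsembleCouplings(
                           volume_on=True, k_v=200.0, v_t=0.9,
                           area_on=True, k_a=5.0, a0=250.0,
                           global_curv_on=True, k_r=1.0, m0=0.1))
        s.resync_every = 0
        s.mc_sweep(40)
        assert s.energy_running == pytest.approx(s.total_energy(), rel=1e-8)

    def test_quench_monotonically_decreases_energy(self, flat88):
        mesh = flat88.copy()
        rng = np.random.default_rng(0)
        mesh.pos[:, 2] += rng.normal(0, 0.15, mesh.n_vertices)  # roughen
        s = d.SimulationState(mesh, membrane=d.MembraneParams(20.0), seed=6)
        energies = [s.total_energy()]
        for _ in range(5):
            zero_temperature_quench(s, 2)
            energies.append(s.total_energy())
        diffs = np.diff(energies)
        assert np.all(diffs <= 1e-6)
        assert energies[-1] < energies[0]


class TestInclusionMoves:
    def test_hop_onto_occupied_vertex_rejected(self, flat88):
        # fully covered membrane: every hop target is occupied
        mesh = flat88.copy()
        geom = d.SurfaceGeometry(mesh)
        field = InclusionField(mesh, [InclusionType("p", 1)])
        for v in range(mesh.n_vertices):
            field.add("p", v, geom=geom, angle=0.0)
        s = d.SimulationState(mesh, membrane=d.MembraneParams(20.0),
                              inclusions=field, frozen=True, seed=5)
        stats = s.mc_sweep(10)
        att, hard, acc = (stats.attempted[2], stats.hard_rejected[2],
                          stats.accepted[2])
        # ~half the trials are hops and all hops are occupancy-rejected;
        # rotations of a flat type-1 inclusion are free and all accepted
        assert hard + acc == att
        assert 0.35 < hard / att < 0.65

    def test_free_rotation_always_accepted(self, flat88):
        mesh = flat88.copy()
        geom = d.SurfaceGeometry(mesh)
        field = InclusionField(mesh, [InclusionType("p", 1)])
        field.add("p", 12, geom=geom, angle=0.0)
        s = d.SimulationState(mesh, membrane=d.MembraneParams(20.0),
                              inclusions=field, frozen=True, seed=5)
        stats = s.mc_sweep(100)
        metro_rejects = stats.attempted[2] - stats.hard_rejected[2] \
            - stats.accepted[2]
        assert metro_rejects == 0


class TestExternalForce:
    def test_energy_values(self, flat88):
        anchor = flat88.pos[10].copy()
        s = make_state(flat88, force=d.ExternalForce(10, anchor, 10.0))
        assert s.harmonic_force_energy() == pytest.approx(0.0)
        s.force.anchor = anchor + np.array([0.0, 0.0, 2.0])
        assert s.harmonic_force_energy() == pytest.approx(5.0 * 4.0)

    def test_pulled_vertex_rises(self, flat88):
        mesh = flat88.copy()
        anchor = mesh.pos[20] + np.array([0.0, 0.0, 4.0])
        s = d.SimulationState(mesh, membrane=d.MembraneParams(10.0),
                              force=d.ExternalForce(20, anchor, 20.0),
                              seed=13)
        z0 = mesh.pos[20, 2]
        s.mc_sweep(300)
        assert s.mesh.pos[20, 2] > z0 + 0.5


class TestBoxMove:
    def test_tensionless_frame_fluctuates_without_violations(self, flat88):
        s = make_state(flat88, couplings=d.EnsembleCouplings(
            tension_on=True, tau=0.0))
        ap0 = s.mesh.box.projected_area
        stats = s.mc_sweep(200)
        assert stats.accepted[3] > 0
        assert s.mesh.box.projected_area != ap0
        assert s.audit() == 0
        assert s.energy_running == pytest.approx(s.total_energy(), rel=1e-7)

    def test_requires_tension_ensemble(self, flat88):
        s = make_state(flat88)
        with pytest.raises(RuntimeError):
            s.attempt_box_resize()


class TestConfinement:
    def test_slab_walls_contain_the_membrane(self, flat88):
        mesh = flat88.copy()
        z0 = float(mesh.pos[0, 2])
        st = d.SimulationState(
            mesh, membrane=d.MembraneParams(5.0),
            confinement=d.Confinement(kind="slab", z0=z0, h=2.0), seed=19)
        st.mc_sweep(300)
        z = st.mesh.pos[:, 2]
        assert z.min() >= z0 - 1.0 - 1e-12
        assert z.max() <= z0 + 1.0 + 1e-12
        assert st.audit() == 0

    def test_initial_violation_is_rejected(self, flat88):
        mesh = flat88.copy()
        with pytest.raises(ValueError, match="violates"):
            d.SimulationState(
                mesh, confinement=d.Confinement(
                    kind="slab", z0=float(mesh.pos[0, 2]) + 5.0, h=2.0),
                seed=1)

    def test_ellipsoid_keeps_vesicle_inside(self, icosphere2):
        mesh = icosphere2.copy()
        c = tuple(mesh.pos.mean(axis=0))
        r = float(np.linalg.norm(mesh.pos - mesh.pos.mean(0), axis=1).max())
        st = d.SimulationState(
            mesh, membrane=d.MembraneParams(10.0),
            confinement=d.Confinement(kind="ellipsoid", center=c,
                                      semi_axes=(r + 1, r + 1, r + 1)),
            seed=19)
        st.mc_sweep(200)
        f = (st.mesh.pos - np.array(c)) / (r + 1)
        assert np.all(np.linalg.norm(f, axis=1) <= 1.0 + 1e-12)


class TestConstraintAudit:
    @pytest.mark.parametrize("coverage", [0.0, 0.2])
    def test_no_violations_on_flat_run(self, flat88, coverage):
        s = make_state(flat88, coverage=coverage, seed=17)
        for _ in range(5):
            s.mc_sweep(100)
            assert s.audit() == 0
            rep = s.mesh.validate()
            assert rep.ok and rep.edge_window_violations == 0
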