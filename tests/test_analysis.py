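"""Spectrum estimator, reduced volume and the physical unit mapping."""

import math

import numpy as np
import pytest

import dtsmem as d
from dtsmem.analysis import (SpectrumResult, fit_spectrum,
                             inclusion_cluster_count, length_mapping,
                             loglog_slope, reduced_volume,
                             synthetic_height_frames, undulation_spectrum)


class TestSpectrum:
    def test_single_flat_frame_is_silent(self, flat88):
        spec = undulation_spectrum([flat88.pos], flat88.box.lengths)
        assert np.all(spec.spectrum < 1e-20)

    def test_noiseless_inversion_is_exact(self):
        q = np.linspace(0.3, 2.0, 12)
        s = 1.0 / (20.0 * q ** 4 + 2.0 * q ** 2)
        spec = SpectrumResult(q=q, spectrum=s, counts=np.ones(12, int),
                              n_frames=1)
        kappa, tau = fit_spectrum(spec)
        assert kappa == pytest.approx(20.0, abs=1e-6)
        assert tau == pytest.approx(2.0, abs=1e-6)

    def test_fit_needs_enough_bins(self):
        q = np.array([0.3, 0.4])
        spec = SpectrumResult(q=q, spectrum=1 / q ** 4,
                              counts=np.ones(2, int), n_frames=1)
        with pytest.raises(ValueError):
            fit_spectrum(spec)

    @pytest.mark.parametrize("method", ["lsq", "direct"])
    def test_sampled_recovery_unbiased(self, method, rng):
        m = d.build_flat_grid(16, 16, 1.2)
        xy = m.pos[:, :2] + rng.normal(0, 0.1, (m.n_vertices, 2))
        box = m.box.lengths
        q_est = 1.2 / math.sqrt(2 * box[0] * box[1]
                                / (math.sqrt(3) * m.n_vertices))
        frames = synthetic_height_frames(20.0, 0.0, box, xy, 400, rng,
                                         q_max=q_est)
        spec = undulation_spectrum(frames, box, method=method)
        kappa, tau = fit_spectrum(spec)
        assert kappa == pytest.approx(20.0, rel=0.10)

    def test_sampled_tau_recovery(self, rng):
        m = d.build_flat_grid(16, 16, 1.2)
        xy = m.pos[:, :2] + rng.normal(0, 0.1, (m.n_vertices, 2))
        box = m.box.lengths
        frames = synthetic_height_frames(20.0, 2.0, box, xy, 600, rng)
        spec = undulation_spectrum(frames, box)
        _, tau = fit_spectrum(spec)
        assert tau == pytest.approx(2.0, rel=0.25)

    def test_lsq_robust_to_heavy_disorder(self, rng):
        # fluid-like vertex disorder: the leakage-corrected estimator keeps
        # the q^-4 tail where the plain sum develops a noise floor
        m = d.build_flat_grid(16, 16, 1.2)
        xy = m.pos[:, :2] + rng.normal(0, 0.3, (m.n_vertices, 2))
        frames = synthetic_height_frames(20.0, 0.0, m.box.lengths, xy, 300,
                                         rng)
        spec = undulation_spectrum(frames, m.box.lengths, method="lsq")
        slope = loglog_slope(spec, spec.q.max() / 2, spec.q.max())
        assert slope == pytest.approx(-4.0, abs=0.4)

    def test_parseval(self, rng):
        m = d.build_flat_grid(16, 16, 1.2)
        xy = m.pos[:, :2].copy()
        box = m.box.lengths
        ap = float(box[0] * box[1])
        a_lat = math.sqrt(2 * ap / (math.sqrt(3) * m.n_vertices))
        q_c = 1.2 / a_lat
        frames = synthetic_height_frames(20.0, 0.0, box, xy, 300, rng,
                                         q_max=q_c)
        spec = undulation_spectrum(frames, box, q_max=q_c, method="lsq")
        mode_sum = float((spec.spectrum * spec.counts).sum()) / spec.n_frames
        var_est = 2.0 * mode_sum / ap ** 2 * ap  # 2 sum_half |u_hat|^2
        var_real = float(np.mean([np.var(f[:, 2]) for f in frames]))
        assert var_est == pytest.approx(var_real, rel=0.05)


class TestReducedVolume:
    def test_sphere_is_one(self, icosphere3):
        assert reduced_volume(icosphere3) == pytest.approx(1.0, abs=0.02)

    def test_rigid_motion_invariance(self, icosphere2):
        m = icosphere2.copy()
        v0 = reduced_volume(m)
        th = 0.7
        rot = np.array([[math.cos(th), -math.sin(th), 0],
                        [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        c = m.pos.mean(axis=0)
        m.pos = (m.pos - c) @ rot.T + c + 1.5
        assert reduced_volume(m) == pytest.approx(v0, rel=1e-10)

    def test_prolate_two_to_one(self, icosphere3):
        """Analytic oracle: prolate with c/a = 2 has
        A = 2 pi a^2 (1 + (c/(a e)) asin e), V = (4/3) pi a^2 c
        => v = 0.8949."""
        m = icosphere3.copy()
        c = m.pos.mean(axis=0)
        m.pos = (m.pos - c) * np.array([1.0, 1.0, 2.0]) + 2 * c
        m.box.lengths[:] = m.pos.max() + 10
        assert reduced_volume(m) == pytest.approx(0.8949, abs=0.01)

    def test_any_nonsphere_below_one(self, icosphere2, rng):
        m = icosphere2.copy()
        c = m.pos.mean(axis=0)
        m.pos = (m.pos - c) * np.array([1.0, 0.8, 1.3]) + c
        assert reduced_volume(m) < 1.0


class TestLengthMapping:
    def test_identity_packing(self):
        # diameter chosen so pi (d/2)^2 = sqrt(3)/2 => l_dts = 1
        dd = 2.0 * math.sqrt(math.sqrt(3.0) / (2.0 * math.pi))
        assert length_mapping(dd).l_dts_nm == pytest.approx(1.0, abs=1e-12)

    def test_cholera_toxin_scale(self):
        lm = length_mapping(7.2)
        assert lm.l_dts_nm == pytest.approx(6.9, abs=0.1)
        assert lm.curvature_to_per_nm(0.4) == pytest.approx(0.058, abs=0.002)
        assert lm.area_to_nm2(1.0) == pytest.approx(lm.l_dts_nm ** 2)

    def test_rejects_nonpositive_size(self):
        with pytest.raises(ValueError):
            length_mapping(0.0)


class TestClusters:
    def test_cluster_count(self, flat88):
        host_inc = np.full(flat88.n_vertices, -1, dtype=np.int32)
        tri = flat88.tris[0]
        for j, v in enumerate(tri):
            host_inc[v] = j
        far = 0 if 0 not in tri else int(np.setdiff1d(
            np.arange(flat88.n_vertices), flat88.neigh[tri[0]])[0])
        # ensure 'far' is not adjacent to the triangle
        adj = set()
        for v in tri:
            adj.update(flat88.neigh[v, :int(flat88.deg[v])])
        far = int(np.setdiff1d(np.arange(flat88.n_vertices),
                               np.array(sorted(adj | set(map(int, tri)))))[0])
        host_inc[far] = 3
        assert inclusion_cluster_count(flat88, host_inc) == 2
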