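"""Generator correctness: geometry, Sarvas forward model, planted dynamics."""

from __future__ import annotations

import numpy as np
import pytest

import meghubs as mh
from meghubs.containers import GeometryError, window_slice
from meghubs.synthetic import MU0, _dipole_gain, coupling_bin_frequencies


# ---------------------------------------------------------------------------
# head and sensor geometry


class TestHeadAndSensors:
    def test_sensors_on_shell(self):
        head, sens = mh.build_head_and_sensors(275, 0.09, 0.12, seed=0)
        assert sens.n_chan == 275
        r = np.linalg.norm(sens.positions - head.center, axis=1)
        assert np.allclose(r, 0.12, atol=1e-9)
        # all in the upper hemisphere, orientations radially inward
        assert np.all(sens.positions[:, 2] >= head.center[2])
        unit = (sens.positions - head.center) / r[:, None]
        assert np.allclose(sens.orientations, -unit, atol=1e-12)

    def test_deterministic_for_seed(self):
        a = mh.build_head_and_sensors(32, 0.09, 0.12, seed=7)
        b = mh.build_head_and_sensors(32, 0.09, 0.12, seed=7)
        assert np.array_equal(a[1].positions, b[1].positions)
        assert np.array_equal(a[1].orientations, b[1].orientations)

    def test_quasi_uniform_spacing_vs_repulsion_oracle(self):
        """Fibonacci layout min spacing within 2× of a repulsion layout."""
        n = 64
        _, sens = mh.build_head_and_sensors(n, 0.09, 0.12, seed=1)

        def min_dist(p):
            d = np.linalg.norm(p[:, None] - p[None, :], axis=2)
            return d[np.triu_indices(len(p), 1)].min()

        # brute-force electrostatic repulsion on the upper hemisphere
        rng = np.random.default_rng(0)
        z = rng.uniform(0.05, 1, n)
        th = rng.uniform(0, 2 * np.pi, n)
        p = np.column_stack([np.sqrt(1 - z**2) * np.cos(th),
                             np.sqrt(1 - z**2) * np.sin(th), z])
        for _ in range(300):
            diff = p[:, None] - p[None, :]
            d = np.linalg.norm(diff, axis=2) + np.eye(n)
            force = (diff / d[:, :, None] ** 3).sum(axis=1)
            p = p + 2e-3 * force
            p[:, 2] = np.abs(p[:, 2])
            p /= np.linalg.norm(p, axis=1, keepdims=True)
        oracle = min_dist(p * 0.12)
        ours = min_dist(sens.positions)
        assert ours >= oracle / 2.0

    def test_rejects_bad_radii(self):
        with pytest.raises(GeometryError):
            mh.build_head_and_sensors(32, -0.09, 0.12)
        with pytest.raises(GeometryError):
            mh.build_head_and_sensors(32, 0.12, 0.09)


class TestSourceGrid:
    def test_points_strictly_inside(self):
        head = mh.HeadModel(center=np.zeros(3), radius=0.09)
        grid = mh.build_source_grid(head, 0.01)
        r = np.linalg.norm(grid.points - head.center, axis=1)
        assert np.all(r < 0.95 * head.radius)

    def test_coarser_grid_has_eighth_the_count(self):
        head = mh.HeadModel(center=np.zeros(3), radius=0.09)
        fine = mh.build_source_grid(head, 0.01)
        coarse = mh.build_source_grid(head, 0.02)
        ratio = fine.n_vox / coarse.n_vox
        assert 8 * 0.7 <= ratio <= 8 * 1.3

    def test_too_coarse_raises(self):
        head = mh.HeadModel(center=np.zeros(3), radius=0.09)
        with pytest.raises(GeometryError):
            mh.build_source_grid(head, 0.2)

    def test_no_midline_voxels(self):
        head = mh.HeadModel(center=np.zeros(3), radius=0.05)
        grid = mh.build_source_grid(head, 0.012)
        assert np.all(np.abs(grid.points[:, 0]) > 1e-12)
        # mirror-symmetric about x = 0
        left = np.sum(grid.points[:, 0] < 0)
        assert left == grid.n_vox - left


# ---------------------------------------------------------------------------
# forward model


def _sarvas_oracle(r0, q, r_sens):
    """Independent direct transcription of the conducting-sphere dipole
    field, written scalar-by-scalar (sphere center at the origin)."""
    out = []
    for r in r_sens:
        a = [r[0] - r0[0], r[1] - r0[1], r[2] - r0[2]]
        an = (a[0] ** 2 + a[1] ** 2 + a[2] ** 2) ** 0.5
        rn = (r[0] ** 2 + r[1] ** 2 + r[2] ** 2) ** 0.5
        r0r = r0[0] * r[0] + r0[1] * r[1] + r0[2] * r[2]
        ar = a[0] * r[0] + a[1] * r[1] + a[2] * r[2]
        F = an * (rn * an + rn * rn - r0r)
        c1 = an * an / rn + ar / an + 2 * an + 2 * rn
        c2 = an + 2 * rn + ar / an
        gF = [c1 * r[i] - c2 * r0[i] for i in range(3)]
        qxr0 = [
            q[1] * r0[2] - q[2] * r0[1],
            q[2] * r0[0] - q[0] * r0[2],
            q[0] * r0[1] - q[1] * r0[0],
        ]
        qxr0_r = qxr0[0] * r[0] + qxr0[1] * r[1] + qxr0[2] * r[2]
        k = MU0 / (4.0 * np.pi * F * F)
        out.append([k * (F * qxr0[i] - qxr0_r * gF[i]) for i in range(3)])
    return np.asarray(out)


class TestLeadfield:
    def test_radial_dipole_is_silent(self, small_head_sensors):
        head, sens = small_head_sensors
        grid = mh.build_source_grid(head, 0.03)
        lf = mh.compute_leadfield(grid, sens, head)
        for v in range(0, grid.n_vox, 7):
            p = grid.points[v] - head.center
            nrm = np.linalg.norm(p)
            if nrm < 1e-9:
                continue
            radial_field = lf.gain[:, v, :] @ (p / nrm)
            tang = np.cross(p / nrm, [0.0, 0.0, 1.0])
            if np.linalg.norm(tang) < 1e-6:
                tang = np.cross(p / nrm, [0.0, 1.0, 0.0])
            tang_field = lf.gain[:, v, :] @ (tang / np.linalg.norm(tang))
            ref = np.abs(tang_field).max()
            if ref > 0:
                assert np.abs(radial_field).max() < 1e-15 * ref

    def test_linearity_negation_and_superposition(self, small_head_sensors):
        head, sens = small_head_sensors
        grid = mh.build_source_grid(head, 0.03)
        lf = mh.compute_leadfield(grid, sens, head)
        q = np.array([0.3, -0.2, 0.5])
        f_pos = lf.gain[:, 3, :] @ q
        f_neg = lf.gain[:, 3, :] @ (-q)
        assert np.allclose(f_pos, -f_neg, rtol=0, atol=1e-25)
        q2 = np.array([-0.1, 0.4, 0.2])
        f_sum = lf.gain[:, 3, :] @ (q + q2)
        f_parts = f_pos + lf.gain[:, 3, :] @ q2
        ref = np.abs(f_sum).max()
        assert np.abs(f_sum - f_parts).max() <= 1e-12 * ref

    def test_matches_independent_sarvas_transcription(self, small_head_sensors):
        head, sens = small_head_sensors
        r0 = np.array([0.0, 0.06, 0.0])  # 6 cm from center
        gain = _dipole_gain(r0, sens, head)
        for q in (np.array([1.0, 0.0, 0.0]), np.array([0.0, 0.0, 1.0])):
            ours = gain @ q
            B = _sarvas_oracle(r0, q, sens.positions - head.center)
            theirs = np.einsum("ij,ij->i", B, sens.orientations)
            ref = np.abs(theirs).max()
            assert np.abs(ours - theirs).max() <= 1e-12 * ref

    def test_center_source_silent_and_sensor_inside_rejected(self, small_head_sensors):
        head, sens = small_head_sensors
        gain = _dipole_gain(head.center.copy(), sens, head)
        assert np.all(gain == 0.0)
        bad = mh.SensorArray(
            positions=sens.positions * 0.5, orientations=sens.orientations
        )
        grid = mh.build_source_grid(head, 0.03)
        with pytest.raises(GeometryError):
            mh.compute_leadfield(grid, bad, head)


# ---------------------------------------------------------------------------
# source dynamics


def _window_band_power(src, times, window, sfreq, band):
    from meghubs.inversion import trial_band_power

    sl = window_slice(times, window, sfreq)
    return trial_band_power(src[:, :, sl], sfreq, band)


class TestSimulateTrialSources:
    def _grid(self):
        head = mh.HeadModel(center=np.zeros(3), radius=0.05)
        return mh.build_source_grid(head, 0.015)

    def test_zero_depth_gives_unit_power_ratio(self):
        grid = self._grid()
        sc = mh.SimulationScenario(
            n_trials=100, sfreq=600.0, erd_voxels=(3,), erd_depth=0.0,
            background_amp=0.0, seed=1,
        )
        src = mh.simulate_trial_sources(sc, grid)
        times = sc.times()
        pb = _window_band_power(src[:, 3:4], times, sc.baseline_window, sc.sfreq, sc.erd_band)
        pa = _window_band_power(src[:, 3:4], times, sc.active_window, sc.sfreq, sc.erd_band)
        assert 0.9 <= pa.mean() / pb.mean() <= 1.1

    def test_half_depth_power_ratio(self):
        grid = self._grid()
        sc = mh.SimulationScenario(
            n_trials=100, sfreq=600.0, erd_voxels=(3,), erd_depth=0.5,
            background_amp=0.0, seed=2,
        )
        src = mh.simulate_trial_sources(sc, grid)
        times = sc.times()
        pb = _window_band_power(src[:, 3:4], times, sc.baseline_window, sc.sfreq, sc.erd_band)
        pa = _window_band_power(src[:, 3:4], times, sc.active_window, sc.sfreq, sc.erd_band)
        assert 0.4 <= pa.mean() / pb.mean() <= 0.6

    def test_full_coupling_gives_high_plv(self):
        """PLV computed directly from active-window DFT phases ≥ 0.95 at c=1."""
        grid = self._grid()
        sc = mh.SimulationScenario(
            n_trials=100, sfreq=600.0, coupled_pairs=((0, 5, 1.0),),
            background_amp=0.0, seed=3,
        )
        src = mh.simulate_trial_sources(sc, grid)
        times = sc.times()
        sl = window_slice(times, sc.active_window, sc.sfreq)
        seg = src[:, [0, 5], :][:, :, sl]
        taper = np.hanning(seg.shape[2])
        spec = np.fft.rfft(seg * taper, axis=2)
        freqs = np.fft.rfftfreq(seg.shape[2], 1 / sc.sfreq)
        bins = np.isin(freqs, coupling_bin_frequencies(sc))
        ph = np.angle(spec[:, :, bins])
        plv = np.abs(np.exp(1j * (ph[:, 0] - ph[:, 1])).mean(axis=0))
        assert plv.min() >= 0.95

    def test_seeded_determinism_bitwise(self):
        grid = self._grid()
        sc = mh.SimulationScenario(
            n_trials=5, sfreq=600.0, erd_voxels=(1,), erd_depth=0.3,
            coupled_pairs=((0, 5, 0.8),), seed=11,
        )
        a = mh.simulate_trial_sources(sc, grid)
        b = mh.simulate_trial_sources(sc, grid)
        assert np.array_equal(a, b)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            mh.SimulationScenario(sfreq=100.0, erd_band=(13.0, 60.0))

    def test_plv_plantability_over_draws(self):
        """Coupled pairs beat the 95th percentile of uncoupled pairs."""
        grid = self._grid()
        hits = 0
        for k in range(20):
            rng = np.random.default_rng(k)
            i, j = [int(v) for v in rng.choice(grid.n_vox, 2, replace=False)]
            sc = mh.SimulationScenario(
                n_trials=60, sfreq=600.0, coupled_pairs=((i, j, 0.9),),
                background_amp=2e-9, seed=100 + k,
            )
            src = mh.simulate_trial_sources(sc, grid)
            times = sc.times()
            from meghubs.connectivity import trial_spectral_phases, plv_adjacency
            from meghubs.containers import SourceEstimate

            sl_a = window_slice(times, sc.active_window, sc.sfreq)
            sl_b = window_slice(times, sc.baseline_window, sc.sfreq)
            pa = trial_spectral_phases(SourceEstimate(src[:, :, sl_a], sc.sfreq, times[sl_a]))
            pb = trial_spectral_phases(SourceEstimate(src[:, :, sl_b], sc.sfreq, times[sl_b]))
            V = plv_adjacency(pa, pb).values
            mask = np.triu(np.ones_like(V, bool), 1)
            mask[i, j] = mask[j, i] = False
            if V[i, j] > np.percentile(V[mask], 95):
                hits += 1
        assert hits >= 19  # coupled pair above the null bulk in ≥95% of draws


class TestProjection:
    def test_noiseless_single_source_equals_gain_column(self, small_head_sensors):
        head, sens = small_head_sensors
        grid = mh.build_source_grid(head, 0.03)
        lf = mh.compute_leadfield(grid, sens, head)
        n_vox = grid.n_vox
        ori = mh.draw_tangential_orientations(grid, head, seed=0)
        tc = np.sin(2 * np.pi * 10 * np.arange(100) / 600.0)
        src = np.zeros((1, n_vox, 100))
        src[0, 4] = tc
        times = np.arange(100) / 600.0
        ep = mh.project_and_add_noise(src, lf, ori, 0.0, 0, 600.0, times)
        expected = np.outer(lf.gain[:, 4, :] @ ori[4], tc)
        scale = np.abs(expected).max()
        assert np.abs(ep.data[0] - expected).max() <= 1e-12 * scale

    def test_linearity_in_amplitude(self, small_head_sensors):
        head, sens = small_head_sensors
        grid = mh.build_source_grid(head, 0.03)
        lf = mh.compute_leadfield(grid, sens, head)
        ori = mh.draw_tangential_orientations(grid, head, seed=0)
        rng = np.random.default_rng(3)
        src = rng.standard_normal((2, grid.n_vox, 50))
        times = np.arange(50) / 600.0
        a = mh.project_and_add_noise(src, lf, ori, 0.0, 0, 600.0, times)
        b = mh.project_and_add_noise(2 * src, lf, ori, 0.0, 0, 600.0, times)
        assert np.allclose(2 * a.data, b.data)

    def test_noise_sd_calibrated(self, small_head_sensors):
        head, sens = small_head_sensors
        grid = mh.build_source_grid(head, 0.03)
        lf = mh.compute_leadfield(grid, sens, head)
        ori = mh.draw_tangential_orientations(grid, head, seed=0)
        n_samp = 10_000
        src = np.zeros((1, grid.n_vox, n_samp))
        times = np.arange(n_samp) / 600.0
        sigma = 3e-14
        ep = mh.project_and_add_noise(src, lf, ori, sigma, 42, 600.0, times)
        sd = ep.data[0].std(axis=1)
        assert np.all(np.abs(sd - sigma) < 0.05 * sigma)

    def test_non_unit_orientation_rejected(self, small_head_sensors):
        head, sens = small_head_sensors
        grid = mh.build_source_grid(head, 0.03)
        lf = mh.compute_leadfield(grid, sens, head)
        ori = mh.draw_tangential_orientations(grid, head, seed=0) * 2.0
        src = np.zeros((1, grid.n_vox, 10))
        with pytest.raises(ValueError):
            mh.project_and_add_noise(src, lf, ori, 0.0, 0, 600.0, np.arange(10) / 600.0)


# ---------------------------------------------------------------------------
# atlas


class TestSyntheticAtlas:
    def test_partition_and_hemisphere_balance(self):
        head = mh.HeadModel(center=np.zeros(3), radius=0.05)
        grid = mh.build_source_grid(head, 0.012)
        atlas = mh.build_synthetic_atlas(grid, 4, seed=0)
        assert len(atlas.parcel_ids) == 8
        # every voxel exactly one label
        assert atlas.labels.shape == (grid.n_vox,)
        assert np.all(atlas.labels >= 0)
        # symmetric grid → equal hemisphere voxel totals (±1)
        n_left = sum(
            np.sum(atlas.labels == p)
            for p in atlas.parcel_ids if atlas.hemisphere[int(p)] == "L"
        )
        assert abs(int(n_left) - (grid.n_vox - int(n_left))) <= 1

    def test_parcels_are_connected_components(self):
        from meghubs.synthetic import _lattice_neighbors

        head = mh.HeadModel(center=np.zeros(3), radius=0.05)
        grid = mh.build_source_grid(head, 0.012)
        atlas = mh.build_synthetic_atlas(grid, 4, seed=1)
        nbrs = _lattice_neighbors(grid.ijk)
        for p in atlas.parcel_ids:
            members = set(np.nonzero(atlas.labels == p)[0].tolist())
            start = next(iter(members))
            seen = {start}
            stack = [start]
            while stack:
                v = stack.pop()
                for w in nbrs[v]:
                    if w in members and w not in seen:
                        seen.add(w)
                        stack.append(w)
            assert seen == members, f"parcel {p} is not 6-connected"

    def test_mirrored_lobe_annotations(self):
        head = mh.HeadModel(center=np.zeros(3), radius=0.05)
        grid = mh.build_source_grid(head, 0.012)
        atlas = mh.build_synthetic_atlas(grid, 4, seed=2)
        for c in range(4):
            assert atlas.lobe[c] == atlas.lobe[4 + c]
            assert atlas.hemisphere[c] == "L" and atlas.hemisphere[4 + c] == "R"

    def test_more_parcels_than_voxels_rejected(self):
        head = mh.HeadModel(center=np.zeros(3), radius=0.05)
        grid = mh.build_source_grid(head, 0.02)
        with pytest.raises(ValueError):
            mh.build_synthetic_atlas(grid, grid.n_vox, seed=0)
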