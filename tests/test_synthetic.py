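"""Generator contracts: packing geometry, motion limits, rendering, disk I/O."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.spatial.distance import pdist

import tumotrack as tt
from tumotrack.scenario import ValidationError
from tumotrack.synthetic import PackingError, SIM_DT

from conftest import grid_trajectories, ground_truth_from_trajectories


class TestMakeTumoroid:
    def test_single_nucleus_inside_sphere(self):
        sc = tt.AssayScenario(n_nuclei=1)
        pts = tt.make_tumoroid(sc, rng_seed=0)
        assert pts.shape == (1, 3)
        assert np.linalg.norm(pts[0] - sc.tumoroid_center) <= sc.tumoroid_radius

    def test_default_packing_geometry(self):
        sc = tt.AssayScenario(n_nuclei=300, tumoroid_radius=75.0,
                              nucleus_spacing=7.0)
        pts = tt.make_tumoroid(sc, rng_seed=1)
        assert len(pts) == 300
        dist_to_center = np.linalg.norm(pts - np.asarray(sc.tumoroid_center), axis=1)
        assert dist_to_center.max() <= 75.0
        assert pdist(pts).min() >= 7.0

    def test_seed_determinism(self):
        sc = tt.AssayScenario(n_nuclei=100)
        a = tt.make_tumoroid(sc, rng_seed=5)
        b = tt.make_tumoroid(sc, rng_seed=5)
        np.testing.assert_array_equal(a, b)

    def test_impossible_density_raises(self):
        sc = tt.AssayScenario(n_nuclei=300, tumoroid_radius=75.0,
                              nucleus_spacing=40.0)
        with pytest.raises(PackingError, match="density"):
            tt.make_tumoroid(sc, rng_seed=0)


class TestSimulateTcells:
    def test_ballistic_limit_displacement(self, diffusion_free_scenario):
        """Zero-diffusion drifting cell moves exactly speed·t toward the target."""
        scenario, motility, killing = diffusion_free_scenario
        gt = tt.simulate_tcells(scenario, motility, killing, rng_seed=0)
        traj = gt.trajectories[0]
        start = traj.positions[0]
        for k, t in enumerate(traj.times):
            disp = np.linalg.norm(traj.positions[k] - start)
            assert disp == pytest.approx(motility.speed * t, abs=1e-9)

    def test_brownian_closed_form(self):
        """Ensemble 3D MSD of pure diffusion matches <r²> = 6 d t within 10%."""
        scenario = tt.AssayScenario(
            volume_size=(600.0, 600.0, 600.0),
            tumoroid_center=(300.0, 300.0, 300.0),
            n_nuclei=1, n_tcells=600, n_seed_contact=600, n_frames=11, seed=0)
        motility = tt.MotilityParams(d_axis=2.0, speed=0.0, switch_mode="never")
        killing = tt.KillingParams(kill_rate_per_contact=0.0)
        gt = tt.simulate_tcells(scenario, motility, killing, rng_seed=11)
        pos = np.stack([tr.positions for tr in gt.trajectories])  # (n, T, 3)
        for lag in (5, 10):
            sq = np.sum((pos[:, lag] - pos[:, 0]) ** 2, axis=1)
            assert sq.mean() == pytest.approx(6.0 * 2.0 * lag, rel=0.10)

    def test_no_killing_leaves_all_alive(self, small_scenario):
        gt = tt.simulate_tcells(small_scenario, tt.MotilityParams(),
                                tt.KillingParams(kill_rate_per_contact=0.0),
                                rng_seed=2)
        assert np.all(np.isnan(gt.death_times))

    def test_determinism_and_trajectory_shape(self, small_scenario):
        a = tt.simulate_tcells(small_scenario, tt.MotilityParams(),
                               tt.KillingParams(), rng_seed=9)
        b = tt.simulate_tcells(small_scenario, tt.MotilityParams(),
                               tt.KillingParams(), rng_seed=9)
        np.testing.assert_array_equal(a.nucleus_positions, b.nucleus_positions)
        np.testing.assert_array_equal(a.death_times, b.death_times)
        for ta, tb in zip(a.trajectories, b.trajectories):
            np.testing.assert_array_equal(ta.positions, tb.positions)
        assert all(len(tr) == small_scenario.n_frames for tr in a.trajectories)
        assert all(np.all(np.diff(tr.times) > 0) for tr in a.trajectories)

    def test_positions_stay_inside_volume(self, small_scenario):
        gt = tt.simulate_tcells(small_scenario, tt.MotilityParams(d_axis=8.0),
                                tt.KillingParams(), rng_seed=4)
        size = np.asarray(small_scenario.volume_size)
        for tr in gt.trajectories:
            assert np.all(tr.positions >= 0.0)
            assert np.all(tr.positions <= size)

    def test_invalid_dt_rejected(self, small_scenario):
        with pytest.raises(ValidationError):
            tt.simulate_tcells(small_scenario, tt.MotilityParams(),
                               tt.KillingParams(), rng_seed=0, dt=-SIM_DT)
        with pytest.raises(ValidationError):
            tt.simulate_tcells(small_scenario, tt.MotilityParams(),
                               tt.KillingParams(), rng_seed=0, dt=2.0)

    def test_scenario_presets_share_geometry(self):
        """Effective vs ineffective differ only in switch/kill parameters."""
        sc_e, mot_e, kill_e = tt.effective_scenario(seed=3)
        sc_i, mot_i, kill_i = tt.ineffective_scenario(seed=3)
        assert sc_e == sc_i
        assert mot_e.d_axis == mot_i.d_axis
        assert mot_e.speed == mot_i.speed
        assert (mot_e.switch_mode, mot_i.switch_mode) == ("on_first_contact", "never")
        assert kill_i.kill_rate_per_contact == 0.0


class TestRenderFrames:
    def test_empty_ground_truth_is_background(self, small_scenario, noise_free_render):
        gt = ground_truth_from_trajectories([])
        stack = tt.render_frames(gt, small_scenario, noise_free_render)
        nz, ny, nx = small_scenario.grid_shape
        assert stack.data.shape == (small_scenario.n_frames, nz, 3, ny, nx)
        np.testing.assert_allclose(stack.data, noise_free_render.background)

    def test_brightest_voxel_at_single_nucleus(self, small_scenario, noise_free_render):
        nucleus = np.array([[101.0, 97.0, 55.0]])
        gt = ground_truth_from_trajectories([], nuclei=nucleus)
        stack = tt.render_frames(gt, small_scenario, noise_free_render)
        vol = stack.volume("nuclei", 0)
        z, y, x = np.unravel_index(np.argmax(vol), vol.shape)
        px, zs = small_scenario.lateral_pixel_size, small_scenario.z_step
        assert x == int(nucleus[0, 0] / px)
        assert y == int(nucleus[0, 1] / px)
        assert z == int(nucleus[0, 2] / zs)

    def test_pi_blobs_only_for_dead_nuclei(self, small_scenario, noise_free_render):
        nuclei = np.array([[80.0, 80.0, 60.0], [120.0, 120.0, 60.0]])
        death = np.array([2.0, np.nan])
        gt = ground_truth_from_trajectories([], nuclei=nuclei, death_times=death,
                                            pi_onset_delay=1.0)
        stack = tt.render_frames(gt, small_scenario, noise_free_render)
        bg = noise_free_render.background
        assert np.all(stack.volume("pi", 2) == bg)          # death+delay not reached
        assert stack.volume("pi", 3).max() > bg + 100.0     # PI on at t=3
        # and only near the dead nucleus
        vol = stack.volume("pi", 3)
        z, y, x = np.unravel_index(np.argmax(vol), vol.shape)
        assert abs((x + 0.5) * 2.0 - 80.0) < 4.0

    def test_render_detect_round_trip(self, noise_free_render):
        """Rendered well-separated cells re-detected within 1 voxel RMS."""
        from tumotrack.tracking import detect_3d
        scenario = tt.AssayScenario(
            volume_size=(400.0, 400.0, 200.0), n_nuclei=0, n_tcells=0,
            n_seed_contact=0, n_frames=1, seed=0)
        trajs = grid_trajectories(5, 10, 1, spacing=36.0, step_sigma=0.0,
                                  z0=100.0, seed=0)
        gt = ground_truth_from_trajectories(trajs)
        stack = tt.render_frames(gt, scenario, noise_free_render)
        dets = detect_3d(stack.volume("tcell", 0), threshold=100.0,
                         lateral_pixel_size=2.0, z_step=10.0)
        assert len(dets) == 50
        truth = np.stack([tr.positions[0] for tr in trajs])
        found = np.stack([d.position for d in dets])
        # match nearest
        errs = []
        for p in truth:
            d = np.linalg.norm(found - p, axis=1)
            errs.append(d.min())
        voxel = np.array([2.0, 2.0, 10.0])
        assert np.sqrt(np.mean(np.square(errs))) <= np.linalg.norm(voxel)

    def test_small_sigma_warns_and_clamps(self, small_scenario):
        params = tt.RenderParams(sigma_xy=(0.5, 3.0, 4.0), poisson_noise=False)
        gt = ground_truth_from_trajectories([])
        with pytest.warns(UserWarning, match="clamp"):
            tt.render_frames(gt, small_scenario, params)


class TestScenarioIO:
    def test_round_trip(self, small_scenario, noise_free_render, tmp_path):
        gt = tt.simulate_tcells(small_scenario, tt.MotilityParams(),
                                tt.KillingParams(), rng_seed=1)
        stack = tt.render_frames(gt, small_scenario, noise_free_render)
        tt.write_scenario(stack, gt, small_scenario, tmp_path)
        stack2, gt2, scenario2 = tt.read_scenario(tmp_path)
        np.testing.assert_array_equal(stack.data, stack2.data)
        assert stack2.lateral_pixel_size == stack.lateral_pixel_size
        assert stack2.z_step == stack.z_step
        assert scenario2 == small_scenario
        np.testing.assert_array_equal(gt2.nucleus_positions, gt.nucleus_positions)
        np.testing.assert_array_equal(gt2.death_times, gt.death_times)
        assert len(gt2.trajectories) == len(gt.trajectories)
        for a, b in zip(gt.trajectories, gt2.trajectories):
            np.testing.assert_array_equal(a.positions, b.positions)

    def test_trajectory_csv_row_count(self, small_scenario, noise_free_render, tmp_path):
        import pandas as pd
        gt = tt.simulate_tcells(small_scenario, tt.MotilityParams(),
                                tt.KillingParams(), rng_seed=1)
        stack = tt.render_frames(gt, small_scenario, noise_free_render)
        paths = tt.write_scenario(stack, gt, small_scenario, tmp_path)
        df = pd.read_csv(paths["trajectories"])
        assert len(df) == sum(len(tr) for tr in gt.trajectories)
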