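"""Forward model: trajectories, navigator simulation, registration emulator."""

import dataclasses

import numpy as np
import pytest

from navpmc.calibration import assemble_design
from navpmc.eddy import apply_baseline, estimate_baseline
from navpmc.geometry import params_to_affine, rms_deviation
from navpmc.synthetic import (MotionTrajectory, ProtocolConfig, WorldConfig,
                              make_calibration_trajectory, make_trajectory,
                              pose_quad_terms, simulate_features,
                              simulate_raw_block, simulate_registration)


class TestTrajectories:
    def test_zero_amplitude_is_zero_trajectory(self, small_protocol):
        traj = make_trajectory("shaking", small_protocol, n_volumes=30,
                               amplitude=0.0)
        assert np.allclose(traj.params, 0.0)

    def test_shaking_excites_rz_plus_coupled_ty_only(self, small_protocol):
        traj = make_trajectory("shaking", small_protocol, n_volumes=60,
                               amplitude=5.0, coupling=0.3)
        assert np.allclose(traj.params[:, [0, 1, 3, 5]], 0.0)
        assert np.max(traj.params[:, 2]) == pytest.approx(5.0, abs=1e-9)
        assert np.allclose(traj.params[:, 4], 0.3 * traj.params[:, 2])

    def test_uncoupled_shaking_is_pure_rz(self, small_protocol):
        traj = make_trajectory("shaking", small_protocol, n_volumes=60,
                               amplitude=5.0, coupling=0.0)
        mask = np.ones(6, bool)
        mask[2] = False
        assert np.allclose(traj.params[:, mask], 0.0)

    def test_nodding_excites_rx(self, small_protocol):
        traj = make_trajectory("nodding", small_protocol, n_volumes=60,
                               amplitude=4.0)
        assert np.max(np.abs(traj.params[:, 0])) == pytest.approx(4.0, abs=1e-9)
        assert np.allclose(traj.params[:, 2], 0.0)

    def test_lead_in_is_motion_free(self, small_protocol):
        for paradigm in ("shaking", "fig8_horizontal", "resting"):
            traj = make_trajectory(paradigm, small_protocol, n_volumes=60,
                                   amplitude=5.0, lead_in_s=10.0, seed=1)
            lead = small_protocol.baseline_window_shots(10.0)
            assert np.allclose(traj.params[:lead], 0.0)

    def test_trajectories_start_at_zero(self, small_protocol):
        for paradigm in ("resting", "nodding", "fig8_vertical"):
            traj = make_trajectory(paradigm, small_protocol, n_volumes=40,
                                   amplitude=3.0, seed=2)
            assert np.allclose(traj.params[0], 0.0)

    def test_fig8_is_a_combination_of_the_instructed_directions(self, small_protocol):
        """Figure-of-8 poses stay in the span of the shaking and nodding
        direction vectors — the premise of the generalization experiment."""
        traj = make_trajectory("fig8_horizontal", small_protocol, n_volumes=60,
                               amplitude=6.0, coupling=0.3)
        basis = np.array([[0, 0, 1, 0, 0.3, 0], [1, 0, 0, 0, 0, 0.3]]).T
        coeffs, res, *_ = np.linalg.lstsq(basis, traj.params.T, rcond=None)
        recon = (basis @ coeffs).T
        assert np.max(np.abs(recon - traj.params)) < 1e-10

    def test_calibration_session_is_two_shake_nod_repeats(self):
        prot = ProtocolConfig()
        traj = make_calibration_trajectory(prot, n_volumes=250)
        assert traj.n_shots == 250 * 21
        labels = [s[0] for s in traj.segments]
        assert labels == ["rest", "shaking", "nodding", "shaking", "nodding"]
        # ~1:45 at 20 ms per shot
        assert traj.times_ms[-1] / 1000.0 == pytest.approx(105.0, abs=0.1)

    def test_unknown_paradigm_rejected(self, small_protocol):
        with pytest.raises(ValueError):
            make_trajectory("jazzhands", small_protocol)

    def test_trajectory_must_start_at_zero_pose(self):
        with pytest.raises(ValueError):
            MotionTrajectory(np.ones((10, 6)), 20.0)


class TestSimulation:
    def test_zero_motion_zero_noise_zero_eddy_gives_constant_streams(
            self, small_protocol):
        world = WorldConfig.random(5, small_protocol, channel_noise_sd=0,
                                   probe_noise_sd=0, eddy_amp=0)
        traj = make_trajectory("shaking", small_protocol, n_volumes=4,
                               amplitude=0.0)
        feats, fields = simulate_features(traj, world, small_protocol)
        assert np.allclose(feats, feats[0], atol=1e-12)
        assert np.allclose(fields, fields[0], atol=1e-9)

    def test_same_seed_gives_bit_identical_streams(self, small_protocol,
                                                   small_world):
        traj = make_trajectory("resting", small_protocol, n_volumes=4,
                               amplitude=1.0, seed=3)
        a = simulate_features(traj, small_world, small_protocol, seed=9)
        b = simulate_features(traj, small_world, small_protocol, seed=9)
        assert np.array_equal(a[0], b[0]) and np.array_equal(a[1], b[1])

    def test_noiseless_linear_features_have_rank_six_after_centering(
            self, small_protocol):
        """kappa = 0, noise 0: eddy-corrected features are exactly affine in
        the 6 DOF, so the centered design has rank <= 6."""
        prot = dataclasses.replace(small_protocol, n_channels=8, n_probes=6)
        world = WorldConfig.random(6, prot, channel_noise_sd=0,
                                   probe_noise_sd=0)
        traj = make_trajectory("resting", prot, n_volumes=40, amplitude=2.0,
                               seed=4)
        feats, fields = simulate_features(traj, world, prot)
        X = assemble_design(feats, fields, "combined").X
        window = prot.baseline_window_shots(10.0)
        X = apply_baseline(X, estimate_baseline(X, world.eddy_cycle, window))
        Xc = X - X.mean(axis=0)
        s = np.linalg.svd(Xc, compute_uv=False)
        assert (s > s[0] * 1e-9).sum() <= 6

    def test_probe_fields_report_world_frequencies_exactly(self, small_protocol):
        world = WorldConfig.random(7, small_protocol, channel_noise_sd=0,
                                   probe_noise_sd=0)
        params = np.array([[1.0, -2.0, 0.5, 0.2, 0.0, 1.0]])
        from navpmc.navigator import fit_probe_field
        from navpmc.synthetic import _probe_freq
        _, probe = simulate_raw_block(params, np.array([0]), world,
                                      small_protocol)
        est = fit_probe_field(probe, small_protocol.probe_dwell_us)
        assert np.allclose(est, _probe_freq(params, np.array([0]), world),
                           atol=1e-6)

    def test_quad_terms_include_cross_products(self):
        q = pose_quad_terms(np.array([1.0, 2.0, 0, 0, 0, 0]))[0]
        assert 2.0 in q  # rx * ry cross product
        assert q.shape == (21,)


class TestRegistration:
    def test_noise_free_registration_hits_center_shot_poses(self, small_protocol):
        traj = make_trajectory("nodding", small_protocol, n_volumes=20,
                               amplitude=3.0)
        reg = simulate_registration(traj, small_protocol, reg_noise_rms=0.0)
        spv = small_protocol.shots_per_volume
        anchors = traj.params[np.arange(20) * spv + small_protocol.center_shot - 1]
        assert np.allclose(reg, anchors, atol=1e-9)

    def test_default_noise_magnitude_calibrated_to_rms_target(self, small_protocol):
        traj = make_trajectory("shaking", small_protocol, n_volumes=250,
                               amplitude=0.0)
        reg = simulate_registration(traj, small_protocol, reg_noise_rms=0.1,
                                    seed=8)
        eye = np.eye(4)
        devs = [rms_deviation(params_to_affine(r), eye) for r in reg]
        assert np.mean(devs) == pytest.approx(0.1, rel=0.2)

    def test_volume_count_is_ceiling_of_shot_ratio(self, small_protocol):
        spv = small_protocol.shots_per_volume
        params = np.zeros((spv * 3 + 5, 6))
        traj = MotionTrajectory(params, small_protocol.tr_shot_ms)
        reg = simulate_registration(traj, small_protocol, 0.0)
        assert reg.shape[0] == 4
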