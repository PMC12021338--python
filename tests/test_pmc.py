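"""Closed-loop PMC behavior and retrospective ground-truth reconstruction."""

import dataclasses

import numpy as np
import pytest

from navpmc.eddy import moving_average
from navpmc.geometry import affine_to_params, params_to_affine
from navpmc.pmc import PMCConfig, retrospective_ground_truth, run_pmc
from navpmc.synthetic import (MotionTrajectory, WorldConfig,
                              make_calibration_trajectory, make_trajectory)
from navpmc.workflows import calibrate_session


@pytest.fixture(scope="module")
def noiseless_setup(small_protocol):
    world = WorldConfig.random(11, small_protocol, channel_noise_sd=0,
                               probe_noise_sd=0)
    caltraj = make_calibration_trajectory(small_protocol, n_volumes=100,
                                          amplitude=5.0)
    cal = calibrate_session(caltraj, world, small_protocol, variant="combined",
                            targets="truth", allow_rank_deficient=True)
    return world, cal.model


def _step_trajectory(protocol, steps, n_volumes=40):
    """Piecewise-constant poses in the span of the instructed directions."""
    n = protocol.n_shots(n_volumes)
    params = np.zeros((n, 6))
    d_shake = np.array([0, 0, 1.0, 0, 0.3, 0])
    d_nod = np.array([1.0, 0, 0, 0, 0, 0.3])
    for i, (shot, a, b) in enumerate(steps):
        params[shot:] = a * d_shake + b * d_nod
    return MotionTrajectory(params, protocol.tr_shot_ms)


class TestClosedLoop:
    def test_zero_motion_gives_identity_updates_and_zero_residual(
            self, small_protocol, noiseless_setup):
        world, model = noiseless_setup
        traj = make_trajectory("shaking", small_protocol, n_volumes=30,
                               amplitude=0.0)
        res = run_pmc(traj, world, small_protocol, model)
        assert np.allclose(res.residual, 0.0, atol=1e-9)
        assert np.allclose(res.applied, np.eye(4), atol=1e-9)

    def test_step_motion_residual_confined_to_latency_window(
            self, small_protocol, noiseless_setup):
        """Perfect model, latency 1: a step at shot s leaves residual only
        at shots [s, s+latency)."""
        world, model = noiseless_setup
        steps = [(600, 2.0, 0.0), (700, 2.0, 1.5)]
        traj = _step_trajectory(small_protocol, steps)
        res = run_pmc(traj, world, small_protocol, model, PMCConfig(latency_shots=1))
        r = res.residual_rms()
        assert r[600] > 1.0 and r[700] > 0.5
        mask = np.ones(traj.n_shots, bool)
        mask[[600, 700]] = False
        mask[:small_protocol.baseline_window_shots(10.0)] = False
        assert np.max(r[mask]) < 1e-9

    def test_residual_definition_composes_with_inverse_update(
            self, small_protocol, noiseless_setup):
        world, model = noiseless_setup
        traj = make_trajectory("fig8_horizontal", small_protocol, n_volumes=30,
                               amplitude=4.0)
        res = run_pmc(traj, world, small_protocol, model)
        t = traj.n_shots - 3
        expect = affine_to_params(
            params_to_affine(traj.params[t]) @ np.linalg.inv(res.applied[t])
        ).as_array()
        assert np.allclose(res.residual[t], expect, atol=1e-10)

    def test_ramp_residual_equals_speed_times_latency(self, small_protocol,
                                                      noiseless_setup):
        """5 deg/s about z with one 20-ms-shot latency leaves ~0.1 deg."""
        world, model = noiseless_setup
        n = small_protocol.n_shots(40)
        t = np.arange(n) * small_protocol.tr_shot_ms * 1e-3
        params = np.zeros((n, 6))
        ramp = np.clip((t - 12.0) * 5.0, 0.0, 8.0)
        params[:, 2] = ramp
        params[:, 4] = 0.3 * ramp
        traj = MotionTrajectory(params, small_protocol.tr_shot_ms)
        res = run_pmc(traj, world, small_protocol, model, PMCConfig(latency_shots=1))
        during = slice(620, 670)  # strictly inside the ramp
        assert np.abs(res.residual[during, 2]).mean() == pytest.approx(0.1,
                                                                       rel=0.05)

    def test_disabled_pmc_reproduces_trajectory_as_residual(
            self, small_protocol, noiseless_setup):
        world, model = noiseless_setup
        traj = make_trajectory("nodding", small_protocol, n_volumes=30,
                               amplitude=3.0)
        res = run_pmc(traj, world, small_protocol, model,
                      PMCConfig(enabled=False))
        assert np.allclose(res.residual, traj.params, atol=1e-10)
        assert np.allclose(res.applied, np.eye(4))

    def test_model_protocol_mismatch_rejected(self, small_protocol,
                                              noiseless_setup):
        world, model = noiseless_setup
        bigger = dataclasses.replace(small_protocol, n_channels=6)
        traj = make_trajectory("shaking", bigger, n_volumes=30, amplitude=1.0)
        with pytest.raises(ValueError, match="mismatch"):
            run_pmc(traj, world, bigger, model)

    def test_residual_grows_with_noise(self, small_protocol, noiseless_setup):
        world, model = noiseless_setup
        traj = make_trajectory("fig8_horizontal", small_protocol, n_volumes=25,
                               amplitude=6.0)
        resids = []
        for sd in (0.001, 0.008):
            w = dataclasses.replace(world, channel_noise_sd=sd, probe_noise_sd=sd)
            resids.append(run_pmc(traj, w, small_protocol, model,
                                  seed=13).mean_rms_residual())
        assert resids[0] < resids[1]


class TestRetrospectiveGroundTruth:
    def test_identity_updates_reduce_to_interpolated_residual(self, rng):
        spv = 21
        vols = rng.normal(scale=0.5, size=(6, 6))
        updates = np.tile(np.eye(4), (6 * spv, 1, 1))
        out = retrospective_ground_truth(vols, updates, spv, center_shot=14)
        from navpmc.geometry import interpolate_motion
        assert np.allclose(out, interpolate_motion(vols, spv, 14), atol=1e-9)

    def test_zero_residuals_reduce_to_smoothed_updates(self, rng):
        spv = 21
        n = 5 * spv
        upd_params = np.cumsum(rng.normal(scale=0.02, size=(n, 6)), axis=0)
        updates = np.stack([params_to_affine(p) for p in upd_params])
        out = retrospective_ground_truth(np.zeros((5, 6)), updates, spv, 14)
        smoothed = moving_average(upd_params, spv, mode="centered")
        assert np.allclose(out, smoothed, atol=1e-6)

    def test_full_pmc_run_reconstruction_matches_truth_within_filter_bias(
            self, small_protocol, noiseless_setup):
        """Reconstructed ground truth must agree with the simulator's true
        trajectory up to the bias of volume-size smoothing and per-volume
        interpolation, both bounded by brute-force oracles."""
        world, model = noiseless_setup
        traj = make_trajectory("fig8_horizontal", small_protocol, n_volumes=40,
                               amplitude=5.0)
        res = run_pmc(traj, world, small_protocol, model)
        spv = small_protocol.shots_per_volume
        n_vol = traj.n_shots // spv
        centers = np.arange(n_vol) * spv + small_protocol.center_shot - 1
        recon = retrospective_ground_truth(res.residual[centers], res.applied,
                                           spv, small_protocol.center_shot)

        from navpmc.geometry import interpolate_motion
        upd = np.vstack([affine_to_params(u).as_array() for u in res.applied])
        smooth_bias = np.max(np.abs(
            moving_average(upd, spv, "centered") - upd))
        interp_bias = np.max(np.abs(
            interpolate_motion(traj.params[centers], spv,
                               small_protocol.center_shot) - traj.params))
        bound = smooth_bias + interp_bias + 1e-6
        assert np.max(np.abs(recon - traj.params)) <= bound

    def test_update_residual_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            retrospective_ground_truth(np.zeros((2, 6)),
                                       np.tile(np.eye(4), (100, 1, 1)), 21, 14)
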