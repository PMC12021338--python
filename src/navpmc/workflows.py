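"""Session-level workflows tying the pipeline stages together.

These mirror the experimental procedure: a calibration scan (instructed
shaking + nodding) fits the navigator-to-motion model; subsequent scans are
either tracked retrospectively (predict per shot, no correction) or run
through the closed PMC loop.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np

from .calibration import (DesignMatrix, LinearMotionModel, assemble_design,
                          calibrate, predict_series)
from .eddy import EddyBaseline, apply_baseline, estimate_baseline, moving_average
from .geometry import interpolate_motion
from .navigator import extract_fidnav, fit_probe_field
from .synthetic import (MotionTrajectory, ProtocolConfig, WorldConfig,
                        simulate_features, simulate_registration)

__all__ = ["CalibrationResult", "extract_container_features",
           "calibrate_session", "track_session"]


@dataclass
class CalibrationResult:
    model: LinearMotionModel
    design: DesignMatrix          # eddy-corrected design matrix
    targets: np.ndarray           # (n_shots, 6)
    baseline: EddyBaseline


def extract_container_features(container) -> tuple[np.ndarray, np.ndarray]:
    """Run the standard feature extraction over a raw navigator container."""
    prot = container.protocol
    feats = np.vstack([
        extract_fidnav(container.fidnav[i], prot.trim, prot.n_avg)
        for i in range(container.n_shots)
    ])
    fields = fit_probe_field(container.probes, prot.probe_dwell_us)
    return feats, fields


def _corrected_design(feats, fields, variant, cycle_length, window_shots,
                      baseline: EddyBaseline | None):
    dm = assemble_design(
        feats if variant in ("fidnav", "combined") else None,
        fields if variant in ("probe", "combined") else None,
        variant,
    )
    if baseline is None:
        baseline = estimate_baseline(dm.X, cycle_length, window_shots)
    X = apply_baseline(dm.X, baseline)
    return DesignMatrix(X, variant, dm.labels), baseline


def calibrate_session(traj: MotionTrajectory, world: WorldConfig,
                      protocol: ProtocolConfig = ProtocolConfig(),
                      variant: str = "combined", ridge_lambda: float = 0.0,
                      targets: str = "registration", reg_noise_rms: float = 0.1,
                      window_s: float = 10.0, cycle_length: int | None = None,
                      allow_rank_deficient: bool = False,
                      seed: int | None = None) -> CalibrationResult:
    """Simulate a calibration scan and fit the linear motion model.

    ``targets="registration"`` follows the full procedure: per-volume
    registration poses (with emulated registration noise) interpolated to
    shot rate anchored at the k-space center shot.  ``targets="truth"`` uses
    the generator's per-shot poses directly, for identifiability studies.
    """
    feats, fields = simulate_features(traj, world, protocol, seed=seed)
    window = protocol.baseline_window_shots(window_s)
    cycle = world.eddy_cycle if cycle_length is None else cycle_length
    dm, baseline = _corrected_design(feats, fields, variant, cycle, window, None)

    if targets == "truth":
        Y = traj.params
    elif targets == "registration":
        reg = simulate_registration(traj, protocol, reg_noise_rms,
                                    seed=world.seed if seed is None else seed)
        Y = interpolate_motion(reg, protocol.shots_per_volume,
                               protocol.center_shot)[: traj.n_shots]
    else:
        raise ValueError("targets must be 'truth' or 'registration'")

    meta = {
        "variant": variant,
        "targets": targets,
        "cycle_length": cycle,
        "window_shots": window,
        "protocol": dataclasses.asdict(protocol),
        "world": {
            "seed": world.seed, "kappa": world.kappa,
            "probe_rx_nonlin": world.probe_rx_nonlin,
            "channel_noise_sd": world.channel_noise_sd,
            "probe_noise_sd": world.probe_noise_sd,
            "eddy_cycle": world.eddy_cycle,
        },
    }
    model = calibrate(dm, Y, ridge_lambda=ridge_lambda,
                      allow_rank_deficient=allow_rank_deficient, meta=meta)
    return CalibrationResult(model=model, design=dm, targets=np.asarray(Y),
                             baseline=baseline)


def track_session(model: LinearMotionModel, traj: MotionTrajectory,
                  world: WorldConfig,
                  protocol: ProtocolConfig = ProtocolConfig(),
                  filter_size: int = 1, window_s: float = 10.0,
                  cycle_length: int | None = None,
                  baseline: EddyBaseline | None = None,
                  seed: int | None = None) -> np.ndarray:
    """Retrospective tracking of a scan without PMC: simulate navigators at
    the true poses, eddy-correct (re-estimating the baseline in this scan's
    initial window unless one is given), optionally filter causally, and
    predict per shot.  Returns the ``(n_shots, 6)`` predicted poses."""
    feats, fields = simulate_features(traj, world, protocol, seed=seed)
    window = protocol.baseline_window_shots(window_s)
    cycle = world.eddy_cycle if cycle_length is None else cycle_length
    dm, _ = _corrected_design(feats, fields, model.variant, cycle, window,
                              baseline)
    X = dm.X
    if filter_size > 1:
        X = moving_average(X, filter_size, mode="causal")
    return predict_series(model, X)
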