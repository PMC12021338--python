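"""Closed-loop prospective motion correction (PMC) simulation.

FIDnavs and field probes are acquired in a gradient-free window, so an FOV
update — which re-orients gradients and adjusts RF frequency/phase — does
not change what they measure: the head's pose relative to the stationary
coil and probes.  The controller therefore sees the *total* pose at every
shot.  Each shot the loop: simulates the navigators at the true pose,
removes the eddy baseline causally, optionally applies the causal
moving-average filter, predicts the absolute pose with the calibrated
linear model, and schedules that prediction as the FOV update taking effect
``latency_shots`` later — emulating a controller that must deliver its
update before the next TR-shot.  The *residual* motion the image actually
experiences is the true pose composed with the inverse of the update in
effect; it is driven by prediction error, control latency and filter group
delay.  During the initial baseline window no updates are issued (that
window estimates the eddy pattern and must stay undisturbed).

Updates compose as full rigid transforms; the hardware split into gradient
rotation versus RF frequency/phase adjustment is not modeled separately.

The module also reconstructs the retrospective ground truth of a PMC scan the
way it is done when no external tracker exists: per-volume residual motion
(from registering the corrected image series) is interpolated to shot rate
and composed with the applied FOV updates smoothed over one volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from . import geometry
from .calibration import LinearMotionModel, predict_series
from .eddy import EddyBaseline, estimate_baseline, moving_average
from .geometry import RmsParams, params_to_affine, affine_to_params, invert, rms_deviation
from .navigator import extract_fidnav, fit_probe_field
from .synthetic import MotionTrajectory, ProtocolConfig, WorldConfig, simulate_raw_block

__all__ = ["PMCConfig", "PMCSessionResult", "run_pmc", "retrospective_ground_truth"]


@dataclass(frozen=True)
class PMCConfig:
    """Controller settings.

    ``filter_size=1`` (no filtering) suits the fast time-series protocol;
    the segmented high-resolution protocol uses 10 shots to suppress residual
    eddy variations at the cost of group delay.
    """

    latency_shots: int = 1
    filter_size: int = 1
    baseline_window_s: float = 10.0
    cycle_length: int | None = None   # default: the world's eddy cycle
    enabled: bool = True

    def __post_init__(self):
        if self.latency_shots < 1:
            raise ValueError("latency must be at least one shot")
        if self.filter_size < 1:
            raise ValueError("filter size must be >= 1")


@dataclass
class PMCSessionResult:
    """Per-shot record of a closed-loop run.

    ``residual`` is the pose the imaging volume actually experienced:
    true pose composed with the inverse of the applied FOV update.
    """

    applied: np.ndarray          # (n, 4, 4) FOV update in effect at each shot
    residual: np.ndarray         # (n, 6)
    predicted: np.ndarray        # (n, 6); NaN before predictions start
    raw_rows: np.ndarray         # (n, p) uncorrected design rows
    corrected_rows: np.ndarray   # (n, p) eddy-corrected design rows
    baseline: EddyBaseline
    truth: np.ndarray            # (n, 6) input trajectory
    config: PMCConfig
    meta: Mapping = field(default_factory=dict)

    @property
    def n_shots(self) -> int:
        return self.residual.shape[0]

    def residual_rms(self, p: RmsParams = RmsParams()) -> np.ndarray:
        """Per-shot RMS-deviation magnitude (mm) of the residual pose."""
        eye = np.eye(4)
        return np.array([
            rms_deviation(params_to_affine(r), eye, p) for r in self.residual
        ])

    def mean_rms_residual(self, p: RmsParams = RmsParams(),
                          skip_shots: int | None = None,
                          exclude: np.ndarray | None = None) -> float:
        """Mean residual magnitude after dropping the baseline window (and,
        optionally, an explicit boolean mask of transient shots)."""
        r = self.residual_rms(p)
        keep = np.ones(self.n_shots, bool)
        keep[: self.meta.get("window_shots", 0) if skip_shots is None else skip_shots] = False
        if exclude is not None:
            keep &= ~exclude
        return float(r[keep].mean())


def _design_row(fid_raw, probe_raw, variant: str, protocol: ProtocolConfig) -> np.ndarray:
    feats = extract_fidnav(fid_raw, protocol.trim, protocol.n_avg)
    if variant == "fidnav":
        return feats
    fields = fit_probe_field(probe_raw, protocol.probe_dwell_us)
    if variant == "probe":
        return fields
    return np.concatenate([feats, fields])


def _expected_p(variant: str, protocol: ProtocolConfig) -> int:
    return {"fidnav": 2 * protocol.n_channels,
            "probe": protocol.n_probes,
            "combined": 2 * protocol.n_channels + protocol.n_probes}[variant]


def run_pmc(traj: MotionTrajectory, world: WorldConfig,
            protocol: ProtocolConfig, model: LinearMotionModel,
            pmc: PMCConfig = PMCConfig(), seed: int | None = None) -> PMCSessionResult:
    """Run the per-shot predict-and-correct loop over a trajectory.

    The model must match the protocol it was calibrated under (feature count
    is checked; provenance metadata is checked when present).
    """
    p = _expected_p(model.variant, protocol)
    if model.beta.shape[0] != p:
        raise ValueError(
            f"model has {model.beta.shape[0]} features but the protocol's "
            f"'{model.variant}' design needs {p}: protocol/model mismatch"
        )
    meta_tr = model.meta.get("protocol", {}).get("tr_shot_ms")
    if meta_tr is not None and not np.isclose(meta_tr, protocol.tr_shot_ms):
        raise ValueError("model was calibrated under a different TR-shot")

    n = traj.n_shots
    window = protocol.baseline_window_shots(pmc.baseline_window_s)
    if window > n:
        raise ValueError("session shorter than the baseline window")
    cycle = pmc.cycle_length if pmc.cycle_length is not None else world.eddy_cycle
    rng = world.noise_rng(2 if seed is None else seed)

    raw_rows = np.empty((n, p))
    corrected = np.full((n, p), np.nan)
    residual = np.empty((n, 6))
    predicted = np.full((n, 6), np.nan)
    applied = np.empty((n, 4, 4))
    baseline: EddyBaseline | None = None

    U = np.eye(4)
    scheduled: dict[int, np.ndarray] = {}
    for t in range(n):
        if t in scheduled:
            U = scheduled.pop(t)
        applied[t] = U
        R = params_to_affine(traj.params[t]) @ invert(U)
        residual[t] = affine_to_params(R).as_array()

        # gradient-free navigators see the total head pose, not the residual
        fid, probe = simulate_raw_block(traj.params[t], np.array([t]),
                                        world, protocol, rng)
        raw_rows[t] = _design_row(fid[0], probe[0], model.variant, protocol)

        if t == window - 1:
            baseline = estimate_baseline(raw_rows[:window], cycle, window)
            phases = np.arange(window) % cycle
            corrected[:window] = raw_rows[:window] - baseline.offsets[phases]
        if baseline is None or t < window:
            continue

        corrected[t] = raw_rows[t] - baseline.offsets[t % cycle]
        lo = max(0, t - pmc.filter_size + 1)
        row = corrected[lo:t + 1].mean(axis=0)
        pred = predict_series(model, row)[0]
        predicted[t] = pred
        if pmc.enabled:
            target = t + pmc.latency_shots
            if target < n:
                scheduled[target] = params_to_affine(pred)

    assert baseline is not None
    return PMCSessionResult(
        applied=applied, residual=residual, predicted=predicted,
        raw_rows=raw_rows, corrected_rows=corrected, baseline=baseline,
        truth=traj.params.copy(), config=pmc,
        meta={"window_shots": window, "cycle_length": cycle,
              "variant": model.variant},
    )


def retrospective_ground_truth(per_volume_residual: np.ndarray,
                               applied_updates: np.ndarray,
                               shots_per_volume: int,
                               center_shot: int = 14) -> np.ndarray:
    """Reconstruct per-shot ground-truth motion of a PMC scan.

    The applied FOV updates are decomposed to 6-DOF parameters and smoothed
    with a centered moving average of one volume (``shots_per_volume``
    shots) to match the temporal resolution of the image-derived residuals;
    the per-volume residual poses are interpolated to shot rate anchored at
    the k-space center shot; per shot the residual is composed with the
    smoothed update.

    Returns an ``(n_shots, 6)`` parameter array.
    """
    updates = np.asarray(applied_updates, float)
    if updates.ndim != 3 or updates.shape[1:] != (4, 4):
        raise ValueError("applied updates must be (n_shots, 4, 4)")
    n = updates.shape[0]
    resid = geometry.interpolate_motion(per_volume_residual, shots_per_volume,
                                        center_shot)
    if resid.shape[0] < n:
        raise ValueError(
            f"{resid.shape[0]} interpolated residual shots cannot cover "
            f"{n} update shots"
        )
    resid = resid[:n]

    upd_params = np.vstack([affine_to_params(u).as_array() for u in updates])
    smoothed = moving_average(upd_params, shots_per_volume, mode="centered")

    out = np.empty((n, 6))
    for t in range(n):
        T = params_to_affine(resid[t]) @ params_to_affine(smoothed[t])
        out[t] = affine_to_params(T).as_array()
    return out
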