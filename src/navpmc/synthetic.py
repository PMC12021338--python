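"""Synthetic navigator sessions: a forward model of the tracking physics.

The tracking method assumes that, for small head motion, multichannel FIDnav
amplitudes/phases and field-probe off-resonances are locally linear in the
6-DOF pose.  The generator here is phenomenological on purpose: it emulates
exactly the statistical structure the method relies on (linear pose response,
optional low-order nonlinearity, sequence-locked eddy patterns, complex
Gaussian receiver noise, probe saturation with excitation rate) rather than
solving electromagnetic field equations, because nothing beyond local
linearizability is assumed by the method under test.

Per shot and channel the FID signal is

    s_c(t) = a_c * (1 + L_c . m + kappa * Q_c . m^2 + e_c[k]) * exp(-t/T2*) + n

with pose vector ``m`` (deg/mm), complex channel sensitivities ``L_c``,
quadratic sensitivities ``Q_c``, and the eddy offset ``e_c[k]`` of cycle
position ``k``.  Probe off-resonance is linear in the pose plus an optional
susceptibility-like ``w_p * rx^2`` term — nodding rotations (Rx, orthogonal
to B0) are the motions most prone to nonlinear field changes at fixed probe
positions — and the probe amplitude is scaled by the steady-state saturation
factor of the per-shot excitation rate.

Instructed motion paradigms are built from two fixed direction vectors in
parameter space (shaking: Rz with a coupled y-translation; nodding: Rx with a
coupled z-translation); figures-of-8 combine both.  Defining coupling this
way makes the generalization premise of the calibration (shaking + nodding
span the poses visited by figures-of-8) hold exactly in the linear world.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import geometry
from .navigator import ProbeConstants, extract_fidnav, fit_probe_field, probe_saturation_factor

__all__ = [
    "ProtocolConfig",
    "WorldConfig",
    "MotionTrajectory",
    "PARADIGMS",
    "make_trajectory",
    "make_calibration_trajectory",
    "simulate_raw_block",
    "simulate_navigators",
    "simulate_features",
    "simulate_registration",
]

PARADIGMS = ("resting", "shaking", "nodding", "fig8_horizontal", "fig8_vertical")


@dataclass(frozen=True)
class ProtocolConfig:
    """Acquisition timing and navigator geometry of the 3D-EPI protocol."""

    tr_shot_ms: float = 20.0
    shots_per_volume: int = 21
    center_shot: int = 14          # 1-based k-space center shot in a volume
    n_channels: int = 32
    n_probes: int = 16
    fid_samples: int = 512
    dwell_us: float = 5.0
    trim: int = 4
    n_avg: int = 4
    probe_samples: int = 64
    probe_dwell_us: float = 5.0
    probe_flip_deg: float = 90.0
    probe: ProbeConstants = field(default_factory=ProbeConstants)

    def __post_init__(self):
        if min(self.tr_shot_ms, self.dwell_us, self.probe_dwell_us) <= 0:
            raise ValueError("timing parameters must be positive")
        if not 1 <= self.center_shot <= self.shots_per_volume:
            raise ValueError("center_shot must lie within a volume")

    @property
    def fid_readout_ms(self) -> float:
        return self.fid_samples * self.dwell_us * 1e-3

    def baseline_window_shots(self, window_s: float = 10.0) -> int:
        """Number of shots in the initial motion-free correction window."""
        return int(round(window_s * 1000.0 / self.tr_shot_ms))

    def n_shots(self, n_volumes: int) -> int:
        return n_volumes * self.shots_per_volume


@dataclass(frozen=True)
class WorldConfig:
    """Pose response, nonlinearity, eddy pattern and noise of one session."""

    seed: int
    channel_baseline: np.ndarray        # (C,) complex
    channel_response: np.ndarray        # (C, 6) complex, per deg / mm
    channel_quad: np.ndarray            # (C, 21) complex, one column per
                                        # pose pair product m_i m_j (i <= j),
                                        # scaled by kappa
    probe_baseline_hz: np.ndarray       # (P,)
    probe_response: np.ndarray          # (P, 6) Hz per deg / mm
    probe_rx_weight: np.ndarray         # (P,) >= 0
    probe_amp: np.ndarray               # (P,)
    eddy_channel_pattern: np.ndarray    # (cycle, C) complex
    eddy_probe_pattern_hz: np.ndarray   # (cycle, P)
    kappa: float = 0.0                  # channel second-order weight
    probe_rx_nonlin: float = 0.0        # Hz per deg^2 nodding nonlinearity
    channel_noise_sd: float = 0.002
    probe_noise_sd: float = 0.002
    eddy_cycle: int = 21
    fid_t2star_ms: float = 25.0
    subject_scale: float = 1.0

    def __post_init__(self):
        if self.kappa < 0 or self.channel_noise_sd < 0 or self.probe_noise_sd < 0:
            raise ValueError("kappa and noise SDs must be >= 0")
        if self.eddy_cycle < 1:
            raise ValueError("eddy cycle must be >= 1")

    @classmethod
    def random(cls, seed: int, protocol: ProtocolConfig = ProtocolConfig(),
               kappa: float = 0.0, probe_rx_nonlin: float = 0.0,
               channel_noise_sd: float = 0.002, probe_noise_sd: float = 0.002,
               eddy_amp: float = 0.01, eddy_cycle: int | None = None,
               subject_scale: float = 1.0) -> "WorldConfig":
        """Draw a random but fixed session world.

        Scales are chosen to mimic in-vivo orders of magnitude: ~1% relative
        FIDnav change and ~10 Hz probe off-resonance per degree/mm, percent-
        level eddy offsets, and sub-percent receiver noise.
        """
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0]))
        C, P = protocol.n_channels, protocol.n_probes
        cyc = protocol.shots_per_volume if eddy_cycle is None else int(eddy_cycle)

        def cnormal(shape, sd):
            return sd * (rng.standard_normal(shape) + 1j * rng.standard_normal(shape))

        baseline = rng.uniform(0.5, 1.5, C) * np.exp(2j * np.pi * rng.uniform(size=C))
        return cls(
            seed=int(seed),
            channel_baseline=baseline,
            channel_response=cnormal((C, 6), 0.01),
            channel_quad=cnormal((C, 21), 1e-3),
            probe_baseline_hz=rng.uniform(-50.0, 50.0, P),
            probe_response=rng.normal(0.0, 10.0, (P, 6)),
            probe_rx_weight=np.abs(rng.standard_normal(P)),
            probe_amp=rng.uniform(0.8, 1.2, P),
            eddy_channel_pattern=cnormal((cyc, C), eddy_amp),
            eddy_probe_pattern_hz=rng.normal(0.0, 200.0 * eddy_amp, (cyc, P)),
            kappa=float(kappa),
            probe_rx_nonlin=float(probe_rx_nonlin),
            channel_noise_sd=float(channel_noise_sd),
            probe_noise_sd=float(probe_noise_sd),
            eddy_cycle=cyc,
            subject_scale=float(subject_scale),
        )

    def noise_rng(self, stream: int = 1) -> np.random.Generator:
        """Deterministic substream generator derived from the session seed."""
        return np.random.default_rng(np.random.SeedSequence([self.seed, int(stream)]))


@dataclass(frozen=True)
class MotionTrajectory:
    """Per-shot ground-truth pose series with paradigm segment labels."""

    params: np.ndarray            # (n_shots, 6): rx ry rz (deg), tx ty tz (mm)
    tr_shot_ms: float
    segments: tuple = ()          # (label, start_shot, stop_shot) triples

    def __post_init__(self):
        if self.params.ndim != 2 or self.params.shape[1] != 6:
            raise ValueError("trajectory params must be (n_shots, 6)")
        if not np.all(np.isfinite(self.params)):
            raise ValueError("trajectory contains non-finite values")
        if self.params.shape[0] and not np.allclose(self.params[0], 0.0):
            raise ValueError("trajectory must start at zero pose")

    @property
    def n_shots(self) -> int:
        return self.params.shape[0]

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.n_shots) * self.tr_shot_ms


# fixed instructed-motion directions in parameter space (per unit amplitude)
def _shake_dir(coupling: float) -> np.ndarray:
    return np.array([0.0, 0.0, 1.0, 0.0, coupling, 0.0])


def _nod_dir(coupling: float) -> np.ndarray:
    return np.array([1.0, 0.0, 0.0, 0.0, 0.0, coupling])


def _hold_oscillation(t: np.ndarray, duration: float, hold: float) -> np.ndarray:
    """One instructed left/right (or up/down) cycle on [0, duration):
    0 -> +1, hold, +1 -> -1, hold, -1 -> 0, with cosine-eased ramps."""
    ramp = (duration - 2.0 * hold) / 3.0
    if ramp <= 0:
        raise ValueError("segment too short for the requested holds")

    def ease(x):  # smooth 0 -> 1
        x = np.clip(x, 0.0, 1.0)
        return 0.5 * (1.0 - np.cos(np.pi * x))

    tt = np.mod(t, duration)
    out = np.zeros_like(tt)
    out += ease(tt / ramp)                                   # rise to +1
    out -= 2.0 * ease((tt - ramp - hold) / ramp)             # swing to -1
    out += ease((tt - 2 * ramp - 2 * hold) / ramp)           # return to 0
    return out


def _fig8(t: np.ndarray, duration: float) -> tuple[np.ndarray, np.ndarray]:
    """Nose 'drawing' a figure-of-8: primary full-period lobe and secondary
    half-period crossing, both zero at segment boundaries."""
    ph = 2.0 * np.pi * np.mod(t, duration) / duration
    return np.sin(ph), 0.5 * np.sin(2.0 * ph)


def make_trajectory(paradigm: str, protocol: ProtocolConfig = ProtocolConfig(),
                    n_volumes: int = 120, amplitude: float = 8.0,
                    seed: int = 0, lead_in_s: float = 10.0,
                    coupling: float = 0.3, hold_s: float = 5.0,
                    segment_s: float = 24.0) -> MotionTrajectory:
    """Build a per-shot instructed-motion trajectory.

    ``amplitude`` is the peak rotation (deg) of the instructed pattern (for
    ``resting`` it is the RMS scale of the random drift, in deg/mm).
    ``coupling`` couples each rotation to its translation partner (mm per
    deg).  The first ``lead_in_s`` seconds are motion-free so the eddy
    baseline window sees an undisturbed stream.
    """
    if paradigm not in PARADIGMS:
        raise ValueError(f"unknown paradigm {paradigm!r}; choose from {PARADIGMS}")
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    n_shots = protocol.n_shots(n_volumes)
    t = np.arange(n_shots) * protocol.tr_shot_ms * 1e-3  # seconds
    active = t >= lead_in_s
    ta = t[active] - lead_in_s
    params = np.zeros((n_shots, 6))

    if paradigm == "resting":
        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
        steps = rng.standard_normal((n_shots, 6))
        steps[~active] = 0.0  # drift starts after the lead-in
        walk = np.cumsum(steps, axis=0)
        # ~1 s causal smoothing keeps the lead-in exactly motion-free
        from .eddy import moving_average
        walk = moving_average(walk, max(1, int(1000 / protocol.tr_shot_ms)),
                              mode="causal")
        rms = float(np.sqrt(np.mean(walk ** 2)))
        params = amplitude * walk / (rms if rms > 0 else 1.0)
    elif paradigm in ("shaking", "nodding"):
        wave = _hold_oscillation(ta, segment_s, hold_s)
        d = _shake_dir(coupling) if paradigm == "shaking" else _nod_dir(coupling)
        params[active] = amplitude * np.outer(wave, d)
    else:
        u, v = _fig8(ta, segment_s)
        if paradigm == "fig8_horizontal":
            params[active] = amplitude * (np.outer(u, _shake_dir(coupling))
                                          + np.outer(v, _nod_dir(coupling)))
        else:
            params[active] = amplitude * (np.outer(u, _nod_dir(coupling))
                                          + np.outer(v, _shake_dir(coupling)))

    segments = (("rest", 0, int(np.searchsorted(t, lead_in_s))),
                (paradigm, int(np.searchsorted(t, lead_in_s)), n_shots))
    return MotionTrajectory(params, protocol.tr_shot_ms, segments)


def make_calibration_trajectory(protocol: ProtocolConfig = ProtocolConfig(),
                                n_volumes: int = 250, amplitude: float = 8.0,
                                lead_in_s: float = 10.0, coupling: float = 0.3,
                                hold_s: float = 5.0, segment_s: float = 24.0
                                ) -> MotionTrajectory:
    """The calibration session: shaking and nodding, each twice (250 volumes,
    ~1:45 at 21 shots x 20 ms), after a motion-free lead-in."""
    n_shots = protocol.n_shots(n_volumes)
    t = np.arange(n_shots) * protocol.tr_shot_ms * 1e-3
    params = np.zeros((n_shots, 6))
    order = ("shaking", "nodding", "shaking", "nodding")
    segments = [("rest", 0, int(np.searchsorted(t, lead_in_s)))]
    for i, label in enumerate(order):
        lo, hi = lead_in_s + i * segment_s, lead_in_s + (i + 1) * segment_s
        sel = (t >= lo) & (t < hi)
        if not np.any(sel):
            break
        wave = _hold_oscillation(t[sel] - lo, segment_s, hold_s)
        d = _shake_dir(coupling) if label == "shaking" else _nod_dir(coupling)
        params[sel] = amplitude * np.outer(wave, d)
        idx = np.flatnonzero(sel)
        segments.append((label, int(idx[0]), int(idx[-1] + 1)))
    return MotionTrajectory(params, protocol.tr_shot_ms, tuple(segments))


_QUAD_I, _QUAD_J = np.triu_indices(6)


def pose_quad_terms(params: np.ndarray) -> np.ndarray:
    """All 21 second-order pose products ``m_i m_j`` (i <= j) per shot.

    The cross products are what makes the second-order world genuinely
    nonlinear for a linear tracker: motions confined to a single axis never
    excite them, but multi-axis motions (figures-of-8) do.
    """
    params = np.atleast_2d(np.asarray(params, float))
    return params[:, _QUAD_I] * params[:, _QUAD_J]


def _channel_gain(params: np.ndarray, world: WorldConfig) -> np.ndarray:
    lin = params @ world.channel_response.T
    quad = pose_quad_terms(params) @ world.channel_quad.T
    return 1.0 + world.subject_scale * (lin + world.kappa * quad)


def _probe_freq(params: np.ndarray, shot_idx: np.ndarray,
                world: WorldConfig) -> np.ndarray:
    f = world.probe_baseline_hz + world.subject_scale * (params @ world.probe_response.T)
    f = f + (world.subject_scale * world.probe_rx_nonlin
             * (params[:, 0] ** 2)[:, None] * world.probe_rx_weight)
    return f + world.eddy_probe_pattern_hz[shot_idx % world.eddy_cycle]


def simulate_raw_block(params: np.ndarray, shot_idx: np.ndarray,
                       world: WorldConfig, protocol: ProtocolConfig,
                       rng: np.random.Generator | None = None
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Raw complex navigator blocks for a batch of shots.

    Returns ``(fid, probe)`` with shapes ``(n, C, fid_samples)`` and
    ``(n, P, probe_samples)``.  ``rng=None`` gives the noiseless signal.
    """
    params = np.atleast_2d(np.asarray(params, float))
    shot_idx = np.atleast_1d(np.asarray(shot_idx, int))
    n = params.shape[0]

    g = _channel_gain(params, world) + world.eddy_channel_pattern[shot_idx % world.eddy_cycle]
    ts_ms = np.arange(protocol.fid_samples) * protocol.dwell_us * 1e-3
    decay = np.exp(-ts_ms / world.fid_t2star_ms)
    fid = world.channel_baseline[None, :, None] * g[:, :, None] * decay[None, None, :]

    f = _probe_freq(params, shot_idx, world)
    tp_s = np.arange(protocol.probe_samples) * protocol.probe_dwell_us * 1e-6
    sat = probe_saturation_factor(protocol.tr_shot_ms, protocol.probe.t1_ms,
                                  protocol.probe_flip_deg)
    env = (world.probe_amp * sat)[None, :, None] * np.exp(-tp_s * 1e3 / protocol.probe.t2_ms)
    probe = env * np.exp(2j * np.pi * f[:, :, None] * tp_s[None, None, :])

    if rng is not None:
        if world.channel_noise_sd > 0:
            fid = fid + world.channel_noise_sd * (
                rng.standard_normal(fid.shape) + 1j * rng.standard_normal(fid.shape))
        if world.probe_noise_sd > 0:
            probe = probe + world.probe_noise_sd * (
                rng.standard_normal(probe.shape) + 1j * rng.standard_normal(probe.shape))
    return fid, probe


def simulate_navigators(traj: MotionTrajectory, world: WorldConfig,
                        protocol: ProtocolConfig = ProtocolConfig(),
                        seed: int | None = None):
    """Simulate the full raw navigator session as a NavigatorContainer.

    Memory scales with shots x channels x samples; for long sessions where
    only the extracted features are needed use :func:`simulate_features`.
    """
    from .io import NavigatorContainer
    rng = world.noise_rng(1 if seed is None else seed)
    fid, probe = simulate_raw_block(traj.params, np.arange(traj.n_shots),
                                    world, protocol, rng)
    return NavigatorContainer(
        fidnav=fid, probes=probe, timestamps_ms=traj.times_ms.copy(),
        protocol=protocol,
    )


def simulate_features(traj: MotionTrajectory, world: WorldConfig,
                      protocol: ProtocolConfig = ProtocolConfig(),
                      seed: int | None = None, chunk: int = 256
                      ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate and immediately reduce a session to its navigator features.

    Runs the same raw forward model as :func:`simulate_navigators` in chunks,
    applying the standard extraction (trim/average for FIDnavs, weighted
    phase fit for probes).  Returns ``(fidnav_features (n, 2C),
    probe_fields_hz (n, P))``.
    """
    rng = world.noise_rng(1 if seed is None else seed)
    n = traj.n_shots
    feats = np.empty((n, 2 * protocol.n_channels))
    fields = np.empty((n, protocol.n_probes))
    for lo in range(0, n, chunk):
        hi = min(n, lo + chunk)
        fid, probe = simulate_raw_block(traj.params[lo:hi], np.arange(lo, hi),
                                        world, protocol, rng)
        for i in range(hi - lo):
            feats[lo + i] = extract_fidnav(fid[i], protocol.trim, protocol.n_avg)
        fields[lo:hi] = fit_probe_field(probe, protocol.probe_dwell_us)
    return feats, fields


def simulate_registration(traj: MotionTrajectory,
                          protocol: ProtocolConfig = ProtocolConfig(),
                          reg_noise_rms: float = 0.1,
                          seed: int = 0) -> np.ndarray:
    """Per-volume registration output: the true pose at each volume's center
    shot plus a random rigid perturbation of RMS-deviation magnitude
    ``reg_noise_rms`` (mm), emulating image-registration error (the actual
    registration is outside this package's scope).

    Returns an ``(n_volumes, 6)`` parameter array.
    """
    if reg_noise_rms < 0:
        raise ValueError("registration noise must be >= 0")
    spv = protocol.shots_per_volume
    n_vol = int(np.ceil(traj.n_shots / spv))
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 5]))
    out = np.empty((n_vol, 6))
    for v in range(n_vol):
        anchor = min(v * spv + protocol.center_shot - 1, traj.n_shots - 1)
        T = geometry.params_to_affine(traj.params[anchor])
        if reg_noise_rms > 0:
            d = rng.standard_normal(6) * 1e-3
            m0 = geometry.rms_deviation(geometry.params_to_affine(d), np.eye(4))
            pert = geometry.params_to_affine(d * reg_noise_rms / m0)
            T = pert @ T
        out[v] = geometry.affine_to_params(T).as_array()
    return out
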