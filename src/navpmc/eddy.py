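"""Eddy-current baseline estimation and removal for navigator streams.

Gradient switching induces transient (eddy-current) fields that contaminate
the navigator readouts with a motion-independent pattern locked to the
sequence's phase-encode schedule: echo-time shifting in the segmented
high-resolution protocol makes it repeat every ``cycle_length = 10`` shots,
and both protocols additionally show a slow systematic variation per volume.
Because the pattern is motion-independent it can be estimated once, during an
initial motion-free window (10 s by default), and subtracted in streaming
order afterwards.

All operators here are linear; the real-time path is causal (output at shot t
depends only on shots <= t).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "EddyBaseline",
    "VolumeTrend",
    "estimate_baseline",
    "apply_baseline",
    "moving_average",
    "estimate_volume_trend",
]


@dataclass(frozen=True)
class EddyBaseline:
    """Cycle-locked navigator offsets: ``offsets[k]`` is subtracted from every
    shot whose index is ``k (mod cycle_length)``.  Offsets are stored after
    removal of the window grand mean so that applying the baseline leaves the
    stream's DC level — which the calibration handles by mean-centering —
    untouched."""

    offsets: np.ndarray  # (cycle_length, n_features)
    cycle_length: int
    window_shots: int

    def __post_init__(self):
        if self.cycle_length < 1:
            raise ValueError("cycle_length must be >= 1")
        if self.offsets.shape[0] != self.cycle_length:
            raise ValueError("offsets must have cycle_length rows")
        if not np.all(np.isfinite(self.offsets)):
            raise ValueError("baseline offsets must be finite")


@dataclass(frozen=True)
class VolumeTrend:
    """Smoothed per-volume-position navigator offsets (one row per shot
    position within a volume)."""

    offsets: np.ndarray  # (shots_per_volume, n_features)
    shots_per_volume: int
    smooth_size: int

    def as_baseline(self, window_shots: int = 0) -> EddyBaseline:
        """View the trend as a cycle-locked baseline with cycle =
        shots_per_volume, so it can be removed with :func:`apply_baseline`."""
        return EddyBaseline(self.offsets, self.shots_per_volume, window_shots)


def estimate_baseline(stream: np.ndarray, cycle_length: int,
                      window_shots: int) -> EddyBaseline:
    """Estimate cycle-locked offsets from the first ``window_shots`` shots.

    ``offsets[k]`` is the mean of all window shots with index equal to
    ``k (mod cycle_length)``, after subtracting the window grand mean per
    feature.  The window is assumed motion-free and free of FOV updates.
    """
    stream = np.asarray(stream, float)
    if stream.ndim != 2:
        raise ValueError("stream must be 2-D (shots x features)")
    if window_shots < cycle_length:
        raise ValueError("window must cover at least one full cycle")
    if window_shots > stream.shape[0]:
        raise ValueError("window exceeds stream length")
    win = stream[:window_shots]
    centered = win - win.mean(axis=0)
    offsets = np.empty((cycle_length, stream.shape[1]))
    phases = np.arange(window_shots) % cycle_length
    for k in range(cycle_length):
        sel = centered[phases == k]
        if sel.shape[0] == 0:
            raise ValueError(f"cycle position {k} unobserved in window")
        offsets[k] = sel.mean(axis=0)
    return EddyBaseline(offsets, cycle_length, window_shots)


def apply_baseline(stream: np.ndarray, baseline: EddyBaseline,
                   start_shot: int = 0) -> np.ndarray:
    """Subtract the cycle-locked offsets from every shot (causal: each
    output depends only on its own input sample).  ``start_shot`` gives the
    absolute index of the first row so cycle phase stays aligned when a
    stream is processed in pieces."""
    stream = np.asarray(stream, float)
    if stream.ndim == 1:
        return apply_baseline(stream[None, :], baseline, start_shot)[0]
    if stream.shape[1] != baseline.offsets.shape[1]:
        raise ValueError("feature dimension does not match baseline")
    phases = (np.arange(stream.shape[0]) + start_shot) % baseline.cycle_length
    return stream - baseline.offsets[phases]


def moving_average(stream: np.ndarray, size: int = 10,
                   mode: str = "causal") -> np.ndarray:
    """Moving-average filter along the shot axis.

    ``causal`` averages the most recent ``min(size, t+1)`` samples and is the
    real-time filter (it adds group delay ~(size-1)/2 shots).  ``centered``
    is the symmetric retrospective filter with shrink-to-valid edge windows.
    """
    stream = np.asarray(stream, float)
    squeeze = stream.ndim == 1
    if squeeze:
        stream = stream[:, None]
    if size < 1:
        raise ValueError("filter size must be >= 1")
    n = stream.shape[0]
    cs = np.vstack([np.zeros((1, stream.shape[1])), np.cumsum(stream, axis=0)])
    idx = np.arange(n)
    if mode == "causal":
        lo = np.maximum(0, idx - size + 1)
        hi = idx + 1
    elif mode == "centered":
        half_l = (size - 1) // 2
        half_r = size // 2
        lo = np.maximum(0, idx - half_l)
        hi = np.minimum(n, idx + half_r + 1)
    else:
        raise ValueError("mode must be 'causal' or 'centered'")
    out = (cs[hi] - cs[lo]) / (hi - lo)[:, None]
    return out[:, 0] if squeeze else out


def estimate_volume_trend(phantom_stream: np.ndarray, shots_per_volume: int,
                          smooth_size: int = 10) -> VolumeTrend:
    """Estimate the slow per-volume navigator variation from a motion-free
    (phantom) stream.

    The stream is folded at ``shots_per_volume``, averaged per within-volume
    shot position across complete volumes, grand-mean removed, and smoothed
    with a centered moving average of ``smooth_size`` shots.
    """
    stream = np.asarray(phantom_stream, float)
    if stream.ndim != 2:
        raise ValueError("stream must be 2-D (shots x features)")
    n_vol = stream.shape[0] // shots_per_volume
    if n_vol < 1:
        raise ValueError("stream must cover at least one full volume")
    folded = stream[: n_vol * shots_per_volume].reshape(
        n_vol, shots_per_volume, stream.shape[1]
    )
    curve = folded.mean(axis=0)
    curve = curve - curve.mean(axis=0)
    smoothed = moving_average(curve, smooth_size, mode="centered")
    return VolumeTrend(smoothed, shots_per_volume, smooth_size)
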