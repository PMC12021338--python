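"""Tracking-accuracy and image-quality metrics.

Tracking accuracy follows the two-metric convention: per-parameter mean
absolute error (MAE, deg or mm) with the standard deviation of the error
(STDerr) as precision, and the sphere-projected RMS deviation as a single
scalar that folds rotations and translations together (rotations evaluated
over an 80-mm sphere by default).  Both series are re-referenced to their
first sample before comparison, so the report describes motion relative to
the starting pose.

Image quality is summarized by NRMSE and SSIM against a motion-free
reference; images must already be registered and shape-matched — the metrics
refuse to resample silently.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter

from .geometry import PARAM_NAMES, RmsParams, params_to_affine, invert, rms_deviation

__all__ = ["TrackingReport", "tracking_report", "nrmse", "ssim"]


@dataclass(frozen=True)
class TrackingReport:
    """Accuracy/precision summary of one tracking comparison."""

    mae: np.ndarray                 # (6,) per parameter, deg / mm
    stderr: np.ndarray              # (6,) std of the error per parameter
    mean_rms_error: float           # mm, mean over shots
    mean_rms_magnitude: float       # mm, ground truth vs identity
    n_shots: int

    @property
    def rotation_mae(self) -> float:
        return float(self.mae[:3].mean())

    @property
    def translation_mae(self) -> float:
        return float(self.mae[3:].mean())

    @property
    def pooled_stderr(self) -> float:
        return float(np.sqrt(np.mean(self.stderr ** 2)))

    def to_dict(self) -> dict:
        return {
            "mae": dict(zip(PARAM_NAMES, map(float, self.mae))),
            "stderr": dict(zip(PARAM_NAMES, map(float, self.stderr))),
            "rotation_mae_deg": self.rotation_mae,
            "translation_mae_mm": self.translation_mae,
            "pooled_stderr": self.pooled_stderr,
            "mean_rms_error_mm": self.mean_rms_error,
            "mean_rms_magnitude_mm": self.mean_rms_magnitude,
            "n_shots": self.n_shots,
        }

    def __str__(self) -> str:
        lines = [f"{'param':>6} {'MAE':>10} {'STDerr':>10}"]
        for name, m, s in zip(PARAM_NAMES, self.mae, self.stderr):
            unit = "deg" if name.startswith("r") else "mm"
            lines.append(f"{name:>6} {m:>10.4f} {s:>10.4f}  [{unit}]")
        lines.append(f"mean RMS error     {self.mean_rms_error:.4f} mm")
        lines.append(f"mean RMS magnitude {self.mean_rms_magnitude:.4f} mm")
        return "\n".join(lines)


def _re_reference(params: np.ndarray) -> list[np.ndarray]:
    """Affines of each pose relative to the series' first sample."""
    T0_inv = invert(params_to_affine(params[0]))
    return [params_to_affine(p) @ T0_inv for p in params]


def tracking_report(truth: np.ndarray, pred: np.ndarray,
                    p: RmsParams = RmsParams()) -> TrackingReport:
    """Compare a predicted pose series against ground truth.

    Both series are re-referenced so they start at zero; errors are then
    computed per shot on the decomposed 6-DOF parameters and on the rigid
    transforms via the RMS-deviation metric.
    """
    truth = np.asarray(truth, float)
    pred = np.asarray(pred, float)
    if truth.shape != pred.shape:
        raise ValueError("truth and prediction series differ in shape")
    if truth.ndim != 2 or truth.shape[1] != 6 or truth.shape[0] < 2:
        raise ValueError("series must be (n_shots >= 2, 6)")

    T_truth = _re_reference(truth)
    T_pred = _re_reference(pred)
    from .geometry import affine_to_params
    truth_p = np.vstack([affine_to_params(T).as_array() for T in T_truth])
    pred_p = np.vstack([affine_to_params(T).as_array() for T in T_pred])
    err = pred_p - truth_p

    eye = np.eye(4)
    rms_err = np.array([rms_deviation(a, b, p) for a, b in zip(T_pred, T_truth)])
    rms_mag = np.array([rms_deviation(a, eye, p) for a in T_truth])

    return TrackingReport(
        mae=np.abs(err).mean(axis=0),
        stderr=err.std(axis=0),
        mean_rms_error=float(rms_err.mean()),
        mean_rms_magnitude=float(rms_mag.mean()),
        n_shots=truth.shape[0],
    )


def nrmse(image: np.ndarray, reference: np.ndarray) -> float:
    """Normalized root-mean-square error: ``||img - ref|| / ||ref||``."""
    image = np.asarray(image, float)
    reference = np.asarray(reference, float)
    if image.shape != reference.shape:
        raise ValueError("image and reference must have the same shape")
    ref_norm = np.linalg.norm(reference)
    if ref_norm == 0:
        raise ValueError("reference image has zero norm")
    return float(np.linalg.norm(image - reference) / ref_norm)


def ssim(image: np.ndarray, reference: np.ndarray,
         data_range: float | None = None, sigma: float = 1.5,
         truncate: float = 3.5, k1: float = 0.01, k2: float = 0.03) -> float:
    """Mean structural similarity index with a Gaussian weighting window.

    Local means, variances and covariance are computed with a Gaussian
    window (sigma 1.5, truncated at 3.5 sigma); the edge region where the
    window is incomplete is cropped before averaging.  ``data_range``
    defaults to the reference's peak-to-peak range.
    """
    x = np.asarray(image, float)
    y = np.asarray(reference, float)
    if x.shape != y.shape:
        raise ValueError("image and reference must have the same shape")
    if data_range is None:
        data_range = float(y.max() - y.min())
        if data_range == 0:
            raise ValueError("flat reference: pass data_range explicitly")

    c1 = (k1 * data_range) ** 2
    c2 = (k2 * data_range) ** 2
    blur = lambda a: gaussian_filter(a, sigma, truncate=truncate)

    ux, uy = blur(x), blur(y)
    uxx, uyy, uxy = blur(x * x), blur(y * y), blur(x * y)
    vx = uxx - ux * ux
    vy = uyy - uy * uy
    cov = uxy - ux * uy

    num = (2 * ux * uy + c1) * (2 * cov + c2)
    den = (ux ** 2 + uy ** 2 + c1) * (vx + vy + c2)
    s = num / den

    r = int(truncate * sigma + 0.5)  # window radius actually used
    crop = tuple(slice(r, dim - r) for dim in s.shape)
    return float(s[crop].mean())
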