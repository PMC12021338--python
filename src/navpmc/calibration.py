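"""Linear calibration of navigator data to 6-DOF rigid head motion.

The tracking model is deliberately simple: after subtracting the calibration
time-series means from the navigator data ``X`` (shots x features) and the
interpolated motion parameters ``Y`` (shots x 6), a linear least-squares fit

    beta = argmin || Xc beta - Yc ||^2   (+ lambda ||beta||^2 for ridge)

maps navigator values to pose.  ``X`` is either the 64 FIDnav real/imaginary
values, the 16 probe field offsets, or their 80-column concatenation.
Prediction is a single matrix-vector product, cheap enough to finish well
within one 20-ms TR-shot in a real-time loop.

The normal-equations formula specifies the estimator, not the algorithm:
the solve uses an SVD-based least-squares factorization, which is what keeps
80 strongly correlated columns numerically tame.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Mapping

import numpy as np

from .geometry import PARAM_NAMES, RigidMotion

__all__ = [
    "VARIANTS",
    "DesignMatrix",
    "LinearMotionModel",
    "assemble_design",
    "calibrate",
    "predict",
    "predict_series",
    "save_model",
    "load_model",
]

VARIANTS = ("fidnav", "probe", "combined")


@dataclass(frozen=True)
class DesignMatrix:
    """Navigator design matrix with its variant tag and column labels."""

    X: np.ndarray  # (n_obs, p)
    variant: str
    labels: tuple[str, ...]

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"variant must be one of {VARIANTS}")
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if not np.all(np.isfinite(self.X)):
            raise ValueError("design matrix contains non-finite entries")
        if len(self.labels) != self.X.shape[1]:
            raise ValueError("one label per column required")


@dataclass(frozen=True)
class LinearMotionModel:
    """Fitted navigator-to-motion model.

    ``beta`` maps mean-centered navigator features to mean-centered motion
    parameters ``(rx, ry, rz, tx, ty, tz)``; the stored means make the model
    self-contained: prediction never re-centers on test data.
    """

    beta: np.ndarray    # (p, 6)
    x_mean: np.ndarray  # (p,)
    y_mean: np.ndarray  # (6,)
    variant: str
    ridge_lambda: float = 0.0
    meta: Mapping = dc_field(default_factory=dict)

    def __post_init__(self):
        if self.beta.shape != (self.x_mean.shape[0], 6):
            raise ValueError("beta must be (p, 6) with p = len(x_mean)")
        if self.y_mean.shape != (6,):
            raise ValueError("y_mean must have 6 entries")
        if self.ridge_lambda < 0:
            raise ValueError("ridge lambda must be >= 0")


def assemble_design(fidnav_features: np.ndarray | None,
                    probe_fields: np.ndarray | None,
                    variant: str) -> DesignMatrix:
    """Stack per-shot navigator streams into a design matrix.

    ``fidnav`` uses the 2*n_channels FIDnav values, ``probe`` the n_probes
    field offsets, ``combined`` their concatenation.  Streams must be aligned
    shot-by-shot.
    """
    if variant not in VARIANTS:
        raise ValueError(f"variant must be one of {VARIANTS}")
    blocks = []
    labels: list[str] = []
    if variant in ("fidnav", "combined"):
        if fidnav_features is None:
            raise ValueError("variant requires FIDnav features")
        F = np.asarray(fidnav_features, float)
        n_ch = F.shape[1] // 2
        blocks.append(F)
        labels += [f"ch{c:02d}_re" for c in range(n_ch)]
        labels += [f"ch{c:02d}_im" for c in range(n_ch)]
    if variant in ("probe", "combined"):
        if probe_fields is None:
            raise ValueError("variant requires probe field estimates")
        P = np.asarray(probe_fields, float)
        blocks.append(P)
        labels += [f"probe{p:02d}_hz" for p in range(P.shape[1])]
    if len(blocks) == 2 and blocks[0].shape[0] != blocks[1].shape[0]:
        raise ValueError("FIDnav and probe streams are not shot-aligned")
    return DesignMatrix(np.hstack(blocks), variant, tuple(labels))


def calibrate(X, Y, ridge_lambda: float = 0.0,
              allow_rank_deficient: bool = False,
              meta: Mapping | None = None) -> LinearMotionModel:
    """Fit the linear motion model on mean-centered data.

    For ``ridge_lambda > 0`` the columns are standardized internally (so
    lambda is unit-free across FIDnav and probe columns) and the ridge
    solution is de-standardized back to raw-feature coefficients.  Rotations
    (deg) and translations (mm) share one target matrix without weighting.

    A rank-deficient design with ``ridge_lambda = 0`` raises by default,
    advising regularization; ``allow_rank_deficient=True`` instead returns
    the SVD minimum-norm solution, whose fitted values are still the exact
    orthogonal projection (useful for noise-free simulated worlds whose
    feature manifold has rank <= 6).
    """
    variant = "fidnav"
    if isinstance(X, DesignMatrix):
        variant = X.variant
        X = X.X
    X = np.asarray(X, float)
    Y = np.asarray(Y, float)
    if Y.ndim != 2 or Y.shape[1] != 6:
        raise ValueError("Y must be (n_obs, 6)")
    if X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must have matching rows")
    n_obs, p = X.shape
    if ridge_lambda == 0 and n_obs <= p and not allow_rank_deficient:
        raise ValueError(
            "n_obs <= n_features with lambda = 0: the fit is underdetermined; "
            "use ridge_lambda > 0 or allow_rank_deficient=True"
        )

    x_mean = X.mean(axis=0)
    y_mean = Y.mean(axis=0)
    Xc = X - x_mean
    Yc = Y - y_mean

    if ridge_lambda == 0:
        beta, _, rank, _ = np.linalg.lstsq(Xc, Yc, rcond=None)
        if rank < p and not allow_rank_deficient:
            raise ValueError(
                f"design matrix is rank deficient (rank {rank} < {p}); "
                "add ridge regularization or pass allow_rank_deficient=True"
            )
    else:
        scale = Xc.std(axis=0, ddof=0)
        scale = np.where(scale > 0, scale, 1.0)
        Xs = Xc / scale
        aug_X = np.vstack([Xs, np.sqrt(ridge_lambda) * np.eye(p)])
        aug_Y = np.vstack([Yc, np.zeros((p, 6))])
        beta_s, *_ = np.linalg.lstsq(aug_X, aug_Y, rcond=None)
        beta = beta_s / scale[:, None]

    return LinearMotionModel(
        beta=beta, x_mean=x_mean, y_mean=y_mean, variant=variant,
        ridge_lambda=float(ridge_lambda), meta=dict(meta or {}),
    )


def predict_series(model: LinearMotionModel, X: np.ndarray) -> np.ndarray:
    """Predict pose parameters for many shots: ``y_mean + (X - x_mean) beta``."""
    X = np.asarray(X, float)
    if X.ndim == 1:
        X = X[None, :]
    if X.shape[1] != model.beta.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} does not match model "
            f"({model.beta.shape[0]})"
        )
    return model.y_mean + (X - model.x_mean) @ model.beta


def predict(model: LinearMotionModel, x: np.ndarray) -> RigidMotion:
    """Predict the pose for a single shot's feature vector."""
    return RigidMotion.from_array(predict_series(model, np.asarray(x, float))[0])


def save_model(model: LinearMotionModel, path) -> None:
    payload = {
        "format": "navpmc-model-1",
        "variant": model.variant,
        "ridge_lambda": model.ridge_lambda,
        "beta": model.beta.tolist(),
        "x_mean": model.x_mean.tolist(),
        "y_mean": model.y_mean.tolist(),
        "param_order": list(PARAM_NAMES),
        "meta": dict(model.meta),
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> LinearMotionModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "navpmc-model-1":
        raise ValueError("unrecognized model file format")
    return LinearMotionModel(
        beta=np.asarray(payload["beta"], float),
        x_mean=np.asarray(payload["x_mean"], float),
        y_mean=np.asarray(payload["y_mean"], float),
        variant=payload["variant"],
        ridge_lambda=float(payload["ridge_lambda"]),
        meta=payload.get("meta", {}),
    )
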