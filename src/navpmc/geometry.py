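"""Rigid-body transform algebra and motion-parameter conventions.

Head pose is described by six degrees of freedom: three rotations about the
scanner x/y/z axes (degrees) and three translations (mm).  Internally poses
are handled either as a :class:`RigidMotion`, as a length-6 parameter vector
in the fixed order ``(rx, ry, rz, tx, ty, tz)``, or as a 4x4 homogeneous
affine matrix in mm.

The Euler convention is intrinsic rotations applied in the order x -> y -> z
(scipy's ``"XYZ"``).  Angles are degrees at every public boundary and radians
only inside scipy calls.  The rotation center is the scanner isocenter unless
an explicit center offset is supplied.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "PARAM_NAMES",
    "DEFAULT_EULER",
    "RigidMotion",
    "RmsParams",
    "params_to_affine",
    "affine_to_params",
    "compose",
    "invert",
    "assert_rigid",
    "is_rigid",
    "rms_deviation",
    "interpolate_motion",
    "image_to_scanner",
]

PARAM_NAMES = ("rx", "ry", "rz", "tx", "ty", "tz")

#: intrinsic rotations about scanner x, then y, then z
DEFAULT_EULER = "XYZ"

_RIGID_TOL = 1e-6


@dataclass(frozen=True)
class RigidMotion:
    """A 6-DOF rigid head pose: rotations in degrees, translations in mm."""

    rx: float = 0.0
    ry: float = 0.0
    rz: float = 0.0
    tx: float = 0.0
    ty: float = 0.0
    tz: float = 0.0

    def __post_init__(self) -> None:
        vals = self.as_array()
        if not np.all(np.isfinite(vals)):
            raise ValueError("rigid motion parameters must be finite")
        if np.any(np.abs(vals[:3]) >= 180.0):
            raise ValueError("rotation angles must satisfy |angle| < 180 deg")

    def as_array(self) -> np.ndarray:
        return np.array([self.rx, self.ry, self.rz, self.tx, self.ty, self.tz], float)

    @classmethod
    def from_array(cls, v: Sequence[float]) -> "RigidMotion":
        v = np.asarray(v, float)
        if v.shape != (6,):
            raise ValueError(f"expected 6 parameters, got shape {v.shape}")
        return cls(*v)


@dataclass(frozen=True)
class RmsParams:
    """Parameters of the sphere-projected RMS deviation metric.

    ``radius`` is the radius (mm) of the solid sphere over which rotational
    displacement is averaged (default 80 mm); ``center`` shifts the rotation
    center away from the isocenter.
    """

    radius: float = 80.0
    center: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if not self.radius > 0:
            raise ValueError("sphere radius must be positive")


def _as_params_array(m) -> np.ndarray:
    if isinstance(m, RigidMotion):
        return m.as_array()
    v = np.asarray(m, float)
    if v.shape != (6,):
        raise ValueError(f"expected a RigidMotion or 6-vector, got shape {v.shape}")
    if not np.all(np.isfinite(v)):
        raise ValueError("rigid motion parameters must be finite")
    return v


def params_to_affine(m, convention: str = DEFAULT_EULER) -> np.ndarray:
    """Build the 4x4 homogeneous affine for a 6-DOF pose."""
    v = _as_params_array(m)
    T = np.eye(4)
    T[:3, :3] = Rotation.from_euler(convention, v[:3], degrees=True).as_matrix()
    T[:3, 3] = v[3:]
    return T


def is_rigid(T: np.ndarray, tol: float = _RIGID_TOL) -> bool:
    T = np.asarray(T, float)
    if T.shape != (4, 4):
        return False
    if not np.allclose(T[3], [0, 0, 0, 1], atol=tol):
        return False
    R = T[:3, :3]
    return (
        np.allclose(R.T @ R, np.eye(3), atol=tol)
        and np.linalg.det(R) > 0
        and bool(np.all(np.isfinite(T)))
    )


def assert_rigid(T: np.ndarray, tol: float = _RIGID_TOL) -> np.ndarray:
    T = np.asarray(T, float)
    if not is_rigid(T, tol):
        raise ValueError("matrix is not a rigid 4x4 transform within tolerance")
    return T


def affine_to_params(T: np.ndarray, convention: str = DEFAULT_EULER,
                     tol: float = _RIGID_TOL) -> RigidMotion:
    """Decompose a rigid affine into Euler angles (deg) and translation (mm).

    Gimbal-adjacent matrices are resolved deterministically by scipy's Euler
    decomposition (the first angle absorbs the degenerate freedom).
    """
    T = assert_rigid(T, tol)
    ang = Rotation.from_matrix(T[:3, :3]).as_euler(convention, degrees=True)
    return RigidMotion(ang[0], ang[1], ang[2], T[0, 3], T[1, 3], T[2, 3])


def compose(*transforms: np.ndarray) -> np.ndarray:
    """Compose transforms left-to-right in application order: the first
    argument is applied last (matrix product in the given order)."""
    out = np.eye(4)
    for T in transforms:
        out = out @ np.asarray(T, float)
    return out


def invert(T: np.ndarray) -> np.ndarray:
    T = np.asarray(T, float)
    R = T[:3, :3]
    out = np.eye(4)
    out[:3, :3] = R.T
    out[:3, 3] = -R.T @ T[:3, 3]
    return out


def rms_deviation(T1: np.ndarray, T2: np.ndarray,
                  p: RmsParams = RmsParams()) -> float:
    """Scalar displacement (mm) between two rigid transforms.

    Rotational displacement is the RMS displacement of points uniformly
    distributed in a solid sphere of radius ``p.radius`` centered at
    ``p.center``: with ``M = T1 T2^-1``, ``A = M_rot - I`` and
    ``t = M_trans + A @ center``,

        RMS = sqrt(radius^2 / 5 * Tr(A^T A) + t^T t).

    Comparing against the identity transform gives the magnitude of a single
    pose.
    """
    T1 = assert_rigid(T1)
    T2 = assert_rigid(T2)
    M = T1 @ invert(T2)
    A = M[:3, :3] - np.eye(3)
    t = M[:3, 3] + A @ np.asarray(p.center, float)
    return float(np.sqrt(p.radius ** 2 / 5.0 * np.trace(A.T @ A) + t @ t))


def interpolate_motion(series, shots_per_volume: int, center_shot: int = 14) -> np.ndarray:
    """Up-sample per-volume poses to per-shot resolution.

    Each volume's registered pose is anchored at its k-space center shot
    (1-based ``center_shot`` within the volume), and the six parameters are
    linearly interpolated between anchors; before the first and after the
    last anchor the boundary value is held.

    Parameters are interpolated independently (adequate for the small
    inter-volume pose deltas this model assumes; no quaternion slerp).

    Returns an ``(n_volumes * shots_per_volume, 6)`` array.
    """
    arr = _series_to_array(series)
    if arr.shape[0] < 1:
        raise ValueError("motion series is empty")
    if not 1 <= center_shot <= shots_per_volume:
        raise ValueError("center_shot must lie within 1..shots_per_volume")
    n_vol = arr.shape[0]
    n_shots = n_vol * shots_per_volume
    anchors = np.arange(n_vol) * shots_per_volume + (center_shot - 1)
    shots = np.arange(n_shots)
    out = np.empty((n_shots, 6))
    for j in range(6):
        out[:, j] = np.interp(shots, anchors, arr[:, j])
    return out


def _series_to_array(series) -> np.ndarray:
    if isinstance(series, np.ndarray):
        arr = np.asarray(series, float)
        if arr.ndim != 2 or arr.shape[1] != 6:
            raise ValueError("motion series array must have shape (n, 6)")
        return arr
    seq: Iterable = series
    rows = [_as_params_array(m) for m in seq]
    if not rows:
        raise ValueError("motion series is empty")
    return np.vstack(rows)


def image_to_scanner(T_img: np.ndarray, basis: np.ndarray) -> np.ndarray:
    """Conjugate an image-space transform into scanner coordinates:
    ``basis @ T_img @ basis^-1``."""
    basis = np.asarray(basis, float)
    if abs(np.linalg.det(basis)) < 1e-12:
        raise ValueError("basis transform is singular")
    return basis @ np.asarray(T_img, float) @ np.linalg.inv(basis)
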