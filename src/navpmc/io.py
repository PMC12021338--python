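"""File formats: the HDF5 navigator container and motion-parameter files.

Motion files come in two dialects:

* FSL-style ``.par`` — one row per volume, six whitespace-separated columns:
  three rotations in **radians** (rx ry rz) then three translations in mm.
  The package works in degrees internally; the unit conversion happens here
  and only here.
* ``affine_dir`` — a directory of plain-text 4x4 homogeneous matrices, one
  file per volume (``MAT_0000``, ``MAT_0001``, ...), as written by
  registration tools that export per-volume transforms.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np

from . import geometry
from .navigator import ProbeConstants
from .synthetic import ProtocolConfig

__all__ = [
    "CONTAINER_FORMAT",
    "CONTAINER_VERSION",
    "NavigatorContainer",
    "write_container",
    "read_container",
    "read_motion",
    "write_motion",
]

CONTAINER_FORMAT = "navpmc-container"
CONTAINER_VERSION = 1


@dataclass
class NavigatorContainer:
    """Raw per-shot navigator session: FIDnav block, probe block, timing and
    protocol metadata."""

    fidnav: np.ndarray        # (shots, channels, samples) complex
    probes: np.ndarray        # (shots, probes, samples) complex
    timestamps_ms: np.ndarray  # (shots,)
    protocol: ProtocolConfig

    def __post_init__(self):
        n = self.fidnav.shape[0]
        if self.probes.shape[0] != n or self.timestamps_ms.shape[0] != n:
            raise ValueError("shot counts differ across container blocks")

    @property
    def n_shots(self) -> int:
        return self.fidnav.shape[0]

    @property
    def fid_readout_ms(self) -> float:
        """ADC duration of the FIDnav block implied by the metadata."""
        return self.fidnav.shape[2] * self.protocol.dwell_us * 1e-3


def _protocol_to_json(protocol: ProtocolConfig) -> str:
    d = dataclasses.asdict(protocol)
    return json.dumps(d)


def _protocol_from_json(s: str) -> ProtocolConfig:
    d = json.loads(s)
    probe = ProbeConstants(**d.pop("probe"))
    return ProtocolConfig(probe=probe, **d)


def write_container(path, container: NavigatorContainer) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["format"] = CONTAINER_FORMAT
        f.attrs["version"] = CONTAINER_VERSION
        f.attrs["protocol"] = _protocol_to_json(container.protocol)
        f.create_dataset("fidnav", data=np.asarray(container.fidnav, complex))
        f.create_dataset("probes", data=np.asarray(container.probes, complex))
        f.create_dataset("timestamps_ms",
                         data=np.asarray(container.timestamps_ms, float))


def read_container(path) -> NavigatorContainer:
    """Read a container; raises a clean error on damaged or foreign files
    and an explicit migration error on version mismatch."""
    try:
        with h5py.File(path, "r") as f:
            if f.attrs.get("format") != CONTAINER_FORMAT:
                raise ValueError(f"{path} is not a navigator container")
            version = int(f.attrs.get("version", -1))
            if version != CONTAINER_VERSION:
                raise ValueError(
                    f"container version {version} needs migration to "
                    f"{CONTAINER_VERSION}; no automatic migration exists"
                )
            return NavigatorContainer(
                fidnav=f["fidnav"][()],
                probes=f["probes"][()],
                timestamps_ms=f["timestamps_ms"][()],
                protocol=_protocol_from_json(f.attrs["protocol"]),
            )
    except OSError as exc:
        raise ValueError(f"cannot read navigator container {path}: {exc}") from exc


def read_motion(path, dialect: str = "par") -> np.ndarray:
    """Read per-volume motion as an ``(n_volumes, 6)`` array in package
    convention (rotations in degrees, translations in mm)."""
    path = Path(path)
    if dialect == "par":
        arr = np.loadtxt(path, ndmin=2)
        if arr.shape[1] != 6:
            raise ValueError(f".par file must have 6 columns, got {arr.shape[1]}")
        out = arr.copy()
        out[:, :3] = np.rad2deg(arr[:, :3])
        return out
    if dialect == "affine_dir":
        files = sorted(path.glob("MAT_*"))
        if not files:
            raise ValueError(f"no MAT_* files in {path}")
        rows = []
        for fp in files:
            T = np.loadtxt(fp)
            if T.shape != (4, 4):
                raise ValueError(f"{fp} is not a 4x4 matrix")
            rows.append(geometry.affine_to_params(T).as_array())
        return np.vstack(rows)
    raise ValueError("dialect must be 'par' or 'affine_dir'")


def write_motion(path, params: np.ndarray, dialect: str = "par") -> None:
    """Write per-volume motion from package convention (deg / mm)."""
    params = np.asarray(params, float)
    if params.ndim != 2 or params.shape[1] != 6:
        raise ValueError("motion array must be (n_volumes, 6)")
    path = Path(path)
    if dialect == "par":
        out = params.copy()
        out[:, :3] = np.deg2rad(params[:, :3])
        np.savetxt(path, out, fmt="%.10g")
        return
    if dialect == "affine_dir":
        path.mkdir(parents=True, exist_ok=True)
        for v, row in enumerate(params):
            np.savetxt(path / f"MAT_{v:04d}",
                       geometry.params_to_affine(row), fmt="%.12g")
        return
    raise ValueError("dialect must be 'par' or 'affine_dir'")
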