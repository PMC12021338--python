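"""Validated run configuration (YAML) for reproducible CLI runs.

Unknown keys are rejected so a typo in a config file fails loudly instead of
silently running defaults.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import yaml
from pydantic import BaseModel, ConfigDict, Field

from .navigator import ProbeConstants
from .pmc import PMCConfig
from .synthetic import ProtocolConfig, WorldConfig

__all__ = ["RunConfig"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class ProtocolSection(_Strict):
    tr_shot_ms: float = 20.0
    shots_per_volume: int = 21
    center_shot: int = 14
    n_channels: int = 32
    n_probes: int = 16
    fid_samples: int = 512
    dwell_us: float = 5.0
    trim: int = 4
    n_avg: int = 4
    probe_samples: int = 64
    probe_dwell_us: float = 5.0
    probe_flip_deg: float = 90.0
    probe_t1_ms: float = 80.0
    probe_t2_ms: float = 50.0
    probe_gamma_over_2pi: float = 40.05


class WorldSection(_Strict):
    kappa: float = 0.0
    probe_rx_nonlin: float = 0.0
    channel_noise_sd: float = 0.002
    probe_noise_sd: float = 0.002
    eddy_amp: float = 0.01
    eddy_cycle: int | None = None


class PMCSection(_Strict):
    latency_shots: int = 1
    filter_size: int = 1
    baseline_window_s: float = 10.0
    cycle_length: int | None = None


class CalibrationSection(_Strict):
    variant: str = "combined"
    ridge_lambda: float = 0.0
    targets: str = "registration"
    reg_noise_rms: float = 0.1


class RunConfig(_Strict):
    seed: int = 0
    paradigm: str = "fig8_horizontal"
    n_volumes: int = 120
    amplitude: float = 8.0
    protocol: ProtocolSection = Field(default_factory=ProtocolSection)
    world: WorldSection = Field(default_factory=WorldSection)
    pmc: PMCSection = Field(default_factory=PMCSection)
    calibration: CalibrationSection = Field(default_factory=CalibrationSection)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.model_validate(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=True))

    def config_hash(self) -> str:
        blob = json.dumps(self.model_dump(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def to_protocol(self) -> ProtocolConfig:
        p = self.protocol
        return ProtocolConfig(
            tr_shot_ms=p.tr_shot_ms, shots_per_volume=p.shots_per_volume,
            center_shot=p.center_shot, n_channels=p.n_channels,
            n_probes=p.n_probes, fid_samples=p.fid_samples,
            dwell_us=p.dwell_us, trim=p.trim, n_avg=p.n_avg,
            probe_samples=p.probe_samples, probe_dwell_us=p.probe_dwell_us,
            probe_flip_deg=p.probe_flip_deg,
            probe=ProbeConstants(
                gamma_over_2pi_mhz_per_t=p.probe_gamma_over_2pi,
                t1_ms=p.probe_t1_ms, t2_ms=p.probe_t2_ms,
            ),
        )

    def to_world(self) -> WorldConfig:
        w = self.world
        return WorldConfig.random(
            self.seed, self.to_protocol(), kappa=w.kappa,
            probe_rx_nonlin=w.probe_rx_nonlin,
            channel_noise_sd=w.channel_noise_sd,
            probe_noise_sd=w.probe_noise_sd, eddy_amp=w.eddy_amp,
            eddy_cycle=w.eddy_cycle,
        )

    def to_pmc(self) -> PMCConfig:
        c = self.pmc
        return PMCConfig(latency_shots=c.latency_shots,
                         filter_size=c.filter_size,
                         baseline_window_s=c.baseline_window_s,
                         cycle_length=c.cycle_length)
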