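"""Pipeline configuration: one YAML/JSON file drives all stages.

Unknown keys are rejected (silent misconfiguration is the dominant
failure mode when pipelines are reused); CLI flags override config
values.  ``dump_config`` is byte-stable under a load→dump round trip.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal, Optional

import yaml
from pydantic import BaseModel, ConfigDict, field_validator

__all__ = ["PipelineConfig", "load_config", "dump_config"]


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid")


class PhantomConfig(_Strict):
    weight_kg: float = 2.8
    heart_rate_bpm: float = 140.0
    grid_shape: tuple[int, int, int] = (96, 96, 96)
    spacing_mm: float = 1.25
    n_frames: int = 8
    vencs: tuple[float, ...] = (50.0, 150.0)
    snr: Optional[float] = None
    background_order: int = 1
    background_amplitude: float = 0.0  # radians; 0 disables background phase

    @field_validator("vencs")
    @classmethod
    def _sorted_positive(cls, v):
        if any(x <= 0 for x in v) or list(v) != sorted(v):
            raise ValueError("vencs must be positive and sorted ascending")
        return v


class ReconConfig(_Strict):
    background_order: int = 1
    phase_std_max: float = 0.1
    mag_min: float = 0.3
    per_vector: bool = False
    angiogram_threshold: float = 0.1


class QuantConfig(_Strict):
    plane_fraction: float = 0.5
    radius_factor: float = 1.15
    align_planes: bool = False
    pct_diff_denominator: Literal["mean", "inflow"] = "mean"
    compare_csv: Optional[str] = None  # vessel,flow table of a second method


class TraceConfig(_Strict):
    sources: tuple[str, ...] = ("MPA", "AAo")
    sinks: tuple[str, ...] = ("DA", "BT", "DAo")
    n_particles: int = 500
    duration_cycles: float = 2.0
    dt_ms: Optional[float] = None
    release_frame: int = 0


class PipelineConfig(_Strict):
    seed: int = 0
    output_dir: str = "fetalflow_out"
    stages: tuple[str, ...] = ("phantom", "reconstruct", "quantify", "trace")
    phantom: PhantomConfig = PhantomConfig()
    recon: ReconConfig = ReconConfig()
    quant: QuantConfig = QuantConfig()
    trace: TraceConfig = TraceConfig()

    @field_validator("stages")
    @classmethod
    def _known_stages(cls, v):
        known = {"phantom", "reconstruct", "quantify", "trace"}
        bad = set(v) - known
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        return v


def load_config(path: str | Path | None = None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML/JSON config file; ``overrides`` take precedence."""
    data: dict = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    if overrides:
        for k, v in overrides.items():
            if v is None:
                continue
            if "." in k:
                section, key = k.split(".", 1)
                data.setdefault(section, {})[key] = v
            else:
                data[k] = v
    return PipelineConfig(**data)


def dump_config(cfg: PipelineConfig) -> str:
    """Canonical YAML serialisation (stable key order)."""
    return yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=True)
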