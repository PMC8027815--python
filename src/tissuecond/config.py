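"""Validated run configuration (JSON or YAML) for the CLI workflows.

The schema is strict: unknown keys are rejected, and a loaded config dumps
back to an equivalent document (load -> dump -> load is the identity on the
validated model).  All randomness in a run flows from the single top-level
``seed``; per-recording seeds are derived from it deterministically.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Literal, Optional

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .errors import ConfigError

__all__ = ["RunConfig", "load_config", "dump_config"]


class _StrictModel(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SampleGeometryConfig(_StrictModel):
    radius_mm: float = 3.0
    thickness_cm: float = 0.56


class GroupConfig(_StrictModel):
    tissue_label: str = "tissue"
    n_samples_per_field: int = Field(default=1, ge=1)
    # ground-truth sigmoid sigma(E) for the generator
    sigma0_S_per_m: float = 0.24
    sigma_max_S_per_m: float = 0.40
    e_del_V_per_cm: float = 1000.0
    slope_V_per_cm: float = 300.0


class ProtocolConfig(_StrictModel):
    fields_V_per_cm: List[float] = Field(
        default_factory=lambda: [500.0, 750.0, 1000.0, 1500.0, 2000.0, 2500.0, 3000.0],
        min_length=1,
    )
    n_pulses: int = Field(default=100, ge=1)
    pulse_width_us: float = Field(default=100.0, gt=0)
    repetition_period_s: float = Field(default=1.0, gt=0)
    sampling_rate_hz: float = Field(default=1e6, gt=0)
    recorded_gap_us: float = Field(default=400.0, gt=0)
    diagnostic_voltage_V: float = Field(default=20.0, gt=0)


class NoiseConfig(_StrictModel):
    relative_gaussian_sd: float = Field(default=0.01, ge=0)
    dc_offset_V: float = 0.0
    dc_offset_A: float = 0.0


class ConditioningConfig(_StrictModel):
    filter_order: int = Field(default=4, ge=1)
    cutoff_fraction_of_fs: float = Field(default=0.05, gt=0, lt=0.5)
    apply_filter: bool = True
    threshold_fraction: float = Field(default=0.5, gt=0, lt=1)
    plateau_fraction: float = Field(default=0.5, gt=0, le=1)
    min_width_samples: int = Field(default=5, ge=1)


class AnalysisConfig(_StrictModel):
    percent_increase_mode: Literal["per_sample", "ratio_of_means"] = "per_sample"
    dispersion: Literal["sd", "sem"] = "sd"
    count_policy: Literal["error", "warn"] = "error"
    max_temp_rise_C: float = 10.0


class ThermalConfig(_StrictModel):
    density_kg_per_m3: float = Field(default=1000.0, gt=0)
    specific_heat_J_per_kg_K: float = Field(default=3600.0, gt=0)
    loss_coefficient_per_s: float = Field(default=0.1, ge=0)
    ambient_temp_C: float = 22.0


class EISConfig(_StrictModel):
    f_min_hz: float = Field(default=1e3, gt=0)
    f_max_hz: float = Field(default=1e6, gt=0)
    n_frequencies: int = Field(default=50, ge=2)
    query_frequencies_hz: List[float] = Field(default_factory=lambda: [1e4, 1e6])
    # Cole–Cole generator parameters
    r0_ohm: float = 1366.0
    r_inf_ohm: float = 534.0
    tau_s: float = 1.6e-6
    alpha: float = 0.85
    relative_noise_sd: float = Field(default=0.0, ge=0)
    n_spectra: int = Field(default=3, ge=1)


class RunConfig(_StrictModel):
    """Top-level configuration for simulate / analyze commands."""

    seed: int = 0
    geometry: SampleGeometryConfig = Field(default_factory=SampleGeometryConfig)
    groups: List[GroupConfig] = Field(default_factory=lambda: [GroupConfig()])
    protocol: ProtocolConfig = Field(default_factory=ProtocolConfig)
    noise: NoiseConfig = Field(default_factory=NoiseConfig)
    conditioning: ConditioningConfig = Field(default_factory=ConditioningConfig)
    analysis: AnalysisConfig = Field(default_factory=AnalysisConfig)
    thermal: ThermalConfig = Field(default_factory=ThermalConfig)
    eis: EISConfig = Field(default_factory=EISConfig)
    output_dir: Optional[str] = None


def load_config(path) -> RunConfig:
    """Load and validate a JSON or YAML config file."""
    path = Path(path)
    text = path.read_text()
    try:
        if path.suffix.lower() in (".yaml", ".yml"):
            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
    except (yaml.YAMLError, json.JSONDecodeError) as exc:
        raise ConfigError(f"{path}: cannot parse as {path.suffix or 'JSON'} ({exc})") from exc
    try:
        return RunConfig.model_validate(data or {})
    except pydantic.ValidationError as exc:
        raise ConfigError(f"{path}: invalid config\n{exc}") from exc


def dump_config(config: RunConfig, path) -> None:
    """Serialize a config back to JSON or YAML (by file extension)."""
    path = Path(path)
    data = config.model_dump()
    if path.suffix.lower() in (".yaml", ".yml"):
        path.write_text(yaml.safe_dump(data, sort_keys=False))
    else:
        path.write_text(json.dumps(data, indent=2))
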