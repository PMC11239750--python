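"""Pipeline configuration: every tunable default in one place.

The configuration is a nested dataclass tree that round-trips through YAML.
Unknown keys are rejected on load so typos cannot silently fall back to
defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml


def _from_mapping(cls, data: dict[str, Any]):
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config key(s) for {cls.__name__}: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if dataclasses.is_dataclass(f.type) or (isinstance(f.default_factory, type) and dataclasses.is_dataclass(f.default_factory)):
            value = _from_mapping(f.default_factory, value)  # type: ignore[arg-type]
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


@dataclass
class FlowConfig:
    method: str = "murray"  # 'murray' or 'length_based'
    murray_exponent: float = 3.0
    q_cor_fraction_of_co: float = 0.045


@dataclass
class FluidConfig:
    density: float = 1.05  # g/cm^3
    viscosity: float = 0.035  # g/(cm s)
    venous_pressure_mmHg: float = 5.0


@dataclass
class HyperemiaConfig:
    tcri: float = 3.0


@dataclass
class StenosisConfig:
    kt: float = 1.52  # turbulent-expansion loss coefficient


@dataclass
class WindkesselConfig:
    r_fractions: tuple[float, float, float] = (0.01, 0.84, 0.15)
    c_fractions: tuple[float, float] = (0.025, 0.975)
    total_arterial_compliance: float = 1.7  # mL/mmHg
    coronary_compliance_fraction: float = 0.045


@dataclass
class TransientConfig:
    dt_s: float = 0.001
    max_cycles: int = 10
    periodicity_tol: float = 1e-3


@dataclass
class TreeConfig:
    n_generations: int = 3
    root_radius_cm: float = 0.15


@dataclass
class MeasurementConfig:
    distal_offset_cm: float = 2.5  # p_d sensor distance distal to the lesion


@dataclass
class WireConfig:
    diameter_cm: float = 0.036
    # 'ostium_to_sensor': wire occupies the whole path from the tree inlet to
    # the measurement segment (the clinical wire course); 'stenotic_branch':
    # only from the lesion segment to the measurement segment.
    path_mode: str = "ostium_to_sensor"


@dataclass
class StudyConfig:
    ffr_cutoff: float = 0.8  # positivity threshold, FFR <= cutoff is positive
    n_per_class: int = 6
    mode: str = "transient"  # 'transient' or 'steady' pipeline FFR


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "coroflow_out"
    flow: FlowConfig = field(default_factory=FlowConfig)
    fluid: FluidConfig = field(default_factory=FluidConfig)
    hyperemia: HyperemiaConfig = field(default_factory=HyperemiaConfig)
    stenosis: StenosisConfig = field(default_factory=StenosisConfig)
    windkessel: WindkesselConfig = field(default_factory=WindkesselConfig)
    transient: TransientConfig = field(default_factory=TransientConfig)
    tree: TreeConfig = field(default_factory=TreeConfig)
    measurement: MeasurementConfig = field(default_factory=MeasurementConfig)
    wire: WireConfig = field(default_factory=WireConfig)
    study: StudyConfig = field(default_factory=StudyConfig)

    def to_dict(self) -> dict[str, Any]:
        def convert(obj):
            if dataclasses.is_dataclass(obj):
                return {f.name: convert(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
            if isinstance(obj, tuple):
                return list(obj)
            return obj

        return convert(self)

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _from_mapping(cls, data)

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=False)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls.from_dict(data or {})
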