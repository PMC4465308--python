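"""Structured pipeline configuration (YAML-backed, validated)."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Mapping

import yaml

from .assembly import AssemblyConfig
from .deconvolution import DeconvolutionConfig, SignalModel
from .simdata import DEFAULT_BIN_BOUNDARIES, NoiseModel

__all__ = ["SimConfig", "ScreenConfig", "PipelineConfig", "load_config"]


@dataclass
class SimConfig:
    """Synthetic arm / library / marker parameters."""

    arm_length_kb: float = 11_500.0
    mean_fragment_kb: float = 2.5
    n_clones: int = 1000
    insert_mean_kb: float = 143.0
    insert_sd_kb: float = 15.0
    purity: float = 0.88
    bin_boundaries: tuple[float, ...] = DEFAULT_BIN_BOUNDARIES
    noise: NoiseModel = field(default_factory=NoiseModel)
    marker_density_per_mb: tuple[float, ...] = (3.17, 3.53, 5.17, 3.58)
    island_fraction: float = 0.8
    island_span_kb: float = 100.0
    syntenic_fraction: float = 0.6

    def __post_init__(self) -> None:
        for key in ("arm_length_kb", "mean_fragment_kb", "insert_mean_kb"):
            value = getattr(self, key)
            if value is None or value <= 0:
                raise ValueError(f"sim.{key} must be a positive number, got {value!r}")
        if self.n_clones < 1:
            raise ValueError(f"sim.n_clones must be >= 1, got {self.n_clones}")


@dataclass
class ScreenConfig:
    """Pool-screening simulation parameters."""

    signal: SignalModel = field(default_factory=SignalModel)
    pcr_fp_rate: float = 0.0
    pcr_fn_rate: float = 0.0
    n_pcr_markers: int = 25


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, with one master seed."""

    seed: int = 1
    sim: SimConfig = field(default_factory=SimConfig)
    assembly: AssemblyConfig = field(default_factory=AssemblyConfig)
    screen: ScreenConfig = field(default_factory=ScreenConfig)
    deconvolution: DeconvolutionConfig = field(default_factory=DeconvolutionConfig)
    min_band_count: int = 5

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


_SECTION_TYPES = {
    "sim": (SimConfig, {"noise": NoiseModel}),
    "assembly": (AssemblyConfig, {}),
    "screen": (ScreenConfig, {"signal": SignalModel}),
    "deconvolution": (DeconvolutionConfig, {}),
}


def _build_section(name: str, cls, nested: Mapping[str, Any], data: Mapping[str, Any]):
    kwargs = {}
    valid = set(cls.__dataclass_fields__)
    for key, value in data.items():
        if key not in valid:
            raise ValueError(f"unknown config key {name}.{key}")
        if key in nested and isinstance(value, Mapping):
            value = nested[key](**value)
        elif isinstance(value, list):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"invalid config section {name!r}: {exc}") from exc


def load_config(source: str | Path | Mapping[str, Any] | None = None) -> PipelineConfig:
    """Build a :class:`PipelineConfig` from a YAML file or mapping.

    Unknown keys raise with the offending key name; omitted sections fall
    back to defaults.
    """
    if source is None:
        return PipelineConfig()
    if isinstance(source, (str, Path)):
        data = yaml.safe_load(Path(source).read_text()) or {}
    else:
        data = dict(source)
    if not isinstance(data, Mapping):
        raise ValueError("config root must be a mapping")
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            cls, nested = _SECTION_TYPES[key]
            if not isinstance(value, Mapping):
                raise ValueError(f"config section {key!r} must be a mapping")
            kwargs[key] = _build_section(key, cls, nested, value)
        elif key in ("seed", "min_band_count"):
            kwargs[key] = int(value)
        else:
            raise ValueError(f"unknown config key {key!r}")
    return PipelineConfig(**kwargs)
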