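"""Pipeline configuration: one YAML file with full defaulting.

Every stage's tunables live in a nested dataclass; unknown keys are
rejected so typos fail loudly instead of silently using defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ConfigurationError

__all__ = ["PipelineConfig", "load_config", "dump_config"]


@dataclass
class SimulatorSection:
    per_class_count: int = 10
    heart_rate_bpm: tuple[float, float] = (50.0, 110.0)
    murmur_intensity: tuple[float, float] = (0.3, 0.6)
    snr_db: tuple[float, float] | None = (10.0, 30.0)
    duration_s: float = 10.0
    sample_rate_hz: float = 4000.0
    af_fraction: float = 0.0
    rr_cv: float = 0.2


@dataclass
class PreprocessSection:
    low_cut_hz: float = 20.0
    high_cut_hz: float = 100.0
    order: int = 4
    frame_s: float = 0.256
    spectral_floor: float = 0.05
    denoise: bool = True
    min_snr_db: float = 5.0
    min_peak: float = 0.01
    include_uninterpretable: bool = False


@dataclass
class SegmentationSection:
    window_ms: float = 20.0
    hop_ms: float = 10.0
    peak_threshold: float = 0.5
    min_gap_ms: float = 120.0
    recovery: bool = True


@dataclass
class FeaturesSection:
    canonical_cycle_s: float = 0.8
    window_s: float = 0.064
    overlap: float = 0.75
    nfft: int = 256
    freq_low_hz: float = 10.0
    freq_high_hz: float = 200.0


@dataclass
class ClassifierSection:
    n_kernels1: int = 8
    n_kernels2: int = 16
    dense_units: int = 128
    learning_rate: float = 0.001
    batch_size: int = 32
    epochs: int = 30
    validation_fraction: float = 0.2


@dataclass
class EvaluationSection:
    level: float = 0.95


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: str = "results"
    simulator: SimulatorSection = field(default_factory=SimulatorSection)
    preprocess: PreprocessSection = field(default_factory=PreprocessSection)
    segmentation: SegmentationSection = field(default_factory=SegmentationSection)
    features: FeaturesSection = field(default_factory=FeaturesSection)
    classifier: ClassifierSection = field(default_factory=ClassifierSection)
    evaluation: EvaluationSection = field(default_factory=EvaluationSection)


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigurationError(f"config section {path or 'root'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigurationError(
            f"unknown config key(s) {sorted(unknown)} in section {path or 'root'}"
        )
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        value = data[name]
        if dataclasses.is_dataclass(f.type) or (isinstance(f.default_factory, type)
                                                and dataclasses.is_dataclass(f.default_factory)):
            kwargs[name] = _build(f.default_factory, value, f"{path}.{name}".lstrip("."))
        elif isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return cls(**kwargs)


def load_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    """Load a YAML config (or defaults when ``path`` is None)."""
    data: dict = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
    if overrides:
        data = {**data, **overrides}
    return _build(PipelineConfig, data, "")


def dump_config(cfg: PipelineConfig, path=None) -> str:
    """Serialize a config to YAML (round-trips through load_config)."""
    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
        if isinstance(obj, tuple):
            return list(obj)
        if isinstance(obj, dict):
            return {k: clean(v) for k, v in obj.items()}
        return obj

    text = yaml.safe_dump(clean(cfg), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
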