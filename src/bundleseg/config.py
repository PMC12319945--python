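"""Run configuration: one YAML file wiring every pipeline stage.

Unknown keys are rejected (typos should fail loudly, not silently fall back
to defaults) and configurations round-trip losslessly through YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
import yaml

from .network import ModelConfig
from .synthetic import SynthConfig
from .trainer import TrainConfig

__all__ = ["RunConfig", "InferConfig", "PostprocessConfig", "DensityConfig",
           "EvaluateConfig", "load_config", "save_config"]


@dataclass
class InferConfig:
    tile_size: int = 1024
    overlap_px: int = 0
    threshold: float = 0.4


@dataclass
class PostprocessConfig:
    min_area_mm2: float = 2.0
    min_border_dist_mm: float = 0.5
    max_dist_mm: float = 0.5
    downsample: int = 10
    use_continuity: bool = True
    use_morphology: bool = True


@dataclass
class DensityConfig:
    clahe_tiles: tuple[int, int] = (8, 8)
    clahe_clip_limit: float = 0.02
    clahe_enabled: bool = True
    min_overlap: float = 0.4


@dataclass
class EvaluateConfig:
    min_frac: float = 0.2
    froc_thresholds: tuple[float, ...] = (0.9, 0.8, 0.7, 0.6, 0.5, 0.4, 0.3, 0.2)


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "runs/out"
    log_level: str = "INFO"
    n_labeled: int = 5
    synth: SynthConfig = field(default_factory=SynthConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    infer: InferConfig = field(default_factory=InferConfig)
    postprocess: PostprocessConfig = field(default_factory=PostprocessConfig)
    density: DensityConfig = field(default_factory=DensityConfig)
    evaluate: EvaluateConfig = field(default_factory=EvaluateConfig)


_TUPLE_FIELDS = {
    "fiber_area_fraction_range", "bundle_axis_ratio_range", "fc_sizes",
    "wm_mean_intensity_range", "blur_sigma_range", "translation_px",
    "rotation_deg", "scale", "clahe_tiles", "froc_thresholds", "tiles",
}


def _build(dc_cls, data: dict, path: str = ""):
    if not isinstance(data, dict):
        raise ValueError(f"{path or dc_cls.__name__}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"{path or dc_cls.__name__}: unknown keys {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        f = fields[name]
        default = (
            f.default_factory() if f.default_factory is not dataclasses.MISSING
            else f.default
        )
        if dataclasses.is_dataclass(default) and isinstance(value, dict):
            kwargs[name] = _build(type(default), value, f"{path}{name}.")
        elif name in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    return dc_cls(**kwargs)


def _to_plain(obj):
    if dataclasses.is_dataclass(obj):
        return {f.name: _to_plain(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (tuple, list)):
        return [_to_plain(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _to_plain(v) for k, v in obj.items()}
    return obj


def load_config(path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return _build(RunConfig, data)


def save_config(cfg: RunConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(_to_plain(cfg), fh, sort_keys=False)


def config_hash(cfg: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(_to_plain(cfg), sort_keys=True).encode()
    ).hexdigest()[:16]
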