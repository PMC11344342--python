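"""Pipeline configuration: one YAML file fully determines a run.

The config nests the simulation spec, segmentation parameters, dataset
options and model hyperparameters; it is echoed into every output directory
so artifacts are self-documenting.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .nn.model import ModelConfig
from .segmentation import SegmentationParams
from .synthetic import SpheroidSpec


@dataclass
class DatasetOptions:
    holdout_images: int = 1
    proportions: tuple[float, float, float] = (0.7, 0.15, 0.15)
    augment: bool = True
    pad_center: bool = False
    group_rotations: bool = True   # False reproduces augment-then-split


@dataclass
class PipelineConfig:
    seed: int = 0
    n_images: int = 4
    simulation: SpheroidSpec = field(
        default_factory=lambda: SpheroidSpec(n_cells=12, spheroid_radius_um=40.0)
    )
    segmentation: SegmentationParams = field(default_factory=SegmentationParams)
    dataset: DatasetOptions = field(default_factory=DatasetOptions)
    model: ModelConfig = field(default_factory=lambda: ModelConfig(n_runs=2, max_epochs=6))
    tile_px: int = 200
    overlap_frac: float = 0.2

    def to_dict(self) -> dict:
        return asdict(self)


def _build(cls, data: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    kwargs = {}
    for f in fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data)
    sim = _build(SpheroidSpec, data.pop("simulation", {}) or {})
    seg = _build(SegmentationParams, data.pop("segmentation", {}) or {})
    ds = _build(DatasetOptions, data.pop("dataset", {}) or {})
    model = _build(ModelConfig, data.pop("model", {}) or {})
    cfg = _build(PipelineConfig, data)
    cfg.simulation, cfg.segmentation, cfg.dataset, cfg.model = sim, seg, ds, model
    return cfg


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return config_from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
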