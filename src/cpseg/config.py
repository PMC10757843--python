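"""Run configuration: YAML schema with strict validation.

Unknown keys are rejected with their full path so that a typo in an
experiment file fails before any computation starts. Every command writes a
resolved-config snapshot next to its outputs, making runs reproducible from
the snapshot plus the seed alone.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import yaml

from .models import SegmenterConfig
from .preprocess import TilingPlan
from .synthdata import SynthConfig
from .training import TrainConfig

TRAINERS = ("supervised", "cps", "cps_cutmix")
STRUCTURES = ("nuclei", "nucleoli")


@dataclass
class PathsConfig:
    volume: str = ""
    masks: str = ""
    layout: str = "tiff_stack"


@dataclass
class RunConfig:
    seed: int = 0
    structure: str = "nucleoli"
    trainer: str = "cps_cutmix"
    n_labeled_slices: int = 7
    output_dir: str = "runs/default"
    equalize: bool = True
    n_bins: int = 256
    paths: PathsConfig = field(default_factory=PathsConfig)
    model: SegmenterConfig = field(default_factory=SegmenterConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    tiling: TilingPlan = field(default_factory=TilingPlan)
    synth: SynthConfig = field(default_factory=SynthConfig)

    def __post_init__(self):
        if self.structure not in STRUCTURES:
            raise ValueError(f"structure must be one of {STRUCTURES}")
        if self.trainer not in TRAINERS:
            raise ValueError(f"trainer must be one of {TRAINERS}")
        if self.n_labeled_slices < 1:
            raise ValueError("n_labeled_slices must be >= 1")
        # the trainer and the samplers must agree on the crop geometry
        self.train.crop_plan = self.tiling
        self.train.seed = self.seed
        self.synth.seed = self.seed

    def to_dict(self) -> dict:
        d = asdict(self)
        d["train"].pop("crop_plan", None)  # lives in the tiling section
        return d


_SECTION_TYPES = {
    "paths": PathsConfig,
    "model": SegmenterConfig,
    "train": TrainConfig,
    "tiling": TilingPlan,
    "synth": SynthConfig,
}


def _build_section(cls, data: dict, path: str):
    allowed = {f.name for f in fields(cls)}
    if cls is TrainConfig:
        allowed.discard("crop_plan")  # set from the tiling section
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path}'")
    clean = {k: (tuple(v) if isinstance(v, list) else v) for k, v in data.items()}
    return cls(**clean)


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration, apply flat overrides, and validate."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError("config file must contain a YAML mapping")
        data = raw
    for key, value in (overrides or {}).items():
        if value is None:
            continue
        parts = key.split(".")
        node = data
        for p in parts[:-1]:
            node = node.setdefault(p, {})
        node[parts[-1]] = value

    top_allowed = {f.name for f in fields(RunConfig)}
    unknown = set(data) - top_allowed
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} at top level")
    kwargs = {}
    for key, value in data.items():
        if key in _SECTION_TYPES:
            if not isinstance(value, dict):
                raise ValueError(f"config section '{key}' must be a mapping")
            kwargs[key] = _build_section(_SECTION_TYPES[key], value, key)
        else:
            kwargs[key] = value
    return RunConfig(**kwargs)


def save_snapshot(cfg: RunConfig, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(cfg.to_dict(), sort_keys=False))
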