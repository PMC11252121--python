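"""Pipeline configuration: one YAML file covering every stage.

The file has four optional blocks (``synth``, ``preprocess``, ``train``,
``split``) plus global keys ``seed``, ``out_dir`` and ``verbosity``.  Any
omitted key falls back to the package default, and a loaded configuration
round-trips through :func:`to_dict`/:func:`from_dict` unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import yaml

from .preprocess import BPBounds, FilterSpec, PreprocessConfig
from .qrs import PanTompkinsConfig
from .synthetic import BPModel, CorruptionConfig, SynthConfig
from .network import NetworkConfig
from .training import SplitSpec, TrainConfig


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str = "bp_pipeline_out"
    verbosity: str = "info"
    synth: SynthConfig = field(default_factory=SynthConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    split: SplitSpec = field(default_factory=SplitSpec)
    train: TrainConfig = field(default_factory=TrainConfig)

    def __post_init__(self) -> None:
        # one global seed drives every stage unless a block overrides it
        self.synth.seed = self.synth.seed or self.seed
        self.split.seed = self.split.seed or self.seed
        self.train.seed = self.train.seed or self.seed


def _nested_asdict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: _nested_asdict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, (list, tuple)):
        return [_nested_asdict(v) for v in obj]
    return obj


def to_dict(cfg: PipelineConfig) -> dict:
    return _nested_asdict(cfg)


def _build(cls, data: dict, nested: dict[str, Any] | None = None):
    nested = nested or {}
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        value = data[f.name]
        if f.name in nested and isinstance(value, dict):
            value = _build(nested[f.name], value)
        elif f.name in nested and isinstance(nested[f.name], tuple):
            value = tuple(value)
        kwargs[f.name] = value
    return cls(**kwargs)


def from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    cfg = PipelineConfig(
        seed=int(data.get("seed", 0)),
        out_dir=str(data.get("out_dir", "bp_pipeline_out")),
        verbosity=str(data.get("verbosity", "info")),
    )
    if "synth" in data:
        synth = dict(data["synth"])
        for key in ("hr_range", "pat_range", "sbp_range", "dbp_range"):
            if key in synth:
                synth[key] = tuple(synth[key])
        for key in ("sbp_model", "dbp_model"):
            if key in synth:
                synth[key] = _build(BPModel, synth[key])
        if "corruption" in synth:
            synth["corruption"] = _build(CorruptionConfig, synth["corruption"])
        cfg.synth = _build(SynthConfig, synth)
    if "preprocess" in data:
        pp = dict(data["preprocess"])
        for key in ("ppg_band", "ecg_band"):
            if key in pp:
                pp[key] = _build(FilterSpec, pp[key])
        if "bounds" in pp:
            pp["bounds"] = _build(BPBounds, pp["bounds"])
        if "pan_tompkins" in pp:
            pt = dict(pp["pan_tompkins"])
            if "band" in pt:
                pt["band"] = tuple(pt["band"])
            pp["pan_tompkins"] = _build(PanTompkinsConfig, pt)
        cfg.preprocess = _build(PreprocessConfig, pp)
    if "split" in data:
        cfg.split = _build(SplitSpec, dict(data["split"]))
    if "train" in data:
        tr = dict(data["train"])
        if "network" in tr:
            net = dict(tr["network"])
            if "conv_layers" in net:
                net["conv_layers"] = tuple(tuple(p) for p in net["conv_layers"])
            tr["network"] = _build(NetworkConfig, net)
        cfg.train = _build(TrainConfig, tr)
    cfg.__post_init__()
    return cfg


def load_config(path: str | Path) -> PipelineConfig:
    return from_dict(yaml.safe_load(Path(path).read_text()) or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(to_dict(cfg), sort_keys=True))


def config_hash(cfg: PipelineConfig) -> str:
    """Stable digest of the full configuration for the run manifest."""
    canon = json.dumps(to_dict(cfg), sort_keys=True)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]
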