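"""YAML-backed run configuration: simulator, encoders, fusion, loss,
training and ablation sections, all optional with library defaults."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import yaml

from .encoder import EncoderConfig, default_encoder_configs
from .fusion import FusionConfig
from .model import ABLATION_FLAGS
from .objectives import LossConfig
from .synthetic import SimConfig
from .training import TrainConfig

__all__ = ["RunConfig", "load_run_config"]


@dataclass
class RunConfig:
    sim: SimConfig = field(default_factory=SimConfig)
    encoders: dict[str, EncoderConfig] = field(default_factory=default_encoder_configs)
    fusion: FusionConfig = field(default_factory=FusionConfig)
    loss: LossConfig = field(default_factory=LossConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    ablation: dict[str, bool] = field(
        default_factory=lambda: {flag: True for flag in ABLATION_FLAGS})

    def __post_init__(self):
        unknown = set(self.ablation) - set(ABLATION_FLAGS)
        if unknown:
            raise ValueError(f"unknown ablation flags: {sorted(unknown)}")


def _build(cls, overrides: dict):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(overrides) - valid
    if unknown:
        raise ValueError(f"unknown {cls.__name__} fields: {sorted(unknown)}")
    return cls(**overrides)


def load_run_config(path=None) -> RunConfig:
    """Build a :class:`RunConfig` from a YAML file (``None`` -> defaults).

    The file may contain any subset of the sections ``sim``, ``encoders``
    (keyed by modality), ``fusion``, ``loss``, ``train`` and ``ablation``;
    unspecified values fall back to the library defaults.
    """
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    sim = _build(SimConfig, raw.get("sim", {}))
    if "modality_shapes" in raw.get("sim", {}):
        shapes = {k: tuple(v) for k, v in raw["sim"]["modality_shapes"].items()}
        sim = dataclasses.replace(sim, modality_shapes=shapes)
    encoders = default_encoder_configs()
    for name, overrides in raw.get("encoders", {}).items():
        if name not in encoders:
            raise ValueError(f"unknown modality {name!r} in encoders section")
        encoders[name] = dataclasses.replace(encoders[name], **overrides)
    fusion = _build(FusionConfig, raw.get("fusion", {}))
    loss = _build(LossConfig, raw.get("loss", {}))
    train = _build(TrainConfig, raw.get("train", {}))
    ablation = {flag: True for flag in ABLATION_FLAGS}
    ablation.update(raw.get("ablation", {}))
    return RunConfig(sim=sim, encoders=encoders, fusion=fusion, loss=loss,
                     train=train, ablation=ablation)
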