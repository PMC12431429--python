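"""The full multimodal vigilance network: three unimodal encoders feeding
the uncertainty-weighted fusion module, plus the ablation switchboard."""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._tensor import Tensor
from .encoder import EncoderConfig, UnimodalEncoder, UnimodalOutput, default_encoder_configs
from .fusion import FusionConfig, FusionModule, FusionState
from .nn import Module

__all__ = ["MODALITY_ORDER", "ModelOutput", "MultimodalVigilanceNet", "apply_ablation",
           "ABLATION_FLAGS", "save_weights", "load_weights"]

#: Fixed modality order everywhere (encoders, fusion tokens, loss columns).
MODALITY_ORDER = ("eeg2hz", "eog", "eeg5bands")

ABLATION_FLAGS = ("cross_modal_attention", "conv_sparse_attention", "multiscale",
                  "uncertainty_weighting")


@dataclass
class ModelOutput:
    unimodal: dict[str, UnimodalOutput]
    fusion: FusionState

    @property
    def y_fusion(self) -> Tensor:
        return self.fusion.y_fusion


class MultimodalVigilanceNet(Module):
    """Three modality encoders plus cross-modal fusion.

    ``forward`` takes a dict ``modality -> [B, n_steps, n_features]`` (NumPy
    arrays or tensors) and returns every intermediate needed by the losses,
    the uncertainty analysis and the attention heatmaps.
    """

    def __init__(self, encoder_configs: dict[str, EncoderConfig] | None = None,
                 fusion_config: FusionConfig | None = None, seed: int = 0):
        super().__init__()
        encoder_configs = encoder_configs or default_encoder_configs()
        missing = set(MODALITY_ORDER) - set(encoder_configs)
        if missing:
            raise ValueError(f"missing encoder configs for {sorted(missing)}")
        self.fusion_config = fusion_config or FusionConfig()
        init_rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
        self.encoders = {name: UnimodalEncoder(encoder_configs[name], init_rng)
                         for name in MODALITY_ORDER}
        cls_dims = [encoder_configs[name].d_model for name in MODALITY_ORDER]
        self.fusion = FusionModule(self.fusion_config, cls_dims, init_rng)
        self.rng = np.random.default_rng(np.random.SeedSequence([seed, 11]))

    def seed_rng(self, seed: int) -> None:
        """Reset the forward-time noise stream (dropout, head sampling)."""
        self.rng = np.random.default_rng(seed)

    def parameter_groups(self) -> dict[str, list]:
        groups = {name: enc.parameters() for name, enc in self.encoders.items()}
        groups["fusion"] = self.fusion.parameters()
        return groups

    def forward(self, batch: dict[str, np.ndarray],
                rng: np.random.Generator | None = None) -> ModelOutput:
        rng = rng if rng is not None else self.rng
        unimodal = {name: self.encoders[name](batch[name], rng) for name in MODALITY_ORDER}
        state = self.fusion([unimodal[name] for name in MODALITY_ORDER], rng)
        return ModelOutput(unimodal=unimodal, fusion=state)

    def predict(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """Deterministic point prediction (evaluation mode forward)."""
        was_training = self.training
        self.eval()
        out = self.forward(batch)
        self.train(was_training)
        return out.y_fusion.data


def save_weights(model: Module, path) -> None:
    """Persist all named parameters to an ``.npz`` archive."""
    arrays = {name: p.data for name, p in model.named_parameters()}
    np.savez(path, **arrays)


def load_weights(model: Module, path) -> None:
    """Load parameters saved by :func:`save_weights` into a same-shaped model."""
    archive = np.load(path)
    named = dict(model.named_parameters())
    missing = set(named) ^ set(archive.files)
    if missing:
        raise ValueError(f"parameter name mismatch: {sorted(missing)[:5]} ...")
    for name, param in named.items():
        stored = archive[name]
        if stored.shape != param.data.shape:
            raise ValueError(f"shape mismatch for {name}")
        param.data = stored.astype(np.float64)


def apply_ablation(model: MultimodalVigilanceNet, flags: dict[str, bool]
                   ) -> MultimodalVigilanceNet:
    """Toggle model components in place; returns the model.

    Disabled components are replaced by the minimal structure-preserving
    substitutes: plain mean over projected features (cross-modal attention
    off), an identity bypass (ConvSparseAttention off), zero-padded
    pass-through of the 6-vector (multi-scale off), and fixed 1/3 weights
    (uncertainty weighting off).
    """
    unknown = set(flags) - set(ABLATION_FLAGS)
    if unknown:
        raise ValueError(f"unknown ablation flags: {sorted(unknown)}")
    if "cross_modal_attention" in flags:
        model.fusion.use_cross_modal_attention = flags["cross_modal_attention"]
    if "multiscale" in flags:
        model.fusion.use_multiscale = flags["multiscale"]
    if "uncertainty_weighting" in flags:
        model.fusion.use_uncertainty_weighting = flags["uncertainty_weighting"]
    if "conv_sparse_attention" in flags:
        for enc in model.encoders.values():
            enc.config = replace(enc.config,
                                 use_conv_sparse_attention=flags["conv_sparse_attention"])
    return model
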