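"""Scikit-learn style estimator facade.

:class:`VigilanceRegressor` wraps model construction, optional per-cell
standardisation, training and prediction behind the familiar
``fit``/``predict`` contract, so the network composes with scikit-learn
model selection utilities.  ``X`` is either a mapping
``modality -> [n, channels, features]`` or a 2-D array whose columns are
the flattened modalities concatenated in canonical order
(``eeg2hz | eog | eeg5bands``).
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, RegressorMixin

from .encoder import default_encoder_configs
from .fusion import FusionConfig
from .model import MODALITY_ORDER, MultimodalVigilanceNet, apply_ablation
from .objectives import LossConfig
from .preprocessing import ModalityStandardizer
from .training import (TrainConfig, UncertaintyEstimate, mc_predict, predict_unimodal,
                       train, train_unimodal)

__all__ = ["VigilanceRegressor"]


class VigilanceRegressor(BaseEstimator, RegressorMixin):
    """Multimodal (or single-modality) vigilance regressor.

    With all three modalities the full fusion network is trained under the
    composite objective; with a single modality only that encoder is
    trained under its Gaussian negative log-likelihood and the predictive
    mean is the output.

    Fitted attributes: ``model_`` (the network or the lone encoder),
    ``standardizer_`` (when ``standardize=True``) and ``history_`` (per-
    epoch loss records).
    """

    def __init__(self, modalities: tuple[str, ...] = MODALITY_ORDER, epochs: int = 50,
                 batch_size: int = 128, lr_eeg2hz: float = 4e-4, lr_eeg5bands: float = 7e-4,
                 lr_eog: float = 3e-4, lr_fusion: float = 5e-4, weight_decay: float = 1e-2,
                 mc_samples: int = 10, lambda_reg: float = 0.001, alpha: float = 1.0,
                 beta: float = 1.0, gamma: float = 0.5, weight_warmup_epochs: int = 5,
                 standardize: bool = True, ablation: dict[str, bool] | None = None,
                 seed: int = 0):
        self.modalities = modalities
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr_eeg2hz = lr_eeg2hz
        self.lr_eeg5bands = lr_eeg5bands
        self.lr_eog = lr_eog
        self.lr_fusion = lr_fusion
        self.weight_decay = weight_decay
        self.mc_samples = mc_samples
        self.lambda_reg = lambda_reg
        self.alpha = alpha
        self.beta = beta
        self.gamma = gamma
        self.weight_warmup_epochs = weight_warmup_epochs
        self.standardize = standardize
        self.ablation = ablation
        self.seed = seed

    # -- plumbing -------------------------------------------------------------

    def _coerce_X(self, X) -> dict[str, np.ndarray]:
        configs = default_encoder_configs()
        if isinstance(X, dict):
            out = {}
            for name in self.modalities:
                if name not in X:
                    raise ValueError(f"missing modality {name!r}")
                arr = np.asarray(X[name], dtype=np.float64)
                if arr.ndim != 3:
                    raise ValueError(f"{name}: expected [n, channels, features]")
                out[name] = arr
            return out
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2:
            raise ValueError("2-D array or modality dict expected")
        out = {}
        offset = 0
        for name in self.modalities:
            c, f = configs[name].n_steps, configs[name].in_features
            out[name] = X[:, offset:offset + c * f].reshape(len(X), c, f)
            offset += c * f
        if offset != X.shape[1]:
            raise ValueError(f"expected {offset} columns, got {X.shape[1]}")
        return out

    def _train_config(self) -> TrainConfig:
        return TrainConfig(lr_eeg2hz=self.lr_eeg2hz, lr_eeg5bands=self.lr_eeg5bands,
                           lr_eog=self.lr_eog, lr_fusion=self.lr_fusion,
                           batch_size=self.batch_size, epochs=self.epochs,
                           mc_samples=self.mc_samples, weight_decay=self.weight_decay,
                           weight_warmup_epochs=self.weight_warmup_epochs,
                           seed=self.seed)

    def _loss_config(self) -> LossConfig:
        return LossConfig(lambda_reg=self.lambda_reg, alpha=self.alpha,
                          beta=self.beta, gamma=self.gamma)

    # -- estimator API --------------------------------------------------------

    def fit(self, X, y) -> "VigilanceRegressor":
        features = self._coerce_X(X)
        y = np.asarray(y, dtype=np.float64).reshape(-1)
        if any(len(arr) != len(y) for arr in features.values()):
            raise ValueError("feature/label length mismatch")
        if self.standardize:
            self.standardizer_ = ModalityStandardizer().fit(features)
            features = self.standardizer_.transform(features)
        else:
            self.standardizer_ = None

        if len(self.modalities) == 1:
            name = self.modalities[0]
            from .encoder import UnimodalEncoder
            init_rng = np.random.default_rng(np.random.SeedSequence([self.seed, 7]))
            self.model_ = UnimodalEncoder(default_encoder_configs()[name], init_rng)
            lr = {"eeg2hz": self.lr_eeg2hz, "eog": self.lr_eog,
                  "eeg5bands": self.lr_eeg5bands}[name]
            self.history_ = train_unimodal(self.model_, features[name], y,
                                           self._train_config(), lr, self._loss_config())
        else:
            if tuple(self.modalities) != MODALITY_ORDER:
                raise ValueError(
                    f"fusion requires the three modalities {MODALITY_ORDER} "
                    f"(got {self.modalities}); single-modality fits are also supported")
            self.model_ = MultimodalVigilanceNet(seed=self.seed)
            if self.ablation:
                apply_ablation(self.model_, self.ablation)
            self.history_ = train(self.model_, features, y, self._train_config(),
                                  self._loss_config())
        return self

    def _prepare(self, X) -> dict[str, np.ndarray]:
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted")
        features = self._coerce_X(X)
        if self.standardizer_ is not None:
            features = self.standardizer_.transform(features)
        return features

    def predict(self, X) -> np.ndarray:
        features = self._prepare(X)
        if len(self.modalities) == 1:
            return predict_unimodal(self.model_, features[self.modalities[0]])
        return self.model_.predict(features)

    def predict_uncertainty(self, X, mc_samples: int | None = None) -> UncertaintyEstimate:
        """Monte-Carlo-dropout prediction with uncertainty decomposition
        (full trimodal models only)."""
        features = self._prepare(X)
        if len(self.modalities) == 1:
            raise ValueError("uncertainty decomposition needs the full trimodal model")
        return mc_predict(self.model_, features, mc_samples or self.mc_samples,
                          seed=self.seed)
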