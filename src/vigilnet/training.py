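"""Training loop, Monte-Carlo-dropout inference, metrics and the
leave-one-subject-out harness.

Training uses AdamW with one parameter group per network module, each with
its own learning rate (4e-4 EEG-2Hz, 7e-4 EEG-5Bands, 3e-4 EOG, 5e-4
fusion), batch size 128 and a fixed epoch budget.  Predictive uncertainty
is quantified by keeping dropout active at inference and averaging 10
stochastic forward passes: the reported prediction is the mean, the
epistemic variance is the across-pass variance of the fused output, and an
aleatoric proxy (the precision-weighted mean of the unimodal variance
heads) is exposed alongside.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.metrics import mean_absolute_error, mean_squared_error

from .encoder import UnimodalEncoder
from .model import MODALITY_ORDER, MultimodalVigilanceNet
from .objectives import LossConfig, composite_loss, nll_unimodal
from .optim import AdamW
from .preprocessing import ModalityStandardizer, make_loocv_splits
from .synthetic import SyntheticDataset

__all__ = ["TrainConfig", "UncertaintyEstimate", "train", "train_unimodal",
           "mc_predict", "evaluate_rmse_mae", "run_loocv"]


def _derived_seed(*entropy: int) -> int:
    return int(np.random.SeedSequence(list(entropy)).generate_state(1)[0] % (2**31))


@dataclass(frozen=True)
class TrainConfig:
    lr_eeg2hz: float = 4e-4
    lr_eeg5bands: float = 7e-4
    lr_eog: float = 3e-4
    lr_fusion: float = 5e-4
    batch_size: int = 128
    epochs: int = 50
    mc_samples: int = 10
    dropout: float = 0.3
    weight_decay: float = 1e-2
    #: Epochs trained with uniform (1/3) modality-loss weights before the
    #: precision weighting takes over; lets every variance head calibrate
    #: before confidence can redistribute the gradient.
    weight_warmup_epochs: int = 5
    seed: int = 0

    def __post_init__(self):
        if min(self.lr_eeg2hz, self.lr_eeg5bands, self.lr_eog, self.lr_fusion) < 0:
            raise ValueError("learning rates must be non-negative")
        if self.mc_samples < 1:
            raise ValueError("mc_samples must be >= 1")
        if self.epochs < 0 or self.batch_size < 1:
            raise ValueError("bad epoch/batch configuration")


@dataclass
class UncertaintyEstimate:
    """Per-sample Monte-Carlo-dropout uncertainty decomposition."""

    mean: np.ndarray        # MC-average prediction (the reported output)
    epistemic: np.ndarray   # variance of the fused output across MC passes
    aleatoric: np.ndarray   # MC average of the precision-weighted unimodal variances
    total: np.ndarray       # epistemic + aleatoric


def _batches(n: int, batch_size: int, rng: np.random.Generator):
    order = rng.permutation(n)
    for start in range(0, n, batch_size):
        yield order[start:start + batch_size]


def train(model: MultimodalVigilanceNet, features: dict[str, np.ndarray],
          labels: np.ndarray, config: TrainConfig = TrainConfig(),
          loss_config: LossConfig = LossConfig()) -> list[dict[str, float]]:
    """Train the full network; returns one loss-breakdown dict per epoch."""
    n = len(labels)
    if n == 0:
        raise ValueError("empty training set")
    groups = model.parameter_groups()
    lrs = {"eeg2hz": config.lr_eeg2hz, "eog": config.lr_eog,
           "eeg5bands": config.lr_eeg5bands, "fusion": config.lr_fusion}
    optimizer = AdamW([{"params": groups[name], "lr": lrs[name]} for name in lrs],
                      weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng(_derived_seed(config.seed, 101))
    model.seed_rng(_derived_seed(config.seed, 202))
    model.train()
    history: list[dict[str, float]] = []
    for epoch in range(config.epochs):
        if epoch < config.weight_warmup_epochs:
            epoch_loss_config = dataclasses.replace(loss_config, weight_mode="uniform")
        else:
            epoch_loss_config = loss_config
        sums: dict[str, float] = {}
        n_batches = 0
        for idx in _batches(n, config.batch_size, shuffle_rng):
            batch = {name: features[name][idx] for name in MODALITY_ORDER}
            out = model(batch)
            breakdown = composite_loss(
                [out.unimodal[name] for name in MODALITY_ORDER], out.fusion,
                labels[idx], epoch_loss_config)
            optimizer.zero_grad()
            breakdown.total.backward()
            optimizer.step()
            for key, value in breakdown.as_floats().items():
                sums[key] = sums.get(key, 0.0) + value
            n_batches += 1
        history.append({key: value / n_batches for key, value in sums.items()})
    model.eval()
    return history


def train_unimodal(encoder: UnimodalEncoder, features: np.ndarray, labels: np.ndarray,
                   config: TrainConfig = TrainConfig(), lr: float = 4e-4,
                   loss_config: LossConfig = LossConfig()) -> list[float]:
    """Train a single modality encoder with its Gaussian NLL objective."""
    n = len(labels)
    if n == 0:
        raise ValueError("empty training set")
    optimizer = AdamW([{"params": encoder.parameters(), "lr": lr}],
                      weight_decay=config.weight_decay)
    shuffle_rng = np.random.default_rng(_derived_seed(config.seed, 303))
    noise_rng = np.random.default_rng(_derived_seed(config.seed, 404))
    encoder.train()
    history: list[float] = []
    for _ in range(config.epochs):
        total = 0.0
        n_batches = 0
        for idx in _batches(n, config.batch_size, shuffle_rng):
            out = encoder(features[idx], noise_rng)
            loss = nll_unimodal(out.mu, out.sigma2, labels[idx], loss_config.lambda_reg)
            optimizer.zero_grad()
            loss.backward()
            optimizer.step()
            total += float(loss.data)
            n_batches += 1
        history.append(total / n_batches)
    encoder.eval()
    return history


def predict_unimodal(encoder: UnimodalEncoder, features: np.ndarray,
                     batch_size: int = 512) -> np.ndarray:
    encoder.eval()
    preds = [encoder(features[s:s + batch_size]).mu.data
             for s in range(0, len(features), batch_size)]
    return np.concatenate(preds)


def mc_predict(model: MultimodalVigilanceNet, batch: dict[str, np.ndarray],
               mc_samples: int = 10, seed: int = 0,
               sample_head_noise: bool = False) -> UncertaintyEstimate:
    """Monte-Carlo-dropout inference.

    Dropout layers stay active across ``mc_samples`` stochastic passes; the
    Gaussian head noise is disabled by default (the sampled prediction
    equals the mean), so dropout is the only source of stochasticity.
    """
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    was_training = model.training
    model.train()
    # dropout is the only stochastic behaviour retained: batch-norm layers
    # keep their running statistics and the Gaussian heads stay deterministic
    from .nn import BatchNorm1d
    for mod in model.modules():
        if isinstance(mod, BatchNorm1d):
            mod.training = False
    if not sample_head_noise:
        for enc in model.encoders.values():
            enc.head.training = False
    rng = np.random.default_rng(seed)
    preds, alea = [], []
    for _ in range(mc_samples):
        out = model.forward(batch, rng)
        preds.append(out.y_fusion.data.copy())
        sigma2 = np.stack([out.unimodal[m].sigma2.data for m in MODALITY_ORDER], axis=1)
        weights = out.fusion.weights.data
        alea.append((weights * sigma2).sum(axis=1))
    model.train(was_training)
    preds = np.stack(preds)
    # shifted moments: exact zero variance (and mean == the single pass)
    # when every stochastic pass coincides, e.g. with dropout disabled
    shifted = preds - preds[0]
    mean = preds[0] + shifted.mean(axis=0)
    epistemic = ((shifted - shifted.mean(axis=0)) ** 2).mean(axis=0)
    aleatoric = np.stack(alea).mean(axis=0)
    return UncertaintyEstimate(mean=mean, epistemic=epistemic,
                               aleatoric=aleatoric, total=epistemic + aleatoric)


def evaluate_rmse_mae(predictions: np.ndarray, labels: np.ndarray) -> tuple[float, float]:
    predictions = np.asarray(predictions, dtype=np.float64).reshape(-1)
    labels = np.asarray(labels, dtype=np.float64).reshape(-1)
    if predictions.size == 0:
        raise ValueError("empty input")
    if predictions.shape != labels.shape:
        raise ValueError("length mismatch")
    rmse = float(np.sqrt(mean_squared_error(labels, predictions)))
    mae = float(mean_absolute_error(labels, predictions))
    return rmse, mae


def run_loocv(dataset: SyntheticDataset, train_config: TrainConfig = TrainConfig(),
              loss_config: LossConfig = LossConfig(),
              encoder_configs=None, fusion_config=None,
              use_mc_dropout: bool = False) -> pd.DataFrame:
    """Leave-one-subject-out evaluation: one model trained from scratch per
    fold, standardiser fit on the training fold only.  Returns a table of
    per-subject RMSE/MAE plus ``Avg`` and ``Std`` rows."""
    splits = make_loocv_splits(dataset.subject_ids)
    rows = {}
    for split in splits:
        train_idx, test_idx = split.train_index, split.test_index
        assert not np.intersect1d(train_idx, test_idx).size, "train/test leakage"
        assert np.all(dataset.subject_ids[test_idx] == split.test_subject)
        standardizer = ModalityStandardizer().fit(
            {m: dataset.features[m][train_idx] for m in MODALITY_ORDER})
        train_x = standardizer.transform(
            {m: dataset.features[m][train_idx] for m in MODALITY_ORDER})
        test_x = standardizer.transform(
            {m: dataset.features[m][test_idx] for m in MODALITY_ORDER})
        fold_seed = _derived_seed(train_config.seed, int(split.test_subject))
        model = MultimodalVigilanceNet(encoder_configs=encoder_configs,
                                       fusion_config=fusion_config, seed=fold_seed)
        fold_config = TrainConfig(**{**train_config.__dict__, "seed": fold_seed})
        train(model, train_x, dataset.labels[train_idx], fold_config, loss_config)
        if use_mc_dropout:
            est = mc_predict(model, test_x, train_config.mc_samples, seed=fold_seed)
            preds = est.mean
        else:
            preds = model.predict(test_x)
        rmse, mae = evaluate_rmse_mae(preds, dataset.labels[test_idx])
        rows[split.test_subject] = {"rmse": rmse, "mae": mae}
    table = pd.DataFrame.from_dict(rows, orient="index").sort_index()
    table.index = table.index.astype(str)
    table.loc["Avg"] = table.mean()
    table.loc["Std"] = table.iloc[:-1].std(ddof=1)
    return table
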