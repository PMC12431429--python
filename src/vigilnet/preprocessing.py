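"""Channel-level z-score standardisation and leave-one-subject-out splits.

Standardisation statistics are computed independently per (channel,
frequency) cell over the sample axis, with the population (1/N) standard
deviation and an ``epsilon`` guard in the denominator so zero-variance
cells map to zero.  In the cross-validation harness the standardiser is fit
on the training fold only and applied unchanged to the held-out subject.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.model_selection import LeaveOneGroupOut

__all__ = [
    "StandardizerStats",
    "LoocvSplit",
    "fit_standardizer",
    "transform",
    "make_loocv_splits",
    "ModalityStandardizer",
    "load_seedvig_subject",
]

EPSILON = 1e-8


@dataclass(frozen=True)
class StandardizerStats:
    """Per-cell mean/std of one modality, shape ``[channels, features]``."""

    mean: np.ndarray
    std: np.ndarray
    epsilon: float = EPSILON

    def __post_init__(self):
        if self.mean.shape != self.std.shape:
            raise ValueError("mean/std shape mismatch")
        if np.any(self.std < 0):
            raise ValueError("std must be non-negative")


@dataclass(frozen=True)
class LoocvSplit:
    """One leave-one-subject-out fold."""

    test_subject: int
    train_index: np.ndarray
    test_index: np.ndarray


def fit_standardizer(features: np.ndarray, epsilon: float = EPSILON) -> StandardizerStats:
    """Fit per-cell statistics over the sample axis of ``[n, C, F]`` data."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3:
        raise ValueError(f"expected rank-3 [n, channels, features], got {features.shape}")
    if features.shape[0] == 0:
        raise ValueError("cannot fit a standardizer on an empty sample axis")
    mean = features.mean(axis=0)
    std = features.std(axis=0)  # population (1/N) standard deviation
    return StandardizerStats(mean=mean, std=std, epsilon=epsilon)


def transform(features: np.ndarray, stats: StandardizerStats) -> np.ndarray:
    """Apply ``(x - mean) / (std + epsilon)`` elementwise."""
    features = np.asarray(features, dtype=np.float64)
    if features.ndim != 3 or features.shape[1:] != stats.mean.shape:
        raise ValueError(
            f"features {features.shape} incompatible with stats {stats.mean.shape}")
    return (features - stats.mean) / (stats.std + stats.epsilon)


def make_loocv_splits(subject_ids: np.ndarray) -> list[LoocvSplit]:
    """One split per subject; each subject's samples form exactly one test fold."""
    subject_ids = np.asarray(subject_ids)
    subjects = np.unique(subject_ids)
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    splitter = LeaveOneGroupOut()
    splits = []
    dummy = np.zeros(len(subject_ids))
    for train_idx, test_idx in splitter.split(dummy, groups=subject_ids):
        test_subject = subject_ids[test_idx[0]]
        splits.append(LoocvSplit(test_subject=int(test_subject),
                                 train_index=train_idx, test_index=test_idx))
    return splits


class ModalityStandardizer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer standardising a dict of modality tensors.

    ``X`` is a mapping ``modality -> [n, channels, features]``.  After
    :meth:`fit`, per-modality statistics live in ``stats_``.
    """

    def __init__(self, epsilon: float = EPSILON):
        self.epsilon = epsilon

    def fit(self, X: dict[str, np.ndarray], y=None) -> "ModalityStandardizer":
        self.stats_ = {name: fit_standardizer(arr, epsilon=self.epsilon)
                       for name, arr in X.items()}
        return self

    def transform(self, X: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
        if not hasattr(self, "stats_"):
            raise RuntimeError("ModalityStandardizer is not fitted")
        return {name: transform(arr, self.stats_[name]) for name, arr in X.items()}


def load_seedvig_subject(path, keys: dict[str, str] | None = None,
                         label_key: str = "perclos") -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Read one subject's MAT file in the SEED-VIG per-subject layout.

    ``keys`` maps modality names to variable names inside the MAT file
    (default: ``eeg2hz``/``eog``/``eeg5bands``).  Returns a feature dict of
    ``[n, channels, features]`` arrays plus the label vector.
    """
    from scipy.io import loadmat

    keys = keys or {"eeg2hz": "eeg2hz", "eog": "eog", "eeg5bands": "eeg5bands"}
    mat = loadmat(path)
    features = {}
    for modality, key in keys.items():
        if key not in mat:
            raise KeyError(f"variable {key!r} not found in {path}")
        arr = np.asarray(mat[key], dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"{key!r} must be [n, channels, features], got {arr.shape}")
        features[modality] = arr
    labels = np.asarray(mat[label_key], dtype=np.float64).reshape(-1)
    return features, labels
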