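"""Attention-heatmap and prediction-trace figures."""

from __future__ import annotations

import numpy as np
import pandas as pd

from .model import MODALITY_ORDER

__all__ = ["plot_attention_heatmap", "plot_prediction_trace"]

_LABELS = {"eeg2hz": "EEG_2Hz", "eog": "EOG", "eeg5bands": "EEG_5Bands"}


def attention_matrix(attn_maps: np.ndarray, sample_id: int | None = None) -> np.ndarray:
    """Head-averaged 3x3 modality attention matrix for one sample.

    ``attn_maps`` may be ``[B, n_heads, 3, 3]`` (then ``sample_id`` selects
    the sample), ``[n_heads, 3, 3]`` or already ``[3, 3]``.
    """
    attn = np.asarray(attn_maps, dtype=np.float64)
    if attn.ndim == 4:
        if sample_id is None or not 0 <= sample_id < attn.shape[0]:
            raise IndexError(f"sample {sample_id} out of range for batch {attn.shape[0]}")
        attn = attn[sample_id]
    if attn.ndim == 3:
        attn = attn.mean(axis=0)
    if attn.shape != (3, 3):
        raise ValueError(f"expected a 3x3 modality matrix, got {attn.shape}")
    return attn


def plot_attention_heatmap(attn_maps: np.ndarray, sample_id: int, out_path) -> np.ndarray:
    """Write a labelled 3x3 modality heatmap PNG plus its CSV twin.

    Returns the head-averaged matrix that was plotted.  The CSV (same stem,
    ``.csv`` suffix) round-trips the matrix exactly.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    matrix = attention_matrix(attn_maps, sample_id)
    labels = [_LABELS[m] for m in MODALITY_ORDER]
    frame = pd.DataFrame(matrix, index=labels, columns=labels)
    out_path = str(out_path)
    csv_path = out_path.rsplit(".", 1)[0] + ".csv"
    frame.to_csv(csv_path, float_format="%.17g")

    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(matrix, cmap="viridis", vmin=0.0)
    ax.set_xticks(range(3), labels)
    ax.set_yticks(range(3), labels)
    ax.set_xlabel("Key modality")
    ax.set_ylabel("Query modality")
    for i in range(3):
        for j in range(3):
            ax.text(j, i, f"{matrix[i, j]:.2f}", ha="center", va="center", color="w")
    fig.colorbar(im, ax=ax)
    ax.set_title(f"Fusion attention (sample {sample_id})")
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
    return matrix


def plot_prediction_trace(predictions: np.ndarray, labels: np.ndarray, out_path,
                          unimodal: dict[str, np.ndarray] | None = None) -> None:
    """Overlay predicted and true PERCLOS series (optionally unimodal traces)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    predictions = np.asarray(predictions).reshape(-1)
    labels = np.asarray(labels).reshape(-1)
    if predictions.shape != labels.shape:
        raise ValueError("predictions and labels must have equal length")

    fig, ax = plt.subplots(figsize=(8, 3.2))
    ax.plot(labels, color="k", lw=1.2, label="True PERCLOS")
    ax.plot(predictions, color="tab:red", lw=1.0, label="Fused prediction")
    if unimodal:
        for name, series in unimodal.items():
            ax.plot(np.asarray(series).reshape(-1), lw=0.7, ls="--",
                    label=_LABELS.get(name, name))
    ax.set_xlabel("Sample")
    ax.set_ylabel("PERCLOS")
    ax.legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
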