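"""Figures: hypnogram overlays, attention heatmaps, training curves.

All plotting functions are pure consumers — they never modify their inputs
and write a file at the requested path (PNG by default; any extension
matplotlib understands works).
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .data_prep import EPOCH_SECONDS
from .stages import StageLabel

#: Clinical y-axis convention: wake on top, deep sleep at the bottom.
HYPNOGRAM_ORDER = (StageLabel.W, StageLabel.REM, StageLabel.N1,
                   StageLabel.N2, StageLabel.N3)


def _to_track(labels) -> np.ndarray:
    return np.array([int(v) for v in labels], dtype=np.int64)


def plot_hypnogram(expert, predicted, out,
                   stage_order=HYPNOGRAM_ORDER) -> float:
    """Overlay expert and model hypnograms; returns the agreement percent.

    Agreement is the fraction of epochs with identical labels, which equals
    the overall accuracy of the per-recording confusion matrix.
    """
    expert = _to_track(expert)
    predicted = _to_track(predicted)
    if expert.shape != predicted.shape:
        raise ValueError("expert and predicted tracks must have equal length")
    agreement = float((expert == predicted).mean() * 100)

    y_of = {int(s): i for i, s in enumerate(stage_order)}
    hours = np.arange(len(expert)) * EPOCH_SECONDS / 3600
    fig, axes = plt.subplots(2, 1, figsize=(10, 4), sharex=True)
    for ax, track, title in zip(axes, (expert, predicted), ("Expert", "Model")):
        ax.step(hours, [y_of[v] for v in track], where="post", lw=0.8)
        ax.set_yticks(range(len(stage_order)))
        ax.set_yticklabels([s.name for s in stage_order])
        ax.invert_yaxis()
        ax.set_ylabel(title)
    axes[1].set_xlabel("Time (h)")
    fig.suptitle(f"Hypnogram overlay — agreement {agreement:.1f}%")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return agreement


def plot_attention(amap: np.ndarray, out, labels=None) -> Path:
    """Heatmap of one sequence's attention map.

    Rows are decoded positions, columns input epochs; brightness is the
    attention weight. Rows must sum to 1.
    """
    amap = np.asarray(amap, dtype=np.float64)
    if amap.ndim != 2 or (amap < 0).any() or np.abs(amap.sum(axis=1) - 1).max() > 1e-6:
        raise ValueError("attention map rows must be non-negative and sum to 1")
    fig, ax = plt.subplots(figsize=(5, 4.5))
    im = ax.imshow(amap, cmap="viridis", aspect="auto", vmin=0)
    ax.set_xlabel("Input epoch")
    ax.set_ylabel("Decoded epoch")
    if labels is not None:
        ax.set_xticks(range(amap.shape[1]))
        ax.set_xticklabels([StageLabel(int(v)).name for v in labels], rotation=45)
    fig.colorbar(im, ax=ax, label="attention weight")
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def plot_training_curves(history: dict, out) -> Path:
    """Train/test accuracy and loss versus training epoch."""
    if not history.get("train_loss"):
        raise ValueError("empty training history")
    epochs = np.arange(1, len(history["train_loss"]) + 1)
    fig, (ax_acc, ax_loss) = plt.subplots(1, 2, figsize=(10, 3.5))
    ax_acc.plot(epochs, history["train_acc"], label="train")
    if history.get("test_acc"):
        ax_acc.plot(epochs, history["test_acc"], label="test")
    ax_acc.set_xlabel("Epoch")
    ax_acc.set_ylabel("Accuracy")
    ax_acc.legend()
    ax_loss.plot(epochs, history["train_loss"], label="train")
    if history.get("test_loss"):
        ax_loss.plot(epochs, history["test_loss"], label="test")
    ax_loss.set_xlabel("Epoch")
    ax_loss.set_ylabel("Loss")
    ax_loss.legend()
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
    return Path(out)


def attention_diagonality(amaps, tolerance: int = 1) -> float:
    """Fraction of attention rows whose maximum lies within ``tolerance``
    positions of the diagonal — the qualitative 'the model attends to the
    epoch it is scoring' check."""
    hits = total = 0
    for amap in amaps:
        arg = np.asarray(amap).argmax(axis=1)
        t = np.arange(len(arg))
        hits += int((np.abs(arg - t) <= tolerance).sum())
        total += len(arg)
    return hits / max(total, 1)
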