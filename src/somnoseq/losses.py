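"""Imbalance-aware training objectives: mean false error and friends.

Plain mean squared error averages the squared prediction error over all
samples, so under heavy class imbalance the majority stages dominate the
gradient and rare stages (N1 above all) are sacrificed. The *mean false
error* (MFE) family instead averages the squared error **within** each
class first and then sums across classes:

    l(c)   = (1/C_c) Σ_{j in class c} ||y_j − ŷ_j||²      (per-class error)
    L_MFE  = Σ_c l(c)
    L_MSFE = Σ_c l(c)²

so every class contributes one term regardless of its frequency, and MSFE
additionally amplifies the worst class. The inner ||·||² is the squared
Euclidean distance between the one-hot target and the predicted probability
vector (a per-dimension mean variant is available via ``inner="mean"``).

All losses accept either plain numpy predictions (returning a float) or
autodiff tensors (returning a differentiable scalar), so the same code path
serves evaluation, the training loop, and gradient checks.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor
from .stages import N_STAGES

logger = logging.getLogger(__name__)


@dataclass
class LossBatch:
    """Predictions and targets for one loss evaluation.

    ``predictions``: (B, D) probability vectors (Tensor or ndarray);
    ``targets``: (B, D) one-hot rows; ``class_of``: (B,) true-class index
    used for the per-class grouping; ``n_classes``: the number of classes N
    in the MFE/MSFE sums (the vector dimension D may exceed it, e.g. when
    an end-of-decoding logit is carried but not treated as a class).
    """

    predictions: Tensor | np.ndarray
    targets: np.ndarray
    class_of: np.ndarray
    n_classes: int = N_STAGES

    def __post_init__(self) -> None:
        self.targets = np.asarray(self.targets, dtype=np.float64)
        self.class_of = np.asarray(self.class_of, dtype=np.int64)
        if self.targets.shape[0] != self.class_of.shape[0]:
            raise ValueError("targets and class_of disagree on batch size")

    @classmethod
    def from_labels(cls, predictions, labels, n_classes: int = N_STAGES,
                    dim: int | None = None) -> "LossBatch":
        """Build a batch from integer labels (one-hot encoded internally)."""
        labels = np.asarray(labels, dtype=np.int64)
        d = dim or (predictions.shape[1] if hasattr(predictions, "shape") else n_classes)
        onehot = np.zeros((len(labels), d))
        onehot[np.arange(len(labels)), labels] = 1.0
        return cls(predictions, onehot, labels, n_classes)

    def class_counts(self) -> np.ndarray:
        return np.bincount(self.class_of, minlength=self.n_classes)

    def _pred_tensor(self) -> tuple[Tensor, bool]:
        if isinstance(self.predictions, Tensor):
            return self.predictions, True
        return Tensor(np.asarray(self.predictions, dtype=np.float64),
                      requires_grad=False), False


def _inner_sq(pred: Tensor, target: np.ndarray, inner: str) -> Tensor:
    """(B,) squared distances between predictions and one-hot targets."""
    diff = pred - Tensor(target, requires_grad=False)
    if inner == "sum":
        return diff.square().sum(axis=1)
    if inner == "mean":
        return diff.square().mean(axis=1)
    raise ValueError(f"inner must be 'sum' or 'mean', got {inner!r}")


def per_class_error(batch: LossBatch, class_index: int, inner: str = "sum"):
    """The mean squared error l(c) over one class's samples.

    A class absent from the batch contributes 0 (with a debug-level note) —
    mini-batches cannot be guaranteed to contain every stage.
    """
    pred, differentiable = batch._pred_tensor()
    mask = batch.class_of == class_index
    if not mask.any():
        logger.debug("class %d absent from batch; per-class error = 0", class_index)
        return Tensor(0.0, requires_grad=False) if differentiable else 0.0
    err = _inner_sq(pred[mask], batch.targets[mask], inner).mean()
    return err if differentiable else err.item()


def mfe(batch: LossBatch, inner: str = "sum"):
    """Mean false error: the sum of per-class mean squared errors."""
    pred, differentiable = batch._pred_tensor()
    total = Tensor(0.0, requires_grad=False)
    for c in range(batch.n_classes):
        e = per_class_error(
            LossBatch(pred, batch.targets, batch.class_of, batch.n_classes), c, inner
        )
        total = total + e
    return total if differentiable else total.item()


def msfe(batch: LossBatch, inner: str = "sum"):
    """Mean squared false error: the sum of squared per-class errors."""
    pred, differentiable = batch._pred_tensor()
    total = Tensor(0.0, requires_grad=False)
    for c in range(batch.n_classes):
        e = per_class_error(
            LossBatch(pred, batch.targets, batch.class_of, batch.n_classes), c, inner
        )
        total = total + e.square() if isinstance(e, Tensor) else total + e**2
    return total if differentiable else total.item()


def mse(batch: LossBatch, inner: str = "sum"):
    """Plain per-sample mean squared error (the imbalance-blind baseline)."""
    pred, differentiable = batch._pred_tensor()
    out = _inner_sq(pred, batch.targets, inner).mean()
    return out if differentiable else out.item()


LOSSES = {"mfe": mfe, "msfe": msfe, "mse": mse}


def l2_penalty(parameters, beta: float):
    """β × Σ‖W‖² over trainable weight arrays (biases excluded by the caller)."""
    if beta < 0:
        raise ValueError("beta must be >= 0")
    params = list(parameters)
    differentiable = any(isinstance(p, Tensor) for p in params)
    total = Tensor(0.0, requires_grad=False)
    for p in params:
        t = p if isinstance(p, Tensor) else Tensor(np.asarray(p, float), requires_grad=False)
        total = total + t.square().sum()
    total = total * float(beta)
    return total if differentiable else total.item()
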