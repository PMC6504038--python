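"""Training loop, subject-wise k-fold cross-validation, and evaluation.

Training minimizes the selected imbalance-aware loss (MFE by default) plus
an L2 weight penalty with RMSProp, teacher forcing on, mini-batches of 20
sequences, learning rate 0.001, for at most 120 passes over the training
sequences. Cross-validation is subject-wise: all recordings of a subject
land in the same fold, so evaluation is always inter-patient. Per-fold test
predictions are pooled into a single confusion matrix and the metric stack
is computed on the pooled counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from . import losses as losses_mod
from .balancing import BALANCERS, OversampleConfig
from .data_prep import Epoch, EpochSequence, PreparedDataset, assemble_sequences
from .losses import LossBatch, l2_penalty
from .metrics import ConfusionMatrix, MetricsReport, confusion, report
from .model import ModelConfig, SleepStager
from .stages import N_STAGES, StageLabel

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# configuration and folds
# ---------------------------------------------------------------------------


@dataclass
class TrainConfig:
    """Optimization hyper-parameters (defaults are the standard recipe)."""

    learning_rate: float = 0.001
    batch_size: int = 20
    max_epochs: int = 120
    l2_beta: float = 0.001
    loss: str = "mfe"  # mfe | msfe | mse
    inner_error: str = "sum"  # squared-distance reduction inside the loss
    rmsprop_decay: float = 0.9
    rmsprop_eps: float = 1e-10
    early_stop_patience: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.learning_rate, self.batch_size, self.max_epochs) < 0:
            raise ValueError("training hyper-parameters must be non-negative")
        if self.loss not in losses_mod.LOSSES:
            raise ValueError(f"unknown loss {self.loss!r}")


@dataclass
class FoldSplit:
    """Subject-wise partition of recordings into k folds."""

    k: int
    assignment: dict[str, int]  # recording_id -> fold index
    granularity: str = "subject"

    def test_recordings(self, fold: int) -> set[str]:
        return {rid for rid, f in self.assignment.items() if f == fold}


def make_folds(
    dataset: PreparedDataset, k: int, seed: int = 0, granularity: str = "subject"
) -> FoldSplit:
    """Shuffle subjects (or recordings) and deal them round-robin into folds."""
    if k < 2:
        raise ValueError("k must be >= 2")
    if granularity == "subject":
        units = dataset.subject_ids()
    elif granularity == "recording":
        units = sorted(r.recording_id for r in dataset.recordings)
    else:
        raise ValueError(f"unknown granularity {granularity!r}")
    if len(units) < k:
        raise ValueError(f"need at least k={k} {granularity}s, have {len(units)}")
    order = list(units)
    np.random.default_rng(seed).shuffle(order)
    unit_fold = {u: i % k for i, u in enumerate(order)}
    assignment = {}
    for rec in dataset.recordings:
        unit = rec.subject_id if granularity == "subject" else rec.recording_id
        assignment[rec.recording_id] = unit_fold[unit]
    return FoldSplit(k=k, assignment=assignment, granularity=granularity)


# ---------------------------------------------------------------------------
# batching and the sequence loss
# ---------------------------------------------------------------------------


def _batch_arrays(sequences: list[EpochSequence], n_classes: int = N_STAGES):
    """Stack sequences into (B, T, 3000) signals and (B, T+1) decoder tracks.

    The SOD/EOD token id is ``n_classes`` (the row after the real stages),
    so the tracks match the model's embedding/output layout for any class
    count.
    """
    x = np.stack([s.samples for s in sequences])
    labels = np.array([[int(l) for l in s.labels] for s in sequences], dtype=np.int64)
    sod = np.full((len(sequences), 1), n_classes, dtype=np.int64)
    target_out = np.concatenate([labels, sod], axis=1)  # EOD shares the id
    # teacher-forced decoder inputs: SOD then the true labels (incl. the
    # last, whose step predicts EOD)
    dec_in = np.concatenate([sod, labels], axis=1)
    return x, dec_in, target_out, labels


def sequence_loss(probs_steps, target_out: np.ndarray, cfg: TrainConfig,
                  n_classes: int):
    """Loss over decoded steps: MFE/MSFE/MSE on stage steps + a plain
    squared-error term for the EOD step (EOD is not one of the N classes)."""
    from .autodiff import concat

    stacked = concat(probs_steps, axis=0)  # step-major (S*B, C+1)
    flat_targets = target_out.T.reshape(-1)  # matching step-major order
    d = stacked.shape[1]
    onehot = np.zeros((flat_targets.size, d))
    onehot[np.arange(flat_targets.size), flat_targets] = 1.0

    stage_idx = np.flatnonzero(flat_targets < n_classes)
    eod_idx = np.flatnonzero(flat_targets >= n_classes)
    stage_batch = LossBatch(
        stacked[stage_idx], onehot[stage_idx], flat_targets[stage_idx], n_classes
    )
    loss_fn = losses_mod.LOSSES[cfg.loss]
    total = loss_fn(stage_batch, inner=cfg.inner_error)
    if eod_idx.size:
        diff = stacked[eod_idx] - onehot[eod_idx]
        total = total + diff.square().sum(axis=1).mean()
    return total


class RMSProp:
    """Root-mean-square propagation with the usual accumulator update."""

    def __init__(self, params: dict, lr: float, decay: float, eps: float):
        self.params = params
        self.lr = lr
        self.decay = decay
        self.eps = eps
        self.cache = {k: np.zeros_like(t.data) for k, t in params.items()}

    def step(self) -> None:
        for name, t in self.params.items():
            if t.grad is None:
                continue
            c = self.cache[name]
            c *= self.decay
            c += (1.0 - self.decay) * t.grad**2
            t.data -= self.lr * t.grad / (np.sqrt(c) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------


def _epoch_batches(sequences, batch_size, rng):
    order = rng.permutation(len(sequences))
    for lo in range(0, len(order), batch_size):
        chunk = [sequences[i] for i in order[lo : lo + batch_size]]
        if chunk:
            yield chunk


def evaluate_sequences(model: SleepStager, sequences: list[EpochSequence],
                       cfg: TrainConfig, batch_size: int = 64):
    """Greedy decoding over sequences; returns (loss, accuracy, y_true,
    y_pred, attention maps). The loss is teacher-forced for comparability
    with training-loss curves."""
    y_true, y_pred, amaps = [], [], []
    total_loss, n_batches = 0.0, 0
    for lo in range(0, len(sequences), batch_size):
        chunk = sequences[lo : lo + batch_size]
        x, dec_in, target_out, labels = _batch_arrays(chunk, model.config.n_classes)
        probs_steps, _, _ = model.forward(x, decoder_inputs=dec_in, train=False)
        loss = sequence_loss(probs_steps, target_out, cfg, model.config.n_classes)
        total_loss += loss.item() if hasattr(loss, "item") else float(loss)
        n_batches += 1
        _, pred, alphas = model.forward(x, decoder_inputs=None, train=False)
        y_true.extend(labels.reshape(-1).tolist())
        y_pred.extend(pred.reshape(-1).tolist())
        amaps.extend(list(alphas))
    acc = float(np.mean(np.array(y_true) == np.array(y_pred))) if y_true else 0.0
    return total_loss / max(n_batches, 1), acc, y_true, y_pred, amaps


def train_fold(
    train_sequences: list[EpochSequence],
    cfg: TrainConfig,
    model_cfg: ModelConfig | None = None,
    test_sequences: list[EpochSequence] | None = None,
    model: SleepStager | None = None,
) -> tuple[SleepStager, dict]:
    """Train one model on one fold's training sequences.

    Returns the model and a history dict with per-epoch train/test loss and
    accuracy (test entries only when ``test_sequences`` is given). Training
    aborts on a NaN loss and supports optional early stopping when the
    monitored (test if available, else train) loss stops improving.
    """
    if not train_sequences:
        raise ValueError("empty training set")
    if model is None:
        if model_cfg is None:
            model_cfg = ModelConfig(init_seed=cfg.seed)
        model = SleepStager(model_cfg)
    opt = RMSProp(model.params, cfg.learning_rate, cfg.rmsprop_decay, cfg.rmsprop_eps)
    rng = np.random.default_rng(cfg.seed + 1)
    history = {"train_loss": [], "train_acc": [], "test_loss": [], "test_acc": []}
    best, since_best = np.inf, 0

    for epoch in range(cfg.max_epochs):
        epoch_loss, n_batches, correct, seen = 0.0, 0, 0, 0
        for chunk in _epoch_batches(train_sequences, cfg.batch_size, rng):
            x, dec_in, target_out, labels = _batch_arrays(chunk, model.config.n_classes)
            model.zero_grad()
            probs_steps, pred_labels, _ = model.forward(
                x, decoder_inputs=dec_in, train=True, rng=rng
            )
            loss = sequence_loss(probs_steps, target_out, cfg, model.config.n_classes)
            loss = loss + l2_penalty(model.weight_tensors(), cfg.l2_beta)
            value = loss.item()
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss {value} at epoch {epoch}; "
                    "lower the learning rate or check the input scaling"
                )
            loss.backward()
            opt.step()
            epoch_loss += value
            n_batches += 1
            # teacher-forced argmax agreement doubles as the train accuracy
            correct += int((pred_labels[:, : labels.shape[1]] == labels).sum())
            seen += labels.size
        history["train_loss"].append(epoch_loss / n_batches)
        history["train_acc"].append(correct / max(seen, 1))
        if test_sequences:
            t_loss, t_acc, *_ = evaluate_sequences(model, test_sequences, cfg)
            history["test_loss"].append(t_loss)
            history["test_acc"].append(t_acc)
        monitored = history["test_loss"][-1] if test_sequences else history["train_loss"][-1]
        if monitored < best - 1e-9:
            best, since_best = monitored, 0
        else:
            since_best += 1
            if cfg.early_stop_patience and since_best >= cfg.early_stop_patience:
                logger.info("early stop at epoch %d (loss plateau)", epoch)
                break
    return model, history


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


def synthetic_sequences(epochs: list[Epoch], maxtime: int) -> list[EpochSequence]:
    """Wrap SMOTE epochs into homogeneous all-one-stage training sequences.

    Interpolated epochs have no temporal context of their own, so they are
    grouped per stage under a dedicated pseudo-recording id.
    """
    by_class: dict[int, list[Epoch]] = {}
    for e in epochs:
        by_class.setdefault(int(e.label), []).append(e)
    out = []
    for c, members in sorted(by_class.items()):
        rid = f"smote-{StageLabel(c).name}"
        relabeled = [
            Epoch(e.samples, e.label, rid, i, synthetic=True)
            for i, e in enumerate(members)
        ]
        out.extend(assemble_sequences(relabeled, maxtime))
    return out


@dataclass
class CrossValResult:
    pooled_confusion: ConfusionMatrix
    pooled_report: MetricsReport
    fold_reports: list[MetricsReport]
    histories: list[dict]
    attention_maps: list[np.ndarray] = field(default_factory=list)
    models: list[SleepStager] = field(default_factory=list)


def cross_validate(
    dataset: PreparedDataset,
    k: int,
    cfg: TrainConfig,
    model_cfg: ModelConfig | None = None,
    maxtime: int = 10,
    balance: str = "none",
    oversample_cfg: OversampleConfig | None = None,
    granularity: str = "subject",
    track_test_curves: bool = False,
    keep_models: bool = False,
) -> CrossValResult:
    """Subject-wise k-fold cross-validation of the full pipeline.

    Balancing (``none``/``smote``/``duplicate``) is applied to training-fold
    epochs only; the harness asserts that test folds contain no synthetic
    epochs. Per-fold test predictions are pooled into one confusion matrix.
    """
    split = make_folds(dataset, k, seed=cfg.seed, granularity=granularity)
    if model_cfg is not None:
        # derive per-run weight init from the run seed, on a copy so the
        # caller's config object is untouched
        model_cfg = ModelConfig.from_dict(model_cfg.to_dict())
        model_cfg.init_seed = cfg.seed
    balancer = BALANCERS[balance]
    oversample_cfg = oversample_cfg or OversampleConfig(seed=cfg.seed)
    pooled_true: list[int] = []
    pooled_pred: list[int] = []
    fold_reports, histories, all_amaps, models = [], [], [], []

    for fold in range(k):
        test_rids = split.test_recordings(fold)
        train_epochs: list[Epoch] = []
        test_epochs: list[Epoch] = []
        for rec in dataset.recordings:
            target = test_epochs if rec.recording_id in test_rids else train_epochs
            target.extend(rec.to_epochs())
        assert not any(e.synthetic for e in test_epochs), (
            "synthetic epochs leaked into a test fold"
        )
        balanced = balancer(train_epochs, oversample_cfg)
        real = [e for e in balanced if not e.synthetic]
        synth = [e for e in balanced if e.synthetic]
        train_seqs = assemble_sequences(real, maxtime) + synthetic_sequences(
            synth, maxtime
        )
        test_seqs = assemble_sequences(test_epochs, maxtime)
        model, history = train_fold(
            train_seqs, cfg, model_cfg=model_cfg,
            test_sequences=test_seqs if track_test_curves else None,
        )
        _, acc, y_true, y_pred, amaps = evaluate_sequences(model, test_seqs, cfg)
        logger.info("fold %d/%d test accuracy %.3f", fold + 1, k, acc)
        pooled_true.extend(y_true)
        pooled_pred.extend(y_pred)
        fold_reports.append(report(confusion(y_true, y_pred)))
        histories.append(history)
        all_amaps.extend(amaps)
        if keep_models:
            models.append(model)

    pooled_cm = confusion(pooled_true, pooled_pred)
    return CrossValResult(
        pooled_confusion=pooled_cm,
        pooled_report=report(pooled_cm),
        fold_reports=fold_reports,
        histories=histories,
        attention_maps=all_amaps,
        models=models,
    )
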