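"""Reference experiments: the standard scaled-down functional runs.

These are the package's benchmark computations, sized for a single CPU:

* :func:`published_metric_recomputation` — feed the published pooled
  confusion matrices through the metrics stack and return every derived
  number alongside the published values.
* :func:`synthetic_cv_benchmark` — subject-wise 4-fold cross-validation of
  the reduced model on the standard synthetic bundle (4 recordings × 240
  epochs, maxtime 5, SMOTE balancing, MFE loss, ≤30 training epochs).
* :func:`imbalance_loss_benchmark` — the directional class-imbalance
  contrast: identical models trained with MFE vs plain MSE on a 95:5
  binary task; MFE should recover more minority-class recall.
"""

from __future__ import annotations

import numpy as np

from .data_prep import Epoch, PreparedDataset, PreparedRecording, assemble_sequences
from .metrics import confusion, report
from .model import CnnBranchConfig, CnnConfig, ModelConfig
from .reference_tables import FPZ_CZ_CONFUSION, PZ_OZ_CONFUSION
from .stages import StageLabel
from .synthetic import SyntheticConfig, generate_dataset, _epoch_wave
from .training import TrainConfig, cross_validate, evaluate_sequences, train_fold
from .viz import attention_diagonality


def published_metric_recomputation() -> dict:
    """Recompute the full metric stack from the published confusion matrices."""
    out = {}
    for key, cm in (("fpz_cz", FPZ_CZ_CONFUSION), ("pz_oz", PZ_OZ_CONFUSION)):
        out[key] = report(cm).to_dict()
    return out


def reduced_model_config() -> ModelConfig:
    """The CPU-scale preset used by the functional benchmarks.

    Hidden size 32 per encoder direction, slim 8-channel CNN branches, and
    lighter dropout (0.25) than the full-scale default — a small network
    regularized as hard as the full one cannot fit even the synthetic task
    in a 30-epoch budget.
    """
    cfg = ModelConfig.reduced()
    cfg.cnn.dropout = 0.25
    return cfg


def synthetic_cv_benchmark(seed: int = 1, max_epochs: int = 30,
                           k: int = 4, maxtime: int = 5) -> dict:
    """Cross-validated training of the reduced model on the standard bundle.

    Returns pooled accuracy / macro-F1 / kappa (percent scale for the first
    two) plus the attention-diagonality fraction of the pooled test maps.
    """
    dataset = generate_dataset(SyntheticConfig(seed=seed))
    cfg = TrainConfig(max_epochs=max_epochs, seed=seed)
    result = cross_validate(
        dataset, k, cfg, model_cfg=reduced_model_config(),
        maxtime=maxtime, balance="smote",
    )
    rep = result.pooled_report
    return {
        "accuracy": rep.accuracy,
        "macro_f1": rep.macro_f1,
        "kappa": rep.kappa,
        "attention_diagonality": attention_diagonality(result.attention_maps),
        "confusion": result.pooled_confusion.counts.tolist(),
        "n_epochs_scored": result.pooled_confusion.total,
    }


# ---------------------------------------------------------------------------
# the 95:5 binary imbalance contrast
# ---------------------------------------------------------------------------

#: Two deliberately overlapping spectral classes: the frequency gap is
#: small relative to the noise floor, so a loss that sacrifices the
#: minority class actually loses minority recall.
_BINARY_SPECTRA = {
    StageLabel.W: [(10.0, 0.7)],   # majority class
    StageLabel.N1: [(8.5, 0.7)],   # minority class
}
_BINARY_NOISE_SD = 1.5
_MINORITY_FRACTION = 0.05


def _binary_dataset(seed: int, n_epochs: int) -> PreparedDataset:
    cfg = SyntheticConfig(
        stage_spectra=dict(_BINARY_SPECTRA),
        noise_sd=_BINARY_NOISE_SD,
        amplitude_jitter=0.2,
        seed=seed,
    )
    rng = np.random.default_rng(seed)
    labels = (rng.random(n_epochs) < _MINORITY_FRACTION).astype(np.int64)
    from .data_prep import normalize_epoch

    epochs = []
    for i, lab in enumerate(labels):
        stage = StageLabel.N1 if lab else StageLabel.W
        e = Epoch(_epoch_wave(stage, cfg, rng), StageLabel(lab), "bin-000", i)
        epochs.append(normalize_epoch(e))
    rec = PreparedRecording(
        recording_id="bin-000",
        subject_id="bin-000",
        epochs=np.stack([e.samples for e in epochs]).astype(np.float32),
        labels=labels,
        indices=np.arange(n_epochs, dtype=np.int64),
    )
    return PreparedDataset([rec])


def _binary_model_config(seed: int) -> ModelConfig:
    return ModelConfig(
        cnn=CnnConfig(
            small=CnnBranchConfig(filters=(50, 8, 8, 8), strides=(6, 1, 1, 1),
                                  channels=(4, 4, 4, 4), pool_size=8),
            large=CnnBranchConfig(filters=(400, 6, 6, 6), strides=(50, 1, 1, 1),
                                  channels=(4, 4, 4, 4), pool_size=4),
            dropout=0.0,
        ),
        encoder_hidden=16,
        decoder_hidden=32,
        embed_dim=8,
        n_classes=2,
        init_seed=seed,
    )


def imbalance_loss_benchmark(seed: int = 1, n_seeds: int = 5,
                             n_train: int = 500, n_test: int = 400,
                             max_epochs: int = 10, maxtime: int = 5) -> dict:
    """Minority-class recall of MFE- vs MSE-trained models, median over seeds.

    Each replicate draws a fresh 95:5 two-class dataset, trains two models
    that differ only in the loss, and measures recall of the minority class
    on held-out epochs.
    """
    recalls = {"mfe": [], "mse": []}
    for rep in range(n_seeds):
        rep_seed = seed + 1000 * rep
        train_ds = _binary_dataset(rep_seed, n_train)
        test_ds = _binary_dataset(rep_seed + 1, n_test)
        train_seqs = assemble_sequences(
            [e for r in train_ds.recordings for e in r.to_epochs()], maxtime
        )
        test_seqs = assemble_sequences(
            [e for r in test_ds.recordings for e in r.to_epochs()], maxtime
        )
        for loss in ("mfe", "mse"):
            cfg = TrainConfig(loss=loss, max_epochs=max_epochs, seed=rep_seed)
            model, _ = train_fold(train_seqs, cfg,
                                  model_cfg=_binary_model_config(rep_seed))
            _, _, y_true, y_pred, _ = evaluate_sequences(model, test_seqs, cfg)
            cm = confusion(y_true, y_pred, n_classes=2, class_names=("maj", "min"))
            tp = cm.counts[1, 1]
            fn = cm.counts[1, 0]
            recalls[loss].append(float(tp / max(tp + fn, 1)))
    return {
        "mfe_minority_recall_median": float(np.median(recalls["mfe"])),
        "mse_minority_recall_median": float(np.median(recalls["mse"])),
        "mfe_minority_recalls": recalls["mfe"],
        "mse_minority_recalls": recalls["mse"],
    }
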