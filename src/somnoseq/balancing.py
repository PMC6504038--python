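"""SMOTE oversampling of minority-stage epochs.

Synthetic minority oversampling creates new minority-class samples by
linear interpolation: pick a real minority epoch x, pick one of its k
nearest same-class neighbors x' (Euclidean distance on the normalized
3000-sample vectors), and emit x + u·(x'−x) with u uniform on [0, 1]. Every
synthetic epoch therefore lies coordinate-wise on the segment between two
real epochs of its class.

Oversampling applies to training folds only; the cross-validation harness
asserts via the per-epoch provenance flag that no synthetic epoch reaches
a test fold. Synthetic epochs carry no temporal context of their own, so
the training harness assembles them into homogeneous all-one-stage
sequences appended after the real ones.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

from .data_prep import Epoch
from .stages import N_STAGES, StageLabel


@dataclass
class OversampleConfig:
    """Targets and neighborhood size for SMOTE.

    ``target_counts`` of ``None`` means "raise every class to the majority
    class count". Explicit targets must not be below the existing counts.
    """

    target_counts: dict[int, int] | None = None
    k_neighbors: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


def smote_epochs(epochs: list[Epoch], cfg: OversampleConfig) -> list[Epoch]:
    """Oversample minority stages to the configured per-class counts.

    Synthetic epochs are flagged ``synthetic=True`` and keep the recording
    id and epoch index of their base sample. Classes absent from the input
    are left absent. Raises if a class needing synthesis has too few
    members for the requested neighborhood.
    """
    rng = np.random.default_rng(cfg.seed)
    by_class: dict[int, list[Epoch]] = {}
    for e in epochs:
        by_class.setdefault(int(e.label), []).append(e)
    counts = {c: len(v) for c, v in by_class.items()}
    if cfg.target_counts is None:
        majority = max(counts.values())
        targets = {c: majority for c in counts}
    else:
        targets = {int(c): int(n) for c, n in cfg.target_counts.items()}
        for c, n in targets.items():
            if n < counts.get(c, 0):
                raise ValueError(
                    f"target count {n} for class {c} is below existing {counts.get(c, 0)}"
                )

    out = list(epochs)
    for c, target in sorted(targets.items()):
        members = by_class.get(c, [])
        n_new = target - len(members)
        if n_new <= 0:
            continue
        if len(members) <= cfg.k_neighbors:
            raise ValueError(
                f"class {StageLabel(c).name} has {len(members)} samples, too few for "
                f"k_neighbors={cfg.k_neighbors}; reduce k"
            )
        x = np.stack([e.samples for e in members])
        # k+1 because each point's nearest neighbor is itself
        nn = NearestNeighbors(n_neighbors=cfg.k_neighbors + 1).fit(x)
        _, idx = nn.kneighbors(x)
        base = rng.integers(0, len(members), size=n_new)
        pick = rng.integers(1, cfg.k_neighbors + 1, size=n_new)
        u = rng.uniform(0.0, 1.0, size=n_new)
        for b, p, w in zip(base, pick, u):
            neighbor = idx[b, p]
            sample = x[b] + w * (x[neighbor] - x[b])
            proto = members[b]
            out.append(
                Epoch(sample, StageLabel(c), proto.recording_id, proto.index,
                      synthetic=True)
            )
    return out


def duplicate_epochs(epochs: list[Epoch], cfg: OversampleConfig) -> list[Epoch]:
    """Naive alternative balancer: duplicate random minority epochs."""
    rng = np.random.default_rng(cfg.seed)
    by_class: dict[int, list[Epoch]] = {}
    for e in epochs:
        by_class.setdefault(int(e.label), []).append(e)
    majority = max(len(v) for v in by_class.values())
    targets = cfg.target_counts or {c: majority for c in by_class}
    out = list(epochs)
    for c, target in sorted(targets.items()):
        members = by_class.get(c, [])
        for b in rng.integers(0, len(members), size=max(0, target - len(members))):
            proto = members[b]
            out.append(Epoch(proto.samples.copy(), proto.label, proto.recording_id,
                             proto.index, synthetic=True))
    return out


BALANCERS = {"none": lambda epochs, cfg: list(epochs),
             "smote": smote_epochs,
             "duplicate": duplicate_epochs}


def class_counts(epochs: list[Epoch], n_classes: int = N_STAGES) -> np.ndarray:
    labels = np.array([int(e.label) for e in epochs], dtype=np.int64)
    return np.bincount(labels, minlength=n_classes)
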