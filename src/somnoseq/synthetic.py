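"""Synthetic single-channel EEG with stage-dependent spectra.

Real overnight EEG is not redistributable alongside this package, so every
downstream component is exercised on a surrogate that keeps the properties
the model actually exploits:

* **Stage-dependent spectral content.** Each stage is a sum of sinusoids in
  its characteristic band — alpha-dominant wake (8–12 Hz), theta N1
  (4–7 Hz), spindle-band N2 (12–14 Hz over theta), high-amplitude slow
  N3 (0.5–2 Hz), and low-amplitude mixed-frequency REM — plus white
  Gaussian noise. Phases and amplitudes are randomized per epoch.
* **Cyclic stage dynamics.** Stages evolve as a first-order Markov chain at
  30-s resolution whose default transition matrix induces NREM→REM cycling
  with realistic dwell times; cycle length is implied by the transition
  probabilities rather than an explicit 90-minute clock.
* **Class imbalance.** The default chain's stationary distribution is
  approximately W:N1:N2:N3:REM = 8 : 2.8 : 18.3 : 5.5 : 8.3, mimicking the
  strong skew of scored Sleep-EDF nights (N2 dominant, N1 rare).

Generation is deterministic under a fixed seed, and the output bundle is
byte-identical across reruns and interchangeable with the preparation
pipeline's output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_prep import (
    Epoch,
    EPOCH_SECONDS,
    HypnogramAnnotation,
    PreparedDataset,
    PreparedRecording,
    RawRecording,
    normalize_epoch,
)
from .stages import StageLabel

#: (center frequency Hz, amplitude µV-scale) components per stage.
DEFAULT_STAGE_SPECTRA: dict[StageLabel, list[tuple[float, float]]] = {
    StageLabel.W: [(10.0, 1.0), (11.5, 0.6)],
    StageLabel.N1: [(5.5, 0.8), (7.0, 0.5)],
    StageLabel.N2: [(13.0, 0.9), (5.0, 0.5)],
    StageLabel.N3: [(1.0, 2.0), (1.8, 1.2)],
    StageLabel.REM: [(6.0, 0.5), (9.0, 0.5), (4.5, 0.4)],
}

#: Default 30-s-resolution stage transition matrix (rows: from W, N1, N2,
#: N3, REM). Self-loops set dwell times; the off-diagonal structure follows
#: the W → N1 → N2 → N3 → N2 → REM cycle. Stationary distribution
#: ≈ (0.186, 0.066, 0.426, 0.128, 0.194).
DEFAULT_TRANSITIONS = np.array(
    [
        [0.905, 0.075, 0.005, 0.000, 0.015],
        [0.050, 0.550, 0.380, 0.000, 0.020],
        [0.012, 0.022, 0.876, 0.048, 0.042],
        [0.000, 0.000, 0.150, 0.840, 0.010],
        [0.048, 0.032, 0.040, 0.000, 0.880],
    ]
)

DEFAULT_STAGE_PRIOR = np.array([1.0, 0.0, 0.0, 0.0, 0.0])  # nights start awake

#: Inverse of the R&K token mapping, for writing hypnogram fixtures.
_STAGE_TO_RAW = {
    StageLabel.W: "W",
    StageLabel.N1: "1",
    StageLabel.N2: "2",
    StageLabel.N3: "3",
    StageLabel.REM: "R",
}


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic-EEG generator; defaults define the standard
    test conditions used throughout the suite."""

    sampling_rate: float = 100.0
    stage_spectra: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_STAGE_SPECTRA.items()}
    )
    transition_matrix: np.ndarray = field(
        default_factory=lambda: DEFAULT_TRANSITIONS.copy()
    )
    stage_prior: np.ndarray = field(default_factory=lambda: DEFAULT_STAGE_PRIOR.copy())
    noise_sd: float = 0.5
    amplitude_jitter: float = 0.2  # per-component uniform ±20% amplitude scatter
    n_recordings: int = 4
    epochs_per_recording: int = 240
    seed: int = 0

    def __post_init__(self) -> None:
        self.transition_matrix = np.asarray(self.transition_matrix, dtype=np.float64)
        self.stage_prior = np.asarray(self.stage_prior, dtype=np.float64)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        _check_stochastic(self.transition_matrix)
        if abs(self.stage_prior.sum() - 1.0) > 1e-9 or (self.stage_prior < 0).any():
            raise ValueError("stage_prior must be a probability vector")


def _check_stochastic(matrix: np.ndarray) -> None:
    if matrix.shape != (len(StageLabel), len(StageLabel)):
        raise ValueError("transition matrix must be 5x5")
    if (matrix < 0).any() or np.abs(matrix.sum(axis=1) - 1.0).max() > 1e-9:
        raise ValueError("transition matrix rows must be non-negative and sum to 1")


def sample_stage_sequence(
    cfg: SyntheticConfig, n: int, rng: np.random.Generator
) -> list[StageLabel]:
    """Draw a length-``n`` stage sequence from the configured Markov chain."""
    if n < 1:
        raise ValueError("n must be >= 1")
    _check_stochastic(cfg.transition_matrix)
    states = np.empty(n, dtype=np.int64)
    states[0] = rng.choice(len(StageLabel), p=cfg.stage_prior)
    for t in range(1, n):
        states[t] = rng.choice(len(StageLabel), p=cfg.transition_matrix[states[t - 1]])
    return [StageLabel(int(s)) for s in states]


def _epoch_wave(
    stage: StageLabel, cfg: SyntheticConfig, rng: np.random.Generator
) -> np.ndarray:
    n = int(cfg.sampling_rate * EPOCH_SECONDS)
    t = np.arange(n) / cfg.sampling_rate
    x = np.zeros(n)
    for freq, amp in cfg.stage_spectra[stage]:
        phase = rng.uniform(0.0, 2.0 * np.pi)
        jitter = 1.0 + cfg.amplitude_jitter * rng.uniform(-1.0, 1.0)
        x += amp * jitter * np.sin(2.0 * np.pi * freq * t + phase)
    if cfg.noise_sd > 0:
        x += rng.normal(0.0, cfg.noise_sd, size=n)
    return x


def synth_epoch(
    stage: StageLabel, cfg: SyntheticConfig, rng: np.random.Generator
) -> Epoch:
    """One un-normalized 30-s epoch of stage-typical synthetic EEG."""
    return Epoch(
        samples=_epoch_wave(stage, cfg, rng),
        label=stage,
        recording_id="synth",
        index=0,
    )


def synth_raw_recording(
    cfg: SyntheticConfig,
    rng: np.random.Generator,
    n_epochs: int,
    recording_id: str = "synth-000",
    subject_id: str = "",
) -> tuple[RawRecording, list[HypnogramAnnotation]]:
    """A continuous synthetic recording plus its hypnogram annotations.

    Consecutive same-stage epochs merge into one annotation span, matching
    how Sleep-EDF hypnograms are stored. Useful for end-to-end tests of the
    EDF/annotation ingestion path.
    """
    labels = sample_stage_sequence(cfg, n_epochs, rng)
    signal = np.concatenate([_epoch_wave(s, cfg, rng) for s in labels])
    annotations: list[HypnogramAnnotation] = []
    run_start = 0
    for i in range(1, n_epochs + 1):
        if i == n_epochs or labels[i] != labels[run_start]:
            raw = _STAGE_TO_RAW[labels[run_start]]
            annotations.append(
                HypnogramAnnotation(
                    onset_s=run_start * EPOCH_SECONDS,
                    duration_s=(i - run_start) * EPOCH_SECONDS,
                    raw_label=raw,
                )
            )
            run_start = i
    rec = RawRecording(
        samples=signal,
        sampling_rate=cfg.sampling_rate,
        channel_name="EEG synth",
        recording_id=recording_id,
        subject_id=subject_id or recording_id,
    )
    return rec, annotations


def generate_dataset(cfg: SyntheticConfig) -> PreparedDataset:
    """Generate the full labeled dataset as a prepared bundle in memory.

    Epochs are normalized exactly as the preparation pipeline normalizes
    real data, so the result is interchangeable with its output.
    """
    rng = np.random.default_rng(cfg.seed)
    recordings = []
    for r in range(cfg.n_recordings):
        rid = f"synth-{r:03d}"
        labels = sample_stage_sequence(cfg, cfg.epochs_per_recording, rng)
        epochs = []
        for i, stage in enumerate(labels):
            e = Epoch(_epoch_wave(stage, cfg, rng), stage, rid, i)
            epochs.append(normalize_epoch(e))
        recordings.append(
            PreparedRecording(
                recording_id=rid,
                subject_id=rid,
                epochs=np.stack([e.samples for e in epochs]).astype(np.float32),
                labels=np.array([int(s) for s in labels], dtype=np.int64),
                indices=np.arange(cfg.epochs_per_recording, dtype=np.int64),
                synthetic=np.zeros(cfg.epochs_per_recording, dtype=bool),
            )
        )
    meta = {
        "source": "synthetic",
        "seed": cfg.seed,
        "n_recordings": cfg.n_recordings,
        "epochs_per_recording": cfg.epochs_per_recording,
        "noise_sd": cfg.noise_sd,
    }
    return PreparedDataset(recordings=recordings, meta=meta)


def export_edf(
    cfg: SyntheticConfig, out_dir, n_epochs: int | None = None
) -> list[tuple[Path, Path]]:
    """Write synthetic recordings as EDF + EDF+ hypnogram file pairs."""
    from .edfwrite import write_edf, write_edf_annotations

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(cfg.seed)
    pairs = []
    for r in range(cfg.n_recordings):
        rid = f"synth-{r:03d}"
        rec, anns = synth_raw_recording(
            cfg, rng, n_epochs or cfg.epochs_per_recording, recording_id=rid
        )
        psg = write_edf(
            out_dir / f"{rid}-PSG.edf", {rec.channel_name: rec.samples},
            cfg.sampling_rate,
        )
        hyp = write_edf_annotations(
            out_dir / f"{rid}-Hypnogram.edf",
            [(a.onset_s, a.duration_s, f"Sleep stage {a.raw_label}") for a in anns],
        )
        pairs.append((psg, hyp))
    return pairs
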