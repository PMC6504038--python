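"""From raw single-channel EEG to labeled, normalized 30-s epochs.

The preparation pipeline mirrors standard sleep-scoring practice on the
Sleep-EDF corpus: cut the continuous signal into 30-second scoring epochs,
attach the hypnogram label of the covering annotation span, merge R&K
stages 3/4 into N3, drop movement-time and unscored epochs, and standardize
each epoch to zero mean and unit variance. No filtering or artifact
rejection is applied — the model consumes raw epochs.

Prepared data is stored as a *bundle*: a directory with one ``.npz`` per
recording (epochs, labels, epoch indices, synthetic-provenance flags) and a
``manifest.json`` recording counts and metadata. The synthetic generator
writes the same format, so everything downstream is source-agnostic.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .stages import EXCLUDED, SOD, EOD, StageLabel, map_label

logger = logging.getLogger(__name__)

EPOCH_SECONDS = 30
SLEEP_EDF_RATE = 100.0
EPOCH_SAMPLES = int(EPOCH_SECONDS * SLEEP_EDF_RATE)

BUNDLE_FORMAT_VERSION = 1


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class RawRecording:
    """A full-night single-channel EEG trace.

    ``samples`` are amplitudes in µV at ``sampling_rate`` Hz (100 Hz for
    Sleep-EDF). ``subject_id`` groups the (typically two) recordings of one
    subject for subject-wise cross-validation.
    """

    samples: np.ndarray
    sampling_rate: float
    channel_name: str
    recording_id: str
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.samples.size == 0:
            raise ValueError("recording has no samples")
        if not self.subject_id:
            self.subject_id = self.recording_id


@dataclass
class HypnogramAnnotation:
    """One scored span of the hypnogram: onset/duration in seconds plus the
    raw R&K token (W, 1, 2, 3, 4, R, M or ?)."""

    onset_s: float
    duration_s: float
    raw_label: str

    def __post_init__(self) -> None:
        if self.onset_s < 0:
            raise ValueError("annotation onset must be >= 0")
        if self.duration_s <= 0:
            raise ValueError("annotation duration must be positive")
        map_label(self.raw_label)  # fail fast on unknown tokens


@dataclass
class Epoch:
    """One 30-s scoring epoch: 3000 samples, its stage, and provenance."""

    samples: np.ndarray
    label: StageLabel
    recording_id: str
    index: int
    synthetic: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)


@dataclass
class EpochSequence:
    """A contiguous run of ``maxtime`` epochs from one recording, with the
    shifted decoder target tracks.

    ``target_in`` starts with the SOD token and feeds the decoder during
    teacher forcing; ``target_out`` appends the EOD class after the last
    stage label.
    """

    epochs: list[Epoch]

    @property
    def recording_id(self) -> str:
        return self.epochs[0].recording_id

    @property
    def labels(self) -> list[StageLabel]:
        return [e.label for e in self.epochs]

    @property
    def target_in(self) -> list[int]:
        return [SOD] + [int(e.label) for e in self.epochs[:-1]]

    @property
    def target_out(self) -> list[int]:
        return [int(e.label) for e in self.epochs] + [EOD]

    @property
    def samples(self) -> np.ndarray:
        """(maxtime, 3000) array of the stacked epoch signals."""
        return np.stack([e.samples for e in self.epochs])

    def __len__(self) -> int:
        return len(self.epochs)


# ---------------------------------------------------------------------------
# ingestion
# ---------------------------------------------------------------------------


def read_recording(path, channel: str, subject_id: str = "") -> RawRecording:
    """Read one channel of an EDF/EDF+ file as a :class:`RawRecording`.

    Amplitudes are returned in µV at the file's true sampling rate. The
    recording id defaults to the file stem.
    """
    import mne

    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        raw = mne.io.read_raw_edf(path, preload=False, verbose="error")
    if channel not in raw.ch_names:
        raise ValueError(
            f"channel {channel!r} not in {path.name}; available: {raw.ch_names}"
        )
    raw = raw.pick([channel])
    raw.load_data(verbose="error")
    data = raw.get_data()[0] * 1e6  # mne loads EEG in volts
    return RawRecording(
        samples=data,
        sampling_rate=float(raw.info["sfreq"]),
        channel_name=channel,
        recording_id=path.stem,
        subject_id=subject_id,
    )


def read_hypnogram(path) -> list[HypnogramAnnotation]:
    """Read hypnogram annotations from EDF+ or a plain TSV table.

    TSV fixtures have a header line ``onset_s<TAB>duration_s<TAB>label``.
    EDF+ files use the Sleep-EDF dialect (descriptions ``"Sleep stage W"``
    etc.). Annotations are returned sorted by onset.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in {".tsv", ".txt"}:
        anns = _read_hypnogram_tsv(path)
    else:
        anns = _read_hypnogram_edf(path)
    anns.sort(key=lambda a: a.onset_s)
    for prev, nxt in zip(anns, anns[1:]):
        if nxt.onset_s < prev.onset_s + prev.duration_s - 1e-9:
            raise ValueError(
                f"overlapping annotations at onset {nxt.onset_s} in {path.name}"
            )
    return anns


def _read_hypnogram_tsv(path: Path) -> list[HypnogramAnnotation]:
    anns = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header[:3] != ["onset_s", "duration_s", "label"]:
            raise ValueError(f"unexpected hypnogram TSV header in {path.name}: {header}")
        for line in fh:
            if not line.strip():
                continue
            onset, duration, label = line.rstrip("\n").split("\t")[:3]
            anns.append(HypnogramAnnotation(float(onset), float(duration), label))
    return anns


def _read_hypnogram_edf(path: Path) -> list[HypnogramAnnotation]:
    import mne

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        ann = mne.read_annotations(str(path))
    out = []
    for onset, duration, desc in zip(ann.onset, ann.duration, ann.description):
        if duration <= 0:
            continue
        out.append(HypnogramAnnotation(float(onset), float(duration), desc))
    return out


# ---------------------------------------------------------------------------
# segmentation and normalization
# ---------------------------------------------------------------------------


def segment_epochs(
    rec: RawRecording, annotations: list[HypnogramAnnotation]
) -> list[Epoch]:
    """Cut a recording into labeled 30-s epochs.

    Epoch ``i`` covers samples ``[3000·i, 3000·(i+1))`` of the recording
    (half-open, 0-based); the epoch index is that position, so excluded
    spans leave gaps in the retained indices. Movement/unscored spans and a
    trailing partial epoch are dropped; annotation spans running past the
    end of the signal are truncated with a warning.
    """
    if rec.sampling_rate != SLEEP_EDF_RATE:
        raise ValueError(
            f"expected {SLEEP_EDF_RATE:g} Hz input, got {rec.sampling_rate:g} Hz "
            "(resampling is out of scope)"
        )
    samples_per_epoch = int(rec.sampling_rate * EPOCH_SECONDS)
    epochs: list[Epoch] = []
    for ann in sorted(annotations, key=lambda a: a.onset_s):
        stage = map_label(ann.raw_label)
        n_ep = int(ann.duration_s // EPOCH_SECONDS)
        for j in range(n_ep):
            start = int(round((ann.onset_s + j * EPOCH_SECONDS) * rec.sampling_rate))
            stop = start + samples_per_epoch
            if stop > rec.samples.size:
                logger.warning(
                    "annotation span exceeds signal end in %s; truncating",
                    rec.recording_id,
                )
                break
            if stage is EXCLUDED:
                continue
            epochs.append(
                Epoch(
                    samples=rec.samples[start:stop],
                    label=stage,
                    recording_id=rec.recording_id,
                    index=start // samples_per_epoch,
                )
            )
    return epochs


def normalize_epoch(e: Epoch) -> Epoch:
    """Standardize an epoch to zero mean and unit variance.

    Idempotent and invariant to affine rescaling of the input. A constant
    epoch has no scale to normalize and raises instead of emitting NaNs.
    """
    sd = float(e.samples.std())
    if sd < 1e-12:
        raise ValueError(
            f"epoch {e.recording_id}[{e.index}] has zero variance; cannot normalize"
        )
    z = (e.samples - e.samples.mean()) / sd
    return Epoch(z, e.label, e.recording_id, e.index, e.synthetic)


def trim_wake(epochs: list[Epoch], minutes: float) -> list[Epoch]:
    """Keep at most ``minutes`` of wake on each side of the sleep period.

    Whole-night recordings open and close with hours of wake; trimming
    them rebalances the epoch pool toward the sleep period. Disabled by
    default in the pipeline.
    """
    keep_n = int(minutes * 60 // EPOCH_SECONDS)
    non_wake = [i for i, e in enumerate(epochs) if e.label != StageLabel.W]
    if not non_wake:
        return list(epochs)
    lo = max(0, non_wake[0] - keep_n)
    hi = min(len(epochs), non_wake[-1] + 1 + keep_n)
    return epochs[lo:hi]


def assemble_sequences(epochs: list[Epoch], maxtime: int) -> list[EpochSequence]:
    """Chunk retained epochs into non-overlapping model-input sequences.

    Epochs are grouped per recording in order; each run of consecutive
    retained epochs becomes ``floor(run/maxtime)`` windows and the
    remainder is dropped, so every training target is a real epoch.
    """
    if maxtime < 1:
        raise ValueError("maxtime must be >= 1")
    sequences: list[EpochSequence] = []
    by_rec: dict[str, list[Epoch]] = {}
    for e in epochs:
        by_rec.setdefault(e.recording_id, []).append(e)
    for rec_epochs in by_rec.values():
        for start in range(0, len(rec_epochs) - maxtime + 1, maxtime):
            sequences.append(EpochSequence(rec_epochs[start : start + maxtime]))
    return sequences


# ---------------------------------------------------------------------------
# prepared bundles
# ---------------------------------------------------------------------------


@dataclass
class PreparedRecording:
    """One recording's worth of prepared (normalized) epochs."""

    recording_id: str
    subject_id: str
    epochs: np.ndarray  # (n, 3000)
    labels: np.ndarray  # (n,) int
    indices: np.ndarray  # (n,) epoch position within the recording
    synthetic: np.ndarray = field(default=None)  # (n,) bool provenance flags

    def __post_init__(self) -> None:
        if self.synthetic is None:
            self.synthetic = np.zeros(len(self.labels), dtype=bool)

    def to_epochs(self) -> list[Epoch]:
        return [
            Epoch(self.epochs[i], StageLabel(int(self.labels[i])),
                  self.recording_id, int(self.indices[i]), bool(self.synthetic[i]))
            for i in range(len(self.labels))
        ]


@dataclass
class PreparedDataset:
    """A loaded bundle: prepared recordings plus manifest metadata."""

    recordings: list[PreparedRecording]
    meta: dict = field(default_factory=dict)

    def class_counts(self) -> np.ndarray:
        counts = np.zeros(len(StageLabel), dtype=np.int64)
        for rec in self.recordings:
            counts += np.bincount(rec.labels, minlength=len(StageLabel))
        return counts

    @property
    def n_epochs(self) -> int:
        return sum(len(r.labels) for r in self.recordings)

    def subject_ids(self) -> list[str]:
        return sorted({r.subject_id for r in self.recordings})


def records_from_epochs(
    epochs: list[Epoch], subject_of: dict[str, str] | None = None
) -> list[PreparedRecording]:
    """Pack per-epoch objects into array-backed per-recording records."""
    by_rec: dict[str, list[Epoch]] = {}
    for e in epochs:
        by_rec.setdefault(e.recording_id, []).append(e)
    records = []
    for rid, eps in by_rec.items():
        records.append(
            PreparedRecording(
                recording_id=rid,
                subject_id=(subject_of or {}).get(rid, rid),
                epochs=np.stack([e.samples for e in eps]).astype(np.float32),
                labels=np.array([int(e.label) for e in eps], dtype=np.int64),
                indices=np.array([e.index for e in eps], dtype=np.int64),
                synthetic=np.array([e.synthetic for e in eps], dtype=bool),
            )
        )
    return records


def save_bundle(path, dataset: PreparedDataset) -> Path:
    """Write a prepared dataset as a bundle directory; returns the path."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in dataset.recordings:
        fname = f"rec_{rec.recording_id}.npz"
        np.savez(
            path / fname,
            epochs=rec.epochs.astype(np.float32),
            labels=rec.labels.astype(np.int64),
            indices=rec.indices.astype(np.int64),
            synthetic=rec.synthetic.astype(bool),
        )
        entries.append(
            {
                "recording_id": rec.recording_id,
                "subject_id": rec.subject_id,
                "file": fname,
                "n_epochs": int(len(rec.labels)),
                "class_counts": np.bincount(
                    rec.labels, minlength=len(StageLabel)
                ).tolist(),
            }
        )
    manifest = {
        "format_version": BUNDLE_FORMAT_VERSION,
        "class_names": [s.name for s in StageLabel],
        "class_counts": dataset.class_counts().tolist(),
        "n_epochs": dataset.n_epochs,
        "recordings": entries,
        "meta": dataset.meta,
    }
    with open(path / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return path


def load_bundle(path) -> PreparedDataset:
    """Load a bundle directory written by :func:`save_bundle`."""
    path = Path(path)
    with open(path / "manifest.json") as fh:
        manifest = json.load(fh)
    recordings = []
    for entry in manifest["recordings"]:
        with np.load(path / entry["file"]) as z:
            recordings.append(
                PreparedRecording(
                    recording_id=entry["recording_id"],
                    subject_id=entry["subject_id"],
                    epochs=z["epochs"].astype(np.float64),
                    labels=z["labels"],
                    indices=z["indices"],
                    synthetic=z["synthetic"],
                )
            )
    return PreparedDataset(recordings=recordings, meta=manifest.get("meta", {}))


def prepare_recording(
    rec: RawRecording,
    annotations: list[HypnogramAnnotation],
    trim_wake_minutes: float | None = None,
) -> PreparedRecording:
    """Segment, optionally wake-trim, and normalize one recording."""
    epochs = segment_epochs(rec, annotations)
    if trim_wake_minutes is not None:
        epochs = trim_wake(epochs, trim_wake_minutes)
    epochs = [normalize_epoch(e) for e in epochs]
    records = records_from_epochs(epochs, {rec.recording_id: rec.subject_id})
    if not records:
        return PreparedRecording(
            rec.recording_id, rec.subject_id,
            np.zeros((0, EPOCH_SAMPLES), dtype=np.float32),
            np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64),
        )
    return records[0]
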