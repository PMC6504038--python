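"""Segmentation, label mapping, normalization, and sequence assembly."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from somnoseq.data_prep import (
    Epoch,
    EPOCH_SAMPLES,
    HypnogramAnnotation,
    PreparedDataset,
    RawRecording,
    assemble_sequences,
    load_bundle,
    normalize_epoch,
    read_hypnogram,
    read_recording,
    records_from_epochs,
    save_bundle,
    segment_epochs,
)
from somnoseq.stages import EXCLUDED, EOD, SOD, StageLabel, map_label


def _recording(n_samples, rid="rec0"):
    rng = np.random.default_rng(0)
    return RawRecording(rng.standard_normal(n_samples), 100.0, "EEG Fpz-Cz", rid)


def _ann(onset, duration, label):
    return HypnogramAnnotation(onset, duration, label)


class TestMapLabel:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("W", StageLabel.W),
            ("1", StageLabel.N1),
            ("2", StageLabel.N2),
            ("3", StageLabel.N3),
            ("4", StageLabel.N3),  # R&K stages 3 and 4 merge into N3
            ("R", StageLabel.REM),
            ("M", EXCLUDED),
            ("?", EXCLUDED),
            ("Sleep stage W", StageLabel.W),
            ("Sleep stage 4", StageLabel.N3),
        ],
    )
    def test_mapping(self, raw, expected):
        assert map_label(raw) is expected

    def test_unknown_token_raises(self):
        with pytest.raises(ValueError, match="XYZ"):
            map_label("XYZ")


class TestSegmentEpochs:
    def test_whole_annotation_splits_into_epochs(self):
        rec = _recording(9000)
        epochs = segment_epochs(rec, [_ann(0, 90, "W")])
        assert [e.label for e in epochs] == [StageLabel.W] * 3
        assert [e.index for e in epochs] == [0, 1, 2]

    def test_trailing_partial_epoch_dropped(self):
        rec = _recording(9100)
        epochs = segment_epochs(rec, [_ann(0, 120, "W")])
        assert len(epochs) == 3  # 100-sample tail cannot form an epoch

    def test_excluded_span_leaves_index_gap(self):
        rec = _recording(12000)
        anns = [_ann(0, 60, "W"), _ann(60, 30, "M"), _ann(90, 30, "2")]
        epochs = segment_epochs(rec, anns)
        assert [e.label for e in epochs] == [StageLabel.W, StageLabel.W, StageLabel.N2]
        assert [e.index for e in epochs] == [0, 1, 3]

    def test_epoch_windows_are_half_open_tiles(self):
        rec = _recording(9000)
        epochs = segment_epochs(rec, [_ann(0, 90, "2")])
        for e in epochs:
            start = e.index * EPOCH_SAMPLES
            np.testing.assert_array_equal(
                e.samples, rec.samples[start : start + EPOCH_SAMPLES]
            )

    def test_non_100hz_input_rejected(self):
        rec = RawRecording(np.ones(6000), 200.0, "EEG", "r")
        with pytest.raises(ValueError, match="100"):
            segment_epochs(rec, [_ann(0, 30, "W")])


class TestNormalizeEpoch:
    def test_sine_with_offset_standardized(self):
        t = np.arange(EPOCH_SAMPLES) / 100
        e = Epoch(2 * np.sin(2 * np.pi * t) + 5, StageLabel.W, "r", 0)
        z = normalize_epoch(e)
        assert abs(z.samples.mean()) < 1e-6
        assert abs(z.samples.var() - 1) < 1e-6

    def test_zero_variance_raises(self):
        e = Epoch(np.full(EPOCH_SAMPLES, 3.0), StageLabel.W, "r", 0)
        with pytest.raises(ValueError, match="variance"):
            normalize_epoch(e)

    @settings(max_examples=20, deadline=None)
    @given(
        scale=st.floats(0.01, 100.0),
        offset=st.floats(-50.0, 50.0),
        seed=st.integers(0, 2**16),
    )
    def test_idempotent_and_affine_invariant(self, scale, offset, seed):
        x = np.random.default_rng(seed).standard_normal(EPOCH_SAMPLES)
        base = normalize_epoch(Epoch(x, StageLabel.N2, "r", 0))
        again = normalize_epoch(base)
        np.testing.assert_allclose(again.samples, base.samples, atol=1e-9)
        scaled = normalize_epoch(Epoch(scale * x + offset, StageLabel.N2, "r", 0))
        np.testing.assert_allclose(scaled.samples, base.samples, atol=1e-6)


class TestAssembleSequences:
    def _epochs(self, labels, rid="r"):
        rng = np.random.default_rng(0)
        return [
            Epoch(rng.standard_normal(EPOCH_SAMPLES), lab, rid, i)
            for i, lab in enumerate(labels)
        ]

    def test_remainder_dropped(self):
        seqs = assemble_sequences(self._epochs([StageLabel.W] * 25), maxtime=10)
        assert len(seqs) == 2 and all(len(s) == 10 for s in seqs)

    def test_maxtime_one_gives_singletons(self):
        seqs = assemble_sequences(self._epochs([StageLabel.W] * 4), maxtime=1)
        assert len(seqs) == 4

    def test_shifted_target_protocol(self):
        labels = [StageLabel.W, StageLabel.N1, StageLabel.N2]
        (seq,) = assemble_sequences(self._epochs(labels), maxtime=3)
        assert seq.target_in == [SOD, int(StageLabel.W), int(StageLabel.N1)]
        assert seq.target_out == [
            int(StageLabel.W), int(StageLabel.N1), int(StageLabel.N2), EOD,
        ]

    def test_flattening_recovers_retained_order(self):
        labels = [StageLabel(i % 5) for i in range(23)]
        epochs = self._epochs(labels)
        seqs = assemble_sequences(epochs, maxtime=5)
        flat = [e for s in seqs for e in s.epochs]
        assert flat == epochs[:20]

    def test_recordings_not_mixed(self):
        epochs = self._epochs([StageLabel.W] * 5, "a") + self._epochs(
            [StageLabel.N2] * 5, "b"
        )
        seqs = assemble_sequences(epochs, maxtime=5)
        assert {s.recording_id for s in seqs} == {"a", "b"}

    def test_bad_maxtime_rejected(self):
        with pytest.raises(ValueError):
            assemble_sequences(self._epochs([StageLabel.W]), maxtime=0)


class TestHypnogramIO:
    def test_tsv_round_trip_all_tokens(self, tmp_path):
        rows = [(i * 30.0, 30.0, tok) for i, tok in enumerate("W 1 2 3 4 R M ?".split())]
        p = tmp_path / "hyp.tsv"
        p.write_text(
            "onset_s\tduration_s\tlabel\n"
            + "".join(f"{o}\t{d}\t{l}\n" for o, d, l in rows)
        )
        anns = read_hypnogram(p)
        assert [a.raw_label for a in anns] == "W 1 2 3 4 R M ?".split()

    def test_out_of_order_sorted(self, tmp_path):
        p = tmp_path / "hyp.tsv"
        p.write_text(
            "onset_s\tduration_s\tlabel\n60\t30\t2\n0\t60\tW\n"
        )
        anns = read_hypnogram(p)
        assert [a.onset_s for a in anns] == [0.0, 60.0]

    def test_unknown_token_named_in_error(self, tmp_path):
        p = tmp_path / "hyp.tsv"
        p.write_text("onset_s\tduration_s\tlabel\n0\t30\tZZ\n")
        with pytest.raises(ValueError, match="ZZ"):
            read_hypnogram(p)

    def test_single_long_annotation(self, tmp_path):
        p = tmp_path / "hyp.tsv"
        p.write_text("onset_s\tduration_s\tlabel\n0\t60\tW\n")
        (ann,) = read_hypnogram(p)
        assert ann.duration_s == 60.0


class TestEdfRoundTrip:
    def test_signal_survives_quantization(self, tmp_path):
        from somnoseq.edfwrite import write_edf

        rng = np.random.default_rng(5)
        x = rng.standard_normal(6000) * 20  # 60 s at 100 Hz
        path = write_edf(tmp_path / "a.edf", {"EEG Fpz-Cz": x}, 100.0)
        rec = read_recording(path, "EEG Fpz-Cz")
        assert rec.samples.size == 6000
        assert rec.channel_name == "EEG Fpz-Cz"
        assert rec.sampling_rate == 100.0
        # 16-bit quantization over the observed range
        step = (x.max() - x.min()) / 65535
        np.testing.assert_allclose(rec.samples, x, atol=2 * step)

    def test_missing_channel_lists_available(self, tmp_path):
        from somnoseq.edfwrite import write_edf

        path = write_edf(tmp_path / "a.edf", {"EEG Pz-Oz": np.ones(600)}, 100.0)
        with pytest.raises(ValueError, match="Pz-Oz"):
            read_recording(path, "EEG Fpz-Cz")

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_recording(tmp_path / "nope.edf", "EEG")

    def test_edfplus_hypnogram_read(self, tmp_path):
        from somnoseq.edfwrite import write_edf_annotations

        path = write_edf_annotations(
            tmp_path / "hyp.edf",
            [(0, 60, "Sleep stage W"), (60, 30, "Sleep stage 2")],
        )
        anns = read_hypnogram(path)
        assert len(anns) == 2
        assert anns[0].duration_s == 60.0
        assert map_label(anns[1].raw_label) is StageLabel.N2


class TestBundleRoundTrip:
    def test_save_load_identity(self, tmp_path, small_dataset):
        save_bundle(tmp_path / "b", small_dataset)
        loaded = load_bundle(tmp_path / "b")
        assert loaded.n_epochs == small_dataset.n_epochs
        np.testing.assert_array_equal(
            loaded.class_counts(), small_dataset.class_counts()
        )
        a = small_dataset.recordings[0]
        b = next(r for r in loaded.recordings if r.recording_id == a.recording_id)
        np.testing.assert_allclose(a.epochs, b.epochs, atol=1e-6)
        np.testing.assert_array_equal(a.labels, b.labels)

    def test_records_from_epochs_groups_by_recording(self):
        rng = np.random.default_rng(0)
        epochs = [
            Epoch(rng.standard_normal(EPOCH_SAMPLES), StageLabel.W, rid, i)
            for rid in ("a", "b")
            for i in range(3)
        ]
        records = records_from_epochs(epochs)
        assert sorted(r.recording_id for r in records) == ["a", "b"]
        assert all(len(r.labels) == 3 for r in records)
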