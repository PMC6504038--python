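"""Network components against hand-computed and brute-force oracles."""

import numpy as np
import pytest

from somnoseq import autodiff as ad
from somnoseq.autodiff import Tensor
from somnoseq.data_prep import EPOCH_SAMPLES, Epoch, EpochSequence
from somnoseq.losses import l2_penalty
from somnoseq.model import (
    CnnBranchConfig,
    CnnConfig,
    ModelConfig,
    SleepStager,
)
from somnoseq.stages import StageLabel
from somnoseq.training import TrainConfig, _batch_arrays, sequence_loss

from conftest import tiny_model_config


def _sequence(labels, seed=0, rid="r"):
    rng = np.random.default_rng(seed)
    return EpochSequence(
        [Epoch(rng.standard_normal(EPOCH_SAMPLES), lab, rid, i)
         for i, lab in enumerate(labels)]
    )


class TestCnnExtract:
    def test_output_dim_independent_of_values(self, tiny_model, rng):
        a = tiny_model.cnn_extract(rng.standard_normal((2, EPOCH_SAMPLES)))
        b = tiny_model.cnn_extract(np.ones((2, EPOCH_SAMPLES)))
        assert a.shape == b.shape == (2, tiny_model.feature_dim)

    def test_zero_input_zero_bias_gives_zero_features(self, tiny_model):
        out = tiny_model.cnn_extract(np.zeros((1, EPOCH_SAMPLES)))
        np.testing.assert_allclose(out.data, 0.0)

    def test_single_layer_matches_hand_convolution(self):
        """One valid conv layer, filter [1,0,-1], stride 1 on a ramp must
        equal the brute-force convolution + ReLU."""
        x = np.arange(10, dtype=float)
        w = Tensor(np.array([[[1.0, 0.0, -1.0]]]))
        b = Tensor(np.zeros(1))
        out = ad.relu(ad.conv1d(Tensor(x.reshape(1, 1, 10)), w, b, stride=1))
        expected = np.array(
            [max(x[i] - x[i + 2], 0.0) for i in range(8)]
        )
        np.testing.assert_allclose(out.data[0, 0], expected)

    def test_bad_geometry_rejected_at_construction(self):
        bad = CnnBranchConfig(filters=(2900, 8, 8, 8), strides=(1, 1, 1, 1),
                              channels=(2, 2, 2, 2), pool_size=200,
                              padding="valid")
        with pytest.raises(ValueError):
            bad.output_length()

    def test_eval_mode_deterministic_despite_dropout(self):
        cfg = tiny_model_config()
        cfg.cnn.dropout = 0.5
        model = SleepStager(cfg)
        x = np.random.default_rng(0).standard_normal((2, EPOCH_SAMPLES))
        a = model.cnn_extract(x, train=False).data
        b = model.cnn_extract(x, train=False).data
        np.testing.assert_array_equal(a, b)


class TestEncoder:
    def test_zero_parameters_give_zero_states(self, tiny_model):
        for name, t in tiny_model.params.items():
            if name.startswith("enc."):
                t.data[:] = 0.0
        feats = [Tensor(np.ones((2, tiny_model.feature_dim))) for _ in range(3)]
        states = tiny_model.encode(feats)
        for s in states:
            np.testing.assert_allclose(s.data, 0.0)

    def test_single_step_sequence_well_defined(self, tiny_model):
        feats = [Tensor(np.random.default_rng(0).standard_normal(
            (1, tiny_model.feature_dim)))]
        (state,) = tiny_model.encode(feats)
        assert state.shape == (1, tiny_model.enc_out_dim)
        assert np.isfinite(state.data).all()

    def test_output_length_equals_input_length(self, tiny_model, rng):
        feats = [Tensor(rng.standard_normal((2, tiny_model.feature_dim)))
                 for _ in range(5)]
        assert len(tiny_model.encode(feats)) == 5

    def test_simple_cell_matches_hand_unrolled_recurrence(self):
        """T=2, scalar hidden: the bidirectional tanh recurrence and the
        linear combination must equal manual unrolling."""
        cfg = tiny_model_config(cell="simple", encoder_hidden=1)
        model = SleepStager(cfg)
        f = model.feature_dim
        w = 0.02 * np.ones(f)
        p = model.params
        p["enc.fwd.W"].data = w.reshape(f, 1).copy()
        p["enc.fwd.V"].data = np.array([[0.5]])
        p["enc.fwd.b"].data = np.array([0.1])
        p["enc.bwd.W"].data = 2 * w.reshape(f, 1)
        p["enc.bwd.V"].data = np.array([[-0.3]])
        p["enc.bwd.b"].data = np.array([-0.2])
        p["enc.U"].data = np.array([[1.0, 2.0], [3.0, -1.0]])
        p["enc.b_y"].data = np.array([0.05, -0.05])

        x1 = np.full((1, f), 0.3)
        x2 = np.full((1, f), -0.1)
        states = model.encode([Tensor(x1), Tensor(x2)])

        hf1 = np.tanh(x1 @ w.reshape(f, 1) + 0.1)
        hf2 = np.tanh(x2 @ w.reshape(f, 1) + 0.5 * hf1 + 0.1)
        hb2 = np.tanh(x2 @ (2 * w).reshape(f, 1) - 0.2)
        hb1 = np.tanh(x1 @ (2 * w).reshape(f, 1) - 0.3 * hb2 - 0.2)
        y1 = np.concatenate([hf1, hb1], 1) @ p["enc.U"].data + p["enc.b_y"].data
        y2 = np.concatenate([hf2, hb2], 1) @ p["enc.U"].data + p["enc.b_y"].data
        np.testing.assert_allclose(states[0].data, y1, atol=1e-12)
        np.testing.assert_allclose(states[1].data, y2, atol=1e-12)


class TestAttention:
    def test_identical_states_give_uniform_weights(self, tiny_model):
        e = Tensor(np.ones((1, tiny_model.enc_out_dim)))
        h = Tensor(np.zeros((1, tiny_model.config.decoder_hidden)))
        alpha, ctx = tiny_model.attend(h, [e, e, e, e])
        np.testing.assert_allclose(alpha.data, 0.25)
        np.testing.assert_allclose(ctx.data, e.data)

    def test_single_state_gets_all_weight(self, tiny_model, rng):
        e = Tensor(rng.standard_normal((1, tiny_model.enc_out_dim)))
        h = Tensor(rng.standard_normal((1, tiny_model.config.decoder_hidden)))
        alpha, ctx = tiny_model.attend(h, [e])
        np.testing.assert_allclose(alpha.data, 1.0)
        np.testing.assert_allclose(ctx.data, e.data)

    def test_three_scalar_states_match_arithmetic_oracle(self):
        cfg = tiny_model_config(attention_dim=1)
        model = SleepStager(cfg)
        p = model.params
        p["att.W_h"].data = np.full((cfg.decoder_hidden, 1), 0.1)
        p["att.W_e"].data = np.full((model.enc_out_dim, 1), 0.2)
        p["att.v"].data = np.array([[1.5]])
        h = np.full((1, cfg.decoder_hidden), 0.3)
        states = [np.full((1, model.enc_out_dim), v) for v in (0.1, -0.4, 0.7)]
        alpha, ctx = model.attend(Tensor(h), [Tensor(s) for s in states])

        hp = (h @ p["att.W_h"].data)[0, 0]
        scores = np.array(
            [1.5 * np.tanh((s @ p["att.W_e"].data)[0, 0] + hp) for s in states]
        )
        expected = np.exp(scores - scores.max())
        expected /= expected.sum()
        np.testing.assert_allclose(alpha.data[0], expected, atol=1e-12)
        expected_ctx = sum(a * s for a, s in zip(expected, states))
        np.testing.assert_allclose(ctx.data, expected_ctx, atol=1e-12)

    def test_rows_sum_to_one_always(self, tiny_model, rng):
        states = [Tensor(rng.standard_normal((3, tiny_model.enc_out_dim)))
                  for _ in range(6)]
        h = Tensor(rng.standard_normal((3, tiny_model.config.decoder_hidden)))
        alpha, _ = tiny_model.attend(h, states)
        np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-12)
        assert (alpha.data >= 0).all()


class TestDecodeStep:
    def test_probability_simplex_output(self, tiny_model, rng):
        states = [Tensor(rng.standard_normal((2, tiny_model.enc_out_dim)))
                  for _ in range(4)]
        dec_state = tiny_model._decoder_initial_state(states, 2)
        probs, _, alpha = tiny_model.decode_step(
            np.array([5, 2]), dec_state, states
        )
        assert probs.shape == (2, 6)
        assert (probs.data >= 0).all()
        np.testing.assert_allclose(probs.data.sum(axis=1), 1.0, atol=1e-6)
        np.testing.assert_allclose(alpha.data.sum(axis=1), 1.0, atol=1e-6)

    def test_zero_parameters_give_uniform_probabilities(self):
        model = SleepStager(tiny_model_config())
        for t in model.params.values():
            t.data[:] = 0.0
        states = [Tensor(np.zeros((1, model.enc_out_dim))) for _ in range(3)]
        dec_state = model._decoder_initial_state(states, 1)
        probs, _, _ = model.decode_step(np.array([5]), dec_state, states)
        np.testing.assert_allclose(probs.data, 1.0 / 6.0, atol=1e-12)


class TestPredictSequence:
    def test_label_count_and_map_shape(self, tiny_model):
        seq = _sequence([StageLabel.W] * 7)
        labels, amap = tiny_model.predict_sequence(seq)
        assert len(labels) == 7
        assert amap.shape == (7, 7)
        np.testing.assert_allclose(amap.sum(axis=1), 1.0, atol=1e-6)

    def test_greedy_equals_manual_decode_loop(self, tiny_model):
        """Greedy decoding must equal step-by-step manual application of
        decode_step with argmax feedback."""
        seq = _sequence([StageLabel.N2, StageLabel.W, StageLabel.N3], seed=3)
        labels, amap = tiny_model.predict_sequence(seq)

        feats = tiny_model.cnn_extract(seq.samples)
        states = tiny_model.encode([feats[i : i + 1] for i in range(3)])
        dec_state = tiny_model._decoder_initial_state(states, 1)
        prev = np.array([tiny_model.config.n_classes])  # SOD
        manual = []
        for t in range(3):
            probs, dec_state, alpha = tiny_model.decode_step(prev, dec_state, states)
            choice = probs.data[0, :5].argmax()
            manual.append(int(choice))
            np.testing.assert_allclose(amap[t], alpha.data[0], atol=1e-12)
            prev = np.array([choice])
        assert [int(l) for l in labels] == manual

    def test_teacher_forcing_coincides_when_predictions_match(self, small_dataset):
        """If greedy output equals the target track, both decoding modes
        produce the same labels."""
        seq = _sequence([StageLabel.W, StageLabel.W])
        model = SleepStager(tiny_model_config())
        greedy, _ = model.predict_sequence(seq, teacher_forcing=False)
        if [int(l) for l in greedy] == [int(l) for l in seq.labels]:
            forced, _ = model.predict_sequence(seq, teacher_forcing=True)
            assert [int(l) for l in forced[:2]] == [int(l) for l in greedy]

    def test_eval_forward_deterministic(self, tiny_model):
        seq = _sequence([StageLabel.REM] * 4, seed=9)
        a, amap_a = tiny_model.predict_sequence(seq)
        b, amap_b = tiny_model.predict_sequence(seq)
        assert [int(x) for x in a] == [int(x) for x in b]
        np.testing.assert_array_equal(amap_a, amap_b)


class TestCheckpoint:
    def test_save_load_round_trip(self, tiny_model, tmp_path):
        seq = _sequence([StageLabel.N1, StageLabel.N2], seed=5)
        before, _ = tiny_model.predict_sequence(seq)
        path = tiny_model.save(tmp_path / "ckpt.npz")
        loaded = SleepStager.load(path)
        after, _ = loaded.predict_sequence(seq)
        assert [int(x) for x in before] == [int(x) for x in after]
        assert loaded.config.to_dict() == tiny_model.config.to_dict()


class TestFullLossGradient:
    def test_numerical_gradient_of_full_objective(self):
        """Analytic gradients of the complete teacher-forced loss (MFE +
        EOD term + L2) agree with central differences on a tiny model."""
        cfg = tiny_model_config(encoder_hidden=2, decoder_hidden=3,
                                embed_dim=2, attention_dim=2)
        model = SleepStager(cfg)
        seqs = [_sequence([StageLabel.W, StageLabel.N2], seed=1),
                _sequence([StageLabel.N1, StageLabel.N1], seed=2)]
        tc = TrainConfig(loss="mfe")
        x, dec_in, target_out, _ = _batch_arrays(seqs, cfg.n_classes)

        def objective() -> float:
            probs, _, _ = model.forward(x, decoder_inputs=dec_in, train=False)
            loss = sequence_loss(probs, target_out, tc, cfg.n_classes)
            return (loss + l2_penalty(model.weight_tensors(), tc.l2_beta)).item()

        model.zero_grad()
        probs, _, _ = model.forward(x, decoder_inputs=dec_in, train=False)
        loss = sequence_loss(probs, target_out, tc, cfg.n_classes)
        total = loss + l2_penalty(model.weight_tensors(), tc.l2_beta)
        total.backward()

        rng = np.random.default_rng(0)
        eps = 1e-5
        checked = 0
        for name in ("dec.W_out", "att.v", "enc.fwd.W", "cnn.small.conv0.w",
                     "dec.embed", "enc.U", "dec.W_c"):
            t = model.params[name]
            flat = t.data.reshape(-1)
            grad = (np.zeros_like(flat) if t.grad is None
                    else t.grad.reshape(-1))
            for idx in rng.choice(flat.size, size=min(4, flat.size), replace=False):
                orig = flat[idx]
                flat[idx] = orig + eps
                fp = objective()
                flat[idx] = orig - eps
                fm = objective()
                flat[idx] = orig
                num = (fp - fm) / (2 * eps)
                denom = max(abs(num), abs(grad[idx]), 1e-8)
                assert abs(num - grad[idx]) / denom < 1e-4, (
                    f"{name}[{idx}]: numeric {num:.3e} vs analytic {grad[idx]:.3e}"
                )
                checked += 1
        assert checked >= 20
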