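"""The sequence-to-sequence sleep-stage scorer.

Architecture, per input sequence of ``maxtime`` 30-s epochs:

1. **Dual-branch CNN** applied to each raw epoch: one branch with small
   filters (fine temporal detail), one with large filters (coarse spectral
   content). Each branch is four 1-D convolutions with ReLU, a max-pool
   after the first layer, and dropout after the last; the two branch
   outputs are concatenated and passed through a final dropout.
2. **Bidirectional recurrent encoder** over the per-epoch feature vectors:
   a forward pass in time order and a backward pass in reverse order, whose
   hidden states are combined linearly position-by-position into encoder
   states e_0 … e_{T−1}. LSTM cells by default; a plain tanh RNN cell is
   selectable to match the schematic recurrences exactly.
3. **Attention decoder** emitting one stage per input epoch. At each step
   the previous decoder state is scored against every encoder state through
   a tanh layer, softmax-normalized into attention weights α (each row of
   the attention map), and the α-weighted sum of encoder states becomes the
   context vector fed to the decoder cell together with the embedded
   previous label. Decoding starts from the SOD token; during training the
   true previous label is fed (teacher forcing) and a final step predicts
   the EOD class, while at test time the decoder consumes its own greedy
   output and emits exactly ``maxtime`` stage labels.

The output projection has 6 logits — the 5 stages plus EOD. EOD is trained
as the final target token only; when stages are reported, the argmax is
taken over the 5 stage logits so every epoch receives a stage.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import autodiff as ad
from .autodiff import Tensor
from .data_prep import EPOCH_SAMPLES, EpochSequence
from .stages import N_STAGES


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass
class CnnBranchConfig:
    """One CNN branch: four conv layers (ReLU), pool after layer 1."""

    filters: tuple[int, ...] = (50, 8, 8, 8)
    strides: tuple[int, ...] = (6, 1, 1, 1)
    channels: tuple[int, ...] = (64, 128, 128, 128)
    pool_size: int = 8
    padding: str = "same"  # "same" or "valid"

    def __post_init__(self) -> None:
        if not (len(self.filters) == len(self.strides) == len(self.channels)):
            raise ValueError("filters/strides/channels must have equal length")

    def output_length(self, length: int = EPOCH_SAMPLES) -> int:
        for i, (k, s) in enumerate(zip(self.filters, self.strides)):
            if self.padding == "same":
                length = -(-length // s)
            else:
                length = (length - k) // s + 1
            if length < 1:
                raise ValueError(
                    f"branch layer {i} yields non-positive length {length}"
                )
            if i == 0:
                length //= self.pool_size
                if length < 1:
                    raise ValueError("pooling collapses the branch to zero length")
        return length


@dataclass
class CnnConfig:
    """Dual-branch feature extractor configuration.

    Defaults follow the widely used dual-resolution design for 100 Hz
    epochs: a small-filter branch (filter 50, stride 6) and a large-filter
    branch (filter 400, stride 50), four conv layers each, max-pool after
    layer 1, dropout 0.5.
    """

    small: CnnBranchConfig = field(default_factory=CnnBranchConfig)
    large: CnnBranchConfig = field(
        default_factory=lambda: CnnBranchConfig(
            filters=(400, 6, 6, 6), strides=(50, 1, 1, 1),
            channels=(64, 128, 128, 128), pool_size=4,
        )
    )
    dropout: float = 0.5

    def feature_dim(self) -> int:
        return (
            self.small.output_length() * self.small.channels[-1]
            + self.large.output_length() * self.large.channels[-1]
        )

    @classmethod
    def reduced(cls, channels: int = 8) -> "CnnConfig":
        """A slimmed configuration for CPU-scale experiments and tests."""
        return cls(
            small=CnnBranchConfig(
                filters=(50, 8, 8, 8), strides=(6, 1, 1, 1),
                channels=(channels,) * 4, pool_size=8,
            ),
            large=CnnBranchConfig(
                filters=(400, 6, 6, 6), strides=(50, 1, 1, 1),
                channels=(channels,) * 4, pool_size=4,
            ),
            dropout=0.5,
        )


@dataclass
class ModelConfig:
    """Full network configuration with the package defaults."""

    cnn: CnnConfig = field(default_factory=CnnConfig)
    encoder_hidden: int = 128  # per direction
    decoder_hidden: int = 256
    embed_dim: int = 64
    n_classes: int = N_STAGES
    cell: str = "lstm"  # "lstm" or "simple" (literal tanh recurrence)
    use_attention: bool = True
    #: width of the tanh attention-scoring layer; the score of encoder
    #: position i is v·tanh(W_h·h_prev + W_e·e_i). Width 1 degenerates to a
    #: purely scalar tanh score.
    attention_dim: int = 16
    init_seed: int = 0

    @classmethod
    def reduced(cls, **overrides) -> "ModelConfig":
        """Small preset (hidden 32, slim CNN) for CPU-scale runs."""
        kwargs = dict(
            cnn=CnnConfig.reduced(),
            encoder_hidden=32,
            decoder_hidden=64,
            embed_dim=16,
        )
        kwargs.update(overrides)
        return cls(**kwargs)

    @property
    def n_outputs(self) -> int:
        return self.n_classes + 1  # stages + EOD

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        d = dict(d)
        cnn = d.pop("cnn")
        cnn = CnnConfig(
            small=CnnBranchConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in cnn["small"].items()}),
            large=CnnBranchConfig(**{k: tuple(v) if isinstance(v, list) else v
                                     for k, v in cnn["large"].items()}),
            dropout=cnn["dropout"],
        )
        return cls(cnn=cnn, **d)


# ---------------------------------------------------------------------------
# cells
# ---------------------------------------------------------------------------


class _Cell:
    """Recurrent cell interface over the parameter store."""

    def __init__(self, model: "SleepStager", prefix: str, in_dim: int, hidden: int):
        self.model = model
        self.prefix = prefix
        self.hidden = hidden
        self.in_dim = in_dim

    def initial_state(self, batch: int):
        raise NotImplementedError

    def step(self, x: Tensor, state):
        raise NotImplementedError


class SimpleCell(_Cell):
    """Literal tanh recurrence: h_t = tanh(W x_t + V h_{t-1} + b)."""

    def __init__(self, model, prefix, in_dim, hidden):
        super().__init__(model, prefix, in_dim, hidden)
        model._add(f"{prefix}.W", (in_dim, hidden))
        model._add(f"{prefix}.V", (hidden, hidden))
        model._add(f"{prefix}.b", (hidden,), bias=True)

    def initial_state(self, batch: int):
        return Tensor(np.zeros((batch, self.hidden)), requires_grad=False)

    def step(self, x: Tensor, h: Tensor):
        p = self.model.params
        h = ad.tanh(x @ p[f"{self.prefix}.W"] + h @ p[f"{self.prefix}.V"]
                    + p[f"{self.prefix}.b"])
        return h, h

    @staticmethod
    def output(state):
        return state


class LSTMCell(_Cell):
    """Standard LSTM with input/forget/cell/output gates (forget bias 1)."""

    def __init__(self, model, prefix, in_dim, hidden):
        super().__init__(model, prefix, in_dim, hidden)
        model._add(f"{prefix}.W", (in_dim, 4 * hidden))
        model._add(f"{prefix}.V", (hidden, 4 * hidden))
        b = model._add(f"{prefix}.b", (4 * hidden,), bias=True)
        b.data[hidden : 2 * hidden] = 1.0  # encourage remembering early on

    def initial_state(self, batch: int):
        zeros = np.zeros((batch, self.hidden))
        return (Tensor(zeros, requires_grad=False),
                Tensor(zeros.copy(), requires_grad=False))

    def step(self, x: Tensor, state):
        h_prev, c_prev = state
        p = self.model.params
        gates = (x @ p[f"{self.prefix}.W"] + h_prev @ p[f"{self.prefix}.V"]
                 + p[f"{self.prefix}.b"])
        n = self.hidden
        i = ad.sigmoid(gates[:, 0:n])
        f = ad.sigmoid(gates[:, n : 2 * n])
        g = ad.tanh(gates[:, 2 * n : 3 * n])
        o = ad.sigmoid(gates[:, 3 * n : 4 * n])
        c = f * c_prev + i * g
        h = o * ad.tanh(c)
        return h, (h, c)

    @staticmethod
    def output(state):
        return state[0]


_CELLS = {"simple": SimpleCell, "lstm": LSTMCell}


# ---------------------------------------------------------------------------
# the model
# ---------------------------------------------------------------------------


class SleepStager:
    """Dual-branch CNN + BiRNN encoder + attention decoder."""

    def __init__(self, config: ModelConfig):
        self.config = config
        self.params: dict[str, Tensor] = {}
        self._bias_names: set[str] = set()
        self._init_rng = np.random.default_rng(config.init_seed)

        cfg = config
        self.feature_dim = cfg.cnn.feature_dim()
        self._build_cnn("cnn.small", cfg.cnn.small)
        self._build_cnn("cnn.large", cfg.cnn.large)

        cell_cls = _CELLS[cfg.cell]
        self.enc_fwd = cell_cls(self, "enc.fwd", self.feature_dim, cfg.encoder_hidden)
        self.enc_bwd = cell_cls(self, "enc.bwd", self.feature_dim, cfg.encoder_hidden)
        #: Eq-3-style combination of the two directions into encoder states.
        self.enc_out_dim = 2 * cfg.encoder_hidden
        self._add("enc.U", (2 * cfg.encoder_hidden, self.enc_out_dim))
        self._add("enc.b_y", (self.enc_out_dim,), bias=True)

        # decoder input: embedded previous label (+ context under attention)
        self._add("dec.embed", (cfg.n_classes + 1, cfg.embed_dim))  # stages + SOD
        dec_in = cfg.embed_dim + (self.enc_out_dim if cfg.use_attention else 0)
        self.dec_cell = cell_cls(self, "dec.cell", dec_in, cfg.decoder_hidden)
        if cfg.use_attention:
            # tanh scoring layer, projected to a scalar per encoder position
            self._add("att.W_h", (cfg.decoder_hidden, cfg.attention_dim))
            self._add("att.W_e", (self.enc_out_dim, cfg.attention_dim))
            self._add("att.v", (cfg.attention_dim, 1))
        else:
            # basic decoder: encoder's last state initializes the decoder
            self._add("dec.init", (self.enc_out_dim, cfg.decoder_hidden))
        if cfg.use_attention:
            # attentional output layer: the context joins the cell output
            # before the class projection, so the step-t prediction gradient
            # reaches the attention weights directly
            self._add("dec.W_c", (cfg.decoder_hidden + self.enc_out_dim,
                                  cfg.decoder_hidden))
        self._add("dec.W_out", (cfg.decoder_hidden, cfg.n_outputs))
        self._add("dec.b_out", (cfg.n_outputs,), bias=True)

    # -- parameters -------------------------------------------------------

    def _add(self, name: str, shape: tuple[int, ...], bias: bool = False) -> Tensor:
        if bias:
            data = np.zeros(shape)
            self._bias_names.add(name)
        else:
            fan_in = shape[0] if len(shape) > 1 else shape[0]
            scale = 1.0 / np.sqrt(fan_in)
            data = self._init_rng.uniform(-scale, scale, size=shape)
        t = Tensor(data)
        self.params[name] = t
        return t

    def weight_tensors(self) -> list[Tensor]:
        """Trainable weights (biases excluded) — the L2-penalized set."""
        return [t for n, t in self.params.items() if n not in self._bias_names]

    def zero_grad(self) -> None:
        for t in self.params.values():
            t.grad = None

    # -- CNN --------------------------------------------------------------

    def _build_cnn(self, prefix: str, branch: CnnBranchConfig) -> None:
        in_ch = 1
        for i, (k, ch) in enumerate(zip(branch.filters, branch.channels)):
            self._add(f"{prefix}.conv{i}.w", (ch, in_ch, k))
            self._add(f"{prefix}.conv{i}.b", (ch,), bias=True)
            in_ch = ch

    def _branch_forward(self, x: Tensor, prefix: str, branch: CnnBranchConfig,
                        train: bool, rng) -> Tensor:
        for i, (k, s) in enumerate(zip(branch.filters, branch.strides)):
            if branch.padding == "same":
                length = x.shape[2]
                total = max((-(-length // s) - 1) * s + k - length, 0)
                pad = (total // 2, total - total // 2)
            else:
                pad = (0, 0)
            x = ad.conv1d(x, self.params[f"{prefix}.conv{i}.w"],
                          self.params[f"{prefix}.conv{i}.b"], stride=s, pad=pad)
            x = ad.relu(x)
            if i == 0:
                x = ad.maxpool1d(x, branch.pool_size)
                x = ad.dropout(x, self.config.cnn.dropout, rng, train)
        x = ad.dropout(x, self.config.cnn.dropout, rng, train)
        b = x.shape[0]
        return x.reshape(b, x.shape[1] * x.shape[2])

    def cnn_extract(self, epochs: np.ndarray | Tensor, train: bool = False,
                    rng: np.random.Generator | None = None) -> Tensor:
        """Per-epoch features: (B, 3000) raw epochs → (B, feature_dim)."""
        rng = rng or np.random.default_rng(0)
        x = epochs if isinstance(epochs, Tensor) else Tensor(epochs, requires_grad=False)
        if x.ndim == 1:
            x = x.reshape(1, x.shape[0])
        b = x.shape[0]
        x = x.reshape(b, 1, x.shape[1])
        small = self._branch_forward(x, "cnn.small", self.config.cnn.small, train, rng)
        large = self._branch_forward(x, "cnn.large", self.config.cnn.large, train, rng)
        out = ad.concat([small, large], axis=1)
        return ad.dropout(out, self.config.cnn.dropout, rng, train)

    # -- encoder ----------------------------------------------------------

    def encode(self, features: list[Tensor]) -> list[Tensor]:
        """BiRNN over per-step features; returns encoder states e_0 … e_{T−1}.

        The forward cell runs t = 1…T, the backward cell t = T…1, and each
        position's two hidden states are combined linearly into the output.
        """
        if not features:
            raise ValueError("empty feature sequence")
        batch = features[0].shape[0]
        state = self.enc_fwd.initial_state(batch)
        fwd = []
        for x in features:
            h, state = self.enc_fwd.step(x, state)
            fwd.append(h)
        state = self.enc_bwd.initial_state(batch)
        bwd = [None] * len(features)
        for t in range(len(features) - 1, -1, -1):
            h, state = self.enc_bwd.step(features[t], state)
            bwd[t] = h
        p = self.params
        return [
            ad.concat([f, b], axis=1) @ p["enc.U"] + p["enc.b_y"]
            for f, b in zip(fwd, bwd)
        ]

    # -- attention --------------------------------------------------------

    def attend(self, h_prev: Tensor, states: list[Tensor]) -> tuple[Tensor, Tensor]:
        """Attention weights over encoder states and the context vector.

        Position i is scored by v·tanh(W_h·h_prev + W_e·e_i); the scores
        are softmax-normalized over positions and the context is the
        weighted sum of encoder states. Returns (alpha (B, T), context
        (B, D)).
        """
        p = self.params
        h_proj = h_prev @ p["att.W_h"]  # (B, d)
        scores = [
            ad.tanh(e @ p["att.W_e"] + h_proj) @ p["att.v"] for e in states
        ]  # each (B, 1)
        alpha = ad.softmax(ad.concat(scores, axis=1), axis=1)  # (B, T)
        ctx = None
        for i, e in enumerate(states):
            term = alpha[:, i : i + 1] * e
            ctx = term if ctx is None else ctx + term
        return alpha, ctx

    # -- decoder ----------------------------------------------------------

    def _decoder_initial_state(self, states: list[Tensor], batch: int):
        if self.config.use_attention:
            ctx0 = Tensor(np.zeros((batch, self.enc_out_dim)), requires_grad=False)
            return (self.dec_cell.initial_state(batch), ctx0)
        h0 = ad.tanh(states[-1] @ self.params["dec.init"])
        if self.config.cell == "lstm":
            _, c0 = self.dec_cell.initial_state(batch)
            return ((h0, c0), None)
        return (h0, None)

    def decode_step(self, prev_tokens: np.ndarray, dec_state,
                    states: list[Tensor]) -> tuple[Tensor, object, Tensor | None]:
        """One decoder step.

        ``prev_tokens``: (B,) previous labels (or SOD); ``dec_state`` is
        ``(cell state, previous context)``. The previous step's context is
        fed into the cell with the embedded label (input feeding), the
        updated hidden state queries the attention, and the fresh context
        joins the output layer. Returns the (B, n_outputs) probability
        rows, the next decoder state, and the attention row (B, T) —
        ``None`` for the basic decoder.
        """
        cell_state, ctx_prev = dec_state
        emb = self.params["dec.embed"][np.asarray(prev_tokens, dtype=np.int64)]
        if self.config.use_attention:
            x = ad.concat([emb, ctx_prev], axis=1)
        else:
            x = emb
        h, cell_state = self.dec_cell.step(x, cell_state)
        if self.config.use_attention:
            alpha, ctx = self.attend(h, states)
            h = ad.tanh(ad.concat([h, ctx], axis=1) @ self.params["dec.W_c"])
        else:
            alpha, ctx = None, None
        logits = h @ self.params["dec.W_out"] + self.params["dec.b_out"]
        return ad.softmax(logits, axis=1), (cell_state, ctx), alpha

    # -- full forward -----------------------------------------------------

    def forward(
        self,
        epochs: np.ndarray,
        decoder_inputs: np.ndarray | None = None,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[list[Tensor], np.ndarray, np.ndarray]:
        """Run the network on a batch of sequences.

        ``epochs``: (B, T, 3000). With ``decoder_inputs`` (B, S) the decoder
        is teacher-forced for S steps; without, it decodes greedily for T
        steps starting from SOD, feeding back its own argmax over the stage
        logits. Returns (per-step probability tensors, predicted stage
        labels (B, T_dec), attention maps (B, T_dec, T)).
        """
        rng = rng or np.random.default_rng(0)
        b, t_enc, n = epochs.shape
        flat = self.cnn_extract(epochs.reshape(b * t_enc, n), train=train, rng=rng)
        # reshape (B*T, F) back into T per-step (B, F) slices
        feats3 = flat.reshape(b, t_enc, self.feature_dim)
        features = [feats3[:, t, :] for t in range(t_enc)]
        states = self.encode(features)

        dec_state = self._decoder_initial_state(states, b)
        steps = decoder_inputs.shape[1] if decoder_inputs is not None else t_enc
        probs_steps: list[Tensor] = []
        alphas = np.zeros((b, steps, t_enc))
        labels = np.zeros((b, steps), dtype=np.int64)
        # the SOD token occupies the last embedding row (index n_classes)
        prev = np.full(b, self.config.n_classes, dtype=np.int64)
        for s in range(steps):
            if decoder_inputs is not None:
                prev = decoder_inputs[:, s]
            probs, dec_state, alpha = self.decode_step(prev, dec_state, states)
            probs_steps.append(probs)
            if alpha is not None:
                alphas[:, s, :] = alpha.data
            stage_pred = probs.data[:, : self.config.n_classes].argmax(axis=1)
            labels[:, s] = stage_pred
            if decoder_inputs is None:
                prev = stage_pred  # greedy feedback of the model's own output
        return probs_steps, labels, alphas

    def predict_sequence(
        self, seq: EpochSequence, teacher_forcing: bool = False
    ) -> tuple[list, np.ndarray]:
        """Score one epoch sequence; returns (labels, attention map).

        Teacher forcing feeds ``target_in``; otherwise the decoder consumes
        its own greedy output starting from SOD. Exactly ``len(seq)`` labels
        come back, and the attention map has one row per decoded epoch.
        """
        from .stages import StageLabel

        x = seq.samples[None, :, :]
        dec_in = np.array([seq.target_in]) if teacher_forcing else None
        _, labels, alphas = self.forward(x, decoder_inputs=dec_in, train=False)
        return [StageLabel(int(v)) for v in labels[0]], alphas[0]

    # -- persistence ------------------------------------------------------

    def save(self, path) -> Path:
        """Checkpoint: npz of parameters + embedded JSON config manifest."""
        path = Path(path)
        arrays = {k.replace(".", "__"): v.data for k, v in self.params.items()}
        manifest = json.dumps(
            {"config": self.config.to_dict(), "bias_names": sorted(self._bias_names)}
        )
        np.savez(path, __manifest__=np.frombuffer(manifest.encode(), dtype=np.uint8),
                 **arrays)
        return path

    @classmethod
    def load(cls, path) -> "SleepStager":
        with np.load(path) as z:
            manifest = json.loads(bytes(z["__manifest__"]).decode())
            model = cls(ModelConfig.from_dict(manifest["config"]))
            for k in model.params:
                model.params[k].data = z[k.replace(".", "__")].copy()
        return model
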