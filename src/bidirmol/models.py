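"""LSTM sequence-model variants producing next-token logits.

Four variants share the same two-layer LSTM core (input one-hot encoded,
batch-normalised; hidden states batch-normalised before the output linear
layer):

``forward`` / ``backward``
    Five layers (BatchNorm, LSTM, LSTM, BatchNorm, Linear).  Information
    flows strictly left-to-right; the backward model is the same network
    run on the reversed string, predicting the token to the *left*.

``fbrnn``
    Same five layers with both the input and the output dimension doubled.
    The network reads the string from its start-token outward in
    synchronised pairs (one token from each side per step) and the linear
    output splits positionally into ``y_plus`` (next token to the right)
    and ``y_minus`` (next token to the left).

``bimodal``
    Seven layers (BatchNorm, two forward LSTMs, two backward LSTMs,
    BatchNorm, Linear).  Both directions read the string and the logits for
    a position combine the forward hidden state of its left context and
    the backward hidden state of its right context,
    ``y = W+ h+ + W- h- + b``.  Generation alternates directions,
    emitting one token per step.

Batch-normalisation layers run in training mode only during
maximum-likelihood fitting; during generation and reinforcement-learning
rollouts they use frozen running statistics, making every logit a
deterministic function of (weights, input).
"""

from __future__ import annotations

import io
import json
from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .nn import Tensor, concat, stack

__all__ = [
    "ModelConfig",
    "UnidirectionalModel",
    "FBRNNModel",
    "BimodalModel",
    "build_model",
    "temperature_softmax",
    "one_hot",
    "save_checkpoint",
    "load_checkpoint",
    "CHECKPOINT_VERSION",
]

VARIANTS = ("forward", "backward", "fbrnn", "bimodal")


@dataclass(frozen=True)
class ModelConfig:
    variant: str
    vocab_size: int
    hidden_size: int = 1024
    init_seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.vocab_size < 2 or self.hidden_size < 1:
            raise ValueError("bad model dimensions")


def temperature_softmax(y: np.ndarray | Tensor, T: float = 1.0) -> np.ndarray:
    """Softmax with temperature, numerically stabilised by max-subtraction."""
    if T <= 0:
        raise ValueError("temperature must be positive")
    y = y.data if isinstance(y, Tensor) else np.asarray(y, dtype=np.float64)
    z = (y - y.max(axis=-1, keepdims=True)) / T
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def one_hot(ids: np.ndarray, n: int) -> np.ndarray:
    ids = np.asarray(ids, dtype=np.int64)
    out = np.zeros(ids.shape + (n,), dtype=np.float64)
    np.put_along_axis(out, ids[..., None], 1.0, axis=-1)
    return out


class _StackBase(nn.Module):
    """BatchNorm -> LSTM -> LSTM core shared by the 5-layer variants."""

    def zero_state(self, batch: int):
        return self.lstm1.zero_state(batch) + self.lstm2.zero_state(batch)

    def core_step(self, x: Tensor, state):
        h1, c1, h2, c2 = state
        h1, c1 = self.lstm1(self.bn1(x), h1, c1)
        h2, c2 = self.lstm2(h1, h2, c2)
        return h2, (h1, c1, h2, c2)

    def run_sequence(self, xs: np.ndarray | Tensor) -> Tensor:
        """Run the core over (B, T, n_in); return hidden states (B, T, H)."""
        xs = Tensor._coerce(xs)
        b, t, f = xs.shape
        xn = self.bn1(xs.reshape(b * t, f)).reshape(b, t, f)
        h1, c1 = self.lstm1.zero_state(b)
        h2, c2 = self.lstm2.zero_state(b)
        hs = []
        for step in range(t):
            x = xn[:, step, :]
            h1, c1 = self.lstm1(x, h1, c1)
            h2, c2 = self.lstm2(h1, h2, c2)
            hs.append(h2)
        return stack(hs, axis=1)


class UnidirectionalModel(_StackBase):
    """Forward or backward next-token model (reading order handled by caller)."""

    def __init__(self, config: ModelConfig):
        if config.variant not in ("forward", "backward"):
            raise ValueError("config is not unidirectional")
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        v, h = config.vocab_size, config.hidden_size
        self.bn1 = nn.BatchNorm(v)
        self.lstm1 = nn.LSTMCell(v, h, rng)
        self.lstm2 = nn.LSTMCell(h, h, rng)
        self.bn2 = nn.BatchNorm(h)
        self.out = nn.Linear(h, v, rng)

    def step(self, ids: np.ndarray, state):
        """One reading step on token ids (B,); returns logits (B, V)."""
        x = Tensor(one_hot(ids, self.config.vocab_size))
        h2, state = self.core_step(x, state)
        return self.out(self.bn2(h2)), state

    def sequence_logits(self, ids: np.ndarray) -> Tensor:
        """Next-token logits at every step of (B, T) in reading order."""
        hs = self.run_sequence(one_hot(ids, self.config.vocab_size))
        b, t, h = hs.shape
        z = self.bn2(hs.reshape(b * t, h))
        return self.out(z).reshape(b, t, self.config.vocab_size)


class FBRNNModel(_StackBase):
    """Synchronised two-sided grower: reads a token pair, emits a pair."""

    def __init__(self, config: ModelConfig):
        if config.variant != "fbrnn":
            raise ValueError("config is not fbrnn")
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        v, h = config.vocab_size, config.hidden_size
        self.bn1 = nn.BatchNorm(2 * v)
        self.lstm1 = nn.LSTMCell(2 * v, h, rng)
        self.lstm2 = nn.LSTMCell(h, h, rng)
        self.bn2 = nn.BatchNorm(h)
        self.out = nn.Linear(h, 2 * v, rng)

    def step(self, left_ids: np.ndarray, right_ids: np.ndarray, state):
        """Read the pair (token at left frontier, token at right frontier).

        Returns (y_minus, y_plus, state): logits for the next token to the
        left and to the right.  y_plus is the first half of the linear
        output, y_minus the second half.
        """
        v = self.config.vocab_size
        x = Tensor(np.concatenate(
            [one_hot(left_ids, v), one_hot(right_ids, v)], axis=-1))
        h2, state = self.core_step(x, state)
        y = self.out(self.bn2(h2))
        return y[:, v:], y[:, :v], state

    def pair_logits(self, left_seq: np.ndarray, right_seq: np.ndarray):
        """Teacher-forced run over aligned (B, T) left/right token streams.

        Returns (y_minus, y_plus) of shape (B, T, V).
        """
        v = self.config.vocab_size
        xs = np.concatenate(
            [one_hot(left_seq, v), one_hot(right_seq, v)], axis=-1)
        hs = self.run_sequence(xs)
        b, t, h = hs.shape
        y = self.out(self.bn2(hs.reshape(b * t, h))).reshape(b, t, 2 * v)
        return y[:, :, v:], y[:, :, :v]


class BimodalModel(nn.Module):
    """Bidirectional reader combining forward and backward context."""

    def __init__(self, config: ModelConfig):
        if config.variant != "bimodal":
            raise ValueError("config is not bimodal")
        self.config = config
        rng = np.random.default_rng(config.init_seed)
        v, h = config.vocab_size, config.hidden_size
        self.bn1 = nn.BatchNorm(v)
        self.f_lstm1 = nn.LSTMCell(v, h, rng)
        self.b_lstm1 = nn.LSTMCell(v, h, rng)
        self.f_lstm2 = nn.LSTMCell(h, h, rng)
        self.b_lstm2 = nn.LSTMCell(h, h, rng)
        self.bn2 = nn.BatchNorm(2 * h)
        self.out = nn.Linear(2 * h, v, rng)

    def _direction_states(self, xs: Tensor, l1, l2) -> Tensor:
        b, t, f = xs.shape
        h1, c1 = l1.zero_state(b)
        h2, c2 = l2.zero_state(b)
        hs = []
        for step in range(t):
            h1, c1 = l1(xs[:, step, :], h1, c1)
            h2, c2 = l2(h1, h2, c2)
            hs.append(h2)
        return stack(hs, axis=1)

    def position_logits(self, ids: np.ndarray) -> Tensor:
        """Logits for the token at every window position p of (B, M),
        combining the forward state over w[0..p-1] and the backward state
        over w[p+1..M-1] (zero state at the boundaries)."""
        v, h = self.config.vocab_size, self.config.hidden_size
        ids = np.asarray(ids, dtype=np.int64)
        b, m = ids.shape
        xs = Tensor._coerce(one_hot(ids, v))
        xn = self.bn1(xs.reshape(b * m, v)).reshape(b, m, v)
        f_states = self._direction_states(xn, self.f_lstm1, self.f_lstm2)
        rev = xn[:, ::-1, :]
        b_states = self._direction_states(rev, self.b_lstm1, self.b_lstm2)
        b_states = b_states[:, ::-1, :]
        zero = Tensor(np.zeros((b, 1, h)))
        f_ctx = concat([zero, f_states[:, :-1, :]], axis=1)
        b_ctx = concat([b_states[:, 1:, :], zero], axis=1)
        z = concat([f_ctx, b_ctx], axis=-1)
        z = self.bn2(z.reshape(b * m, 2 * h))
        return self.out(z).reshape(b, m, v)


    def next_token_logits(self, ids: np.ndarray, pos: int) -> Tensor:
        """Logits for window position ``pos`` only (generation fast path).

        Forward direction reads w[0..pos-1], backward reads w[M-1..pos+1];
        either context may be empty at the window edge.
        """
        v, h = self.config.vocab_size, self.config.hidden_size
        ids = np.asarray(ids, dtype=np.int64)
        b, m = ids.shape
        zero = Tensor(np.zeros((b, h)))

        def last_state(sub_ids, l1, l2):
            if sub_ids.shape[1] == 0:
                return zero
            xs = Tensor._coerce(one_hot(sub_ids, v))
            nb, nt, nf = xs.shape
            xn = self.bn1(xs.reshape(nb * nt, nf)).reshape(nb, nt, nf)
            return self._direction_states(xn, l1, l2)[:, -1, :]

        f_ctx = last_state(ids[:, :pos], self.f_lstm1, self.f_lstm2)
        b_ctx = last_state(ids[:, :pos:-1], self.b_lstm1, self.b_lstm2)
        z = self.bn2(concat([f_ctx, b_ctx], axis=-1))
        return self.out(z)


def build_model(config: ModelConfig):
    if config.variant in ("forward", "backward"):
        return UnidirectionalModel(config)
    if config.variant == "fbrnn":
        return FBRNNModel(config)
    return BimodalModel(config)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

CHECKPOINT_VERSION = 1


def save_checkpoint(model, path, vocab_json: str | None = None,
                    meta: dict | None = None) -> None:
    """Single-archive checkpoint: config, tensors, vocabulary, metadata."""
    header = {
        "version": CHECKPOINT_VERSION,
        "config": asdict(model.config),
        "vocab": vocab_json,
        "meta": meta or {},
    }
    arrays = {f"param/{k}": v for k, v in model.state_dict().items()}
    with open(path, "wb") as fh:
        np.savez(fh, __header__=np.frombuffer(
            json.dumps(header).encode(), dtype=np.uint8), **arrays)


def load_checkpoint(path):
    """Returns (model, vocab_json, meta)."""
    with np.load(path) as data:
        header = json.loads(bytes(data["__header__"]).decode())
        if header["version"] > CHECKPOINT_VERSION:
            raise ValueError("checkpoint from a newer version")
        state = {
            k[len("param/"):]: data[k]
            for k in data.files if k.startswith("param/")
        }
    config = ModelConfig(**header["config"])
    model = build_model(config)
    model.load_state_dict(state)
    return model, header.get("vocab"), header.get("meta", {})
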