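"""Minimal reverse-mode automatic differentiation over numpy arrays.

The sequence models in this package are small (two stacked LSTM layers on
vocabularies of a few dozen tokens), so a vectorised numpy engine with a
dynamically built tape is entirely adequate and keeps the package
self-contained.  All arithmetic is float64.

Contents: a :class:`Tensor` with the operations the LSTM variants need
(matmul, broadcasting arithmetic, sigmoid/tanh, log-softmax, gather,
concatenation, reductions), a :class:`no_grad` context, batch
normalisation with running statistics, an LSTM cell faithful to the
standard gate equations, and Adam / AdamW (decoupled weight decay)
optimisers.
"""

from __future__ import annotations

import contextlib
from dataclasses import dataclass

import numpy as np

__all__ = [
    "Tensor",
    "no_grad",
    "concat",
    "stack",
    "Linear",
    "BatchNorm",
    "LSTMGateParams",
    "lstm_cell_step",
    "LSTMCell",
    "Adam",
    "AdamW",
    "uniform_init",
]

_GRAD_ENABLED = [True]


@contextlib.contextmanager
def no_grad():
    _GRAD_ENABLED.append(False)
    try:
        yield
    finally:
        _GRAD_ENABLED.pop()


def grad_enabled() -> bool:
    return _GRAD_ENABLED[-1]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and grad.shape[i] != 1:
            grad = grad.sum(axis=i, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.requires_grad = requires_grad
        self._parents = parents
        self._backward = backward

    # -- graph bookkeeping -------------------------------------------------

    @staticmethod
    def _make(data, parents, backward):
        if grad_enabled() and any(p.requires_grad for p in parents):
            return Tensor(data, requires_grad=True,
                          parents=parents, backward=backward)
        return Tensor(data)

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def backward(self, grad=None) -> None:
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        grads = {id(self): np.asarray(grad, dtype=np.float64)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if t.requires_grad and t._backward is None:
                t.grad = g if t.grad is None else t.grad + g
            if t._backward is not None:
                for p, pg in zip(t._parents, t._backward(g)):
                    if pg is None or not p.requires_grad:
                        continue
                    key = id(p)
                    grads[key] = pg if key not in grads else grads[key] + pg

    # -- arithmetic --------------------------------------------------------

    @staticmethod
    def _coerce(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data + other.data, (self, other),
            lambda g: (_unbroadcast(g, self.shape),
                       _unbroadcast(g, other.shape)))

    __radd__ = __add__

    def __neg__(self):
        return Tensor._make(-self.data, (self,), lambda g: (-g,))

    def __sub__(self, other):
        return self + (-self._coerce(other))

    def __rsub__(self, other):
        return self._coerce(other) + (-self)

    def __mul__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data * other.data, (self, other),
            lambda g: (_unbroadcast(g * other.data, self.shape),
                       _unbroadcast(g * self.data, other.shape)))

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data / other.data, (self, other),
            lambda g: (_unbroadcast(g / other.data, self.shape),
                       _unbroadcast(-g * self.data / other.data**2,
                                    other.shape)))

    def __rtruediv__(self, other):
        return self._coerce(other) / self

    def __pow__(self, exponent: float):
        return Tensor._make(
            self.data**exponent, (self,),
            lambda g: (g * exponent * self.data**(exponent - 1),))

    def __matmul__(self, other):
        other = self._coerce(other)
        return Tensor._make(
            self.data @ other.data, (self, other),
            lambda g: (g @ other.data.T, self.data.T @ g))

    def sigmoid(self):
        out = 1.0 / (1.0 + np.exp(-self.data))
        return Tensor._make(out, (self,), lambda g: (g * out * (1 - out),))

    def tanh(self):
        out = np.tanh(self.data)
        return Tensor._make(out, (self,), lambda g: (g * (1 - out**2),))

    def exp(self):
        out = np.exp(self.data)
        return Tensor._make(out, (self,), lambda g: (g * out,))

    def log(self):
        return Tensor._make(np.log(self.data), (self,),
                            lambda g: (g / self.data,))

    def sum(self, axis=None, keepdims=False):
        out = self.data.sum(axis=axis, keepdims=keepdims)

        def back(g):
            g = np.asarray(g)
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            return (np.broadcast_to(g, self.shape).copy(),)

        return Tensor._make(out, (self,), back)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.shape
        return Tensor._make(self.data.reshape(*shape), (self,),
                            lambda g: (g.reshape(old),))

    def __getitem__(self, idx):
        def back(g):
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            return (full,)

        return Tensor._make(self.data[idx], (self,), back)

    def log_softmax(self, axis=-1):
        """Numerically stabilised log-probabilities along ``axis``."""
        z = self.data - self.data.max(axis=axis, keepdims=True)
        logsum = np.log(np.exp(z).sum(axis=axis, keepdims=True))
        out = z - logsum
        softmax = np.exp(out)

        def back(g):
            return (g - softmax * g.sum(axis=axis, keepdims=True),)

        return Tensor._make(out, (self,), back)

    def gather(self, indices: np.ndarray, axis=-1):
        """take_along_axis with integer indices (no grad through indices)."""
        idx = np.asarray(indices, dtype=np.int64)
        idx_exp = np.expand_dims(idx, axis)
        out = np.take_along_axis(self.data, idx_exp, axis=axis)
        out = out.squeeze(axis)

        def back(g):
            full = np.zeros_like(self.data)
            np.put_along_axis(full, idx_exp, np.expand_dims(g, axis), axis)
            return (full,)

        return Tensor._make(out, (self,), back)


def concat(tensors: list[Tensor], axis: int = -1) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def back(g):
        return tuple(np.split(g, splits, axis=axis))

    return Tensor._make(
        np.concatenate([t.data for t in tensors], axis=axis),
        tuple(tensors), back)


def stack(tensors: list[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._coerce(t) for t in tensors]

    def back(g):
        return tuple(np.moveaxis(g, axis, 0))

    return Tensor._make(
        np.stack([t.data for t in tensors], axis=axis), tuple(tensors), back)


# ---------------------------------------------------------------------------
# layers
# ---------------------------------------------------------------------------


def uniform_init(rng: np.random.Generator, shape, fan_in: int) -> Tensor:
    """Standard U(-1/sqrt(fan_in), 1/sqrt(fan_in)) parameter init."""
    bound = 1.0 / np.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape), requires_grad=True)


class Module:
    """Tiny parameter container with named sub-modules."""

    def parameters(self) -> list[Tensor]:
        return [t for _, t in self.named_parameters()]

    def named_parameters(self):
        out = []
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                out.append((name, val))
            elif isinstance(val, Module):
                out.extend((f"{name}.{k}", t)
                           for k, t in val.named_parameters())
        return out

    def state_dict(self) -> dict:
        d = {k: t.data.copy() for k, t in self.named_parameters()}
        for name, val in vars(self).items():
            if isinstance(val, Module):
                for k, v in val.state_dict().items():
                    d.setdefault(f"{name}.{k}", v)
        for k, v in self._buffers().items():
            d[k] = v.copy()
        return d

    def load_state_dict(self, d: dict) -> None:
        params = dict(self.named_parameters())
        for k, v in d.items():
            if k in params:
                params[k].data = np.asarray(v, dtype=np.float64).copy()
            else:
                self._load_buffer(k, v)

    def _buffers(self) -> dict:
        out = {}
        for name, val in vars(self).items():
            if isinstance(val, Module):
                for k, v in val._buffers().items():
                    out[f"{name}.{k}"] = v
        return out

    def _load_buffer(self, key: str, value) -> None:
        head, _, rest = key.partition(".")
        sub = getattr(self, head, None)
        if isinstance(sub, Module):
            sub._load_buffer(rest, value)

    def set_train(self, mode: bool) -> None:
        for val in vars(self).values():
            if isinstance(val, Module):
                val.set_train(mode)


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        self.W = uniform_init(rng, (n_in, n_out), n_in)
        self.b = uniform_init(rng, (n_out,), n_in)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class BatchNorm(Module):
    """Feature-dimension batch normalisation over (batch, features).

    Training mode normalises with batch statistics and updates running
    estimates; eval mode is a fixed affine map of the running statistics,
    making everything downstream a deterministic function of the weights.
    """

    def __init__(self, n_features: int, momentum: float = 0.1,
                 eps: float = 1e-5):
        self.gamma = Tensor(np.ones(n_features), requires_grad=True)
        self.beta = Tensor(np.zeros(n_features), requires_grad=True)
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps
        self.training = False

    def set_train(self, mode: bool) -> None:
        self.training = mode

    def _buffers(self) -> dict:
        return {"running_mean": self.running_mean,
                "running_var": self.running_var}

    def _load_buffer(self, key: str, value) -> None:
        if key == "running_mean":
            self.running_mean = np.asarray(value, dtype=np.float64).copy()
        elif key == "running_var":
            self.running_var = np.asarray(value, dtype=np.float64).copy()

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=0, keepdims=True)
            centred = x - mu
            var = (centred**2).mean(axis=0, keepdims=True)
            n = x.shape[0]
            unbiased = var.data.squeeze(0) * (n / max(n - 1, 1))
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean \
                + m * mu.data.squeeze(0)
            self.running_var = (1 - m) * self.running_var + m * unbiased
            xhat = centred * (var + self.eps)**-0.5
        else:
            xhat = (x - self.running_mean) \
                / np.sqrt(self.running_var + self.eps)
        return xhat * self.gamma + self.beta


@dataclass
class LSTMGateParams:
    """Separate per-gate weights of one LSTM cell.

    ``W_*`` act on the input, ``U_*`` on the previous hidden state; the
    fourth set parameterises the candidate cell state.
    """

    W_i: Tensor
    W_f: Tensor
    W_o: Tensor
    W_c: Tensor
    U_i: Tensor
    U_f: Tensor
    U_o: Tensor
    U_c: Tensor
    b_i: Tensor
    b_f: Tensor
    b_o: Tensor
    b_c: Tensor


def lstm_cell_step(x: Tensor, h_prev: Tensor, c_prev: Tensor,
                   p: LSTMGateParams) -> tuple[Tensor, Tensor]:
    """One LSTM step: gates by sigmoid, candidate by tanh.

        i = sigma(W_i x + U_i h + b_i)      f = sigma(W_f x + U_f h + b_f)
        o = sigma(W_o x + U_o h + b_o)      c~ = tanh(W_c x + U_c h + b_c)
        c' = f * c + i * c~                 h' = o * tanh(c')
    """
    x, h_prev, c_prev = map(Tensor._coerce, (x, h_prev, c_prev))
    i = (x @ p.W_i + h_prev @ p.U_i + p.b_i).sigmoid()
    f = (x @ p.W_f + h_prev @ p.U_f + p.b_f).sigmoid()
    o = (x @ p.W_o + h_prev @ p.U_o + p.b_o).sigmoid()
    c_tilde = (x @ p.W_c + h_prev @ p.U_c + p.b_c).tanh()
    c = f * c_prev + i * c_tilde
    h = o * c.tanh()
    return h, c


class LSTMCell(Module):
    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_in, self.n_hidden = n_in, n_hidden
        for gate in "ifoc":
            setattr(self, f"W_{gate}",
                    uniform_init(rng, (n_in, n_hidden), n_hidden))
            setattr(self, f"U_{gate}",
                    uniform_init(rng, (n_hidden, n_hidden), n_hidden))
            setattr(self, f"b_{gate}",
                    uniform_init(rng, (n_hidden,), n_hidden))

    @property
    def gates(self) -> LSTMGateParams:
        return LSTMGateParams(**{
            f"{kind}_{gate}": getattr(self, f"{kind}_{gate}")
            for kind in ("W", "U", "b") for gate in "ifoc"
        })

    def __call__(self, x, h_prev, c_prev):
        return lstm_cell_step(x, h_prev, c_prev, self.gates)

    def zero_state(self, batch: int) -> tuple[Tensor, Tensor]:
        z = np.zeros((batch, self.n_hidden))
        return Tensor(z), Tensor(z.copy())


# ---------------------------------------------------------------------------
# optimisers
# ---------------------------------------------------------------------------


class _AdamBase:
    def __init__(self, params: list[Tensor], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def _adam_direction(self, i: int, grad: np.ndarray) -> np.ndarray:
        b1, b2 = self.betas
        self.m[i] = b1 * self.m[i] + (1 - b1) * grad
        self.v[i] = b2 * self.v[i] + (1 - b2) * grad**2
        mhat = self.m[i] / (1 - b1**self.t)
        vhat = self.v[i] / (1 - b2**self.t)
        return mhat / (np.sqrt(vhat) + self.eps)


class Adam(_AdamBase):
    """Adam with (coupled) L2 regularisation added to the gradient."""

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            grad = p.grad + self.weight_decay * p.data
            p.data -= self.lr * self._adam_direction(i, grad)


class AdamW(_AdamBase):
    """Adam with decoupled weight decay."""

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            p.data -= self.lr * self.weight_decay * p.data
            p.data -= self.lr * self._adam_direction(i, p.grad)
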