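"""Neural-network layers for 1-D physiological-signal regression.

Conventions: batches are channel-last, ``(B, L, C)`` — batch, temporal length,
feature channels. Convolutions use "same" zero padding; max-pooling uses
ceil-mode length arithmetic (``L_out = ceil(L / stride)``) with ignored
(-inf) padding at the right edge, so a 625-sample window shrinks through
four stride-3 pools as 625 -> 209 -> 70 -> 24 -> 8.
"""

from __future__ import annotations

import math

import numpy as np

from .tensor import Tensor, concat

__all__ = [
    "Module",
    "Linear",
    "Conv1dSame",
    "BatchNorm1d",
    "MaxPool1dCeil",
    "GRUCell",
    "BiGRU",
    "FeedForwardAttention",
]


class Module:
    """Base class: parameter traversal and train/eval mode switching."""

    def parameters(self) -> list[Tensor]:
        params: list[Tensor] = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
        return params

    def modules(self) -> list["Module"]:
        mods: list[Module] = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                mods.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        mods.extend(item.modules())
        return mods

    def train(self) -> None:
        for m in self.modules():
            m.training = True

    def eval(self) -> None:
        for m in self.modules():
            m.training = False

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.zero_grad()

    def state_dict(self) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {}

        def visit(obj: "Module", prefix: str) -> None:
            for name, v in obj.__dict__.items():
                if isinstance(v, Tensor):
                    out[prefix + name] = v.data.copy()
                elif isinstance(v, np.ndarray):
                    out[prefix + name] = v.copy()
                elif isinstance(v, Module):
                    visit(v, f"{prefix}{name}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{prefix}{name}.{i}.")

        visit(self, "")
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        def visit(obj: "Module", prefix: str) -> None:
            for name, v in obj.__dict__.items():
                key = prefix + name
                if isinstance(v, Tensor) and key in state:
                    v.data = np.array(state[key], dtype=np.float64)
                elif isinstance(v, np.ndarray) and key in state:
                    setattr(obj, name, np.array(state[key], dtype=np.float64))
                elif isinstance(v, Module):
                    visit(v, f"{key}.")
                elif isinstance(v, (list, tuple)):
                    for i, item in enumerate(v):
                        if isinstance(item, Module):
                            visit(item, f"{key}.{i}.")

        visit(self, "")


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int, shape) -> Tensor:
    limit = math.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=shape), requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, rng: np.random.Generator):
        self.W = _glorot(rng, in_features, out_features, (in_features, out_features))
        self.b = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1dSame(Module):
    """Kernel-3, stride-1 temporal convolution with same padding.

    Implemented as an unfold (three shifted views concatenated on the channel
    axis) followed by one affine map, so gradients come for free from the
    primitive ops.
    """

    def __init__(self, in_channels: int, out_channels: int, rng: np.random.Generator,
                 kernel: int = 3):
        if kernel % 2 != 1:
            raise ValueError("kernel must be odd for same padding")
        self.kernel = kernel
        self.W = _glorot(rng, kernel * in_channels, out_channels,
                         (kernel * in_channels, out_channels))
        self.b = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        half = self.kernel // 2
        xp = x.pad(((0, 0), (half, half), (0, 0)))
        cols = concat([xp[:, k:k + L, :] for k in range(self.kernel)], axis=2)
        return cols @ self.W + self.b


class BatchNorm1d(Module):
    """Per-channel batch normalization over the batch and time axes."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5):
        self.gamma = Tensor(np.ones(channels), requires_grad=True)
        self.beta = Tensor(np.zeros(channels), requires_grad=True)
        self.running_mean = np.zeros(channels)
        self.running_var = np.ones(channels)
        self.momentum = momentum
        self.eps = eps
        self.training = True

    def __call__(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 1), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 1), keepdims=True)
            self.running_mean = ((1 - self.momentum) * self.running_mean
                                 + self.momentum * mu.data.ravel())
            self.running_var = ((1 - self.momentum) * self.running_var
                                + self.momentum * var.data.ravel())
            xhat = (x - mu) / (var + self.eps).sqrt()
        else:
            xhat = (x - self.running_mean) * (1.0 / np.sqrt(self.running_var + self.eps))
        return xhat * self.gamma + self.beta


class MaxPool1dCeil(Module):
    """Max pool, size == stride, ceil-mode (same-padding length arithmetic)."""

    def __init__(self, size: int = 3):
        self.size = size

    def __call__(self, x: Tensor) -> Tensor:
        B, L, C = x.shape
        L_out = -(-L // self.size)  # ceil division
        padded = x.pad(((0, 0), (0, L_out * self.size - L), (0, 0)), value=-np.inf)
        return padded.reshape(B, L_out, self.size, C).max(axis=2)


class GRUCell(Module):
    """Gated recurrent unit cell.

    Update gate z, reset gate r and candidate state act on the concatenation
    ``[h_prev, x]``:

        z = sigmoid(W_z [h, x] + b_z)
        r = sigmoid(W_r [h, x] + b_r)
        h~ = tanh(W_h [r * h, x] + b_h)
        h' = (1 - z) * h + z * h~

    Biases are standard practice and on by default; ``bias=False`` reproduces
    the bare-matrix formulation.
    """

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 bias: bool = True):
        self.input_size = input_size
        self.hidden_size = hidden_size
        cat = hidden_size + input_size
        self.W_z = _glorot(rng, cat, hidden_size, (cat, hidden_size))
        self.W_r = _glorot(rng, cat, hidden_size, (cat, hidden_size))
        self.W_h = _glorot(rng, cat, hidden_size, (cat, hidden_size))
        self.bias = bias
        if bias:
            self.b_z = Tensor(np.zeros(hidden_size), requires_grad=True)
            self.b_r = Tensor(np.zeros(hidden_size), requires_grad=True)
            self.b_h = Tensor(np.zeros(hidden_size), requires_grad=True)

    def __call__(self, h_prev: Tensor, x: Tensor) -> Tensor:
        cat = concat([h_prev, x], axis=-1)
        z = cat @ self.W_z
        r = cat @ self.W_r
        if self.bias:
            z = z + self.b_z
            r = r + self.b_r
        z = z.sigmoid()
        r = r.sigmoid()
        cand = concat([r * h_prev, x], axis=-1) @ self.W_h
        if self.bias:
            cand = cand + self.b_h
        h_tilde = cand.tanh()
        return (1.0 - z) * h_prev + z * h_tilde


class BiGRU(Module):
    """Bidirectional GRU: forward and backward passes concatenated per step."""

    def __init__(self, input_size: int, hidden_size: int, rng: np.random.Generator,
                 bias: bool = True):
        self.fwd = GRUCell(input_size, hidden_size, rng, bias=bias)
        self.bwd = GRUCell(input_size, hidden_size, rng, bias=bias)
        self.hidden_size = hidden_size

    def _run(self, cell: GRUCell, xs: list[Tensor], B: int) -> list[Tensor]:
        h = Tensor(np.zeros((B, cell.hidden_size)))
        out = []
        for x in xs:
            h = cell(h, x)
            out.append(h)
        return out

    def __call__(self, x: Tensor) -> Tensor:
        B, T, F = x.shape
        if T < 1:
            raise ValueError("empty sequence")
        steps = [x[:, t, :] for t in range(T)]
        hf = self._run(self.fwd, steps, B)
        hb = self._run(self.bwd, steps[::-1], B)[::-1]
        per_step = [concat([f, b], axis=-1).reshape(B, 1, 2 * self.hidden_size)
                    for f, b in zip(hf, hb)]
        return concat(per_step, axis=1)


class FeedForwardAttention(Module):
    """Scalar score per timestep -> softmax weights -> weighted sum.

    score_i = tanh(W_s h_i + b); a = softmax(score); v = sum_i a_i h_i.
    """

    def __init__(self, feature_size: int, rng: np.random.Generator):
        self.W_s = _glorot(rng, feature_size, 1, (feature_size, 1))
        self.b = Tensor(np.zeros(1), requires_grad=True)

    def __call__(self, H: Tensor) -> tuple[Tensor, Tensor]:
        s = (H @ self.W_s + self.b).tanh()     # (B, T, 1)
        a = s.softmax(axis=1)                  # weights over timesteps
        v = (a * H).sum(axis=1)                # (B, F)
        B, T, _ = H.shape
        return v, a.reshape(B, T)
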