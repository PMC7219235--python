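"""CNN + Bi-GRU + feed-forward-attention blood-pressure regressor.

Architecture (for a 625-sample, C-channel 5-s window at 125 Hz):

* VGG-style 1-D CNN: four blocks of {2, 2, 3, 3} conv(kernel 3, same
  padding)-BN-ReLU layers with channel widths 64/128/256/512, each block
  closed by a max-pool of size 3, stride 3 with ceil-mode lengths, so the
  temporal axis shrinks 625 -> 209 -> 70 -> 24 -> 8.
* Bi-GRU with 64 hidden nodes per direction; per-timestep concatenation
  gives 128 features at each of the 8 steps.
* Feed-forward (self-)attention: a one-layer perceptron maps each 128-d
  hidden state to a scalar tanh score; softmax over timesteps yields
  weights a_i; the context vector is the weighted sum of hidden states.
* A final affine layer maps the 128-d context to (SBP, DBP).

The attention weights are surfaced by ``forward`` so heat-map analyses can
attribute the estimate to window sections.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import (
    BatchNorm1d,
    BiGRU,
    Conv1dSame,
    FeedForwardAttention,
    Linear,
    MaxPool1dCeil,
    Module,
    Tensor,
)

__all__ = ["ModelConfig", "BPModel", "cnn_output_lengths"]

FULL_CONV_BLOCKS = [(2, 64), (2, 128), (3, 256), (3, 512)]
REDUCED_CONV_BLOCKS = [(1, 8), (1, 16), (1, 32), (1, 64)]


@dataclass
class ModelConfig:
    """Hyperparameters of the regressor.

    ``conv_blocks`` lists (n_conv_layers, out_channels) per block; the
    default mirrors the full network, :meth:`reduced` gives a small variant
    for CPU-scale experiments with the same depth-4 pooling chain.
    """

    in_channels: int = 3
    conv_blocks: list[tuple[int, int]] = field(
        default_factory=lambda: [tuple(b) for b in FULL_CONV_BLOCKS])
    kernel: int = 3
    pool_size: int = 3
    gru_hidden: int = 64
    head_out: int = 2
    gru_bias: bool = True
    seed: int = 0

    @classmethod
    def reduced(cls, in_channels: int = 3, gru_hidden: int = 16,
                seed: int = 0) -> "ModelConfig":
        return cls(in_channels=in_channels,
                   conv_blocks=[tuple(b) for b in REDUCED_CONV_BLOCKS],
                   gru_hidden=gru_hidden, seed=seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self))

    @classmethod
    def from_json(cls, s: str) -> "ModelConfig":
        d = json.loads(s)
        d["conv_blocks"] = [tuple(b) for b in d["conv_blocks"]]
        return cls(**d)


def cnn_output_lengths(L: int, n_blocks: int = 4, pool: int = 3) -> list[int]:
    """Temporal lengths through the pooling chain (ceil-mode), input first."""
    out = [L]
    for _ in range(n_blocks):
        L = -(-L // pool)
        out.append(L)
    return out


class BPModel(Module):
    """The end-to-end regressor; see the module docstring for the layout."""

    def __init__(self, config: ModelConfig | None = None):
        self.config = config or ModelConfig()
        rng = np.random.default_rng(self.config.seed)
        self.convs: list[Conv1dSame] = []
        self.bns: list[BatchNorm1d] = []
        self.block_sizes: list[int] = []
        c_in = self.config.in_channels
        for n_layers, c_out in self.config.conv_blocks:
            self.block_sizes.append(n_layers)
            for _ in range(n_layers):
                self.convs.append(Conv1dSame(c_in, c_out, rng,
                                             kernel=self.config.kernel))
                self.bns.append(BatchNorm1d(c_out))
                c_in = c_out
        self.pool = MaxPool1dCeil(self.config.pool_size)
        self.bigru_layer = BiGRU(c_in, self.config.gru_hidden, rng,
                                 bias=self.config.gru_bias)
        feat = 2 * self.config.gru_hidden
        self.attention = FeedForwardAttention(feat, rng)
        self.head = Linear(feat, self.config.head_out, rng)
        # affine output calibration (set by training when targets are
        # normalized for optimization; identity by default)
        self.target_mean = np.zeros(self.config.head_out)
        self.target_scale = np.ones(self.config.head_out)

    # -- stages ---------------------------------------------------------------

    def cnn_encode(self, x: Tensor | np.ndarray) -> Tensor:
        """Conv blocks + pools: (B, L, C_in) -> (B, ceil(L/81), C_last)."""
        h = x if isinstance(x, Tensor) else Tensor(np.asarray(x))
        if h.ndim == 2:
            h = h.reshape(1, *h.shape)
        if h.shape[-1] != self.config.in_channels:
            raise ValueError(
                f"expected {self.config.in_channels} input channels, "
                f"got {h.shape[-1]}")
        i = 0
        for n_layers in self.block_sizes:
            for _ in range(n_layers):
                h = self.bns[i](self.convs[i](h)).relu()
                i += 1
            h = self.pool(h)
        return h

    def bigru(self, seq: Tensor) -> Tensor:
        """(B, T, C) -> (B, T, 2 * gru_hidden) bidirectional hidden states."""
        return self.bigru_layer(seq)

    def attention_pool(self, H: Tensor) -> tuple[Tensor, Tensor]:
        """(B, T, F) -> context (B, F) and attention weights (B, T)."""
        return self.attention(H)

    def forward(self, x: Tensor | np.ndarray) -> tuple[Tensor, Tensor]:
        """Full pass: returns ((B, 2) BP estimates, (B, T) attention)."""
        feats = self.cnn_encode(x)
        H = self.bigru(feats)
        v, a = self.attention_pool(H)
        return self.head(v), a

    __call__ = forward

    def predict(self, X: np.ndarray, batch_size: int = 512
                ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Numpy inference: (sbp_hat, dbp_hat, attention) per input window."""
        self.eval()
        outs, atts = [], []
        for i in range(0, len(X), batch_size):
            y, a = self.forward(X[i:i + batch_size])
            outs.append(y.data)
            atts.append(a.data)
        y = np.concatenate(outs) * self.target_scale + self.target_mean
        a = np.concatenate(atts)
        return y[:, 0], y[:, 1], a

    # -- bookkeeping ----------------------------------------------------------

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def summary(self, input_len: int = 625) -> str:
        """A layer/shape table for a given input length."""
        rows = [("Network", "Layer", "Shape", "Out")]
        L = input_len
        c_in = self.config.in_channels
        for bi, (n_layers, c_out) in enumerate(self.config.conv_blocks):
            for _ in range(n_layers):
                rows.append(("CNN", "Conv+BN+ReLU", f"{L}x{c_in}", str(c_out)))
                c_in = c_out
            L_next = -(-L // self.config.pool_size)
            rows.append(("CNN", f"Maxpool(size={self.config.pool_size})",
                         f"{L}x{c_in}", "-"))
            L = L_next
        h = self.config.gru_hidden
        rows.append(("Bi-GRU", "Forward", f"{L}x{c_in}", str(h)))
        rows.append(("Bi-GRU", "Backward", f"{L}x{c_in}", str(h)))
        rows.append(("Attention", "1-layer perceptron", f"{L}x{2 * h}", "1"))
        rows.append(("Head", "1-layer perceptron", str(2 * h),
                     str(self.config.head_out)))
        width = [max(len(r[i]) for r in rows) for i in range(4)]
        return "\n".join(
            "  ".join(col.ljust(w) for col, w in zip(r, width)) for r in rows)

    def save(self, path: str | Path) -> None:
        """Checkpoint: one .npz with weights plus the JSON config."""
        state = self.state_dict()
        state["__config__"] = np.frombuffer(
            self.config.to_json().encode(), dtype=np.uint8)
        np.savez(path, **state)

    @classmethod
    def load(cls, path: str | Path) -> "BPModel":
        with np.load(path) as data:
            cfg = ModelConfig.from_json(bytes(data["__config__"]).decode())
            model = cls(cfg)
            state = {k: data[k] for k in data.files if k != "__config__"}
        model.load_state_dict(state)
        return model
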