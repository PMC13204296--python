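"""Neural-network building blocks on top of the autodiff engine."""
from __future__ import annotations

import math
from collections import OrderedDict

import numpy as np

from .tensor import Tensor, causal_conv1d, softmax

__all__ = [
    "RngRef",
    "Module",
    "ModuleList",
    "Linear",
    "CausalConv1d",
    "BatchNorm1d",
    "LayerNorm",
    "Dropout",
    "LearnedPositionalEncoding",
    "SinusoidalPositionalEncoding",
    "MultiHeadAttention",
    "FeedForward",
    "EncoderLayer",
    "xavier_uniform",
]


class RngRef:
    """Shared, reseedable random stream for stochastic layers (dropout)."""

    def __init__(self, seed: int | None = None):
        self.gen = np.random.default_rng(seed)

    def reseed(self, seed: int) -> None:
        self.gen = np.random.default_rng(seed)


def xavier_uniform(shape: tuple[int, ...], fan_in: int, fan_out: int, rng) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=shape)


class Module:
    """Minimal module system: parameter discovery, train/eval, state dicts."""

    def __init__(self):
        self.training = True

    def forward(self, x: Tensor) -> Tensor:  # pragma: no cover - abstract
        raise NotImplementedError

    def __call__(self, x: Tensor) -> Tensor:
        return self.forward(x)

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, ModuleList):
                for i, m in enumerate(val):
                    yield f"{name}.{i}", m

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix=f"{prefix}{cname}.")

    def parameters(self) -> list[Tensor]:
        return [p for _, p in self.named_parameters()]

    def train(self, mode: bool = True):
        self.training = mode
        for _, child in self._children():
            child.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def _buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, np.ndarray):
                yield prefix + name, val
        for cname, child in self._children():
            yield from child._buffers(prefix=f"{prefix}{cname}.")

    def state_dict(self) -> "OrderedDict[str, np.ndarray]":
        out: OrderedDict[str, np.ndarray] = OrderedDict()
        for name, p in self.named_parameters():
            out[name] = p.data.copy()
        for name, buf in self._buffers():
            out[name] = buf.copy()
        return out

    def load_state_dict(self, state: dict) -> None:
        params = dict(self.named_parameters())
        buffers = dict(self._buffers())
        for name, arr in state.items():
            if name in params:
                if params[name].data.shape != arr.shape:
                    raise ValueError(f"shape mismatch for parameter {name!r}")
                params[name].data = np.asarray(arr, dtype=np.float64).copy()
            elif name in buffers:
                buffers[name][...] = arr
            else:
                raise KeyError(f"unexpected key in state dict: {name!r}")
        missing = set(params) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")


class ModuleList(list):
    pass


class Linear(Module):
    def __init__(self, in_features: int, out_features: int, bias: bool = True, *, rng):
        super().__init__()
        self.weight = Tensor(
            xavier_uniform((in_features, out_features), in_features, out_features, rng),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True) if bias else None

    def forward(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class CausalConv1d(Module):
    """Dilated causal convolution with stride; preserves length at stride 1."""

    def __init__(
        self,
        in_channels: int,
        out_channels: int,
        kernel_size: int,
        dilation: int = 1,
        stride: int = 1,
        bias: bool = True,
        *,
        rng,
    ):
        super().__init__()
        fan_in = in_channels * kernel_size
        fan_out = out_channels * kernel_size
        self.weight = Tensor(
            xavier_uniform((out_channels, in_channels, kernel_size), fan_in, fan_out, rng),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True) if bias else None
        self.dilation = dilation
        self.stride = stride

    def forward(self, x: Tensor) -> Tensor:
        return causal_conv1d(x, self.weight, self.bias, self.dilation, self.stride)


class BatchNorm1d(Module):
    """Batch normalization over (batch, time) for each channel of (B, C, T)."""

    def __init__(self, num_features: int, eps: float = 1e-5, momentum: float = 0.1, affine: bool = True):
        super().__init__()
        self.eps = eps
        self.momentum = momentum
        if affine:
            self.weight = Tensor(np.ones(num_features), requires_grad=True)
            self.bias = Tensor(np.zeros(num_features), requires_grad=True)
        else:
            self.weight = None
            self.bias = None
        self.running_mean = np.zeros(num_features)
        self.running_var = np.ones(num_features)

    def forward(self, x: Tensor) -> Tensor:
        if self.training:
            mu = x.mean(axis=(0, 2), keepdims=True)
            var = ((x - mu) ** 2).mean(axis=(0, 2), keepdims=True)
            m = self.momentum
            self.running_mean = (1 - m) * self.running_mean + m * mu.data.reshape(-1)
            self.running_var = (1 - m) * self.running_var + m * var.data.reshape(-1)
        else:
            mu = Tensor(self.running_mean[None, :, None])
            var = Tensor(self.running_var[None, :, None])
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        if self.weight is not None:
            w = self.weight.reshape(1, -1, 1)
            b = self.bias.reshape(1, -1, 1)
            xhat = xhat * w + b
        return xhat


class LayerNorm(Module):
    """Normalization over the trailing feature axis with learned affine."""

    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.eps = eps
        self.weight = Tensor(np.ones(dim), requires_grad=True)
        self.bias = Tensor(np.zeros(dim), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        var = ((x - mu) ** 2).mean(axis=-1, keepdims=True)
        xhat = (x - mu) / ((var + self.eps) ** 0.5)
        return xhat * self.weight + self.bias


class Dropout(Module):
    def __init__(self, p: float, rng_ref: RngRef):
        super().__init__()
        if not 0.0 <= p < 1.0:
            raise ValueError("dropout probability must be in [0, 1)")
        self.p = p
        self.rng_ref = rng_ref

    def forward(self, x: Tensor) -> Tensor:
        if not self.training or self.p == 0.0:
            return x
        keep = 1.0 - self.p
        mask = (self.rng_ref.gen.random(x.shape) < keep) / keep
        return x * Tensor(mask)


class LearnedPositionalEncoding(Module):
    """Trainable per-time-step offset table added to projected embeddings."""

    def __init__(self, max_len: int, d_model: int, *, rng):
        super().__init__()
        self.max_len = max_len
        self.table = Tensor(0.02 * rng.standard_normal((1, max_len, d_model)), requires_grad=True)

    def forward(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        if T > self.max_len:
            raise ValueError(
                f"sequence length {T} exceeds positional table length {self.max_len}"
            )
        return x + self.table[:, :T, :]


class SinusoidalPositionalEncoding(Module):
    def __init__(self, max_len: int, d_model: int):
        super().__init__()
        self.max_len = max_len
        pos = np.arange(max_len)[:, None]
        i = np.arange(d_model // 2)[None, :]
        angles = pos / np.power(10000.0, 2 * i / d_model)
        table = np.zeros((max_len, d_model))
        table[:, 0::2] = np.sin(angles)
        table[:, 1::2] = np.cos(angles)
        self.pe = table[None]  # buffer, not trained

    def forward(self, x: Tensor) -> Tensor:
        T = x.shape[1]
        if T > self.max_len:
            raise ValueError(
                f"sequence length {T} exceeds positional table length {self.max_len}"
            )
        return x + Tensor(self.pe[:, :T, :])


class MultiHeadAttention(Module):
    """Scaled dot-product attention with h parallel heads and output projection."""

    def __init__(self, d_model: int, n_heads: int, dropout: float, rng_ref: RngRef, *, rng, bias: bool = True):
        super().__init__()
        if d_model % n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        self.d_model = d_model
        self.n_heads = n_heads
        self.d_k = d_model // n_heads
        self.wq = Linear(d_model, d_model, bias=bias, rng=rng)
        self.wk = Linear(d_model, d_model, bias=bias, rng=rng)
        self.wv = Linear(d_model, d_model, bias=bias, rng=rng)
        self.wo = Linear(d_model, d_model, bias=bias, rng=rng)
        self.attn_dropout = Dropout(dropout, rng_ref)

    def _split(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        return x.reshape(B, T, self.n_heads, self.d_k).transpose(0, 2, 1, 3)

    def attention_weights(self, x: Tensor) -> np.ndarray:
        """Row-stochastic (B, h, T, T) attention matrix, inference only."""
        q, k = self._split(self.wq(x)), self._split(self.wk(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_k))
        return softmax(scores, axis=-1).data

    def forward(self, x: Tensor) -> Tensor:
        B, T, _ = x.shape
        q, k, v = self._split(self.wq(x)), self._split(self.wk(x)), self._split(self.wv(x))
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / math.sqrt(self.d_k))
        attn = softmax(scores, axis=-1)
        attn = self.attn_dropout(attn)
        ctx = attn @ v  # (B, h, T, d_k)
        ctx = ctx.transpose(0, 2, 1, 3).reshape(B, T, self.d_model)
        return self.wo(ctx)


class FeedForward(Module):
    """Position-wise two-layer network with ReLU between."""

    def __init__(self, d_model: int, ffn_dim: int, dropout: float, rng_ref: RngRef, *, rng, bias: bool = True):
        super().__init__()
        self.fc1 = Linear(d_model, ffn_dim, bias=bias, rng=rng)
        self.fc2 = Linear(ffn_dim, d_model, bias=bias, rng=rng)
        self.dropout = Dropout(dropout, rng_ref)

    def forward(self, x: Tensor) -> Tensor:
        return self.fc2(self.dropout(self.fc1(x).relu()))


class EncoderLayer(Module):
    """Post-norm residual encoder layer: attention then feed-forward."""

    def __init__(self, d_model: int, n_heads: int, ffn_dim: int, dropout: float, rng_ref: RngRef, *, rng):
        super().__init__()
        self.mha = MultiHeadAttention(d_model, n_heads, dropout, rng_ref, rng=rng)
        self.norm1 = LayerNorm(d_model)
        self.ffn = FeedForward(d_model, ffn_dim, dropout, rng_ref, rng=rng)
        self.norm2 = LayerNorm(d_model)

    def forward(self, x: Tensor) -> Tensor:
        z1 = self.norm1(x + self.mha(x))
        return self.norm2(z1 + self.ffn(z1))
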