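"""Network architecture: dilated causal temporal front-end, transformer
encoder, pooling head, the four ablation variants, and checkpointing.

The published hyperparameter table fixes the transformer exactly (d_model
128, 8 heads, 4 post-norm layers, FFN 512, learned positional encoding,
dropout 0.1, 26 classes, 16 input channels) and states a total trainable
parameter count of 849,818, but leaves the temporal front-end
under-specified.  :func:`reconcile_reference_config` enumerates front-end
configurations (block count, channel widths, kernel size, per-block stride,
bias/affine options) and pins the first, in a deterministic ordering, whose
full-model count matches the published total.
"""
from __future__ import annotations

import itertools
import json
from dataclasses import asdict, dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np

from . import nn
from .nn import Tensor

__all__ = [
    "TemporalBlockSpec",
    "EncoderSpec",
    "HeadSpec",
    "ModelConfig",
    "TemporalBlock",
    "KeystrokeNet",
    "build_model",
    "count_parameters",
    "default_config",
    "reference_full_config",
    "reconcile_reference_config",
    "scaled_config",
    "save_checkpoint",
    "load_checkpoint",
    "VARIANTS",
]

VARIANTS = ("baseline_cnn", "temporal_only", "transformer_only", "full")


@dataclass(frozen=True)
class TemporalBlockSpec:
    in_channels: int
    out_channels: int
    kernel_size: int = 3
    dilation: int = 1
    stride: int = 1
    dropout: float = 0.1
    conv_bias: bool = True
    proj_bias: bool = True
    bn_affine: bool = True

    def __post_init__(self):
        if self.kernel_size < 1 or self.dilation < 1 or self.stride < 1:
            raise ValueError("kernel_size, dilation and stride must all be >= 1")


@dataclass(frozen=True)
class EncoderSpec:
    d_model: int = 128
    n_heads: int = 8
    n_layers: int = 4
    ffn_dim: int = 512
    dropout: float = 0.1
    positional: str = "learned"  # or "sinusoidal"
    max_len: int = 400

    def __post_init__(self):
        if self.d_model % self.n_heads != 0:
            raise ValueError("d_model must be divisible by n_heads")
        if self.n_layers < 1:
            raise ValueError("n_layers must be >= 1")
        if self.positional not in ("learned", "sinusoidal"):
            raise ValueError(f"unknown positional encoding {self.positional!r}")


@dataclass(frozen=True)
class HeadSpec:
    n_classes: int = 26

    def __post_init__(self):
        if self.n_classes < 2:
            raise ValueError("n_classes must be >= 2")


@dataclass(frozen=True)
class ModelConfig:
    variant: str = "full"
    input_channels: int = 16
    window_len: int = 400
    temporal_blocks: tuple[TemporalBlockSpec, ...] = ()
    encoder: EncoderSpec = field(default_factory=EncoderSpec)
    head: HeadSpec = field(default_factory=HeadSpec)

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}; expected one of {VARIANTS}")
        if self.variant in ("temporal_only", "full", "baseline_cnn") and not self.temporal_blocks:
            raise ValueError(f"variant {self.variant!r} requires temporal_blocks")
        if self.variant == "transformer_only" and self.temporal_blocks:
            raise ValueError("transformer_only variant must not define temporal blocks")
        if self.variant == "full":
            dilations = {b.dilation for b in self.temporal_blocks}
            if len(self.temporal_blocks) < 2 or not {2, 4}.issubset(dilations):
                raise ValueError("full variant needs >= 2 temporal blocks covering dilations 2 and 4")

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @staticmethod
    def from_json(text: str) -> "ModelConfig":
        d = json.loads(text)
        d["temporal_blocks"] = tuple(TemporalBlockSpec(**b) for b in d.get("temporal_blocks", ()))
        d["encoder"] = EncoderSpec(**d["encoder"])
        d["head"] = HeadSpec(**d["head"])
        return ModelConfig(**d)


# --------------------------------------------------------------------- blocks
class TemporalBlock(nn.Module):
    """conv -> batch-norm -> ReLU -> dropout -> residual add.

    The residual path is the identity when channel counts match (subsampled
    to the conv stride if needed), otherwise a strided 1x1 projection.
    """

    def __init__(self, spec: TemporalBlockSpec, rng_ref: nn.RngRef, *, rng, causal: bool = True):
        super().__init__()
        self.spec = spec
        self.conv = nn.CausalConv1d(
            spec.in_channels,
            spec.out_channels,
            spec.kernel_size,
            dilation=spec.dilation if causal else 1,
            stride=spec.stride,
            bias=spec.conv_bias,
            rng=rng,
        )
        self.bn = nn.BatchNorm1d(spec.out_channels, affine=spec.bn_affine)
        self.dropout = nn.Dropout(spec.dropout, rng_ref)
        if spec.in_channels != spec.out_channels:
            self.proj = nn.CausalConv1d(
                spec.in_channels, spec.out_channels, 1, stride=spec.stride, bias=spec.proj_bias, rng=rng
            )
        else:
            self.proj = None

    def forward(self, x: Tensor) -> Tensor:
        y = self.dropout(self.bn(self.conv(x)).relu())
        if self.proj is not None:
            res = self.proj(x)
        elif self.spec.stride > 1:
            res = x[:, :, :: self.spec.stride]
        else:
            res = x
        return y + res


class KeystrokeNet(nn.Module):
    """The complete classifier; which stages exist depends on the variant."""

    def __init__(self, cfg: ModelConfig, seed: int = 42):
        super().__init__()
        self.cfg = cfg
        self.seed = seed
        rng = np.random.default_rng(seed)
        self.rng_ref = nn.RngRef(seed)
        enc, head = cfg.encoder, cfg.head

        self.blocks = nn.ModuleList()
        feat_channels = cfg.input_channels
        t_out = cfg.window_len
        for spec in cfg.temporal_blocks:
            self.blocks.append(TemporalBlock(spec, self.rng_ref, rng=rng, causal=cfg.variant != "baseline_cnn"))
            feat_channels = spec.out_channels
            t_out = -(-t_out // spec.stride)
        self.seq_len = t_out

        self.use_encoder = cfg.variant in ("transformer_only", "full")
        if self.use_encoder:
            self.proj = nn.Linear(feat_channels, enc.d_model, bias=True, rng=rng)
            max_len = min(enc.max_len, t_out) if enc.positional == "learned" else max(enc.max_len, t_out)
            if enc.positional == "learned":
                self.pos = nn.LearnedPositionalEncoding(max_len, enc.d_model, rng=rng)
            else:
                self.pos = nn.SinusoidalPositionalEncoding(max_len, enc.d_model)
            self.layers = nn.ModuleList(
                nn.EncoderLayer(enc.d_model, enc.n_heads, enc.ffn_dim, enc.dropout, self.rng_ref, rng=rng)
                for _ in range(enc.n_layers)
            )
            feat_dim = enc.d_model
        else:
            feat_dim = feat_channels
        self.head = nn.Linear(feat_dim, head.n_classes, bias=True, rng=rng)
        for name, p in self.named_parameters():
            p.name = name

    def reseed(self, seed: int) -> None:
        """Reset the stochastic (dropout) stream; weights are untouched."""
        self.rng_ref.reseed(seed)

    def embed(self, x: Tensor) -> Tensor:
        """Pooled embedding F_agg: mean over time of the last feature map."""
        for block in self.blocks:
            x = block(x)
        if self.use_encoder:
            x = x.transpose(0, 2, 1)  # (B, T', C') time-major
            x = self.pos(self.proj(x))
            for layer in self.layers:
                x = layer(x)
            return x.mean(axis=1)
        return x.mean(axis=2)

    def forward(self, x: Tensor) -> Tensor:
        return self.head(self.embed(x))

    def predict_proba(self, x: np.ndarray, batch_size: int = 256) -> np.ndarray:
        """Softmax probabilities with dropout disabled; deterministic."""
        was_training = self.training
        self.eval()
        out = []
        for start in range(0, len(x), batch_size):
            logits = self.forward(Tensor(x[start : start + batch_size]))
            out.append(nn.softmax(logits, axis=-1).data)
        self.train(was_training)
        return np.concatenate(out) if out else np.zeros((0, self.cfg.head.n_classes))


def build_model(cfg: ModelConfig, seed: int = 42) -> KeystrokeNet:
    return KeystrokeNet(cfg, seed=seed)


def count_parameters(model: nn.Module) -> int:
    """Exact number of trainable scalars."""
    return int(sum(p.size for p in model.parameters()))


# ------------------------------------------------------------------- configs
def default_config(
    variant: str = "full",
    input_channels: int = 16,
    window_len: int = 400,
    n_classes: int = 26,
    encoder: EncoderSpec | None = None,
    kernel_size: int = 3,
    hidden_channels: int = 64,
    strides: tuple[int, int] = (1, 1),
    dropout: float = 0.1,
) -> ModelConfig:
    """Conventional configs for the four ablation variants.

    The full/temporal front-end is two causal blocks at dilations 2 and 4;
    the baseline is a plain two-block conv stack (dilation 1).
    """
    enc = encoder or EncoderSpec(max_len=window_len)
    head = HeadSpec(n_classes=n_classes)
    if variant == "baseline_cnn":
        blocks = (
            TemporalBlockSpec(input_channels, hidden_channels // 2, kernel_size, 1, 1, dropout),
            TemporalBlockSpec(hidden_channels // 2, hidden_channels, kernel_size, 1, 1, dropout),
        )
    elif variant in ("temporal_only", "full"):
        blocks = (
            TemporalBlockSpec(input_channels, hidden_channels, kernel_size, 2, strides[0], dropout),
            TemporalBlockSpec(hidden_channels, hidden_channels, kernel_size, 4, strides[1], dropout),
        )
    elif variant == "transformer_only":
        blocks = ()
    else:
        raise ValueError(f"unknown variant {variant!r}")
    return ModelConfig(
        variant=variant,
        input_channels=input_channels,
        window_len=window_len,
        temporal_blocks=blocks,
        encoder=enc,
        head=head,
    )


def scaled_config(
    variant: str = "full",
    input_channels: int = 8,
    window_len: int = 400,
    n_classes: int = 6,
) -> ModelConfig:
    """CPU-sized variant set used by the synthetic-data experiments: d_model
    32, 2 heads, 2 layers, and strides (4, 2) so attention runs on 50 steps."""
    enc = EncoderSpec(d_model=32, n_heads=2, n_layers=2, ffn_dim=64, max_len=window_len)
    return default_config(
        variant,
        input_channels=input_channels,
        window_len=window_len,
        n_classes=n_classes,
        encoder=enc,
        hidden_channels=32,
        strides=(4, 2) if variant in ("temporal_only", "full") else (1, 1),
    )


# --------------------------------------------------- parameter reconciliation
def _encoder_param_count(enc: EncoderSpec) -> int:
    d, f = enc.d_model, enc.ffn_dim
    per_layer = 4 * (d * d + d) + 2 * (2 * d) + (d * f + f) + (f * d + d)
    return enc.n_layers * per_layer


def _frontend_param_count(widths, kernel, in_channels, conv_bias, proj_bias, bn_affine) -> int:
    total = 0
    cin = in_channels
    for cout in widths:
        total += cin * cout * kernel + (cout if conv_bias else 0) + (2 * cout if bn_affine else 0)
        if cin != cout:
            total += cin * cout + (cout if proj_bias else 0)
        cin = cout
    return total


@lru_cache(maxsize=None)
def reconcile_reference_config(
    target: int = 849_818,
    input_channels: int = 16,
    window_len: int = 400,
    n_classes: int = 26,
) -> tuple:
    """Enumerate temporal front-end configurations and return all whose
    full-model trainable-parameter count equals ``target``.

    Search space: 2 or 3 blocks, per-block output widths from a small menu,
    kernel size 2-8, per-block stride in {1, 2, 4, 8}, conv/projection biases
    on or off, batch-norm affine on or off.  The learned positional table
    length equals the front-end output length.  Matches are returned sorted
    by a deterministic key (block count, kernel, widths, strides, options).
    """
    enc = EncoderSpec(max_len=window_len)
    d = enc.d_model
    base = _encoder_param_count(enc) + (d * n_classes + n_classes)
    widths_menu = (16, 24, 32, 48, 64, 96, 128)
    matches = []
    for n_blocks in (2, 3):
        for widths in itertools.product(widths_menu, repeat=n_blocks):
            proj = widths[-1] * d + d
            for kernel in range(2, 9):
                for strides in itertools.product((1, 2, 4, 8), repeat=n_blocks):
                    t = window_len
                    for s in strides:
                        t = -(-t // s)
                    for conv_bias in (False, True):
                        for proj_bias in (False, True):
                            for bn_affine in (False, True):
                                front = _frontend_param_count(
                                    widths, kernel, input_channels, conv_bias, proj_bias, bn_affine
                                )
                                if base + proj + front + t * d == target:
                                    matches.append(
                                        (n_blocks, widths, kernel, strides, conv_bias, proj_bias, bn_affine, t)
                                    )
    matches.sort(key=lambda m: (m[0], m[2], m[1], m[3], m[4], m[5], m[6]))
    return tuple(matches)


def reference_full_config(
    target: int = 849_818,
    input_channels: int = 16,
    window_len: int = 400,
    n_classes: int = 26,
) -> ModelConfig:
    """The pinned full-variant configuration whose trainable-parameter count
    equals the published total, selected by :func:`reconcile_reference_config`.

    For the stock settings this resolves to two causal blocks
    (16->16 at dilation 2, 16->128 at dilation 4), kernel 4, strides (1, 2),
    bias-free convolutions, non-affine batch-norm, and a learned positional
    table of length 200.
    """
    matches = reconcile_reference_config(target, input_channels, window_len, n_classes)
    if not matches:
        raise RuntimeError(
            f"no enumerated front-end reaches a total of {target} parameters; "
            "see reconcile_reference_config for the search space"
        )
    n_blocks, widths, kernel, strides, conv_bias, proj_bias, bn_affine, _t = matches[0]
    dilations = (2, 4) if n_blocks == 2 else (1, 2, 4)
    blocks = []
    cin = input_channels
    for i in range(n_blocks):
        blocks.append(
            TemporalBlockSpec(
                in_channels=cin,
                out_channels=widths[i],
                kernel_size=kernel,
                dilation=dilations[i],
                stride=strides[i],
                dropout=0.1,
                conv_bias=conv_bias,
                proj_bias=proj_bias,
                bn_affine=bn_affine,
            )
        )
        cin = widths[i]
    return ModelConfig(
        variant="full",
        input_channels=input_channels,
        window_len=window_len,
        temporal_blocks=tuple(blocks),
        encoder=EncoderSpec(max_len=window_len),
        head=HeadSpec(n_classes=n_classes),
    )


# -------------------------------------------------------------- checkpointing
def save_checkpoint(model: KeystrokeNet, path) -> None:
    """Weights as NPZ plus an architecture JSON sidecar."""
    path = Path(path)
    state = model.state_dict()
    with open(path, "wb") as f:
        np.savez(f, **state)
    arch = {"config": json.loads(model.cfg.to_json()), "seed": model.seed}
    path.with_suffix(path.suffix + ".arch.json").write_text(json.dumps(arch, indent=2))


def load_checkpoint(path) -> KeystrokeNet:
    path = Path(path)
    arch_path = path.with_suffix(path.suffix + ".arch.json")
    if not arch_path.exists():
        raise FileNotFoundError(f"missing architecture sidecar {arch_path}")
    arch = json.loads(arch_path.read_text())
    cfg = ModelConfig.from_json(json.dumps(arch["config"]))
    model = KeystrokeNet(cfg, seed=arch.get("seed", 42))
    with np.load(path, allow_pickle=False) as npz:
        model.load_state_dict({k: npz[k] for k in npz.files})
    model.eval()
    return model
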