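"""Network architectures: the attention-augmented multi-scale regressor
(``incepspect_cbam``) plus the two deep baselines (``deepspectra``,
``cnn1d``), and the ablation variants.

Topology of ``incepspect_cbam``:

    stem conv(32, k7, s3) -> inception block 1 -> inception block 2
    -> CBAM -> + residual (block-1 output through a 1x1-conv adapter)
    -> Mish -> flatten -> BN -> FC (Mish, BN) -> dropout -> 1 output

Batch norm follows every convolution, the flatten and the FC layer; Mish
follows every convolution and FC layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autograd import Tensor, concat
from .layers import (
    AdaptiveMaxPool1d,
    BatchNorm1d,
    Conv1d,
    Dropout,
    Linear,
    MaxPool1d,
    Module,
)

__all__ = [
    "InceptionSpec",
    "CbamSpec",
    "NetConfig",
    "ChannelAttention",
    "SpatialAttention",
    "Cbam",
    "InceptionBlock",
    "mish",
    "channel_attention",
    "spatial_attention",
    "cbam",
    "build_network",
]

ARCHITECTURES = ("incepspect_cbam", "deepspectra", "cnn1d")
VARIANTS = ("full", "no_cbam", "no_inception", "no_residual")


def mish(x):
    """Elementwise x * tanh(softplus(x)), numerically stable, for plain
    arrays; Tensor inputs go through the autodiff op."""
    if isinstance(x, Tensor):
        return x.mish()
    x = np.asarray(x, dtype=float)
    sp = np.maximum(x, 0.0) + np.log1p(np.exp(-np.abs(x)))
    return x * np.tanh(sp)


@dataclass(frozen=True)
class InceptionSpec:
    """Output channels per branch: 1x1, 3x1, 5x1 and pool->1x1."""

    ch_1x1: int = 8
    ch_3x1: int = 8
    ch_5x1: int = 8
    ch_pool: int = 8

    def __post_init__(self) -> None:
        if min(self.ch_1x1, self.ch_3x1, self.ch_5x1, self.ch_pool) < 1:
            raise ValueError("all branch channel counts must be >= 1")

    @property
    def out_channels(self) -> int:
        return self.ch_1x1 + self.ch_3x1 + self.ch_5x1 + self.ch_pool


@dataclass(frozen=True)
class CbamSpec:
    reduction_ratio: int = 8
    spatial_kernel: int = 7

    def __post_init__(self) -> None:
        if self.reduction_ratio < 1:
            raise ValueError("reduction_ratio must be >= 1")
        if self.spatial_kernel % 2 != 1:
            raise ValueError("spatial_kernel must be odd")


@dataclass(frozen=True)
class NetConfig:
    architecture: str = "incepspect_cbam"
    variant: str = "full"
    stem_filters: int = 32
    stem_kernel: int = 7
    stem_stride: int = 3
    inception1: InceptionSpec = InceptionSpec(8, 8, 8, 8)
    inception2: InceptionSpec = InceptionSpec(16, 16, 16, 16)
    cbam: CbamSpec = CbamSpec()
    fc_units: int = 64
    dropout_rate: float = 0.2
    l2_lambda: float = 0.001
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 500
    patience: int = 50
    seed: int = 0

    def __post_init__(self) -> None:
        if self.architecture not in ARCHITECTURES:
            raise ValueError(f"unknown architecture '{self.architecture}'")
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant '{self.variant}'")
        if not 0.0 <= self.dropout_rate < 1.0:
            raise ValueError("dropout_rate must lie in [0, 1)")
        if self.l2_lambda < 0:
            raise ValueError("l2_lambda must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# attention


class ChannelAttention(Module):
    """Shared two-layer MLP over average- and max-pooled channel descriptors,
    gated by a sigmoid."""

    def __init__(self, channels: int, reduction: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        hidden = max(1, channels // reduction)
        self.fc1 = Linear(channels, hidden, rng=rng)
        self.fc2 = Linear(hidden, channels, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, C, L) -> per-channel gates (N, C), each in (0, 1)."""
        avg = x.mean(axis=2)  # (N, C)
        mx = x.max(axis=2)
        shared = lambda d: self.fc2(self.fc1(d).mish())
        return (shared(avg) + shared(mx)).sigmoid()


class SpatialAttention(Module):
    """Convolution over the stacked channelwise mean/max maps, gated by a
    sigmoid."""

    def __init__(self, kernel: int, rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv1d(2, 1, kernel, padding=kernel // 2, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        """x: (N, C, L) -> per-position gates (N, 1, L), each in (0, 1)."""
        avg = x.mean(axis=1, keepdims=True)  # (N, 1, L)
        mx = x.max(axis=1, keepdims=True)
        return self.conv(concat([avg, mx], axis=1)).sigmoid()


class Cbam(Module):
    """Sequential channel-then-spatial attention gating."""

    def __init__(self, channels: int, spec: CbamSpec,
                 rng: np.random.Generator | None = None,
                 identity_init: bool = False):
        super().__init__()
        self.channel = ChannelAttention(channels, spec.reduction_ratio, rng=rng)
        self.spatial = SpatialAttention(spec.spatial_kernel, rng=rng)
        if identity_init:
            # start with flat gates (exactly 0.5 everywhere): the gated path
            # is then a scaled copy of its input and attention must be learned
            self.channel.fc2.weight.data[...] = 0.0
            self.channel.fc2.bias.data[...] = 0.0
            self.spatial.conv.weight.data[...] = 0.0
            self.spatial.conv.bias.data[...] = 0.0

    def __call__(self, x: Tensor) -> Tensor:
        mc = self.channel(x)  # (N, C)
        x = x * mc.reshape(mc.shape[0], mc.shape[1], 1)
        ms = self.spatial(x)  # (N, 1, L)
        return x * ms

    def zero_init(self) -> None:
        """Zero all attention parameters (both gates become exactly 0.5)."""
        for p in self.parameters():
            p.data[...] = 0.0


# functional wrappers over freshly built modules (deterministic given rng)


def channel_attention(feature_map: np.ndarray, spec: CbamSpec,
                      rng: np.random.Generator | None = None,
                      zero_init: bool = False) -> np.ndarray:
    """Per-channel attention weights in (0, 1) for a (N, C, L) array."""
    fm = np.asarray(feature_map, dtype=float)
    mod = ChannelAttention(fm.shape[1], spec.reduction_ratio,
                           rng=rng or np.random.default_rng(0))
    if zero_init:
        for p in mod.parameters():
            p.data[...] = 0.0
    mod.eval()
    return mod(Tensor(fm)).data


def spatial_attention(feature_map: np.ndarray, spec: CbamSpec,
                      rng: np.random.Generator | None = None,
                      zero_init: bool = False) -> np.ndarray:
    """Per-position attention weights in (0, 1) for a (N, C, L) array."""
    fm = np.asarray(feature_map, dtype=float)
    mod = SpatialAttention(spec.spatial_kernel,
                           rng=rng or np.random.default_rng(0))
    if zero_init:
        for p in mod.parameters():
            p.data[...] = 0.0
    mod.eval()
    return mod(Tensor(fm)).data


def cbam(feature_map: np.ndarray, spec: CbamSpec,
         rng: np.random.Generator | None = None,
         zero_init: bool = False) -> np.ndarray:
    """Apply channel-then-spatial gating to a (N, C, L) array."""
    fm = np.asarray(feature_map, dtype=float)
    mod = Cbam(fm.shape[1], spec, rng=rng or np.random.default_rng(0),
               identity_init=False)
    if zero_init:
        mod.zero_init()
    mod.eval()
    return mod(Tensor(fm)).data


# ---------------------------------------------------------------------------
# building blocks


class ConvBnMish(Module):
    def __init__(self, cin: int, cout: int, kernel: int, stride: int = 1,
                 padding: int | str = "same",
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.conv = Conv1d(cin, cout, kernel, stride=stride, padding=padding, rng=rng)
        self.bn = BatchNorm1d(cout)

    def __call__(self, x: Tensor) -> Tensor:
        return self.bn(self.conv(x)).mish()


class InceptionBlock(Module):
    """Four parallel branches concatenated along channels, length-preserving.

    Branches: 1x1 conv; 1x1 reduce -> 3x1 conv; 1x1 reduce -> 5x1 conv;
    maxpool(3, same) -> 1x1 conv.
    """

    def __init__(self, cin: int, spec: InceptionSpec,
                 rng: np.random.Generator | None = None):
        super().__init__()
        self.b1 = ConvBnMish(cin, spec.ch_1x1, 1, rng=rng)
        self.b2_reduce = ConvBnMish(cin, spec.ch_3x1, 1, rng=rng)
        self.b2_conv = ConvBnMish(spec.ch_3x1, spec.ch_3x1, 3, rng=rng)
        self.b3_reduce = ConvBnMish(cin, spec.ch_5x1, 1, rng=rng)
        self.b3_conv = ConvBnMish(spec.ch_5x1, spec.ch_5x1, 5, rng=rng)
        self.pool = MaxPool1d(3, stride=1, padding=1)
        self.b4_conv = ConvBnMish(cin, spec.ch_pool, 1, rng=rng)
        self.out_channels = spec.out_channels

    def __call__(self, x: Tensor) -> Tensor:
        return concat(
            [
                self.b1(x),
                self.b2_conv(self.b2_reduce(x)),
                self.b3_conv(self.b3_reduce(x)),
                self.b4_conv(self.pool(x)),
            ],
            axis=1,
        )


class DeepSpectraInception(Module):
    """Three-branch block with kernel pairs (1,3), (1,5), (3,3)."""

    def __init__(self, cin: int, branch_channels: int = 8,
                 rng: np.random.Generator | None = None):
        super().__init__()
        c = branch_channels
        self.b1a = ConvBnMish(cin, c, 1, rng=rng)
        self.b1b = ConvBnMish(c, c, 3, rng=rng)
        self.b2a = ConvBnMish(cin, c, 1, rng=rng)
        self.b2b = ConvBnMish(c, c, 5, rng=rng)
        self.b3a = ConvBnMish(cin, c, 3, rng=rng)
        self.b3b = ConvBnMish(c, c, 3, rng=rng)
        self.out_channels = 3 * c

    def __call__(self, x: Tensor) -> Tensor:
        return concat(
            [self.b1b(self.b1a(x)), self.b2b(self.b2a(x)), self.b3b(self.b3a(x))],
            axis=1,
        )


# ---------------------------------------------------------------------------
# full networks


class IncepSpectCbam(Module):
    def __init__(self, config: NetConfig, input_length: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        c = config
        self.stem = ConvBnMish(1, c.stem_filters, c.stem_kernel,
                               stride=c.stem_stride,
                               padding=c.stem_kernel // 2, rng=rng)
        stem_len = (input_length + 2 * (c.stem_kernel // 2) - c.stem_kernel) // c.stem_stride + 1

        if c.variant == "no_inception":
            # matched-output-channel standard convolutions
            self.block1 = ConvBnMish(c.stem_filters, c.inception1.out_channels, 3, rng=rng)
            self.block2 = ConvBnMish(c.inception1.out_channels,
                                     c.inception2.out_channels, 3, rng=rng)
        else:
            self.block1 = InceptionBlock(c.stem_filters, c.inception1, rng=rng)
            self.block2 = InceptionBlock(c.inception1.out_channels, c.inception2, rng=rng)

        ch_out = c.inception2.out_channels
        self.use_cbam = c.variant != "no_cbam"
        if self.use_cbam:
            self.attn = Cbam(ch_out, c.cbam, rng=rng)
        self.use_residual = c.variant != "no_residual"
        if self.use_residual:
            # 1x1-conv adapter from block-1 output to the CBAM-output shape;
            # blocks are length-preserving so no pooling is needed here
            self.shortcut = Conv1d(c.inception1.out_channels, ch_out, 1, rng=rng)
        self.flat_bn = BatchNorm1d(ch_out * stem_len)
        self.fc = Linear(ch_out * stem_len, c.fc_units, rng=rng)
        self.fc_bn = BatchNorm1d(c.fc_units)
        self.dropout = Dropout(c.dropout_rate, rng=np.random.default_rng(rng.integers(2**63)))
        self.head = Linear(c.fc_units, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.stem(x)
        h1 = self.block1(h)
        h2 = self.block2(h1)
        if self.use_cbam:
            h2 = self.attn(h2)
        if self.use_residual:
            h2 = h2 + self.shortcut(h1)
        h2 = h2.mish()
        n = h2.shape[0]
        flat = self.flat_bn(h2.reshape(n, -1))
        z = self.fc_bn(self.fc(flat)).mish()
        z = self.dropout(z)
        return self.head(z)


class DeepSpectra(Module):
    def __init__(self, config: NetConfig, input_length: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.stem = ConvBnMish(1, 4, 5, stride=3, padding=2, rng=rng)
        stem_len = (input_length + 4 - 5) // 3 + 1
        self.inception = DeepSpectraInception(4, 8, rng=rng)
        self.fc = Linear(24 * stem_len, 100, rng=rng)
        self.fc_bn = BatchNorm1d(100)
        self.dropout = Dropout(0.1, rng=np.random.default_rng(rng.integers(2**63)))
        self.head = Linear(100, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.inception(self.stem(x))
        n = h.shape[0]
        z = self.fc_bn(self.fc(h.reshape(n, -1))).mish()
        return self.head(self.dropout(z))


class Cnn1d(Module):
    """Plain sequential baseline: convs 7/1/16, 5/1/32, 3/1/64, adaptive max
    pool to 128, FC 8192 -> 128 -> 64 -> 1."""

    def __init__(self, config: NetConfig, input_length: int,
                 rng: np.random.Generator):
        super().__init__()
        self.config = config
        self.conv1 = ConvBnMish(1, 16, 7, rng=rng)
        self.conv2 = ConvBnMish(16, 32, 5, rng=rng)
        self.conv3 = ConvBnMish(32, 64, 3, rng=rng)
        self.pool = AdaptiveMaxPool1d(min(128, input_length))
        flat = 64 * min(128, input_length)
        self.fc1 = Linear(flat, 128, rng=rng)
        self.bn1 = BatchNorm1d(128)
        self.fc2 = Linear(128, 64, rng=rng)
        self.bn2 = BatchNorm1d(64)
        self.dropout = Dropout(config.dropout_rate,
                               rng=np.random.default_rng(rng.integers(2**63)))
        self.head = Linear(64, 1, rng=rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.pool(self.conv3(self.conv2(self.conv1(x))))
        n = h.shape[0]
        z = self.bn1(self.fc1(h.reshape(n, -1))).mish()
        z = self.bn2(self.fc2(z)).mish()
        return self.head(self.dropout(z))


def build_network(config: NetConfig, input_length: int) -> Module:
    """Construct an untrained network; identical seeds give identical
    initial parameters."""
    if input_length < config.stem_kernel:
        raise ValueError(
            f"input length {input_length} shorter than stem kernel "
            f"{config.stem_kernel} (layer: stem)"
        )
    rng = np.random.default_rng(config.seed)
    if config.architecture == "incepspect_cbam":
        return IncepSpectCbam(config, input_length, rng)
    if config.architecture == "deepspectra":
        return DeepSpectra(config, input_length, rng)
    if config.architecture == "cnn1d":
        return Cnn1d(config, input_length, rng)
    raise ValueError(f"unknown architecture '{config.architecture}'")
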