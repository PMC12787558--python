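"""MBConv image backbone with squeeze-and-excitation channel attention.

The visual encoder follows the EfficientNet-B0 layout: a strided 3x3 stem,
seven stages of mobile inverted bottleneck blocks (1x1 expansion, depthwise
spatial convolution, squeeze-and-excitation recalibration, linear 1x1
projection, residual when shapes match), and a 1x1 head convolution followed
by global average pooling into a fixed-length embedding.

Two profiles are provided: the ``full`` reference at 224 px (the deployment
configuration, ~4.0 M backbone parameters) and a ``tiny`` profile (width
multiplier 0.25, one block per stage, 96 px) sized for CPU-bound training
runs.  Both share every structural invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import tensor as T
from .nn.layers import BatchNorm2d, Conv2d, DepthwiseConv2d, Linear, Module
from .nn.tensor import Tensor

__all__ = [
    "BlockConfig",
    "BackboneConfig",
    "efficientnet_b0_config",
    "tiny_backbone_config",
    "SqueezeExcite",
    "MBConv",
    "Backbone",
]


@dataclass(frozen=True)
class BlockConfig:
    """Configuration of one MBConv block."""

    expansion: int
    kernel: int
    stride: int
    in_ch: int
    out_ch: int
    se_ratio: float = 0.25  # squeeze width relative to the block's input channels

    def __post_init__(self):
        if self.expansion < 1:
            raise ValueError("expansion factor must be >= 1")
        if self.kernel not in (3, 5):
            raise ValueError("kernel size must be 3 or 5")
        if self.stride not in (1, 2):
            raise ValueError("stride must be 1 or 2")

    @property
    def expanded_ch(self) -> int:
        return self.in_ch * self.expansion

    @property
    def squeeze_ch(self) -> int:
        return max(1, int(self.in_ch * self.se_ratio))

    @property
    def has_residual(self) -> bool:
        """Residual permitted iff stride 1 and matching channel counts."""
        return self.stride == 1 and self.in_ch == self.out_ch


# (expansion, kernel, stride, out_ch, repeats) per stage
_B0_STAGES = (
    (1, 3, 1, 16, 1),
    (6, 3, 2, 24, 2),
    (6, 5, 2, 40, 2),
    (6, 3, 2, 80, 3),
    (6, 5, 1, 112, 3),
    (6, 5, 2, 192, 4),
    (6, 3, 1, 320, 1),
)

_TINY_STAGES = (
    (1, 3, 1, 4, 1),
    (6, 3, 2, 6, 1),
    (6, 5, 2, 10, 1),
    (6, 3, 2, 20, 1),
    (6, 5, 1, 28, 1),
    (6, 5, 2, 48, 1),
    (6, 3, 1, 80, 1),
)


@dataclass(frozen=True)
class BackboneConfig:
    stem_ch: int
    blocks: tuple[BlockConfig, ...]  # fully unrolled, repeats expanded
    head_ch: int
    resolution: int

    def __post_init__(self):
        stride_product = 2  # stem
        for b in self.blocks:
            stride_product *= b.stride
        if stride_product != 32:
            raise ValueError(
                f"cumulative stride product must be 32, got {stride_product}")

    @property
    def embed_width(self) -> int:
        return self.head_ch

    def spatial_sizes(self):
        """Spatial size after the stem and after every block."""
        h = _conv_out(self.resolution, 3, 2)
        sizes = [h]
        for b in self.blocks:
            h = _conv_out(h, b.kernel, b.stride)
            sizes.append(h)
        return sizes


def _conv_out(h: int, kernel: int, stride: int) -> int:
    pad = kernel // 2
    return (h + 2 * pad - kernel) // stride + 1


def _unroll(stages, stem_ch: int) -> tuple[BlockConfig, ...]:
    blocks = []
    in_ch = stem_ch
    for expansion, kernel, stride, out_ch, repeats in stages:
        for r in range(repeats):
            blocks.append(BlockConfig(
                expansion=expansion,
                kernel=kernel,
                stride=stride if r == 0 else 1,
                in_ch=in_ch,
                out_ch=out_ch,
            ))
            in_ch = out_ch
    return tuple(blocks)


def efficientnet_b0_config(resolution: int = 224) -> BackboneConfig:
    """The canonical B0 stage table: 16 MBConv blocks, 1280-wide embedding."""
    return BackboneConfig(stem_ch=32, blocks=_unroll(_B0_STAGES, 32),
                          head_ch=1280, resolution=resolution)


def tiny_backbone_config(resolution: int = 96) -> BackboneConfig:
    """Width multiplier 0.25, repeats capped at 1 — for CPU-scale training."""
    return BackboneConfig(stem_ch=8, blocks=_unroll(_TINY_STAGES, 8),
                          head_ch=320, resolution=resolution)


class SqueezeExcite(Module):
    """Channel recalibration: GAP -> FC -> SiLU -> FC -> sigmoid gate.

    The gate values lie strictly in (0, 1); with zero gating weights every
    gate equals sigmoid(0) = 0.5.
    """

    def __init__(self, channels: int, squeeze_ch: int,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if squeeze_ch < 1:
            raise ValueError("squeeze width must be >= 1")
        rng = rng or np.random.default_rng(0)
        self.channels = channels
        self.fc1 = Linear(channels, squeeze_ch, rng=rng)
        self.fc2 = Linear(squeeze_ch, channels, rng=rng)

    def gate(self, x: Tensor) -> Tensor:
        descriptor = T.spatial_mean(x)  # (N, C)
        g = T.sigmoid(self.fc2(T.silu(self.fc1(descriptor))))
        return T.reshape(g, (x.shape[0], self.channels, 1, 1))

    def __call__(self, x: Tensor) -> Tensor:
        return T.mul(x, self.gate(x))


class MBConv(Module):
    """Mobile inverted bottleneck block.

    Expansion (1x1 conv, skipped when the factor is 1), depthwise spatial
    convolution, squeeze-and-excitation, then a linear 1x1 projection with no
    activation.  The input is added back when stride is 1 and channel counts
    match.  ``use_se=False`` omits the SE stage entirely (gate fixed at 1),
    which is the no-SE ablation variant.
    """

    def __init__(self, cfg: BlockConfig, rng: np.random.Generator | None = None,
                 use_se: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        exp_ch = cfg.expanded_ch
        if cfg.expansion != 1:
            self.expand_conv = Conv2d(cfg.in_ch, exp_ch, 1, rng=rng)
            self.expand_bn = BatchNorm2d(exp_ch)
        else:
            self.expand_conv = None
            self.expand_bn = None
        self.dw_conv = DepthwiseConv2d(exp_ch, cfg.kernel, stride=cfg.stride, rng=rng)
        self.dw_bn = BatchNorm2d(exp_ch)
        self.se = SqueezeExcite(exp_ch, cfg.squeeze_ch, rng=rng) if use_se else None
        self.project_conv = Conv2d(exp_ch, cfg.out_ch, 1, rng=rng)
        self.project_bn = BatchNorm2d(cfg.out_ch)

    def depthwise_separable(self, x: Tensor) -> Tensor:
        """Expansion + depthwise stage: conv -> BN -> SiLU (twice)."""
        h = x
        if self.expand_conv is not None:
            h = T.silu(self.expand_bn(self.expand_conv(h)))
        return T.silu(self.dw_bn(self.dw_conv(h)))

    def project(self, h: Tensor) -> Tensor:
        """Linear 1x1 projection: conv -> BN, no activation."""
        return self.project_bn(self.project_conv(h))

    def __call__(self, x: Tensor) -> Tensor:
        h = self.depthwise_separable(x)
        if self.se is not None:
            h = self.se(h)
        h = self.project(h)
        if self.cfg.has_residual:
            h = T.add(h, x)
        return h


class Backbone(Module):
    """Stem -> MBConv stages -> 1x1 head conv -> global average pooling."""

    def __init__(self, cfg: BackboneConfig, rng: np.random.Generator | None = None,
                 use_se: bool = True, strict_resolution: bool = True):
        super().__init__()
        rng = rng or np.random.default_rng(0)
        self.cfg = cfg
        self.strict_resolution = strict_resolution
        self.stem_conv = Conv2d(3, cfg.stem_ch, 3, stride=2, rng=rng)
        self.stem_bn = BatchNorm2d(cfg.stem_ch)
        self.blocks = [MBConv(b, rng=rng, use_se=use_se) for b in cfg.blocks]
        self.head_conv = Conv2d(cfg.blocks[-1].out_ch, cfg.head_ch, 1, rng=rng)
        self.head_bn = BatchNorm2d(cfg.head_ch)

    @property
    def embed_width(self) -> int:
        return self.cfg.head_ch

    def __call__(self, x) -> Tensor:
        """Map a (N, 3, H, W) image batch to (N, embed_width) embeddings."""
        if not isinstance(x, Tensor):
            x = Tensor(np.asarray(x))
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError(f"expected (N, 3, H, W) input, got {x.shape}")
        if self.strict_resolution and (x.shape[2] != self.cfg.resolution
                                       or x.shape[3] != self.cfg.resolution):
            raise ValueError(
                f"expected {self.cfg.resolution}px input, got {x.shape[2]}x{x.shape[3]}")
        h = T.silu(self.stem_bn(self.stem_conv(x)))
        for block in self.blocks:
            h = block(h)
        h = T.silu(self.head_bn(self.head_conv(h)))
        return T.spatial_mean(h)
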