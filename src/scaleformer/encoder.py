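"""Hierarchical encoder: local perception units and MSEAU attention blocks.

Each of the four stages runs one Local Perception Unit (LPU) followed by
``L_i`` Multi-Scale Extraction and Aggregation Units (MSEAU).  The LPU is
a convolutional residual block —

    LPU(X) = Skip(X) + Proj(SE(DWConv(Conv(Norm(X)))))

— that injects locality and translation structure the attention blocks
lack; its skip is the identity within a stage and a pooling + channel
projection when the stage downsamples.  An MSEAU is four pre-norm
residual sub-blocks: GMSA, FFN, ISA, FFN.  The stem is a 7x7 stride-4
patch embedding, so the stages emit a feature pyramid at strides
4/8/16/32 (56/28/14/7 pixels for a 224 input).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import as_tensor, avg_pool2d
from .exceptions import ConfigurationError, ShapeError
from .gmsa import GMSAConfig, GroupedMultiScaleAttention
from .isa import ISAConfig, InterScaleAttention
from .nn import (BatchNorm2d, ChannelLayerNorm, Conv2d, DepthwiseConv2d,
                 Module, Sequential, SqueezeExcite)

__all__ = ["StageConfig", "LocalPerceptionUnit", "FeedForward", "MSEAU",
           "Encoder"]


@dataclass
class StageConfig:
    channels: int
    depth: int = 2
    scales: list = field(default_factory=lambda: [1, 2, 4, 7])
    isa_groups: int = 2
    ffn_ratio: int = 4
    lpu_expand: int = 4
    heads_per_group: list | None = None

    def validate(self):
        if self.depth < 1:
            raise ConfigurationError("stage depth must be >= 1")
        GMSAConfig(self.channels, list(self.scales),
                   heads_per_group=self.heads_per_group).validate()
        ISAConfig(self.channels, self.isa_groups).validate()


class LocalPerceptionUnit(Module):
    """Convolutional residual unit; optionally downsamples by 2.

    ``pad_mode`` controls the depthwise conv padding; ``"wrap"`` makes
    the unit exactly translation-equivariant (used to verify the design
    motivation in tests).
    """

    def __init__(self, in_ch: int, out_ch: int, rng: np.random.Generator,
                 downsample: bool = False, expand: int = 4,
                 pad_mode: str = "zero"):
        super().__init__()
        self.downsample = downsample
        hidden = in_ch * expand
        self.norm = BatchNorm2d(in_ch)
        self.conv_expand = Conv2d(in_ch, hidden, 1, rng)
        self.bn1 = BatchNorm2d(hidden)
        self.dwconv = DepthwiseConv2d(hidden, 3, rng,
                                      stride=2 if downsample else 1,
                                      pad_mode=pad_mode)
        self.bn2 = BatchNorm2d(hidden)
        self.se = SqueezeExcite(hidden, rng)
        self.proj = Conv2d(hidden, out_ch, 1, rng)
        if downsample or in_ch != out_ch:
            self.skip_proj = Conv2d(in_ch, out_ch, 1, rng)
        else:
            self.skip_proj = None

    def forward(self, x):
        x = as_tensor(x)
        h = self.norm(x)
        h = self.bn1(self.conv_expand(h)).gelu()
        h = self.bn2(self.dwconv(h)).gelu()
        h = self.proj(self.se(h))
        if self.skip_proj is None:
            skip = x
        else:
            skip = self.skip_proj(avg_pool2d(x, 2) if self.downsample else x)
        return skip + h


class FeedForward(Module):
    """Pointwise two-layer expansion FFN (shape preserving)."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 ratio: int = 4):
        super().__init__()
        hidden = channels * ratio
        self.fc1 = Conv2d(channels, hidden, 1, rng)
        self.fc2 = Conv2d(hidden, channels, 1, rng)

    def forward(self, x):
        return self.fc2(self.fc1(x).gelu())


class MSEAU(Module):
    """GMSA + FFN + ISA + FFN, each a pre-norm residual sub-block."""

    def __init__(self, cfg: StageConfig, rng: np.random.Generator):
        super().__init__()
        c = cfg.channels
        self.norm1 = ChannelLayerNorm(c)
        self.gmsa = GroupedMultiScaleAttention(
            GMSAConfig(c, list(cfg.scales),
                       heads_per_group=cfg.heads_per_group), rng)
        self.norm2 = ChannelLayerNorm(c)
        self.ffn1 = FeedForward(c, rng, cfg.ffn_ratio)
        self.norm3 = ChannelLayerNorm(c)
        self.isa = InterScaleAttention(ISAConfig(c, cfg.isa_groups), rng)
        self.norm4 = ChannelLayerNorm(c)
        self.ffn2 = FeedForward(c, rng, cfg.ffn_ratio)

    def forward(self, x):
        x = as_tensor(x)
        x = x + self.gmsa(self.norm1(x))
        x = x + self.ffn1(self.norm2(x))
        x = x + self.isa(self.norm3(x))
        x = x + self.ffn2(self.norm4(x))
        return x


class Encoder(Module):
    """7x7/4 patch-embedding stem + four LPU/MSEAU stages -> feature pyramid."""

    def __init__(self, stage_cfgs, rng: np.random.Generator,
                 in_channels: int = 1):
        super().__init__()
        if len(stage_cfgs) != 4:
            raise ConfigurationError("encoder expects exactly four stages")
        for cfg in stage_cfgs:
            cfg.validate()
        self.stage_cfgs = list(stage_cfgs)
        c1 = stage_cfgs[0].channels
        self.stem = Conv2d(in_channels, c1, 7, rng, stride=4, padding=3)
        self.stem_norm = BatchNorm2d(c1)
        self.lpus = []
        self.stages = []
        prev = c1
        for i, cfg in enumerate(stage_cfgs):
            self.lpus.append(LocalPerceptionUnit(
                prev, cfg.channels, rng, downsample=(i > 0),
                expand=cfg.lpu_expand))
            self.stages.append(Sequential(
                *[MSEAU(cfg, rng) for _ in range(cfg.depth)]))
            prev = cfg.channels

    def forward(self, image):
        image = as_tensor(image)
        B, C, H, W = image.shape
        if H % 32 or W % 32:
            raise ShapeError(
                f"input {H}x{W} not divisible by 32; resize required")
        x = self.stem_norm(self.stem(image))
        pyramid = []
        for lpu, blocks in zip(self.lpus, self.stages):
            x = blocks(lpu(x))
            pyramid.append(x)
        return pyramid
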