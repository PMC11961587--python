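"""Feature-rich decoder with deep-supervision heads.

The decoder walks the encoder pyramid from stride 32 back to stride 4.
The deepest map enters directly (no fusion partner exists yet); every
shallower level upsamples the running state by 2, fuses it with the
same-resolution encoder map through a Context Perception Block (CPB),
then refines with an Inception multi-branch block and a channel+spatial
attention (CSA) block.  Auxiliary 1x1 classification heads tap the
stride-8/16/32 decoder states for deep supervision; the stride-4 state
is merged with two low-level image stems (full and half resolution)
through simple bilinear-upsample+concat fusions before the main head,
so the prediction returns to the input resolution without a blunt 4x
upsample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, depthwise_conv2d, \
    resize_bilinear
from .exceptions import ConfigurationError, ShapeError
from .nn import (BatchNorm2d, Conv2d, Module, SqueezeExcite)

__all__ = ["LogitsBundle", "ContextPerceptionBlock", "InceptionBlock",
           "CSABlock", "Stems", "SimpleFusion", "Decoder"]


@dataclass
class LogitsBundle:
    """Main full-resolution logits plus auxiliaries at strides 8/16/32."""

    main: Tensor
    aux8: Tensor
    aux16: Tensor
    aux32: Tensor

    @property
    def aux(self):
        return [self.aux8, self.aux16, self.aux32]

    def num_classes(self) -> int:
        return self.main.shape[1]


class ContextPerceptionBlock(Module):
    """Fuse an encoder and a decoder stream with a gated residual.

    x' = conv(SE(concat(enc, dec))); gate = sigmoid(conv(dec));
    out = enc + gate * x'.
    """

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        self.se = SqueezeExcite(2 * channels, rng)
        self.fuse = Conv2d(2 * channels, channels, 3, rng)
        self.gate_conv = Conv2d(channels, channels, 3, rng)

    def forward(self, enc, dec):
        enc, dec = as_tensor(enc), as_tensor(dec)
        if enc.shape[2:] != dec.shape[2:]:
            raise ShapeError(
                f"CPB spatial mismatch: encoder {enc.shape[2:]} vs "
                f"decoder {dec.shape[2:]}")
        fused = self.fuse(self.se(concat([enc, dec], axis=1)))
        gate = self.gate_conv(dec).sigmoid()
        return enc + gate * fused


_SMOOTH3 = np.full((3, 3), 1.0 / 9.0, dtype=np.float32)


class InceptionBlock(Module):
    """Parallel 1x1 / 3x3 / 5x5 (two stacked 3x3) / pooled branches."""

    def __init__(self, channels: int, rng: np.random.Generator):
        super().__init__()
        if channels % 4:
            raise ConfigurationError(
                f"Inception block needs channels divisible by 4, "
                f"got {channels}")
        w = channels // 4
        self.b1 = Conv2d(channels, w, 1, rng)
        self.b3 = Conv2d(channels, w, 3, rng)
        self.b5a = Conv2d(channels, w, 3, rng)
        self.b5b = Conv2d(w, w, 3, rng)
        self.bp = Conv2d(channels, w, 1, rng)
        self.project = Conv2d(channels, channels, 1, rng)

    def branches(self, x):
        x = as_tensor(x)
        C = x.shape[1]
        smooth = Tensor(np.broadcast_to(_SMOOTH3, (C, 3, 3)).copy())
        pooled = depthwise_conv2d(x, smooth, padding=1, pad_mode="edge")
        return [self.b1(x), self.b3(x), self.b5b(self.b5a(x)),
                self.bp(pooled)]

    def forward(self, x):
        return self.project(concat(self.branches(x), axis=1))


class CSABlock(Module):
    """Channel-attention then spatial-attention reweighting.

    Channel gate: global pool -> bottleneck MLP -> sigmoid (per channel).
    Spatial gate: channel-mean statistic -> 7x7 conv -> sigmoid (per pixel).
    """

    def __init__(self, channels: int, rng: np.random.Generator,
                 reduction: int = 4):
        super().__init__()
        self.channel_gate = SqueezeExcite(channels, rng, reduction)
        # edge padding keeps the gate spatially constant on uniform maps
        self.spatial_conv = Conv2d(1, 1, 7, rng, pad_mode="edge")

    def forward(self, x):
        x = self.channel_gate(as_tensor(x))
        stat = x.mean(axis=1, keepdims=True)
        gate = self.spatial_conv(stat).sigmoid()
        return x * gate


class Stems(Module):
    """Two cascaded conv-BN-ReLU blocks: features at H x W and H/2 x W/2."""

    def __init__(self, in_channels: int, stem_channels: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv1 = Conv2d(in_channels, stem_channels, 3, rng)
        self.bn1 = BatchNorm2d(stem_channels)
        self.conv2 = Conv2d(stem_channels, stem_channels, 3, rng, stride=2)
        self.bn2 = BatchNorm2d(stem_channels)

    def forward(self, image):
        f_full = self.bn1(self.conv1(as_tensor(image))).relu()
        f_half = self.bn2(self.conv2(f_full)).relu()
        return f_full, f_half


class SimpleFusion(Module):
    """Upsample the deep stream x2, concat the shallow one, conv-BN-ReLU."""

    def __init__(self, high_ch: int, low_ch: int, out_ch: int,
                 rng: np.random.Generator):
        super().__init__()
        self.conv = Conv2d(high_ch + low_ch, out_ch, 3, rng)
        self.bn = BatchNorm2d(out_ch)

    def forward(self, high, low):
        high, low = as_tensor(high), as_tensor(low)
        up = resize_bilinear(high, 2 * high.shape[2], 2 * high.shape[3])
        if up.shape[2:] != low.shape[2:]:
            raise ShapeError(
                f"fusion mismatch: upsampled {up.shape[2:]} vs "
                f"low-level {low.shape[2:]}")
        return self.bn(self.conv(concat([up, low], axis=1))).relu()


class Decoder(Module):
    """Pyramid -> LogitsBundle.  ``channels`` is the encoder channel plan
    [C1, C2, C3, C4]; stem features carry ``stem_channels``."""

    def __init__(self, channels, stem_channels: int, num_classes: int,
                 rng: np.random.Generator):
        super().__init__()
        if num_classes < 2:
            raise ConfigurationError("need at least two classes")
        c1, c2, c3, c4 = channels
        self.num_classes = num_classes
        self.incep4 = InceptionBlock(c4, rng)
        self.csa4 = CSABlock(c4, rng)
        self.reduce43 = Conv2d(c4, c3, 1, rng)
        self.cpb3 = ContextPerceptionBlock(c3, rng)
        self.incep3 = InceptionBlock(c3, rng)
        self.csa3 = CSABlock(c3, rng)
        self.reduce32 = Conv2d(c3, c2, 1, rng)
        self.cpb2 = ContextPerceptionBlock(c2, rng)
        self.incep2 = InceptionBlock(c2, rng)
        self.csa2 = CSABlock(c2, rng)
        self.reduce21 = Conv2d(c2, c1, 1, rng)
        self.cpb1 = ContextPerceptionBlock(c1, rng)
        self.incep1 = InceptionBlock(c1, rng)
        self.csa1 = CSABlock(c1, rng)
        self.fuse_half = SimpleFusion(c1, stem_channels, stem_channels, rng)
        self.fuse_full = SimpleFusion(stem_channels, stem_channels,
                                      stem_channels, rng)
        self.head = Conv2d(stem_channels, num_classes, 1, rng)
        self.aux_head8 = Conv2d(c2, num_classes, 1, rng)
        self.aux_head16 = Conv2d(c3, num_classes, 1, rng)
        self.aux_head32 = Conv2d(c4, num_classes, 1, rng)

    def forward(self, pyramid, f_full, f_half) -> LogitsBundle:
        e1, e2, e3, e4 = [as_tensor(e) for e in pyramid]
        d4 = self.csa4(self.incep4(e4))                      # stride 32
        up = resize_bilinear(self.reduce43(d4), *e3.shape[2:])
        d3 = self.csa3(self.incep3(self.cpb3(e3, up)))       # stride 16
        up = resize_bilinear(self.reduce32(d3), *e2.shape[2:])
        d2 = self.csa2(self.incep2(self.cpb2(e2, up)))       # stride 8
        up = resize_bilinear(self.reduce21(d2), *e1.shape[2:])
        d1 = self.csa1(self.incep1(self.cpb1(e1, up)))       # stride 4
        x = self.fuse_half(d1, f_half)                       # stride 2
        x = self.fuse_full(x, f_full)                        # stride 1
        return LogitsBundle(
            main=self.head(x),
            aux8=self.aux_head8(d2),
            aux16=self.aux_head16(d3),
            aux32=self.aux_head32(d4),
        )
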