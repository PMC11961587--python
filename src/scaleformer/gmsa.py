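"""Grouped multi-scale attention (GMSA).

The input feature map is split into ``G`` channel groups.  Group *i* is
projected to queries/keys/values, its spatial map is tokenized onto an
``s_i x s_i`` grid by non-overlapping average pooling (patch size
``(H/s_i, W/s_i)``, hence ``N_i = s_i**2`` tokens), scaled-dot-product
attention runs over those tokens, and the attended tokens are broadcast
back over their source patches.  Groups with small ``s_i`` see large
patches (global context); groups with large ``s_i`` keep finer spatial
detail at a cost growing like ``s_i**4 * d_i`` for the attention scores.
Concatenating the groups restores the original channel count, so one
layer carries several receptive-field scales at once.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .autodiff import Tensor, as_tensor, concat, pad2d, report_multiplies
from .exceptions import ConfigurationError, ShapeError
from .nn import Linear, Module

__all__ = [
    "GMSAConfig", "split_channels", "tokenize", "detokenize",
    "scaled_dot_attention", "GroupedMultiScaleAttention", "gmsa_cost",
]


@dataclass
class GMSAConfig:
    """Configuration of one GMSA layer.

    ``group_widths=None`` means an equal split of ``channels`` over the
    groups; ``heads_per_group=None`` defaults each group to
    ``max(1, d_i // 32)`` heads.
    """

    channels: int
    scales: list = field(default_factory=lambda: [1, 2, 4, 7])
    group_widths: list | None = None
    heads_per_group: list | None = None

    def resolved_widths(self) -> list:
        G = len(self.scales)
        if self.group_widths is not None:
            widths = list(self.group_widths)
            if len(widths) != G:
                raise ConfigurationError(
                    f"{len(widths)} group widths for {G} scales")
            if sum(widths) != self.channels:
                raise ConfigurationError(
                    f"group widths sum to {sum(widths)}, expected "
                    f"{self.channels} channels")
            return widths
        if self.channels % G:
            raise ConfigurationError(
                f"{self.channels} channels not divisible into {G} equal groups")
        return [self.channels // G] * G

    def resolved_heads(self) -> list:
        widths = self.resolved_widths()
        if self.heads_per_group is not None:
            heads = list(self.heads_per_group)
        else:
            heads = [max(1, d // 32) for d in widths]
        for d, h in zip(widths, heads):
            if d % h:
                raise ConfigurationError(
                    f"group width {d} not divisible by {h} heads")
        return heads

    def validate(self):
        if any(s < 1 for s in self.scales):
            raise ConfigurationError(f"scales must be >= 1, got {self.scales}")
        self.resolved_widths()
        self.resolved_heads()


def split_channels(x, widths) -> list:
    """Partition a [B,C,H,W] map along channels; concat of the parts is x."""
    x = as_tensor(x)
    C = x.shape[1]
    if sum(widths) != C:
        raise ConfigurationError(
            f"channel split {list(widths)} sums to {sum(widths)}, "
            f"input has {C} channels")
    parts, start = [], 0
    for w in widths:
        parts.append(x[:, start:start + w])
        start += w
    return parts


def tokenize(x, s: int) -> Tensor:
    """Average-pool a [B,d,H,W] map onto an s x s grid -> [B, s*s, d] tokens.

    Tokens are ordered row-major over the grid.  If H or W is not a
    multiple of s the map is edge-padded (bottom/right) up to the next
    multiple before pooling.
    """
    x = as_tensor(x)
    if s < 1:
        raise ConfigurationError(f"token grid size must be >= 1, got {s}")
    B, d, H, W = x.shape
    if H < s or W < s:
        raise ShapeError(f"spatial size {H}x{W} smaller than token grid {s}")
    Hp = -(-H // s) * s
    Wp = -(-W // s) * s
    if (Hp, Wp) != (H, W):
        x = pad2d(x, 0, Hp - H, 0, Wp - W, mode="edge")
    ph, pw = Hp // s, Wp // s
    pooled = x.reshape(B, d, s, ph, s, pw).mean(axis=(3, 5))   # B,d,s,s
    return pooled.reshape(B, d, s * s).swapaxes(1, 2)          # B,s*s,d


def detokenize(tokens, s: int, height: int, width: int) -> Tensor:
    """Broadcast s*s tokens [B,N,d] back over their patches -> [B,d,H,W]."""
    tokens = as_tensor(tokens)
    B, N, d = tokens.shape
    if N != s * s:
        raise ShapeError(f"expected {s * s} tokens for grid {s}, got {N}")
    Hp = -(-height // s) * s
    Wp = -(-width // s) * s
    ph, pw = Hp // s, Wp // s
    grid = tokens.swapaxes(1, 2).reshape(B, d, s, 1, s, 1)
    full = (grid + Tensor(np.zeros((1, 1, 1, ph, 1, pw), dtype=np.float32)))
    full = full.reshape(B, d, Hp, Wp)
    if (Hp, Wp) != (height, width):
        full = full[:, :, :height, :width]
    return full


def scaled_dot_attention(q, k, v, heads: int = 1, return_weights: bool = False):
    """Multi-head softmax(Q Kᵀ / sqrt(d_h)) V over [B,N,d] token matrices."""
    q, k, v = as_tensor(q), as_tensor(k), as_tensor(v)
    if q.shape != k.shape or q.shape != v.shape:
        raise ShapeError(
            f"Q/K/V shapes differ: {q.shape}, {k.shape}, {v.shape}")
    B, N, d = q.shape
    if d % heads:
        raise ConfigurationError(f"width {d} not divisible by {heads} heads")
    dh = d // heads

    def split_heads(t):
        return t.reshape(B, N, heads, dh).transpose((0, 2, 1, 3))

    qh, kh, vh = split_heads(q), split_heads(k), split_heads(v)
    scores = (qh @ kh.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
    report_multiplies(B * heads * N * N * dh)          # attention-score MACs
    weights = scores.softmax(axis=-1)
    out = (weights @ vh).transpose((0, 2, 1, 3)).reshape(B, N, d)
    if return_weights:
        return out, weights
    return out


class GroupedMultiScaleAttention(Module):
    """One GMSA layer; shape-preserving on [B, channels, H, W] maps."""

    def __init__(self, cfg: GMSAConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        self.widths = cfg.resolved_widths()
        self.heads = cfg.resolved_heads()
        self.scales = list(cfg.scales)
        self.q_proj = [Linear(d, d, rng) for d in self.widths]
        self.k_proj = [Linear(d, d, rng) for d in self.widths]
        self.v_proj = [Linear(d, d, rng) for d in self.widths]
        self.out_proj = [Linear(d, d, rng) for d in self.widths]

    def forward(self, x):
        x = as_tensor(x)
        B, C, H, W = x.shape
        if C != self.cfg.channels:
            raise ConfigurationError(
                f"input has {C} channels, layer configured for "
                f"{self.cfg.channels}")
        for s in self.scales:
            if s > min(H, W):
                raise ConfigurationError(
                    f"scale s={s} exceeds stage resolution {H}x{W}")
        outs = []
        for g, x_g in enumerate(split_channels(x, self.widths)):
            d, s = self.widths[g], self.scales[g]
            flat = x_g.reshape(B, d, H * W).swapaxes(1, 2)     # B,HW,d
            q = self.q_proj[g](flat).swapaxes(1, 2).reshape(B, d, H, W)
            k = self.k_proj[g](flat).swapaxes(1, 2).reshape(B, d, H, W)
            v = self.v_proj[g](flat).swapaxes(1, 2).reshape(B, d, H, W)
            attended = scaled_dot_attention(
                tokenize(q, s), tokenize(k, s), tokenize(v, s),
                heads=self.heads[g])
            spatial = detokenize(attended, s, H, W)            # B,d,H,W
            flat_out = spatial.reshape(B, d, H * W).swapaxes(1, 2)
            proj = self.out_proj[g](flat_out).swapaxes(1, 2).reshape(B, d, H, W)
            outs.append(proj)
        return concat(outs, axis=1)


def gmsa_cost(cfg: GMSAConfig, stage_resolution: int | tuple) -> dict:
    """Token counts and attention-score multiply estimate per group.

    The per-group attention-score cost is ``N_i**2 * d_i = s_i**4 * d_i``
    multiply-accumulates, so the layer total is ``sum_i s_i**4 d_i``.
    """
    cfg.validate()
    if isinstance(stage_resolution, int):
        stage_resolution = (stage_resolution, stage_resolution)
    H, W = stage_resolution
    widths = cfg.resolved_widths()
    groups = []
    for s, d in zip(cfg.scales, widths):
        if s > min(H, W):
            raise ConfigurationError(
                f"scale s={s} exceeds stage resolution {H}x{W}")
        groups.append({
            "scale": int(s),
            "width": int(d),
            "tokens": int(s * s),
            "patch": [int(-(-H // s)), int(-(-W // s))],
            "attention_mults": int(s ** 4 * d),
        })
    return {
        "resolution": [int(H), int(W)],
        "groups": groups,
        "total_attention_mults": int(sum(g["attention_mults"] for g in groups)),
    }
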