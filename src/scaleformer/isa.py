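"""Inter-scale attention (ISA).

Where GMSA lets each channel group attend at its own spatial scale, ISA
exchanges information *between* the groups.  It works on channel
affinities instead of token-token attention, so its cost is linear in
the token count N = h*w:

1. project the flattened map to Q, K, V of shape [B, N, c];
2. split into g channel groups; per group form the channel-affinity
   matrix ``CA_i = softmax_tokens(k_i)ᵀ v_i`` of shape [d_g, d_g];
3. global-pool each ``CA_i`` to one scalar, pass the g scalars through a
   small gate network and a sigmoid, and scale each affinity by its gate;
4. fuse the g gated affinities across the group axis into one shared map
   ``A`` with a learned linear combination;
5. every group's output is ``softmax_channels(q_i) @ A``; groups are
   concatenated and reshaped back to the input layout.

Step 5 applies the *shared* A to every group's queries, which is what
makes the exchange cross-group: perturbing one group's input moves every
group's output through A and the gates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .autodiff import Tensor, as_tensor, concat, report_multiplies
from .exceptions import ConfigurationError
from .nn import Linear, Module, Parameter

__all__ = ["ISAConfig", "channel_affinity", "InterScaleAttention"]


@dataclass
class ISAConfig:
    channels: int
    num_groups: int = 2
    gate_reduction: int = 2

    def validate(self):
        if self.num_groups < 1:
            raise ConfigurationError("ISA needs at least one group")
        if self.channels % self.num_groups:
            raise ConfigurationError(
                f"{self.channels} channels not divisible by "
                f"{self.num_groups} ISA groups")

    @property
    def group_width(self) -> int:
        return self.channels // self.num_groups


def channel_affinity(k_g, v_g) -> Tensor:
    """``softmax_tokens(k)ᵀ v`` -> [B, d_g, d_g] channel-channel affinity.

    The softmax normalizes each key channel over the token axis, so the
    product is a weighted average of value rows — cost ``N * d_g**2``,
    linear in the number of tokens.
    """
    k_g, v_g = as_tensor(k_g), as_tensor(v_g)
    B, N, d = k_g.shape
    report_multiplies(B * N * d * v_g.shape[-1])
    return k_g.softmax(axis=1).swapaxes(1, 2) @ v_g


class InterScaleAttention(Module):
    """One ISA layer; shape-preserving on [B, channels, H, W] maps."""

    def __init__(self, cfg: ISAConfig, rng: np.random.Generator):
        super().__init__()
        cfg.validate()
        self.cfg = cfg
        c, g = cfg.channels, cfg.num_groups
        self.q_proj = Linear(c, c, rng)
        self.k_proj = Linear(c, c, rng)
        self.v_proj = Linear(c, c, rng)
        hidden = max(1, g // cfg.gate_reduction)
        self.gate_fc1 = Linear(g, hidden, rng)
        self.gate_fc2 = Linear(hidden, g, rng)
        # learned linear combination across the group axis (the output
        # projection fusing the g gated affinities into one shared map)
        self.mix_weight = Parameter(np.full(g, 1.0 / g))
        self.mix_bias = Parameter(np.zeros(1))

    def project_qkv(self, x):
        """Flatten [B,c,H,W] to [B,N,c] tokens and project to Q, K, V."""
        x = as_tensor(x)
        B, C, H, W = x.shape
        if C != self.cfg.channels:
            raise ConfigurationError(
                f"input has {C} channels, ISA configured for "
                f"{self.cfg.channels}")
        flat = x.reshape(B, C, H * W).swapaxes(1, 2)
        return self.q_proj(flat), self.k_proj(flat), self.v_proj(flat)

    def group_gate(self, affinities) -> Tensor:
        """Pool each [B,d,d] affinity to a scalar and gate -> [B,g] in (0,1)."""
        pooled = concat([ca.mean(axis=(1, 2), keepdims=True).reshape(-1, 1)
                         for ca in affinities], axis=1)       # B,g
        # GELU rather than ReLU: the bottleneck can be a single unit and a
        # dead ReLU there would cut the whole gate path out of the graph
        return self.gate_fc2(self.gate_fc1(pooled).gelu()).sigmoid()

    def fuse_affinities(self, gated) -> Tensor:
        """Mix g gated [B,d,d] maps into the shared A with learned weights."""
        g = self.cfg.num_groups
        stacked = concat([ca.reshape(ca.shape[0], 1, *ca.shape[1:])
                          for ca in gated], axis=1)           # B,g,d,d
        mixed = (stacked * self.mix_weight.reshape(1, g, 1, 1)).sum(axis=1)
        return mixed + self.mix_bias.reshape(1, 1, 1)

    def forward(self, x):
        x = as_tensor(x)
        B, C, H, W = x.shape
        g = self.cfg.num_groups
        d = self.cfg.group_width
        q, k, v = self.project_qkv(x)
        affinities, queries = [], []
        for i in range(g):
            sl = slice(i * d, (i + 1) * d)
            affinities.append(channel_affinity(k[:, :, sl], v[:, :, sl]))
            queries.append(q[:, :, sl])
        gates = self.group_gate(affinities)                   # B,g in (0,1)
        gated = [affinities[i] * gates[:, i].reshape(B, 1, 1)
                 for i in range(g)]
        A = self.fuse_affinities(gated)                       # B,d,d
        outs = [qi.softmax(axis=2) @ A for qi in queries]     # each B,N,d
        fused = concat(outs, axis=2)                          # B,N,c
        return fused.swapaxes(1, 2).reshape(B, C, H, W)
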