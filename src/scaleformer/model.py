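"""The full segmentation network and its configuration schema.

`ScaleFormerConfig` collects every architectural knob (stage channels,
depths, per-stage scale lists, ISA groups, FFN ratio, decoder stem
width) with defaults matching the reference design: four stages at
strides 4/8/16/32 and per-stage scale lists [1,2,4,7] / [1,2,4,7] /
[1,7] / [1,7].  Configured scales larger than a stage's spatial
resolution are clamped to it at build time (small inputs would otherwise
make the token grid exceed the map).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

from .autodiff import as_tensor
from .decoder import Decoder, LogitsBundle, Stems
from .encoder import Encoder, StageConfig
from .exceptions import ConfigurationError
from .nn import Module

__all__ = ["ScaleFormerConfig", "ScaleFormer", "TINY_CONFIG"]

DEFAULT_SCALES = [[1, 2, 4, 7], [1, 2, 4, 7], [1, 7], [1, 7]]


@dataclass
class ScaleFormerConfig:
    input_size: int = 224
    in_channels: int = 1
    num_classes: int = 9
    stage_channels: list = field(default_factory=lambda: [64, 128, 256, 512])
    stage_depths: list = field(default_factory=lambda: [2, 2, 2, 2])
    stage_scales: list = field(default_factory=lambda:
                               [list(s) for s in DEFAULT_SCALES])
    ffn_ratio: int = 4
    isa_groups: int = 2
    lpu_expand: int = 4
    stem_channels: int | None = None     # None -> stage_channels[0] // 2
    seed: int = 0

    def __post_init__(self):
        if len(self.stage_channels) != 4 or len(self.stage_depths) != 4 \
                or len(self.stage_scales) != 4:
            raise ConfigurationError(
                "stage_channels / stage_depths / stage_scales must have "
                "four entries")
        if self.input_size % 32:
            raise ConfigurationError(
                f"input_size {self.input_size} must be divisible by 32")

    def stage_resolutions(self) -> list:
        return [self.input_size // s for s in (4, 8, 16, 32)]

    def effective_scales(self) -> list:
        """Per-stage scales clamped to the stage resolution."""
        out = []
        for res, scales in zip(self.stage_resolutions(), self.stage_scales):
            out.append([min(int(s), res) for s in scales])
        return out

    def stage_configs(self) -> list:
        return [StageConfig(channels=c, depth=d, scales=s,
                            isa_groups=self.isa_groups,
                            ffn_ratio=self.ffn_ratio,
                            lpu_expand=self.lpu_expand)
                for c, d, s in zip(self.stage_channels, self.stage_depths,
                                   self.effective_scales())]

    def resolved_stem_channels(self) -> int:
        return (self.stem_channels if self.stem_channels is not None
                else max(4, self.stage_channels[0] // 2))

    # ---- (de)serialization ------------------------------------------
    def to_dict(self) -> dict:
        return {
            "input_size": self.input_size,
            "in_channels": self.in_channels,
            "num_classes": self.num_classes,
            "stage_channels": list(self.stage_channels),
            "stage_depths": list(self.stage_depths),
            "stage_scales": [list(s) for s in self.stage_scales],
            "ffn_ratio": self.ffn_ratio,
            "isa_groups": self.isa_groups,
            "lpu_expand": self.lpu_expand,
            "stem_channels": self.stem_channels,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ScaleFormerConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        unknown = set(d) - set(known)
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**known)

    @classmethod
    def from_yaml(cls, path) -> "ScaleFormerConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


#: The desk-scale configuration used throughout the test suite.
TINY_CONFIG = dict(
    input_size=64,
    in_channels=1,
    num_classes=3,
    stage_channels=[16, 32, 64, 128],
    stage_depths=[1, 1, 1, 1],
    stage_scales=[list(s) for s in DEFAULT_SCALES],
    ffn_ratio=2,
    lpu_expand=2,
)


class ScaleFormer(Module):
    """Encoder-decoder segmentation network producing a LogitsBundle."""

    def __init__(self, config: ScaleFormerConfig,
                 rng: np.random.Generator | None = None):
        super().__init__()
        if rng is None:
            rng = np.random.default_rng(config.seed)
        self.config = config
        self.encoder = Encoder(config.stage_configs(), rng,
                               in_channels=config.in_channels)
        self.stems = Stems(config.in_channels,
                           config.resolved_stem_channels(), rng)
        self.decoder = Decoder(config.stage_channels,
                               config.resolved_stem_channels(),
                               config.num_classes, rng)

    def forward(self, image) -> LogitsBundle:
        image = as_tensor(image)
        pyramid = self.encoder(image)
        f_full, f_half = self.stems(image)
        return self.decoder(pyramid, f_full, f_half)
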