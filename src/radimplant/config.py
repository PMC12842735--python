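"""Run configuration and deterministic seed fan-out.

A single root seed is expanded into named substreams (mask sampling,
augmentation, weight init, splits, scene generation ...) so that any
stage can be re-run in isolation and reproduce its draws.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

__all__ = ["RunConfig", "TrainConfig", "rng_for"]


def rng_for(seed: int, name: str) -> np.random.Generator:
    """Named, independent random substream derived from one root seed."""
    return np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF,
                                                         zlib.crc32(name.encode())]))


@dataclass
class RunConfig:
    """Shared knobs for data, tokenisation and model geometry.

    Defaults follow the full-scale protocol (416 x 416 inputs, 16 x 16
    patches, 25% mask ratio); tests and the bundled experiments use the
    scaled-down presets from :func:`RunConfig.tiny`.
    """

    seed: int = 0
    image_size: int = 416
    patch_size: int = 16
    mask_ratio: float = 0.25
    enc_dim: int = 768
    enc_depth: int = 12
    enc_heads: int = 12
    dec_dim: int = 512
    dec_depth: int = 4
    dec_heads: int = 8
    augment_ops: tuple = ("noise", "hflip", "vflip", "rot90cw", "rot90ccw")

    def __post_init__(self):
        if not 0.0 < self.mask_ratio < 1.0:
            raise ValueError(f"mask_ratio {self.mask_ratio} outside (0, 1)")
        if self.image_size % self.patch_size != 0:
            raise ValueError(
                f"image_size {self.image_size} not divisible by patch_size {self.patch_size}")

    @classmethod
    def tiny(cls, seed: int = 0, **overrides) -> "RunConfig":
        """CPU-friendly preset: 64 x 64 images, P=8, 2-layer D=64 encoder."""
        kwargs = dict(seed=seed, image_size=64, patch_size=8, mask_ratio=0.25,
                      enc_dim=64, enc_depth=2, enc_heads=4,
                      dec_dim=64, dec_depth=1, dec_heads=4)
        kwargs.update(overrides)
        return cls(**kwargs)

    def rng(self, name: str) -> np.random.Generator:
        return rng_for(self.seed, name)

    @property
    def grid(self) -> tuple[int, int]:
        n = self.image_size // self.patch_size
        return (n, n)

    def to_yaml(self, path):
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        if "augment_ops" in doc:
            doc["augment_ops"] = tuple(doc["augment_ops"])
        return cls(**doc)


@dataclass
class TrainConfig:
    """Optimiser and schedule settings (AdamW, linear warmup + cosine decay)."""

    base_lr: float = 1.5e-4
    weight_decay: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.95
    warmup_epochs: int = 10
    total_epochs: int = 100
    batch_size: int = 16
    objective: str = "mde"  # or "mae"

    def __post_init__(self):
        if self.base_lr <= 0:
            raise ValueError("base_lr must be positive")
        if self.warmup_epochs > self.total_epochs:
            raise ValueError("warmup_epochs exceeds total_epochs")
        if self.objective not in ("mde", "mae"):
            raise ValueError(f"unknown objective {self.objective!r}")
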