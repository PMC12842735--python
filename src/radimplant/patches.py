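"""Patch tokenisation, positional encodings, random masking, augmentation.

Images are partitioned into non-overlapping P x P patches in row-major
order and flattened channel-last, exactly invertible by
:func:`unpatchify`. Masking hides a fixed, exact number of patches:
``round_half_up(r * N)`` for mask ratio ``r`` over ``N`` patches.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .records import AnnotationRecord, RadiographSample

__all__ = [
    "PatchGrid",
    "MaskSpec",
    "patchify",
    "unpatchify",
    "positional_encoding",
    "sample_mask",
    "augment",
    "AUGMENT_OPS",
]

AUGMENT_OPS = ("noise", "hflip", "vflip", "rot90cw", "rot90ccw")


@dataclass
class PatchGrid:
    patch_size: int
    rows: int
    cols: int
    channels: int
    patches: np.ndarray  # (N, P*P*C), row-major patch order

    @property
    def n_patches(self) -> int:
        return self.rows * self.cols


@dataclass
class MaskSpec:
    n_patches: int
    masked_idx: np.ndarray
    visible_idx: np.ndarray
    ratio: float

    def __post_init__(self):
        self.masked_idx = np.asarray(self.masked_idx, dtype=np.int64)
        self.visible_idx = np.asarray(self.visible_idx, dtype=np.int64)
        if len(np.intersect1d(self.masked_idx, self.visible_idx)) != 0:
            raise ValueError("masked and visible index sets overlap")
        joined = np.sort(np.concatenate([self.masked_idx, self.visible_idx]))
        if not np.array_equal(joined, np.arange(self.n_patches)):
            raise ValueError("masked + visible indices do not cover all patches")


def patchify(image: np.ndarray, patch_size: int) -> PatchGrid:
    """Split an (H, W) or (H, W, C) image into flattened P x P patches."""
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[:, :, None]
    if img.ndim != 3:
        raise ValueError(f"expected 2-D or 3-D image, got shape {image.shape}")
    h, w, c = img.shape
    p = int(patch_size)
    if h % p != 0 or w % p != 0:
        raise ValueError(f"image {h}x{w} not divisible by patch size {p}")
    rows, cols = h // p, w // p
    # (rows, cols, p, p, c) -> (N, p*p*c), channel-last within a patch
    patches = img.reshape(rows, p, cols, p, c).transpose(0, 2, 1, 3, 4).reshape(rows * cols, p * p * c)
    return PatchGrid(patch_size=p, rows=rows, cols=cols, channels=c, patches=patches)


def unpatchify(grid: PatchGrid) -> np.ndarray:
    """Exact inverse of :func:`patchify`; returns (H, W) when C == 1."""
    p, c = grid.patch_size, grid.channels
    img = (grid.patches.reshape(grid.rows, grid.cols, p, p, c)
           .transpose(0, 2, 1, 3, 4)
           .reshape(grid.rows * p, grid.cols * p, c))
    return img[:, :, 0] if c == 1 else img


def positional_encoding(grid_shape: tuple[int, int], dim: int) -> np.ndarray:
    """Fixed 2-D sine-cosine position table, (rows*cols, dim), values in [-1, 1].

    Half the channels encode the row coordinate, half the column, each as
    interleaved sin/cos over a geometric frequency ladder — the standard
    non-learnable embedding for masked-autoencoder pipelines.
    """
    rows, cols = grid_shape
    if dim % 4 != 0:
        raise ValueError(f"positional dim {dim} must be divisible by 4")
    half = dim // 2

    def _1d(positions: np.ndarray) -> np.ndarray:
        omega = np.arange(half // 2, dtype=np.float64) / (half / 2.0)
        omega = 1.0 / 10000 ** omega
        out = positions[:, None] * omega[None, :]
        return np.concatenate([np.sin(out), np.cos(out)], axis=1)  # (n, half)

    grid_y, grid_x = np.meshgrid(np.arange(rows, dtype=np.float64),
                                 np.arange(cols, dtype=np.float64), indexing="ij")
    emb_y = _1d(grid_y.reshape(-1))
    emb_x = _1d(grid_x.reshape(-1))
    return np.concatenate([emb_y, emb_x], axis=1)


def mask_count(n_patches: int, ratio: float) -> int:
    """Number of masked patches: round-half-up of ratio * N."""
    return int(np.floor(ratio * n_patches + 0.5))


def sample_mask(n_patches: int, ratio: float, rng: np.random.Generator) -> MaskSpec:
    """Uniform random mask over patches with an exact masked count."""
    if not 0.0 < ratio < 1.0:
        raise ValueError(f"mask ratio {ratio} outside (0, 1)")
    if n_patches < 1:
        raise ValueError("need at least one patch")
    m = mask_count(n_patches, ratio)
    if m == 0 or m == n_patches:
        raise ValueError(f"degenerate mask: {m} of {n_patches} patches masked at ratio {ratio}")
    masked = rng.choice(n_patches, size=m, replace=False)
    masked = np.sort(masked)
    visible = np.setdiff1d(np.arange(n_patches), masked)
    return MaskSpec(n_patches=n_patches, masked_idx=masked, visible_idx=visible, ratio=ratio)


# ---------------------------------------------------------------------------
# Augmentation


def _transform_box(box, op: str, width: float, height: float):
    x, y, w, h = box
    if op == "hflip":
        return (width - x - w, y, w, h)
    if op == "vflip":
        return (x, height - y - h, w, h)
    if op == "rot90cw":
        # (x, y) in an HxW image maps to (H - y - h, x) in the WxH result
        return (height - y - h, x, h, w)
    if op == "rot90ccw":
        return (y, width - x - w, h, w)
    raise ValueError(f"unknown geometric op {op!r}")


def augment(sample: RadiographSample, ops, rng: np.random.Generator,
            max_noise_fraction: float = 0.06) -> RadiographSample:
    """Apply augmentations in the given order, keeping boxes consistent.

    ``noise`` replaces a uniformly chosen set of at most
    ``max_noise_fraction`` of the pixels (fraction drawn uniformly per
    image) with values drawn from the image's own intensity range.
    Geometric ops transform annotation boxes together with the pixels.
    """
    unknown = set(ops) - set(AUGMENT_OPS)
    if unknown:
        raise ValueError(f"unknown augmentation ops {sorted(unknown)}")
    img = np.asarray(sample.image, dtype=np.float64).copy()
    anns = [AnnotationRecord(a.image_id, tuple(a.box), a.category, a.level, a.patient_id)
            for a in sample.annotations]
    for op in ops:
        h, w = img.shape[:2]
        if op == "noise":
            frac = rng.uniform(0.0, max_noise_fraction)
            n_pix = int(frac * h * w)
            if n_pix > 0:
                flat_idx = rng.choice(h * w, size=n_pix, replace=False)
                lo, hi = float(img.min()), float(img.max())
                img.reshape(-1)[flat_idx] = rng.uniform(lo, hi, size=n_pix)
        elif op == "hflip":
            img = img[:, ::-1].copy()
        elif op == "vflip":
            img = img[::-1, :].copy()
        elif op == "rot90cw":
            img = np.rot90(img, k=-1).copy()
        elif op == "rot90ccw":
            img = np.rot90(img, k=1).copy()
        if op != "noise":
            for a in anns:
                a.box = _transform_box(a.box, op, w, h)
    return RadiographSample(image=img, annotations=anns,
                            image_id=sample.image_id, patient_id=sample.patient_id)
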