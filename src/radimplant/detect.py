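"""Stage 1: design-part detection with a fine-tuned ViT backbone.

The pre-trained encoder (or a random initialisation) provides a
stride-P token map. A minimal anchor-free dense head predicts, per
stride-P cell, an objectness logit, design-class logits and a box
regression (center offsets and log sizes relative to the stride). This
deliberately replaces a full two-stage detector: the scientific
contribution under test is the pre-training objective and the part
assembly, and the detector is a pluggable contract — anything that
emits scored part boxes can feed stage 2.

Class imbalance is handled with inverse-frequency class weights and a
focal term that down-weights easy dominant classes.

Target assignment: a cell is positive when its center lies inside a
ground-truth part box; when several boxes contain the center, the
smallest box wins.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import nn
from ._autograd import Tensor
from .coco import DatasetIndex
from .config import RunConfig, TrainConfig, rng_for
from .model import MaskedAutoencoder
from .records import PartDetection

__all__ = [
    "FeaturePyramid",
    "build_feature_pyramid",
    "focal_loss",
    "Detector",
    "run_finetune",
    "predict_parts",
    "nms",
]


@dataclass
class FeaturePyramid:
    """Multi-stride maps derived from the stride-P token map."""

    maps: dict[int, np.ndarray]  # stride -> (H_s, W_s, D)


def tokens_to_map(tokens: np.ndarray, grid: tuple[int, int]) -> np.ndarray:
    """Reshape a (N, D) token sequence to an (rows, cols, D) map.

    Token k lands at cell (k // cols, k % cols) — the row-major patch order.
    """
    rows, cols = grid
    tokens = np.asarray(tokens)
    if tokens.shape[0] != rows * cols:
        raise ValueError(f"{tokens.shape[0]} tokens cannot fill a {rows}x{cols} grid")
    return tokens.reshape(rows, cols, -1)


def build_feature_pyramid(encoder: MaskedAutoencoder, image: np.ndarray) -> FeaturePyramid:
    """Simple feature pyramid from the single-scale ViT map.

    The stride-P map is the reshaped token sequence; finer levels
    (strides P/2, P/4) are produced by nearest-neighbour upsampling and
    the coarser level (stride 2P) by 2x2 average pooling. Channels stay
    uniform, so the lateral projection is the identity.
    """
    tokens = encoder.encoder_features(image).data
    rows, cols = encoder.cfg.grid
    base = tokens_to_map(tokens, (rows, cols))
    p = encoder.cfg.patch_size
    maps = {p: base}
    maps[p // 2] = base.repeat(2, axis=0).repeat(2, axis=1)
    maps[p // 4] = base.repeat(4, axis=0).repeat(4, axis=1)
    pooled = base[: rows // 2 * 2, : cols // 2 * 2]
    pooled = pooled.reshape(rows // 2, 2, cols // 2, 2, -1).mean(axis=(1, 3))
    maps[2 * p] = pooled
    return FeaturePyramid(maps=maps)


def focal_loss(logits: Tensor | np.ndarray, labels: np.ndarray, gamma: float = 2.0,
               class_weights: np.ndarray | None = None) -> Tensor:
    """Focal cross-entropy: mean over rows of ``-w_y (1 - p_y)^γ log p_y``.

    With γ = 0 and unit weights this is exactly (weighted) cross-entropy.
    """
    if gamma < 0:
        raise ValueError("gamma must be >= 0")
    x = logits if isinstance(logits, Tensor) else Tensor(np.asarray(logits, dtype=np.float64))
    labels = np.asarray(labels, dtype=np.int64)
    n, k = x.shape
    if class_weights is None:
        class_weights = np.ones(k)
    class_weights = np.asarray(class_weights, dtype=np.float64)
    if np.any(class_weights <= 0):
        raise ValueError("class weights must be positive")
    logp = x.log_softmax(axis=-1)
    rows = np.arange(n)
    logp_true = logp[(rows, labels)]  # (n,)
    p_true = logp_true.exp()
    w = Tensor(class_weights[labels])
    if gamma == 0:
        per_row = -(w * logp_true)
    else:
        per_row = -(w * (1.0 - p_true) ** float(gamma) * logp_true)
    return per_row.mean()


class DenseHead(nn.Module):
    """Per-cell predictions: [objectness, K class logits, (tx, ty, tw, th)]."""

    def __init__(self, dim: int, n_classes: int, rng, hidden: int | None = None):
        hidden = hidden or dim
        self.n_classes = n_classes
        self.fc1 = nn.Linear(dim, hidden, rng)
        self.out = nn.Linear(hidden, 1 + n_classes + 4, rng)

    def __call__(self, tokens: Tensor) -> Tensor:
        return self.out(self.fc1(tokens).gelu())


class Detector(nn.Module):
    """ViT backbone + dense head over the stride-P cell grid."""

    def __init__(self, run_cfg: RunConfig, categories: list[str],
                 encoder_state: dict[str, np.ndarray] | None = None,
                 init_seed: int | None = None):
        self.run_cfg = run_cfg
        self.categories = list(categories)
        self.backbone = MaskedAutoencoder(run_cfg, head="embedding", init_seed=init_seed)
        if encoder_state is not None:
            self.backbone.load_encoder_state(encoder_state)
        rng = rng_for(run_cfg.seed if init_seed is None else init_seed, "head-init")
        self.head = DenseHead(run_cfg.enc_dim, len(categories), rng)

    def named_parameters(self, prefix: str = ""):
        # backbone decoder/head params never train or predict here
        wanted = ("tokenizer.", "encoder.", "enc_norm.")
        for name, p in self.backbone.named_parameters(prefix=prefix + "backbone."):
            if name.split("backbone.", 1)[1].startswith(wanted):
                yield name, p
        yield from self.head.named_parameters(prefix=prefix + "head.")

    def forward(self, images: np.ndarray) -> Tensor:
        """(B, H, W) images -> (B, N_cells, 1 + K + 4) raw predictions."""
        tokens = self.backbone.encoder_features(images)
        return self.head(tokens)


# ---------------------------------------------------------------------------
# target assignment


def assign_targets(annotations, categories: list[str], grid: tuple[int, int],
                   stride: int) -> dict:
    """Center-in-box assignment on the stride-P cell grid; smallest box wins ties."""
    rows, cols = grid
    n = rows * cols
    cat_idx = {c: i for i, c in enumerate(categories)}
    obj = np.zeros(n)
    cls = np.zeros(n, dtype=np.int64)
    box = np.zeros((n, 4))
    best_area = np.full(n, np.inf)
    cy = (np.arange(rows) + 0.5) * stride
    cx = (np.arange(cols) + 0.5) * stride
    for a in annotations:
        if a.level != "part" or a.category not in cat_idx:
            continue
        x, y, w, h = a.box
        area = w * h
        r_in = np.nonzero((cy > y) & (cy < y + h))[0]
        c_in = np.nonzero((cx > x) & (cx < x + w))[0]
        for r in r_in:
            for c in c_in:
                k = r * cols + c
                if area < best_area[k]:
                    best_area[k] = area
                    obj[k] = 1.0
                    cls[k] = cat_idx[a.category]
                    box[k] = ((x + w / 2 - cx[c]) / stride,
                              (y + h / 2 - cy[r]) / stride,
                              np.log(w / stride), np.log(h / stride))
    return {"obj": obj, "cls": cls, "box": box}


def decode_cells(raw: np.ndarray, categories: list[str], grid: tuple[int, int],
                 stride: int) -> list[PartDetection]:
    """Raw per-cell outputs -> scored boxes (before thresholding/NMS)."""
    rows, cols = grid
    k = len(categories)
    obj = 1.0 / (1.0 + np.exp(-raw[:, 0]))
    logits = raw[:, 1:1 + k]
    probs = np.exp(logits - logits.max(axis=1, keepdims=True))
    probs /= probs.sum(axis=1, keepdims=True)
    t = raw[:, 1 + k:]
    dets = []
    for idx in range(rows * cols):
        r, c = divmod(idx, cols)
        cx = (c + 0.5) * stride + t[idx, 0] * stride
        cy = (r + 0.5) * stride + t[idx, 1] * stride
        w = float(np.exp(np.clip(t[idx, 2], -6, 6)) * stride)
        h = float(np.exp(np.clip(t[idx, 3], -6, 6)) * stride)
        ci = int(np.argmax(probs[idx]))
        score = float(obj[idx] * probs[idx, ci])
        dets.append(PartDetection(box=(cx - w / 2, cy - h / 2, w, h),
                                  part_category=categories[ci], score=score))
    return dets


def nms(detections: list[PartDetection], iou_thresh: float = 0.5) -> list[PartDetection]:
    """Greedy per-category non-maximum suppression, descending score."""
    from .evaluate import iou as box_iou

    kept: list[PartDetection] = []
    for cat in {d.part_category for d in detections}:
        cands = sorted((d for d in detections if d.part_category == cat),
                       key=lambda d: -d.score)
        chosen: list[PartDetection] = []
        for d in cands:
            if all(box_iou(d.box, c.box) < iou_thresh for c in chosen):
                chosen.append(d)
        kept.extend(chosen)
    return sorted(kept, key=lambda d: -d.score)


def predict_parts(detector: Detector, image: np.ndarray, score_thresh: float = 0.3,
                  nms_iou: float = 0.5) -> list[PartDetection]:
    raw = detector.forward(np.asarray(image)[None]).data[0]
    stride = detector.run_cfg.patch_size
    dets = decode_cells(raw, detector.categories, detector.run_cfg.grid, stride)
    dets = [d for d in dets if d.score >= score_thresh]
    return nms(dets, iou_thresh=nms_iou)


# ---------------------------------------------------------------------------
# fine-tuning loop


@dataclass
class FinetuneConfig:
    lr: float = 1e-4          # full-scale downstream default
    weight_decay: float = 0.05
    beta1: float = 0.9
    beta2: float = 0.95
    epochs: int = 40
    batch_size: int = 10
    gamma: float = 2.0        # focal exponent
    box_weight: float = 1.0
    cls_weight: float = 1.0


def inverse_frequency_weights(index: DatasetIndex, categories: list[str]) -> np.ndarray:
    counts = np.zeros(len(categories))
    pos = {c: i for i, c in enumerate(categories)}
    for a in index.annotations:
        if a.level == "part" and a.category in pos:
            counts[pos[a.category]] += 1
    counts = np.maximum(counts, 1.0)
    w = counts.sum() / (len(categories) * counts)
    return w


def run_finetune(index: DatasetIndex, images: dict[int, np.ndarray], run_cfg: RunConfig,
                 cfg: FinetuneConfig | None = None,
                 encoder_state: dict[str, np.ndarray] | None = None,
                 ) -> tuple[Detector, list[dict]]:
    """Train the backbone + dense head end-to-end on part annotations."""
    cfg = cfg or FinetuneConfig()
    categories = [name for name, meta in index.categories.items() if meta["level"] == "part"]
    if not any(a.level == "part" for a in index.annotations):
        raise ValueError("dataset has no part-level annotations")
    det = Detector(run_cfg, categories, encoder_state=encoder_state)
    params = [p for _, p in det.named_parameters()]
    opt = nn.AdamW(params, lr=cfg.lr, betas=(cfg.beta1, cfg.beta2),
                   weight_decay=cfg.weight_decay)
    class_w = inverse_frequency_weights(index, categories)
    by_image = index.by_image()
    grid, stride = run_cfg.grid, run_cfg.patch_size
    targets = {iid: assign_targets(anns, categories, grid, stride)
               for iid, anns in by_image.items()}
    ids = sorted(images)
    rng = rng_for(run_cfg.seed, "finetune-order")
    history: list[dict] = []
    n_cells = grid[0] * grid[1]
    k = len(categories)
    for epoch in range(cfg.epochs):
        order = rng.permutation(len(ids))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(ids), cfg.batch_size):
            batch_ids = [ids[i] for i in order[start:start + cfg.batch_size]]
            imgs = np.stack([images[i] for i in batch_ids])
            raw = det.forward(imgs)  # (B, N, 1+K+4)
            b = len(batch_ids)
            obj_t = np.stack([targets[i]["obj"] for i in batch_ids])  # (B, N)
            cls_t = np.stack([targets[i]["cls"] for i in batch_ids])
            box_t = np.stack([targets[i]["box"] for i in batch_ids])
            flat = raw.reshape(b * n_cells, 1 + k + 4)
            obj_logit = flat[(np.arange(b * n_cells), np.zeros(b * n_cells, dtype=np.int64))]
            y = Tensor(obj_t.reshape(-1))
            # numerically-stable BCE with logits: max(z,0) - z*y + log(1+exp(-|z|))
            z = obj_logit
            bce = z.relu() - z * y + (1.0 + (-z.abs()).exp()).log()
            loss = bce.mean()
            pos = np.nonzero(obj_t.reshape(-1) > 0)[0]
            if len(pos):
                cls_logits = flat[(pos[:, None], 1 + np.arange(k)[None, :])]
                loss = loss + cfg.cls_weight * focal_loss(
                    cls_logits, cls_t.reshape(-1)[pos], gamma=cfg.gamma, class_weights=class_w)
                box_pred = flat[(pos[:, None], 1 + k + np.arange(4)[None, :])]
                diff = box_pred - Tensor(box_t.reshape(-1, 4)[pos])
                loss = loss + cfg.box_weight * (diff * diff).mean()
            opt.zero_grad()
            loss.backward()
            opt.step()
            epoch_loss += float(loss.data)
            n_batches += 1
        history.append({"epoch": epoch, "loss": epoch_loss / max(1, n_batches)})
    return det, history
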