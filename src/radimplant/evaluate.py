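"""Average-precision evaluation, cross-validated reporting, ratio sweep.

AP follows the COCO recipe: detections are matched to ground truth
greedily in descending score order, one-to-one per ground truth at
IoU >= threshold, and the precision-recall curve is integrated with
101-point interpolation. Values are reported x100. Both AP50 and the
COCO average over IoU 0.50:0.05:0.95 are always computed, with AP50 as
the headline number.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "iou",
    "average_precision",
    "evaluate_detections",
    "EvalReport",
    "crossval_evaluate",
    "run_mask_ratio_sweep",
]

COCO_IOU_THRESHOLDS = np.arange(0.50, 0.96, 0.05)


def iou(box_a, box_b) -> float:
    """Intersection-over-union of two (x, y, w, h) boxes."""
    ax, ay, aw, ah = box_a
    bx, by, bw, bh = box_b
    if aw <= 0 or ah <= 0 or bw <= 0 or bh <= 0:
        raise ValueError("boxes must have positive area")
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union


def _ap_from_matches(scores: np.ndarray, is_tp: np.ndarray, n_gt: int) -> float:
    """101-point interpolated AP (x100) from per-detection TP flags."""
    if n_gt == 0:
        return float("nan")
    order = np.argsort(-scores, kind="stable")
    tp = np.cumsum(is_tp[order])
    fp = np.cumsum(~is_tp[order])
    recall = tp / n_gt
    precision = tp / np.maximum(tp + fp, 1)
    # precision envelope, then sample at 101 recall points
    ap = 0.0
    for r in np.linspace(0.0, 1.0, 101):
        mask = recall >= r - 1e-12
        ap += precision[mask].max() if mask.any() else 0.0
    return 100.0 * ap / 101.0


def average_precision(dets, gts, iou_thresh: float = 0.5) -> dict[str, float]:
    """Per-class AP over a detection/ground-truth collection.

    ``dets``: iterable of (image_id, category, box, score);
    ``gts``: iterable of (image_id, category, box).
    Classes without ground truth are skipped (no entry in the result).
    """
    dets = list(dets)
    gts = list(gts)
    classes = sorted({g[1] for g in gts})
    result: dict[str, float] = {}
    for cls in classes:
        cls_gts: dict[int, list] = {}
        for g in gts:
            if g[1] == cls:
                cls_gts.setdefault(g[0], []).append(list(g[2]))
        matched: dict[int, np.ndarray] = {iid: np.zeros(len(b), dtype=bool)
                                          for iid, b in cls_gts.items()}
        cls_dets = sorted((d for d in dets if d[1] == cls), key=lambda d: -d[3])
        scores = np.array([d[3] for d in cls_dets])
        is_tp = np.zeros(len(cls_dets), dtype=bool)
        for i, (iid, _, box, _score) in enumerate(cls_dets):
            candidates = cls_gts.get(iid, [])
            best, best_iou = -1, iou_thresh
            for j, gt_box in enumerate(candidates):
                if matched[iid][j]:
                    continue
                val = iou(box, gt_box)
                if val >= best_iou:
                    best, best_iou = j, val
            if best >= 0:
                matched[iid][best] = True
                is_tp[i] = True
        n_gt = sum(len(b) for b in cls_gts.values())
        result[cls] = _ap_from_matches(scores, is_tp, n_gt)
    return result


@dataclass
class EvalReport:
    per_class_ap50: dict[str, float]
    ap50: float
    ap_coco: float
    per_fold: list[dict] = field(default_factory=list)

    def summary(self) -> str:
        lines = [f"AP50 = {self.ap50:.1f}   AP[.50:.95] = {self.ap_coco:.1f}"]
        for cls, ap in sorted(self.per_class_ap50.items()):
            lines.append(f"  {cls:<24s} AP50 = {ap:6.1f}")
        return "\n".join(lines)


def evaluate_detections(dets, gts) -> EvalReport:
    """AP50 and COCO-averaged AP (means over classes with ground truth)."""
    per_class = average_precision(dets, gts, iou_thresh=0.5)
    ap50 = float(np.nanmean(list(per_class.values()))) if per_class else float("nan")
    all_thresh = []
    for t in COCO_IOU_THRESHOLDS:
        vals = average_precision(dets, gts, iou_thresh=float(t)).values()
        all_thresh.append(np.nanmean(list(vals)) if vals else np.nan)
    return EvalReport(per_class_ap50=per_class, ap50=ap50,
                      ap_coco=float(np.nanmean(all_thresh)))


def crossval_evaluate(index, pipeline, n_sets: int = 5, seed: int = 0) -> EvalReport:
    """Five-set patient-level cross-validation with a fixed test set.

    ``pipeline(train_ids, test_ids) -> (dets, gts)`` runs training and
    inference for one fold; the last split is the constant test set and
    each remaining set in turn plays validation.
    """
    from .coco import split_patient_level

    sets = split_patient_level(index, n_sets=n_sets, seed=seed)
    test_ids = sets[-1]
    folds = []
    for holdout in range(n_sets - 1):
        train_ids = set().union(*(sets[i] for i in range(n_sets - 1) if i != holdout))
        dets, gts = pipeline(train_ids, test_ids)
        rep = evaluate_detections(dets, gts)
        folds.append({"fold": holdout, "ap50": rep.ap50, "ap_coco": rep.ap_coco,
                      "per_class_ap50": rep.per_class_ap50})
    ap50s = [f["ap50"] for f in folds]
    apcs = [f["ap_coco"] for f in folds]
    merged: dict[str, list] = {}
    for f in folds:
        for cls, v in f["per_class_ap50"].items():
            merged.setdefault(cls, []).append(v)
    return EvalReport(
        per_class_ap50={c: float(np.nanmean(v)) for c, v in merged.items()},
        ap50=float(np.mean(ap50s)), ap_coco=float(np.mean(apcs)), per_fold=folds)


def run_mask_ratio_sweep(ratios, epochs_list, seeds, n_images: int = 48,
                         pretrain_steps: int = 60, finetune_epochs: int = 15,
                         image_size: int = 64) -> list[dict]:
    """Mask-ratio / epoch sweep at synthetic scale.

    For each (ratio, epochs, seed): pre-train a tiny model on synthetic
    radiographs, fine-tune the part detector from the resulting encoder,
    and record held-out AP50. Rows that fail (e.g. a degenerate mask
    ratio) are marked failed and the sweep continues. No claim is made
    that trends at this scale transfer to clinical data.
    """
    from .config import RunConfig, TrainConfig
    from .detect import FinetuneConfig, predict_parts, run_finetune
    from .pretrain import run_pretraining
    from .synthetic import GeneratorParams, generate_dataset

    rows = []
    for ratio in ratios:
        for epochs in epochs_list:
            for seed in seeds:
                row = {"mask_ratio": ratio, "epochs": epochs, "seed": seed,
                       "ap50": float("nan"), "status": "ok"}
                try:
                    run_cfg = RunConfig.tiny(seed=seed, mask_ratio=ratio)
                    params = GeneratorParams.easy(image_size=image_size)
                    index, images = generate_dataset(n_images, params, seed=seed)
                    ids = sorted(images)
                    split = int(0.75 * len(ids))
                    train_ids, test_ids = set(ids[:split]), set(ids[split:])
                    train_imgs = np.stack([images[i] for i in sorted(train_ids)])
                    tcfg = TrainConfig(base_lr=1e-3, warmup_epochs=2, total_epochs=epochs,
                                       batch_size=16, objective="mde")
                    model, _ = run_pretraining(train_imgs, run_cfg, tcfg,
                                               n_steps=pretrain_steps)
                    sub_index = _subset_index(index, train_ids)
                    det, _ = run_finetune(sub_index, {i: images[i] for i in train_ids},
                                          run_cfg,
                                          FinetuneConfig(lr=1e-3, epochs=finetune_epochs),
                                          encoder_state=model.encoder_state())
                    dets, gts = [], []
                    by_image = index.by_image()
                    for iid in sorted(test_ids):
                        for d in predict_parts(det, images[iid]):
                            dets.append((iid, d.part_category, d.box, d.score))
                        for a in by_image[iid]:
                            if a.level == "part":
                                gts.append((iid, a.category, a.box))
                    row["ap50"] = evaluate_detections(dets, gts).ap50
                except ValueError as exc:
                    row["status"] = f"failed: {exc}"
                rows.append(row)
    return rows


def _subset_index(index, image_ids: set[int]):
    from .coco import DatasetIndex

    return DatasetIndex(
        images=[im for im in index.images if im.image_id in image_ids],
        annotations=[a for a in index.annotations if a.image_id in image_ids],
        categories=dict(index.categories))
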