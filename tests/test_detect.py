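"""Feature pyramid, focal loss, target assignment, NMS, fine-tune loop."""

import numpy as np
import pytest

from radimplant import RunConfig
from radimplant.coco import DatasetIndex, ImageEntry
from radimplant.detect import (Detector, FinetuneConfig, assign_targets,
                               build_feature_pyramid, focal_loss, nms,
                               run_finetune, tokens_to_map)
from radimplant.evaluate import iou
from radimplant.model import MaskedAutoencoder
from radimplant.records import AnnotationRecord, PartDetection


# ---------------------------------------------------------------------------
# feature pyramid


def test_pyramid_strides_and_shapes(rng):
    cfg = RunConfig.tiny(seed=1)  # 64x64, P=8 -> 8x8 tokens
    enc = MaskedAutoencoder(cfg, head="embedding")
    fp = build_feature_pyramid(enc, rng.random((64, 64)))
    assert {s: m.shape[:2] for s, m in fp.maps.items()} == {
        8: (8, 8), 4: (16, 16), 2: (32, 32), 16: (4, 4)}
    assert len({m.shape[2] for m in fp.maps.values()}) == 1  # uniform channels


def test_token_to_map_index_oracle():
    rows, cols = 3, 5
    tokens = np.arange(rows * cols)[:, None] * np.ones((1, 2))
    fmap = tokens_to_map(tokens, (rows, cols))
    for k in range(rows * cols):
        assert fmap[k // cols, k % cols, 0] == k
    with pytest.raises(ValueError):
        tokens_to_map(tokens, (4, 4))


# ---------------------------------------------------------------------------
# focal loss


def test_focal_gamma_zero_equals_cross_entropy(rng):
    logits = rng.normal(size=(20, 5))
    labels = rng.integers(0, 5, size=20)
    focal = focal_loss(logits, labels, gamma=0.0).data
    # independent cross-entropy
    z = logits - logits.max(axis=1, keepdims=True)
    logp = z - np.log(np.exp(z).sum(axis=1, keepdims=True))
    ce = -logp[np.arange(20), labels].mean()
    assert abs(float(focal) - ce) < 1e-7


def test_focal_binary_half_probability_is_ln2():
    logits = np.array([[0.0, 0.0]])
    assert float(focal_loss(logits, np.array([0]), gamma=0.0).data) == \
        pytest.approx(np.log(2.0))


def test_focal_elementwise_formula_oracle():
    p_true = 0.9
    logits = np.array([[np.log(p_true), np.log(1 - p_true)]])
    val = float(focal_loss(logits, np.array([0]), gamma=2.0).data)
    assert val == pytest.approx(-(1 - p_true) ** 2 * np.log(p_true), abs=1e-9)


def test_focal_confident_correct_prediction_vanishes():
    logits = np.array([[30.0, 0.0]])
    assert float(focal_loss(logits, np.array([0]), gamma=2.0).data) < 1e-10


def test_focal_decreasing_in_true_class_probability():
    vals = []
    for p in (0.3, 0.5, 0.7, 0.9):
        logits = np.array([[np.log(p), np.log(1 - p)]])
        vals.append(float(focal_loss(logits, np.array([0]), gamma=2.0).data))
    assert all(b < a for a, b in zip(vals, vals[1:]))


def test_focal_rejects_bad_arguments(rng):
    with pytest.raises(ValueError, match="gamma"):
        focal_loss(rng.normal(size=(2, 3)), np.zeros(2, dtype=int), gamma=-1)
    with pytest.raises(ValueError, match="weights"):
        focal_loss(rng.normal(size=(2, 3)), np.zeros(2, dtype=int),
                   class_weights=np.array([1.0, -1.0, 1.0]))


# ---------------------------------------------------------------------------
# assignment and NMS


def test_center_in_box_assignment_smallest_wins():
    anns = [
        AnnotationRecord(1, (0.0, 0.0, 32.0, 32.0), "coronal_bone", "part", "p"),
        AnnotationRecord(1, (8.0, 8.0, 8.0, 8.0), "middle_parallel", "part", "p"),
    ]
    t = assign_targets(anns, ["coronal_bone", "middle_parallel"], (8, 8), 8)
    # cell (1, 1) center (12, 12) lies in both; smaller box wins
    assert t["obj"][1 * 8 + 1] == 1.0 and t["cls"][1 * 8 + 1] == 1
    # cell (0, 0) center (4, 4) lies only in the big box
    assert t["obj"][0] == 1.0 and t["cls"][0] == 0
    assert t["obj"][7 * 8 + 7] == 0.0


def _det(x, y, w, h, score, cat="c"):
    return PartDetection(box=(x, y, w, h), part_category=cat, score=score)


def test_nms_keeps_best_of_identical_boxes():
    out = nms([_det(0, 0, 10, 10, 0.9), _det(0, 0, 10, 10, 0.8)], iou_thresh=0.5)
    assert len(out) == 1 and out[0].score == 0.9


def test_nms_matches_brute_force_oracle(rng):
    def oracle(dets, thresh):
        keep = []
        for d in sorted(dets, key=lambda d: -d.score):
            if all(d.part_category != k.part_category or iou(d.box, k.box) < thresh
                   for k in keep):
                keep.append(d)
        return sorted((id(k) for k in keep))

    for _ in range(30):
        dets = [_det(rng.uniform(0, 40), rng.uniform(0, 40), rng.uniform(4, 20),
                     rng.uniform(4, 20), float(rng.random()),
                     cat=str(rng.integers(0, 2))) for _ in range(12)]
        ours = sorted(id(d) for d in nms(dets, 0.5))
        assert ours == oracle(dets, 0.5)


def test_nms_idempotent(rng):
    dets = [_det(rng.uniform(0, 30), rng.uniform(0, 30), 10, 10,
                 float(rng.random())) for _ in range(15)]
    once = nms(dets, 0.5)
    twice = nms(once, 0.5)
    assert [d.box for d in twice] == [d.box for d in once]


# ---------------------------------------------------------------------------
# fine-tune loop


def _mini_index():
    cats = {"coronal_bone": {"id": 1, "level": "part"}}
    index = DatasetIndex(categories=cats)
    index.images.append(ImageEntry(1, "", 64, 64, "p1"))
    index.annotations.append(AnnotationRecord(1, (20.0, 10.0, 16.0, 20.0),
                                              "coronal_bone", "part", "p1"))
    return index


def test_zero_epoch_finetune_returns_initialization():
    index = _mini_index()
    images = {1: np.zeros((64, 64))}
    cfg = RunConfig.tiny(seed=8)
    det, hist = run_finetune(index, images, cfg, FinetuneConfig(epochs=0))
    ref = Detector(cfg, ["coronal_bone"])
    for (_, a), (_, b) in zip(det.named_parameters(), ref.named_parameters()):
        np.testing.assert_array_equal(a.data, b.data)
    assert hist == []


def test_finetune_requires_part_annotations():
    index = _mini_index()
    index.annotations = []
    with pytest.raises(ValueError, match="part"):
        run_finetune(index, {1: np.zeros((64, 64))}, RunConfig.tiny(seed=8),
                     FinetuneConfig(epochs=1))


def test_detections_depend_only_on_weights(rng):
    """Same weights => identical detections (backbone-swap property)."""
    from radimplant.detect import predict_parts

    cfg = RunConfig.tiny(seed=8)
    img = rng.random((64, 64))
    a = Detector(cfg, ["coronal_bone"], init_seed=4)
    b = Detector(cfg, ["coronal_bone"], init_seed=4)
    da = predict_parts(a, img, score_thresh=0.0)
    db = predict_parts(b, img, score_thresh=0.0)
    assert [(d.box, d.score) for d in da] == [(d.box, d.score) for d in db]
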