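"""Part grouping, missing-part inference, implant box assembly."""

import itertools

import numpy as np
import pytest

from radimplant.assembly import (AssemblyConfig, assemble_implant_boxes,
                                 assemble_scene, cluster_parts,
                                 estimate_implant_count, infer_missing_part)
from radimplant.records import PartDetection, PartGroup


def _det(x, y, w, h, cat, score=0.9, hint=None):
    return PartDetection(box=(x, y, w, h), part_category=cat, score=score,
                         system_hint=hint)


def _triplet(x0, y0, w=20, hint=None):
    return [
        _det(x0, y0, w + 6, 14, "coronal_bone", 0.9, hint),
        _det(x0 + 3, y0 + 14, w, 30, "middle_parallel", 0.8, hint),
        _det(x0 + 5, y0 + 44, w - 6, 14, "apical_hole_round", 0.7, hint),
    ]


# ---------------------------------------------------------------------------
# implant count


def test_count_from_coronal_parts():
    assert estimate_implant_count(_triplet(10, 10)) == 1
    assert estimate_implant_count(_triplet(10, 10) + _triplet(200, 10)) == 2


def test_count_fallback_without_coronal():
    dets = [_det(0, 0, 5, 5, "middle_parallel") for _ in range(4)]
    assert estimate_implant_count(dets) == 2  # ceil(4 / 3)
    assert estimate_implant_count([]) == 0


def test_count_literal_mode_is_number_of_parts():
    dets = _triplet(10, 10)
    assert estimate_implant_count(dets, AssemblyConfig(literal_k=True)) == 3


# ---------------------------------------------------------------------------
# clustering


def test_two_distant_implants_recovered_exactly():
    dets = _triplet(40, 50) + _triplet(240, 60)
    groups = cluster_parts(dets, 2, seed=0)
    assert len(groups) == 2
    memberships = sorted(tuple(sorted(m.center[0] for m in g.members))
                         for g in groups)
    expected = sorted(tuple(sorted(d.center[0] for d in dets[i:i + 3]))
                      for i in (0, 3))
    assert memberships == expected


def test_k_equals_n_gives_singletons():
    dets = _triplet(10, 10)
    groups = cluster_parts(dets, 3, seed=0)
    assert sorted(len(g.members) for g in groups) == [1, 1, 1]


def test_k_too_large_raises():
    with pytest.raises(ValueError, match="infeasible"):
        cluster_parts(_triplet(0, 0), 4, seed=0)


def test_kmeans_objective_beats_random_assignments(rng):
    dets = _triplet(30, 40) + _triplet(250, 30) + _triplet(140, 200)
    centers = np.array([d.center for d in dets])
    groups = cluster_parts(dets, 3, seed=1)
    label_of = {}
    for gi, g in enumerate(groups):
        for m in g.members:
            label_of[id(m)] = gi
    labels = np.array([label_of[id(d)] for d in dets])

    def objective(lab):
        total = 0.0
        for g in set(lab):
            pts = centers[lab == g]
            total += ((pts - pts.mean(axis=0)) ** 2).sum()
        return total

    ours = objective(labels)
    for _ in range(1000):
        rand = rng.integers(0, 3, size=len(dets))
        assert ours <= objective(rand) + 1e-9


def test_exhaustive_partition_oracle_small_instance(rng):
    """k-means grouping is no worse than the best 2-partition by center
    variance on a 6-detection instance."""
    dets = _triplet(40, 30) + _triplet(200, 50)
    centers = np.array([d.center for d in dets])
    best = np.inf
    for assign in itertools.product([0, 1], repeat=6):
        lab = np.array(assign)
        if len(set(assign)) < 2:
            continue
        total = sum(((centers[lab == g] - centers[lab == g].mean(axis=0)) ** 2).sum()
                    for g in (0, 1))
        best = min(best, total)
    groups = cluster_parts(dets, 2, seed=0)
    label_of = {id(m): gi for gi, g in enumerate(groups) for m in g.members}
    lab = np.array([label_of[id(d)] for d in dets])
    ours = sum(((centers[lab == g] - centers[lab == g].mean(axis=0)) ** 2).sum()
               for g in set(lab))
    assert ours <= best + 1e-9


def test_conservation_every_detection_grouped_or_logged():
    dets = _triplet(40, 50) + _triplet(240, 60)
    stray = _det(400, 400, 10, 10, "coronal_bone", 0.5)  # far from everything
    groups = cluster_parts(dets + [stray], 3, seed=0)
    grouped = [id(m) for g in groups for m in g.members]
    logged = [id(m) for g in groups for m, _reason in g.discarded]
    assert sorted(grouped + logged) == sorted(id(d) for d in dets + [stray])
    for g in groups:
        for _m, reason in g.discarded:
            assert reason  # non-empty explanation


# ---------------------------------------------------------------------------
# missing-part inference


def test_infer_middle_spans_gap_between_neighbours():
    group = PartGroup(members=[
        _det(10, 10, 20, 30, "coronal_bone"),
        _det(12, 100, 16, 30, "apical_hole_round")])
    group.axis = (0.0, 1.0)
    box = infer_missing_part(group, "middle").box
    assert box[1] == pytest.approx(40, abs=2)
    assert box[1] + box[3] == pytest.approx(100, abs=2)


def test_infer_apical_extrapolates_below_middle_with_ratio():
    cfg = AssemblyConfig()
    group = PartGroup(members=[
        _det(10, 10, 22, 14, "coronal_bone"),
        _det(12, 24, 18, 40, "middle_parallel")])
    group.axis = (0.0, 1.0)
    box = infer_missing_part(group, "apical", cfg).box
    rho = cfg.height_ratios["apical"] / cfg.height_ratios["middle"]
    assert box[3] == pytest.approx(40 * rho, abs=1e-9)
    assert box[1] == pytest.approx(64, abs=1e-9)  # directly below the middle


def test_inference_follows_horizontal_axis():
    """An implant lying on its side is completed along the rotated axis."""
    group = PartGroup(members=[
        _det(10, 10, 30, 20, "coronal_bone"),     # leftmost
        _det(100, 12, 30, 16, "apical_hole_round")])  # rightmost
    group.axis = (1.0, 0.0)
    box = infer_missing_part(group, "middle").box
    assert box[0] == pytest.approx(40, abs=2)
    assert box[0] + box[2] == pytest.approx(100, abs=2)


def test_infer_errors():
    with pytest.raises(ValueError, match="empty"):
        infer_missing_part(PartGroup(members=[]), "middle")
    full = PartGroup(members=_triplet(0, 0))
    with pytest.raises(ValueError, match="already"):
        infer_missing_part(full, "middle")


# ---------------------------------------------------------------------------
# assembly


def test_union_box_arithmetic():
    group = PartGroup(members=[
        _det(10, 10, 20, 30, "coronal_bone", 0.9, "SystemA"),
        _det(12, 40, 16, 50, "middle_parallel", 0.8, "SystemA"),
        _det(14, 90, 12, 20, "apical_hole_round", 0.7, "SystemB")])
    out = assemble_implant_boxes([group])
    assert len(out) == 1
    assert out[0].box == (10, 10, 20, 100)
    assert out[0].score == pytest.approx((0.9 + 0.8 + 0.7) / 3)
    assert out[0].system_class == "SystemA"  # total-score vote 1.7 > 0.7


def test_members_contained_in_implant_box(rng):
    for _ in range(20):
        members = [_det(rng.uniform(0, 50), rng.uniform(0, 150), rng.uniform(5, 30),
                        rng.uniform(5, 40), "middle_parallel", 0.5)
                   for _ in range(3)]
        for m, lvl in zip(members, ("coronal_bone", "middle_parallel",
                                    "apical_hole_round")):
            m.part_category = lvl
        out = assemble_implant_boxes([PartGroup(members=members)],
                                     AssemblyConfig(infer_missing=False))
        x, y, w, h = out[0].box
        eps = 1e-9
        for m in members:
            mx, my, mw, mh = m.box
            assert mx >= x - eps and my >= y - eps
            assert mx + mw <= x + w + eps and my + mh <= y + h + eps


def test_permutation_invariance_of_assembly(rng):
    dets = _triplet(40, 50, hint="SystemA") + _triplet(240, 60, hint="SystemC")
    base = {tuple(np.round(i.box, 6)) for i in assemble_scene(dets, seed=0)}
    for _ in range(5):
        perm = list(dets)
        rng.shuffle(perm)
        got = {tuple(np.round(i.box, 6)) for i in assemble_scene(perm, seed=0)}
        assert got == base


def test_single_member_group_box_is_member_box():
    g = PartGroup(members=[_det(5, 6, 7, 8, "coronal_bone")])
    out = assemble_implant_boxes([g], AssemblyConfig(min_levels_to_keep=1,
                                                     infer_missing=False))
    assert out[0].box == (5, 6, 7, 8)


def test_full_scene_pipeline_with_jittered_oracle_detections(full_scale_dataset):
    """Ground-truth part boxes + <=2 px jitter -> every implant recovered
    at IoU >= 0.9 with the correct implant count."""
    from radimplant.evaluate import iou

    index, _ = full_scale_dataset
    rng = np.random.default_rng(5)
    by_image = index.by_image()
    for anns in by_image.values():
        parts = [a for a in anns if a.level == "part"]
        implants = [a for a in anns if a.level == "implant"]
        dets = []
        for a in parts:
            j = rng.uniform(-2, 2, 4)
            x, y, w, h = a.box
            dets.append(PartDetection(box=(x + j[0], y + j[1], w + j[2], h + j[3]),
                                      part_category=a.category, score=0.9))
        out = assemble_scene(dets, seed=0)
        assert len(out) == len(implants)
        for gt in implants:
            assert max(iou(gt.box, o.box) for o in out) >= 0.9
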