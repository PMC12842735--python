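"""Stage 2: group part detections into whole-implant boxes.

Parts are grouped by k-means over box centers (k-means++ seeding, at
most 300 iterations, 10 restarts). The number of implants is taken as
the number of detected coronal-level parts when at least one is present
(every implant exposes exactly one platform), falling back to
``ceil(n_parts / 3)`` otherwise; a literal mode setting k to the number
of detected parts is available for comparison, though it degenerates to
singleton groups. Groups are then refined by spatial-consistency
thresholds, missing levels are inferred along the implant axis, and the
final implant box is the tight union of member (and inferred) boxes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from sklearn.cluster import KMeans

from .records import PART_LEVELS, ImplantDetection, PartDetection, PartGroup

__all__ = [
    "AssemblyConfig",
    "estimate_implant_count",
    "cluster_parts",
    "infer_missing_part",
    "assemble_implant_boxes",
    "assemble_scene",
]

# relative part heights (coronal : middle : apical) used when extrapolating
DEFAULT_HEIGHT_RATIOS = {"coronal": 0.25, "middle": 0.50, "apical": 0.25}


@dataclass
class AssemblyConfig:
    max_center_dist_factor: float = 1.5   # x median implant extent
    max_lateral_offset_factor: float = 0.5  # x coronal width
    height_ratios: dict = None
    kmeans_restarts: int = 10
    kmeans_max_iter: int = 300
    literal_k: bool = False  # k = number of detected parts (degenerate reading)
    min_levels_to_keep: int = 2
    infer_missing: bool = True

    def __post_init__(self):
        if self.height_ratios is None:
            self.height_ratios = dict(DEFAULT_HEIGHT_RATIOS)


def estimate_implant_count(dets: list[PartDetection],
                           cfg: AssemblyConfig | None = None) -> int:
    cfg = cfg or AssemblyConfig()
    if not dets:
        return 0
    if cfg.literal_k:
        return len(dets)
    n_coronal = sum(1 for d in dets if d.level == "coronal")
    k = n_coronal if n_coronal >= 1 else math.ceil(len(dets) / 3)
    return min(k, len(dets))


def _principal_axis(centers: np.ndarray) -> tuple[float, float]:
    """Unit direction of maximal spread of member centers; vertical default."""
    if len(centers) < 2:
        return (0.0, 1.0)
    c = centers - centers.mean(axis=0)
    _, _, vt = np.linalg.svd(c, full_matrices=False)
    vx, vy = vt[0]
    if vy < 0 or (vy == 0 and vx < 0):
        vx, vy = -vx, -vy
    return (float(vx), float(vy))


def cluster_parts(dets: list[PartDetection], k: int, seed: int = 0,
                  cfg: AssemblyConfig | None = None) -> list[PartGroup]:
    """k-means++ grouping of part centers followed by consistency refinement.

    Refinement: members farther from their group's center than
    ``max_center_dist_factor`` x the median group extent are discarded
    with a logged reason, and duplicate levels keep only the
    highest-scoring member.
    """
    cfg = cfg or AssemblyConfig()
    if not 1 <= k <= len(dets):
        raise ValueError(f"k={k} infeasible for {len(dets)} detections")
    centers = np.array([d.center for d in dets])
    # Anisotropic scaling: parts of one implant string out along the
    # (vertical) implant axis but stay laterally aligned, so lateral
    # offsets are weighted by the coronal-width tolerance and axial
    # offsets by the implant-height tolerance before clustering.
    coronal_w = [d.box[2] for d in dets if d.level == "coronal"]
    lateral_tol = cfg.max_lateral_offset_factor * float(
        np.median(coronal_w if coronal_w else [d.box[2] for d in dets]))
    extents = [max(d.box[2], d.box[3]) for d in dets]
    implant_extent = float(np.median(extents)) / DEFAULT_HEIGHT_RATIOS["middle"]
    axial_tol = cfg.max_center_dist_factor * implant_extent
    scaled = centers / np.array([max(1e-6, lateral_tol), max(1e-6, axial_tol)])
    if k == len(dets):
        labels = np.arange(len(dets))
    else:
        km = KMeans(n_clusters=k, init="k-means++", n_init=cfg.kmeans_restarts,
                    max_iter=cfg.kmeans_max_iter, random_state=seed & 0x7FFFFFFF)
        labels = km.fit_predict(scaled)
    groups: list[PartGroup] = []
    for g in range(k):
        members = [d for d, lab in zip(dets, labels) if lab == g]
        if not members:
            continue
        group = PartGroup(members=[], axis=_principal_axis(
            np.array([m.center for m in members])))
        centroid = np.mean([m.center for m in members], axis=0)
        # consistency refinement: drop members too far from the group
        for m in members:
            lat = abs(m.center[0] - centroid[0])
            axial = abs(m.center[1] - centroid[1])
            if lat > 2.0 * lateral_tol or axial > axial_tol:
                group.discarded.append(
                    (m, f"offset ({lat:.1f}, {axial:.1f})px from group centroid"))
            else:
                group.members.append(m)
        # one member per level: keep the highest score
        for level in PART_LEVELS:
            same = [m for m in group.members if m.level == level]
            if len(same) > 1:
                same.sort(key=lambda m: -m.score)
                for extra in same[1:]:
                    group.members.remove(extra)
                    group.discarded.append((extra, f"duplicate {level} member"))
        if group.members:
            groups.append(group)
    return groups


def _axis_frame(group: PartGroup):
    """Return (axis, lateral) unit vectors with axis oriented coronal->apical."""
    v = np.array(group.axis, dtype=float)
    proj = {m.level: float(np.dot(m.center, v)) for m in group.members}
    if "coronal" in proj and "apical" in proj and proj["coronal"] > proj["apical"]:
        v = -v
    elif "coronal" in proj and "middle" in proj and proj["coronal"] > proj["middle"]:
        v = -v
    elif "middle" in proj and "apical" in proj and proj["middle"] > proj["apical"]:
        v = -v
    return v


def infer_missing_part(group: PartGroup, level: str,
                       cfg: AssemblyConfig | None = None) -> PartDetection:
    """Estimate the box of a missing level along the implant axis.

    With both neighbours present the part spans the gap between them
    (linear interpolation along the axis); otherwise it is extrapolated
    beyond the nearest member with a height set by the configured
    coronal:middle:apical ratios.
    """
    cfg = cfg or AssemblyConfig()
    if not group.members:
        raise ValueError("cannot infer parts for an empty group")
    present = {m.level: m for m in group.members}
    if level in present:
        raise ValueError(f"group already has a {level} member")
    v = _axis_frame(group)
    vertical = abs(v[1]) >= abs(v[0])
    ratios = cfg.height_ratios

    def edges(m: PartDetection):
        x, y, w, h = m.box
        return (y, y + h) if vertical else (x, x + w)

    def lateral_span(ms):
        lo = min((m.box[0] if vertical else m.box[1]) for m in ms)
        hi = max(((m.box[0] + m.box[2]) if vertical else (m.box[1] + m.box[3])) for m in ms)
        return lo, hi

    sign = 1.0 if (v[1] if vertical else v[0]) >= 0 else -1.0

    if level == "middle" and "coronal" in present and "apical" in present:
        e_c, e_a = edges(present["coronal"]), edges(present["apical"])
        lo = min(e_c[1], e_a[1])
        hi = max(e_c[0], e_a[0])
        lat_lo, lat_hi = lateral_span([present["coronal"], present["apical"]])
        lat_w = max(2.0, 0.8 * (lat_hi - lat_lo))
        lat_c = (lat_lo + lat_hi) / 2
        if vertical:
            box = (lat_c - lat_w / 2, lo, lat_w, max(1.0, hi - lo))
        else:
            box = (lo, lat_c - lat_w / 2, max(1.0, hi - lo), lat_w)
    else:
        # extrapolate beyond the nearest existing neighbour
        order = {"coronal": 0, "middle": 1, "apical": 2}
        neighbours = sorted(present.values(), key=lambda m: abs(order[m.level] - order[level]))
        ref = neighbours[0]
        ref_lo, ref_hi = edges(ref)
        length = (ref_hi - ref_lo) * ratios[level] / ratios[ref.level]
        direction = sign if order[level] > order[ref.level] else -sign
        if direction > 0:
            lo, hi = ref_hi, ref_hi + length
        else:
            lo, hi = ref_lo - length, ref_lo
        lat_lo, lat_hi = lateral_span([ref])
        lat_w = 0.9 * (lat_hi - lat_lo)
        lat_c = (lat_lo + lat_hi) / 2
        if vertical:
            box = (lat_c - lat_w / 2, lo, lat_w, max(1.0, hi - lo))
        else:
            box = (lo, lat_c - lat_w / 2, max(1.0, hi - lo), lat_w)
    score = float(np.mean([m.score for m in group.members]))
    return PartDetection(box=box, part_category=f"{level}_inferred", score=score,
                         system_hint=None)


def assemble_implant_boxes(groups: list[PartGroup],
                           cfg: AssemblyConfig | None = None) -> list[ImplantDetection]:
    """Union each group's (members + inferred) boxes into one implant box.

    Score is the mean member score; the system class is decided by a
    highest-total-score vote over member system hints (ties broken by
    the highest single hint score). Groups covering fewer than
    ``min_levels_to_keep`` levels are dropped.
    """
    cfg = cfg or AssemblyConfig()
    out: list[ImplantDetection] = []
    for group in groups:
        levels_present = {m.level for m in group.members}
        if len(levels_present) < cfg.min_levels_to_keep and len(group.members) < 3:
            continue
        if cfg.infer_missing:
            for level in PART_LEVELS:
                if level not in levels_present and len(levels_present) >= 2:
                    group.inferred.append(infer_missing_part(group, level, cfg))
        boxes = [m.box for m in group.members] + [m.box for m in group.inferred]
        x1 = min(b[0] for b in boxes)
        y1 = min(b[1] for b in boxes)
        x2 = max(b[0] + b[2] for b in boxes)
        y2 = max(b[1] + b[3] for b in boxes)
        votes: dict[str, list[float]] = {}
        for m in group.members:
            if m.system_hint is not None:
                votes.setdefault(m.system_hint, []).append(m.score)
        system = None
        if votes:
            system = max(votes, key=lambda s: (sum(votes[s]), max(votes[s])))
        out.append(ImplantDetection(
            box=(x1, y1, x2 - x1, y2 - y1), system_class=system,
            score=float(np.mean([m.score for m in group.members])),
            member_categories=[m.part_category for m in group.members],
            inferred_levels=[p.part_category.split("_")[0] for p in group.inferred]))
    return out


def assemble_scene(dets: list[PartDetection], seed: int = 0,
                   cfg: AssemblyConfig | None = None) -> list[ImplantDetection]:
    """Full stage 2 on one image: count, cluster, complete, assemble."""
    cfg = cfg or AssemblyConfig()
    k = estimate_implant_count(dets, cfg)
    if k == 0:
        return []
    groups = cluster_parts(dets, k, seed=seed, cfg=cfg)
    return assemble_implant_boxes(groups, cfg)
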