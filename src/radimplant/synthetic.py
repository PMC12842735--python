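"""Procedural implant-bearing radiograph generator with exact annotations.

Scenes contain vertically oriented screw-like implants composed of three
design parts (coronal platform, threaded middle body, tapering apical
tip) rendered as bright silhouettes over a smoothed-noise background,
mimicking radiopacity without any physics model. Three synthetic
implant systems (analogues of distinct commercial product lines) differ
deterministically in body width and platform proportions so they are
separable in principle. Design-class frequencies default to the
observed clinical imbalance (coronal bone:tissue:microthread:no-threads
= 1240:870:410:208, and similarly for middle and apical classes).

Every rendered part contributes one part-level box and each implant one
implant-level box that is the exact union of its part boxes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter

from .coco import DatasetIndex, ImageEntry, write_coco
from .config import rng_for
from .records import AnnotationRecord, RadiographSample

__all__ = [
    "SYSTEM_CLASSES",
    "DEFAULT_CLASS_WEIGHTS",
    "GeneratorParams",
    "ImplantTemplate",
    "PlacedImplant",
    "SceneSpec",
    "sample_template",
    "render_scene",
    "generate_dataset",
]

SYSTEM_CLASSES = ("SystemA", "SystemB", "SystemC")

# Per-level design-class frequencies (clinical counts used as weights).
DEFAULT_CLASS_WEIGHTS = {
    "coronal": {"coronal_bone": 1240, "coronal_tissue": 870,
                "coronal_microthread": 410, "coronal_nothreads": 208},
    "middle": {"middle_parallel": 1935, "middle_tapered": 621, "middle_vshaped": 382},
    "apical": {"apical_hole_round": 1710, "apical_hole_oblong": 545,
               "apical_apex_cone": 364, "apical_apex_flat": 188},
}

EASY_CLASS_WEIGHTS = {
    "coronal": {"coronal_bone": 1},
    "middle": {"middle_parallel": 1},
    "apical": {"apical_hole_round": 1},
}

# System geometry priors: body width as a fraction of implant height, and
# the platform-to-body width ratio. Distinct means make mean part widths
# separable with a nearest-centroid rule.
_SYSTEM_GEOMETRY = {
    "SystemA": {"body_frac": 0.26, "platform_ratio": 1.25},
    "SystemB": {"body_frac": 0.40, "platform_ratio": 1.10},
    "SystemC": {"body_frac": 0.33, "platform_ratio": 1.40},
}


@dataclass
class GeneratorParams:
    image_size: int = 416
    n_implants_range: tuple[int, int] = (1, 3)
    patients_per_group: int = 2
    height_frac_range: tuple[float, float] = (0.65, 0.80)
    noise_std: float = 0.02
    max_overlap_iou: float = 0.05
    class_weights: dict = field(default_factory=lambda: DEFAULT_CLASS_WEIGHTS)
    system_weights: dict = field(default_factory=lambda: {s: 1.0 for s in SYSTEM_CLASSES})

    @classmethod
    def easy(cls, image_size: int = 64, **overrides) -> "GeneratorParams":
        """Single centered implant, one design class per level, low noise."""
        kwargs = dict(image_size=image_size, n_implants_range=(1, 1),
                      noise_std=0.01, class_weights=EASY_CLASS_WEIGHTS)
        kwargs.update(overrides)
        return cls(**kwargs)

    def taxonomy(self) -> dict[str, dict]:
        """Category table: part design classes plus implant system classes."""
        cats: dict[str, dict] = {}
        cid = 1
        for level in ("coronal", "middle", "apical"):
            for name in self.class_weights[level]:
                cats[name] = {"id": cid, "level": "part"}
                cid += 1
        for name in SYSTEM_CLASSES:
            cats[name] = {"id": cid, "level": "implant"}
            cid += 1
        return cats


@dataclass
class ImplantTemplate:
    system_class: str
    coronal_class: str
    middle_class: str
    apical_class: str
    height: int            # total implant height, px
    part_heights: tuple[int, int, int]  # coronal, middle, apical; sums to height
    body_width: int
    platform_width: int
    apical_width: int
    groove: bool = False

    def __post_init__(self):
        if sum(self.part_heights) != self.height:
            raise ValueError("part heights must sum to implant height")
        if min(self.body_width, self.platform_width, self.apical_width) <= 0:
            raise ValueError("widths must be positive")


@dataclass
class PlacedImplant:
    template: ImplantTemplate
    cx: int        # horizontal center, px
    y0: int        # top edge, px
    rotation: int = 0  # degrees, multiple of 90


@dataclass
class SceneSpec:
    image_size: int
    implants: list[PlacedImplant]
    bg_seed: int
    noise_std: float = 0.02
    patient_id: str = "p0"
    image_id: int = 0


def _weighted_choice(rng: np.random.Generator, weights: dict[str, float]) -> str:
    names = list(weights)
    w = np.asarray([weights[n] for n in names], dtype=np.float64)
    return names[rng.choice(len(names), p=w / w.sum())]


def sample_template(system_class: str, rng: np.random.Generator,
                    params: GeneratorParams | None = None) -> ImplantTemplate:
    """Draw an implant template from the configured design-class weights."""
    params = params or GeneratorParams()
    if system_class not in _SYSTEM_GEOMETRY:
        raise ValueError(f"unknown system class {system_class!r}")
    geo = _SYSTEM_GEOMETRY[system_class]
    coronal = _weighted_choice(rng, params.class_weights["coronal"])
    middle = _weighted_choice(rng, params.class_weights["middle"])
    apical = _weighted_choice(rng, params.class_weights["apical"])
    height = int(round(params.image_size * rng.uniform(*params.height_frac_range)))
    rho_c = rng.uniform(0.22, 0.28)
    rho_a = rng.uniform(0.22, 0.28)
    h_c = max(4, int(round(rho_c * height)))
    h_a = max(4, int(round(rho_a * height)))
    h_m = height - h_c - h_a
    # widths scale with the nominal (not sampled) implant height so the
    # three system classes stay separable by width despite length variation
    ref_height = params.image_size * float(np.mean(params.height_frac_range))
    body = max(3, int(round(ref_height * (geo["body_frac"] + rng.normal(0.0, 0.015)))))
    platform = max(body + 2, int(round(body * geo["platform_ratio"])))
    apical_w = max(2, int(round(body * 0.75)))
    return ImplantTemplate(system_class=system_class, coronal_class=coronal,
                           middle_class=middle, apical_class=apical,
                           height=height, part_heights=(h_c, h_m, h_a),
                           body_width=body, platform_width=platform,
                           apical_width=apical_w, groove=bool(rng.random() < 0.3))


def _part_boxes(t: ImplantTemplate, cx: int, y0: int) -> dict[str, tuple[int, int, int, int]]:
    h_c, h_m, h_a = t.part_heights
    boxes = {
        "coronal": (cx - t.platform_width // 2, y0, t.platform_width, h_c),
        "middle": (cx - t.body_width // 2, y0 + h_c, t.body_width, h_m),
        "apical": (cx - t.apical_width // 2, y0 + h_c + h_m, t.apical_width, h_a),
    }
    return boxes


def _render_implant_stamp(t: ImplantTemplate) -> tuple[np.ndarray, dict[str, tuple[int, int, int, int]]]:
    """Render one vertical implant on a local canvas; returns (canvas, part boxes)."""
    w = t.platform_width
    canvas = np.zeros((t.height, w), dtype=np.float64)
    cx = w // 2
    boxes = _part_boxes(t, cx, 0)
    h_c, h_m, h_a = t.part_heights

    # coronal platform: full-width bright block
    canvas[0:h_c, :] = 0.45
    if t.coronal_class == "coronal_tissue":
        canvas[0:max(2, h_c // 4), :] = 0.60  # brighter collar at tissue level
    if t.coronal_class == "coronal_microthread":
        canvas[0:h_c:2, :] *= 0.8  # fine alternating micro-bands

    # middle body: parallel or tapered column with thread bands
    bx, by, bw, bh = boxes["middle"]
    x_off = bx  # left edge of body within canvas
    for i in range(bh):
        if t.middle_class == "middle_tapered":
            frac = 1.0 - 0.3 * (i / max(1, bh - 1))
        else:
            frac = 1.0
        half = max(1, int(round(bw * frac / 2)))
        canvas[by + i, cx - half:cx + half] = 0.45
    spacing = 3 if t.middle_class == "middle_vshaped" else 4
    for i in range(0, bh, spacing):
        row = canvas[by + i, x_off:x_off + bw]
        row[row > 0] *= 0.75  # thread grooves as darker bands

    # apical tip: taper toward apex, optional dark hole
    ax, ay, aw, ah = boxes["apical"]
    flat = t.apical_class == "apical_apex_flat"
    for i in range(ah):
        frac = 1.0 if flat else 1.0 - 0.8 * (i / max(1, ah - 1))
        half = max(1, int(round(aw * frac / 2)))
        canvas[ay + i, cx - half:cx + half] = 0.45
    # guarantee support touches the bottom row and the box sides at the top
    canvas[ay, cx - aw // 2:cx - aw // 2 + aw] = 0.45
    canvas[t.height - 1, cx - 1:cx + 1] = 0.45
    if t.apical_class in ("apical_hole_round", "apical_hole_oblong"):
        ry = ah // 3
        rx = max(1, aw // 5) if t.apical_class == "apical_hole_round" else max(1, aw // 8)
        yy, xx = np.mgrid[0:t.height, 0:w]
        hole = (((xx - cx) / max(1, rx)) ** 2 + ((yy - (ay + ah // 2)) / max(1, ry)) ** 2) <= 1.0
        canvas[hole & (canvas > 0)] *= 0.3
    if t.groove:
        canvas[ay + ah // 2, ax:ax + aw] *= 0.6
    return canvas, boxes


def _rotate_box(box, k: int, h: int, w: int):
    """Rotate a box with an image rotated by numpy rot90(img, -k) (k quarter turns cw)."""
    x, y, bw, bh = box
    for _ in range(k % 4):
        x, y, bw, bh = (h - y - bh, x, bh, bw)
        h, w = w, h
    return (x, y, bw, bh)


def _box_iou(a, b) -> float:
    ax, ay, aw, ah = a
    bx, by, bw, bh = b
    ix = max(0.0, min(ax + aw, bx + bw) - max(ax, bx))
    iy = max(0.0, min(ay + ah, by + bh) - max(ay, by))
    inter = ix * iy
    union = aw * ah + bw * bh - inter
    return inter / union if union > 0 else 0.0


def render_scene(spec: SceneSpec) -> RadiographSample:
    """Deterministically render a scene with exact part/implant annotations."""
    s = spec.image_size
    rng = np.random.default_rng(spec.bg_seed)
    bg = rng.normal(0.0, 1.0, size=(s, s))
    bg = gaussian_filter(bg, sigma=max(2.0, s / 32.0))
    bg = (bg - bg.min()) / max(1e-9, bg.max() - bg.min()) * 0.25 + 0.15
    img = bg
    annotations: list[AnnotationRecord] = []
    for placed in spec.implants:
        stamp, boxes = _render_implant_stamp(placed.template)
        k = (placed.rotation // 90) % 4
        h0, w0 = stamp.shape
        if k:
            stamp = np.rot90(stamp, -k)
            boxes = {lvl: _rotate_box(b, k, h0, w0) for lvl, b in boxes.items()}
        sh, sw = stamp.shape
        x0 = placed.cx - sw // 2
        y0 = placed.y0
        if x0 < 0 or y0 < 0 or x0 + sw > s or y0 + sh > s:
            raise ValueError(f"implant at ({placed.cx}, {placed.y0}) out of {s}x{s} bounds")
        img[y0:y0 + sh, x0:x0 + sw] += stamp
        t = placed.template
        part_class = {"coronal": t.coronal_class, "middle": t.middle_class,
                      "apical": t.apical_class}
        shifted = {}
        for lvl, (bx, by, bw, bh) in boxes.items():
            shifted[lvl] = (bx + x0, by + y0, bw, bh)
            annotations.append(AnnotationRecord(
                image_id=spec.image_id, box=shifted[lvl], category=part_class[lvl],
                level="part", patient_id=spec.patient_id))
        xs = [b[0] for b in shifted.values()]
        ys = [b[1] for b in shifted.values()]
        x2 = [b[0] + b[2] for b in shifted.values()]
        y2 = [b[1] + b[3] for b in shifted.values()]
        union = (min(xs), min(ys), max(x2) - min(xs), max(y2) - min(ys))
        annotations.append(AnnotationRecord(
            image_id=spec.image_id, box=union, category=t.system_class,
            level="implant", patient_id=spec.patient_id))
    if spec.noise_std > 0:
        img = img + rng.normal(0.0, spec.noise_std, size=img.shape)
    img = np.clip(img, 0.0, 1.0)
    return RadiographSample(image=img, annotations=annotations,
                            image_id=spec.image_id, patient_id=spec.patient_id)


def sample_scene(params: GeneratorParams, rng: np.random.Generator,
                 image_id: int = 0, patient_id: str = "p0") -> SceneSpec:
    """Draw a placement-valid scene: implant boxes respect the overlap cap."""
    s = params.image_size
    n = int(rng.integers(params.n_implants_range[0], params.n_implants_range[1] + 1))
    placed: list[PlacedImplant] = []
    footprints: list[tuple] = []
    for _ in range(n):
        for _attempt in range(200):
            system = _weighted_choice(rng, params.system_weights)
            t = sample_template(system, rng, params)
            w = t.platform_width
            cx = int(rng.integers(w // 2 + 1, s - w // 2 - 1))
            y0 = int(rng.integers(1, max(2, s - t.height - 1)))
            fp = (cx - w // 2, y0, w, t.height)
            if all(_box_iou(fp, other) <= params.max_overlap_iou for other in footprints):
                placed.append(PlacedImplant(template=t, cx=cx, y0=y0))
                footprints.append(fp)
                break
        else:
            break  # image stays less crowded if placement keeps colliding
    return SceneSpec(image_size=s, implants=placed,
                     bg_seed=int(rng.integers(0, 2 ** 31)),
                     noise_std=params.noise_std,
                     patient_id=patient_id, image_id=image_id)


def generate_dataset(n_images: int, params: GeneratorParams | None = None,
                     seed: int = 0, out_dir: str | Path | None = None,
                     ) -> tuple[DatasetIndex, dict[int, np.ndarray]]:
    """Generate a dataset: index with exact COCO annotations plus pixel arrays.

    Patients are assigned in blocks of ``patients_per_group`` consecutive
    images. When ``out_dir`` is given, PNG images and ``annotations.json``
    are written there.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    params = params or GeneratorParams()
    rng = rng_for(seed, "synthetic-scenes")
    index = DatasetIndex(categories=params.taxonomy())
    images: dict[int, np.ndarray] = {}
    for i in range(n_images):
        image_id = i + 1
        patient_id = f"p{i // max(1, params.patients_per_group):04d}"
        spec = sample_scene(params, rng, image_id=image_id, patient_id=patient_id)
        sample = render_scene(spec)
        images[image_id] = sample.image
        index.images.append(ImageEntry(image_id=image_id, path=f"img_{image_id:05d}.png",
                                       width=params.image_size, height=params.image_size,
                                       patient_id=patient_id))
        index.annotations.extend(sample.annotations)
    index.validate()
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for im in index.images:
            arr = (np.clip(images[im.image_id], 0, 1) * 255).astype(np.uint8)
            Image.fromarray(arr).save(out / im.path)
        write_coco(index, out / "annotations.json")
    return index, images
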