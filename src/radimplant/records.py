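"""Shared record types used across the pipeline.

Box convention, used everywhere in this package: COCO-style
``(x, y, w, h)`` in pixels, 0-based, origin at the top-left corner of
the image, ``x`` growing rightwards and ``y`` growing downwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

PART_LEVELS = ("coronal", "middle", "apical")


def part_level(category: str) -> str:
    """Anatomical level encoded in a part category name, e.g. 'coronal_bone' -> 'coronal'."""
    head = category.split("_", 1)[0]
    if head not in PART_LEVELS:
        raise ValueError(f"category {category!r} does not encode a part level")
    return head


@dataclass
class AnnotationRecord:
    """One ground-truth box: a design part or a whole implant."""

    image_id: int
    box: tuple[float, float, float, float]  # (x, y, w, h)
    category: str
    level: str  # "part" or "implant"
    patient_id: str

    def validate(self, width: float | None = None, height: float | None = None,
                 taxonomy: set[str] | None = None):
        x, y, w, h = self.box
        if w <= 0 or h <= 0:
            raise ValueError(f"degenerate box {self.box} on image {self.image_id}")
        if self.level not in ("part", "implant"):
            raise ValueError(f"unknown level {self.level!r}")
        if width is not None and (x < 0 or y < 0 or x + w > width + 1e-6 or y + h > height + 1e-6):
            raise ValueError(f"box {self.box} outside {width}x{height} image {self.image_id}")
        if taxonomy is not None and self.category not in taxonomy:
            raise ValueError(f"category {self.category!r} not in taxonomy")


@dataclass
class RadiographSample:
    """An image with its annotations."""

    image: np.ndarray  # (H, W) float in [0, 1]
    annotations: list[AnnotationRecord]
    image_id: int = 0
    patient_id: str = "p0"


@dataclass
class PartDetection:
    """A scored design-part box emitted by the first detection stage."""

    box: tuple[float, float, float, float]
    part_category: str
    score: float
    system_hint: str | None = None

    @property
    def level(self) -> str:
        return part_level(self.part_category)

    @property
    def center(self) -> tuple[float, float]:
        x, y, w, h = self.box
        return (x + w / 2.0, y + h / 2.0)


@dataclass
class PartGroup:
    """Parts attributed to one implant, plus any inferred members."""

    members: list[PartDetection]
    axis: tuple[float, float] = (0.0, 1.0)  # unit vector coronal -> apical
    inferred: list[PartDetection] = field(default_factory=list)
    discarded: list[tuple[PartDetection, str]] = field(default_factory=list)

    @property
    def completeness(self) -> dict[str, bool]:
        present = {m.level for m in self.members} | {m.level for m in self.inferred}
        return {lvl: lvl in present for lvl in PART_LEVELS}


@dataclass
class ImplantDetection:
    """A whole-implant box assembled from a part group."""

    box: tuple[float, float, float, float]
    system_class: str | None
    score: float
    member_categories: list[str] = field(default_factory=list)
    inferred_levels: list[str] = field(default_factory=list)
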