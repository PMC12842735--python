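"""COCO-dialect dataset I/O and patient-level splitting.

Annotations travel as detection-dialect COCO JSON: ``images`` (with a
``patient_id`` extension field), ``annotations`` with ``bbox`` as
``(x, y, w, h)``, and ``categories`` whose ``supercategory`` encodes
whether the label is a design-part class or an implant-system class.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .records import AnnotationRecord

__all__ = [
    "DatasetIndex",
    "CocoFormatError",
    "CocoIntegrityError",
    "read_coco",
    "write_coco",
    "split_patient_level",
]


class CocoFormatError(ValueError):
    """The file is not valid detection-dialect COCO JSON."""


class CocoIntegrityError(ValueError):
    """Cross-references inside the file are inconsistent."""


@dataclass
class ImageEntry:
    image_id: int
    path: str
    width: int
    height: int
    patient_id: str


@dataclass
class DatasetIndex:
    images: list[ImageEntry] = field(default_factory=list)
    annotations: list[AnnotationRecord] = field(default_factory=list)
    categories: dict[str, dict] = field(default_factory=dict)  # name -> {id, level}

    def image_ids(self) -> list[int]:
        return [im.image_id for im in self.images]

    def by_image(self) -> dict[int, list[AnnotationRecord]]:
        out: dict[int, list[AnnotationRecord]] = {im.image_id: [] for im in self.images}
        for a in self.annotations:
            out[a.image_id].append(a)
        return out

    def validate(self):
        ids = set()
        for im in self.images:
            if im.image_id in ids:
                raise CocoIntegrityError(f"duplicate image id {im.image_id}")
            ids.add(im.image_id)
        sizes = {im.image_id: (im.width, im.height) for im in self.images}
        taxonomy = set(self.categories) if self.categories else None
        for a in self.annotations:
            if a.image_id not in ids:
                raise CocoIntegrityError(f"annotation references unknown image id {a.image_id}")
            w, h = sizes[a.image_id]
            a.validate(width=w, height=h, taxonomy=taxonomy)
        cat_ids = [c["id"] for c in self.categories.values()]
        if len(cat_ids) != len(set(cat_ids)):
            raise CocoIntegrityError("category ids are not unique")


_REQUIRED_KEYS = ("images", "annotations", "categories")


def read_coco(path: str | Path) -> DatasetIndex:
    with open(path) as fh:
        doc = json.load(fh)
    for key in _REQUIRED_KEYS:
        if key not in doc:
            raise CocoFormatError(f"missing top-level key {key!r} in {path}")
    categories: dict[str, dict] = {}
    id_to_name: dict[int, str] = {}
    for cat in doc["categories"]:
        try:
            name, cid = cat["name"], int(cat["id"])
        except KeyError as exc:
            raise CocoFormatError(f"category missing key {exc} in {path}") from exc
        level = cat.get("supercategory", "part")
        categories[name] = {"id": cid, "level": level}
        id_to_name[cid] = name
    index = DatasetIndex(categories=categories)
    patient_of: dict[int, str] = {}
    for im in doc["images"]:
        try:
            entry = ImageEntry(image_id=int(im["id"]), path=im.get("file_name", ""),
                               width=int(im["width"]), height=int(im["height"]),
                               patient_id=str(im.get("patient_id", f"p{im['id']}")))
        except KeyError as exc:
            raise CocoFormatError(f"image entry missing key {exc} in {path}") from exc
        index.images.append(entry)
        patient_of[entry.image_id] = entry.patient_id
    for ann in doc["annotations"]:
        try:
            image_id = int(ann["image_id"])
            bbox = tuple(float(v) for v in ann["bbox"])
            cid = int(ann["category_id"])
        except KeyError as exc:
            raise CocoFormatError(f"annotation missing key {exc} in {path}") from exc
        if cid not in id_to_name:
            raise CocoIntegrityError(f"annotation references unknown category id {cid}")
        if image_id not in patient_of:
            raise CocoIntegrityError(f"annotation references unknown image id {image_id}")
        name = id_to_name[cid]
        index.annotations.append(AnnotationRecord(
            image_id=image_id, box=bbox, category=name,
            level=categories[name]["level"], patient_id=patient_of[image_id]))
    index.validate()
    return index


def write_coco(index: DatasetIndex, path: str | Path):
    doc = {
        "images": [
            {"id": im.image_id, "file_name": im.path, "width": im.width,
             "height": im.height, "patient_id": im.patient_id}
            for im in index.images
        ],
        "annotations": [
            {"id": i + 1, "image_id": a.image_id,
             "category_id": index.categories[a.category]["id"],
             "bbox": list(a.box), "area": a.box[2] * a.box[3], "iscrowd": 0}
            for i, a in enumerate(index.annotations)
        ],
        "categories": [
            {"id": meta["id"], "name": name, "supercategory": meta["level"]}
            for name, meta in sorted(index.categories.items(), key=lambda kv: kv[1]["id"])
        ],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, sort_keys=True)


def split_patient_level(index: DatasetIndex, n_sets: int, seed: int) -> list[set[int]]:
    """Partition image ids into ``n_sets`` patient-disjoint sets.

    All images of one patient land in one set. The last returned set is
    the designated fixed test set: the first ``n_sets - 1`` sets aim for
    ``floor(n_images / n_sets)`` images each and the test set absorbs the
    remainder, so 5572 single-image patients split five ways yield four
    sets of 1114 and a 1116-image test set. Patients are packed greedily
    by descending image count into the set with the largest remaining
    deficit, which keeps sizes as close to the targets as patient
    granularity allows.
    """
    if n_sets < 2:
        raise ValueError("need at least 2 sets")
    patients: dict[str, list[int]] = {}
    for im in index.images:
        patients.setdefault(im.patient_id, []).append(im.image_id)
    if len(patients) < n_sets:
        raise ValueError(f"only {len(patients)} patients for {n_sets} sets")
    n_images = len(index.images)
    base = n_images // n_sets
    targets = [base] * (n_sets - 1) + [n_images - base * (n_sets - 1)]
    rng = np.random.default_rng(seed)
    order = sorted(patients)
    rng.shuffle(order)
    order.sort(key=lambda p: -len(patients[p]))  # stable: ties keep shuffled order
    sets: list[set[int]] = [set() for _ in range(n_sets)]
    sizes = [0] * n_sets
    for pid in order:
        deficits = [targets[i] - sizes[i] for i in range(n_sets)]
        i = int(np.argmax(deficits))
        sets[i].update(patients[pid])
        sizes[i] += len(patients[pid])
    return sets
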