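"""Annotation readers/writers: LabelImg/Pascal-VOC XML and COCO JSON.

Conventions
-----------
* VOC xmin/ymin/xmax/ymax values are taken verbatim (no 1-pixel origin
  shift); this is the LabelImg dialect choice and makes both roundtrips exact.
* COCO bboxes are [x, y, w, h] with (x, y) the upper-left corner, mapping to
  corner boxes as (x, y, x + w, y + h).
* The single default category is "spike" with id 1.
"""

from __future__ import annotations

import json
import xml.etree.ElementTree as ET
from pathlib import Path

import numpy as np

from .synth import AnnotatedImage

__all__ = [
    "AnnotationError",
    "read_labelimg_xml",
    "write_labelimg_xml",
    "read_coco_json",
    "write_coco_json",
    "detections_to_coco_results",
]

SPIKE_CATEGORY = {"id": 1, "name": "spike", "supercategory": "plant"}


class AnnotationError(ValueError):
    """Malformed annotation file."""


def read_labelimg_xml(path) -> dict:
    """Parse a VOC XML file into {file_name, size, boxes, names}."""
    path = Path(path)
    try:
        root = ET.parse(path).getroot()
    except ET.ParseError as e:
        raise AnnotationError(f"{path}: malformed XML ({e})") from None
    size = root.find("size")
    record = {
        "file_name": root.findtext("filename", default=""),
        "width": int(size.findtext("width")) if size is not None else None,
        "height": int(size.findtext("height")) if size is not None else None,
        "boxes": [],
        "names": [],
    }
    for i, obj in enumerate(root.iter("object")):
        bnd = obj.find("bndbox")
        if bnd is None:
            raise AnnotationError(f"{path}: object {i} has no bndbox")
        try:
            x0 = float(bnd.findtext("xmin"))
            y0 = float(bnd.findtext("ymin"))
            x1 = float(bnd.findtext("xmax"))
            y1 = float(bnd.findtext("ymax"))
        except (TypeError, ValueError):
            raise AnnotationError(f"{path}: object {i} has malformed bndbox") from None
        if x1 <= x0 or y1 <= y0:
            raise AnnotationError(
                f"{path}: object {i} degenerate box ({x0}, {y0}, {x1}, {y1})"
            )
        record["boxes"].append([x0, y0, x1, y1])
        record["names"].append(obj.findtext("name", default="spike"))
    record["boxes"] = np.asarray(record["boxes"], dtype=np.float64).reshape(-1, 4)
    return record


def _sub(parent, tag, text=None):
    el = ET.SubElement(parent, tag)
    if text is not None:
        el.text = str(text)
    return el


def write_labelimg_xml(rec: AnnotatedImage, path, filename: str | None = None) -> None:
    root = ET.Element("annotation")
    _sub(root, "folder", "images")
    _sub(root, "filename", filename or f"image_{rec.image_id:05d}.png")
    size = _sub(root, "size")
    _sub(size, "width", rec.image.shape[1])
    _sub(size, "height", rec.image.shape[0])
    _sub(size, "depth", 3)
    _sub(root, "segmented", 0)
    for box in rec.boxes:
        obj = _sub(root, "object")
        _sub(obj, "name", "spike")
        _sub(obj, "pose", "Unspecified")
        _sub(obj, "truncated", 0)
        _sub(obj, "difficult", 0)
        bnd = _sub(obj, "bndbox")
        _sub(bnd, "xmin", repr(float(box[0])))
        _sub(bnd, "ymin", repr(float(box[1])))
        _sub(bnd, "xmax", repr(float(box[2])))
        _sub(bnd, "ymax", repr(float(box[3])))
    ET.indent(root)
    ET.ElementTree(root).write(path, encoding="unicode", xml_declaration=True)


def write_coco_json(records, path) -> None:
    """Write ground-truth records as a COCO dataset JSON (category 'spike')."""
    images, annotations = [], []
    ann_id = 1
    for rec in records:
        h, w = rec.image.shape[:2]
        images.append(
            {
                "id": int(rec.image_id),
                "file_name": rec.metadata.get("file_name", f"image_{rec.image_id:05d}.png"),
                "width": int(w),
                "height": int(h),
            }
        )
        for box in rec.boxes:
            x0, y0, x1, y1 = (float(v) for v in box)
            annotations.append(
                {
                    "id": ann_id,
                    "image_id": int(rec.image_id),
                    "category_id": SPIKE_CATEGORY["id"],
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "area": (x1 - x0) * (y1 - y0),
                    "iscrowd": 0,
                }
            )
            ann_id += 1
    doc = {"images": images, "annotations": annotations,
           "categories": [SPIKE_CATEGORY]}
    Path(path).write_text(json.dumps(doc, indent=1))


def read_coco_json(path) -> dict:
    """Read a COCO dataset JSON into per-image corner boxes.

    Returns {"images": {...}, "boxes": {image_id: (N, 4) array},
    "categories": [...]}.
    """
    try:
        doc = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise AnnotationError(f"{path}: invalid JSON ({e})") from None
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise AnnotationError(f"{path}: missing COCO key {key!r}")
    images = {int(im["id"]): im for im in doc["images"]}
    boxes: dict[int, list] = {iid: [] for iid in images}
    classes: dict[int, list] = {iid: [] for iid in images}
    for ann in doc["annotations"]:
        x, y, w, h = ann["bbox"]
        boxes[int(ann["image_id"])].append([x, y, x + w, y + h])
        classes[int(ann["image_id"])].append(int(ann["category_id"]))
    return {
        "images": images,
        "boxes": {k: np.asarray(v, dtype=np.float64).reshape(-1, 4)
                  for k, v in boxes.items()},
        "classes": {k: np.asarray(v, dtype=np.int64) for k, v in classes.items()},
        "categories": doc["categories"],
    }


def detections_to_coco_results(per_image: dict) -> list[dict]:
    """Convert {image_id: [Detection, ...]} into COCO-results entries."""
    results = []
    for image_id, dets in per_image.items():
        for d in dets:
            x0, y0, x1, y1 = (float(v) for v in d.box)
            results.append(
                {
                    "image_id": int(image_id),
                    "category_id": int(d.class_id),
                    "bbox": [x0, y0, x1 - x0, y1 - y0],
                    "score": float(d.score),
                }
            )
    return results
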