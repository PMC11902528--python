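"""Annotation and raster IO: LabelMe JSON, COCO JSON, PNG masks, JSONL.

All file writes are atomic (write to a temp file in the target directory,
then rename).  Masks are serialized as single-channel 8-bit PNG with 0 =
background and 255 = foreground.  Polygon coordinates are treated as
continuous and rasterized at pixel centers, 0-based.
"""

from __future__ import annotations

import json
import os
import tempfile
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from PIL import Image

from amodalgrape.mask_core import BBox

__all__ = [
    "AnnotationRecord",
    "read_labelme",
    "write_labelme",
    "read_coco",
    "write_coco",
    "rasterize_records",
    "read_mask_png",
    "write_mask_png",
    "write_rgb_png",
    "read_jsonl",
    "write_jsonl",
    "atomic_write_bytes",
    "bbox_to_coco",
    "coco_to_bbox",
]


@dataclass
class AnnotationRecord:
    """One polygon instance annotation."""

    image_path: str
    instance_id: int
    points: list[tuple[float, float]]
    label: str = "grape"
    complete: bool = True

    def __post_init__(self) -> None:
        if len(self.points) < 3:
            raise ValueError("polygon needs at least 3 vertices")


def atomic_write_bytes(path: str | Path, data: bytes) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=".tmp-")
    try:
        with os.fdopen(fd, "wb") as fh:
            fh.write(data)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_write_text(path: str | Path, text: str) -> None:
    atomic_write_bytes(path, text.encode("utf-8"))


# -- LabelMe ------------------------------------------------------------


def read_labelme(path: str | Path) -> list[AnnotationRecord]:
    """Read polygon shapes from a LabelMe JSON file.

    Non-polygon shapes are skipped with a warning; coordinates outside the
    recorded image size are clipped with a warning.
    """
    path = Path(path)
    try:
        doc = json.loads(path.read_text())
    except json.JSONDecodeError as exc:
        raise ValueError(f"{path}: malformed JSON at line {exc.lineno}") from exc
    image_path = doc.get("imagePath", str(path))
    h = doc.get("imageHeight")
    w = doc.get("imageWidth")
    records = []
    for i, shape in enumerate(doc.get("shapes", [])):
        if shape.get("shape_type", "polygon") != "polygon":
            warnings.warn(
                f"{path}: skipping non-polygon shape #{i} "
                f"({shape.get('shape_type')})"
            )
            continue
        pts = [(float(x), float(y)) for x, y in shape["points"]]
        if h and w:
            clipped = [
                (min(max(x, 0.0), w - 1e-9), min(max(y, 0.0), h - 1e-9))
                for x, y in pts
            ]
            if clipped != pts:
                warnings.warn(f"{path}: clipped out-of-bounds vertices in shape #{i}")
            pts = clipped
        records.append(
            AnnotationRecord(
                image_path=image_path,
                instance_id=i + 1,
                points=pts,
                label=shape.get("label", "grape"),
                complete=bool(shape.get("flags", {}).get("complete", True)),
            )
        )
    return records


def write_labelme(
    records: Sequence[AnnotationRecord], path: str | Path, image_hw: tuple[int, int]
) -> None:
    doc = {
        "version": "5.5.0",
        "imagePath": records[0].image_path if records else "",
        "imageHeight": image_hw[0],
        "imageWidth": image_hw[1],
        "imageData": None,
        "shapes": [
            {
                "label": r.label,
                "points": [[float(x), float(y)] for x, y in r.points],
                "shape_type": "polygon",
                "flags": {"complete": r.complete},
            }
            for r in records
        ],
    }
    _atomic_write_text(path, json.dumps(doc, indent=1))


def rasterize_records(
    records: Sequence[AnnotationRecord], image_hw: tuple[int, int]
) -> np.ndarray:
    """Paint polygon records into an instance label map (later wins)."""
    from skimage.draw import polygon as draw_polygon

    lab = np.zeros(image_hw, dtype=np.int32)
    for r in records:
        xs = np.asarray([p[0] for p in r.points])
        ys = np.asarray([p[1] for p in r.points])
        rr, cc = draw_polygon(ys, xs, shape=image_hw)
        lab[rr, cc] = r.instance_id
    return lab


# -- COCO ---------------------------------------------------------------


def bbox_to_coco(box: BBox) -> list[float]:
    return [float(box.x0), float(box.y0), float(box.width), float(box.height)]


def coco_to_bbox(xywh: Sequence[float]) -> BBox:
    x, y, w, h = xywh
    return BBox(int(round(x)), int(round(y)), int(round(x + w)), int(round(y + h)))


def _polygon_bbox(points: Sequence[tuple[float, float]]) -> list[float]:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    return [min(xs), min(ys), max(xs) - min(xs), max(ys) - min(ys)]


def write_coco(
    records: Sequence[AnnotationRecord],
    path: str | Path,
    image_hw: tuple[int, int] = (720, 1280),
) -> None:
    """Write records as a minimal COCO instances JSON."""
    image_ids: dict[str, int] = {}
    images = []
    annotations = []
    for i, r in enumerate(records):
        if r.image_path not in image_ids:
            image_ids[r.image_path] = len(image_ids) + 1
            images.append(
                {
                    "id": image_ids[r.image_path],
                    "file_name": r.image_path,
                    "height": image_hw[0],
                    "width": image_hw[1],
                }
            )
        flat = [float(v) for xy in r.points for v in xy]
        annotations.append(
            {
                "id": i + 1,
                "image_id": image_ids[r.image_path],
                "category_id": 1,
                "segmentation": [flat],
                "bbox": _polygon_bbox(r.points),
                "iscrowd": 0,
                "attributes": {"instance_id": r.instance_id, "complete": r.complete},
            }
        )
    doc = {
        "images": images,
        "annotations": annotations,
        "categories": [{"id": 1, "name": records[0].label if records else "grape"}],
    }
    _atomic_write_text(path, json.dumps(doc))


def read_coco(path: str | Path) -> list[AnnotationRecord]:
    doc = json.loads(Path(path).read_text())
    for key in ("images", "annotations", "categories"):
        if key not in doc:
            raise ValueError(f"COCO file missing required field '{key}'")
    images = {im["id"]: im["file_name"] for im in doc["images"]}
    cats = {c["id"]: c["name"] for c in doc["categories"]}
    records = []
    for ann in doc["annotations"]:
        for key in ("image_id", "segmentation", "bbox"):
            if key not in ann:
                raise ValueError(f"COCO annotation missing required field '{key}'")
        seg = ann["segmentation"][0]
        pts = [(seg[i], seg[i + 1]) for i in range(0, len(seg), 2)]
        attrs = ann.get("attributes", {})
        records.append(
            AnnotationRecord(
                image_path=images[ann["image_id"]],
                instance_id=int(attrs.get("instance_id", ann["id"])),
                points=pts,
                label=cats.get(ann.get("category_id", 1), "grape"),
                complete=bool(attrs.get("complete", True)),
            )
        )
    return records


# -- rasters and logs ---------------------------------------------------


def write_mask_png(mask: np.ndarray, path: str | Path) -> None:
    img = Image.fromarray((np.asarray(mask, dtype=bool) * 255).astype(np.uint8), "L")
    import io

    buf = io.BytesIO()
    img.save(buf, format="PNG")
    atomic_write_bytes(path, buf.getvalue())


def read_mask_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("L")) >= 128


def write_rgb_png(rgb: np.ndarray, path: str | Path) -> None:
    img = Image.fromarray(np.asarray(rgb, dtype=np.uint8), "RGB")
    import io

    buf = io.BytesIO()
    img.save(buf, format="PNG")
    atomic_write_bytes(path, buf.getvalue())


def write_jsonl(rows: Iterable[dict], path: str | Path) -> None:
    _atomic_write_text(path, "".join(json.dumps(r) + "\n" for r in rows))


def read_jsonl(path: str | Path) -> list[dict]:
    return [
        json.loads(line)
        for line in Path(path).read_text().splitlines()
        if line.strip()
    ]
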