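"""Dataset preparation: VOC XML parsing, YOLO txt, letterboxing, splits.

Ground truth is authored in LabelImg's Pascal VOC XML dialect (1-based
inclusive pixel coordinates), converted to YOLO txt (normalized center
format) for training, with every image standardized to a 640×640 canvas
by aspect-preserving letterboxing.  Internally a single coordinate truth
is used: 0-based, half-open [x_min, x_max) × [y_min, y_max); each external
dialect is translated at its boundary.

Lesion classes are the three esophageal-cancer manifestations annotated
as A (dysplasia), B (squamous cell carcinoma), C (polyp), mapped to YOLO
class indices 0, 1, 2.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from lxml import etree
from PIL import Image

from .color_transfer import as_float

#: Gray level used to pad the letterbox canvas (YOLOv5 convention).
LETTERBOX_PAD_LEVEL = 114
DEFAULT_TARGET_SIZE = 640


class LesionClass(enum.Enum):
    """Lesion classes: bijection code ↔ name ↔ YOLO index."""

    DYSPLASIA = ("A", "dysplasia", 0)
    SCC = ("B", "SCC", 1)
    POLYP = ("C", "polyp", 2)

    def __init__(self, code: str, label: str, index: int):
        self.code = code
        self.label = label
        self.index = index

    @classmethod
    def from_name(cls, name: str) -> "LesionClass":
        key = name.strip()
        for member in cls:
            if key in (member.code, member.label, member.label.lower(), str(member.index)):
                return member
        raise KeyError(f"unknown lesion class name: {name!r}")

    @classmethod
    def from_index(cls, index: int) -> "LesionClass":
        for member in cls:
            if member.index == index:
                return member
        raise KeyError(f"unknown lesion class index: {index}")


@dataclass(frozen=True)
class Box:
    """Axis-aligned box, 0-based half-open pixel coordinates."""

    x_min: float
    y_min: float
    x_max: float
    y_max: float

    def __post_init__(self) -> None:
        if not (self.x_min < self.x_max and self.y_min < self.y_max):
            raise ValueError(f"degenerate box: {self}")

    @property
    def width(self) -> float:
        return self.x_max - self.x_min

    @property
    def height(self) -> float:
        return self.y_max - self.y_min

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class Annotation:
    """Ground truth for one image; ``boxes`` may be empty (normal mucosa)."""

    image_id: str
    width: int
    height: int
    boxes: tuple[tuple[Box, LesionClass], ...] = ()

    def __post_init__(self) -> None:
        for box, _ in self.boxes:
            if not (0 <= box.x_min and box.x_max <= self.width
                    and 0 <= box.y_min and box.y_max <= self.height):
                raise ValueError(
                    f"box {box} outside image extent {self.width}×{self.height}"
                )


# ---------------------------------------------------------------------------
# Pascal VOC XML (LabelImg dialect)
# ---------------------------------------------------------------------------

def read_voc_xml(doc: str | bytes) -> Annotation:
    """Parse a LabelImg VOC XML document.

    VOC coordinates are 1-based inclusive; the internal convention is
    0-based half-open, so xmin/ymin shift down by one and xmax/ymax carry
    over unchanged.
    """
    if isinstance(doc, str):
        doc = doc.encode()
    try:
        root = etree.fromstring(doc)
    except etree.XMLSyntaxError as exc:
        raise ValueError(f"malformed VOC XML: {exc}") from exc
    image_id = root.findtext("filename", default="unknown")
    for suffix in (".png", ".jpg", ".jpeg", ".xml"):
        if image_id.lower().endswith(suffix):
            image_id = image_id[: -len(suffix)]
    width = int(root.findtext("size/width"))
    height = int(root.findtext("size/height"))
    boxes = []
    for obj in root.findall("object"):
        lesion = LesionClass.from_name(obj.findtext("name"))
        bnd = obj.find("bndbox")
        xmin = float(bnd.findtext("xmin"))
        ymin = float(bnd.findtext("ymin"))
        xmax = float(bnd.findtext("xmax"))
        ymax = float(bnd.findtext("ymax"))
        boxes.append((Box(xmin - 1.0, ymin - 1.0, xmax, ymax), lesion))
    return Annotation(image_id=image_id, width=width, height=height,
                      boxes=tuple(boxes))


def write_voc_xml(ann: Annotation, folder: str = "images") -> str:
    """Serialize an annotation back to LabelImg-style VOC XML."""
    root = etree.Element("annotation")
    etree.SubElement(root, "folder").text = folder
    etree.SubElement(root, "filename").text = f"{ann.image_id}.png"
    size = etree.SubElement(root, "size")
    etree.SubElement(size, "width").text = str(ann.width)
    etree.SubElement(size, "height").text = str(ann.height)
    etree.SubElement(size, "depth").text = "3"
    for box, lesion in ann.boxes:
        obj = etree.SubElement(root, "object")
        etree.SubElement(obj, "name").text = lesion.code
        etree.SubElement(obj, "pose").text = "Unspecified"
        etree.SubElement(obj, "truncated").text = "0"
        etree.SubElement(obj, "difficult").text = "0"
        bnd = etree.SubElement(obj, "bndbox")
        etree.SubElement(bnd, "xmin").text = str(int(round(box.x_min + 1)))
        etree.SubElement(bnd, "ymin").text = str(int(round(box.y_min + 1)))
        etree.SubElement(bnd, "xmax").text = str(int(round(box.x_max)))
        etree.SubElement(bnd, "ymax").text = str(int(round(box.y_max)))
    return etree.tostring(root, pretty_print=True, encoding="unicode")


# ---------------------------------------------------------------------------
# YOLO txt
# ---------------------------------------------------------------------------

def to_yolo_txt(ann: Annotation) -> str:
    """One line per box: ``<class_index> <cx> <cy> <w> <h>``, normalized.

    Center and size are divided by the image width/height and printed with
    six decimal places; an empty annotation yields an empty string.
    """
    if ann.width <= 0 or ann.height <= 0:
        raise ValueError(f"invalid image extent {ann.width}×{ann.height}")
    lines = []
    for box, lesion in ann.boxes:
        cx = (box.x_min + box.x_max) / 2.0 / ann.width
        cy = (box.y_min + box.y_max) / 2.0 / ann.height
        w = box.width / ann.width
        h = box.height / ann.height
        lines.append(f"{lesion.index} {cx:.6f} {cy:.6f} {w:.6f} {h:.6f}")
    return "\n".join(lines) + ("\n" if lines else "")


def read_yolo_txt(text: str, image_id: str, width: int, height: int) -> Annotation:
    """Inverse of :func:`to_yolo_txt` for a known image extent."""
    boxes = []
    for line in text.strip().splitlines():
        if not line.strip():
            continue
        parts = line.split()
        idx = int(parts[0])
        cx, cy, w, h = (float(p) for p in parts[1:5])
        # 6-decimal quantization can overshoot the extent by < 0.5 px; clip
        boxes.append(
            (
                Box(
                    max(0.0, (cx - w / 2.0) * width),
                    max(0.0, (cy - h / 2.0) * height),
                    min(float(width), (cx + w / 2.0) * width),
                    min(float(height), (cy + h / 2.0) * height),
                ),
                LesionClass.from_index(idx),
            )
        )
    return Annotation(image_id=image_id, width=width, height=height,
                      boxes=tuple(boxes))


# ---------------------------------------------------------------------------
# Letterboxing
# ---------------------------------------------------------------------------

def letterbox_resize(
    img: np.ndarray,
    ann: Annotation | None = None,
    target: int = DEFAULT_TARGET_SIZE,
) -> tuple[np.ndarray, Annotation | None]:
    """Aspect-preserving resize onto a ``target``×``target`` gray canvas.

    The image is scaled by min(target/w, target/h), centered, and padded
    symmetrically with gray level 114; box coordinates are scaled and
    offset by the same transform, so each box's aspect ratio is preserved
    exactly.
    """
    if target < 32:
        raise ValueError(f"target size must be ≥ 32, got {target}")
    arr = as_float(img)
    h, w = arr.shape[:2]
    scale = min(target / w, target / h)
    new_w = int(round(w * scale))
    new_h = int(round(h * scale))
    if (new_w, new_h) != (w, h):
        pil = Image.fromarray(np.floor(arr * 255.0 + 0.5).astype(np.uint8))
        arr = np.asarray(pil.resize((new_w, new_h), Image.BILINEAR),
                         dtype=np.float64) / 255.0
    pad_x = (target - new_w) // 2
    pad_y = (target - new_h) // 2
    canvas = np.full((target, target, 3), LETTERBOX_PAD_LEVEL / 255.0)
    canvas[pad_y:pad_y + new_h, pad_x:pad_x + new_w] = arr
    out_ann = None
    if ann is not None:
        # box transform uses the exact scale, not the rounded raster size
        boxes = tuple(
            (
                Box(
                    box.x_min * scale + pad_x,
                    box.y_min * scale + pad_y,
                    box.x_max * scale + pad_x,
                    box.y_max * scale + pad_y,
                ),
                lesion,
            )
            for box, lesion in ann.boxes
        )
        out_ann = Annotation(image_id=ann.image_id, width=target,
                             height=target, boxes=boxes)
    return canvas, out_ann


# ---------------------------------------------------------------------------
# Dataset splitting
# ---------------------------------------------------------------------------

def split_dataset(
    ids: Sequence[str],
    train_fraction: float = 0.7,
    seed: int = 0,
    val_fraction: float = 0.0,
) -> tuple[list[str], list[str]] | tuple[list[str], list[str], list[str]]:
    """Seeded 70:30 train/test partition (validation = test by default).

    Deterministic shuffle under ``seed``; train size = round(n·fraction);
    the partition is disjoint and exhaustive.  A positive ``val_fraction``
    carves a separate validation set out of the remainder instead.
    """
    if not 0 < train_fraction < 1:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    if len(set(ids)) != len(ids):
        raise ValueError("image ids must be unique")
    if val_fraction < 0 or train_fraction + val_fraction >= 1:
        raise ValueError(f"invalid val_fraction {val_fraction}")
    rng = np.random.default_rng(seed)
    order = list(ids)
    rng.shuffle(order)
    n_train = round(len(order) * train_fraction)
    if val_fraction > 0:
        n_val = round(len(order) * val_fraction)
        return (order[:n_train], order[n_train:n_train + n_val],
                order[n_train + n_val:])
    return order[:n_train], order[n_train:]


def scale_box(box: Box, scale: float, dx: float = 0.0, dy: float = 0.0) -> Box:
    return Box(box.x_min * scale + dx, box.y_min * scale + dy,
               box.x_max * scale + dx, box.y_max * scale + dy)


def replace_boxes(ann: Annotation, boxes) -> Annotation:
    return replace(ann, boxes=tuple(boxes))
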