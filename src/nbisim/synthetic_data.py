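"""Seeded synthetic endoscopy data: WLI-like frames, NBI-like references,
lesion annotations, and planted detection sets.

No public imaging dataset backs this tool, so every downstream module is
exercised on generated data instead: smooth pinkish mucosa backgrounds
with darker curvilinear vascular texture and a mild vignette stand in for
white-light frames; a chromatically shifted teal/brown palette stands in
for the narrow-band reference; elliptical blobs with class-specific hue
stand in for lesions (the textures are cosmetic, not biologically
meaningful).  All artifacts — pixels, VOC XML bytes, YOLO txt bytes — are
bit-reproducible functions of the configured seed; no global RNG state is
touched.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter

from .annotations import Annotation, Box, LesionClass, to_yolo_txt, write_voc_xml
from .detection_eval import ConfusionCounts, Detection


@dataclass(frozen=True)
class SynthConfig:
    """Generation conditions for the synthetic dataset.

    ``lesion_rate`` is the per-class probability that an image receives a
    lesion of that class (images may carry 0–3 lesions); palettes are mean
    RGB levels the backgrounds are built around.
    """

    seed: int = 0
    size: int = 640
    n_images: int = 20
    lesion_rate: dict = field(
        default_factory=lambda: {
            LesionClass.DYSPLASIA: 0.35,
            LesionClass.SCC: 0.25,
            LesionClass.POLYP: 0.30,
        }
    )
    #: pinkish mucosa: strong red, moderate green/blue
    wli_palette: tuple = (0.78, 0.45, 0.42)
    #: teal/brown narrow-band appearance: suppressed red, raised green/blue
    nbi_palette: tuple = (0.35, 0.55, 0.52)

    def __post_init__(self) -> None:
        if self.size < 64:
            raise ValueError(f"size must be ≥ 64, got {self.size}")
        for c, p in self.lesion_rate.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"lesion rate for {c} outside [0,1]: {p}")


def _rng(cfg: SynthConfig, *stream: int) -> np.random.Generator:
    # one independent, named stream per artifact: (seed, stream ids)
    return np.random.default_rng([cfg.seed, *stream])


def _smooth_field(rng: np.random.Generator, size: int, sigma: float) -> np.ndarray:
    """Zero-mean unit-ish smooth noise field."""
    noise = rng.standard_normal((size, size))
    smooth = gaussian_filter(noise, sigma=sigma, mode="reflect")
    sd = smooth.std()
    return smooth / sd if sd > 0 else smooth


def _vignette(size: int, strength: float = 0.25) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    c = (size - 1) / 2.0
    r2 = ((xx - c) ** 2 + (yy - c) ** 2) / (2.0 * c * c)
    return 1.0 - strength * r2


def _vessels(rng: np.random.Generator, size: int, n: int = 12) -> np.ndarray:
    """Mask of dark curvilinear strokes emulating submucosal vessels."""
    mask = np.zeros((size, size))
    for _ in range(n):
        x = rng.uniform(0, size)
        y = rng.uniform(0, size)
        angle = rng.uniform(0, 2 * np.pi)
        steps = int(rng.integers(size // 4, size))
        for _ in range(steps):
            angle += rng.normal(0.0, 0.25)
            x = (x + np.cos(angle)) % size
            y = (y + np.sin(angle)) % size
            mask[int(y), int(x)] = 1.0
    mask = gaussian_filter(mask, sigma=1.2, mode="wrap")
    peak = mask.max()
    return mask / peak if peak > 0 else mask


def make_mucosa_image(cfg: SynthConfig, index: int) -> np.ndarray:
    """One WLI-like frame, deterministic per (seed, index).

    Low-frequency pinkish background plus darker red vessel strokes and a
    mild vignette; the red channel mean exceeds the blue channel mean.
    """
    rng = _rng(cfg, 0, index)
    size = cfg.size
    img = np.empty((size, size, 3))
    for ch, base in enumerate(cfg.wli_palette):
        img[..., ch] = base + 0.06 * _smooth_field(rng, size, sigma=size / 8.0)
    vessels = _vessels(rng, size)
    # vessels darken green/blue more than red → redder vasculature
    img[..., 0] -= 0.10 * vessels
    img[..., 1] -= 0.18 * vessels
    img[..., 2] -= 0.16 * vessels
    img *= _vignette(size)[..., None]
    return np.clip(img, 0.0, 1.0)


def make_nbi_reference(cfg: SynthConfig) -> np.ndarray:
    """NBI-like reference frame whose lαβ statistics sit away from the
    WLI palette (red–green mean shifted down, yellow–blue shifted)."""
    rng = _rng(cfg, 1)
    size = cfg.size
    img = np.empty((size, size, 3))
    for ch, base in enumerate(cfg.nbi_palette):
        img[..., ch] = base + 0.08 * _smooth_field(rng, size, sigma=size / 10.0)
    vessels = _vessels(rng, size, n=18)
    # narrow-band light renders capillaries brown/dark on teal mucosa
    img[..., 0] -= 0.05 * vessels
    img[..., 1] -= 0.20 * vessels
    img[..., 2] -= 0.22 * vessels
    img *= _vignette(size, strength=0.15)[..., None]
    return np.clip(img, 0.0, 1.0)


# hue/contrast offsets per class — cosmetic, to make classes separable
_LESION_TINT = {
    LesionClass.DYSPLASIA: np.array([0.10, -0.08, -0.06]),
    LesionClass.SCC: np.array([-0.12, -0.14, -0.10]),
    LesionClass.POLYP: np.array([0.06, 0.04, -0.10]),
}


def _paint_lesion(
    img: np.ndarray, rng: np.random.Generator, lesion: LesionClass
) -> Box:
    """Paint one elliptical blob; return its tight bounding box."""
    size = img.shape[0]
    a = rng.uniform(0.05, 0.16) * size   # semi-axes
    b = rng.uniform(0.05, 0.16) * size
    cx = rng.uniform(a + 2, size - a - 2)
    cy = rng.uniform(b + 2, size - b - 2)
    yy, xx = np.mgrid[0:size, 0:size]
    d2 = ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2
    blob = np.clip(1.0 - d2, 0.0, 1.0) ** 0.7
    tint = _LESION_TINT[lesion]
    img += blob[..., None] * tint
    np.clip(img, 0.0, 1.0, out=img)
    return Box(
        float(np.floor(cx - a)), float(np.floor(cy - b)),
        float(np.ceil(cx + a)), float(np.ceil(cy + b)),
    )


@dataclass(frozen=True)
class LesionDataset:
    images: list           # list of H×W×3 float arrays
    annotations: list      # list of Annotation
    voc_xml: list          # list of XML strings, parallel
    yolo_txt: list         # list of txt strings, parallel


def make_lesion_dataset(cfg: SynthConfig) -> LesionDataset:
    """Annotated synthetic dataset: 0–3 lesions per image, all classes.

    Every box lies inside the image extent, and the emitted VOC XML and
    YOLO txt are mutually consistent re-parsings of the same annotation.
    """
    if cfg.n_images < 1:
        raise ValueError("n_images must be ≥ 1")
    images, anns, xmls, txts = [], [], [], []
    for index in range(cfg.n_images):
        img = make_mucosa_image(cfg, index)
        rng = _rng(cfg, 2, index)
        boxes = []
        for lesion in LesionClass:
            if rng.uniform() < cfg.lesion_rate.get(lesion, 0.0):
                boxes.append((_paint_lesion(img, rng, lesion), lesion))
        ann = Annotation(
            image_id=f"synth_{index:04d}", width=cfg.size, height=cfg.size,
            boxes=tuple(boxes),
        )
        images.append(img)
        anns.append(ann)
        xmls.append(write_voc_xml(ann))
        txts.append(to_yolo_txt(ann))
    return LesionDataset(images=images, annotations=anns, voc_xml=xmls,
                         yolo_txt=txts)


def plant_detections(
    truths: list,
    seed: int = 0,
    fn_per_class: dict | None = None,
    fp_per_class: dict | None = None,
) -> tuple[list, dict]:
    """Detections with controlled errors and their exact confusion counts.

    Starts from perfect detections (every truth echoed at IoU 1), then
    drops the first ``fn_per_class[c]`` truths of class c (→ FN) and adds
    ``fp_per_class[c]`` small spurious boxes far from any truth (→ FP).
    Returns (detections, expected per-class ConfusionCounts), giving the
    evaluator an exact oracle.
    """
    fn_per_class = fn_per_class or {}
    fp_per_class = fp_per_class or {}
    rng = np.random.default_rng([seed, 3])
    dets: list[Detection] = []
    expected = {c: ConfusionCounts() for c in LesionClass}
    dropped = {c: 0 for c in LesionClass}
    gt_per_image = {c: {a.image_id: 0 for a in truths} for c in LesionClass}
    det_per_image = {c: {a.image_id: 0 for a in truths} for c in LesionClass}
    for ann in truths:
        for box, lesion in ann.boxes:
            gt_per_image[lesion][ann.image_id] += 1
            if dropped[lesion] < fn_per_class.get(lesion, 0):
                dropped[lesion] += 1
                expected[lesion].fn += 1
                continue
            dets.append(Detection(
                image_id=ann.image_id, box=box, lesion=lesion,
                confidence=float(rng.uniform(0.6, 0.99)),
            ))
            det_per_image[lesion][ann.image_id] += 1
            expected[lesion].tp += 1
    for lesion, n_fp in fp_per_class.items():
        for k in range(n_fp):
            ann = truths[int(rng.integers(len(truths)))]
            # tiny corner box: guaranteed IoU < 0.5 with any planted truth,
            # which the generator keeps ≥ 2 px away from the border
            x0 = 0.25 * k % 1.0
            dets.append(Detection(
                image_id=ann.image_id,
                box=Box(x0, 0.0, x0 + 1.0, 1.0),
                lesion=lesion,
                confidence=float(rng.uniform(0.3, 0.55)),
            ))
            det_per_image[lesion][ann.image_id] += 1
            expected[lesion].fp += 1
    for lesion in LesionClass:
        for ann in truths:
            if gt_per_image[lesion][ann.image_id] == 0 and \
               det_per_image[lesion][ann.image_id] == 0:
                expected[lesion].tn += 1
    return dets, expected
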