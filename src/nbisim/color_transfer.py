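"""RGB ↔ lαβ transform chain and per-channel statistics transfer.

Simulated narrow-band imaging (NBI) is produced from a white-light
endoscopy image (WLI) by transferring the per-channel mean and standard
deviation of a reference NBI image onto the WLI image in the decorrelated
lαβ color space (Ruderman's perceptual space built on log LMS cone
responses; Reinhard's statistics-transfer method).  The axes are l
(achromatic), α (yellow–blue opponent) and β (red–green opponent); because
the axes are decorrelated, each can be rescaled independently without
introducing cross-channel artefacts.

Pipeline::

    RGB --(cone matrix)--> LMS --(log10)--> log-LMS --(Ruderman)--> lαβ
        --(mean/SD transfer)--> lαβ' --(inverse chain, clamp)--> RGB

All images are H×W×3 float64 arrays; displayable RGB is normalized to
[0, 1].  8-bit arrays are accepted at the boundary and divided by 255.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, asdict
from typing import Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Floor applied before the logarithm; one tenth of an 8-bit quantum
#: (1/2550), bounding the log-LMS range below at log10(1/2550) ≈ -3.41
#: without visibly altering dark pixels.
DEFAULT_EPSILON = 1.0 / 2550.0

#: Combined RGB → LMS cone-response matrix (the RGB→XYZ→LMS two-step
#: collapsed into a single matrix; ITU primaries).
RGB_TO_LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)

LMS_TO_RGB = np.linalg.inv(RGB_TO_LMS)

#: Ruderman decorrelation: lαβ = diag(1/√3, 1/√6, 1/√2) · B · logLMS.
_B = np.array([[1.0, 1.0, 1.0], [1.0, 1.0, -2.0], [1.0, -1.0, 0.0]])
LOGLMS_TO_LAB = np.diag([1.0 / math.sqrt(3), 1.0 / math.sqrt(6), 1.0 / math.sqrt(2)]) @ _B
LAB_TO_LOGLMS = np.linalg.inv(LOGLMS_TO_LAB)

_AXES = ("l", "a", "b")


class ShapeError(ValueError):
    """Raised when an image is not an H×W×3 array."""


class DegenerateSourceError(ValueError):
    """Raised when a source channel has zero spread but rescaling is required."""


@dataclass(frozen=True)
class ChannelStats:
    """Per-axis mean and population standard deviation in lαβ space.

    This six-number summary is the entire fitted "model": transferring it
    from a reference image onto a source image is the whole conversion.
    """

    mean_l: float
    mean_a: float
    mean_b: float
    sd_l: float
    sd_a: float
    sd_b: float

    def __post_init__(self) -> None:
        for f, v in asdict(self).items():
            if not math.isfinite(v):
                raise ValueError(f"non-finite ChannelStats field {f}: {v}")
            if f.startswith("sd_") and v < 0:
                raise ValueError(f"negative standard deviation {f}: {v}")

    @property
    def means(self) -> np.ndarray:
        return np.array([self.mean_l, self.mean_a, self.mean_b])

    @property
    def sds(self) -> np.ndarray:
        return np.array([self.sd_l, self.sd_a, self.sd_b])

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2)

    @classmethod
    def from_json(cls, text: str) -> "ChannelStats":
        return cls(**json.loads(text))


def _check_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    arr = np.asarray(img)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ShapeError(f"{name} must be H×W×3, got shape {arr.shape}")
    if arr.shape[0] < 1 or arr.shape[1] < 1:
        raise ShapeError(f"{name} must have H ≥ 1 and W ≥ 1, got {arr.shape}")
    return arr


def as_float(img: np.ndarray) -> np.ndarray:
    """Return the image as float64 in [0, 1] (8-bit input divided by 255)."""
    arr = _check_image(img)
    if arr.dtype == np.uint8:
        return arr.astype(np.float64) / 255.0
    return arr.astype(np.float64)


def to_uint8(img: np.ndarray) -> np.ndarray:
    """Quantize a [0, 1] float image to 8 bits, rounding half up."""
    arr = np.clip(as_float(img), 0.0, 1.0)
    return np.floor(arr * 255.0 + 0.5).astype(np.uint8)


# ---------------------------------------------------------------------------
# Forward chain
# ---------------------------------------------------------------------------

def _apply_matrix(img: np.ndarray, m: np.ndarray) -> np.ndarray:
    return np.einsum("ij,hwj->hwi", m, img)


def rgb_to_lms(img: np.ndarray) -> np.ndarray:
    """Map normalized RGB to LMS cone responses (nonnegative for valid input)."""
    return _apply_matrix(as_float(img), RGB_TO_LMS)


def lms_to_log(img: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """log10 of each cone channel, flooring at ``epsilon`` so output is finite."""
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    arr = _check_image(img, "LMS image").astype(np.float64)
    return np.log10(np.maximum(arr, epsilon))


def loglms_to_lab(img: np.ndarray) -> np.ndarray:
    """Ruderman decorrelation of log-LMS into lαβ.

    l = (L+M+S)/√3, α = (L+M−2S)/√6, β = (L−M)/√2.  Achromatic pixels
    (L=M=S) land on α = β = 0.
    """
    return _apply_matrix(_check_image(img, "log-LMS image"), LOGLMS_TO_LAB)


def rgb_to_lab(img: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> np.ndarray:
    """Full forward chain RGB → lαβ."""
    return loglms_to_lab(lms_to_log(rgb_to_lms(img), epsilon))


# ---------------------------------------------------------------------------
# Statistics
# ---------------------------------------------------------------------------

def compute_channel_stats(lab: np.ndarray) -> ChannelStats:
    """Per-axis mean and population SD (divide by N) over all pixels.

    Pixel sets are treated as complete populations, not samples; the
    distinction is negligible at image scale but is fixed so transfers
    match target statistics exactly.
    """
    arr = _check_image(lab, "lab image")
    if arr.shape[0] * arr.shape[1] < 2:
        logger.warning("single-pixel image: standard deviation defined as 0")
    flat = arr.reshape(-1, 3).astype(np.float64)
    means = flat.mean(axis=0)
    sds = flat.std(axis=0)  # ddof=0: population SD
    return ChannelStats(
        mean_l=float(means[0]), mean_a=float(means[1]), mean_b=float(means[2]),
        sd_l=float(sds[0]), sd_a=float(sds[1]), sd_b=float(sds[2]),
    )


def transfer_statistics(
    src: np.ndarray, src_stats: ChannelStats, tgt_stats: ChannelStats
) -> np.ndarray:
    """Reinhard transfer: per axis, out = (σ_t/σ_s)·(in − μ_s) + μ_t.

    The target mean is re-added after scaling so the output's channel
    statistics equal ``tgt_stats`` exactly (before any clamping).  An axis
    whose target SD is zero needs no scaling; the output there is the
    constant target mean.
    """
    arr = _check_image(src, "lab image").astype(np.float64)
    scale = np.empty(3)
    for i, axis in enumerate(_AXES):
        s_sd, t_sd = src_stats.sds[i], tgt_stats.sds[i]
        if t_sd > 0 and s_sd == 0:
            raise DegenerateSourceError(
                f"source axis {axis!r} has zero standard deviation but the "
                f"target requires spread (sd={t_sd})"
            )
        scale[i] = t_sd / s_sd if s_sd > 0 else 0.0
    return (arr - src_stats.means) * scale + tgt_stats.means


# ---------------------------------------------------------------------------
# Inverse chain
# ---------------------------------------------------------------------------

def lab_to_rgb(lab: np.ndarray, epsilon: float = DEFAULT_EPSILON) -> tuple[np.ndarray, float]:
    """Invert the chain back to displayable RGB.

    Applies the inverse Ruderman map, exponentiates (10**·), applies the
    inverse cone matrix, and clamps to [0, 1].  Returns the image together
    with the fraction of channel values that were clamped — an auditable
    measure of out-of-gamut distortion.  Away from the clamp boundary and
    for LMS values above ``epsilon`` the composition with the forward chain
    is the identity to ~1e-6.
    """
    if epsilon <= 0:
        raise ValueError(f"epsilon must be positive, got {epsilon}")
    arr = _check_image(lab, "lab image").astype(np.float64)
    loglms = _apply_matrix(arr, LAB_TO_LOGLMS)
    lms = np.power(10.0, loglms)
    rgb = _apply_matrix(lms, LMS_TO_RGB)
    clamp_fraction = float(np.mean((rgb < 0.0) | (rgb > 1.0)))
    return np.clip(rgb, 0.0, 1.0), clamp_fraction


# ---------------------------------------------------------------------------
# Reference fitting and full simulation
# ---------------------------------------------------------------------------

def fit_reference(
    refs: Sequence[np.ndarray],
    epsilon: float = DEFAULT_EPSILON,
    per_image: bool = False,
) -> ChannelStats:
    """Fit target lαβ statistics from one or more reference NBI images.

    By default all pixels of all references are pooled with equal weight
    into a single population.  ``per_image=True`` instead averages each
    image's own stats (equal image weight regardless of size).
    """
    if len(refs) == 0:
        raise ValueError("fit_reference requires at least one reference image")
    labs = [rgb_to_lab(r, epsilon) for r in refs]
    if per_image:
        per = [compute_channel_stats(lab) for lab in labs]
        return ChannelStats(
            *(float(np.mean([getattr(s, f) for s in per]))
              for f in ("mean_l", "mean_a", "mean_b", "sd_l", "sd_a", "sd_b"))
        )
    pooled = np.concatenate([lab.reshape(-1, 3) for lab in labs], axis=0)
    return compute_channel_stats(pooled.reshape(1, -1, 3))


@dataclass(frozen=True)
class NbiSimulation:
    """Full diagnostic output of one WLI → simulated-NBI conversion."""

    image: np.ndarray          # clamped RGB in [0,1]
    lab_pre_clamp: np.ndarray  # transferred lαβ before the inverse chain
    src_stats: ChannelStats
    ref_stats: ChannelStats
    clamp_fraction: float


def simulate_nbi_full(
    wli: np.ndarray, ref: ChannelStats, epsilon: float = DEFAULT_EPSILON
) -> NbiSimulation:
    """Run the full conversion, keeping intermediate diagnostics."""
    lab = rgb_to_lab(wli, epsilon)
    src_stats = compute_channel_stats(lab)
    lab_out = transfer_statistics(lab, src_stats, ref)
    rgb, clamp_fraction = lab_to_rgb(lab_out, epsilon)
    return NbiSimulation(
        image=rgb, lab_pre_clamp=lab_out, src_stats=src_stats,
        ref_stats=ref, clamp_fraction=clamp_fraction,
    )


def simulate_nbi(
    wli: np.ndarray, ref: ChannelStats, epsilon: float = DEFAULT_EPSILON
) -> np.ndarray:
    """Convert a WLI image into a simulated NBI image (same dimensions)."""
    return simulate_nbi_full(wli, ref, epsilon).image
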