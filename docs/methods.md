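# Methods

## The color-transfer model

A simulated narrow-band image is produced from a white-light image by
matching first- and second-order channel statistics in the decorrelated
lαβ color space. The chain is:

1. **RGB → LMS.** Normalized RGB in [0, 1] is mapped to cone responses
   through a single 3×3 matrix (the RGB→XYZ→LMS two-step collapsed into
   one matrix with ITU primaries). The matrix is applied exactly with its
   published four-decimal entries. A consequence worth knowing: its rows
   sum to 0.9996 / 0.9993 / 0.9973 rather than exactly 1, so a perfectly
   gray input maps to a *constant* chroma offset of ≈ 8·10⁻⁴ rather than
   exactly α = β = 0. The offset carries no spatial structure and is
   invisible after quantization; the test suite asserts the constancy
   property rather than exact zero.
2. **log10.** Cone responses are strongly skewed; the log compresses
   them. The log base is 10 (any fixed base gives identical output
   because the subsequent map is linear and the statistics transfer is
   affine; base 10 keeps worked values readable). Values are floored at
   **ε = 1/2550** (one tenth of an 8-bit quantum) before the log, so the
   log-domain range is bounded below at ≈ −3.41 and black pixels are not
   visibly altered.
3. **lαβ.** The Ruderman decorrelation
   l = (L+M+S)/√3, α = (L+M−2S)/√6, β = (L−M)/√2
   applied to log responses: l is achromatic, α yellow–blue, β red–green.
   Its exact matrix inverse is used on the way back.
4. **Statistics transfer.** Per axis, out = (σt/σs)·(x − μs) + μt, where
   source statistics come from the image itself and target statistics
   from the reference. The target mean is re-added after scaling — the
   published transfer formula prints only the scaling step, but without
   re-adding the target mean the output means would be zero and could
   never match the reference distribution, which is the stated goal of
   the method. Standard deviations are **population** SDs (divide by N):
   pixel sets are complete populations, and only a fixed convention makes
   the post-transfer statistics match the target exactly (to ~1e-14 in
   double precision, verified in tests). A source axis with zero SD where
   the target requires spread raises an error naming the axis; where the
   target SD is also zero the output is the constant target mean.
5. **Inverse chain and clamp.** Inverse Ruderman map, 10^(·), inverse
   cone matrix, then clamp to [0, 1]. The fraction of clamped channel
   values is returned as a diagnostic; a nonzero fraction flags that the
   requested statistics pushed pixels out of gamut and the post-clamp
   statistics no longer match the target exactly.

Reference statistics may be fitted from several NBI images; the default
pools all pixels with equal weight into one population (a single
well-defined estimator). Per-image averaging is available as a flag.

All arithmetic is double precision; 8-bit quantization (round half-up)
happens only at file write.

**Assumptions and limitations.** The transfer is global: one scale and
shift per axis for the whole frame. Source and reference should be
compositionally comparable (mucosa onto mucosa); transferring between
images with very different content shifts colors wrongly, and no
per-region or content-aware variant is attempted. Nothing spectral is
simulated — the 415/540 nm physics of real narrow-band optics is only
emulated in the sense of "look like the reference".

## Quality metrics

* **SSIM**: computed on the BT.601 luminance plane (the canonical
  formulation is single-channel), Gaussian window 11×11 with σ = 1.5,
  K1 = 0.01, K2 = 0.03, dynamic range 255, mean over valid (fully
  interior) windows. The implementation is an explicit windowed
  computation; tests verify it against both a brute-force sliding-window
  oracle (to 1e-9) and scikit-image's implementation.
* **PSNR**: 10·log10(255²/MSE) with the MSE pooled over all three
  channels (not per-channel PSNR averaged); +∞ for identical images.
* **Entropy**: Shannon entropy of the 256-bin histogram of the rounded
  (half-up) BT.601 grayscale image, in bits. The disparity between a
  source and its conversion is reported as |H_src − H_out| / H_src × 100,
  i.e. relative to the source image — the published protocol reports a
  percentage without printing the formula, and a source-relative absolute
  difference is the natural reading.

## Dataset preparation

Internal box coordinates are 0-based half-open; the two external dialects
are translated at their boundaries: Pascal VOC XML (LabelImg) is 1-based
inclusive (xmin−1 on read), YOLO txt is normalized center format with six
decimals. The round trip through either format moves a box by at most
0.5 px (normalization quantization; reconstructed YOLO boxes are clipped
to the image extent). Letterboxing scales by min(target/w, target/h),
centers, and pads symmetrically with gray 114 (the convention the
downstream detector family expects); box transforms use the exact scale,
so box aspect ratios are preserved exactly. The dataset split is a
seeded deterministic shuffle with train size round(n·0.7). The published
protocol names training/testing/validation sets but a single 70:30
ratio; the implementation does a two-way 70:30 split with validation
equal to the test set, and offers `val_fraction` for a true three-way
split. The split seed defaults to 0 and is always recorded.

## Detection evaluation

* **Matching** (the protocol never states one): greedy per image and
  class in descending confidence, one-to-one, IoU ≥ 0.5, the standard
  PASCAL VOC rule and the one consistent with mAP50. Confidence ties are
  broken by stable input order.
* **True negatives** are undefined at box level for a detector;
  specificity and accuracy use image-level TNs (images with neither
  ground truth nor detections of the class). Written reports carry this
  definition in their header.
* **AP50** is the exact area under the precision–recall step curve (all
  points, no 11-point sampling, no monotone envelope interpolation);
  mAP50 is the unweighted mean over classes that have ground truth —
  a class with no ground truth raises rather than scoring silently 0.
* **Reference losses** (the three YOLO terms) use natural-log binary
  cross-entropy with probabilities clamped to [1e-7, 1−1e-7], and
  λ_noobj = 0.5 by default (the published description leaves its value
  unstated). The classification term as published is typographically
  garbled (its summation header contradicts a classification loss); the
  implementation follows the printed BCE body with standard YOLO
  semantics: per-class BCE summed over cells that contain objects. These
  are reference computations for auditing a training run, not a training
  loop.
* 0/0 metric ratios are defined as 0 and logged.

## Synthetic data

The generator stands in for an unavailable clinical dataset. It emulates
the features the pipeline actually exercises: low-frequency pinkish
backgrounds with darker red curvilinear vessel strokes and a mild
vignette (WLI-like), a teal/brown palette with the red–green mean shifted
well below the WLI palette (NBI-like), and 0–3 elliptical lesion blobs
per frame with class-specific tints, boxes tight to the blobs, emitted
simultaneously as VOC XML and YOLO txt. Class incidence is Bernoulli per
class per image (defaults 0.35/0.25/0.30 for dysplasia/SCC/polyp, chosen
so that 1000-image runs exercise empty, single- and multi-lesion frames
while keeping each class common enough for stable statistics). All
randomness flows through named `numpy` generators seeded as
(seed, stream, index); every artifact is byte-reproducible.

What it does **not** emulate: real endoscopic optics (specular
highlights, blur, flare — precisely the distortions that depressed SSIM
in clinical material), true lesion morphology or texture, and the subtle
chromatic relationship between real WLI and real NBI. Passing tests
therefore certify the algorithms' mathematical contracts, not clinical
image quality; headline clinical numbers (mean SSIM ≈ 98%, PSNR ≈ 28 dB
on endoscope data) depend on the data and detector weights and are not
reproducible from synthetic frames. In particular the synthetic
WLI→NBI shift is deliberately large, so the PSNR of a synthetic
conversion (~12–13 dB) is far below what a subtle clinical shift yields.

`plant_detections` builds a detection set with exactly known errors:
every ground-truth box echoed at IoU 1, the first k truths of a class
dropped (FN), plus tiny corner boxes guaranteed below the IoU threshold
(FP). Its returned confusion counts are an exact oracle for the matcher.

## Problem sizes

Test and acceptance runs use frames of 64–256 px (the statistics
transfer is resolution-independent: it acts on pooled pixel
populations), 20-pair quality studies mirroring the 20-image assessment
protocol, 100-repeat property sweeps for the transfer identities, 1000
randomized grids for the loss zero-sets, and 40–60-image planted-truth
evaluations. The 640 px production default is exercised where the
contract is about the canvas itself (letterboxing).
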