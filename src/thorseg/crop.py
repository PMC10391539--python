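"""Trachea-centroid-driven crop localization for the second-stage network.

The esophagus almost always lies just posterior-left of the trachea, so the
stage-2 region of interest is a fixed-size square (default 64×64 px) placed
from the trachea's per-slice centre of gravity. At inference the centre is
shifted 5 mm toward the image left and 5 mm up to leave room for the
esophagus; at training time the label-derived centre is additionally
jittered by a random displacement of up to 4 mm (uniform magnitude, uniform
direction) to mimic stage-1 localisation error. Slices whose trachea mask
is empty — or training crops that miss the esophagus — fall back to the
previous slice's centre stepped 1 mm further left, chained layer by layer.

Pixel-window convention: the crop is the half-open window
``[r-size/2, r+size/2) × [c-size/2, c+size/2)`` around the centre rounded
half-up; out-of-image area is zero-padded and recorded so crops paste back
exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import EmptyMaskError, LocalizerError, ValidationError
from .volume_io import LabelVolume

__all__ = ["CropSpec", "CropRegion", "centroid", "inference_center", "training_center",
           "extract_crop", "paste_crop", "fallback_center", "paste_esophagus"]


@dataclass(frozen=True)
class CropSpec:
    """Stage-2 localisation contract (all distances in mm)."""

    crop_size: int = 64
    shift_left_mm: float = 5.0
    shift_up_mm: float = 5.0
    jitter_range_mm: tuple[float, float] = (0.0, 4.0)
    fallback_step_mm: float = 1.0
    fallback_direction: tuple[float, float] = (0.0, -1.0)  # (row, col) unit step: leftward

    def __post_init__(self):
        if self.crop_size < 8 or self.crop_size % 2:
            raise ValidationError("crop_size must be even and >= 8")
        if min(self.shift_left_mm, self.shift_up_mm, self.fallback_step_mm,
               *self.jitter_range_mm) < 0:
            raise ValidationError("mm parameters must be >= 0")


@dataclass(frozen=True)
class CropRegion:
    """Placement record of one crop: slice index, top-left (row, col) of the
    *unclipped* window, its size, and the zero-padding applied per edge
    ``((top, bottom), (left, right))``."""

    slice_index: int
    origin: tuple[int, int]
    size: int
    pad: tuple[tuple[int, int], tuple[int, int]] = ((0, 0), (0, 0))


def centroid(mask2d) -> tuple[float, float]:
    """Arithmetic mean (row, col) of a 2D mask's foreground pixels."""
    mask2d = np.asarray(mask2d, dtype=bool)
    if not mask2d.any():
        raise EmptyMaskError("centroid of an empty mask")
    rows, cols = np.nonzero(mask2d)
    return float(rows.mean()), float(cols.mean())


def inference_center(trachea_centroid, spacing, spec: CropSpec) -> tuple[float, float]:
    """Shift a trachea centroid left/up by the spec's mm offsets.

    ``spacing`` is the in-plane ``(dy, dx)`` in mm. Up means decreasing row,
    left means decreasing column.
    """
    dy, dx = spacing
    r, c = trachea_centroid
    return r - spec.shift_up_mm / dy, c - spec.shift_left_mm / dx


def training_center(label_trachea_centroid, spacing, spec: CropSpec,
                    rng: np.random.Generator) -> tuple[float, float]:
    """Inference centre plus an isotropic jitter: displacement magnitude
    uniform on ``jitter_range_mm``, direction uniform on the circle."""
    dy, dx = spacing
    r, c = inference_center(label_trachea_centroid, spacing, spec)
    mag = rng.uniform(*spec.jitter_range_mm)
    ang = rng.uniform(0.0, 2.0 * math.pi)
    return r + mag * math.sin(ang) / dy, c + mag * math.cos(ang) / dx


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def extract_crop(image2d, center, spec: CropSpec, slice_index: int = 0):
    """Cut a ``crop_size``² window centred at ``round(center)``; out-of-image
    area is zero-padded and recorded. Returns ``(crop, CropRegion)``."""
    image2d = np.asarray(image2d)
    half = spec.crop_size // 2
    r0 = _round_half_up(center[0]) - half
    c0 = _round_half_up(center[1]) - half
    h, w = image2d.shape
    s = spec.crop_size
    top = min(max(0, -r0), s)
    left = min(max(0, -c0), s)
    bottom = min(max(0, r0 + s - h), s)
    right = min(max(0, c0 + s - w), s)
    crop = np.zeros((s, s), dtype=image2d.dtype)
    if top + bottom < s and left + right < s:  # window overlaps the image
        crop[top:s - bottom, left:s - right] = \
            image2d[r0 + top:r0 + s - bottom, c0 + left:c0 + s - right]
    return crop, CropRegion(slice_index=slice_index, origin=(r0, c0), size=spec.crop_size,
                            pad=((top, bottom), (left, right)))


def paste_crop(target2d: np.ndarray, crop: np.ndarray, region: CropRegion) -> None:
    """Write the in-bounds part of a crop back into ``target2d`` in place
    (inverse of :func:`extract_crop` on the unpadded area)."""
    (top, bottom), (left, right) = region.pad
    r0, c0 = region.origin
    s = region.size
    target2d[r0 + top:r0 + s - bottom, c0 + left:c0 + s - right] = \
        crop[top:s - bottom, left:s - right]


def fallback_center(prev_center, spacing, spec: CropSpec) -> tuple[float, float]:
    """Step the previous slice's centre ``fallback_step_mm`` along
    ``fallback_direction`` (default: further left)."""
    if prev_center is None:
        raise LocalizerError("no previous-slice centre to fall back on")
    dy, dx = spacing
    ur, uc = spec.fallback_direction
    return (prev_center[0] + spec.fallback_step_mm * ur / dy,
            prev_center[1] + spec.fallback_step_mm * uc / dx)


def paste_esophagus(stage1_labels: LabelVolume, crop_preds) -> LabelVolume:
    """Correct a stage-1 label volume with stage-2 esophagus crops.

    ``crop_preds`` is an iterable of ``(binary crop, CropRegion)``. The
    esophagus is exclusively stage 2's: all stage-1 esophagus voxels are
    erased; inside each crop, stage-2 foreground becomes esophagus wherever
    stage 1 assigned background (or esophagus), while every other stage-1
    organ label wins the conflict and is left bitwise unchanged.
    """
    out = stage1_labels.copy()
    eso = out.label_table["esophagus"]
    out.labels[out.labels == eso] = 0
    nz = out.shape[0]
    for crop, region in crop_preds:
        crop = np.asarray(crop, dtype=bool)
        if not 0 <= region.slice_index < nz:
            raise ValidationError(f"crop slice {region.slice_index} outside volume of {nz} slices")
        if crop.shape != (region.size, region.size):
            raise ValidationError(f"crop shape {crop.shape} does not match region size {region.size}")
        plane = out.labels[region.slice_index]
        window = np.zeros_like(plane, dtype=bool)
        paste_crop(window, crop, region)
        plane[window & (plane == 0)] = eso
    return out
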