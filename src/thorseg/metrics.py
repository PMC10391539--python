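"""Spacing-aware overlap and surface-distance metrics (DSC, HD95, ASD).

All three metrics are computed in 3D per patient volume with anisotropic
voxel spacing — the standard benchmark convention, and a material choice
when slices are 5 mm thick. Conventions that the literature leaves open are
fixed explicitly here and exposed for sensitivity checks:

* the surface of a mask is the set of foreground voxels with at least one
  face-adjacent (6-connected) background or out-of-volume neighbour, and
  distances are measured centre-to-centre;
* HD95 combines directions by taking the max of the two directed 95th
  percentiles (``directed_combine="max"``; ``"pooled"`` percentiles over the
  union of both directed distance sets are available as a variant);
* percentiles use linear interpolation, which keeps the HD95 of two single
  voxels equal to their exact distance.

ASD is the symmetric average: the sum of all directed nearest-surface
distances in both directions divided by the total surface voxel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import EmptyMaskError, ValidationError
from .volume_io import LabelVolume

__all__ = [
    "MetricsRecord",
    "dsc",
    "extract_surface",
    "directed_distances",
    "hd95",
    "asd",
    "evaluate_patient",
]

_FACE_STRUCT = ndimage.generate_binary_structure(3, 1)  # 6-connectivity


@dataclass(frozen=True)
class MetricsRecord:
    """Per-patient, per-organ metric triple. Distances are NaN when either
    mask is empty (a missing value, never reported as 0)."""

    patient_id: str
    organ: str
    dsc: float
    hd95: float  # mm, NaN if undefined
    asd: float  # mm, NaN if undefined


def _as_mask(a) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 3:
        raise ValidationError(f"masks must be 3D, got shape {a.shape}")
    return a.astype(bool)


def dsc(a, b) -> float:
    """Dice similarity coefficient ``2|A∩B| / (|A|+|B|)``; 1.0 if both empty."""
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    denom = int(a.sum()) + int(b.sum())
    if denom == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / denom


def extract_surface(mask) -> np.ndarray:
    """Boolean surface of a mask: foreground voxels with a 6-connected
    background neighbour, counting out-of-volume as background."""
    mask = _as_mask(mask)
    if not mask.any():
        raise EmptyMaskError("cannot extract the surface of an empty mask")
    interior = ndimage.binary_erosion(mask, structure=_FACE_STRUCT, border_value=0)
    return mask & ~interior


def directed_distances(src_surface, dst_surface, spacing) -> np.ndarray:
    """For every voxel of ``src_surface``, the Euclidean mm distance to the
    nearest voxel of ``dst_surface`` (anisotropic spacing applied)."""
    src, dst = _as_mask(src_surface), _as_mask(dst_surface)
    if not src.any() or not dst.any():
        raise EmptyMaskError("directed_distances requires two non-empty surfaces")
    dt = ndimage.distance_transform_edt(~dst, sampling=spacing)
    return dt[src]


def _surface_distance_sets(a, b, spacing):
    a, b = _as_mask(a), _as_mask(b)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch {a.shape} vs {b.shape}")
    if not a.any() or not b.any():
        raise EmptyMaskError("surface-distance metrics require two non-empty masks")
    sa, sb = extract_surface(a), extract_surface(b)
    return directed_distances(sa, sb, spacing), directed_distances(sb, sa, spacing)


def hd95(a, b, spacing, q: float = 95.0, directed_combine: str = "max") -> float:
    """95th-percentile Hausdorff distance in mm.

    ``directed_combine="max"`` (default) takes the larger of the two directed
    q-th percentiles; ``"pooled"`` takes the q-th percentile of the pooled
    directed distances.
    """
    d_ab, d_ba = _surface_distance_sets(a, b, spacing)
    if directed_combine == "max":
        return float(max(np.percentile(d_ab, q), np.percentile(d_ba, q)))
    if directed_combine == "pooled":
        return float(np.percentile(np.concatenate([d_ab, d_ba]), q))
    raise ValidationError(f"unknown directed_combine {directed_combine!r}")


def asd(a, b, spacing) -> float:
    """Symmetric average surface distance in mm."""
    d_ab, d_ba = _surface_distance_sets(a, b, spacing)
    return float((d_ab.sum() + d_ba.sum()) / (d_ab.size + d_ba.size))


def evaluate_patient(pred: LabelVolume, gt: LabelVolume,
                     organs=None, patient_id: str = "") -> list[MetricsRecord]:
    """Per-organ metric records for one predicted/reference volume pair.

    An organ empty in both volumes scores DSC 1 with missing distances; an
    organ empty in exactly one scores DSC 0 with missing distances.
    """
    if pred.shape != gt.shape:
        raise ValidationError(f"volume shapes disagree: {pred.shape} vs {gt.shape}")
    if not np.allclose(pred.spacing, gt.spacing):
        raise ValidationError(f"spacings disagree: {pred.spacing} vs {gt.spacing}")
    organs = list(organs) if organs is not None else sorted(gt.label_table, key=gt.label_table.get)
    records = []
    for organ in organs:
        p, g = pred.mask(organ), gt.mask(organ)
        d = dsc(p, g)
        if p.any() and g.any():
            h, a = hd95(p, g, gt.spacing), asd(p, g, gt.spacing)
        else:
            h = a = float("nan")
        records.append(MetricsRecord(patient_id=patient_id, organ=organ, dsc=d, hd95=h, asd=a))
    return records
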