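"""CT window/level intensity mapping and expert-mask assembly.

Display windowing maps the Hounsfield interval
``[level - width/2, level + width/2]`` linearly onto ``[0, out_max]`` and
clips outside it. The defaults (width 400 HU, level 40 HU, out_max 255) are
the standard mediastinal soft-tissue window. Windowed intensities are kept
as reals; quantisation to 8 bits happens only on PNG export, so training
inputs are never double-rounded.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import ContractError, ValidationError
from .volume_io import CTVolume, LabelVolume

__all__ = ["WindowConfig", "apply_window", "to_unit_interval", "assemble_labels", "OVERLAP_PRECEDENCE"]


@dataclass(frozen=True)
class WindowConfig:
    """Window width/level in HU and the output ceiling."""

    window_width: float = 400.0
    window_level: float = 40.0
    out_max: float = 255.0

    def __post_init__(self):
        if self.window_width <= 0 or self.out_max <= 0:
            raise ValidationError("window_width and out_max must be > 0")


def apply_window(vol: CTVolume, cfg: WindowConfig = WindowConfig()) -> CTVolume:
    """Window/level a HU volume into real-valued ``[0, out_max]`` intensities."""
    if vol.intensity_space != "HU":
        raise ContractError(f"apply_window needs HU input, got {vol.intensity_space}")
    lo = cfg.window_level - cfg.window_width / 2.0
    scaled = np.clip((vol.voxels.astype(np.float64) - lo) / cfg.window_width, 0.0, 1.0)
    return replace(vol, voxels=(scaled * cfg.out_max).astype(np.float32),
                   intensity_space="normalized_0_255")


def to_unit_interval(vol: CTVolume, out_max: float = 255.0) -> CTVolume:
    """Rescale a windowed ``[0, out_max]`` volume to ``[0, 1]`` network input."""
    if vol.intensity_space != "normalized_0_255":
        raise ContractError(f"to_unit_interval needs normalized_0_255 input, got {vol.intensity_space}")
    return replace(vol, voxels=(vol.voxels / out_max).astype(np.float32),
                   intensity_space="unit_interval")


#: When expert masks overlap, later entries claim the voxel. The thin air
#: column of the trachea must stay stable against the adjacent esophagus
#: (networks tend to confuse the two), hence trachea on top.
OVERLAP_PRECEDENCE = ("left_lung", "right_lung", "heart", "esophagus", "cord", "trachea")


def assemble_labels(per_organ_masks: dict[str, np.ndarray],
                    label_table: dict[str, int],
                    spacing=(1.0, 1.0, 1.0)) -> LabelVolume:
    """Merge per-organ binary masks into one exclusive integer label volume.

    Overlapping claims are resolved by :data:`OVERLAP_PRECEDENCE` (later
    wins); organs absent from the precedence list are painted first, in
    sorted-name order, so named organs always override them.
    """
    if not per_organ_masks:
        raise ValidationError("no masks supplied")
    shapes = {np.asarray(m).shape for m in per_organ_masks.values()}
    if len(shapes) != 1:
        raise ValidationError(f"mask shapes disagree: {shapes}")
    unknown = set(per_organ_masks) - set(label_table)
    if unknown:
        raise ValidationError(f"masks {sorted(unknown)} missing from label_table")

    rank = {name: i for i, name in enumerate(OVERLAP_PRECEDENCE)}
    order = sorted(per_organ_masks, key=lambda n: (rank.get(n, -1), n))
    out = np.zeros(shapes.pop(), dtype=np.int16)
    for name in order:
        out[np.asarray(per_organ_masks[name], dtype=bool)] = label_table[name]
    return LabelVolume(out, spacing=spacing, label_table=dict(label_table))
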