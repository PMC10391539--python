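"""CT and label volume containers plus the package's only file I/O.

Axis convention: arrays are indexed ``(slice z, row y, col x)``, 0-based,
with rows increasing downward as in 2D image display. Spacing is the matching
``(dz, dy, dx)`` triple in millimetres. NIfTI is the canonical on-disk
format; directories of 8-bit grayscale PNG slices with a JSON sidecar are
supported read-only for small fixtures.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, replace

import numpy as np
import nibabel as nib

from .errors import ValidationError, VolumeFormatError

__all__ = [
    "CTVolume",
    "LabelVolume",
    "DEFAULT_LABEL_TABLE",
    "read_volume",
    "write_volume",
    "read_labelmap",
    "write_labelmap",
]

#: Organ label codes used throughout the package. Background is 0.
DEFAULT_LABEL_TABLE = {
    "left_lung": 1,
    "right_lung": 2,
    "heart": 3,
    "cord": 4,
    "trachea": 5,
    "esophagus": 6,
}

#: Valid values of :attr:`CTVolume.intensity_space`.
INTENSITY_SPACES = ("HU", "normalized_0_255", "unit_interval")


def _check_spacing(spacing) -> tuple[float, float, float]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != 3 or any(s <= 0 for s in spacing):
        raise ValidationError(f"spacing must be 3 strictly positive values, got {spacing}")
    return spacing


@dataclass
class CTVolume:
    """A 3D scalar field with voxel spacing in mm.

    Parameters
    ----------
    voxels
        ``(n_slices, n_rows, n_cols)`` array of intensities.
    spacing
        ``(dz, dy, dx)`` voxel spacing in mm, all strictly positive.
    intensity_space
        One of ``"HU"``, ``"normalized_0_255"`` (window/level mapped reals in
        ``[0, 255]``) or ``"unit_interval"``.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    intensity_space: str = "HU"

    def __post_init__(self):
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3 or min(self.voxels.shape) < 1:
            raise ValidationError(f"voxels must be 3D with positive dims, got shape {self.voxels.shape}")
        self.spacing = _check_spacing(self.spacing)
        if self.intensity_space not in INTENSITY_SPACES:
            raise ValidationError(f"unknown intensity_space {self.intensity_space!r}")
        if self.intensity_space == "normalized_0_255":
            lo, hi = float(self.voxels.min()), float(self.voxels.max())
            if lo < -1e-6 or hi > 255 + 1e-6:
                raise ValidationError(f"normalized_0_255 voxels outside [0,255]: range [{lo}, {hi}]")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    def copy(self) -> "CTVolume":
        return replace(self, voxels=self.voxels.copy())


@dataclass
class LabelVolume:
    """An integer organ-label field aligned with a :class:`CTVolume`.

    Every nonzero voxel value must appear in ``label_table``; zero is
    background. Labels are mutually exclusive by construction (one integer
    per voxel).
    """

    labels: np.ndarray
    spacing: tuple[float, float, float]
    label_table: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_LABEL_TABLE))

    def __post_init__(self):
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValidationError(f"labels must be 3D, got shape {self.labels.shape}")
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise VolumeFormatError(f"labels must be integer-valued, got dtype {self.labels.dtype}")
        self.spacing = _check_spacing(self.spacing)
        codes = set(np.unique(self.labels).tolist()) - {0}
        known = set(self.label_table.values())
        unknown = codes - known
        if unknown:
            raise ValidationError(f"label values {sorted(unknown)} missing from label_table {self.label_table}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def mask(self, organ: str) -> np.ndarray:
        """Binary mask of one organ by name."""
        return self.labels == self.label_table[organ]

    def copy(self) -> "LabelVolume":
        return replace(self, labels=self.labels.copy(), label_table=dict(self.label_table))


# ---------------------------------------------------------------------------
# NIfTI round trip. We store arrays as (z, y, x); nibabel's canonical in-file
# order is (x, y, z), so data are transposed on the way through and zooms are
# reversed. The intensity-space flag rides in the header 'descrip' field.
# ---------------------------------------------------------------------------

def _nifti_write(array: np.ndarray, spacing, path, descrip: str) -> None:
    data = np.transpose(array, (2, 1, 0))
    img = nib.Nifti1Image(data, affine=np.diag([spacing[2], spacing[1], spacing[0], 1.0]))
    img.header.set_zooms((spacing[2], spacing[1], spacing[0]))
    img.header["descrip"] = descrip.encode()
    nib.save(img, os.fspath(path))


def _nifti_read(path):
    img = nib.load(os.fspath(path))
    if img.ndim != 3:
        raise VolumeFormatError(f"{path}: expected a 3D NIfTI, got {img.ndim}D")
    data = np.transpose(np.asarray(img.dataobj), (2, 1, 0))
    zx, zy, zz = img.header.get_zooms()[:3]
    descrip = bytes(img.header["descrip"].tobytes()).split(b"\x00", 1)[0].decode(errors="replace")
    return data, (float(zz), float(zy), float(zx)), descrip


def _read_png_stack(path) -> CTVolume:
    import imageio.v3 as iio

    sidecar = os.path.join(path, "meta.json")
    if not os.path.exists(sidecar):
        raise VolumeFormatError(f"PNG stack {path} has no meta.json spacing sidecar")
    with open(sidecar) as fh:
        meta = json.load(fh)
    names = sorted(n for n in os.listdir(path) if n.lower().endswith(".png"))
    if not names:
        raise VolumeFormatError(f"{path}: no PNG slices found")
    slices = [np.asarray(iio.imread(os.path.join(path, n))) for n in names]
    shapes = {s.shape for s in slices}
    if len(shapes) != 1 or slices[0].ndim != 2:
        raise VolumeFormatError(f"{path}: inconsistent or non-grayscale slice shapes {shapes}")
    return CTVolume(
        np.stack(slices).astype(np.float32),
        spacing=tuple(meta["spacing"]),
        intensity_space="normalized_0_255",
    )


def read_volume(path) -> CTVolume:
    """Read a CT volume from a NIfTI file or a PNG-stack directory.

    NIfTI volumes come back in the intensity space recorded when they were
    written (HU unless flagged otherwise); PNG stacks are 8-bit and therefore
    always ``normalized_0_255``.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    if os.path.isdir(path):
        return _read_png_stack(path)
    data, spacing, descrip = _nifti_read(path)
    space = "HU"
    for token in descrip.split():
        if token.startswith("intensity_space="):
            space = token.split("=", 1)[1]
    return CTVolume(data.astype(np.float32), spacing=spacing, intensity_space=space)


def write_volume(vol: CTVolume, path) -> None:
    """Write a CT volume as NIfTI; readable back by :func:`read_volume`."""
    _nifti_write(
        vol.voxels.astype(np.float32),
        vol.spacing,
        path,
        f"intensity_space={vol.intensity_space}",
    )


def _sidecar_path(path) -> str:
    base = os.fspath(path)
    for suffix in (".nii.gz", ".nii"):
        if base.endswith(suffix):
            base = base[: -len(suffix)]
            break
    return base + ".labels.json"


def read_labelmap(path) -> LabelVolume:
    """Read an integer label volume plus its JSON label-table sidecar."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    data, spacing, _ = _nifti_read(path)
    if not np.allclose(data, np.round(data)):
        raise VolumeFormatError(f"{path}: label volume contains non-integer values")
    sidecar = _sidecar_path(path)
    if os.path.exists(sidecar):
        with open(sidecar) as fh:
            label_table = {k: int(v) for k, v in json.load(fh)["label_table"].items()}
    else:
        label_table = dict(DEFAULT_LABEL_TABLE)
    return LabelVolume(data.astype(np.int16), spacing=spacing, label_table=label_table)


def write_labelmap(lv: LabelVolume, path) -> None:
    """Write a label volume as NIfTI plus a ``*.labels.json`` sidecar."""
    _nifti_write(lv.labels.astype(np.int16), lv.spacing, path, "labels")
    with open(_sidecar_path(path), "w") as fh:
        json.dump({"label_table": lv.label_table}, fh, indent=1)
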