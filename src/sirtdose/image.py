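"""Minimal 3-D volume container and NIfTI-1 I/O.

Most numerical routines in this package operate on plain numpy arrays plus a
voxel ``spacing`` triple (mm); :class:`VolumeImage` is the boundary object used
wherever volumes cross the filesystem or the CLI. World coordinates of voxel
centers are ``index * spacing`` under the default axis-aligned affine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

from .errors import GridMismatchError, InvalidInputError


def _default_affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class VolumeImage:
    """A 3-D scalar grid with anisotropic voxel spacing in mm."""

    data: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise InvalidInputError(f"expected a 3-D volume, got ndim={self.data.ndim}")
        self.spacing = tuple(float(s) for s in self.spacing)
        if any(s <= 0 for s in self.spacing):
            raise InvalidInputError(f"voxel spacing must be positive, got {self.spacing}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)
        self.affine = np.asarray(self.affine, dtype=float)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape  # type: ignore[return-value]

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing))

    @property
    def voxel_volume_mL(self) -> float:
        return self.voxel_volume_mm3 / 1000.0

    def same_grid(self, other: "VolumeImage") -> bool:
        return self.shape == other.shape and np.allclose(self.spacing, other.spacing)


def ensure_same_grid(*volumes: VolumeImage, what: str = "input volumes") -> None:
    """Raise :class:`GridMismatchError` unless all volumes share shape+spacing."""
    ref = volumes[0]
    for v in volumes[1:]:
        if not ref.same_grid(v):
            raise GridMismatchError(ref.shape, v.shape, what=what)


def read_volume(path) -> VolumeImage:
    """Read a NIfTI-1 volume, preserving dtype, spacing, and affine."""
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise InvalidInputError(f"cannot read NIfTI volume {path}: {exc}") from exc
    data = np.asanyarray(img.dataobj)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return VolumeImage(data=data, spacing=spacing, affine=np.asarray(img.affine))


def write_volume(vol: VolumeImage, path) -> None:
    """Write a :class:`VolumeImage` as NIfTI-1, keeping the array dtype."""
    data = vol.data
    if data.dtype == bool:
        data = data.astype(np.uint8)
    elif data.dtype == np.int64:  # NIfTI-1 has no 64-bit integer type
        data = data.astype(np.int32)
    elif data.dtype == np.float64:
        data = data.astype(np.float32)
    img = nib.Nifti1Image(data, vol.affine)
    img.header.set_zooms(vol.spacing)
    nib.save(img, str(path))
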