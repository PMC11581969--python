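"""Volume containers, NIfTI I/O, intensity windowing and isotropic resampling.

CT volumes are carried around as :class:`ImageVolume` (a 3D scalar grid with
voxel spacing and a phase tag) and binary tumor masks as :class:`RoiMask`.
Preprocessing follows the usual contrast-CT radiomics recipe: clip intensities
to a fixed Hounsfield window and rescale to [0, 1], then resample to 1 mm
isotropic voxels so texture matrices are comparable across scanners.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "ImageVolume",
    "RoiMask",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "normalize_intensity",
    "resample_isotropic",
]

#: Default CT windowing bounds in Hounsfield units.
DEFAULT_WINDOW = (-200.0, 300.0)


@dataclasses.dataclass
class ImageVolume:
    """A 3D scalar image with physical voxel spacing.

    Parameters
    ----------
    values : ndarray, shape (nx, ny, nz)
        Voxel intensities (HU for raw CT, [0, 1] after normalization).
    spacing_mm : tuple of float
        Voxel edge lengths along each axis, in mm. All components > 0.
    origin_mm : tuple of float
        World coordinate of voxel (0, 0, 0).
    phase : str
        Acquisition phase tag, ``"ACE"`` (arterial) or ``"VCE"`` (venous).
    """

    values: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    phase: str = "ACE"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 3:
            raise ValueError(
                f"expected 3D volume, got {self.values.ndim}D array"
            )
        if self.values.size == 0:
            raise ValueError("empty volume")
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)
        if any(s <= 0 for s in self.spacing_mm):
            raise ValueError(f"spacing must be positive, got {self.spacing_mm}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def affine(self) -> np.ndarray:
        aff = np.diag(list(self.spacing_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclasses.dataclass
class RoiMask:
    """A binary tumor mask aligned to an :class:`ImageVolume`."""

    labels: np.ndarray
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise ValueError(
                f"expected 3D mask, got {self.labels.ndim}D array"
            )
        uniq = np.unique(self.labels)
        if not np.isin(uniq, [0, 1]).all():
            raise ValueError(f"mask labels outside {{0,1}}: {uniq}")
        self.labels = self.labels.astype(np.uint8)
        self.spacing_mm = tuple(float(s) for s in self.spacing_mm)
        self.origin_mm = tuple(float(o) for o in self.origin_mm)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.labels.shape

    def voxel_count(self) -> int:
        return int(self.labels.sum())

    def as_bool(self) -> np.ndarray:
        return self.labels.astype(bool)


def _load_nifti(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(f"expected 3D volume in {path}, got {data.ndim}D")
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    origin = tuple(float(o) for o in img.affine[:3, 3])
    return np.asarray(data), zooms, origin


def read_volume(path: str | Path, phase: str = "ACE") -> ImageVolume:
    """Read a 3D NIfTI-1 image as an :class:`ImageVolume`."""
    data, zooms, origin = _load_nifti(path)
    return ImageVolume(data.astype(np.float64), zooms, origin, phase)


def write_volume(volume: ImageVolume, path: str | Path) -> None:
    """Write an :class:`ImageVolume` as NIfTI-1 (float32 on disk)."""
    img = nib.Nifti1Image(volume.values.astype(np.float32), volume.affine())
    img.header.set_zooms(volume.spacing_mm)
    nib.save(img, str(path))


def read_mask(path: str | Path) -> RoiMask:
    """Read a binary ROI mask; labels outside {0, 1} raise."""
    data, zooms, origin = _load_nifti(path)
    return RoiMask(np.rint(data).astype(np.int64), zooms, origin)


def write_mask(mask: RoiMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.labels.astype(np.uint8), ImageVolume(
        mask.labels.astype(float), mask.spacing_mm, mask.origin_mm).affine())
    img.header.set_zooms(mask.spacing_mm)
    nib.save(img, str(path))


def normalize_intensity(
    volume: ImageVolume,
    low: float = DEFAULT_WINDOW[0],
    high: float = DEFAULT_WINDOW[1],
) -> ImageVolume:
    """Clip intensities to a fixed window and map linearly to [0, 1].

    The window is fixed (not per-image min-max) so that normalized
    intensities are comparable across patients; the default −200..300 HU
    window covers the soft-tissue range of contrast-enhanced abdominal CT
    while suppressing extreme values (air, dense bone, metal).
    """
    if low >= high:
        raise ValueError(f"low ({low}) must be < high ({high})")
    clipped = np.clip(volume.values, low, high)
    scaled = (clipped - low) / (high - low)
    return ImageVolume(scaled, volume.spacing_mm, volume.origin_mm, volume.phase)


def resample_isotropic(
    volume: ImageVolume,
    mask: RoiMask,
    target_mm: float = 1.0,
) -> tuple[ImageVolume, RoiMask]:
    """Resample volume and mask to isotropic voxels.

    The image is interpolated trilinearly and the mask by nearest neighbor,
    so the mask stays binary. Raises if the ROI vanishes after resampling.
    """
    if volume.shape != mask.shape:
        raise ValueError("volume and mask shapes differ")
    factors = tuple(s / target_mm for s in volume.spacing_mm)
    if all(abs(f - 1.0) < 1e-9 for f in factors):
        new_vals = volume.values.copy()
        new_labels = mask.labels.copy()
    else:
        new_vals = ndimage.zoom(volume.values.astype(np.float64), factors, order=1)
        new_labels = ndimage.zoom(mask.labels, factors, order=0)
    out_spacing = (target_mm,) * 3
    out_vol = ImageVolume(new_vals, out_spacing, volume.origin_mm, volume.phase)
    out_mask = RoiMask(new_labels, out_spacing, mask.origin_mm)
    if out_mask.voxel_count() == 0:
        raise ValueError("ROI vanished after resampling")
    return out_vol, out_mask
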