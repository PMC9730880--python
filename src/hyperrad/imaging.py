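"""Volume/mask containers, NIfTI IO and the image preprocessing chain.

The preprocessing applied to every lesion before feature extraction is:
resampling to isotropic 2 mm voxels (trilinear), fixed-bin-width intensity
discretization (5 HU for CT anchored at -1000 HU, 0.25 SUV for PET anchored
at 0 SUV), and a minimum-volume filter that drops lesions below 0.5 cc,
evaluated on the original segmentation grid.

Geometry convention: axis-aligned grids, voxel-center coordinates, 0-based
indices, world = origin + index * spacing.  Orientation matrices beyond a
diagonal affine are not supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "LesionVolume",
    "LesionMask",
    "DiscretizedROI",
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "resample_isotropic",
    "resample_mask",
    "discretize",
    "lesion_volume_filter",
    "default_bin_width",
    "default_anchor",
]

#: IBSI-style fixed bin sizes per modality.
DEFAULT_BIN_WIDTH = {"CT": 5.0, "PET": 0.25}
#: Lower edge of bin 1 per modality, fixed so bins align across lesions.
DEFAULT_ANCHOR = {"CT": -1000.0, "PET": 0.0}


def default_bin_width(modality: str) -> float:
    return DEFAULT_BIN_WIDTH[modality]


def default_anchor(modality: str) -> float:
    return DEFAULT_ANCHOR[modality]


@dataclass
class LesionVolume:
    """One modality's 3D intensity grid (HU or SUV) plus geometry."""

    intensities: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    modality: str = "CT"

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.intensities.ndim != 3:
            raise ValueError(f"expected a 3D volume, got ndim={self.intensities.ndim}")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive on every axis")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("volume contains non-finite intensities")
        if self.modality not in ("CT", "PET"):
            raise ValueError(f"unknown modality {self.modality!r}")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))


@dataclass
class LesionMask:
    """Binary 3D lesion region on the same grid as its LesionVolume."""

    voxels: np.ndarray
    spacing_mm: np.ndarray
    origin_mm: np.ndarray
    lesion_id: str = "lesion"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels).astype(bool)
        self.spacing_mm = np.asarray(self.spacing_mm, dtype=float).reshape(3)
        self.origin_mm = np.asarray(self.origin_mm, dtype=float).reshape(3)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D mask, got ndim={self.voxels.ndim}")
        if np.any(self.spacing_mm <= 0):
            raise ValueError("voxel spacing must be positive on every axis")

    @property
    def voxel_volume_mm3(self) -> float:
        return float(np.prod(self.spacing_mm))

    @property
    def volume_mm3(self) -> float:
        return float(self.voxels.sum()) * self.voxel_volume_mm3


@dataclass
class DiscretizedROI:
    """Integer bin indices on the mask grid; 0 marks out-of-mask voxels.

    Bin i covers [anchor + (i-1)*w, anchor + i*w); intensities below the
    anchor clamp to bin 1, so in-mask indices are always >= 1.
    """

    bin_indices: np.ndarray
    bin_width: float
    anchor: float
    mask: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.bin_indices = np.asarray(self.bin_indices, dtype=np.int64)
        if self.mask is None:
            self.mask = self.bin_indices > 0
        self.mask = np.asarray(self.mask).astype(bool)

    @property
    def in_mask_bins(self) -> np.ndarray:
        return self.bin_indices[self.mask]


# ---------------------------------------------------------------------------
# NIfTI IO


def _geometry_from_img(img) -> tuple[np.ndarray, np.ndarray]:
    spacing = np.asarray(img.header.get_zooms()[:3], dtype=float)
    origin = np.asarray(img.affine[:3, 3], dtype=float)
    return spacing, origin


def read_volume(path: str | Path, modality: str = "CT") -> LesionVolume:
    """Read a 3D single-channel NIfTI volume."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    spacing, origin = _geometry_from_img(img)
    return LesionVolume(data.astype(float), spacing, origin, modality)


def write_volume(volume: LesionVolume, path: str | Path) -> None:
    affine = np.diag(np.append(volume.spacing_mm, 1.0))
    affine[:3, 3] = volume.origin_mm
    nib.save(nib.Nifti1Image(volume.intensities.astype(np.float64), affine), str(path))


def read_mask(path: str | Path, lesion_id: str = "lesion") -> LesionMask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise ValueError(f"{path}: expected 3D data, got shape {data.shape}")
    spacing, origin = _geometry_from_img(img)
    return LesionMask(data > 0.5, spacing, origin, lesion_id)


def write_mask(mask: LesionMask, path: str | Path) -> None:
    affine = np.diag(np.append(mask.spacing_mm, 1.0))
    affine[:3, 3] = mask.origin_mm
    nib.save(nib.Nifti1Image(mask.voxels.astype(np.uint8), affine), str(path))


# ---------------------------------------------------------------------------
# Resampling


def _resample_grid(data: np.ndarray, spacing: np.ndarray, target_mm: float,
                   order: int) -> np.ndarray:
    """Trilinear resample onto an isotropic grid sharing the input origin.

    The output grid spans the input physical extent (last voxel center at or
    just past the input's); samples beyond the input edge clamp to the edge.
    """
    shape_out = [
        max(int(math.ceil((n - 1) * s / target_mm)) + 1, 1)
        for n, s in zip(data.shape, spacing)
    ]
    axes = [np.arange(n) * target_mm / s for n, s in zip(shape_out, spacing)]
    coords = np.meshgrid(*axes, indexing="ij")
    return ndimage.map_coordinates(
        data.astype(float), np.array(coords), order=order, mode="nearest"
    )


def resample_isotropic(volume: LesionVolume, target_mm: float = 2.0) -> LesionVolume:
    """Resample a volume to isotropic voxels by trilinear interpolation."""
    out = _resample_grid(volume.intensities, volume.spacing_mm, target_mm, order=1)
    return LesionVolume(out, np.full(3, target_mm), volume.origin_mm.copy(),
                        volume.modality)


def resample_mask(mask: LesionMask, target_mm: float = 2.0) -> LesionMask:
    """Resample a binary mask: trilinear on the 0/1 field, threshold at 0.5."""
    frac = _resample_grid(mask.voxels.astype(float), mask.spacing_mm, target_mm,
                          order=1)
    voxels = frac >= 0.5
    if not voxels.any():
        raise ValueError(f"lesion {mask.lesion_id!r} vanished during resampling")
    return LesionMask(voxels, np.full(3, target_mm), mask.origin_mm.copy(),
                      mask.lesion_id)


# ---------------------------------------------------------------------------
# Discretization and volume filter


def discretize(volume: LesionVolume, mask: LesionMask,
               bin_width: float | None = None,
               anchor: float | None = None) -> DiscretizedROI:
    """Fixed-bin-width discretization of in-mask intensities.

    bin index = floor((x - anchor) / w) + 1, clamped below at 1.
    """
    if volume.intensities.shape != mask.voxels.shape:
        raise ValueError("volume and mask grids differ in shape")
    if not np.allclose(volume.spacing_mm, mask.spacing_mm):
        raise ValueError("volume and mask grids differ in spacing")
    w = default_bin_width(volume.modality) if bin_width is None else float(bin_width)
    a = default_anchor(volume.modality) if anchor is None else float(anchor)
    idx = np.floor((volume.intensities - a) / w).astype(np.int64) + 1
    idx = np.maximum(idx, 1)
    idx[~mask.voxels] = 0
    return DiscretizedROI(idx, w, a, mask.voxels)


def lesion_volume_filter(mask: LesionMask, min_cc: float = 0.5) -> bool:
    """True iff the lesion volume on its native grid is >= ``min_cc`` cm3.

    Applied before resampling; the bound is inclusive (>= keeps).
    """
    return mask.volume_mm3 >= min_cc * 1000.0
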