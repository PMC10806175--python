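"""Volume ingestion, VOI cropping, isotropic resampling and gray-level requantization.

Arrays are indexed ``(z, y, x)`` (the natural axis order of a CT stack read
slice-by-slice); ``spacing`` and ``origin`` triplets are aligned with the
array axes, i.e. ``spacing[0]`` is the slice thickness in mm.  SimpleITK,
which stores geometry in ``(x, y, z)`` order, is used behind this module for
file I/O and resampling; the conversion is confined to the helpers here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import SimpleITK as sitk

__all__ = [
    "CTVolume",
    "VOIMask",
    "QuantizedVolume",
    "GridMismatchError",
    "EmptyMaskError",
    "read_case",
    "write_case",
    "crop_to_voi",
    "resample_isotropic",
    "quantize",
]

#: tolerance (mm) when checking that an image and its mask share a grid
GRID_ATOL = 1e-4

#: voxels of context kept around the VOI bounding box when cropping
DEFAULT_PAD = 8


class GridMismatchError(ValueError):
    """Image and mask do not live on the same voxel grid."""


class EmptyMaskError(ValueError):
    """The VOI mask contains no foreground voxel."""


@dataclass(frozen=True)
class CTVolume:
    """A 3D scalar CT image in Hounsfield units.

    Attributes
    ----------
    values : ndarray
        3D float array, index order ``(z, y, x)``.
    spacing : tuple of float
        Voxel size in mm per array axis.
    origin : tuple of float
        World coordinate (mm) of voxel ``(0, 0, 0)``, per array axis.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError(f"expected a 3D volume, got shape {self.values.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("volume contains non-finite intensities")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def with_values(self, values: np.ndarray) -> "CTVolume":
        """Same grid, different voxel values (e.g. a wavelet subband)."""
        return CTVolume(np.asarray(values, dtype=float), self.spacing, self.origin)


@dataclass(frozen=True)
class VOIMask:
    """Binary volume-of-interest mask on the same grid as its CTVolume."""

    flags: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        if self.flags.ndim != 3:
            raise ValueError(f"expected a 3D mask, got shape {self.flags.shape}")
        vals = np.unique(self.flags)
        if not np.all(np.isin(vals, (0, 1))):
            raise ValueError("mask must be strictly {0, 1}; binarize on read")
        if not self.flags.any():
            raise EmptyMaskError("mask contains no foreground voxel")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.flags.shape

    @property
    def voxel_count(self) -> int:
        return int(self.flags.sum())

    def as_bool(self) -> np.ndarray:
        return self.flags.astype(bool)


@dataclass(frozen=True)
class QuantizedVolume:
    """Gray levels 1..Ng inside the mask (0 outside), fixed bin width.

    ``Ng = floor((max - min) / bin_width) + 1`` with the bin anchor at the
    in-mask minimum, so a shift of all intensities by a constant leaves the
    levels unchanged.
    """

    levels: np.ndarray
    mask: np.ndarray
    bin_width: float
    n_levels: int
    intensity_min: float

    def __post_init__(self) -> None:
        inside = self.levels[self.mask.astype(bool)]
        if inside.size and (inside.min() < 1 or inside.max() > self.n_levels):
            raise ValueError("in-mask levels must lie in [1, Ng]")


# ---------------------------------------------------------------------------
# SimpleITK bridge
# ---------------------------------------------------------------------------

def _to_sitk(values: np.ndarray, spacing, origin) -> sitk.Image:
    img = sitk.GetImageFromArray(np.ascontiguousarray(values))
    img.SetSpacing(tuple(float(s) for s in spacing[::-1]))
    img.SetOrigin(tuple(float(o) for o in origin[::-1]))
    return img


def _from_sitk(img: sitk.Image) -> tuple[np.ndarray, tuple, tuple]:
    arr = sitk.GetArrayFromImage(img)
    spacing = tuple(img.GetSpacing())[::-1]
    origin = tuple(img.GetOrigin())[::-1]
    return arr, spacing, origin


def write_case(image_path, vol: CTVolume, mask_path, mask: VOIMask) -> None:
    """Write an image/mask pair as NIfTI (or any format SimpleITK infers)."""
    sitk.WriteImage(_to_sitk(vol.values.astype(np.float32), vol.spacing, vol.origin),
                    str(image_path))
    sitk.WriteImage(_to_sitk(mask.flags.astype(np.uint8), mask.spacing, mask.origin),
                    str(mask_path))


def read_case(image_path, mask_path) -> tuple[CTVolume, VOIMask]:
    """Read an image and its VOI mask, verifying they share a grid.

    The mask is binarized (> 0 becomes 1).  Raises :class:`GridMismatchError`
    when shapes or spacings differ, :class:`EmptyMaskError` when the mask is
    all background.
    """
    for p in (image_path, mask_path):
        if not Path(p).exists():
            raise FileNotFoundError(p)
    img = sitk.ReadImage(str(image_path), sitk.sitkFloat64)
    msk = sitk.ReadImage(str(mask_path))
    ivals, ispacing, iorigin = _from_sitk(img)
    mvals, mspacing, _ = _from_sitk(msk)
    if ivals.shape != mvals.shape or not np.allclose(ispacing, mspacing, atol=GRID_ATOL):
        raise GridMismatchError(
            f"image grid {ivals.shape}@{ispacing} != mask grid {mvals.shape}@{mspacing}"
        )
    flags = (mvals > 0).astype(np.uint8)
    if not flags.any():
        raise EmptyMaskError(f"mask {mask_path} has no foreground voxel")
    vol = CTVolume(ivals.astype(float), ispacing, iorigin)
    return vol, VOIMask(flags, ispacing, iorigin)


# ---------------------------------------------------------------------------
# Cropping, resampling, quantization
# ---------------------------------------------------------------------------

def crop_to_voi(vol: CTVolume, mask: VOIMask, pad: int = DEFAULT_PAD) -> tuple[CTVolume, VOIMask]:
    """Crop image and mask to the VOI bounding box plus ``pad`` voxels.

    Cropping bounds the wavelet/resampling cost without touching in-mask
    statistics; the pad keeps boundary effects of subsequent filtering away
    from the VOI.
    """
    if vol.shape != mask.shape:
        raise GridMismatchError(f"{vol.shape} != {mask.shape}")
    idx = np.argwhere(mask.flags > 0)
    lo = np.maximum(idx.min(axis=0) - pad, 0)
    hi = np.minimum(idx.max(axis=0) + 1 + pad, mask.shape)
    sl = tuple(slice(int(a), int(b)) for a, b in zip(lo, hi))
    new_origin = tuple(o + s * int(a) for o, s, a in zip(vol.origin, vol.spacing, lo))
    return (
        CTVolume(vol.values[sl].copy(), vol.spacing, new_origin),
        VOIMask(mask.flags[sl].copy(), mask.spacing, new_origin),
    )


def _resample(img: sitk.Image, target: float, interp) -> sitk.Image:
    in_size = np.array(img.GetSize(), dtype=float)
    in_spacing = np.array(img.GetSpacing(), dtype=float)
    # keep every output voxel center inside the input center span so that
    # interpolation never extrapolates past the grid
    out_size = np.maximum(np.floor((in_size - 1) * in_spacing / target) + 1, 1).astype(int)
    return sitk.Resample(
        img,
        [int(n) for n in out_size],
        sitk.Transform(),
        interp,
        img.GetOrigin(),
        (float(target),) * 3,
        img.GetDirection(),
        0.0,
        img.GetPixelID(),
    )


def resample_isotropic(
    vol: CTVolume, mask: VOIMask, target: float = 2.0
) -> tuple[CTVolume, VOIMask]:
    """Resample to an isotropic ``target`` mm grid.

    The image is trilinearly interpolated, the mask with nearest-neighbor;
    the output field of view covers the full input extent (hence the VOI
    bounding box).  Raises when the VOI collapses to zero voxels.
    """
    if target <= 0:
        raise ValueError("target spacing must be positive")
    img = _resample(_to_sitk(vol.values, vol.spacing, vol.origin), target,
                    sitk.sitkLinear)
    msk = _resample(_to_sitk(mask.flags.astype(np.uint8), mask.spacing, mask.origin),
                    target, sitk.sitkNearestNeighbor)
    ivals, ispacing, iorigin = _from_sitk(img)
    mvals, _, _ = _from_sitk(msk)
    if not (mvals > 0).any():
        raise EmptyMaskError(
            f"VOI collapsed to zero voxels at {target} mm resampling"
        )
    return (
        CTVolume(ivals.astype(float), ispacing, iorigin),
        VOIMask((mvals > 0).astype(np.uint8), ispacing, iorigin),
    )


def resample_like_isotropic(values: np.ndarray, ref: CTVolume, target: float = 2.0) -> np.ndarray:
    """Trilinearly resample an array sharing ``ref``'s grid (e.g. a wavelet
    subband) to the isotropic ``target`` grid; returns the array only."""
    img = _resample(_to_sitk(np.asarray(values, dtype=float), ref.spacing, ref.origin),
                    target, sitk.sitkLinear)
    return _from_sitk(img)[0].astype(float)


def quantize(vol: CTVolume, mask: VOIMask, bin_width: float = 25.0) -> QuantizedVolume:
    """Requantize in-mask intensities with a fixed bin width.

    ``level(v) = floor((I(v) - min_in_mask) / bin_width) + 1``; only in-mask
    voxels get a level, background stays 0.  The anchor at the in-mask
    minimum makes the levels invariant to a global intensity shift.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if vol.shape != mask.shape:
        raise GridMismatchError(f"{vol.shape} != {mask.shape}")
    m = mask.as_bool()
    inside = vol.values[m]
    lo = float(inside.min())
    hi = float(inside.max())
    n_levels = int(np.floor((hi - lo) / bin_width)) + 1
    levels = np.zeros(vol.shape, dtype=np.int32)
    levels[m] = np.floor((inside - lo) / bin_width).astype(np.int32) + 1
    # guard the upper edge against float round-off
    np.clip(levels, 0, n_levels, out=levels)
    return QuantizedVolume(levels, mask.flags, float(bin_width), n_levels, lo)
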