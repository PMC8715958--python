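"""Template-space FDG-PET intensity preprocessing.

Spatial normalisation is assumed to have already happened: every volume
lives on the same template grid.  The steps implemented here are the
intensity side of a standard FDG pipeline:

1. pons-referenced SUVr normalisation (:func:`suv_to_suvr`),
2. isotropic Gaussian smoothing specified as FWHM in mm (:func:`smooth`),
3. brain-mask vectorisation with an exact inverse (:func:`apply_mask`).

Masked feature vectors use a fixed scan order — ascending (z, y, x) index,
i.e. row-major over the transposed grid — so that vectors from different
volumes sharing a mask are aligned element-wise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import nibabel as nib
from scipy.ndimage import gaussian_filter

#: FWHM of a Gaussian equals sigma * 2*sqrt(2*ln 2).
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class PreprocessingError(ValueError):
    pass


@dataclass
class BrainVolume:
    """A 3-D intensity grid with its voxel size (mm) and brain mask.

    ``data`` is indexed ``[x, y, z]`` (the nibabel convention); ``mask`` is
    a boolean grid of the same shape.
    """

    data: np.ndarray
    voxel_mm: float
    mask: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 3:
            raise PreprocessingError("volume data must be 3-D")
        if self.data.shape != self.mask.shape:
            raise PreprocessingError(
                f"data shape {self.data.shape} != mask shape {self.mask.shape}"
            )
        if self.voxel_mm <= 0:
            raise PreprocessingError("voxel size must be positive")
        if np.isnan(self.data[self.mask]).any():
            raise PreprocessingError("NaN intensities inside the brain mask")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    def to_nifti(self) -> nib.Nifti1Image:
        affine = np.diag([self.voxel_mm] * 3 + [1.0])
        return nib.Nifti1Image(np.asarray(self.data, dtype=np.float32), affine)

    def save(self, path) -> None:
        nib.save(self.to_nifti(), str(path))

    @classmethod
    def from_nifti(cls, path, mask: np.ndarray | None = None) -> "BrainVolume":
        img = nib.load(str(path))
        data = np.asarray(img.dataobj, dtype=np.float32)
        voxel = float(img.header.get_zooms()[0])
        if mask is None:
            mask = np.ones(data.shape, dtype=bool)
        return cls(data=data, voxel_mm=voxel, mask=mask)


def suv_to_suvr(volume: BrainVolume, pons_mask: np.ndarray) -> BrainVolume:
    """Divide every voxel by the mean uptake over the pons reference region.

    The output pons mean is exactly 1, so the operation is idempotent on
    noise-free data and invariant to global intensity scaling.
    """
    pons_mask = np.asarray(pons_mask, dtype=bool)
    if pons_mask.shape != volume.shape:
        raise PreprocessingError("pons mask shape mismatch")
    if not pons_mask.any():
        raise PreprocessingError("empty pons mask")
    ref = float(volume.data[pons_mask].mean())
    if ref <= 0:
        raise PreprocessingError(f"non-positive pons mean uptake ({ref})")
    return BrainVolume(
        data=volume.data / ref, voxel_mm=volume.voxel_mm, mask=volume.mask
    )


def smooth(volume: BrainVolume, fwhm_mm: float = 8.0) -> BrainVolume:
    """Separable Gaussian smoothing with reflect boundary handling.

    ``fwhm_mm`` is converted to a per-axis sigma in voxel units,
    ``sigma = fwhm / (2 sqrt(2 ln 2)) / voxel_mm``.  ``fwhm_mm = 0`` is the
    identity.
    """
    if fwhm_mm < 0:
        raise PreprocessingError("FWHM must be non-negative")
    if fwhm_mm == 0:
        return BrainVolume(
            data=volume.data.copy(), voxel_mm=volume.voxel_mm, mask=volume.mask
        )
    sigma_vox = fwhm_mm / FWHM_PER_SIGMA / volume.voxel_mm
    out = gaussian_filter(
        np.asarray(volume.data, dtype=np.float64), sigma=sigma_vox, mode="reflect"
    )
    return BrainVolume(
        data=out.astype(volume.data.dtype, copy=False),
        voxel_mm=volume.voxel_mm,
        mask=volume.mask,
    )


@dataclass(frozen=True)
class MaskIndex:
    """Index map from an in-mask feature vector back to grid positions.

    ``flat`` holds positions into the (z, y, x)-transposed, raveled grid,
    in ascending order; this fixes the scan order of every vector drawn
    with the same mask.
    """

    shape: tuple[int, int, int]
    flat: np.ndarray

    def to_volume(self, vector: np.ndarray, fill: float = 0.0) -> np.ndarray:
        vector = np.asarray(vector)
        if vector.shape != self.flat.shape:
            raise PreprocessingError("vector length does not match index map")
        zyx = np.full(int(np.prod(self.shape)), fill, dtype=vector.dtype)
        zyx[self.flat] = vector
        nz, ny, nx = self.shape[2], self.shape[1], self.shape[0]
        return zyx.reshape(nz, ny, nx).transpose(2, 1, 0)


def apply_mask(volume: BrainVolume) -> tuple[np.ndarray, MaskIndex]:
    """Extract in-mask voxels as a vector in ascending (z, y, x) order."""
    if not volume.mask.any():
        raise PreprocessingError("empty brain mask")
    mask_t = volume.mask.transpose(2, 1, 0)
    flat = np.flatnonzero(mask_t.ravel())
    vector = volume.data.transpose(2, 1, 0).ravel()[flat]
    return vector, MaskIndex(shape=volume.shape, flat=flat)
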