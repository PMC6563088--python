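"""Preprocessing of slab-structured ASE acquisitions.

Order of operations is fixed (and logged by the pipeline): sub-slice
collapse -> brain masking -> in-plane smoothing.  Motion correction and
registration are out of scope; inputs are assumed co-registered and the
motion score travels as metadata only.
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "collapse_subslices",
    "smooth_inplane",
    "brain_mask_from_spin_echo",
    "fwhm_to_sigma",
]

log = logging.getLogger(__name__)

#: FWHM = 2*sqrt(2*ln 2) * sigma for a Gaussian.
FWHM_FACTOR = 2.0 * np.sqrt(2.0 * np.log(2.0))


def fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / FWHM_FACTOR


def collapse_subslices(data: np.ndarray, subslice_count: int = 4,
                       slice_axis: int = 2) -> np.ndarray:
    """Average groups of thin sub-slices into full slices.

    The reference acquisition oversamples each 5 mm slab as four 1.25 mm
    sub-slices; averaging them restores one 5 mm slice per slab.  The slice
    axis length must be an exact multiple of ``subslice_count``.
    """
    data = np.asarray(data)
    n = data.shape[slice_axis]
    if subslice_count < 1 or n % subslice_count:
        raise ValueError(
            f"slice axis length {n} is not a multiple of the sub-slice "
            f"count {subslice_count}")
    moved = np.moveaxis(data, slice_axis, 0)
    collapsed = moved.reshape(n // subslice_count, subslice_count,
                              *moved.shape[1:]).mean(axis=1)
    return np.moveaxis(collapsed, 0, slice_axis)


def smooth_inplane(data: np.ndarray, fwhm_mm: float,
                   voxel_size_mm=(2.3, 2.3, 5.0)) -> np.ndarray:
    """2D Gaussian smoothing within each slice (axes 0 and 1).

    No through-slice smoothing is applied: the FWHM is matched to the
    in-plane resolution and slices are thick slabs that must not mix.
    Reflection padding at the boundary; the kernel is normalised, so a
    constant image is unchanged.  Works on 3D volumes or 4D tau-series
    (each tau volume smoothed independently).
    """
    data = np.asarray(data, dtype=float)
    if fwhm_mm <= 0:
        raise ValueError("fwhm_mm must be > 0")
    sigma_mm = fwhm_to_sigma(fwhm_mm)
    sigma_vox = (sigma_mm / voxel_size_mm[0], sigma_mm / voxel_size_mm[1])
    if max(sigma_vox) * FWHM_FACTOR < 0.1:
        warnings.warn("smoothing FWHM below 0.1 voxel; returning input unchanged")
        return data.copy()
    sigma = [sigma_vox[0], sigma_vox[1]] + [0.0] * (data.ndim - 2)
    return ndimage.gaussian_filter(data, sigma=sigma, mode="reflect")


def brain_mask_from_spin_echo(spin_echo: np.ndarray,
                              fraction: float = 0.1) -> np.ndarray:
    """Binary brain mask by intensity thresholding of the spin-echo volume.

    Threshold at ``fraction`` times the robust maximum (98th percentile),
    keep the largest 3D connected component (26-connectivity) and fill
    internal holes slice by slice.  A heuristic stand-in for a full brain
    extraction tool, adequate for phantoms and pre-masked data.
    """
    if not 0 < fraction < 1:
        raise ValueError("fraction must be in (0, 1)")
    spin_echo = np.asarray(spin_echo, dtype=float)
    robust_max = np.percentile(spin_echo, 98)
    mask = spin_echo > fraction * robust_max
    if not mask.any():
        raise ValueError("brain mask is empty after thresholding")
    labels = measure.label(mask, connectivity=3)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    mask = labels == counts.argmax()
    for z in range(mask.shape[2]):
        mask[:, :, z] = ndimage.binary_fill_holes(mask[:, :, z])
    log.info("brain mask: %d voxels", int(mask.sum()))
    return mask
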