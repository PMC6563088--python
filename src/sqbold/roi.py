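"""Tissue-outcome regions of interest for acute ischaemic stroke.

The presenting lesion is segmented by thresholding the apparent diffusion
coefficient (ADC) map at 620e-6 mm^2/s, cleaned by cluster selection,
light Gaussian smoothing and repeat clustering.  Combining it with the
final-infarct mask yields the three tissue outcomes:

  core          -- presenting ADC lesion AND final infarct (non-viable),
  growth        -- final infarct NOT in the presenting lesion,
  contralateral -- composite (presenting OR final) mirrored across the
                   midline, the subject's internal reference.

Mirroring is a grid flip about the centre plane of the midline axis; inputs
are assumed midsagittally aligned (template registration is out of scope).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage import measure

__all__ = [
    "LesionMask",
    "TissueOutcomeSet",
    "ADC_THRESHOLD",
    "adc_lesion_mask",
    "mirror_mask",
    "tissue_outcomes",
    "largest_component",
]

log = logging.getLogger(__name__)

#: ADC threshold marking acute ischaemic injury (mm^2/s).
ADC_THRESHOLD = 620e-6


class NoLesionError(ValueError):
    """Raised when the ADC threshold yields no lesion voxels."""


@dataclass
class LesionMask:
    mask: np.ndarray
    source: str                      # "adc_presenting" or "final_infarct"
    threshold_used: float | None = None
    stage_counts: dict = field(default_factory=dict)


@dataclass
class TissueOutcomeSet:
    core: np.ndarray
    growth: np.ndarray
    contralateral: np.ndarray
    voxel_counts: dict = field(default_factory=dict)

    def masks(self) -> dict:
        return {"core": self.core, "growth": self.growth,
                "contralateral": self.contralateral}


def largest_component(mask: np.ndarray, connectivity: int = 3) -> np.ndarray:
    """Largest 3D connected component (connectivity 3 = 26 neighbours)."""
    labels = measure.label(np.asarray(mask).astype(bool),
                           connectivity=connectivity)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    if counts.max() == 0:
        raise NoLesionError("no foreground voxels")
    return labels == counts.argmax()


def adc_lesion_mask(adc_map: np.ndarray, threshold: float = ADC_THRESHOLD,
                    smooth_sigma_mm: float = 1.0,
                    voxel_size_mm=(2.3, 2.3, 5.0),
                    connectivity: int = 3) -> LesionMask:
    """Presenting-lesion mask from an ADC map.

    Steps: (1) binarise adc < threshold; (2) keep the largest connected
    component; (3) Gaussian-smooth the binary mask (sigma in mm, converted
    per axis to voxels); (4) re-binarise at 0.5 (the half-maximum contour);
    (5) keep the largest component again.  The small smoothing pass removes
    isolated noisy voxels and sharpens specificity to the lesion.
    """
    adc_map = np.asarray(adc_map, dtype=float)
    if threshold <= 0:
        raise ValueError("threshold must be > 0")
    counts = {}
    raw = adc_map < threshold
    counts["thresholded"] = int(raw.sum())
    if not raw.any():
        raise NoLesionError(
            f"no voxels below ADC threshold {threshold:g} mm^2/s")
    clustered = largest_component(raw, connectivity)
    counts["largest_cluster"] = int(clustered.sum())
    sigma_vox = [smooth_sigma_mm / v for v in voxel_size_mm]
    smoothed = ndimage.gaussian_filter(clustered.astype(float),
                                       sigma=sigma_vox, mode="constant")
    rebinarised = smoothed > 0.5
    counts["rebinarised"] = int(rebinarised.sum())
    if not rebinarised.any():
        raise NoLesionError("lesion vanished after smoothing/re-binarisation")
    final = largest_component(rebinarised, connectivity)
    counts["final"] = int(final.sum())
    log.info("ADC lesion stages: %s", counts)
    return LesionMask(mask=final, source="adc_presenting",
                      threshold_used=threshold, stage_counts=counts)


def mirror_mask(mask: np.ndarray, midline_axis: int = 0) -> np.ndarray:
    """Mirror a mask across the grid centre plane of ``midline_axis``.

    Index x maps to (W-1-x); an involution.  Exact for midsagittally
    symmetric grids (the phantom generator guarantees this).
    """
    return np.flip(np.asarray(mask), axis=midline_axis)


def tissue_outcomes(presenting: LesionMask | np.ndarray,
                    final: LesionMask | np.ndarray,
                    midline_axis: int = 0) -> TissueOutcomeSet:
    """Partition the final infarct into core and growth; mirror the composite.

    core = presenting AND final; growth = final AND NOT presenting;
    contralateral = mirror(presenting OR final).  By construction
    |core| + |growth| = |final|.
    """
    pres = (presenting.mask if isinstance(presenting, LesionMask)
            else np.asarray(presenting)).astype(bool)
    fin = (final.mask if isinstance(final, LesionMask)
           else np.asarray(final)).astype(bool)
    if pres.shape != fin.shape:
        raise ValueError(
            f"presenting grid {pres.shape} != final grid {fin.shape}")
    if not fin.any():
        raise ValueError("final infarct mask is empty")
    core = pres & fin
    growth = fin & ~pres
    contralateral = mirror_mask(pres | fin, midline_axis)
    counts = {"presenting": int(pres.sum()), "final": int(fin.sum()),
              "core": int(core.sum()), "growth": int(growth.sum()),
              "contralateral": int(contralateral.sum())}
    log.info("tissue outcomes: %s", counts)
    return TissueOutcomeSet(core=core, growth=growth,
                            contralateral=contralateral, voxel_counts=counts)
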