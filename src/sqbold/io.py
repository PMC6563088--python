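"""NIfTI and sidecar I/O.

All internal indexing is 0-based; affines carry world coordinates and are
never used to resample — a grid mismatch between paired inputs is always an
error, since cross-modal registration is out of scope and inputs must
arrive co-registered.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import nibabel as nib
import numpy as np

from .fitting import TauSeriesVolume

__all__ = [
    "read_volume",
    "write_volume",
    "read_mask",
    "write_mask",
    "read_tau_sidecar",
    "write_tau_sidecar",
    "load_tau_series",
    "save_tau_series",
    "check_same_grid",
]


def read_volume(path):
    """Read a NIfTI volume; returns (float data, affine)."""
    img = nib.load(str(path))
    return np.asarray(img.get_fdata(), dtype=float), img.affine


def write_volume(data, path, affine=None, dtype=np.float32) -> None:
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(np.asarray(data, dtype=dtype), affine)
    nib.save(img, str(path))


def read_mask(path):
    """Read a binary mask; values {0, 255} are normalised with a warning."""
    data, affine = read_volume(path)
    values = set(np.unique(data).tolist())
    if values <= {0.0, 255.0} and 255.0 in values:
        warnings.warn(f"{path}: mask uses {{0, 255}}; normalising to {{0, 1}}")
        data = data / 255.0
    elif not values <= {0.0, 1.0}:
        raise ValueError(f"{path}: mask values {sorted(values)[:5]}... "
                         "are not binary")
    return data.astype(bool), affine


def write_mask(mask, path, affine=None) -> None:
    write_volume(np.asarray(mask).astype(np.uint8), path, affine,
                 dtype=np.uint8)


def read_tau_sidecar(path) -> dict:
    with open(path) as fh:
        sidecar = json.load(fh)
    if "tau_values_s" not in sidecar:
        raise ValueError(f"{path}: sidecar is missing 'tau_values_s'")
    return sidecar


def write_tau_sidecar(path, tau_values, te: float = 0.082,
                      **metadata) -> None:
    payload = {"tau_values_s": [float(t) for t in tau_values],
               "te_s": te, **metadata}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def load_tau_series(nifti_path, sidecar_path) -> TauSeriesVolume:
    """Load a 4D tau-series and its JSON sidecar, validating lengths."""
    data, affine = read_volume(nifti_path)
    sidecar = read_tau_sidecar(sidecar_path)
    taus = sidecar["tau_values_s"]
    if data.ndim != 4 or data.shape[3] != len(taus):
        raise ValueError(
            f"{nifti_path}: volume has shape {data.shape} but the sidecar "
            f"lists {len(taus)} tau values")
    hdr = nib.load(str(nifti_path)).header
    zooms = hdr.get_zooms()[:3]
    meta = {k: v for k, v in sidecar.items() if k != "tau_values_s"}
    meta["affine"] = affine
    return TauSeriesVolume(data=data, tau_values=taus,
                           voxel_size=tuple(float(z) for z in zooms),
                           metadata=meta)


def save_tau_series(volume: TauSeriesVolume, nifti_path, sidecar_path,
                    affine=None) -> None:
    affine_mat = np.eye(4)
    affine_mat[0, 0], affine_mat[1, 1], affine_mat[2, 2] = volume.voxel_size
    write_volume(volume.data, nifti_path,
                 affine if affine is not None else affine_mat)
    meta = {k: v for k, v in volume.metadata.items() if k != "affine"}
    write_tau_sidecar(sidecar_path, volume.tau_values,
                      te=meta.pop("te_s", 0.082), **meta)


def check_same_grid(name_a: str, shape_a, name_b: str, shape_b) -> None:
    if tuple(shape_a) != tuple(shape_b):
        raise ValueError(
            f"grid mismatch: {name_a} has grid {tuple(shape_a)} but "
            f"{name_b} has grid {tuple(shape_b)}; inputs must be "
            "co-registered on one grid")
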