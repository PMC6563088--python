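"""Voxel-wise weighted least-squares estimation of DBV, R2' and [dHb].

The long-tau log-signal is linear in the three unknowns (DBV, R2',
log S0 - TE*R2), so each voxel reduces to a small weighted linear system

    A x = b,   A row for tau=0:  (0, 0, 1)
               A row for tau_i:  (1, -tau_i, 1)

solved in closed form.  Standard deviations come from the estimator
covariance sigma^2 (A' W A)^-1 with the residual variance estimated on
n - 3 degrees of freedom.  Estimates are NOT clamped to physical ranges;
downstream medians include negative excursions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .model import (
    AcquisitionProtocol,
    PhysioConstants,
    VoxelParams,
    dhb_from_ratio,
    propagate_dhb_std,
)

__all__ = [
    "TauSeriesVolume",
    "ParameterMaps",
    "select_fit_taus",
    "build_design",
    "fit_weights",
    "fit_voxel",
    "fit_volume",
]

log = logging.getLogger(__name__)

WEIGHT_SCHEMES = ("inverse_tau", "uniform")


@dataclass
class TauSeriesVolume:
    """A 4D ASE tau-series on a regular grid.

    data has shape (x, y, z, n_tau) matching tau_values (s).  metadata
    carries subject id, time point and the motion score, which is input
    metadata only (motion correction itself is out of scope).
    """

    data: np.ndarray
    tau_values: tuple
    voxel_size: tuple = (2.3, 2.3, 5.0)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.tau_values = tuple(float(t) for t in self.tau_values)
        if self.data.ndim != 4:
            raise ValueError(f"expected 4D data, got shape {self.data.shape}")
        if self.data.shape[3] != len(self.tau_values):
            raise ValueError(
                f"4th dimension ({self.data.shape[3]}) does not match "
                f"tau schedule length ({len(self.tau_values)})"
            )


@dataclass
class ParameterMaps:
    """Voxel-wise sqBOLD parameter maps on the tau-series grid.

    All maps are float arrays defined on mask voxels; elsewhere (and at
    failed voxels) they carry NaN.  dbv is a fraction here; CSV reporting
    converts to percent.
    """

    r2p: np.ndarray
    dbv: np.ndarray
    dhb: np.ndarray
    r2p_std: np.ndarray
    dbv_std: np.ndarray
    dhb_std: np.ndarray
    intercept: np.ndarray
    mask: np.ndarray
    fit_report: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "r2p": self.r2p, "dbv": self.dbv, "dhb": self.dhb,
            "r2p_std": self.r2p_std, "dbv_std": self.dbv_std,
            "dhb_std": self.dhb_std, "intercept": self.intercept,
        }


def select_fit_taus(protocol: AcquisitionProtocol):
    """Indices of the fit rows: the spin echo and the ascending long taus.

    Negative-tau and short-tau (e.g. 8 ms) volumes are excluded: only the
    spin echo and the mono-exponential regime enter the linear model.
    """
    taus = np.asarray(protocol.tau_values)
    se = int(np.flatnonzero(taus == 0.0)[0])
    long_idx = np.flatnonzero(taus > protocol.fit_tau_min)
    long_idx = long_idx[np.argsort(taus[long_idx])]
    if 1 + long_idx.size < 3:
        raise ValueError("fewer than 3 usable rows: fit is underdetermined")
    return se, [int(i) for i in long_idx]


def build_design(long_taus) -> np.ndarray:
    """Design matrix over (DBV, R2', intercept).

    First row is the spin echo (insensitive to DBV and R2'); each long-tau
    row is (1, -tau, 1).
    """
    long_taus = np.asarray(long_taus, dtype=float)
    if long_taus.size == 0:
        raise ValueError("long_taus must be non-empty")
    n = long_taus.size
    design = np.empty((n + 1, 3))
    design[0] = (0.0, 0.0, 1.0)
    design[1:, 0] = 1.0
    design[1:, 1] = -long_taus
    design[1:, 2] = 1.0
    return design


def fit_weights(taus, scheme: str = "inverse_tau") -> np.ndarray:
    """Per-row fit weights, normalised to mean 1.

    ``inverse_tau`` down-weights long taus as 1/tau (later echoes carry more
    noise after more decay); the tau=0 row, where 1/tau is undefined, gets
    the largest long-tau weight.  ``uniform`` is ordinary least squares.
    """
    taus = np.asarray(taus, dtype=float)
    if scheme == "uniform":
        return np.ones_like(taus)
    if scheme != "inverse_tau":
        raise ValueError(f"unknown weight scheme {scheme!r}; "
                         f"expected one of {WEIGHT_SCHEMES}")
    pos = taus[taus > 0]
    if pos.size == 0:
        raise ValueError("inverse_tau weighting needs at least one tau > 0")
    w = np.where(taus > 0, 1.0 / np.where(taus > 0, taus, 1.0), 1.0 / pos.min())
    return w / w.mean()


def _wls(log_signals: np.ndarray, design: np.ndarray, weights: np.ndarray):
    """Batch WLS solve.  log_signals: (..., n).  Returns (x, std, ok)."""
    sw = np.sqrt(weights)
    aw = design * sw[:, None]
    gram = aw.T @ aw
    if np.linalg.matrix_rank(design) < 3:
        raise np.linalg.LinAlgError("design matrix is rank deficient")
    gram_inv = np.linalg.inv(gram)
    solver = gram_inv @ aw.T                       # (3, n), maps sw*b -> x
    x = (log_signals * sw) @ solver.T              # (..., 3)
    resid = log_signals - x @ design.T
    rss_w = np.sum(weights * resid**2, axis=-1)
    dof = design.shape[0] - 3
    if dof > 0:
        sigma2 = rss_w / dof
    else:
        sigma2 = np.full_like(rss_w, np.nan)
    std = np.sqrt(sigma2[..., None] * np.diag(gram_inv))
    return x, std


def fit_voxel(log_signals, design, weights,
              constants: PhysioConstants | None = None) -> VoxelParams:
    """Weighted least-squares fit of one voxel's fit-row log-signals.

    Returns a :class:`VoxelParams`; a singular system or non-finite input
    marks the voxel missing (all-NaN) rather than raising, so map-level
    loops can continue.
    """
    log_signals = np.asarray(log_signals, dtype=float)
    design = np.asarray(design, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if not (log_signals.shape[0] == design.shape[0] == weights.shape[0]):
        raise ValueError("log_signals, design and weights disagree in length")
    if not np.all(np.isfinite(log_signals)):
        return VoxelParams()
    try:
        x, std = _wls(log_signals, design, weights)
    except np.linalg.LinAlgError:
        return VoxelParams()
    dbv, r2p, intercept = (float(v) for v in x)
    dbv_std, r2p_std, _ = (float(v) for v in std)
    params = VoxelParams(r2p=r2p, dbv=dbv, s0_attenuated=intercept,
                         r2p_std=r2p_std, dbv_std=dbv_std)
    if constants is not None:
        params.dhb = dhb_from_ratio(r2p, dbv, constants)
        params.dhb_std = propagate_dhb_std(r2p, r2p_std, dbv, dbv_std, constants)
    return params


def fit_volume(volume: TauSeriesVolume, mask: np.ndarray,
               protocol: AcquisitionProtocol | None = None,
               constants: PhysioConstants | None = None,
               weight_scheme: str = "inverse_tau") -> ParameterMaps:
    """Fit every mask voxel of a tau-series volume (vectorised).

    Voxels with any non-positive or non-finite signal among the fit rows are
    excluded (the log is undefined) and reported in the fit report, together
    with the weight scheme and an echo of the protocol.
    """
    protocol = protocol or AcquisitionProtocol(
        tau_values=volume.tau_values if 0.0 in volume.tau_values
        else AcquisitionProtocol().tau_values)
    constants = constants or PhysioConstants()
    mask = np.asarray(mask).astype(bool)
    if mask.shape != volume.data.shape[:3]:
        raise ValueError(
            f"mask grid {mask.shape} does not match volume grid "
            f"{volume.data.shape[:3]}")
    if not mask.any():
        raise ValueError("empty brain mask")
    if tuple(volume.tau_values) != tuple(protocol.tau_values):
        protocol = AcquisitionProtocol(
            tau_values=volume.tau_values, te=protocol.te, tr=protocol.tr,
            voxel_size=protocol.voxel_size, fit_tau_min=protocol.fit_tau_min)

    se, long_idx = select_fit_taus(protocol)
    rows = [se] + long_idx
    taus = np.asarray(protocol.tau_values)[rows]
    design = build_design(taus[1:])
    weights = fit_weights(taus, weight_scheme)

    signals = volume.data[..., rows][mask]          # (V, n)
    valid = np.all(np.isfinite(signals) & (signals > 0), axis=1)
    x = np.full((signals.shape[0], 3), np.nan)
    std = np.full((signals.shape[0], 3), np.nan)
    if valid.any():
        x[valid], std[valid] = _wls(np.log(signals[valid]), design, weights)

    shape = mask.shape
    maps = {}
    for j, name in enumerate(("dbv", "r2p", "intercept")):
        m = np.full(shape, np.nan)
        m[mask] = x[:, j]
        maps[name] = m
    for j, name in enumerate(("dbv_std", "r2p_std", "intercept_std")):
        m = np.full(shape, np.nan)
        m[mask] = std[:, j]
        maps[name] = m

    dhb = dhb_from_ratio(maps["r2p"], maps["dbv"], constants)
    dhb_std = propagate_dhb_std(maps["r2p"], maps["r2p_std"],
                                maps["dbv"], maps["dbv_std"], constants)

    n_failed = int(np.count_nonzero(~valid))
    if n_failed == signals.shape[0]:
        raise ValueError("all mask voxels failed to fit")
    report = {
        "n_mask_voxels": int(mask.sum()),
        "n_failed_voxels": n_failed,
        "weight_scheme": weight_scheme,
        "fit_taus_s": [float(t) for t in taus],
        "te_s": protocol.te,
        "fit_tau_min_s": protocol.fit_tau_min,
        "motion_score": volume.metadata.get("motion_score"),
    }
    log.info("fit_volume: %d voxels fitted, %d failed",
             report["n_mask_voxels"] - n_failed, n_failed)
    return ParameterMaps(
        r2p=maps["r2p"], dbv=maps["dbv"], dhb=dhb,
        r2p_std=maps["r2p_std"], dbv_std=maps["dbv_std"], dhb_std=dhb_std,
        intercept=maps["intercept"], mask=mask, fit_report=report)
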