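"""Physical model for streamlined qBOLD (sqBOLD) relaxometry.

The signal of an asymmetric spin-echo (ASE) acquisition decays with the
spin-echo displacement time tau.  In the long-tau regime (tau > ~15 ms) the
log-signal is linear in tau with slope -R2', and the offset between the
measured spin echo (tau = 0) and the extrapolated long-tau intercept equals
the deoxygenated blood volume fraction (DBV):

    log S(0)   = log S0 - TE * R2
    log S(tau) = log S0 - TE * R2 + DBV - R2' * tau      (tau > tau_min)

The deoxyhaemoglobin concentration [dHb] follows from the static-dephasing
relation  delta_omega = (4/3) * pi * gamma * dchi0 * kappa * [dHb] * B0  and
R2' = DBV * delta_omega, i.e. [dHb] is proportional to the ratio R2'/DBV and
requires no haematocrit assumption.

The short-tau (quadratic) qBOLD regime is deliberately not modelled; the fit
uses only the spin echo and the mono-exponential long-tau points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "PhysioConstants",
    "AcquisitionProtocol",
    "VoxelParams",
    "UnsupportedTauError",
    "dhb_from_ratio",
    "forward_log_signal",
    "forward_signal",
    "propagate_dhb_std",
    "long_tau_log_signal",
]


class UnsupportedTauError(ValueError):
    """Raised when a signal value is requested in the short-tau regime.

    The two-regime linear model only describes tau = 0 and tau > fit_tau_min;
    0 < tau <= fit_tau_min falls in the quadratic regime that this package
    does not implement.
    """


@dataclass(frozen=True)
class PhysioConstants:
    """Physical constants entering the [dHb] relation.

    delta_chi0
        Susceptibility difference between fully deoxygenated and fully
        oxygenated red blood cells (dimensionless, CGS convention).
    kappa
        Haemoglobin-concentration scaling constant (per g/dL convention).
    gamma
        Proton gyromagnetic ratio (rad s^-1 T^-1).
    b0
        Main magnetic field strength (T).
    """

    delta_chi0: float = 0.264e-6
    kappa: float = 0.03
    gamma: float = 2.675e8
    b0: float = 3.0

    def __post_init__(self) -> None:
        for name in ("delta_chi0", "kappa", "gamma", "b0"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be strictly positive")

    @property
    def dhb_coefficient(self) -> float:
        """k = (4/3)*pi*gamma*dchi0*kappa*B0, in s^-1 per (g/dL).

        With the default constants k ~= 26.6 s^-1 per g/dL, so that
        [dHb] = (R2'/DBV) / k.
        """
        return (4.0 / 3.0) * math.pi * self.gamma * self.delta_chi0 * self.kappa * self.b0


#: Spin-echo displacement times used in the reference protocol (s): the spin
#: echo plus the seven long-tau samples 16..64 ms.
DEFAULT_FIT_TAUS = (0.0, 0.016, 0.024, 0.032, 0.040, 0.048, 0.056, 0.064)

#: Full acquisition schedule tau_start/tau_finish/dtau = -16/64/8 ms.  The
#: negative-tau and 8 ms volumes are acquired but never fitted.
ACQUISITION_TAUS = (-0.016, -0.008, 0.0, 0.008, 0.016, 0.024, 0.032,
                    0.040, 0.048, 0.056, 0.064)


@dataclass(frozen=True)
class AcquisitionProtocol:
    """ASE acquisition timing and geometry.

    tau_values are in seconds and must contain 0 exactly once; fit_tau_min
    is the lower edge of the mono-exponential regime (values at or below it,
    other than tau = 0, are excluded from the fit).
    """

    tau_values: tuple = DEFAULT_FIT_TAUS
    te: float = 0.082
    tr: float = 3.0
    voxel_size: tuple = (2.3, 2.3, 5.0)
    fit_tau_min: float = 0.015

    def __post_init__(self) -> None:
        taus = tuple(float(t) for t in self.tau_values)
        object.__setattr__(self, "tau_values", taus)
        if self.fit_tau_min <= 0:
            raise ValueError("fit_tau_min must be > 0")
        if sum(1 for t in taus if t == 0.0) != 1:
            raise ValueError("tau_values must contain 0 exactly once")
        if sum(1 for t in taus if t > self.fit_tau_min) < 2:
            raise ValueError(
                "need at least 2 tau values above fit_tau_min "
                "(the fit has 3 unknowns)"
            )

    @property
    def long_taus(self) -> tuple:
        """Tau values in the mono-exponential regime, ascending."""
        return tuple(sorted(t for t in self.tau_values if t > self.fit_tau_min))


@dataclass
class VoxelParams:
    """Per-voxel sqBOLD parameter estimates and their standard deviations.

    s0_attenuated holds log S0 - TE*R2 (the spin-echo log-amplitude); dbv is
    a fraction (reported as % downstream); dhb is in g/dL.
    """

    r2p: float = np.nan
    dbv: float = np.nan
    dhb: float = np.nan
    s0_attenuated: float = np.nan
    r2p_std: float = np.nan
    dbv_std: float = np.nan
    dhb_std: float = np.nan

    def is_missing(self) -> bool:
        return not (np.isfinite(self.r2p) and np.isfinite(self.dbv))


def dhb_from_ratio(r2p, dbv, constants: PhysioConstants | None = None):
    """Deoxyhaemoglobin concentration (g/dL) from R2' (s^-1) and DBV (fraction).

    [dHb] = (R2'/DBV) / k with k = (4/3)*pi*gamma*dchi0*kappa*B0.  Vectorised;
    voxels with dbv <= 0 (or non-finite inputs) are returned as NaN rather
    than raising, so whole maps can be converted in one call.
    """
    constants = constants or PhysioConstants()
    r2p = np.asarray(r2p, dtype=float)
    dbv = np.asarray(dbv, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(dbv > 0, (r2p / dbv) / constants.dhb_coefficient, np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def long_tau_log_signal(tau, dbv, r2p, s0_attenuated):
    """Mono-exponential-regime log-signal, evaluated without the regime guard.

    Used by the phantom generator to fill format-realism volumes (negative
    and 8 ms taus) with the model at |tau|; fitting code never consumes these.
    """
    tau = np.asarray(tau, dtype=float)
    return s0_attenuated + dbv - r2p * tau


def forward_log_signal(dbv, r2p, s0_attenuated,
                       protocol: AcquisitionProtocol | None = None,
                       taus=None):
    """Log-signal at each requested tau under the two-regime linear model.

    log S(0) = s0_attenuated; log S(tau) = s0_attenuated + dbv - r2p*tau for
    tau > fit_tau_min.  Requests in the short-tau band (0, fit_tau_min] raise
    :class:`UnsupportedTauError`.
    """
    protocol = protocol or AcquisitionProtocol()
    if taus is None:
        taus = protocol.tau_values
    taus = np.atleast_1d(np.asarray(taus, dtype=float))
    bad = (taus != 0.0) & (taus <= protocol.fit_tau_min)
    if np.any(bad):
        raise UnsupportedTauError(
            f"tau values {taus[bad].tolist()} fall in the unmodelled "
            f"short-tau regime (0, {protocol.fit_tau_min}]"
        )
    out = np.where(taus == 0.0, s0_attenuated,
                   long_tau_log_signal(taus, dbv, r2p, s0_attenuated))
    return out


def forward_signal(params: VoxelParams, protocol: AcquisitionProtocol | None = None,
                   taus=None):
    """Linear-scale signal S(tau) for a voxel (arbitrary units)."""
    return np.exp(forward_log_signal(params.dbv, params.r2p,
                                     params.s0_attenuated, protocol, taus))


def propagate_dhb_std(r2p, r2p_std, dbv, dbv_std,
                      constants: PhysioConstants | None = None):
    """First-order error propagation for the ratio-based [dHb] estimate.

    Treats the R2' and DBV errors as independent:
    dhb_std = |dhb| * sqrt((r2p_std/r2p)^2 + (dbv_std/dbv)^2).
    Voxels with non-positive r2p or dbv propagate as NaN.
    """
    constants = constants or PhysioConstants()
    r2p = np.asarray(r2p, dtype=float)
    dbv = np.asarray(dbv, dtype=float)
    r2p_std = np.asarray(r2p_std, dtype=float)
    dbv_std = np.asarray(dbv_std, dtype=float)
    dhb = dhb_from_ratio(r2p, dbv, constants)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.sqrt((r2p_std / r2p) ** 2 + (dbv_std / dbv) ** 2)
        out = np.where((r2p > 0) & (dbv > 0), np.abs(dhb) * rel, np.nan)
    if out.ndim == 0:
        return float(out)
    return out
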