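"""Synthetic stroke phantoms with known ground truth.

A phantom is a brain-like ellipsoidal support on a regular grid, built
midsagittally symmetric so that grid-flip mirroring is exact, containing
four tissue classes:

  normal  -- healthy tissue (contralateral reference values),
  core    -- the presenting ischaemic lesion (ADC below threshold),
  growth  -- the shell of the final infarct outside the presenting lesion,
  csf     -- two symmetric ventricles (FLAIR-nulled signal).

Each class carries true R2', DBV, S0, R2, ADC and CBF; the tau-series is
simulated from the two-regime log-linear signal model with magnitude noise
at a stated spin-echo SNR.  Core geometry is strictly inside the final
infarct, and the core-class ADC is the only one below the 620e-6 mm^2/s
threshold, so ADC segmentation recovers the core geometry exactly when ADC
noise is disabled (the default).

Geometry is specified in fractions of the grid, so phantoms scale to any
grid size; all randomness flows from a single integer seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .datasets import cohort_variance_decomposition
from .model import (
    AcquisitionProtocol,
    ACQUISITION_TAUS,
    PhysioConstants,
    dhb_from_ratio,
    long_tau_log_signal,
)
from .fitting import TauSeriesVolume

__all__ = [
    "TissueClass",
    "PhantomSpec",
    "PhantomTruth",
    "DEFAULT_CLASSES",
    "generate_phantom",
    "simulate_tau_series",
    "inject_csf_failure",
    "simulate_cbf_map",
    "cohort_specs",
]

LABELS = {"background": 0, "normal": 1, "core": 2, "growth": 3, "csf": 4}


@dataclass(frozen=True)
class TissueClass:
    """Ground-truth parameters of one tissue class.

    r2p in s^-1, dbv as a fraction, s0 in signal units, r2 in s^-1,
    adc in mm^2/s, cbf in mL 100g^-1 min^-1.
    """
    r2p: float
    dbv: float
    s0: float
    r2: float
    adc: float
    cbf: float


# Oxygenation defaults follow the reference cohort's group means (core
# r2p 5.4, dbv 5.4%; growth 4.5, 4.7%; contralateral 3.6, 4.1%); S0/R2 are
# typical 3T grey-matter values, CSF is FLAIR-attenuated with a long T2.
DEFAULT_CLASSES = {
    "normal": TissueClass(r2p=3.6, dbv=0.041, s0=1000.0, r2=11.1,
                          adc=850e-6, cbf=42.5),
    "core":   TissueClass(r2p=5.4, dbv=0.054, s0=950.0, r2=10.0,
                          adc=450e-6, cbf=54.6),
    "growth": TissueClass(r2p=4.5, dbv=0.047, s0=980.0, r2=10.5,
                          adc=750e-6, cbf=37.1),
    "csf":    TissueClass(r2p=0.5, dbv=0.02, s0=200.0, r2=2.0,
                          adc=3000e-6, cbf=0.0),
}

# Ellipsoid geometry as (centre, semi-axes) in fractions of the grid
# dimensions; x is the midline axis and the brain/ventricles are symmetric
# about its centre plane.  The lesion sits entirely in the left hemisphere.
_GEOMETRY_FRACTIONS = {
    "brain":     {"semi": (0.44, 0.46, 0.52)},
    "ventricle": {"dx": 0.104, "cy": 0.65, "semi": (0.042, 0.06, 0.17)},
    "final":     {"cx": 0.27, "cy": 0.42, "semi": (0.167, 0.198, 0.49)},
    "core":      {"cx": 0.27, "cy": 0.42, "semi": (0.104, 0.125, 0.38)},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Complete description of one synthetic subject."""

    grid_shape: tuple = (96, 96, 9)
    voxel_size: tuple = (2.3, 2.3, 5.0)
    classes: dict = field(default_factory=lambda: dict(DEFAULT_CLASSES))
    snr: float = 100.0
    noise_model: str = "gaussian"
    adc_noise_sd: float = 0.0        # mm^2/s; 0 keeps ADC segmentation exact
    lesion_scale: float = 1.0        # multiplies the final/core semi-axes
    seed: int = 0
    midline_axis: int = 0
    motion_score: float = 0.5

    def __post_init__(self) -> None:
        if self.snr <= 0:
            raise ValueError("snr must be > 0")
        if self.noise_model not in ("gaussian", "rician"):
            raise ValueError(f"unknown noise model {self.noise_model!r}")
        core, thr = self.classes["core"].adc, 620e-6
        others = [c.adc for name, c in self.classes.items() if name != "core"]
        if not (core < thr and all(a > thr for a in others)):
            raise ValueError(
                "core ADC must lie below 620e-6 mm^2/s and every other "
                "class above it")


@dataclass
class PhantomTruth:
    """Ground-truth volumes and masks of a generated phantom."""

    labels: np.ndarray
    volumes: dict                     # name -> 3D float array (NaN outside)
    presenting_mask: np.ndarray
    final_mask: np.ndarray
    brain_mask: np.ndarray
    midline_axis: int
    spec: PhantomSpec

    def class_mask(self, name: str) -> np.ndarray:
        return self.labels == LABELS[name]


def _ellipsoid(grid_shape, center, semi) -> np.ndarray:
    coords = np.ogrid[tuple(slice(0, n) for n in grid_shape)]
    acc = np.zeros(grid_shape)
    for x, c, s in zip(coords, center, semi):
        acc = acc + ((x - c) / s) ** 2
    return acc <= 1.0


def generate_phantom(spec: PhantomSpec | None = None) -> PhantomTruth:
    """Build the label volume, truth maps and lesion masks for one subject.

    Deterministic given the spec's seed.  The brain support is symmetric
    about the midline-axis centre plane, so mirroring the composite lesion
    lands entirely in homologous normal tissue.
    """
    spec = spec or PhantomSpec()
    w, h, d = spec.grid_shape
    cx, cy, cz = ((n - 1) / 2.0 for n in spec.grid_shape)
    g = _GEOMETRY_FRACTIONS

    def semi(name):
        scale = spec.lesion_scale if name in ("final", "core") else 1.0
        return tuple(scale * f * n
                     for f, n in zip(g[name]["semi"], spec.grid_shape))

    for name in ("final", "core"):
        c = (g[name]["cx"] * (w - 1), g[name]["cy"] * (h - 1))
        sx, sy = semi(name)[:2]
        # the lesion must stay inside the grid and strictly in one
        # hemisphere, or the mirrored contralateral ROI would overlap it
        if (c[0] - sx < 0 or c[0] + sx >= cx or c[1] - sy < 0
                or c[1] + sy > h - 1):
            raise ValueError(
                f"{name} geometry exceeds the grid or crosses the midline")

    brain = _ellipsoid(spec.grid_shape, (cx, cy, cz), semi("brain"))
    vent_dx = g["ventricle"]["dx"] * w
    vent_cy = g["ventricle"]["cy"] * (h - 1)
    csf = (_ellipsoid(spec.grid_shape, (cx - vent_dx, vent_cy, cz),
                      semi("ventricle"))
           | _ellipsoid(spec.grid_shape, (cx + vent_dx, vent_cy, cz),
                        semi("ventricle")))
    lesion_c = (g["final"]["cx"] * (w - 1), g["final"]["cy"] * (h - 1), cz)
    final = _ellipsoid(spec.grid_shape, lesion_c, semi("final")) & brain
    core = _ellipsoid(spec.grid_shape, lesion_c, semi("core")) & brain

    labels = np.zeros(spec.grid_shape, dtype=np.uint8)
    labels[brain] = LABELS["normal"]
    labels[csf & brain] = LABELS["csf"]
    labels[final] = LABELS["growth"]
    labels[core] = LABELS["core"]

    constants = PhysioConstants()
    volumes = {}
    for prop in ("r2p", "dbv", "s0", "r2", "adc", "cbf"):
        vol = np.full(spec.grid_shape, np.nan)
        for name, cls in spec.classes.items():
            vol[labels == LABELS[name]] = getattr(cls, prop)
        volumes[prop] = vol
    volumes["s0"] = np.where(brain, volumes["s0"], 0.0)
    volumes["cbf"] = np.where(brain, volumes["cbf"], 0.0)
    volumes["dhb"] = dhb_from_ratio(volumes["r2p"], volumes["dbv"], constants)

    if spec.adc_noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        volumes["adc"] = volumes["adc"] + np.where(
            brain, rng.normal(0.0, spec.adc_noise_sd, spec.grid_shape), 0.0)

    return PhantomTruth(labels=labels, volumes=volumes,
                        presenting_mask=labels == LABELS["core"],
                        final_mask=(labels == LABELS["core"])
                        | (labels == LABELS["growth"]),
                        brain_mask=brain, midline_axis=spec.midline_axis,
                        spec=spec)


def _log_signal_volume(truth: PhantomTruth, tau: float,
                       protocol: AcquisitionProtocol) -> np.ndarray:
    """Noise-free log-signal at one tau (brain voxels; NaN outside)."""
    v = truth.volumes
    with np.errstate(divide="ignore", invalid="ignore"):
        s0_att = np.log(v["s0"]) - protocol.te * v["r2"]
    if tau == 0.0:
        return s0_att
    # negative-tau and 8 ms volumes are emitted for format realism only,
    # as the long-tau model evaluated at |tau|; they are flagged non-fit
    # and never consumed by the fitting stage.
    return long_tau_log_signal(abs(tau), v["dbv"], v["r2p"], s0_att)


def simulate_tau_series(truth: PhantomTruth,
                        protocol: AcquisitionProtocol | None = None,
                        snr: float | None = None,
                        noise_model: str | None = None,
                        seed: int | None = None,
                        full_schedule: bool = False) -> TauSeriesVolume:
    """Simulate the ASE tau-series of a phantom.

    With ``full_schedule`` the acquisition taus -16..64 ms (step 8) are
    emitted and the non-fit volumes flagged in metadata; otherwise only the
    spin echo and the long-tau samples.  Noise: ``gaussian`` adds magnitude
    noise of SD = class spin-echo amplitude / SNR; ``rician`` takes the
    magnitude of a complex signal with that per-channel SD.  ``snr=None``
    uses the spec's SNR; ``snr=inf`` disables noise.
    """
    spec = truth.spec
    protocol = protocol or AcquisitionProtocol()
    snr = spec.snr if snr is None else snr
    noise_model = noise_model or spec.noise_model
    seed = spec.seed if seed is None else seed
    taus = ACQUISITION_TAUS if full_schedule else protocol.tau_values

    brain = truth.brain_mask
    data = np.zeros(spec.grid_shape + (len(taus),))
    for i, tau in enumerate(taus):
        logs = _log_signal_volume(truth, tau, protocol)
        data[..., i] = np.where(brain, np.exp(np.where(brain, logs, 0.0)), 0.0)

    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        se_amp = truth.volumes["s0"] * np.exp(-protocol.te * truth.volumes["r2"])
        sigma = np.where(brain, se_amp / snr, 0.0)[..., None]
        if noise_model == "gaussian":
            data = data + rng.normal(size=data.shape) * sigma
        else:
            real = data + rng.normal(size=data.shape) * sigma
            imag = rng.normal(size=data.shape) * sigma
            data = np.hypot(real, imag)

    non_fit = [float(t) for t in taus
               if t != 0.0 and t <= protocol.fit_tau_min]
    return TauSeriesVolume(
        data=data, tau_values=taus, voxel_size=spec.voxel_size,
        metadata={"subject": f"sim-{seed}", "timepoint": "presentation",
                  "motion_score": spec.motion_score,
                  "non_fit_taus_s": non_fit, "snr": snr,
                  "noise_model": noise_model if np.isfinite(snr) else "none"})


def inject_csf_failure(volume: TauSeriesVolume, truth: PhantomTruth,
                       nulled_fraction: float,
                       decay_rate: float = 25.0,
                       amplitude_scale: float = 2.0) -> TauSeriesVolume:
    """Add residual un-nulled CSF signal (a motion-corrupted FLAIR confound).

    CSF voxels receive an extra component
    (1 - nulled_fraction) * A * exp(-decay_rate * |tau|), with A equal to
    ``amplitude_scale`` times the nulled CSF spin-echo amplitude.  Perfect
    nulling (fraction 1) is a no-op; fraction 0 elevates the apparent CSF
    R2' in the downstream fit, the direction of the real artefact.  The
    decay rate is illustrative, not a measured quantity.
    """
    if not 0.0 <= nulled_fraction <= 1.0:
        raise ValueError("nulled_fraction must be in [0, 1]")
    csf = truth.class_mask("csf")
    cls = truth.spec.classes["csf"]
    amp = amplitude_scale * cls.s0 * np.exp(-0.082 * cls.r2)
    taus = np.abs(np.asarray(volume.tau_values))
    extra = (1.0 - nulled_fraction) * amp * np.exp(-decay_rate * taus)
    data = volume.data.copy()
    data[csf] = data[csf] + extra
    return TauSeriesVolume(data=data, tau_values=volume.tau_values,
                           voxel_size=volume.voxel_size,
                           metadata={**volume.metadata,
                                     "csf_nulled_fraction": nulled_fraction})


def simulate_cbf_map(truth: PhantomTruth, snr: float | None = None,
                     seed: int | None = None) -> np.ndarray:
    """Class-constant CBF map plus seeded Gaussian noise (SD = value/SNR)."""
    spec = truth.spec
    snr = spec.snr if snr is None else snr
    seed = spec.seed + 1 if seed is None else seed
    cbf = truth.volumes["cbf"].copy()
    if np.isfinite(snr):
        rng = np.random.default_rng(seed)
        cbf = cbf + rng.normal(size=cbf.shape) * (np.abs(cbf) / snr)
    return np.where(truth.brain_mask, cbf, np.nan)


# --- cohort generation -----------------------------------------------------

_ROI_TO_CLASS = {"core": "core", "growth": "growth",
                 "contralateral": "normal"}
_FLOORS = {"r2p": 0.5, "dhb": 0.3, "cbf": 2.0}


def cohort_specs(n_subjects: int = 9, seed: int = 0,
                 grid_shape: tuple = (96, 96, 9),
                 snr: float = 100.0) -> list:
    """Per-subject phantom specs with reference-cohort-matched variability.

    For R2', [dHb] and CBF each subject's class truth is
    class mean + shared subject effect + independent class residual, with
    the between-/within-subject SDs estimated from the bundled nine-patient
    medians table (see :func:`sqbold.datasets.cohort_variance_decomposition`).
    DBV is derived from the sampled R2' and [dHb] through the static-
    dephasing relation so the three oxygenation parameters stay mutually
    consistent (the printed table's columns are not; see the datasets
    module).  Values are floored at small physical minima.
    """
    rng = np.random.default_rng(seed)
    decomp = {p: cohort_variance_decomposition(p)
              for p in ("r2p", "dhb", "cbf")}
    k = PhysioConstants().dhb_coefficient
    specs = []
    for i in range(n_subjects):
        subject_effect = {p: rng.normal(0.0, decomp[p]["sigma_between"])
                          for p in decomp}
        sampled = {}
        for p in decomp:
            sw = decomp[p]["sigma_within"]
            sampled[p] = {
                roi: max(decomp[p]["means"][roi] + subject_effect[p]
                         + rng.normal(0.0, sw), _FLOORS[p])
                for roi in _ROI_TO_CLASS}
        classes = dict(DEFAULT_CLASSES)
        for roi, cls_name in _ROI_TO_CLASS.items():
            dbv = float(np.clip(sampled["r2p"][roi]
                                / (k * sampled["dhb"][roi]), 0.005, 0.25))
            classes[cls_name] = replace(
                DEFAULT_CLASSES[cls_name], r2p=sampled["r2p"][roi],
                dbv=dbv, cbf=sampled["cbf"][roi])
        specs.append(PhantomSpec(grid_shape=grid_shape, classes=classes,
                                 snr=snr,
                                 seed=int(rng.integers(0, 2**31 - 1))))
    return specs
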