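# sqbold

Streamlined quantitative BOLD (sqBOLD) analysis for acute ischaemic stroke:
voxel-wise mapping of the reversible transverse relaxation rate R2′, the
deoxygenated blood volume fraction (DBV) and the deoxyhaemoglobin
concentration [dHb] from asymmetric spin-echo (ASE) MRI τ-series, together
with ADC-based tissue-outcome regions of interest, the regional statistics
used to compare them, and a synthetic phantom generator with known ground
truth so the entire pipeline is testable without patient data.

It is written for imaging scientists who work with qBOLD/ASE relaxometry in
cerebrovascular disease and want a reproducible, scriptable implementation
of the standard analysis chain.

## Model

In the long-τ regime (τ > 15 ms) the ASE log-signal decays linearly at rate
R2′, and the offset between the measured spin echo (τ = 0) and the
extrapolated long-τ intercept equals DBV:

```
log S(0) = log S0 − TE·R2
log S(τ) = log S0 − TE·R2 + DBV − R2′·τ        (τ > 15 ms)
```

Each voxel is solved as a weighted least-squares linear system in
(DBV, R2′, log S0 − TE·R2), inversely weighted for τ, with parameter
standard deviations from the estimator covariance.  [dHb] follows from the
static-dephasing relation — no haematocrit assumption is needed:

```
[dHb] = 3·R2′ / (DBV · 4·γ·π·Δχ0·κ·B0),   Δχ0 = 0.264×10⁻⁶, κ = 0.03
```

Tissue outcomes are built from the presenting ADC lesion (ADC threshold
620×10⁻⁶ mm²/s, cluster → 1 mm Gaussian smooth → re-cluster) and the final
infarct mask: **core** = presenting ∩ final, **growth** = final \
presenting, **contralateral** = the mirrored composite mask.

## Worked example

```python
import numpy as np
from sqbold import (PhantomSpec, generate_phantom, simulate_tau_series,
                    fit_volume, adc_lesion_mask, tissue_outcomes)
from sqbold.stats import summarize_regions, patient_level_analysis
from sqbold.datasets import stroke_cohort_medians

truth = generate_phantom(PhantomSpec(seed=42))          # 96×96×9 phantom
series = simulate_tau_series(truth, snr=100.0)          # noisy ASE τ-series
maps = fit_volume(series, truth.brain_mask)             # WLS parameter maps
lesion = adc_lesion_mask(truth.volumes["adc"])          # presenting lesion
rois = tissue_outcomes(lesion, truth.final_mask)        # core/growth/contra
print(summarize_regions({"r2p": maps.r2p, "dbv": maps.dbv,
                         "dhb": maps.dhb}, rois, subject="sim01"))
```

prints (abridged) the per-ROI medians of the fitted maps, which recover the
simulated class truths (core R2′ 5.4 s⁻¹, DBV 0.054; contralateral 3.6 s⁻¹,
0.041) to well under a percent at SNR 100:

```
subject   roi            parameter  median  n_voxels
sim01     core           r2p        5.402   1737
sim01     core           dbv        0.054   1737
sim01     contralateral  r2p        3.602   5358
sim01     contralateral  dbv        0.041   5358
```

The patient-level statistics on the bundled nine-patient reference medians
reproduce the reference-cohort finding that [dHb] — but not R2′, DBV or CBF alone —
separates the tissue outcomes:

```python
result = patient_level_analysis(stroke_cohort_medians(), "dhb")
# F = 18.37, p = 0.00007
# core vs contralateral:   diff +0.844 g/dL, adjusted p = 0.0001
# core vs growth:          diff +0.611 g/dL, adjusted p = 0.0017
# growth vs contralateral: diff +0.233 g/dL, adjusted p = 0.2654
```

A command-line interface mirrors the library:
`sqbold simulate|fit|roi|stats|run` (see `sqbold --help`).

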