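"""Bundled reference data: per-patient ROI medians from a nine-patient
acute ischaemic stroke cohort (values as printed at one decimal place).

Each patient contributes the median R2' (s^-1), DBV (%), [dHb] (g/dL) and
CBF (mL 100g^-1 min^-1) of the ischaemic-core, infarct-growth and mirrored
contralateral ROIs at the presenting scan.  The table drives the group
statistics examples and tests and calibrates the cohort phantom generator's
between- and within-subject variability.

Note: because a median of voxel-wise ratios is not the ratio of medians,
the printed R2', DBV and [dHb] columns are not mutually consistent under
the static-dephasing relation; they are treated as independent per-patient
summaries.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["stroke_cohort_medians", "cohort_variance_decomposition"]

_SUBJECTS = ["P01", "P02", "P03", "P04", "P05", "P06", "P07", "P08", "P09"]

# parameter -> {roi: nine per-patient medians}
_MEDIANS = {
    "r2p": {   # s^-1
        "core":          [5.3, 3.6, 5.1, 3.5, 8.4, 12.4, 3.3, 2.9, 3.9],
        "growth":        [5.1, 3.2, 4.7, 4.3, 9.6, 4.3, 2.4, 4.1, 2.8],
        "contralateral": [3.2, 3.5, 3.2, 2.4, 4.1, 7.5, 2.3, 4.3, 2.1],
    },
    "dbv": {   # percent
        "core":          [7.2, 4.2, 6.9, 6.5, 2.7, 8.8, 4.2, 2.5, 5.3],
        "growth":        [6.5, 4.1, 7.0, 3.6, 3.4, 6.0, 3.9, 4.2, 3.6],
        "contralateral": [3.7, 5.1, 3.1, 4.5, 1.3, 6.6, 2.9, 5.3, 4.1],
    },
    "dhb": {   # g/dL
        "core":          [2.7, 3.6, 2.7, 1.8, 1.1, 4.1, 2.6, 3.3, 2.4],
        "growth":        [2.6, 2.8, 2.3, 1.9, 1.0, 2.6, 1.9, 2.0, 1.7],
        "contralateral": [2.2, 2.3, 2.0, 1.6, 0.5, 2.7, 1.6, 2.5, 1.3],
    },
    "cbf": {   # mL 100g^-1 min^-1
        "core":          [9.3, 23.4, 11.1, 67.6, 16.0, 85.1, 110.8, 90.3, 77.5],
        "growth":        [12.8, 19.3, 14.8, 54.3, 22.0, 35.1, 53.2, 60.1, 61.8],
        "contralateral": [58.8, 29.7, 37.5, 40.5, 17.3, 25.9, 44.7, 53.4, 74.2],
    },
}


def stroke_cohort_medians() -> pd.DataFrame:
    """Tidy frame of the reference cohort's per-patient ROI medians.

    Columns: subject, timepoint ("presentation"), roi, parameter, median,
    n_voxels (unknown for this table, set to 0).
    """
    rows = []
    for param, by_roi in _MEDIANS.items():
        for roi, values in by_roi.items():
            for subj, val in zip(_SUBJECTS, values):
                rows.append({"subject": subj, "timepoint": "presentation",
                             "roi": roi, "parameter": param,
                             "median": float(val), "n_voxels": 0})
    return pd.DataFrame(rows)


def cohort_variance_decomposition(parameter: str) -> dict:
    """Between-/within-subject variance split for one parameter.

    Models a patient's ROI median as  m_roi + b_subject + e  with a shared
    subject effect b and an independent residual e.  The residual variance
    is estimated from the paired ROI differences (var(diff) = 2 sigma_e^2,
    averaged over the three ROI pairs); the subject-effect variance is the
    mean marginal variance minus sigma_e^2 (floored at 0).  Returns class
    means and both SDs.
    """
    by_roi = _MEDIANS[parameter]
    rois = list(by_roi)
    arrays = {r: np.asarray(v, dtype=float) for r, v in by_roi.items()}
    means = {r: float(a.mean()) for r, a in arrays.items()}
    diff_vars = []
    for i in range(len(rois)):
        for j in range(i + 1, len(rois)):
            diff_vars.append(np.var(arrays[rois[i]] - arrays[rois[j]], ddof=1))
    sigma_e2 = float(np.mean(diff_vars)) / 2.0
    marginal = float(np.mean([np.var(a, ddof=1) for a in arrays.values()]))
    sigma_b2 = max(marginal - sigma_e2, 0.0)
    return {"means": means, "sigma_between": np.sqrt(sigma_b2),
            "sigma_within": np.sqrt(sigma_e2)}
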