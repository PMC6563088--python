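"""Regional and serial statistics for tissue-outcome ROI analyses.

Two levels of analysis are provided.  The voxel level pools voxel values
across subjects per ROI and compares distributions with a Kruskal-Wallis
test followed by Tukey-Kramer post hoc comparisons on the pooled ranks.
The patient level reduces each (subject, ROI) cell to its median and uses
an unreplicated two-way ANOVA (tissue outcome x subject block, no
interaction) with Tukey-Kramer post hoc on the residual variance.  Paired
Cohen's d and two-tailed paired t-tests quantify effect sizes and serial
change after within-scan normalisation to the contralateral ROI.

Significance level alpha = 0.05 throughout, two-tailed; medians use the
mean-of-central-pair convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

__all__ = [
    "GroupTestResult",
    "PairwiseComparison",
    "ROIS",
    "PARAMETERS",
    "extract_region_values",
    "summarize_regions",
    "group_mean_sd",
    "kruskal_wallis",
    "tukey_kramer_posthoc",
    "tukey_kramer_from_summary",
    "two_way_anova",
    "cohens_d_paired",
    "normalize_to_contralateral",
    "paired_ttest_two_tailed",
    "voxel_level_analysis",
    "patient_level_analysis",
]

ROIS = ("core", "growth", "contralateral")
PARAMETERS = ("r2p", "dbv", "dhb", "cbf")
ALPHA = 0.05


@dataclass
class PairwiseComparison:
    pair: tuple
    estimate: float          # difference of (rank) means
    p_adjusted: float


@dataclass
class GroupTestResult:
    name: str
    statistic: float
    pvalue: float
    pairwise: list | None = None
    alpha: float = ALPHA
    extra: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        d = {"name": self.name, "statistic": self.statistic,
             "pvalue": self.pvalue, "alpha": self.alpha, **self.extra}
        if self.pairwise is not None:
            d["pairwise"] = [
                {"pair": list(c.pair), "estimate": c.estimate,
                 "p_adjusted": c.p_adjusted} for c in self.pairwise]
        return d


def extract_region_values(parameter_map: np.ndarray,
                          mask: np.ndarray) -> np.ndarray:
    """Values of a map at mask voxels, raster order, missing (NaN) dropped."""
    parameter_map = np.asarray(parameter_map, dtype=float)
    mask = np.asarray(mask).astype(bool)
    if parameter_map.shape != mask.shape:
        raise ValueError(
            f"map grid {parameter_map.shape} != mask grid {mask.shape}")
    if not mask.any():
        raise ValueError("empty ROI mask")
    vals = parameter_map[mask]
    return vals[np.isfinite(vals)]


def summarize_regions(maps_by_parameter: dict, outcomes,
                      subject: str = "S01",
                      timepoint: str = "presentation") -> pd.DataFrame:
    """Per-ROI medians of each parameter map for one subject and time point.

    ``maps_by_parameter`` maps parameter name -> 3D array; ``outcomes`` is a
    TissueOutcomeSet (or a dict roi -> mask).  Returns a tidy frame with one
    row per (subject, timepoint, roi, parameter).  An ROI that is empty or
    all-missing for one map yields a NaN row; other rows are unaffected.
    """
    roi_masks = outcomes.masks() if hasattr(outcomes, "masks") else dict(outcomes)
    rows = []
    for roi, mask in roi_masks.items():
        for param, pmap in maps_by_parameter.items():
            try:
                vals = extract_region_values(pmap, mask)
            except ValueError:
                vals = np.array([])
            rows.append({
                "subject": subject, "timepoint": timepoint, "roi": roi,
                "parameter": param,
                "median": float(np.median(vals)) if vals.size else np.nan,
                "n_voxels": int(vals.size),
            })
    return pd.DataFrame(rows)


def group_mean_sd(summary: pd.DataFrame, parameter: str,
                  timepoint: str | None = None) -> pd.DataFrame:
    """Across-subject mean and n-1 sample SD of per-subject medians, per ROI."""
    df = summary[summary["parameter"] == parameter]
    if timepoint is not None and "timepoint" in df:
        df = df[df["timepoint"] == timepoint]
    if df.empty:
        raise ValueError(f"no rows for parameter {parameter!r}")
    out = (df.groupby("roi")["median"]
             .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
             .reset_index())
    out.loc[out["n"] < 2, "sd"] = np.nan
    return out


def kruskal_wallis(groups: dict | list) -> GroupTestResult:
    """Kruskal-Wallis H test across >=2 value groups (tie-corrected).

    p from the chi-squared approximation with k-1 df.  If every value in the
    pooled sample is identical the test is degenerate: H = 0, p = 1.
    """
    labels, arrays = _as_groups(groups)
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if np.unique(np.concatenate(arrays)).size <= 1:
        h, p = 0.0, 1.0      # all values identical: degenerate
    else:
        h, p = sps.kruskal(*arrays)
    return GroupTestResult(name="kruskal_wallis", statistic=float(h),
                           pvalue=float(p),
                           extra={"groups": labels,
                                  "df": len(arrays) - 1})


def tukey_kramer_from_summary(means, ns, mse: float, df: int,
                              labels=None) -> list:
    """Tukey-Kramer pairwise comparisons from group means and a shared MSE.

    The studentized-range statistic for groups a, b is
    q = |m_a - m_b| / sqrt(MSE/2 * (1/n_a + 1/n_b)) (the Kramer correction
    for unequal n); adjusted p = sf of the studentized range with k groups
    and ``df`` error degrees of freedom.
    """
    means = np.asarray(means, dtype=float)
    ns = np.asarray(ns)
    k = means.size
    if labels is None:
        labels = [f"g{i}" for i in range(k)]
    if np.any(ns < 1):
        raise ValueError("every group needs at least one observation")
    out = []
    for a, b in combinations(range(k), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        diff = means[a] - means[b]
        if se == 0:
            p = 1.0 if diff == 0 else 0.0
        else:
            q = abs(diff) / se
            p = float(sps.studentized_range.sf(q, k, df))
        out.append(PairwiseComparison(pair=(labels[a], labels[b]),
                                      estimate=float(diff),
                                      p_adjusted=min(max(p, 0.0), 1.0)))
    return out


def tukey_kramer_posthoc(groups: dict | list,
                         on_ranks: bool = False) -> list:
    """Tukey-Kramer honest-significant-difference comparisons between groups.

    With ``on_ranks`` (the convention after a Kruskal-Wallis test) the
    comparisons operate on the pooled ranks of all values.  MSE is the
    pooled within-group variance on N - k degrees of freedom.
    """
    labels, arrays = _as_groups(groups)
    if len(arrays) < 2:
        raise ValueError("need at least 2 groups")
    if any(a.size == 0 for a in arrays):
        raise ValueError("every group needs at least one observation")
    if on_ranks:
        pooled = np.concatenate(arrays)
        ranks = sps.rankdata(pooled)
        split = np.cumsum([a.size for a in arrays])[:-1]
        arrays = np.split(ranks, split)
    ns = np.array([a.size for a in arrays])
    means = np.array([a.mean() for a in arrays])
    df = int(ns.sum() - len(arrays))
    if df < 1:
        raise ValueError("no residual degrees of freedom for Tukey-Kramer")
    sse = sum(float(((a - a.mean()) ** 2).sum()) for a in arrays)
    mse = sse / df
    return tukey_kramer_from_summary(means, ns, mse, df, labels)


def two_way_anova(summary: pd.DataFrame, parameter: str,
                  timepoint: str | None = None) -> GroupTestResult:
    """Unreplicated two-way ANOVA: tissue outcome + subject block.

    One median per (subject, ROI) cell leaves no replication, so no
    interaction term is estimable; the subject factor absorbs between-
    subject offsets and the tissue-outcome F is tested against the
    (k-1)(n-1)-df residual.  Post hoc Tukey-Kramer comparisons reuse the
    residual mean square.  Missing cells are an error (no imputation).
    """
    df = summary[summary["parameter"] == parameter]
    if timepoint is not None and "timepoint" in df:
        df = df[df["timepoint"] == timepoint]
    table = df.pivot_table(index="subject", columns="roi", values="median",
                           aggfunc="first")
    if table.isna().any().any() or table.shape[1] < 2 or table.shape[0] < 2:
        raise ValueError(
            f"two-way ANOVA needs a complete subject x ROI table; got\n{table}")
    long = table.reset_index().melt(id_vars="subject", var_name="roi",
                                    value_name="value")
    fit = smf.ols("value ~ C(roi) + C(subject)", data=long).fit()
    anova = sm.stats.anova_lm(fit, typ=2)
    ss_roi = float(anova.loc["C(roi)", "sum_sq"])
    ss_res = float(anova.loc["Residual", "sum_sq"])
    total = float(anova["sum_sq"].sum())
    resid_df = int(anova.loc["Residual", "df"])
    rois = list(table.columns)
    n = table.shape[0]
    roi_means = table.mean(axis=0).to_numpy()
    # degenerate case: tissue and residual sums of squares both vanish
    # (identical columns up to floating-point noise)
    if total == 0 or (ss_roi < 1e-12 * max(total, 1.0)
                      and ss_res < 1e-12 * max(total, 1.0)):
        f_tissue, p_tissue, mse = 0.0, 1.0, 0.0
        pairwise = [PairwiseComparison(pair=(rois[a], rois[b]),
                                       estimate=float(roi_means[a]
                                                      - roi_means[b]),
                                       p_adjusted=1.0)
                    for a, b in combinations(range(len(rois)), 2)]
    else:
        f_tissue = float(anova.loc["C(roi)", "F"])
        p_tissue = float(anova.loc["C(roi)", "PR(>F)"])
        mse = ss_res / resid_df if resid_df else np.nan
        pairwise = tukey_kramer_from_summary(
            roi_means, np.full(len(rois), n), mse, resid_df, rois)
    return GroupTestResult(
        name="two_way_anova", statistic=f_tissue, pvalue=p_tissue,
        pairwise=pairwise,
        extra={"parameter": parameter, "df_tissue": len(rois) - 1,
               "df_resid": resid_df, "n_subjects": n, "mse": mse})


def cohens_d_paired(x, y) -> float:
    """Paired Cohen's d: mean difference over the SD of the differences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance of paired differences: d undefined")
    return float(d.mean() / sd)


def paired_ttest_two_tailed(x, y) -> GroupTestResult:
    """Two-tailed paired t-test that the mean difference is zero.

    t = mean(d) / (sd(d)/sqrt(n)) with n-1 degrees of freedom; satisfies
    t = d * sqrt(n) with the paired Cohen's d.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("x and y must be equal-length with n >= 2")
    if (x - y).std(ddof=1) == 0:
        raise ValueError("zero variance of paired differences")
    t, p = sps.ttest_rel(x, y)
    return GroupTestResult(name="paired_ttest", statistic=float(t),
                           pvalue=float(p), extra={"df": x.size - 1})


def normalize_to_contralateral(summary: pd.DataFrame,
                               timepoint: str | None = None) -> pd.DataFrame:
    """Divide each scan's core/growth medians by its contralateral median.

    Normalisation is within (subject, timepoint, parameter); contralateral
    rows become exactly 1.  A zero or missing contralateral median marks the
    whole cell group missing (NaN).  Idempotent.
    """
    df = summary.copy()
    if timepoint is not None:
        df = df[df["timepoint"] == timepoint].copy()
    keys = ["subject", "timepoint", "parameter"]

    def _norm(group: pd.DataFrame) -> pd.DataFrame:
        contra = group.loc[group["roi"] == "contralateral", "median"]
        ref = contra.iloc[0] if len(contra) else np.nan
        group = group.copy()
        if not np.isfinite(ref) or ref == 0:
            group["median"] = np.nan
        else:
            group["median"] = group["median"] / ref
        return group

    out = (df.groupby(keys, group_keys=False, sort=False)
             .apply(_norm, include_groups=False))
    # groupby.apply with include_groups drops key columns; restore them
    out[keys] = df[keys]
    return out[df.columns]


def voxel_level_analysis(values_by_roi: dict) -> GroupTestResult:
    """Pooled voxel-level comparison: Kruskal-Wallis + Tukey-Kramer on ranks."""
    result = kruskal_wallis(values_by_roi)
    result.pairwise = tukey_kramer_posthoc(values_by_roi, on_ranks=True)
    return result


def patient_level_analysis(summary: pd.DataFrame, parameter: str,
                           timepoint: str | None = None) -> GroupTestResult:
    """Patient-level comparison of per-subject ROI medians (two-way ANOVA)."""
    return two_way_anova(summary, parameter, timepoint)


def _as_groups(groups: dict | list):
    if isinstance(groups, dict):
        labels = list(groups.keys())
        arrays = [np.asarray(v, dtype=float) for v in groups.values()]
    else:
        arrays = [np.asarray(v, dtype=float) for v in groups]
        labels = [f"g{i}" for i in range(len(arrays))]
    arrays = [a[np.isfinite(a)] for a in arrays]
    return labels, arrays
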