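"""Regional statistics: extraction, group summaries, tests and effect sizes."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats as sps

from sqbold.datasets import stroke_cohort_medians
from sqbold.stats import (
    cohens_d_paired,
    extract_region_values,
    group_mean_sd,
    kruskal_wallis,
    normalize_to_contralateral,
    paired_ttest_two_tailed,
    summarize_regions,
    tukey_kramer_posthoc,
    two_way_anova,
    voxel_level_analysis,
)


@pytest.fixture(scope="module")
def cohort():
    return stroke_cohort_medians()


class TestExtractRegionValues:
    def test_single_voxel(self):
        m = np.arange(8.0).reshape(2, 2, 2)
        mask = np.zeros((2, 2, 2), bool)
        mask[1, 0, 1] = True
        assert extract_region_values(m, mask) == [5.0]

    def test_median_robust_to_outlier(self):
        m = np.zeros((5, 1, 1))
        m[:, 0, 0] = [1, 2, 3, 4, 100]
        mask = np.ones((5, 1, 1), bool)
        assert np.median(extract_region_values(m, mask)) == 3.0

    def test_enumeration_oracle_and_raster_order(self):
        rng = np.random.default_rng(9)
        m = rng.random((4, 3, 2))
        mask = rng.random((4, 3, 2)) > 0.5
        expected = [m[i] for i in np.ndindex(4, 3, 2) if mask[i]]
        assert np.array_equal(extract_region_values(m, mask), expected)

    def test_missing_dropped_and_empty_rejected(self):
        m = np.full((2, 2, 1), np.nan)
        m[0, 0, 0] = 1.0
        assert extract_region_values(m, np.ones((2, 2, 1), bool)) == [1.0]
        with pytest.raises(ValueError):
            extract_region_values(m, np.zeros((2, 2, 1), bool))


class TestSummarizeRegions:
    def test_constant_class_truth_exact(self):
        maps = {"r2p": np.full((6, 6, 2), 3.6)}
        mask = np.zeros((6, 6, 2), bool)
        mask[1:3, 1:3, :] = True
        s = summarize_regions(maps, {"core": mask})
        assert s.loc[0, "median"] == 3.6
        assert s.loc[0, "n_voxels"] == 8

    def test_even_count_median_convention(self):
        m = np.zeros((4, 1, 1))
        m[:, 0, 0] = [1, 2, 3, 10]
        s = summarize_regions({"p": m}, {"roi": np.ones((4, 1, 1), bool)})
        assert s.loc[0, "median"] == 2.5


class TestGroupMeanSd:
    def test_identical_subjects_zero_sd(self):
        df = pd.DataFrame({"subject": list("abc"), "roi": ["core"] * 3,
                           "parameter": ["r2p"] * 3, "median": [2.0] * 3})
        out = group_mean_sd(df, "r2p").set_index("roi")
        assert out.loc["core", "sd"] == 0.0

    def test_two_subject_closed_form(self):
        df = pd.DataFrame({"subject": ["a", "b"], "roi": ["core"] * 2,
                           "parameter": ["r2p"] * 2, "median": [1.0, 4.0]})
        out = group_mean_sd(df, "r2p").set_index("roi")
        assert out.loc["core", "sd"] == pytest.approx(3.0 / np.sqrt(2))

    def test_single_subject_sd_missing(self):
        df = pd.DataFrame({"subject": ["a"], "roi": ["core"],
                           "parameter": ["r2p"], "median": [1.0]})
        assert np.isnan(group_mean_sd(df, "r2p")["sd"]).all()

    def test_reference_cohort_core_r2p(self, cohort):
        out = group_mean_sd(cohort, "r2p").set_index("roi")
        assert round(out.loc["core", "mean"], 1) == 5.4
        assert round(out.loc["core", "sd"], 1) == 3.1


class TestKruskalWallis:
    def test_rank_formula_oracle(self):
        # H = 12/(N(N+1)) * sum R_j^2/n_j - 3(N+1) on untied groups
        groups = [[1, 2, 3], [4, 5, 6], [7, 8, 9]]
        ranks = {1: 1, 2: 2, 3: 3, 4: 4, 5: 5, 6: 6, 7: 7, 8: 8, 9: 9}
        n = 9
        h_hand = 12 / (n * (n + 1)) * sum(
            sum(ranks[v] for v in g) ** 2 / len(g) for g in groups) - 3 * (n + 1)
        result = kruskal_wallis(groups)
        assert h_hand == pytest.approx(7.2)
        assert result.statistic == pytest.approx(h_hand)
        assert result.pvalue == pytest.approx(sps.chi2.sf(7.2, 2))

    def test_rank_invariance_under_monotone_transform(self):
        groups = [[1.0, 2, 3.5], [4, 5.5, 6], [7, 8, 9.5]]
        a = kruskal_wallis(groups).statistic
        b = kruskal_wallis([[v**3 for v in g] for g in groups]).statistic
        assert a == pytest.approx(b)

    def test_permutation_within_group_invariance(self):
        a = kruskal_wallis([[3, 1, 2], [6, 4, 5]]).statistic
        b = kruskal_wallis([[1, 2, 3], [4, 5, 6]]).statistic
        assert a == pytest.approx(b)

    def test_degenerate_identical_values(self):
        r = kruskal_wallis([[2, 2], [2, 2, 2]])
        assert r.statistic == 0.0 and r.pvalue == 1.0


class TestTukeyKramer:
    def test_two_group_equivalence_to_pooled_t(self):
        a = np.array([1.0, 2.0, 3.0, 4.0])
        b = np.array([2.0, 4.0, 5.0, 7.0])
        pw = tukey_kramer_posthoc([a, b])
        _, p_t = sps.ttest_ind(a, b)
        assert pw[0].p_adjusted == pytest.approx(p_t, rel=1e-6)

    def test_matches_scipy_tukey_hsd(self):
        rng = np.random.default_rng(12)
        groups = [rng.normal(m, 1, n) for m, n in ((0, 8), (0.5, 6), (2, 7))]
        ours = tukey_kramer_posthoc(groups)
        ref = sps.tukey_hsd(*groups)
        for comp in ours:
            i = int(comp.pair[0][1:])
            j = int(comp.pair[1][1:])
            assert comp.p_adjusted == pytest.approx(ref.pvalue[i, j],
                                                    abs=1e-6)

    def test_identical_groups_p_one(self):
        pw = tukey_kramer_posthoc([[1.0, 1.0], [1.0, 1.0]])
        assert pw[0].p_adjusted == 1.0

    def test_extreme_group_has_smaller_ps(self):
        rng = np.random.default_rng(13)
        g1 = rng.normal(0, 1, 10)
        g2 = rng.normal(0.2, 1, 10)
        g3 = rng.normal(8, 1, 10)
        pw = {c.pair: c.p_adjusted for c in
              tukey_kramer_posthoc({"a": g1, "b": g2, "c": g3})}
        assert pw[("a", "c")] < pw[("a", "b")]
        assert pw[("b", "c")] < pw[("a", "b")]


class TestTwoWayAnova:
    @staticmethod
    def _tidy(table):
        rows = []
        for i, subj in enumerate(table):
            for j, roi in enumerate(("core", "growth", "contralateral")):
                rows.append({"subject": f"S{i}", "roi": roi,
                             "parameter": "p", "median": table[i][j]})
        return pd.DataFrame(rows)

    def test_identical_columns_give_f_zero(self):
        df = self._tidy([[1, 1, 1], [2, 2, 2], [5, 5, 5]])
        r = two_way_anova(df, "p")
        assert r.statistic == pytest.approx(0.0, abs=1e-20)
        assert r.pvalue == pytest.approx(1.0)

    def test_hand_computed_sums_of_squares(self):
        table = [[1.0, 2.0, 3.0], [2.0, 4.0, 6.0], [3.0, 3.0, 9.0]]
        arr = np.array(table)
        grand = arr.mean()
        ss_roi = arr.shape[0] * ((arr.mean(axis=0) - grand) ** 2).sum()
        ss_subj = arr.shape[1] * ((arr.mean(axis=1) - grand) ** 2).sum()
        ss_tot = ((arr - grand) ** 2).sum()
        ss_res = ss_tot - ss_roi - ss_subj
        f_hand = (ss_roi / 2) / (ss_res / 4)
        r = two_way_anova(self._tidy(table), "p")
        assert r.statistic == pytest.approx(f_hand, rel=1e-10)
        assert r.pvalue == pytest.approx(sps.f.sf(f_hand, 2, 4), rel=1e-10)

    def test_subject_constant_invariance(self):
        rng = np.random.default_rng(14)
        base = rng.random((5, 3))
        shifted = base + rng.random((5, 1)) * 10
        f1 = two_way_anova(self._tidy(base.tolist()), "p").statistic
        f2 = two_way_anova(self._tidy(shifted.tolist()), "p").statistic
        assert f1 == pytest.approx(f2, rel=1e-8)

    def test_missing_cell_rejected(self):
        df = self._tidy([[1, 2, 3], [2, 4, 6]]).iloc[:-1]
        with pytest.raises(ValueError):
            two_way_anova(df, "p")

    def test_reference_cohort_dhb_tissue_effect(self, cohort):
        # [dHb] separates the tissue outcomes; the other parameters do not
        assert two_way_anova(cohort, "dhb").pvalue < 0.001
        for param in ("r2p", "dbv", "cbf"):
            assert two_way_anova(cohort, param).pvalue > 0.05


class TestEffectSizeAndTtest:
    def test_constant_difference_rejected(self):
        with pytest.raises(ValueError):
            cohens_d_paired([1, 2, 3], [0, 1, 2])

    def test_antisymmetry(self):
        x, y = [1.0, 2, 4], [0.5, 1, 1]
        assert cohens_d_paired(x, y) == pytest.approx(-cohens_d_paired(y, x))

    def test_hand_computed_t(self):
        x = [1.0, 2.0, 3.0, 4.0]
        y = [0.0, 0.0, 1.0, 2.0]
        r = paired_ttest_two_tailed(x, y)
        # d = {1,2,2,2}: mean 1.75, sd 0.5, t = 1.75/(0.5/2) = 7.0
        assert r.statistic == pytest.approx(7.0)
        assert r.extra["df"] == 3
        assert r.pvalue == pytest.approx(2 * sps.t.sf(7.0, 3))

    def test_swap_negates_t_keeps_p(self):
        x, y = [1.0, 2, 4, 8], [0.0, 1, 5, 2]
        a = paired_ttest_two_tailed(x, y)
        b = paired_ttest_two_tailed(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.pvalue == pytest.approx(b.pvalue)

    def test_t_equals_d_times_sqrt_n(self):
        rng = np.random.default_rng(15)
        x, y = rng.random(9), rng.random(9)
        t = paired_ttest_two_tailed(x, y).statistic
        d = cohens_d_paired(x, y)
        assert t == pytest.approx(d * 3.0, abs=1e-12)


class TestNormalizeToContralateral:
    def test_contralateral_becomes_one_and_printed_ratio(self, cohort):
        out = normalize_to_contralateral(cohort)
        contra = out[out["roi"] == "contralateral"]
        assert np.allclose(contra["median"], 1.0)
        row = out[(out.subject == "P01") & (out.roi == "core")
                  & (out.parameter == "r2p")]
        assert row["median"].iloc[0] == pytest.approx(5.3 / 3.2, abs=1e-9)

    def test_idempotent(self, cohort):
        once = normalize_to_contralateral(cohort)
        twice = normalize_to_contralateral(once)
        pd.testing.assert_frame_equal(once.reset_index(drop=True),
                                      twice.reset_index(drop=True))

    def test_scale_invariance(self, cohort):
        scaled = cohort.copy()
        scaled["median"] = scaled["median"] * 3.0
        a = normalize_to_contralateral(cohort)
        b = normalize_to_contralateral(scaled)
        assert np.allclose(a["median"], b["median"], equal_nan=True)

    def test_zero_contralateral_marks_missing(self):
        df = pd.DataFrame({
            "subject": ["a"] * 3, "timepoint": ["presentation"] * 3,
            "roi": ["core", "growth", "contralateral"],
            "parameter": ["r2p"] * 3, "median": [2.0, 1.0, 0.0]})
        out = normalize_to_contralateral(df)
        assert out["median"].isna().all()


class TestVoxelLevelAnalysis:
    def test_separated_groups_significant(self):
        rng = np.random.default_rng(16)
        groups = {"core": rng.normal(5.4, 1.0, 300),
                  "growth": rng.normal(4.5, 1.0, 300),
                  "contralateral": rng.normal(3.6, 1.0, 300)}
        r = voxel_level_analysis(groups)
        assert r.pvalue < 0.001
        assert len(r.pairwise) == 3
        assert all(c.p_adjusted < 0.01 for c in r.pairwise)
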