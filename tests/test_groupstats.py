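"""GLM t-maps, multiplicity control, clusters, GDS battery, ANOVA."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from petriage.groupstats import (
    StatsError,
    anova_subsampled,
    bh_fdr,
    cluster_filter,
    gds_itemwise,
    glm_tmap,
    roi_compare,
    threshold_map,
)
from petriage.synthetic import GeneratorConfig, VolumeParams, generate_cohort


class TestGlmTmap:
    def test_no_covariates_equals_pooled_two_sample_t(self, rng):
        vols = rng.normal(1.0, 0.1, (24, 6, 6, 6))
        group = np.repeat([0, 1], 12)
        sm = glm_tmap(vols, group)
        t_ref, _ = stats.ttest_ind(
            vols[group == 1], vols[group == 0], axis=0, equal_var=True,
        )
        np.testing.assert_allclose(sm.t, t_ref, atol=1e-10)
        assert sm.df == 22

    def test_covariates_consume_degrees_of_freedom(self, rng):
        vols = rng.normal(1.0, 0.1, (30, 4, 4, 4))
        group = np.repeat([0, 1], 15)
        cov = pd.DataFrame({
            "age": rng.normal(75, 7, 30),
            "sex": rng.choice(["M", "F"], 30),
            "education": rng.normal(7, 3, 30),
            "apoe4": rng.integers(0, 2, 30),
        })
        sm = glm_tmap(vols, group, covariates=cov)
        assert sm.df == 30 - 6

    def test_constant_group_raises_design_error(self, rng):
        vols = rng.normal(size=(10, 3, 3, 3))
        with pytest.raises(StatsError, match="group"):
            glm_tmap(vols, np.ones(10))

    def test_covariate_effect_removed(self, rng):
        # intensity depends on age only; group is age-confounded
        n = 60
        age = rng.normal(75, 7, n)
        group = (age > np.median(age)).astype(float)
        vols = np.ones((n, 3, 3, 3)) * age[:, None, None, None] * 0.01
        vols += rng.normal(0, 0.01, vols.shape)
        adjusted = glm_tmap(vols, group, covariates=pd.DataFrame({"age": age}))
        naive = glm_tmap(vols, group)
        assert np.abs(adjusted.t).mean() < np.abs(naive.t).mean()


class TestThresholding:
    def test_bonferroni_threshold_is_alpha_over_v(self, rng):
        vols = rng.normal(size=(20, 10, 10, 10))
        group = np.repeat([0, 1], 10)
        sm = glm_tmap(vols, group)
        threshold_map(sm, "fwe", alpha=0.05)
        v = sm.n_voxels
        inside = sm.masks["fwe"][sm.brain_mask]
        np.testing.assert_array_equal(inside, sm.p[sm.brain_mask] < 0.05 / v)

    def test_fdr_step_up_hand_example(self):
        # all four rejected: largest k with p(k) <= k * alpha / m is k = 4
        assert bh_fdr(np.array([0.01, 0.02, 0.03, 0.04]), 0.05).all()

    def test_all_p_one_rejects_nothing(self, rng):
        vols = np.ones((10, 3, 3, 3)) + rng.normal(0, 1e-12, (10, 3, 3, 3))
        sm = glm_tmap(vols, np.repeat([0, 1], 5))
        sm.p[:] = 1.0
        threshold_map(sm, "fwe")
        threshold_map(sm, "fdr")
        assert not sm.masks["fwe"].any() and not sm.masks["fdr"].any()

    def test_fdr_matches_reference_implementation(self, rng):
        from statsmodels.stats.multitest import multipletests

        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(3, 60)))
            mine = bh_fdr(p, 0.05)
            ref = multipletests(p, alpha=0.05, method="fdr_bh")[0]
            np.testing.assert_array_equal(mine, ref)

    def test_bad_alpha_rejected(self, rng):
        vols = rng.normal(size=(10, 3, 3, 3))
        sm = glm_tmap(vols, np.repeat([0, 1], 5))
        with pytest.raises(StatsError):
            threshold_map(sm, "fwe", alpha=1.5)


class TestClusterFilter:
    @staticmethod
    def _mask_with(coords, shape=(12, 12, 12)):
        m = np.zeros(shape, bool)
        for c in coords:
            m[c] = True
        return m

    def test_five_voxel_cluster_removed_by_strict_rule(self):
        mask = self._mask_with([(2, 2, z) for z in range(5)])
        kept, table = cluster_filter(mask, min_extent=5)
        assert not kept.any() and len(table) == 0

    def test_six_voxel_line_kept(self):
        mask = self._mask_with([(2, 2, z) for z in range(6)])
        kept, table = cluster_filter(mask, min_extent=5)
        assert kept.sum() == 6
        assert table.iloc[0]["size"] == 6

    def test_edge_connectivity_joins_under_18_not_6(self):
        mask = self._mask_with([(5, 5, 5), (5, 6, 6)])  # share an edge
        _, t18 = cluster_filter(mask, min_extent=0, connectivity=18)
        _, t6 = cluster_filter(mask, min_extent=0, connectivity=6)
        assert len(t18) == 1 and len(t6) == 2

    def test_peak_location_follows_value_grid(self):
        mask = self._mask_with([(2, 2, z) for z in range(6)])
        values = np.zeros((12, 12, 12))
        values[2, 2, 4] = -7.0
        _, table = cluster_filter(mask, min_extent=5, values=values)
        assert tuple(table.iloc[0][["peak_x", "peak_y", "peak_z"]]) == (2, 2, 4)


class TestRoiCompare:
    def test_identical_volumes_give_zero_t(self, atlas32):
        vols = np.ones((10, 32, 32, 32))
        table = roi_compare(vols, atlas32, np.repeat([0, 1], 5))
        assert np.allclose(table["t"], 0.0)
        assert "pons" not in set(table["roi"])

    def test_injected_ad_effect_detected_in_precuneus(self, atlas32):
        cfg = GeneratorConfig(seed=2)
        cfg.volume_params = VolumeParams(noise_sd=0.05)
        from petriage.synthetic import generate_volume

        vols, group = [], []
        for i in range(60):
            imp = i < 30
            sample = {
                "triage_label": "certain_impaired" if imp else "certain_healthy",
                "true_state": "impaired" if imp else "healthy",
                "energetic": 1,
            }
            vols.append(generate_volume(sample, atlas32, cfg, seed=i).data)
            group.append(int(imp))
        table = roi_compare(np.stack(vols), atlas32, np.array(group))
        row = table[table["roi"] == "precuneus"].iloc[0]
        assert row["p_corrected"] < 0.001 and row["t"] < 0


class TestGdsItemwise:
    def test_family_wise_threshold_two_significant_figures(self, cohort2000):
        _, threshold = gds_itemwise(cohort2000, "certainty")
        assert threshold == pytest.approx(0.05 / 16)
        assert float(f"{threshold:.2g}") == 0.0031

    def test_memory_item_tracks_impairment(self, cohort2000):
        table, _ = gds_itemwise(cohort2000, "impairment")
        assert table.set_index("item").loc["memory", "significant"]

    def test_balanced_table_gives_chi2_zero(self):
        table = np.array([[10, 10], [10, 10]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == 0.0 and p == 1.0

    def test_chi2_closed_form_2x2(self):
        # n (ad - bc)^2 / (r1 r2 c1 c2)
        table = np.array([[30, 10], [10, 30]])
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        assert chi2 == pytest.approx(20.0)
        assert p == pytest.approx(7.7e-6, rel=0.01)

    def test_unknown_factor_rejected(self, cohort2000):
        with pytest.raises(StatsError):
            gds_itemwise(cohort2000, "sex")


class TestAnova:
    @staticmethod
    def _null_cohort(rng, n_per_cell=40, effect=0.0):
        rows = []
        for certain in (0, 1):
            for impaired in (0, 1):
                for i in range(n_per_cell):
                    rows.append({
                        "triage_label": (
                            "certain_impaired" if certain else "uncertain"
                        ),
                        "true_state": "impaired" if impaired else "healthy",
                        "diagnosis": "none",
                        "gds_total": rng.normal(effect * certain, 1.0),
                    })
        return pd.DataFrame(rows)

    def test_matches_statsmodels_reference(self, rng):
        import statsmodels.api as sm
        from statsmodels.formula.api import ols

        cohort = self._null_cohort(rng, n_per_cell=25, effect=0.4)
        res = anova_subsampled(cohort, repeats=1, seed=0)
        # with equal cells the subsample is the full table
        df = cohort.copy()
        df["certain"] = df["triage_label"].ne("uncertain").astype(int)
        df["impaired"] = df["true_state"].eq("impaired").astype(int)
        ref = sm.stats.anova_lm(
            ols("gds_total ~ certain * impaired", data=df).fit(), typ=2,
        )
        assert res.mean_p["certainty"] == pytest.approx(
            ref.loc["certain", "PR(>F)"], abs=1e-10,
        )
        assert res.mean_p["impairment"] == pytest.approx(
            ref.loc["impaired", "PR(>F)"], abs=1e-10,
        )
        assert res.mean_p["interaction"] == pytest.approx(
            ref.loc["certain:impaired", "PR(>F)"], abs=1e-10,
        )

    def test_zero_variance_reported_absent(self, rng):
        cohort = self._null_cohort(rng, n_per_cell=10)
        cohort["gds_total"] = 2.0
        res = anova_subsampled(cohort, repeats=3, seed=0)
        assert np.isnan(res.mean_p["certainty"])

    def test_injected_certainty_effect_detected(self, rng):
        cohort = self._null_cohort(rng, n_per_cell=100, effect=2.0)
        res = anova_subsampled(cohort, repeats=20, seed=1)
        assert res.mean_p["certainty"] < 0.001
        assert res.mean_p["impairment"] > 0.1

    def test_reproducible_under_seed(self, rng):
        cohort = self._null_cohort(rng, n_per_cell=30, effect=0.5)
        a = anova_subsampled(cohort, repeats=10, seed=4).mean_p
        b = anova_subsampled(cohort, repeats=10, seed=4).mean_p
        assert a == b

    def test_empty_cell_rejected(self, rng):
        cohort = self._null_cohort(rng, n_per_cell=10)
        cohort = cohort[~(
            cohort["triage_label"].ne("uncertain")
            & cohort["true_state"].eq("impaired")
        )]
        with pytest.raises(StatsError, match="empty cell"):
            anova_subsampled(cohort, repeats=2, seed=0)
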