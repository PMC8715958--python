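"""Generator: atlas geometry, cohort calibration, trajectories, phantoms."""

import numpy as np
import pandas as pd
import pytest

from petriage.longitudinal import fit_trend
from petriage.synthetic import (
    AD_PATTERN,
    DEPRESSION_PATTERN,
    GDS_ITEMS,
    ROI_NAMES,
    AtlasSizingError,
    GeneratorConfig,
    GeneratorError,
    VolumeParams,
    build_atlas,
    generate_cohort,
    generate_longitudinal,
    generate_volume,
)
from petriage.triage import CERTAIN_HEALTHY, CERTAIN_IMPAIRED, UNCERTAIN, triage_cohort


class TestAtlas:
    def test_all_required_rois_present_and_disjoint(self, atlas32):
        assert sorted(atlas32.names.values()) == sorted(ROI_NAMES)
        for label in atlas32.names:
            assert (atlas32.labels == label).sum() >= 1
        # disjointness is structural: every voxel holds at most one label
        assert atlas32.labels.max() <= len(ROI_NAMES)

    def test_pons_outside_cerebral_mask(self, atlas32):
        pons = atlas32.roi_mask("pons")
        assert pons.any()
        assert not (pons & atlas32.brain_mask).any()

    def test_cerebral_rois_inside_brain_mask(self, atlas32):
        for label, name in atlas32.names.items():
            if name != "pons":
                roi = atlas32.labels == label
                assert not (roi & ~atlas32.brain_mask).any(), name

    def test_deterministic_construction(self):
        a, b = build_atlas(32), build_atlas(32)
        np.testing.assert_array_equal(a.labels, b.labels)
        np.testing.assert_array_equal(a.brain_mask, b.brain_mask)

    def test_too_small_grid_raises_sizing_error(self):
        with pytest.raises(AtlasSizingError):
            build_atlas(8)


class TestConfig:
    def test_invalid_proportions_rejected(self):
        with pytest.raises(GeneratorError):
            GeneratorConfig(group_proportions=(0.5, 0.4, 0.2))

    def test_invalid_effect_fraction_rejected(self):
        with pytest.raises(GeneratorError):
            VolumeParams(delta_ad=1.2)

    def test_yaml_round_trip(self, tmp_path):
        cfg = GeneratorConfig(n_samples=50, seed=9)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        back = GeneratorConfig.from_yaml(path)
        assert back.n_samples == 50 and back.seed == 9
        assert back.volume_params == cfg.volume_params


class TestCohort:
    def test_triage_reproduces_intended_labels(self, cohort2000):
        labelled, _ = triage_cohort(cohort2000)
        assert (labelled["triage_label"] == cohort2000["triage_label"]).all()

    def test_uncertain_fraction_matches_published_rate(self, cohort2000):
        frac = (cohort2000["triage_label"] == UNCERTAIN).mean()
        assert frac == pytest.approx(1741 / 2386, abs=0.05)

    def test_mmse_means_match_demographic_table(self, cohort2000):
        by = cohort2000.groupby("triage_label")["mmse_recall"].mean()
        assert by[CERTAIN_IMPAIRED] == pytest.approx(0.19, abs=0.15)
        assert by[CERTAIN_HEALTHY] == pytest.approx(2.87, abs=0.15)

    def test_adas_means_match_table_up_to_truncation_bias(self, cohort2000):
        # rejection against the triage rule truncates the ADAS normal
        # (integer scores make the certain-impaired cut effectively 11.5,
        # truncated-normal mean shift ~ -0.5, similarly +0.5 for healthy)
        by = cohort2000.groupby("triage_label")["adas_recall"].mean()
        assert by[CERTAIN_IMPAIRED] == pytest.approx(8.49, abs=0.75)
        assert by[CERTAIN_HEALTHY] == pytest.approx(25.02, abs=0.75)
        assert by[UNCERTAIN] == pytest.approx(17.54, abs=0.6)

    def test_gds_total_counts_depression_keyed_items(self, cohort2000):
        items = cohort2000[[f"gds_{i}" for i in GDS_ITEMS]]
        assert (items.sum(axis=1) == cohort2000["gds_total"]).all()
        assert items.isin([0, 1]).all().all()

    def test_energy_item_mirrors_energetic_flag(self, cohort2000):
        assert (
            cohort2000["gds_energy"] == 1 - cohort2000["energetic"]
        ).all()

    def test_certain_true_state_follows_triage(self, cohort2000):
        ci = cohort2000[cohort2000.triage_label == CERTAIN_IMPAIRED]
        ch = cohort2000[cohort2000.triage_label == CERTAIN_HEALTHY]
        assert (ci["true_state"] == "impaired").all()
        assert (ch["true_state"] == "healthy").all()

    def test_byte_identical_under_same_seed(self):
        cfg = GeneratorConfig(n_samples=100, seed=7)
        a = generate_cohort(cfg).to_csv()
        b = generate_cohort(GeneratorConfig(n_samples=100, seed=7)).to_csv()
        assert a == b

    def test_infeasible_scores_raise_configuration_error(self):
        params = GeneratorConfig().score_params
        # certain-impaired scores centred deep in healthy territory can
        # never satisfy the impaired conjunction
        params[CERTAIN_IMPAIRED]["mmse_recall"] = (3.0, 0.0)
        params[CERTAIN_IMPAIRED]["cdr_memory"] = (0.0, 0.0)
        cfg = GeneratorConfig(
            n_samples=30, score_params=params, seed=0, max_resample=50,
        )
        with pytest.raises(GeneratorError, match="conflict"):
            generate_cohort(cfg)


class TestLongitudinal:
    @pytest.fixture(scope="class")
    def cohort(self):
        return generate_cohort(GeneratorConfig(n_samples=240, seed=5))

    def test_noise_free_impaired_slopes_within_published_interval(self, cohort):
        cfg = GeneratorConfig(seed=5)
        impaired = cohort[cohort["true_state"] == "impaired"].head(20)
        visits = generate_longitudinal(impaired, config=cfg, noise_scale=0.0)
        for sid, chunk in visits.groupby("sample_id"):
            slope = fit_trend(chunk, "cdr_memory").slope
            assert 0.0046 - 1e-9 <= slope <= 0.0076 + 1e-9

    def test_noise_free_fit_recovers_drawn_slope_exactly(self, cohort):
        cfg = GeneratorConfig(seed=5)
        healthy = cohort[cohort["true_state"] == "healthy"].head(5)
        visits, slopes = generate_longitudinal(
            healthy, config=cfg, noise_scale=0.0, return_slopes=True,
        )
        for sid, chunk in visits.groupby("sample_id"):
            fit = fit_trend(chunk, "cdr_memory")
            assert fit.slope == pytest.approx(slopes[sid], abs=1e-12)

    def test_visit_months_are_interval_multiples(self, cohort):
        visits = generate_longitudinal(cohort.head(3), config=GeneratorConfig())
        months = np.sort(visits["months"].unique())
        np.testing.assert_allclose(months, np.arange(6, 97, 6))

    def test_impaired_decline_steeper_than_healthy(self, cohort):
        from scipy import stats

        cfg = GeneratorConfig(seed=5)
        visits = generate_longitudinal(cohort, config=cfg)
        slopes = {}
        for sid, chunk in visits.groupby("sample_id"):
            slopes[sid] = fit_trend(chunk, "cdr_memory").slope
        s = pd.Series(slopes)
        state = cohort.set_index("id")["true_state"]
        imp = s[state == "impaired"]
        hea = s[state == "healthy"]
        t, p = stats.ttest_ind(imp, hea, equal_var=False)
        assert t > 0 and p < 1e-3

    def test_bad_interval_rejected(self, cohort):
        with pytest.raises(GeneratorError):
            generate_longitudinal(cohort.head(2), interval=0)
        with pytest.raises(GeneratorError):
            generate_longitudinal(cohort.head(2), interval=12, horizon=6)


class TestVolumes:
    @staticmethod
    def _sample(triage_label, true_state, energetic):
        return {
            "triage_label": triage_label, "true_state": true_state,
            "energetic": energetic,
        }

    @pytest.fixture(scope="class")
    def quiet_config(self):
        cfg = GeneratorConfig(seed=0)
        cfg.volume_params = VolumeParams(noise_sd=0.0)
        return cfg

    def test_precuneus_ratio_equals_effect_fraction(self, atlas32, quiet_config):
        imp = generate_volume(
            self._sample(CERTAIN_IMPAIRED, "impaired", 1), atlas32, quiet_config, 0,
        )
        hea = generate_volume(
            self._sample(CERTAIN_HEALTHY, "healthy", 1), atlas32, quiet_config, 0,
        )
        roi = atlas32.roi_mask("precuneus")
        ratio = imp.data[roi].mean() / hea.data[roi].mean()
        assert ratio == pytest.approx(
            1 - quiet_config.volume_params.delta_ad, abs=1e-6
        )

    def test_energetic_flag_only_touches_depression_rois(self, atlas32, quiet_config):
        a = generate_volume(
            self._sample(CERTAIN_HEALTHY, "healthy", 1), atlas32, quiet_config, 0,
        )
        b = generate_volume(
            self._sample(CERTAIN_HEALTHY, "healthy", 0), atlas32, quiet_config, 0,
        )
        diff = a.data != b.data
        dep = atlas32.pattern_mask(DEPRESSION_PATTERN)
        assert diff.any()
        assert not (diff & ~dep).any()

    def test_severity_only_touches_ad_rois(self, atlas32, quiet_config):
        a = generate_volume(
            self._sample(CERTAIN_IMPAIRED, "impaired", 1), atlas32, quiet_config, 0,
        )
        b = generate_volume(
            self._sample(CERTAIN_HEALTHY, "healthy", 1), atlas32, quiet_config, 0,
        )
        diff = a.data != b.data
        ad = atlas32.pattern_mask(AD_PATTERN)
        assert diff.any()
        assert not (diff & ~ad).any()

    def test_pons_set_to_reference_intensity(self, atlas32, quiet_config):
        vol = generate_volume(
            self._sample(UNCERTAIN, "impaired", 0), atlas32, quiet_config, 0,
        )
        pons = atlas32.roi_mask("pons")
        assert np.allclose(
            vol.data[pons], quiet_config.volume_params.pons_intensity
        )

    def test_same_seed_gives_identical_noise(self, atlas32, default_config):
        s = self._sample(UNCERTAIN, "healthy", 1)
        a = generate_volume(s, atlas32, default_config, 42)
        b = generate_volume(s, atlas32, default_config, 42)
        np.testing.assert_array_equal(a.data, b.data)

    def test_grid_mismatch_raises(self, default_config):
        atlas16 = build_atlas(16)
        with pytest.raises(GeneratorError, match="grid"):
            generate_volume(
                self._sample(UNCERTAIN, "healthy", 1), atlas16, default_config, 0,
            )
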