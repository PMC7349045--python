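"""Synthetic cohort generator: determinism, score ranges, process structure,
coupling recovery and the observation (missingness) process."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import moodcast as mc
from moodcast.cohort import (
    BASE_COUPLINGS,
    DASS_ITEM_MAX,
    DASS_N_ITEMS,
    dass_depression_score,
    generate_dass_items,
    simulate_weather,
)
from moodcast.exceptions import ConfigError


class TestProfiles:
    def test_count_matches_request(self):
        profiles = mc.generate_profiles(mc.CohortConfig(n_persons=31, seed=1))
        assert len(profiles) == 31

    def test_baseline_scores_within_questionnaire_range(self):
        for seed in range(5):
            for p in mc.generate_profiles(mc.CohortConfig(n_persons=20, seed=seed)):
                assert 0 <= p.baseline_dass_d <= 42

    def test_deterministic_given_seed(self):
        cfg = mc.CohortConfig(n_persons=8, seed=3)
        a = mc.generate_profiles(cfg)
        b = mc.generate_profiles(cfg)
        assert [(p.person_id, p.race_group, p.baseline_dass_d, p.coupling_vector) for p in a] == [
            (p.person_id, p.race_group, p.baseline_dass_d, p.coupling_vector) for p in b
        ]

    def test_invalid_race_distribution_rejected(self):
        with pytest.raises(ConfigError):
            mc.generate_profiles(
                mc.CohortConfig(race_distribution={"a": 0.5, "b": 0.6}, seed=0)
            )

    def test_flip_fraction_flips_coupling_signs(self):
        cfg = mc.CohortConfig(
            n_persons=9, flip_fraction=1 / 3, coupling_heterogeneity=0.0, seed=4
        )
        profiles = mc.generate_profiles(cfg)
        signs = [np.sign(p.coupling_vector["hr_mean"]) for p in profiles]
        assert signs.count(-np.sign(BASE_COUPLINGS["hr_mean"])) == 3


class TestBaselineQuestionnaire:
    def test_attainable_score_range_is_0_to_42(self):
        assert dass_depression_score(np.zeros(DASS_N_ITEMS, dtype=int)) == 0
        assert dass_depression_score(np.full(DASS_N_ITEMS, DASS_ITEM_MAX)) == 42

    def test_generated_items_stay_on_item_scale(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            items = generate_dass_items(rng)
            assert items.min() >= 0 and items.max() <= DASS_ITEM_MAX
            assert 0 <= dass_depression_score(items) <= 42

    def test_wrong_item_count_rejected(self):
        with pytest.raises(ConfigError):
            dass_depression_score(np.zeros(7, dtype=int))


class TestLatentMood:
    def _profile(self, cfg):
        return mc.generate_profiles(cfg)[0]

    def test_degenerate_process_is_constant_at_intercept(self):
        cfg = mc.CohortConfig(
            n_persons=1, n_days=2, ar_coefficient=0.0, diurnal_amplitude=0.0,
            noise_sd=0.0, seed=5,
        )
        latent = mc.simulate_latent_mood(self._profile(cfg), cfg)
        assert np.ptp(latent) == 0.0

    def test_pure_diurnal_is_exact_24h_sinusoid(self):
        cfg = mc.CohortConfig(
            n_persons=1, n_days=3, ar_coefficient=0.0, diurnal_amplitude=5.0,
            noise_sd=0.0, seed=5,
        )
        latent = mc.simulate_latent_mood(self._profile(cfg), cfg)
        hours = np.arange(cfg.n_hours)
        expected = latent[0] + 5.0 * np.sin(2 * np.pi * hours / 24.0)
        np.testing.assert_allclose(latent, expected, atol=1e-12)
        assert np.isclose((latent - latent.mean()).max(), 5.0, atol=1e-6)

    def test_ar1_lag1_autocorrelation_recovered(self):
        # empirical ACF oracle over a long simulated series
        cfg = mc.CohortConfig(
            n_persons=1, n_days=300, ar_coefficient=0.9, diurnal_amplitude=0.0,
            noise_sd=1.0, seed=6,
        )
        x = mc.simulate_latent_mood(self._profile(cfg), cfg)
        x = x - x.mean()
        acf1 = np.dot(x[1:], x[:-1]) / np.dot(x, x)
        assert abs(acf1 - 0.9) < 0.03


class TestSensors:
    def test_weather_shared_across_persons(self, tiny_cohort):
        panel, _ = tiny_cohort
        df = panel.data
        for col in ["temperature", "humidity", "precipitation"]:
            wide = df.pivot(index="hour_index", columns="person_id", values=col)
            wide = wide.dropna()  # sensor MCAR dropout differs by person
            assert (wide.nunique(axis=1) == 1).all()

    def test_null_coupling_sensors_independent_of_latent(self):
        # diurnal term off: sensor daily cycles are clock-driven, so the
        # mood-sensor dependence being tested is the coupling channel alone
        cfg = mc.CohortConfig(
            n_persons=1, n_days=250, coupling_scale=0.0, sensor_missing_rate=0.0,
            diurnal_amplitude=0.0, seed=7,
        )
        panel, truth = mc.generate_complete_panel(cfg)
        latent = truth.latent["p000"]
        for col in ["hr_mean", "hrv_rmssd", "light_level"]:
            r, p = stats.pearsonr(latent, panel.data[col])
            n = latent.size
            half = 1.96 / np.sqrt(n - 3)
            z = np.arctanh(r)
            assert z - half < 0 < z + half, f"{col}: r={r:.3f} CI excludes 0"

    def test_negative_calls_coupling_recovered_by_rank_correlation(self):
        cfg = mc.CohortConfig(
            n_persons=1, n_days=250, coupling_scale=1.0, coupling_heterogeneity=0.0,
            sensor_missing_rate=0.0, seed=8,
        )
        profile = mc.generate_profiles(cfg)[0]
        profile.coupling_vector["outgoing_calls"] = -0.5
        latent = mc.simulate_latent_mood(profile, cfg)
        sensors = mc.simulate_sensors(latent, profile, cfg, simulate_weather(cfg))
        rho = stats.spearmanr(latent, sensors["outgoing_calls"]).statistic
        assert rho < -0.1

    def test_calls_are_nonnegative_integers_and_source_in_dictionary(self, tiny_cohort):
        panel, _ = tiny_cohort
        calls = panel.data["outgoing_calls"].dropna()
        assert (calls >= 0).all() and np.allclose(calls, np.round(calls))
        src = panel.data["location_source"].dropna()
        assert set(src) <= {"gps", "wifi"}


class TestMissingness:
    def test_full_compliance_all_wake_hours_no_mood_missingness(self):
        cfg = mc.CohortConfig(
            n_persons=2, n_days=7, wake_hours_per_day=24, compliance_rate=1.0,
            sensor_missing_rate=0.0, seed=9,
        )
        panel, _ = mc.generate_cohort(cfg)
        assert panel.data["sad"].notna().all()
        assert panel.data["lonely"].notna().all()

    def test_zero_compliance_no_mood_observations(self):
        cfg = mc.CohortConfig(n_persons=2, n_days=3, compliance_rate=0.0, seed=9)
        panel, _ = mc.generate_cohort(cfg)
        assert panel.data["sad"].isna().all()

    def test_expected_prompt_count_matches_study_compliance(self):
        # 16 wake hours x 7 prompting days x 0.46 compliance ~ 52 prompts
        cfg = mc.CohortConfig(
            n_persons=31, n_days=8, wake_hours_per_day=16, compliance_rate=0.46,
            prompt_days=7, seed=10,
        )
        panel, _ = mc.generate_cohort(cfg)
        per_person = panel.data.groupby("person_id")["sad"].apply(lambda s: s.notna().sum())
        n_trials = 16 * 7
        expect = n_trials * 0.46
        se = np.sqrt(n_trials * 0.46 * 0.54 / 31)
        assert abs(per_person.mean() - expect) < 4 * se

    def test_mood_only_during_wake_hours(self, tiny_cohort):
        panel, _ = tiny_cohort
        asleep = panel.data[panel.data["awake"] == 0]
        assert asleep["sad"].isna().all()


class TestCohortComposition:
    def test_grid_size(self):
        cfg = mc.CohortConfig(n_persons=31, n_days=8, seed=12)
        panel, _ = mc.generate_cohort(cfg)
        assert len(panel.data) == 31 * 192
        assert panel.data.groupby("person_id").size().eq(192).all()

    def test_byte_identical_across_runs(self, tiny_config):
        a, _ = mc.generate_cohort(tiny_config)
        b, _ = mc.generate_cohort(tiny_config)
        pd.testing.assert_frame_equal(a.data, b.data)

    def test_ground_truth_retained(self, tiny_cohort, tiny_config):
        panel, truth = tiny_cohort
        assert set(truth.latent) == set(panel.person_ids)
        assert all(v.size == tiny_config.n_hours for v in truth.latent.values())
        assert set(truth.couplings["p000"]) == set(BASE_COUPLINGS)

    def test_sad_lonely_convergent_validity_near_066(self):
        cfg = mc.CohortConfig(
            n_persons=25, n_days=8, compliance_rate=1.0, wake_hours_per_day=24,
            prompt_days=8, sensor_missing_rate=0.0, seed=13,
        )
        panel, _ = mc.generate_cohort(cfg)
        r = stats.pearsonr(panel.data["sad"], panel.data["lonely"]).statistic
        assert 0.5 < r < 0.8
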