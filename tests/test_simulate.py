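"""Synthetic cohort generator: determinism, schedule geometry, group
splits, planted-episode recovery and artefact robustness."""

import numpy as np
import pytest

from vitalwatch import (
    CohortSimParams,
    GroupLabel,
    ThresholdTier,
    analyze_cohort,
    analyze_patient,
    assign_group,
    detect_channel_episodes,
    generate_cohort,
    generate_patient,
    load_scenario,
    plant_interval,
    quiet_params,
)
from vitalwatch.preprocess import to_minute_grid
from vitalwatch.simulate import bp_schedule_offsets


def small(**kw):
    defaults = dict(n_patients=5, monitoring_hours=24, spo2_interval_s=30, seed=7)
    defaults.update(kw)
    return CohortSimParams(**defaults)


class TestDeterminism:
    def test_same_seed_reproduces_every_sample(self):
        a = generate_patient(small(), 2)
        b = generate_patient(small(), 2)
        assert a.first_sae_time == b.first_sae_time
        for ch in a.series:
            assert np.array_equal(a.series[ch].values, b.series[ch].values)
            assert np.array_equal(a.series[ch].times, b.series[ch].times)

    def test_different_seed_changes_streams_not_schema(self):
        a = generate_patient(small(seed=1), 0)
        b = generate_patient(small(seed=2), 0)
        assert set(a.series) == set(b.series) == {"HR", "RR", "SPO2", "SBP"}
        assert not np.array_equal(a.series["HR"].values, b.series["HR"].values)

    def test_artifact_stream_is_independent(self):
        # switching artefacts on must not disturb the signal draws
        none = {"HR": 0.0, "RR": 0.0, "SPO2": 0.0, "SBP": 0.0}
        clean = generate_patient(small(artifact_rate=none), 1)
        arty = generate_patient(
            small(artifact_rate={"HR": 0.0, "RR": 0.0, "SPO2": 0.2, "SBP": 0.0}), 1)
        assert np.array_equal(clean.series["HR"].values, arty.series["HR"].values)
        assert np.array_equal(clean.series["SBP"].values, arty.series["SBP"].values)


class TestDeterministicSkeleton:
    def test_noise_free_patient_is_baseline_plus_circadian(self):
        params = quiet_params(n_patients=1, monitoring_hours=24,
                              spo2_interval_s=60, seed=0)
        p = generate_patient(params, 0)
        hr = p.series["HR"]
        start_mod = int((p.monitoring_start
                         - p.monitoring_start.astype("datetime64[D]"))
                        / np.timedelta64(1, "s")) // 60
        k = np.arange(len(hr))
        expected = 75.0 + 6.0 * np.cos(
            2 * np.pi * ((start_mod + k) / 60.0 - 16.0) / 24.0)
        assert np.allclose(hr.values, expected, atol=1e-9)

    def test_spo2_ceiling_respected(self):
        p = generate_patient(small(seed=3), 0)
        assert p.series["SPO2"].values.max() <= 100.0


class TestBpSchedule:
    def test_full_day_has_39_measurements(self):
        # 30 day marks at 30-min spacing over 15 h + 9 night marks hourly
        offs = bp_schedule_offsets(7 * 60, 1440)
        assert len(offs) == 39

    @pytest.mark.parametrize("start_mod", [0, 420, 600, 1319, 1439])
    def test_any_24h_window_has_39_measurements(self, start_mod):
        assert len(bp_schedule_offsets(start_mod, 1440)) == 39

    def test_day_marks_every_30_minutes(self):
        offs = bp_schedule_offsets(8 * 60, 120)  # 08:00-10:00
        assert offs.tolist() == [0, 30, 60, 90]


class TestGroupSplit:
    def test_paper_sized_cohort_splits_as_expected(self):
        params = CohortSimParams(n_patients=491, seed=5, monitoring_hours=79)
        records = [generate_patient(params, i) for i in range(491)]
        labels = [assign_group(r) for r in records]
        n_during = sum(l is GroupLabel.SAE_DURING for l in labels)
        n_after = sum(l is GroupLabel.SAE_AFTER for l in labels)
        n_none = sum(l is GroupLabel.NO_SAE for l in labels)
        # expectations 69 / 113 / 309; allow ~3 binomial SDs
        assert abs(n_during - 69) <= 25
        assert abs(n_after - 113) <= 30
        assert abs(n_none - 309) <= 32

    def test_zero_prevalence_means_no_sae(self):
        params = small(sae_prevalence=0.0)
        assert all(r.first_sae_time is None for r in generate_cohort(params))

    def test_full_prevalence_all_during(self):
        params = small(sae_prevalence=1.0, fraction_sae_during=1.0)
        for r in generate_cohort(params):
            assert assign_group(r) is GroupLabel.SAE_DURING

    def test_all_after_when_fraction_during_is_zero(self):
        params = small(sae_prevalence=1.0, fraction_sae_during=0.0)
        for r in generate_cohort(params):
            assert r.first_sae_time is not None
            assert r.first_sae_time > r.monitoring_end


class TestPlantedEpisodes:
    def test_planted_desaturation_recovered_exactly(self):
        params = quiet_params(n_patients=1, monitoring_hours=24,
                              spo2_interval_s=60, seed=0)
        p = generate_patient(params, 0)
        plant_interval(p, "SPO2", start_minute=100, duration=7, value=84.0)
        plant_interval(p, "SPO2", start_minute=300, duration=3, value=84.0)
        grid = to_minute_grid(p.series["SPO2"],
                              (p.monitoring_start, p.monitoring_end))
        t = ThresholdTier(channel="SPO2", direction="below", threshold=85,
                          min_persistence=5)
        eps = detect_channel_episodes(grid, t, 5)
        assert [(e.start, e.end, e.duration) for e in eps] == [(100, 106, 7.0)]

    def test_planted_tachycardia_through_full_analysis(self):
        params = quiet_params(n_patients=1, monitoring_hours=24,
                              spo2_interval_s=60, seed=0)
        p = generate_patient(params, 0)
        plant_interval(p, "HR", start_minute=200, duration=65, value=120.0)
        res = analyze_patient(p)
        out = res.tiers["HR>110>=60min"]
        assert out.n_episodes == 1
        assert out.condition_minutes == 65.0
        assert out.normalized_count == pytest.approx(1.0)

    def test_artifact_spikes_do_not_change_episode_counts(self):
        """SpO2 spike artefacts violate the slope rule by construction, so
        the filter removes them and recovered episodes are unchanged."""
        base = dict(n_patients=8, monitoring_hours=24, spo2_interval_s=10,
                    seed=21, gap_rate_per_hour={"HR": 0.0, "RR": 0.0, "SPO2": 0.0},
                    noise_sd={"HR": 0.0, "RR": 0.0, "SPO2": 0.0},
                    desat_rate_per_hour=1.5)
        clean = analyze_cohort(generate_cohort(CohortSimParams(
            **base, artifact_rate={"HR": 0, "RR": 0, "SPO2": 0.0, "SBP": 0})))
        arty = analyze_cohort(generate_cohort(CohortSimParams(
            **base, artifact_rate={"HR": 0, "RR": 0, "SPO2": 0.01, "SBP": 0})))
        for pc, pa in zip(clean.patients, arty.patients):
            for label, out in pc.tiers.items():
                if out.tier.channel == "SPO2":
                    assert pa.tiers[label].n_episodes == out.n_episodes


class TestPreSaeEffect:
    def test_step_effect_raises_hr_only_before_sae(self):
        params = quiet_params(
            n_patients=1, monitoring_hours=24, spo2_interval_s=60, seed=0,
            sae_prevalence=1.0, fraction_sae_during=1.0,
            sae_time_mode="end_of_monitoring",
            pre_sae_effect={"HR": 45.0}, pre_sae_effect_hours=6,
            pre_sae_effect_shape="step")
        p = generate_patient(params, 0)
        hr = p.series["HR"].values
        assert hr[: 18 * 60].max() < 110
        assert hr[18 * 60 :].min() > 110

    def test_scenarios_load_by_name(self):
        for name in ("null", "tachycardia-effect", "hypotension-effect",
                     "paper-like"):
            params = load_scenario(name, seed=1)
            assert params.seed == 1
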