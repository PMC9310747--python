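"""Grouping by SAE timing, exposure windows, 24-h normalization and
day/night stratification."""

import numpy as np
import pytest

from vitalwatch import (
    AnalysisConfig,
    ExposureWindow,
    GroupLabel,
    PatientRecord,
    analyze_patient,
    assign_group,
    build_contingency,
    day_night_partition,
    exposure_window,
    has_abnormality,
    normalized_counts,
)

from conftest import T0, make_series, ts

H = 3600


def patient(mon_hours=79, sae_hours=None):
    return PatientRecord(
        patient_id="P1",
        monitoring_start=T0,
        monitoring_end=ts(mon_hours * H),
        first_sae_time=None if sae_hours is None else ts(sae_hours * H),
    )


class TestAssignGroup:
    def test_sae_inside_monitoring(self):
        assert assign_group(patient(79, 30)) is GroupLabel.SAE_DURING

    def test_sae_on_day_eight(self):
        assert assign_group(patient(96, 8 * 24)) is GroupLabel.SAE_AFTER

    def test_no_sae(self):
        assert assign_group(patient(79, None)) is GroupLabel.NO_SAE

    def test_sae_beyond_followup_counts_as_no_sae(self):
        assert assign_group(patient(79, 31 * 24)) is GroupLabel.NO_SAE

    def test_sae_before_monitoring_is_an_error(self):
        p = PatientRecord("P1", ts(H), ts(10 * H), first_sae_time=T0)
        with pytest.raises(ValueError, match="precedes monitoring"):
            assign_group(p)


class TestExposureWindow:
    def test_full_24h_before_sae(self):
        p = patient(79, 30)
        w = exposure_window(p, GroupLabel.SAE_DURING)
        assert w.start == ts(6 * H) and w.end == ts(30 * H)
        assert w.normalization_factor == pytest.approx(1.0)

    def test_short_pre_sae_history_scales_up(self):
        p = patient(79, 12)
        w = exposure_window(p, GroupLabel.SAE_DURING)
        assert w.start == T0 and w.end == ts(12 * H)
        assert w.normalization_factor == pytest.approx(2.0)

    def test_long_monitoring_scales_down(self):
        p = patient(48, None)
        w = exposure_window(p, GroupLabel.NO_SAE)
        assert w.normalization_factor == pytest.approx(0.5)

    def test_normalized_counts_scaling(self):
        w24 = ExposureWindow(T0, ts(24 * H), 1.0)
        w48 = ExposureWindow(T0, ts(48 * H), 0.5)
        w12 = ExposureWindow(T0, ts(12 * H), 2.0)
        assert normalized_counts(2, 100, w24) == (2.0, 100.0)
        assert normalized_counts(1, 100, w48) == (0.5, 50.0)
        assert normalized_counts(3, 100, w12) == (6.0, 200.0)

    def test_abnormality_flag_boundary(self):
        assert not has_abnormality(0.5)
        assert has_abnormality(1.0)
        assert not has_abnormality(0.0)


class TestDayNight:
    def test_full_calendar_day_splits_900_540(self, config):
        midnight = np.datetime64("2022-03-02T00:00:00", "s")
        w = ExposureWindow(midnight, midnight + np.timedelta64(24 * H, "s"), 1.0)
        assert day_night_partition(w, config) == (900, 540)

    def test_evening_window_straddles_the_boundary(self, config):
        start = np.datetime64("2022-03-01T21:00:00", "s")
        w = ExposureWindow(start, start + np.timedelta64(2 * H, "s"), 12.0)
        assert day_night_partition(w, config) == (60, 60)

    @pytest.mark.parametrize("start_hour, hours", [(0, 7), (5, 13), (13, 30), (18, 96)])
    def test_partition_is_exhaustive(self, config, start_hour, hours):
        start = np.datetime64("2022-03-01T00:00:00", "s") + np.timedelta64(start_hour * H, "s")
        w = ExposureWindow(start, start + np.timedelta64(hours * H, "s"), 1.0)
        day, night = day_night_partition(w, config)
        assert day + night == hours * 60


class TestContingency:
    def test_counts_match_direct_tally(self):
        flags = {
            GroupLabel.SAE_DURING: [True] * 11 + [False] * 59,
            GroupLabel.SAE_AFTER: [True] * 8 + [False] * 104,
            GroupLabel.NO_SAE: [True] * 12 + [False] * 297,
        }
        t = build_contingency(flags)
        assert t.with_abnormality.tolist() == [11, 8, 12]
        assert t.group_sizes.tolist() == [70, 112, 309]

    def test_no_abnormalities_gives_zero_top_row(self):
        t = build_contingency({GroupLabel.SAE_DURING: [False] * 5,
                               GroupLabel.NO_SAE: [False] * 7})
        assert t.with_abnormality.tolist() == [0, 0]

    def test_empty_group_is_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            build_contingency({GroupLabel.SAE_DURING: [],
                               GroupLabel.NO_SAE: [True]})


def test_post_sae_data_never_enters_the_analysis():
    """A SAE-during patient's tachycardia after the event must not count."""
    sae_h = 30
    n_min = 79 * 60
    seconds = [60 * k for k in range(n_min)]
    hr = [70.0 if s < sae_h * H else 140.0 for s in seconds]
    p = PatientRecord(
        "P1", T0, ts(79 * H),
        series={"HR": make_series("HR", seconds, hr)},
        first_sae_time=ts(sae_h * H),
    )
    res = analyze_patient(p)
    assert res.group is GroupLabel.SAE_DURING
    for out in res.tiers.values():
        if out.tier.channel == "HR" and out.tier.direction == "above":
            assert out.n_episodes == 0
            assert out.condition_minutes == 0
        for e in out.episodes:
            assert np.datetime64(e["end"], "s") <= res.window.end
    assert res.window.end == ts(sae_h * H)


def test_monitoring_capped_at_96_hours():
    n_min = 100 * 60
    seconds = [60 * k for k in range(n_min)]
    p = PatientRecord("P1", T0, ts(100 * H),
                      series={"HR": make_series("HR", seconds, [70.0] * n_min)})
    res = analyze_patient(p)
    assert res.window.length_minutes == pytest.approx(96 * 60)


def test_coverage_based_normalization_divides_by_observed_minutes():
    cfg = AnalysisConfig(coverage_based_normalization=True,
                         locf_channels=())
    seconds = [60 * k for k in range(720)]  # 12 h of data in a 24-h stay
    p = PatientRecord("P1", T0, ts(24 * H),
                      series={"HR": make_series("HR", seconds, [70.0] * 720)})
    res = analyze_patient(p, cfg)
    assert res.window.normalization_factor == pytest.approx(2.0)
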