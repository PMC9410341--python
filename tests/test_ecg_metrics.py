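"""Burden, incidence, heart rate, QTc and Bland–Altman agreement."""

import math
import warnings

import numpy as np
import pytest

from stormquant import (
    EcgSimSpec,
    Episode,
    EpisodeSet,
    bland_altman,
    classify_beat_origin,
    compute_burden,
    compute_heart_rate,
    compute_incidence,
    compute_qtc,
    cycles_to_minutes,
    detect_r_peaks,
    detect_vt_episodes,
    simulate_ecg,
)
from stormquant.simulate import PlantedEpisode


def eset(intervals, kind="VT", horizon=86400.0):
    return EpisodeSet(
        [Episode(kind, a, b, max(4, int((b - a) / 0.06))) for a, b in intervals],
        horizon,
    )


class TestBurden:
    def test_additivity_and_hourly_partition(self):
        out = compute_burden(eset([(10.0, 13.0), (100.0, 107.0)]), horizon_s=86400.0)
        assert out["VT"]["burden_s"] == pytest.approx(10.0)
        assert out["VT"]["per_bin_s"].sum() == pytest.approx(10.0)
        assert out["VT"]["per_bin_s"].size == 24

    def test_ep_mode_excludes_sub_second_vt(self):
        out = compute_burden(eset([(5.0, 5.8)]), horizon_s=3600.0, min_episode_s=1.0)
        assert out["VT"]["burden_s"] == 0.0
        assert out["VT"]["n_episodes"] == 0

    def test_empty_episode_set(self):
        out = compute_burden(eset([]), horizon_s=3600.0)
        assert out["VT"]["burden_s"] == 0.0 and out["Vfib"]["burden_s"] == 0.0

    def test_clipping_at_horizon(self):
        out = compute_burden(eset([(3500.0, 3700.0)]), horizon_s=3600.0)
        assert out["VT"]["burden_s"] == pytest.approx(100.0)
        assert out["VT"]["per_bin_s"].sum() == pytest.approx(out["VT"]["burden_s"])

    def test_episode_spanning_hour_boundary_is_split(self):
        out = compute_burden(eset([(3590.0, 3620.0)]), horizon_s=7200.0)
        assert out["VT"]["per_bin_s"][0] == pytest.approx(10.0)
        assert out["VT"]["per_bin_s"][1] == pytest.approx(20.0)

    def test_invalid_horizon(self):
        with pytest.raises(ValueError):
            compute_burden(eset([]), horizon_s=0.0)


class TestIncidence:
    def test_nine_of_ten(self):
        rows = [{"VT_burden_s": 5.0 if i < 9 else 0.0, "Vfib_burden_s": 0.0}
                for i in range(10)]
        out = compute_incidence(rows)
        assert out["VT_incidence"] == pytest.approx(0.9)
        assert out["VT_burden_mean_s"] == pytest.approx(5.0)

    def test_all_zero_burden_flagged(self):
        out = compute_incidence([{"VT_burden_s": 0.0, "Vfib_burden_s": 0.0}] * 4)
        assert out["VT_incidence"] == 0.0
        assert out["VT_burden_subset_empty"]
        assert math.isnan(out["VT_burden_mean_s"])

    def test_subject_with_both_kinds_counted_in_each(self):
        out = compute_incidence([{"VT_burden_s": 2.0, "Vfib_burden_s": 3.0}])
        assert out["VT_incidence"] == 1.0 and out["Vfib_incidence"] == 1.0

    def test_empty_cohort_rejected(self):
        with pytest.raises(ValueError):
            compute_incidence([])


def test_constant_rr_gives_600_bpm():
    from stormquant import BeatList

    times = np.arange(20) * 0.1
    beats = BeatList(times, np.full(20, 0.01), np.ones(20), np.ones(20),
                     np.array(["sinus"] * 20, dtype=object))
    out = compute_heart_rate(beats, EpisodeSet([], 10.0))
    assert out["sr_bpm"] == pytest.approx(600.0)
    assert not out["vt_defined"]


def test_synthetic_sr_and_vt_rates_recovered(storm_trace, storm_beats):
    from stormquant import detect_vfib_episodes, resolve_episode_precedence

    trace, _ = storm_trace
    eps = resolve_episode_precedence(
        detect_vt_episodes(storm_beats, trace.duration_s),
        detect_vfib_episodes(trace, storm_beats),
    )
    out = compute_heart_rate(storm_beats, eps)
    assert out["sr_bpm"] == pytest.approx(550.0, rel=0.01)
    assert out["vt_bpm"] == pytest.approx(1100.0, rel=0.01)
    assert out["vt_bpm"] / out["sr_bpm"] == pytest.approx(2.0, rel=0.02)


class TestQtc:
    def test_rr_100ms_means_qtc_equals_qt(self):
        trace, _ = simulate_ecg(EcgSimSpec(duration_s=10.0, sinus_rate_bpm=600.0, seed=0))
        beats = classify_beat_origin(detect_r_peaks(trace))
        q = compute_qtc(trace, beats)
        assert q.qtc_s == pytest.approx(q.qt_s, abs=1e-12)

    def test_known_qt_recovered(self, sinus_trace):
        trace, gt = sinus_trace
        beats = classify_beat_origin(detect_r_peaks(trace))
        q = compute_qtc(trace, beats, n_cycles=10)
        assert q.qt_s == pytest.approx(gt.qt_s, abs=0.004)
        assert q.n_cycles_used >= 5

    def test_correction_scales_with_sqrt_rr(self):
        """At fixed measured QT, halving RR must raise QTc by sqrt(2)."""
        fast, _ = simulate_ecg(EcgSimSpec(duration_s=10.0, sinus_rate_bpm=1200.0, seed=0))
        slow, _ = simulate_ecg(EcgSimSpec(duration_s=10.0, sinus_rate_bpm=600.0, seed=0))
        qf = compute_qtc(fast, classify_beat_origin(detect_r_peaks(fast)))
        qs = compute_qtc(slow, classify_beat_origin(detect_r_peaks(slow)))
        assert qf.qtc_s / qf.qt_s == pytest.approx(
            math.sqrt(2) * qs.qtc_s / qs.qt_s, rel=1e-6
        )

    def test_fewer_than_five_cycles_rejected(self, sinus_trace):
        trace, _ = sinus_trace
        beats = classify_beat_origin(detect_r_peaks(trace))
        with pytest.raises(ValueError, match="five"):
            compute_qtc(trace, beats, n_cycles=3)


class TestBlandAltman:
    def test_identical_observers(self):
        r = bland_altman([3.0, 5.0, 7.0], [3.0, 5.0, 7.0])
        assert r.bias_pct == 0.0
        assert r.loa_low == 0.0 and r.loa_high == 0.0

    def test_five_percent_systematic_offset(self):
        b = np.array([2.0, 4.0, 9.0, 30.0])
        r = bland_altman(1.05 * b, b)
        assert r.bias_pct == pytest.approx(100 * 0.05 / 1.025)
        assert r.loa_low == pytest.approx(r.loa_high)  # constant ratio: zero spread

    def test_single_pair_has_no_limits(self):
        r = bland_altman([5.0], [4.0])
        assert math.isnan(r.loa_low) and math.isnan(r.loa_high)
        assert r.n_pairs == 1

    def test_zero_mean_pair_excluded_with_warning(self):
        with pytest.warns(UserWarning, match="zero mean"):
            r = bland_altman([0.0, 5.0], [0.0, 5.0])
        assert r.n_excluded == 1


def test_burden_cycles_to_minutes_conversion():
    assert cycles_to_minutes(10_000, 800.0) == pytest.approx(12.5)
    assert cycles_to_minutes(10_000, 800.0) >= 12.0
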