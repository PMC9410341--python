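"""VT/Vfib episode calling: printed criteria, oracle identity, precedence."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stormquant import (
    BeatList,
    classify_beat_origin,
    detect_r_peaks,
    detect_vfib_episodes,
    detect_vt_episodes,
    resolve_episode_precedence,
    simulate_ecg,
)
from stormquant.simulate import EcgSimSpec, PlantedEpisode

from oracles import brute_force_vt_intervals


def beats_from(times, origins):
    times = np.asarray(times, dtype=float)
    n = times.size
    return BeatList(
        r_peak_times_s=times,
        qrs_width_s=np.full(n, 0.01),
        template_corr=np.where(np.asarray(origins) == "sinus", 1.0, -0.5),
        amplitude_mv=np.ones(n),
        origins=np.asarray(origins, dtype=object),
    )


@pytest.mark.parametrize(
    "rr_s,n_beats,expect_episodes",
    [
        (0.070, 4, 1),   # 857 bpm, 4 beats: VT
        (0.080, 4, 0),   # 750 bpm: below the >800 bpm criterion
        (0.060, 3, 0),   # run of 3: below the four-beat minimum
    ],
)
def test_vt_rule_threshold_arithmetic(rr_s, n_beats, expect_episodes):
    beats = beats_from(np.arange(n_beats) * rr_s, ["ventricular"] * n_beats)
    eps = detect_vt_episodes(beats, 10.0)
    assert len(eps.episodes) == expect_episodes
    if expect_episodes:
        assert eps.episodes[0].n_cycles == n_beats


def test_sinus_interruption_splits_run():
    times = np.arange(9) * 0.07
    origins = ["ventricular"] * 4 + ["sinus"] + ["ventricular"] * 4
    eps = detect_vt_episodes(beats_from(times, origins), 10.0)
    assert len(eps.episodes) == 2
    assert all(e.n_cycles == 4 for e in eps.episodes)


def test_slow_interval_inside_run_splits_it():
    """Seven ventricular beats whose middle gap is 80 ms: neither half
    reaches four beats, so no VT is called."""
    times = np.cumsum([0, 0.07, 0.07, 0.07, 0.08, 0.07, 0.07])
    eps = detect_vt_episodes(beats_from(times, ["ventricular"] * 7), 10.0)
    assert len(eps.episodes) == 1  # first run has exactly 4 beats
    assert eps.episodes[0].n_cycles == 4


@settings(max_examples=200, derandomize=True, deadline=None)
@given(st.data())
def test_detector_matches_brute_force_oracle_on_random_beatlists(data):
    """Property: on arbitrary labeled beat sequences, the run-scanner
    agrees exactly with a verbatim application of the printed criteria."""
    n = data.draw(st.integers(2, 40))
    rrs = data.draw(
        st.lists(st.sampled_from([0.05, 0.06, 0.074, 0.076, 0.09]),
                 min_size=n - 1, max_size=n - 1)
    )
    origins = data.draw(
        st.lists(st.sampled_from(["sinus", "ventricular"]), min_size=n, max_size=n)
    )
    times = np.concatenate([[0.0], np.cumsum(rrs)])
    beats = beats_from(times, origins)
    det = detect_vt_episodes(beats, float(times[-1]) + 1.0).intervals("VT")
    oracle = brute_force_vt_intervals(times, [o == "ventricular" for o in origins])
    assert [(pytest.approx(a), pytest.approx(b)) for a, b in oracle] == det


def test_detector_matches_oracle_on_synthetic_traces():
    for seed in range(3):
        from stormquant.simulate import random_telemetry_spec

        trace, _ = simulate_ecg(random_telemetry_spec(seed, duration_s=120.0))
        beats = classify_beat_origin(detect_r_peaks(trace))
        det = detect_vt_episodes(beats, trace.duration_s).intervals("VT")
        oracle = brute_force_vt_intervals(
            beats.r_peak_times_s, [o == "ventricular" for o in beats.origins]
        )
        assert det == oracle


def test_monotonicity_in_rate_threshold_and_run_length(storm_beats):
    beats = storm_beats
    burdens = []
    counts = []
    for thresh in (800.0, 900.0, 1000.0, 1200.0):
        eps = detect_vt_episodes(beats, 60.0, rate_thresh_bpm=thresh)
        burdens.append(sum(e.duration_s for e in eps.episodes))
    assert all(a >= b for a, b in zip(burdens, burdens[1:]))
    for run in (4, 6, 10, 20):
        counts.append(len(detect_vt_episodes(beats, 60.0, min_run=run).episodes))
    assert all(a >= b for a, b in zip(counts, counts[1:]))


def test_pure_sinus_yields_no_vt_and_no_vfib(sinus_trace):
    trace, _ = sinus_trace
    beats = classify_beat_origin(detect_r_peaks(trace))
    assert detect_vt_episodes(beats, trace.duration_s).episodes == []
    assert detect_vfib_episodes(trace, beats).episodes == []


def test_planted_vfib_recovered_within_one_window(storm_trace, storm_beats):
    trace, gt = storm_trace
    eps = detect_vfib_episodes(trace, storm_beats).intervals("Vfib")
    (kind, lo, hi) = next(e for e in gt.episodes if e[0] == "Vfib")
    assert len(eps) == 1
    assert eps[0][0] == pytest.approx(lo, abs=1.0)
    assert eps[0][1] == pytest.approx(hi, abs=1.0)


def test_regular_vt_is_not_vfib(storm_trace, storm_beats):
    """The planted VT run has near-constant RR, so its interval CV stays
    far below the Vfib variability criterion."""
    trace, gt = storm_trace
    eps = detect_vfib_episodes(trace, storm_beats).intervals("Vfib")
    vt = next(e for e in gt.episodes if e[0] == "VT")
    assert not any(lo < vt[2] and hi > vt[1] for lo, hi in eps)


def test_window_longer_than_trace_rejected(storm_beats):
    from stormquant import ECGTrace

    short = ECGTrace(np.zeros(1000), 2000.0)
    with pytest.raises(ValueError, match="window"):
        detect_vfib_episodes(short, storm_beats, window_s=1.0)


def test_vfib_takes_precedence_over_overlapping_vt(storm_trace, storm_beats):
    trace, gt = storm_trace
    vt = detect_vt_episodes(storm_beats, trace.duration_s)
    vf = detect_vfib_episodes(trace, storm_beats)
    combined = resolve_episode_precedence(vt, vf)
    vfib_iv = combined.intervals("Vfib")
    for lo, hi in combined.intervals("VT"):
        assert not any(lo < b and hi > a for a, b in vfib_iv)
    assert vfib_iv == vf.intervals("Vfib")
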