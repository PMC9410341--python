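"""Telemetry ECG analysis for mouse arrhythmia studies.

Implements the full quantification chain used on single-lead rodent
telemetry: R-peak detection, beat-origin classification against a sinus
template, rule-based VT and Vfib episode calling, arrhythmia burden and
incidence accounting, heart-rate summaries, rate-corrected QT, and
Bland–Altman inter-observer agreement.

Classification rules
--------------------
A ventricular tachycardia (VT) episode is a maximal run of at least four
consecutive beats of ventricular origin (broad QRS, no intrinsic sinus
complex) in which every inter-beat interval corresponds to a rate above
800 beats per minute.  Ventricular fibrillation (Vfib) is called on sliding
windows showing disorganized high-rate activity: pronounced variability of
both peak-to-peak interval and peak amplitude, with no recurring waveform.
Where a VT call overlaps a Vfib interval the Vfib call wins (the more
severe class).

All episode intervals are half-open ``[start, end)`` in seconds from the
start of the recording.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

__all__ = [
    "ECGTrace",
    "BeatList",
    "Episode",
    "EpisodeSet",
    "QtMeasurement",
    "BlandAltmanResult",
    "detect_r_peaks",
    "classify_beat_origin",
    "detect_vt_episodes",
    "detect_vfib_episodes",
    "resolve_episode_precedence",
    "compute_burden",
    "compute_incidence",
    "compute_heart_rate",
    "compute_qtc",
    "bland_altman",
    "cycles_to_minutes",
]

#: Maximum plausible ventricular rate in mice (bpm); used to validate min RR.
MAX_PLAUSIBLE_RATE_BPM = 1400.0

SINUS = "sinus"
VENTRICULAR = "ventricular"
INDETERMINATE = "indeterminate"


@dataclass
class ECGTrace:
    """A uniformly sampled single-lead ECG voltage series in mV."""

    samples: np.ndarray
    sampling_rate_hz: float
    start_time_s: float = 0.0
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1 or self.samples.size == 0:
            raise ValueError("samples must be a non-empty 1-D array")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("samples must be finite")
        if self.sampling_rate_hz <= 0:
            raise ValueError("sampling_rate_hz must be positive")

    @property
    def duration_s(self) -> float:
        return self.samples.size / self.sampling_rate_hz

    @property
    def times_s(self) -> np.ndarray:
        return self.start_time_s + np.arange(self.samples.size) / self.sampling_rate_hz


@dataclass
class BeatList:
    """Detected beats with per-beat morphology features.

    ``template_corr`` is the Pearson correlation of each beat's waveform
    window with the median (sinus-dominated) beat template; ``origins`` is
    one of ``sinus`` / ``ventricular`` / ``indeterminate`` per beat.
    """

    r_peak_times_s: np.ndarray
    qrs_width_s: np.ndarray
    template_corr: np.ndarray
    amplitude_mv: np.ndarray
    origins: np.ndarray
    flat_signal: bool = False

    def __post_init__(self) -> None:
        self.r_peak_times_s = np.asarray(self.r_peak_times_s, dtype=float)
        self.qrs_width_s = np.asarray(self.qrs_width_s, dtype=float)
        self.template_corr = np.asarray(self.template_corr, dtype=float)
        self.amplitude_mv = np.asarray(self.amplitude_mv, dtype=float)
        self.origins = np.asarray(self.origins, dtype=object)
        if self.r_peak_times_s.size and np.any(np.diff(self.r_peak_times_s) <= 0):
            raise ValueError("r_peak_times_s must be strictly increasing")
        if np.any(self.qrs_width_s < 0):
            raise ValueError("qrs_width_s must be non-negative")

    def __len__(self) -> int:
        return int(self.r_peak_times_s.size)


@dataclass(frozen=True)
class Episode:
    """One classified arrhythmia interval, half-open [start_s, end_s)."""

    kind: str  # "VT" | "Vfib" | "extrasystole"
    start_s: float
    end_s: float
    n_cycles: int

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class EpisodeSet:
    """Classified arrhythmia intervals plus the recording horizon."""

    episodes: list[Episode]
    recording_duration_s: float

    def __post_init__(self) -> None:
        for ep in self.episodes:
            if ep.end_s < ep.start_s:
                raise ValueError("episode end before start")
        for kind in {ep.kind for ep in self.episodes}:
            eps = sorted(self.of_kind(kind), key=lambda e: e.start_s)
            for a, b in zip(eps, eps[1:]):
                if b.start_s < a.end_s:
                    raise ValueError(f"overlapping {kind} episodes")

    def of_kind(self, kind: str) -> list[Episode]:
        return [ep for ep in self.episodes if ep.kind == kind]

    def intervals(self, kind: str) -> list[tuple[float, float]]:
        return [(ep.start_s, ep.end_s) for ep in self.of_kind(kind)]


@dataclass(frozen=True)
class QtMeasurement:
    """QT/QTc averaged over at least five sinus cardiac cycles."""

    qt_s: float
    rr_s: float
    qtc_s: float
    n_cycles_used: int

    def __post_init__(self) -> None:
        if self.n_cycles_used < 5:
            raise ValueError("QTc requires at least five cardiac cycles")
        if not self.qt_s < self.rr_s:
            raise ValueError("QT must be shorter than RR")


@dataclass(frozen=True)
class BlandAltmanResult:
    bias_pct: float
    loa_low: float
    loa_high: float
    n_pairs: int
    n_excluded: int


# ---------------------------------------------------------------------------
# beat detection & classification
# ---------------------------------------------------------------------------

def detect_r_peaks(
    trace: ECGTrace,
    min_rr_s: float = 0.043,
    prominence_frac: float = 0.3,
    template_halfwidth_s: float = 0.03,
) -> BeatList:
    """Detect R peaks and measure per-beat morphology.

    Peaks are found on the rectified, baseline-subtracted signal so that
    both upright sinus complexes and inverted ventricular complexes are
    captured.  QRS width is measured at 20% of peak height (the 80%
    drop from the apex).  Each beat's signed waveform window is correlated
    against the pointwise-median beat template, which in a telemetry trace
    is dominated by sinus morphology.

    Parameters
    ----------
    min_rr_s:
        Refractory interval between peaks; values shorter than the interval
        of the maximum plausible mouse rate (1400 bpm) are rejected.
    prominence_frac:
        Peak prominence threshold as a fraction of the robust (99th
        percentile) rectified amplitude.
    """
    if min_rr_s < 60.0 / MAX_PLAUSIBLE_RATE_BPM:
        raise ValueError(
            f"min_rr_s={min_rr_s} is below the interval of the maximum "
            f"plausible mouse rate ({MAX_PLAUSIBLE_RATE_BPM:.0f} bpm)"
        )
    fs = trace.sampling_rate_hz
    x = trace.samples - np.median(trace.samples)
    rect = np.abs(x)
    scale = float(np.percentile(rect, 99))
    if scale <= 0:
        return BeatList(
            np.empty(0), np.empty(0), np.empty(0), np.empty(0),
            np.empty(0, dtype=object), flat_signal=True,
        )
    prom = prominence_frac * scale
    distance = max(1, int(round(min_rr_s * fs)))
    peaks, _ = sps.find_peaks(rect, distance=distance, prominence=prom, height=prom)
    if peaks.size == 0:
        return BeatList(
            np.empty(0), np.empty(0), np.empty(0), np.empty(0),
            np.empty(0, dtype=object), flat_signal=False,
        )

    widths_samp = sps.peak_widths(rect, peaks, rel_height=0.8)[0]
    widths_s = widths_samp / fs

    half = max(2, int(round(template_halfwidth_s * fs)))
    n = x.size
    windows = np.zeros((peaks.size, 2 * half + 1))
    for i, p in enumerate(peaks):
        lo, hi = p - half, p + half + 1
        src = x[max(lo, 0): min(hi, n)]
        windows[i, max(0, -lo): max(0, -lo) + src.size] = src
    template = np.median(windows, axis=0)
    corr = _rowwise_pearson(windows, template)

    return BeatList(
        r_peak_times_s=trace.start_time_s + peaks / fs,
        qrs_width_s=widths_s,
        template_corr=corr,
        amplitude_mv=rect[peaks],
        origins=np.array([INDETERMINATE] * peaks.size, dtype=object),
    )


def _rowwise_pearson(rows: np.ndarray, template: np.ndarray) -> np.ndarray:
    t = template - template.mean()
    tn = np.linalg.norm(t)
    r = rows - rows.mean(axis=1, keepdims=True)
    rn = np.linalg.norm(r, axis=1)
    denom = rn * tn
    out = np.zeros(rows.shape[0])
    ok = denom > 0
    out[ok] = (r[ok] @ t) / denom[ok]
    return out


def classify_beat_origin(
    beats: BeatList,
    width_ratio_thresh: float = 1.5,
    corr_thresh: float = 0.7,
) -> BeatList:
    """Label each beat sinus or ventricular.

    A beat is of ventricular origin iff its QRS width exceeds
    ``width_ratio_thresh`` times the median sinus width, or its correlation
    with the sinus template falls below ``corr_thresh``.  With fewer than
    ten beats no sinus template can be established and every beat is
    labeled indeterminate.
    """
    n = len(beats)
    origins = np.array([INDETERMINATE] * n, dtype=object)
    if n < 10:
        beats.origins = origins
        return beats
    sinus_like = beats.template_corr >= corr_thresh
    ref_width = float(
        np.median(beats.qrs_width_s[sinus_like]) if sinus_like.any()
        else np.median(beats.qrs_width_s)
    )
    ventricular = (beats.qrs_width_s > width_ratio_thresh * ref_width) | (
        beats.template_corr < corr_thresh
    )
    origins[:] = SINUS
    origins[ventricular] = VENTRICULAR
    beats.origins = origins
    return beats


# ---------------------------------------------------------------------------
# episode detection
# ---------------------------------------------------------------------------

def detect_vt_episodes(
    beats: BeatList,
    recording_duration_s: float,
    min_run: int = 4,
    rate_thresh_bpm: float = 800.0,
) -> EpisodeSet:
    """Call VT episodes: maximal runs of >= ``min_run`` consecutive
    ventricular beats with every inter-beat interval faster than
    ``rate_thresh_bpm`` (default 800 bpm, i.e. RR < 75 ms), uninterrupted
    by any sinus complex.

    Episode start/end are the first/last R peaks of the run and
    ``n_cycles`` its beat count.
    """
    max_rr = 60.0 / rate_thresh_bpm
    t = beats.r_peak_times_s
    episodes: list[Episode] = []
    run: list[int] = []

    def close() -> None:
        if len(run) >= min_run:
            episodes.append(
                Episode("VT", float(t[run[0]]), float(t[run[-1]]), len(run))
            )
        run.clear()

    for i in range(len(beats)):
        if beats.origins[i] != VENTRICULAR:
            close()
            continue
        if run and t[i] - t[run[-1]] >= max_rr:
            close()
        run.append(i)
    close()
    return EpisodeSet(episodes, recording_duration_s)


def detect_vfib_episodes(
    trace: ECGTrace,
    beats: BeatList,
    window_s: float = 1.0,
    interval_cv_thresh: float = 0.3,
    amp_cv_thresh: float = 0.3,
    min_rate_bpm: float = 800.0,
    corr_max: float = 0.5,
    min_peaks_per_window: int = 5,
) -> EpisodeSet:
    """Call Vfib on sliding windows (50% overlap).

    A window is flagged when the detected peaks inside it show
    peak-to-peak interval CV and amplitude CV above their thresholds, a
    mean rate above ``min_rate_bpm`` and no beat resembling the sinus
    template (maximal template correlation below ``corr_max``).
    Contiguous flagged windows are merged into one episode.
    """
    if window_s > trace.duration_s:
        raise ValueError("Vfib window longer than the recording")
    t = beats.r_peak_times_s
    step = window_s / 2.0
    t0 = trace.start_time_s
    n_win = max(1, int(math.floor((trace.duration_s - window_s) / step)) + 1)
    flagged: list[tuple[float, float]] = []
    for w in range(n_win):
        lo = t0 + w * step
        hi = lo + window_s
        sel = (t >= lo) & (t < hi)
        if sel.sum() < min_peaks_per_window:
            continue
        tt = t[sel]
        rr = np.diff(tt)
        amps = beats.amplitude_mv[sel]
        if rr.size < 2:
            continue
        mean_rr = rr.mean()
        rate = 60.0 / mean_rr
        cv_rr = rr.std(ddof=1) / mean_rr
        cv_amp = amps.std(ddof=1) / amps.mean()
        max_corr = beats.template_corr[sel].max()
        if (
            cv_rr > interval_cv_thresh
            and cv_amp > amp_cv_thresh
            and rate > min_rate_bpm
            and max_corr < corr_max
        ):
            flagged.append((lo, hi))

    merged: list[list[float]] = []
    for lo, hi in flagged:
        if merged and lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    episodes = [
        Episode("Vfib", lo, hi, int(((t >= lo) & (t < hi)).sum()))
        for lo, hi in merged
    ]
    return EpisodeSet(episodes, trace.duration_s)


def resolve_episode_precedence(vt: EpisodeSet, vfib: EpisodeSet) -> EpisodeSet:
    """Combine VT and Vfib calls; Vfib (the more severe class) takes
    precedence, so VT episodes overlapping any Vfib interval are dropped."""
    if vt.recording_duration_s != vfib.recording_duration_s:
        raise ValueError("episode sets cover different recordings")
    vfib_iv = vfib.intervals("Vfib")
    kept = [
        ep for ep in vt.of_kind("VT")
        if not any(ep.start_s < hi and ep.end_s > lo for lo, hi in vfib_iv)
    ]
    return EpisodeSet(kept + list(vfib.episodes), vt.recording_duration_s)


# ---------------------------------------------------------------------------
# burden / incidence / rate metrics
# ---------------------------------------------------------------------------

def compute_burden(
    episodes: EpisodeSet,
    horizon_s: float,
    min_episode_s: float = 0.0,
    kinds: Sequence[str] = ("VT", "Vfib"),
    bin_s: float = 3600.0,
) -> dict:
    """Cumulative arrhythmia burden per kind over an observation horizon.

    Episodes shorter than ``min_episode_s`` are dropped first (telemetry
    mode uses 0; invasive EP-study mode uses 1.0 s, excluding all VTs
    shorter than one second).  Episodes are clipped to ``[0, horizon_s)``;
    the per-bin vector (default hourly) partitions the total burden.
    """
    if horizon_s <= 0:
        raise ValueError("horizon_s must be positive")
    n_bins = int(math.ceil(horizon_s / bin_s))
    out: dict = {}
    for kind in kinds:
        kept = [
            ep for ep in episodes.of_kind(kind) if ep.duration_s >= min_episode_s
        ]
        per_bin = np.zeros(n_bins)
        burden = 0.0
        cycles = 0
        for ep in kept:
            lo = max(ep.start_s, 0.0)
            hi = min(ep.end_s, horizon_s)
            if hi <= lo:
                continue
            burden += hi - lo
            cycles += ep.n_cycles
            b0, b1 = int(lo // bin_s), int(min(hi // bin_s, n_bins - 1))
            for b in range(b0, b1 + 1):
                per_bin[b] += min(hi, (b + 1) * bin_s) - max(lo, b * bin_s)
        out[kind] = {
            "burden_s": burden,
            "burden_cycles": cycles,
            "n_episodes": sum(
                1 for ep in kept if min(ep.end_s, horizon_s) > max(ep.start_s, 0.0)
            ),
            "per_bin_s": per_bin,
        }
    return out


def compute_incidence(cohort: Iterable[dict]) -> dict:
    """Cohort incidence and burden-subset summaries.

    Incidence counts every subject; burden statistics are reported only
    over subjects with burden > 0 s for that arrhythmia, mirroring the
    convention of atrial-fibrillation burden guidelines.
    """
    rows = list(cohort)
    if not rows:
        raise ValueError("empty cohort")
    df = pd.DataFrame(rows)
    out: dict = {"n_subjects": len(df)}
    for kind in ("VT", "Vfib"):
        col = f"{kind}_burden_s"
        has = df[col] > 0 if col in df else pd.Series(False, index=df.index)
        subset = df.loc[has, col] if col in df else pd.Series(dtype=float)
        out[f"{kind}_incidence"] = float(has.mean())
        out[f"{kind}_n_affected"] = int(has.sum())
        out[f"{kind}_burden_subset_empty"] = bool(subset.empty)
        out[f"{kind}_burden_mean_s"] = float(subset.mean()) if not subset.empty else float("nan")
        ccol = f"{kind}_burden_cycles"
        if ccol in df and not subset.empty:
            out[f"{kind}_burden_mean_cycles"] = float(df.loc[has, ccol].mean())
    return out


def compute_heart_rate(beats: BeatList, episodes: EpisodeSet) -> dict:
    """Mean instantaneous heart rate (60/RR) during sinus rhythm vs VT.

    Sinus-rhythm intervals require both bounding beats to be sinus-labeled
    and outside every episode; VT intervals require both beats inside one
    VT episode.
    """
    t = beats.r_peak_times_s
    if len(beats) < 2:
        raise ValueError("need at least two beats")
    vt_iv = episodes.intervals("VT")
    all_iv = [(ep.start_s, ep.end_s) for ep in episodes.episodes]

    def inside(ts: float, ivs: list[tuple[float, float]]) -> bool:
        return any(lo - 1e-9 <= ts <= hi + 1e-9 for lo, hi in ivs)

    sr_rates, vt_rates = [], []
    for i in range(len(beats) - 1):
        rr = t[i + 1] - t[i]
        if inside(t[i], vt_iv) and inside(t[i + 1], vt_iv):
            vt_rates.append(60.0 / rr)
        elif (
            beats.origins[i] == SINUS
            and beats.origins[i + 1] == SINUS
            and not inside(t[i], all_iv)
            and not inside(t[i + 1], all_iv)
        ):
            sr_rates.append(60.0 / rr)

    vt_defined = len(vt_rates) >= 2
    return {
        "sr_bpm": float(np.mean(sr_rates)) if len(sr_rates) >= 2 else float("nan"),
        "vt_bpm": float(np.mean(vt_rates)) if vt_defined else float("nan"),
        "vt_defined": vt_defined,
        "n_sr_intervals": len(sr_rates),
        "n_vt_intervals": len(vt_rates),
    }


# ---------------------------------------------------------------------------
# QT / QTc
# ---------------------------------------------------------------------------

def compute_qtc(
    trace: ECGTrace,
    beats: BeatList,
    n_cycles: int = 5,
    onset_frac: float = 0.2,
    rr_ref_s: float = 0.1,
    min_sinus_corr: float = 0.9,
) -> QtMeasurement:
    """QT and rate-corrected QT from an ensemble average of sinus cycles.

    Windows around the R peaks of ``n_cycles`` clean sinus beats are
    averaged (ensemble averaging suppresses noise by √n) and QT is
    measured once on the averaged beat: from QRS onset — the last upward
    crossing of ``onset_frac`` × R amplitude before the R peak — to
    T-wave end by the tangent method, extrapolating the tangent at the
    steepest point of the T wave's decaying limb to the isoelectric
    baseline.  The rate correction is the rodent normalization
    QTc = QT / sqrt(RR / 100 ms).
    """
    if n_cycles < 5:
        raise ValueError("QTc requires at least five cardiac cycles")
    fs = trace.sampling_rate_hz
    x = trace.samples - np.median(trace.samples)
    t0 = trace.start_time_s
    peaks_idx = np.round((beats.r_peak_times_s - t0) * fs).astype(int)

    usable = [
        i for i in range(len(beats) - 1)
        if beats.origins[i] == SINUS and beats.template_corr[i] >= min_sinus_corr
        and beats.origins[i + 1] == SINUS and x[peaks_idx[i]] > 0
    ]
    if len(usable) < 5:
        raise ValueError(f"only {len(usable)} usable sinus cycles (need >= 5)")
    usable = usable[:n_cycles]
    rr = float(np.mean([
        beats.r_peak_times_s[i + 1] - beats.r_peak_times_s[i] for i in usable
    ]))

    pre = int(round(0.02 * fs))
    post = int(round(0.8 * rr * fs))
    segs = [
        x[peaks_idx[i] - pre: peaks_idx[i] + post]
        for i in usable
        if peaks_idx[i] - pre >= 0 and peaks_idx[i] + post <= x.size
    ]
    if len(segs) < 5:
        raise ValueError("fewer than five complete sinus cycles in the trace")
    avg = np.mean(segs, axis=0)
    qt = _measure_qt(avg, pre, fs, onset_frac)
    if qt is None or not qt < rr:
        raise ValueError("QT measurement failed on the averaged beat")
    return QtMeasurement(qt, rr, qt / math.sqrt(rr / rr_ref_s), len(segs))


def _measure_qt(
    beat: np.ndarray, r_idx: int, fs: float, onset_frac: float
) -> float | None:
    """QT on one (averaged) beat whose R peak sits at ``r_idx``."""
    amp = beat[r_idx]
    thresh = onset_frac * amp
    seg = beat[: r_idx + 1]
    below = np.nonzero(seg < thresh)[0]
    if below.size == 0 or below[-1] + 1 > r_idx:
        return None
    j = below[-1]  # last sample below threshold before R
    frac = (thresh - seg[j]) / (seg[j + 1] - seg[j])
    onset = (j + frac - r_idx) / fs  # relative to R

    w_lo = r_idx + int(round(0.008 * fs))
    if beat.size - w_lo < 8:
        return None
    from scipy.ndimage import gaussian_filter1d

    tw = gaussian_filter1d(beat[w_lo:], max(1.0, 0.0015 * fs))
    tp = int(np.argmax(tw))
    decay = tw[tp:]
    if decay.size < 4:
        return None
    d = np.gradient(decay)
    k = int(np.argmin(d))
    slope = d[k] * fs
    if slope >= 0:
        return None
    t_k = (w_lo + tp + k - r_idx) / fs  # relative to R
    t_end = t_k - decay[k] / slope
    return t_end - onset


# ---------------------------------------------------------------------------
# agreement & unit helpers
# ---------------------------------------------------------------------------

def bland_altman(
    burden_a: Sequence[float], burden_b: Sequence[float]
) -> BlandAltmanResult:
    """Bland–Altman agreement between two observers on percent scale.

    Per pair, the difference is expressed as a percentage of the pair mean:
    ``100 * (a - b) / mean(a, b)``.  Bias is the mean difference; limits of
    agreement are bias ± 1.96 SD.  Pairs with zero mean carry no percent
    difference and are excluded with a warning.
    """
    a = np.asarray(burden_a, dtype=float)
    b = np.asarray(burden_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired 1-D lists of equal length required")
    means = (a + b) / 2.0
    ok = means > 0
    n_excl = int((~ok).sum())
    if n_excl:
        warnings.warn(f"{n_excl} pair(s) with zero mean excluded", stacklevel=2)
    if not ok.any():
        raise ValueError("no usable pairs")
    d = 100.0 * (a[ok] - b[ok]) / means[ok]
    bias = float(d.mean())
    if d.size < 2:
        return BlandAltmanResult(bias, float("nan"), float("nan"), int(d.size), n_excl)
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(
        bias, bias - 1.96 * sd, bias + 1.96 * sd, int(d.size), n_excl
    )


def episode_match_stats(
    detected: list[tuple[float, float]],
    truth: list[tuple[float, float]],
) -> dict:
    """Episode-level agreement between detected and true intervals.

    A detected interval matches an unmatched true interval when the two
    overlap; matching is greedy in time order.  Returns sensitivity
    (recall over true episodes) and precision (over detections).
    """
    detected = sorted(detected)
    truth = sorted(truth)
    used = [False] * len(truth)
    tp = 0
    for lo, hi in detected:
        for k, (tlo, thi) in enumerate(truth):
            if not used[k] and lo < thi and hi > tlo:
                used[k] = True
                tp += 1
                break
    fp = len(detected) - tp
    fn = len(truth) - tp
    return {
        "tp": tp,
        "fp": fp,
        "fn": fn,
        "sensitivity": tp / len(truth) if truth else float("nan"),
        "precision": tp / len(detected) if detected else float("nan"),
    }


def cycles_to_minutes(n_cycles: float, rate_bpm: float) -> float:
    """Convert an arrhythmia burden in cardiac cycles to minutes at a given
    rate (cycles / rate); e.g. 10,000 cycles at the 800 bpm VT rate
    criterion corresponds to 12.5 minutes."""
    if rate_bpm <= 0:
        raise ValueError("rate_bpm must be positive")
    return n_cycles / rate_bpm
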