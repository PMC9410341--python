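"""Synthetic mouse telemetry ECG with planted arrhythmia episodes.

Sinus beats share one biphasic (Mexican-hat) QRS template followed by a
Gaussian T wave; ventricular beats (VT runs and extrasystoles) use a
twice-as-wide inverted template with no T wave, replacing the intrinsic
sinus complex for the episode's duration.  Vfib segments are irregular
spike trains — lognormal peak-to-peak intervals and amplitudes, random
width and polarity per spike — over a band-limited noise floor, so that
interval and amplitude coefficients of variation both exceed 0.3 and no
repeating waveform exists.

Rates follow the murine regimes of the study: sinus around 550 bpm,
planted VT above 800 bpm (typically ~1100 bpm, about twice sinus).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

from stormquant.ecg import ECGTrace

__all__ = ["EcgSimSpec", "PlantedEpisode", "EcgGroundTruth", "simulate_ecg"]

# waveform constants (seconds / mV)
SINUS_QRS_SIGMA_S = 0.0025
SINUS_R_AMP_MV = 1.0
T_WAVE_DELAY_S = 0.025     # R peak -> T apex
T_WAVE_SIGMA_S = 0.007
T_WAVE_AMP_MV = 0.25
VENT_QRS_SIGMA_S = 0.005   # 2x sinus width
VENT_R_AMP_MV = 0.8


@dataclass(frozen=True)
class PlantedEpisode:
    """A ground-truth arrhythmia interval to plant into the trace."""

    kind: str  # "VT" | "Vfib" | "extrasystole"
    start_s: float
    duration_s: float
    rate_bpm: float | None = None  # required for VT

    @property
    def end_s(self) -> float:
        return self.start_s + self.duration_s


@dataclass
class EcgSimSpec:
    """Parameters of one synthetic telemetry recording."""

    duration_s: float
    sampling_rate_hz: float = 2000.0
    sinus_rate_bpm: float = 550.0
    planted_episodes: list[PlantedEpisode] = field(default_factory=list)
    noise_sd_mv: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        if self.sampling_rate_hz < 1000.0:
            raise ValueError(
                "sampling_rate_hz must be >= 1000 Hz to resolve RR < 75 ms"
            )
        if self.duration_s <= 0 or self.sinus_rate_bpm <= 0:
            raise ValueError("duration_s and sinus_rate_bpm must be positive")
        if self.noise_sd_mv < 0:
            raise ValueError("noise_sd_mv must be non-negative")
        eps = sorted(self.planted_episodes, key=lambda e: e.start_s)
        for e in eps:
            if e.kind not in ("VT", "Vfib", "extrasystole"):
                raise ValueError(f"unknown episode kind {e.kind!r}")
            if e.start_s < 0 or e.end_s > self.duration_s:
                raise ValueError(
                    f"episode [{e.start_s}, {e.end_s}) outside [0, {self.duration_s})"
                )
            if e.kind == "VT":
                if e.rate_bpm is None or e.rate_bpm <= 800.0:
                    raise ValueError("planted VT rate must exceed 800 bpm")
        for a, b in zip(eps, eps[1:]):
            if b.start_s < a.end_s:
                raise ValueError(
                    f"overlapping planted episodes at {b.start_s:.3f} s: "
                    f"[{a.start_s}, {a.end_s}) and [{b.start_s}, {b.end_s})"
                )


@dataclass
class EcgGroundTruth:
    """Planted truth for one synthetic recording (JSON-serializable)."""

    episodes: list[tuple[str, float, float]]      # (kind, start_s, end_s)
    beat_times_s: np.ndarray                      # all beats, sorted
    beat_labels: list[str]                        # "sinus" | "ventricular" | "vfib_peak"
    episode_beat_spans: list[tuple[str, float, float]]  # first->last beat per episode
    qt_s: float
    rr_s: float
    sinus_rate_bpm: float

    def to_dict(self) -> dict:
        return {
            "episodes": [list(e) for e in self.episodes],
            "beat_times_s": self.beat_times_s.tolist(),
            "beat_labels": list(self.beat_labels),
            "episode_beat_spans": [list(e) for e in self.episode_beat_spans],
            "qt_s": self.qt_s,
            "rr_s": self.rr_s,
            "sinus_rate_bpm": self.sinus_rate_bpm,
        }


def _mexican_hat(t: np.ndarray, sigma: float) -> np.ndarray:
    u = t / sigma
    return (1.0 - u * u) * np.exp(-0.5 * u * u)


def _sinus_beat_template(fs: float) -> tuple[np.ndarray, int]:
    """Rendered sinus beat (QRS + T wave); returns (waveform, R index)."""
    pre, post = 0.012, 0.050
    t = np.arange(-pre, post, 1.0 / fs)
    v = SINUS_R_AMP_MV * _mexican_hat(t, SINUS_QRS_SIGMA_S)
    v += T_WAVE_AMP_MV * np.exp(-0.5 * ((t - T_WAVE_DELAY_S) / T_WAVE_SIGMA_S) ** 2)
    return v, int(round(pre * fs))


def _vent_beat_template(fs: float) -> tuple[np.ndarray, int]:
    pre = 0.02
    t = np.arange(-pre, pre, 1.0 / fs)
    return -VENT_R_AMP_MV * _mexican_hat(t, VENT_QRS_SIGMA_S), int(round(pre * fs))


def _true_qt(fs: float, onset_frac: float = 0.2) -> float:
    """Ground-truth QT of the sinus template: QRS onset at the last upward
    crossing of onset_frac x R amplitude before R, to the tangent-method
    T end (analytically T apex + 2 sigma for a Gaussian T wave)."""
    v, r_idx = _sinus_beat_template(fs)
    thresh = onset_frac * v[r_idx]
    below = np.nonzero(v[:r_idx + 1] < thresh)[0]
    j = below[-1]
    frac = (thresh - v[j]) / (v[j + 1] - v[j])
    onset = (j + frac - r_idx) / fs  # relative to R peak
    t_end = T_WAVE_DELAY_S + 2.0 * T_WAVE_SIGMA_S
    return t_end - onset


def simulate_ecg(spec: EcgSimSpec) -> tuple[ECGTrace, EcgGroundTruth]:
    """Generate one telemetry trace plus its planted ground truth.

    Raises ``ValueError`` for overlapping episodes, a VT rate at or below
    800 bpm, or a sampling rate below 1 kHz.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    fs = spec.sampling_rate_hz
    n = int(round(spec.duration_s * fs))
    v = np.zeros(n)

    episodes = sorted(spec.planted_episodes, key=lambda e: e.start_s)
    guard = 0.02  # s of sinus suppression around planted windows

    # --- sinus beats, suppressed inside planted windows
    rr_sinus = 60.0 / spec.sinus_rate_bpm
    sinus_times = np.arange(0.06, spec.duration_s - 0.06, rr_sinus)
    for e in episodes:
        sinus_times = sinus_times[
            (sinus_times < e.start_s - guard) | (sinus_times >= e.end_s + guard)
        ]

    beat_times: list[float] = list(sinus_times)
    beat_labels: list[str] = ["sinus"] * len(sinus_times)
    spans: list[tuple[str, float, float]] = []

    sinus_tpl, sinus_r = _sinus_beat_template(fs)
    vent_tpl, vent_r = _vent_beat_template(fs)
    for t in sinus_times:
        _add(v, sinus_tpl, int(round(t * fs)) - sinus_r)

    # --- planted episodes
    for e in episodes:
        if e.kind == "VT":
            rr = 60.0 / float(e.rate_bpm)
            times = np.arange(e.start_s, e.end_s - 1e-9, rr)
            for t in times:
                _add(v, vent_tpl, int(round(t * fs)) - vent_r)
            beat_times += list(times)
            beat_labels += ["ventricular"] * len(times)
            spans.append(("VT", float(times[0]), float(times[-1])))
        elif e.kind == "extrasystole":
            _add(v, vent_tpl, int(round(e.start_s * fs)) - vent_r)
            beat_times.append(e.start_s)
            beat_labels.append("ventricular")
            spans.append(("extrasystole", e.start_s, e.start_s))
        elif e.kind == "Vfib":
            times = _vfib_render(rng, v, fs, e.start_s, e.end_s)
            beat_times += list(times)
            beat_labels += ["vfib_peak"] * len(times)
            spans.append(("Vfib", float(times[0]), float(times[-1])))

    if spec.noise_sd_mv > 0:
        v += rng.normal(0.0, spec.noise_sd_mv, n)

    order = np.argsort(beat_times)
    bt = np.asarray(beat_times)[order]
    bl = [beat_labels[i] for i in order]

    truth = EcgGroundTruth(
        episodes=[(e.kind, e.start_s, e.end_s) for e in episodes],
        beat_times_s=bt,
        beat_labels=bl,
        episode_beat_spans=spans,
        qt_s=_true_qt(fs),
        rr_s=rr_sinus,
        sinus_rate_bpm=spec.sinus_rate_bpm,
    )
    return ECGTrace(v, fs, subject_id=f"sim-{spec.seed}"), truth


def _vfib_render(
    rng: np.random.Generator,
    buf: np.ndarray,
    fs: float,
    start: float,
    end: float,
) -> np.ndarray:
    """Render one Vfib segment into ``buf``; returns deflection times.

    Disorganized activity is synthesized as an irregular train of broad
    Gaussian deflections with random polarity, width and amplitude over a
    band-limited noise floor.  Inter-deflection intervals mix short
    couplings (~44–50 ms) with intermittent pauses (~100–160 ms), so the
    realized mean rate stays above the 800 bpm criterion while the
    interval CV exceeds 0.3; amplitudes are drawn bimodally (CV > 0.3);
    the zero-mean biphasic sinus QRS is nearly orthogonal to these smooth
    monophasic deflections, so no waveform recurs that resembles the
    sinus template.
    """
    times = []
    t = start + 0.03
    until_pause = int(rng.integers(3, 7))
    while t < end - 0.03:
        times.append(t)
        if until_pause == 0:
            t += rng.uniform(0.10, 0.16)   # intermittent pause
            until_pause = int(rng.integers(3, 7))
        else:
            t += rng.uniform(0.0435, 0.050)
            until_pause -= 1
    for t in times:
        amp = rng.uniform(0.7, 1.0) if rng.random() < 0.5 else rng.uniform(1.5, 2.2)
        sigma = rng.uniform(0.003, 0.007)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        tt = np.arange(-3 * sigma, 3 * sigma, 1.0 / fs)
        _add(buf, sign * amp * np.exp(-0.5 * (tt / sigma) ** 2),
             int(round(t * fs)) - tt.size // 2)
    lo, hi = int(round(start * fs)), int(round(end * fs))
    buf[lo:hi] += 0.04 * gaussian_filter1d(rng.normal(0.0, 1.0, hi - lo), 3.0)
    return np.asarray(times)


def random_telemetry_spec(
    seed: int,
    duration_s: float = 600.0,
    n_vt: tuple[int, int] = (3, 6),
    vt_rate_bpm: tuple[float, float] = (900.0, 1200.0),
    vt_duration_s: tuple[float, float] = (2.0, 8.0),
    n_extrasystoles: tuple[int, int] = (0, 3),
    p_vfib: float = 0.0,
    vfib_duration_s: tuple[float, float] = (3.0, 6.0),
    noise_sd_mv: float = 0.05,
) -> EcgSimSpec:
    """Build a randomized telemetry recording spec emulating the study's
    post-infarction mice: several VT runs of a few seconds at 900–1200 bpm
    on a 550 bpm sinus background, occasional extrasystoles, and (with
    probability ``p_vfib``) one Vfib segment.

    Episodes are placed by rejection sampling with a 1 s margin so they
    never overlap.  All ranges are inclusive uniform draws.
    """
    rng = np.random.default_rng(seed)
    episodes: list[PlantedEpisode] = []

    def place(duration: float) -> float | None:
        for _ in range(200):
            start = rng.uniform(1.0, duration_s - duration - 1.0)
            if all(
                start + duration + 1.0 < e.start_s or start > e.end_s + 1.0
                for e in episodes
            ):
                return start
        return None

    if p_vfib > 0 and rng.random() < p_vfib:
        dur = rng.uniform(*vfib_duration_s)
        start = place(dur)
        if start is not None:
            episodes.append(PlantedEpisode("Vfib", start, dur))
    for _ in range(int(rng.integers(n_vt[0], n_vt[1] + 1))):
        dur = rng.uniform(*vt_duration_s)
        start = place(dur)
        if start is not None:
            episodes.append(PlantedEpisode("VT", start, dur, rng.uniform(*vt_rate_bpm)))
    for _ in range(int(rng.integers(n_extrasystoles[0], n_extrasystoles[1] + 1))):
        start = place(0.05)
        if start is not None:
            episodes.append(PlantedEpisode("extrasystole", start, 0.05))

    return EcgSimSpec(
        duration_s=duration_s,
        planted_episodes=sorted(episodes, key=lambda e: e.start_s),
        noise_sd_mv=noise_sd_mv,
        seed=int(rng.integers(2**31)),
    )


def _add(buf: np.ndarray, tpl: np.ndarray, at: int) -> None:
    lo, hi = at, at + tpl.size
    s_lo, s_hi = max(0, -lo), tpl.size - max(0, hi - buf.size)
    lo, hi = max(lo, 0), min(hi, buf.size)
    if hi > lo:
        buf[lo:hi] += tpl[s_lo:s_hi]
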