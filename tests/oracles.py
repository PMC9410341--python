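"""Independent brute-force oracles used to cross-check the implementation.

These deliberately re-derive each quantity from first principles (nested
loops, literal rule application) and share no code with the package paths
they verify.
"""

from __future__ import annotations

import numpy as np


def brute_force_vt_intervals(
    times: np.ndarray,
    is_ventricular: list[bool],
    min_run: int = 4,
    rate_thresh_bpm: float = 800.0,
) -> list[tuple[float, float]]:
    """Scan every window of >= min_run consecutive beats and apply the VT
    criteria verbatim: all beats ventricular, every inter-beat interval
    faster than the rate criterion, and the window not extendable on
    either side (maximality)."""
    max_rr = 60.0 / rate_thresh_bpm
    n = len(times)
    out = set()
    for i in range(n):
        for j in range(i + min_run - 1, n):
            window_ok = all(is_ventricular[k] for k in range(i, j + 1)) and all(
                times[k + 1] - times[k] < max_rr for k in range(i, j)
            )
            if not window_ok:
                break
            extends_left = (
                i > 0 and is_ventricular[i - 1] and times[i] - times[i - 1] < max_rr
            )
            extends_right = (
                j < n - 1 and is_ventricular[j + 1] and times[j + 1] - times[j] < max_rr
            )
            if not extends_left and not extends_right:
                out.add((float(times[i]), float(times[j])))
    return sorted(out)


def naive_sd_map(frames: np.ndarray) -> np.ndarray:
    """Two-pass per-pixel sample SD computed with explicit loops."""
    t, h, w = frames.shape
    out = np.empty((h, w))
    for r in range(h):
        for c in range(w):
            series = frames[:, r, c]
            mean = sum(series) / t
            ss = sum((v - mean) ** 2 for v in series)
            out[r, c] = (ss / (t - 1)) ** 0.5
    return out


def brute_force_jt(groups: list[np.ndarray]) -> float:
    """JT statistic by explicit double loop over all cross-group pairs."""
    jt = 0.0
    for i in range(len(groups)):
        for j in range(i + 1, len(groups)):
            for x in groups[i]:
                for y in groups[j]:
                    if x < y:
                        jt += 1.0
                    elif x == y:
                        jt += 0.5
    return jt


def enumerate_jt_null(pooled: np.ndarray, sizes: list[int]) -> np.ndarray:
    """JT under every distinct assignment of pooled values to groups,
    enumerated recursively over index combinations."""
    from itertools import combinations

    stats = []

    def rec(remaining: tuple[int, ...], k: int, chosen: list[np.ndarray]) -> None:
        if k == len(sizes) - 1:
            stats.append(brute_force_jt(chosen + [pooled[list(remaining)]]))
            return
        for pick in combinations(range(len(remaining)), sizes[k]):
            pick_set = set(pick)
            grp = pooled[[remaining[p] for p in pick]]
            rest = tuple(
                remaining[q] for q in range(len(remaining)) if q not in pick_set
            )
            rec(rest, k + 1, chosen + [grp])

    rec(tuple(range(len(pooled))), 0, [])
    return np.asarray(stats)
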