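"""Jonckheere–Terpstra trend test for a priori ordered groups.

Used on the clinical cohort to test whether a marker (e.g. neutrophil
count) rises across ordered arrhythmia-severity groups:
(i) no arrhythmia, (ii) ventricular ectopic beats, (iii) non-sustained VT,
(iv) sustained VT or Vfib.

The statistic is the sum over ordered group pairs (i < j) of Mann–Whitney
counts, ties counted as ½:

    JT = Σ_{i<j} #{(x ∈ group_i, y ∈ group_j): x < y} + ½ #{x = y}

Under H0 (no trend) E[JT] = (N² − Σ nᵢ²)/4 and the tie-corrected variance
follows Hollander & Wolfe.  Besides the normal approximation, an exact
null by full enumeration of group assignments is available for small
samples, falling back to seeded Monte-Carlo permutations otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OrderedGroups",
    "TrendTestResult",
    "jonckheere_terpstra",
    "cohort_trend_table",
]

EXACT_MAX_N = 10


@dataclass
class OrderedGroups:
    """Numeric samples in a fixed, a priori order."""

    groups: list[np.ndarray]
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.groups = [np.asarray(g, dtype=float).ravel() for g in self.groups]
        if len(self.groups) < 2:
            raise ValueError("need at least two ordered groups")
        if any(g.size == 0 for g in self.groups):
            raise ValueError("every group must be non-empty")
        if self.labels is None:
            self.labels = [f"group{i}" for i in range(len(self.groups))]

    @property
    def sizes(self) -> list[int]:
        return [int(g.size) for g in self.groups]

    @property
    def total_n(self) -> int:
        return sum(self.sizes)

    @property
    def max_statistic(self) -> float:
        n = self.sizes
        return sum(n[i] * n[j] for i, j in combinations(range(len(n)), 2))


@dataclass
class TrendTestResult:
    statistic: float
    expected: float
    variance: float
    z: float
    p_one_sided: float
    p_two_sided: float
    method: str                # "normal_approx" | "exact_permutation"
    alternative: str           # "increasing" | "decreasing"
    n_permutations: int | None = None


def _jt_statistic(groups: list[np.ndarray]) -> float:
    jt = 0.0
    for i, j in combinations(range(len(groups)), 2):
        x, y = groups[i], groups[j]
        jt += np.sum(x[:, None] < y[None, :]) + 0.5 * np.sum(x[:, None] == y[None, :])
    return float(jt)


def _jt_moments(sizes: list[int], pooled: np.ndarray) -> tuple[float, float]:
    """Null expectation and tie-corrected variance (Hollander & Wolfe)."""
    N = sum(sizes)
    n2 = sum(n * n for n in sizes)
    expected = (N * N - n2) / 4.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    t = tie_counts.astype(float)
    n = np.asarray(sizes, dtype=float)
    a = (
        N * (N - 1) * (2 * N + 5)
        - np.sum(n * (n - 1) * (2 * n + 5))
        - np.sum(t * (t - 1) * (2 * t + 5))
    ) / 72.0
    b = 0.0
    if N > 2:
        b = (
            np.sum(n * (n - 1) * (n - 2)) * np.sum(t * (t - 1) * (t - 2))
        ) / (36.0 * N * (N - 1) * (N - 2))
    c = (
        np.sum(n * (n - 1)) * np.sum(t * (t - 1))
    ) / (8.0 * N * (N - 1))
    return expected, float(a + b + c)


def _enumerate_null(pooled: np.ndarray, sizes: list[int]) -> np.ndarray:
    """JT under every distinct assignment of the pooled values to groups."""
    stats_out: list[float] = []

    def rec(remaining: tuple[int, ...], k: int, chosen: list[np.ndarray]) -> None:
        if k == len(sizes) - 1:
            rec_groups = chosen + [pooled[list(remaining)]]
            stats_out.append(_jt_statistic(rec_groups))
            return
        for pick in combinations(range(len(remaining)), sizes[k]):
            pick_set = set(pick)
            grp = pooled[[remaining[p] for p in pick]]
            rest = tuple(remaining[q] for q in range(len(remaining)) if q not in pick_set)
            rec(rest, k + 1, chosen + [grp])

    rec(tuple(range(pooled.size)), 0, [])
    return np.asarray(stats_out)


def jonckheere_terpstra(
    groups: OrderedGroups | list,
    alternative: str = "increasing",
    method: str = "normal_approx",
    n_perm: int = 10_000,
    seed: int | None = 0,
    max_exact_n: int = EXACT_MAX_N,
) -> TrendTestResult:
    """Jonckheere–Terpstra test for a monotone trend across ordered groups.

    Parameters
    ----------
    alternative:
        ``"increasing"`` (default; values rise with group order) or
        ``"decreasing"``.
    method:
        ``"normal_approx"`` uses the tie-corrected normal approximation;
        ``"exact_permutation"`` uses full enumeration of group assignments
        when the pooled sample size is at most ``max_exact_n``, otherwise
        ``n_perm`` seeded random permutations.
    """
    if not isinstance(groups, OrderedGroups):
        groups = OrderedGroups(list(groups))
    if alternative not in ("increasing", "decreasing"):
        raise ValueError("alternative must be 'increasing' or 'decreasing'")
    if method not in ("normal_approx", "exact_permutation"):
        raise ValueError("method must be 'normal_approx' or 'exact_permutation'")

    jt = _jt_statistic(groups.groups)
    pooled = np.concatenate(groups.groups)
    sizes = groups.sizes
    expected, variance = _jt_moments(sizes, pooled)
    z = (jt - expected) / math.sqrt(variance) if variance > 0 else 0.0

    tol = 1e-9
    n_used: int | None = None
    if method == "normal_approx":
        if variance > 0:
            # continuity correction: JT moves on a half-integer lattice
            sd = math.sqrt(variance)
            p_up = float(stats.norm.sf((jt - expected - 0.5) / sd))
            p_down = float(stats.norm.cdf((jt - expected + 0.5) / sd))
            p_two = float(2 * stats.norm.sf((abs(jt - expected) - 0.5) / sd))
        else:
            p_up = p_down = p_two = 1.0
    else:
        if groups.total_n <= max_exact_n:
            null = _enumerate_null(pooled, sizes)
        else:
            rng = np.random.default_rng(seed)
            null = np.empty(n_perm)
            bounds = np.cumsum([0] + sizes)
            for b in range(n_perm):
                perm = rng.permutation(pooled)
                null[b] = _jt_statistic(
                    [perm[bounds[i]:bounds[i + 1]] for i in range(len(sizes))]
                )
            n_used = n_perm
        p_up = float(np.mean(null >= jt - tol))
        p_down = float(np.mean(null <= jt + tol))
        p_two = float(np.mean(np.abs(null - expected) >= abs(jt - expected) - tol))

    p_one = p_up if alternative == "increasing" else p_down
    return TrendTestResult(
        statistic=jt,
        expected=expected,
        variance=variance,
        z=z,
        p_one_sided=min(1.0, p_one),
        p_two_sided=min(1.0, p_two),
        method=method,
        alternative=alternative,
        n_permutations=n_used,
    )


def cohort_trend_table(
    df: pd.DataFrame,
    score_order: list[str],
    score_col: str = "score",
    value_col: str = "value",
    subject_col: str = "subject",
) -> OrderedGroups:
    """Assemble ordered groups from a per-subject table.

    Every subject must carry exactly one score, and every score must be
    one of ``score_order``; groups are returned in that fixed order.
    """
    if df[subject_col].duplicated().any():
        raise ValueError("each subject must appear exactly once")
    bad = set(df[score_col]) - set(score_order)
    if bad or df[score_col].isna().any():
        raise ValueError(f"subjects with unassigned or unknown scores: {sorted(map(str, bad))}")
    groups, labels = [], []
    for s in score_order:
        g = df.loc[df[score_col] == s, value_col].to_numpy(dtype=float)
        if g.size == 0:
            continue
        groups.append(g)
        labels.append(s)
    return OrderedGroups(groups, labels)
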