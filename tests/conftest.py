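"""Shared fixtures and small independent oracles used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from tedose.amplification import AmplificationCurve, PRESENCE
from tedose.synth import PlateScenario, dosage_series_scenario


def exponential_curve(
    fold: float = 2.0,
    baseline: float = 3.0,
    amp0: float = 1e-4,
    n_cycles: int = 40,
    sample: str = "s",
    locus: str = "L",
    assay: str = PRESENCE,
    well: str = "w1",
) -> AmplificationCurve:
    """Pure exponential curve f(c) = baseline + amp0 * fold**c (no plateau)."""
    c = np.arange(1, n_cycles + 1)
    return AmplificationCurve(sample, locus, assay, well, baseline + amp0 * fold**c)


@pytest.fixture
def noiseless_scenario() -> PlateScenario:
    return dosage_series_scenario(seed=11).noiseless()


@pytest.fixture
def default_noise_scenario() -> PlateScenario:
    """The study conditions: 5 replicates, Ct sd 0.15, efficiency sd 2%."""
    return dosage_series_scenario(seed=11)


# ---------------------------------------------------------------------------
# independent oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def bruteforce_window(points, min_len=4, max_len=6):
    """Exhaustive window-of-linearity search using numpy polyfit.

    Enumerates every contiguous 4-6 point window over consecutive cycles,
    fits with np.polyfit, computes R^2 from the residuals, and applies the
    same tie rule (R^2, then slope, then earliest start, then length).
    """
    pts = sorted(points)
    runs = []
    for p in pts:
        if runs and p[0] == runs[-1][-1][0] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    best = None
    best_key = None
    for run in runs:
        for length in range(min_len, max_len + 1):
            for i in range(len(run) - length + 1):
                xs = np.array([p[0] for p in run[i : i + length]])
                ys = np.array([p[1] for p in run[i : i + length]])
                slope, intercept = np.polyfit(xs, ys, 1)
                if slope <= 0:
                    continue
                resid = ys - (slope * xs + intercept)
                sst = np.sum((ys - ys.mean()) ** 2)
                r2 = 0.0 if sst == 0 else max(0.0, min(1.0, 1.0 - np.sum(resid**2) / sst))
                key = (r2, slope, -xs[0], length)
                if best_key is None or key > best_key:
                    best_key = key
                    best = (int(xs[0]), int(xs[-1]), float(slope), float(r2))
    return best


def bruteforce_upgma_heights(d: np.ndarray) -> list[float]:
    """Merge heights of UPGMA computed from scratch at every step.

    Clusters are kept as frozensets of leaf indices; the distance between
    two clusters is recomputed each step as the plain mean of the original
    pairwise distances across their members (the defining property of
    average linkage), so no distance-update recurrence is shared with the
    implementation under test.
    """
    n = d.shape[0]
    clusters: list[frozenset[int]] = [frozenset([i]) for i in range(n)]
    heights = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean([d[a, b] for a in clusters[i] for b in clusters[j]])
                if best is None or dist < best[0]:
                    best = (dist, i, j)
        dist, i, j = best
        heights.append(dist / 2.0)
        merged = clusters[i] | clusters[j]
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    return heights


def bruteforce_global_alignment_score(
    a: str, b: str, match=1.0, mismatch=-1.0, gap_open=-5.0, gap_extend=-1.0
) -> float:
    """Optimal global alignment score by plain recursion with memoisation.

    Affine gaps: a length-L gap costs gap_open + (L-1)*gap_extend; end gaps
    are penalised like internal ones.  Exponential-state recursion over
    (i, j, previous move), only viable for short strings.
    """
    from functools import lru_cache

    @lru_cache(maxsize=None)
    def go(i: int, j: int, prev: str) -> float:
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            options.append(s + go(i + 1, j + 1, "M"))
        if i < len(a):
            cost = gap_extend if prev == "X" else gap_open
            options.append(cost + go(i + 1, j, "X"))
        if j < len(b):
            cost = gap_extend if prev == "Y" else gap_open
            options.append(cost + go(i, j + 1, "Y"))
        return max(options)

    return go(0, 0, "M")


def jukes_cantor(p_mismatch: float) -> float:
    """JC69 distance from the raw mismatch proportion."""
    import math

    return -0.75 * math.log(1.0 - 4.0 * p_mismatch / 3.0)
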