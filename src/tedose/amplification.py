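"""Per-reaction amplification efficiency and Ct from raw qPCR fluorescence curves.

The estimator follows the window-of-linearity approach: after baseline
subtraction, log10 fluorescence is fitted against cycle number inside the
contiguous 4-6 cycle window that maximises the linear-fit R^2 subject to a
positive slope.  The fitted slope gives the per-cycle fold amplification
E = 10**slope (E = 2.0 corresponds to 100% efficiency), and Ct is the
fractional cycle at which the baseline-corrected signal first crosses a
user-set threshold inside the exponential phase.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import NamedTuple, Sequence

import numpy as np

from .errors import MalformedInputError

PRESENCE = "presence"
ABSENCE = "absence"

#: minimum curve length: enough baseline cycles plus the smallest fit window
MIN_CYCLES = 12

#: fits with R^2 below this are treated as no exponential phase
DEFAULT_MIN_R2 = 0.99

#: a curve whose corrected signal never reaches this level carries no
#: quantifiable product (baseline-corrected fluorescence units, same scale
#: as the Ct threshold)
DEFAULT_MIN_SIGNAL = 0.5

DEFAULT_GROUND_CYCLES = 10
DEFAULT_CT_THRESHOLD = 1.0

WINDOW_MIN = 4
WINDOW_MAX = 6


@dataclass(frozen=True)
class AmplificationCurve:
    """One well's cycle-by-cycle fluorescence with its assay labels.

    ``fluorescence[i]`` is the reading at cycle ``i + 1``; cycles are
    implicit, contiguous and start at 1.
    """

    sample_id: str
    locus_id: str
    assay: str
    well_id: str
    fluorescence: np.ndarray

    def __post_init__(self) -> None:
        f = np.asarray(self.fluorescence, dtype=float)
        object.__setattr__(self, "fluorescence", f)
        if self.assay not in (PRESENCE, ABSENCE):
            raise MalformedInputError(
                f"assay must be '{PRESENCE}' or '{ABSENCE}', got {self.assay!r}"
            )
        if f.ndim != 1 or f.size < MIN_CYCLES:
            raise MalformedInputError(
                f"curve {self.well_id!r} needs >= {MIN_CYCLES} cycles, got {f.size}"
            )
        if not np.all(np.isfinite(f)):
            raise MalformedInputError(f"curve {self.well_id!r} has non-finite readings")

    @property
    def n_cycles(self) -> int:
        return int(self.fluorescence.size)

    @property
    def cycles(self) -> np.ndarray:
        return np.arange(1, self.n_cycles + 1)


class WindowFit(NamedTuple):
    """Best-fitting exponential-phase window on log10 fluorescence."""

    start: int  # first cycle of the window (1-based)
    end: int  # last cycle, inclusive
    slope: float  # log10 fluorescence per cycle
    intercept: float
    r2: float


class CtCall(NamedTuple):
    ct: float | None
    reliable: bool


@dataclass
class ReactionResult:
    """Efficiency, fit window and Ct for one well."""

    well_id: str
    sample_id: str
    locus_id: str
    assay: str
    baseline: float
    efficiency_fold: float  # nan when not amplified
    window: tuple[int, int] | None
    fit_r2: float
    ct: float | None
    amplified: bool
    ct_reliable: bool = True

    @property
    def efficiency_pct(self) -> float:
        """Percent efficiency: (fold - 1) * 100, so fold 2.0 is 100%."""
        return (self.efficiency_fold - 1.0) * 100.0


def estimate_baseline(curve: AmplificationCurve, ground_cycles: int = DEFAULT_GROUND_CYCLES) -> float:
    """Baseline fluorescence as the mean of cycles 3..ground_cycles.

    Cycles 1-2 are excluded because the first readings of a run commonly
    carry instrument settling artifacts.
    """
    if ground_cycles < 3:
        raise MalformedInputError("ground_cycles must be >= 3")
    if curve.n_cycles < ground_cycles + WINDOW_MIN:
        raise MalformedInputError(
            f"curve {curve.well_id!r} too short for ground_cycles={ground_cycles}"
        )
    return float(np.mean(curve.fluorescence[2:ground_cycles]))


def _lsq_line(xs: Sequence[float], ys: Sequence[float]) -> tuple[float, float, float]:
    """Least-squares line through (xs, ys): (slope, intercept, r2)."""
    n = len(xs)
    sx = math.fsum(xs)
    sy = math.fsum(ys)
    sxx = math.fsum(x * x for x in xs)
    sxy = math.fsum(x * y for x, y in zip(xs, ys))
    syy = math.fsum(y * y for y in ys)
    vx = sxx - sx * sx / n
    vy = syy - sy * sy / n
    cxy = sxy - sx * sy / n
    if vx <= 0.0:
        return 0.0, sy / n, 0.0
    slope = cxy / vx
    intercept = (sy - slope * sx) / n
    if vy <= 0.0:
        # flat response: define r2 = 0 (no signal variance to explain)
        return slope, intercept, 0.0
    r2 = (cxy * cxy) / (vx * vy)
    return slope, intercept, min(max(r2, 0.0), 1.0)


def find_window_of_linearity(
    points: Sequence[tuple[float, float]],
    min_len: int = WINDOW_MIN,
    max_len: int = WINDOW_MAX,
) -> WindowFit | None:
    """Contiguous 4-6 point window of (cycle, log10 fluorescence) maximising R^2.

    Only windows over consecutive cycles with positive slope are considered.
    Ties on R^2 are broken by larger slope, then earlier start cycle, then
    longer window.  Returns None when no window has a positive slope, which
    downstream marks the reaction as not amplified.
    """
    pts = sorted(points)
    best: WindowFit | None = None
    best_key: tuple[float, float, float, int] | None = None
    # maximal runs of consecutive integer cycles
    runs: list[list[tuple[float, float]]] = []
    for p in pts:
        if runs and p[0] == runs[-1][-1][0] + 1:
            runs[-1].append(p)
        else:
            runs.append([p])
    for run in runs:
        m = len(run)
        for length in range(min_len, max_len + 1):
            for i in range(0, m - length + 1):
                window = run[i : i + length]
                xs = [p[0] for p in window]
                ys = [p[1] for p in window]
                slope, intercept, r2 = _lsq_line(xs, ys)
                if slope <= 0.0:
                    continue
                key = (r2, slope, -xs[0], length)
                if best_key is None or key > best_key:
                    best_key = key
                    best = WindowFit(int(xs[0]), int(xs[-1]), slope, intercept, r2)
    return best


def call_ct(curve: AmplificationCurve, threshold: float, baseline: float) -> CtCall:
    """Fractional cycle at which corrected fluorescence first crosses ``threshold``.

    Interpolates log10 fluorescence linearly between the bracketing cycles
    (exact for exponential growth).  A crossing already present at cycle 1
    cannot be bracketed and is flagged unreliable; a curve that never crosses
    yields ``ct=None``.
    """
    if threshold <= 0:
        raise MalformedInputError("Ct threshold must be positive")
    corrected = curve.fluorescence - baseline
    above = np.nonzero(corrected >= threshold)[0]
    if above.size == 0:
        return CtCall(None, True)
    i = int(above[0])
    if i == 0:
        return CtCall(1.0, False)
    lo, hi = corrected[i - 1], corrected[i]
    if hi == threshold:
        return CtCall(float(i + 1), True)
    if lo > 0.0:
        frac = (math.log10(threshold) - math.log10(lo)) / (math.log10(hi) - math.log10(lo))
    else:
        # previous point at/below baseline: fall back to linear interpolation
        frac = (threshold - lo) / (hi - lo)
    return CtCall(float(i) + float(frac), True)


def estimate_efficiency(
    curve: AmplificationCurve,
    ground_cycles: int = DEFAULT_GROUND_CYCLES,
    ct_threshold: float | None = DEFAULT_CT_THRESHOLD,
    min_r2: float = DEFAULT_MIN_R2,
    min_signal: float = DEFAULT_MIN_SIGNAL,
) -> ReactionResult:
    """Full single-well analysis: baseline, window of linearity, efficiency, Ct.

    A reaction counts as amplified only when a positive-slope window exists,
    its fit reaches ``min_r2``, and the corrected signal rises at least to
    ``min_signal`` (flat wells never do).  Non-amplified reactions carry no
    Ct and a NaN efficiency.
    """
    baseline = estimate_baseline(curve, ground_cycles)
    corrected = curve.fluorescence - baseline
    usable = corrected > 0.0
    points = [
        (float(c), math.log10(corrected[c - 1]))
        for c in range(1, curve.n_cycles + 1)
        if usable[c - 1]
    ]
    fit = find_window_of_linearity(points) if len(points) >= WINDOW_MIN else None
    amplified = (
        fit is not None
        and fit.r2 >= min_r2
        and float(np.max(corrected)) >= min_signal
    )
    if not amplified:
        return ReactionResult(
            well_id=curve.well_id,
            sample_id=curve.sample_id,
            locus_id=curve.locus_id,
            assay=curve.assay,
            baseline=baseline,
            efficiency_fold=float("nan"),
            window=None if fit is None else (fit.start, fit.end),
            fit_r2=0.0 if fit is None else fit.r2,
            ct=None,
            amplified=False,
        )
    ct: float | None = None
    reliable = True
    if ct_threshold is not None:
        ct, reliable = call_ct(curve, ct_threshold, baseline)
    return ReactionResult(
        well_id=curve.well_id,
        sample_id=curve.sample_id,
        locus_id=curve.locus_id,
        assay=curve.assay,
        baseline=baseline,
        efficiency_fold=10.0 ** fit.slope,
        window=(fit.start, fit.end),
        fit_r2=fit.r2,
        ct=ct,
        amplified=True,
        ct_reliable=reliable,
    )


def analyze_plate(
    curves: Sequence[AmplificationCurve],
    ct_threshold: float = DEFAULT_CT_THRESHOLD,
    ground_cycles: int = DEFAULT_GROUND_CYCLES,
    min_r2: float = DEFAULT_MIN_R2,
    min_signal: float = DEFAULT_MIN_SIGNAL,
) -> list[ReactionResult]:
    """Run :func:`estimate_efficiency` over every well of a plate."""
    return [
        estimate_efficiency(
            c,
            ground_cycles=ground_cycles,
            ct_threshold=ct_threshold,
            min_r2=min_r2,
            min_signal=min_signal,
        )
        for c in curves
    ]
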