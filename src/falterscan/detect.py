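"""Episode detection: spline smoothing, velocity zero crossings, segmentation.

A weight-faltering episode is a bounded interval of weight loss and regain.
Each subject's gridded weight series is smoothed with a least-squares cubic
B-spline (25 equally spaced interior knots by default) to remove day-to-day
intake/excretion fluctuation; peaks and troughs of the smoothed curve are then
read off sign changes of its analytic first derivative sampled at the
measurement days, and each peak-trough pair is expanded into the four episode
stages:

1. Initiation — the derivative turns from positive to negative (a peak);
2. Dip — the subsequent stretch of weight loss;
3. Depth maximum — the derivative turns back positive (a trough); depth is
   the smoothed weight lost between initiation and the trough;
4. Rebound — weight regain after the trough, ending at the last measurement
   at or below the initiation weight before the curve first exceeds it.

If the very first point after the trough already exceeds the initiation
weight the episode terminates at the depth maximum (no rebound stage); a
trailing peak with no subsequent trough is a censored episode.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.interpolate import make_lsq_spline

from .preprocess import DepthThreshold, SubjectSeries

__all__ = [
    "SmoothedCurve",
    "Extremum",
    "FalteringEpisode",
    "SeriesTooShortError",
    "fit_smoothing_spline",
    "locate_extrema",
    "segment_episodes",
    "apply_depth_filter",
    "detect_episodes",
]

DEFAULT_KNOTS = 25
ZERO_TOL = 1e-9  # kg/day below which the derivative counts as exactly zero
MIN_POINTS = 8
POINTS_PER_KNOT = 3  # least-squares smoothing needs residual df per knot interval


class SeriesTooShortError(ValueError):
    """Raised when a series has too few points to smooth."""


@dataclass
class SmoothedCurve:
    """A fitted spline evaluated on the subject's measurement grid."""

    grid: np.ndarray       # days
    smoothed: np.ndarray   # kg
    deriv: np.ndarray      # kg/day, analytic spline derivative
    knot_count: int

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=int)
        self.smoothed = np.asarray(self.smoothed, dtype=float)
        self.deriv = np.asarray(self.deriv, dtype=float)
        if np.any(np.diff(self.grid) <= 0):
            raise ValueError("grid must be strictly increasing")
        if not (len(self.grid) == len(self.smoothed) == len(self.deriv)):
            raise ValueError("grid, smoothed and deriv must have equal length")
        if not np.all(np.isfinite(self.smoothed)):
            raise ValueError("smoothed values must be finite")


@dataclass(frozen=True)
class Extremum:
    kind: str  # "peak" | "trough"
    day: int
    smoothed_weight: float


@dataclass
class FalteringEpisode:
    """One episode's stage boundaries and smoothed weights.

    ``depthmax_day`` and the fields derived from it are absent for censored
    episodes (an initiation with no trough before the end of the record).
    """

    initiation_day: int
    w_init: float
    depthmax_day: int | None = None
    w_depthmax: float | None = None
    rebound_end_day: int | None = None
    w_rebound_end: float | None = None
    depth_g: float | None = None
    censored: bool = False
    terminated_at_depthmax: bool = False

    def __post_init__(self) -> None:
        if not self.censored:
            if self.depthmax_day is None or self.depth_g is None:
                raise ValueError("non-censored episode requires a depth maximum")
            if not self.initiation_day < self.depthmax_day:
                raise ValueError("initiation must precede depth maximum")
            if self.rebound_end_day is not None and self.rebound_end_day < self.depthmax_day:
                raise ValueError("rebound end cannot precede depth maximum")
            if self.depth_g < 0:
                raise ValueError("depth must be non-negative")

    @property
    def end_day(self) -> int:
        """Last day of the episode: rebound end, else the depth maximum."""
        if self.censored:
            raise ValueError("censored episode has no end day")
        return self.rebound_end_day if self.rebound_end_day is not None else self.depthmax_day


def fit_smoothing_spline(
    series: SubjectSeries,
    knot_count: int = DEFAULT_KNOTS,
) -> SmoothedCurve:
    """Least-squares cubic B-spline with equally spaced interior knots.

    The knot count is reduced (with a warning) when the series is too short
    to support it: a cubic with m interior knots has m+4 coefficients, the
    knots must satisfy the Schoenberg-Whitney interlacing condition with the
    data, and a least-squares *smoother* (rather than an interpolant that
    chases measurement noise) needs residual degrees of freedom, enforced
    here as at least ``POINTS_PER_KNOT`` data points per interior knot.  The
    derivative is the analytic spline derivative.
    """
    if knot_count < 1:
        raise ValueError("knot_count must be >= 1")
    x = np.asarray(series.times, dtype=float)
    y = np.asarray(series.weights, dtype=float)
    n = len(x)
    if n < MIN_POINTS:
        raise SeriesTooShortError("series too short to smooth")

    k_use = min(knot_count, n - 4, max(n // POINTS_PER_KNOT, 1))
    spline = None
    while k_use >= 1:
        interior = np.linspace(x[0], x[-1], k_use + 2)[1:-1]
        t = np.concatenate(([x[0]] * 4, interior, [x[-1]] * 4))
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                spline = make_lsq_spline(x, y, t, k=3)
            if np.all(np.isfinite(spline(x))):
                break
            spline = None
        except (ValueError, np.linalg.LinAlgError):
            pass
        k_use -= 1
    if spline is None:  # cubic fit with no interior knots as last resort
        t = np.concatenate(([x[0]] * 4, [x[-1]] * 4))
        spline = make_lsq_spline(x, y, t, k=3)
        k_use = 0
    if k_use < knot_count:
        warnings.warn(
            f"knot count reduced from {knot_count} to {k_use} "
            f"for {n}-point series {series.subject_id!r}",
            stacklevel=2,
        )
    return SmoothedCurve(
        grid=series.times,
        smoothed=spline(x),
        deriv=spline.derivative()(x),
        knot_count=k_use,
    )


def locate_extrema(curve: SmoothedCurve, zero_tol: float = ZERO_TOL) -> list[Extremum]:
    """Peaks and troughs of the smoothed curve from derivative sign changes.

    The derivative is examined only at grid days, so event times are
    quantized to the measurement grid.  A run of (near-)zero derivatives is
    assigned to its last day before the sign flips: a peak sits at the last
    day with non-negative derivative before the first negative day, a trough
    at the last non-positive day before the first positive day.
    """
    d = np.asarray(curve.deriv, dtype=float)
    sign = np.where(np.abs(d) < zero_tol, 0, np.sign(d)).astype(int)
    nz = np.flatnonzero(sign)
    out: list[Extremum] = []
    for a, b in zip(nz[:-1], nz[1:]):
        if sign[a] == sign[b]:
            continue
        idx = b - 1  # last day before the new sign takes over
        kind = "peak" if sign[a] > 0 else "trough"
        out.append(
            Extremum(kind=kind, day=int(curve.grid[idx]), smoothed_weight=float(curve.smoothed[idx]))
        )
    return out


def segment_episodes(
    curve: SmoothedCurve,
    extrema: Sequence[Extremum],
    weights: np.ndarray | None = None,
) -> list[FalteringEpisode]:
    """Expand alternating peak/trough extrema into faltering episodes.

    For each peak: the episode initiates there; the following trough is the
    depth maximum; the rebound runs over the contiguous grid days after the
    trough whose weight stays at or below the initiation weight, ending at
    the last such day before the curve first exceeds it (or at the end of
    the record if it never does).  A peak whose immediate successor grid day
    after the trough already exceeds the initiation weight yields an episode
    terminated at the depth maximum; a trailing peak with no trough is
    censored.

    ``weights`` selects the basis for stage weights, depth and re-attainment
    comparisons: pass the measured grid series (the 10 g-precision weights
    the scale actually produced — the default used by
    :func:`detect_episodes`) or omit it to fall back on the smoothed values.
    Extremum *locations* always come from the smoothed derivative.
    """
    if weights is None:
        w = curve.smoothed
    else:
        w = np.asarray(weights, dtype=float)
        if len(w) != len(curve.grid):
            raise ValueError("weights must align with the curve grid")
    days = [e.day for e in extrema]
    # The spline locates an extremum only to within its knot resolution, so
    # each stage day is snapped to the extremal basis weight inside that
    # half-window (bounded by the neighbouring extrema).  On the smoothed
    # basis the curve is monotone between sign changes, so this is a no-op.
    span = float(curve.grid[-1] - curve.grid[0])
    half_window_d = 0.5 * span / (curve.knot_count + 1)
    if days != sorted(days):
        raise ValueError("extrema must be time-ordered")
    for prev, nxt in zip(extrema[:-1], extrema[1:]):
        if prev.kind == nxt.kind:
            raise ValueError("extrema must alternate peak/trough")

    day_index = {int(d): i for i, d in enumerate(curve.grid)}
    grid = curve.grid

    def _snap(ext_idx: int, lo: int, hi: int, minimum: bool) -> int:
        """Index of the extremal basis weight within the resolution window."""
        a = max(lo, int(np.searchsorted(grid, grid[ext_idx] - half_window_d)))
        b = min(hi, int(np.searchsorted(grid, grid[ext_idx] + half_window_d, side="right")) - 1)
        if a > b:
            return ext_idx
        seg = w[a : b + 1]
        off = int(np.argmin(seg)) if minimum else int(np.argmax(seg))
        return a + off

    episodes: list[FalteringEpisode] = []
    prev_trough_idx = 0
    for i, ext in enumerate(extrema):
        if ext.kind != "peak":
            continue
        peak_idx = day_index[ext.day]
        if i + 1 >= len(extrema):
            init_idx = _snap(peak_idx, prev_trough_idx, len(grid) - 1, minimum=False)
            episodes.append(
                FalteringEpisode(
                    initiation_day=int(grid[init_idx]),
                    w_init=float(w[init_idx]),
                    censored=True,
                )
            )
            break
        trough = extrema[i + 1]
        trough_ext_idx = day_index[trough.day]
        next_peak_idx = (
            day_index[extrema[i + 2].day] if i + 2 < len(extrema) else len(grid)
        )
        init_idx = _snap(peak_idx, prev_trough_idx, trough_ext_idx - 1, minimum=False)
        it = _snap(trough_ext_idx, init_idx + 1, next_peak_idx - 1, minimum=True)
        prev_trough_idx = it
        w_init = float(w[init_idx])
        w_trough = float(w[it])
        depth_g = 1000.0 * (w_init - w_trough)
        j = it + 1
        rebound_end = None
        w_rebound_end = None
        terminated = False
        if j < len(curve.grid):
            if w[j] > w_init:
                terminated = True
            else:
                last_ok = j
                while j + 1 < len(curve.grid) and w[j + 1] <= w_init:
                    j += 1
                    last_ok = j
                rebound_end = int(curve.grid[last_ok])
                w_rebound_end = float(w[last_ok])
        episodes.append(
            FalteringEpisode(
                initiation_day=int(grid[init_idx]),
                w_init=w_init,
                depthmax_day=int(grid[it]),
                w_depthmax=w_trough,
                rebound_end_day=rebound_end,
                w_rebound_end=w_rebound_end,
                depth_g=max(depth_g, 0.0),
                terminated_at_depthmax=terminated,
            )
        )
    return episodes


def apply_depth_filter(
    episodes: Sequence[FalteringEpisode],
    threshold: DepthThreshold | float,
    which: str | float = "base",
) -> list[FalteringEpisode]:
    """Retain quantified episodes with depth strictly above the threshold.

    Censored episodes (no depth) are always dropped here.
    """
    if isinstance(threshold, DepthThreshold):
        cutoff = threshold.select(which)
    else:
        cutoff = float(threshold)
    return [ep for ep in episodes if not ep.censored and ep.depth_g > cutoff]


def detect_episodes(
    series: SubjectSeries,
    knot_count: int = DEFAULT_KNOTS,
    zero_tol: float = ZERO_TOL,
    weight_basis: str = "measured",
) -> tuple[SmoothedCurve, list[FalteringEpisode]]:
    """Full per-subject detection: smooth, find extrema, segment.

    ``weight_basis`` chooses which weights quantify the stages: the
    ``"measured"`` grid series (default — the smoothing spline only locates
    the velocity sign changes) or the ``"smoothed"`` curve itself.
    """
    if weight_basis not in ("measured", "smoothed"):
        raise ValueError("weight_basis must be 'measured' or 'smoothed'")
    curve = fit_smoothing_spline(series, knot_count)
    extrema = locate_extrema(curve, zero_tol)
    weights = series.weights if weight_basis == "measured" else None
    return curve, segment_episodes(curve, extrema, weights=weights)
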