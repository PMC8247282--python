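"""Raw anthropometry intake: triplicate consolidation, measurement error, gridding.

Field protocols for infant anthropometry typically record each weight three
times to the nearest 10 g.  This module turns such raw triplicate tables into
per-subject regular-grid weight series ready for smoothing, and estimates the
technical error of measurement (TEM) that anchors the episode depth threshold.

The consolidation rule: replicates are averaged when their coefficient of
variation (CV) is below a cutoff (default 5%); above the cutoff, a single
replicate lying at least ``outlier_gap_kg`` (default 1 kg) from both others is
dropped and the remaining two averaged; otherwise the visit is treated as
missing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import groupby
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "TriplicateRecord",
    "SubjectSeries",
    "TEMEstimate",
    "DepthThreshold",
    "Consolidated",
    "consolidate_triplicates",
    "compute_tem",
    "estimate_tem",
    "depth_threshold",
    "check_eligibility",
    "interpolate_to_grid",
    "read_cohort",
    "consolidate_cohort",
    "build_subject_series",
    "default_schedule",
]

#: Scheduled visit days of the emulated protocol: every other day, day 9-365.
DEFAULT_SCHEDULE = np.arange(9, 366, 2)


def default_schedule(start: int = 9, stop: int = 365, step: int = 2) -> np.ndarray:
    """Scheduled measurement days (inclusive of ``start``, up to ``stop``)."""
    return np.arange(start, stop + 1, step)


@dataclass(frozen=True)
class TriplicateRecord:
    """One subject-visit with up to three replicate weights in kg."""

    subject_id: str
    age_days: int
    w1: float | None = None
    w2: float | None = None
    w3: float | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.age_days <= 400):
            raise ValueError(f"age_days {self.age_days} outside [0, 400]")
        for w in (self.w1, self.w2, self.w3):
            if w is not None and not (0.0 < w < 30.0):
                raise ValueError(f"replicate weight {w} kg outside (0, 30)")

    def replicates(self) -> tuple[float, ...]:
        """Present replicate weights, in recording order."""
        return tuple(w for w in (self.w1, self.w2, self.w3) if w is not None)


@dataclass
class SubjectSeries:
    """A subject's weight series on a regular day grid.

    ``observed`` flags which grid points carry a consolidated measurement;
    the rest were linearly interpolated.
    """

    subject_id: str
    times: np.ndarray
    weights: np.ndarray
    observed: np.ndarray
    collection_interval: int

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=int)
        self.weights = np.asarray(self.weights, dtype=float)
        self.observed = np.asarray(self.observed, dtype=bool)
        if not (len(self.times) == len(self.weights) == len(self.observed)):
            raise ValueError("times, weights and observed must have equal length")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if not np.all(np.isfinite(self.weights)) or np.any(self.weights <= 0):
            raise ValueError("weights must be finite and positive")

    def __len__(self) -> int:
        return len(self.times)


@dataclass(frozen=True)
class TEMEstimate:
    """Technical error of measurement: sqrt(sum(D^2) / 2N) over replicate deviations."""

    tem_kg: float
    n_subjects: int
    deviations_used: int

    def __post_init__(self) -> None:
        if self.tem_kg < 0:
            raise ValueError("tem_kg must be non-negative")


@dataclass(frozen=True)
class DepthThreshold:
    """Episode depth cutoffs in grams.

    ``base_g`` is the weight change distinguishable from measurement error at
    95% confidence (2*sqrt(2)*TEM); ``combined_g`` adds an allowance for
    non-tissue weight change (a full infant bladder, ~60 g).
    """

    base_g: float
    bladder_allowance_g: float
    combined_g: float

    def __post_init__(self) -> None:
        if min(self.base_g, self.bladder_allowance_g, self.combined_g) < 0:
            raise ValueError("thresholds must be non-negative")
        if not math.isclose(self.combined_g, self.base_g + self.bladder_allowance_g):
            raise ValueError("combined_g must equal base_g + bladder_allowance_g")

    def select(self, which: str | float) -> float:
        """Resolve ``'base'``, ``'combined'`` or a numeric grams value."""
        if which == "base":
            return self.base_g
        if which == "combined":
            return self.combined_g
        return float(which)


@dataclass(frozen=True)
class Consolidated:
    """Outcome of consolidating one visit's replicates."""

    weight_kg: float | None
    status: str  # "mean_all" | "outlier_dropped" | "rejected"
    reason: str | None = None

    @property
    def rejected(self) -> bool:
        return self.weight_kg is None


def _cv_pct(values: Sequence[float]) -> float:
    arr = np.asarray(values, dtype=float)
    return 100.0 * arr.std(ddof=1) / arr.mean()


def consolidate_triplicates(
    rec: TriplicateRecord,
    cv_cutoff_pct: float = 5.0,
    outlier_gap_kg: float = 1.0,
) -> Consolidated:
    """Collapse a visit's replicate weights to a single value.

    Mean of all present replicates when their CV (sample SD / mean, %) is
    below ``cv_cutoff_pct``; otherwise, if exactly one replicate lies at least
    ``outlier_gap_kg`` from each of the other two, it is dropped and the
    remaining two averaged; otherwise the visit is rejected (treated missing).
    """
    reps = rec.replicates()
    if len(reps) < 2:
        return Consolidated(None, "rejected", "insufficient replicates")
    if _cv_pct(reps) < cv_cutoff_pct:
        return Consolidated(float(np.mean(reps)), "mean_all")
    if len(reps) == 3:
        outliers = [
            i
            for i in range(3)
            if all(abs(reps[i] - reps[j]) >= outlier_gap_kg for j in range(3) if j != i)
        ]
        if len(outliers) == 1:
            keep = [reps[j] for j in range(3) if j != outliers[0]]
            return Consolidated(float(np.mean(keep)), "outlier_dropped")
    return Consolidated(None, "rejected", "high CV, no single outlier")


def compute_tem(deviations: Iterable[float], n_subjects: int) -> TEMEstimate:
    """TEM = sqrt(sum(D^2) / (2*N)) over replicate deviations D.

    ``n_subjects`` is the N of the formula — the number of measurement units
    (pairs or subjects, depending on the sampling scheme) the deviations come
    from.
    """
    devs = np.asarray(list(deviations), dtype=float)
    if devs.size == 0:
        raise ValueError("no deviations")
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    if not np.all(np.isfinite(devs)):
        raise ValueError("deviations must be finite")
    tem = math.sqrt(float(np.sum(devs**2)) / (2 * n_subjects))
    return TEMEstimate(tem_kg=tem, n_subjects=n_subjects, deviations_used=devs.size)


def estimate_tem(records: Iterable[TriplicateRecord]) -> TEMEstimate:
    """Estimate TEM from raw visit records.

    D is taken as every pairwise difference among a visit's present
    replicates, and N as the number of such pairs; under independent replicate
    noise of SD sigma, E[D^2] = 2*sigma^2 per pair, so the estimate converges
    to sigma.
    """
    devs: list[float] = []
    for rec in records:
        reps = rec.replicates()
        for i in range(len(reps)):
            for j in range(i + 1, len(reps)):
                devs.append(reps[i] - reps[j])
    if not devs:
        raise ValueError("no deviations")
    return compute_tem(devs, len(devs))


def depth_threshold(
    tem: TEMEstimate | float, bladder_allowance_g: float = 60.0
) -> DepthThreshold:
    """Episode depth thresholds from a TEM estimate.

    The base threshold is 2*sqrt(TEM^2 + TEM^2) = 2*sqrt(2)*TEM — the weight
    difference between two measured values (initiation and depth maximum)
    exceeding which we are 95% confident is not measurement error alone —
    rounded to the nearest gram.  At TEM = 0.005 kg this gives 14 g, and 74 g
    with the 60 g bladder allowance.
    """
    if bladder_allowance_g < 0:
        raise ValueError("bladder allowance must be non-negative")
    tem_kg = tem.tem_kg if isinstance(tem, TEMEstimate) else float(tem)
    if tem_kg < 0:
        raise ValueError("TEM must be non-negative")
    base_g = float(round(1000.0 * 2.0 * math.sqrt(tem_kg**2 + tem_kg**2)))
    return DepthThreshold(
        base_g=base_g,
        bladder_allowance_g=float(bladder_allowance_g),
        combined_g=base_g + float(bladder_allowance_g),
    )


def check_eligibility(
    missing: SubjectSeries | Sequence[bool] | np.ndarray,
    max_consecutive_missing: int = 5,
) -> tuple[bool, int]:
    """Eligibility rule: fewer than ``max_consecutive_missing`` consecutive
    scheduled visits without a consolidated weight.

    Accepts either a boolean missing-mask over the scheduled visits, or a
    :class:`SubjectSeries` (whose non-observed points count as missing).
    Returns ``(eligible, longest_missing_run)``.
    """
    if isinstance(missing, SubjectSeries):
        mask = ~missing.observed
    else:
        mask = np.asarray(missing, dtype=bool)
    if mask.size == 0:
        raise ValueError("empty series")
    longest = max(
        (sum(1 for _ in grp) for val, grp in groupby(mask) if val), default=0
    )
    return longest < max_consecutive_missing, longest


def interpolate_to_grid(
    observed: Sequence[tuple[int, float]],
    grid: Sequence[int] | np.ndarray,
    subject_id: str = "",
    collection_interval: int | None = None,
) -> SubjectSeries:
    """Linearly interpolate observed (day, kg) points onto a regular grid.

    Observed days keep their values exactly; grid days outside the observed
    range raise (no extrapolation).
    """
    pts = sorted(observed)
    if len(pts) < 2:
        raise ValueError("need at least two observed points")
    days = np.asarray([p[0] for p in pts], dtype=float)
    vals = np.asarray([p[1] for p in pts], dtype=float)
    if np.any(np.diff(days) <= 0):
        raise ValueError("observed days must be distinct")
    grid = np.asarray(grid, dtype=int)
    if grid.size and (grid.min() < days[0] or grid.max() > days[-1]):
        raise ValueError("extrapolation not permitted")
    weights = np.interp(grid.astype(float), days, vals)
    observed_mask = np.isin(grid, days.astype(int))
    # exact pass-through at observed days, immune to interp round-off
    day_to_val = {int(d): v for d, v in zip(days, vals)}
    weights = np.array(
        [day_to_val.get(int(d), w) for d, w in zip(grid, weights)], dtype=float
    )
    if collection_interval is None:
        steps = np.diff(grid)
        collection_interval = int(steps.min()) if steps.size else 0
    return SubjectSeries(
        subject_id=subject_id,
        times=grid,
        weights=weights,
        observed=observed_mask,
        collection_interval=collection_interval,
    )


# ---------------------------------------------------------------------------
# Table-level I/O


def read_cohort(path) -> pd.DataFrame:
    """Read a raw cohort table (CSV or TSV) with columns
    subject_id, age_days, weight1_kg, weight2_kg, weight3_kg."""
    df = pd.read_csv(path, sep=None, engine="python")
    required = {"subject_id", "age_days", "weight1_kg", "weight2_kg", "weight3_kg"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    return df


def _records_from_frame(df: pd.DataFrame) -> list[TriplicateRecord]:
    recs = []
    for row in df.itertuples(index=False):
        ws = [
            None if pd.isna(w) else float(w)
            for w in (row.weight1_kg, row.weight2_kg, row.weight3_kg)
        ]
        recs.append(
            TriplicateRecord(str(row.subject_id), int(row.age_days), *ws)
        )
    return recs


def consolidate_cohort(
    df: pd.DataFrame,
    cv_cutoff_pct: float = 5.0,
    outlier_gap_kg: float = 1.0,
) -> pd.DataFrame:
    """Consolidate every visit of a raw cohort table.

    Returns a long table ``subject_id, age_days, weight_kg, source`` where
    source is ``observed`` or ``rejected`` (weight_kg empty when rejected).
    """
    rows = []
    for rec in _records_from_frame(df):
        res = consolidate_triplicates(rec, cv_cutoff_pct, outlier_gap_kg)
        rows.append(
            {
                "subject_id": rec.subject_id,
                "age_days": rec.age_days,
                "weight_kg": res.weight_kg,
                "source": "rejected" if res.rejected else "observed",
            }
        )
    return pd.DataFrame(rows)


def build_subject_series(
    consolidated: pd.DataFrame,
    schedule: np.ndarray | None = None,
    max_consecutive_missing: int = 5,
) -> tuple[dict[str, SubjectSeries], pd.DataFrame]:
    """Grid every eligible subject of a consolidated long table.

    For each subject, eligibility is checked on the scheduled-visit missing
    mask; eligible subjects are linearly interpolated onto the part of the
    schedule covered by their observations.  Returns the series keyed by
    subject plus an eligibility report.
    """
    if schedule is None:
        schedule = DEFAULT_SCHEDULE
    schedule = np.asarray(schedule, dtype=int)
    interval = int(np.diff(schedule).min()) if len(schedule) > 1 else 0
    series: dict[str, SubjectSeries] = {}
    report = []
    for sid, grp in consolidated.groupby("subject_id", sort=True):
        have = grp.dropna(subset=["weight_kg"]).drop_duplicates("age_days")
        obs_days = set(have["age_days"].astype(int))
        missing_mask = np.array([d not in obs_days for d in schedule])
        eligible, run = check_eligibility(missing_mask, max_consecutive_missing)
        n_obs = len(obs_days & set(schedule.tolist()))
        report.append(
            {
                "subject_id": sid,
                "eligible": eligible,
                "longest_missing_run": run,
                "n_observed": n_obs,
            }
        )
        if not eligible or len(have) < 2:
            continue
        pairs = list(zip(have["age_days"].astype(int), have["weight_kg"].astype(float)))
        lo, hi = min(obs_days), max(obs_days)
        sub_grid = schedule[(schedule >= lo) & (schedule <= hi)]
        series[str(sid)] = interpolate_to_grid(
            pairs, sub_grid, subject_id=str(sid), collection_interval=interval
        )
    return series, pd.DataFrame(report)
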