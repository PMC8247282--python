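"""Per-episode and per-subject faltering metrics, and cohort descriptives.

Metrics follow the episode anatomy: dip duration (initiation to depth
maximum), rebound duration (depth maximum to re-attainment), episode duration
(their sum), depth (grams lost between initiation and the trough), dip
rate (negative,
g/day) and rebound rate (positive, g/day).  Rates and rebound duration are
undefined when the rebound stage did not start before the end of the record
or when the episode terminated at the depth maximum.

Per-subject summaries average each metric over that subject's retained
episodes and add the proportion of the observation window spent inside
episodes (interval union by default, so overlapping rebounds are not double
counted).  Cohort descriptives are computed over the per-subject means — the
cohort mean of a metric is the mean of subject means, not the pooled episode
mean.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import FalteringEpisode

__all__ = [
    "EpisodeMetrics",
    "SubjectSummary",
    "compute_episode_metrics",
    "summarize_subject",
    "summarize_cohort",
    "METRIC_FIELDS",
]


@dataclass(frozen=True)
class EpisodeMetrics:
    depth_g: float
    dip_duration_d: float
    rebound_duration_d: float | None
    episode_duration_d: float | None
    dip_rate_gpd: float | None       # <= 0
    rebound_rate_gpd: float | None   # >= 0


@dataclass(frozen=True)
class SubjectSummary:
    subject_id: str
    episode_count: int
    mean_depth_g: float | None
    mean_dip_duration_d: float | None
    mean_rebound_duration_d: float | None
    mean_episode_duration_d: float | None
    mean_dip_rate_gpd: float | None
    mean_rebound_rate_gpd: float | None
    proportion_in_episodes: float


#: summary attribute -> cohort table row label
METRIC_FIELDS = {
    "episode_count": "count",
    "mean_depth_g": "depth_g",
    "proportion_in_episodes": "proportion",
    "mean_dip_duration_d": "dip_duration_d",
    "mean_rebound_duration_d": "rebound_duration_d",
    "mean_episode_duration_d": "episode_duration_d",
    "mean_dip_rate_gpd": "dip_rate_gpd",
    "mean_rebound_rate_gpd": "rebound_rate_gpd",
}


def compute_episode_metrics(
    ep: FalteringEpisode, record_end_day: int
) -> EpisodeMetrics:
    """Quantify one retained episode.

    Rates and the rebound/episode durations are left undefined when (a) the
    rebound stage did not start before ``record_end_day`` (the depth maximum
    falls on the record's final day) or (b) the episode terminated at the
    depth maximum because the next measurement already exceeded the
    initiation weight.
    """
    if ep.censored:
        raise ValueError("metrics undefined for censored episode")
    dip_d = float(ep.depthmax_day - ep.initiation_day)
    no_rebound = (
        ep.terminated_at_depthmax
        or ep.rebound_end_day is None
        or ep.depthmax_day >= record_end_day
    )
    if no_rebound:
        return EpisodeMetrics(
            depth_g=ep.depth_g,
            dip_duration_d=dip_d,
            rebound_duration_d=None,
            episode_duration_d=None,
            dip_rate_gpd=None,
            rebound_rate_gpd=None,
        )
    reb_d = float(ep.rebound_end_day - ep.depthmax_day)
    regained_g = (
        1000.0 * (ep.w_rebound_end - ep.w_depthmax)
        if ep.w_rebound_end is not None
        else ep.depth_g
    )
    return EpisodeMetrics(
        depth_g=ep.depth_g,
        dip_duration_d=dip_d,
        rebound_duration_d=reb_d,
        episode_duration_d=dip_d + reb_d,
        dip_rate_gpd=-ep.depth_g / dip_d,
        rebound_rate_gpd=max(regained_g, 0.0) / reb_d,
    )


def _union_length(intervals: list[tuple[float, float]], window: tuple[float, float]) -> float:
    lo, hi = window
    clipped = sorted(
        (max(a, lo), min(b, hi)) for a, b in intervals if min(b, hi) > max(a, lo)
    )
    total = 0.0
    cur_a = cur_b = None
    for a, b in clipped:
        if cur_b is None or a > cur_b:
            if cur_b is not None:
                total += cur_b - cur_a
            cur_a, cur_b = a, b
        else:
            cur_b = max(cur_b, b)
    if cur_b is not None:
        total += cur_b - cur_a
    return total


def _mean_or_none(values: list[float]) -> float | None:
    return float(np.mean(values)) if values else None


def summarize_subject(
    episodes: Sequence[FalteringEpisode],
    window: tuple[int, int],
    subject_id: str | None = None,
    overlap: str = "union",
) -> SubjectSummary:
    """Per-subject summary over retained (depth-filtered) episodes.

    ``window`` is the subject's observation span in days, e.g. (9, 365).
    The proportion of time in episodes counts each day inside the union of
    [initiation, rebound end] intervals (``overlap="sum"`` instead adds
    possibly-overlapping episode lengths, capped at 1).  Means are taken over
    episodes whose value is defined; episodes with no rebound contribute no
    rebound or rate values.
    """
    first, last = window
    if last <= first:
        raise ValueError("empty window")
    if overlap not in ("union", "sum"):
        raise ValueError("overlap must be 'union' or 'sum'")
    mets = [compute_episode_metrics(ep, last) for ep in episodes]
    intervals = [(float(ep.initiation_day), float(ep.end_day)) for ep in episodes]
    if overlap == "union":
        covered = _union_length(intervals, (float(first), float(last)))
    else:
        covered = sum(
            min(b, last) - max(a, first) for a, b in intervals if min(b, last) > max(a, first)
        )
    span = float(last - first)
    return SubjectSummary(
        subject_id=subject_id if subject_id is not None else "",
        episode_count=len(episodes),
        mean_depth_g=_mean_or_none([m.depth_g for m in mets]),
        mean_dip_duration_d=_mean_or_none([m.dip_duration_d for m in mets]),
        mean_rebound_duration_d=_mean_or_none(
            [m.rebound_duration_d for m in mets if m.rebound_duration_d is not None]
        ),
        mean_episode_duration_d=_mean_or_none(
            [m.episode_duration_d for m in mets if m.episode_duration_d is not None]
        ),
        mean_dip_rate_gpd=_mean_or_none(
            [m.dip_rate_gpd for m in mets if m.dip_rate_gpd is not None]
        ),
        mean_rebound_rate_gpd=_mean_or_none(
            [m.rebound_rate_gpd for m in mets if m.rebound_rate_gpd is not None]
        ),
        proportion_in_episodes=min(covered / span, 1.0),
    )


def summarize_cohort(
    summaries: Sequence[SubjectSummary],
    n_total_subjects: int | None = None,
) -> pd.DataFrame:
    """Descriptive statistics per metric over subjects with episodes.

    Statistics (mean, sample SD, min, max) are computed for each metric over
    the subjects for whom it is defined; subjects without episodes are
    excluded from metric statistics but counted in the reported percentage.
    A single contributing subject yields SD 0 (flagged by n=1).
    """
    if not summaries:
        raise ValueError("need at least one subject summary")
    n_total = n_total_subjects if n_total_subjects is not None else len(summaries)
    with_eps = [s for s in summaries if s.episode_count > 0]
    rows = []
    for attr, label in METRIC_FIELDS.items():
        vals = [getattr(s, attr) for s in with_eps]
        vals = [float(v) for v in vals if v is not None]
        if vals:
            arr = np.asarray(vals)
            sd = float(arr.std(ddof=1)) if len(vals) > 1 else 0.0
            rows.append(
                {
                    "metric": label,
                    "n": len(vals),
                    "mean": float(arr.mean()),
                    "sd": sd,
                    "min": float(arr.min()),
                    "max": float(arr.max()),
                }
            )
        else:
            rows.append(
                {"metric": label, "n": 0, "mean": np.nan, "sd": np.nan,
                 "min": np.nan, "max": np.nan}
            )
    table = pd.DataFrame(rows)
    table.attrs["n_subjects_with_episodes"] = len(with_eps)
    table.attrs["n_total_subjects"] = n_total
    table.attrs["pct_subjects_with_episodes"] = (
        100.0 * len(with_eps) / n_total if n_total else float("nan")
    )
    return table
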