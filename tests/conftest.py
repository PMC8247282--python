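import numpy as np
import pytest

import falterscan as fs


@pytest.fixture(scope="session")
def seed_case_a():
    """Canonical single-episode trajectory on a linear baseline.

    Baseline w(t) = 3 + 0.02 t kg; one cosine-shaped episode initiating at
    day 100 with a 20-day dip of 200 g and a 20-day rebound, so the true
    curve peaks at 5.0 kg on day 100, bottoms at 4.8 kg on day 120 and
    re-attains 5.0 kg on day 140.  Sampled noiselessly on the alternate-day
    grid.
    """
    days = np.arange(0, 366)
    baseline = 3.0 + 0.02 * days
    spec = fs.EpisodeSpec(
        initiation_day=100, dip_duration_d=20, depth_g=200.0,
        rebound_duration_d=20, shape="smooth",
    )
    daily = fs.inject_episodes(baseline, [spec])
    grid = np.arange(9, 366, 2)
    series = fs.SubjectSeries(
        subject_id="caseA", times=grid, weights=daily[grid],
        observed=np.ones(len(grid), dtype=bool), collection_interval=2,
    )
    return {"daily": daily, "baseline": baseline, "series": series, "spec": spec}


@pytest.fixture(scope="session")
def noisy_cohort():
    """n=50 synthetic cohort with TEM-scale noise, consolidated and gridded."""
    subjects = fs.simulate_cohort(50, seed=0)
    meas, truth = fs.cohort_to_frames(subjects)
    consolidated = fs.consolidate_cohort(meas)
    series, report = fs.build_subject_series(consolidated)
    return {"subjects": subjects, "truth": truth, "series": series, "report": report}


def make_series(days, weights, subject_id="T", interval=None):
    days = np.asarray(days, dtype=int)
    if interval is None:
        interval = int(np.diff(days).min())
    return fs.SubjectSeries(
        subject_id=subject_id, times=days, weights=np.asarray(weights, float),
        observed=np.ones(len(days), dtype=bool), collection_interval=interval,
    )
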