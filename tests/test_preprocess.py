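"""Triplicate consolidation, TEM, thresholds, eligibility, gridding."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import falterscan as fs
from falterscan.preprocess import Consolidated


def rec(*weights, day=100):
    return fs.TriplicateRecord("s", day, *weights)


class TestConsolidateTriplicates:
    @pytest.mark.parametrize(
        "weights,expected,status",
        [
            ((5.00, 5.00, 5.00), 5.00, "mean_all"),          # identical replicates
            ((5.00, 5.01, 5.02), 5.01, "mean_all"),          # CV ~0.2% < 5%
            ((5.00, 5.01, 6.50), 5.005, "outlier_dropped"),  # CV ~15.6%, 6.50 is the outlier
            ((5.00, 5.02), 5.01, "mean_all"),                # two replicates only
        ],
    )
    def test_examples(self, weights, expected, status):
        res = fs.consolidate_triplicates(rec(*weights))
        assert res.status == status
        assert res.weight_kg == pytest.approx(expected, abs=1e-12)

    def test_single_replicate_rejected(self):
        res = fs.consolidate_triplicates(rec(5.0))
        assert res.rejected and res.reason == "insufficient replicates"

    def test_high_cv_no_single_outlier_rejected(self):
        # all three mutually >= 1 kg apart: no unique outlier
        res = fs.consolidate_triplicates(rec(3.0, 5.0, 7.0))
        assert res.rejected

    def test_high_cv_two_replicates_rejected(self):
        # with two replicates far apart no outlier can be singled out
        res = fs.consolidate_triplicates(rec(4.0, 6.0))
        assert res.rejected

    @given(
        w=st.tuples(
            st.floats(1.0, 15.0), st.floats(1.0, 15.0), st.floats(1.0, 15.0)
        ),
        perm=st.permutations([0, 1, 2]),
    )
    @settings(max_examples=200, derandomize=True)
    def test_permutation_invariant(self, w, perm):
        a = fs.consolidate_triplicates(rec(*w))
        b = fs.consolidate_triplicates(rec(*(w[i] for i in perm)))
        assert a.rejected == b.rejected
        if not a.rejected:
            assert a.weight_kg == pytest.approx(b.weight_kg, rel=1e-12)


class TestTEM:
    @pytest.mark.parametrize(
        "devs,n,expected",
        [
            ([0.0, 0.0, 0.0], 3, 0.0),
            ([0.02, 0.01], 2, math.sqrt(0.0005 / 4)),  # ~0.01118
            ([0.01], 1, math.sqrt(0.0001 / 2)),        # ~0.00707
        ],
    )
    def test_formula(self, devs, n, expected):
        est = fs.compute_tem(devs, n)
        assert est.tem_kg == pytest.approx(expected, rel=1e-12)
        assert est.deviations_used == len(devs)

    def test_empty_deviations_error(self):
        with pytest.raises(ValueError, match="no deviations"):
            fs.compute_tem([], 1)

    @given(
        devs=st.lists(st.floats(-0.1, 0.1), min_size=1, max_size=20),
        scale=st.floats(0.1, 10.0),
    )
    @settings(max_examples=100, derandomize=True)
    def test_sign_order_and_scale(self, devs, scale):
        n = len(devs)
        base = fs.compute_tem(devs, n).tem_kg
        flipped = fs.compute_tem([-d for d in devs], n).tem_kg
        shuffled = fs.compute_tem(list(reversed(devs)), n).tem_kg
        scaled = fs.compute_tem([scale * d for d in devs], n).tem_kg
        assert flipped == pytest.approx(base, rel=1e-12)
        assert shuffled == pytest.approx(base, rel=1e-12)
        assert scaled == pytest.approx(scale * base, rel=1e-9)

    def test_estimator_consistency_under_gaussian_noise(self):
        # pair differences of iid N(0, sigma) replicates: TEM -> sigma
        rng = np.random.default_rng(12345)
        sigma = 0.005
        pairs = rng.normal(0, sigma, (10_000, 2))
        devs = pairs[:, 0] - pairs[:, 1]
        est = fs.compute_tem(devs, len(devs))
        assert est.tem_kg == pytest.approx(sigma, rel=0.05)


class TestDepthThreshold:
    def test_study_values(self):
        thr = fs.depth_threshold(0.005, bladder_allowance_g=60.0)
        assert thr.base_g == 14.0
        assert thr.combined_g == 74.0

    def test_zero_tem(self):
        assert fs.depth_threshold(0.0).base_g == 0.0

    def test_matches_closed_form_and_monotone(self):
        prev = -1.0
        for tem in np.linspace(0.0, 0.05, 40):
            base = fs.depth_threshold(float(tem)).base_g
            assert abs(base - 1000 * 2 * math.sqrt(2) * tem) <= 0.5  # gram rounding
            assert base >= prev
            prev = base

    def test_negative_allowance_error(self):
        with pytest.raises(ValueError):
            fs.depth_threshold(0.005, bladder_allowance_g=-1)


class TestEligibility:
    @pytest.mark.parametrize(
        "runs,cutoff,eligible,longest",
        [
            ([], 5, True, 0),
            ([2, 4], 5, True, 4),
            ([5], 5, False, 5),
        ],
    )
    def test_missing_runs(self, runs, cutoff, eligible, longest):
        mask = np.zeros(60, dtype=bool)
        pos = 3
        for run in runs:
            mask[pos : pos + run] = True
            pos += run + 2
        got_eligible, got_longest = fs.check_eligibility(mask, cutoff)
        assert (got_eligible, got_longest) == (eligible, longest)

    def test_empty_series_error(self):
        with pytest.raises(ValueError):
            fs.check_eligibility(np.array([], dtype=bool))


class TestInterpolateToGrid:
    def test_midpoint(self):
        s = fs.interpolate_to_grid([(9, 3.0), (13, 3.2)], [9, 11, 13])
        assert np.allclose(s.weights, [3.0, 3.1, 3.2])
        assert list(s.observed) == [True, False, True]

    def test_identity_when_fully_observed(self):
        obs = [(d, 3.0 + 0.01 * d) for d in range(9, 30, 2)]
        s = fs.interpolate_to_grid(obs, [d for d, _ in obs])
        assert np.array_equal(s.weights, [w for _, w in obs])
        assert s.observed.all()

    def test_linear_fill(self):
        s = fs.interpolate_to_grid([(9, 3.0), (17, 3.4)], np.arange(9, 18, 2))
        assert np.allclose(s.weights, [3.0, 3.1, 3.2, 3.3, 3.4])

    def test_no_extrapolation(self):
        with pytest.raises(ValueError, match="extrapolation"):
            fs.interpolate_to_grid([(9, 3.0), (13, 3.2)], [7, 9, 11, 13])

    def test_idempotent(self):
        grid = np.arange(9, 41, 2)
        s1 = fs.interpolate_to_grid([(9, 3.0), (21, 3.3), (39, 4.1)], grid)
        s2 = fs.interpolate_to_grid(list(zip(s1.times, s1.weights)), grid)
        assert np.array_equal(s1.weights, s2.weights)


class TestCohortTable:
    def test_consolidate_cohort_roundtrip(self, tmp_path):
        import pandas as pd

        df = pd.DataFrame(
            {
                "subject_id": ["a", "a", "b"],
                "age_days": [9, 11, 9],
                "weight1_kg": [3.00, 3.05, 3.50],
                "weight2_kg": [3.02, 3.07, None],
                "weight3_kg": [3.01, None, None],
            }
        )
        path = tmp_path / "cohort.csv"
        df.to_csv(path, index=False)
        out = fs.consolidate_cohort(fs.read_cohort(path))
        assert list(out["source"]) == ["observed", "observed", "rejected"]
        assert out["weight_kg"].iloc[0] == pytest.approx(3.01)

    def test_build_subject_series_interpolates_missing(self):
        import pandas as pd

        sched = np.arange(9, 30, 2)
        rows = [
            {"subject_id": "a", "age_days": int(d), "weight_kg": 3.0 + 0.01 * d,
             "source": "observed"}
            for d in sched
            if d != 15
        ]
        series, report = fs.build_subject_series(pd.DataFrame(rows), sched)
        s = series["a"]
        assert 15 in s.times
        assert s.weights[list(s.times).index(15)] == pytest.approx(3.15)
        assert report["eligible"].all()
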