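"""Spline smoothing, extremum location and episode segmentation."""

import numpy as np
import pytest

import falterscan as fs
from falterscan.detect import SeriesTooShortError, segment_episodes, locate_extrema

from conftest import make_series


def brute_force_extrema(curve, zero_tol=1e-9):
    """Naive loop-based sign-change scan, independent of the implementation."""
    sign = []
    for d in curve.deriv:
        sign.append(0 if abs(d) < zero_tol else (1 if d > 0 else -1))
    out = []
    last_sign, last_idx = 0, None
    for i, s in enumerate(sign):
        if s == 0:
            continue
        if last_sign != 0 and s != last_sign:
            kind = "peak" if last_sign > 0 else "trough"
            out.append((kind, int(curve.grid[i - 1])))
        last_sign, last_idx = s, i
    return out


class TestFitSmoothingSpline:
    def test_reproduces_linear_series(self):
        days = np.arange(9, 366, 2)
        s = make_series(days, 3.0 + 0.02 * days)
        curve = fs.fit_smoothing_spline(s, 25)
        assert np.max(np.abs(curve.smoothed - s.weights)) < 1e-6
        assert np.max(np.abs(curve.deriv - 0.02)) < 1e-6

    def test_constant_series_has_zero_derivative(self):
        days = np.arange(9, 100, 2)
        s = make_series(days, np.full(len(days), 5.0))
        curve = fs.fit_smoothing_spline(s, 10)
        assert np.max(np.abs(curve.deriv)) < 1e-8

    def test_tracks_noiseless_episode_trajectory(self, seed_case_a):
        curve = fs.fit_smoothing_spline(seed_case_a["series"], 25)
        resid = np.abs(curve.smoothed - seed_case_a["series"].weights)
        assert resid.max() < 0.030  # < 30 g everywhere

    def test_too_short_series_raises(self):
        days = np.arange(9, 22, 2)
        with pytest.raises(SeriesTooShortError):
            fs.fit_smoothing_spline(make_series(days, 3 + 0.01 * days), 5)

    def test_knot_reduction_warns(self):
        days = np.arange(9, 41, 2)  # 16 points cannot carry 25 knots
        with pytest.warns(UserWarning, match="knot count reduced"):
            curve = fs.fit_smoothing_spline(make_series(days, 3 + 0.01 * days), 25)
        assert curve.knot_count < 25


class TestLocateExtrema:
    def test_monotone_curve_has_no_extrema(self):
        days = np.arange(9, 366, 2)
        curve = fs.fit_smoothing_spline(make_series(days, 3.0 + 0.02 * days), 25)
        assert fs.locate_extrema(curve) == []

    def test_single_dip_yields_peak_then_trough(self, seed_case_a):
        curve = fs.fit_smoothing_spline(seed_case_a["series"], 25)
        kinds = [e.kind for e in fs.locate_extrema(curve)]
        assert kinds == ["peak", "trough"]

    def test_seed_case_days_near_truth(self, seed_case_a):
        curve = fs.fit_smoothing_spline(seed_case_a["series"], 25)
        peak, trough = fs.locate_extrema(curve)
        assert abs(peak.day - 100) <= 4
        assert abs(trough.day - 120) <= 4

    def test_matches_brute_force_scan(self, seed_case_a):
        curve = fs.fit_smoothing_spline(seed_case_a["series"], 25)
        got = [(e.kind, e.day) for e in fs.locate_extrema(curve)]
        assert got == brute_force_extrema(curve)

    def test_alternates_on_wiggly_curve(self):
        days = np.arange(9, 366, 2)
        w = 5 + 0.3 * np.sin(days / 20.0) + 0.004 * days
        curve = fs.fit_smoothing_spline(make_series(days, w), 25)
        ext = fs.locate_extrema(curve)
        assert len(ext) > 2
        for a, b in zip(ext[:-1], ext[1:]):
            assert a.kind != b.kind and a.day < b.day


class TestSegmentEpisodes:
    def test_no_extrema_no_episodes(self):
        days = np.arange(9, 366, 2)
        curve = fs.fit_smoothing_spline(make_series(days, 3.0 + 0.02 * days), 25)
        assert segment_episodes(curve, []) == []

    def test_seed_case_episode_anatomy(self, seed_case_a):
        curve, eps = fs.detect_episodes(seed_case_a["series"], 25)
        assert len(eps) == 1
        ep = eps[0]
        assert not ep.censored and not ep.terminated_at_depthmax
        assert ep.depth_g == pytest.approx(200, abs=30)
        assert abs(ep.rebound_end_day - 140) <= 6
        assert ep.initiation_day < ep.depthmax_day <= ep.rebound_end_day

    def test_termination_when_next_point_exceeds_initiation(self):
        # V-shape whose recovery overshoots the initiation weight immediately
        days = np.arange(9, 366, 2)
        w = np.where(days < 150, 4 + 0.002 * days,
                     np.where(days < 160, 4 + 0.002 * 150 - 0.02 * (days - 150),
                              4 + 0.05 * (days - 160) + 0.002 * 150 - 0.2))
        curve = fs.fit_smoothing_spline(make_series(days, w), 25)
        eps = segment_episodes(curve, locate_extrema(curve), weights=w)
        assert any(ep.terminated_at_depthmax for ep in eps if not ep.censored)
        for ep in eps:
            if ep.terminated_at_depthmax:
                assert ep.rebound_end_day is None

    def test_trailing_peak_is_censored(self):
        days = np.arange(9, 366, 2)
        # rises, then declines to the end of the record: initiation, no trough
        w = np.where(days < 300, 3 + 0.01 * days, 3 + 0.01 * 300 - 0.01 * (days - 300))
        curve = fs.fit_smoothing_spline(make_series(days, w), 25)
        eps = segment_episodes(curve, locate_extrema(curve))
        assert eps and eps[-1].censored

    def test_malformed_extrema_error(self, seed_case_a):
        curve = fs.fit_smoothing_spline(seed_case_a["series"], 25)
        peak, trough = fs.locate_extrema(curve)
        with pytest.raises(ValueError):
            segment_episodes(curve, [trough, peak, peak][::-1])

    def test_translation_invariance(self, seed_case_a):
        series = seed_case_a["series"]
        shifted = make_series(series.times, series.weights + 2.0)
        _, eps0 = fs.detect_episodes(series, 25)
        _, eps1 = fs.detect_episodes(shifted, 25)
        assert [(e.initiation_day, e.depthmax_day, e.rebound_end_day) for e in eps0] == [
            (e.initiation_day, e.depthmax_day, e.rebound_end_day) for e in eps1
        ]
        for a, b in zip(eps0, eps1):
            assert a.depth_g == pytest.approx(b.depth_g, abs=1e-6)

    def test_monotone_trajectories_yield_no_episodes_any_knots(self):
        days = np.arange(0, 366)
        base = fs.baseline_weight(days.astype(float))
        grid = np.arange(9, 366, 2)
        s = make_series(grid, base[grid])
        for knots in (5, 10, 25, 40):
            _, eps = fs.detect_episodes(s, knots)
            assert eps == []

    def test_episode_cores_are_ordered_and_disjoint(self):
        days = np.arange(0, 366)
        base = fs.baseline_weight(days.astype(float))
        specs = [
            fs.EpisodeSpec(60, 15, 300.0, 20, "smooth"),
            fs.EpisodeSpec(160, 12, 250.0, 15, "smooth"),
            fs.EpisodeSpec(260, 20, 400.0, 30, "smooth"),
        ]
        daily = fs.inject_episodes(base, specs)
        grid = np.arange(9, 366, 2)
        _, eps = fs.detect_episodes(make_series(grid, daily[grid]), 25)
        quantified = [e for e in eps if not e.censored]
        assert len(quantified) == 3
        for a, b in zip(quantified[:-1], quantified[1:]):
            assert a.depthmax_day < b.initiation_day


class TestApplyDepthFilter:
    def _episode(self, depth):
        return fs.FalteringEpisode(
            initiation_day=100, w_init=5.0, depthmax_day=110,
            w_depthmax=5.0 - depth / 1000, depth_g=depth,
        )

    def test_strict_threshold(self):
        eps = [self._episode(d) for d in (10.0, 14.0, 15.0)]
        kept = fs.apply_depth_filter(eps, 14.0)
        assert [e.depth_g for e in kept] == [15.0]

    def test_combined_threshold(self):
        thr = fs.depth_threshold(0.005, 60.0)
        eps = [self._episode(d) for d in (80.0, 74.0, 20.0)]
        kept = fs.apply_depth_filter(eps, thr, which="combined")
        assert [e.depth_g for e in kept] == [80.0]

    def test_empty_and_censored(self):
        assert fs.apply_depth_filter([], 14.0) == []
        censored = fs.FalteringEpisode(initiation_day=300, w_init=6.0, censored=True)
        assert fs.apply_depth_filter([censored], 0.0) == []
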