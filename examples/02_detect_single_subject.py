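"""Detect faltering episodes in one weight trajectory, start to finish.

Constructs a noiseless trajectory with a single known episode (200 g lost
over 20 days starting at day 100, regained over the next 20), smooths it with
the 25-knot cubic spline, reads peaks and troughs off the spline's first
derivative, and prints the resulting episode with its metrics.
"""

import numpy as np

import falterscan as fs

days = np.arange(0, 366)
baseline = 3.0 + 0.02 * days  # linear growth, 20 g/day
spec = fs.EpisodeSpec(initiation_day=100, dip_duration_d=20, depth_g=200.0,
                      rebound_duration_d=20, shape="smooth")
daily = fs.inject_episodes(baseline, [spec])

grid = np.arange(9, 366, 2)  # alternate-day visit schedule
series = fs.SubjectSeries("demo", grid, daily[grid],
                          np.ones(len(grid), dtype=bool), collection_interval=2)

curve, episodes = fs.detect_episodes(series, knot_count=25)
retained = fs.apply_depth_filter(episodes, fs.depth_threshold(0.005), "base")

print(f"injected: initiation day {spec.initiation_day}, depth {spec.depth_g:.0f} g, "
      f"re-attainment day {spec.end_day}")
for ep in retained:
    m = fs.compute_episode_metrics(ep, record_end_day=int(grid[-1]))
    print(f"detected: initiation day {ep.initiation_day}, depth maximum day "
          f"{ep.depthmax_day}, rebound end day {ep.rebound_end_day}")
    print(f"          depth {ep.depth_g:.0f} g, dip {m.dip_duration_d:.0f} d at "
          f"{m.dip_rate_gpd:.1f} g/day, rebound {m.rebound_duration_d:.0f} d at "
          f"+{m.rebound_rate_gpd:.1f} g/day")
print(
    "\nDetected stage days are quantized to the 2-day measurement grid and the"
    "\nspline locates the velocity sign changes to within a few days, so the"
    "\ndetected anatomy should bracket the injected one closely."
)
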