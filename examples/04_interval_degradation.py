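"""How much episode information survives coarser measurement schedules?

Subsamples each subject's alternate-day series to 4-, 8-, 16- and 32-day
collection intervals, re-runs the whole detection pipeline at each, and
prints the drift of every faltering metric: fewer episodes, longer apparent
stages, rates shrunk toward zero.
"""

import falterscan as fs

subjects = fs.simulate_cohort(40, seed=11)
measurements, _ = fs.cohort_to_frames(subjects)
series, _ = fs.build_subject_series(fs.consolidate_cohort(measurements))

results = fs.run_interval_experiment(
    series, factors=(1, 2, 4, 8, 16), thresholds=(14.0,)
)

header = f"{'interval':>8} {'N subj':>6} {'count':>6} {'depth g':>8} " \
         f"{'dip d':>6} {'reb d':>6} {'dip g/d':>8} {'reb g/d':>8}"
print(header)
for res in results:
    t = res.cohort_table.set_index("metric")["mean"]

    def fmt(key):
        v = t[key]
        return "   --" if v != v else f"{v:6.1f}"

    print(f"{res.interval_days:>7}d {res.n_subjects_with_episodes:>6} "
          f"{fmt('count')} {fmt('depth_g'):>8} {fmt('dip_duration_d')} "
          f"{fmt('rebound_duration_d')} {fmt('dip_rate_gpd'):>8} "
          f"{fmt('rebound_rate_gpd'):>8}")
print(
    "\nReading down the columns: as visits get sparser, episodes are missed"
    "\n(count and N fall), apparent stage durations stretch, and loss/regain"
    "\nrates are underestimated; '--' marks metrics that no longer exist"
    "\nbecause no detected episode has a quantifiable rebound at that interval."
)
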