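# Methods

## Problem and model

Short-term weight faltering in infancy — losing tens to hundreds of grams
over one to several weeks and regaining them — is invisible to attained-size
indicators but is well defined on a densely sampled weight curve as a
bounded excursion of the growth *velocity*. `falterscan` operationalises an
episode as a peak-to-re-attainment structure on a smoothed weight curve:

* **Initiation** — the smoothed first derivative changes from positive to
  negative (a velocity peak);
* **Dip** — the following stretch of weight loss;
* **Depth maximum** — the derivative changes back to positive (a trough);
  the episode's depth is the weight lost between initiation and the trough;
* **Rebound** — the regain stage, ending at the last measurement at or
  below the initiation weight before the curve first exceeds it. If the
  very first measurement after the trough already exceeds the initiation
  weight, the episode terminates at the depth maximum and neither rate nor
  the rebound duration is defined. A trailing peak with no subsequent
  trough before the record ends is a *censored* episode, excluded from all
  counts and metrics.

## Preprocessing

Visits carry up to three replicate weights recorded to 10 g. A visit's
consolidated weight is the mean of the replicates when their coefficient of
variation (100 · sample SD / mean) is below 5%; otherwise, if exactly one
replicate lies ≥ 1 kg from each of the others ("a whole number" on a kg
scale), it is dropped and the other two averaged; otherwise the visit is
treated as missing. Subjects are eligible when no run of ≥ 5 consecutive
scheduled visits is missing; eligible subjects' gaps are filled by linear
interpolation on the visit grid (never extrapolated).

The technical error of measurement is estimated as
TEM = sqrt(Σ D² / 2N) with D the pairwise differences among a visit's
replicates and N the number of such pairs; under independent replicate
noise of SD σ each pair difference has variance 2σ², so the estimate
converges to σ. Note that 10 g rounding adds variance 0.01²/12 kg², so TEM
estimated from rounded records is ≈ 15% above the underlying noise SD at
σ = 5 g; the estimator itself is unbiased for the total replicate scatter.

Two depth thresholds follow from TEM. The *base* threshold,
2·sqrt(TEM² + TEM²) = 2√2·TEM, rounded to the nearest gram, is the smallest
difference between two measured weights that is distinguishable from
measurement error with 95% confidence — 14 g at TEM = 5 g. The *combined*
threshold adds 60 g for the largest plausible non-tissue weight change (a
full infant bladder): 74 g. Episodes must exceed the selected threshold
*strictly* to be retained.

## Smoothing and event location

Each subject's gridded series is fitted with an ordinary least-squares cubic
B-spline with 25 equally spaced interior knots (configurable). Knots are
reduced, with a warning, when a series cannot support them, on three
grounds: the coefficient count (m interior knots need m + 4 coefficients
≤ n points), the Schoenberg–Whitney interlacing condition, and a smoothing
constraint of at least 3 data points per interior knot — without the last,
short subsampled series get near-interpolating fits that chase replicate
noise and fabricate single-grid-step dips. Series under 8 points are
rejected.

Peaks and troughs are located by sign changes of the analytic spline
derivative *sampled at the grid days* — event times are quantized to the
measurement grid, not root-found between visits. Derivatives within 1e-9
kg/day of zero count as zero, and a run of zeros belongs to the day before
the sign flips.

### Weight basis for stage quantities

The spline locates events; it does not measure them. By default all stage
weights — initiation, depth maximum, rebound end, the depth itself, and the
re-attainment comparison — are taken from the **measured** grid series (the
consolidated 10 g-precision weights), with the smoothed values available
via `weight_basis="smoothed"`. Two facts drove this choice. First, the
least-squares spline attenuates sharp features: a 200 g episode lasting
25 days loses 40–60% of its depth in the smoothed curve, so smoothed-basis
depths systematically understate weight loss and miscalibrate the TEM-based
threshold, which is derived for differences of *measured* values. Second,
because the spline resolves an extremum only to within its knot spacing,
each detected stage day is snapped to the extremal measured weight inside
that half-window (bounded by the neighbouring extrema). On the smoothed
basis the curve is monotone between sign changes and the snap is a no-op.

## Metrics

Per episode: dip duration (initiation → depth maximum), rebound duration
(depth maximum → rebound end), episode duration (their sum), depth (g), dip
rate = −depth / dip duration (g/day, ≤ 0), rebound rate = regained weight /
rebound duration (g/day, ≥ 0; the regain is measured at the rebound end, so
records ending mid-rebound are not credited with the full depth). Rates and
the rebound/episode durations are undefined when the rebound never started
before the record's end or the episode terminated at its depth maximum.

Per subject: episode count, per-metric means over episodes with defined
values, and the proportion of the observation window (last − first observed
day, ≈ 356 days for a full record) covered by the union of episode
intervals `[initiation, rebound end (or depth maximum)]` — union semantics
keep the proportion in [0, 1] under overlapping rebounds; summed-length
semantics are available behind `overlap="sum"`. Cohort descriptives (mean,
n−1 SD, min, max; SD reported as 0 with n = 1) are computed over per-subject
means — the cohort mean of a metric is the mean of subject means, not the
pooled episode mean — alongside the number and percentage of subjects with
at least one retained episode.

## Collection-interval experiment

`subsample_series` keeps every k-th grid point (phase 0 by default, i.e.
starting from the first visit), multiplying the nominal interval; factors
(2, 4, 8, 16) on the 2-day base mimic 4-, 8-, 16- and 32-day protocols.
Interpolation of missing visits happens *before* subsampling. The full
pipeline is re-run per (factor, threshold) cell with the same 25-knot
setting, reduced only when the shortened series cannot support it. Expected
signature of coarsening, which the tests assert directionally: episode
counts fall, stage durations inflate (events quantize to the wider grid),
and both rates shrink toward zero. At the 32-day interval most detected
episodes terminate at their depth maximum (the next measurement already
exceeds the initiation weight after a month of growth), so rate and rebound
metrics may cease to exist entirely — the limiting case of rate
underestimation; the directional tests for those metrics therefore compare
the native interval against the coarsest interval where the metric is still
defined.

## Synthetic cohorts

The generator emulates a dense infant-growth protocol: alternate-day visits
(day 9–365), triplicate weights with iid Gaussian replicate noise at
TEM = 0.005 kg rounded to 10 g, and 0–4-visit missing runs (~1 per
subject), so default subjects stay eligible. Baseline growth is a
saturating exponential anchored at w0 ≈ 3.2 kg (day 9) and w365 ≈ 8.9 kg
with rate constant k ≈ 0.006/day (≈ 34 g/day at one month decaying to
≈ 7 g/day at one year); per-subject parameters are drawn around these
anchors.

Episodes are carved into the daily curve as a tent anchored at the
initiation-day weight: down `depth_g` over the dip, back up over the
rebound — cosine ramps by default (`shape="smooth"`; weight loss is not
piecewise linear), with a piecewise-linear variant. After the rebound the
baseline's daily *increments* resume from the re-attained weight, so the
injected curve re-attains the pre-episode weight exactly at
initiation + dip + rebound and the true anatomy is recoverable from the
noiseless daily curve by direct scan. Episode counts are truncated-Poisson
(mean 2.5, max 6; some subjects draw zero), depths lognormal with mean
≈ 170 g clipped to [20, 1100] g, dip durations normal (mean 18, SD 6 d,
clipped [10, 48]), rebound durations lognormal (mean ≈ 15, SD ≈ 20 d,
clipped [4, 148] — the heavy tail supplies the occasional multi-month
rebound that keeps rebound metrics defined at coarse intervals), with ≥ 12
clear days enforced between episodes.

What the synthetic cohorts do **not** emulate: day-to-day biological weight
fluctuation beyond replicate noise (intake/excretion), seasonal or
illness-driven episode timing, correlated missingness, length/height, and
real curves' irregular baseline drift. Passing recovery tests therefore
demonstrates that the algorithm inverts its own generative model under
realistic measurement noise and sampling — not that field data would yield
the same recovery rates.

## Numerical choices and degenerate inputs

* Zero-derivative tolerance 1e-9 kg/day; tie runs resolve to the last day
  before the sign flip.
* Snap windows are half the fitted knot spacing, clipped to the
  neighbouring extrema, guaranteeing time-ordered, core-disjoint episodes;
  ties inside a window resolve to the earliest day.
* A record starting mid-dip yields no episode (an episode requires a
  detected initiation); negative computed depths (possible from replicate
  noise at the snap boundaries) are clamped to zero and removed by any
  positive threshold.
* Per-subject failures (too-short subsampled series) are logged and
  excluded from that experiment cell only.
* Problem sizes in the tests and the acceptance script — cohorts of
  10–50 subjects at 179 visits, 100 curves for the oracle-equivalence sweep
  — were chosen as the smallest sizes at which cohort statistics stabilise.

## Known limitations

The 25-knot spline bounds resolution: episodes whose full span is at or
under the ~14-day knot spacing can leave no sign change in the smoothed
derivative regardless of depth (observed for 14-day-span episodes as deep
as 275 g on noiseless data); spans ≥ 24 days are reliably detected. Event
times are grid-quantized, so all durations are multiples of the collection
interval. The CV consolidation rule cannot rescue a visit whose three
replicates are mutually discordant. Depth thresholds assume the TEM is
known or estimable from the same protocol; a misspecified TEM shifts both
thresholds proportionally.
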