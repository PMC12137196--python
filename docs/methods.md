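# Methods

`bearacc` turns raw collar accelerometry from brown bears into behavioural
time budgets. This note records the models, conventions and numerical choices
the package fixes, and what its synthetic tests do and do not demonstrate.

## Signal model and feature chain

The collar records tri-axial acceleration at 8 Hz in units of g: x = sway
(side-to-side), y = surge (forward-backward), z = heave (up-and-down). The
stream is split into consecutive, non-overlapping 3 s windows of 24 samples,
anchored at the first sample. Three seconds is long enough to contain several
gait cycles of a galloping bear yet short enough that most windows hold a
single behaviour. Windows with missing samples or internal timestamp gaps
(sampling interval more than 1% above nominal) are flagged incomplete and
dropped; they are never padded or interpolated.

Each window is summarized by 36 statistics over eight signal channels:

* **static acceleration** per axis: a 3 s (24-sample) centred running mean,
  12 samples before the current one, the current one and 11 after, truncated
  at recording edges. It is computed on the *continuous* stream before
  windowing, so window edges borrow neighbouring samples; only streams'
  first/last 1.5 s use truncated means. Centred truncation avoids the phase
  lag a trailing mean would introduce.
* **dynamic body acceleration (DBA)** per axis: raw − static.
* **ODBA**: |DBAx| + |DBAy| + |DBAz|, a standard proxy for movement
  intensity.
* **magnitude**: sqrt(x² + y² + z²) of the raw axes.

The 36 features are mean, standard deviation, max, min, kurtosis and
skewness of x, y, z and magnitude (24); pairwise Pearson correlations of the
raw axes (3); mean DBA per axis (3); ODBA summed and averaged over the
window (2; proportional at fixed window length but both retained as
predictors); and the dominant power spectrum of x, y, z and magnitude (4).

Conventions fixed so every value is exactly reproducible:

* standard deviation uses the sample convention (ddof = 1), matching R's
  `sd`; correlations are plain Pearson on the raw axes;
* skewness and kurtosis are population moment ratios m₃/m₂^1.5 and m₄/m₂²
  (no bias correction, kurtosis not excess);
* a zero-variance channel reports 0 for its correlations, skewness and
  kurtosis — quantized sensors can emit exactly constant resting windows and
  those must remain classifiable, not NaN;
* the dominant power spectrum is the maximum of the one-sided, mean-removed,
  boxcar periodogram (density scaling) over strictly positive frequencies.
  A 24-point window at 8 Hz gives 1/3 Hz resolution; a constant channel
  returns exactly 0. The value returned is the maximal density, not its
  frequency.

## Training-set preparation

Annotation event tables (behaviour, start, end) come from video observation
and run on the camera clock. Behaviours outside the four-category ethogram
(resting, feeding, walking, running) — playing, fighting, shaking,
scratching, swimming, tree rubbing, drinking — are dropped; labels are
matched case- and whitespace-insensitively, and unknown labels are dropped
with a warning.

The camera clock typically runs ahead of the collar clock by one to a few
minutes. `estimate_clock_lag` automates the usual visual alignment: it
correlates a per-second binary activity signal from the events (active = any
non-resting behaviour) with per-second mean ODBA, scanning candidate lags
and returning the lag by which the annotation clock leads the collar clock
(ties toward the smallest lag; `apply_clock_lag(events, -lag)` then moves
the events onto the collar clock). The estimate requires both active and
inactive events, otherwise the objective is flat.

Labelled windows are tiled from each event's own start rather than a global
grid, so short events remain usable; any remainder shorter than 3 s is
discarded. Because a window must lie fully inside a single event, behaviour
transitions are excluded by construction. No class rebalancing is applied:
the forest is trained on the raw, imbalanced set.

## Classifier

A random forest with 1000 trees maps the 36 features to the four behaviours.
The number of predictors tried per split (mtry) is selected by out-of-bag
(OOB) error over the candidate grid {3, 6, 9, 12, 18} — a geometric
neighbourhood of floor(√36) = 6 — with ties to the smallest candidate. Other
tree hyper-parameters stay at the scikit-learn defaults and are recorded in
the serialized model. Training is seeded and deterministic; prediction ties
are broken by the fixed class order (feeding, resting, running, walking),
which is also the sorted label order of the ensemble.

Performance is reported as the OOB error, the OOB confusion matrix (rows
observed, columns predicted), and per-class one-vs-rest precision
(TP/(TP+FP)), recall (TP/(TP+FN)) and Matthews correlation coefficient
MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)). MCC is the headline
metric because the classes are heavily imbalanced (running is two orders of
magnitude rarer than resting). A metric whose denominator is zero is
reported as NaN, never silently as 0.

## Activity budgets

For wild data, walking and feeding are merged into one **feedwalking** state:
bears foraging on berries walk slowly while feeding, and the two signatures
are not reliably separable outside captivity.

Running is analysed as **bouts**: maximal runs of consecutive running
windows. Any other label or any recording gap ends a bout; bout duration is
(number of windows) × 3 s. Per bear-day the package computes the bout count
and the proportion of bouts inside **legal hunting hours** — 1 h before
local sunrise to 2 h before local sunset, computed by the package's NOAA
solar-position routine (zenith 90.833°) at the fixed study centroid
(61° N, 15° E, UTC+2). Choices fixed here: the interval is half-open
[sunrise − 1 h, sunset − 2 h); a bout belongs to the interval by its *start*
timestamp (bouts are seconds long, so start vs. midpoint is immaterial, but
the rule must be fixed); dates break at local midnight; a single site-level
solar geometry is used rather than per-bear positions. The study month
splits into pre-hunting (Aug 1–20) and hunting (Aug 21–31) periods, matched
by month/day so one calendar serves multi-year data.

Daily distance travelled is the sum of straight-line distances between
successive hourly GPS fixes whose endpoints share a date (Euclidean for
planar tracks, great-circle for geographic ones); days with fewer than two
fixes are undefined. For models downstream of this package, the 3 s label
stream can be thinned to 10 random windows per bear-hour (seeded, without
replacement) to blunt serial autocorrelation, and exported with period,
demographic group and time-of-day columns. A descriptive diel profile
(feedwalking proportion per time-of-day bin with a bear-day bootstrap CI)
summarizes the daily activity cycle.

## Synthetic data

The simulator emulates the statistical structure the pipeline assumes, not
bear biomechanics:

* **schedule**: a semi-Markov chain with exponential dwell times per
  behaviour. Exponential dwells are the simplest choice reproducing the
  overdispersion of short running bouts (mean ≈ SD ≈ 10 s). At each
  transition the next state is drawn with weights that, for feeding and
  walking, follow an hour-of-day activity profile (default: crepuscular,
  peaks at 04:00 and 20:00) — producing the bimodal diel pattern typical of
  this population — and fixed baseline propensities for resting and running.
  A per-behaviour override (`diel_by_behavior`) lets scenario studies place
  running preferentially in chosen hours, e.g. daytime hound-hunt escapes.
* **signal**: per behaviour, a constant gravity/posture vector plus a single
  gait sinusoid on surge and heave (90° apart) plus white Gaussian noise.
  Defaults: resting noise 0.02 g; feeding 0.08 g; walking 1.5 Hz at 0.25 g;
  running 3 Hz at 0.8 g; dwell means 120/60/30/9 s for
  resting/feeding/walking/running. These are separability fixtures (mean
  per-window ODBA orders running > walking > feeding > resting), chosen once
  and documented — no field estimates of wild-bear accelerations exist to
  calibrate against.
* **annotations**: schedule entries shifted by a configurable clock lag with
  optional Bernoulli dropout.
* **GPS**: hourly fixes displaced by (fraction of hour active) × nominal
  hourly distance in a random heading, plus noise.

Everything takes an explicit integer seed; there is no global random state.

What passing tests show — and do not. On synthetic data the classifier is
essentially perfect (OOB error ≈ 0), because single-sinusoid gaits plus
white noise are far cleaner than real collar data; published collar studies
report a few percent OOB error. The synthetic results therefore validate the
*machinery* (feature definitions, OOB bookkeeping, bout logic, solar
arithmetic, direction of the legal-hour shift), not field-level accuracy.
Real data add posture drift, collar rotation, behaviour mixtures within
windows and annotation error, none of which the simulator models.

## Problem sizes and numerical notes

Tests and the acceptance script use deliberately modest sizes — hundreds of
windows per class for forest training, a few simulated bears over ~8 days
for population scenarios, 1800 s streams for lag recovery — chosen as the
smallest sizes at which the checked properties are stable across seeds.
Degenerate inputs are handled explicitly: empty streams yield empty tables;
constant channels yield 0-valued spectral/shape features; days without
running bouts report an undefined (NaN) legal-hour proportion; zero-count
metric denominators yield NaN; polar day/night raises in the solar routine
(impossible at 61° N in August). The schedule generator's expected entry
count over a horizon T is T/mean_dwell + 1 (renewal boundary effect), which
the tests assert.

## Known limitations

* No resampling or axis re-orientation: streams are assumed continuous,
  calibrated and in g (an m/s² conversion flag exists).
* The feedwalk merge is applied globally; if a deployment *can* separate
  walking from feeding, work upstream of `merge_feedwalk`.
* Legal hours use one site-level solar geometry, not per-bear longitude.
* The package stops at analysis-ready tables; the downstream GAMM/GLMM
  model fits are out of scope by design.
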