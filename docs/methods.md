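# Methods

This note documents the models, estimators and numerical choices behind
`gutmotion`, what the synthetic generators do and do not emulate, and the
limitations a user should know before trusting the numbers on real data.

## Motility signal model

The pipeline's central object is the diameter matrix *D(x, t)* in mm: 30
equally spaced loci (sections of width `segment_length/n_loci`, 0.667 mm for
the default 2 cm segment) along the oral→aboral axis, sampled at 25 frames/s.
Loci are indexed from the oral end; all outputs carry fps and spacing so
units are recoverable from files alone.

**Edge tracking.** For video input, each frame's width is divided into
`n_loci` column bands. The row-intensity profile of a band is thresholded
with Otsu's method, recomputed per frame, which makes the result invariant to
any monotone brightness rescaling of a (near-)bimodal image. The outermost
above-threshold rows give the tube borders, and each border is refined by
linearly interpolating where the intensity ramp crosses the midpoint between
the local background and plateau levels — the half-coverage point of an
anti-aliased edge pixel. On rendered stacks this recovers the truth to
≲ 0.2 px (1 px is the guaranteed bound asserted in tests). Frames in which
any band has no above-threshold pixel (dropped or dark frames) are flagged
and filled per locus by linear interpolation in time; more than 10% flagged
frames is an error rather than a silent repair. No motion compensation is
attempted: organ-bath recordings are assumed spatially fixed.

**Baseline correction.** The slow component *B(x, t)* is a per-locus centred
moving median. A median rather than a mean because contraction troughs are
deep and asymmetric; a mean would be dragged down during every contraction,
a median is untouched while troughs occupy < 50% of the window. The window
must be much longer than a cycle: defaults of 20 s for small-intestine-like
signals (cycle ≈ 0.4–1.5 s) and 300 s for large-intestine-like signals
(cycle ≈ 70–105 s), both exposed in the API and CLI. Two caveats are inherent
to any finite window: (i) at the trace ends the window is one-sided and the
baseline bends toward the data (tests therefore assert on the interior), and
(ii) curvature of the drift leaves a residual of order `drift'' · w²/24`
(≈ 0.02 mm for 0.5 mm drift over 120 s with a 20 s window), which is why the
hysteresis band must not be made small relative to the drift scale.
`amplitude + baseline` reconstructs the input exactly; loci are processed
independently, so locus order is irrelevant.

**Normalisation.** The "initial diameter" that scales each locus is the mean
reconstructed diameter over the first second (not frame 0, which would
inherit a single frame's noise). Contraction-negative sign is preserved.

## Cycle detection and endpoints

**Hysteresis trigger.** Onsets are detected per locus by a Schmitt trigger
on *A(x, t)* in mm: the state machine arms above *+h/2* and fires when the
signal falls below *−h/2*; the onset time is the last zero crossing between
those passages, linearly interpolated between samples. The default band
h = 0.075 mm is the midpoint of the 0.05–0.1 mm range appropriate for real
recordings; the band applies to raw (not normalised) amplitude because that
is the scale on which measurement noise lives. Noise bounded inside the half
band can never fire the trigger — that is the point of the hysteresis — and
the generator's default Gaussian noise (sd 0.02 mm) stays inside it in
practice for fast signals.

For *slow* signals the raw trigger has a failure mode worth understanding:
with a ~70 s period the amplitude takes several seconds (> 100 frames) to
cross the band, and independent frame noise can re-arm the trigger mid
descent, double-counting cycles. `detect_cycles(..., smooth_s=...)` applies a
centred moving average (zero phase shift) before the trigger; 1–2 s — two
orders of magnitude below the cycle period — suppresses the frame noise by
√n without displacing the crossings. It defaults to off and should stay off
for sub-second cycles.

**Endpoints.**

* *Contraction rate*: the median over loci of per-locus onset counts,
  rescaled to the reporting window (per min or per 10 min). Median, not mean,
  so a dead locus at a segment edge cannot bias the count.
* *Mean interval*: intervals are full onset→onset cycles only (partial
  cycles at the boundaries are discarded); each locus is averaged first and
  the locus means are then averaged unweighted. This per-locus-then-grand
  mean (rather than pooling all cycles) keeps a locus with many short cycles
  from dominating. With no full cycle anywhere the interval is *missing*,
  never 0.
* *Velocity*: onsets are chained across adjacent loci when the lag is below
  half the local mean interval (the gate prevents chaining distinct waves);
  chains spanning ≥ 10 consecutive loci are kept, onset time is regressed on
  locus position, and the wave velocity is 1/slope, signed (aboral positive,
  retrograde negative). A chain whose fitted time spread across its span is
  below one frame period is flagged synchronous and excluded with a warning —
  an automated replacement for manually aligning a cursor along a wave front.
  The segment velocity is the unweighted mean over accepted waves.

"Leading edge" is taken as the *downward* crossing (contraction onset),
consistent with the contractions-negative sign convention.

## Synthetic motility data

`simulate_trace` builds `D = baseline + drift + noise − wave` with the
contraction onset of locus *i* lagging locus 0 by `i·spacing/velocity`
(infinite velocity = synchronous, negative = retrograde). The wave is
periodic and biphasic: a half-sine contraction trough of depth `amplitude`
occupying 40% of the period, then a half-sine dilatation lobe (default half
the trough depth) filling the remainder — so the diameter swings above and
below its slow average, as the sign convention requires, with one
zero-crossing pair per cycle. Half-sines rather than smoother lobes on
purpose: contractions should *start* decisively, giving the zero crossing a
non-zero slope; an infinitely smooth junction parks the signal inside the
hysteresis band for seconds at long periods and any detector will then ride
the noise. Drift is a single slow sinusoid (random phase) plus optional
linear ramp, shared by all loci, spanning both drift archetypes; noise is
additive per frame, Gaussian (sd 0.02 mm by default, below the hysteresis
band) or bounded uniform. Drift phase and noise come from independent
substreams of the seed, so toggling drift leaves the noise realisation
unchanged — that is what makes the drift-invariance checks exact rather than
confounded.

`simulate_cohort` draws independently seeded animals and applies a lognormal
between-animal jitter (`between_cv`, default 0.06) to each animal's frequency
and velocity. Without it, every animal in a group yields an identical
integer contraction count and group statistics degenerate; 0.06 matches the
spread typical of real contraction-rate cohorts.

What the generator does **not** emulate: non-stationary rhythms, mixed
motility patterns (segmentation vs peristalsis), wave-to-wave amplitude
variability, optical artefacts (shadows, meniscus, specular highlights), or
spatially correlated tracking noise. Passing the recovery tests therefore
demonstrates the *estimators* are correct and calibrated on signals of the
stated geometry — not that edge tracking will survive arbitrary video
quality.

## Count-matrix workflow

Housekeeping normalisation multiplies each sample by
`mean_s(gm_s) / gm_s`, where `gm_s` is the geometric mean of the
housekeeping counts (Actb, B2m, Gapdh, Rpl19) in sample *s* — the standard
scheme for digital hybridisation counts (an arithmetic-mean variant is
behind a flag). It exactly inverts per-sample scaling and is idempotent;
note the *target level* is the across-sample average, so a single rescaled
sample rejoins the cohort up to one global factor. Any non-positive
housekeeping count is an error naming the feature and sample, not a silent
pseudo-count.

The expression filter keeps features whose **mean normalised count across
all samples** is ≥ 100 (boundary inclusive). The per-sample-vs-mean reading
is ambiguous in common practice; the mean interpretation is recorded in the
CLI provenance output.

Differential expression is a two-sided equal-variance Student's t per
expressed feature on `log2(count + 1)` — the log stabilises count variance
and the pseudo-count avoids log 0 — with fold change reported on the linear
scale. The headline `significant` flag is raw p ≤ 0.05 to match the volcano
convention of the assay; Benjamini–Hochberg q-values are emitted alongside
for modern use but do not feed that flag. Features with zero within-group
variance on both sides get p = 1 when the means agree and a flagged missing
p otherwise. On spiked simulations (166 expressed features, 45 spiked
two-fold, n = 5 vs 6, NB dispersion 0.05) the pipeline recovers ≥ 90% of
spikes with a null false-positive rate of ~0.05.

Counter-regulation pairing intersects significantly *up* miRNAs with
significantly *down* proteins through a user-supplied two-column target map;
no target prediction or pathway inference is performed here.

## Image quantification

Binarisation defaults to Otsu (no method is canonical for "converted to
binary pictures"; a fixed threshold is available for audits); "positive" is
strictly above threshold, and a constant image is 0% positive by definition.
With a mask, the denominator is the mask area (marker per ganglionic area).
Cell counting is 8-connected components with an area floor (`min_area_px`,
boundary inclusive); there is deliberately no watershed, so bridged objects
merge — the failure mode is documented rather than half-fixed. In live/dead
counting, double-positive pixels are assigned to the dead channel
(conservative). Percent reductions are reported to two decimals, rounded
half away from zero.

## Statistics layer

Student's (equal-variance) t is the default because it is the convention for
these cohort sizes; Welch's t sits behind a flag. The Shapiro–Wilk screen is
always run (n ≥ 3) and recorded, and a non-normal outcome is logged
prominently but does not switch the test — silent test-switching makes
results irreproducible across cohorts. All tests are two-sided. Cohen's d
uses the pooled sd and is computable from raw samples or from (n, mean, sd)
summaries; the two paths agree to 1e−12, and d is 0 for identical groups but
*missing* when the pooled sd is 0 with unequal means. Two-way ANOVA uses
type-II sums of squares; with one observation per cell the interaction is
not estimable and is reported missing from an additive fit rather than
invented. Stars follow p ≤ 0.05/0.01/0.001, boundary inclusive.

Calibration, verified in the test suite at nominal α = 0.05 over null
simulations: the expressed-feature false-positive rate of the count pipeline
and the ANOVA factor rejection rate sit within [0.03, 0.07]; a single
200-draw binomial estimate of any such rate has sd ≈ 0.015, so individual
batches can land outside that band by chance roughly one run in seven.

## Problem sizes

The verification suite runs on desk-scale versions of the assay conditions:
60 s traces at 25 frames/s × 30 loci for small-intestine-like signals
(10 min for the slow large-intestine-like check), 20 seeded replicates for
parameter recovery, 100 for noise rejection, 200 for each null-calibration
estimate, and 578-feature × 11-sample count matrices. These sizes keep the
whole suite under a minute per stage while leaving the Monte Carlo error of
each asserted quantity well below its tolerance.

## Known limitations

* Baseline correction operates on diameters; if a tracking stage outputs
  border *positions*, correct them upstream.
* The velocity estimator assumes one dominant wave front per cycle per
  region; colliding or branching fronts will be chained imperfectly (the
  interval gate only bounds the damage).
* The expression filter and DE assume two groups; multi-group designs go
  through the ANOVA layer instead.
* Otsu binarisation presumes a roughly bimodal intensity histogram; uneven
  illumination needs flat-field correction before quantification.
* No 3-D quantification, deconvolution, ganglion segmentation, target
  prediction or pathway analysis.
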