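# Methods

`nestrhythm` reconstructs biparental incubation schedules from two nest
logger streams and analyses the quality, amount, and timing of incubation.
Because raw field recordings are rarely redistributable, the package ships
a synthetic sensor-data generator with known ground truth; every stage of
the pipeline is validated end-to-end against that ground truth.  This note
documents the models, the generator, the numerical choices, and what the
validation does and does not show.

## The measurement problem

A pair of shorebirds shares incubation in alternating bouts of roughly
half a day.  Two loggers watch the nest:

* a temperature probe between the eggs (2-min interval by default) that
  sits at a warm plateau (~35 °C) while a bird incubates and relaxes
  toward the surface tundra temperature when the nest is uncovered;
* an RFID antenna in the nest cup that reads the tag of the sitting bird
  every 5 s, with occasional missed reads.

A reference ("tundra") logger beside the nest provides the uncovered
baseline.  From these streams the pipeline derives, per nest: incubation
bouts with lengths and owner identity, per-bout incubation constancy
(fraction of the allocation actually spent sitting), exchange gaps at
changeovers, and disturbance flags from field-worker GPS tracks.

## Segmentation (temperature state machine)

Classification runs on the nest-probe grid.  Let `e_t` be the excess of
nest temperature over the rolling-median-smoothed tundra baseline
(10-min window) and `s_t` the temperature slope in °C per 2 min.
The state machine switches

* incubated → off on a steep decrease (`s_t ≤ −1.5`) or on the excess
  falling below `threshold − hysteresis` (3 − 1 °C);
* off → incubated on a steep increase (`s_t ≥ +1.5`), or on sustained
  excess above threshold while **not falling** — the non-falling guard
  prevents re-entry during the slow cooling tail of a long absence.

Off runs shorter than 120 s are folded back into the surrounding
incubated state.  Transition times are placed at the midpoint of the
sample step on which they fire, so changepoints on noise-free traces are
recovered to within half a native sample and the constancy estimate is
unbiased to first order.  All thresholds live in `SegmentationParams`;
the defaults were chosen so that noise-free recovery is exact and
recovery at default noise exceeds 95% per-instant agreement.

## RFID fusion and bout accounting

Reads are run-length encoded per tag; runs shorter than a 2-min majority
window that are flanked by the partner's runs are absorbed (single-tick
misreads).  A changeover occurs where tag dominance switches.  A bout's
allocation runs from its owner's first read after the previous changeover
to the partner's first read; the exchange gap (partner's first read minus
owner's last read minus one tick, floored at zero) therefore falls inside
the **departing** parent's allocation and lowers its constancy.  Whether
the original field protocol attributed changeover gaps to the departing
or arriving bird is not documented; this convention keeps
"bout + gap" accounting consistent with allocation-based bout length,
and the package applies it uniformly.

Constancy is classified-incubated time within the owner's duty window
divided by allocation length.  Per-bout median z-scored temperature uses
the within-nest z-transform (mean 0, SD 1 by construction) over
owner-incubated samples.

Gap durations inherit the 5-s tick quantisation.  Summary medians of
detectable gaps therefore use a grouped-data median (linear interpolation
across the tick bin straddling the half point); the raw sample median of
tick-multiples flips between adjacent ticks when an atom sits near the
50% point.

## Exclusion rules

In order: (1) the first two bouts after the first parent capture (the
earlier of the two parents' capture times); (2) the bout during which the
nest was deserted or depredated; (3) bouts ending within 6 h before the
start of hatching (read literally: a bout is excluded when its *end*
falls in that window); (4) nests left with fewer than four bouts.
Exclusion is annotation, not deletion, and is idempotent.
Day-of-incubation is real-valued days from incubation start to the bout
midpoint (the anchor within a bout is not standardised anywhere; the
midpoint is symmetric and makes the day covariate insensitive to bout
length to first order).

## Mixed models of quality and amount

Five per-bout responses are modelled: median z-temperature, arcsine-
square-root constancy, bout length (min), detectable-gap occurrence
(binomial), and log gap duration.  Fixed effects: sex (uncentred, female
reference) in interaction with day of incubation, previous (partner's)
bout length for the bout model, and confounders (disturbance, radio tag,
within-sex-centred mass and culmen, season start, probe type where
relevant); all non-sex predictors mean-centred.  Random structure: nest
intercept plus a z-scored-day random slope.

Gaussian models are maximum-likelihood `MixedLM` fits (ML rather than
REML so nested fits are comparable; the recovery contract, not the
estimation flavour, is what the tests pin down).  When the variance
profile collapses at the boundary — where `MixedLM` can return degenerate
fixed effects — the fit degrades gracefully: random slope dropped, then
random intercept, ultimately OLS with variances reported as 0.  The
binomial gap-occurrence model uses the variational Bayes approximation
(`BinomialBayesMixedGLM`); its posterior is factorised, so only a
diagonal coefficient covariance is available downstream.

Simultaneous inference follows the single-step max-|z| construction:
the adjusted p of coefficient j is P(max_k |Z_k| ≥ |z_j|) under the joint
normal with the fit's coefficient correlation, computed by seeded Monte
Carlo (10^5 draws) over **all** fixed-effect coefficients (the original
analysis does not document a narrower contrast set).  With independent
coefficients this approaches the Šidák bound; with perfectly correlated
ones it returns the raw p.

## Circular timing analysis

The per-5-s incubation state is strongly autocorrelated, so each
analysis iteration subsamples 0.025% of each nest's usable ticks
(allocation time of retained bouts), accepted greedily in random order
under a ≥2.5-h pairwise spacing, giving ~40 points per nest and ~2000
per iteration at study scale.  Clock time enters as sin/cos of the
time-of-day angle (midnight = 0; the choice of phase anchor is immaterial
because the model class is rotation-equivariant), each in three-way
interaction with day of incubation and season start; nest is a random
intercept with independent sin/cos random slopes.

The random-effects fit is variational Bayes.  Note that independent
sin/cos slope variances are *not* closed under clock rotation (only an
isotropic slope covariance is), so exact rotation equivariance holds for
the fixed-effects logistic model (`random_effects=False`, Newton to
1e-10), which is what the equivariance test pins at 1e-6; the
random-effects fit is checked for validity and sign stability instead.
Iterations with a single response class, separation, or divergent
posteriors are flagged invalid and dropped from aggregation, mirroring
the bookkeeping of "iterations with p < 0.05" out of the valid count.
Aggregates are means and 0.025/0.975 quantiles over iterations;
per-iteration seeds are spawned deterministically from the master seed,
so summaries are reproducible and invariant to iteration order.

## Rhythm classification

A cycle is one female bout plus the male bout that follows it.  The
changeover clock trajectory is unwrapped (differences mapped to
(−12, 12] h) and differentiated with central differences; drift
statistics are time-weighted because running cycles are shorter than
24-h cycles and raw cycle counts would over-weight them.  Labels:
day-night when the median cycle is within 1 h of 24 h and the mean
absolute drift is ≤ 0.5 h/day; running when drift beyond 0.5 h/day with
one sign covers ≥ 70% of the record; mixed otherwise; nests with fewer
than four cycles are unclassified.  The numeric thresholds are package
defaults (the source material describes the classes qualitatively) and
are validated only against generator labels.

## The synthetic-data generator

The generator emulates a 48-nest high-Arctic season under continuous
daylight.  Nest life history: incubation starts spread over 26 calendar
days (discretised Beta(1.6, 4.4), median day 7); loggers deployed 3–9
days into incubation (both parents caught then); 50% of nests hatch at
day 21, 45% are depredated and 5% deserted at a uniform time after
deployment.  These choices put the retained-bout count at study scale
(~900–1050 from 48 nests) and are fixed, not tuned per run.

Two bout-generation modes:

* **model** — bout length (min) follows
  `L_i = 692.2 − 50.9·male + 7.8·(day − mid) + 0.4·(L_{i−1} − 666.75)
  + u_nest + ε`, with `u ~ N(0, 2032)`, `ε ~ N(0, 13779)`, floored at
  5 min.  The partner-coupling term is an AR(1)-style completion on the
  grand-mean-centred previous bout: the published model is a regression,
  and this is the minimal generative process whose conditional
  expectation reproduces its coefficients.
* **pattern** — nests are assigned day-night / running / mixed rhythms
  (default mix 1/3 each).  Day-night nests anchor the female bout so that
  a fraction `female_night_bias` of the 12-h cold window falls inside it;
  running nests drift ±1–3 h/day; mixed nests switch regime near the
  middle of the monitored window.  Records shorter than 9 days cannot
  express a regime change and are assigned a pure rhythm instead — the
  ground-truth label describes the generated record, which is what a
  classifier can be held to.

Exchange gaps have a point mass of instantaneous changeovers
(P ≈ 0.51 at the record midpoint, logit day slope −0.155) and otherwise
log-normal durations (median 35 s, σ_log 1.35 — the value implied by the
published residual variance of log gap duration — log-median day slope
−0.09).  Both day trends are negative, so detectable gaps oversample
early days; the duration model is therefore anchored at the
detectability-weighted mean day, which makes the realised median
detectable gap equal the configured median.  Within-bout breaks realise
per-bout constancy: off-nest fraction log-normal around a median of 5.1%
(female), split into Poisson-many breaks of ≥2 min placed uniformly
without overlap; the male offset is scaled by exp(−σ²/2) so that the
*mean* female−male constancy difference equals the configured 0.9
percentage points.

Temperatures: tundra is a diel sinusoid parameterised by warm-half and
cold-half daily means (defaults 10 °C and 1.5 °C, minimum at 03:30 —
night mean ≈ 15% of day mean, below-median window 21:30–09:30) plus
Gaussian noise (SD 0.8 °C).  The nest probe follows a first-order
relaxation (τ = 15 min) toward the plateau when the owner sits and
toward the concurrent tundra temperature when it does not, plus 0.25 °C
noise; the discrete filter relaxes toward the target of the *previous*
sample so a grid-aligned break end matches the closed form
`tundra + (plateau − tundra)·exp(−Δt/τ)` exactly.  RFID reads the
owner's tag on every 5-s tick inside attendance, with 1% independent
dropout.  Worker GPS tracks walk daily survey rounds between nests and
define ground-truth disturbance windows.

Calibrated constants: `female_night_bias = 0.75` was set once by a
simulation sweep so the pipeline's median per-nest-day female share of
the cold window lands near 72.6% under the default mix, and left alone
thereafter.

### What the generator does not emulate

Weather beyond the diel temperature cycle, predation timing structure,
renesting, chick care, egg-cooling physiology inside bouts (the plateau
is flat), probe placement drift, and reader failures longer than single
ticks.  Passing the validation therefore shows that the pipeline's
*extraction and statistics* are correct under the stated sensor physics
and schedule structure, not that the segmentation thresholds are optimal
for any particular real logger deployment.

## Known limitations and numerical notes

* Boundary truncation of records (deployment, nest fate) combined with
  the exclusion rules mildly attenuates the bout-model coefficients
  recovered through the full pipeline (≈4–6% on the sex, day, and
  previous-bout terms at study scale); single-study estimates are noisy
  (e.g. SE ≈ 1.5–1.9 min/day on the day slope), which is why the
  reproduction script averages coefficients over replicate studies.
* The VB binomial fits provide no full coefficient covariance; the
  max-|z| adjustment then degenerates toward Šidák for those models.
* `derive_cold_window` assumes a single contiguous cold interval per
  day; multimodal diel profiles would need a different definition.
* Problem sizes in the test suite are scaled for a desk run: the CI
  coverage check uses 50 replicate 12-nest studies, and timing-iteration
  tests use handfuls of iterations; the full 5000-iteration analysis is
  available behind `--iterations` on the command line.
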