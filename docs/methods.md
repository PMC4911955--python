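# Methods

This note records the statistical model behind `streampass`, the defaults
and their rationale, the numerical conventions, and the known limits of
what the synthetic tests demonstrate.

## Double-sampling estimator

The estimand is season escapement: net fish entering a stream to spawn.
The auxiliary variable (hourly time-lapse photo counts, both directions)
is measured for every hour; the accurate variable (video-enumerated
passage) only for a subsample of hours chosen deliberately to span the
observed range of photo counts, from strong downstream to strong upstream
movement. Because the subsample is not a probability sample, the link is
*model-based*: a regression of video passage on photo count, valid so long
as the regression is correctly specified, with no requirement that video
cover the whole season. (The design-based alternative — expand the photo
total by a ratio estimated from a random subsample — is deliberately not
implemented; it needs complete, perfect-detection video coverage.)

Direction is encoded by sign (upstream +, downstream −) so one regression
serves both directions; an hour contributes two signed observations, and a
70-hour subsample yields 140 values.

### Candidate forms and selection

All four candidate forms pass through the origin — zero photos, zero
passage — which is both physically required and what makes the segmented
forms identifiable with the split point pinned at x = 0. The split point
is never estimated. The segmented-polynomial quadratic is a single shared
x² coefficient by default (three slope parameters); a sign-antisymmetric
x·|x| variant is selectable because either convention is defensible and
published examples of this model family are ambiguous between them.

Fits are plain least squares (no weighting; the field data this mirrors
were fitted unweighted). AICc uses the Gaussian least-squares likelihood
with the residual variance counted as a parameter, K = slopes + 1, and the
additive constant n·ln(2π) + n included. Absolute AICc values therefore
depend on a bookkeeping convention; only AICc *differences* are meaningful
and only orderings are ever asserted. The slope-only count k is reported
alongside for comparison with conventions that omit the variance. Ties
within 1e-9 go to the smaller K.

LOOCV uses the exact hat-matrix identity ŷ₍₋ᵢ₎ = yᵢ − eᵢ/(1 − hᵢᵢ), which
for a linear model equals an explicit refit with observation i removed
(the test suite checks this against the brute-force refit). Accuracy is
the signed percent difference between summed LOO predictions and summed
signed observations — net passage, so over-predicted upstream movement can
cancel over-predicted downstream movement, which is the operationally
relevant error for an escapement estimate. MSE of the LOO predictions is
the precision metric.

### Escapement and its interval

Escapement is Σ over season hours of f(+up photo) + f(−down photo) under
the selected fit. Gap hours (camera outages) are reported and excluded by
default; a zero-fill flag treats them as zero counts instead. Neither
choice is "correct" — excluding gaps assumes no passage during outages,
exactly like zero-filling, but keeps the coverage honest in the output.

The 95% CI is a percentile bootstrap: redraw the signed observations with
replacement at the original subsample size, refit the selected form,
re-predict the season total; 10,000 replicates by default. The resampling
unit is the single signed observation (an hour's up and down values are
resampled independently); an hour-paired mode is available for users who
consider the two directions of an hour dependent. Rank-deficient redraws
(e.g. a segmented form with an empty branch) are rejected and redrawn,
counted, and the run aborts if they exceed half of all draws. Because
percentile intervals are asymmetric, the output reports the bounds, half
the interval width, and the larger deviation of either bound from the
point estimate.

### Attenuation under thinned detection

If photo counts are binomial thinnings of true passage, regressing video
on photo estimates E[video | photo], which is *shrunk* relative to
photo/p: an extreme photo count partly reflects lucky detection. The
fitted slope therefore sits below 1/p, increasingly so as hourly counts
shrink, and season totals inherit a small negative bias at realistic count
scales (measured at the default scenario: about −6% point-estimate bias
against a bootstrap interval roughly ±33% of the truth; replicated
coverage of the nominal 95% interval is 96–100%). At very low escapements
(a few thousand fish) hourly photo counts barely vary and the regression
carries little information — the same regime practitioners are warned
about in the field, and the reason slope-recovery checks are run at high
hourly counts.

## Stream life and survival

Stream life (entry to death, days) is modelled per stream as a
death-count-weighted average across mortality mechanisms (senescence,
predation, stranding), then regressed with intercept on one morphology
predictor. Depth and width are strongly collinear in real stream-life
data, so only simple regressions are fitted and the predictor is chosen by
AICc (K = 3); both AICc values and the width–depth correlation are always
reported. The stream-life SD is tied to the mean, SD = 0.499·mean, rather
than modelled separately — the mean–SD correlation in published
stream-life data is ~0.95 — with the ratio configurable. The regression
prediction SE of the mean is reported alongside the ratio-based SD because
published stream-life uncertainties are ambiguous between the two
conventions.

The survival curve is S_t = 1 − F(t) at integer days with S_0 forced to 1.
The lifetime distribution family is genuinely unspecified by the method's
provenance; the default is a normal truncated below at zero (minimal
assumption given only a mean and SD; truncation, not clamping, so the
density is renormalised), with untruncated-clamped-normal and gamma
alternatives. N, the practical end of a cohort, is the first integer day
with S_t < eps (default 1e-4 — a continuous CDF never reaches zero
exactly); the evaluation horizon comes from the distribution's own tail
quantile so heavy-tailed choices still terminate. SD = 0 degenerates to a
step curve (S = 1 before the mean, 0.5 at an integer mean, 0 after).

## In-stream abundance

Daily net passage P_x (calendar-day sums of the signed hourly predictions,
gap days zero-filled inside the season span) is convolved with S:
A_x = Σ_{t=0..N} P_{x−t}·S_t. Today's entrants count in full (S_0 = 1) and
each earlier cohort contributes its surviving fraction; the series extends
N days past the last passage day so the run tail dies out in-window.
Negative P (net departures) propagates through the convolution as-is — the
model cannot know which cohort departed — and any negative A is floored to
zero for reporting, with the raw series retained and a warning issued.

Run duration is the count of days with A at least 10% of the *unaltered*
model's maximum; in sensitivity runs the threshold stays anchored to that
baseline maximum so that altered scenarios are scored against the same
absolute bar. Sensitivity perturbs the mean and the SD one at a time
(the SD is not re-scaled by 0.499 when the mean moves), skipping deltas
that drive the mean non-positive.

## Synthetic-data generator

The generator emulates the deployment conditions the method was built for:
a 75-day summer season; 30,000 entries in two pulses (2.0- and 2.5-day
spreads, chosen so peak hourly passage reaches the several-hundred-fish
scale of real deployments — at much lower counts the detection-attenuation
regime above dominates); a diel profile putting 80% of movement between
12:00 and 20:00; per-fish same-day down-then-up excursions at 0.08/day
(bidirectional movement is common where bears hunt spawners), which leave
net passage equal to entries; stream life 7.1 d mean, SD 0.499·mean,
truncated-normal; photo detection probabilities 0.065 up / 0.053 down
(reciprocals of representative fitted slopes; slower upstream swimmers are
more detectable); 70 subsampled hours. Video is modelled as exact truth,
matching a subsample protocol restricted to hours with near-perfect
detection.

What the simulator does *not* reproduce: fish loitering over the contrast
panels (extra-binomial photo noise), glare/night-time video quality,
species mixtures, burst-level geometry (detection is thinned per hour, not
per three-frame burst), and excursions spanning midnight. Passing tests
therefore certify the estimation machinery under an idealised observation
model, not field performance; the real residual scatter is larger than
binomial, which widens real intervals relative to synthetic ones.

## Problem sizes and numerics

Default test and acceptance problem sizes — 200 replicate seasons with
300-replicate bootstraps for coverage, 2,000-replicate bootstraps for
single-season intervals, 400-replicate per-fish oracles — were chosen as
the smallest sizes at which Monte-Carlo error is comfortably inside the
asserted tolerances. OLS solves use QR/lstsq; bootstrap refits use the
normal equations on the resampled design for speed, with singular redraws
rejected. All simulation and bootstrap randomness descends from a single
seed via spawned child sequences; fixed seeds give bit-identical output.

## Known limitations

- The escapement estimator is only as good as the fitted photo↔video
  relationship; at escapements below a few thousand fish it is weakly
  identified (see attenuation note above).
- Negative-abundance flooring is ad hoc; a cohort-resolved model would be
  needed to attribute departures properly.
- The stream-life regression machinery assumes the user supplies a
  stream-life table relevant to their system; the shipped example table is
  synthetic and illustrative only.
- The abundance equation treats all entrants as subject to the same
  survival curve regardless of entry date (no seasonal mortality trend).
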