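# Methods

This note documents the models and procedures implemented in `pupdyad`,
the choices made where the design was genuinely open, and what the
synthetic test bed does and does not establish about real recordings.

## Clocks and synchronization

Video (30 fps) and ultrasound audio are recorded by independent devices; a
beep marks trial start in both.  The trial clock places t = 0 at the first
video frame with an audible beep (and at the audio sampling point before
it) and ends the trial 100 s later.  Frame indices are 0-based; frame *k*
maps to time *k*/fps; all intervals are half-open `[start, stop)`.

The audio stream is trimmed at 25 fps granularity, so the two clocks can
disagree by up to one trim frame.  We model this as a reported
`alignment_uncertainty` (1/25 s = 40 ms at defaults) rather than by
resampling: every downstream feature operates at time scales (seconds)
where a 40 ms shift is immaterial, and resampling would create a false
sense of sub-frame precision.

Calls overlapping `[0, hand_exit)` — the interval from the beep until the
experimenter's hand has left the cage — are removed *whole*, not truncated:
a partial call is not a meaningful biological unit, and the removal count
is surfaced per trial so the choice is auditable.  Removal and
trial-window clipping commute, which the suite verifies.

## Trajectory quality control and retrieval estimation

The distance series d(t) is the Euclidean distance (px / `px_per_mm`, in
mm) between the nest point and the pup centroid, where the centroid
averages pup keypoints with likelihood ≥ `keypoint_p_cutoff` (0.10).  A
second, stricter rule discards frames whose likelihood averaged over *all*
pup keypoints is < 0.01; the two thresholds are deliberately distinct (one
selects keypoints within a frame, the other rejects whole frames).

The chain is: start clamp → likelihood filter → loess rejection → first
crossing.  Each stage only adds missingness or clamps values; none invents
data.

* **Start clamp.** The rolling median is *trailing* over the most recent 90
  frames with shrinking windows at the start, making "the first frame where
  the rolling median exceeds 85 mm" well defined from frame 1 (a centred
  window would leave the first 45 frames undefined).  If the median never
  exceeds 85 mm the clamp is skipped and a quality flag raised.
* **Loess.** Degree-2 local regression with tricube weights over a
  k-nearest-neighbour span of 0.25 of the present points, predictor = time
  in seconds, fitted once on pre-rejection data (no refit after outlier
  removal — refitting is not clearly better and makes the rejection set
  order-dependent).  Missing frames are simply absent points; no
  interpolation.  The implementation is hand-written (the installed stack
  only offers degree-1 lowess) and verified to machine precision against an
  independent reference local-regression implementation on a frozen
  fixture (`tests/data/loess_oracle.csv`).  Observations deviating more
  than 15 mm from the fit become missing.
* **Nest entry.** Retrieval time is the first *cleaned observed* frame with
  d ≤ `nest_entry_radius`.  The radius default (30 mm, about a pup body
  length) is a package choice — "entered the nest" has no canonical metric
  definition — and is echoed into every output file.  Trials that never
  cross are censored: success = 0 and retrieval time = 100 s, the same
  convention used for manual scores.

**Known limitation — smoothing-induced lag.**  With a 0.25 span on a
3000-frame trial the loess window is ~25 s wide, while a maternal carry
covers ~300 mm in 2–4 s.  No 25 s-window smoother can track that descent
within 15 mm, so the rejection step removes a band of frames around the
entry event (typically ±3–8 s) and the first *surviving* in-nest frame
lands ~2.5–4.5 s after the true entry.  The consequences, measured on the
synthetic cohort:

* retrieval-time estimates carry a systematic positive lag (median ≈ 3 s)
  but remain tightly rank-correlated with truth (r > 0.98), so censored
  regressions — which are rank-based within risk sets — are essentially
  unaffected;
* success calls agree with ground truth in ~98% of trials (errors arise
  only for true entries in the last seconds of the window);
* sub-frame agreement between estimate and truth is *not* achievable under
  these published smoothing parameters; the acceptance test asserting a
  one-frame bound documents this as a failing check rather than silently
  relaxing it.

Self-returns (pup walks itself to the nest) are flagged when the dam
centroid stays farther than 50 mm from the pup throughout the 3 s before
entry.  Both numbers are heuristics — the original identification was by
eye — and are config knobs.

## Call features

All features use the segment *start* for window membership: a call
straddling the retrieval instant counts as "before retrieval", and a call
starting exactly at 10 s is outside the early window.  Rate divides the
before-retrieval count by the retrieval time (censored trials: 100 s);
durations are stored in seconds and reported in ms.  A silent trial yields
a complete record with zero counts and missing duration/latency.

## Validation

The confusion summary takes manual scores as reference and **"not
retrieved" as the positive class** — the only convention under which a
published agreement table's sensitivity and specificity follow from its
cells.  The accuracy CI is exact Clopper–Pearson (the common default when
a binomial CI is reported without naming a method); its coverage is
property-tested on simulated Bernoulli draws.  Segment detectors are
evaluated sample-wise on a 1 ms grid rather than event-wise: it matches
the frame-labelling formulation of segmenters and makes "overall accuracy"
well defined.  Overlapping segments are merged (union semantics) with a
warning before gridding.

## Statistics

Models adjust for pup sex, test day (PND) and condition as fixed effects
and maternal trial sequence as a continuous covariate.  Reference levels:
sex = female, day = PND5, condition = first level alphabetically; these are
package choices recorded in the output metadata.  Success is fitted by a
binomial GLM with logit link; exponentiated coefficients are reported as
**odds ratios** (field usage sometimes labels them "HR"; we keep each
model's precise name).  Latency is fitted by Cox proportional hazards with
censoring at 100 s and the Efron tie approximation, cross-checked against
an independent partial-likelihood implementation on a frozen tied fixture.
Dam identity does not enter as a random effect; an optional cluster-robust
variance switch (by dam) is exposed instead.  Analyses of the 10 s call
count exclude trials retrieved before 10 s (the count and rate are
otherwise truncated by the outcome); the exclusion count is reported.

Poor retrievers are dams retrieving on *strictly fewer* than 50% of their
trials (2/4 is kept).  Repeatability matrices correlate dam × sex trait
means across day pairs, with cells suppressed below 3 complete units.

## Synthetic cohorts

The generator reproduces the study design: 29 dams, litters culled to six,
days PND 5/7/9/11/13, six trials per dam on PND5 and four otherwise (22
per dam, 638 total), pup sex counterbalanced within dam, three condition
groups assigned per litter.

Per trial, a latent call rate λ is drawn from a Gamma distribution (shape
4) around a day-specific mean peaking at PND7–9 (1.8, 2.8, 2.6, 2.0, 1.4
calls/s — chosen to mirror the developmental inverted-U of isolation
calling), call events follow a homogeneous Poisson process at λ, and call
durations are lognormal (mean 35 ms, σ = 0.35) with an 8 ms shorter mean
for males.  Retrieval is drawn as `2 s + Exponential(h)` with

    h = 0.04 · exp(log(0.58)·λ + log(1.19)·(trial − 1)),

censored at 100 s.  The fixed 2 s offset keeps the proportional-hazards
structure exact (a shared baseline shift) while preventing retrieval
before the hand has left the cage; the base hazard 0.04/s puts the
marginal retrieval fraction near 75–80%, in the range typical for
C57BL/6J dams.  The rate→hazard direction is generative convenience, not a
causal claim; a reverse (hazard→rate) coupling is available for
sensitivity analyses.  Trajectories place the pup ~310 mm from the nest,
carry it linearly to the nest so that it crosses the entry radius exactly
at the drawn retrieval time, and emit keypoints with 2 mm Gaussian jitter,
5% dropout and Beta-mixture confidence scores whose low component
exercises both likelihood thresholds.  Manual scores add 3 s Gaussian
timing error and disagree on success in 4% of trials; 2% of trials are
self-returns (scored "not retrieved" by the manual observer, as a human
would).  Every trial owns an RNG stream keyed by (seed, dam, day, trial),
so bundles are byte-identical across runs and generation orders.

**Measurement artifact worth knowing.** The *measured* rate
(count/retrieval time, with hand-interval calls censored) is not a clean
proxy for λ: the hand interval removes a fixed ~1–2 s of calling, which
deflates the measured rate more for fast retrievals, and the denominator
is the outcome itself.  Regressing on the measured rate therefore biases
the rate hazard ratio away from 1 (≈0.50 instead of 0.58) and breaks
Type-I calibration even under a null coupling.  Recovery and Type-I
checks consequently use the latent λ stored in the ground truth; the
full-pipeline closed loop uses measured features and is checked for effect
*signs* only.  Real studies face the same artifact; the package surfaces
both covariates so analysts can choose deliberately.

## What the tests do and do not show

Oracle-equivalence and published-table checks establish numerical
correctness of the primitives.  The synthetic closed loop establishes that
the chain as a whole preserves the generating effect structure under the
modelled noise (Gaussian keypoint jitter, dropout, occlusion, manual
error).  Real tracking failures — identity swaps between dam and pup,
long occlusions in the cup, reflections — are not modelled, so passing
tests bound what the pipeline can do on clean data, not what a given video
corpus will deliver.  Problem sizes in the suite (8-dam closed loop,
200-replicate recovery, 1000 null simulations, 100-trial noiseless runs)
were chosen as the smallest cohorts at which the checked statistics are
stable.
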