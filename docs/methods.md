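# Methods

## The measurement model

The pipeline's unit of analysis is the leave-one-out intersubject
correlation (ISC).  For each (participant, condition, fROI) cell the
regional BOLD series is correlated with the plain average of the remaining
participants' series for the same cell; the average is computed over
already z-scored series and is not re-standardized (z-score → average →
correlate, in that order).  Correlations are Fisher-transformed,
`z = atanh(r)`, before any parametric statistics; `|r| = 1` is an error by
default (infinities would poison the mixed models) with opt-in clipping at
1 − 1e−7.

Preprocessing drops `round(6 s / TR)` samples at stimulus onset (3 samples
at TR = 2 s) to exclude the initial hemodynamic rise, then z-scores each
series with the n−1 variance convention.  Offset trimming is not applied
(nothing analogous to the onset rise exists there), and input series are
expected to already exclude pre/post fixation periods — the condition
durations in the built-in design templates include 2 × 16 s of fixation,
and the generator emits `round((duration − 32 s)/TR)` samples accordingly.

## Synthetic data

The generator exists so every statistical routine can be validated against
a known truth.  Its signal model is additive Gaussian with equal variance
across participants:

    x_icf = sqrt(a_cf) · s_c + sqrt(1 − a_cf) · ε_icf

with one shared signal `s_c` per condition (common to all fROIs) and
independent participant noise.  Both streams are temporally smoothed
(Gaussian kernel, default FWHM 3 TRs) to mimic hemodynamic
autocorrelation — smoothing rather than HRF convolution, because what the
peak-removal machinery needs is realistic autocorrelation, not a
biophysical response shape — and standardized to unit sample variance, so
the tracking strength `a` (the fraction of variance that is
stimulus-locked) is realized exactly in every run.  Under this model

    E[ISC] = a / sqrt(a + (1 − a)/(n − 1)),

and the default strengths a = {+M/+L: 0.11, +M/−L: 0.047, −M/−L: 0.003}
were solved from this expression so the three condition-type mean ISCs land
near 0.295 / 0.164 / 0.016 at n ≈ 30 — the regime the published design
operates in.  The `paper` template reproduces that design exactly: 10
conditions with Ns {33,32,32,31,34,31,29,29,14,15}, durations 4:36–7:06,
five language fROIs, a 47-participant pool.  Participants are assigned to
conditions by seeded random sampling that matches the per-condition Ns;
the joint per-participant pattern of the original study is not published
and is treated as free.

One global seed expands into named substreams (signal, noise,
participation, text) via `SeedSequence` spawn keys, so every artifact is
reproducible independently of evaluation order; identical seeds give
bit-identical outputs.

What the generator does **not** emulate: head motion, scanner drift,
physiological noise, voxel-level spatial correlation (outside the t-map
fixture), inter-regional heterogeneity of the hemodynamic response, and
non-Gaussian stimulus-locked dynamics.  Passing tests therefore certify
the statistical machinery under the additive model, not robustness to real
scanner artifacts.

For the peak-sensitivity analyses a separate constructive fixture
concentrates the shared signal in ~10% of time points (amplitude 3 bursts
on unit noise), so the group average exceeds z = 1 exactly where the
intersubject coupling lives; removing detected peaks should then, and
does, collapse the ISC while count-matched trough removal leaves it
intact.

## fROI definition

Within each group-level parcel, the gray-matter mask is applied first and
the top `ceil(0.10 · m)` of the m surviving voxels by localizer-contrast t
value form the fROI.  Ceiling (not floor or round) guarantees nonempty
fROIs for tiny parcels; ties at the cutoff break by lowest linear voxel
index so selection is deterministic across platforms.  The participant QC
counts suprathreshold voxels (one-tailed p < 0.001, from the contrast's t
distribution) across all parcels∩GM and fails strictly below 100 — a count
of exactly 100 passes.  fROI extraction z-scores each voxel over time
before averaging, which absorbs per-voxel affine gain/offset; constant
voxels are dropped with a warning.

## Peak and trough removal

The detection series for a condition is the grand average over all
participating participants **and** all fROIs, z-normalized; peaks are
strict z > +1, troughs strict z < −1.  (Per-fROI detection is available
behind a flag but off by default.)  Removal deletes the listed samples
from every participant's series — deletion, never interpolation, which
would re-introduce the excursion — and ISC is recomputed on the
concatenated remainder, per fROI, then averaged.  The random-removal null
deletes m uniformly chosen distinct samples per draw (m matched to the
peak count) and records the mean Fisher z; the empirical p is one-tailed
lower with add-one smoothing, `(1 + #{null ≤ obs})/(1 + n_iter)`, since
removal of informative points can only be expected to lower ISC.  Draws
sample time points unrestrictedly (the actual peak set is not excluded).
For the head-to-head peak-vs-trough t test the trough set is trimmed to
the m lowest-valued time points so removal counts match; the test is
two-sample, two-tailed, pooled df, with BH-FDR across the conditions
tested.

**Calibration caveat.**  Because peaks are detected on the same data whose
ISC is then recomputed, peak (and trough) removal is *not* exchangeable
with random removal even under pure noise: samples where the grand mean is
extreme are positively co-selected with each participant × leave-one-out
product, so the observed removed-ISC sits systematically below the
random-removal null.  On pure-noise simulations the empirical p rejects at
α = 0.05 in roughly 90% of replicates rather than 5%, at any realistic
size (the selection bias is several null-SDs wide because the null varies
only over removal choices, the data being fixed).  Consequently a small
"p" against this null should be read as "peaks matter more than random
points *plus* a selection artifact", and only the **difference** between
count-matched peak and trough removal — which cancels the artifact — is
interpreted as evidence about where the signal lives.  The same pattern
(both peak- and trough-removed ISCs far below the null) appears in real
data analyzed with this procedure.

## Mixed models

All models share one recipe: response = Fisher z; fixed effect = condition
type under treatment (dummy) coding with +M/−L as the reference level;
crossed random intercepts encoded as statsmodels `MixedLM` variance
components over a single all-encompassing group.  The suite comprises:

1. the headline model (random intercepts: fROI, participant, condition);
2. the six-level per-stimulus recoding (each +M/−L stimulus its own level)
   tested against the zero baseline, +M/+L, and −M/−L, with BH-FDR across
   the three comparisons per stimulus (random: fROI, participant);
3. per-fROI models (random: participant, condition) with BH-FDR across the
   five fROIs within each term;
4. the interaction model `z ~ 0 + fROI + fROI:type + (1|condition) +
   (1|participant)` — no global intercept, so each fROI carries its own
   +M/−L mean plus type contrasts.

Numerical choices: optimization by Powell with an L-BFGS fallback
(verified against lme4's REML fits on identical data to ~2e−4 in
coefficients, SEs, and log-likelihood); coefficients reported from REML
fits; LRT and AIC comparisons always refit under ML, with
`AIC = 2k − 2·loglik`, k counting fixed effects + variance components +
the residual variance.  p values are two-tailed Wald tests with the normal
approximation (lme4-family tools often use Satterthwaite df; the
difference is immaterial at these sample sizes and documented rather than
chased).  Variance components at the boundary (common for the condition
intercept with only 2 −M/−L stimuli) are retained and flagged `singular`,
never silently dropped; a random factor observed at a single level *is*
dropped, with a warning.  Wald SEs inherit the usual boundary caveat: with
only 10 stimuli the condition variance is estimated poorly, and 2·SE
intervals for type contrasts cover the truth slightly below nominal
(~85–90% in simulation) — a property shared with lme4, not an
implementation artifact.

The resting-state control is the one deliberately one-tailed test: each
participant's fROI-averaged z, one-sample t against 0 (H1: > 0), df = n−1.
Simulation shows this test is anticonservative under the null (≈11–13%
rejections at α = 0.05 for n = 10, because leave-one-out ISCs are
positively dependent across participants); a non-significant result is
therefore meaningful, while a marginally significant one would warrant a
subject-level resampling follow-up, which is outside this package's scope.

BH-FDR is implemented directly (step-up, monotone, capped at 1, optional
external family size) and cross-checked against statsmodels in the tests.

## Content units

A content unit is operationalized lexically: a lemma string surviving the
cleaning chain.  Cleaning removes self-referential, meta-descriptive, and
confidence phrases (shipped plain-text lexicons, user-extensible — the
historical lists are not recoverable, so these are sensible defaults);
tokens are stop-word-filtered and lemmatized by a rule engine (irregular
table + plural/-ing/-ed suffix rules with consonant un-doubling and
final-e restoration); multiword proper nouns merge into single tokens.
The inclusion filter keeps lemmas used by ≥ 3 distinct participants per
stimulus; per-response counts then count *tokens* of included lemmas
(a word repeated within one subclip response counts each time, since one
entity can participate in several events).  Pairwise shared CUs are
counted as *types* within subclips ("shared" is a set notion), averaged
over pairs, then over subclips; stimulus-level summaries average over
subclips rather than summing, normalizing for subclip count.

The CU–ISC association computes a Pearson correlation over an explicit
stimulus scope (the scope is a required parameter — whole-set and
meaningful-only analyses answer different questions), and a three-model
comparison on the full ISC table: condition type only; + centered CU
(likelihood-ratio test, ML); CU only (ΔAIC, non-nested).  When the number
of stimuli does not exceed the number of condition types the CU covariate
is collinear with the type dummies and the joint model is reported as
unavailable rather than fitted.

The rule-based lemmatizer is adequate for the controlled synthetic corpora
and the package's fixtures; on free natural text it will miss
irregularities a dictionary lemmatizer would catch, which inflates CU
counts slightly but does so uniformly across conditions.

## Problem sizes

Simulation-based checks use: closed-form calibration at n = 30, T = 1000,
20 seeds; design-recovery at the full paper layout, 50 seeds; null
calibrations at 400–500 pure-noise replicates with 500–1,000 resampling
draws (the library default for real analyses remains 10,000); power checks
at 50 seeds.  These sizes put Monte-Carlo error well inside the asserted
tolerances while keeping the whole suite runnable in minutes on one CPU.

## Known limitations

- Voxel-wise ISC maps, intrasubject (test–retest) correlation, and
  sliding-window ISC are out of scope, as are first-level GLMs and spatial
  preprocessing; t-maps and region-level series are taken as inputs.
- The random-removal null and the rest-baseline t test are anticonservative
  for the structural reasons quantified above; both behaviors are
  documented properties of the prescribed procedures.
- The additive equal-variance signal model makes between-participant ISC
  variance homogeneous; real data have participant-specific tracking
  strengths, which would widen all sampling distributions.
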