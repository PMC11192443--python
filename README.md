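# natisc — intersubject correlation analysis of naturalistic fMRI

`natisc` implements the analysis pipeline behind a naturalistic-cognition
fMRI study design: does a functionally localized brain network "track" a
rich, task-free stimulus (a film, a story, a piece of music)?  Tracking is
measured with the **leave-one-out intersubject correlation (ISC)**: for
participant *i*, condition *c*, and functional region of interest (fROI) *f*,

    ISC_icf = Pearson( x_icf , mean_{j != i} x_jcf ),   z = atanh(ISC)

where `x` are temporally z-scored regional BOLD time courses (first 6 s
after stimulus onset discarded).  Around this core the package provides:

- **Subject-specific fROI definition** — the top 10% of gray-matter voxels
  by localizer-contrast t value inside each group-level parcel, with the
  "fewer than 100 suprathreshold voxels" participant QC.
- **Peak/trough-removal resampling** — time points where the group-average
  series exceeds z = ±1 are deleted and ISC recomputed, benchmarked against
  a null of m randomly deleted time points (default 10,000 draws).
- **A crossed random-intercept mixed-model suite** — Fisher-z ISCs modeled
  with condition type (+M/+L verbal, +M/−L meaningful nonverbal, −M/−L
  non-meaningful) as fixed effect and fROI / participant / condition
  (stimulus) intercepts; per-stimulus, per-fROI, and fROI×type variants;
  Benjamini–Hochberg FDR; LRT and AIC model comparison.
- **Content-unit (CU) scoring** — a lemma-level semantic-richness metric for
  free-text stimulus descriptions (phrase cleaning, stop-word removal,
  rule-based lemmatization, proper-noun merging, a ≥3-participant inclusion
  filter, token counting, and pairwise shared-type counts), and its
  association with ISC.
- **A synthetic-data generator** whose additive signal model
  `x = sqrt(a)·s + sqrt(1−a)·ε` has the closed-form expectation
  `E[ISC] = a / sqrt(a + (1−a)/(n−1))`, giving every statistical routine an
  analytic oracle.  Its default tracking strengths
  (a = 0.11 / 0.047 / 0.003) place the three condition-type mean ISCs near
  0.295 / 0.164 / 0.016 at n ≈ 30.

## Worked example

The `analysis/` scripts run the full study on simulated data — the
published condition layout (10 stimuli, Ns 14–34 from a 47-participant
pool, five left-hemisphere language fROIs):

```
python analysis/01_simulate_dataset.py
python analysis/02_compute_isc.py
```

prints

```
mean ISC (r) by condition type:
condition_type
+M/+L    0.2909
+M/-L    0.1638
-M/-L   -0.0046
rest baseline: one-tailed t(9) = 1.031, p = 0.165 (no intersubject coupling at rest)
```

— verbal stimuli are tracked most, meaningful nonverbal stimuli
intermediately, music/kaleidoscope hardly at all, and resting-state scans
show no spurious coupling.  `python analysis/03_mixed_models.py` fits the
mixed models:

```
condition-type model (+M/-L reference):
     term    beta     se   p
Intercept  0.1691 0.0119 0.0
    +M/+L  0.1360 0.0138 0.0
    -M/-L -0.1736 0.0190 0.0
```

The intercept is the +M/−L mean Fisher z; the two coefficients say verbal
stimuli are tracked reliably more, and non-meaningful stimuli reliably
less, than meaningful nonverbal ones.  `04_peak_removal.py` shows that
deleting the strongest-response time points does not abolish the ISC, and
`05_content_units.py` shows CU counts separate meaningful from
non-meaningful stimuli (beta = −5.55 for −M/−L) while failing to explain
the verbal-vs-nonverbal ISC difference (LRT χ²(1) = 0.27, p = 0.60;
condition type preferred by AIC).

A single-command equivalent over a miniature design:
`natisc run --config <config.yaml>` (see `natisc --help` for the
stage-by-stage commands).

## Layout

```
src/natisc/      library: synthdata, localizer, isc, extremes, stats, cu,
                 pipeline, cli
analysis/        numbered narrative drivers over the library
tests/           unit + property + acceptance suites (pytest, hypothesis)
docs/methods.md  model assumptions, numerical choices, known limitations
```
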