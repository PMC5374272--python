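# Methods

This note documents the models, conventions and design choices behind
`phenotrace`: what each stage computes, what the synthetic-data generator does
and does not emulate, and the numerical details that matter for
reproducibility.

## Problem setting

The pipeline predicts the presence/absence of four clinician-assessed
psychiatric symptoms — depressed mood, diminished interest, fatigue, and
avoidance (social connectedness) — from passively collected phone data over
the week preceding the assessment. Three symptoms are modeled from digital
trace data (calls, SMS, GPS); depressed mood is modeled from acoustic features
of voluntary audio diaries. Participants with indeterminate or subthreshold
symptom status are assumed excluded upstream; labels are binary
(present = 1).

All timestamps are UTC epoch seconds. Every window is half-open
`[start, end)`; the analysis window is anchored to the assessment timestamp
(not to calendar weeks), `[t_assess − 7 days, t_assess)`.

## Trace features

The catalogue holds 14 descriptive statistics over social and location
events:

| feature | definition |
|---|---|
| call.out.sum / call.in.sum | total out/in call minutes |
| call.out.count / call.in.count | call counts |
| call.dur.mean / call.dur.sd | mean / sample SD of call minutes (all calls) |
| sms.out.count / sms.in.count | SMS counts |
| sms.address.count / sms.in.address.count | unique counterparties texted / texting in |
| travel.distance.sum | haversine path length over consecutive GPS fixes (km) |
| travel.distance.daily.mean / .sd | mean / SD of the seven daily path lengths |
| gps.radius.max | max distance from the median (home-proxy) location |

Conventions worth noting:

* `call.out.sum` is **minutes of outbound-call duration**, not a call count;
  `sms.address.count` counts **outgoing** counterparties only (the incoming
  analogue is a separate feature).
* Distances use the IUGG mean Earth radius 6371.0088 km. Segments shorter
  than a configurable jitter floor (default 0.03 km ≈ 2× the generator's 15 m
  jitter SD) are dropped so a stationary phone does not accumulate distance.
  The floor removes roughly two thirds of pure-jitter segments (consecutive
  two-endpoint jitter has scale σ√2 ≈ 21 m), so a small jitter-driven
  distance residue remains by design; tests bound it with a Monte-Carlo
  oracle of the jitter model rather than asserting zero.
* SD-type statistics over fewer than two observations are **masked missing**,
  never zero; mean/max-type location features are masked when no GPS fix
  exists. Counts and sums over an empty window are 0.
* Accelerometer/gyroscope and screen-interaction streams are tolerated on
  input and ignored (screen events are generated and parsed but feed no
  feature).

## Acoustic features

Recordings are PCM mono, 8 kHz, 16-bit. Frames are 200 samples (25 ms) with
80-sample hop (10 ms); the final partial frame is dropped.

* **F0**: normalized-autocorrelation peak search. With 200-sample frames the
  longest usable lag is 100 samples, so the search floor is 80 Hz (a 60 Hz
  floor would need 2×133 lag samples); the ceiling is 400 Hz. A frame is
  voiced iff the peak value reaches 0.45 (configurable). Among local maxima
  within 10% of the best, the shortest lag wins — this suppresses
  octave-down errors on strongly periodic frames. The winning lag is refined
  by parabolic interpolation.
* **PitchVar** is the within-recording SD of voiced-frame F0 in Hz (not
  semitones); `MeanPitchVar` is its across-recording mean. The feature names
  follow the field's convention; the definitions here are the simplest
  consistent readings and are isolated in the feature registry so
  alternatives can be swapped.
* **Vocal effort** is the spectral balance 10·log₁₀(E[1–4 kHz)/E[0–1 kHz))
  of the Hann-windowed frame — a standard tilt-based effort correlate that is
  computable at 8 kHz bandwidth. A flat spectrum gives 10·log₁₀(3) ≈ 4.77 dB.
* **HNR** = 10·log₁₀(r/(1−r)) at the pitch lag, clamped to [−20, 40] dB.
* **Speaking rate** counts peaks of the 50 ms RMS envelope above
  median + 2·MAD with ≥100 ms separation and a prominence of 20% of the
  envelope maximum (a steady tone has ripple above the MAD threshold but no
  prominent bursts), divided by duration.

Per-recording aggregates are means over voiced (F0, HNR) or non-silent
(effort) frames; pitch fields are missing when no frame is voiced.
Per-participant features are means across the recordings inside the
assessment window. Transcoding from compressed capture formats is out of
scope; the package consumes WAV directly. Lexical content is never analyzed.

## Reduction

* **Correlation clustering** (trace catalogue): agglomerative, average
  linkage, distance 1 − |Pearson r| on pairwise-complete observations, cut at
  a fixed `n_clusters` (default 3; there is deliberately no automatic
  cut-height selection). Representative per cluster = member with maximal
  mean |r| to its co-members, ties lexicographic. The procedure is invariant
  to feature scaling and sign flips.
* **LASSO logistic screening** (acoustic registry): coordinate descent
  (IRLS-outer, coordinate-soft-threshold inner) minimizing
  −(1/n)·loglik + λ‖β‖₁ on internally standardized predictors, coefficients
  reported on the original scale. Grid: 50 geometric points from the
  analytic λ_max = max|Xᵀ(y−ȳ)|/n down three decades. Convergence at
  max|Δβ| < 1e-8; coefficients below 1e-12 are snapped to exact zero so the
  λ_max KKT condition holds exactly in floating point. λ is chosen to
  minimize 10-fold cross-validated binomial deviance (no 1-SE rule — the
  selection criterion is the plain minimum; ties go to the largest λ, i.e.
  the sparsest fit). Folds are stratified by class and seeded. Deviance is
  smooth and conventional for LASSO cross-validation, which is why it is
  preferred over AUC here.

Participants with any missing modeling feature are dropped from that model's
fit (complete-case analysis).

## Candidate models and selection

Over exactly three representative features the candidate space is the unique
natural 10-model scheme: 3 single-feature models, 3 two-feature main-effect
models, the same 3 pairs with their interaction, and the full three-feature
main-effects model. When LASSO screening leaves k ≠ 3 acoustic features the
scheme generalizes to all 1- and 2-feature main-effect models, all 2-feature
models with interaction, and the full main-effects model (k = 5 gives 26
candidates).

Fitting is IRLS maximum likelihood: convergence when the log-likelihood
change is below 1e-10 or after 100 iterations; a rank-deficient design raises
an error naming an aliased term. Quasi-perfect separation is flagged (any
standardized coefficient magnitude > 15) as `converged=False`, but the fitted
scores remain usable for ranking. Interaction terms are products of raw
(unstandardized) features.

Cross-validation uses seeded, stratified folds (default 10), re-drawn if any
training fold lacks a class. All out-of-fold scores are pooled into a
**single ROC** (tie-grouped descending-score sweep; trapezoidal AUC, which
equals the Mann-Whitney pair statistic with ties counted ½). Pooled rather
than fold-averaged AUC is the primary criterion because it is stabler at
cohort sizes near 10² (fold-mean AUCs are also recorded). The best candidate
is the AUC argmax; ties prefer fewer coefficients, then enumeration order.
Threshold metrics predict positive iff score ≥ threshold; PPV/NPV are
reported missing when their denominator is zero.

## Synthetic cohort generator

The generator defines the study conditions under which the pipeline is
validated. Defaults: 73 participants, 12 weeks, symptom prevalence 0.4 per
symptom with mutually independent labels (the assessment sits at the end of
the simulated period).

**Trace streams.** Conditional on per-person traits, events are homogeneous
Poisson processes: outbound calls 2/day with lognormal durations (median
2 min, log-SD 0.9), inbound calls 2/day, SMS 6/day out and 5/day in against
a 30-contact pool with 8 unique counterparties texted per week, GPS fixes
every 300 s following a home-anchored out-and-back walk (2 excursions/day,
Gamma-distributed radii with mean 3 km, walking speed 1.4 m/s, 15 m Gaussian
positioning jitter), and screen toggles (unused downstream). Counterpart
descriptors are salted hashes of synthetic integers — no real numbers appear
in any stream.

Each data source is scaled by a stable per-person lognormal **trait**
(mean 1, log-SD 0.4): phone sociability (calls), texting habit (SMS), and
mobility (excursion radius). The traits are what make features of the same
source correlate across participants, so the correlation-cluster stage
recovers the three conceptual sources (calls / texts / location) the way it
does on real cohorts.

**Planted effects.** `effect_sizes[(symptom, feature)] = d` shifts the named
weekly feature by `d` nominal SDs for symptom-positive participants, where
the nominal moments are computed analytically from the compound-Poisson
model *including* the between-person trait variance
(`v = exp(0.4²) − 1`), and are exposed via `nominal_feature_moments` so
tests can verify recovery against the generator's own parameters. The shift
is applied as a multiplicative factor on the whole data source (calibrated
on the named feature): behavioral withdrawal suppresses outgoing and
incoming calling alike, and texting breadth and volume together. Effect
directions are assumptions — the defaults reduce call minutes, texting
counterparties and travel by d = 0.8 SD for the relevant symptoms — and are
fully configurable, including sign.

**Audio.** Each diary is a glottal-style impulse train whose F0 follows a
slowly varying contour (Gaussian noise smoothed to ~0.3 s, standardized to
the configured mean/SD), shaped by an exact dB/octave spectral-tilt filter
(reference 1 kHz), gated into Hann-shaped syllable bursts (4/s, 45% duty),
and mixed with white noise at the configured SNR (measured over
speech-active samples). Depressed mood switches the F0-SD and tilt
parameters (defaults: 15 vs 30 Hz, −14 vs −9 dB/oct — flattened prosody and
reduced effort when present); stable per-person offsets (F0 mean SD 10 Hz,
F0-SD SD 8 Hz, tilt SD 3.5 dB/oct) create realistic between-speaker overlap
so the groups are not trivially separable. The sidecar ground truth records
the statistics of the *realized* contour over the voiced region, the exact
tilt, burst rate and SNR.

**Reproducibility.** All randomness derives from one master seed with one
RNG stream per (participant, modality, recording), spawned via
`SeedSequence([seed, participant_index, modality, …])` — enlarging a cohort
never perturbs earlier participants, and a fixed (config, seed) yields
byte-identical fixture directories and pipeline summaries.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: phone-OS probe scheduling and battery effects,
sensor dropout beyond an optional uniform event-drop rate, non-stationary or
circadian behavior, correlated symptom labels (an option left off by
default), real glottal source/vocal-tract acoustics, room reverberation, or
lexical content. Results on synthetic cohorts validate the *machinery*
(feature definitions, reduction, selection, calibration), not clinical
effect sizes.

## Problem sizes used in validation

The simulation studies use cohorts and replicate counts chosen to keep the
whole validation suite at desk scale while leaving Monte-Carlo noise well
inside the asserted tolerances: end-to-end runs at n = 120 participants over
2 simulated weeks (only the final week is analyzed either way); support- and
structure-recovery studies at n = 300–500 with 100 seeded replicates;
calibration studies at n = 400 with 20–50 seeds; logistic parameter recovery
at n = 5000. The acceptance script reports each quantity together with the n
it used.

## Known limitations

* The acoustic feature definitions stand in for a proprietary feature
  library referenced by field studies; names match, algorithms are this
  package's own (documented above).
* The F0 tracker's 80 Hz floor excludes very low-pitched voices; use longer
  frames if that matters.
* The 10-candidate scheme is a reconstruction of the "combinations of three
  features" described in the field; it is the unique 3+3+3+1 scheme whose
  members include every published model form.
* No regularization of the final per-candidate fits, no calibration curves,
  and no nested cross-validation to correct selection optimism — the
  selected model's pooled CV AUC is itself mildly optimistic, as in the
  original analysis design.
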