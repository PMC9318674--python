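# Methods

## Overview

moodsense implements a smartphone-only depressed-mood prediction pipeline:
per-participant sensor tables are validated and bundled, 33 behavioral
features are extracted, and a random forest classifies each held-out
participant as depressed or not, with questionnaire cut-points or clinician
diagnosis as truth. This note records the model assumptions, the defaults
and why they were chosen, what the synthetic cohort does and does not
emulate, and the numerical conventions.

## Sensor model and feature extraction

### Sleep from screen events

The sleep proxy assumes one dominant nocturnal phone-untouched period per
day: nightly sleep is the longest screen-off interval of a noon-to-noon day.
Conventions, chosen where the underlying rule is silent:

* **Day attribution.** Off-intervals are grouped into noon-to-noon windows by
  their midpoint, and the estimate is attributed to the calendar date of the
  window's end. This keeps an overnight interval intact instead of splitting
  it at midnight.
* **Afternoon exclusion.** Candidates lying *entirely* inside local
  12:00–18:00 are discarded (a span that cannot be night sleep); intervals
  merely overlapping the afternoon survive. Candidates over 24 h are
  discarded.
* **Boundary truncation.** Noon-to-noon windows cut by the collection-window
  boundary are dropped. A truncated window cannot contain a full night, and
  without this rule the first morning and last evening of a recording
  contribute short daytime gaps as bogus "sleep" days, biasing every sleep
  statistic low.
* Duplicate same-state screen events are collapsed to the first occurrence
  so ON/OFF strictly alternate; a trailing OFF is closed at the window end
  and flagged.

Usage (screen-on hours) is summed per local calendar day, splitting spans at
midnight; with a known collection window, uncovered days count as 0 h.
Each daily series is summarized by max, min, mean, SD (n−1 denominator, 0
for a single day), and quartiles by linear interpolation — 14 features.

Timestamps are stored timezone-aware with their original offset: the instant
is unambiguous (UTC-comparable) while `date()`/`time()` give the local clock
the sleep and afternoon rules operate on.

### Mobility from GPS

Significant places are DBSCAN clusters under the haversine metric
(scikit-learn implementation). Defaults `eps = 300 m`, `min_samples = 5` —
values in the common range for separating home/work/errand-scale places from
transit fixes; both configurable, as is everything below, through
`FeatureConfig`. Cluster ids are renumbered by first appearance in timestamp
order so labels are deterministic for a given input.

* **Location variance** `log(σ²_lat + σ²_lon)` uses population variances in
  degrees², floored at `1e−12 deg²` before the log so a single-place
  participant stays finite rather than −∞.
* **Entropy** `−Σ pᵢ ln pᵢ` (nats) over the fraction of *non-noise* fixes per
  cluster, assuming fixes sample time uniformly; 0 or 1 cluster gives 0.0,
  all-noise marks the feature missing.

### Physical activity

ENTER/EXIT transition events are paired per motion class; an unmatched
trailing ENTER is closed at the window end. The feature is the mean over
observed days (days touched by any episode) of hours in the included
classes. The default included set is {stationary, running, walking} exactly
as the source protocol states it, with a locomotion-only alternative
{walking, running, walking-or-running} available in config — the inclusion
of "stationary" under *physical* activity is surprising but is implemented
as stated rather than second-guessed. Cycling is always excluded
(confusable with vehicle). Days observed only in excluded classes contribute
0 h rather than being dropped.

### Expression

Weekly 16-d facial-expression embeddings are aggregated by element-wise
mean — the simplest participant-level summary; no aggregation rule is
prescribed by the protocol. The embedding network itself is out of scope:
the pipeline consumes numeric vectors, and a deterministic stub embedder
(string → unit-norm 16-vector) stands in for tests and simulations behind
the same record type.

### Assembly and missing data

The fixed feature order is 14 sleep/usage, 2 mobility, 1 activity, 16
expression. Each block carries a provenance flag (observed/missing/imputed).
The default policy drops participants with any missing block (the study
default); the alternative keeps NaNs and imputes *training-set* column means
at split time in `model_eval.impute_train_means` — imputation is deferred to
after the split so test participants never inform the fill values.

## Labels and protocol

PHQ-9 (9 items, 0–3 each, total 0–27) is depressed at ≥ 10; CESD-R
(20 items, scored 0–3 here, total 0–60) at ≥ 13, the Korean-calibrated
cut-point. The CESD-R range is deliberately enforced as 0–60 rather than the
instrument's usual 0–80. Severity bands default to the five-band scheme
(normal 0–4, minimum 5–9, mild 10–14, moderate 15–19, severe 20–27); a
six-band variant with a configurable minimal/minor split (default edge 7) is
available. The labeling wave defaults to baseline (M1) and is configurable;
no wave is singled out by the protocol.

The classifier is scikit-learn's random forest with 1000 trees, max depth
100, majority (0.5) voting, and an explicit seed. The cohort is split 3:1
with the test size rounded up (106 → 79/27). Aggregate report rows are
computed both macro- and support-weighted and labeled as such — no single
aggregation convention reproduces all published totals, so both are shown.
Undefined precision (no predicted positives) is reported as missing, not 0.
The ablation re-trains one forest per feature block — sleep (14 columns),
activity (mobility + daily activity, 3), expression (16) — plus all 33.

## Synthetic cohort

The generator emulates the study's *shape*: 106 participants, 28 days,
with an 84:22 (CESD-R-like) default imbalance and a 55:51 (PHQ-9-like)
scenario helper. A latent group per participant sets:

| parameter | depressed | control | units |
|---|---|---|---|
| sleep mean / sd | 9.5 / 1.0 | 7.0 / 0.8 | h/night |
| usage mean / sd | 6.0 / 1.2 | 3.5 / 1.0 | h/day |
| visit probabilities | (.85,.09,.03,.03) | (.40,.25,.20,.15) | — |
| activity mean / sd | 0.8 / 0.3 | 2.5 / 0.6 | h/day |
| expression centroid gap | 1.0 (2 within-group SD) | — | — |
| PHQ-9 mean / sd | 16 / 4 | 5 / 2.5 | points |
| CESD-R mean / sd | 30 / 9 | 7 / 3.5 | points |

The depressed profile (hypersomnia, heavy screen use, homebound low-entropy
mobility, little activity, elevated scores) follows the direction of effects
reported across the passive-sensing literature; magnitudes are chosen to
give clear group separation so end-to-end discrimination is testable at desk
scale. Clinician diagnosis agrees with the latent group with probability
0.9.

Construction is deliberately exact-by-design: nightly off-intervals realize
the drawn sleep duration exactly (daytime gaps are bounded below the minimum
sleep length); daily usage budgets are realized exactly by eight evenly
spaced sessions; activity budgets by walking/running episodes (plus
vehicle/cycling distractors the extractor must reject — stationary episodes
are not emitted, so the extracted value matches the target under either
included-class config); GPS fixes are hourly draws from the visit vector
with 10 m jitter around places 5 km apart. Noiseless specs
(`CohortSpec.noiseless()`) therefore round-trip generative parameters
exactly, and noisy defaults recover per-participant realized values with
correlation ≈ 1.

All randomness derives from one root seed via named (participant, stream)
sub-streams, so adding a stream type never perturbs existing draws and any
single participant is reproducible in isolation.

**What the generator does not emulate:** real circadian variability (naps,
shift work, insomnia fragmentation), GPS dropout and urban-canyon noise,
correlated missingness, device heterogeneity, or any causal pathway from
mood to behavior beyond mean shifts. Passing tests demonstrate that the
*pipeline* is correct and that the protocol discriminates separable groups —
not that real depressed and non-depressed users are this separable; the
published accuracies on the private clinical cohort are not reproducible
from synthetic data and are not targeted.

## Validation and exclusion

Participants are excluded when (a) any required questionnaire wave
(PHQ-9 and CESD-R at M1, M2, M3 by default) is missing, or (b) sensor
coverage is insufficient — defaults: ≥ 50% of window days with at least one
screen event, ≥ 1 expression record. The policy is fully parameterized; the
source protocol's own exclusion counts do not reconcile arithmetically, so
no fixed constant is hard-coded. Collected-but-unused tables (calls, SMS,
WiFi, Bluetooth, battery, cell, raw IMU) are parsed and validated but
generate no features. Tables with > 50% malformed rows are rejected;
individual bad rows are skipped and counted.

## Numerical conventions and edge cases

* Entropy and variance logs are natural; location variance is population
  (n), summary-statistic SD is sample (n−1).
* Quartiles: linear interpolation (numpy default).
* A single observed day gives SD 0 and degenerate quartiles.
* Empty feature inputs signal "group missing" (None/NaN), never exceptions.
* Great-circle distance uses the haversine formula with R = 6371 km.
* Test-size rounding is ceil; forest voting threshold 0.5.

## Known limitations

* The screen-off sleep proxy conflates "phone untouched" with sleep; heavy
  nighttime phone abstinence or daytime sleep outside the modeled windows
  misestimates sleep. The boundary-truncation rule discards the first and
  last partial day of every recording.
* Entropy depends on fix-count proportions, assuming uniform temporal
  sampling of GPS; duty-cycled sampling would bias pᵢ.
* One feature vector is computed per collection window (per-window variants
  are a config away but untested against any reference).
* The CLI persists models with joblib/pickle; artifacts are only loadable
  in a compatible scikit-learn environment.
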