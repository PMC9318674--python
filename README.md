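# moodsense

Smartphone-only digital phenotyping for depressed mood: turn passively
collected phone streams and self-report questionnaires into behavioral
features and a binary depressed-mood prediction, evaluated against both
questionnaire cut-points and clinician diagnosis.

The package is aimed at mental-health sensing researchers who have (or want
to simulate) per-participant smartphone logs — screen on/off events, GPS
fixes, activity-recognition transitions and precomputed facial-expression
embeddings — and need a tested, reproducible path from raw CSV tables to a
classifier with interpretable feature groups.

## The method

Each participant contributes a 33-dimensional feature vector over a 4-week
collection window:

* **Sleep (14)** — nightly sleep is estimated as the longest screen-off
  interval of each noon-to-noon day, discarding candidates longer than 24 h
  or lying entirely in the 12:00–18:00 afternoon span; daily screen-on time
  ("usage") proxies sleep quality. Each daily series is summarized by seven
  statistics: max, min, mean, SD, Q1, Q2, Q3.
* **Mobility (2)** — significant places are found with DBSCAN under the
  haversine metric; the features are the log location variance
  `log(σ²_lat + σ²_lon)` and the place entropy `−Σᵢ pᵢ ln pᵢ` of the fix
  distribution over clusters (noise excluded). Low entropy means homebound
  behavior.
* **Physical activity (1)** — mean daily hours in the stationary, running
  and walking motion classes (cycling excluded as confusable with vehicle),
  from paired ENTER/EXIT activity-transition events.
* **Expression (16)** — the element-wise mean of weekly 16-d facial-expression
  embeddings (metric-learning vectors computed on-device; consumed here as
  numbers, never images).

Depressed mood is labeled from questionnaire totals — PHQ-9 ≥ 10 or
CESD-R ≥ 13 (Korean calibration) — and predicted with a random forest
(1000 trees, max depth 100) trained on a random 3:1 participant split
(106 → 79 train / 27 test). Reports give per-class precision/recall/F1 and
accuracy, a per-feature-group ablation, and a comparison of predictions with
the clinician diagnosis.

Because real cohorts of this kind are private, the package ships a
first-class synthetic-cohort generator with a latent depressed/control state
driving every stream, plus per-participant ground truth for round-trip
testing.

## Worked example

```bash
python examples/train_and_evaluate.py
```

simulates the study-shaped cohort (106 participants, 28 days, 84:22
depressed/non-depressed), extracts features, trains the forest and prints:

```
Accuracy by derived feature group (%)
  sleep           92.59
  activity        92.59
  expression      85.19
  all features    92.59

Classification vs questionnaire truth (n=27)
  class            precision  recall      f1
  depressed            91.30  100.00   95.45
  non_depressed       100.00   66.67   80.00
  total (macro)        95.65   83.33   87.73
  total (weighted)     93.24   92.59   92.02
  accuracy 92.59%
...
split: {'train': 79, 'test': 27}
```

Accuracy is high because the synthetic groups are well separated by design;
the interesting structure is the ablation (each feature group alone carries
signal, expression slightly less under these defaults) and the 79/27 split
reproducing the 3:1 protocol. `examples/` holds one short script per
capability (questionnaire scoring, feature extraction, mobility clustering,
full pipeline).

A thin CLI mirrors the library:

```bash
moodsense simulate --out cohort/ --seed 1
moodsense extract --input cohort/ --out features.csv --labels-out labels.csv
moodsense train --features features.csv --labels-file labels.csv --labels cesdr --seed 1 --out model.joblib
moodsense evaluate --model model.joblib --features features.csv --labels-file labels.csv --truth diagnosis
moodsense run-all --config run.yaml
```

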