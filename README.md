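# gaitrisk

Fall-risk screening for lower-limb amputees from a single pelvis-worn
smartphone during a six-minute walk test (6MWT).

People with lower-limb amputations fall more often than age-matched
able-bodied adults, yet the 6MWT — a routine functional-capacity
assessment — normally yields only a walking distance. `gaitrisk` turns the
smartphone IMU signals recorded during that same walk into a fall-risk
classification: it detects every foot strike, derives a step-based gait
profile, and classifies the participant as fall risk / no fall risk, so a
clinician gets screening information from an assessment the patient already
performs.

## Pipeline

1. **Preprocess** (`signal_io`) — linear re-interpolation of all channels to
   a uniform 50 Hz grid, then a fourth-order zero-lag Butterworth low-pass
   at 4 Hz (forward–backward, so the net response is |H(f)|² with zero
   phase shift).
2. **Foot-strike detection** (`footstrike`) — a foot strike appears as an
   anterior-posterior (AP) acceleration peak followed within ~0.1 s by a
   vertical peak. Two detectors are provided: a rule-based labeller built
   directly on that peak ordering, and a trainable windowed MLP sequence
   labeller that predicts a per-frame strike probability. Raw predictions
   are post-processed: runs of consecutive positives collapse to the frame
   of peak AP acceleration; inter-strike gaps longer than 1.5× the previous
   step are searched for missed strikes inside a window shrunk by half the
   adaptive *locking period* (a per-trial refractory interval derived from
   the dominant step period of the first 5 s of vertical acceleration);
   sides are assigned by alternation anchored on medio-lateral sway.
3. **Features** (`features`) — 62 features per step (5 temporal including
   the symmetry index SI = |t_R − t_L| / (½(t_R + t_L)) × 100, 27
   descriptive statistics, 30 spectral including the even/odd harmonic
   power ratio REOH), aggregated as min/max/mean/SD over all included
   steps into a 248-value participant vector. Turning steps are excluded.
4. **Classification** (`classify`) — correlation-based feature selection
   (CFS), scoring a subset S of size k by
   merit(S) = k·r̄_cf / √(k + k(k−1)·r̄_ff),
   searched best-first; then a 100-tree random forest evaluated by
   leave-one-out cross-validation (LOOCV), with CFS re-run inside every
   fold so the held-out participant never leaks into selection.

Because clinical 6MWT recordings of this population are not publicly
available, the package ships a synthetic gait simulator
(`synthetic_gait`) that generates 6MWT-like walks — 20 m hallway, periodic
180° turns, left/right step-time asymmetry, sensor noise — with exact
ground-truth strike schedules, so every stage is testable end to end.

## Worked example

Simulate a cohort of 25 walkers (9 fall risk, 16 not) and run the full
pipeline with rule-based detection:

```
$ gaitrisk simulate --cohort-dir cohort --n-fall-risk 9 --n-no-fall-risk 16 \
      --duration 120 --seed 42
cohort manifest: cohort/manifest.json
$ gaitrisk run --manifest cohort/manifest.json --out-dir results
accuracy 76.0% | sensitivity 55.6% | specificity 87.5%
```

`results/report.json` holds the LOOCV confusion matrix
`{"tn": 14, "fp": 2, "fn": 4, "tp": 5}` (rows: actual no-fall-risk /
fall-risk): 19 of 25 participants classified correctly, 5 of the 9
fall-risk walkers recognised (sensitivity 55.6%), 14 of 16 non-fall-risk
walkers correctly cleared (specificity 87.5%). The report also lists the
features CFS picked in each fold — on this cohort predominantly cadence,
symmetry-index and spectral-magnitude aggregates, the features the
simulator ties to the fall-risk label.

Single-walk stages work the same way:

```
$ gaitrisk simulate --duration 120 --cadence 96 --asymmetry 1.15 --seed 7 \
      --out walk.csv --events truth.csv
simulated 192 strikes over 120 s
$ gaitrisk detect --input walk.csv --out events.csv
detected 198 foot strikes
$ gaitrisk features --recording walk.csv --events events.csv \
      --out steps.csv --aggregate participant.csv --label 1 --participant-id demo
176 steps x 62 features
```

A trainable detector is fitted with `gaitrisk train-detector --manifest
cohort/manifest.json --out model.joblib` and used via
`gaitrisk detect --model model.joblib`; `gaitrisk run` accepts the same
`--model`. See `docs/methods.md` for the model and every tunable constant.

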