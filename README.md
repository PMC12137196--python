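# bearacc

Accelerometry-to-behaviour analysis for collar-tagged brown bears
(*Ursus arctos*), built for movement ecologists studying how hunting risk
reshapes activity budgets.

Tri-axial collar accelerometers sample sway/surge/heave at 8 Hz around the
clock. `bearacc` converts that stream into behaviour: it windows the signal
into 3 s sequences, computes 36 summary-statistic features per window
(moments, axis correlations, dynamic body acceleration, ODBA, dominant power
spectra), classifies each window into resting / feeding / walking / running
with a 1000-tree random forest tuned by out-of-bag error, and aggregates the
labels into the quantities a hunting-risk analysis needs: running bouts,
daily bout counts, the proportion of bouts inside legal hunting hours
(1 h before local sunrise to 2 h before local sunset, via a built-in NOAA
solar routine), diel activity profiles and daily GPS distances, stratified
by pre-hunting vs. hunting period and demographic group.

The core quantities, in the field's usual notation:

* static acceleration = 3 s running mean per axis; DBA = raw − static;
  ODBA = |DBAx| + |DBAy| + |DBAz|; magnitude = √(x² + y² + z²);
* per class (one-vs-rest): precision = TP/(TP+FP), recall = TP/(TP+FN),
  MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN)) — MCC is the
  headline metric because running is orders of magnitude rarer than resting.

A synthetic-data module simulates collar-like accelerometry with known
behavioural ground truth (semi-Markov schedules with a crepuscular diel
profile, per-behaviour gait sinusoids, annotation clock lag, hourly GPS), so
the full pipeline is testable without field data. See `docs/methods.md` for
models, conventions and limitations.

## Worked example

Train on simulated labelled windows, evaluate held-out recovery, and measure
the legal-hour shift of running bouts in a simulated hunted population:

```python
from bearacc import synthetic as syn, classifier as clf, activity as act

train = syn.simulate_labeled_windows(300, seed=42)
test  = syn.simulate_labeled_windows(100, seed=43)

mtry, log = clf.tune_mtry(train, n_trees=300, seed=0)
model = clf.train_forest(train, clf.ForestConfig(n_trees=1000, mtry=mtry, seed=0))
print(model.oob_error)                      # 0.0

pred = clf.predict_behaviors(model, test)
m = clf.metrics(clf.confusion(pred, test["label"]))
print(m.per_class[["precision", "recall", "mcc"]])
#          precision  recall  mcc
# feeding        1.0     1.0  1.0
# resting        1.0     1.0  1.0
# running        1.0     1.0  1.0
# walking        1.0     1.0  1.0

labels, demo = syn.simulate_hunting_response_population(n_bears=3, days_per_period=4, seed=11)
bouts = act.detect_bouts(labels, "running")
rec = act.daily_metrics(bouts, labels, demographics=demo)
print(rec.groupby("period")["prop_legal"].mean())
# hunting        0.998574
# pre_hunting    0.769725
```

The forest separates the four synthetic behaviours perfectly (OOB error 0.0;
real collar data are harder — see `docs/methods.md`), and the simulated
population, whose running is pushed into daylight hours after the hunting
season opens, shows the expected rise in the daily proportion of running
bouts inside legal hunting hours (0.77 → 1.00; the pre-hunting baseline is
the daylight fraction of the day).

The same pipeline is scriptable from the shell:

```
bearacc simulate --days 1 --seed 4 --outdir demo/
bearacc features --in demo/accel.csv --out demo/features.csv
bearacc prepare-training --accel demo/accel.csv --events demo/events.csv --lag-s auto --out demo/train.csv
bearacc train --in demo/train.csv --tune-mtry --seed 0 --out demo/model.joblib
bearacc predict --model demo/model.joblib --features demo/features.csv --out demo/labels.csv
bearacc bouts --labels demo/labels.csv --behavior running --out demo/bouts.csv
```

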