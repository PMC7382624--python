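# clinicrec

Anticipating clinical orders and order-set usage from EHR event streams.

Hospitals already ship decision support for order entry: committee-authored
**order sets** — templates bundling the orders for a scenario (admission for
pneumonia, post-surgical care, ...).  They are static, maintained by hand,
and often overlooked.  `clinicrec` implements the alternative: treat every
clinical item entry in the EHR as a recommendation opportunity, summarize
the patient's history up to that instant, and train multi-label models to
rank (a) which individual orders and (b) which existing order-set templates
a clinician will use in the next 24 hours.  The package is aimed at clinical
informatics researchers who want a tested, leakage-safe reference
implementation of this problem structure — including the standard-of-care
baselines it must beat and a synthetic EHR generator to exercise it, since
real order-entry data is access-restricted.

## What it computes

For every clinical item entry at time *t* of a patient:

* **features** — counts of each vocabulary item in the lookback windows
  (*t*−1d, *t*), (*t*−7d, *t*), (*t*−30d, *t*), (−∞, *t*) (the current
  entry is never part of its own features), plus sin/cos month and hour
  encodings and demographic one-hots; counts are log2(1+x)-transformed and
  z-scored with training-set statistics, low-variance columns dropped;
* **labels** — for each target order (or order-set template), whether it
  occurs in [*t*, *t*+24h); the triggering order counts toward its own
  label.

Scorers: multi-label **logistic regression** (BCE, vanilla SGD, lr 0.01,
1 epoch) and a **feed-forward network** (ReLU layers, optional batch norm /
dropout, Nesterov Adam) trained on a positive-weighted cross-entropy

    −(1/m) Σᵢ [ w·yᵢ log ŷᵢ + (1−yᵢ) log(1−ŷᵢ) ] + (λ/2) Σₗ ‖Wₗ‖²

against two standard-of-care heuristics: the **institutional order-set
contents** baseline (predict exactly the member items of the template the
clinician opened) and an **admissions-frequency** baseline (rank order sets
by historical usage within 2 days of admissions sharing the patient's
3-digit admission diagnosis, with a global "bestseller" fallback).
Metrics — AUROC, average precision, and recall-matched precision/F1 — carry
95% confidence intervals from a bootstrap randomized by *patient*, so
prolific patients do not dominate the evaluation.  See `docs/methods.md`
for conventions and design rationale.

## Worked example

One patient: acetaminophen at 08:00, again an hour later, a third dose ten
days later, aspirin three minutes after that, and a second aspirin five
minutes later.

```python
import pandas as pd
from clinicrec import build_feature_rows, build_response_rows

t0 = pd.Timestamp("2010-03-01 08:00:00")
t3 = t0 + pd.Timedelta(days=10, hours=1)
events = pd.DataFrame({
    "patient_id": "P1",
    "item_id": ["acetaminophen"] * 3 + ["aspirin"] * 2,
    "category": "medication_order",
    "timestamp": [t0, t0 + pd.Timedelta(hours=1), t3,
                  t3 + pd.Timedelta(minutes=3), t3 + pd.Timedelta(minutes=8)],
    "source_order_set_id": None,
})
fm = build_feature_rows(events, ["acetaminophen", "aspirin"])
rm = build_response_rows(events, ["acetaminophen", "aspirin"])
```

The windowed count features (one row per entry) come out as:

```
       acetaminophen            aspirin
       pre-1 pre-7 pre-30 pre-any  pre-1 pre-7 pre-30 pre-any
row 1      0     0      0       0      0     0      0       0
row 2      1     1      1       1      0     0      0       0
row 3      0     0      2       2      0     0      0       0
row 4      1     1      3       3      0     0      0       0
row 5      1     1      3       3      1     1      1       1
```

Row 1 is all zero (no history yet).  Row 2 sees the first acetaminophen in
all four windows.  By row 3, ten days on, the two prior doses have aged out
of the 1- and 7-day windows but remain in pre-30/pre-any.  Row 5 sees the
first aspirin (three minutes earlier) in every window.  The next-24-hour
labels:

```
       acetaminophen|post-1  aspirin|post-1
row 1                     1               0
row 2                     1               0
row 3                     1               1
row 4                     0               1
row 5                     0               1
```

Row 3 is positive for acetaminophen — the triggering order itself counts —
and for aspirin, which follows within minutes.

## Running an experiment

```bash
clinicrec run-all --out runs/demo --seed 5
```

simulates a multi-year synthetic cohort (power-law item usage,
order-set-driven co-ordering, admission-diagnosis context with a tunable
planted signal), builds both tasks' matrices, makes a patient-disjoint
70/15/15 split with calendar cuts, trains both learners, fits both
baselines, and writes `metric_reports.json` with bootstrap CIs plus a run
manifest (seeds, input hashes).  `clinicrec simulate|featurize|split|train|
baseline|evaluate` run individual stages on the same run directory; all
accept `--config` (YAML), `--seed`, `--out`, `--log-level`.  Reruns with the
same seed are bit-identical.

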