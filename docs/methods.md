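# Methods

`clinicrec` implements a recommender pipeline for inpatient clinical orders:
from a timestamped clinical event stream it derives, for every clinical item
entry, a snapshot of the patient's history (the features) and the set of
orders and order-set templates placed in the following 24 hours (the
labels), and trains multi-label scorers to rank what a clinician will order
next.  This note records the model, the conventions, the synthetic data
design, and the judgment calls.

## The prediction problem

Every clinical item entry (a medication order, a resulted lab, a diagnosis
code, ...) generates one row.  Row *t* for a patient contains:

* **Windowed counts.** For each vocabulary item *i* and lookback window
  *w* ∈ {1 day, 7 days, 30 days, unbounded}: the number of entries of *i*
  for that patient with timestamp in the open interval (*t* − *w*, *t*).
  The current entry is never part of its own features; neither is any other
  entry at exactly *t*, nor an entry at exactly *t* − *w*.  Strict
  inequalities at both edges are a deliberate tie-break: they are
  deterministic, and they make a row generated at an instant with no new
  prior history exactly equal to its predecessor.
* **Time features.** sin/cos of 2π(month−1)/12 and 2π·hour/24 — cyclical
  encodings so December neighbors January and 23:00 neighbors 00:00.
  Minutes are deliberately ignored; hour-of-day is the clinically meaningful
  resolution.
* **Demographics.** Timestamp-free one-hot attributes of the patient,
  replicated into every row.

The response row marks target *j* positive iff an entry of *j* (or, for the
order-set task, a usage of template *j*) occurs in [*t*, *t* + 24 h) — a
horizon that *includes* the triggering instant, so an order's own row is
labeled positive for that order.  The asymmetry (open past, closed-at-*t*
future) is what makes the five-order worked example in the README come out
exactly: prior-only features, self-inclusive labels.

One consequence worth stating: if an order is co-signed at the same instant
as another order, the two rows are identical in their count features (same
history), while an order placed even a minute later legitimately sees its
predecessor in every window.

## Vocabulary and transforms

* **Order vocabulary.** Orderable items (medication and other physician
  orders; never nursing orders, labs, diagnoses, teams, or demographics)
  with at least `min_count` entries — default 256.  Clinical order volume is
  heavily concentrated (an 80/20-style power law), so the cutoff removes the
  long sparse tail while keeping most of the order volume.
* **ICD hierarchy.** A diagnosis code contributes itself plus every
  truncation to its stem (786.05 → 786.0 → 786), one decimal digit at a
  time.  Stems follow the ICD-9 convention: three digits, V + two digits, or
  E + three digits.  (How V/E codes were handled upstream of this package's
  inputs is not standardized; this is our documented choice.)
* **Medication normalization.** Table-driven collapse of brand/generic names
  to "Ingredient(s) (Route)".  A user-supplied two-column table is the
  interface; unmapped names pass through verbatim and are tallied so
  coverage can be audited.  No live terminology service is consulted.
* **Count transform.** Counts are mapped through log2(1 + x) — the +1 shift
  resolves log2 of zero counts and leaves zeros at zero, preserving
  sparsity.  All columns (including one-hots and time features) are then
  z-scored with *training-partition* statistics; columns with training SD
  below 0.01 are dropped; columns whose SD is numerically zero (< 1e−12)
  are centered but not scaled.

## Partitioning

Rows of one patient are correlated, so the 70/15/15 split is by patient
(seeded shuffle, contiguous slices), and calendar cuts then drop rows that
could straddle partitions in time: training keeps rows before the training
cutoff, validation rows inside the validation year, test rows from the test
start on (defaults 2011-01-01 / 2011 / 2012-01-01; configurable, because
synthetic date ranges need not match any particular hospital's years).  For
the order-set task, rows with no order-set usage in the next 24 h are
dropped — they carry no signal for that task and would otherwise dominate
the label matrix with zeros.

## Models

Both learners emit one independent logistic output per target.

* **Logistic baseline.** A single linear layer + sigmoid per target, mean
  binary cross-entropy, vanilla SGD at learning rate 0.01, one epoch.
* **Feed-forward network.** ReLU hidden layers (depth/width configurable),
  optional batch normalization and inverted dropout, sigmoid outputs,
  trained with Nesterov Adam on the positive-weighted objective

      −(1/m) Σᵢ [ w·yᵢ log ŷᵢ + (1−yᵢ) log(1−ŷᵢ) ] + (λ/2) Σₗ ‖Wₗ‖²

  Natural log is used (the standard cross-entropy convention).  The positive
  weight *w* counteracts extreme label sparsity; λ penalizes layer weight
  matrices only, not biases (the usual reading of a Σ‖wₗ‖² penalty).
  Outputs are clipped to [1e−7, 1 − 1e−7] before the log for numerical
  safety.  Default batch size 1024.  The implementation is a self-contained
  NumPy multilayer perceptron; training is deterministic given a seed, and a
  non-finite batch loss aborts with diagnostics rather than training on.
* **Hyperparameter search.** Random search over {layers, units, dropout,
  batch norm, positive weight, λ} on a 50 000-row training subsample, scored
  by validation micro average precision, arg-max wins, full trial log
  emitted.  The default space (layers 1–4, units 64–1024, dropout 0–0.5,
  w 1–100, λ 0–1e−3) is a package choice, not a reproduction of any
  specific search.

## Standard-of-care baselines

* **Institutional order-set contents** (item task): on rows whose triggering
  event was ordered from within an order set, predict exactly the
  template's member items.  Rows where one clinical item carries two
  order-set attributions at once are ambiguous and excluded (counted).
  Because this predictor has a single operating point, AUROC is not
  reported for it; continuous scorers are thresholded to match its recall so
  precision/F1 are comparable.
* **Admissions frequency** (order-set task): count order-set usages within
  2 days of each admission (inclusive of the admission instant, half-open at
  +2 days), keyed by the admission's 3-digit diagnosis; scale each
  diagnosis's counts to [0, 1] by dividing by that diagnosis's maximum
  count (per-diagnosis min–max — the simplest reading of "scaled to 0–1";
  a proportion-of-total variant would only rescale, and every metric used
  here is invariant to monotone per-row rescaling).  Diagnoses with fewer
  than 50 total usages are dropped; they, and rows with no admission on
  record, fall back to the global "bestseller" table.  A row's admission is
  the patient's latest admission at or before the row's timestamp.

## Evaluation

AUROC (Mann–Whitney; ties half) and average precision (step-interpolated
PR area) are computed on micro-flattened (row, target) pairs; per-target
tables are emitted for diagnostics.  Macro alternatives are a cheap
post-processing of those tables; micro is the headline because the task is
ranking the union of candidate orders.  Confidence intervals use a
patient-level bootstrap: per iteration, patients are drawn with replacement
and their rows concatenated until the per-sample row budget (default
10 000) is met, the metric computed on the flattened sample, over 1000
iterations; the reported point estimate is the bootstrap mean and the CI
the 2.5/97.5 percentiles.  Whole patients are accumulated (the row budget
can be slightly exceeded) because hitting an exact row count would break
patient-level randomization.  Iterations where a metric is undefined
(single-class sample) are resampled and counted.  Rows within a patient are
correlated, so these intervals can be anti-conservative; no correction is
applied.

## Synthetic cohorts

The generator emulates the statistical structure of a multi-year inpatient
stream, not its clinical semantics:

* **Power-law catalogue.** Item base probabilities ∝ rank^−α, α = 1.75 by
  default, putting ≳90% of order volume in the top fifth of items.
* **Admissions and bursts.** Each patient gets ≥1 admission (Poisson);
  each admission spans 2–6 days with Poisson-many ordering bursts;
  within-burst gaps are exponential minutes.  The minutes/days/months gap
  mixture is deliberate: it makes the 1/7/30-day windows see materially
  different histories.
* **Context.** Each admission draws a latent context that (a) fixes the
  admission diagnosis (emitted both as a diagnosis event and as an
  admissions-table row, the linkage the admissions baseline needs),
  (b) prefers one order set (probability 0.9 when a template fires;
  templates fire on 25% of bursts; each member item is included with
  probability 0.7, at least one always, since clinicians rarely order a full
  template), and (c) tilts the single-order item distribution.  The tilt is
  a rank-stratified Latin square: items are stratified by frequency rank
  into strata of size *K* (the context count) and context *k* concentrates
  each stratum's probability mass on one member.  Every item is preferred by
  exactly one context per stratum, so increasing `context_signal_strength`
  *s* (the mixture weight of the tilt) makes history more predictive of
  future orders while leaving stratum-level base rates and the power law
  essentially unchanged.  At *s* = 0 the stream is context-free.
* **Determinism.** All randomness flows from one seeded generator; a fixed
  spec and seed reproduce the TSV outputs byte for byte.

What the generator does **not** model: real drug–disease semantics, repeat
prescriptions with clinical schedules, lab values (labs are presence
events), inter-provider variation, or documentation artifacts.  Passing
tests on this substrate demonstrate that the pipeline's mechanics —
leakage-safe binning, provenance handling, baseline logic, bootstrap — are
correct and that planted signal of a known kind is recovered; they say
nothing about performance on any real EHR.

## Problem sizes

Test and example runs use desk-scale cohorts chosen once: 150–400 patients
for structural and recovery checks, 2 500 patients (~10⁵ events) for the
power-law concentration check, 250 patients × 3 signal settings for the
monotonicity check, 200 replicates × 200 bootstrap iterations at n = 300
for CI coverage against the closed-form binormal AUROC Φ(Δ/√(σ₀²+σ₁²)),
and a 200-patient cohort for the end-to-end smoke run.  Vocabulary and
usage thresholds scale with cohort size in those runs (e.g. `min_count` 30
at 200 patients); the defaults (256, 50, 10 000 × 1000) are the reference
operating point for full-scale data.

## Known limitations

* Dense transforms: z-scored matrices are materialized densely; fine at
  desk scale, a chunked path would be needed for tens of millions of rows.
* The logistic baseline's single SGD epoch is faithful to its reference
  protocol but underfits small synthetic cohorts; tests that need a
  converged linear learner use more epochs explicitly.
* Bootstrap CIs inherit the row-correlation caveat above.
* `hour`-resolution time features ignore minutes; windows are exact to the
  event timestamp resolution (seconds in the generator).
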