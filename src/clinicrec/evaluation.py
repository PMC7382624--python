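"""Ranking metrics, recall-matched thresholding, and patient-level bootstrap
confidence intervals.

Multi-label score/label matrices are evaluated *micro-averaged*: all
(row, target) pairs are flattened into one long vector before computing
AUROC, average precision, or thresholded precision/recall/F1.  Confidence
intervals come from a bootstrap that resamples *patients* (not rows) with
replacement, accumulating each sampled patient's rows until the per-sample
row budget is reached — so prolific patients do not dominate the uncertainty
estimate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, NamedTuple

import numpy as np
import pandas as pd
import scipy.sparse
from sklearn.metrics import average_precision_score, roc_auc_score


class MetricUndefinedError(ValueError):
    """Raised when a metric has no defined value on the given labels."""


def _flatten(scores, labels) -> tuple[np.ndarray, np.ndarray]:
    if scipy.sparse.issparse(labels):
        labels = np.asarray(labels.todense())
    if scipy.sparse.issparse(scores):
        scores = np.asarray(scores.todense())
    return np.asarray(scores, dtype=float).ravel(), np.asarray(labels, dtype=float).ravel()


def auroc(scores, labels) -> float:
    """Probability that a random positive outscores a random negative, ties
    counted one-half (Mann–Whitney formulation)."""
    s, y = _flatten(scores, labels)
    if y.min() == y.max():
        raise MetricUndefinedError("AUROC undefined: labels contain a single class")
    return float(roc_auc_score(y, s))


def average_precision(scores, labels) -> float:
    """Area under the precision–recall step curve,
    ``Σ_k (R_k − R_{k−1})·P_k`` over descending-score operating points."""
    s, y = _flatten(scores, labels)
    if y.sum() == 0:
        raise MetricUndefinedError("average precision undefined: no positive labels")
    return float(average_precision_score(y, s))


class PRF(NamedTuple):
    precision: float
    recall: float
    f1: float
    degenerate: bool  # a zero-denominator case was coerced to 0


def prf_at_threshold(scores, labels, tau: float) -> PRF:
    """Micro-averaged precision/recall/F1 at ``prediction = score >= tau``."""
    if not np.isfinite(tau):
        raise ValueError("threshold must be finite")
    s, y = _flatten(scores, labels)
    pred = s >= tau
    tp = float((pred & (y == 1)).sum())
    fp = float((pred & (y == 0)).sum())
    fn = float((~pred & (y == 1)).sum())
    degenerate = False
    if tp + fp == 0:
        precision, degenerate = 0.0, True
    else:
        precision = tp / (tp + fp)
    if tp + fn == 0:
        recall, degenerate = 0.0, True
    else:
        recall = tp / (tp + fn)
    if precision + recall == 0:
        f1, degenerate = 0.0, True
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return PRF(precision, recall, f1, degenerate)


def match_recall_threshold(scores, labels, target_recall: float) -> float:
    """Threshold whose recall is closest to ``target_recall`` over the grid of
    distinct scores; ties broken toward higher precision.

    Used to compare a continuous scorer against a single-operating-point
    baseline at equal recall, so precision and F1 are comparable.
    """
    if not 0.0 < target_recall <= 1.0:
        raise ValueError("target_recall must be in (0, 1]")
    s, y = _flatten(scores, labels)
    grid = np.unique(s)
    best = None
    for tau in grid:
        p = prf_at_threshold(s, y, tau)
        key = (abs(p.recall - target_recall), -p.precision)
        if best is None or key < best[0]:
            best = (key, tau)
    return float(best[1])


@dataclass
class BootstrapResult:
    mean: float
    lo: float
    hi: float
    rows_per_sample: int
    iterations: int
    seed: int
    n_undefined_resampled: int = 0
    samples: np.ndarray | None = None

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "ci_lo": self.lo,
            "ci_hi": self.hi,
            "rows_per_sample": self.rows_per_sample,
            "iterations": self.iterations,
            "seed": self.seed,
            "n_undefined_resampled": self.n_undefined_resampled,
        }


def bootstrap_ci(
    metric: Callable[[np.ndarray, np.ndarray], float],
    patient_ids: np.ndarray,
    scores,
    labels,
    rows_per_sample: int = 10_000,
    iterations: int = 1_000,
    seed: int = 0,
    max_retries: int = 100,
    keep_samples: bool = False,
) -> BootstrapResult:
    """Patient-level bootstrap of a metric.

    Per iteration: sample patients uniformly with replacement, concatenating
    each sampled patient's rows until at least ``rows_per_sample`` rows are
    accumulated (whole patients — the budget can be slightly exceeded), then
    compute the metric on the micro-flattened sample.  Reports the mean and
    the 2.5/97.5 percentiles across iterations.  Iterations on which the
    metric is undefined (e.g. a single-class AUROC sample) are resampled and
    counted.
    """
    patient_ids = np.asarray(patient_ids)
    if scipy.sparse.issparse(labels):
        labels = np.asarray(labels.todense())
    labels = np.asarray(labels, dtype=float)
    scores = np.asarray(scores, dtype=float)
    if len(patient_ids) != scores.shape[0] or scores.shape != labels.shape:
        raise ValueError("patient_ids, scores and labels must align row-wise")

    uniq, inv = np.unique(patient_ids, return_inverse=True)
    rows_of = [np.flatnonzero(inv == u) for u in range(len(uniq))]
    rows_per_patient = np.array([len(r) for r in rows_of])
    mean_rows = rows_per_patient.mean()

    rng = np.random.default_rng(seed)
    stats = np.empty(iterations)
    n_undefined = 0
    for it in range(iterations):
        for _ in range(max_retries):
            n_draw = max(1, int(np.ceil(rows_per_sample / mean_rows * 1.2)))
            picked: list[int] = []
            total = 0
            while total < rows_per_sample:
                chunk = rng.integers(len(uniq), size=n_draw)
                cum = np.cumsum(rows_per_patient[chunk])
                stop = np.searchsorted(cum, rows_per_sample - total, side="left") + 1
                picked.extend(chunk[:stop].tolist())
                total += int(cum[min(stop, len(cum)) - 1])
            idx = np.concatenate([rows_of[p] for p in picked])
            try:
                stats[it] = metric(scores[idx], labels[idx])
                break
            except MetricUndefinedError:
                n_undefined += 1
        else:
            raise MetricUndefinedError(
                f"metric undefined on {max_retries} consecutive bootstrap samples"
            )
    lo, hi = np.percentile(stats, [2.5, 97.5])
    return BootstrapResult(
        mean=float(stats.mean()),
        lo=float(lo),
        hi=float(hi),
        rows_per_sample=rows_per_sample,
        iterations=iterations,
        seed=seed,
        n_undefined_resampled=n_undefined,
        samples=stats if keep_samples else None,
    )


@dataclass
class MetricReport:
    """Point estimates (bootstrap means) and 95% CIs for one model × task."""

    model: str
    task: str
    metrics: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, result: BootstrapResult) -> None:
        self.metrics[name] = result.as_dict()

    def as_dict(self) -> dict:
        return {"model": self.model, "task": self.task, "metrics": self.metrics}


def per_target_metrics(scores, labels, target_names: list[str]) -> pd.DataFrame:
    """Diagnostic per-target AUROC/AP (NaN where undefined)."""
    if scipy.sparse.issparse(labels):
        labels = np.asarray(labels.todense())
    scores = np.asarray(scores, dtype=float)
    rows = []
    for j, name in enumerate(target_names):
        y = labels[:, j]
        s = scores[:, j]
        try:
            a = auroc(s, y)
        except MetricUndefinedError:
            a = float("nan")
        try:
            ap = average_precision(s, y)
        except MetricUndefinedError:
            ap = float("nan")
        rows.append({"target": name, "n_positive": int(y.sum()), "auroc": a, "average_precision": ap})
    return pd.DataFrame(rows)
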