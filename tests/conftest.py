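"""Shared fixtures: the worked five-order scenario and brute-force oracles."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from clinicrec.features import WindowSpec


def make_scenario(aspirin_same_instant: bool = False) -> pd.DataFrame:
    """The five-order scenario: acetaminophen at t0, again one hour later, a
    third ten days after that; aspirin a few minutes later, and a second
    aspirin several minutes after the first.

    With ``aspirin_same_instant`` the first aspirin is co-signed at the same
    instant as the third acetaminophen, so its feature row sees an identical
    patient history.
    """
    t0 = pd.Timestamp("2010-03-01 08:00:00")
    t3 = t0 + pd.Timedelta(days=10, hours=1)
    t4 = t3 if aspirin_same_instant else t3 + pd.Timedelta(minutes=3)
    rows = [
        ("P1", "acetaminophen", t0),
        ("P1", "acetaminophen", t0 + pd.Timedelta(hours=1)),
        ("P1", "acetaminophen", t3),
        ("P1", "aspirin", t4),
        ("P1", "aspirin", t4 + pd.Timedelta(minutes=5)),
    ]
    return pd.DataFrame(
        {
            "patient_id": [r[0] for r in rows],
            "item_id": [r[1] for r in rows],
            "category": "medication_order",
            "timestamp": [r[2] for r in rows],
            "source_order_set_id": None,
        }
    )


@pytest.fixture
def scenario_events() -> pd.DataFrame:
    return make_scenario()


def brute_force_features(
    events: pd.DataFrame, vocab: list[str], windows: WindowSpec = WindowSpec()
) -> np.ndarray:
    """Independent oracle: per-row full rescan of the patient history.

    For every generating event, re-scan all of that patient's events and
    count, per vocabulary item and lookback window w, the events with
    t_row - w < t < t_row.
    """
    vocab = sorted(vocab)
    labels = windows.window_labels
    durs = dict(windows.feature_windows)
    out = np.zeros((len(events), len(vocab) * len(labels)))
    ev = events.reset_index(drop=True)
    for r in range(len(ev)):
        pid, t = ev.at[r, "patient_id"], ev.at[r, "timestamp"]
        hist = ev[(ev["patient_id"] == pid) & (ev["timestamp"] < t)]
        for i, item in enumerate(vocab):
            item_ts = hist.loc[hist["item_id"] == item, "timestamp"]
            for w, lab in enumerate(labels):
                d = durs[lab]
                n = len(item_ts) if d is None else int((item_ts > t - d).sum())
                out[r, i * len(labels) + w] = n
    return out


def brute_force_responses(
    events: pd.DataFrame,
    targets: list[str],
    horizon: pd.Timedelta = pd.Timedelta(days=1),
    kind: str = "items",
) -> np.ndarray:
    targets = sorted(targets)
    ev = events.reset_index(drop=True)
    out = np.zeros((len(ev), len(targets)))
    key = "item_id" if kind == "items" else "source_order_set_id"
    for r in range(len(ev)):
        pid, t = ev.at[r, "patient_id"], ev.at[r, "timestamp"]
        fut = ev[
            (ev["patient_id"] == pid) & (ev["timestamp"] >= t) & (ev["timestamp"] < t + horizon)
        ]
        for j, tgt in enumerate(targets):
            out[r, j] = float((fut[key] == tgt).any())
    return out


def pairwise_auroc(scores: np.ndarray, labels: np.ndarray) -> float:
    """Oracle AUROC: exhaustive positive x negative pair comparison, ties 1/2."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for n in neg:
            wins += 1.0 if p > n else (0.5 if p == n else 0.0)
    return wins / (len(pos) * len(neg))


def step_average_precision(scores: np.ndarray, labels: np.ndarray) -> float:
    """Oracle AP: cumulative precision scan over the descending-score list."""
    order = np.argsort(-scores, kind="stable")
    y = labels[order]
    n_pos = y.sum()
    tp = 0.0
    ap = 0.0
    prev_recall = 0.0
    for k in range(len(y)):
        tp += y[k]
        # operating point after each distinct score block
        if k + 1 < len(y) and scores[order[k + 1]] == scores[order[k]]:
            continue
        precision = tp / (k + 1)
        recall = tp / n_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


def scalar_loop_bce(y: np.ndarray, yhat: np.ndarray, w: float, lam: float, weights) -> float:
    """Oracle: element-by-element evaluation of the weighted BCE + L2 formula."""
    import math

    y2 = np.atleast_2d(y)
    yh2 = np.atleast_2d(yhat)
    m = y.shape[0]
    total = 0.0
    for i in range(y2.shape[0]):
        for j in range(y2.shape[1]):
            p = min(max(yh2[i, j], 1e-7), 1 - 1e-7)
            total += w * y2[i, j] * math.log(p) + (1 - y2[i, j]) * math.log(1 - p)
    reg = 0.0
    for W in weights:
        for v in np.asarray(W).ravel():
            reg += v * v
    return -total / m + 0.5 * lam * reg
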