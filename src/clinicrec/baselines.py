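"""Standard-of-care heuristic baselines.

Two heuristics mirror how clinical decision support works today:

* **Institutional order-set contents** (individual-order task): whenever a
  clinician opens an order-set template to place an item, predict exactly the
  template's member items.  Evaluated only on rows whose triggering event
  carries order-set provenance; the rare rows where one clinical item is
  attributed to two order sets at once are excluded as ambiguous.

* **Admissions frequency** (order-set task): score each order set by how often
  it has historically been used within two days of admissions sharing the
  patient's 3-digit admission diagnosis, min–max scaled to [0, 1] per
  diagnosis.  Diagnoses with fewer than 50 recorded usages — and rows with no
  admission on record — fall back to the global "bestseller" ranking.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

from clinicrec.events import OrderSetDefinition


def orderset_contents_prediction(
    row_index: pd.DataFrame,
    order_sets: dict[str, OrderSetDefinition],
    order_vocab: list[str],
) -> tuple[np.ndarray, scipy.sparse.csr_matrix, int]:
    """Predict the full contents of the order set each row was ordered from.

    Parameters
    ----------
    row_index
        Feature-row metadata (patient_id, item_id, timestamp,
        source_order_set_id), one row per triggering event.
    order_sets
        Definitions keyed by order-set id.
    order_vocab
        The target item vocabulary; columns of the returned prediction matrix.

    Returns
    -------
    (row_positions, predictions, n_excluded)
        Positions of rows ordered from within an order set (minus ambiguous
        dual-provenance rows), the aligned binary member-indicator matrix,
        and the count of excluded dual-provenance rows.
    """
    vocab = sorted(order_vocab)
    pos = {item: j for j, item in enumerate(vocab)}

    has_src = row_index["source_order_set_id"].notna()
    unknown = set(row_index.loc[has_src, "source_order_set_id"]) - set(order_sets)
    if unknown:
        raise KeyError(f"events reference undefined order sets: {sorted(unknown)}")

    # dual provenance: the same (patient, item, timestamp) attributed to >1 set
    sub = row_index[has_src]
    n_sets = sub.groupby(["patient_id", "item_id", "timestamp"])["source_order_set_id"].transform(
        "nunique"
    )
    ambiguous_idx = sub.index[n_sets > 1]
    keep_idx = sub.index.difference(ambiguous_idx)
    n_excluded = int(len(ambiguous_idx))

    rows, cols = [], []
    keep = np.asarray(sorted(keep_idx))
    for r, i in enumerate(keep):
        members = order_sets[row_index.at[i, "source_order_set_id"]].member_items
        for item in members:
            j = pos.get(item)
            if j is not None:
                rows.append(r)
                cols.append(j)
    pred = scipy.sparse.coo_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(len(keep), len(vocab))
    ).tocsr()
    return keep, pred, n_excluded


@dataclass
class AdmissionFrequencyModel:
    """Per-diagnosis order-set usage frequencies with a bestseller fallback."""

    orderset_vocab: list[str]
    diagnosis_scores: dict[str, np.ndarray] = field(default_factory=dict)
    bestseller_scores: np.ndarray = field(default_factory=lambda: np.zeros(0))
    raw_counts: dict[str, dict[str, int]] = field(default_factory=dict)
    min_usage: int = 50
    window: pd.Timedelta = pd.Timedelta(days=2)

    def to_json(self) -> dict:
        return {
            "orderset_vocab": self.orderset_vocab,
            "diagnosis_scores": {d: s.tolist() for d, s in self.diagnosis_scores.items()},
            "bestseller_scores": self.bestseller_scores.tolist(),
            "raw_counts": self.raw_counts,
            "min_usage": self.min_usage,
            "window_days": self.window / pd.Timedelta(days=1),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "AdmissionFrequencyModel":
        return cls(
            orderset_vocab=list(obj["orderset_vocab"]),
            diagnosis_scores={d: np.asarray(s) for d, s in obj["diagnosis_scores"].items()},
            bestseller_scores=np.asarray(obj["bestseller_scores"]),
            raw_counts={d: dict(c) for d, c in obj["raw_counts"].items()},
            min_usage=int(obj["min_usage"]),
            window=pd.Timedelta(days=obj["window_days"]),
        )


def _orderset_usages(events: pd.DataFrame) -> pd.DataFrame:
    """Distinct order-set usages: one (patient, order_set, timestamp) per
    template activation, regardless of how many member orders it emitted."""
    used = events.dropna(subset=["source_order_set_id"])
    return (
        used[["patient_id", "source_order_set_id", "timestamp"]]
        .drop_duplicates()
        .reset_index(drop=True)
    )


def _minmax(counts: np.ndarray) -> np.ndarray:
    top = counts.max()
    return counts / top if top > 0 else counts.astype(float)


def fit_admission_baseline(
    events: pd.DataFrame,
    admissions: pd.DataFrame,
    orderset_vocab: list[str],
    min_usage: int = 50,
    window: pd.Timedelta = pd.Timedelta(days=2),
) -> AdmissionFrequencyModel:
    """Count order-set usages within ``window`` of each admission, keyed by
    the admission's 3-digit diagnosis; min–max scale per diagnosis; drop
    diagnoses with fewer than ``min_usage`` total usages.

    The bestseller table (global usage counts, min–max scaled) backs every
    fallback path.  An empty training stream yields a bestseller-only model.
    """
    import warnings

    vocab = sorted(orderset_vocab)
    pos = {os_id: j for j, os_id in enumerate(vocab)}
    usages = _orderset_usages(events)

    global_counts = np.zeros(len(vocab))
    for os_id, cnt in usages["source_order_set_id"].value_counts().items():
        if os_id in pos:
            global_counts[pos[os_id]] = cnt
    model = AdmissionFrequencyModel(
        orderset_vocab=vocab,
        bestseller_scores=_minmax(global_counts),
        min_usage=min_usage,
        window=window,
    )
    if usages.empty or admissions.empty:
        warnings.warn("no order-set usages or admissions in training data; bestseller-only model")
        return model

    # attribute each usage to the patient's latest admission whose 2-day
    # post-admission window (inclusive of the admission instant) contains it
    adm_sorted = {
        pid: grp.sort_values("timestamp") for pid, grp in admissions.groupby("patient_id")
    }
    counts: dict[str, np.ndarray] = {}
    for row in usages.itertuples(index=False):
        grp = adm_sorted.get(row.patient_id)
        if grp is None:
            continue
        ts = grp["timestamp"].to_numpy()
        k = np.searchsorted(ts, np.datetime64(row.timestamp), side="right") - 1
        if k < 0:
            continue
        adm_ts = grp["timestamp"].iloc[k]
        if not (adm_ts <= row.timestamp < adm_ts + window):
            continue
        diag = grp["diagnosis_code"].iloc[k]
        if diag not in counts:
            counts[diag] = np.zeros(len(vocab))
        j = pos.get(row.source_order_set_id)
        if j is not None:
            counts[diag][j] += 1

    for diag, c in sorted(counts.items()):
        total = int(c.sum())
        model.raw_counts[diag] = {
            vocab[j]: int(c[j]) for j in np.nonzero(c)[0]
        }
        if total >= min_usage:
            model.diagnosis_scores[diag] = _minmax(c)
    return model


def score_admission_baseline(
    model: AdmissionFrequencyModel,
    row_index: pd.DataFrame,
    admissions: pd.DataFrame,
) -> np.ndarray:
    """Score each row with its admission diagnosis's table, falling back to
    the bestseller table when the row has no admission on record or its
    diagnosis was under the usage threshold."""
    adm_sorted = {
        pid: grp.sort_values("timestamp") for pid, grp in admissions.groupby("patient_id")
    }
    out = np.empty((len(row_index), len(model.orderset_vocab)))
    ts_all = row_index["timestamp"].to_numpy()
    pids = row_index["patient_id"].to_numpy()
    for r in range(len(row_index)):
        grp = adm_sorted.get(pids[r])
        scores = model.bestseller_scores
        if grp is not None:
            ts = grp["timestamp"].to_numpy()
            k = np.searchsorted(ts, ts_all[r], side="right") - 1
            if k >= 0:
                diag = grp["diagnosis_code"].iloc[k]
                scores = model.diagnosis_scores.get(diag, model.bestseller_scores)
        out[r] = scores
    return out
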