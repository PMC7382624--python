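"""Per-event temporal feature rows and 24-hour forward response vectors.

Every clinical item entry generates one row.  The row's features summarize the
patient's record strictly before that instant: counts of each vocabulary item
inside lookback windows of 1, 7 and 30 days plus an unbounded "any time prior"
window, cyclical (sine/cosine) encodings of the entry's month and hour, and
the patient's demographic one-hots.  The aligned response row marks, for each
target order (or order-set template), whether it occurs within the next 24
hours — a horizon that *includes* the triggering instant, so an order's own
row is labeled positive for that order.

Window conventions: a lookback window ``w`` covers timestamps in the open
interval ``(t - w, t)`` — events at exactly ``t - w`` or at exactly ``t`` are
excluded; the response horizon covers ``[t, t + 24h)``.  These asymmetric
conventions are what make the worked five-order scenario (two acetaminophen
orders an hour apart, a third ten days later, two aspirin orders minutes
after that) come out exactly right: prior history only in the features, the
current order counted in its own label.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse

DAY_NS = 86_400_000_000_000  # one day in nanoseconds

TIME_FEATURE_NAMES = ["time:month_sin", "time:month_cos", "time:hour_sin", "time:hour_cos"]


@dataclass(frozen=True)
class WindowSpec:
    """Lookback windows for features and the forward horizon for responses.

    ``feature_windows`` maps window labels to lookback durations; ``None``
    denotes the unbounded "any time prior" window and must come last.
    """

    feature_windows: tuple[tuple[str, pd.Timedelta | None], ...] = (
        ("pre-1", pd.Timedelta(days=1)),
        ("pre-7", pd.Timedelta(days=7)),
        ("pre-30", pd.Timedelta(days=30)),
        ("pre-any", None),
    )
    response_horizon: pd.Timedelta = pd.Timedelta(days=1)

    def __post_init__(self) -> None:
        durations = [d for _, d in self.feature_windows]
        if durations[-1] is not None:
            raise ValueError("last feature window must be unbounded (None)")
        finite = [d for d in durations if d is not None]
        if any(b <= a for a, b in zip(finite, finite[1:])):
            raise ValueError("feature windows must be strictly increasing")
        if self.response_horizon <= pd.Timedelta(0):
            raise ValueError("response horizon must be positive")

    @property
    def window_labels(self) -> list[str]:
        return [label for label, _ in self.feature_windows]


@dataclass
class FeatureMatrix:
    """Sparse per-event feature rows with row and column metadata.

    ``row_index`` has one row per generating event (patient_id, timestamp,
    item_id, source_order_set_id); ``column_index`` has one row per column
    (name, kind ∈ {count, time, demographic}, item_id, window).
    """

    X: scipy.sparse.csr_matrix
    row_index: pd.DataFrame
    column_index: pd.DataFrame

    @property
    def column_names(self) -> list[str]:
        return list(self.column_index["name"])

    @property
    def count_mask(self) -> np.ndarray:
        return (self.column_index["kind"] == "count").to_numpy()


@dataclass
class ResponseMatrix:
    """Binary response rows aligned row-for-row with a FeatureMatrix."""

    Y: scipy.sparse.csr_matrix
    row_index: pd.DataFrame
    target_vocab: list[str]


def encode_time_features(timestamp: pd.Timestamp) -> tuple[float, float, float, float]:
    """Cyclical encoding of a timestamp's month and hour.

    Returns ``(month_sin, month_cos, hour_sin, hour_cos)`` where the month
    phase is ``2π(month-1)/12`` and the hour phase is ``2π·hour/24``, so
    January at midnight encodes as (0, 1, 0, 1) and December sits next to
    January rather than a year away.
    """
    ts = pd.Timestamp(timestamp)
    month_phase = 2.0 * math.pi * (ts.month - 1) / 12.0
    hour_phase = 2.0 * math.pi * ts.hour / 24.0
    return (
        math.sin(month_phase),
        math.cos(month_phase),
        math.sin(hour_phase),
        math.cos(hour_phase),
    )


def _check_sorted(events: pd.DataFrame) -> None:
    for patient, grp in events.groupby("patient_id", sort=False):
        ts = grp["timestamp"].to_numpy()
        if len(ts) > 1 and (np.diff(ts.astype("int64")) < 0).any():
            raise ValueError(f"events of patient {patient!r} are not time-sorted")


def build_feature_rows(
    events: pd.DataFrame,
    vocab: list[str] | set[str],
    windows: WindowSpec = WindowSpec(),
    demographics: pd.DataFrame | None = None,
) -> FeatureMatrix:
    """Build the sparse feature matrix: one row per clinical item entry.

    Parameters
    ----------
    events
        Event stream, time-sorted within each patient.  Every row generates a
        feature row, including events of items outside ``vocab`` (those
        contribute a row but no count features).
    vocab
        The feature item vocabulary; column blocks are one item × window.
    windows
        Lookback windows; defaults to 1/7/30 days plus unbounded.
    demographics
        Optional (patient_id, item_id) table of demographic attributes,
        replicated as timestamp-free one-hot columns into each of the
        patient's rows.
    """
    if not vocab:
        raise ValueError("feature vocabulary must be non-empty")
    _check_sorted(events)
    vocab = sorted(vocab)
    item_pos = {item: i for i, item in enumerate(vocab)}
    labels = windows.window_labels
    finite = [d.value for _, d in windows.feature_windows if d is not None]
    n_windows = len(labels)
    n_items = len(vocab)
    n_count_cols = n_items * n_windows

    demo_cols: list[str] = []
    demo_of_patient: dict[str, list[int]] = {}
    if demographics is not None and len(demographics):
        demo_cols = sorted(demographics["item_id"].unique())
        demo_pos = {d: j for j, d in enumerate(demo_cols)}
        for pid, grp in demographics.groupby("patient_id", sort=False):
            demo_of_patient[pid] = [demo_pos[d] for d in grp["item_id"]]

    n_time = len(TIME_FEATURE_NAMES)
    rows_i: list[np.ndarray] = []
    cols_i: list[np.ndarray] = []
    vals: list[np.ndarray] = []
    time_block = np.empty((len(events), n_time))

    events = events.reset_index(drop=True)
    for pid, grp in events.groupby("patient_id", sort=False):
        ridx = grp.index.to_numpy()  # original row positions of this patient
        ts = grp["timestamp"].to_numpy().astype("int64")
        items = np.array([item_pos.get(i, -1) for i in grp["item_id"]], dtype=np.int64)
        n = len(ts)
        # Sliding per-window item counts: for row r the window w holds events
        # with t_r - w < t < t_r.  `hi` and the per-window `lo` pointers are
        # monotone, so the whole patient costs O(n * n_windows).
        counts = np.zeros((n_windows, n_items), dtype=np.float64)
        lo = [0] * n_windows
        hi = 0
        for r in range(n):
            t = ts[r]
            while hi < r and ts[hi] < t:
                it = items[hi]
                if it >= 0:
                    counts[:, it] += 1.0
                hi += 1
            for w, wdur in enumerate(finite):
                edge = t - wdur
                while lo[w] < hi and ts[lo[w]] <= edge:
                    it = items[lo[w]]
                    if it >= 0:
                        counts[w, it] -= 1.0
                    lo[w] += 1
            for w in range(n_windows):
                nz = np.nonzero(counts[w])[0]
                if len(nz):
                    rows_i.append(np.full(len(nz), ridx[r], dtype=np.int64))
                    cols_i.append(nz * n_windows + w)
                    vals.append(counts[w, nz].copy())
        # demographic one-hots, replicated into every row of the patient
        djs = demo_of_patient.get(pid)
        if djs:
            for j in djs:
                rows_i.append(ridx.astype(np.int64))
                cols_i.append(np.full(n, n_count_cols + n_time + j, dtype=np.int64))
                vals.append(np.ones(n))
        for r, t in enumerate(grp["timestamp"]):
            time_block[ridx[r]] = encode_time_features(t)

    n_cols = n_count_cols + n_time + len(demo_cols)
    tr, tc = np.nonzero(time_block)
    rows_all = np.concatenate(rows_i + [tr]) if rows_i else tr
    cols_all = np.concatenate(cols_i + [tc + n_count_cols]) if cols_i else tc + n_count_cols
    vals_all = np.concatenate(vals + [time_block[tr, tc]]) if vals else time_block[tr, tc]
    X = scipy.sparse.coo_matrix(
        (vals_all, (rows_all, cols_all)), shape=(len(events), n_cols)
    ).tocsr()

    row_index = events[["patient_id", "item_id", "timestamp", "source_order_set_id"]].reset_index(
        drop=True
    )
    col_records = [
        {"name": f"{item}|{label}", "kind": "count", "item_id": item, "window": label}
        for item in vocab
        for label in labels
    ]
    col_records += [
        {"name": name, "kind": "time", "item_id": "", "window": ""} for name in TIME_FEATURE_NAMES
    ]
    col_records += [
        {"name": f"demo:{d}", "kind": "demographic", "item_id": d, "window": ""} for d in demo_cols
    ]
    return FeatureMatrix(X, row_index, pd.DataFrame(col_records))


def build_response_rows(
    events: pd.DataFrame,
    targets: list[str] | set[str],
    horizon: pd.Timedelta = pd.Timedelta(days=1),
    kind: str = "items",
) -> ResponseMatrix:
    """Build binary next-``horizon`` labels aligned to the feature rows.

    For ``kind="items"`` a target is positive in row ``r`` when an event of
    that item occurs in ``[t_r, t_r + horizon)`` — the triggering event
    itself counts toward its own label.  For ``kind="ordersets"`` a target
    order set is positive when any event in that interval carries it as
    ``source_order_set_id``.
    """
    if horizon <= pd.Timedelta(0):
        raise ValueError("response horizon must be positive")
    if kind not in ("items", "ordersets"):
        raise ValueError(f"unknown response kind {kind!r}")
    _check_sorted(events)
    targets = sorted(targets)
    pos = {t: i for i, t in enumerate(targets)}
    hz = horizon.value
    n_targets = len(targets)

    rows_i: list[np.ndarray] = []
    cols_i: list[np.ndarray] = []
    events = events.reset_index(drop=True)
    for _, grp in events.groupby("patient_id", sort=False):
        ridx = grp.index.to_numpy()
        ts = grp["timestamp"].to_numpy().astype("int64")
        if kind == "items":
            key = grp["item_id"]
        else:
            key = grp["source_order_set_id"]
        tgt = np.array([pos.get(k, -1) if pd.notna(k) else -1 for k in key], dtype=np.int64)
        n = len(ts)
        for r in range(n):
            lo = np.searchsorted(ts, ts[r], side="left")
            hi = np.searchsorted(ts, ts[r] + hz, side="left")
            hits = np.unique(tgt[lo:hi])
            hits = hits[hits >= 0]
            if len(hits):
                rows_i.append(np.full(len(hits), ridx[r], dtype=np.int64))
                cols_i.append(hits)

    if rows_i:
        rows_all = np.concatenate(rows_i)
        cols_all = np.concatenate(cols_i)
    else:
        rows_all = np.empty(0, dtype=np.int64)
        cols_all = np.empty(0, dtype=np.int64)
    Y = scipy.sparse.coo_matrix(
        (np.ones(len(rows_all)), (rows_all, cols_all)), shape=(len(events), n_targets)
    ).tocsr()
    row_index = events[["patient_id", "item_id", "timestamp", "source_order_set_id"]].reset_index(
        drop=True
    )
    return ResponseMatrix(Y, row_index, targets)


@dataclass
class TransformStats:
    """Training-set column statistics for the log2 + z-score transform.

    Means and standard deviations are computed on log2(1+x)-transformed count
    columns (other columns untransformed); the retain ``mask`` drops columns
    whose training SD falls below ``sd_threshold`` — near-constant features
    carry no signal and destabilize standardization.
    """

    column_names: list[str]
    mean: np.ndarray
    sd: np.ndarray
    count_mask: np.ndarray
    mask: np.ndarray
    sd_threshold: float
    sd_floor: float = 1e-12
    version: str = field(default="1")

    def to_json(self) -> dict:
        return {
            "version": self.version,
            "sd_threshold": self.sd_threshold,
            "sd_floor": self.sd_floor,
            "column_names": self.column_names,
            "mean": self.mean.tolist(),
            "sd": self.sd.tolist(),
            "count_mask": self.count_mask.astype(int).tolist(),
            "mask": self.mask.astype(int).tolist(),
        }

    @classmethod
    def from_json(cls, obj: dict) -> "TransformStats":
        return cls(
            column_names=list(obj["column_names"]),
            mean=np.asarray(obj["mean"], dtype=float),
            sd=np.asarray(obj["sd"], dtype=float),
            count_mask=np.asarray(obj["count_mask"], dtype=bool),
            mask=np.asarray(obj["mask"], dtype=bool),
            sd_threshold=float(obj["sd_threshold"]),
            sd_floor=float(obj["sd_floor"]),
            version=str(obj["version"]),
        )


def _log2_transform(X: scipy.sparse.spmatrix, count_mask: np.ndarray) -> scipy.sparse.csr_matrix:
    """log2(1 + x) on count columns only; zeros map to zero so sparsity is kept."""
    X = scipy.sparse.csc_matrix(X, copy=True)
    for j in np.nonzero(count_mask)[0]:
        sl = slice(X.indptr[j], X.indptr[j + 1])
        X.data[sl] = np.log2(1.0 + X.data[sl])
    return X.tocsr()


def fit_transform_stats(
    train: FeatureMatrix, sd_threshold: float = 0.01
) -> TransformStats:
    """Fit the log2 + z-score statistics on the *training* rows only.

    Fitting on training data alone is what keeps standardization leakage-safe:
    validation/test rows are scaled by statistics they never influenced.
    """
    if train.X.shape[0] == 0:
        raise ValueError("cannot fit transform statistics on an empty training matrix")
    count_mask = train.count_mask
    Xl = _log2_transform(train.X, count_mask)
    n = Xl.shape[0]
    mean = np.asarray(Xl.mean(axis=0)).ravel()
    sq = np.asarray(Xl.multiply(Xl).mean(axis=0)).ravel()
    var = np.maximum(sq - mean**2, 0.0)
    sd = np.sqrt(var * n / max(n - 1, 1))
    mask = sd >= sd_threshold
    return TransformStats(
        column_names=train.column_names,
        mean=mean,
        sd=sd,
        count_mask=count_mask,
        mask=mask,
        sd_threshold=sd_threshold,
    )


def apply_transforms(matrix: FeatureMatrix, stats: TransformStats) -> np.ndarray:
    """log2(1+x) counts, z-score every column with training statistics, drop
    masked columns.  Columns whose training SD is numerically zero are
    centered but not scaled.  Returns a dense array (centering destroys
    sparsity)."""
    if matrix.column_names != stats.column_names:
        raise ValueError(
            "feature columns do not match fitted statistics: "
            f"{len(matrix.column_names)} columns vs {len(stats.column_names)} fitted"
        )
    Xl = _log2_transform(matrix.X, stats.count_mask)
    dense = np.asarray(Xl.todense(), dtype=float)
    dense -= stats.mean
    scale = np.where(stats.sd > stats.sd_floor, stats.sd, 1.0)
    dense /= scale
    return dense[:, stats.mask]
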