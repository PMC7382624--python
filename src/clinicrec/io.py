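"""Plain-text persistence: TSV event streams, order sets, mapping tables,
admissions, split manifests; MatrixMarket matrices with TSV sidecar indexes.

Timestamps are serialized in a single fixed form (``YYYY-MM-DDTHH:MM:SSZ``,
UTC, second resolution) so that write → read → write round-trips are
byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from clinicrec.events import EVENT_COLUMNS, OrderSetDefinition

TIMESTAMP_FORMAT = "%Y-%m-%dT%H:%M:%SZ"


def format_timestamps(ts: pd.Series) -> pd.Series:
    return ts.dt.strftime(TIMESTAMP_FORMAT)


def parse_timestamps(raw: pd.Series) -> pd.Series:
    return pd.to_datetime(raw, format=TIMESTAMP_FORMAT)


def write_events(events: pd.DataFrame, path: str | Path) -> None:
    """Write an event stream TSV (header + one row per clinical item entry)."""
    out = events[EVENT_COLUMNS].copy()
    out["timestamp"] = format_timestamps(out["timestamp"])
    out["source_order_set_id"] = out["source_order_set_id"].fillna("")
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_events(path: str | Path) -> pd.DataFrame:
    """Read an event stream TSV. Missing source_order_set_id becomes NaN."""
    df = pd.read_csv(
        path,
        sep="\t",
        dtype={
            "patient_id": str,
            "item_id": str,
            "category": str,
            "source_order_set_id": str,
        },
        keep_default_na=False,
    )
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"event stream {path} is missing columns: {missing}")
    df["timestamp"] = parse_timestamps(df["timestamp"])
    df["source_order_set_id"] = df["source_order_set_id"].replace("", np.nan)
    return df[EVENT_COLUMNS]


def write_order_sets(order_sets: dict[str, OrderSetDefinition], path: str | Path) -> None:
    rows = [
        {"order_set_id": os_id, "item_id": item}
        for os_id, defn in sorted(order_sets.items())
        for item in sorted(defn.member_items)
    ]
    pd.DataFrame(rows, columns=["order_set_id", "item_id"]).to_csv(
        path, sep="\t", index=False, lineterminator="\n"
    )


def read_order_sets(path: str | Path) -> dict[str, OrderSetDefinition]:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    out = {}
    for os_id, grp in df.groupby("order_set_id", sort=True):
        out[os_id] = OrderSetDefinition(os_id, frozenset(grp["item_id"]))
    return out


def write_admissions(admissions: pd.DataFrame, path: str | Path) -> None:
    out = admissions[["patient_id", "timestamp", "diagnosis_code"]].copy()
    out["timestamp"] = format_timestamps(out["timestamp"])
    out.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_admissions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"patient_id": str, "diagnosis_code": str})
    df["timestamp"] = parse_timestamps(df["timestamp"])
    return df


def read_mapping_table(path: str | Path) -> dict[str, str]:
    """Two-column TSV (raw value → normalized value) as a dict."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    if df.shape[1] != 2:
        raise ValueError(f"mapping table {path} must have exactly 2 columns")
    return dict(zip(df.iloc[:, 0], df.iloc[:, 1]))


def write_split_manifest(assignment: dict[str, str], path: str | Path) -> None:
    pd.DataFrame(
        sorted(assignment.items()), columns=["patient_id", "partition"]
    ).to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_split_manifest(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    return dict(zip(df["patient_id"], df["partition"]))


def write_sparse_matrix(
    matrix: scipy.sparse.spmatrix,
    row_index: pd.DataFrame,
    column_index: pd.DataFrame,
    prefix: str | Path,
) -> None:
    """Persist a sparse matrix as MatrixMarket plus row/column TSV sidecars."""
    prefix = Path(prefix)
    scipy.io.mmwrite(str(prefix) + ".mtx", scipy.sparse.coo_matrix(matrix))
    rows = row_index.copy()
    if "timestamp" in rows.columns:
        rows["timestamp"] = format_timestamps(rows["timestamp"])
    rows.to_csv(str(prefix) + ".rows.tsv", sep="\t", index=False, lineterminator="\n")
    column_index.to_csv(str(prefix) + ".cols.tsv", sep="\t", index=False, lineterminator="\n")


def read_sparse_matrix(prefix: str | Path):
    prefix = Path(prefix)
    matrix = scipy.sparse.csr_matrix(scipy.io.mmread(str(prefix) + ".mtx"))
    rows = pd.read_csv(str(prefix) + ".rows.tsv", sep="\t", dtype={"patient_id": str})
    if "timestamp" in rows.columns:
        rows["timestamp"] = parse_timestamps(rows["timestamp"])
    cols = pd.read_csv(str(prefix) + ".cols.tsv", sep="\t", keep_default_na=False)
    return matrix, rows, cols


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def read_json(path: str | Path):
    return json.loads(Path(path).read_text())
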