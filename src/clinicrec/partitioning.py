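"""Patient-disjoint train/validation/test splitting with temporal subsetting.

Rows from one patient are strongly correlated, so the split is by *patient*:
a seeded shuffle assigns each patient to exactly one partition at the 70/15/15
default fractions.  On top of the patient split, calendar cuts remove rows
that could leak across time: training keeps only rows before the training
cutoff, validation only rows inside the validation year, test only rows from
the test start onward.  Rows outside their partition's calendar range are
dropped entirely.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse

PARTITIONS = ("train", "val", "test")


@dataclass(frozen=True)
class SplitSpec:
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15)
    train_before: pd.Timestamp = pd.Timestamp("2011-01-01")
    val_year: int = 2011
    test_from: pd.Timestamp = pd.Timestamp("2012-01-01")
    seed: int = 0

    def __post_init__(self) -> None:
        if any(f <= 0 for f in self.fractions):
            raise ValueError("fractions must be positive")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")
        if not (self.train_before <= pd.Timestamp(f"{self.val_year}-01-01") < self.test_from):
            raise ValueError("temporal cuts must be ordered train < val-year < test")


def split_patients(patient_ids, spec: SplitSpec = SplitSpec()) -> dict[str, str]:
    """Assign each patient to train/val/test by seeded shuffle + contiguous
    slicing.  Deterministic given the seed; partition sizes are within one
    patient of ``fraction * n``."""
    ids = sorted(set(patient_ids))
    n = len(ids)
    if n < 3:
        raise ValueError(f"need at least 3 patients to form 3 partitions, got {n}")
    rng = np.random.default_rng(spec.seed)
    order = rng.permutation(n)
    n_train = int(round(spec.fractions[0] * n))
    n_val = int(round(spec.fractions[1] * n))
    n_train = min(n_train, n - 2)
    n_val = max(1, min(n_val, n - n_train - 1))
    assignment = {}
    for rank, idx in enumerate(order):
        if rank < n_train:
            part = "train"
        elif rank < n_train + n_val:
            part = "val"
        else:
            part = "test"
        assignment[ids[idx]] = part
    return assignment


def apply_temporal_filter(
    row_index: pd.DataFrame,
    assignment: dict[str, str],
    spec: SplitSpec = SplitSpec(),
) -> dict[str, np.ndarray]:
    """Return, per partition, the positional indices of rows that survive both
    the patient assignment and the partition's calendar range."""
    parts = row_index["patient_id"].map(assignment)
    ts = row_index["timestamp"]
    out = {}
    keep_train = (parts == "train") & (ts < spec.train_before)
    keep_val = (parts == "val") & (ts.dt.year == spec.val_year)
    keep_test = (parts == "test") & (ts >= spec.test_from)
    for name, mask in (("train", keep_train), ("val", keep_val), ("test", keep_test)):
        out[name] = np.flatnonzero(mask.to_numpy())
    return out


def filter_orderset_task_rows(
    row_positions: np.ndarray, orderset_responses: scipy.sparse.spmatrix
) -> np.ndarray:
    """Keep only rows with at least one order-set usage in the next 24 hours.

    The order-set task is evaluated on rows where a template was actually
    used; all-zero label rows are uninformative for it and are dropped.
    ``row_positions`` indexes into the full response matrix.
    """
    row_positions = np.asarray(row_positions)
    if row_positions.size and row_positions.max() >= orderset_responses.shape[0]:
        raise ValueError(
            f"row position {row_positions.max()} out of range for response matrix "
            f"with {orderset_responses.shape[0]} rows"
        )
    sums = np.asarray(orderset_responses.sum(axis=1)).ravel()
    return row_positions[sums[row_positions] >= 1]
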