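"""Core domain types for clinical event streams and vocabulary construction.

An *event stream* is the atomic substrate of the package: one row per clinical
item entry — a patient id, an item id, the item's category, a timestamp, and
(for orders placed from within an institutional order-set template) the id of
the source order set.  In-memory the stream is a :class:`pandas.DataFrame`
with the columns of :data:`EVENT_COLUMNS`; the dataclasses here give names to
the row-level concepts and carry their invariants.
"""

from __future__ import annotations

import re
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

#: Recognized clinical item categories.
CATEGORIES = frozenset(
    {
        "medication_order",
        "lab_result",
        "diagnosis_code",
        "treatment_team",
        "demographic",
        "nursing_order",
        "other_order",
    }
)

#: Categories a physician can order. Nursing orders are deliberately not
#: orderable recommendation targets: they mostly reflect standard process
#: templates (e.g. "check vital signs") rather than decisions to anticipate.
ORDERABLE_CATEGORIES = frozenset({"medication_order", "other_order"})

#: Categories excluded by default when building the order vocabulary.
DEFAULT_EXCLUDED_CATEGORIES = frozenset(
    {"nursing_order", "diagnosis_code", "lab_result", "treatment_team", "demographic"}
)

#: Column order of the canonical event-stream DataFrame / TSV.
EVENT_COLUMNS = ["patient_id", "item_id", "category", "timestamp", "source_order_set_id"]


@dataclass(frozen=True)
class ClinicalItem:
    """Anything recordable in the EHR for a patient: a medication order, a
    resulted lab test, a diagnosis code, a treatment team, a demographic
    attribute."""

    item_id: str
    category: str

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r} for item {self.item_id!r}")

    @property
    def orderable(self) -> bool:
        return self.category in ORDERABLE_CATEGORIES


@dataclass(frozen=True)
class ClinicalEvent:
    """A single timestamped clinical item entry for a patient — the unit that
    generates one feature/response row downstream."""

    patient_id: str
    item_id: str
    category: str
    timestamp: pd.Timestamp
    source_order_set_id: str | None = None

    def __post_init__(self) -> None:
        ts = pd.Timestamp(self.timestamp)
        if pd.isna(ts):
            raise ValueError(f"non-finite timestamp for event of {self.item_id!r}")
        if self.source_order_set_id is not None and self.category not in ORDERABLE_CATEGORIES:
            raise ValueError(
                f"source_order_set_id set on non-orderable event {self.item_id!r} "
                f"(category {self.category!r})"
            )


@dataclass(frozen=True)
class OrderSetDefinition:
    """An institution-authored template bundling orderable items for a clinical
    scenario; selecting it can place many orders at once."""

    order_set_id: str
    member_items: frozenset[str]

    def __post_init__(self) -> None:
        if not self.member_items:
            raise ValueError(f"order set {self.order_set_id!r} has no member items")


@dataclass
class PatientRecord:
    """A patient as a time-ordered sequence of clinical item entries, plus
    timestamp-free demographic attributes and the admission-diagnosis log."""

    patient_id: str
    events: list[ClinicalEvent] = field(default_factory=list)
    demographics: dict[str, object] = field(default_factory=dict)
    admission_events: list[tuple[pd.Timestamp, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        stamps = [e.timestamp for e in self.events]
        if any(b < a for a, b in zip(stamps, stamps[1:])):
            raise ValueError(f"events of patient {self.patient_id!r} are not time-sorted")


# plain codes have 3-digit stems; V-codes V + 2 digits; E-codes E + 3 digits
_ICD_PATTERN = re.compile(r"^(?P<stem>V\d{2}|E\d{3}|\d{3})(?:\.(?P<decimals>\d+))?$")


def expand_icd_hierarchy(code: str) -> list[str]:
    """Expand an ICD9-style diagnosis code into itself plus every truncation
    down to its 3-digit stem, most specific first.

    ``"786.05"`` becomes ``["786.05", "786.0", "786"]`` — each level of the
    coding hierarchy counts as its own clinical item, so a specific diagnosis
    also activates its broader parents.  Letter prefixes (V/E codes) stay
    attached to the stem.

    Raises
    ------
    ValueError
        If ``code`` does not look like an ICD9 code (3-digit stem with an
        optional V/E prefix and optional decimal digits).
    """
    m = _ICD_PATTERN.match(code.strip())
    if m is None:
        raise ValueError(f"malformed ICD9-style diagnosis code: {code!r}")
    stem = m.group("stem")
    decimals = m.group("decimals") or ""
    out = []
    for k in range(len(decimals), 0, -1):
        out.append(f"{stem}.{decimals[:k]}")
    out.append(stem)
    return out


class MedicationNormalizer:
    """Table-driven medication-name normalization to "Ingredient(s) (Route)".

    Brand and generic names that denote the same active-ingredient/route
    combination must collapse to one item id (e.g. Norco and Vicodin pills are
    both acetaminophen-hydrocodone by mouth).  The mapping is a user-supplied
    raw-name → ingredient table; unmapped names pass through verbatim and are
    tallied in :attr:`unmapped` so callers can audit coverage.
    """

    def __init__(self, mapping: Mapping[str, str] | None = None):
        self.mapping = dict(mapping or {})
        self.unmapped: Counter[str] = Counter()

    @property
    def unmapped_count(self) -> int:
        return sum(self.unmapped.values())

    def normalize(self, raw_name: str, route: str) -> str:
        if not raw_name:
            raise ValueError("empty medication name")
        ingredient = self.mapping.get(raw_name)
        if ingredient is None:
            self.unmapped[raw_name] += 1
            ingredient = raw_name
        return f"{ingredient} ({route})"


def load_demo_medication_table() -> dict[str, str]:
    """Small bundled brand-name → ingredient table for demos and tests.

    Real deployments supply their own terminology mapping; this table only
    covers a handful of common brands.
    """
    import csv
    from importlib.resources import files

    text = files("clinicrec.data").joinpath("medication_demo.tsv").read_text()
    rows = list(csv.reader(text.splitlines(), delimiter="\t"))
    return {raw: ing for raw, ing in rows[1:]}


def normalize_medication(
    raw_name: str, route: str, mapping: Mapping[str, str], normalizer: MedicationNormalizer | None = None
) -> str:
    """Functional convenience wrapper around :class:`MedicationNormalizer`."""
    if normalizer is None:
        normalizer = MedicationNormalizer(mapping)
    return normalizer.normalize(raw_name, route)


def build_order_vocabulary(
    events: pd.DataFrame,
    min_count: int = 256,
    excluded_categories: Iterable[str] = DEFAULT_EXCLUDED_CATEGORIES,
) -> set[str]:
    """Select the orderable items frequent enough to model.

    Clinical order usage is heavy-tailed (a small fraction of the catalogue
    accounts for the vast majority of order volume), so items with fewer than
    ``min_count`` total entries are dropped to control sparsity while keeping
    most of the order volume.  Non-order categories and nursing orders are
    excluded outright.

    Parameters
    ----------
    events
        Event stream with at least ``item_id`` and ``category`` columns.
    min_count
        Minimum number of entries an item needs to be kept (default 256).
    excluded_categories
        Categories removed before counting, in addition to anything
        non-orderable.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    excluded = set(excluded_categories)
    if events.empty:
        return set()
    keep = events["category"].isin(ORDERABLE_CATEGORIES - excluded)
    counts = events.loc[keep, "item_id"].value_counts()
    return set(counts.index[counts >= min_count])
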