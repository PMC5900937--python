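"""Binary screening-indicator matrices and item catalogs.

The analysis unit is a *transaction matrix*: one row per patient, one 0/1
column per screening item, where 1 means the screen (blood pressure reading,
lipid panel, smoking status, ...) is present in the patient's record within
its lookback window. Absence of a record is encoded 0; there is no separate
missing-data state, because presence of the screen is itself the quantity
under study.

The :class:`ItemCatalog` carries the item order and the grouping of items
into clinical categories (vitals, laboratory, lifestyle) used for
category-level ("multilevel") analyses.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ItemCatalog",
    "TransactionMatrix",
    "study_catalog",
    "load_transactions",
    "save_transactions",
    "item_prevalence",
    "categorize",
    "venn_counts",
    "binary_correlation_matrix",
]

#: Canonical study items in reporting order.
STUDY_ITEMS = (
    "BP", "BMI", "WC", "LDL", "A1c", "smoking", "alcohol", "diet", "exercise",
)

STUDY_CATEGORIES: dict[str, str] = {
    "BP": "vitals",
    "BMI": "vitals",
    "WC": "vitals",
    "LDL": "laboratory",
    "A1c": "laboratory",
    "smoking": "lifestyle",
    "alcohol": "lifestyle",
    "diet": "lifestyle",
    "exercise": "lifestyle",
}

STUDY_DESCRIPTIONS: dict[str, str] = {
    "BP": "Blood pressure measured in past 2 years",
    "BMI": "Body mass index measured in past 2 years",
    "WC": "Waist circumference measured in past 2 years",
    "LDL": "Low-density lipoprotein measured in past 3 years",
    "A1c": "Fasting blood glucose or haemoglobin A1c measured in past 3 years",
    "smoking": "Smoking information in the summary health profile",
    "alcohol": "Alcohol information in the summary health profile",
    "diet": "Diet information in the summary health profile",
    "exercise": "Exercise information in the summary health profile",
}


@dataclass(frozen=True)
class ItemCatalog:
    """Ordered item list with a category per item.

    Parameters
    ----------
    items
        Ordered, unique item identifiers.
    category_of
        Mapping item -> category label; every item must be present.
    description
        Optional free text per item (e.g. the lookback window).
    """

    items: tuple[str, ...]
    category_of: Mapping[str, str]
    description: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.items)) != len(self.items):
            raise ValueError("item identifiers must be unique")
        missing = [i for i in self.items if i not in self.category_of]
        if missing:
            raise ValueError(f"items without a category: {missing}")

    @property
    def categories(self) -> tuple[str, ...]:
        """Distinct categories in order of first appearance."""
        seen: dict[str, None] = {}
        for item in self.items:
            seen.setdefault(self.category_of[item], None)
        return tuple(seen)

    def items_in(self, category: str) -> tuple[str, ...]:
        return tuple(i for i in self.items if self.category_of[i] == category)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "items": list(self.items),
            "category_of": dict(self.category_of),
            "description": dict(self.description),
        }
        Path(path).write_text(json.dumps(payload, indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "ItemCatalog":
        payload = json.loads(Path(path).read_text())
        return cls(
            items=tuple(payload["items"]),
            category_of=payload["category_of"],
            description=payload.get("description", {}),
        )


def study_catalog() -> ItemCatalog:
    """The 9-item catalog of the study: 3 vitals, 2 laboratory, 4 lifestyle."""
    return ItemCatalog(STUDY_ITEMS, STUDY_CATEGORIES, STUDY_DESCRIPTIONS)


@dataclass(frozen=True)
class TransactionMatrix:
    """n patients x m items, values strictly 0/1."""

    patient_ids: tuple[str, ...]
    items: tuple[str, ...]
    values: np.ndarray  # (n, m) uint8

    def __post_init__(self) -> None:
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise ValueError("values must be 2-dimensional")
        if values.shape != (len(self.patient_ids), len(self.items)):
            raise ValueError(
                f"shape {values.shape} inconsistent with "
                f"{len(self.patient_ids)} patients x {len(self.items)} items"
            )
        bad = ~np.isin(values, (0, 1))
        if bad.any():
            row = int(np.argwhere(bad)[0, 0])
            raise ValueError(f"non-binary value at data row {row}")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("patient_ids must be unique")
        if len(set(self.items)) != len(self.items):
            raise ValueError("item identifiers must be unique")
        object.__setattr__(self, "values", values.astype(np.uint8))

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    @property
    def m(self) -> int:
        return len(self.items)

    def column(self, item: str) -> np.ndarray:
        try:
            j = self.items.index(item)
        except ValueError:
            raise KeyError(f"unknown item {item!r}") from None
        return self.values[:, j]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=list(self.items))
        df.insert(0, "patient_id", list(self.patient_ids))
        return df

    @classmethod
    def from_arrays(
        cls,
        values: np.ndarray | Sequence[Sequence[int]],
        items: Sequence[str],
        patient_ids: Sequence[str] | None = None,
    ) -> "TransactionMatrix":
        values = np.asarray(values)
        if patient_ids is None:
            patient_ids = tuple(f"P{i + 1}" for i in range(values.shape[0]))
        return cls(tuple(patient_ids), tuple(items), values)


def load_transactions(path: str | Path, catalog: ItemCatalog) -> TransactionMatrix:
    """Read a CSV transaction matrix (header row, first column patient_id).

    Columns are re-ordered to the catalog's item order. A missing item column
    raises a format error naming the column; a non-binary cell raises a
    validation error with its data-row index.
    """
    df = pd.read_csv(path, dtype=str)
    if df.columns[0] != "patient_id":
        raise ValueError("first column must be 'patient_id'")
    for item in catalog.items:
        if item not in df.columns:
            raise ValueError(f"missing item column {item!r}")
    raw = df[list(catalog.items)].to_numpy()
    values = np.zeros(raw.shape, dtype=np.uint8)
    for (i, j), cell in np.ndenumerate(raw):
        if cell == "0":
            continue
        if cell == "1":
            values[i, j] = 1
        else:
            raise ValueError(
                f"non-binary value {cell!r} at data row {i}, column "
                f"{catalog.items[j]!r}"
            )
    return TransactionMatrix(
        tuple(df["patient_id"].astype(str)), tuple(catalog.items), values
    )


def save_transactions(T: TransactionMatrix, path: str | Path) -> None:
    """Write the standard CSV dialect; round-trips bit-exactly via load."""
    T.to_frame().to_csv(path, index=False)


def item_prevalence(T: TransactionMatrix) -> pd.Series:
    """Proportion of patients with each item present, indexed by item."""
    if T.n == 0:
        raise ValueError("empty transaction matrix")
    return pd.Series(T.values.mean(axis=0), index=list(T.items), name="prevalence")


def categorize(T: TransactionMatrix, catalog: ItemCatalog) -> TransactionMatrix:
    """Collapse items to category indicators: 1 iff any member item is 1."""
    unknown = [i for i in T.items if i not in catalog.category_of]
    if unknown:
        raise ValueError(f"items without a category: {unknown}")
    cats = catalog.categories
    cols = []
    for cat in cats:
        members = [i for i in catalog.items_in(cat) if i in T.items]
        if not members:
            raise ValueError(f"category {cat!r} has no items in the matrix")
        stacked = np.column_stack([T.column(i) for i in members])
        cols.append(stacked.any(axis=1).astype(np.uint8))
    return TransactionMatrix(T.patient_ids, cats, np.column_stack(cols))


def venn_counts(T: TransactionMatrix, items: Iterable[str]) -> dict[tuple[int, ...], int]:
    """Patient counts for every presence/absence region of 2-4 items.

    Keys are 0/1 tuples aligned with ``items``; e.g. for items (a, b) the key
    (1, 0) is the "a only" region and (0, 0) the all-absent region. Counts
    over all 2^k regions sum to n.
    """
    items = list(items)
    if not 2 <= len(items) <= 4:
        raise ValueError("venn_counts requires between 2 and 4 items")
    if T.n == 0:
        raise ValueError("empty transaction matrix")
    cols = np.column_stack([T.column(i) for i in items])
    out: dict[tuple[int, ...], int] = {}
    for pattern in itertools.product((0, 1), repeat=len(items)):
        out[pattern] = int((cols == np.array(pattern)).all(axis=1).sum())
    return out


def binary_correlation_matrix(T: TransactionMatrix) -> pd.DataFrame:
    """Product-moment (phi) correlation matrix of the indicator columns.

    This is the observed-scale correlation; the latent-scale (tetrachoric)
    analogue lives in :mod:`screenmine.latent`.
    """
    values = T.values.astype(float)
    sd = values.std(axis=0)
    constant = np.flatnonzero(sd == 0)
    if constant.size:
        raise ValueError(f"constant column: {T.items[constant[0]]!r}")
    r = np.corrcoef(values, rowvar=False)
    np.fill_diagonal(r, 1.0)
    return pd.DataFrame(r, index=list(T.items), columns=list(T.items))
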