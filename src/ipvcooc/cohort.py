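"""Loading, validation, filtering and scoring of the survivor-by-item matrix.

The central object is a survivor x item response matrix with ordinal entries
in {0..4} (0 = never, 4 = more than fifty times in the past year).  Survivors
who report no incident on any of the 39 violence items are removed before any
analysis; per-type scores are the arithmetic mean of a survivor's responses
over the items assigned to that type.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .items import ITEM_DEFS, REASSIGNMENTS, assigned_type

logger = logging.getLogger(__name__)

#: The four violence types, in canonical order.
TYPES: tuple[str, ...] = ("PV", "PA", "SV", "MA")

VALID_RESPONSES = frozenset(range(5))


@dataclass
class ResponseMatrix:
    """Survivors x items ordinal response matrix with entries in {0..4}."""

    survivor_ids: list[str]
    item_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        n, m = self.values.shape
        if n != len(self.survivor_ids) or m != len(self.item_ids):
            raise ValueError(
                f"shape {self.values.shape} inconsistent with "
                f"{len(self.survivor_ids)} survivors x {len(self.item_ids)} items"
            )
        if len(set(self.survivor_ids)) != n:
            raise ValueError("duplicate survivor IDs")
        if len(set(self.item_ids)) != m:
            raise ValueError("duplicate item IDs")
        bad = (self.values < 0) | (self.values > 4)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"response out of range {{0..4}}: value {self.values[i, j]} at "
                f"survivor {self.survivor_ids[i]!r}, item {self.item_ids[j]!r}"
            )
        self.values = self.values.astype(np.int64)

    @property
    def n_survivors(self) -> int:
        return len(self.survivor_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.survivor_ids, name="survivor_id"),
            columns=self.item_ids,
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ResponseMatrix":
        return cls(
            survivor_ids=[str(i) for i in df.index],
            item_ids=[str(c) for c in df.columns],
            values=df.to_numpy(),
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path)


@dataclass
class ItemCatalog:
    """Item ID -> label, original subscale, assigned violence type.

    ``table`` has columns item_id, label, original_type, assigned_type.
    """

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"item_id", "label", "original_type", "assigned_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"catalog missing columns: {sorted(missing)}")
        if self.table["item_id"].duplicated().any():
            dup = self.table.loc[self.table["item_id"].duplicated(), "item_id"].iloc[0]
            raise ValueError(f"duplicate item ID in catalog: {dup!r}")
        bad = ~self.table["assigned_type"].isin(TYPES)
        if bad.any():
            raise ValueError(
                f"unknown assigned type {self.table.loc[bad, 'assigned_type'].iloc[0]!r}"
            )
        self.table = self.table.reset_index(drop=True)

    @classmethod
    def default(cls, reassigned: bool = True) -> "ItemCatalog":
        """The built-in 39-item catalog, before or after item reassignment."""
        rows = []
        for orig_id, new_id, orig_type, label in ITEM_DEFS:
            if reassigned:
                rows.append((new_id, label, orig_type, assigned_type(new_id)))
            else:
                rows.append((orig_id, label, orig_type, orig_type))
        return cls(pd.DataFrame(rows, columns=["item_id", "label", "original_type", "assigned_type"]))

    def items_for(self, violence_type: str) -> list[str]:
        sel = self.table["assigned_type"] == violence_type
        return self.table.loc[sel, "item_id"].tolist()

    def assigned_counts(self) -> dict[str, int]:
        counts = self.table["assigned_type"].value_counts().to_dict()
        return {t: int(counts.get(t, 0)) for t in TYPES}

    def type_of(self) -> dict[str, str]:
        return dict(zip(self.table["item_id"], self.table["assigned_type"]))

    def to_json(self, path) -> None:
        self.table.to_json(path, orient="records", indent=2)

    @classmethod
    def read(cls, path) -> "ItemCatalog":
        path = str(path)
        if path.endswith(".json"):
            return cls(pd.read_json(path, orient="records"))
        return cls(pd.read_csv(path))


def load_matrix(path, missing_policy: str = "zero") -> ResponseMatrix:
    """Read a response CSV (first column survivor ID, header row of item IDs).

    Blank cells are imputed as 0 (= "never") under ``missing_policy='zero'``
    (the count is logged) or rejected under ``missing_policy='strict'``.
    Out-of-range or non-integer values raise with their coordinates.
    """
    if missing_policy not in ("zero", "strict"):
        raise ValueError(f"unknown missing_policy {missing_policy!r}")
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    n_missing = int(df.isna().to_numpy().sum())
    if n_missing:
        if missing_policy == "strict":
            raise ValueError(f"{n_missing} missing cells under strict policy")
        logger.info("imputed %d missing responses as 0", n_missing)
        df = df.fillna(0)
    arr = df.to_numpy()
    if not np.issubdtype(arr.dtype, np.number):
        raise ValueError("non-numeric response values in matrix")
    if not np.allclose(arr, np.round(arr)):
        i, j = np.argwhere(~np.isclose(arr, np.round(arr)))[0]
        raise ValueError(
            f"non-integer response {arr[i, j]} at survivor {df.index[i]!r}, "
            f"item {df.columns[j]!r}"
        )
    return ResponseMatrix.from_frame(df.round().astype(np.int64))


def apply_reassignment(catalog: ItemCatalog) -> ItemCatalog:
    """Move the three reassigned items to their working violence types.

    PA3 becomes the micro-aggression item MA1, PV1 ("made threats to
    physically harm") moves to psychological aggression as PA6, and PV8
    ("forced you to engage in sexual activity") moves to sexual violence as
    SV22.  Applying the operation to an already-reassigned catalog is a
    no-op; a catalog missing a referenced item raises.
    """
    table = catalog.table.copy()
    ids = set(table["item_id"])
    if all(orig not in ids for orig in REASSIGNMENTS):
        # Possibly already reassigned: every target ID must be present with
        # the right type.
        by_id = dict(zip(table["item_id"], table["assigned_type"]))
        for orig, (new_id, new_type) in REASSIGNMENTS.items():
            if by_id.get(new_id) != new_type:
                raise ValueError(
                    f"catalog has neither original item {orig!r} nor "
                    f"reassigned item {new_id!r} of type {new_type}"
                )
        return ItemCatalog(table)
    for orig, (new_id, new_type) in REASSIGNMENTS.items():
        if orig not in ids:
            raise ValueError(f"catalog missing item {orig!r} required for reassignment")
        sel = table["item_id"] == orig
        table.loc[sel, "item_id"] = new_id
        table.loc[sel, "assigned_type"] = new_type
    return ItemCatalog(table)


def filter_survivors(matrix: ResponseMatrix) -> ResponseMatrix:
    """Retain survivors who responded 1-4 to at least one item.

    Row order is preserved.  An empty result is returned with a warning,
    not an error.
    """
    keep = (matrix.values > 0).any(axis=1)
    n_keep = int(keep.sum())
    logger.info("filter_survivors: retained %d of %d survivors", n_keep, matrix.n_survivors)
    if n_keep == 0:
        warnings.warn("no survivor reports any incident; empty cohort", stacklevel=2)
    return ResponseMatrix(
        survivor_ids=[s for s, k in zip(matrix.survivor_ids, keep) if k],
        item_ids=list(matrix.item_ids),
        values=matrix.values[keep],
    )


def compute_type_scores(matrix: ResponseMatrix, catalog: ItemCatalog) -> pd.DataFrame:
    """Per-survivor mean response over each type's assigned items.

    Returns a DataFrame indexed by survivor ID with columns PV, PA, SV, MA,
    each score in [0, 4].  The MA score equals the single MA item response.
    """
    unknown = set(matrix.item_ids) - set(catalog.table["item_id"])
    if unknown:
        raise ValueError(f"matrix items not in catalog: {sorted(unknown)}")
    df = matrix.to_frame()
    scores = {}
    for t in TYPES:
        cols = [c for c in catalog.items_for(t) if c in df.columns]
        if not cols:
            raise ValueError(f"no items assigned to type {t} present in the matrix")
        scores[t] = df[cols].mean(axis=1)
    return pd.DataFrame(scores)


def item_frequencies(matrix: ResponseMatrix) -> pd.Series:
    """Fraction of survivors with a nonzero response, per item."""
    freq = (matrix.values > 0).mean(axis=0) if matrix.n_survivors else np.zeros(matrix.n_items)
    return pd.Series(freq, index=matrix.item_ids, name="frequency")
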