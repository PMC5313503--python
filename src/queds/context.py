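"""Clinical contexts: the items x attributes Boolean incidence structure.

A *clinical context* relates questionnaire items (objects) to the clinical
criteria (attributes) they investigate, as a 0/1 incidence matrix.  This
module defines the data model, the built-in QuEDS instrument, CSV/JSON
serialization, structural validation (no empty rows or columns), factor
subcontexts and coverage, and the Cohen kappa agreement statistic used when
several experts fill the incidence matrix independently.
"""

from __future__ import annotations

import csv
import json
import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

import numpy as np
import pandas as pd

from . import instrument
from .errors import ContextParseError, ValidationError

__all__ = [
    "Attribute",
    "Item",
    "ClinicalContext",
    "FactorDefinition",
    "ValidationReport",
    "builtin_queds",
    "read_context",
    "write_context",
    "validate_context",
    "subcontext",
    "attribute_coverage",
    "cohen_kappa",
    "mean_pairwise_kappa",
]


@dataclass(frozen=True)
class Attribute:
    """A clinical criterion (e.g. ``A7`` = agitation)."""

    id: str
    label: str
    source: str = "literature"

    def __post_init__(self) -> None:
        if not self.id:
            raise ValidationError("attribute id must be non-empty")
        if not self.label:
            raise ValidationError(f"attribute {self.id!r}: label must be non-empty")


@dataclass(frozen=True)
class Item:
    """A questionnaire item together with the attribute set it investigates."""

    id: int
    text: str
    intent: frozenset[str]

    def __post_init__(self) -> None:
        object.__setattr__(self, "intent", frozenset(self.intent))


@dataclass(frozen=True)
class FactorDefinition:
    """A named subscale: the set of item ids loading on one factor."""

    name: str
    item_ids: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(self, "item_ids", frozenset(self.item_ids))


@dataclass(frozen=True)
class ClinicalContext:
    """Ordered items and attributes; incidence row i is item i's intent.

    Item intents may reference only declared attributes and ids must be
    unique.  Empty intents (all-zero rows) and uninvestigated attributes
    (all-zero columns) are representable — they are *reported* by
    :func:`validate_context`, not rejected here, so that defective expert
    matrices can be loaded and examined.
    """

    items: tuple[Item, ...]
    attributes: tuple[Attribute, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", tuple(self.items))
        object.__setattr__(self, "attributes", tuple(self.attributes))
        item_ids = [it.id for it in self.items]
        if len(set(item_ids)) != len(item_ids):
            dupes = sorted({i for i in item_ids if item_ids.count(i) > 1})
            raise ValidationError(f"duplicate item ids: {dupes}")
        attr_ids = [a.id for a in self.attributes]
        if len(set(attr_ids)) != len(attr_ids):
            raise ValidationError("duplicate attribute ids")
        known = set(attr_ids)
        for it in self.items:
            unknown = it.intent - known
            if unknown:
                raise ValidationError(
                    f"item {it.id}: intent references unknown attributes {sorted(unknown)}"
                )

    # -- lookups -----------------------------------------------------------
    @property
    def item_ids(self) -> tuple[int, ...]:
        return tuple(it.id for it in self.items)

    @property
    def attribute_ids(self) -> tuple[str, ...]:
        return tuple(a.id for a in self.attributes)

    def item(self, item_id: int) -> Item:
        for it in self.items:
            if it.id == item_id:
                return it
        raise ValidationError(f"unknown item id {item_id}")

    def intent(self, item_id: int) -> frozenset[str]:
        return self.item(item_id).intent

    def incidence(self) -> np.ndarray:
        """The 0/1 incidence matrix, items in rows, attributes in columns."""
        cols = {a: j for j, a in enumerate(self.attribute_ids)}
        m = np.zeros((len(self.items), len(self.attributes)), dtype=np.int8)
        for i, it in enumerate(self.items):
            for a in it.intent:
                m[i, cols[a]] = 1
        return m

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.incidence(), index=list(self.item_ids), columns=list(self.attribute_ids)
        )


@dataclass(frozen=True)
class ValidationReport:
    """Structural defects of a context; empty everywhere for a sound one."""

    empty_rows: frozenset[int] = field(default_factory=frozenset)
    empty_cols: frozenset[str] = field(default_factory=frozenset)
    duplicate_rows: frozenset[int] = field(default_factory=frozenset)

    @property
    def ok(self) -> bool:
        # duplicate intents are informational (distinct items may legitimately
        # probe the same criterion), so they do not fail the report
        return not self.empty_rows and not self.empty_cols


@lru_cache(maxsize=1)
def builtin_queds() -> tuple[ClinicalContext, tuple[FactorDefinition, FactorDefinition, FactorDefinition]]:
    """The built-in 41-item, 23-attribute QuEDS and its factor partition.

    Returns the instrument's clinical context (rows ordered 1..41, columns
    A1..A23) and the (cognitive, somatic, affective) factor definitions.
    """
    attributes = tuple(
        Attribute(aid, label, source)
        for aid, (label, source) in instrument.ATTRIBUTE_TABLE.items()
    )
    items = tuple(
        Item(iid, text, frozenset(intent))
        for iid, (text, intent) in sorted(instrument.ITEM_TABLE.items())
    )
    ctx = ClinicalContext(items, attributes)
    factors = tuple(
        FactorDefinition(name, ids) for name, ids in instrument.FACTOR_ITEMS.items()
    )
    return ctx, factors  # type: ignore[return-value]


# ---------------------------------------------------------------------------
# validation & restriction


def validate_context(ctx: ClinicalContext) -> ValidationReport:
    """Report empty rows, empty columns and duplicated item intents."""
    empty_rows = frozenset(it.id for it in ctx.items if not it.intent)
    used = frozenset().union(*[it.intent for it in ctx.items]) if ctx.items else frozenset()
    empty_cols = frozenset(a for a in ctx.attribute_ids if a not in used)
    by_intent: dict[frozenset[str], list[int]] = {}
    for it in ctx.items:
        by_intent.setdefault(it.intent, []).append(it.id)
    duplicates = frozenset(
        i for ids in by_intent.values() if len(ids) > 1 for i in ids
    )
    return ValidationReport(empty_rows, empty_cols, duplicates)


def subcontext(ctx: ClinicalContext, item_ids: Iterable[int]) -> ClinicalContext:
    """Restrict to the given items and to the attributes they still investigate."""
    wanted = set(item_ids)
    if not wanted:
        raise ValidationError("subcontext requires a non-empty item set")
    unknown = wanted - set(ctx.item_ids)
    if unknown:
        raise ValidationError(f"unknown item ids: {sorted(unknown)}")
    items = tuple(it for it in ctx.items if it.id in wanted)
    used = frozenset().union(*[it.intent for it in items])
    attributes = tuple(a for a in ctx.attributes if a.id in used)
    return ClinicalContext(items, attributes)


def attribute_coverage(
    ctx: ClinicalContext, factors: Sequence[FactorDefinition]
) -> dict[str, frozenset[str]]:
    """Map each attribute to the factors whose subcontext retains it.

    The factor item sets must partition the context's items.
    """
    union: set[int] = set()
    total = 0
    for f in factors:
        union |= f.item_ids
        total += len(f.item_ids)
    if union != set(ctx.item_ids) or total != len(ctx.item_ids):
        raise ValidationError("factor definitions must partition the context items")
    coverage: dict[str, set[str]] = {a: set() for a in ctx.attribute_ids}
    for f in factors:
        for it in ctx.items:
            if it.id in f.item_ids:
                for a in it.intent:
                    coverage[a].add(f.name)
    return {a: frozenset(names) for a, names in coverage.items()}


# ---------------------------------------------------------------------------
# serialization

_CSV_HEAD = ("item_id", "text")


def write_context(ctx: ClinicalContext, path: str | Path) -> None:
    """Write a context as CSV (incidence) or JSON (full fidelity) by extension."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        doc = {
            "items": [
                {"id": it.id, "text": it.text, "attributes": sorted(it.intent)}
                for it in ctx.items
            ],
            "attributes": [
                {"id": a.id, "label": a.label, "source": a.source}
                for a in ctx.attributes
            ],
        }
        path.write_text(json.dumps(doc, indent=1), encoding="utf-8")
        return
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(list(_CSV_HEAD) + list(ctx.attribute_ids))
        for it in ctx.items:
            w.writerow(
                [it.id, it.text] + [1 if a in it.intent else 0 for a in ctx.attribute_ids]
            )


def read_context(path: str | Path) -> ClinicalContext:
    """Read a context written by :func:`write_context` (CSV or JSON)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        return _read_json(path)
    return _read_csv(path)


def _read_json(path: Path) -> ClinicalContext:
    try:
        doc = json.loads(path.read_text(encoding="utf-8"))
        attributes = tuple(
            Attribute(a["id"], a["label"], a.get("source", "literature"))
            for a in doc["attributes"]
        )
        items = tuple(
            Item(int(it["id"]), it.get("text", ""), frozenset(it["attributes"]))
            for it in doc["items"]
        )
    except (KeyError, TypeError, ValueError, json.JSONDecodeError) as exc:
        raise ContextParseError(f"{path}: malformed context JSON ({exc})") from exc
    return ClinicalContext(items, attributes)


def _read_csv(path: Path) -> ClinicalContext:
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ContextParseError(f"{path}: empty file")
    header = rows[0]
    if len(header) < 3 or header[0] != "item_id":
        raise ContextParseError(
            f"{path}: missing header (expected 'item_id,text,<attribute ids...>')"
        )
    has_text = header[1] == "text"
    attr_ids = header[2:] if has_text else header[1:]
    if not attr_ids:
        raise ContextParseError(f"{path}: header declares no attribute columns")
    items = []
    for r, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        try:
            iid = int(row[0])
        except ValueError as exc:
            raise ContextParseError(f"{path}: row {r}: bad item id {row[0]!r}") from exc
        text = row[1] if has_text else ""
        cells = row[2:] if has_text else row[1:]
        if len(cells) != len(attr_ids):
            raise ContextParseError(
                f"{path}: row {r}: expected {len(attr_ids)} incidence cells, got {len(cells)}"
            )
        intent = set()
        for a, cell in zip(attr_ids, cells):
            if cell not in ("0", "1"):
                raise ContextParseError(
                    f"{path}: row {r}, column {a}: cell must be 0 or 1, got {cell!r}"
                )
            if cell == "1":
                intent.add(a)
        items.append(Item(iid, text, frozenset(intent)))
    attributes = tuple(Attribute(a, a) for a in attr_ids)
    return ClinicalContext(tuple(items), attributes)


# ---------------------------------------------------------------------------
# expert agreement


def cohen_kappa(m1: np.ndarray, m2: np.ndarray) -> float:
    """Cell-wise Cohen kappa between two 0/1 matrices of equal shape.

    Returns NaN when the chance agreement is 1 (both raters constant and
    identical), where kappa is undefined.
    """
    a = np.asarray(m1)
    b = np.asarray(m2)
    if a.shape != b.shape:
        raise ValidationError(f"shape mismatch: {a.shape} vs {b.shape}")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ValidationError("kappa requires 0/1 matrices")
    a = a.ravel()
    b = b.ravel()
    n = a.size
    po = float(np.mean(a == b))
    p1a, p1b = float(a.mean()), float(b.mean())
    pe = p1a * p1b + (1 - p1a) * (1 - p1b)
    if math.isclose(pe, 1.0):
        return float("nan")
    return (po - pe) / (1 - pe)


def mean_pairwise_kappa(tables: Sequence[np.ndarray]) -> float:
    """Mean Cohen kappa over all unordered pairs of expert matrices."""
    if len(tables) < 2:
        raise ValidationError("need at least two matrices")
    ks = [
        cohen_kappa(tables[i], tables[j])
        for i in range(len(tables))
        for j in range(i + 1, len(tables))
    ]
    return float(np.mean(ks))
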