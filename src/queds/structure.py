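"""Formal-concept and knowledge-space machinery over a clinical context.

Given the Boolean item x attribute incidence, this module computes

* the Galois derivation operators (attributes common to a set of items,
  items possessing a set of attributes),
* all formal concepts, enumerated deterministically in lectic order by
  NextClosure,
* the prerequisite (surmise) quasi-order between items: ``i`` precedes
  ``j`` when every criterion of ``i`` is also carried by ``j``, so an
  affirmative answer to ``j`` presupposes the symptoms of ``i``,
* the delineated *clinical structure* under the conjunctive attribution
  model: endorsing an item entails possessing all of its attributes, hence
  the admissible response patterns are exactly K(S) = {q : intent(q) <= S}
  for S ranging over the attribute subsets.

Item and attribute sets are represented internally as fixed-width bit
masks over the context's declared ordering; the public API speaks in
``frozenset``s of item ids and attribute tokens.
"""

from __future__ import annotations

from collections.abc import Iterable
from dataclasses import dataclass
from typing import Callable

from .context import ClinicalContext
from .errors import StructureSizeError, ValidationError

__all__ = [
    "Concept",
    "PrerequisiteRelation",
    "ClinicalStructure",
    "derive_items",
    "derive_attrs",
    "formal_concepts",
    "prerequisites",
    "delineate",
    "is_state",
    "DEFAULT_STATE_CAP",
]

DEFAULT_STATE_CAP = 5_000_000


# ---------------------------------------------------------------------------
# bit-mask plumbing


class _Index:
    """Bit positions for a context's items and attributes."""

    def __init__(self, ctx: ClinicalContext) -> None:
        self.ctx = ctx
        self.item_ids = list(ctx.item_ids)
        self.attr_ids = list(ctx.attribute_ids)
        self.item_pos = {q: i for i, q in enumerate(self.item_ids)}
        self.attr_pos = {a: j for j, a in enumerate(self.attr_ids)}
        self.n_items = len(self.item_ids)
        self.n_attrs = len(self.attr_ids)
        self.all_items = (1 << self.n_items) - 1
        self.all_attrs = (1 << self.n_attrs) - 1
        # intent mask per item, in item order
        self.intents = [self._attr_mask(it.intent) for it in ctx.items]

    def _attr_mask(self, attrs: Iterable[str]) -> int:
        m = 0
        for a in attrs:
            try:
                m |= 1 << self.attr_pos[a]
            except KeyError:
                raise ValidationError(f"unknown attribute id {a!r}") from None
        return m

    def _item_mask(self, items: Iterable[int]) -> int:
        m = 0
        for q in items:
            try:
                m |= 1 << self.item_pos[q]
            except KeyError:
                raise ValidationError(f"unknown item id {q!r}") from None
        return m

    def items_of(self, mask: int) -> frozenset[int]:
        return frozenset(q for i, q in enumerate(self.item_ids) if mask >> i & 1)

    def attrs_of(self, mask: int) -> frozenset[str]:
        return frozenset(a for j, a in enumerate(self.attr_ids) if mask >> j & 1)

    def common_attrs(self, item_mask: int) -> int:
        """AND of the intents of the items in ``item_mask`` (Galois up)."""
        m = self.all_attrs
        for i, intent in enumerate(self.intents):
            if item_mask >> i & 1:
                m &= intent
        return m

    def items_with(self, attr_mask: int) -> int:
        """Items whose intent contains every attribute in ``attr_mask`` (Galois down)."""
        m = 0
        for i, intent in enumerate(self.intents):
            if intent & attr_mask == attr_mask:
                m |= 1 << i
        return m

    def downset(self, attr_mask: int) -> int:
        """K(S): items fully explained by the symptom set S."""
        m = 0
        for i, intent in enumerate(self.intents):
            if intent | attr_mask == attr_mask:
                m |= 1 << i
        return m


# ---------------------------------------------------------------------------
# derivations & concepts


def derive_items(ctx: ClinicalContext, item_ids: Iterable[int]) -> frozenset[str]:
    """Attributes common to every item in the set (all attributes for the empty set)."""
    ix = _Index(ctx)
    return ix.attrs_of(ix.common_attrs(ix._item_mask(item_ids)))


def derive_attrs(ctx: ClinicalContext, attr_ids: Iterable[str]) -> frozenset[int]:
    """Items possessing every attribute in the set (all items for the empty set)."""
    ix = _Index(ctx)
    return ix.items_of(ix.items_with(ix._attr_mask(attr_ids)))


@dataclass(frozen=True)
class Concept:
    """A formal concept: a maximal (extent, intent) rectangle of the incidence."""

    extent: frozenset[int]
    intent: frozenset[str]


def formal_concepts(ctx: ClinicalContext) -> list[Concept]:
    """All formal concepts, in lectic (NextClosure) order of their intents."""
    ix = _Index(ctx)
    n = ix.n_attrs

    def closure(attr_mask: int) -> int:
        ext = ix.items_with(attr_mask)
        return ix.common_attrs(ext)

    concepts = []
    b = closure(0)
    concepts.append(Concept(ix.items_of(ix.items_with(b)), ix.attrs_of(b)))
    while b != ix.all_attrs:
        for j in range(n - 1, -1, -1):
            if b >> j & 1:
                continue
            below = (1 << j) - 1
            d = closure((b & below) | (1 << j))
            # lectic test: nothing smaller than j may have been added
            if (d & below) == (b & below):
                b = d
                concepts.append(Concept(ix.items_of(ix.items_with(b)), ix.attrs_of(b)))
                break
        else:  # pragma: no cover - cannot happen: all_attrs is closed
            break
    return concepts


# ---------------------------------------------------------------------------
# prerequisite relation


@dataclass(frozen=True)
class PrerequisiteRelation:
    """Reflexive-transitive surmise relation: (i, j) means i is prerequisite of j."""

    pairs: frozenset[tuple[int, int]]

    def implies(self, i: int, j: int) -> bool:
        return (i, j) in self.pairs

    def to_edges(self) -> list[tuple[int, int]]:
        """Sorted non-reflexive edge list for graph tooling."""
        return sorted(p for p in self.pairs if p[0] != p[1])


def prerequisites(ctx: ClinicalContext) -> PrerequisiteRelation:
    """(i, j) present iff intent(i) is a subset of intent(j)."""
    ix = _Index(ctx)
    pairs = set()
    for a, qa in enumerate(ix.item_ids):
        ia = ix.intents[a]
        for b, qb in enumerate(ix.item_ids):
            if ia & ix.intents[b] == ia:
                pairs.add((qa, qb))
    return PrerequisiteRelation(frozenset(pairs))


# ---------------------------------------------------------------------------
# delineation


class ClinicalStructure:
    """The family of admissible response patterns delineated by a context.

    Contains the empty pattern and the full item set, is closed under
    intersection, and every member is a down-set of the prerequisite
    relation.  States are stored in a deterministic order (by size, then
    lexicographically on sorted item ids).
    """

    def __init__(self, context: ClinicalContext, states: Iterable[frozenset[int]]) -> None:
        self.context = context
        self.states: tuple[frozenset[int], ...] = tuple(
            sorted(set(states), key=lambda s: (len(s), sorted(s)))
        )
        self._member = frozenset(self.states)

    def __len__(self) -> int:
        return len(self.states)

    def __contains__(self, item_set: Iterable[int]) -> bool:
        return frozenset(item_set) in self._member

    def __iter__(self):
        return iter(self.states)

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "n_items": len(self.context.items),
                "n_states": len(self.states),
                "states": [sorted(s) for s in self.states],
            }
        )


def delineate(ctx: ClinicalContext, max_states: int = DEFAULT_STATE_CAP) -> ClinicalStructure:
    """Delineate the clinical structure of a context (conjunctive model).

    The distinct values of K(S) over all attribute subsets S are obtained
    from the union-closure of the item intents: K(S) = K(S') where S' is
    the union of the intents of the items in K(S).  The union family is
    grown breadth-first; exceeding ``max_states`` raises
    :class:`StructureSizeError` with advice to delineate per-factor
    subcontexts instead.
    """
    ix = _Index(ctx)
    bases = sorted(set(m for m in ix.intents if m))
    closed: set[int] = {0}
    frontier = [0]
    while frontier:
        nxt = []
        for u in frontier:
            for b in bases:
                v = u | b
                if v not in closed:
                    closed.add(v)
                    nxt.append(v)
                    if len(closed) > max_states:
                        raise StructureSizeError(
                            f"state family exceeds cap ({max_states}); "
                            "delineate a factor subcontext instead"
                        )
        frontier = nxt
    states = {ix.downset(s) for s in closed}
    return ClinicalStructure(ctx, (ix.items_of(m) for m in states))


def is_state(structure: ClinicalStructure, item_set: Iterable[int]) -> bool:
    """Membership of a response pattern in the delineated family."""
    return frozenset(item_set) in structure
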