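"""Scoring and clinical-state derivation: the output beyond the numeric score.

A respondent's *clinical state* is the set of items answered affirmatively
together with the attribute profile those items imply (the union of their
intents).  Two respondents with the same total score can therefore carry
different symptom profiles; :func:`compare_states` decomposes two profiles
into shared and respondent-specific criteria, which is the clinically
actionable output of the instrument.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Sequence
from dataclasses import dataclass
from pathlib import Path
from typing import NamedTuple

from .context import ClinicalContext, FactorDefinition, builtin_queds
from .errors import ContextParseError, ValidationError
from .structure import ClinicalStructure

__all__ = [
    "ResponsePattern",
    "ClinicalState",
    "StateComparison",
    "SubscaleScores",
    "ConsistencyResult",
    "score",
    "subscale_scores",
    "clinical_state",
    "compare_states",
    "pattern_consistency",
    "read_responses",
    "write_responses",
]


@dataclass(frozen=True)
class ResponsePattern:
    """The items a subject answered affirmatively (0/1 over the instrument)."""

    subject_id: str
    endorsed: frozenset[int]
    group: str | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "endorsed", frozenset(self.endorsed))
        if self.group not in (None, "clinical", "nonclinical"):
            raise ValidationError(
                f"subject {self.subject_id}: group must be 'clinical', 'nonclinical' or empty"
            )


@dataclass(frozen=True)
class ClinicalState:
    """Endorsed items plus the symptom profile they imply."""

    endorsed: frozenset[int]
    profile: frozenset[str]


@dataclass(frozen=True)
class StateComparison:
    """Set-algebraic decomposition of two symptom profiles."""

    shared: frozenset[str]
    only_first: frozenset[str]
    only_second: frozenset[str]


class SubscaleScores(NamedTuple):
    cognitive: int
    somatic: int
    affective: int


class ConsistencyResult(NamedTuple):
    is_state: bool
    min_distance: int
    nearest: frozenset[int]


def _check_items(ctx: ClinicalContext, endorsed: Iterable[int]) -> frozenset[int]:
    endorsed = frozenset(endorsed)
    unknown = endorsed - set(ctx.item_ids)
    if unknown:
        raise ValidationError(f"unknown item ids: {sorted(unknown)}")
    return endorsed


def score(pattern: ResponsePattern, ctx: ClinicalContext | None = None) -> int:
    """Total score: the number of affirmatively answered items."""
    ctx = ctx or builtin_queds()[0]
    return len(_check_items(ctx, pattern.endorsed))


def subscale_scores(
    pattern: ResponsePattern,
    factors: Sequence[FactorDefinition] | None = None,
    ctx: ClinicalContext | None = None,
) -> SubscaleScores:
    """Endorsed-item counts per factor; the components sum to the total score."""
    if factors is None or ctx is None:
        bctx, bfactors = builtin_queds()
        ctx = ctx or bctx
        factors = factors if factors is not None else bfactors
    endorsed = _check_items(ctx, pattern.endorsed)
    union: set[int] = set()
    total = 0
    for f in factors:
        union |= f.item_ids
        total += len(f.item_ids)
    if union != set(ctx.item_ids) or total != len(ctx.item_ids):
        raise ValidationError("factors must partition the context items")
    by_name = {f.name: len(endorsed & f.item_ids) for f in factors}
    return SubscaleScores(
        by_name.get("cognitive", 0), by_name.get("somatic", 0), by_name.get("affective", 0)
    )


def clinical_state(ctx: ClinicalContext, pattern: ResponsePattern) -> ClinicalState:
    """The clinical state: endorsed items and the union of their intents."""
    endorsed = _check_items(ctx, pattern.endorsed)
    profile: frozenset[str] = frozenset()
    for q in endorsed:
        profile |= ctx.intent(q)
    return ClinicalState(endorsed, profile)


def compare_states(s1: ClinicalState, s2: ClinicalState) -> StateComparison:
    """Shared and respondent-specific criteria of two clinical states."""
    return StateComparison(
        shared=s1.profile & s2.profile,
        only_first=s1.profile - s2.profile,
        only_second=s2.profile - s1.profile,
    )


def pattern_consistency(
    structure: ClinicalStructure, pattern: ResponsePattern | Iterable[int]
) -> ConsistencyResult:
    """Distance of an observed pattern from the delineated state family.

    Returns whether the pattern is itself a state, the minimum symmetric
    difference to any state, and the nearest state (ties resolved by the
    lexicographically smallest sorted id list).
    """
    endorsed = (
        frozenset(pattern.endorsed)
        if isinstance(pattern, ResponsePattern)
        else frozenset(pattern)
    )
    endorsed = _check_items(structure.context, endorsed)
    if endorsed in structure:
        return ConsistencyResult(True, 0, endorsed)
    best: tuple[int, list[int]] | None = None
    best_state: frozenset[int] = frozenset()
    for s in structure.states:
        d = len(endorsed ^ s)
        key = (d, sorted(s))
        if best is None or key < best:
            best = key
            best_state = s
    assert best is not None
    return ConsistencyResult(False, best[0], best_state)


# ---------------------------------------------------------------------------
# responses CSV: subject_id,group,I1..I41 with 0/1 cells


def _item_columns(ctx: ClinicalContext) -> list[str]:
    return [f"I{q}" for q in ctx.item_ids]


def write_responses(
    patterns: Sequence[ResponsePattern], path: str | Path, ctx: ClinicalContext | None = None
) -> None:
    ctx = ctx or builtin_queds()[0]
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "group"] + _item_columns(ctx))
        for p in patterns:
            w.writerow(
                [p.subject_id, p.group or ""]
                + [1 if q in p.endorsed else 0 for q in ctx.item_ids]
            )


def read_responses(
    path: str | Path, ctx: ClinicalContext | None = None
) -> list[ResponsePattern]:
    """Read response patterns from the one-row-per-subject CSV dialect."""
    ctx = ctx or builtin_queds()[0]
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        rows = list(csv.reader(fh))
    if not rows:
        raise ContextParseError(f"{path}: empty file")
    header = rows[0]
    expected = ["subject_id", "group"] + _item_columns(ctx)
    if header != expected:
        raise ContextParseError(
            f"{path}: bad header; expected {','.join(expected[:4])},..."
        )
    out = []
    seen: set[str] = set()
    for r, row in enumerate(rows[1:], start=2):
        if not row:
            continue
        if len(row) != len(expected):
            raise ContextParseError(f"{path}: row {r}: wrong number of cells")
        sid, group = row[0], row[1] or None
        if sid in seen:
            raise ValidationError(f"{path}: duplicate subject id {sid!r}")
        seen.add(sid)
        endorsed = set()
        for q, cell in zip(ctx.item_ids, row[2:]):
            if cell not in ("0", "1"):
                raise ContextParseError(
                    f"{path}: row {r}, column I{q}: cell must be 0 or 1, got {cell!r}"
                )
            if cell == "1":
                endorsed.add(q)
        out.append(ResponsePattern(sid, frozenset(endorsed), group))
    return out
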