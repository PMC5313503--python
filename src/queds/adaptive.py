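"""Deterministic adaptive administration over a delineated clinical structure.

The candidate set starts as the whole state family.  Each turn the session
asks the unanswered item that most evenly splits the remaining candidates
(the half-split rule, ties to the smallest item id), discards the candidates
inconsistent with the answer, and stops when a single state remains; the
answers to the never-asked items are then inferred from that state.  With an
error-free respondent the recovered state is exact, and the number of
questions is bounded by log2 of the family size in the best case and by the
number of items always.  There is no response-error model: a respondent that
contradicts every state triggers a flagged fall-back to exhaustive
administration.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Iterable, Sequence

import numpy as np

from .errors import AdaptiveError, ValidationError
from .structure import ClinicalStructure

__all__ = ["SessionTranscript", "next_question", "run_session", "savings_report"]

Responder = Callable[[int], int]


@dataclass(frozen=True)
class SessionTranscript:
    """Full record of one adaptive session."""

    asked: tuple[tuple[int, int], ...]
    inferred: frozenset[tuple[int, int]]
    final_state: frozenset[int]
    consistent: bool = True

    @property
    def n_asked(self) -> int:
        return len(self.asked)

    def to_dict(self) -> dict:
        return {
            "asked": [list(qa) for qa in self.asked],
            "inferred": sorted([list(qa) for qa in self.inferred]),
            "final_state": sorted(self.final_state),
            "consistent": self.consistent,
        }


def next_question(
    candidate_states: Sequence[Iterable[int]], asked_items: Iterable[int]
) -> int:
    """The unasked item whose membership most evenly splits the candidates."""
    states = [frozenset(s) for s in candidate_states]
    if len(states) < 2:
        raise ValidationError("need at least two candidate states")
    asked = set(asked_items)
    n = len(states)
    universe = frozenset().union(*states)
    best: tuple[int, int] | None = None
    for q in sorted(universe):
        if q in asked:
            continue
        c = sum(1 for s in states if q in s)
        if c == 0 or c == n:  # uninformative
            continue
        key = (abs(2 * c - n), q)
        if best is None or key < best:
            best = key
    if best is None:
        raise AdaptiveError(
            "no informative item remains although several candidates do "
            "(duplicate states in the structure?)"
        )
    return best[1]


def run_session(
    structure: ClinicalStructure, responder: Responder, verify: bool = False
) -> SessionTranscript:
    """Administer adaptively until a single candidate state remains.

    ``responder`` maps an item id to a 0/1 answer and is consulted once per
    asked item.  Because every question splits the candidates, elimination
    always leaves at least one state, so a respondent who contradicts the
    structure is only detectable on the inferred items: with ``verify=True``
    the session administers the remaining items too (exhaustive
    administration) and, on any mismatch, flags the transcript inconsistent
    and reports the observed pattern instead of the inferred state.
    """
    all_items = list(structure.context.item_ids)
    candidates = list(structure.states)
    if not candidates:
        raise ValidationError("structure has no states")
    asked: list[tuple[int, int]] = []
    answers: dict[int, int] = {}
    while len(candidates) > 1:
        q = next_question(candidates, answers)
        a = 1 if responder(q) else 0
        asked.append((q, a))
        answers[q] = a
        candidates = [s for s in candidates if (q in s) == bool(a)]
    final = candidates[0]
    if verify:
        mismatch = False
        for q in all_items:
            if q not in answers:
                a = 1 if responder(q) else 0
                asked.append((q, a))
                answers[q] = a
                mismatch = mismatch or a != (1 if q in final else 0)
        if mismatch:
            final = frozenset(q for q, a in answers.items() if a)
        return SessionTranscript(tuple(asked), frozenset(), final, consistent=not mismatch)
    inferred = frozenset(
        (q, 1 if q in final else 0) for q in all_items if q not in answers
    )
    return SessionTranscript(tuple(asked), inferred, final, consistent=True)


def savings_report(
    structure: ClinicalStructure,
    seed: int | None = None,
    exhaustive_limit: int = 2048,
    sample_size: int = 500,
) -> dict:
    """Question-count statistics of error-free sessions over the state family.

    All states are simulated when the family is small (``exhaustive_limit``);
    larger families are sampled with the given seed.
    """
    states = structure.states
    if len(states) > exhaustive_limit:
        rng = np.random.default_rng(seed)
        idx = rng.choice(len(states), size=sample_size, replace=False)
        states = tuple(states[i] for i in idx)
    counts = []
    for s in states:
        t = run_session(structure, lambda q, s=s: 1 if q in s else 0)
        assert t.final_state == s
        counts.append(t.n_asked)
    return {
        "mean_asked": float(np.mean(counts)) if counts else 0.0,
        "max_asked": int(max(counts)) if counts else 0,
        "n_items": len(structure.context.items),
        "n_states": len(structure.states),
    }
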