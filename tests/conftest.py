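"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from queds.context import Attribute, ClinicalContext, Item, builtin_queds

# Endorsed-item sets of the published worked examples: two clinical
# respondents with identical totals but different symptom profiles, one
# non-clinical respondent, and two same-score affective-subscale patterns.
SC_ITEMS = frozenset(
    {1, 3, 5, 6, 10, 12, 13, 14, 15, 16, 17, 18, 20, 22, 23, 24, 25, 26,
     27, 28, 29, 30, 31, 32, 33, 34, 35, 36, 39, 40, 41}
)
FG_ITEMS = frozenset(
    {2, 4, 5, 6, 7, 8, 9, 10, 11, 12, 13, 14, 15, 16, 18, 19, 20, 21, 24,
     25, 26, 27, 29, 32, 33, 34, 36, 37, 38, 40, 41}
)
MT_ITEMS = frozenset({1, 11, 13, 27, 31, 33})
PATTERN_A = frozenset({7, 8, 15, 34, 37, 38, 40})
PATTERN_B = frozenset({12, 15, 17, 18, 29, 34, 36})


@pytest.fixture(scope="session")
def queds_context():
    ctx, _ = builtin_queds()
    return ctx


@pytest.fixture(scope="session")
def queds_factors():
    _, factors = builtin_queds()
    return {f.name: f for f in factors}


def make_context(intents: dict, attrs: list | None = None) -> ClinicalContext:
    """Build a small ad-hoc context from {item_id: iterable of attr tokens}."""
    if attrs is None:
        used = sorted({a for s in intents.values() for a in s})
        attrs = used
    attributes = tuple(Attribute(a, a) for a in attrs)
    items = tuple(
        Item(i, f"item {i}", frozenset(s)) for i, s in sorted(intents.items())
    )
    return ClinicalContext(items, attributes)


def random_context(rng: np.random.Generator, max_items: int = 10, max_attrs: int = 7) -> ClinicalContext:
    n_items = int(rng.integers(1, max_items + 1))
    n_attrs = int(rng.integers(1, max_attrs + 1))
    attrs = [f"a{j}" for j in range(n_attrs)]
    intents = {}
    for i in range(1, n_items + 1):
        mask = rng.random(n_attrs) < rng.uniform(0.15, 0.7)
        intent = {attrs[j] for j in range(n_attrs) if mask[j]}
        if not intent:  # keep the context sound: no empty rows
            intent = {attrs[int(rng.integers(n_attrs))]}
        intents[i] = intent
    return make_context(intents, attrs)


# ---------------------------------------------------------------------------
# independent oracles (exhaustive enumeration; never reuse package internals)


def brute_delineate(ctx: ClinicalContext) -> set[frozenset[int]]:
    """All distinct K(S) over every attribute subset S, by exhaustion."""
    states = set()
    for r in range(len(ctx.attributes) + 1):
        for S in itertools.combinations(ctx.attribute_ids, r):
            s = set(S)
            states.add(frozenset(q for q in ctx.item_ids if set(ctx.intent(q)) <= s))
    return states


def brute_concepts(ctx: ClinicalContext) -> set[tuple[frozenset[int], frozenset[str]]]:
    """All concepts by closing every item subset."""
    out = set()
    ids = list(ctx.item_ids)
    for r in range(len(ids) + 1):
        for E in itertools.combinations(ids, r):
            common = set(ctx.attribute_ids)
            for q in E:
                common &= set(ctx.intent(q))
            extent = frozenset(
                q for q in ids if common <= set(ctx.intent(q))
            )
            out.add((extent, frozenset(common)))
    return out


def brute_auc(scores, labels) -> float:
    """Pair-counting AUC: wins + half-ties over all positive x negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = 0.0
    for p in pos:
        for q in neg:
            wins += 1.0 if p > q else 0.5 if p == q else 0.0
    return wins / (len(pos) * len(neg))
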