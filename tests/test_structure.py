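"""Galois derivations, concepts, prerequisite relation, and delineation."""

from __future__ import annotations

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from queds import (
    StructureSizeError,
    builtin_queds,
    delineate,
    derive_attrs,
    derive_items,
    formal_concepts,
    is_state,
    prerequisites,
    subcontext,
)

from conftest import brute_concepts, brute_delineate, make_context, random_context


class TestDerivations:
    def test_published_examples(self, queds_context):
        assert derive_items(queds_context, {2}) == {"A6", "A7"}
        assert derive_attrs(queds_context, {"A4"}) == {22, 23}

    def test_empty_set_conventions(self, queds_context):
        assert derive_items(queds_context, set()) == set(queds_context.attribute_ids)
        assert derive_attrs(queds_context, set()) == set(queds_context.item_ids)

    def test_unknown_ids(self, queds_context):
        from queds import ValidationError

        with pytest.raises(ValidationError):
            derive_items(queds_context, {999})
        with pytest.raises(ValidationError):
            derive_attrs(queds_context, {"A99"})


class TestFormalConcepts:
    @pytest.mark.parametrize(
        "intents, n_concepts",
        [
            ({1: {"a"}, 2: {"b"}}, 4),
            ({1: {"a"}, 2: {"a", "b"}}, 2),
        ],
    )
    def test_toy_counts(self, intents, n_concepts):
        assert len(formal_concepts(make_context(intents))) == n_concepts

    def test_closure_invariant_on_instrument(self, queds_context):
        for c in formal_concepts(queds_context):
            assert derive_attrs(queds_context, c.intent) == c.extent
            assert derive_items(queds_context, c.extent) == c.intent

    def test_matches_brute_force_on_random_contexts(self):
        rng = np.random.default_rng(2024)
        for _ in range(25):
            ctx = random_context(rng, max_items=7, max_attrs=5)
            got = {(c.extent, c.intent) for c in formal_concepts(ctx)}
            assert got == brute_concepts(ctx)

    def test_enumeration_is_deterministic(self, queds_context):
        assert formal_concepts(queds_context) == formal_concepts(queds_context)


class TestPrerequisites:
    def test_published_subset_pairs(self, queds_context):
        rel = prerequisites(queds_context)
        assert rel.implies(4, 2)   # insomnia item precedes waking+agitation item
        assert rel.implies(34, 7)  # sadness precedes crying-spell item

    def test_reflexive_on_instrument(self, queds_context):
        rel = prerequisites(queds_context)
        assert all(rel.implies(q, q) for q in queds_context.item_ids)

    def test_reflexive_and_transitive_on_random_contexts(self):
        rng = np.random.default_rng(7)
        for _ in range(25):
            ctx = random_context(rng)
            rel = prerequisites(ctx)
            ids = ctx.item_ids
            assert all((q, q) in rel.pairs for q in ids)
            for (i, j) in rel.pairs:
                for (k, l) in rel.pairs:
                    if j == k:
                        assert (i, l) in rel.pairs

    def test_edges_exclude_loops(self, queds_context):
        edges = prerequisites(queds_context).to_edges()
        assert all(i != j for i, j in edges)
        assert edges == sorted(edges)


class TestDelineation:
    @pytest.mark.parametrize(
        "intents, expected",
        [
            ({1: {"a"}, 2: {"a", "b"}}, {frozenset(), frozenset({1}), frozenset({1, 2})}),
            (
                {1: {"a"}, 2: {"b"}, 3: {"a", "b"}},
                {frozenset(), frozenset({1}), frozenset({2}), frozenset({1, 2, 3})},
            ),
        ],
    )
    def test_toy_families(self, intents, expected):
        st = delineate(make_context(intents))
        assert set(st.states) == expected

    def test_matches_exhaustive_oracle_on_random_contexts(self):
        rng = np.random.default_rng(99)
        for _ in range(30):
            ctx = random_context(rng, max_items=12, max_attrs=8)
            assert set(delineate(ctx).states) == brute_delineate(ctx)

    @pytest.mark.parametrize("factor", ["cognitive", "somatic", "affective"])
    def test_matches_exhaustive_oracle_on_factor_subcontexts(self, factor, queds_factors, queds_context):
        fctx = subcontext(queds_context, queds_factors[factor].item_ids)
        assert set(delineate(fctx).states) == brute_delineate(fctx)

    def test_family_properties(self, queds_context, queds_factors):
        fctx = subcontext(queds_context, queds_factors["affective"].item_ids)
        st = delineate(fctx)
        states = set(st.states)
        assert frozenset() in states
        assert frozenset(fctx.item_ids) in states
        rel = prerequisites(fctx)
        for s in states:
            # down-set of the prerequisite relation
            for j in s:
                assert all(i in s for (i, jj) in rel.pairs if jj == j)
        for s1, s2 in itertools.combinations(states, 2):
            assert s1 & s2 in states

    def test_downset_operator_is_monotone(self, queds_context, queds_factors):
        fctx = subcontext(queds_context, queds_factors["affective"].item_ids)
        st = delineate(fctx)
        rng = np.random.default_rng(5)
        attrs = list(fctx.attribute_ids)
        for _ in range(20):
            s1 = {a for a in attrs if rng.random() < 0.4}
            s2 = s1 | {a for a in attrs if rng.random() < 0.4}
            k1 = frozenset(q for q in fctx.item_ids if set(fctx.intent(q)) <= s1)
            k2 = frozenset(q for q in fctx.item_ids if set(fctx.intent(q)) <= s2)
            assert k1 <= k2
            assert k1 in st and k2 in st

    def test_cap_raises(self, queds_context):
        with pytest.raises(StructureSizeError, match="subcontext"):
            delineate(queds_context, max_states=10)

    def test_is_state(self):
        st = delineate(make_context({1: {"a"}, 2: {"a", "b"}}))
        assert is_state(st, set()) and is_state(st, {1, 2})
        assert not is_state(st, {2})


@st.composite
def small_contexts(draw):
    n_attrs = draw(st.integers(1, 5))
    attrs = [f"a{j}" for j in range(n_attrs)]
    n_items = draw(st.integers(1, 6))
    intents = {
        i: draw(st.sets(st.sampled_from(attrs), min_size=1))
        for i in range(1, n_items + 1)
    }
    return make_context(intents, attrs)


@settings(max_examples=60, deadline=None, derandomize=True)
@given(small_contexts())
def test_property_delineation_equals_oracle(ctx):
    """For arbitrary sound contexts the delineated family is exactly the
    exhaustive one and satisfies the family axioms."""
    states = set(delineate(ctx).states)
    assert states == brute_delineate(ctx)
    assert frozenset() in states and frozenset(ctx.item_ids) in states
    for s1 in states:
        for s2 in states:
            assert s1 & s2 in states


@settings(max_examples=60, deadline=None, derandomize=True)
@given(small_contexts())
def test_property_prerequisites_quasi_order(ctx):
    """The surmise relation is reflexive and transitive on arbitrary contexts,
    and every delineated state is one of its down-sets."""
    rel = prerequisites(ctx)
    for q in ctx.item_ids:
        assert (q, q) in rel.pairs
    for (i, j) in rel.pairs:
        for (k, l) in rel.pairs:
            if j == k:
                assert (i, l) in rel.pairs
    for s in delineate(ctx).states:
        assert all(i in s for (i, j) in rel.pairs if j in s)
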