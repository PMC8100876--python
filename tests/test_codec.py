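"""Arc-graph encoding/decoding: worked example, round trips, repair policy."""

import itertools

import numpy as np
import pytest

from conftest import random_annotations
from famgraph import codec
from famgraph.codec import EncodingError
from famgraph.types import (
    APP_LABEL,
    FAMILY_MEMBER,
    LIVING_STATUS,
    NULL_LABEL,
    OBSERVATION,
    ArcGraph,
    Entity,
    LabelScheme,
    Relation,
    Token,
)

THREE = LabelScheme(LabelScheme.THREE)
FIVE = LabelScheme(LabelScheme.FIVE)


@pytest.fixture
def children_sentence():
    """'His children are generally healthy' with FM 'children',
    LS 'generally healthy' and the relation between them."""
    tokens = Token.sequence(["His", "children", "are", "generally", "healthy"])
    fm = Entity(0, 1, 1, FAMILY_MEMBER)
    ls = Entity(0, 3, 4, LIVING_STATUS)
    return tokens, [fm, ls], [Relation(fm, ls)]


class TestEncode:
    def test_children_example(self, children_sentence):
        """Multi-token entity chains by app arcs; the relation is the arc
        from the family member to the dependent's last token."""
        tokens, entities, relations = children_sentence
        g = codec.encode_graph(tokens, entities, relations, THREE)
        assert g.heads == (0, 0, 0, 5, 2)
        assert g.labels == ("NULL", "FamilyMember", "NULL", "app", "LivingStatus")

    def test_no_entities_all_null(self):
        tokens = Token.sequence(["a", "b", "c"])
        g = codec.encode_graph(tokens, [], [], THREE)
        assert g.heads == (0, 0, 0)
        assert set(g.labels) == {NULL_LABEL}

    def test_arc_count_conservation(self, rng):
        for _ in range(50):
            tokens, ents, rels = random_annotations(rng)
            g = codec.encode_graph(tokens, ents, rels, THREE)
            assert len(g.heads) == len(g.labels) == len(tokens)
            n_typed = sum(lab in THREE.entity_types for lab in g.labels)
            n_app = sum(lab == APP_LABEL for lab in g.labels)
            assert n_typed == len(ents)
            assert n_app == sum(e.last - e.first for e in ents)
            non_root_non_app = sum(
                1
                for j in range(len(tokens))
                if g.labels[j] != APP_LABEL and g.heads[j] != 0
            )
            assert non_root_non_app == len(rels)

    def test_app_heads_point_right(self, rng):
        """Within an entity every app arc goes to the adjacent right token."""
        for _ in range(50):
            tokens, ents, rels = random_annotations(rng)
            g = codec.encode_graph(tokens, ents, rels, THREE)
            for j, lab in enumerate(g.labels):
                if lab == APP_LABEL:
                    assert g.heads[j] == j + 2

    def test_overlapping_entities_rejected(self):
        tokens = Token.sequence(["a", "b", "c"])
        e1 = Entity(0, 0, 1, OBSERVATION)
        e2 = Entity(0, 1, 2, LIVING_STATUS)
        with pytest.raises(EncodingError, match="overlap"):
            codec.encode_graph(tokens, [e1, e2], [], THREE)

    def test_double_dependent_rejected(self):
        tokens = Token.sequence(["a", "b", "c", "d"])
        fm1 = Entity(0, 0, 0, FAMILY_MEMBER)
        fm2 = Entity(0, 1, 1, FAMILY_MEMBER)
        ob = Entity(0, 3, 3, OBSERVATION)
        with pytest.raises(EncodingError, match="dependent of two"):
            codec.encode_graph(
                tokens, [fm1, fm2, ob], [Relation(fm1, ob), Relation(fm2, ob)], THREE
            )

    def test_five_type_label_carries_side(self):
        tokens = Token.sequence(["grandmother"])
        fm = Entity(0, 0, 0, FAMILY_MEMBER, side="Maternal")
        g = codec.encode_graph(tokens, [fm], [], FIVE)
        assert g.labels == ("FM-Maternal",)


class TestNerOnly:
    def test_children_example_all_root(self, children_sentence):
        tokens, entities, _ = children_sentence
        g = codec.encode_ner_only(tokens, entities, THREE)
        assert g.heads == (0, 0, 0, 0, 0)
        assert g.labels == ("NULL", "FamilyMember", "NULL", "app", "LivingStatus")

    def test_empty(self):
        g = codec.encode_ner_only(Token.sequence(["x"]), [], THREE)
        assert g.heads == (0,) and g.labels == (NULL_LABEL,)

    def test_round_trip_recovers_entities_no_relations(self, rng):
        for _ in range(100):
            tokens, ents, _ = random_annotations(rng)
            g = codec.encode_ner_only(tokens, ents, THREE)
            e2, r2 = codec.decode_graph(g, THREE)
            assert {e.core() for e in e2} == {e.core() for e in ents}
            assert r2 == []


class TestDecode:
    def test_children_example(self, children_sentence):
        tokens, entities, relations = children_sentence
        g = codec.encode_graph(tokens, entities, relations, THREE)
        ents, rels = codec.decode_graph(g, THREE)
        assert {e.core() for e in ents} == {e.core() for e in entities}
        assert [r.core() for r in rels] == [r.core() for r in relations]

    def test_all_null(self):
        g = ArcGraph((0, 0, 0), (NULL_LABEL,) * 3)
        assert codec.decode_graph(g, THREE) == ([], [])

    def test_dangling_app_chain_dropped(self):
        # app chain runs off the end of the sentence: no entity
        g = ArcGraph((2, 3, 0), (APP_LABEL, APP_LABEL, NULL_LABEL))
        assert codec.decode_graph(g, THREE) == ([], [])

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="equal length"):
            ArcGraph((0, 0), (NULL_LABEL,))

    @pytest.mark.parametrize("scheme", [THREE, FIVE], ids=["three", "five"])
    def test_round_trip_random(self, scheme, rng):
        """encode then decode returns the identical annotation set."""
        for _ in range(300):
            tokens, ents, rels = random_annotations(
                rng, with_sides=scheme is FIVE
            )
            g = codec.encode_graph(tokens, ents, rels, scheme)
            e2, r2 = codec.decode_graph(g, scheme)
            gold_e = {(e.first, e.last, scheme.entity_label(e)) for e in ents}
            got_e = {(e.first, e.last, scheme.entity_label(e)) for e in e2}
            assert gold_e == got_e
            gold_r = {(r.head.span, r.dep.span) for r in rels}
            got_r = {(r.head.span, r.dep.span) for r in r2}
            assert gold_r == got_r

    def test_total_on_all_three_token_graphs(self):
        """Exhaustive: decoding never raises and matches an independent
        reference decoder on every possible 3-token graph."""
        labels = THREE.labels
        n = 3
        for labs in itertools.product(labels, repeat=n):
            for heads in itertools.product(range(n + 1), repeat=n):
                g = ArcGraph(tuple(heads), tuple(labs))
                ents, rels = codec.decode_graph(g, THREE)
                ref_e, ref_r = _reference_decode(g, THREE)
                assert {(e.first, e.last, e.etype) for e in ents} == ref_e
                assert {(r.head.span, r.dep.span) for r in rels} == ref_r

    def test_idempotent_under_reencode(self, rng):
        """Decoding arbitrary graphs then re-encoding and re-decoding is
        stable."""
        for _ in range(200):
            n = int(rng.integers(1, 8))
            g = ArcGraph(
                tuple(int(rng.integers(0, n + 1)) for _ in range(n)),
                tuple(THREE.labels[int(rng.integers(len(THREE.labels)))] for _ in range(n)),
            )
            ents, rels = codec.decode_graph(g, THREE)
            try:
                g2 = codec.encode_graph(Token.sequence(["x"] * n), ents, rels, THREE)
            except EncodingError:
                pytest.fail("decoded annotations must always be encodable")
            e2, r2 = codec.decode_graph(g2, THREE)
            assert {e.core() for e in e2} == {e.core() for e in ents}
            assert {(r.head.span, r.dep.span) for r in r2} == {
                (r.head.span, r.dep.span) for r in rels
            }


def _reference_decode(g: ArcGraph, scheme: LabelScheme):
    """Independent brute-force decoder: maximal app runs ending at an
    entity-type label become entities; non-app arcs between last tokens of
    a family-member entity (head side) and a non-family entity yield
    relations."""
    n = len(g)
    typed = set(scheme.entity_types)
    spans = {}
    for j in range(n):
        if g.labels[j] in typed:
            first = j
            while first > 0 and g.labels[first - 1] == APP_LABEL:
                first -= 1
            spans[j] = (first, j, g.labels[j])
    entities = {(f, l, t) for f, l, t in spans.values()}
    relations = set()
    fm_last = {j for j, (_, _, t) in spans.items() if t == FAMILY_MEMBER}
    for j in range(n):
        h = g.heads[j]
        if g.labels[j] == APP_LABEL or h == 0:
            continue
        if j in spans and spans[j][2] != FAMILY_MEMBER and (h - 1) in fm_last:
            f1, l1, _ = spans[h - 1]
            f2, l2, _ = spans[j]
            relations.add(((f1, l1), (f2, l2)))
    return entities, relations


class TestConll:
    def test_round_trip(self, rng):
        sents, graphs = [], []
        for _ in range(5):
            tokens, ents, rels = random_annotations(rng)
            sents.append(tokens)
            graphs.append(codec.encode_graph(tokens, ents, rels, THREE))
        text = codec.graphs_to_conll(sents, graphs)
        sents2, graphs2 = codec.conll_to_graphs(text)
        assert graphs2 == graphs
        assert [[t.text for t in s] for s in sents2] == [
            [t.text for t in s] for s in sents
        ]

    def test_malformed_rejected(self):
        with pytest.raises(ValueError, match="4 columns"):
            codec.conll_to_graphs("0\tword\t0\n")
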