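"""Bidirectional conversion between annotations and dependency-style arc graphs.

The joint extraction target treats a sentence like a dependency tree over a
dummy ROOT: tokens inside a multi-token entity chain to the token on their
right with the ``app`` label; the last token of an entity carries the
entity-type label, and its head is ROOT unless the entity is the dependent
of a relation, in which case its head is the rightmost token of the
governing family-member entity.  Tokens outside any entity attach to ROOT
with the ``NULL`` label.  Decoding is total: model output may be an
arbitrary head/label assignment and is repaired deterministically.
"""

from __future__ import annotations

from typing import Iterable, Sequence

from .types import (
    APP_LABEL,
    NULL_LABEL,
    ArcGraph,
    Entity,
    LabelScheme,
    Relation,
    Token,
)


class EncodingError(ValueError):
    """Raised for gold annotations that the arc schema cannot represent."""


def _check_entities(n: int, entities: Sequence[Entity]) -> None:
    seen = [False] * n
    for e in entities:
        if e.last >= n:
            raise EncodingError(f"entity span {e.span} exceeds sentence length {n}")
        for j in range(e.first, e.last + 1):
            if seen[j]:
                raise EncodingError(
                    f"overlapping entities at token {j}: spans must be disjoint"
                )
            seen[j] = True


def encode_graph(
    tokens: Sequence[Token],
    entities: Iterable[Entity],
    relations: Iterable[Relation],
    scheme: LabelScheme,
) -> ArcGraph:
    """Encode (entities, relations) of one sentence as an :class:`ArcGraph`.

    Raises :class:`EncodingError` for overlapping entities or an entity that
    is the dependent of more than one relation (the schema is single-head).
    Relations that cross sentence boundaries cannot be constructed as
    :class:`~famgraph.types.Relation` at all, so they never reach here; a
    relation whose endpoints are not among ``entities`` is rejected.
    """
    n = len(tokens)
    entities = list(entities)
    relations = list(relations)
    _check_entities(n, entities)

    spans = {e.core().span: e for e in entities}
    heads = [0] * n
    labels = [NULL_LABEL] * n

    for e in entities:
        for j in range(e.first, e.last):
            heads[j] = j + 2  # token to the right, 1-based
            labels[j] = APP_LABEL
        labels[e.last] = scheme.entity_label(e)
        heads[e.last] = 0

    dependents_seen: set[tuple[int, int]] = set()
    for r in relations:
        hs, ds = r.head.span, r.dep.span
        if hs not in spans or ds not in spans:
            raise EncodingError(f"relation endpoints {hs}->{ds} not in entity set")
        if ds in dependents_seen:
            raise EncodingError(
                f"entity at span {ds} is the dependent of two relations; "
                "the single-head schema cannot encode it"
            )
        dependents_seen.add(ds)
        heads[ds[1]] = hs[1] + 1  # rightmost token of head entity, 1-based

    return ArcGraph(tuple(heads), tuple(labels))


def encode_ner_only(
    tokens: Sequence[Token], entities: Iterable[Entity], scheme: LabelScheme
) -> ArcGraph:
    """NER-only variant: all heads attach to ROOT, labels mark entities.

    Non-entity tokens get NULL, the last token of each entity its type, the
    remaining entity tokens ``app``.
    """
    n = len(tokens)
    entities = list(entities)
    _check_entities(n, entities)
    labels = [NULL_LABEL] * n
    for e in entities:
        for j in range(e.first, e.last):
            labels[j] = APP_LABEL
        labels[e.last] = scheme.entity_label(e)
    return ArcGraph(tuple([0] * n), tuple(labels))


def decode_graph(
    graph: ArcGraph, scheme: LabelScheme, sentence_id: int = 0
) -> tuple[list[Entity], list[Relation]]:
    """Decode an (arbitrary, possibly inconsistent) arc graph.

    Repair policy for model output: an entity-type-labeled token always ends
    a (possibly single-token) entity; the entity extends leftward over the
    maximal contiguous run of ``app``-labeled tokens immediately before it.
    ``app`` runs not terminated by an entity-type label are dropped.  A
    non-``app``, non-ROOT arc yields a relation only if it connects the last
    token of a decoded non-family entity (the dependent) to the last token
    of a decoded family-member entity (the head).  Never raises on any
    well-formed :class:`ArcGraph`.
    """
    entity_types = set(scheme.entity_types)
    n = len(graph)

    entities: list[Entity] = []
    last_token_to_entity: dict[int, Entity] = {}
    j = 0
    while j < n:
        lab = graph.labels[j]
        if lab == APP_LABEL:
            # follow the app run rightward to its terminator
            k = j
            while k < n and graph.labels[k] == APP_LABEL:
                k += 1
            if k < n and graph.labels[k] in entity_types:
                e = _make_entity(sentence_id, j, k, graph.labels[k])
                entities.append(e)
                last_token_to_entity[k] = e
            # else: dangling app chain, no entity emitted
            j = k + 1
        elif lab in entity_types:
            e = _make_entity(sentence_id, j, j, lab)
            entities.append(e)
            last_token_to_entity[j] = e
            j += 1
        else:
            j += 1

    relations: list[Relation] = []
    for j in range(n):
        if graph.labels[j] == APP_LABEL or graph.heads[j] == 0:
            continue
        dep = last_token_to_entity.get(j)
        head = last_token_to_entity.get(graph.heads[j] - 1)
        if dep is None or head is None:
            continue
        if not head.is_family_member() or dep.is_family_member():
            continue
        relations.append(Relation(head, dep))
    return entities, relations


def _make_entity(sid: int, first: int, last: int, label: str) -> Entity:
    side = LabelScheme.side_of_label(label)
    if side is not None:
        return Entity(sid, first, last, label, side=side)
    return Entity(sid, first, last, label)


# CoNLL-like serialization ---------------------------------------------------


def graphs_to_conll(
    sentences: Sequence[Sequence[Token]], graphs: Sequence[ArcGraph]
) -> str:
    """Serialize sentences with their arc graphs as a CoNLL-like TSV.

    Columns: token_index (0-based), token_text, head_index (0 = ROOT,
    k = k-th token 1-based), label.  Blank line between sentences.
    """
    blocks = []
    for toks, g in zip(sentences, graphs):
        if len(toks) != len(g):
            raise ValueError("sentence/graph length mismatch")
        lines = [
            f"{t.index}\t{t.text}\t{g.heads[j]}\t{g.labels[j]}"
            for j, t in enumerate(toks)
        ]
        blocks.append("\n".join(lines))
    return "\n\n".join(blocks) + "\n"


def conll_to_graphs(text: str) -> tuple[list[list[Token]], list[ArcGraph]]:
    """Parse the CoNLL-like TSV produced by :func:`graphs_to_conll`."""
    sentences: list[list[Token]] = []
    graphs: list[ArcGraph] = []
    for block in text.strip().split("\n\n"):
        if not block.strip():
            continue
        toks: list[Token] = []
        heads: list[int] = []
        labels: list[str] = []
        for line in block.splitlines():
            cols = line.rstrip("\n").split("\t")
            if len(cols) != 4:
                raise ValueError(f"expected 4 columns, got {len(cols)}: {line!r}")
            idx, word, head, lab = cols
            toks.append(Token(int(idx), word))
            heads.append(int(head))
            labels.append(lab)
        sentences.append(toks)
        graphs.append(ArcGraph(tuple(heads), tuple(labels)))
    return sentences, graphs
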