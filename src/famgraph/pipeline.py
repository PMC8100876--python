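"""End-to-end inference: predict arc graphs, decode, apply rules."""

from __future__ import annotations

import dataclasses

from . import codec
from .model import BiaffineFamilyHistoryTagger
from .postprocess import DocumentResult, apply_rules
from .types import Document, Entity, Relation


def extract_document(
    model: BiaffineFamilyHistoryTagger, doc: Document, window: int = 3
) -> DocumentResult:
    """Run the full pipeline on one segmented document."""
    sentences = [s.words for s in doc.sentences if len(s) > 0]
    sids = [i for i, s in enumerate(doc.sentences) if len(s) > 0]
    entities: list[Entity] = []
    relations: list[Relation] = []
    if sentences:
        graphs = model.predict_graphs(sentences)
        for sid, g in zip(sids, graphs):
            ents, rels = codec.decode_graph(g, model.scheme_, sentence_id=sid)
            entities.extend(ents)
            relations.extend(rels)
    return apply_rules(doc, entities, relations, model.scheme_, window=window)


def annotate_document(
    model: BiaffineFamilyHistoryTagger, doc: Document
) -> tuple[list[Entity], list[Relation]]:
    """Decoded raw annotations (before rules) with document sentence ids."""
    entities: list[Entity] = []
    relations: list[Relation] = []
    sentences = [s.words for s in doc.sentences if len(s) > 0]
    sids = [i for i, s in enumerate(doc.sentences) if len(s) > 0]
    if sentences:
        for sid, g in zip(sids, model.predict_graphs(sentences)):
            ents, rels = codec.decode_graph(g, model.scheme_, sentence_id=sid)
            entities.extend(ents)
            relations.extend(rels)
    return entities, relations
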