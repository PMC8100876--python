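"""Seeded generator of annotated family-history documents.

The generator emulates the structural properties of family-history
sections in clinical notes that the model and the rule system assume:
family-member mentions (including compound possessives), observations
drawn from a disease lexicon, living-status phrases built from the scoring
keyword table, maternal/paternal side indicators and section headings,
partner-side sections (exclusion pathway), negation cues, reversal
phrases, and no-entity distractor sentences.

Gold attributes (side, negation, living-status scores) are derived by
running the rule-based postprocessor on the generated surface forms, so
generator and rules are mutually consistent by construction.  Gold
annotations are always encodable as arc graphs: one head per dependent
entity, no cross-sentence relations, no overlapping entities.

Templates come in an ``easy`` split (unambiguous, one family member per
sentence) and a ``hard`` split that adds controlled ambiguity (two family
members with their own observations in one sentence, pronoun subjects).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as fio
from .postprocess import (
    apply_rules,
    detect_negation,
    infer_side,
    load_disease_lexicon,
    normalize_family_member,
    score_living_status,
)
from .types import (
    FAMILY_MEMBER,
    LIVING_STATUS,
    OBSERVATION,
    Document,
    Entity,
    LabelScheme,
    Relation,
)

# surface pools -----------------------------------------------------------------

FIRST_DEGREE_KIN = [
    "father", "mother", "sister", "brother", "daughter", "son", "children",
]
SECOND_DEGREE_KIN = [
    "grandmother", "grandfather", "aunt", "uncle", "cousin", "siblings",
]
COMPOUND_KIN = [  # pairs that compose to a normalized name
    ("father", "father"), ("father", "mother"), ("mother", "father"),
    ("mother", "mother"), ("father", "brother"), ("mother", "sister"),
    ("aunt", "son"), ("uncle", "daughter"), ("father", "sister"),
    ("mother", "brother"),
]
LIVING_STATUS_PHRASES = [
    "alive and well", "living and healthy", "alive", "living",
    "in good health", "healthy and well", "doing well",
    "deceased", "dead", "died at age 61", "passed away", "stillborn",
    "status unknown", "age 53",
]
DISTRACTORS = [
    "The patient works as a teacher .",
    "Routine follow up visit today .",
    "Vital signs were stable at the visit .",
    "The patient enjoys gardening and walking .",
]
PRONOUNS = ["His", "Her", "Their"]

EASY_TEMPLATES = (
    "fm_ob", "fm_ls", "fm_ob_ls", "negated_ob", "reversal",
    "compound_kinship", "indicator_side", "section_headed",
    "partner_excluded", "distractor",
)
HARD_TEMPLATES = ("two_fm_ob", "pronoun_ob")


@dataclass
class GeneratorConfig:
    """Knobs of the synthetic corpus; seeded runs are bitwise reproducible."""

    n_documents: int = 20
    sentences_per_document: tuple[int, int] = (3, 8)
    template_weights: dict = field(
        default_factory=lambda: {name: 1.0 for name in EASY_TEMPLATES}
    )
    difficulty: str = "easy"  # adds HARD_TEMPLATES when "hard"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.difficulty not in ("easy", "hard"):
            raise ValueError("difficulty must be 'easy' or 'hard'")
        if self.difficulty == "hard":
            for name in HARD_TEMPLATES:
                self.template_weights.setdefault(name, 1.0)
        if any(w < 0 for w in self.template_weights.values()):
            raise ValueError("template weights must be non-negative")
        if not any(w > 0 for w in self.template_weights.values()):
            raise ValueError("at least one template weight must be positive")
        known = set(EASY_TEMPLATES) | set(HARD_TEMPLATES)
        unknown = set(self.template_weights) - known
        if unknown:
            raise ValueError(f"unknown templates: {sorted(unknown)}")


@dataclass
class SyntheticDocument:
    """A generated document plus the template provenance of each sentence."""

    document: Document
    templates: list[str]


# -- sentence builders -----------------------------------------------------------


class _SentenceDraft:
    """One sentence under construction: words + entity/relation factories."""

    def __init__(self):
        self.words: list[str] = []
        self.entities: list[tuple[int, int, str]] = []  # (first, last, etype)
        self.relations: list[tuple[int, int]] = []  # entity index pairs

    def add(self, *words: str) -> None:
        self.words.extend(words)

    def add_entity(self, words: list[str], etype: str) -> int:
        first = len(self.words)
        self.words.extend(words)
        self.entities.append((first, len(self.words) - 1, etype))
        return len(self.entities) - 1

    def relate(self, head_idx: int, dep_idx: int) -> None:
        self.relations.append((head_idx, dep_idx))


def _split_phrase(phrase: str) -> list[str]:
    return phrase.split()


class _Generator:
    def __init__(self, config: GeneratorConfig):
        self.cfg = config
        self.rng = np.random.default_rng(config.seed)
        self.diseases = load_disease_lexicon()
        names = [n for n, w in config.template_weights.items() if w > 0]
        weights = np.array([config.template_weights[n] for n in names], float)
        self.template_names = names
        self.template_probs = weights / weights.sum()

    def choice(self, seq):
        return seq[int(self.rng.integers(len(seq)))]

    def disease(self) -> list[str]:
        return _split_phrase(self.choice(self.diseases))

    def pronoun(self) -> str:
        return self.choice(PRONOUNS)

    # each builder returns (draft, section_header or None)

    def build(self, name: str) -> tuple[_SentenceDraft, str | None]:
        return getattr(self, f"_t_{name}")()

    def _t_fm_ob(self):
        d = _SentenceDraft()
        d.add(self.pronoun())
        fm = d.add_entity([self.choice(FIRST_DEGREE_KIN + SECOND_DEGREE_KIN)], FAMILY_MEMBER)
        d.add(*self.choice([["has"], ["was", "diagnosed", "with"], ["suffers", "from"]]))
        ob = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ob)
        return d, None

    def _t_fm_ls(self):
        d = _SentenceDraft()
        d.add(self.pronoun())
        fm = d.add_entity([self.choice(FIRST_DEGREE_KIN + SECOND_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("is")
        ls = d.add_entity(_split_phrase(self.choice(LIVING_STATUS_PHRASES)), LIVING_STATUS)
        d.add(".")
        d.relate(fm, ls)
        return d, None

    def _t_fm_ob_ls(self):
        d = _SentenceDraft()
        d.add(self.pronoun())
        fm = d.add_entity([self.choice(FIRST_DEGREE_KIN + SECOND_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("is")
        ls = d.add_entity(_split_phrase(self.choice(LIVING_STATUS_PHRASES)), LIVING_STATUS)
        d.add("and", "has")
        ob = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ls)
        d.relate(fm, ob)
        return d, None

    def _t_negated_ob(self):
        d = _SentenceDraft()
        d.add(self.pronoun())
        fm = d.add_entity([self.choice(FIRST_DEGREE_KIN + SECOND_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("has", "no", "history", "of")
        ob = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ob)
        return d, None

    def _t_reversal(self):
        d = _SentenceDraft()
        d.add("There", "is", "no", "history", "of")
        d.add_entity(self.disease(), OBSERVATION)
        d.add(*_split_phrase(self.choice(["apart from", "except for"])))
        d.add(self.pronoun().lower())
        fm = d.add_entity([self.choice(FIRST_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("'s", "history", "of")
        ob2 = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ob2)
        return d, None

    def _t_compound_kinship(self):
        d = _SentenceDraft()
        d.add(self.pronoun())
        k1, k2 = self.choice(COMPOUND_KIN)
        fm = d.add_entity([k1, "'s", k2], FAMILY_MEMBER)
        d.add("has")
        ob = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ob)
        return d, None

    def _t_indicator_side(self):
        d = _SentenceDraft()
        d.add("The", self.choice(["maternal", "paternal"]))
        fm = d.add_entity([self.choice(SECOND_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("has")
        ob = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ob)
        return d, None

    def _t_section_headed(self):
        # second-degree kin so the section (not the first-degree rule)
        # actually decides the side
        d = _SentenceDraft()
        d.add(self.pronoun())
        fm = d.add_entity([self.choice(SECOND_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("has")
        ob = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ob)
        side = self.choice(["Maternal", "Paternal"])
        return d, f"{side} family history:"

    def _t_partner_excluded(self):
        d = _SentenceDraft()
        d.add(self.pronoun())
        fm = d.add_entity([self.choice(FIRST_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("has")
        ob = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ob)
        return d, "Partner's family history:"

    def _t_distractor(self):
        d = _SentenceDraft()
        d.add(*self.choice(DISTRACTORS).split())
        return d, None

    def _t_two_fm_ob(self):
        d = _SentenceDraft()
        d.add(self.pronoun())
        fm1 = d.add_entity([self.choice(FIRST_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("has")
        ob1 = d.add_entity(self.disease(), OBSERVATION)
        d.add("and", self.pronoun().lower())
        fm2 = d.add_entity([self.choice(SECOND_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("has")
        ob2 = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm1, ob1)
        d.relate(fm2, ob2)
        return d, None

    def _t_pronoun_ob(self):
        d = _SentenceDraft()
        d.add(self.pronoun())
        fm = d.add_entity([self.choice(FIRST_DEGREE_KIN)], FAMILY_MEMBER)
        d.add("reports", "that", "she", "has")
        ob = d.add_entity(self.disease(), OBSERVATION)
        d.add(".")
        d.relate(fm, ob)
        return d, None


def generate_corpus(config: GeneratorConfig) -> list[SyntheticDocument]:
    """Generate ``config.n_documents`` annotated documents."""
    gen = _Generator(config)
    rng = gen.rng
    docs: list[SyntheticDocument] = []
    lo, hi = config.sentences_per_document
    for di in range(config.n_documents):
        n_sent = int(rng.integers(lo, hi + 1))
        lines: list[str] = ["Family history:"]
        drafts: list[tuple[_SentenceDraft, str]] = []
        templates: list[str] = []
        for _ in range(n_sent):
            name = gen.template_names[
                int(rng.choice(len(gen.template_names), p=gen.template_probs))
            ]
            draft, header = gen.build(name)
            if header is not None:
                lines.append(header)
                section = header[:-1]
            else:
                section = ""
            lines.append(fio.detokenize(draft.words))
            if header is not None:
                lines.append("Family history:")  # close the section
            drafts.append((draft, section))
            templates.append(name)
        text = "\n".join(lines) + "\n"
        doc = Document(doc_id=f"doc{config.seed:03d}_{di:04d}", text=text)
        doc.sentences = fio.segment(text)
        assert len(doc.sentences) == len(drafts), "one generated sentence per line"
        for sid, (draft, section) in enumerate(drafts):
            sent = doc.sentences[sid]
            assert sent.words == draft.words, (sent.words, draft.words)
            entities = _attach_gold(sid, draft, sent.words, section)
            doc.entities.extend(entities)
            for hi_, dep_i in draft.relations:
                doc.relations.append(Relation(entities[hi_], entities[dep_i]))
        docs.append(SyntheticDocument(doc, templates))
    return docs


def _attach_gold(
    sid: int, draft: _SentenceDraft, words: list[str], section: str
) -> list[Entity]:
    """Materialize entities with gold attributes derived from the rules."""
    entities: list[Entity] = []
    for first, last, etype in draft.entities:
        mention = " ".join(words[first : last + 1])
        if etype == FAMILY_MEMBER:
            name = normalize_family_member(mention, section)
            side = (
                infer_side(name, words, first, section)
                if name != "EXCLUDED"
                else "NA"
            )
            entities.append(
                Entity(
                    sid, first, last, FAMILY_MEMBER,
                    side=side,
                    normalized_name=None if name == "EXCLUDED" else name,
                )
            )
        elif etype == OBSERVATION:
            entities.append(
                Entity(
                    sid, first, last, OBSERVATION,
                    negation=detect_negation(words, first),
                )
            )
        else:
            alive, healthy, _ = score_living_status(mention)
            entities.append(
                Entity(
                    sid, first, last, LIVING_STATUS,
                    alive_score=alive, healthy_score=healthy,
                )
            )
    return entities


def corpus_statistics(docs: list[SyntheticDocument]) -> dict:
    """Counts table mirroring the evaluation categories plus template mix."""
    stats = {
        "documents": len(docs),
        "sentences": 0,
        "FM: overall": 0, "FM: NA": 0, "FM: Maternal": 0, "FM: Paternal": 0,
        "OB": 0, "LS": 0,
        "FM-OB: overall": 0, "FM-OB: NA": 0, "FM-OB: Maternal": 0, "FM-OB: Paternal": 0,
        "FM-LS: overall": 0, "FM-LS: NA": 0, "FM-LS: Maternal": 0, "FM-LS: Paternal": 0,
        "templates": {},
    }
    for sd in docs:
        doc = sd.document
        stats["sentences"] += len(doc.sentences)
        for t in sd.templates:
            stats["templates"][t] = stats["templates"].get(t, 0) + 1
        for e in doc.entities:
            if e.is_family_member():
                stats["FM: overall"] += 1
                stats[f"FM: {e.side or 'NA'}"] += 1
            elif e.etype == OBSERVATION:
                stats["OB"] += 1
            else:
                stats["LS"] += 1
        for r in doc.relations:
            side = r.head.side or "NA"
            kind = "FM-OB" if r.dep.etype == OBSERVATION else "FM-LS"
            stats[f"{kind}: overall"] += 1
            stats[f"{kind}: {side}"] += 1
    return stats


# -- emission ---------------------------------------------------------------------


def sentence_corpus(
    docs: list[SyntheticDocument],
) -> list[tuple[list[str], tuple[list[Entity], list[Relation]]]]:
    """Flatten documents to per-sentence (tokens, (entities, relations))
    training pairs with sentence-local entity copies (sentence_id 0)."""
    pairs = []
    for sd in docs:
        doc = sd.document
        for sid, sent in enumerate(doc.sentences):
            ents = [
                dataclasses.replace(e, sentence_id=0)
                for e in doc.sentence_entities(sid)
            ]
            emap = {
                (e.first, e.last): ne
                for e, ne in zip(doc.sentence_entities(sid), ents)
            }
            rels = [
                Relation(emap[r.head.span], emap[r.dep.span])
                for r in doc.sentence_relations(sid)
            ]
            pairs.append((sent.words, (ents, rels)))
    return pairs


def gold_results(docs: list[SyntheticDocument], scheme: LabelScheme):
    """Evaluation-dialect gold derived from the gold annotations."""
    return [
        apply_rules(sd.document, sd.document.entities, sd.document.relations, scheme)
        for sd in docs
    ]


def write_corpus(
    docs: list[SyntheticDocument], out_dir: str | Path, config: GeneratorConfig
) -> None:
    """Emit documents (.txt), annotation TSV, both evaluation-dialect gold
    TSVs, and a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for sd in docs:
        (out / f"{sd.document.doc_id}.txt").write_text(
            sd.document.text, encoding="utf-8"
        )
    fio.write_annotations([sd.document for sd in docs], out / "annotations.tsv")
    results = gold_results(docs, LabelScheme(LabelScheme.THREE))
    fio.write_subtask1(results, out / "gold_subtask1.tsv")
    fio.write_subtask2(results, out / "gold_subtask2.tsv")
    manifest = {
        "generator": "famgraph.synthetic",
        "config": {
            **dataclasses.asdict(config),
            "sentences_per_document": list(config.sentences_per_document),
        },
        "tokenizer_version": fio.TOKENIZER_VERSION,
        "statistics": corpus_statistics(docs),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
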