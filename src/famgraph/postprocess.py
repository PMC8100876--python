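"""Rule-based postprocessing of decoded annotations.

Five rule groups turn raw model output into challenge-style results:

1. structure conversion — arc graphs to entities/relations, delegated to
   :func:`famgraph.codec.decode_graph`;
2. family-member normalization — mapping surface mentions (including
   compound possessives like ``father's father``) onto the normalized
   inventory, and excluding non-blood relatives such as partner-side kin;
3. side-of-family inference (three-type scheme) — first-degree relatives
   are NA, then section headings, then nearby ``maternal``/``paternal``
   indicators decide, defaulting to NA;
4. living-status scoring — keyword lookup sets the Alive and Healthy
   property scores (yes=2, NA=1, no=0); the total is their product;
5. observation negation — a cue keyword in the observation's sentence
   context (searched to the observation's left) marks it Negated unless a
   reversal phrase between the cue and the observation flips it back.

All operations are pure functions over their inputs; the lexicons driving
them ship as editable data files loaded at import time.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass
from importlib import resources
from typing import Optional, Sequence

from .types import (
    LIVING_STATUS,
    OBSERVATION,
    Document,
    Entity,
    LabelScheme,
    Relation,
)

logger = logging.getLogger(__name__)

EXCLUDED = "EXCLUDED"
NEGATED = "Negated"
NON_NEGATED = "Non_Negated"


def _load_json(name: str) -> dict:
    with resources.files("famgraph.lexicons").joinpath(name).open() as fh:
        return json.load(fh)


def load_disease_lexicon() -> list[str]:
    text = resources.files("famgraph.lexicons").joinpath("diseases.txt").read_text()
    return [ln.strip() for ln in text.splitlines() if ln.strip() and not ln.startswith("#")]


_KIN = _load_json("kinship.json")
_LS = _load_json("living_status.json")
_NEG = _load_json("negation.json")
_SECTIONS = _load_json("sections.json")

FIRST_DEGREE = frozenset(_KIN["normalized"]["degree1"])
NORMALIZED_NAMES = FIRST_DEGREE | frozenset(_KIN["normalized"]["degree2"])

_POSSESSIVE_RE = re.compile(r"\s*(?:'|’)\s*s\b", re.IGNORECASE)


# -- rule 2: family-member normalization ---------------------------------------


@dataclass(frozen=True)
class KinshipNormalizer:
    """Maps kinship surface expressions to the normalized inventory.

    Compound possessive chains resolve left-to-right through a composition
    table keyed by relation class; a composition without a normalized name
    (e.g. ``sister's son``) or a non-blood relative yields ``EXCLUDED``.
    """

    surface: dict
    classes: dict
    composition: dict
    exclusion_terms: frozenset

    @staticmethod
    def default() -> "KinshipNormalizer":
        return KinshipNormalizer(
            surface=_KIN["surface"],
            classes={k: tuple(v) for k, v in _KIN["classes"].items()},
            composition=_KIN["composition"],
            exclusion_terms=frozenset(_KIN["exclusion_terms"]),
        )

    def base(self, word: str) -> Optional[str]:
        return self.surface.get(word.lower())

    def compose(self, left: str, right: str) -> Optional[str]:
        lclass, _ = self.classes[left]
        rclass, rgender = self.classes[right]
        table = self.composition.get(f"{lclass},{rclass}")
        if table is None:
            return None
        return table.get(rgender)

    def normalize(self, mention_text: str) -> str:
        """Normalize one family-member mention (no section logic)."""
        text = mention_text.strip().lower()
        if any(term in text for term in self.exclusion_terms):
            return EXCLUDED
        chunks = [c.strip() for c in _POSSESSIVE_RE.split(text)]
        names: list[str] = []
        for chunk in chunks:
            if not chunk:
                continue
            # drop side indicators and articles inside the mention
            words = [
                w
                for w in re.findall(r"[a-z\-]+", chunk)
                if w not in ("maternal", "paternal", "the", "a", "an", "his", "her", "their")
            ]
            if len(words) != 1:
                logger.warning("unparseable kinship expression %r", mention_text)
                return EXCLUDED
            name = self.base(words[0])
            if name is None:
                logger.warning("unknown kinship term %r in %r", words[0], mention_text)
                return EXCLUDED
            names.append(name)
        if not names:
            return EXCLUDED
        result = names[0]
        for nxt in names[1:]:
            composed = self.compose(result, nxt)
            if composed is None:
                logger.warning(
                    "kinship composition %r . %r has no normalized name", result, nxt
                )
                return EXCLUDED
            result = composed
        return result


_DEFAULT_NORMALIZER = KinshipNormalizer.default()


def section_kind(section_heading: str) -> str:
    """Classify a section heading: 'maternal', 'paternal', 'exclude' or ''."""
    text = section_heading.lower()
    for kind in ("exclude", "maternal", "paternal"):
        for pat in _SECTIONS[kind]:
            if re.search(pat, text):
                return kind
    return ""


def normalize_family_member(
    mention_text: str,
    section_context: str = "",
    normalizer: KinshipNormalizer = _DEFAULT_NORMALIZER,
) -> str:
    """Normalized family-member name, or ``EXCLUDED``.

    ``section_context`` is the text of the enclosing section heading ("" if
    none); mentions under partner-side or in-law sections are excluded
    because the resulting relative is not in the normalized inventory.
    """
    if section_context and section_kind(section_context) == "exclude":
        return EXCLUDED
    return normalizer.normalize(mention_text)


# -- rule 3: side of family -----------------------------------------------------

SIDE_INDICATORS = {"maternal": "Maternal", "paternal": "Paternal"}


def infer_side(
    normalized_name: str,
    sentence_words: Sequence[str],
    first_token: int,
    section_context: str = "",
    window: int = 3,
) -> str:
    """Side of family for a (three-type scheme) family member.

    Priority: first-degree relatives are NA; then maternal/paternal family
    history sections; then a ``maternal``/``paternal`` indicator within
    ``window`` tokens to the left of the mention; else NA.
    """
    if normalized_name in FIRST_DEGREE:
        return "NA"
    kind = section_kind(section_context) if section_context else ""
    if kind in ("maternal", "paternal"):
        return kind.capitalize()
    lo = max(0, first_token - window)
    for w in sentence_words[lo : first_token + 1]:
        side = SIDE_INDICATORS.get(w.lower().strip(",.;:"))
        if side:
            return side
    return "NA"


# -- rule 4: living-status scoring ---------------------------------------------


def _phrase_found(phrase: str, text: str) -> bool:
    return re.search(rf"\b{re.escape(phrase)}\b", text) is not None


def score_living_status(ls_text: str) -> tuple[int, int, int]:
    """(alive, healthy, total) scores of a living-status mention.

    Each property scores 2 if an affirming keyword is present, 0 if a
    negating keyword is present (Alive only), and otherwise NA = 1; the
    total is alive x healthy, hence always in {0, 1, 2, 4}.
    """
    text = " ".join(ls_text.lower().split())
    alive = 1
    if any(_phrase_found(k, text) for k in _LS["alive_no"]):
        alive = 0
    elif any(_phrase_found(k, text) for k in _LS["alive_yes"]):
        alive = 2
    healthy = 2 if any(_phrase_found(k, text) for k in _LS["healthy_yes"]) else 1
    return alive, healthy, alive * healthy


# -- rule 5: observation negation ------------------------------------------------

NEGATION_CUES = frozenset(_NEG["cues"])
REVERSAL_PHRASES = tuple(_NEG["reversal_phrases"])


def detect_negation(
    sentence_words: Sequence[str],
    obs_first: int,
    extra_reversal_phrases: Sequence[str] = (),
) -> str:
    """Negation status of the observation starting at token ``obs_first``.

    A cue keyword among the tokens to the observation's left marks it
    Negated; a reversal phrase between the cue and the observation flips it
    back to Non_Negated.  Matching is case-insensitive on token boundaries.
    """
    words = [w.lower() for w in sentence_words]
    cue_pos = None
    for i in range(obs_first):
        if words[i] in NEGATION_CUES:
            cue_pos = i
    if cue_pos is None:
        return NON_NEGATED
    between = " ".join(words[cue_pos + 1 : obs_first])
    for phrase in tuple(REVERSAL_PHRASES) + tuple(extra_reversal_phrases):
        if _phrase_found(phrase.lower(), between):
            return NON_NEGATED
    return NEGATED


def detect_negation_text(observation_text: str, sentence_context: str) -> str:
    """String-based convenience wrapper around :func:`detect_negation`."""
    words = sentence_context.split()
    obs_words = observation_text.lower().split()
    lowered = [w.lower().strip(",.;:") for w in words]
    for start in range(len(words) - len(obs_words) + 1):
        if lowered[start : start + len(obs_words)] == obs_words:
            return detect_negation(lowered, start)
    return NON_NEGATED


# -- full document pass ---------------------------------------------------------


@dataclass(frozen=True)
class FamilyMemberResult:
    doc_id: str
    name: str
    side: str


@dataclass(frozen=True)
class ObservationResult:
    doc_id: str
    text: str
    negation: str


@dataclass(frozen=True)
class LivingStatusRelation:
    doc_id: str
    family_member: str
    side: str
    score: int


@dataclass(frozen=True)
class ObservationRelation:
    doc_id: str
    family_member: str
    side: str
    observation: str
    negation: str


@dataclass
class DocumentResult:
    family_members: list[FamilyMemberResult]
    observations: list[ObservationResult]
    ls_relations: list[LivingStatusRelation]
    ob_relations: list[ObservationRelation]


def apply_rules(
    doc: Document,
    entities: list[Entity],
    relations: list[Relation],
    scheme: LabelScheme,
    window: int = 3,
) -> DocumentResult:
    """Rule groups 2-5 over decoded annotations of one document.

    ``entities``/``relations`` carry sentence-level spans (rule group 1,
    the structure conversion, has already produced them).  Family members
    that normalize to ``EXCLUDED`` are dropped together with their
    relations.
    """
    fm_results: dict[tuple[int, int, int], tuple[str, str]] = {}
    fms: list[FamilyMemberResult] = []
    obs: list[ObservationResult] = []
    ls_rel: list[LivingStatusRelation] = []
    ob_rel: list[ObservationRelation] = []

    def _unique(items: list) -> list:
        # document-level results are fact sets; keep first occurrence
        seen, out = set(), []
        for it in items:
            if it not in seen:
                seen.add(it)
                out.append(it)
        return out

    def sent(e: Entity):
        return doc.sentences[e.sentence_id]

    for e in entities:
        if not e.is_family_member():
            continue
        s = sent(e)
        mention = e.text(s.tokens)
        name = normalize_family_member(mention, s.section)
        if name == EXCLUDED:
            continue
        if scheme.scheme == LabelScheme.FIVE and e.side is not None:
            side = e.side
        else:
            side = infer_side(name, s.words, e.first, s.section, window)
        fm_results[(e.sentence_id, e.first, e.last)] = (name, side)
        fms.append(FamilyMemberResult(doc.doc_id, name, side))

    for e in entities:
        if e.etype != OBSERVATION:
            continue
        s = sent(e)
        negation = detect_negation(s.words, e.first)
        obs.append(ObservationResult(doc.doc_id, e.text(s.tokens), negation))

    for r in relations:
        key = (r.head.sentence_id, r.head.first, r.head.last)
        if key not in fm_results:
            continue  # head excluded by rule 2
        name, side = fm_results[key]
        s = sent(r.dep)
        if r.dep.etype == LIVING_STATUS:
            _, _, total = score_living_status(r.dep.text(s.tokens))
            ls_rel.append(LivingStatusRelation(doc.doc_id, name, side, total))
        elif r.dep.etype == OBSERVATION:
            negation = detect_negation(s.words, r.dep.first)
            ob_rel.append(
                ObservationRelation(
                    doc.doc_id, name, side, r.dep.text(s.tokens), negation
                )
            )
    return DocumentResult(_unique(fms), _unique(obs), _unique(ls_rel), _unique(ob_rel))
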