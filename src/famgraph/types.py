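"""Core domain types for family-history information extraction.

A clinical document is segmented into sentences of tokens.  Annotations
consist of entities (family members, observations, living-status phrases)
and binary relations from a family member to an observation or
living-status entity.  The unified target structure for the joint model is
an :class:`ArcGraph`: one head index and one arc label per token, with a
dummy ROOT node at head index 0 (tokens are addressed 1..n as heads; the
stored token lists remain 0-based everywhere else).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

# Entity types (three-type scheme) -----------------------------------------

FAMILY_MEMBER = "FamilyMember"
OBSERVATION = "Observation"
LIVING_STATUS = "LivingStatus"

# Five-type scheme folds side-of-family into the family-member label.
FM_NA = "FM-NA"
FM_MATERNAL = "FM-Maternal"
FM_PATERNAL = "FM-Paternal"

SIDES = ("NA", "Maternal", "Paternal")

NULL_LABEL = "NULL"
APP_LABEL = "app"

_FM_LABEL_BY_SIDE = {"NA": FM_NA, "Maternal": FM_MATERNAL, "Paternal": FM_PATERNAL}
_SIDE_BY_FM_LABEL = {v: k for k, v in _FM_LABEL_BY_SIDE.items()}


@dataclass(frozen=True)
class Token:
    """A token with 0-based half-open character offsets into its document."""

    index: int
    text: str
    char_start: int = 0
    char_end: int = 0

    @staticmethod
    def sequence(words: Sequence[str]) -> list["Token"]:
        """Build a token list from plain words, space-joined offsets."""
        toks = []
        pos = 0
        for i, w in enumerate(words):
            toks.append(Token(i, w, pos, pos + len(w)))
            pos += len(w) + 1
        return toks


@dataclass(frozen=True)
class Entity:
    """An annotated mention: inclusive token span plus type and attributes.

    Which attributes may be set depends on ``etype``: family members carry
    ``side`` and ``normalized_name``; observations carry ``negation``;
    living-status entities carry ``alive_score``/``healthy_score`` (each in
    {0,1,2}) whose product is the total living-status score.
    """

    sentence_id: int
    first: int
    last: int
    etype: str
    side: Optional[str] = None
    normalized_name: Optional[str] = None
    negation: Optional[str] = None
    alive_score: Optional[int] = None
    healthy_score: Optional[int] = None

    def __post_init__(self) -> None:
        if self.first > self.last:
            raise ValueError(f"entity span [{self.first}, {self.last}] is empty")
        if self.side is not None and self.side not in SIDES:
            raise ValueError(f"unknown side {self.side!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.first, self.last)

    @property
    def ls_score(self) -> Optional[int]:
        if self.alive_score is None or self.healthy_score is None:
            return None
        return self.alive_score * self.healthy_score

    def is_family_member(self) -> bool:
        return self.etype in (FAMILY_MEMBER, FM_NA, FM_MATERNAL, FM_PATERNAL)

    def text(self, tokens: Sequence[Token]) -> str:
        return " ".join(tokens[i].text for i in range(self.first, self.last + 1))

    def core(self) -> "Entity":
        """The identity-relevant part (span + type), attributes stripped."""
        return Entity(self.sentence_id, self.first, self.last, self.etype)

    def with_attrs(self, **kw) -> "Entity":
        return replace(self, **kw)


@dataclass(frozen=True)
class Relation:
    """Directed relation from a family-member entity to an observation or
    living-status entity in the same sentence."""

    head: Entity
    dep: Entity

    def __post_init__(self) -> None:
        if self.head.sentence_id != self.dep.sentence_id:
            raise ValueError("cross-sentence relations are not representable")
        if not self.head.is_family_member() or self.dep.is_family_member():
            raise ValueError(
                "relations run from a family member to an observation or "
                "living-status entity"
            )

    def core(self) -> "Relation":
        return Relation(self.head.core(), self.dep.core())


@dataclass(frozen=True)
class ArcGraph:
    """Per-token head indices and arc labels for one sentence.

    ``heads[j]`` is in {0..n} where 0 is the dummy ROOT and k>0 refers to
    the k-th token (1-based); ``labels[j]`` comes from the active
    :class:`LabelScheme`.  ``heads`` and ``labels`` are indexed by 0-based
    token position j.
    """

    heads: tuple[int, ...]
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.heads) != len(self.labels):
            raise ValueError(
                f"heads ({len(self.heads)}) and labels ({len(self.labels)}) "
                "must have equal length"
            )
        n = len(self.heads)
        for j, h in enumerate(self.heads):
            if not 0 <= h <= n:
                raise ValueError(f"head {h} of token {j} outside 0..{n}")

    def __len__(self) -> int:
        return len(self.heads)


@dataclass(frozen=True)
class LabelScheme:
    """Arc-label vocabulary: NULL, app, plus the entity-type labels.

    ``three_type`` leaves side-of-family to rule-based postprocessing;
    ``five_type`` splits the family-member label by side.
    """

    scheme: str

    THREE = "three_type"
    FIVE = "five_type"

    def __post_init__(self) -> None:
        if self.scheme not in (self.THREE, self.FIVE):
            raise ValueError(f"unknown scheme {self.scheme!r}")

    @property
    def entity_types(self) -> tuple[str, ...]:
        if self.scheme == self.THREE:
            return (FAMILY_MEMBER, OBSERVATION, LIVING_STATUS)
        return (FM_NA, FM_MATERNAL, FM_PATERNAL, OBSERVATION, LIVING_STATUS)

    @property
    def labels(self) -> tuple[str, ...]:
        return (NULL_LABEL, APP_LABEL) + self.entity_types

    def __len__(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def entity_label(self, entity: Entity) -> str:
        """The arc label carried by an entity's last token under this scheme."""
        if entity.etype in self.entity_types:
            return entity.etype
        if self.scheme == self.FIVE and entity.etype == FAMILY_MEMBER:
            return _FM_LABEL_BY_SIDE[entity.side or "NA"]
        if self.scheme == self.THREE and entity.etype in _SIDE_BY_FM_LABEL:
            return FAMILY_MEMBER
        raise ValueError(f"entity type {entity.etype!r} not encodable in {self.scheme}")

    @staticmethod
    def side_of_label(label: str) -> Optional[str]:
        return _SIDE_BY_FM_LABEL.get(label)


@dataclass
class Sentence:
    """Tokens of one sentence plus the section heading it falls under."""

    tokens: list[Token]
    section: str = ""

    def __len__(self) -> int:
        return len(self.tokens)

    @property
    def words(self) -> list[str]:
        return [t.text for t in self.tokens]


@dataclass
class Document:
    """A clinical document: raw text, sentences, and gold annotations."""

    doc_id: str
    text: str = ""
    sentences: list[Sentence] = field(default_factory=list)
    entities: list[Entity] = field(default_factory=list)
    relations: list[Relation] = field(default_factory=list)

    def sentence_entities(self, sid: int) -> list[Entity]:
        return [e for e in self.entities if e.sentence_id == sid]

    def sentence_relations(self, sid: int) -> list[Relation]:
        return [r for r in self.relations if r.head.sentence_id == sid]
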