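"""Document and annotation IO.

Documents are plain UTF-8 text, one per file.  A rule-based, versioned
tokenizer records 0-based half-open character offsets so detokenization
reproduces the original string; sentence splitting is line- and
punctuation-based, and lines ending with a colon act as section headings
that scope the sentences after them.

Three TSV dialects are read and written:

* ``annotation`` — token-span entities and relations per document
  (the training/gold interchange format);
* ``subtask1`` — entity-level results: family members with side, and
  observations with negation;
* ``subtask2`` — relation-level results: family member/side with either a
  living-status score or an observation + negation.

Token indices in files are 0-based; the 1-based-plus-ROOT head convention
exists only inside :class:`~famgraph.types.ArcGraph`.
"""

from __future__ import annotations

import logging
import re
from pathlib import Path
from typing import Iterable, Sequence

from .postprocess import (
    DocumentResult,
    FamilyMemberResult,
    LivingStatusRelation,
    ObservationRelation,
    ObservationResult,
)
from .types import Document, Entity, Relation, Sentence, Token

logger = logging.getLogger(__name__)

TOKENIZER_VERSION = "ws-punct-1"

_TOKEN_RE = re.compile(r"[A-Za-z0-9_\-]+|'s|’s|[^\w\s]")
_SENT_END = {".", "!", "?"}

# tokens that attach to the previous token without a space when rendering
NO_SPACE_BEFORE = {",", ".", ";", ":", "!", "?", "'s", "’s", ")", "]"}


def tokenize(text: str, base_offset: int = 0) -> list[Token]:
    """Tokenize one sentence-sized string, recording character offsets."""
    toks = []
    for i, m in enumerate(_TOKEN_RE.finditer(text)):
        toks.append(Token(i, m.group(), base_offset + m.start(), base_offset + m.end()))
    return toks


def detokenize(words: Sequence[str]) -> str:
    """Render tokens back to text (inverse of the generator's rendering)."""
    out: list[str] = []
    for w in words:
        if out and w not in NO_SPACE_BEFORE:
            out.append(" ")
        out.append(w)
    return "".join(out)


def segment(text: str) -> list[Sentence]:
    """Sentence segmentation with section tracking.

    Lines ending with a colon are section headings (they scope following
    sentences and are not themselves sentences); other lines are split at
    sentence-final punctuation.
    """
    sentences: list[Sentence] = []
    section = ""
    offset = 0
    for line in text.split("\n"):
        stripped = line.strip()
        if stripped.endswith(":"):
            section = stripped[:-1].strip()
        elif stripped:
            line_toks = tokenize(line, base_offset=offset)
            start = 0
            for i, t in enumerate(line_toks):
                if t.text in _SENT_END or i == len(line_toks) - 1:
                    chunk = line_toks[start : i + 1]
                    if chunk:
                        toks = [
                            Token(j, t2.text, t2.char_start, t2.char_end)
                            for j, t2 in enumerate(chunk)
                        ]
                        sentences.append(Sentence(toks, section=section))
                    start = i + 1
        offset += len(line) + 1
    return sentences


def read_document(path: str | Path) -> Document:
    path = Path(path)
    try:
        text = path.read_text(encoding="utf-8")
    except UnicodeDecodeError as exc:
        raise ValueError(f"{path}: undecodable bytes at {exc.start}") from exc
    return Document(doc_id=path.stem, text=text, sentences=segment(text))


def read_documents(path: str | Path) -> list[Document]:
    """All ``*.txt`` documents under a directory (or one file), sorted."""
    path = Path(path)
    files = sorted(path.glob("*.txt")) if path.is_dir() else [path]
    return [read_document(f) for f in files]


# -- annotation dialect ---------------------------------------------------------

_ANN_HEADER = (
    "# famgraph annotation v1: doc_id sentence kind "
    "(T: first last etype side normalized negation alive healthy | "
    "R: head_first head_last dep_first dep_last)"
)


def write_annotations(docs: Iterable[Document], path: str | Path) -> None:
    lines = [_ANN_HEADER]
    for doc in docs:
        for e in doc.entities:
            lines.append(
                "\t".join(
                    [
                        doc.doc_id,
                        str(e.sentence_id),
                        "T",
                        str(e.first),
                        str(e.last),
                        e.etype,
                        e.side or "",
                        e.normalized_name or "",
                        e.negation or "",
                        "" if e.alive_score is None else str(e.alive_score),
                        "" if e.healthy_score is None else str(e.healthy_score),
                    ]
                )
            )
        for r in doc.relations:
            lines.append(
                "\t".join(
                    [
                        doc.doc_id,
                        str(r.head.sentence_id),
                        "R",
                        str(r.head.first),
                        str(r.head.last),
                        str(r.dep.first),
                        str(r.dep.last),
                    ]
                )
            )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_annotations(path: str | Path) -> dict[str, tuple[list[Entity], list[Relation]]]:
    """Entities and relations keyed by doc_id; row-level diagnostics."""
    out: dict[str, tuple[list[Entity], list[Relation]]] = {}
    entity_index: dict[tuple[str, int, int, int], Entity] = {}
    pending_relations: list[tuple[int, str, int, int, int, int, int]] = []
    text = Path(path).read_text(encoding="utf-8")
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        kind = cols[2] if len(cols) > 2 else "?"
        try:
            if kind == "T":
                if len(cols) != 11:
                    raise ValueError(f"T row needs 11 columns, got {len(cols)}")
                doc_id, sid = cols[0], int(cols[1])
                e = Entity(
                    sentence_id=sid,
                    first=int(cols[3]),
                    last=int(cols[4]),
                    etype=cols[5],
                    side=cols[6] or None,
                    normalized_name=cols[7] or None,
                    negation=cols[8] or None,
                    alive_score=int(cols[9]) if cols[9] else None,
                    healthy_score=int(cols[10]) if cols[10] else None,
                )
                out.setdefault(doc_id, ([], []))[0].append(e)
                entity_index[(doc_id, sid, e.first, e.last)] = e
            elif kind == "R":
                if len(cols) != 7:
                    raise ValueError(f"R row needs 7 columns, got {len(cols)}")
                pending_relations.append(
                    (ln, cols[0], int(cols[1]), int(cols[3]), int(cols[4]), int(cols[5]), int(cols[6]))
                )
            else:
                raise ValueError(f"unknown row kind {kind!r}")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln}: {exc}") from exc
    for ln, doc_id, sid, hf, hl, df, dl in pending_relations:
        head = entity_index.get((doc_id, sid, hf, hl))
        dep = entity_index.get((doc_id, sid, df, dl))
        if head is None or dep is None:
            raise ValueError(f"{path}:{ln}: relation endpoints not among entities")
        out.setdefault(doc_id, ([], []))[1].append(Relation(head, dep))
    return out


# -- subtask dialects ------------------------------------------------------------


def write_subtask1(results: Iterable[DocumentResult], path: str | Path) -> None:
    lines = []
    for res in results:
        for fm in res.family_members:
            lines.append(f"{fm.doc_id}\tFamilyMember\t{fm.name}\t{fm.side}")
        for ob in res.observations:
            lines.append(f"{ob.doc_id}\tObservation\t{ob.text}\t{ob.negation}")
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def write_subtask2(results: Iterable[DocumentResult], path: str | Path) -> None:
    lines = []
    for res in results:
        for ls in res.ls_relations:
            lines.append(
                f"{ls.doc_id}\tFamilyMember\t{ls.family_member}\t{ls.side}"
                f"\tLivingStatus\t{ls.score}"
            )
        for ob in res.ob_relations:
            lines.append(
                f"{ob.doc_id}\tFamilyMember\t{ob.family_member}\t{ob.side}"
                f"\tObservation\t{ob.observation}\t{ob.negation}"
            )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def read_subtask1(
    path: str | Path,
) -> tuple[list[FamilyMemberResult], list[ObservationResult]]:
    fms: list[FamilyMemberResult] = []
    obs: list[ObservationResult] = []
    for ln, cols in _rows(path):
        if len(cols) >= 2 and cols[1] == "FamilyMember":
            if len(cols) != 4:
                raise ValueError(f"{path}:{ln}: FamilyMember row needs 4 columns")
            fms.append(FamilyMemberResult(cols[0], cols[2], cols[3]))
        elif len(cols) >= 2 and cols[1] == "Observation":
            if len(cols) == 3:  # negation column optional on input
                obs.append(ObservationResult(cols[0], cols[2], ""))
            elif len(cols) == 4:
                obs.append(ObservationResult(cols[0], cols[2], cols[3]))
            else:
                raise ValueError(f"{path}:{ln}: Observation row needs 3 or 4 columns")
        else:
            raise ValueError(f"{path}:{ln}: unrecognized subtask1 row")
    return fms, obs


def read_subtask2(
    path: str | Path,
) -> tuple[list[LivingStatusRelation], list[ObservationRelation]]:
    ls: list[LivingStatusRelation] = []
    ob: list[ObservationRelation] = []
    for ln, cols in _rows(path):
        if len(cols) >= 5 and cols[4] == "LivingStatus":
            if len(cols) != 6:
                raise ValueError(f"{path}:{ln}: LivingStatus row needs 6 columns")
            ls.append(LivingStatusRelation(cols[0], cols[2], cols[3], int(cols[5])))
        elif len(cols) >= 5 and cols[4] == "Observation":
            if len(cols) != 7:
                raise ValueError(f"{path}:{ln}: Observation row needs 7 columns")
            ob.append(ObservationRelation(cols[0], cols[2], cols[3], cols[5], cols[6]))
        else:
            raise ValueError(f"{path}:{ln}: unrecognized subtask2 row")
    return ls, ob


def _rows(path: str | Path):
    text = Path(path).read_text(encoding="utf-8")
    for ln, raw in enumerate(text.splitlines(), start=1):
        line = raw.rstrip("\r")
        if not line or line.startswith("#"):
            continue
        yield ln, line.split("\t")
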