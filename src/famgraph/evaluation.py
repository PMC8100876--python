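"""Challenge-style scoring with partial observation matching.

Subtask 1 scores entity-level results: family members match on exact
(normalized name, side); observations match if the predicted text is a
contiguous token subsequence of the gold text (partial matching — a
predicted "diabetes" against gold "type 2 diabetes" is a true positive).
Subtask 2 scores relation-level results: (family member, side,
living-status score) exactly, and (family member, side, observation,
negation) with the same partial matching on the observation text.

Matching is one-to-one and greedy in document order, with exact matches
consumed before partial ones; duplicate identical predictions are collapsed
before counting.  Precision, recall and F1 use the 0-on-zero-denominator
convention.
"""

from __future__ import annotations

import json
import logging
from collections import Counter
from dataclasses import dataclass, field

from .postprocess import (
    FamilyMemberResult,
    LivingStatusRelation,
    ObservationRelation,
    ObservationResult,
)

logger = logging.getLogger(__name__)


@dataclass
class MatchCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0

    def __iadd__(self, other: "MatchCounts") -> "MatchCounts":
        self.tp += other.tp
        self.fp += other.fp
        self.fn += other.fn
        return self


def prf(counts: MatchCounts) -> tuple[float, float, float]:
    """Precision, recall, F1 with zero-denominator cases returning 0."""
    tp, fp, fn = counts.tp, counts.fp, counts.fn
    p = tp / (tp + fp) if tp + fp else 0.0
    r = tp / (tp + fn) if tp + fn else 0.0
    f1 = 2 * p * r / (p + r) if p + r else 0.0
    return p, r, f1


def observation_text_match(pred: str, gold: str, symmetric: bool = False) -> bool:
    """Partial matching: predicted tokens form a contiguous subsequence of
    the gold tokens (case-insensitive).  ``symmetric=True`` also credits the
    converse containment."""
    pt, gt = pred.lower().split(), gold.lower().split()

    def contains(outer, inner):
        if not inner:
            return False
        return any(
            outer[i : i + len(inner)] == inner
            for i in range(len(outer) - len(inner) + 1)
        )

    return contains(gt, pt) or (symmetric and contains(pt, gt))


def _dedupe(items: list) -> list:
    counts = Counter(items)
    for item, c in counts.items():
        if c > 1:
            logger.info("collapsed %d duplicate predictions of %r", c - 1, item)
    seen = set()
    out = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


def match_items(gold: list, pred: list, match_fn) -> MatchCounts:
    """Greedy one-to-one matching: exact equality first, then ``match_fn``.

    Results are document-level fact sets, so duplicate identical items are
    collapsed on both sides before counting.  Gold items are each matched
    at most once.  Returns tp/fp/fn counts (tp + fn == unique gold items,
    tp + fp == unique predictions).
    """
    gold = _dedupe(gold)
    pred = _dedupe(pred)
    gold_free = list(range(len(gold)))
    matched_pred: set[int] = set()
    # pass 1: exact
    for pi, p in enumerate(pred):
        for slot, gi in enumerate(gold_free):
            if gold[gi] == p:
                matched_pred.add(pi)
                gold_free.pop(slot)
                break
    # pass 2: partial / predicate
    for pi, p in enumerate(pred):
        if pi in matched_pred:
            continue
        for slot, gi in enumerate(gold_free):
            if match_fn(p, gold[gi]):
                matched_pred.add(pi)
                gold_free.pop(slot)
                break
    tp = len(matched_pred)
    return MatchCounts(tp=tp, fp=len(pred) - tp, fn=len(gold_free))


# -- item match predicates -------------------------------------------------------


def _fm_match(p: FamilyMemberResult, g: FamilyMemberResult) -> bool:
    return p == g  # exact (doc, normalized name, side)


def _ob_match(ignore_negation: bool, symmetric: bool):
    def fn(p: ObservationResult, g: ObservationResult) -> bool:
        if p.doc_id != g.doc_id:
            return False
        if not ignore_negation and p.negation != g.negation:
            return False
        return observation_text_match(p.text, g.text, symmetric)

    return fn


def _obrel_match(symmetric: bool):
    def fn(p: ObservationRelation, g: ObservationRelation) -> bool:
        return (
            p.doc_id == g.doc_id
            and p.family_member == g.family_member
            and p.side == g.side
            and p.negation == g.negation
            and observation_text_match(p.observation, g.observation, symmetric)
        )

    return fn


def _lsrel_match(p: LivingStatusRelation, g: LivingStatusRelation) -> bool:
    return p == g


# -- reports ---------------------------------------------------------------------


@dataclass
class EvalReport:
    """Per-category and overall precision/recall/F1."""

    subtask: int
    categories: dict[str, dict] = field(default_factory=dict)

    def add(self, name: str, counts: MatchCounts) -> None:
        p, r, f1 = prf(counts)
        self.categories[name] = {
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "precision": p,
            "recall": r,
            "f1": f1,
        }

    def __getitem__(self, name: str) -> dict:
        return self.categories[name]

    def to_json(self) -> str:
        return json.dumps({"subtask": self.subtask, "categories": self.categories}, indent=2)

    def pretty(self) -> str:
        rows = [f"subtask{self.subtask} evaluation"]
        w = max(len(k) for k in self.categories) if self.categories else 8
        rows.append(f"{'category':<{w}}  {'P':>6}  {'R':>6}  {'F1':>6}   tp/fp/fn")
        for name, m in self.categories.items():
            rows.append(
                f"{name:<{w}}  {m['precision']:>6.4f}  {m['recall']:>6.4f}  "
                f"{m['f1']:>6.4f}   {m['tp']}/{m['fp']}/{m['fn']}"
            )
        return "\n".join(rows)


def _by_side(items: list) -> dict[str, list]:
    out: dict[str, list] = {"NA": [], "Maternal": [], "Paternal": []}
    for it in items:
        out.setdefault(it.side, []).append(it)
    return out


def evaluate_subtask1(
    gold_fm: list[FamilyMemberResult],
    gold_ob: list[ObservationResult],
    pred_fm: list[FamilyMemberResult],
    pred_ob: list[ObservationResult],
    ignore_negation: bool = True,
    symmetric_partial: bool = False,
) -> EvalReport:
    """Entity-level report: FM overall and by side, OB, and overall.

    ``ignore_negation`` (default) scores observations on text alone, the
    negation attribute being a subtask-2 matter; set False to require
    agreement.
    """
    report = EvalReport(subtask=1)
    fm_counts = match_items(gold_fm, pred_fm, _fm_match)
    report.add("FM: overall", fm_counts)
    gside, pside = _by_side(gold_fm), _by_side(pred_fm)
    for side in ("NA", "Maternal", "Paternal"):
        report.add(f"FM: {side}", match_items(gside[side], pside[side], _fm_match))
    ob_counts = match_items(
        gold_ob, pred_ob, _ob_match(ignore_negation, symmetric_partial)
    )
    report.add("OB", ob_counts)
    total = MatchCounts()
    total += fm_counts
    total += ob_counts
    report.add("Overall", total)
    return report


def evaluate_subtask2(
    gold_ls: list[LivingStatusRelation],
    gold_ob: list[ObservationRelation],
    pred_ls: list[LivingStatusRelation],
    pred_ob: list[ObservationRelation],
    symmetric_partial: bool = False,
) -> EvalReport:
    """Relation-level report: FM-OB and FM-LS overall and by side."""
    report = EvalReport(subtask=2)
    ob_counts = match_items(gold_ob, pred_ob, _obrel_match(symmetric_partial))
    report.add("FM-OB: overall", ob_counts)
    gside, pside = _by_side(gold_ob), _by_side(pred_ob)
    for side in ("NA", "Maternal", "Paternal"):
        report.add(
            f"FM-OB: {side}",
            match_items(gside[side], pside[side], _obrel_match(symmetric_partial)),
        )
    ls_counts = match_items(gold_ls, pred_ls, _lsrel_match)
    report.add("FM-LS: overall", ls_counts)
    gside, pside = _by_side(gold_ls), _by_side(pred_ls)
    for side in ("NA", "Maternal", "Paternal"):
        report.add(
            f"FM-LS: {side}", match_items(gside[side], pside[side], _lsrel_match)
        )
    total = MatchCounts()
    total += ob_counts
    total += ls_counts
    report.add("Overall", total)
    return report


def evaluate_files(gold_path, pred_path, subtask: int) -> EvalReport:
    """Score a prediction TSV against a gold TSV in the same dialect."""
    from . import io as fio

    if subtask == 1:
        gf, go = fio.read_subtask1(gold_path)
        pf, po = fio.read_subtask1(pred_path)
        return evaluate_subtask1(gf, go, pf, po)
    if subtask == 2:
        gl, go2 = fio.read_subtask2(gold_path)
        pl, po2 = fio.read_subtask2(pred_path)
        return evaluate_subtask2(gl, go2, pl, po2)
    raise ValueError("subtask must be 1 or 2")
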