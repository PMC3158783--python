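"""Correspondence between structural words and interval annotations.

Annotations are feature-table-style records: a protein chain, a 1-based
inclusive residue interval, a feature key (first level, e.g. NP_BIND,
CA_BIND, Binding, Repeat, Disulfide, Active site) and a free-text
description (second level, e.g. the ligand: ATP/GTP, NAD(P), SAH/SAM).

Two scores quantify the match between a word and an annotation label:

* precision — the fraction of the word's fragments that carry the
  annotation (a word is *functional* when it is extreme
  superfamily-specific and some label reaches precision ≥ 0.40);
* sensitivity — the fraction of loop-located annotation instances
  covered by the word (annotations lying entirely in regular secondary
  structure are discarded from the denominator).

A fragment matches an annotation when they share at least
``min_overlap`` residues on the same protein chain (default 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .classify import WordSummary
from .loops import LoopSequence, WordOccurrence

LEVELS = ("feature", "description")


@dataclass(frozen=True)
class AnnotationRecord:
    protein_id: str
    chain_id: str
    residue_start: int  # 1-based inclusive
    residue_end: int
    feature_key: str
    description: str = ""

    def __post_init__(self) -> None:
        if self.residue_start > self.residue_end:
            raise ValueError("annotation interval reversed")

    def label(self, level: str) -> str:
        if level == "feature":
            return self.feature_key
        if level == "description":
            return " ".join(self.description.split())
        raise ValueError(f"unknown level {level!r}")


def _overlap(a: tuple[int, int], b: tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]) + 1)


def fragment_matches(
    occ: WordOccurrence,
    annotations: list[AnnotationRecord],
    level: str = "feature",
    min_overlap: int = 1,
) -> set[str]:
    """Labels of all annotations sharing ≥ min_overlap residues with the
    fragment on the same protein chain."""
    if min_overlap < 1:
        raise ValueError("min_overlap must be >= 1")
    out = set()
    for ann in annotations:
        if (ann.protein_id, ann.chain_id) != (occ.protein_id, occ.chain_id):
            continue
        if _overlap(occ.residue_span, (ann.residue_start, ann.residue_end)) >= min_overlap:
            out.add(ann.label(level))
    return out


def precision(
    word: str,
    occurrences: list[WordOccurrence],
    annotations: list[AnnotationRecord],
    label: str,
    level: str = "feature",
    min_overlap: int = 1,
) -> float:
    """Fraction of the word's fragments annotated with ``label``."""
    frags = [o for o in occurrences if o.word == word]
    if not frags:
        raise ValueError(f"word {word!r} has no occurrences; precision undefined")
    label = " ".join(label.split())
    hit = sum(
        1 for o in frags if label in fragment_matches(o, annotations, level, min_overlap)
    )
    return hit / len(frags)


def _loop_located(
    annotations: list[AnnotationRecord], loops: list[LoopSequence], label: str, level: str
) -> list[AnnotationRecord]:
    label = " ".join(label.split())
    spans: dict[tuple[str, str], list[tuple[int, int]]] = {}
    for lp in loops:
        spans.setdefault((lp.protein_id, lp.chain_id), []).append(lp.residue_span)
    kept = []
    for ann in annotations:
        if ann.label(level) != label:
            continue
        for span in spans.get((ann.protein_id, ann.chain_id), []):
            if _overlap(span, (ann.residue_start, ann.residue_end)) >= 1:
                kept.append(ann)
                break
    return kept


def sensitivity(
    word: str,
    occurrences: list[WordOccurrence],
    annotations: list[AnnotationRecord],
    label: str,
    loops: list[LoopSequence],
    level: str = "feature",
    min_overlap: int = 1,
) -> float:
    """Fraction of loop-located instances of ``label`` covered by the word.

    One record (one interval) is one instance.  Instances with no
    residue inside any loop are discarded; an empty denominator is an
    error (the score is undefined).
    """
    denom = _loop_located(annotations, loops, label, level)
    if not denom:
        raise ValueError(f"no loop-located annotation instance with label {label!r}")
    frags = [o for o in occurrences if o.word == word]
    hit = 0
    for ann in denom:
        for o in frags:
            if (o.protein_id, o.chain_id) == (ann.protein_id, ann.chain_id) and _overlap(
                o.residue_span, (ann.residue_start, ann.residue_end)
            ) >= min_overlap:
                hit += 1
                break
    return hit / len(denom)


def score_words(
    words: list[str],
    occurrences: list[WordOccurrence],
    annotations: list[AnnotationRecord],
    loops: list[LoopSequence],
    min_overlap: int = 1,
) -> pd.DataFrame:
    """Precision/sensitivity of each word against every annotation label
    present, at both annotation levels.

    Sensitivity is left missing for labels with no loop-located
    instance.
    """
    rows = []
    occ_by_word: dict[str, list[WordOccurrence]] = {}
    for o in occurrences:
        occ_by_word.setdefault(o.word, []).append(o)
    for level in LEVELS:
        labels = sorted({a.label(level) for a in annotations} - {""})
        for label in labels:
            n_ann = sum(1 for a in annotations if a.label(level) == label)
            for word in words:
                frags = occ_by_word.get(word, [])
                if not frags:
                    continue
                prec = precision(word, frags, annotations, label, level, min_overlap)
                try:
                    sens = sensitivity(
                        word, frags, annotations, label, loops, level, min_overlap
                    )
                except ValueError:
                    sens = float("nan")
                rows.append(
                    {
                        "word": word,
                        "label": label,
                        "level": level,
                        "precision": prec,
                        "sensitivity": sens,
                        "n_fragments": len(frags),
                        "n_annotations": n_ann,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=[
            "word",
            "label",
            "level",
            "precision",
            "sensitivity",
            "n_fragments",
            "n_annotations",
        ],
    )


def call_functional(
    summaries: list[WordSummary],
    precision_table: pd.DataFrame,
    thr_precision: float = 0.40,
) -> set[str]:
    """Functional words: extreme superfamily-specific category AND best
    precision over all labels (both levels) ≥ the threshold."""
    if precision_table.empty:
        return set()
    best = precision_table.groupby("word")["precision"].max()
    out = set()
    for s in summaries:
        if s.category != "extreme_superfamily_specific":
            continue
        if s.word in best.index and float(best[s.word]) >= thr_precision:
            out.add(s.word)
    return out
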