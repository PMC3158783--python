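"""Loop extraction and structural words.

Helix- and strand-class letters are removed from encoded chains; what
remains are *loops* — maximal runs of loop-class letters.  Each loop is
split into all overlapping words of L consecutive letters (default
L = 4, i.e. 7-residue fragments), and word types too rare to be
statistically meaningful are dropped (default: fewer than 5 corpus
occurrences).

Residue coordinates are 1-based inclusive in all I/O; letter i of a
sequence covers residues i … i+3 of its segment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import pandas as pd

from .alphabet import AlphabetModel, LetterSequence


@dataclass
class LoopSequence:
    """A maximal run of loop-class letters with residue provenance.

    ``residue_span`` is the 1-based inclusive residue interval covered
    by the loop; a loop of m letters spans m + 3 residues.
    """

    protein_id: str
    chain_id: str
    letters: str
    letter_positions: list[int]  # indices into the parent letter sequence
    residue_span: tuple[int, int]
    loop_id: str = ""
    group_id: str = ""

    def __post_init__(self) -> None:
        m = len(self.letters)
        if len(self.letter_positions) != m:
            raise ValueError("one parent position per letter required")
        lo, hi = self.residue_span
        if hi - lo + 1 != m + 3:
            raise ValueError("residue_span must cover letter count + 3 residues")

    def __len__(self) -> int:
        return len(self.letters)


@dataclass
class WordOccurrence:
    """One occurrence of a structural word inside a loop."""

    word: str
    protein_id: str
    chain_id: str
    loop_id: str
    start_letter_pos: int  # 0-based offset within the loop
    residue_span: tuple[int, int]  # 1-based inclusive, len(word) + 3 residues
    group_id: str = ""

    def __post_init__(self) -> None:
        lo, hi = self.residue_span
        if hi - lo + 1 != len(self.word) + 3:
            raise ValueError("residue_span must cover word length + 3 residues")


def extract_loops(seq: LetterSequence, model: AlphabetModel) -> list[LoopSequence]:
    """Maximal loop-class runs of an encoded segment.

    Helix/strand-class letters never appear inside a returned loop.
    Runs of loop letters that are non-contiguous in residue space
    (window anchors jump, e.g. across a dropped window) are split.
    """
    cls = {l: c for l, c in zip(model.letters, model.classes)}
    for ch in seq.letters:
        if ch not in cls:
            raise ValueError(f"letter {ch!r} not classed in model")
    loops: list[LoopSequence] = []
    run_start = None
    n = len(seq.letters)
    for i in range(n + 1):
        in_loop = i < n and cls[seq.letters[i]] == "loop"
        contiguous = (
            i > 0
            and i < n
            and seq.residue_anchor[i] == seq.residue_anchor[i - 1] + 1
        )
        if in_loop and run_start is not None and not contiguous:
            _close_run(loops, seq, run_start, i)
            run_start = i
        elif in_loop and run_start is None:
            run_start = i
        elif not in_loop and run_start is not None:
            _close_run(loops, seq, run_start, i)
            run_start = None
    return loops


def _close_run(loops: list[LoopSequence], seq: LetterSequence, a: int, b: int) -> None:
    first = seq.residue_anchor[a]
    last = seq.residue_anchor[b - 1] + 3
    loops.append(
        LoopSequence(
            protein_id=seq.protein_id,
            chain_id=seq.chain_id,
            letters=seq.letters[a:b],
            letter_positions=list(range(a, b)),
            residue_span=(first + 1, last + 1),  # anchors are 0-based
            loop_id=f"{seq.protein_id}_{seq.chain_id}/{seq.segment_index}:{a}",
        )
    )


def extract_words(loops: list[LoopSequence], L: int = 4) -> list[WordOccurrence]:
    """All overlapping L-letter words of each loop, in order.

    A loop of m letters yields max(0, m − L + 1) words; each word of L
    letters covers L + 3 residues (7 for the default L = 4).
    """
    if L < 1:
        raise ValueError("word length must be >= 1")
    occs: list[WordOccurrence] = []
    for loop in loops:
        r0 = loop.residue_span[0]
        for j in range(len(loop) - L + 1):
            occs.append(
                WordOccurrence(
                    word=loop.letters[j : j + L],
                    protein_id=loop.protein_id,
                    chain_id=loop.chain_id,
                    loop_id=loop.loop_id,
                    start_letter_pos=j,
                    residue_span=(r0 + j, r0 + j + L + 2),
                    group_id=loop.group_id,
                )
            )
    return occs


def filter_words(
    occurrences: list[WordOccurrence],
    min_count: int = 5,
    scope: str = "corpus",
) -> pd.DataFrame:
    """Word-type table with corpus counts.

    ``scope='corpus'`` drops word types observed fewer than
    ``min_count`` times in the whole corpus.  ``scope='group'`` keeps
    every type — the per-group minimum is applied later by the
    enrichment engine.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    if scope not in ("corpus", "group"):
        raise ValueError("scope must be 'corpus' or 'group'")
    counts = Counter(o.word for o in occurrences)
    rows = [
        {"word": w, "count": c}
        for w, c in sorted(counts.items())
        if scope == "group" or c >= min_count
    ]
    return pd.DataFrame(rows, columns=["word", "count"])


def fragment_residue_span(occ: WordOccurrence) -> tuple[int, int]:
    """1-based inclusive residue interval of a word occurrence:
    L letters cover L + 3 residues."""
    return occ.residue_span


def loops_to_frame(loops: list[LoopSequence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "protein_id": lp.protein_id,
                "chain_id": lp.chain_id,
                "loop_id": lp.loop_id,
                "group_id": lp.group_id,
                "letters": lp.letters,
                "start_letter": lp.letter_positions[0] if lp.letter_positions else -1,
                "residue_start": lp.residue_span[0],
                "residue_end": lp.residue_span[1],
            }
            for lp in loops
        ]
    )


def occurrences_to_frame(occs: list[WordOccurrence]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "word": o.word,
                "protein_id": o.protein_id,
                "chain_id": o.chain_id,
                "loop_id": o.loop_id,
                "group_id": o.group_id,
                "start_letter": o.start_letter_pos,
                "residue_start": o.residue_span[0],
                "residue_end": o.residue_span[1],
            }
            for o in occs
        ]
    )
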