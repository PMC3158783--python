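"""Word taxonomy and coverage rates.

Per-group Lp scores are aggregated into two criteria per word:

* ``Lp_max`` — the maximal Lp over all groups where the word was tested;
* ``nb_sf*`` — the number of groups where the word is significantly
  over-represented (Lp at or above the Bonferroni-corrected threshold).

Words then fall into a taxonomy: over-represented words split into
*ubiquitous* words (significant in ≥ 5 superfamilies — structural
building blocks such as turns, nests and niches) and
*superfamily-specific* words (significant in < 5 — candidate
functional motifs), each with "extreme" strata at higher Lp_max.
A *functional* word is an extreme superfamily-specific word whose
fragments match an annotation with sufficient precision; that last
call is made by :mod:`samotif.annotate`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .loops import LoopSequence, WordOccurrence
from .stats import EnrichmentResult

#: Significance threshold (on the Lp scale) used by the original
#: genome-scale survey of loop words over the 2008 PDB/SCOP corpus
#: (Bonferroni at alpha = 0.05 over all word x superfamily tests run
#: there).  Kept as a documented constant for corpus-mimicking runs;
#: analyses should normally recompute the threshold from their own
#: test count with :func:`bonferroni_threshold`.
REFERENCE_LP_THRESHOLD = 5.97

CATEGORIES = (
    "not_over_represented",
    "over_represented",
    "ubiquitous",
    "extreme_ubiquitous",
    "superfamily_specific",
    "moderately_superfamily_specific",
    "extreme_superfamily_specific",
    "functional",
)


@dataclass
class Thresholds:
    """Taxonomy thresholds (all on the Lp = −log10 p scale)."""

    lp_sig: float = REFERENCE_LP_THRESHOLD
    ubiq_min_sf: int = 5
    extreme_ubiq_lp: float = 10.0
    moderate_lp: float = 10.0
    extreme_spec_lp: float = 50.0
    functional_precision: float = 0.40

    def __post_init__(self) -> None:
        import logging

        if not (self.extreme_spec_lp >= self.moderate_lp >= self.lp_sig):
            logging.getLogger(__name__).warning(
                "unusual threshold ordering: extreme %.3g / moderate %.3g / sig %.3g",
                self.extreme_spec_lp,
                self.moderate_lp,
                self.lp_sig,
            )


@dataclass
class WordSummary:
    word: str
    Lp_max: float
    nb_sf_star: int  # groups where significantly over-represented
    nb_sf: int  # groups where seen at least once
    category: str = "not_over_represented"

    def __post_init__(self) -> None:
        if self.nb_sf_star > self.nb_sf:
            raise ValueError("nb_sf* cannot exceed nb_sf")


def bonferroni_threshold(n_tests: int, alpha: float = 0.05) -> float:
    """Bonferroni-corrected significance threshold on the Lp scale:
    −log10(alpha / n_tests), with n_tests the number of (word, group)
    pairs actually tested."""
    if n_tests < 1:
        raise ValueError("n_tests must be >= 1")
    if not (0.0 < alpha < 1.0):
        raise ValueError("alpha must be in (0, 1)")
    return -math.log10(alpha / n_tests)


def summarize(
    word: str, per_group_results: list[EnrichmentResult], lp_sig: float
) -> WordSummary:
    """Aggregate one word's per-group results into (Lp_max, nb_sf*, nb_sf).

    Invariant to result order.  A word with no tested group gets
    Lp_max = 0.
    """
    rel = [r for r in per_group_results if r.word == word]
    if len(rel) != len(per_group_results):
        raise ValueError("results for several words passed to summarize")
    tested = [r for r in rel if r.tested and r.Lp is not None]
    lp_max = max((r.Lp for r in tested), default=0.0)
    nb_star = sum(1 for r in tested if r.Lp >= lp_sig)
    nb_sf = sum(1 for r in rel if r.N_obs >= 1)
    return WordSummary(word=word, Lp_max=lp_max, nb_sf_star=nb_star, nb_sf=nb_sf)


def categorize(summary: WordSummary, thr: Thresholds) -> str:
    """Taxonomy rules on (Lp_max, nb_sf*).

    Over-represented iff Lp_max ≥ lp_sig; then ubiquitous (extreme if
    Lp_max ≥ 10) when nb_sf* ≥ 5, superfamily-specific otherwise
    (moderately if Lp_max ≥ 10, extreme if Lp_max ≥ 50).  The
    'functional' refinement is assigned by the annotation stage only.
    """
    if summary.Lp_max < thr.lp_sig:
        return "not_over_represented"
    if summary.nb_sf_star >= thr.ubiq_min_sf:
        return "extreme_ubiquitous" if summary.Lp_max >= thr.extreme_ubiq_lp else "ubiquitous"
    if summary.Lp_max >= thr.extreme_spec_lp:
        return "extreme_superfamily_specific"
    if summary.Lp_max >= thr.moderate_lp:
        return "moderately_superfamily_specific"
    return "superfamily_specific"


def summarize_all(
    results: list[EnrichmentResult], thr: Thresholds
) -> list[WordSummary]:
    """Summaries + categories for every word appearing in the results."""
    by_word: dict[str, list[EnrichmentResult]] = {}
    for r in results:
        by_word.setdefault(r.word, []).append(r)
    out = []
    for word in sorted(by_word):
        s = summarize(word, by_word[word], thr.lp_sig)
        s.category = categorize(s, thr)
        out.append(s)
    return out


def coverage_rates(
    word_subset: set[str],
    occurrences: list[WordOccurrence],
    loops: list[LoopSequence],
    proteins: list[str] | None = None,
) -> dict[str, float]:
    """Four coverage rates (percent) of a word subset over a corpus.

    * word coverage — fraction of word types in the subset;
    * fragment coverage — fraction of fragments encoded by subset words;
    * loop-length coverage — fraction of loop residues covered by at
      least one subset-word span (union; overlaps counted once);
    * protein coverage — fraction of proteins with ≥ 1 subset occurrence.
    """
    all_types = {o.word for o in occurrences}
    unknown = word_subset - all_types
    if unknown:
        raise ValueError(f"subset words absent from corpus: {sorted(unknown)[:5]}")
    if proteins is None:
        proteins = sorted({lp.protein_id for lp in loops})
    n_types = len(all_types)
    n_frag = len(occurrences)
    sub_occ = [o for o in occurrences if o.word in word_subset]

    covered: dict[tuple[str, str], set[int]] = {}
    for o in sub_occ:
        covered.setdefault((o.protein_id, o.chain_id), set()).update(
            range(o.residue_span[0], o.residue_span[1] + 1)
        )
    loop_res = 0
    loop_cov = 0
    for lp in loops:
        lo, hi = lp.residue_span
        loop_res += hi - lo + 1
        got = covered.get((lp.protein_id, lp.chain_id))
        if got:
            loop_cov += sum(1 for r in range(lo, hi + 1) if r in got)
    prot_with = {o.protein_id for o in sub_occ}

    def pct(num: int, den: int) -> float:
        return 100.0 * num / den if den else 0.0

    return {
        "word_cov": pct(len(word_subset), n_types),
        "fragment_cov": pct(len(sub_occ), n_frag),
        "loop_length_cov": pct(loop_cov, loop_res),
        "protein_cov": pct(len(prot_with & set(proteins)), len(proteins)),
    }


def summaries_to_frame(summaries: list[WordSummary]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "word": s.word,
                "Lp_max": s.Lp_max,
                "nb_sf_star": s.nb_sf_star,
                "nb_sf": s.nb_sf,
                "category": s.category,
            }
            for s in summaries
        ],
        columns=["word", "Lp_max", "nb_sf_star", "nb_sf", "category"],
    )
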