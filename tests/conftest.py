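"""Shared fixtures.

The heavyweight fixtures (planted grouped corpora plus their full
enrichment runs) are session-scoped: several tests interrogate the
same study, so it is generated and analysed once.
"""

from __future__ import annotations

import numpy as np
import pytest

from samotif.alphabet import HMMSA_CLASSES, AlphabetModel
from samotif.classify import Thresholds, bonferroni_threshold, summarize_all
from samotif.loops import extract_words, filter_words
from samotif.stats import enrich
from samotif.synthetic import CorpusSpec, Plant, sample_corpus


@pytest.fixture(scope="session")
def hmmsa_like_model() -> AlphabetModel:
    """A 27-letter model with the canonical letter names and classes.

    Emission parameters are synthetic placeholders (the original
    27-letter parameters were never published); loop/helix/strand
    extraction only needs the names and classes.
    """
    letters = ["a"] + [c for c in "ABCDEFGHIJKLMNOPQRSTUVWXYZ"]
    K = len(letters)
    rng = np.random.default_rng(1)
    means = rng.uniform([4, 4, 4, -4], [9, 12, 9, 4], size=(K, 4))
    covs = np.array([np.eye(4) * 0.25] * K)
    trans = np.full((K, K), 1.0 / K)
    init = np.full(K, 1.0 / K)
    classes = [HMMSA_CLASSES[l] for l in letters]
    return AlphabetModel(
        letters=letters, means=means, covs=covs, transition=trans, initial=init, classes=classes
    )


def _run_study(spec: CorpusSpec) -> dict:
    corpus, truth, annotations = sample_corpus(spec)
    flat = [lp for g in sorted(corpus) for lp in corpus[g]]
    occurrences = extract_words(flat)
    table = filter_words(occurrences, min_count=5)
    grouped = {g: [lp.letters for lp in corpus[g]] for g in corpus}
    results = enrich(grouped, table)
    n_tests = sum(r.tested for r in results)
    thr = Thresholds(lp_sig=bonferroni_threshold(n_tests))
    summaries = summarize_all(results, thr)
    return {
        "spec": spec,
        "corpus": corpus,
        "loops": flat,
        "truth": truth,
        "annotations": annotations,
        "occurrences": occurrences,
        "word_table": table,
        "grouped": grouped,
        "results": results,
        "n_tests": n_tests,
        "thresholds": thr,
        "summaries": summaries,
        "by_word": {s.word: s for s in summaries},
    }


@pytest.fixture(scope="session")
def planted_study() -> dict:
    """20 groups x 400 loops with one word planted 10x in one group and
    another planted 3x in ten groups; planted occurrences annotated at
    rate q = 0.5."""
    spec = CorpusSpec(
        n_groups=20,
        loops_per_group=400,
        plants=[Plant("BCDB", "SF003", 10.0)]
        + [Plant("CDBC", f"SF{i:03d}", 3.0) for i in range(10)],
        annotation_rate=0.5,
        seed=11,
    )
    return _run_study(spec)


@pytest.fixture(scope="session")
def single_plant_study() -> dict:
    """A smaller study with a single 10x group-specific plant and
    annotations at q = 0.5 — used for precision calibration, where a
    second overlapping plant would contaminate the measurement."""
    spec = CorpusSpec(
        n_groups=10,
        loops_per_group=300,
        plants=[Plant("BCDD", "SF002", 10.0)],
        annotation_rate=0.5,
        seed=23,
    )
    return _run_study(spec)
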