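"""The end-to-end analysis pipeline.

encode → extract loops → split into words → per-group exact
over-representation → taxonomy + coverage → annotation scoring.
Each stage writes a TSV consumed by the next, so stages can also be
re-run independently from intermediates; a manifest records the
configuration hash and seeds, making reruns reproducible.

Entry points: either protein structures (PDB directory + alphabet
file) or a pre-encoded loop corpus (TSV), so the statistics engine is
testable standalone.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as sio
from .alphabet import AlphabetModel, encode_trace
from .annotate import AnnotationRecord, call_functional, score_words
from .classify import (
    Thresholds,
    bonferroni_threshold,
    coverage_rates,
    summaries_to_frame,
    summarize_all,
)
from .loops import (
    LoopSequence,
    extract_loops,
    extract_words,
    filter_words,
    occurrences_to_frame,
)
from .stats import enrich, enrichment_to_frame

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    output_dir: str
    structures_dir: str | None = None
    alphabet_file: str | None = None
    loops_file: str | None = None  # pre-encoded corpus entry point
    groups_file: str | None = None
    annotations_file: str | None = None
    word_length: int = 4
    min_count_corpus: int = 5
    min_count_group: int = 5
    markov_order: int = 1
    bg_scope: str = "corpus"
    alpha: float = 0.05
    max_ca_gap: float = 4.5
    thresholds: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.word_length < 1:
            raise ValueError("word length must be >= 1")
        for name in ("min_count_corpus", "min_count_group"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")

    def to_dict(self) -> dict:
        return {k: v for k, v in self.__dict__.items()}

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        return cls(**sio.load_config(path))


def _load_loops(config: RunConfig) -> list[LoopSequence]:
    if config.loops_file:
        return sio.read_loops(config.loops_file)
    if not config.structures_dir:
        raise ValueError("missing input: provide structures_dir or loops_file")
    if not config.alphabet_file:
        raise ValueError("missing input: alphabet_file is required with structures_dir")
    model = AlphabetModel.load(config.alphabet_file)
    loops: list[LoopSequence] = []
    n_failed = 0
    pdb_files = sorted(Path(config.structures_dir).glob("*.pdb"))
    if not pdb_files:
        raise ValueError(f"no .pdb files in {config.structures_dir}")
    for f in pdb_files:
        try:
            traces = sio.read_ca_traces(f)
        except Exception:
            n_failed += 1
            logger.warning("unparseable structure %s skipped", f)
            continue
        for trace in traces:
            if len(trace) < 4:
                continue
            for seq in encode_trace(trace, model, max_ca_gap=config.max_ca_gap):
                loops.extend(extract_loops(seq, model))
    if n_failed:
        logger.warning("%d structure files skipped as unparseable", n_failed)
    return loops


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the result bundle (also written as
    TSVs + a manifest under ``config.output_dir``)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    loops = _load_loops(config)
    if not loops:
        raise ValueError("no loops extracted from the inputs")

    if config.groups_file:
        mapping = sio.read_groups(config.groups_file)
        for lp in loops:
            lp.group_id = mapping.get(lp.protein_id, lp.group_id)
    missing = [lp for lp in loops if not lp.group_id]
    if missing:
        raise ValueError(
            f"{len(missing)} loops have no group assignment; provide groups_file"
        )

    occurrences = extract_words(loops, L=config.word_length)
    word_table = filter_words(occurrences, min_count=config.min_count_corpus)
    sio.write_loops(loops, out / "loops.tsv")
    occurrences_to_frame(occurrences).to_csv(out / "words.tsv", sep="\t", index=False)
    word_table.to_csv(out / "word_table.tsv", sep="\t", index=False)

    grouped: dict[str, list[str]] = {}
    for lp in loops:
        grouped.setdefault(lp.group_id, []).append(lp.letters)
    results = enrich(
        grouped,
        word_table,
        bg_scope=config.bg_scope,
        order=config.markov_order,
        min_count_group=config.min_count_group,
    )
    enr = enrichment_to_frame(results)
    enr.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    n_tests = int(enr["tested"].sum())
    thr_kwargs = dict(config.thresholds)
    if "lp_sig" not in thr_kwargs:
        thr_kwargs["lp_sig"] = bonferroni_threshold(max(n_tests, 1), alpha=config.alpha)
    thr = Thresholds(**thr_kwargs)
    summaries = summarize_all(results, thr)
    cls_frame = summaries_to_frame(summaries)

    retained = set(word_table["word"])
    kept_occ = [o for o in occurrences if o.word in retained]
    over = {s.word for s in summaries if s.category != "not_over_represented"}
    cov_rows = []
    for name, subset in (("over_represented", over), ("all_words", retained)):
        rates = coverage_rates(subset, kept_occ, loops)
        cov_rows.append({"subset": name, "n_words": len(subset), **rates})
    cov = pd.DataFrame(cov_rows)
    cov.to_csv(out / "coverage.tsv", sep="\t", index=False)

    ann_frame = pd.DataFrame()
    functional: set[str] = set()
    annotations: list[AnnotationRecord] = []
    if config.annotations_file:
        annotations = sio.read_annotations(config.annotations_file)
        extreme = [
            s.word for s in summaries if s.category == "extreme_superfamily_specific"
        ]
        if extreme and annotations:
            ann_frame = score_words(extreme, kept_occ, annotations, loops)
            functional = call_functional(
                summaries, ann_frame, thr_precision=thr.functional_precision
            )
            for s in summaries:
                if s.word in functional:
                    s.category = "functional"
            cls_frame = summaries_to_frame(summaries)
        ann_frame.to_csv(out / "annotation_scores.tsv", sep="\t", index=False)
    cls_frame.to_csv(out / "classification.tsv", sep="\t", index=False)

    manifest = {
        "config": config.to_dict(),
        "config_hash": sio.config_hash(config.to_dict()),
        "n_loops": len(loops),
        "n_occurrences": len(occurrences),
        "n_word_types": int(len(word_table)),
        "n_tests": n_tests,
        "lp_sig": thr.lp_sig,
        "n_functional": len(functional),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))

    return {
        "loops": loops,
        "occurrences": occurrences,
        "word_table": word_table,
        "enrichment": results,
        "enrichment_frame": enr,
        "summaries": summaries,
        "classification": cls_frame,
        "coverage": cov,
        "annotation_scores": ann_frame,
        "functional_words": functional,
        "thresholds": thr,
        "manifest": manifest,
    }
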