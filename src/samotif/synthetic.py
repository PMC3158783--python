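"""Synthetic inputs for every pipeline stage.

Real inputs to the pipeline are curated protein structures, a trained
structural alphabet, a protein→superfamily table and feature-table
annotations.  This module emulates each of them so the whole pipeline
is testable without downloads:

* Cα backbones assembled from ideal α-helix (2.3 Å radius, 1.5 Å rise,
  100°/residue), extended-strand (3.4 Å rise zigzag) and self-avoiding
  random-walk loop segments, with optional Gaussian coordinate noise;
* planted structural alphabets with well-separated Gaussian emissions
  and generator-assigned letter classes;
* grouped loop-letter corpora drawn from a Markov background, with
  designated words injected into designated groups at a stated
  enrichment factor over their background expectation, and annotation
  intervals co-located with the planted words;
* uniform group-label shuffles for null controls.

All generators are pure functions of their arguments and seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .alphabet import AlphabetModel, default_letter_names
from .annotate import AnnotationRecord
from .geometry import CaTrace, Descriptor4, descriptor_from_points
from .loops import LoopSequence
from .stats import ExpectedCountCalculator, MarkovBackground

CA_STEP = 3.8  # canonical Cα–Cα distance, Å

HELIX_RADIUS = 2.3
HELIX_RISE = 1.5
HELIX_TWIST = math.radians(100.0)
STRAND_RISE = 3.4


def _helix_coords(n: int) -> np.ndarray:
    t = np.arange(n)
    return np.column_stack(
        [
            HELIX_RADIUS * np.cos(HELIX_TWIST * t),
            HELIX_RADIUS * np.sin(HELIX_TWIST * t),
            HELIX_RISE * t,
        ]
    )


def _strand_coords(n: int) -> np.ndarray:
    lateral = math.sqrt(max(CA_STEP**2 - STRAND_RISE**2, 0.0)) / 2.0
    t = np.arange(n)
    return np.column_stack(
        [lateral * (-1.0) ** t, np.zeros(n), STRAND_RISE * t]
    )


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array(
        [
            [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
            [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
            [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
        ]
    )


def _loop_coords(n: int, start: np.ndarray, prev_pts: np.ndarray, rng) -> np.ndarray:
    """Self-avoiding 3.8 Å random walk (rejection with a clash radius)."""
    pts = [start]
    direction = _random_unit(rng)
    for _ in range(n - 1):
        best_cand, best_step, best_clear = None, None, -np.inf
        for _try in range(60):
            step = direction + 0.8 * rng.normal(size=3)
            step /= np.linalg.norm(step)
            cand = pts[-1] + CA_STEP * step
            others = np.vstack([prev_pts, np.array(pts[:-1])]) if len(pts) > 1 else prev_pts
            clearance = (
                np.min(np.linalg.norm(others - cand, axis=1)) if len(others) else np.inf
            )
            if clearance > best_clear:
                best_cand, best_step, best_clear = cand, step, clearance
            if clearance >= 3.4:
                break
        pts.append(best_cand)
        direction = best_step
    return np.array(pts)


def _random_unit(rng) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def generate_backbone(
    segments: list[tuple[str, int]],
    noise_sd: float = 0.0,
    seed: int = 0,
    protein_id: str = "synth",
    chain_id: str = "A",
) -> CaTrace:
    """A Cα trace assembled from (kind, length) segments, kind in
    {helix, strand, loop}.  Consecutive Cα steps are ~3.8 Å (the ideal
    helix chord is 3.83 Å); independent Gaussian noise of sd
    ``noise_sd`` Å is added to every coordinate."""
    rng = np.random.default_rng(seed)
    coords: list[np.ndarray] = []
    for kind, length in segments:
        if length < 1:
            raise ValueError("segment lengths must be >= 1")
        if kind == "helix":
            seg = _helix_coords(length)
        elif kind == "strand":
            seg = _strand_coords(length)
        elif kind == "loop":
            seg = None
        else:
            raise ValueError(f"unknown segment kind {kind!r}")
        if not coords:
            origin = np.zeros(3)
            prev = np.empty((0, 3))
        else:
            prev = np.vstack(coords)
            origin = prev[-1] + CA_STEP * _random_unit(rng)
        if kind == "loop":
            seg = _loop_coords(length, origin, prev, rng)
        else:
            R = _random_rotation(rng)
            seg = (seg - seg[0]) @ R.T + origin
        coords.append(seg)
    xyz = np.vstack(coords)
    if noise_sd > 0:
        xyz = xyz + rng.normal(scale=noise_sd, size=xyz.shape)
    n = len(xyz)
    return CaTrace(
        protein_id=protein_id,
        chain_id=chain_id,
        residue_ids=[str(i + 1) for i in range(n)],
        coords=xyz,
    )


def ideal_helix_descriptor() -> Descriptor4:
    """Descriptor of a noiseless ideal α-helix window."""
    return descriptor_from_points(_helix_coords(4))


def ideal_strand_descriptor() -> Descriptor4:
    """Descriptor of a noiseless extended-strand window."""
    return descriptor_from_points(_strand_coords(4))


# --------------------------------------------------------------------------
# planted alphabets and descriptor corpora
# --------------------------------------------------------------------------


def generate_alphabet(
    K: int,
    separation: float = 6.0,
    sd: float = 0.4,
    seed: int = 0,
    trans_concentration: float = 0.6,
) -> AlphabetModel:
    """A planted K-letter alphabet with well-separated Gaussian means.

    Letter 0 is centred on the ideal helix descriptor and classed
    helix, letter 1 on the ideal strand descriptor and classed strand,
    the rest get random loop-like means at pairwise distance at least
    ``separation``·sd.  Transitions are random sparse Dirichlet rows.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    rng = np.random.default_rng(seed)
    means = [ideal_helix_descriptor().as_array(), ideal_strand_descriptor().as_array()]
    lo = np.array([4.0, 4.0, 4.0, -5.0])
    hi = np.array([9.0, 12.0, 9.0, 5.0])
    while len(means) < K:
        cand = rng.uniform(lo, hi)
        if all(np.linalg.norm(cand - m) >= separation * sd for m in means):
            means.append(cand)
    means = np.array(means)
    covs = np.array([np.eye(4) * sd**2 for _ in range(K)])
    trans = rng.dirichlet(np.full(K, trans_concentration), size=K)
    trans = np.clip(trans, 1e-4, None)
    trans /= trans.sum(axis=1, keepdims=True)
    initial = np.full(K, 1.0 / K)
    classes = ["helix", "strand"] + ["loop"] * (K - 2)
    return AlphabetModel(
        letters=default_letter_names(K),
        means=means,
        covs=covs,
        transition=trans,
        initial=initial,
        classes=classes,
    )


def sample_descriptor_corpus(
    model: AlphabetModel, n_sequences: int, length: int, seed: int = 0
) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Descriptor sequences (and their hidden state paths) drawn from an
    alphabet model's HMM."""
    rng = np.random.default_rng(seed)
    chols = [np.linalg.cholesky(c) for c in model.covs]
    seqs, paths = [], []
    for _ in range(n_sequences):
        states = np.empty(length, dtype=int)
        states[0] = rng.choice(model.K, p=model.initial)
        for t in range(1, length):
            states[t] = rng.choice(model.K, p=model.transition[states[t - 1]])
        X = np.array(
            [model.means[k] + chols[k] @ rng.normal(size=4) for k in states]
        )
        seqs.append(X)
        paths.append(states)
    return seqs, paths


# --------------------------------------------------------------------------
# grouped loop corpora with planted enrichment
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class Plant:
    """One enrichment plant: inject ``word`` into ``group`` ('ALL' for
    every group) until its in-group rate is ``factor`` times the
    background expectation."""

    word: str
    group: str  # group id or "ALL"
    factor: float

    def __post_init__(self) -> None:
        if self.factor < 1.0:
            raise ValueError("enrichment factor must be >= 1")


@dataclass
class CorpusSpec:
    """Study conditions of a synthetic grouped loop corpus."""

    n_groups: int = 20
    loops_per_group: int = 400
    loop_length: tuple[int, int] = (8, 18)  # uniform, inclusive
    background: MarkovBackground | None = None
    plants: list[Plant] = field(default_factory=list)
    annotation_rate: float = 0.0  # q: P(an occurrence of a planted word is annotated)
    feature_key: str = "Binding"
    description: str = "ATP/GTP"
    loops_per_protein: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.annotation_rate <= 1.0):
            raise ValueError("annotation rate must be in [0, 1]")


def default_loop_background(seed: int = 0) -> MarkovBackground:
    """Order-1 background over 8 loop letters with a skewed marginal
    (three frequent letters near 0.22, five near 0.068) and mildly
    context-dependent rows — the regime in which a handful of word
    types recur often enough to be testable, as in real loop corpora
    (the all-frequent words reach per-group expectations in the tens,
    comparable to the mean occurrence of real loop words)."""
    rng = np.random.default_rng(seed)
    letters = list("BCDEFGHI")
    marginal = np.array([0.22, 0.22, 0.22, 0.068, 0.068, 0.068, 0.068, 0.068])
    rows = rng.dirichlet(marginal * 60.0, size=len(letters))
    rows = np.clip(rows, 1e-6, None)
    rows /= rows.sum(axis=1, keepdims=True)
    return MarkovBackground(order=1, letters=letters, transition=rows, initial=marginal)


def group_names(n: int) -> list[str]:
    return [f"SF{i:03d}" for i in range(n)]


def sample_corpus(
    spec: CorpusSpec,
) -> tuple[dict[str, list[LoopSequence]], pd.DataFrame, list[AnnotationRecord]]:
    """Grouped loops + ground-truth plant table + annotations.

    Loops are drawn from the background; each plant overwrites random
    loop windows in its target group(s) until the word's in-group
    count reaches ``factor`` times its background expectation (windows
    are replaced, never appended, so loop lengths are preserved).
    Every occurrence of a planted word anywhere in the corpus is then
    annotated with probability q over its exact residue span.
    """
    rng = np.random.default_rng(spec.seed)
    bg = spec.background or default_loop_background()
    groups = group_names(spec.n_groups)
    for p in spec.plants:
        for ch in p.word:
            if ch not in bg.letters:
                raise ValueError(f"planted word {p.word!r} incompatible with alphabet")
        if p.group != "ALL" and p.group not in groups:
            raise ValueError(f"unknown target group {p.group!r}")

    lo, hi = spec.loop_length
    corpus: dict[str, list[LoopSequence]] = {}
    letters_by_group: dict[str, list[list[str]]] = {}
    for g in groups:
        seqs = []
        for j in range(spec.loops_per_group):
            seqs.append(list(bg.sample(int(rng.integers(lo, hi + 1)), rng)))
        letters_by_group[g] = seqs

    calc = ExpectedCountCalculator(bg, hi)
    truth_rows = []
    planted_sites: dict[str, list[tuple[str, int, int]]] = {}  # word -> (group, loop, pos)
    for p in spec.plants:
        targets = groups if p.group == "ALL" else [p.group]
        L = len(p.word)
        wl = list(p.word)
        for g in targets:
            seqs = letters_by_group[g]
            expected = calc.total([len(s) for s in seqs], p.word)
            current = sum(
                1
                for s in seqs
                for i in range(len(s) - L + 1)
                if s[i : i + L] == wl
            )
            target_count = p.factor * expected
            n_extra = max(0, int(np.floor(target_count - current + rng.random())))
            eligible = [(j, i) for j, s in enumerate(seqs) for i in range(len(s) - L + 1)]
            injected = 0
            if n_extra and eligible:
                pick = rng.choice(len(eligible), size=min(n_extra, len(eligible)), replace=False)
                for k in pick:
                    j, i = eligible[int(k)]
                    seqs[j][i : i + L] = wl
                    planted_sites.setdefault(p.word, []).append((g, j, i))
                    injected += 1
            truth_rows.append(
                {
                    "word": p.word,
                    "group_id": g,
                    "factor": p.factor,
                    "expected_background": expected,
                    "n_injected": injected,
                }
            )

    # materialise LoopSequences with per-loop residue offsets
    annotations: list[AnnotationRecord] = []
    planted_words = [p.word for p in spec.plants]
    for g in groups:
        out = []
        for j, s in enumerate(letters_by_group[g]):
            prot = f"{g}_p{j // spec.loops_per_protein:04d}"
            slot = j % spec.loops_per_protein
            r0 = 1 + 100 * slot  # loops of one protein live in disjoint ranges
            lp = LoopSequence(
                protein_id=prot,
                chain_id="A",
                letters="".join(s),
                letter_positions=list(range(len(s))),
                residue_span=(r0, r0 + len(s) + 2),
                loop_id=f"{g}_loop{j:05d}",
                group_id=g,
            )
            out.append(lp)
            for word in planted_words:
                L = len(word)
                for i in range(len(s) - L + 1):
                    if lp.letters[i : i + L] == word and rng.random() < spec.annotation_rate:
                        annotations.append(
                            AnnotationRecord(
                                protein_id=prot,
                                chain_id="A",
                                residue_start=r0 + i,
                                residue_end=r0 + i + L + 2,
                                feature_key=spec.feature_key,
                                description=spec.description,
                            )
                        )
        corpus[g] = out
    truth = pd.DataFrame(
        truth_rows,
        columns=["word", "group_id", "factor", "expected_background", "n_injected"],
    )
    return corpus, truth, annotations


def shuffle_group_labels(
    assignment: dict[str, str], seed: int = 0
) -> dict[str, str]:
    """Uniform random permutation of the group labels of a loop→group
    assignment; the label multiset is preserved exactly."""
    if not assignment:
        raise ValueError("empty assignment")
    rng = np.random.default_rng(seed)
    keys = sorted(assignment)
    labels = [assignment[k] for k in keys]
    perm = rng.permutation(len(labels))
    return {k: labels[p] for k, p in zip(keys, perm)}


def regroup_loops(
    grouped: dict[str, list[LoopSequence]], seed: int = 0
) -> dict[str, list[LoopSequence]]:
    """Corpus with loop→group labels shuffled (the randomised-group
    null control)."""
    flat = [lp for g in sorted(grouped) for lp in grouped[g]]
    assignment = {lp.loop_id: lp.group_id for lp in flat}
    shuffled = shuffle_group_labels(assignment, seed=seed)
    out: dict[str, list[LoopSequence]] = {g: [] for g in grouped}
    for lp in flat:
        out[shuffled[lp.loop_id]].append(lp)
    return out
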