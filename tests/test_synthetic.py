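"""Synthetic generators: backbones, alphabets, planted corpora."""

from collections import Counter

import numpy as np
import pytest

from samotif.geometry import compute_descriptors
from samotif.stats import ExpectedCountCalculator, count_occurrences
from samotif.synthetic import (
    CorpusSpec,
    Plant,
    default_loop_background,
    generate_alphabet,
    generate_backbone,
    regroup_loops,
    sample_corpus,
    shuffle_group_labels,
)


def test_noiseless_helix_geometry():
    tr = generate_backbone([("helix", 12)], noise_sd=0.0, seed=0)
    steps = np.linalg.norm(np.diff(tr.coords, axis=0), axis=1)
    assert steps.max() - steps.min() < 1e-6
    descs = np.array([d.as_array() for d in compute_descriptors(tr)])
    # every window of an ideal helix is congruent: identical descriptors
    assert np.abs(descs - descs[0]).max() < 1e-6
    # constant handedness
    assert np.all(np.sign(descs[:, 3]) == np.sign(descs[0, 3]))
    assert descs[0, 3] > 0  # right-handed helix


def test_backbone_step_lengths_and_determinism():
    segs = [("helix", 8), ("loop", 10), ("strand", 6)]
    tr = generate_backbone(segs, noise_sd=0.1, seed=3)
    assert len(tr) == 24
    steps = np.linalg.norm(np.diff(tr.coords, axis=0), axis=1)
    assert np.all(np.abs(steps - 3.8) < 0.05 + 3 * 2 * 0.1)
    tr2 = generate_backbone(segs, noise_sd=0.1, seed=3)
    assert np.array_equal(tr.coords, tr2.coords)


def test_generate_alphabet_contract():
    m = generate_alphabet(9, seed=4)
    assert len(set(m.letters)) == 9
    assert np.allclose(m.transition.sum(axis=1), 1.0)
    assert m.classes[:2] == ["helix", "strand"]
    assert m.classes.count("loop") == 7
    m2 = generate_alphabet(9, seed=4)
    assert np.array_equal(m.means, m2.means)
    assert np.array_equal(m.transition, m2.transition)
    # pairwise separation of emission means
    D = np.linalg.norm(m.means[:, None, :] - m.means[None, :, :], axis=2)
    np.fill_diagonal(D, np.inf)
    assert D.min() >= 6.0 * 0.4 - 1e-9


def test_unplanted_counts_match_background_expectation():
    spec = CorpusSpec(n_groups=4, loops_per_group=300, plants=[], seed=5)
    corpus, truth, anns = sample_corpus(spec)
    assert truth.empty and anns == []
    bg = default_loop_background()
    seqs = [lp.letters for g in corpus for lp in corpus[g]]
    calc = ExpectedCountCalculator(bg, max(len(s) for s in seqs))
    for word in ["BCD", "CDBC"]:
        exp = calc.total([len(s) for s in seqs], word)
        obs = sum(count_occurrences(s, word) for s in seqs)
        assert abs(obs - exp) <= 4 * np.sqrt(exp)  # ~Poisson fluctuation


def test_planted_word_reaches_target_rate():
    spec = CorpusSpec(
        n_groups=4, loops_per_group=300, plants=[Plant("BCDB", "SF001", 8.0)], seed=6
    )
    corpus, truth, _ = sample_corpus(spec)
    row = truth.iloc[0]
    seqs = [lp.letters for lp in corpus["SF001"]]
    obs = sum(count_occurrences(s, "BCDB") for s in seqs)
    assert abs(obs - 8.0 * row.expected_background) <= 4 * np.sqrt(8.0 * row.expected_background)
    # plants in other groups stay at background
    other = sum(count_occurrences(lp.letters, "BCDB") for lp in corpus["SF000"])
    assert other <= row.expected_background + 4 * np.sqrt(row.expected_background)


def test_plant_with_unknown_letter_rejected():
    with pytest.raises(ValueError, match="incompatible"):
        sample_corpus(CorpusSpec(n_groups=2, loops_per_group=10, plants=[Plant("QQQQ", "ALL", 2.0)]))


def test_annotations_cover_planted_spans():
    spec = CorpusSpec(
        n_groups=3,
        loops_per_group=200,
        plants=[Plant("BCDB", "SF000", 10.0)],
        annotation_rate=1.0,
        seed=7,
    )
    corpus, _, anns = sample_corpus(spec)
    by_loc = {(lp.protein_id, lp.chain_id, lp.residue_span[0]): lp for g in corpus for lp in corpus[g]}
    n_occ = sum(
        count_occurrences(lp.letters, "BCDB") for g in corpus for lp in corpus[g]
    )
    assert len(anns) == n_occ  # q=1 annotates every occurrence
    for a in anns:
        assert a.residue_end - a.residue_start + 1 == 7
        assert a.feature_key == "Binding"


def test_shuffle_preserves_label_multiset_and_is_seeded():
    assignment = {f"l{i}": f"g{i % 3}" for i in range(30)}
    out = shuffle_group_labels(assignment, seed=1)
    assert Counter(out.values()) == Counter(assignment.values())
    assert out == shuffle_group_labels(assignment, seed=1)
    assert out != shuffle_group_labels(assignment, seed=2)
    with pytest.raises(ValueError):
        shuffle_group_labels({}, seed=0)


def test_regroup_preserves_group_sizes():
    spec = CorpusSpec(n_groups=3, loops_per_group=50, plants=[], seed=8)
    corpus, _, _ = sample_corpus(spec)
    shuffled = regroup_loops(corpus, seed=9)
    assert {g: len(v) for g, v in shuffled.items()} == {g: len(v) for g, v in corpus.items()}
    flat_a = sorted(lp.loop_id for g in corpus for lp in corpus[g])
    flat_b = sorted(lp.loop_id for g in shuffled for lp in shuffled[g])
    assert flat_a == flat_b


def test_letter_frequencies_approach_stationary_distribution():
    bg = default_loop_background()
    spec = CorpusSpec(n_groups=2, loops_per_group=800, plants=[], seed=10)
    corpus, _, _ = sample_corpus(spec)
    text = "".join(lp.letters for g in corpus for lp in corpus[g])
    counts = np.array([text.count(l) for l in bg.letters], dtype=float)
    freq = counts / counts.sum()
    # stationary distribution of the order-1 chain
    T = bg.transition
    vals, vecs = np.linalg.eig(T.T)
    pi = np.real(vecs[:, np.argmax(np.real(vals))])
    pi = pi / pi.sum()
    chi2 = counts.sum() * np.sum((freq - pi) ** 2 / pi)
    # generous bound: 8 categories, seeded run far from pathological
    assert chi2 < 40.0
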