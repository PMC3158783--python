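"""Exact word statistics: backgrounds, automata, count distributions."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from samotif.stats import (
    CountDistribution,
    MarkovBackground,
    build_dfa,
    count_distribution,
    count_occurrences,
    enrich,
    expected_count,
    fit_background,
    lp_score,
    pvalue_ge,
)


# ---- background fitting ----


def test_forced_mle_on_alternating_corpus():
    bg = fit_background(["ABAB"], order=1)
    a, b = bg.letter_index("A"), bg.letter_index("B")
    assert bg.transition[a, b] == pytest.approx(1.0)
    assert bg.transition[b, a] == pytest.approx(1.0)
    assert bg.initial[a] == pytest.approx(1.0)


def test_laplace_smoothing_arithmetic():
    # the alphabet is inferred from the corpus, so a lone B sequence
    # makes it {A, B}; the A row then smooths to (1+1)/(1+2)
    bg = fit_background(["AA", "B"], order=1, pseudocount=1.0)
    a = bg.letter_index("A")
    assert bg.transition[a, a] == pytest.approx(2.0 / 3.0)
    assert np.allclose(bg.transition.sum(axis=1), 1.0)


def test_unseen_context_gets_uniform_conditional():
    bg = fit_background(["AAB"], order=1)
    b = bg.letter_index("B")  # context B never followed by anything
    assert np.allclose(bg.transition[b], 0.5)


def test_order0_background_is_letter_marginal():
    bg = fit_background(["AAB", "ABB"], order=0)
    a = bg.letter_index("A")
    assert bg.transition[0, a] == pytest.approx(0.5)
    assert bg.initial == pytest.approx(np.array([1.0]))


# ---- word automata ----


def test_dfa_of_nonoverlapping_word_has_word_len_plus_one_states():
    dfa = build_dfa("PZCD", list("PZCDX"))
    assert dfa.delta.shape[0] == 5
    assert dfa.match_state == 4
    # the only counting transition is the final letter of the word
    assert dfa.counting_transitions == {(3, "D")}
    # after a match, a non-matching letter returns toward the start
    assert dfa.delta[4, dfa.letters.index("X")] == 0
    assert dfa.delta[4, dfa.letters.index("P")] == 1


def test_self_overlapping_word_reenters_match_state():
    dfa = build_dfa("AAAA", ["A", "B"])
    a = dfa.letters.index("A")
    assert dfa.delta[dfa.match_state, a] == dfa.match_state  # emits again
    assert dfa.count("AAAAAA") == 3


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.data())
def test_dfa_count_equals_naive_scan(data):
    letters = ["A", "B", "C"]
    word = data.draw(st.text(alphabet=letters, min_size=1, max_size=4))
    seq = data.draw(st.text(alphabet=letters, min_size=0, max_size=30))
    dfa = build_dfa(word, letters)
    assert dfa.count(seq) == count_occurrences(seq, word)


@pytest.mark.parametrize(
    "seq,word,n",
    [("AAAAAA", "AAAA", 3), ("SPZCDS", "PZCD", 1), ("AB", "ABC", 0)],
)
def test_overlapping_occurrence_counting(seq, word, n):
    assert count_occurrences(seq, word) == n


def test_dfa_rejects_foreign_letters():
    with pytest.raises(ValueError, match="not in alphabet"):
        build_dfa("AX", ["A", "B"])


# ---- exact distributions ----


def uniform_bg(letters):
    A = len(letters)
    return MarkovBackground(
        order=0, letters=list(letters), transition=np.full((1, A), 1 / A), initial=np.array([1.0])
    )


def test_three_letter_enumeration_example():
    bg = uniform_bg("AB")
    dfa = build_dfa("AA", ["A", "B"])
    dist = count_distribution([3], dfa, bg, cap=2)
    assert dist.probs == pytest.approx([5 / 8, 2 / 8, 1 / 8], abs=1e-12)
    assert pvalue_ge(dist, 1) == pytest.approx(0.375, abs=1e-12)


def test_word_longer_than_sequences_never_occurs():
    bg = uniform_bg("AB")
    dfa = build_dfa("AAAA", ["A", "B"])
    dist = count_distribution([2, 3], dfa, bg, cap=1)
    assert dist.probs[0] == pytest.approx(1.0)


def _enum_distribution(lengths, word, bg, cap):
    """Exhaustive enumeration over all sequence tuples (the oracle)."""
    letters = bg.letters

    def seq_prob(s):
        idx = [letters.index(c) for c in s]
        if bg.order == 0:
            return float(np.prod([bg.transition[0, i] for i in idx]))
        p = float(bg.initial[bg.context_index(tuple(idx[: bg.order]))]) if len(idx) >= bg.order else 1.0
        ctx = bg.context_index(tuple(idx[: bg.order])) if len(idx) >= bg.order else 0
        for c in idx[bg.order :]:
            p *= bg.transition[ctx, c]
            ctx = bg.shift_context(ctx, c)
        return p

    probs = np.zeros(cap + 1)
    pools = [itertools.product(letters, repeat=n) for n in lengths]
    for combo in itertools.product(*pools):
        seqs = ["".join(t) for t in combo]
        n = sum(count_occurrences(s, word) for s in seqs)
        p = math.prod(seq_prob(s) for s in seqs)
        probs[min(n, cap)] += p
    return probs


@pytest.mark.parametrize(
    "letters,order,lengths,word",
    [
        ("AB", 0, [5], "AB"),
        ("AB", 1, [4, 5], "ABA"),
        ("ABC", 1, [6], "AA"),
    ],
)
def test_distribution_matches_enumeration(letters, order, lengths, word):
    rng = np.random.default_rng(7)
    A = len(letters)
    if order == 0:
        bg = MarkovBackground(
            order=0,
            letters=list(letters),
            transition=rng.dirichlet(np.ones(A))[None, :],
            initial=np.array([1.0]),
        )
    else:
        bg = MarkovBackground(
            order=1,
            letters=list(letters),
            transition=rng.dirichlet(np.ones(A), size=A),
            initial=rng.dirichlet(np.ones(A)),
        )
    cap = max(lengths)
    dfa = build_dfa(word, list(letters))
    dist = count_distribution(lengths, dfa, bg, cap=cap)
    oracle = _enum_distribution(lengths, word, bg, cap)
    assert np.abs(dist.probs - oracle).max() < 1e-12


def test_distribution_invariant_to_sequence_order():
    bg = uniform_bg("ABC")
    dfa = build_dfa("AB", ["A", "B", "C"])
    d1 = count_distribution([3, 7, 5], dfa, bg, cap=4)
    d2 = count_distribution([7, 5, 3], dfa, bg, cap=4)
    assert d1.probs == pytest.approx(d2.probs, abs=1e-15)


def test_expected_count_matches_iid_closed_form():
    bg = uniform_bg("ABC")
    # p(word) = (1/3)^2; positions per sequence = len - 1
    exp = expected_count([5, 8], "AB", bg)
    assert exp == pytest.approx((4 + 7) * (1 / 3) ** 2, abs=1e-12)


def test_pvalue_tail_properties():
    bg = uniform_bg("AB")
    dfa = build_dfa("AA", ["A", "B"])
    dist = count_distribution([6], dfa, bg, cap=5)
    assert pvalue_ge(dist, 0) == 1.0
    tails = [pvalue_ge(dist, n) for n in range(6)]
    assert all(a >= b for a, b in zip(tails, tails[1:]))
    with pytest.raises(ValueError, match="cap"):
        pvalue_ge(dist, 6)


def test_lp_score_values_and_domain():
    assert lp_score(1e-3) == pytest.approx(3.0, abs=1e-12)
    assert lp_score(1.0) == 0.0
    assert lp_score(0.375) == pytest.approx(0.4260, abs=1e-4)
    with pytest.raises(ValueError):
        lp_score(0.0)
    with pytest.raises(ValueError):
        lp_score(-0.1)


def test_count_distribution_is_a_distribution():
    d = CountDistribution(probs=np.array([0.5, 0.3, 0.2]), cap=2)
    assert d.probs.sum() == pytest.approx(1.0)
    with pytest.raises(ValueError):
        CountDistribution(probs=np.array([0.5, 0.6]), cap=1)


# ---- enrichment engine ----


def test_enrich_marks_rare_words_untested():
    rng = np.random.default_rng(5)
    groups = {
        "g1": ["".join(rng.choice(list("ABC"), size=12)) for _ in range(20)],
        "g2": ["".join(rng.choice(list("ABC"), size=12)) for _ in range(20)],
    }
    # force a word with known in-group count of 4 < 5
    groups["g1"][0] = "XYZW" + groups["g1"][0][4:]
    for i in range(1, 4):
        groups["g1"][i] = "XYZW" + groups["g1"][i][4:]
    res = enrich(groups, ["XYZW", "ABC"], min_count_group=5)
    by = {(r.word, r.group_id): r for r in res}
    r = by[("XYZW", "g1")]
    assert r.N_obs == 4 and not r.tested and r.Lp is None and r.p_value is None


def test_enrich_pvalues_match_direct_computation():
    rng = np.random.default_rng(6)
    groups = {
        "g1": ["".join(rng.choice(list("AB"), size=10)) for _ in range(8)],
    }
    res = enrich(groups, ["AB"], min_count_group=1, order=0)
    r = next(x for x in res if x.tested)
    bg = fit_background(groups["g1"], order=0)
    dfa = build_dfa("AB", bg.letters)
    dist = count_distribution([10] * 8, dfa, bg, cap=r.N_obs)
    assert r.p_value == pytest.approx(pvalue_ge(dist, r.N_obs), rel=1e-9)
    assert r.Lp == pytest.approx(lp_score(r.p_value), abs=1e-9)
    assert r.expected == pytest.approx(expected_count([10] * 8, "AB", bg), rel=1e-9)


def test_enrich_requires_groups():
    with pytest.raises(ValueError):
        enrich({}, ["AB"])
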