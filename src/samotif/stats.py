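"""Exact over-representation statistics of words in short sequences.

The observed occurrence count N_obs of a word w in a set of sequences
is compared with its exact distribution under a homogeneous Markov
background.  The over-representation score is

    Lp = −log10 p,    p = P(N ≥ N_obs),

so Lp = 3 means over-representation at p = 1e-3.  The distribution of
N is computed exactly by Markov-chain embedding: a KMP deterministic
finite automaton recognises w (overlapping occurrences included —
after a match the automaton resumes from the longest proper suffix of
w that is a prefix), and a dynamic program over
(Markov context × DFA state × count) propagates probability one letter
at a time.  Counts are capped, with the cap bucket holding the
aggregated tail mass P(N ≥ cap); only the tail at N_obs is needed for
a p-value, so the enrichment engine caps at N_obs.

Per-sequence distributions depend only on sequence length, so they are
cached by (word, length, cap) under a corpus-wide background and
combined across a sequence set by convolution (repeated squaring over
length multiplicities).  Exactness is unaffected by either shortcut.
"""

from __future__ import annotations

import math
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd


# --------------------------------------------------------------------------
# background model
# --------------------------------------------------------------------------


@dataclass
class MarkovBackground:
    """Homogeneous Markov model of order ``order`` over ``letters``.

    ``transition`` has one row per context (all ``len(letters)**order``
    tuples of the last ``order`` letters, in lexicographic index order)
    and one column per next letter.  ``initial`` is the distribution of
    the first ``order`` letters, indexed like the contexts (for order 0
    it is the scalar distribution [1.0] and ``transition`` holds the
    letter marginals in its single row).
    """

    order: int
    letters: list[str]
    transition: np.ndarray
    initial: np.ndarray

    def __post_init__(self) -> None:
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        A = len(self.letters)
        n_ctx = A**self.order
        if self.transition.shape != (n_ctx, A):
            raise ValueError("transition must be (A**order, A)")
        if self.initial.shape != (n_ctx,):
            raise ValueError("initial must have one entry per context")
        if np.any(self.transition < 0) or np.any(self.initial < 0):
            raise ValueError("negative probabilities")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("conditional rows must sum to 1")
        if not math.isclose(float(self.initial.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("initial must sum to 1")
        self._index = {l: i for i, l in enumerate(self.letters)}

    @property
    def n_contexts(self) -> int:
        return len(self.letters) ** self.order

    def letter_index(self, letter: str) -> int:
        return self._index[letter]

    def context_index(self, ctx: tuple[int, ...]) -> int:
        A = len(self.letters)
        idx = 0
        for c in ctx:
            idx = idx * A + c
        return idx

    def context_letters(self, idx: int) -> tuple[int, ...]:
        A = len(self.letters)
        out = []
        for _ in range(self.order):
            out.append(idx % A)
            idx //= A
        return tuple(reversed(out))

    def shift_context(self, ctx_idx: int, letter_idx: int) -> int:
        A = len(self.letters)
        return (ctx_idx * A + letter_idx) % (A**self.order) if self.order else 0

    def context_operator(self) -> np.ndarray:
        """(n_ctx, n_ctx) one-step operator on context marginals."""
        n_ctx, A = self.n_contexts, len(self.letters)
        T = np.zeros((n_ctx, n_ctx))
        for ci in range(n_ctx):
            for c in range(A):
                T[ci, self.shift_context(ci, c)] += self.transition[ci, c]
        return T

    def sample(self, length: int, rng: np.random.Generator) -> str:
        """One sequence of the given length (used by simulations)."""
        A = len(self.letters)
        if self.order == 0:
            ids = rng.choice(A, size=length, p=self.transition[0])
            return "".join(self.letters[i] for i in ids)
        ctx_idx = int(rng.choice(self.n_contexts, p=self.initial))
        out = list(self.context_letters(ctx_idx))[:length]
        while len(out) < length:
            c = int(rng.choice(A, p=self.transition[ctx_idx]))
            out.append(c)
            ctx_idx = self.shift_context(ctx_idx, c)
        return "".join(self.letters[i] for i in out)


def fit_background(
    sequences: list[str], order: int = 1, pseudocount: float = 0.0
) -> MarkovBackground:
    """Maximum-likelihood Markov background with additive smoothing.

    Contexts never observed get uniform conditionals.  The initial
    distribution is the (smoothed) empirical distribution of the first
    ``order`` letters of each sequence; sequences shorter than
    ``order`` contribute only to transition counts they can support.
    """
    if not sequences:
        raise ValueError("no sequences")
    if order < 0:
        raise ValueError("order must be >= 0")
    letters = sorted(set("".join(sequences)))
    A = len(letters)
    index = {l: i for i, l in enumerate(letters)}
    n_ctx = A**order
    trans_counts = np.zeros((n_ctx, A))
    init_counts = np.zeros(n_ctx)
    powers = [A**k for k in range(order, 0, -1)]
    for seq in sequences:
        ids = [index[c] for c in seq]
        if order > 0 and len(ids) >= order:
            idx0 = 0
            for c in ids[:order]:
                idx0 = idx0 * A + c
            init_counts[idx0] += 1
        ctx = 0
        for t, c in enumerate(ids):
            if t >= order:
                trans_counts[ctx, c] += 1
            ctx = (ctx * A + c) % n_ctx
    trans = trans_counts + pseudocount
    row_tot = trans.sum(axis=1, keepdims=True)
    unseen = row_tot[:, 0] == 0
    trans[unseen] = 1.0
    row_tot[unseen] = A
    trans /= row_tot
    if order == 0:
        initial = np.array([1.0])
    else:
        init = init_counts + pseudocount
        if init.sum() == 0:
            init = np.ones(n_ctx)
        initial = init / init.sum()
    return MarkovBackground(order=order, letters=letters, transition=trans, initial=initial)


# --------------------------------------------------------------------------
# word automaton
# --------------------------------------------------------------------------


@dataclass
class WordDFA:
    """KMP automaton of a word: state s = length of the longest suffix
    of the processed text that is a prefix of the word.  Entering the
    final state emits one (overlapping) occurrence, after which the
    automaton continues from the longest proper suffix that is again a
    prefix — so e.g. from the match state of AAAA, letter A re-enters
    the match state and emits again.
    """

    word: str
    letters: list[str]
    delta: np.ndarray  # (len(word)+1, A) next-state table
    match_state: int

    def count(self, sequence: str) -> int:
        idx = {l: i for i, l in enumerate(self.letters)}
        s, n = 0, 0
        for ch in sequence:
            s = int(self.delta[s, idx[ch]])
            if s == self.match_state:
                n += 1
        return n

    @property
    def counting_transitions(self) -> set[tuple[int, str]]:
        src, col = np.nonzero(self.delta == self.match_state)
        return {(int(s), self.letters[c]) for s, c in zip(src, col)}


def build_dfa(word: str, letters: list[str]) -> WordDFA:
    if not word:
        raise ValueError("empty word")
    index = {l: i for i, l in enumerate(letters)}
    for ch in word:
        if ch not in index:
            raise ValueError(f"word letter {ch!r} not in alphabet")
    L, A = len(word), len(letters)
    w = [index[c] for c in word]
    delta = np.zeros((L + 1, A), dtype=int)
    delta[0, :] = 0
    delta[0, w[0]] = 1
    fail = 0  # DFA state reached by the failure (proper-suffix) link
    for s in range(1, L + 1):
        for c in range(A):
            delta[s, c] = (s + 1) if (s < L and c == w[s]) else delta[fail, c]
        if s < L:
            fail = delta[fail, w[s]]
    return WordDFA(word=word, letters=list(letters), delta=delta, match_state=L)


def count_occurrences(sequence: str, word: str) -> int:
    """Overlapping occurrence count of ``word`` in ``sequence``."""
    L = len(word)
    return sum(1 for i in range(len(sequence) - L + 1) if sequence[i : i + L] == word)


# --------------------------------------------------------------------------
# exact count distribution
# --------------------------------------------------------------------------


@dataclass
class CountDistribution:
    """Distribution of the total occurrence count, capped at ``cap``:
    ``probs[n]`` is P(N = n) for n < cap and P(N ≥ cap) at n = cap."""

    probs: np.ndarray
    cap: int

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        if len(self.probs) != self.cap + 1:
            raise ValueError("need cap + 1 probability entries")
        if np.any(self.probs < -1e-12):
            raise ValueError("negative probability")
        if not math.isclose(float(self.probs.sum()), 1.0, abs_tol=1e-9):
            raise ValueError("probabilities must sum to 1")


def _sequence_distribution(
    length: int, dfa: WordDFA, bg: MarkovBackground, cap: int
) -> np.ndarray:
    """Exact capped count distribution for one background sequence."""
    A = len(bg.letters)
    n_states = dfa.match_state + 1
    n_ctx = bg.n_contexts
    eff_cap = min(cap, max(0, length - len(dfa.word) + 1))
    P = np.zeros((n_ctx, n_states, eff_cap + 1))
    remaining = length
    if bg.order == 0:
        P[0, 0, 0] = 1.0
    else:
        k = min(bg.order, length)
        for ctx_idx in range(n_ctx):
            p0 = bg.initial[ctx_idx]
            if p0 == 0.0:
                continue
            s, cnt = 0, 0
            for c in bg.context_letters(ctx_idx)[:k]:
                s = int(dfa.delta[s, c])
                if s == dfa.match_state:
                    cnt += 1
            P[ctx_idx, s, min(cnt, eff_cap)] += p0
        remaining = length - k
    emits = dfa.delta == dfa.match_state  # (n_states, A)
    shift = np.array(
        [[bg.shift_context(ci, c) for c in range(A)] for ci in range(n_ctx)], dtype=int
    )
    for _ in range(remaining):
        newP = np.zeros_like(P)
        for c in range(A):
            pc = bg.transition[:, c][:, None]
            dctx = shift[:, c]
            for s in range(n_states):
                col = P[:, s, :]
                if not col.any():
                    continue
                col = col * pc
                if emits[s, c] and eff_cap > 0:
                    rolled = np.empty_like(col)
                    rolled[:, 0] = 0.0
                    rolled[:, 1:] = col[:, :-1]
                    rolled[:, -1] += col[:, -1]
                    col = rolled
                np.add.at(newP[:, dfa.delta[s, c], :], dctx, col)
        P = newP
    dist = P.sum(axis=(0, 1))
    out = np.zeros(cap + 1)
    out[: eff_cap + 1] = dist
    return out


def _convolve_capped(a: np.ndarray, b: np.ndarray, cap: int) -> np.ndarray:
    full = np.convolve(a, b)
    out = full[: cap + 1].copy()
    out[cap] += full[cap + 1 :].sum()
    return out


def _power_capped(d: np.ndarray, m: int, cap: int) -> np.ndarray:
    """m-fold convolution of a capped distribution by repeated squaring."""
    acc: np.ndarray | None = None
    base = d
    while m:
        if m & 1:
            acc = base if acc is None else _convolve_capped(acc, base, cap)
        m >>= 1
        if m:
            base = _convolve_capped(base, base, cap)
    assert acc is not None
    return acc


def count_distribution(
    seq_lengths: list[int],
    dfa: WordDFA,
    bg: MarkovBackground,
    cap: int,
) -> CountDistribution:
    """Exact distribution of the total count of a word over a set of
    independent background sequences, capped at ``cap`` (the cap bucket
    aggregates P(N ≥ cap)).  Invariant to the order of the sequences."""
    if cap < 1:
        raise ValueError("cap must be >= 1")
    if not seq_lengths:
        raise ValueError("no sequences")
    total: np.ndarray | None = None
    for length, m in sorted(Counter(int(l) for l in seq_lengths).items()):
        d = _power_capped(_sequence_distribution(length, dfa, bg, cap), m, cap)
        total = d if total is None else _convolve_capped(total, d, cap)
    total = np.clip(total, 0.0, None)
    total /= total.sum()
    return CountDistribution(probs=total, cap=cap)


def pvalue_ge(dist: CountDistribution, N_obs: int) -> float:
    """Inclusive upper-tail probability P(N ≥ N_obs)."""
    if N_obs < 0:
        raise ValueError("N_obs must be >= 0")
    if N_obs == 0:
        return 1.0
    if N_obs > dist.cap:
        raise ValueError("N_obs exceeds the distribution cap; recompute with a larger cap")
    return float(dist.probs[N_obs:].sum())


def lp_score(p: float) -> float:
    """Over-representation score Lp = −log10(p); Lp = 3 ⇔ p = 1e-3."""
    if not (0.0 < p <= 1.0):
        raise ValueError("p must be in (0, 1]")
    return -math.log10(p)


class ExpectedCountCalculator:
    """Exact E[N] of words under a background, amortised over many words.

    Context marginals m_s (distribution of the ``order`` letters
    starting at position s) are propagated once up to the longest
    sequence; the probability of a word starting at position s ≥ 2 is
    then m_s[ctx0] times a per-word product of conditionals, so the sum
    over positions reduces to a prefix-sum lookup.
    """

    def __init__(self, bg: MarkovBackground, max_len: int):
        self.bg = bg
        self.max_len = max_len
        if bg.order > 0:
            T = bg.context_operator()
            n_pos = max(max_len, 1)
            M = np.empty((n_pos + 1, bg.n_contexts))  # M[s] = marginal at position s
            M[1] = bg.initial
            for s in range(2, n_pos + 1):
                M[s] = M[s - 1] @ T
            self.M = M
            self.cum = np.cumsum(M, axis=0)  # cum[t] = sum_{s<=t} M[s]
        self._word_cache: dict[str, tuple[float, int, float]] = {}

    def _word_factors(self, word: str) -> tuple[float, int, float]:
        """(p1, ctx0, r): probability of the word at position 1, the
        context index of its first ``order`` letters, and the product
        of conditionals for its remaining letters."""
        bg = self.bg
        if word in self._word_cache:
            return self._word_cache[word]
        w = [bg.letter_index(c) for c in word]
        o = bg.order
        if len(w) >= o:
            ctx0 = bg.context_index(tuple(w[:o]))
            r = 1.0
            cur = ctx0
            for c in w[o:]:
                r *= bg.transition[cur, c]
                cur = bg.shift_context(cur, c)
            p1 = float(bg.initial[ctx0]) * r
        else:  # word shorter than the order: sum over matching contexts
            ctx0 = -1
            r = 0.0
            p1 = 0.0
            for ci in range(bg.n_contexts):
                if bg.context_letters(ci)[: len(w)] == tuple(w):
                    p1 += float(bg.initial[ci])
        out = (p1, ctx0, r)
        self._word_cache[word] = out
        return out

    def expected_for_length(self, word: str, length: int) -> float:
        bg = self.bg
        L = len(word)
        if length < L:
            return 0.0
        if bg.order == 0:
            w = [bg.letter_index(c) for c in word]
            p = float(np.prod(bg.transition[0, w]))
            return (length - L + 1) * p
        p1, ctx0, r = self._word_factors(word)
        total = p1
        last = length - L + 1
        if last >= 2:
            if ctx0 >= 0:
                total += r * float(self.cum[last, ctx0] - self.cum[1, ctx0])
            else:  # word shorter than order
                w = tuple(bg.letter_index(c) for c in word)
                for s in range(2, last + 1):
                    for ci in range(bg.n_contexts):
                        if bg.context_letters(ci)[: len(w)] == w:
                            total += float(self.M[s, ci])
        return total

    def total(self, seq_lengths: list[int], word: str) -> float:
        return sum(
            m * self.expected_for_length(word, length)
            for length, m in Counter(int(l) for l in seq_lengths).items()
        )


def expected_count(seq_lengths: list[int], word: str, bg: MarkovBackground) -> float:
    """Exact expected occurrence count of ``word`` over a sequence set."""
    if not seq_lengths:
        return 0.0
    return ExpectedCountCalculator(bg, max(seq_lengths)).total(seq_lengths, word)


# --------------------------------------------------------------------------
# per-group enrichment
# --------------------------------------------------------------------------


@dataclass
class EnrichmentResult:
    word: str
    group_id: str
    N_obs: int
    expected: float
    p_value: float | None
    Lp: float | None
    tested: bool


def enrich(
    groups: dict[str, list[str]],
    words: list[str] | pd.DataFrame,
    bg_scope: str = "corpus",
    order: int = 1,
    min_count_group: int = 5,
    pseudocount: float = 0.0,
    background: MarkovBackground | None = None,
) -> list[EnrichmentResult]:
    """Exact per-(word, group) over-representation.

    ``groups`` maps group id → list of loop letter strings.  A result
    row is produced for every candidate word observed at least once in
    a group; the exact p-value and Lp are computed only when the
    in-group count reaches ``min_count_group`` (tested=True), with the
    count cap set to N_obs.  The background is fitted on the whole
    corpus by default (``bg_scope='corpus'``, which makes group-level
    enrichment detectable) or per group; a pre-fitted ``background``
    overrides both.
    """
    if not groups:
        raise ValueError("no groups")
    if bg_scope not in ("corpus", "group"):
        raise ValueError("bg_scope must be 'corpus' or 'group'")
    word_list = list(words["word"]) if isinstance(words, pd.DataFrame) else list(words)
    word_set = set(word_list)
    wlens = sorted({len(w) for w in word_list})
    corpus_bg = background
    if corpus_bg is None and bg_scope == "corpus":
        all_seqs = [s for g in sorted(groups) for s in groups[g]]
        corpus_bg = fit_background(all_seqs, order=order, pseudocount=pseudocount)

    # pass 1: per-group window counts for every candidate word
    group_counts: dict[str, Counter] = {}
    for group_id in sorted(groups):
        wc: Counter = Counter()
        for s in groups[group_id]:
            for L in wlens:
                for i in range(len(s) - L + 1):
                    w = s[i : i + L]
                    if w in word_set:
                        wc[w] += 1
        group_counts[group_id] = wc
    # maximal cap needed per word across groups (tested pairs only)
    cap_word: dict[str, int] = {}
    for wc in group_counts.values():
        for w, n in wc.items():
            if n >= min_count_group:
                cap_word[w] = max(cap_word.get(w, 0), n)

    results: list[EnrichmentResult] = []
    dfa_cache: dict[str, WordDFA] = {}
    seqdist_cache: dict[tuple[str, int], np.ndarray] = {}
    shared_calc = (
        ExpectedCountCalculator(
            corpus_bg, max((len(s) for g in groups.values() for s in g), default=1)
        )
        if corpus_bg is not None
        else None
    )

    def _fold(d: np.ndarray, cap: int) -> np.ndarray:
        if len(d) == cap + 1:
            return d
        out = d[: cap + 1].copy()
        out[cap] += d[cap + 1 :].sum()
        return out

    for group_id in sorted(groups):
        seqs = groups[group_id]
        bg = corpus_bg
        calc = shared_calc
        if bg is None:
            bg = fit_background(seqs, order=order, pseudocount=pseudocount)
            calc = ExpectedCountCalculator(bg, max((len(s) for s in seqs), default=1))
        lengths = [len(s) for s in seqs]
        window_counts = group_counts[group_id]
        cacheable = corpus_bg is not None
        for word in word_list:
            n_obs = window_counts.get(word, 0)
            if n_obs == 0:
                continue
            exp = calc.total(lengths, word)
            if n_obs < min_count_group:
                results.append(
                    EnrichmentResult(word, group_id, n_obs, exp, None, None, False)
                )
                continue
            if word not in dfa_cache:
                dfa_cache[word] = build_dfa(word, bg.letters)
            dfa = dfa_cache[word]
            big_cap = cap_word[word] if cacheable else n_obs
            total: np.ndarray | None = None
            for length, m in sorted(Counter(lengths).items()):
                key = (word, length)
                if cacheable and key in seqdist_cache:
                    d = seqdist_cache[key]
                else:
                    d = _sequence_distribution(length, dfa, bg, big_cap)
                    if cacheable:
                        seqdist_cache[key] = d
                dm = _power_capped(_fold(d, n_obs), m, n_obs)
                total = dm if total is None else _convolve_capped(total, dm, n_obs)
            probs = np.clip(total, 0.0, None)
            probs /= probs.sum()
            dist = CountDistribution(probs=probs, cap=n_obs)
            p = pvalue_ge(dist, n_obs)
            results.append(
                EnrichmentResult(word, group_id, n_obs, exp, p, lp_score(p), True)
            )
    return results


def enrichment_to_frame(results: list[EnrichmentResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "word": r.word,
                "group_id": r.group_id,
                "N_obs": r.N_obs,
                "expected": r.expected,
                "p_value": r.p_value,
                "Lp": r.Lp,
                "tested": r.tested,
            }
            for r in results
        ],
        columns=["word", "group_id", "N_obs", "expected", "p_value", "Lp", "tested"],
    )
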