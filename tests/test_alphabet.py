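"""Alphabet models: Viterbi encoding, EM training, model selection."""

import itertools

import numpy as np
import pytest

from samotif import _hmm
from samotif.alphabet import (
    AlphabetModel,
    assign_letter_classes,
    encode,
    encode_trace,
    n_free_parameters,
    select_model,
    train_alphabet,
)
from samotif.synthetic import (
    generate_alphabet,
    generate_backbone,
    ideal_helix_descriptor,
    ideal_strand_descriptor,
    sample_descriptor_corpus,
)


def brute_force_best_logprob(X, model):
    logb = _hmm.log_gaussian_density(X, model.means, model.covs)
    lt, li = np.log(model.transition), np.log(model.initial)
    best = -np.inf
    best_path = None
    for path in itertools.product(range(model.K), repeat=len(X)):
        lp = li[path[0]] + logb[0, path[0]]
        for t in range(1, len(path)):
            lp += lt[path[t - 1], path[t]] + logb[t, path[t]]
        if lp > best:
            best, best_path = lp, path
    return best, best_path


def path_logprob(path, X, model):
    logb = _hmm.log_gaussian_density(X, model.means, model.covs)
    lp = np.log(model.initial[path[0]]) + logb[0, path[0]]
    for t in range(1, len(path)):
        lp += np.log(model.transition[path[t - 1], path[t]]) + logb[t, path[t]]
    return lp


def test_single_descriptor_maximizes_initial_times_density():
    model = generate_alphabet(4, seed=0)
    X = model.means[2][None, :] + 0.01
    seq = encode(X, model)
    logb = _hmm.log_gaussian_density(X, model.means, model.covs)[0]
    assert seq.letters == model.letters[int(np.argmax(np.log(model.initial) + logb))]


@pytest.mark.parametrize("seed", range(20))
def test_viterbi_equals_bruteforce_path(seed):
    rng = np.random.default_rng(seed)
    K = int(rng.integers(2, 5))
    T = int(rng.integers(2, 7))
    model = generate_alphabet(K, seed=seed + 100)
    X = rng.uniform([3, 3, 3, -4], [9, 11, 9, 4], size=(T, 4))
    seq = encode(X, model)
    got = np.array([model.letters.index(c) for c in seq.letters])
    best, best_path = brute_force_best_logprob(X, model)
    assert path_logprob(got, X, model) == pytest.approx(best, abs=1e-9)
    assert tuple(got) == best_path


def test_encode_trace_gives_n_minus_3_letters():
    model = generate_alphabet(5, seed=1)
    tr = generate_backbone([("helix", 6), ("loop", 4)], noise_sd=0.1, seed=2)
    seqs = encode_trace(tr, model)
    assert len(seqs) == 1
    assert len(seqs[0].letters) == len(tr) - 3


def test_encode_rejects_non_finite_descriptor():
    model = generate_alphabet(3, seed=1)
    X = np.ones((4, 4))
    X[2, 1] = np.nan
    with pytest.raises(ValueError, match="window 2"):
        encode(X, model)


def test_train_single_state_closed_form():
    model = generate_alphabet(3, seed=5)
    seqs, _ = sample_descriptor_corpus(model, 20, 30, seed=6)
    fit = train_alphabet(seqs, 1, seed=0, restarts=1, reg=1e-6)
    X = np.concatenate(seqs)
    assert fit.transition == pytest.approx(np.array([[1.0]]))
    assert fit.means[0] == pytest.approx(X.mean(axis=0), abs=1e-9)
    assert fit.covs[0] == pytest.approx(
        np.cov(X.T, bias=True) + 1e-6 * np.eye(4), abs=1e-8
    )


def test_train_is_deterministic_given_seed():
    model = generate_alphabet(3, seed=5)
    seqs, _ = sample_descriptor_corpus(model, 30, 40, seed=6)
    a = train_alphabet(seqs, 3, seed=42, restarts=2)
    b = train_alphabet(seqs, 3, seed=42, restarts=2)
    assert np.array_equal(a.means, b.means)
    assert np.array_equal(a.covs, b.covs)
    assert np.array_equal(a.transition, b.transition)


def test_em_loglik_history_monotone():
    model = generate_alphabet(3, seed=5)
    seqs, _ = sample_descriptor_corpus(model, 30, 40, seed=7)
    *_, hist = _hmm.em_fit(seqs, 3, seed=1)
    assert len(hist) >= 2
    assert all(b >= a - 1e-6 for a, b in zip(hist, hist[1:]))


def test_loglik_and_viterbi_agree_with_hmmlearn():
    hmmlearn = pytest.importorskip("hmmlearn.hmm")
    model = generate_alphabet(3, seed=5)
    seqs, _ = sample_descriptor_corpus(model, 10, 50, seed=8)
    fit = train_alphabet(seqs, 3, seed=7, restarts=2)
    h = hmmlearn.GaussianHMM(n_components=3, covariance_type="full", init_params="")
    h.startprob_, h.transmat_ = fit.initial, fit.transition
    h.means_, h.covars_ = fit.means, fit.covs
    X = np.concatenate(seqs)
    ours = _hmm.total_loglik(seqs, fit.means, fit.covs, fit.transition, fit.initial)
    assert ours == pytest.approx(h.score(X, [50] * 10), rel=1e-9)
    _, path = h.decode(seqs[0])
    assert encode(seqs[0], fit).letters == "".join(fit.letters[k] for k in path)


def test_select_model_single_candidate_and_k1_bic_closed_form():
    model = generate_alphabet(3, seed=5)
    seqs, _ = sample_descriptor_corpus(model, 20, 30, seed=9)
    best, table = select_model(seqs, [1], seed=0, restarts=1)
    assert best == 1
    # closed-form Gaussian log-likelihood for one state: the fitted
    # covariance is the biased MLE plus the ridge, so the average
    # Mahalanobis term is tr((S + rI)^-1 S) rather than exactly d
    X = np.concatenate(seqs)
    n, d = X.shape
    S = np.cov(X.T, bias=True)
    cov = S + 1e-6 * np.eye(d)
    tr = np.trace(np.linalg.solve(cov, S))
    ll = -0.5 * n * (d * np.log(2 * np.pi) + np.log(np.linalg.det(cov)) + tr)
    bic = -2 * ll + n_free_parameters(1) * np.log(n)
    assert table.loc[0, "bic"] == pytest.approx(bic, rel=1e-6)


def test_model_json_roundtrip_is_bit_stable(tmp_path):
    model = generate_alphabet(4, seed=3)
    p = tmp_path / "alphabet.json"
    model.save(p)
    back = AlphabetModel.load(p)
    assert back.letters == model.letters
    assert np.array_equal(back.means, model.means)
    assert np.array_equal(back.covs, model.covs)
    assert np.array_equal(back.transition, model.transition)
    assert back.classes == model.classes
    back.save(tmp_path / "again.json")
    assert (tmp_path / "again.json").read_bytes() == p.read_bytes()


def test_assign_letter_classes_references_and_agreement():
    model = generate_alphabet(6, seed=4)
    classes = assign_letter_classes(model)
    # letters 0/1 sit exactly on the helix/strand references by construction
    assert classes[0] == "helix"
    assert classes[1] == "strand"
    agreement = np.mean([a == b for a, b in zip(classes, model.classes)])
    assert agreement >= 0.9
    # a mean far from both references is a loop
    far = AlphabetModel(
        letters=["A", "B"],
        means=np.array([[50.0, 50, 50, 0], ideal_helix_descriptor().as_array()]),
        covs=np.array([np.eye(4)] * 2),
        transition=np.full((2, 2), 0.5),
        initial=np.array([0.5, 0.5]),
    )
    got = assign_letter_classes(far)
    assert got == ["loop", "helix"]


def test_model_validation_rejects_bad_rows():
    model = generate_alphabet(3, seed=0)
    bad = model.transition.copy()
    bad[0, 0] += 0.1
    with pytest.raises(ValueError, match="sum to 1"):
        AlphabetModel(
            letters=model.letters,
            means=model.means,
            covs=model.covs,
            transition=bad,
            initial=model.initial,
            classes=model.classes,
        )
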