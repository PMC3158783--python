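"""Structural alphabets: hidden-Markov models over fragment descriptors.

A structural alphabet is a set of K "structural letters", each a
Gaussian prototype of the 4-D fragment descriptor, linked by a letter
transition matrix.  Encoding a backbone replaces its ``n`` residues by
``n − 3`` letters — one per overlapping 4-residue window — via joint
maximum-a-posteriori (Viterbi) decoding.  Letters are labelled by the
secondary structure they describe (helix, strand or loop); the
canonical 27-letter alphabet devotes {A, a, W, V} to α-helices and
{L, M, N, T, X} to β-strands, the remaining 18 letters to loops.
"""

from __future__ import annotations

import json
import string
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import _hmm
from .geometry import Descriptor4

#: Secondary-structure classes of the canonical 27-letter alphabet.
HMMSA_CLASSES: dict[str, str] = {
    **{c: "helix" for c in "AaWV"},
    **{c: "strand" for c in "LMNTX"},
    **{
        c: "loop"
        for c in string.ascii_uppercase
        if c not in set("AWVLMNTX")
    },
}

VALID_CLASSES = ("helix", "strand", "loop")


def default_letter_names(K: int) -> list[str]:
    """Single-character letter names: the 27-letter convention
    (a, A–Z) when K == 27, otherwise A, B, … then lowercase."""
    pool = list(string.ascii_uppercase) + list(string.ascii_lowercase)
    if K == 27:
        return ["a"] + list(string.ascii_uppercase)
    if K > len(pool):
        raise ValueError("too many letters for single-character names")
    return pool[:K]


@dataclass
class AlphabetModel:
    """A structural alphabet: Gaussian emissions + letter transitions."""

    letters: list[str]
    means: np.ndarray  # (K, 4)
    covs: np.ndarray  # (K, 4, 4)
    transition: np.ndarray  # (K, K), row-stochastic
    initial: np.ndarray  # (K,)
    classes: list[str] = field(default_factory=list)  # helix/strand/loop
    representative: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.covs = np.asarray(self.covs, dtype=float)
        self.transition = np.asarray(self.transition, dtype=float)
        self.initial = np.asarray(self.initial, dtype=float)
        if not self.classes:
            self.classes = ["loop"] * len(self.letters)
        self.validate()

    @property
    def K(self) -> int:
        return len(self.letters)

    def validate(self) -> None:
        K = self.K
        if len(set(self.letters)) != K:
            raise ValueError("letter names not unique")
        if self.means.shape != (K, 4) or self.covs.shape != (K, 4, 4):
            raise ValueError("emission parameter shapes inconsistent with K")
        if self.transition.shape != (K, K) or self.initial.shape != (K,):
            raise ValueError("transition/initial shapes inconsistent with K")
        if not np.allclose(self.transition.sum(axis=1), 1.0, atol=1e-9):
            raise ValueError("transition rows must sum to 1")
        if not np.isclose(self.initial.sum(), 1.0, atol=1e-9):
            raise ValueError("initial must sum to 1")
        for k in range(K):
            try:
                np.linalg.cholesky(self.covs[k])
            except np.linalg.LinAlgError as exc:
                raise ValueError(f"covariance of letter {self.letters[k]} not PD") from exc
        if len(self.classes) != K or any(c not in VALID_CLASSES for c in self.classes):
            raise ValueError("classes must be helix/strand/loop, one per letter")

    def class_of(self, letter: str) -> str:
        return self.classes[self.letters.index(letter)]

    def loop_letters(self) -> set[str]:
        return {l for l, c in zip(self.letters, self.classes) if c == "loop"}

    # ---- persistence (JSON; floats round-trip bit-stably) ----

    def to_dict(self) -> dict:
        d = {
            "letters": list(self.letters),
            "means": self.means.tolist(),
            "covariances": self.covs.tolist(),
            "transition": self.transition.tolist(),
            "initial": self.initial.tolist(),
            "classes": list(self.classes),
        }
        if self.representative:
            d["representative"] = {
                k: np.asarray(v).tolist() for k, v in self.representative.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "AlphabetModel":
        return cls(
            letters=list(d["letters"]),
            means=np.asarray(d["means"], dtype=float),
            covs=np.asarray(d["covariances"], dtype=float),
            transition=np.asarray(d["transition"], dtype=float),
            initial=np.asarray(d["initial"], dtype=float),
            classes=list(d.get("classes") or []),
            representative={
                k: np.asarray(v, dtype=float)
                for k, v in (d.get("representative") or {}).items()
            },
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "AlphabetModel":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class LetterSequence:
    """A structural-letter string for one unbroken chain segment.

    ``residue_anchor[i]`` is the index, within the parent segment, of
    the first residue of letter i's 4-residue fragment; an unbroken
    segment of n residues yields n − 3 letters.
    """

    protein_id: str
    chain_id: str
    letters: str
    residue_anchor: list[int]
    segment_index: int = 0
    residue_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if len(self.residue_anchor) != len(self.letters):
            raise ValueError("one residue anchor per letter required")

    def __len__(self) -> int:
        return len(self.letters)


def _descriptor_matrix(descriptors) -> np.ndarray:
    if len(descriptors) == 0:
        raise ValueError("no descriptors to encode")
    X = np.stack(
        [d.as_array() if isinstance(d, Descriptor4) else np.asarray(d, float) for d in descriptors]
    )
    if not np.all(np.isfinite(X)):
        bad = int(np.where(~np.isfinite(X).all(axis=1))[0][0])
        raise ValueError(f"non-finite descriptor in window {bad}")
    return X


def encode(
    descriptors,
    model: AlphabetModel,
    protein_id: str = "",
    chain_id: str = "",
    residue_anchor: list[int] | None = None,
    segment_index: int = 0,
) -> LetterSequence:
    """Viterbi (joint-MAP) encoding of a descriptor run into letters.

    Deterministic; ties are resolved toward the lowest letter index.
    """
    X = _descriptor_matrix(descriptors)
    logb = _hmm.log_gaussian_density(X, model.means, model.covs)
    with np.errstate(divide="ignore"):
        path = _hmm.viterbi_path(
            logb, np.log(model.transition), np.log(model.initial)
        )
    letters = "".join(model.letters[k] for k in path)
    if residue_anchor is None:
        residue_anchor = list(range(len(letters)))
    return LetterSequence(
        protein_id=protein_id,
        chain_id=chain_id,
        letters=letters,
        residue_anchor=residue_anchor,
        segment_index=segment_index,
    )


def encode_trace(trace, model: AlphabetModel, max_ca_gap: float = 4.5) -> list[LetterSequence]:
    """Encode every unbroken run of a Cα trace; one letter sequence per run."""
    from .geometry import descriptor_segments

    out = []
    for idx, (seg, descs, anchors) in enumerate(descriptor_segments(trace, max_ca_gap)):
        ls = encode(
            descs,
            model,
            protein_id=trace.protein_id,
            chain_id=trace.chain_id,
            residue_anchor=anchors,
            segment_index=idx,
        )
        ls.residue_ids = list(seg.residue_ids)
        out.append(ls)
    return out


def train_alphabet(
    corpus: list[np.ndarray],
    K: int,
    seed: int = 0,
    restarts: int = 5,
    reg: float = 1e-6,
    n_iter: int = 200,
    tol: float = 1e-6,
) -> AlphabetModel:
    """Fit a K-letter alphabet by Baum–Welch (full-covariance Gaussians).

    The best of ``restarts`` k-means-seeded runs (by log-likelihood) is
    kept; runs that collapse a state are retried with a fresh seed.
    Reproducible for a given ``seed``.
    """
    if K < 1:
        raise ValueError("K must be >= 1")
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in corpus]
    n_obs = sum(len(s) for s in seqs)
    if n_obs < 10 * K:
        raise ValueError(f"need at least {10 * K} observations for K={K}")
    rng = np.random.default_rng(seed)
    best = None
    failures = 0
    attempts = 0
    while attempts < restarts and failures < 4 * restarts:
        sub_seed = int(rng.integers(2**31 - 1))
        try:
            means, covs, trans, init, hist = _hmm.em_fit(
                seqs, K, seed=sub_seed, reg=reg, n_iter=n_iter, tol=tol
            )
        except _hmm.EmptyStateError:
            failures += 1
            continue
        attempts += 1
        if best is None or hist[-1] > best[-1]:
            best = (means, covs, trans, init, hist[-1])
    if best is None:
        raise RuntimeError("all EM restarts failed (empty states / singular covariances)")
    means, covs, trans, init, _ = best
    return AlphabetModel(
        letters=default_letter_names(K),
        means=means,
        covs=covs,
        transition=trans,
        initial=init,
        classes=["loop"] * K,
    )


def n_free_parameters(K: int, dim: int = 4) -> int:
    """Free parameters of a K-state full-covariance Gaussian HMM:
    (K−1) initial + K(K−1) transition + K·(dim + dim(dim+1)/2) emission."""
    return (K - 1) + K * (K - 1) + K * (dim + dim * (dim + 1) // 2)


def select_model(
    corpus: list[np.ndarray],
    K_values: list[int],
    seed: int = 0,
    **fit_kwargs,
) -> tuple[int, pd.DataFrame]:
    """Fit each alphabet size and pick the one minimising
    BIC = −2·logL + p·log(N)."""
    seqs = [np.atleast_2d(np.asarray(s, dtype=float)) for s in corpus]
    n_obs = sum(len(s) for s in seqs)
    rows = []
    for K in K_values:
        try:
            model = train_alphabet(seqs, K, seed=seed, **fit_kwargs)
            ll = _hmm.total_loglik(
                seqs, model.means, model.covs, model.transition, model.initial
            )
            p = n_free_parameters(K)
            rows.append({"K": K, "loglik": ll, "n_params": p, "bic": -2.0 * ll + p * np.log(n_obs)})
        except (ValueError, RuntimeError):
            rows.append({"K": K, "loglik": np.nan, "n_params": n_free_parameters(K), "bic": np.nan})
    table = pd.DataFrame(rows)
    if table["bic"].isna().all():
        raise RuntimeError("no alphabet size could be fitted")
    best_K = int(table.loc[table["bic"].idxmin(), "K"])
    return best_K, table


def assign_letter_classes(
    model: AlphabetModel,
    helix_ref: Descriptor4 | None = None,
    strand_ref: Descriptor4 | None = None,
    tol: float = 3.0,
) -> list[str]:
    """Label each letter helix/strand/loop by the Mahalanobis distance of
    its emission mean to reference helix/strand descriptors (under the
    letter's own covariance); everything farther than ``tol`` is loop.

    Defaults references come from ideal noiseless helix/strand backbones.
    """
    if helix_ref is None or strand_ref is None:
        from .synthetic import ideal_helix_descriptor, ideal_strand_descriptor

        helix_ref = helix_ref or ideal_helix_descriptor()
        strand_ref = strand_ref or ideal_strand_descriptor()
    refs = {"helix": helix_ref.as_array(), "strand": strand_ref.as_array()}
    classes = []
    for k in range(model.K):
        inv = np.linalg.inv(model.covs[k])
        best, best_d = "loop", np.inf
        for name, ref in refs.items():
            diff = model.means[k] - ref
            d = float(np.sqrt(diff @ inv @ diff))
            if d < tol and d < best_d:
                best, best_d = name, d
        classes.append(best)
    return classes
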