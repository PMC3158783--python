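"""Rigid-body superposition of Cα fragments.

RMSD between two equal-length fragments is computed after the optimal
proper rotation + translation (Kabsch superposition with determinant
correction — backbone fragments are chiral, so reflections are
disallowed).  The structural similarity of two *words* is summarised
by the mean ± sd RMSD over randomly sampled cross pairs of their
fragments (30 pairs by default).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation


@dataclass
class Fragment3D:
    """Ordered Cα coordinates of one word occurrence (L+3 points, Å)."""

    coords: np.ndarray
    occurrence: object | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (n, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")


def _as_points(x) -> np.ndarray:
    return x.coords if isinstance(x, Fragment3D) else np.asarray(x, dtype=float)


def kabsch_rmsd(X, Y) -> float:
    """Minimal RMSD between two point sets under proper rotation +
    translation; symmetric in its arguments."""
    P = _as_points(X)
    Q = _as_points(Y)
    if P.shape != Q.shape or len(P) < 3:
        raise ValueError("point sets must have equal shape with >= 3 points")
    Pc = P - P.mean(axis=0)
    Qc = Q - Q.mean(axis=0)
    # degenerate: a set collapsed to a point leaves rotation undefined;
    # report the RMSD of the centered sets under the identity rotation
    if np.linalg.norm(Pc) < 1e-12 or np.linalg.norm(Qc) < 1e-12:
        return float(np.sqrt(np.mean(np.sum((Pc - Qc) ** 2, axis=1))))
    rot, _ = Rotation.align_vectors(Pc, Qc)
    # evaluate the residual directly: the reported rssd loses precision
    # near zero (congruent fragments must give ~0, not ~1e-7)
    diff = Pc - rot.apply(Qc)
    return float(np.sqrt(np.mean(np.sum(diff**2, axis=1))))


def word_pair_rmsd(
    frags_A: list[Fragment3D],
    frags_B: list[Fragment3D],
    n_pairs: int = 30,
    seed: int = 0,
) -> tuple[float, float]:
    """Mean and sd of the Kabsch RMSD over randomly sampled cross pairs.

    Pairs are drawn without replacement from the |A| x |B| cross
    product when enough distinct pairs exist, with replacement
    otherwise; reproducible for a given seed.
    """
    if not frags_A or not frags_B:
        raise ValueError("both fragment sets must be non-empty")
    rng = np.random.default_rng(seed)
    total = len(frags_A) * len(frags_B)
    replace = total < n_pairs
    idx = rng.choice(total, size=n_pairs, replace=replace)
    vals = np.array(
        [kabsch_rmsd(frags_A[i // len(frags_B)], frags_B[i % len(frags_B)]) for i in idx]
    )
    return float(vals.mean()), float(vals.std(ddof=1) if n_pairs > 1 else 0.0)
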