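"""Four-residue backbone geometry.

A protein backbone is reduced to its Cα trace and cut into overlapping
windows of four consecutive residues.  Each window is summarised by a
4-D geometric descriptor: the three distances between non-successive
Cα atoms (d13, d14, d24) and the signed out-of-plane component ``h`` of
the fourth Cα relative to the plane spanned by the first three.  The
sign of ``h`` follows the right-handed normal (p2−p1)×(p3−p1), so the
descriptor distinguishes mirror-image conformations (protein backbones
are chiral).

Chain continuity matters: windows spanning a chain break — a Cα–Cα
step longer than ``max_ca_gap`` or a jump in author residue numbering —
produce no descriptor, and downstream letter sequences are split at the
break.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

import numpy as np

logger = logging.getLogger(__name__)

#: Default maximal Cα–Cα distance (Å) regarded as a peptide-bonded step.
DEFAULT_MAX_CA_GAP = 4.5

_RESID_RE = re.compile(r"^(-?\d+)([A-Za-z]?)$")


@dataclass
class CaTrace:
    """The Cα trace of one protein chain.

    ``residue_ids`` are author residue identifiers as strings, e.g.
    ``"42"`` or ``"42A"`` (insertion code kept).  ``coords`` is an
    ``(n, 3)`` array in Å.
    """

    protein_id: str
    chain_id: str
    residue_ids: list[str]
    coords: np.ndarray

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be an (n, 3) array")
        if len(self.residue_ids) != len(self.coords):
            raise ValueError("residue_ids and coords must have equal length")
        if len(self.coords) < 1:
            raise ValueError("empty trace")

    def __len__(self) -> int:
        return len(self.residue_ids)

    def residue_numbers(self) -> np.ndarray:
        """Numeric part of each residue id (insertion codes stripped)."""
        nums = []
        for rid in self.residue_ids:
            m = _RESID_RE.match(str(rid).strip())
            if m is None:
                raise ValueError(f"unparseable residue id {rid!r}")
            nums.append(int(m.group(1)))
        return np.asarray(nums, dtype=int)


@dataclass(frozen=True)
class Descriptor4:
    """Geometric descriptor of one 4-residue fragment (all in Å).

    ``h`` is signed: it flips sign under mirror reflection of the
    coordinates and is zero for coplanar fragments.
    """

    d13: float
    d14: float
    d24: float
    h: float

    def as_array(self) -> np.ndarray:
        return np.array([self.d13, self.d14, self.d24, self.h], dtype=float)

    @staticmethod
    def from_array(x: np.ndarray) -> "Descriptor4":
        x = np.asarray(x, dtype=float)
        return Descriptor4(float(x[0]), float(x[1]), float(x[2]), float(x[3]))


def descriptor_from_points(p: np.ndarray) -> Descriptor4:
    """Descriptor of a single 4-point window.

    Raises ``ValueError`` if the first three points are collinear
    (the plane, hence ``h``, is undefined).
    """
    p = np.asarray(p, dtype=float)
    if p.shape != (4, 3):
        raise ValueError("expected a (4, 3) window")
    d13 = float(np.linalg.norm(p[0] - p[2]))
    d14 = float(np.linalg.norm(p[0] - p[3]))
    d24 = float(np.linalg.norm(p[1] - p[3]))
    normal = np.cross(p[1] - p[0], p[2] - p[0])
    nn = np.linalg.norm(normal)
    scale = max(np.linalg.norm(p[1] - p[0]) * np.linalg.norm(p[2] - p[0]), 1e-30)
    if nn / scale < 1e-8:
        raise ValueError("first three points collinear; plane undefined")
    h = float(np.dot(normal / nn, p[3] - p[0]))
    return Descriptor4(d13, d14, d24, h)


def split_segments(trace: CaTrace, max_ca_gap: float = DEFAULT_MAX_CA_GAP) -> list[CaTrace]:
    """Split a trace into unbroken segments.

    A break is declared between residues i and i+1 when the Cα step
    exceeds ``max_ca_gap`` or the author numbering is discontinuous
    (numeric difference > 1; insertion-coded residues share a number
    and are treated as consecutive).
    """
    if max_ca_gap <= 0:
        raise ValueError("max_ca_gap must be positive")
    n = len(trace)
    if n == 1:
        return [trace]
    steps = np.linalg.norm(np.diff(trace.coords, axis=0), axis=1)
    nums = trace.residue_numbers()
    dnum = np.diff(nums)
    breaks = (steps > max_ca_gap) | (dnum > 1) | (dnum < 0)
    segments: list[CaTrace] = []
    start = 0
    for i in range(n - 1):
        if breaks[i]:
            segments.append(_subtrace(trace, start, i + 1))
            start = i + 1
    segments.append(_subtrace(trace, start, n))
    return segments


def _subtrace(trace: CaTrace, a: int, b: int) -> CaTrace:
    return CaTrace(
        protein_id=trace.protein_id,
        chain_id=trace.chain_id,
        residue_ids=trace.residue_ids[a:b],
        coords=trace.coords[a:b],
    )


def segment_descriptors(segment: CaTrace) -> list[Descriptor4]:
    """Descriptors of every 4-residue window of an unbroken segment.

    Degenerate windows (first three Cα collinear) are dropped with a
    warning; this also truncates the window list at that point only,
    not the whole segment — callers that need contiguity should treat a
    dropped window as a break, which :func:`encode_trace` does.
    """
    out: list[Descriptor4] = []
    for i in range(len(segment) - 3):
        window = segment.coords[i : i + 4]
        if not np.all(np.isfinite(window)):
            raise ValueError(
                f"non-finite coordinates in window starting at residue "
                f"{segment.residue_ids[i]} of {segment.protein_id}_{segment.chain_id}"
            )
        try:
            out.append(descriptor_from_points(window))
        except ValueError:
            logger.warning(
                "degenerate window (collinear Cα) at residue %s of %s_%s; dropped",
                segment.residue_ids[i],
                segment.protein_id,
                segment.chain_id,
            )
            out.append(None)  # type: ignore[arg-type]
    return out


def compute_descriptors(
    trace: CaTrace, max_ca_gap: float = DEFAULT_MAX_CA_GAP
) -> list[Descriptor4]:
    """All descriptors of a trace; windows spanning chain breaks or
    degenerate geometry yield none."""
    if len(trace) < 4:
        raise ValueError("trace has fewer than 4 residues")
    descs: list[Descriptor4] = []
    for seg in split_segments(trace, max_ca_gap):
        if len(seg) < 4:
            continue
        descs.extend(d for d in segment_descriptors(seg) if d is not None)
    return descs


def descriptor_segments(
    trace: CaTrace, max_ca_gap: float = DEFAULT_MAX_CA_GAP
) -> list[tuple[CaTrace, list[Descriptor4], list[int]]]:
    """Per-segment descriptors with window anchors.

    Returns ``(segment, descriptors, anchors)`` triples where
    ``anchors[j]`` is the index (within the segment) of the first
    residue of descriptor ``j``.  Degenerate windows split the
    descriptor run, so each returned run is contiguous.
    """
    if len(trace) < 4:
        raise ValueError("trace has fewer than 4 residues")
    out = []
    for seg in split_segments(trace, max_ca_gap):
        if len(seg) < 4:
            continue
        descs = segment_descriptors(seg)
        run: list[Descriptor4] = []
        anchors: list[int] = []
        for j, d in enumerate(descs):
            if d is None:
                if run:
                    out.append((seg, run, anchors))
                run, anchors = [], []
            else:
                run.append(d)
                anchors.append(j)
        if run:
            out.append((seg, run, anchors))
    return out
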