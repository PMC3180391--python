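"""Pairwise global alignment and the two guide-tree distance measures.

Two distances feed tree construction: the *DP distance* (mismatch fraction
of a global pairwise alignment, in [0, 1]) computed from unaligned
sequences, and the *Kimura protein distance* -ln(1 - D - 0.2 D^2) computed
from already-aligned rows, where D is the observed non-identity fraction
over columns with both residues present.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from math import log

import numpy as np

from ._kernels import DIAG, UP, affine_dp
from .core import (
    GAP,
    Alignment,
    AlignmentError,
    GapModel,
    Sequence,
    SubstitutionMatrix,
)

#: Distances whose Kimura log argument underflows are capped here.
KIMURA_CAP = 10.0
_KIMURA_EPS = 1e-9


@dataclass(frozen=True)
class PairwiseAlignment:
    """A global alignment of two sequences with its affine-gap score."""

    row_a: str
    row_b: str
    score: float
    align_length: int
    mismatch_count: int


@dataclass(frozen=True)
class PairwiseIdentity:
    """Identity bookkeeping over gap-free columns of an aligned pair."""

    exact_matches: int
    positions_scored: int

    @property
    def S_frac(self) -> float:
        return self.exact_matches / self.positions_scored

    @property
    def D(self) -> float:
        return 1.0 - self.S_frac


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric nonnegative pairwise distances with a zero diagonal."""

    labels: tuple[str, ...]
    d: np.ndarray
    method: str

    def __post_init__(self) -> None:
        d = self.d
        if d.shape != (len(self.labels), len(self.labels)):
            raise AlignmentError("distance matrix shape does not match labels")
        if not np.allclose(d, d.T) or not np.all(np.diag(d) == 0):
            raise AlignmentError("distance matrix must be symmetric with zero diagonal")
        if not np.all(np.isfinite(d)):
            raise AlignmentError("distance matrix entries must be finite")

    def to_phylip(self) -> str:
        """PHYLIP-style square matrix text."""
        lines = [f"{len(self.labels)}"]
        for name, row in zip(self.labels, self.d):
            lines.append(
                f"{name:<10} " + " ".join(f"{v:.6f}" for v in row)
            )
        return "\n".join(lines) + "\n"


def global_align(
    a: Sequence, b: Sequence, m: SubstitutionMatrix, gaps: GapModel
) -> PairwiseAlignment:
    """Needleman-Wunsch global alignment with affine gap runs costing
    ``g + n*x`` (terminal gaps penalised like internal ones).

    The returned score is the maximum of sum-of-matrix-scores over
    residue-residue columns plus the affine cost of every gap run.
    """
    if not a.residues or not b.residues:
        raise AlignmentError("cannot align an empty sequence")
    ab = np.frombuffer(a.residues.encode(), dtype=np.uint8)
    bb = np.frombuffer(b.residues.encode(), dtype=np.uint8)
    S = m.lut[np.ix_(ab, bb)]
    score, moves = affine_dp(S, gaps.g + gaps.x, gaps.x)
    ra, rb = [], []
    i = j = 0
    for mv in moves:
        if mv == DIAG:
            ra.append(a.residues[i])
            rb.append(b.residues[j])
            i += 1
            j += 1
        elif mv == UP:
            ra.append(a.residues[i])
            rb.append(GAP)
            i += 1
        else:
            ra.append(GAP)
            rb.append(b.residues[j])
            j += 1
    row_a = "".join(ra)
    row_b = "".join(rb)
    mismatches = sum(1 for x, y in zip(row_a, row_b) if x != y or x == GAP)
    return PairwiseAlignment(row_a, row_b, float(score), len(row_a), mismatches)


def dp_distance(pw: PairwiseAlignment) -> float:
    """Mismatch fraction of a pairwise alignment: mismatch / align length.

    Residue-vs-gap columns count as mismatches, which keeps the value in
    [0, 1] since the denominator includes gap columns.
    """
    if pw.align_length < 1:
        raise AlignmentError("alignment length must be >= 1")
    return pw.mismatch_count / pw.align_length


def pairwise_identity(row_a: str, row_b: str) -> PairwiseIdentity:
    if len(row_a) != len(row_b):
        raise AlignmentError("aligned rows must have equal length")
    scored = 0
    matches = 0
    for x, y in zip(row_a, row_b):
        if x == GAP or y == GAP:
            continue
        scored += 1
        if x == y:
            matches += 1
    if scored == 0:
        raise AlignmentError("no scored positions (all columns involve a gap)")
    return PairwiseIdentity(matches, scored)


def kimura_distance(row_a: str, row_b: str) -> float:
    """Kimura-corrected protein distance -ln(1 - D - 0.2 D^2).

    Gap positions are ignored and only exact residue matches count towards
    the identity fraction S = 1 - D.  When the log argument underflows
    (D >~ 0.854) the distance is capped at :data:`KIMURA_CAP` with a warning
    so that neighbour-joining always receives finite inputs.
    """
    ident = pairwise_identity(row_a, row_b)
    D = ident.D
    arg = 1.0 - D - 0.2 * D * D
    if arg <= _KIMURA_EPS:
        warnings.warn(
            f"Kimura distance undefined for D={D:.3f}; capping at {KIMURA_CAP}",
            RuntimeWarning,
            stacklevel=2,
        )
        return KIMURA_CAP
    return -log(arg)


def distance_matrix_dp(
    seqs: list[Sequence], m: SubstitutionMatrix, gaps: GapModel
) -> DistanceMatrix:
    """DP distances between all unordered sequence pairs (computed once per
    pair, mirrored for symmetry)."""
    n = len(seqs)
    if n < 2:
        raise AlignmentError("need at least two sequences")
    d = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = dp_distance(global_align(seqs[i], seqs[j], m, gaps))
    return DistanceMatrix(tuple(s.id for s in seqs), d, "dp")


def distance_matrix_kimura(aln: Alignment) -> DistanceMatrix:
    """Kimura distances between all row pairs of an alignment."""
    n = aln.N
    rows = aln.rows
    d = np.zeros((n, n))
    for i in range(n - 1):
        for j in range(i + 1, n):
            try:
                d[i, j] = d[j, i] = kimura_distance(rows[i], rows[j])
            except AlignmentError as exc:
                raise AlignmentError(
                    f"rows {aln.seq_ids[i]!r}/{aln.seq_ids[j]!r}: {exc}"
                ) from exc
    return DistanceMatrix(aln.seq_ids, d, "kimura")
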