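"""Alignment fitness (weighted sum-of-pairs, WSPM) and reference accuracy
(SPS and CS).

WSPM scores every unordered row pair of an alignment on its gap-gap-deleted
projection: residue-residue columns contribute the pair weight times the
substitution score, and each maximal residue-vs-gap run of length n
contributes the pair weight times the affine penalty g + n*x.  Gap-gap
columns cost nothing and neither open nor interrupt a run.

SPS is the fraction of reference residue pairs (two residues of different
sequences sharing a reference column) that also share a column in the test
alignment; CS is the fraction of reference columns reproduced exactly.
Both lie in [0, 1] and equal 1 on self-comparison.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence as TSequence

import numpy as np

from ._kernels import wspm_kernel
from .core import (
    GAP_BYTE,
    Alignment,
    AlignmentError,
    GapModel,
    SubstitutionMatrix,
)
from .tree import WeightVector


@dataclass(frozen=True)
class ScoreBreakdown:
    """WSPM decomposition: column substitution scores plus gap penalties."""

    total: float
    per_column: np.ndarray
    gap_total: float


@dataclass(frozen=True)
class ReferenceScore:
    sps: float
    cs: float
    core_columns: Optional[tuple[int, ...]] = None


def gap_penalty(n: int, gaps: GapModel) -> float:
    """Affine penalty G = g + n*x of one gap run of length n >= 1."""
    return gaps.run_cost(n)


def wspm(
    aln: Alignment,
    w: WeightVector,
    m: SubstitutionMatrix,
    gaps: GapModel,
) -> ScoreBreakdown:
    """Weighted sum-of-pairs score of an alignment."""
    if len(w.w) != aln.N:
        raise AlignmentError("weight vector does not match alignment rows")
    per_col, gap_total = wspm_kernel(
        aln.matrix, np.asarray(w.w, dtype=np.float64), m.lut, gaps.g, gaps.x, GAP_BYTE
    )
    return ScoreBreakdown(float(per_col.sum() + gap_total), per_col, float(gap_total))


def wspm_range(
    aln: Alignment,
    w: WeightVector,
    m: SubstitutionMatrix,
    gaps: GapModel,
    col_from: int,
    col_to: int,
) -> ScoreBreakdown:
    """WSPM of the column slice [col_from, col_to) scored as a standalone
    sub-alignment: all-gap columns inside the slice are dropped and gap runs
    truncate at the slice boundaries."""
    if not (0 <= col_from < col_to <= aln.L):
        raise AlignmentError("empty or out-of-range column slice")
    if len(w.w) != aln.N:
        raise AlignmentError("weight vector does not match alignment rows")
    sub = aln.matrix[:, col_from:col_to]
    keep = (sub != GAP_BYTE).any(axis=0)
    sub = sub[:, keep]
    if sub.shape[1] == 0:
        raise AlignmentError("column slice is entirely gaps")
    per_col, gap_total = wspm_kernel(
        np.ascontiguousarray(sub),
        np.asarray(w.w, dtype=np.float64),
        m.lut,
        gaps.g,
        gaps.x,
        GAP_BYTE,
    )
    return ScoreBreakdown(float(per_col.sum() + gap_total), per_col, float(gap_total))


def _match_rows(test: Alignment, ref: Alignment) -> Alignment:
    """Reorder test rows to the reference's id order and check that both
    alignments house the same ungapped sequences."""
    if set(test.seq_ids) != set(ref.seq_ids):
        raise AlignmentError("test and reference sequence ids differ")
    order = [test.seq_ids.index(sid) for sid in ref.seq_ids]
    test = Alignment(test.matrix[order], ref.seq_ids)
    for i in range(ref.N):
        if test.stripped(i) != ref.stripped(i):
            raise AlignmentError(
                f"sequence {ref.seq_ids[i]!r} differs between test and reference"
            )
    return test


def _ordinals(aln: Alignment) -> np.ndarray:
    """(N, L) array: residue ordinal (0-based) at each cell, -1 at gaps."""
    res = aln.matrix != GAP_BYTE
    ords = np.cumsum(res, axis=1) - 1
    ords[~res] = -1
    return ords


def sps(
    test: Alignment,
    ref: Alignment,
    core_columns: Optional[TSequence[int]] = None,
) -> float:
    """Sum-of-pairs score of ``test`` against ``ref`` in [0, 1].

    Residues are identified by (sequence, residue ordinal); the score is the
    fraction of reference residue pairs co-columned in the test alignment,
    optionally restricted to ``core_columns`` of the reference.
    """
    test = _match_rows(test, ref)
    cols = range(ref.L) if core_columns is None else core_columns
    ref_ords = _ordinals(ref)
    test_ords = _ordinals(test)
    # residue ordinal -> test column, per sequence
    test_pos = [
        {int(o): c for c, o in enumerate(row) if o >= 0} for row in test_ords
    ]
    total = matched = 0
    for c in cols:
        present = [(i, int(ref_ords[i, c])) for i in range(ref.N) if ref_ords[i, c] >= 0]
        for a in range(len(present) - 1):
            i, oi = present[a]
            for b in range(a + 1, len(present)):
                j, oj = present[b]
                total += 1
                if test_pos[i][oi] == test_pos[j][oj]:
                    matched += 1
    if total == 0:
        raise AlignmentError("reference alignment contains no residue pairs")
    return matched / total


def cs(
    test: Alignment,
    ref: Alignment,
    core_columns: Optional[TSequence[int]] = None,
) -> float:
    """Column score: fraction of (core) reference columns whose full residue
    content, gaps included, is reproduced as a column of the test alignment."""
    test = _match_rows(test, ref)
    cols = range(ref.L) if core_columns is None else core_columns
    ref_ords = _ordinals(ref)
    test_ords = _ordinals(test)
    test_columns = {tuple(int(v) for v in test_ords[:, c]) for c in range(test.L)}
    total = reproduced = 0
    for c in cols:
        column = tuple(int(v) for v in ref_ords[:, c])
        total += 1
        if column in test_columns:
            reproduced += 1
    if total == 0:
        raise AlignmentError("no reference columns to score")
    return reproduced / total


def score_reference(
    test: Alignment,
    ref: Alignment,
    core_columns: Optional[TSequence[int]] = None,
) -> ReferenceScore:
    return ReferenceScore(
        sps(test, ref, core_columns),
        cs(test, ref, core_columns),
        tuple(core_columns) if core_columns is not None else None,
    )
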