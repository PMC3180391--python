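"""Progressive multiple alignment along a guide tree.

Leaves become single-row profiles; each internal node aligns its children's
profiles by global affine-gap DP over profile columns ("once a gap, always
a gap").  The column-pair score is the unweighted mean of cross-pair
substitution scores, with any pair involving an existing gap scoring 0; a
new gap run of length n inserted into a profile is charged g + n*x once per
run, unscaled by profile size.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from ._kernels import merge_profiles_kernel
from .core import (
    GAP_BYTE,
    Alignment,
    AlignmentError,
    GapModel,
    Sequence,
    SubstitutionMatrix,
)
from .tree import GuideTree, TreeNode


@dataclass
class Profile:
    """A rectangular group of aligned rows plus their sequence indices.

    ``counts`` caches per-column residue counts over the substitution
    matrix's alphabet (gaps not counted); it is maintained incrementally
    through merges.
    """

    matrix: np.ndarray  # (k, L) uint8
    members: list[int]
    counts: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def k(self) -> int:
        return self.matrix.shape[0]


def _residue_counts(mat: np.ndarray, m: SubstitutionMatrix) -> np.ndarray:
    """Per-column residue counts, (L, n_letters); gaps are not counted."""
    idx = m.alphabet_map[mat]  # (k, L)
    n_letters = len(m.alphabet)
    C = np.zeros((mat.shape[1], n_letters + 1))
    cols = np.arange(mat.shape[1])
    for row in idx:
        C[cols, row] += 1.0
    return np.ascontiguousarray(C[:, :n_letters])


def _ensure_counts(p: Profile, m: SubstitutionMatrix) -> np.ndarray:
    if p.counts is None:
        p.counts = _residue_counts(p.matrix, m)
    return p.counts


def align_profiles(
    pa: Profile, pb: Profile, m: SubstitutionMatrix, gaps: GapModel
) -> tuple[Profile, float]:
    """Align two profiles; returns the merged profile (rows of ``pa`` then
    ``pb``) and the profile-level DP score."""
    if pa.k == 0 or pb.k == 0 or pa.L == 0 or pb.L == 0:
        raise AlignmentError("cannot align an empty profile")
    if set(pa.members) & set(pb.members):
        raise AlignmentError("profiles share member sequences")
    out, counts, score = merge_profiles_kernel(
        np.ascontiguousarray(pa.matrix),
        np.ascontiguousarray(pb.matrix),
        _ensure_counts(pa, m),
        _ensure_counts(pb, m),
        m.dense,
        gaps.g + gaps.x,
        gaps.x,
        GAP_BYTE,
    )
    return (
        Profile(out, list(pa.members) + list(pb.members), counts),
        float(score),
    )


def _leaf_profile(seq: Sequence, idx: int) -> Profile:
    row = np.frombuffer(seq.residues.encode(), dtype=np.uint8).reshape(1, -1)
    return Profile(row.copy(), [idx])


def progressive_align(
    seqs: list[Sequence],
    t: GuideTree,
    m: SubstitutionMatrix,
    gaps: GapModel,
) -> Alignment:
    """Post-order progressive alignment of ``seqs`` along guide tree ``t``.

    Gaps inserted at an earlier merge are never removed.  The output row
    order matches the input sequence order and the result is free of
    all-gap columns.
    """
    if sorted(t.leaf_indices()) != list(range(len(seqs))):
        raise AlignmentError("guide-tree leaves do not match the sequence list")

    def build(node: TreeNode) -> Profile:
        if node.is_leaf:
            return _leaf_profile(seqs[node.leaf], node.leaf)
        left = build(node.children[0])
        right = build(node.children[1])
        merged, _ = align_profiles(left, right, m, gaps)
        return merged

    prof = build(t.root)
    order = np.argsort(np.asarray(prof.members, dtype=np.intp), kind="stable")
    mat = prof.matrix[order]
    keep = (mat != GAP_BYTE).any(axis=0)
    return Alignment(np.ascontiguousarray(mat[:, keep]), [s.id for s in seqs])
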