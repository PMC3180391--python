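"""Core domain types for protein multiple sequence alignment.

The package works on three elementary objects: ungapped :class:`Sequence`
records, rectangular gapped :class:`Alignment` matrices, and the scoring
parameters (:class:`SubstitutionMatrix`, :class:`GapModel`) used everywhere
downstream.  Alignments are stored as ``uint8`` byte matrices so that the
dynamic-programming and scoring kernels can operate on them without copying.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass
from typing import Iterable, Sequence as TSequence

import numpy as np
from Bio.Align import substitution_matrices

GAP = "-"
GAP_BYTE = ord(GAP)

#: The 20 standard amino acids.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Ambiguity codes accepted on input and scored via the matrix file's own rows.
AMBIGUITY_CODES = "BZX"
#: Every residue letter a Sequence may contain.
RESIDUE_ALPHABET = AMINO_ACIDS + AMBIGUITY_CODES

_VALID_RESIDUES = frozenset(RESIDUE_ALPHABET)


class AlignmentError(ValueError):
    """Raised for malformed sequences, alignments or scoring inputs."""


@dataclass(frozen=True)
class Sequence:
    """A named, ungapped protein sequence.

    Residues are uppercase letters drawn from the 20 amino acids plus the
    ambiguity codes B, Z and X; gap characters are rejected because gaps only
    exist inside alignments.
    """

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise AlignmentError("sequence id must be non-empty")
        if not self.residues:
            raise AlignmentError(f"sequence {self.id!r}: empty residue string")
        if GAP in self.residues:
            raise AlignmentError(
                f"sequence {self.id!r}: gap character '-' in unaligned input"
            )
        bad = set(self.residues) - _VALID_RESIDUES
        if bad:
            raise AlignmentError(
                f"sequence {self.id!r}: non-amino-acid characters {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


class Alignment:
    """A rectangular gapped matrix over named sequences.

    Rows are stored as a ``(N, L)`` uint8 matrix of ASCII codes.  Stripping
    the gaps from row *i* recovers the *i*-th input sequence character for
    character — every operator in the package preserves this invariant.
    """

    __slots__ = ("matrix", "seq_ids")

    def __init__(self, rows: TSequence[str] | np.ndarray, seq_ids: TSequence[str]):
        if isinstance(rows, np.ndarray):
            mat = np.ascontiguousarray(rows, dtype=np.uint8)
        else:
            rows = list(rows)
            if len({len(r) for r in rows}) > 1:
                raise AlignmentError("not a rectangular alignment")
            mat = np.frombuffer("".join(rows).encode("ascii"), dtype=np.uint8)
            mat = mat.reshape(len(rows), -1).copy()
        if mat.ndim != 2:
            raise AlignmentError("alignment matrix must be two-dimensional")
        if mat.shape[0] < 2:
            raise AlignmentError("an alignment needs at least two rows")
        if mat.shape[1] < 1:
            raise AlignmentError("empty alignment")
        seq_ids = tuple(seq_ids)
        if len(seq_ids) != mat.shape[0]:
            raise AlignmentError("one id per alignment row required")
        if len(set(seq_ids)) != len(seq_ids):
            raise AlignmentError("duplicate sequence ids in alignment")
        self.matrix = mat
        self.seq_ids = seq_ids

    @property
    def N(self) -> int:
        return self.matrix.shape[0]

    @property
    def L(self) -> int:
        return self.matrix.shape[1]

    @property
    def rows(self) -> list[str]:
        return [bytes(r).decode("ascii") for r in self.matrix]

    def row(self, i: int) -> str:
        return bytes(self.matrix[i]).decode("ascii")

    def stripped(self, i: int) -> str:
        """Row *i* with all gaps removed."""
        r = self.matrix[i]
        return bytes(r[r != GAP_BYTE]).decode("ascii")

    def sequences(self) -> list[Sequence]:
        """The ungapped sequences housed by this alignment, in row order."""
        return [Sequence(sid, self.stripped(i)) for i, sid in enumerate(self.seq_ids)]

    @property
    def text(self) -> str:
        """Canonical text form (rows joined by newlines); used for equality
        and duplicate detection."""
        return "\n".join(self.rows)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Alignment):
            return NotImplemented
        return self.seq_ids == other.seq_ids and np.array_equal(
            self.matrix, other.matrix
        )

    def __hash__(self) -> int:
        return hash((self.seq_ids, self.matrix.tobytes()))

    def __repr__(self) -> str:
        return f"<Alignment N={self.N} L={self.L}>"


def canonicalise(aln: Alignment) -> Alignment:
    """Remove all-gap columns; everything else is untouched.

    All-gap columns contribute zero to the fitness but perturb affine gap-run
    counting, so every operator normalises its output through this function.
    """
    keep = (aln.matrix != GAP_BYTE).any(axis=0)
    if not keep.any():
        raise AlignmentError("empty alignment after removing all-gap columns")
    if keep.all():
        return aln
    return Alignment(aln.matrix[:, keep], aln.seq_ids)


@dataclass(frozen=True)
class GapModel:
    """Affine gap penalty G = g + n*x for a run of n gap positions.

    Defaults are the CLUSTAL W-style protein defaults: opening -10 and
    extension -0.20 per position (so a length-1 run costs -10.2).
    """

    g: float = -10.0
    x: float = -0.20

    def __post_init__(self) -> None:
        if self.g > 0 or self.x > 0:
            raise AlignmentError("gap penalties must be <= 0")

    def run_cost(self, n: int) -> float:
        if n < 1:
            raise AlignmentError("gap run length must be >= 1")
        return self.g + n * self.x


class SubstitutionMatrix:
    """Symmetric residue-pair score lookup (e.g. PAM250).

    Wraps a biopython substitution matrix and exposes a dense 256x256 lookup
    table indexed by ASCII codes for use inside the numeric kernels.  Scores
    for ambiguity codes come from the matrix file's own rows.
    """

    def __init__(self, name: str, bio_matrix) -> None:
        self.name = name
        self._bio = bio_matrix
        lut = np.zeros((256, 256), dtype=np.float64)
        letters = str(bio_matrix.alphabet)
        for a in letters:
            for b in letters:
                lut[ord(a), ord(b)] = float(bio_matrix[a, b])
        self.lut = lut
        self.alphabet = letters
        # byte -> alphabet-index map (gaps/unknowns collect at index
        # len(alphabet)) and the dense score block, for the profile kernels
        amap = np.full(256, len(letters), dtype=np.intp)
        for i, ch in enumerate(letters):
            amap[ord(ch)] = i
        self.alphabet_map = amap
        self.dense = self.submatrix(letters)

    def score(self, a: str, b: str) -> float:
        if a == GAP or b == GAP:
            raise AlignmentError("substitution scores are defined for residues only")
        return float(self.lut[ord(a), ord(b)])

    def submatrix(self, letters: str) -> np.ndarray:
        """Dense score matrix over the given letters, in their order."""
        idx = np.frombuffer(letters.encode("ascii"), dtype=np.uint8)
        return self.lut[np.ix_(idx, idx)]

    def __repr__(self) -> str:
        return f"SubstitutionMatrix({self.name!r})"


def load_matrix(name_or_path: str = "pam250") -> SubstitutionMatrix:
    """Load a substitution matrix from NCBI whitespace-delimited text.

    ``"pam250"`` (any case) resolves to the packaged PAM250 file; anything
    else is treated as a path to a matrix file in the same format.
    """
    if name_or_path.lower() == "pam250":
        ref = importlib.resources.files("vdga.data") / "pam250.txt"
        with importlib.resources.as_file(ref) as path:
            mat = substitution_matrices.read(str(path))
        return SubstitutionMatrix("PAM250", mat)
    mat = substitution_matrices.read(name_or_path)
    return SubstitutionMatrix(name_or_path, mat)


def check_ids_unique(seqs: Iterable[Sequence]) -> None:
    seen: set[str] = set()
    for s in seqs:
        if s.id in seen:
            raise AlignmentError(f"duplicate sequence id {s.id!r}")
        seen.add(s.id)
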