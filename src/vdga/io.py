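"""File I/O: FASTA sequences, and FASTA/CLUSTAL/MSF alignments.

Reading goes through Bio.SeqIO / Bio.AlignIO.  Biopython has no GCG MSF
writer, so a minimal standards-conformant one (with GCG checksums) lives
here.  The internal gap character is always ``-``; the MSF dialect gaps
``.`` and ``~`` are normalised on read.
"""

from __future__ import annotations

import io as _stdio
import os
from typing import Iterable

from Bio import AlignIO, SeqIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .core import GAP, Alignment, AlignmentError, Sequence, check_ids_unique

ALIGNMENT_FORMATS = ("fasta", "clustal", "msf")


def read_fasta(path: str | os.PathLike) -> list[Sequence]:
    """Read unaligned protein sequences from a FASTA file.

    Lowercase residues are uppercased; gap characters and non-amino-acid
    letters are rejected with the offending record named.
    """
    seqs: list[Sequence] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        residues = str(rec.seq).upper()
        if GAP in residues:
            raise AlignmentError(
                f"record {rec.id!r}: gap character '-' in unaligned input"
            )
        seqs.append(Sequence(rec.id, residues))
    if not seqs:
        raise AlignmentError(f"no sequences in {path}")
    check_ids_unique(seqs)
    return seqs


def write_fasta(seqs: Iterable[Sequence], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s.residues), id=s.id, description="") for s in seqs]
    SeqIO.write(records, str(path), "fasta")


def read_alignment(path: str | os.PathLike, format: str = "fasta") -> Alignment:
    """Read a rectangular alignment in FASTA, CLUSTAL or MSF dialect.

    ``.`` and ``~`` gap characters are normalised to ``-``.
    """
    fmt = format.lower()
    if fmt not in ALIGNMENT_FORMATS:
        raise AlignmentError(f"unsupported alignment format {format!r}")
    try:
        msa = AlignIO.read(str(path), fmt)
    except ValueError as exc:
        if "same length" in str(exc):
            raise AlignmentError("not a rectangular alignment") from exc
        raise AlignmentError(f"cannot parse {path} as {fmt}: {exc}") from exc
    rows = [str(rec.seq).upper().replace(".", GAP).replace("~", GAP) for rec in msa]
    ids = [rec.id for rec in msa]
    if len({len(r) for r in rows}) > 1:
        raise AlignmentError("not a rectangular alignment")
    return Alignment(rows, ids)


def write_alignment(
    aln: Alignment, path: str | os.PathLike, format: str = "fasta"
) -> None:
    """Write an alignment in FASTA, CLUSTAL or MSF dialect.

    Output is deterministic: a fixed alignment always yields identical bytes.
    """
    fmt = format.lower()
    if fmt not in ALIGNMENT_FORMATS:
        raise AlignmentError(f"unsupported alignment format {format!r}")
    if fmt == "msf":
        with open(path, "w") as fh:
            fh.write(_to_msf(aln))
        return
    records = [
        SeqRecord(Seq(row), id=sid, description="")
        for sid, row in zip(aln.seq_ids, aln.rows)
    ]
    if fmt == "fasta":
        SeqIO.write(records, str(path), "fasta")
    else:
        AlignIO.write(MultipleSeqAlignment(records), str(path), "clustal")


def _gcg_checksum(seq: str) -> int:
    # Standard GCG rolling checksum: position-weighted character sum mod 10000.
    check = 0
    for i, ch in enumerate(seq):
        check += ((i % 57) + 1) * ord(ch)
    return check % 10000


def _to_msf(aln: Alignment) -> str:
    rows = [row.replace(GAP, ".") for row in aln.rows]
    checks = [_gcg_checksum(r) for r in rows]
    total = sum(checks) % 10000
    name_w = max(len(s) for s in aln.seq_ids)
    buf = _stdio.StringIO()
    buf.write("PileUp\n\n")
    buf.write(
        f"   MSF: {aln.L}  Type: P  Check: {total}  ..\n\n"
    )
    for sid, row, chk in zip(aln.seq_ids, rows, checks):
        buf.write(
            f" Name: {sid:<{name_w}}  Len: {aln.L}  Check: {chk:4d}  Weight: 1.00\n"
        )
    buf.write("\n//\n\n")
    for start in range(0, aln.L, 50):
        for sid, row in zip(aln.seq_ids, rows):
            chunk = row[start : start + 50]
            blocks = " ".join(chunk[i : i + 10] for i in range(0, len(chunk), 10))
            buf.write(f"{sid:<{name_w}}  {blocks}\n")
        buf.write("\n")
    return buf.getvalue()
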