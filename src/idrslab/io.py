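"""Sequence and alignment I/O.

Reads FASTA protein records and clustal alignments, and extracts
intrinsically disordered regions (IDRs) defined as everything upstream
(N-terminal) of the folded YTH domain.  YTH-domain start coordinates are
1-based and supplied through a sidecar TSV annotation table, since FASTA
cannot carry them.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

CANONICAL_AA = "ACDEFGHIKLMNPQRSTVWY"
#: residues accepted on input; 'X' is rejected later by parameterized stages
INPUT_ALPHABET = set(CANONICAL_AA + "X")


class SequenceError(ValueError):
    """Raised for malformed sequence or alignment input."""


@dataclass(frozen=True)
class ProteinRecord:
    """A full-length protein with an optional YTH-domain start coordinate.

    ``yth_start`` is the 1-based index of the first YTH-domain residue;
    the IDR is residues ``1 .. yth_start - 1``.
    """

    id: str
    sequence: str
    yth_start: Optional[int] = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"record {self.id!r}: empty sequence")
        bad = set(self.sequence) - INPUT_ALPHABET
        if bad:
            raise SequenceError(
                f"record {self.id!r}: illegal residue(s) {sorted(bad)}"
            )
        if self.yth_start is not None and not (
            2 <= self.yth_start <= len(self.sequence) + 1
        ):
            raise SequenceError(
                f"record {self.id!r}: yth_start {self.yth_start} outside "
                f"[2, {len(self.sequence) + 1}]"
            )


@dataclass(frozen=True)
class IDRSequence:
    """An extracted disordered region (plain one-letter sequence)."""

    id: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise SequenceError(f"IDR {self.id!r}: empty sequence")
        bad = set(self.sequence) - INPUT_ALPHABET
        if bad:
            raise SequenceError(f"IDR {self.id!r}: illegal residue(s) {sorted(bad)}")

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class AlignmentMatrix:
    """A gapped multiple sequence alignment ('-' is the gap character)."""

    ids: tuple
    rows: tuple

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise SequenceError("ids and rows length mismatch")
        if len(set(self.ids)) != len(self.ids):
            raise SequenceError("duplicate sequence ids in alignment")
        if not self.rows:
            raise SequenceError("empty alignment")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            raise SequenceError(f"ragged alignment rows: lengths {sorted(lengths)}")
        if self.n_columns == 0:
            raise SequenceError("alignment has zero columns")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def read_fasta(path) -> list[ProteinRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Sequences are uppercased and whitespace-stripped.  Duplicate ids and
    illegal residue characters are errors.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise SequenceError(f"{path}: FASTA record with empty id")
        if rec.id in seen:
            raise SequenceError(f"{path}: duplicate FASTA id {rec.id!r}")
        seen.add(rec.id)
        seq = str(rec.seq).upper().replace(" ", "")
        bad = set(seq) - INPUT_ALPHABET
        if bad:
            raise SequenceError(
                f"{path}: record {rec.id!r} contains illegal residue(s) "
                f"{sorted(bad)}"
            )
        records.append(ProteinRecord(id=rec.id, sequence=seq))
    return records


def write_fasta(records, path, width: int = 60) -> None:
    """Write records as wrapped FASTA (inverse of :func:`read_fasta`)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description="") for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def read_annotations(path) -> dict[str, int]:
    """Read the YTH-start sidecar table (TSV with header ``id\\tyth_start``)."""
    path = Path(path)
    table: dict[str, int] = {}
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        if reader.fieldnames is None or not {"id", "yth_start"} <= set(
            reader.fieldnames
        ):
            raise SequenceError(
                f"{path}: annotation table must have columns 'id' and 'yth_start'"
            )
        for i, row in enumerate(reader, start=2):
            rid = row["id"].strip()
            if rid in table:
                raise SequenceError(f"{path}:{i}: duplicate id {rid!r}")
            try:
                table[rid] = int(row["yth_start"])
            except (TypeError, ValueError):
                raise SequenceError(
                    f"{path}:{i}: yth_start {row['yth_start']!r} is not an integer"
                ) from None
    return table


def annotate(records, annotations) -> list[ProteinRecord]:
    """Attach yth_start coordinates to records from an annotation mapping."""
    out = []
    for rec in records:
        ys = annotations.get(rec.id)
        out.append(ProteinRecord(id=rec.id, sequence=rec.sequence, yth_start=ys))
    return out


def extract_idr(record: ProteinRecord) -> IDRSequence:
    """Extract the IDR: the entire sequence upstream of the YTH domain.

    With ``yth_start = k`` the IDR is residues 1..k-1 (1-based, closed);
    ``yth_start = len + 1`` means the whole sequence is disordered and
    ``yth_start = 1`` is an error (no IDR).
    """
    if record.yth_start is None:
        raise SequenceError(f"record {record.id!r}: yth_start not annotated")
    if record.yth_start == 1:
        raise SequenceError(f"record {record.id!r}: empty IDR (yth_start = 1)")
    return IDRSequence(id=record.id, sequence=record.sequence[: record.yth_start - 1])


def read_clustal(path) -> AlignmentMatrix:
    """Read a clustal ``.aln`` file (interleaved blocks are concatenated)."""
    path = Path(path)
    try:
        aln = AlignIO.read(str(path), "clustal")
    except ValueError as exc:
        raise SequenceError(f"{path}: not a valid clustal file ({exc})") from exc
    ids = tuple(rec.id for rec in aln)
    rows = tuple(str(rec.seq).upper() for rec in aln)
    return AlignmentMatrix(ids=ids, rows=rows)


def write_clustal(aln: AlignmentMatrix, path) -> None:
    """Write an alignment in clustal format."""
    from Bio.Align import MultipleSeqAlignment

    msa = MultipleSeqAlignment(
        [SeqRecord(Seq(row), id=sid, description="") for sid, row in zip(aln.ids, aln.rows)]
    )
    AlignIO.write(msa, str(path), "clustal")
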