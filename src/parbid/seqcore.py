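"""Nucleotide sequence data model and FASTA/FASTQ input/output.

All modules share a single canonical alphabet: upper-case IUPAC nucleotide
codes with ``U`` normalized to ``T`` on ingest, and ``-`` permitted only
inside alignments.  Coordinates throughout the package are 0-based,
half-open, on the plus strand of the stored record.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, List, Optional, Sequence, Union

from Bio import SeqIO

__all__ = [
    "SequenceRecord",
    "ReadRecord",
    "ParseError",
    "IUPAC_SETS",
    "IUPAC_COMPLEMENT",
    "read_fasta",
    "write_fasta",
    "read_fastq",
    "reverse_complement",
    "iupac_match",
]

#: Base sets denoted by each IUPAC nucleotide code.
IUPAC_SETS = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

#: Watson-Crick complement extended over the full ambiguity alphabet.
IUPAC_COMPLEMENT = {
    "A": "T", "T": "A", "C": "G", "G": "C",
    "R": "Y", "Y": "R", "S": "S", "W": "W",
    "K": "M", "M": "K", "B": "V", "V": "B",
    "D": "H", "H": "D", "N": "N", "-": "-",
}

_ALPHABET = frozenset(IUPAC_SETS) | {"-"}


class ParseError(ValueError):
    """Raised on malformed FASTA/FASTQ input; message names the line."""


def _normalize(residues: str, *, allow_gaps: bool, context: str) -> str:
    seq = residues.upper().replace("U", "T")
    allowed = _ALPHABET if allow_gaps else frozenset(IUPAC_SETS)
    bad = set(seq) - allowed
    if bad:
        raise ParseError(
            f"{context}: non-IUPAC character(s) {sorted(bad)!r} in sequence"
        )
    return seq


@dataclass
class SequenceRecord:
    """A named IUPAC nucleotide sequence.

    Residues are upper-cased and ``U``-to-``T`` normalized on construction.
    ``-`` is accepted only when ``allow_gaps`` is set (alignment rows).
    """

    id: str
    residues: str
    description: str = ""
    allow_gaps: bool = field(default=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("SequenceRecord id must be non-empty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: residues must be non-empty")
        self.residues = _normalize(
            self.residues, allow_gaps=self.allow_gaps, context=f"record {self.id!r}"
        )

    def __len__(self) -> int:
        return len(self.residues)

    def ungapped(self) -> "SequenceRecord":
        return SequenceRecord(self.id, self.residues.replace("-", ""), self.description)


@dataclass
class ReadRecord:
    """A sequencing read, optionally with per-base Phred quality scores."""

    id: str
    residues: str
    qualities: Optional[List[int]] = None

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("ReadRecord id must be non-empty")
        self.residues = _normalize(
            self.residues, allow_gaps=False, context=f"read {self.id!r}"
        )
        if self.qualities is not None and len(self.qualities) != len(self.residues):
            raise ValueError(
                f"read {self.id!r}: quality length {len(self.qualities)} != "
                f"sequence length {len(self.residues)}"
            )

    def __len__(self) -> int:
        return len(self.residues)


def read_fasta(
    path: Union[str, Path, io.TextIOBase], *, allow_gaps: bool = False
) -> List[SequenceRecord]:
    """Read a (possibly wrapped) multi-record FASTA file.

    Order-preserving; duplicate ids are rejected.  Malformed headers and
    empty sequences raise :class:`ParseError` naming the offending line.
    """
    if isinstance(path, io.TextIOBase):
        lines = path.read().splitlines()
        name = "<stream>"
    else:
        name = str(path)
        lines = Path(path).read_text().splitlines()

    records: List[SequenceRecord] = []
    seen: set[str] = set()
    header: Optional[str] = None
    header_line = 0
    chunks: List[str] = []

    def flush() -> None:
        if header is None:
            return
        seq = "".join(chunks)
        if not seq:
            raise ParseError(f"{name}:{header_line}: record {header!r} has an empty sequence")
        rid, _, desc = header.partition(" ")
        if rid in seen:
            raise ParseError(f"{name}:{header_line}: duplicate record id {rid!r}")
        seen.add(rid)
        records.append(SequenceRecord(rid, seq, desc.strip(), allow_gaps=allow_gaps))

    for lineno, raw in enumerate(lines, start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            if not header:
                raise ParseError(f"{name}:{lineno}: empty FASTA header")
            header_line = lineno
            chunks = []
        else:
            if header is None:
                raise ParseError(f"{name}:{lineno}: sequence data before any '>' header")
            chunks.append(line)
    flush()
    if not records:
        raise ParseError(f"{name}:1: no FASTA records found")
    return records


def write_fasta(
    records: Iterable[Union[SequenceRecord, ReadRecord]],
    path: Union[str, Path, io.TextIOBase],
    *,
    width: int = 60,
) -> None:
    """Write records as 60-column wrapped FASTA."""

    def render(out: io.TextIOBase) -> None:
        for rec in records:
            desc = getattr(rec, "description", "")
            header = f">{rec.id} {desc}".rstrip()
            out.write(header + "\n")
            seq = rec.residues
            for i in range(0, len(seq), width):
                out.write(seq[i : i + width] + "\n")

    if isinstance(path, io.TextIOBase):
        render(path)
    else:
        with open(path, "w") as fh:
            render(fh)


def read_fastq(path: Union[str, Path]) -> List[ReadRecord]:
    """Read 4-line FASTQ records (via Biopython) into :class:`ReadRecord`."""
    reads: List[ReadRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fastq"):
        if rec.id in seen:
            raise ParseError(f"{path}: duplicate read id {rec.id!r}")
        seen.add(rec.id)
        reads.append(
            ReadRecord(
                rec.id,
                str(rec.seq),
                list(rec.letter_annotations.get("phred_quality", [])) or None,
            )
        )
    if not reads:
        raise ParseError(f"{path}: no FASTQ records found")
    return reads


def reverse_complement(residues: str) -> str:
    """Reverse complement over the full IUPAC alphabet (R<->Y, S<->S, ...)."""
    try:
        return "".join(IUPAC_COMPLEMENT[b] for b in reversed(residues.upper()))
    except KeyError as exc:
        raise ValueError(f"non-IUPAC character {exc.args[0]!r} in sequence") from None


def iupac_match(primer_base: str, template_base: str) -> bool:
    """True iff the two codes' base sets intersect (template ``N`` matches all)."""
    try:
        return bool(IUPAC_SETS[primer_base] & IUPAC_SETS[template_base])
    except KeyError:
        raise ValueError(
            f"non-IUPAC base in pair ({primer_base!r}, {template_base!r})"
        ) from None
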