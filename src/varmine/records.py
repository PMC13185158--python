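"""Sequence records, repositories and FASTA I/O.

The mining pipeline operates on a *repository*: one reference coding
sequence (CDS) plus an ordered collection of variant CDSs (or their
protein translations), each carrying provenance metadata.  Everything
downstream (mutation calling, filtering, motif mining) is anchored to the
repository's reference.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO
from Bio.Seq import Seq

NUCLEOTIDE_ALPHABET = frozenset("ACGTN")
# 20 canonical residues, stop (*) and X for codons that contain N.
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWY*X")

NUCLEOTIDE = "nucleotide"
PROTEIN = "protein"


class SequenceError(ValueError):
    """Raised for malformed sequences or repositories."""


@dataclass(frozen=True)
class SequenceRecord:
    """An identified nucleotide or protein sequence with provenance.

    Parameters
    ----------
    id : str
        Unique identifier (FASTA header token before the first whitespace).
    seq : str
        Uppercase IUPAC sequence; nucleotides over ``{A,C,G,T,N}``,
        proteins over the 20 canonical letters plus ``*`` (stop).
    kind : str
        ``"nucleotide"`` or ``"protein"``.
    source : str
        Free-text provenance, e.g. ``"synthetic"`` or ``"database"``.
    cycle : int
        Mining-cycle index at which the record entered the repository.
    """

    id: str
    seq: str
    kind: str
    source: str = "unknown"
    cycle: int = 0

    def __post_init__(self) -> None:
        if not self.id:
            raise SequenceError("record id must be non-empty")
        object.__setattr__(self, "seq", self.seq.upper())
        if not self.seq:
            raise SequenceError(f"{self.id}: sequence must be non-empty")
        if self.kind not in (NUCLEOTIDE, PROTEIN):
            raise SequenceError(f"{self.id}: unknown kind {self.kind!r}")
        if self.cycle < 0:
            raise SequenceError(f"{self.id}: cycle must be non-negative")
        alphabet = NUCLEOTIDE_ALPHABET if self.kind == NUCLEOTIDE else PROTEIN_ALPHABET
        for pos, ch in enumerate(self.seq, start=1):
            if ch not in alphabet:
                raise SequenceError(
                    f"{self.id}: illegal {self.kind} character {ch!r} at position {pos}"
                )

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class Repository:
    """A reference sequence plus an ordered collection of same-kind members."""

    reference: SequenceRecord
    members: list[SequenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = {self.reference.id}
        for rec in self.members:
            if rec.kind != self.reference.kind:
                raise SequenceError(
                    f"{rec.id}: kind {rec.kind!r} differs from reference kind "
                    f"{self.reference.kind!r}"
                )
            if rec.id in seen:
                raise SequenceError(f"duplicate id {rec.id!r} in repository")
            seen.add(rec.id)

    def __iter__(self) -> Iterator[SequenceRecord]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def get(self, rec_id: str) -> SequenceRecord:
        if rec_id == self.reference.id:
            return self.reference
        for rec in self.members:
            if rec.id == rec_id:
                return rec
        raise KeyError(rec_id)

    def subset(self, ids: Iterable[str]) -> "Repository":
        wanted = set(ids)
        return Repository(self.reference, [m for m in self.members if m.id in wanted])


def _open_maybe_gzip(path: Path, mode: str = "rt"):
    if str(path).endswith(".gz"):
        return gzip.open(path, mode)
    return open(path, mode)


def read_fasta(path: str | Path, kind: str, source: str = "file", cycle: int = 0) -> list[SequenceRecord]:
    """Read a (possibly gzip-compressed) FASTA file into SequenceRecords.

    Order is preserved; sequences are uppercased; the header token before
    the first whitespace becomes the record id.  Empty files, duplicate ids
    and characters outside the alphabet raise :class:`SequenceError`.
    """
    path = Path(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    with _open_maybe_gzip(path) as handle:
        for entry in SeqIO.parse(handle, "fasta"):
            if entry.id in seen:
                raise SequenceError(f"duplicate FASTA id {entry.id!r} in {path}")
            seen.add(entry.id)
            records.append(
                SequenceRecord(id=entry.id, seq=str(entry.seq), kind=kind,
                               source=source, cycle=cycle)
            )
    if not records:
        raise SequenceError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path, line_width: int = 60) -> Path:
    """Write records as FASTA wrapped at ``line_width`` (default 60)."""
    if line_width <= 0:
        raise ValueError(f"line_width must be positive, got {line_width}")
    records = list(records)
    if not records:
        raise SequenceError("cannot write an empty record list")
    path = Path(path)
    with _open_maybe_gzip(path, "wt") as handle:
        for rec in records:
            handle.write(f">{rec.id}\n")
            for i in range(0, len(rec.seq), line_width):
                handle.write(rec.seq[i:i + line_width] + "\n")
    return path


def read_repository(path: str | Path, kind: str = NUCLEOTIDE, **kwargs) -> Repository:
    """Read a FASTA file whose first record is the reference."""
    records = read_fasta(path, kind, **kwargs)
    return Repository(records[0], records[1:])


def translate(cds: SequenceRecord) -> SequenceRecord:
    """Translate a CDS with the standard genetic code.

    The first codon is translated literally (no alternative-start
    handling); internal and terminal stops are rendered as ``*``; codons
    containing ``N`` translate to the IUPAC residue when unambiguous,
    otherwise ``X``.
    """
    if cds.kind != NUCLEOTIDE:
        raise SequenceError(f"{cds.id}: can only translate nucleotide records")
    remainder = len(cds.seq) % 3
    if remainder:
        raise SequenceError(
            f"{cds.id}: length {len(cds.seq)} not divisible by 3 (remainder {remainder})"
        )
    protein = str(Seq(cds.seq).translate(table=1))
    return SequenceRecord(id=cds.id, seq=protein, kind=PROTEIN,
                          source=cds.source, cycle=cds.cycle)


def translate_codon(codon: str) -> str:
    """Translate one codon (standard code); codons with N may yield X."""
    if len(codon) != 3:
        raise SequenceError(f"codon must have length 3, got {codon!r}")
    return str(Seq(codon).translate(table=1))


def with_cycle(rec: SequenceRecord, cycle: int) -> SequenceRecord:
    return replace(rec, cycle=cycle)
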