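"""FASTA and annotation-table input/output.

Genomes and TE libraries are plain (optionally line-wrapped) FASTA over the
IUPAC nucleotide alphabet.  TE annotations travel as headerless tab-separated
tables with four columns: sequence name, first position, last position and
family label.  Coordinates in files are 1-based inclusive; all internal
computation uses 0-based half-open intervals and converts only here, at the
I/O boundary.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO

__all__ = [
    "FormatError",
    "SequenceRecord",
    "GenomeAssembly",
    "TELibraryEntry",
    "TEAnnotation",
    "read_fasta",
    "write_fasta",
    "parse_family",
    "read_library",
    "read_annotations",
    "write_annotations",
]

# Accepted residue codes.  U is normalised to T on read; case is preserved
# because lowercase marks pre-existing soft masking (still searchable).
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV" + "ACGTUNRYSWKMBDHV".lower())

_U_TO_T = str.maketrans("Uu", "Tt")


class FormatError(ValueError):
    """Malformed input file (FASTA or annotation table)."""


@dataclass
class SequenceRecord:
    """A named nucleotide sequence.

    ``name`` is the first whitespace-delimited token of the FASTA header and
    ``description`` the remainder (possibly empty).
    """

    name: str
    seq: str
    description: str = ""

    def __len__(self) -> int:
        return len(self.seq)


@dataclass
class GenomeAssembly:
    """An ordered collection of uniquely named sequences."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        names = [r.name for r in self.records]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate sequence name(s): {', '.join(dup)}")
        self._by_name = {r.name: r for r in self.records}

    @property
    def total_length(self) -> int:
        return sum(len(r) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    def get(self, name: str) -> SequenceRecord:
        return self._by_name[name]


@dataclass
class TELibraryEntry:
    """One curated library sequence with its hierarchical family label."""

    id: str
    family: str
    seq: str

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class TEAnnotation:
    """A TE interval on a genome sequence, 1-based inclusive.

    ``source_id`` records the library entry (or prior-round annotation) whose
    hits produced the interval; ``support`` counts the clustered k-mer hits.
    """

    seq_name: str
    first: int
    last: int
    family: str = "Unknown"
    source_id: str = ""
    support: int = 1

    def __post_init__(self) -> None:
        if not (1 <= self.first <= self.last):
            raise ValueError(
                f"invalid interval {self.seq_name}:{self.first}-{self.last}"
            )

    @property
    def length(self) -> int:
        return self.last - self.first + 1


def _validate_seq(name: str, seq: str) -> None:
    for ch in seq:
        if ch not in IUPAC_CODES:
            raise FormatError(
                f"record '{name}' contains non-IUPAC character {ch!r}"
            )


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of validated :class:`SequenceRecord`.

    Raises :class:`FormatError` on an empty file, duplicate record names, or
    characters outside the IUPAC nucleotide alphabet.  U/u is normalised to
    T/t; case is otherwise preserved.
    """
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        name = rec.id
        if not name:
            raise FormatError(f"{path}: record with empty name")
        if name in seen:
            raise FormatError(f"{path}: duplicate record name '{name}'")
        seen.add(name)
        seq = str(rec.seq)
        if not seq:
            raise FormatError(f"{path}: record '{name}' has empty sequence")
        _validate_seq(name, seq)
        desc = rec.description[len(rec.id):].strip() if rec.description else ""
        records.append(SequenceRecord(name, seq.translate(_U_TO_T), desc))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    return records


def write_fasta(records, path: str | os.PathLike, width: int = 80) -> None:
    """Write records (SequenceRecord or TELibraryEntry) wrapped at ``width``."""
    with open(path, "w") as fh:
        for rec in records:
            name = getattr(rec, "name", None) or rec.id
            desc = getattr(rec, "description", "")
            header = f">{name} {desc}".rstrip()
            fh.write(header + "\n")
            seq = rec.seq
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def parse_family(header: str) -> str:
    """Extract the hierarchical family label from a library FASTA header.

    Follows the RepeatMasker-library dialect used by Repbase, Inpactor2 and
    similar sources: if the name token contains ``#``, the family is whatever
    follows the first ``#`` (e.g. ``TE_0001#LTR/Gypsy`` -> ``LTR/Gypsy``);
    otherwise the full name token is taken as a flat family label.
    """
    token = header.split()[0]
    if "#" in token:
        fam = token.split("#", 1)[1]
        if fam:
            return fam
    return token


def read_library(path: str | os.PathLike) -> list[TELibraryEntry]:
    """Read a curated TE library FASTA, parsing family labels from headers."""
    entries = [
        TELibraryEntry(id=r.name, family=parse_family(r.name), seq=r.seq)
        for r in read_fasta(path)
    ]
    return entries


def read_annotations(path: str | os.PathLike) -> list[TEAnnotation]:
    """Read a tab-separated annotation table (>= 3 columns, no header).

    Column 4 (family) is optional and defaults to ``Unknown``.  Raises
    :class:`FormatError` with the offending line number on short lines,
    non-integer coordinates or inverted intervals.
    """
    annotations: list[TEAnnotation] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: expected >= 3 tab-separated columns"
                )
            try:
                first, last = int(fields[1]), int(fields[2])
            except ValueError:
                raise FormatError(
                    f"{path}:{lineno}: non-integer coordinates "
                    f"{fields[1]!r}/{fields[2]!r}"
                ) from None
            if first < 1 or first > last:
                raise FormatError(
                    f"{path}:{lineno}: invalid interval {first}-{last}"
                )
            family = fields[3] if len(fields) > 3 and fields[3] else "Unknown"
            annotations.append(TEAnnotation(fields[0], first, last, family))
    return annotations


def write_annotations(annotations, path: str | os.PathLike) -> None:
    """Write the 4-column annotation table (headerless TSV, 1-based)."""
    with open(path, "w") as fh:
        for a in annotations:
            fh.write(f"{a.seq_name}\t{a.first}\t{a.last}\t{a.family}\n")
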