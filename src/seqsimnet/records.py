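"""Labeled sequence records and their on-disk formats.

A dataset is a collection of :class:`SequenceRecord` objects: the residue
string itself plus the provenance labels the network pipeline keys on — the
origin of the sequence (a cellular domain, a mobile genetic element, an
environmental sample, or a generic "published" reference) and the sample it
came from.  Sequences travel as FASTA; the labels travel in a sidecar
tab-separated metadata table (columns: id, origin, sample_id).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, TextIO

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: Recognised origin labels.  ``Published`` is a catch-all for reference
#: sequences whose domain is unknown or irrelevant.
ORIGINS = ("Archaea", "Bacteria", "Eukaryote", "MGE", "Environment", "Published")

#: Origins treated as "published" (non-environmental) when scoring the
#: closest published relative of an environmental sequence.
PUBLISHED_ORIGINS = frozenset(o for o in ORIGINS if o != "Environment")

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
DNA_ALPHABET = "ACGT"


@dataclass(frozen=True)
class SequenceRecord:
    """One labeled sequence.

    Parameters
    ----------
    id : str
        Unique identifier within a dataset.
    residues : str
        Protein or nucleotide residues, non-empty, no gaps.
    alphabet : {"protein", "dna"}
    origin : str
        One of :data:`ORIGINS`.
    sample_id : str
        Sample of origin for environmental sequences; may be empty.
    """

    id: str
    residues: str
    alphabet: str = "protein"
    origin: str = "Published"
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("sequence id must be non-empty")
        if not self.residues:
            raise ValueError(f"sequence {self.id!r}: residues must be non-empty")
        if self.alphabet not in ("protein", "dna"):
            raise ValueError(f"sequence {self.id!r}: unknown alphabet {self.alphabet!r}")
        if self.origin not in ORIGINS:
            raise ValueError(
                f"sequence {self.id!r}: unknown origin {self.origin!r}; "
                f"expected one of {ORIGINS}"
            )

    @property
    def length(self) -> int:
        return len(self.residues)

    @property
    def is_environmental(self) -> bool:
        return self.origin == "Environment"


@dataclass
class SequenceSet:
    """An id-keyed collection of records with uniqueness enforcement."""

    records: dict[str, SequenceRecord] = field(default_factory=dict)

    def add(self, rec: SequenceRecord) -> None:
        if rec.id in self.records:
            raise ValueError(f"duplicate sequence id {rec.id!r}")
        self.records[rec.id] = rec

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records.values())

    def __contains__(self, seq_id: str) -> bool:
        return seq_id in self.records

    def __getitem__(self, seq_id: str) -> SequenceRecord:
        return self.records[seq_id]

    def ids(self) -> list[str]:
        return list(self.records)

    def lengths(self) -> dict[str, int]:
        return {r.id: r.length for r in self}

    def origins(self) -> dict[str, str]:
        return {r.id: r.origin for r in self}

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        out = SequenceSet()
        for i in ids:
            out.add(self.records[i])
        return out

    def redundant_groups(self) -> list[list[str]]:
        """Groups of ids sharing an identical residue string.

        Identical (redundant) sequences carry no extra signal in a similarity
        network and are filtered before analysis; this reports them so the
        caller can keep one representative per group.
        """
        by_residues: dict[str, list[str]] = {}
        for rec in self:
            by_residues.setdefault(rec.residues, []).append(rec.id)
        return [sorted(ids) for ids in by_residues.values() if len(ids) > 1]

    def deduplicate(self) -> "SequenceSet":
        """Keep the lexicographically smallest id per identical residue string."""
        drop: set[str] = set()
        for group in self.redundant_groups():
            drop.update(group[1:])
        return self.subset(i for i in self.records if i not in drop)


def read_fasta(
    source: str | Path | TextIO,
    *,
    alphabet: str = "protein",
    metadata: Mapping[str, tuple[str, str]] | None = None,
    min_length: int = 1,
) -> SequenceSet:
    """Read a FASTA file into a :class:`SequenceSet`.

    ``metadata`` maps id -> (origin, sample_id); ids absent from it default to
    origin ``Published`` with an empty sample.  Records shorter than
    ``min_length`` are dropped (reference protein datasets conventionally keep
    only sequences longer than 50 amino acids; pass ``min_length=51``).
    """
    out = SequenceSet()
    for rec in SeqIO.parse(source if not isinstance(source, Path) else str(source), "fasta"):
        residues = str(rec.seq).upper()
        if len(residues) < min_length:
            continue
        origin, sample = ("Published", "")
        if metadata and rec.id in metadata:
            origin, sample = metadata[rec.id]
        out.add(SequenceRecord(rec.id, residues, alphabet=alphabet, origin=origin, sample_id=sample))
    return out


def write_fasta(seqs: Iterable[SequenceRecord], dest: str | Path | TextIO) -> None:
    """Write records as FASTA wrapped at 60 columns."""
    records = [SeqRecord(Seq(r.residues), id=r.id, description="") for r in seqs]
    if isinstance(dest, (str, Path)):
        with open(dest, "w") as fh:
            SeqIO.write(records, fh, "fasta")
    else:
        SeqIO.write(records, dest, "fasta")


def read_metadata(source: str | Path | TextIO) -> dict[str, tuple[str, str]]:
    """Read the id/origin/sample_id TSV sidecar (header optional)."""
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    out: dict[str, tuple[str, str]] = {}
    for lineno, line in enumerate(io.StringIO(text), start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if parts[0] == "id":  # header row
            continue
        if len(parts) < 2:
            raise ValueError(f"metadata line {lineno}: expected at least 2 tab-separated fields")
        sample = parts[2] if len(parts) > 2 else ""
        out[parts[0]] = (parts[1], sample)
    return out


def write_metadata(seqs: Iterable[SequenceRecord], dest: str | Path | TextIO) -> None:
    lines = ["id\torigin\tsample_id"]
    lines += [f"{r.id}\t{r.origin}\t{r.sample_id}" for r in seqs]
    text = "\n".join(lines) + "\n"
    if isinstance(dest, (str, Path)):
        Path(dest).write_text(text)
    else:
        dest.write(text)
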