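"""Sequence I/O and alphabet utilities shared by every module.

Conventions used throughout the toolkit:

* all coordinates are 1-based and inclusive, on the stored (sense) strand;
* residues are stored uppercase over the IUPAC DNA alphabet, with ``U``
  mapped to ``T`` at parse time;
* an ``N`` in a *subject* sequence never satisfies a concrete pattern base
  (conservative: low-quality stretches do not produce spurious cut or
  primer sites), while ``N`` in a *pattern* matches anything.
"""

from __future__ import annotations

import urllib.request
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

__all__ = [
    "IUPAC_DNA",
    "IUPAC_SETS",
    "NucleotideSequence",
    "SequenceSet",
    "SequenceParseError",
    "read_fasta",
    "write_fasta",
    "reverse_complement",
    "iupac_match",
    "fetch_accession",
]

#: Concrete-base expansion of every IUPAC DNA code.
IUPAC_SETS: dict[str, frozenset[str]] = {
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

IUPAC_DNA = frozenset(IUPAC_SETS)

_COMPLEMENT = str.maketrans("ACGTRYSWKMBDHVN", "TGCAYRSWMKVHDBN")


class SequenceParseError(ValueError):
    """Raised when a record contains characters outside the IUPAC DNA alphabet."""


def _normalize(residues: str, record: str = "<sequence>") -> str:
    """Uppercase, map U->T and validate; error message names record and position."""
    s = residues.upper().replace("U", "T")
    for i, ch in enumerate(s, start=1):
        if ch not in IUPAC_DNA:
            raise SequenceParseError(
                f"record {record!r}: invalid character {ch!r} at position {i}"
            )
    return s


@dataclass(frozen=True)
class NucleotideSequence:
    """An identified DNA string with provenance."""

    id: str
    residues: str
    description: str = ""
    accession: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", _normalize(self.residues, self.id))

    def __len__(self) -> int:
        return len(self.residues)

    def subseq(self, start: int, end: int) -> str:
        """Residues of the 1-based inclusive span ``start``..``end``."""
        if not (1 <= start <= end <= len(self.residues)):
            raise ValueError(f"span {start}-{end} outside 1-{len(self.residues)}")
        return self.residues[start - 1 : end]

    def reverse_complemented(self) -> "NucleotideSequence":
        return NucleotideSequence(
            id=self.id,
            residues=reverse_complement(self.residues),
            description=self.description,
            accession=self.accession,
        )


@dataclass
class SequenceSet:
    """An ordered, id-unique collection of sequences."""

    name: str = ""
    members: list[NucleotideSequence] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.id for m in self.members]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate sequence id {dup!r}")

    def __iter__(self) -> Iterator[NucleotideSequence]:
        return iter(self.members)

    def __len__(self) -> int:
        return len(self.members)

    def __getitem__(self, key: int | str) -> NucleotideSequence:
        if isinstance(key, str):
            for m in self.members:
                if m.id == key:
                    return m
            raise KeyError(key)
        return self.members[key]

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]


def read_fasta(path: str | Path) -> SequenceSet:
    """Read a multi-record FASTA file into a :class:`SequenceSet`.

    The header token before the first whitespace becomes the id; the rest of
    the header line is kept as the description.  Residues are normalized
    (uppercase, U->T) and validated against the IUPAC DNA alphabet.
    """
    path = Path(path)
    members = []
    for rec in SeqIO.parse(str(path), "fasta"):
        desc = rec.description[len(rec.id) :].strip() if rec.description else ""
        members.append(
            NucleotideSequence(id=rec.id, residues=str(rec.seq), description=desc)
        )
    if not members:
        raise SequenceParseError(f"{path}: no FASTA records found")
    return SequenceSet(name=path.stem, members=members)


def write_fasta(seqs: SequenceSet | Iterable[NucleotideSequence],
                path: str | Path, width: int = 70) -> None:
    """Write sequences as wrapped FASTA; errors on an empty set."""
    if width < 1:
        raise ValueError("width must be positive")
    members = list(seqs)
    if not members:
        raise ValueError("refusing to write an empty sequence set")
    with open(path, "w") as fh:
        for m in members:
            header = f">{m.id}" + (f" {m.description}" if m.description else "")
            fh.write(header + "\n")
            for i in range(0, len(m.residues), width):
                fh.write(m.residues[i : i + width] + "\n")


def reverse_complement(residues: str) -> str:
    """IUPAC-aware reverse complement (R<->Y, K<->M, B<->V, D<->H, S/W/N self)."""
    s = residues.upper().replace("U", "T")
    bad = set(s) - IUPAC_DNA
    if bad:
        raise SequenceParseError(f"invalid character(s) {sorted(bad)} in sequence")
    return s.translate(_COMPLEMENT)[::-1]


def iupac_match(seq_base: str, pattern_base: str) -> bool:
    """True iff the subject base is compatible with the pattern base.

    Compatibility is intersection of the concrete-base sets, except that a
    subject ``N`` (an unread base, not a genuine 4-fold degeneracy) matches
    only a pattern ``N``.
    """
    s, p = seq_base.upper(), pattern_base.upper()
    if s not in IUPAC_SETS or p not in IUPAC_SETS:
        raise ValueError(f"non-IUPAC base in comparison: {seq_base!r} vs {pattern_base!r}")
    if s == "N":
        return p == "N"
    return bool(IUPAC_SETS[s] & IUPAC_SETS[p])


_EFETCH = (
    "https://eutils.ncbi.nlm.nih.gov/entrez/eutils/efetch.fcgi"
    "?db=nucleotide&rettype=fasta&retmode=text&id={acc}"
)


def fetch_accession(accession: str, out_path: str | Path, timeout: float = 30.0) -> Path:
    """Fetch one nucleotide record from NCBI and write it as FASTA.

    This is a thin network helper for convenience only; every core operation
    takes local files.  Requires internet access.
    """
    out_path = Path(out_path)
    with urllib.request.urlopen(_EFETCH.format(acc=accession), timeout=timeout) as resp:
        data = resp.read().decode()
    if not data.startswith(">"):
        raise IOError(f"no FASTA record returned for accession {accession!r}")
    out_path.write_text(data)
    return out_path
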