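"""Mismatch-tolerant primer-site search and in silico PCR.

A primer hit is a Hamming-distance match of the oligo against one strand
(no indels), with an exact-match requirement over the 3'-terminal bases —
the anchor a polymerase needs to extend.  Minus-strand hits are reported in
sense-strand coordinates as the segment the oligo anneals to (the
"sense-site" convention: the synthesized reverse oligo is the reverse
complement of that segment).

The packaged primer constants are the AEFB diagnostic-marker pair used
throughout the toolkit.  The forward primer is published in two forms that
differ at the third base (CTA... in the running text, CTG... consistently
in the specificity table); both constants ship and the CTG form is the
default, the table being internally consistent about it.
"""

from __future__ import annotations

from dataclasses import dataclass

from .seqio import NucleotideSequence, iupac_match, reverse_complement

__all__ = [
    "Primer",
    "PrimerHit",
    "Amplicon",
    "PRIMER_463F",
    "PRIMER_463F_TEXT_VARIANT",
    "PRIMER_463R",
    "PRIMER_463R_SENSE_SITE",
    "find_primer_hits",
    "annotate_variant",
    "insilico_pcr",
]


@dataclass(frozen=True)
class Primer:
    """A PCR primer as synthesized, 5'->3'."""

    name: str
    oligo: str
    role: str  # "forward" | "reverse"

    def __post_init__(self) -> None:
        if self.role not in ("forward", "reverse"):
            raise ValueError(f"role must be forward or reverse, got {self.role!r}")
        oligo = self.oligo.upper().replace("U", "T")
        if not 15 <= len(oligo) <= 35:
            raise ValueError(f"primer {self.name!r}: length must be 15-35")
        object.__setattr__(self, "oligo", oligo)

    def __len__(self) -> int:
        return len(self.oligo)


#: Sense-strand segment the reverse primer anneals to.
PRIMER_463R_SENSE_SITE = "AATACGTTCCCGGGCCTT"

#: Default forward primer (the specificity table's unbolded form).
PRIMER_463F = Primer("463F", "CTGAAACTCAAAGGAATTGACG", "forward")
#: Alternative forward primer as printed in the running text (CTA... form).
PRIMER_463F_TEXT_VARIANT = Primer("463F-A", "CTAAAACTCAAAGGAATTGACG", "forward")
#: Reverse primer oligo = reverse complement of its sense-strand site.
PRIMER_463R = Primer("463R", reverse_complement(PRIMER_463R_SENSE_SITE), "reverse")


@dataclass(frozen=True)
class PrimerHit:
    """A primer annealing site in sense-strand coordinates (1-based inclusive)."""

    primer_name: str
    strand: str  # "plus" | "minus"
    site_start: int
    site_end: int
    mismatches: int
    mismatch_positions: tuple[int, ...]  # 1-based offsets within the site
    site_sequence: str


@dataclass(frozen=True)
class Amplicon:
    """A predicted PCR product; outer span includes both primer sites."""

    fwd_hit: PrimerHit
    rev_hit: PrimerHit
    start: int
    end: int
    residues: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def _scan(residues: str, pattern: str, max_mismatches: int,
          anchor_offsets: frozenset[int]) -> list[tuple[int, tuple[int, ...]]]:
    """Hamming scan of ``pattern`` over ``residues`` (IUPAC-aware).

    ``anchor_offsets`` are 0-based pattern offsets that must match exactly.
    Returns (0-based window start, 1-based mismatch offsets) pairs.
    """
    k = len(pattern)
    out = []
    for i in range(len(residues) - k + 1):
        mm: list[int] = []
        ok = True
        for j in range(k):
            if not iupac_match(residues[i + j], pattern[j]):
                if j in anchor_offsets or len(mm) >= max_mismatches:
                    ok = False
                    break
                mm.append(j + 1)
        if ok:
            out.append((i, tuple(mm)))
    return out


def find_primer_hits(seq: NucleotideSequence, primer: Primer,
                     max_mismatches: int = 2,
                     anchor_3prime: int = 3) -> list[PrimerHit]:
    """All annealing sites of ``primer`` on either strand of ``seq``.

    A hit allows at most ``max_mismatches`` substitutions and none within
    the 3'-terminal ``anchor_3prime`` bases of the oligo.  Indels are not
    modeled.  Hits are sorted by site_start, plus strand first.
    """
    k = len(primer.oligo)
    if anchor_3prime < 0 or anchor_3prime > k:
        raise ValueError("anchor_3prime out of range")
    hits: list[PrimerHit] = []

    # plus strand: oligo read as-is; its 3' end is the rightmost site base
    plus_anchor = frozenset(range(k - anchor_3prime, k))
    for i, mm in _scan(seq.residues, primer.oligo, max_mismatches, plus_anchor):
        hits.append(PrimerHit(primer.name, "plus", i + 1, i + k, len(mm), mm,
                              seq.residues[i : i + k]))

    # minus strand: the oligo anneals where the sense strand reads its
    # reverse complement; the oligo 3' end maps to the site's first base
    sense_site = reverse_complement(primer.oligo)
    minus_anchor = frozenset(range(anchor_3prime))
    for i, mm in _scan(seq.residues, sense_site, max_mismatches, minus_anchor):
        hits.append(PrimerHit(primer.name, "minus", i + 1, i + k, len(mm), mm,
                              seq.residues[i : i + k]))

    hits.sort(key=lambda h: (h.site_start, 0 if h.strand == "plus" else 1))
    return hits


def annotate_variant(site_sequence: str | PrimerHit, canonical_site: str,
                     open_mark: str = "[", close_mark: str = "]") -> str:
    """Mark the positions where an observed site differs from the canonical one.

    Reproduces, in plain text, the convention of bolding mismatched bases in
    a primer-variant table: ``AATACGTTCCCGGGTCTT`` vs the canonical reverse
    site becomes ``AATACGTTCCCGGG[T]CTT``.
    """
    observed = site_sequence.site_sequence if isinstance(site_sequence, PrimerHit) \
        else site_sequence.upper()
    canonical = canonical_site.upper()
    if len(observed) != len(canonical):
        raise ValueError("observed and canonical sites differ in length")
    return "".join(
        o if iupac_match(o, c) else f"{open_mark}{o}{close_mark}"
        for o, c in zip(observed, canonical)
    )


def insilico_pcr(seq: NucleotideSequence, fwd: Primer, rev: Primer,
                 max_mismatches: int = 2, anchor_3prime: int = 3,
                 product_window: tuple[int, int] = (300, 700)) -> list[Amplicon]:
    """Predict PCR products of a primer pair on one template.

    Every (plus-strand forward hit, minus-strand reverse hit) pair with the
    forward site upstream and an outer product length inside
    ``product_window`` yields one amplicon; outer coordinates include both
    primer sites.  The template orientation is not assumed: the mirror-image
    pairing (forward primer annealing to the minus strand downstream of a
    plus-strand reverse-primer site) is detected too, so results are
    invariant under reverse-complementing the input.  For such products the
    residues are reported 5'->3' as synthesized (starting with the forward
    primer), while start/end stay in input-strand coordinates.  Zero
    amplicons is a valid result (a specificity-screen negative).
    """
    if fwd.role != "forward" or rev.role != "reverse":
        raise ValueError("insilico_pcr needs a forward and a reverse primer")
    lo, hi = product_window
    fwd_hits = find_primer_hits(seq, fwd, max_mismatches, anchor_3prime)
    rev_hits = find_primer_hits(seq, rev, max_mismatches, anchor_3prime)
    out = []
    for fh in (h for h in fwd_hits if h.strand == "plus"):
        for rh in (h for h in rev_hits if h.strand == "minus"):
            if fh.site_start < rh.site_start:
                length = rh.site_end - fh.site_start + 1
                if lo <= length <= hi:
                    out.append(Amplicon(
                        fwd_hit=fh, rev_hit=rh,
                        start=fh.site_start, end=rh.site_end,
                        residues=seq.subseq(fh.site_start, rh.site_end),
                    ))
    for fh in (h for h in fwd_hits if h.strand == "minus"):
        for rh in (h for h in rev_hits if h.strand == "plus"):
            if rh.site_start < fh.site_start:
                length = fh.site_end - rh.site_start + 1
                if lo <= length <= hi:
                    out.append(Amplicon(
                        fwd_hit=fh, rev_hit=rh,
                        start=rh.site_start, end=fh.site_end,
                        residues=reverse_complement(
                            seq.subseq(rh.site_start, fh.site_end)),
                    ))
    out.sort(key=lambda a: (a.start, a.length))
    return out
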