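"""In silico restriction digestion and gel-like band patterns.

Models the ARDRA experiment computationally: find recognition sites of a
(possibly degenerate) restriction enzyme on a linear template, cut the top
strand after ``cut_offset`` bases of the site, and summarize the fragment
lengths the way a 2% agarose gel would display them — short run-off
fragments invisible, nearby lengths merged into one band.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .seqio import IUPAC_DNA, NucleotideSequence, iupac_match

__all__ = [
    "Enzyme",
    "HAEIII",
    "CutSite",
    "Fragment",
    "ArdraPattern",
    "find_sites",
    "digest",
    "band_pattern",
    "has_diagnostic_band",
]


@dataclass(frozen=True)
class Enzyme:
    """A restriction enzyme: IUPAC recognition pattern plus top-strand cut offset.

    ``cut_offset`` is the number of site bases left of the cut; HaeIII
    (GG^CC) has offset 2.  Only the top-strand cut is modeled; for blunt
    cutters such as HaeIII both strands share it.
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self) -> None:
        rec = self.recognition.upper()
        if len(rec) < 4:
            raise ValueError("recognition site must be at least 4 bp")
        if set(rec) - IUPAC_DNA:
            raise ValueError(f"non-IUPAC recognition sequence {self.recognition!r}")
        if not 0 <= self.cut_offset <= len(rec):
            raise ValueError("cut_offset must lie within the recognition site")
        object.__setattr__(self, "recognition", rec)

    def __len__(self) -> int:
        return len(self.recognition)


#: The toolkit's default enzyme: HaeIII, blunt cutter, GG^CC.
HAEIII = Enzyme(name="HaeIII", recognition="GGCC", cut_offset=2)


@dataclass(frozen=True)
class CutSite:
    """One recognition-site occurrence (1-based)."""

    site_start: int
    cut_after: int  # backbone cut falls between cut_after and cut_after + 1


@dataclass(frozen=True)
class Fragment:
    """A digest fragment: 1-based inclusive span plus its residues."""

    start: int
    end: int
    residues: str

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ArdraPattern:
    """Gel-like band summary: (bin center, fragment count) pairs."""

    bands: list[tuple[int, int]] = field(default_factory=list)
    bin_tolerance: int = 10

    @property
    def centers(self) -> list[int]:
        return [c for c, _ in self.bands]


def find_sites(seq: NucleotideSequence, enzyme: Enzyme = HAEIII) -> list[CutSite]:
    """All recognition-site occurrences, ascending; overlaps all reported."""
    res = seq.residues
    pat = enzyme.recognition
    k = len(pat)
    sites = []
    for i in range(len(res) - k + 1):
        if all(iupac_match(res[i + j], pat[j]) for j in range(k)):
            sites.append(CutSite(site_start=i + 1, cut_after=i + enzyme.cut_offset))
    return sites


def digest(seq: NucleotideSequence, enzyme: Enzyme = HAEIII) -> list[Fragment]:
    """Cut a linear template at every site; fragments tile the sequence.

    Cut positions at the very ends of the molecule (offset 0 sites at
    position 1, or sites cutting after the final base) produce no empty
    fragments.
    """
    L = len(seq.residues)
    cuts = sorted({s.cut_after for s in find_sites(seq, enzyme)} - {0, L})
    bounds = [0, *cuts, L]
    return [
        Fragment(start=a + 1, end=b, residues=seq.residues[a:b])
        for a, b in zip(bounds, bounds[1:])
    ]


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def band_pattern(fragments: list[Fragment], bin_tolerance: int = 10,
                 min_visible_length: int = 60) -> ArdraPattern:
    """Cluster fragment lengths into gel-like bands.

    Fragments shorter than ``min_visible_length`` are dropped (they run off
    a 2% agarose gel).  Remaining lengths are clustered by single linkage:
    a gap greater than ``bin_tolerance`` between successive sorted lengths
    starts a new band.  Band center = round-half-up mean of member lengths.
    """
    if bin_tolerance < 0:
        raise ValueError("bin_tolerance must be >= 0")
    lengths = sorted(f.length for f in fragments if f.length >= min_visible_length)
    bands: list[tuple[int, int]] = []
    cluster: list[int] = []
    for ln in lengths:
        if cluster and ln - cluster[-1] > bin_tolerance:
            bands.append((_round_half_up(sum(cluster) / len(cluster)), len(cluster)))
            cluster = []
        cluster.append(ln)
    if cluster:
        bands.append((_round_half_up(sum(cluster) / len(cluster)), len(cluster)))
    return ArdraPattern(bands=bands, bin_tolerance=bin_tolerance)


def has_diagnostic_band(pattern: ArdraPattern, target: int = 460,
                        tolerance: int = 15) -> bool:
    """True iff some band center lies within ``target`` +/- ``tolerance``."""
    return any(abs(center - target) <= tolerance for center, _ in pattern.bands)
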