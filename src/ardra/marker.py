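"""Diagnostic-marker extraction, screening and de novo discovery.

The marker of interest is a restriction-site-delimited region of the 16S
rRNA gene (for aerobic endospore-forming bacilli: the ~463 bp region
amplified by the 463F/463R pair and flanked by HaeIII cut sites).  This
module

* extracts and classifies the marker on single sequences (``extract_marker``),
* reproduces a specificity-screen table over a panel (``screen_panel``),
* generalizes the original observation into a procedure that discovers
  diagnostic digest-fragment bins for arbitrary target/outgroup sets
  (``discover_marker``), and
* proposes primer pairs for a discovered fragment with a deliberately
  simple consensus + GC-formula designer (``design_primers``) in place of a
  full thermodynamic tool.

Percent identities are integer-rounded, matching the convention of the
published specificity table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd
from Bio import Align

from .amplify import (
    Amplicon,
    Primer,
    PRIMER_463F,
    PRIMER_463R,
    PRIMER_463R_SENSE_SITE,
    annotate_variant,
    insilico_pcr,
)
from .restriction import Enzyme, Fragment, HAEIII, digest, find_sites
from .seqio import IUPAC_SETS, NucleotideSequence, SequenceSet, reverse_complement

__all__ = [
    "Scoring",
    "Alignment",
    "MarkerCall",
    "MarkerCandidate",
    "PrimerPairProposal",
    "global_align",
    "percent_identity",
    "extract_marker",
    "screen_panel",
    "discover_marker",
    "design_primers",
    "primer_tm",
    "load_table2_subset",
]


# ---------------------------------------------------------------------------
# pairwise global alignment


@dataclass(frozen=True)
class Scoring:
    """Alignment scoring: a gap run of length k costs gap_open + (k-1)*gap_extend."""

    match: float = 1.0
    mismatch: float = -1.0
    gap_open: float = -2.0
    gap_extend: float = -1.0


@dataclass(frozen=True)
class Alignment:
    """A pairwise global alignment: two equal-length gapped strings."""

    a: str
    b: str
    score: float
    scoring: Scoring = Scoring()

    def __post_init__(self) -> None:
        if len(self.a) != len(self.b):
            raise ValueError("gapped strings differ in length")

    def columns(self):
        return zip(self.a, self.b)


def global_align(a: str, b: str, scoring: Scoring = Scoring()) -> Alignment:
    """Optimal Needleman-Wunsch global alignment with affine gaps.

    Deterministic: among co-optimal alignments the aligner's first
    traceback is returned.
    """
    if not a or not b:
        raise ValueError("cannot align empty sequences")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    aln = next(iter(aligner.align(a.upper(), b.upper())))
    return Alignment(a=aln[0], b=aln[1], score=aln.score, scoring=scoring)


def percent_identity(aln: Alignment, mode: str = "excluding_gaps") -> int:
    """Identical columns / counted columns x 100, rounded to nearest integer.

    ``excluding_gaps`` counts only columns where both sequences have a
    residue; ``including_gaps`` counts every alignment column.
    """
    if mode not in ("excluding_gaps", "including_gaps"):
        raise ValueError(f"unknown mode {mode!r}")
    ident = sum(1 for x, y in aln.columns() if x == y and x != "-")
    if mode == "excluding_gaps":
        counted = sum(1 for x, y in aln.columns() if x != "-" and y != "-")
    else:
        counted = len(aln.a)
    if counted == 0:
        raise ValueError("alignment has no counted columns")
    return int(math.floor(ident / counted * 100 + 0.5))


# ---------------------------------------------------------------------------
# marker extraction and panel screening


@dataclass(frozen=True)
class MarkerCall:
    """Outcome of the marker screen on one sequence."""

    seq_id: str
    classification: str  # "positive" | "negative" | "indeterminate"
    amplicon: Amplicon | None = None
    digest_fragment: Fragment | None = None
    internal_site_present: bool | None = None
    percent_identity: int | None = None

    def __post_init__(self) -> None:
        if self.classification == "positive" and self.amplicon is None:
            raise ValueError("positive call requires an amplicon")
        if self.percent_identity is not None and not 0 <= self.percent_identity <= 100:
            raise ValueError("percent_identity outside [0, 100]")


def _site_flag(sites, site_len: int, amplicon: Amplicon, rule: str) -> bool:
    """Evaluate the restriction-site presence column under a configurable rule.

    ``any``      - some recognition site lies entirely within the
                   primer-delimited span (the default: it tracks the
                   published +/- column, which goes negative in taxa whose
                   reverse-primer-internal site is ablated);
    ``interior`` - some site lies within the span without overlapping the
                   reverse-primer region;
    ``flanking`` - cut positions exist on both sides of the span midpoint no
                   farther than one site length outside the span, i.e. the
                   fragment around the midpoint is cut-delimited.
    """
    start, end = amplicon.start, amplicon.end
    rs, re_ = amplicon.rev_hit.site_start, amplicon.rev_hit.site_end
    ends = {s.site_start: s.site_start + site_len - 1 for s in sites}
    if rule == "any":
        return any(s.site_start >= start and ends[s.site_start] <= end for s in sites)
    if rule == "interior":
        return any(
            s.site_start >= start and ends[s.site_start] <= end
            and (ends[s.site_start] < rs or s.site_start > re_)
            for s in sites
        )
    if rule == "flanking":
        # delimiting cuts may fall slightly outside the primer span (the
        # digest fragment is a few bp short of the amplicon)
        slack = 2 * site_len
        mid = (start + end) // 2
        return (any(start - slack <= s.cut_after < mid for s in sites)
                and any(mid <= s.cut_after <= end + slack for s in sites))
    raise ValueError(f"unknown site rule {rule!r}")


def extract_marker(
    seq: NucleotideSequence,
    fwd: Primer = PRIMER_463F,
    rev: Primer = PRIMER_463R,
    enzyme: Enzyme = HAEIII,
    *,
    max_mismatches: int = 2,
    anchor_3prime: int = 3,
    product_window: tuple[int, int] = (300, 700),
    site_rule: str = "any",
    reference_marker: str | None = None,
) -> MarkerCall:
    """Run the full single-sequence marker screen.

    In silico PCR with the primer pair; exactly one product => positive
    (with the digest fragment containing the amplicon midpoint, the
    restriction-site flag, and optionally percent identity against a
    reference marker); no product => negative; multiple products =>
    indeterminate.
    """
    amps = insilico_pcr(seq, fwd, rev, max_mismatches, anchor_3prime, product_window)
    if not amps:
        return MarkerCall(seq_id=seq.id, classification="negative")
    if len(amps) > 1:
        return MarkerCall(seq_id=seq.id, classification="indeterminate")
    amp = amps[0]
    frags = digest(seq, enzyme)
    mid = (amp.start + amp.end) // 2
    frag = next(f for f in frags if f.start <= mid <= f.end)
    sites = find_sites(seq, enzyme)
    flag = _site_flag(sites, len(enzyme), amp, site_rule)
    pid = None
    if reference_marker is not None:
        pid = percent_identity(global_align(amp.residues, reference_marker))
    return MarkerCall(
        seq_id=seq.id,
        classification="positive",
        amplicon=amp,
        digest_fragment=frag,
        internal_site_present=flag,
        percent_identity=pid,
    )


SCREEN_COLUMNS = [
    "seq_id", "classification", "start", "end", "length",
    "fwd_mismatches", "rev_mismatches", "fwd_variant", "rev_variant",
    "internal_site", "percent_identity",
]


def screen_panel(
    panel: SequenceSet,
    reference_marker: str | None = None,
    fwd: Primer = PRIMER_463F,
    rev: Primer = PRIMER_463R,
    enzyme: Enzyme = HAEIII,
    **kwargs,
) -> pd.DataFrame:
    """Screen every panel member; one row per sequence, input order kept.

    Variant columns show the observed primer sites with mismatching bases
    bracketed (the plain-text analogue of bolding them); the reverse site
    is reported in the sense-strand convention.
    """
    def canonical(hit, primer):
        # sense-strand representation of the primer at this hit's orientation
        return primer.oligo if hit.strand == "plus" \
            else reverse_complement(primer.oligo)

    rows = []
    for seq in panel:
        call = extract_marker(seq, fwd, rev, enzyme,
                              reference_marker=reference_marker, **kwargs)
        row = dict.fromkeys(SCREEN_COLUMNS)
        row["seq_id"] = seq.id
        row["classification"] = call.classification
        if call.amplicon is not None:
            amp = call.amplicon
            row.update(
                start=amp.start, end=amp.end, length=amp.length,
                fwd_mismatches=amp.fwd_hit.mismatches,
                rev_mismatches=amp.rev_hit.mismatches,
                fwd_variant=annotate_variant(amp.fwd_hit, canonical(amp.fwd_hit, fwd)),
                rev_variant=annotate_variant(amp.rev_hit, canonical(amp.rev_hit, rev)),
                internal_site="+" if call.internal_site_present else "-",
                percent_identity=call.percent_identity,
            )
        rows.append(row)
    table = pd.DataFrame(rows, columns=SCREEN_COLUMNS)
    for col in ("start", "end", "length", "fwd_mismatches", "rev_mismatches",
                "percent_identity"):
        table[col] = table[col].astype("Int64")
    return table


# ---------------------------------------------------------------------------
# de novo diagnostic-fragment discovery


@dataclass(frozen=True)
class PrimerPairProposal:
    """A proposed primer pair for a fragment: consensus oligos plus stats."""

    fwd: str
    rev: str  # emitted 5'->3' as synthesized (reverse complement of the site)
    tm_fwd: float
    tm_rev: float
    degenerate_fwd: int
    degenerate_rev: int


@dataclass(frozen=True)
class MarkerCandidate:
    """A digest-fragment length bin that separates targets from outgroup."""

    bin_center: int
    target_prevalence: float
    outgroup_prevalence: float
    spans: dict[str, list[tuple[int, int]]]  # seq_id -> member fragment spans
    primer_proposals: tuple[PrimerPairProposal, ...] = ()

    def __post_init__(self) -> None:
        if not self.target_prevalence > self.outgroup_prevalence:
            raise ValueError("candidate must be enriched in the target set")


def _length_bins(lengths: list[int], tol: int) -> list[tuple[int, int]]:
    """Single-linkage 1-D clustering; (lo, hi) per bin."""
    bins = []
    cur: list[int] = []
    for ln in sorted(lengths):
        if cur and ln - cur[-1] > tol:
            bins.append((cur[0], cur[-1]))
            cur = []
        cur.append(ln)
    if cur:
        bins.append((cur[0], cur[-1]))
    return bins


def discover_marker(
    targets: SequenceSet,
    outgroup: SequenceSet,
    enzyme: Enzyme = HAEIII,
    length_window: tuple[int, int] = (200, 800),
    min_target_prev: float = 0.9,
    max_outgroup_prev: float = 0.1,
    bin_tolerance: int = 10,
    design: bool = True,
    **design_kwargs,
) -> list[MarkerCandidate]:
    """Find digest-fragment length bins diagnostic for the target set.

    Digest every sequence, pool fragment lengths inside ``length_window``,
    cluster them into bins (single linkage, gap > ``bin_tolerance`` starts a
    new bin), compute per-set prevalence of each bin, and keep bins with
    target prevalence >= ``min_target_prev`` and outgroup prevalence <=
    ``max_outgroup_prev``.  Candidates are ranked by prevalence difference,
    then bin size.  For each candidate the member fragments of target
    sequences are collected and a primer pair is proposed from them.
    """
    if not len(targets) or not len(outgroup):
        raise ValueError("both sequence sets must be non-empty")
    lo, hi = length_window

    frag_map: dict[str, list[Fragment]] = {}
    for seqset in (targets, outgroup):
        for seq in seqset:
            frag_map[seq.id] = [f for f in digest(seq, enzyme) if lo <= f.length <= hi]

    pooled = [f.length for frs in frag_map.values() for f in frs]
    candidates = []
    for blo, bhi in _length_bins(pooled, bin_tolerance):
        in_bin = lambda f: blo <= f.length <= bhi
        t_hit = [s.id for s in targets if any(map(in_bin, frag_map[s.id]))]
        o_hit = [s.id for s in outgroup if any(map(in_bin, frag_map[s.id]))]
        t_prev = len(t_hit) / len(targets)
        o_prev = len(o_hit) / len(outgroup)
        if t_prev < min_target_prev or o_prev > max_outgroup_prev or t_prev <= o_prev:
            continue
        members = [f for sid in t_hit for f in frag_map[sid] if in_bin(f)]
        spans = {sid: [(f.start, f.end) for f in frag_map[sid] if in_bin(f)]
                 for sid in t_hit}
        center = int(math.floor(sum(f.length for f in members) / len(members) + 0.5))
        proposals = ()
        if design:
            proposals = tuple(design_primers([f.residues for f in members],
                                             **design_kwargs))
        candidates.append(MarkerCandidate(
            bin_center=center, target_prevalence=t_prev, outgroup_prevalence=o_prev,
            spans=spans, primer_proposals=proposals,
        ))
    candidates.sort(key=lambda c: (-(c.target_prevalence - c.outgroup_prevalence),
                                   -sum(len(v) for v in c.spans.values()),
                                   c.bin_center))
    return candidates


# ---------------------------------------------------------------------------
# simplified primer design

_CODE_BY_SET = {v: k for k, v in IUPAC_SETS.items()}


def primer_tm(oligo: str) -> float:
    """Basic GC-content melting temperature: 64.9 + 41*(GC - 16.4)/length.

    Degenerate positions contribute the mean GC content of their base set.
    """
    gc = 0.0
    for b in oligo.upper():
        s = IUPAC_SETS[b]
        gc += len(s & {"G", "C"}) / len(s)
    return 64.9 + 41.0 * (gc - 16.4) / len(oligo)


def _terminal_consensus(regions: list[str], length: int, end: str) -> tuple[str, int]:
    """Consensus over the first/last ``length`` columns; returns (IUPAC string,
    number of non-unanimous columns)."""
    windows = [r[:length] if end == "5p" else r[-length:] for r in regions]
    consensus = []
    degenerate = 0
    for col in zip(*windows):
        bases = frozenset(col)
        if len(bases) > 1:
            degenerate += 1
        consensus.append(_CODE_BY_SET[bases] if bases in _CODE_BY_SET else "N")
    return "".join(consensus), degenerate


def design_primers(
    regions: list[str],
    primer_len: tuple[int, int] = (18, 25),
    max_degeneracy: int = 1,
    tm_window: tuple[float, float] = (50.0, 65.0),
) -> list[PrimerPairProposal]:
    """Propose primer pairs from the termini of a set of homologous regions.

    Windows are anchored at the region termini (the fragments are
    cut-site-delimited, so primers amplifying the whole fragment must sit at
    its very ends) and vary in length over ``primer_len``.  A window
    survives if it has at most ``max_degeneracy`` non-unanimous columns
    (emitted as IUPAC degenerate codes) and a GC-formula Tm inside
    ``tm_window``.  Pairs are ranked by total degeneracy, then Tm balance,
    then length.  The reverse oligo is emitted 5'->3' as synthesized.
    """
    if not regions:
        raise ValueError("need at least one region")
    regions = [r.upper() for r in regions]
    shortest = min(len(r) for r in regions)
    lmin, lmax = primer_len
    lmax = min(lmax, shortest // 2)  # fwd and rev windows must not overlap
    tlo, thi = tm_window

    fwd_cands, rev_cands = [], []
    for L in range(lmin, lmax + 1):
        cons, deg = _terminal_consensus(regions, L, "5p")
        if deg <= max_degeneracy and tlo <= primer_tm(cons) <= thi:
            fwd_cands.append((cons, deg))
        cons, deg = _terminal_consensus(regions, L, "3p")
        oligo = reverse_complement(cons)
        if deg <= max_degeneracy and tlo <= primer_tm(oligo) <= thi:
            rev_cands.append((oligo, deg))

    pairs = [
        PrimerPairProposal(
            fwd=f, rev=r, tm_fwd=primer_tm(f), tm_rev=primer_tm(r),
            degenerate_fwd=df, degenerate_rev=dr,
        )
        for f, df in fwd_cands for r, dr in rev_cands
    ]
    pairs.sort(key=lambda p: (
        p.degenerate_fwd + p.degenerate_rev,
        abs(p.tm_fwd - p.tm_rev),
        len(p.fwd), len(p.rev),
    ))
    return pairs


# ---------------------------------------------------------------------------
# packaged specificity-table subset (test fixture)


def load_table2_subset() -> pd.DataFrame:
    """Machine-readable subset of the published primer-specificity table.

    Columns: taxon, accession, fwd_variant, rev_variant (bracket-marked
    mismatches, sense-strand convention), pct_similarity, site_flag, span.
    Shipped as a validation fixture only.
    """
    with resources.files("ardra.data").joinpath("table2_subset.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", dtype=str)
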