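# Methods

This note documents the models, conventions and deliberate simplifications
behind the toolkit, in the order a user meets them.

## Sequence model and conventions

Sequences are DNA over the IUPAC alphabet, stored uppercase with `U`
mapped to `T` at parse time.  Every coordinate in the toolkit is 1-based
and inclusive on the stored (sense) strand; spans such as 909–1371 include
both endpoints, so length = end − start + 1.

Degenerate-base comparison is set intersection of the concrete bases, with
one asymmetry: an `N` in a *subject* sequence matches nothing but a
pattern `N`.  An `N` in a record is an unread base, not a genuine 4-fold
degeneracy, and treating it as a wildcard would conjure cut sites and
primer sites out of low-quality sequence.  Pattern-side degeneracy
(enzyme sites like `GSCC`, degenerate primers) behaves as usual.

## Restriction digestion and band patterns

An enzyme is a recognition pattern plus a top-strand cut offset (HaeIII:
`GGCC`, offset 2).  Digestion is linear — the inputs are PCR amplicons or
gene regions, not plasmids — and only the top-strand cut is modeled, which
is exact for blunt cutters like HaeIII; for enzymes with 5'/3' overhangs
the fragment boundaries refer to the top strand only.  Fragments tile the
sequence: they are contiguous, non-overlapping and length-conserving, and
overlapping site occurrences are all reported.

Band patterns emulate what a 2% agarose gel with a 100 bp ladder resolves:
fragments shorter than 60 bp (default, configurable) run off; remaining
lengths are clustered by single linkage, a gap of more than `bin_tolerance`
(default 10 bp) starting a new band; the band center is the round-half-up
mean of member lengths.  The diagnostic-band test asks whether any band
center falls within 460 ± 15 bp, the size window at which the AEFB marker
fragment runs.

## Primer-site search and in silico PCR

Primer hits are Hamming matches (no indels — the observed site variants in
AEFB 16S genes are substitution-only) with at most `max_mismatches`
(default 2) substitutions and none in the 3'-terminal `anchor_3prime`
bases (default 3) of the oligo: a polymerase does not extend a mismatched
3' end.  Minus-strand hits are reported in sense-strand coordinates as the
segment the oligo anneals to ("sense-site" convention); the packaged 463R
oligo is the reverse complement of its printed sense site.

In silico PCR pairs upstream plus-strand forward hits with downstream
minus-strand reverse hits whose outer span (including both primer sites —
this is what makes the spans reproduce the published 909–1371-style
coordinates) lies inside the product window (default 300–700 bp).  The
mirror orientation is detected symmetrically, so results do not depend on
which strand a record was deposited in.  Zero products is a valid
result — it is exactly the specificity-screen negative.  Multiple products
make a marker call "indeterminate" rather than guessing.

The forward primer ships in two forms that differ at base 3 (`CTG…` vs
`CTA…`), both of which circulate for this marker; the `CTG…` form is the
default because the specificity data are internally consistent with it,
and the other is selectable (`PRIMER_463F_TEXT_VARIANT`, CLI
`--fwd-variant a`).

## Marker extraction, screening and the site flag

`extract_marker` classifies a sequence positive iff in silico PCR yields
exactly one product; it then locates the digest fragment containing the
amplicon midpoint and evaluates a restriction-site flag.  Which site the
published "+/−" column refers to is not defined anywhere authoritative, so
the rule is configurable:

* `any` (default): some HaeIII site lies entirely within the
  primer-delimited span.  This tracks the observed data best — taxa whose
  reverse-primer-internal GGCC is ablated (`GGTC` variants) are the ones
  scored "−".
* `interior`: a site inside the span but clear of the reverse-primer
  region.
* `flanking`: cut positions exist on both sides of the span midpoint no
  farther than two site lengths outside the span, i.e. the midpoint
  fragment is cut-delimited rather than end-delimited.

Percent identity is computed from a pairwise global alignment
(Needleman–Wunsch, affine gaps; match +1, mismatch −1, gap open −2, gap
extend −1, a length-k gap run costing −2 − (k−1)) and reported as
identical/counted columns, gap columns excluded by default, rounded to the
nearest integer to match how such screens are tabulated.  Alignment is
delegated to Biopython's `PairwiseAligner`; the first co-optimal traceback
is used, and for distance computation argument order is canonicalized so
co-optimal gap placement cannot make distances order-dependent.  No default
reference marker is hardcoded: published similarity percentages for this
marker have an ambiguous reference (a type-strain self-comparison listed
below 100%), so identity is only computed against a user-supplied
reference.

## Diagnostic-fragment discovery and primer design

`discover_marker` generalizes the original observation into a procedure:
digest every target and outgroup sequence, pool fragment lengths inside a
length window (default 200–800 bp), cluster them into bins by single
linkage (same tolerance as banding), and keep bins whose target prevalence
is ≥ 0.9 and outgroup prevalence ≤ 0.1 (defaults), ranked by prevalence
difference then bin occupancy.  Prevalence is the fraction of sequences in
a set with at least one fragment in the bin.

For each candidate the member fragments are collected and a primer pair is
proposed.  The designer is deliberately simple, standing in for a full
thermodynamic tool: windows are anchored at the fragment termini (the
fragment is cut-site-delimited, so a pair amplifying the whole fragment
must sit at its ends) and vary in length (default 18–25 nt); a window
survives if it has at most `max_degeneracy` non-unanimous consensus
columns (emitted as IUPAC codes) and a melting temperature inside the
window (default 50–65 °C) by the basic GC formula

    Tm = 64.9 + 41 · (nGC − 16.4) / length,

with degenerate positions contributing their base set's mean GC content.
Pairs are ranked by total degeneracy, then |Tm_f − Tm_r|, then length.
Nearest-neighbor thermodynamics, dimer and hairpin checks are out of
scope.

## Distances and trees

Marker distances are pairwise: p-distance (mismatched / compared columns,
gap columns excluded) or Jukes–Cantor, −(3/4)·ln(1 − 4p/3), undefined at
p ≥ 0.75.  Pairwise alignment replaces a multiple alignment deliberately:
the published use of the marker for grouping is qualitative, and pairwise
NJ input is fully specified and exactly testable; a center-star or
progressive MSA is explicitly not attempted.

Neighbor joining is the canonical Saitou–Nei algorithm with deterministic
tie-breaking (first minimal Q pair in working order, original label order
first) and is exact on additive matrices — the property the tests enforce
up to 6 taxa.  Negative limb-length estimates are clamped to zero with the
deficit moved to the sister branch, the common convention.  Trees are
unrooted, represented with a trifurcating root, serialized to Newick with
6 significant digits, and cut into k groups by removing the k − 1 longest
internal edges (ties broken by preorder position).

## The synthetic-sequence generator

`make_aefb_like` emulates exactly the features of a full-length
(default 1550 bp) AEFB 16S gene that the toolkit measures, and nothing
else: ~55% GC background (typical of 16S), the forward-primer site planted
at position 909, the reverse sense site ending at 1371 (outer span 463
bp), an upstream flanking `GGCC` cutting at 904 so the diagnostic digest
fragment is 905–1367 = 463 bp, a configurable number of decoy `GGCC` sites
outside the marker, and optional marker-interior substitutions.  All other
`GGCC` occurrences are scrubbed from the background, so cut-site counts
are exactly controlled, and decoy placement is constrained so no
non-diagnostic fragment falls within 430–490 bp (the diagnostic bin plus
binning slack).  Every sequence carries a truth record of planted
coordinates, and generation is a pure function of the spec.

`make_cohort` derives targets from one base sequence with optional
clade-level drift plus per-member substitutions that avoid primer 3'
anchors and planted cut sites, never create a `GGCC`, and are capped at two
per primer site, so every target amplifies by construction.  Cohort decoys
are zoned downstream of the marker so the only target fragment inside the
default discovery window is the marker itself.  Outgroup members are
independent backgrounds with no planted primer sites and no fragment near
the diagnostic bin.

What the generator does not emulate — rRNA secondary structure and
covariation, indels, chimeras, sequencing error, real phylogenetic
signal — bounds what green tests mean: they validate the machinery
(coordinates, counting, clustering, tree building) exactly, not the
biological specificity of the marker across real lineages, which only real
records can show (see `examples/06_fetch_and_screen_accession.py`).

## Problem sizes and numerics

The test suite and the acceptance script run at desk scale by design:
1000 random sequences for digestion properties, a 10 + 10 cohort for
discovery, 6-taxon matrices for NJ exactness, 8 reconstructed published
span cases.  Band centers use round-half-up; percent identities round to
integers; Newick serialization uses `%.6g`; NJ comparisons use absolute
tolerances of 1e-8 (exactness) and 1e-4 (serialization round-trips).
Degenerate inputs are defined rather than accidental: empty FASTA, empty
sequence sets, zero amplicons, no discovery candidates and sub-3-taxon
matrices all have specified outcomes (error or empty result) and tests.
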