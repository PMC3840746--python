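"""Synthetic 16S-like sequences with fully controlled marker geometry.

Real full-length 16S rRNA genes of aerobic endospore-forming bacilli carry
the diagnostic marker as a HaeIII-delimited ~463 bp fragment near the 3'
end, with the forward primer site around position 909 and the reverse site
ending around 1371.  The generator reproduces exactly that geometry on a
random background:

* background composition ~55% GC (typical of 16S genes);
* every GGCC occurrence outside the planted positions is scrubbed away, so
  cut-site counts are exactly controlled;
* the forward primer site, the reverse sense-strand site (whose interior
  GGCC provides the downstream cut), an upstream flanking GGCC delimiting
  the diagnostic fragment, and a configurable number of decoy GGCC sites
  are planted at known coordinates;
* decoy positions are constrained so that no non-diagnostic fragment falls
  anywhere near the diagnostic length bin.

Every generated sequence comes with a truth record of all planted
coordinates; generation is a pure function of the spec (same seed, same
residues).  What the generator does *not* emulate: rRNA secondary
structure, covariation, indels, chimeras or sequencing error.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, asdict

import numpy as np

from .amplify import PRIMER_463F, PRIMER_463R_SENSE_SITE, Primer
from .restriction import HAEIII
from .seqio import NucleotideSequence, SequenceSet

__all__ = ["FixtureSpec", "FixtureTruth", "make_aefb_like", "make_cohort"]

_BASES = np.array(list("ACGT"))
_SITE = HAEIII.recognition  # planted sites are HaeIII sites
_FORBIDDEN_BAND = (430, 490)  # non-diagnostic fragments must avoid this window


@dataclass(frozen=True)
class FixtureSpec:
    """Everything the generator needs; a pure function of these fields."""

    seed: int = 0
    total_length: int = 1550
    fwd_site_start: int = 909
    marker_length: int = 463
    n_marker_substitutions: int = 0
    decoy_ggcc_count: int = 3
    gc_fraction: float = 0.55
    ablate_fwd_site: bool = False
    ablate_rev_site: bool = False
    extra_fwd_site_start: int | None = None
    decoy_zones: tuple[tuple[int, int], ...] | None = None
    fwd_primer: Primer = PRIMER_463F
    rev_sense_site: str = PRIMER_463R_SENSE_SITE

    def __post_init__(self) -> None:
        if self.fwd_site_start + self.marker_length - 1 > self.total_length:
            raise ValueError("marker does not fit in the sequence")
        if _SITE not in self.rev_sense_site:
            raise ValueError("reverse sense site must contain a HaeIII site")


@dataclass(frozen=True)
class FixtureTruth:
    """Planted coordinates (1-based inclusive spans) and mutations."""

    fwd_span: tuple[int, int] | None
    rev_span: tuple[int, int] | None
    amplicon_span: tuple[int, int] | None
    amplicon_length: int | None
    flank_cut: int | None
    rev_cut: int | None
    diagnostic_fragment: tuple[int, int] | None
    decoy_site_starts: tuple[int, ...]
    substitution_positions: tuple[int, ...]

    def as_dict(self) -> dict:
        return asdict(self)


def _spans_geometry(spec: FixtureSpec):
    fwd_span = (spec.fwd_site_start, spec.fwd_site_start + len(spec.fwd_primer) - 1)
    rev_end = spec.fwd_site_start + spec.marker_length - 1
    rev_span = (rev_end - len(spec.rev_sense_site) + 1, rev_end)
    site_off = spec.rev_sense_site.index(_SITE)
    rev_cut = rev_span[0] + site_off + HAEIII.cut_offset - 1
    flank_cut = rev_cut - spec.marker_length
    flank_span = (flank_cut - 1, flank_cut + 2)  # the GGCC providing flank_cut
    if flank_span[0] < 1:
        raise ValueError("no room for the upstream flanking cut site")
    if flank_span[1] >= fwd_span[0]:
        raise ValueError("flanking site would collide with the forward primer site")
    return fwd_span, rev_span, rev_cut, flank_cut, flank_span


def _random_background(rng: np.random.Generator, n: int, gc: float) -> np.ndarray:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return rng.choice(_BASES, size=n, p=p)


def _plant(arr: np.ndarray, start_1based: int, text: str) -> None:
    arr[start_1based - 1 : start_1based - 1 + len(text)] = list(text)


def _find_all(s: str, motif: str) -> list[int]:
    """All 0-based occurrence starts (overlapping)."""
    out, i = [], s.find(motif)
    while i != -1:
        out.append(i)
        i = s.find(motif, i + 1)
    return out


def _scrub(arr: np.ndarray, rng: np.random.Generator,
           allowed_starts: set[int], protected: list[tuple[int, int]]) -> None:
    """Mutate away every unplanned GGCC without touching protected spans."""
    prot = np.zeros(len(arr), dtype=bool)
    for a, b in protected:
        prot[a - 1 : b] = True
    for _ in range(200):
        hits = [h for h in _find_all("".join(arr), _SITE) if h + 1 not in allowed_starts]
        if not hits:
            return
        for h in hits:
            free = [p for p in range(h, h + len(_SITE)) if not prot[p]]
            if not free:  # cannot happen with the planted layouts used here
                raise RuntimeError("unremovable recognition site inside protected span")
            p = free[rng.integers(len(free))]
            arr[p] = rng.choice(_BASES[_BASES != arr[p]])
    raise RuntimeError("site scrubbing did not converge")


def _fragment_lengths(cuts: list[int], total: int) -> list[tuple[int, int]]:
    """(start_cut, length) of every fragment given top-strand cut positions."""
    bounds = [0, *sorted(cuts), total]
    return [(a, b - a) for a, b in zip(bounds, bounds[1:])]


def _place_decoys(rng: np.random.Generator, spec: FixtureSpec,
                  fixed_cuts: list[int], keep_free: list[tuple[int, int]],
                  diagnostic: tuple[int, int] | None) -> list[int]:
    """Decoy site starts whose cuts keep every non-diagnostic fragment length
    outside the forbidden band around the diagnostic bin."""
    decoys: list[int] = []
    lo, hi = _FORBIDDEN_BAND
    zones = spec.decoy_zones or ((10, spec.total_length - len(_SITE) - 10),)
    for _ in range(spec.decoy_ggcc_count):
        for _attempt in range(200):
            zlo, zhi = zones[rng.integers(len(zones))]
            s = int(rng.integers(zlo, min(zhi, spec.total_length - len(_SITE)) + 1))
            span = (s, s + len(_SITE) - 1)
            if any(span[0] <= b + 8 and span[1] >= a - 8 for a, b in keep_free):
                continue
            if any(abs(s - d) < 12 for d in decoys):
                continue
            cut = s + HAEIII.cut_offset - 1
            cuts = fixed_cuts + [d + HAEIII.cut_offset - 1 for d in decoys] + [cut]
            ok = all(
                not (lo <= ln <= hi) or (diagnostic is not None
                                         and (c, c + ln) == diagnostic)
                for c, ln in _fragment_lengths(cuts, spec.total_length)
            )
            if ok:
                decoys.append(s)
                break
        else:
            raise RuntimeError("could not place decoy sites under the constraints")
    return decoys


def _apply_substitutions(arr: np.ndarray, rng: np.random.Generator, n: int,
                         allowed: np.ndarray, per_site_caps: list[list[int]] | None
                         = None, cap: int = 2) -> list[int]:
    """``n`` random substitutions at allowed 0-based positions; never creates a
    GGCC; optionally at most ``cap`` substitutions per listed primer span."""
    counts = [0] * len(per_site_caps or [])
    chosen: list[int] = []
    pool = np.flatnonzero(allowed)
    for _ in range(n):
        for _attempt in range(500):
            p = int(pool[rng.integers(len(pool))])
            if p in chosen:
                continue
            spans_hit = [k for k, span in enumerate(per_site_caps or [])
                         if span[0] <= p <= span[1]]
            if any(counts[k] >= cap for k in spans_hit):
                continue
            old = arr[p]
            arr[p] = rng.choice(_BASES[_BASES != old])
            window = "".join(arr[max(0, p - 3) : p + 4])
            if _SITE in window:
                arr[p] = old
                continue
            chosen.append(p)
            for k in spans_hit:
                counts[k] += 1
            break
        else:
            raise RuntimeError("could not place a substitution under the constraints")
    return sorted(chosen)


def make_aefb_like(spec: FixtureSpec = FixtureSpec(),
                   seq_id: str = "aefb_fixture") -> tuple[NucleotideSequence,
                                                          FixtureTruth]:
    """One synthetic sequence with the marker geometry planted, plus truth.

    With the defaults the sequence yields exactly one in silico PCR product
    spanning 909-1371 (length 463) and a HaeIII digest fragment of 463 bp
    delimited by the upstream flanking cut and the cut inside the reverse
    primer site.
    """
    rng = np.random.default_rng(spec.seed)
    fwd_span, rev_span, rev_cut, flank_cut, flank_span = _spans_geometry(spec)
    arr = _random_background(rng, spec.total_length, spec.gc_fraction)

    protected: list[tuple[int, int]] = []
    allowed_sites: set[int] = set()

    if not spec.ablate_fwd_site:
        _plant(arr, fwd_span[0], spec.fwd_primer.oligo)
        protected.append(fwd_span)
    if spec.extra_fwd_site_start is not None:
        span2 = (spec.extra_fwd_site_start,
                 spec.extra_fwd_site_start + len(spec.fwd_primer) - 1)
        _plant(arr, span2[0], spec.fwd_primer.oligo)
        protected.append(span2)
    if not spec.ablate_rev_site:
        _plant(arr, rev_span[0], spec.rev_sense_site)
        protected.append(rev_span)
        allowed_sites.add(rev_cut - HAEIII.cut_offset + 1)
    _plant(arr, flank_span[0], _SITE)
    protected.append(flank_span)
    allowed_sites.add(flank_span[0])

    diagnostic = (flank_cut, rev_cut) if not spec.ablate_rev_site else None
    fixed_cuts = [flank_cut] + ([rev_cut] if not spec.ablate_rev_site else [])
    # decoys stay clear of the whole marker region, not just the primer sites
    keep_free = protected + [(flank_span[0], rev_span[1])]
    decoys = _place_decoys(rng, spec, fixed_cuts, keep_free, diagnostic)
    for s in decoys:
        _plant(arr, s, _SITE)
        protected.append((s, s + len(_SITE) - 1))
        allowed_sites.add(s)

    _scrub(arr, rng, allowed_sites, protected)

    subs: list[int] = []
    if spec.n_marker_substitutions:
        allowed = np.zeros(spec.total_length, dtype=bool)
        allowed[fwd_span[1] : rev_span[0] - 1] = True  # marker interior only
        subs = _apply_substitutions(arr, rng, spec.n_marker_substitutions, allowed)

    seq = NucleotideSequence(id=seq_id, residues="".join(arr))
    amp = None if (spec.ablate_fwd_site or spec.ablate_rev_site) else \
        (spec.fwd_site_start, spec.fwd_site_start + spec.marker_length - 1)
    truth = FixtureTruth(
        fwd_span=None if spec.ablate_fwd_site else fwd_span,
        rev_span=None if spec.ablate_rev_site else rev_span,
        amplicon_span=amp,
        amplicon_length=spec.marker_length if amp else None,
        flank_cut=flank_cut,
        rev_cut=None if spec.ablate_rev_site else rev_cut,
        diagnostic_fragment=(flank_cut + 1, rev_cut) if diagnostic else None,
        decoy_site_starts=tuple(decoys),
        substitution_positions=tuple(p + 1 for p in subs),
    )
    return seq, truth


def make_cohort(
    spec: FixtureSpec = FixtureSpec(),
    n_target: int = 10,
    n_outgroup: int = 10,
    divergence: int = 5,
    n_clades: int = 1,
    clade_divergence: int = 40,
) -> tuple[SequenceSet, SequenceSet, dict]:
    """A target cohort carrying the marker and an outgroup lacking it.

    Targets derive from one planted base sequence: optional clade-level
    substitutions (splitting the cohort into ``n_clades`` diverged groups)
    followed by ``divergence`` per-member substitutions.  Substitutions
    never touch primer 3' anchors, the planted cut sites, or create new
    GGCC sites, and at most two fall inside any one primer site, so every
    target amplifies.  Outgroup members are independent backgrounds with no
    primer sites and no fragment near the diagnostic length bin.
    """
    if spec.ablate_fwd_site or spec.ablate_rev_site:
        raise ValueError("cohorts require an intact marker in the base spec")
    rng = np.random.default_rng([spec.seed, n_target, n_outgroup, divergence])
    if spec.decoy_zones is None:
        # keep every non-diagnostic fragment out of the discovery length
        # window: decoys go downstream of the marker, leaving one long
        # (> 800 bp) upstream fragment and short tail pieces
        rev_end = spec.fwd_site_start + spec.marker_length - 1
        spec = dataclasses.replace(
            spec, decoy_zones=((rev_end + 8, spec.total_length - 8),))
    base, truth = make_aefb_like(spec)
    fwd_span, rev_span, flank_cut = truth.fwd_span, truth.rev_span, truth.flank_cut
    rev_site_start = truth.rev_cut - HAEIII.cut_offset + 1
    rev_site_span = (rev_site_start, rev_site_start + len(_SITE) - 1)
    flank_span = (flank_cut - 1, flank_cut + 2)

    # 0-based positions a member substitution may touch
    allowed = np.ones(spec.total_length, dtype=bool)
    for a, b in [(fwd_span[1] - 2, fwd_span[1]),       # fwd 3' anchor
                 (rev_span[0], rev_span[0] + 2),       # rev oligo 3' anchor
                 rev_site_span, flank_span]:
        allowed[a - 1 : b] = False
    for s in truth.decoy_site_starts:
        allowed[s - 1 : s + 3] = False
    caps = [[fwd_span[0] - 1, fwd_span[1] - 1], [rev_span[0] - 1, rev_span[1] - 1]]

    clade_bases, clade_subs = [np.array(list(base.residues))], {0: ()}
    clade_allowed = allowed.copy()
    for a, b in (fwd_span, rev_span):  # clade-level drift spares primer sites
        clade_allowed[a - 1 : b] = False
    for c in range(1, n_clades):
        arr = np.array(list(base.residues))
        subs = _apply_substitutions(arr, rng, clade_divergence, clade_allowed)
        clade_bases.append(arr)
        clade_subs[c] = tuple(p + 1 for p in subs)

    targets, t_truth = [], {}
    for t in range(n_target):
        clade = t * n_clades // n_target
        arr = clade_bases[clade].copy()
        subs = _apply_substitutions(arr, rng, divergence, allowed, caps, cap=2)
        sid = f"target_{t + 1:02d}"
        targets.append(NucleotideSequence(id=sid, residues="".join(arr)))
        t_truth[sid] = {"clade": clade,
                        "substitutions": tuple(p + 1 for p in subs)}

    outgroup = []
    for o in range(n_outgroup):
        arr = _random_background(rng, spec.total_length, spec.gc_fraction)
        decoys = _place_decoys(rng, spec, [], [], None)
        for s in decoys:
            _plant(arr, s, _SITE)
        _scrub(arr, rng, set(decoys), [(s, s + 3) for s in decoys])
        outgroup.append(NucleotideSequence(id=f"outgroup_{o + 1:02d}",
                                           residues="".join(arr)))

    cohort_truth = {
        "base": truth,
        "targets": t_truth,
        "clade_substitutions": clade_subs,
        "marker_length": spec.marker_length,
        "diagnostic_fragment_length": (truth.rev_cut - truth.flank_cut
                                       if truth.rev_cut else None),
    }
    return (SequenceSet(name="targets", members=targets),
            SequenceSet(name="outgroup", members=outgroup),
            cohort_truth)
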