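import functools

import numpy as np
import pytest

from ardra.amplify import PRIMER_463F, PRIMER_463R, PRIMER_463R_SENSE_SITE
from ardra.fixtures import FixtureSpec, make_aefb_like, make_cohort
from ardra.marker import (
    Scoring,
    annotate_variant,
    design_primers,
    discover_marker,
    extract_marker,
    global_align,
    load_table2_subset,
    percent_identity,
    primer_tm,
    screen_panel,
)
from ardra.restriction import HAEIII, digest
from ardra.seqio import NucleotideSequence, SequenceSet, reverse_complement

from conftest import random_dna


def brute_force_score(a, b, scoring=Scoring()):
    """Exhaustive optimal global alignment score with affine gaps.

    A gap run of length k costs gap_open + (k-1)*gap_extend, matching the
    package's convention.
    """

    @functools.lru_cache(maxsize=None)
    def rec(i, j, last):
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = scoring.match if a[i] == b[j] else scoring.mismatch
            best = max(best, s + rec(i + 1, j + 1, "d"))
        if i < len(a):
            g = scoring.gap_extend if last == "u" else scoring.gap_open
            best = max(best, g + rec(i + 1, j, "u"))
        if j < len(b):
            g = scoring.gap_extend if last == "l" else scoring.gap_open
            best = max(best, g + rec(i, j + 1, "l"))
        return best

    return rec(0, 0, "d")


class TestGlobalAlign:
    def test_identical(self):
        aln = global_align("ACGT", "ACGT")
        assert aln.score == 4 and aln.a == aln.b == "ACGT"

    def test_single_gap(self):
        aln = global_align("ACGT", "ACT")
        assert sum(c == "-" for c in aln.a + aln.b) == 1
        assert aln.score == brute_force_score("ACGT", "ACT")

    def test_score_equals_brute_force_on_short_strings(self, rng):
        for _ in range(60):
            a = random_dna(rng, int(rng.integers(1, 9)))
            b = random_dna(rng, int(rng.integers(1, 9)))
            assert global_align(a, b).score == pytest.approx(
                brute_force_score(a, b)), (a, b)

    def test_score_symmetry(self, rng):
        for _ in range(20):
            a, b = random_dna(rng, 30), random_dna(rng, 25)
            assert global_align(a, b).score == global_align(b, a).score

    def test_degapping_recovers_inputs(self, rng):
        a, b = random_dna(rng, 40), random_dna(rng, 33)
        aln = global_align(a, b)
        assert aln.a.replace("-", "") == a and aln.b.replace("-", "") == b


class TestPercentIdentity:
    def test_self_is_100(self, rng):
        for _ in range(10):
            s = random_dna(rng, int(rng.integers(5, 60)))
            assert percent_identity(global_align(s, s)) == 100

    def test_three_quarters(self):
        assert percent_identity(global_align("AAAA", "AAAT")) == 75

    def test_marker_with_14_substitutions_rounds_to_97(self, rng):
        ref = random_dna(rng, 463)
        pos = rng.choice(463, size=14, replace=False)
        flip = {"A": "C", "C": "G", "G": "T", "T": "A"}
        mut = list(ref)
        for p in pos:
            mut[p] = flip[mut[p]]
        # (463 - 14) / 463 = 96.98 -> 97
        assert percent_identity(global_align(ref, "".join(mut))) == 97

    def test_symmetric(self, rng):
        a, b = random_dna(rng, 50), random_dna(rng, 48)
        assert percent_identity(global_align(a, b)) == \
            percent_identity(global_align(b, a))


class TestExtractMarker:
    def test_positive_with_full_annotation(self, default_fixture):
        seq, truth = default_fixture
        call = extract_marker(seq)
        assert call.classification == "positive"
        assert (call.amplicon.start, call.amplicon.end) == truth.amplicon_span
        assert call.amplicon.length == 463
        assert (call.digest_fragment.start, call.digest_fragment.end) == \
            truth.diagnostic_fragment
        assert call.internal_site_present is True

    def test_ablated_reverse_site_negative(self):
        seq, _ = make_aefb_like(FixtureSpec(seed=1, ablate_rev_site=True))
        assert extract_marker(seq).classification == "negative"

    def test_two_products_indeterminate(self):
        seq, _ = make_aefb_like(FixtureSpec(seed=2, extra_fwd_site_start=1000))
        assert extract_marker(seq).classification == "indeterminate"

    def test_classification_invariant_under_reverse_complement(self):
        for spec in (FixtureSpec(seed=3), FixtureSpec(seed=3, ablate_rev_site=True)):
            seq, _ = make_aefb_like(spec)
            assert extract_marker(seq).classification == \
                extract_marker(seq.reverse_complemented()).classification

    def test_site_rules(self, default_fixture):
        seq, _ = default_fixture
        # the only site inside the span sits in the reverse-primer region:
        # counted by "any", excluded by "interior", delimiting by "flanking"
        assert extract_marker(seq, site_rule="any").internal_site_present
        assert not extract_marker(seq, site_rule="interior").internal_site_present
        assert extract_marker(seq, site_rule="flanking").internal_site_present

    def test_percent_identity_against_reference(self, default_fixture):
        seq, _ = default_fixture
        ref = extract_marker(seq).amplicon.residues
        call = extract_marker(seq, reference_marker=ref)
        assert call.percent_identity == 100


class TestScreenPanel:
    def make_panel(self):
        members = [make_aefb_like(FixtureSpec(seed=s), seq_id=f"s{s}")[0]
                   for s in (0, 1)]
        members.append(make_aefb_like(FixtureSpec(seed=2, ablate_rev_site=True),
                                      seq_id="ablated")[0])
        return SequenceSet("panel", members)

    def test_rows_follow_input_order_and_classification(self):
        table = screen_panel(self.make_panel())
        assert list(table.seq_id) == ["s0", "s1", "ablated"]
        assert list(table.classification) == ["positive", "positive", "negative"]
        pos = table[table.classification == "positive"]
        assert set(pos.length) == {463} and set(pos.internal_site) == {"+"}

    def test_empty_panel(self):
        table = screen_panel(SequenceSet("empty", []))
        assert len(table) == 0 and "classification" in table.columns

    def test_rescreen_is_byte_identical(self, tmp_path):
        panel = self.make_panel()
        a = screen_panel(panel).to_csv(sep="\t", index=False)
        b = screen_panel(panel).to_csv(sep="\t", index=False)
        assert a == b


class TestDiscoverMarker:
    def test_perfect_recovery_on_standard_cohort(self, cohort):
        targets, outgroup, truth = cohort
        cands = discover_marker(targets, outgroup)
        assert len(cands) == 1
        c = cands[0]
        assert c.bin_center == truth["diagnostic_fragment_length"] == 463
        assert c.target_prevalence == 1.0 and c.outgroup_prevalence == 0.0
        assert set(c.spans) == set(targets.ids)
        assert c.primer_proposals  # a primer pair was proposed

    def test_targets_equal_outgroup_yields_nothing(self, cohort):
        targets, _, _ = cohort
        clone = SequenceSet("clone", list(targets.members))
        assert discover_marker(targets, clone) == []

    def test_prevalence_equals_per_sequence_membership_count(self, cohort):
        targets, outgroup, _ = cohort
        c = discover_marker(targets, outgroup)[0]
        lo = min(e - s + 1 for spans in c.spans.values() for s, e in spans) - 10
        hi = max(e - s + 1 for spans in c.spans.values() for s, e in spans) + 10
        n_with = sum(
            any(lo <= f.length <= hi for f in digest(s, HAEIII))
            for s in targets
        )
        assert c.target_prevalence == n_with / len(targets)
        n_out = sum(
            any(lo <= f.length <= hi for f in digest(s, HAEIII))
            for s in outgroup
        )
        assert c.outgroup_prevalence == n_out / len(outgroup)


class TestDesignPrimers:
    P22 = "CTGAAACTCAAAGGAATTGACG"

    def test_consensus_of_one_region(self):
        p25 = self.P22 + "ATC"
        region = p25 + "GCATTACGGATCACGA" * 20 + reverse_complement(p25)
        best = design_primers([region])[0]
        assert best.fwd == self.P22
        assert best.rev == self.P22  # 3' terminus was planted as its complement
        assert best.degenerate_fwd == best.degenerate_rev == 0

    def test_variable_terminal_column_with_zero_degeneracy(self, rng):
        r1 = random_dna(rng, 120)
        r2 = list(r1)
        r2[10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r2[10]]
        r2[-10] = {"A": "C", "C": "G", "G": "T", "T": "A"}[r2[-10]]
        assert design_primers([r1, "".join(r2)], max_degeneracy=0) == []

    def test_gc_formula_melting_temperature(self):
        # 8 G+C over 22 bases: 64.9 + 41*(8 - 16.4)/22
        assert primer_tm("CTAAAACTCAAAGGAATTGACG") == pytest.approx(49.245, abs=5e-3)
        assert primer_tm(self.P22) == pytest.approx(51.109, abs=5e-3)

    def test_degenerate_column_emitted_as_iupac(self):
        r1 = "GC" * 30
        r2 = "GC" * 30
        r2 = r2[:5] + "A" + r2[6:]  # column 6: C vs A -> M
        props = design_primers([r1, r2], primer_len=(18, 18),
                               tm_window=(0, 120), max_degeneracy=2)
        assert props and props[0].fwd[5] == "M"


class TestPackagedSpecificityTable:
    def test_variant_marks_reproduced_by_annotate(self):
        table = load_table2_subset()
        assert len(table) >= 25
        canon = {"fwd_variant": PRIMER_463F.oligo,
                 "rev_variant": PRIMER_463R_SENSE_SITE}
        for _, row in table.iterrows():
            for col, canonical in canon.items():
                marked = row[col]
                raw = marked.replace("[", "").replace("]", "")
                assert annotate_variant(raw, canonical) == marked, row.accession

    def test_spans_are_consistent_marker_coordinates(self):
        table = load_table2_subset()
        for _, row in table.iterrows():
            start, end = map(int, row.span.split("-"))
            assert 850 < start < 1000
            assert 455 <= end - start + 1 <= 470
            assert row.site_flag in "+-"
            assert 0 <= int(row.pct_similarity) <= 100
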