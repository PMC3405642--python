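"""Position summaries, haplogroup assignment and subset association."""

from fractions import Fraction

import numpy as np
import pytest

import mitomatch as mm
from mitomatch.association import _round_percent
from mitomatch.errors import ValidationError

from conftest import WORKED_EXAMPLES


def exact_carrier(profile, sample_id="carrier"):
    """Variant set carrying every entry of a profile (one allele per locus)."""
    calls = {}
    for e in profile:
        calls.setdefault(e.locus, e.mutant_allele)
    return mm.VariantSet(sample_id, calls)


class TestSummarizePositions:
    def test_nine_mutant_six_normal_rendering(self, reference):
        # nine members carry C at 16362, six carry the normal base
        normal = reference[16361]
        members = [
            mm.VariantSet(f"m{i}", {16362: "C"} if i < 9 else {}) for i in range(15)
        ]
        (summary,) = mm.summarize_positions(members, reference)
        assert summary.rendered() == f"16362 {normal}>C (9/6)"
        assert (summary.mutant_count, summary.normal_count) == (9, 6)

    def test_all_reference_members_empty_summary(self, reference):
        members = [mm.VariantSet(f"m{i}", {}) for i in range(5)]
        assert mm.summarize_positions(members, reference) == []

    def test_counts_match_bruteforce_tally(self, reference):
        # oracle: naive per-position counting loop
        rng = np.random.default_rng(11)
        loci = [100, 200, 300, 16519]
        members = []
        for i in range(10):
            calls = {}
            for locus in loci:
                if rng.random() < 0.5:
                    choices = [b for b in "ACGT" if b != reference[locus - 1]]
                    calls[locus] = choices[rng.integers(0, 3)]
            members.append(mm.VariantSet(f"m{i}", calls))
        summaries = mm.summarize_positions(members, reference)
        for s in summaries:
            expected_y = sum(
                1 for m in members if m.allele_at(s.locus) == s.mutant_allele
            )
            expected_x = sum(
                1
                for m in members
                if m.allele_at(s.locus) in (None, s.normal_allele)
            )
            assert (s.mutant_count, s.normal_count) == (expected_y, expected_x)
            assert s.mutant_count + s.normal_count + s.other_count == len(members)

    def test_third_allele_outside_y_and_x(self, reference):
        locus = 1000
        normal = reference[locus - 1]
        others = [b for b in "ACGT" if b != normal]
        members = [
            mm.VariantSet("a", {locus: others[0]}),
            mm.VariantSet("b", {locus: others[1]}),
            mm.VariantSet("c", {}),
        ]
        summaries = mm.summarize_positions(members, reference)
        assert len(summaries) == 2  # one per mutant allele
        for s in summaries:
            assert s.mutant_count == 1 and s.normal_count == 1 and s.other_count == 1

    def test_empty_subset_rejected(self, reference):
        with pytest.raises(ValidationError):
            mm.summarize_positions([], reference)


class TestAssignHaplogroup:
    def test_exact_carrier_gets_fraction_one(self, tables):
        table = tables["AD patients"]
        v = exact_carrier(table["G2a"])
        name, fraction = mm.assign_haplogroup(v, table)
        assert name == "G2a" and fraction == 1

    def test_worked_example_matches_exhaustive_ratio(self, tables):
        # oracle: ratios over both AD profiles, computed independently
        calls, (label, hap, matched, total) = WORKED_EXAMPLES["ad_person"]
        table = tables[label]
        v = mm.VariantSet("p", calls)
        ratios = {
            p.haplogroup_name: Fraction(
                sum(1 for e in p if calls.get(e.locus) == e.mutant_allele), p.size
            )
            for p in table
        }
        assert ratios == {"G2a": Fraction(11, 13), "N9b1": Fraction(0, 1)}
        name, fraction = mm.assign_haplogroup(v, table)
        assert (name, fraction) == (hap, Fraction(matched, total))

    def test_empty_variants_no_assignment(self, tables):
        name, fraction = mm.assign_haplogroup(
            mm.VariantSet("p", {}), tables["AD patients"]
        )
        assert name is None and fraction == 0

    def test_fraction_one_iff_full_carrier(self, tables):
        profile = tables["PD patients"]["B5b"]
        v = exact_carrier(profile)
        partial = dict(v.variants)
        partial.pop(profile.loci[0])
        _, full = mm.assign_haplogroup(v, tables["PD patients"])
        _, part = mm.assign_haplogroup(
            mm.VariantSet("q", partial), tables["PD patients"]
        )
        assert full == 1 and part < 1


class TestAssociateSubset:
    def test_printed_percentages_composition(self, tables, reference):
        """8 G2a carriers + 3 N9b1 carriers + 4 unmatched -> 53% / 20%."""
        table = tables["AD patients"]
        rng = np.random.default_rng(4)
        members = [exact_carrier(table["G2a"], f"g{i}") for i in range(8)]
        members += [exact_carrier(table["N9b1"], f"n{i}") for i in range(3)]
        profile_loci = {e.locus for p in table for e in p}
        for i in range(4):
            locus = int(rng.choice([l for l in range(30, 90)
                                    if l not in profile_loci]))
            allele = next(b for b in "ACGT" if b != reference[locus - 1])
            members.append(mm.VariantSet(f"u{i}", {locus: allele}))
        report = mm.associate_subset(members, table)
        assert report.subset_size == 15
        assert report.percent_of("G2a") == 53
        assert report.percent_of("N9b1") == 20
        assert report.n_unassigned == 4

    def test_uniform_carriers_hundred_percent(self, tables):
        table = tables["T2D patients"]
        members = [exact_carrier(table["D4b2b"], f"c{i}") for i in range(6)]
        report = mm.associate_subset(members, table)
        assert report.entries[0].percent == 100
        assert report.modal_haplogroup == "D4b2b"

    def test_matches_bruteforce_assignment_loop(self, tables):
        # oracle: exhaustive best-ratio matcher, re-derived here
        table = tables["Centenarians"]
        rng = np.random.default_rng(8)
        members = []
        for i in range(20):
            profile = list(table)[rng.integers(0, len(table))]
            calls = {}
            for e in profile:
                if rng.random() < 0.8:
                    calls.setdefault(e.locus, e.mutant_allele)
            if calls:
                members.append(mm.VariantSet(f"m{i}", calls))
        report = mm.associate_subset(members, table, min_fraction=0.5)
        counts = {}
        for m in members:
            best = max(
                (
                    (
                        Fraction(
                            sum(
                                1
                                for e in p
                                if m.variants.get(e.locus) == e.mutant_allele
                            ),
                            p.size,
                        ),
                        p.size,
                        p.haplogroup_name,
                    )
                    for p in table
                ),
                key=lambda t: (t[0], t[1], [-ord(c) for c in t[2]]),
            )
            if best[0] >= Fraction(1, 2):
                counts[best[2]] = counts.get(best[2], 0) + 1
        assert {e.haplogroup_name: e.n_assigned for e in report.entries} == counts

    def test_percent_rounding_half_away(self):
        assert _round_percent(Fraction(8, 15)) == 53
        assert _round_percent(Fraction(3, 15)) == 20
        assert _round_percent(Fraction(1, 8)) == 13
        assert _round_percent(Fraction(1, 200)) == 1  # 0.5 rounds away from zero
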