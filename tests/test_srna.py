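"""Read cleaning, tag collapsing, classification and conserved miRNAs."""

import pytest
from hypothesis import given, strategies as st

from srnapipe._refdata import MATURE_MIRNAS, NCRNA_REFS
from srnapipe.seq import revcomp_rna
from srnapipe.srna import (
    SmallRNATag,
    classify_tags,
    clean_and_collapse,
    family_of,
    identify_conserved_mirnas,
    length_distribution,
    trim_adaptor,
)

ADAPTOR = "TGGAATTCTCGGGTGCCAAGG"
INSERT = "TGACAGAAGAGAGTGAGCACA"  # 21 nt DNA


class TestTrimAdaptor:
    def test_full_adaptor_is_removed(self):
        trimmed, found = trim_adaptor(INSERT + ADAPTOR, ADAPTOR)
        assert trimmed == INSERT and found

    def test_partial_adaptor_prefix_at_three_prime_end(self):
        trimmed, found = trim_adaptor(INSERT + ADAPTOR[:6], ADAPTOR, min_overlap=6)
        assert trimmed == INSERT and found

    def test_overlap_below_minimum_is_not_trimmed(self):
        trimmed, found = trim_adaptor(INSERT + ADAPTOR[:5], ADAPTOR, min_overlap=6)
        assert trimmed == INSERT + ADAPTOR[:5] and not found

    def test_read_without_adaptor_is_kept_whole_and_flagged(self):
        trimmed, found = trim_adaptor(INSERT, ADAPTOR)
        assert trimmed == INSERT and not found

    def test_leftmost_occurrence_wins(self):
        read = "ACGT" + ADAPTOR + "CCCC" + ADAPTOR
        trimmed, found = trim_adaptor(read, ADAPTOR)
        assert trimmed == "ACGT" and found

    def test_empty_read_raises(self):
        with pytest.raises(ValueError, match="empty"):
            trim_adaptor("", ADAPTOR)


class TestCleanCollapse:
    def test_identical_reads_collapse_to_one_tag(self):
        tags, rej = clean_and_collapse([INSERT] * 10)
        assert len(tags) == 1
        assert tags[0].count == 10
        assert tags[0].sequence == INSERT.replace("T", "U")
        assert not rej

    def test_length_and_ambiguity_filters(self):
        reads = ["A" * 15, "C" * 31, "ACGTN" + "A" * 13, "", INSERT]
        tags, rej = clean_and_collapse(reads)
        assert rej == {"too-short": 1, "too-long": 1, "ambiguous-base": 1, "empty": 1}
        assert len(tags) == 1

    @given(
        st.lists(
            st.text(alphabet="ACGTN", min_size=10, max_size=35), min_size=0, max_size=60
        )
    )
    def test_read_counts_are_conserved(self, reads):
        tags, rej = clean_and_collapse(reads)
        assert sum(t.count for t in tags) + sum(rej.values()) == len(reads)

    def test_sorted_by_count_then_sequence(self):
        reads = ["C" * 20] * 2 + ["A" * 20] * 2 + ["G" * 20] * 5
        tags, _ = clean_and_collapse(reads)
        assert [(t.sequence[0], t.count) for t in tags] == [("G", 5), ("A", 2), ("C", 2)]


class TestClassify:
    def test_tag_from_reference_slice_is_classified(self):
        ref_seq = NCRNA_REFS["rRNA"][0][1]
        tag = SmallRNATag(ref_seq[10:31], 4)
        census, labels = classify_tags([tag], NCRNA_REFS)
        assert labels == ["rRNA"]
        assert census.reads == {"rRNA": 4}

    def test_reverse_complement_matches_too(self):
        tag = SmallRNATag(revcomp_rna(NCRNA_REFS["tRNA"][1][1][5:27]), 1)
        _census, labels = classify_tags([tag], NCRNA_REFS)
        assert labels == ["tRNA"]

    def test_multi_category_collision_resolves_by_fixed_priority(self):
        seq = "ACGUACGUACGUACGUACGU"
        refs = {
            "tRNA": [("t", "GGG" + seq + "CCC")],
            "rRNA": [("r", "AAA" + seq + "UUU")],
        }
        for _ in range(3):  # deterministic across repeated calls
            _c, labels = classify_tags([SmallRNATag(seq, 1)], refs)
            assert labels == ["rRNA"]  # rRNA outranks tRNA

    def test_unmatched_tag_is_unannotated_and_census_conserves(self):
        tags = [
            SmallRNATag(NCRNA_REFS["snoRNA"][0][1][:20], 3),
            SmallRNATag("AUGCAUGCAUGCAUGCAUGC", 7),
        ]
        census, labels = classify_tags(tags, NCRNA_REFS)
        assert labels[1] == "unannotated"
        assert census.total_reads() == 10
        assert census.total_tags() == 2

    def test_empty_reference_category_raises(self):
        with pytest.raises(ValueError, match="empty"):
            classify_tags([SmallRNATag("A" * 20, 1)], {"rRNA": []})


class TestLengthDistribution:
    def test_single_length(self):
        tags = [SmallRNATag("A" * 24, 5), SmallRNATag("C" * 24, 5)]
        assert length_distribution(tags) == {24: 1.0}

    def test_count_weighted_fractions(self):
        tags = [SmallRNATag("A" * 21, 3), SmallRNATag("C" * 22, 1)]
        assert length_distribution(tags) == {21: 0.75, 22: 0.25}

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            length_distribution([])


@pytest.mark.parametrize(
    "name,family",
    [
        ("miR166h", "miR166"),
        ("osa-miR156g-3p", "miR156"),
        ("ath-miR166a-5p", "miR166"),
        ("candidate_007", "unknown"),
    ],
)
def test_family_parsing(name, family):
    assert family_of(name) == family


class TestConservedMirnas:
    REF = list(MATURE_MIRNAS.items())

    def test_exact_tag_is_assigned_with_its_full_count(self):
        name, seq = self.REF[0]
        recs = identify_conserved_mirnas([SmallRNATag(seq, 9)], self.REF)
        by_name = {r.name: r.matched_count for r in recs}
        assert by_name[name] == 9
        assert sum(by_name.values()) == 9

    def test_mismatch_outside_seed_is_tolerated(self):
        name, seq = self.REF[1]
        mutated = seq[:14] + ("A" if seq[14] != "A" else "C") + seq[15:]
        recs = identify_conserved_mirnas([SmallRNATag(mutated, 2)], self.REF, max_mismatch=2)
        assert {r.name: r.matched_count for r in recs}[name] == 2

    def test_mismatch_inside_seed_blocks_assignment(self):
        name, seq = self.REF[1]
        mutated = seq[:4] + ("A" if seq[4] != "A" else "C") + seq[5:]  # position 5
        recs = identify_conserved_mirnas([SmallRNATag(mutated, 2)], self.REF, max_mismatch=2)
        assert all(r.matched_count == 0 for r in recs)

    def test_length_overhang_tolerance_is_two(self):
        name, seq = self.REF[2]
        ok = identify_conserved_mirnas([SmallRNATag(seq + "AA", 1)], self.REF)
        too_long = identify_conserved_mirnas([SmallRNATag(seq + "AAA", 1)], self.REF)
        assert {r.name: r.matched_count for r in ok}[name] == 1
        assert all(r.matched_count == 0 for r in too_long)

    def test_order_independence(self):
        tags = [SmallRNATag(s, i + 1) for i, (_n, s) in enumerate(self.REF[:5])]
        fwd = identify_conserved_mirnas(tags, self.REF)
        rev = identify_conserved_mirnas(list(reversed(tags)), self.REF)
        assert [(r.name, r.matched_count) for r in fwd] == [
            (r.name, r.matched_count) for r in rev
        ]

    def test_malformed_reference_record_raises_with_index(self):
        with pytest.raises(ValueError, match="index 1"):
            identify_conserved_mirnas([], [("ok", "ACGU" * 5), ("", "")])
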