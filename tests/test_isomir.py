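import numpy as np
import pytest

from isomirkit.isomir import (
    IsomiRRecord,
    aggregate_mirna,
    classify_alignments,
    classify_modification,
    hairpin_stack_report,
    modification_profile,
    summarize_shifts,
)
from isomirkit.mapper import HairpinAlignment, HairpinIndex, map_read
from isomirkit.preprocess import UniqueRead
from isomirkit.refmodel import Hairpin, MatureAnnotation

RNG = np.random.default_rng(42)
BASES = np.array(list("ACGU"))


def rand_seq(n):
    return "".join(BASES[RNG.integers(0, 4, n)])


@pytest.fixture(scope="module")
def hairpin():
    return Hairpin("hsa-mir-511-1", rand_seq(87))


@pytest.fixture(scope="module")
def annotation(hairpin):
    return MatureAnnotation("hsa-mir-511-1", "hsa-miR-511-5p", "5p", 16, 36)


def aln(hairpin, start, match_len, suffix="", count=1, weight=1.0, lib="n"):
    matched = hairpin.subseq(start, start + match_len - 1)
    return HairpinAlignment(
        read_seq=matched + suffix, count=count, library=lib,
        hairpin_id=hairpin.id, start=start, match_len=match_len,
        mod_suffix=suffix, weight=weight,
    )


@pytest.mark.parametrize(
    "suffix,expected",
    [("A", "A"), ("U", "U"), ("AA", "AA"), ("UU", "UU"), ("AU", "AU"),
     ("C", "C"), ("G", "G"), ("", "none"), ("AGC", "other"), ("UA", "other")],
)
def test_modification_categories(suffix, expected):
    assert classify_modification(suffix) == expected


class TestClassifyAlignments:
    def test_reference_isoform_has_zero_shifts(self, hairpin, annotation):
        records, unassigned = classify_alignments(
            [aln(hairpin, 16, 21)], [annotation], {hairpin.id: hairpin}
        )
        (r,) = records
        assert (r.shift5, r.shift3, r.mod_category) == (0, 0, "none")
        assert r.mature_name == "hsa-miR-511-5p" and not unassigned

    def test_shift_arithmetic(self, hairpin, annotation):
        # start 17, matched end 35: one base in at both ends
        (r,), _ = classify_alignments(
            [aln(hairpin, 17, 19)], [annotation], {hairpin.id: hairpin}
        )
        assert (r.shift5, r.shift3) == (1, -1)

    def test_tail_is_not_a_position_shift(self, hairpin, annotation):
        (r,), _ = classify_alignments(
            [aln(hairpin, 16, 21, suffix="AA")], [annotation], {hairpin.id: hairpin}
        )
        assert (r.shift5, r.shift3, r.mod_category) == (0, 0, "AA")

    def test_opposite_arm_detection_on_single_annotation_hairpin(
        self, hairpin, annotation
    ):
        # reads on the unannotated 3p half become a provisional novel locus
        records, _ = classify_alignments(
            [aln(hairpin, 60, 21, count=9), aln(hairpin, 61, 21, count=2)],
            [annotation],
            {hairpin.id: hairpin},
        )
        assert all(r.opposite_arm for r in records)
        assert {r.mature_name for r in records} == {"hsa-mir-511-1-3p-novel"}
        # shifts are relative to the modal (most abundant) window
        by_count = {r.count: (r.shift5, r.shift3) for r in records}
        assert by_count[9] == (0, 0)
        assert by_count[2] == (1, 1)

    def test_alignment_far_from_annotation_is_unassigned(self, hairpin, annotation):
        records, unassigned = classify_alignments(
            [aln(hairpin, 2, 20)], [annotation], {hairpin.id: hairpin},
            shift_window=5,
        )
        assert records == [] and len(unassigned) == 1

    def test_paralog_alignments_merge_to_one_count(self, hairpin, annotation):
        clone = Hairpin("hsa-mir-511-2", hairpin.seq)
        ann2 = MatureAnnotation("hsa-mir-511-2", "hsa-miR-511-5p", "5p", 16, 36)
        alns = [
            aln(hairpin, 16, 21, count=6, weight=0.5),
            aln(clone, 16, 21, count=6, weight=0.5),
        ]
        records, _ = classify_alignments(
            alns, [annotation, ann2], {h.id: h for h in (hairpin, clone)}
        )
        (r,) = records  # one record; the read counts once for the shared name
        assert r.count == pytest.approx(6.0)


def rec(shift5=0, shift3=0, suffix="", count=1.0, name="m1", opp=False):
    return IsomiRRecord(
        mature_name=name, hairpin_id="h1", arm="5p", shift5=shift5, shift3=shift3,
        mod_suffix=suffix, mod_category=classify_modification(suffix),
        count=count, library="n", opposite_arm=opp,
    )


class TestSummaries:
    def test_degenerate_shift_distribution(self):
        assert summarize_shifts([rec(), rec()], "5p") == {0: 1.0}

    def test_count_weighted_shift_fractions(self):
        records = [rec(shift5=0, count=95), rec(shift5=-1, count=1), rec(shift5=1, count=4)]
        assert summarize_shifts(records, "5p") == pytest.approx(
            {-1: 0.01, 0: 0.95, 1: 0.04}
        )

    def test_shift_fractions_sum_to_one(self):
        records = [rec(shift3=s, count=c) for s, c in [(-2, 3), (0, 11), (2, 5)]]
        assert sum(summarize_shifts(records, "3p").values()) == pytest.approx(1.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            summarize_shifts([], "5p")
        with pytest.raises(ValueError):
            modification_profile([])

    def test_modification_profile_fractions(self):
        records = [rec(count=88), rec(suffix="A", count=8), rec(suffix="U", count=4)]
        profile = modification_profile(records)
        assert profile["modified_fraction"] == pytest.approx(0.12)
        assert profile["A"] == pytest.approx(0.08)
        total = sum(v for k, v in profile.items() if k != "modified_fraction")
        assert total == pytest.approx(1.0)

    def test_no_tails_means_zero_modified_fraction(self):
        assert modification_profile([rec(), rec()])["modified_fraction"] == 0.0


class TestAggregate:
    def test_counts_summed_and_reference_top(self):
        records = [rec(count=10), rec(shift3=-1, count=5)]
        df = aggregate_mirna(records)
        assert df.loc[0, "count"] == 15
        assert bool(df.loc[0, "reference_most_abundant"])

    def test_reference_not_always_most_abundant(self):
        records = [rec(count=3), rec(shift5=1, count=9)]
        df = aggregate_mirna(records)
        assert not bool(df.loc[0, "reference_most_abundant"])

    def test_empty_gives_empty_table(self):
        assert len(aggregate_mirna([])) == 0

    def test_aggregation_conserves_counts(self):
        records = [rec(count=2.5, name="a"), rec(count=1.5, name="a"),
                   rec(count=4, name="b", shift3=1)]
        df = aggregate_mirna(records)
        assert df["count"].sum() == pytest.approx(8.0)


def test_identity_path_exact_mature_read_gives_reference_isoform(hairpin, annotation):
    """Mapping an unmutated mature sequence must return shift (0,0), no tail."""
    read = UniqueRead(hairpin.subseq(annotation.start, annotation.end), 5, "n")
    alns = map_read(read, HairpinIndex([hairpin]))
    records, _ = classify_alignments(alns, [annotation], {hairpin.id: hairpin})
    (r,) = records
    assert (r.shift5, r.shift3, r.mod_category, r.opposite_arm) == (0, 0, "none", False)


def test_hairpin_stack_report_shows_counts_shifts_and_lowercase_tail(hairpin, annotation):
    report = hairpin_stack_report(
        hairpin, [annotation], [aln(hairpin, 16, 21, suffix="AA", count=7)]
    )
    assert "5p:16-36" in report
    assert "+0,+0" in report and "aa" in report and "7" in report
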