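import pytest

from isomirkit.refmodel import (
    Hairpin,
    MatureAnnotation,
    ReferenceSet,
    infer_arm,
    locate_mature_by_sequence,
    read_hairpin_fasta,
    read_mature_annotations,
    validate_annotations,
    write_hairpin_fasta,
)

HP60_DNA = "ACGT" * 15  # 60 nt, DNA alphabet
HP87 = (
    "GCGGGUGCUCUGCUGGUCUUCUCUCCAGUGUGAUCCUGAUGCAGUCAUAAGCAGGAUCACAC"
    "UGGAGGAGAAGACCAGCAGAGCGCC"
)  # 87 nt


def write_fasta(path, records):
    with open(path, "w") as fh:
        for name, seq in records:
            fh.write(f">{name}\n{seq}\n")


class TestHairpin:
    def test_dna_input_is_normalized_to_rna_uppercase(self, tmp_path):
        p = tmp_path / "h.fa"
        write_fasta(p, [("h1", HP60_DNA.lower())])
        (hp,) = read_hairpin_fasta(p)
        assert hp.seq == "ACGU" * 15
        assert hp.length == 60

    def test_duplicate_id_is_an_error(self, tmp_path):
        p = tmp_path / "h.fa"
        write_fasta(p, [("h1", HP60_DNA), ("h1", HP87)])
        with pytest.raises(ValueError, match="duplicate"):
            read_hairpin_fasta(p)

    def test_empty_file_gives_empty_collection(self, tmp_path):
        p = tmp_path / "h.fa"
        p.write_text("")
        assert read_hairpin_fasta(p) == []

    def test_non_nucleotide_character_is_an_error(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            Hairpin(id="bad", seq="ACGX" * 15)

    def test_too_short_hairpin_rejected(self):
        with pytest.raises(ValueError, match="length"):
            Hairpin(id="short", seq="ACGU" * 5)

    def test_fasta_round_trip_preserves_objects(self, tmp_path):
        hps = [Hairpin("h1", HP60_DNA), Hairpin("h2", HP87)]
        out = tmp_path / "rt.fa"
        write_hairpin_fasta(hps, out)
        assert read_hairpin_fasta(out) == hps


class TestAnnotations:
    def test_coordinates_match_the_convention(self, tmp_path):
        # a mature spanning nucleotides 16..36 of its hairpin, 1-based inclusive
        hp = Hairpin("hsa-mir-511-1", HP87)
        p = tmp_path / "ann.tsv"
        p.write_text(
            "hairpin_id\tmature_name\tarm\tstart\tend\n"
            "hsa-mir-511-1\thsa-miR-511-5p\t5p\t16\t36\n"
        )
        (ann,) = read_mature_annotations(p, [hp])
        assert (ann.start, ann.end, ann.arm) == (16, 36, "5p")
        assert ann.length == 21

    def test_end_beyond_hairpin_length_is_an_error(self, tmp_path):
        hp = Hairpin("h1", HP60_DNA)
        p = tmp_path / "ann.tsv"
        p.write_text(
            "hairpin_id\tmature_name\tarm\tstart\tend\nh1\tm1\t5p\t50\t70\n"
        )
        with pytest.raises(ValueError, match="beyond"):
            read_mature_annotations(p, [hp])

    def test_unknown_hairpin_is_an_error(self, tmp_path):
        p = tmp_path / "ann.tsv"
        p.write_text("hairpin_id\tmature_name\tarm\tstart\tend\nnope\tm1\t5p\t16\t36\n")
        with pytest.raises(ValueError, match="unknown hairpin"):
            read_mature_annotations(p, [Hairpin("h1", HP60_DNA)])

    def test_duplicate_hairpin_arm_pair_is_an_error(self):
        hp = Hairpin("h1", HP87)
        anns = [
            MatureAnnotation("h1", "m1", "5p", 16, 36),
            MatureAnnotation("h1", "m2", "5p", 14, 34),
        ]
        with pytest.raises(ValueError, match="duplicate"):
            validate_annotations(anns, [hp])

    @pytest.mark.parametrize(
        "start,end", [(0, 20), (20, 20), (1, 10), (1, 40)]
    )
    def test_invalid_intervals_rejected(self, start, end):
        with pytest.raises(ValueError):
            MatureAnnotation("h1", "m1", "5p", start, end)


class TestLocateMatureBySequence:
    def test_exact_substring_yields_annotation_and_5p_arm(self, tmp_path):
        hp = Hairpin("h1", HP87)
        mature = hp.subseq(16, 36)
        p = tmp_path / "m.fa"
        write_fasta(p, [("m-5p", mature)])
        (ann,) = locate_mature_by_sequence(p, [hp])
        assert (ann.start, ann.end, ann.arm) == (16, 36, "5p")
        # the located window extracts exactly the input mature
        assert hp.subseq(ann.start, ann.end) == mature

    def test_3p_half_midpoint_infers_3p_arm(self, tmp_path):
        hp = Hairpin("h1", HP87)
        mature = hp.subseq(62, 83)
        p = tmp_path / "m.fa"
        write_fasta(p, [("m-3p", mature)])
        (ann,) = locate_mature_by_sequence(p, [hp])
        assert ann.arm == "3p"

    def test_unmatched_mature_is_skipped_with_warning(self, tmp_path, caplog):
        p = tmp_path / "m.fa"
        write_fasta(p, [("ghost", "UUUAAACCCGGGUUUAAACCC")])
        import logging

        with caplog.at_level(logging.WARNING):
            anns = locate_mature_by_sequence(p, [Hairpin("h1", HP87)])
        assert anns == []
        assert "ghost" in caplog.text

    def test_ambiguous_position_is_an_error(self, tmp_path):
        # the mature occurs twice within one hairpin
        mature = "ACGUACGUACGUACGUACGU"
        hp = Hairpin("h1", mature + "CCCCCAAAAA" + mature)
        p = tmp_path / "m.fa"
        write_fasta(p, [("m1", mature)])
        with pytest.raises(ValueError, match="multiple positions"):
            locate_mature_by_sequence(p, [hp])


def test_infer_arm_uses_hairpin_midpoint():
    hp = Hairpin("h1", "A" * 35 + "C" * 5 + "G" * 40)  # length 80
    assert infer_arm(hp, 5, 26) == "5p"
    assert infer_arm(hp, 55, 76) == "3p"


def test_reference_set_rejects_unknown_class_and_empty_sets():
    with pytest.raises(ValueError):
        ReferenceSet(class_label="lncRNA", sequences=[("a", "ACGU")])
    with pytest.raises(ValueError):
        ReferenceSet(class_label="tRNA", sequences=[])
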