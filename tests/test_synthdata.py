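import numpy as np
import pytest

from isomirkit import pipeline
from isomirkit.mapper import HairpinIndex, map_read
from isomirkit.preprocess import UniqueRead
from isomirkit.synthdata import (
    SynthConfig,
    generate_paired_study,
    generate_references,
    save_study,
    study_config,
)


class TestReferences:
    def test_deterministic_under_seed(self):
        cfg = study_config(seed=3, n_reads=1000)
        a = generate_references(cfg)
        b = generate_references(cfg)
        assert [h.seq for h in a.hairpins] == [h.seq for h in b.hairpins]
        assert a.annotations == b.annotations

    def test_both_arms_annotated_unless_single_arm(self):
        cfg = SynthConfig(seed=0, n_hairpins=10, n_single_arm=0)
        refs = generate_references(cfg)
        assert len(refs.annotations) == 20

    def test_single_arm_hairpins_lack_3p_annotation(self):
        cfg = study_config(seed=0, n_reads=1000, n_single_arm=2)
        refs = generate_references(cfg)
        ann_3p = {a.hairpin_id for a in refs.annotations if a.arm == "3p"}
        assert "syn-mir-029" not in ann_3p and "syn-mir-030" not in ann_3p
        # but the arm is still transcribed (a window exists)
        assert "syn-miR-030-3p" in refs.mature_windows

    def test_hairpin_lengths_within_configured_range(self):
        cfg = SynthConfig(seed=2, n_hairpins=12, hairpin_len_range=(64, 72))
        refs = generate_references(cfg)
        assert all(64 <= h.length <= 72 for h in refs.hairpins)

    def test_no_repeated_18mer_across_references(self):
        refs = generate_references(SynthConfig(seed=4, n_hairpins=15))
        seen = set()
        pool = [h.seq for h in refs.hairpins] + [
            s for rs in refs.reference_sets for _, s in rs.sequences
        ] + refs.unknown_pool
        for seq in pool:
            for i in range(len(seq) - 17):
                kmer = seq[i : i + 18]
                assert kmer not in seen
                seen.add(kmer)

    def test_infeasible_length_range_is_an_error(self):
        with pytest.raises(ValueError, match="len_range"):
            SynthConfig(hairpin_len_range=(45, 50)).validate()

    def test_mis_normalized_law_is_an_error(self):
        cfg = SynthConfig(shift5_law={0: 0.9, 1: 0.2})
        with pytest.raises(ValueError, match="sum"):
            cfg.validate()


class TestStudyGeneration:
    def test_byte_identical_reads_and_truth_under_fixed_seed(self):
        cfg = study_config(seed=5, n_reads=2000)
        s1 = generate_paired_study(cfg)
        s2 = generate_paired_study(cfg)
        assert s1.reads == s2.reads
        assert s1.truth.equals(s2.truth)

    def test_truth_join_completeness(self, small_study):
        cfg, study = small_study
        assert len(study.truth) == 2 * cfg.n_reads
        for lib in cfg.libraries:
            assert len(study.reads[lib]) == (study.truth.library == lib).sum()

    def test_zero_tailing_probability_emits_no_tails(self):
        cfg = study_config(seed=6, n_reads=3000,
                           tailing_prob={"normal": 0.0, "tumor": 0.0})
        study = generate_paired_study(cfg)
        assert (study.truth.tail_seq == "").all()

    def test_point_mass_shift_laws_give_exact_matures(self):
        cfg = study_config(seed=6, n_reads=2000, shift5_law={0: 1.0},
                           shift3_law={0: 1.0},
                           tailing_prob={"normal": 0.0, "tumor": 0.0})
        study = generate_paired_study(cfg)
        mirna = study.truth[study.truth.source_class == "miRNA"]
        windows = study.references.mature_windows
        hp = {h.id: h for h in study.references.hairpins}
        for name, grp in mirna.groupby("mature_name"):
            hid, _arm, start, end = windows[name]
            expected = hp[hid].subseq(start, end)
            assert (grp.clean_seq == expected).all()

    def test_class_counts_follow_configured_proportions(self, small_study):
        cfg, study = small_study
        for lib in cfg.libraries:
            t = study.truth[study.truth.library == lib]
            fracs = t.source_class.value_counts(normalize=True)
            for label, p in cfg.class_proportions[lib].items():
                assert abs(fracs.get(label, 0.0) - p) < 0.02

    def test_tail_first_base_never_matches_next_templated_base(self, small_study):
        _cfg, study = small_study
        hp = {h.id: h for h in study.references.hairpins}
        windows = study.references.mature_windows
        tailed = study.truth[(study.truth.tail_seq != "")].head(500)
        for row in tailed.itertuples():
            _hid, _arm, start, end = windows[row.mature_name]
            w_end = end + int(row.shift3)
            seq = hp[row.hairpin_id].seq
            if w_end < len(seq):
                assert row.tail_seq[0] != seq[w_end]


def test_paralog_family_splits_weights_and_counts_once():
    cfg = study_config(seed=9, n_reads=1000, n_paralog_copies=3)
    refs = generate_references(cfg)
    index = HairpinIndex(refs.hairpins)
    hid, _arm, start, end = refs.mature_windows["syn-miR-001-5p"]
    hp = next(h for h in refs.hairpins if h.id == hid)
    read = UniqueRead(hp.subseq(start, end), 6, "normal")
    alns = map_read(read, index)
    assert len(alns) == 3  # prototype plus two clones
    assert all(a.weight == pytest.approx(1 / 3) for a in alns)
    from isomirkit.isomir import classify_alignments

    records, _ = classify_alignments(alns, refs.annotations, index.hairpins)
    assert sum(r.count for r in records) == pytest.approx(6.0)
    assert len(records) == 1  # shared mature name: the read counts once


def test_save_study_writes_all_artifacts(tmp_path):
    cfg = study_config(seed=8, n_reads=500)
    study = generate_paired_study(cfg)
    save_study(study, tmp_path)
    for fname in ("normal.fastq", "tumor.fastq", "hairpins.fasta",
                  "annotations.tsv", "truth.tsv", "config.yaml",
                  "ref_tRNA.fasta", "ref_other_ncRNA.fasta"):
        assert (tmp_path / fname).exists(), fname
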