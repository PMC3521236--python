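"""Synthetic paired small-RNA study generator with per-read ground truth.

Builds a complete two-library (normal/tumor) study — hairpin references,
mature annotations, contaminant reference sets and raw reads — whose
statistical structure follows the published breast-tissue study conditions
bundled in :mod:`isomirkit.datasets`: the clean-read class composition, the
5'/3' isomiR position-shift spectra, the 3'-tailing rate and composition,
designated fold-change multipliers and per-library 5p:3p arm ratios. Every
emitted read carries a truth row, so pipeline recovery can be checked
against the generating distributions.

Design points that make truth assignment unambiguous:

* no 18-mer occurs twice across hairpins, contaminant references and unknown
  reads, so the >= 18-nt exact mapper has a unique hit unless a paralog
  family is explicitly requested;
* the first base of a 3' tail always differs from the next templated hairpin
  base, so the mapper never absorbs a tail base into the template match;
* random sequences never contain the adapter's seed prefix, so adapter
  trimming always cuts exactly at the insert/adapter junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import datasets
from .refmodel import (
    CASCADE_CLASSES,
    Hairpin,
    MatureAnnotation,
    ReferenceSet,
    normalize_rna,
    write_hairpin_fasta,
    write_mature_annotations,
)

_BASES = np.array(list("ACGU"))
_OTHER_TAILS = ("AG", "GA", "CU", "UC", "CA", "GC")
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"  # Illumina small-RNA 3' adapter


def _check_law(name: str, law: Mapping) -> None:
    total = sum(law.values())
    if abs(total - 1.0) > 1e-9:
        raise ValueError(f"{name} probabilities sum to {total}, not 1")


@dataclass
class SynthConfig:
    """All knobs of the generator; defaults are the emulated study conditions."""

    seed: int = 0
    n_hairpins: int = 30
    hairpin_len_range: tuple[int, int] = (64, 90)
    n_reads: int = 100_000  # per library
    libraries: tuple[str, str] = ("normal", "tumor")
    class_proportions: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in datasets.CLASS_PROPORTIONS.items()}
    )
    shift5_law: dict = field(default_factory=lambda: dict(datasets.SHIFT5_LAW))
    shift3_law: dict = field(default_factory=lambda: dict(datasets.SHIFT3_LAW))
    tailing_prob: dict = field(default_factory=lambda: dict(datasets.TAILING_PROB))
    tail_composition: dict = field(default_factory=lambda: dict(datasets.TAIL_COMPOSITION))
    expression_sigma: float = 1.2  # log-normal spread of per-hairpin expression
    #: mature name -> target tumor/normal TPM ratio
    fc_multipliers: dict = field(default_factory=dict)
    #: hairpin id -> {library: 5p/3p ratio}; hairpins not listed get one
    #: intrinsic ratio shared by both libraries
    arm_ratios: dict = field(default_factory=dict)
    arm_ratio_log2_sd: float = 1.0
    n_single_arm: int = 2  # hairpins annotated on the 5p arm only
    single_arm_opposite_ratio: float = 0.5  # 5p:3p ratio of those hairpins
    designated_expression: float = 2.0  # fixed expression of DE / arm-switch hairpins
    n_paralog_copies: int = 0  # >=2 clones hairpin 1 into a paralog family
    adapter: str = DEFAULT_ADAPTER
    n_refs_per_class: int = 4
    ref_len_range: tuple[int, int] = (120, 300)
    contaminant_read_len: tuple[int, int] = (18, 28)

    def validate(self) -> None:
        for lib, props in self.class_proportions.items():
            _check_law(f"class_proportions[{lib}]", props)
        _check_law("shift5_law", self.shift5_law)
        _check_law("shift3_law", self.shift3_law)
        _check_law("tail_composition", self.tail_composition)
        if self.hairpin_len_range[0] < 54:
            raise ValueError("hairpin_len_range lower bound must be >= 54 to fit two arms")
        if self.n_single_arm + 6 > self.n_hairpins:
            raise ValueError("too few hairpins for the designated roles")


def study_config(seed: int = 0, n_reads: int = 100_000, **overrides) -> SynthConfig:
    """The default study: designated arm-switch hairpins and DE matures.

    Hairpins 1-2 carry the examined per-library arm ratios (233:341 vs
    317:91, and 99:72 vs 107:308); matures on hairpins 3-6 carry fold-change
    multipliers 9.88, 2.90, 0.49 and 0.15. The last ``n_single_arm``
    hairpins are annotated 5p-only but transcribe both arms, emulating
    opposite-arm detection.
    """
    cfg = SynthConfig(
        seed=seed,
        n_reads=n_reads,
        arm_ratios={
            "syn-mir-001": {"normal": 233 / 341, "tumor": 317 / 91},
            "syn-mir-002": {"normal": 99 / 72, "tumor": 107 / 308},
        },
        fc_multipliers={
            "syn-miR-003-5p": 9.88,
            "syn-miR-004-5p": 2.90,
            "syn-miR-005-3p": 0.49,
            "syn-miR-006-5p": 0.15,
        },
        **overrides,
    )
    cfg.validate()
    return cfg


@dataclass
class SynthReferences:
    hairpins: list[Hairpin]
    annotations: list[MatureAnnotation]
    #: every transcribed mature window, annotated or not:
    #: name -> (hairpin_id, arm, start, end)
    mature_windows: dict[str, tuple[str, str, int, int]]
    reference_sets: list[ReferenceSet]
    unknown_pool: list[str]
    base_expression: dict[str, float]  # per hairpin
    arm_ratio: dict[str, dict[str, float]]  # hairpin -> library -> 5p/3p
    paralog_groups: dict[str, list[str]]  # mature name -> hairpin ids


@dataclass
class SynthStudy:
    config: SynthConfig
    references: SynthReferences
    reads: dict[str, list[str]]  # library -> raw reads (DNA, adapter attached)
    truth: pd.DataFrame  # one row per emitted read


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _fresh_seq(
    rng: np.random.Generator, length: int, kmer_bank: set[str], forbidden: str,
    k: int = 18, tries: int = 200,
) -> str:
    """A random sequence sharing no k-mer with anything generated before."""
    for _ in range(tries):
        s = _random_seq(rng, length)
        if forbidden in s:
            continue
        kmers = {s[i : i + k] for i in range(max(0, len(s) - k + 1))}
        if len(s) >= k and (kmers & kmer_bank or len(kmers) < len(s) - k + 1):
            continue
        kmer_bank |= kmers
        return s
    raise RuntimeError("could not generate a non-repetitive sequence; constraints infeasible")


def generate_references(config: SynthConfig) -> SynthReferences:
    """Hairpins with annotated arms, contaminant reference sets, unknown pool."""
    config.validate()
    master = np.random.default_rng(config.seed)
    rng = master.spawn(1)[0]
    adapter_seed = normalize_rna(config.adapter)[:6]
    bank: set[str] = set()

    lo, hi = config.hairpin_len_range
    hairpins: list[Hairpin] = []
    annotations: list[MatureAnnotation] = []
    windows: dict[str, tuple[str, str, int, int]] = {}
    arm_ratio: dict[str, dict[str, float]] = {}
    base_expr: dict[str, float] = {}
    paralog_groups: dict[str, list[str]] = {}
    designated = set()

    single_arm_start = config.n_hairpins - config.n_single_arm
    for i in range(config.n_hairpins):
        hid = f"syn-mir-{i + 1:03d}"
        L = int(rng.integers(lo, hi + 1))
        seq = _fresh_seq(rng, L, bank, adapter_seed)
        while True:
            start5 = int(rng.integers(6, 11))
            d3 = int(rng.integers(4, 8))
            end5 = start5 + 21
            start3, end3 = L - d3 - 21, L - d3
            if start3 >= end5 + 2:
                break
        hairpins.append(Hairpin(id=hid, seq=seq))
        name5, name3 = f"syn-miR-{i + 1:03d}-5p", f"syn-miR-{i + 1:03d}-3p"
        windows[name5] = (hid, "5p", start5, end5)
        windows[name3] = (hid, "3p", start3, end3)
        annotations.append(MatureAnnotation(hid, name5, "5p", start5, end5))
        if i < single_arm_start:
            annotations.append(MatureAnnotation(hid, name3, "3p", start3, end3))

        # expression and per-library arm usage
        # designated hairpins get a fixed, comfortably-sampled expression so
        # their fold-change / arm-ratio estimates are not depth-starved
        e = float(np.exp(rng.normal(0.0, config.expression_sigma)))
        if hid in config.arm_ratios or name5 in config.fc_multipliers or \
                name3 in config.fc_multipliers:
            e = config.designated_expression
            designated.add(hid)
        base_expr[hid] = e
        if hid in config.arm_ratios:
            arm_ratio[hid] = dict(config.arm_ratios[hid])
        elif i >= single_arm_start:
            r = config.single_arm_opposite_ratio
            arm_ratio[hid] = {lib: r for lib in config.libraries}
        else:
            r = float(2.0 ** rng.normal(0.0, config.arm_ratio_log2_sd))
            arm_ratio[hid] = {lib: r for lib in config.libraries}

    # optional paralog family: exact clones of hairpin 1 sharing mature names
    if config.n_paralog_copies >= 2:
        proto = hairpins[0]
        name5 = "syn-miR-001-5p"
        name3 = "syn-miR-001-3p"
        paralog_groups = {name5: [proto.id], name3: [proto.id]}
        for j in range(2, config.n_paralog_copies + 1):
            hid = f"{proto.id}-copy{j}"
            hairpins.append(Hairpin(id=hid, seq=proto.seq))
            _, _, s5, e5 = windows[name5]
            _, _, s3, e3 = windows[name3]
            annotations.append(MatureAnnotation(hid, name5, "5p", s5, e5))
            if 0 < single_arm_start:
                annotations.append(MatureAnnotation(hid, name3, "3p", s3, e3))
            paralog_groups[name5].append(hid)
            paralog_groups[name3].append(hid)

    reference_sets = []
    rlo, rhi = config.ref_len_range
    for label in CASCADE_CLASSES:
        seqs = [
            (f"{label.replace(' ', '_')}-ref-{j + 1}",
             _fresh_seq(rng, int(rng.integers(rlo, rhi + 1)), bank, adapter_seed))
            for j in range(config.n_refs_per_class)
        ]
        reference_sets.append(ReferenceSet(class_label=label, sequences=seqs))

    clo, chi = config.contaminant_read_len
    unknown_pool = [
        _fresh_seq(rng, int(rng.integers(clo, chi + 1)), bank, adapter_seed)
        for _ in range(120)
    ]

    return SynthReferences(
        hairpins=hairpins,
        annotations=annotations,
        mature_windows=windows,
        reference_sets=reference_sets,
        unknown_pool=unknown_pool,
        base_expression=base_expr,
        arm_ratio=arm_ratio,
        paralog_groups=paralog_groups,
    )


def _mature_probs(config: SynthConfig, refs: SynthReferences) -> dict[str, dict[str, float]]:
    """Per-library sampling probabilities over mature windows.

    Tumor probabilities of matures with a configured fold-change multiplier
    are solved so that the *expected TPM ratio* equals the multiplier:
    p_T(m) = mult * (f_N / f_T) * p_N(m), with f the per-library miRNA
    class fraction; the remaining mass is shared by the other matures in
    proportion to their intrinsic weights.
    """
    lib_n, lib_t = config.libraries
    weights: dict[str, dict[str, float]] = {lib: {} for lib in config.libraries}
    for name, (hid, arm, _s, _e) in refs.mature_windows.items():
        if hid.endswith(tuple(f"-copy{j}" for j in range(2, 10))):
            continue  # paralog copies share their prototype's mature name
        e = refs.base_expression[hid]
        for lib in config.libraries:
            r = refs.arm_ratio[hid][lib]
            share = r / (1.0 + r) if arm == "5p" else 1.0 / (1.0 + r)
            weights[lib][name] = e * share
    p_n = {m: w / sum(weights[lib_n].values()) for m, w in weights[lib_n].items()}
    raw_t = weights[lib_t]
    f_n = config.class_proportions[lib_n]["miRNA"]
    f_t = config.class_proportions[lib_t]["miRNA"]
    p_t: dict[str, float] = {}
    for m, mult in config.fc_multipliers.items():
        if m not in p_n:
            raise ValueError(f"fc multiplier for unknown mature {m!r}")
        p_t[m] = mult * (f_n / f_t) * p_n[m]
    de_mass = sum(p_t.values())
    if de_mass >= 0.9:
        raise ValueError("designated DE matures absorb too much probability mass")
    rest = [m for m in p_n if m not in p_t]
    rest_total = sum(raw_t[m] for m in rest)
    for m in rest:
        p_t[m] = (1.0 - de_mass) * raw_t[m] / rest_total
    return {lib_n: p_n, lib_t: p_t}


def _draw_tail(
    rng: np.random.Generator, composition: dict, next_base: str | None
) -> tuple[str, str]:
    """Draw a (category, tail sequence) whose first base != next_base."""
    cats = list(composition)
    probs = np.array([composition[c] for c in cats])
    probs = probs / probs.sum()
    for _ in range(100):
        cat = cats[int(rng.choice(len(cats), p=probs))]
        tail = _OTHER_TAILS[int(rng.integers(len(_OTHER_TAILS)))] if cat == "other" else cat
        if next_base is None or tail[0] != next_base:
            return cat, tail
    raise RuntimeError("cannot draw a tail differing from the templated base")


def generate_library(
    config: SynthConfig,
    refs: SynthReferences,
    library: str,
    mature_probs: Mapping[str, float],
    rng: np.random.Generator,
) -> tuple[list[str], pd.DataFrame]:
    """Emit one library's raw reads (DNA, adapter appended) plus truth rows."""
    props = config.class_proportions[library]
    class_order = list(props)
    counts = rng.multinomial(config.n_reads, [props[c] for c in class_order])
    adapter = config.adapter.upper().replace("U", "T")
    hp_by_id = {h.id: h for h in refs.hairpins}

    reads: list[str] = []
    truth: dict[str, list] = {
        "library": [], "clean_seq": [], "source_class": [], "mature_name": [],
        "hairpin_id": [], "arm": [], "shift5": [], "shift3": [],
        "tail_seq": [], "tail_category": [],
    }

    def emit(clean: str, source: str, name="", hid="", arm="",
             s5=np.nan, s3=np.nan, tail="", cat="") -> None:
        reads.append(clean.replace("U", "T") + adapter)
        truth["library"].append(library)
        truth["clean_seq"].append(clean)
        truth["source_class"].append(source)
        truth["mature_name"].append(name)
        truth["hairpin_id"].append(hid)
        truth["arm"].append(arm)
        truth["shift5"].append(s5)
        truth["shift3"].append(s3)
        truth["tail_seq"].append(tail)
        truth["tail_category"].append(cat)

    for label, n_class in zip(class_order, counts):
        if n_class == 0:
            continue
        if label == "miRNA":
            _emit_mirna_reads(config, refs, library, mature_probs, rng,
                              int(n_class), hp_by_id, emit)
        elif label == "unknown":
            _emit_pool_reads(rng, int(n_class), refs.unknown_pool, "unknown", emit)
        else:
            rs = next(r for r in refs.reference_sets if r.class_label == label)
            pool = _species_pool(rng, rs, int(n_class), config.contaminant_read_len)
            _emit_pool_reads(rng, int(n_class), pool, label, emit)

    return reads, pd.DataFrame(truth)


def _species_pool(
    rng: np.random.Generator, rs: ReferenceSet, n_class: int,
    len_range: tuple[int, int],
) -> list[str]:
    """Distinct read species (reference substrings) for one contaminant class.

    The pool size scales with the class read count so that each species'
    expected multiplicity stays well above the count >= 2 clean-read filter.
    """
    n_species = max(3, min(60, n_class // 15))
    lo, hi = len_range
    pool: list[str] = []
    seen: set[str] = set()
    while len(pool) < n_species:
        _sid, seq = rs.sequences[int(rng.integers(len(rs.sequences)))]
        ln = int(rng.integers(lo, hi + 1))
        start = int(rng.integers(0, len(seq) - ln + 1))
        s = seq[start : start + ln]
        if s not in seen:
            seen.add(s)
            pool.append(s)
    return pool


def _emit_pool_reads(rng, n_class: int, pool: Sequence[str], label: str, emit) -> None:
    n_use = max(3, min(len(pool), n_class // 15))
    idx = rng.integers(0, n_use, size=n_class)
    for i in idx:
        emit(pool[int(i)], label)


def _emit_mirna_reads(config, refs, library, mature_probs, rng, n_class,
                      hp_by_id, emit) -> None:
    names = sorted(mature_probs)
    probs = np.array([mature_probs[m] for m in names])
    per_mature = rng.multinomial(n_class, probs / probs.sum())
    s5_vals = np.array(sorted(config.shift5_law))
    s5_p = np.array([config.shift5_law[v] for v in s5_vals], dtype=float)
    s3_vals = np.array(sorted(config.shift3_law))
    s3_p = np.array([config.shift3_law[v] for v in s3_vals], dtype=float)
    tail_p = config.tailing_prob[library]

    for name, n_m in zip(names, per_mature):
        if n_m == 0:
            continue
        hid, arm, start, end = refs.mature_windows[name]
        hp = hp_by_id[hid]
        s5s = rng.choice(s5_vals, size=n_m, p=s5_p / s5_p.sum())
        s3s = rng.choice(s3_vals, size=n_m, p=s3_p / s3_p.sum())
        tailed = rng.random(n_m) < tail_p
        for s5, s3, has_tail in zip(s5s, s3s, tailed):
            w_start, w_end = start + int(s5), end + int(s3)
            window = hp.subseq(w_start, w_end)
            tail = cat = ""
            if has_tail:
                nxt = hp.seq[w_end] if w_end < hp.length else None
                cat, tail = _draw_tail(rng, config.tail_composition, nxt)
            emit(window + tail, "miRNA", name, hid, arm, int(s5), int(s3), tail, cat)


def generate_paired_study(config: SynthConfig) -> SynthStudy:
    """Generate references and both libraries; deterministic under the seed."""
    config.validate()
    refs = generate_references(config)
    probs = _mature_probs(config, refs)
    master = np.random.default_rng(config.seed)
    _ref_rng, *lib_rngs = master.spawn(1 + len(config.libraries))
    all_reads: dict[str, list[str]] = {}
    truths = []
    for lib, rng in zip(config.libraries, lib_rngs):
        reads, truth = generate_library(config, refs, lib, probs[lib], rng)
        all_reads[lib] = reads
        truths.append(truth)
    return SynthStudy(
        config=config, references=refs, reads=all_reads,
        truth=pd.concat(truths, ignore_index=True),
    )


def expected_fc(config: SynthConfig, mature_name: str) -> float:
    """The TPM ratio a designated DE mature was generated to have."""
    return config.fc_multipliers[mature_name]


def save_study(study: SynthStudy, outdir: str | Path) -> None:
    """Write FASTQ per library, reference FASTA/TSV, truth TSV and config."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for lib, reads in study.reads.items():
        with open(out / f"{lib}.fastq", "w") as fh:
            for i, seq in enumerate(reads, 1):
                fh.write(f"@{lib}_{i:07d}\n{seq}\n+\n{'I' * len(seq)}\n")
    write_hairpin_fasta(study.references.hairpins, out / "hairpins.fasta")
    write_mature_annotations(study.references.annotations, out / "annotations.tsv")
    for rs in study.references.reference_sets:
        fname = f"ref_{rs.class_label.replace(' ', '_')}.fasta"
        with open(out / fname, "w") as fh:
            for sid, seq in rs.sequences:
                fh.write(f">{sid}\n{seq}\n")
    study.truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    cfg = {
        k: (dict(v) if isinstance(v, dict) else list(v) if isinstance(v, tuple) else v)
        for k, v in vars(study.config).items()
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
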