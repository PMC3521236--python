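"""End-to-end orchestration: clean reads -> mapping -> isomiRs -> reports.

Two entry points:

* :func:`analyze_study` — in-memory API over raw read lists; returns a
  :class:`StudyResult` holding every stage's output (used by tests and the
  simulation-recovery workflow).
* :func:`run` — file-driven pipeline configured by a YAML file; emits the
  tabular reports (per-library summary, class fractions, isomiR tables,
  shift/modification profiles, fold-change and arm-usage tables) plus a
  manifest echoing every parameter and stage row counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import quantify
from .cascade import (
    ALL_CLASSES,
    CascadeClassifier,
    ClassAssignment,
    DEFAULT_ORDER,
    summarize_categories,
    write_category_tsv,
)
from .isomir import (
    IsomiRRecord,
    aggregate_mirna,
    classify_alignments,
    modification_profile,
    summarize_shifts,
    write_isomir_tsv,
)
from .mapper import (
    HairpinAlignment,
    HairpinIndex,
    map_library,
    mapped_read_count,
    write_alignments_tsv,
)
from .preprocess import RawRead, UniqueRead, preprocess_library, read_fastx
from .refmodel import (
    Hairpin,
    MatureAnnotation,
    ReferenceSet,
    read_hairpin_fasta,
    read_mature_annotations,
    read_reference_fasta,
)

logger = logging.getLogger(__name__)


@dataclass
class AnalysisParams:
    """Every threshold of the pipeline, with the documented defaults."""

    adapter: str | None = None  # None: reads are already trimmed
    min_overlap: int = 6
    min_count: int = 2
    min_len: int = 18
    max_len: int = 30
    shift_window: int = 5
    fc_pseudo: float = 0.0
    cascade_order: tuple = DEFAULT_ORDER
    libraries: tuple[str, str] = ("normal", "tumor")


@dataclass
class LibraryResult:
    library: str
    clean_reads: list[UniqueRead]
    alignments: list[HairpinAlignment]
    unmapped: list[UniqueRead]
    records: list[IsomiRRecord]
    unassigned: list[HairpinAlignment]
    assignments: list[ClassAssignment]
    summary: dict[str, float]
    class_fractions: dict[str, float]
    shift5: dict[int, float]
    shift3: dict[int, float]
    mod_profile: dict[str, float]


@dataclass
class StudyResult:
    libraries: dict[str, LibraryResult]
    aggregated: pd.DataFrame  # per (mature, library) counts
    expression: pd.DataFrame  # with TPM per library
    fold_changes: pd.DataFrame
    arm_usage: pd.DataFrame
    params: AnalysisParams = field(default_factory=AnalysisParams)


def analyze_library(
    raw_reads: Sequence[str] | Sequence[RawRead],
    library: str,
    hairpins: Sequence[Hairpin],
    annotations: Sequence[MatureAnnotation],
    classifier: CascadeClassifier | None,
    params: AnalysisParams,
    index: HairpinIndex | None = None,
) -> LibraryResult:
    """Run one library through trim/collapse/filter, mapping and classification."""
    raw = [
        r if isinstance(r, RawRead) else RawRead(seq=r, library=library)
        for r in raw_reads
    ]
    clean = preprocess_library(
        raw, adapter=params.adapter, min_overlap=params.min_overlap,
        min_count=params.min_count, min_len=params.min_len, max_len=params.max_len,
    )
    if index is None:
        index = HairpinIndex(hairpins)
    alignments, unmapped = map_library(clean, index)
    records, unassigned = classify_alignments(
        alignments, annotations, index.hairpins, shift_window=params.shift_window
    )
    assignments = (
        classifier.classify_library(unmapped) if classifier is not None
        else [
            ClassAssignment(r.seq, r.count, r.library, "unknown", 0) for r in unmapped
        ]
    )
    mirna_count = mapped_read_count(alignments)
    fractions = (
        summarize_categories(assignments, mirna_count)
        if clean else {c: 0.0 for c in ALL_CLASSES}
    )
    return LibraryResult(
        library=library,
        clean_reads=clean,
        alignments=alignments,
        unmapped=unmapped,
        records=records,
        unassigned=unassigned,
        assignments=assignments,
        summary=quantify.library_summary(clean, alignments, records),
        class_fractions=fractions,
        shift5=summarize_shifts(records, "5p") if records else {},
        shift3=summarize_shifts(records, "3p") if records else {},
        mod_profile=modification_profile(records) if records else {},
    )


def analyze_study(
    reads_by_library: Mapping[str, Sequence[str]],
    hairpins: Sequence[Hairpin],
    annotations: Sequence[MatureAnnotation],
    reference_sets: Sequence[ReferenceSet] = (),
    params: AnalysisParams | None = None,
) -> StudyResult:
    """Analyze two libraries and build the cross-library comparison tables."""
    params = params or AnalysisParams()
    classifier = (
        CascadeClassifier(reference_sets, order=params.cascade_order)
        if reference_sets else None
    )
    index = HairpinIndex(hairpins)
    lib_results = {
        lib: analyze_library(reads, lib, hairpins, annotations, classifier,
                             params, index=index)
        for lib, reads in reads_by_library.items()
    }
    all_records = [r for lr in lib_results.values() for r in lr.records]
    aggregated = aggregate_mirna(all_records)

    # TPM against each library's total clean-read count
    totals = {
        lib: sum(r.count for r in lr.clean_reads) for lib, lr in lib_results.items()
    }
    expression = aggregated.copy()
    expression["tpm"] = [
        row["count"] / totals[row["library"]] * 1e6 if totals[row["library"]] else 0.0
        for _, row in expression.iterrows()
    ]

    lib_n, lib_t = params.libraries
    tpm_n = {
        r.mature_name: r.tpm
        for r in expression.itertuples() if r.library == lib_n
    }
    tpm_t = {
        r.mature_name: r.tpm
        for r in expression.itertuples() if r.library == lib_t
    }
    fc_records = quantify.fold_change_table(tpm_n, tpm_t, pseudo=params.fc_pseudo)
    fold_changes = pd.DataFrame(
        [
            {"mature_name": r.mature_name, "tpm_normal": r.tpm_normal,
             "tpm_tumor": r.tpm_tumor, "fc": r.fc, "preference": r.preference}
            for r in fc_records
        ]
    )
    arm = quantify.arm_usage_table(all_records, annotations, libraries=params.libraries)
    return StudyResult(
        libraries=lib_results,
        aggregated=aggregated,
        expression=expression,
        fold_changes=fold_changes,
        arm_usage=arm,
        params=params,
    )


@dataclass
class RunConfig:
    """File-driven run configuration (parsed from YAML)."""

    reads: dict  # library -> FASTQ/FASTA path
    hairpin_fasta: str
    annotation_tsv: str
    outdir: str
    class_references: dict = field(default_factory=dict)  # label -> FASTA path
    gmt: str | None = None  # pathway memberships for enrichment
    target_lists: list = field(default_factory=list)  # gene-list files (union)
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        params = AnalysisParams(**raw.get("params", {}))
        if isinstance(params.cascade_order, list):
            params.cascade_order = tuple(params.cascade_order)
        if isinstance(params.libraries, list):
            params.libraries = tuple(params.libraries)
        cfg = cls(
            reads=raw["reads"],
            hairpin_fasta=raw["hairpin_fasta"],
            annotation_tsv=raw["annotation_tsv"],
            outdir=raw["outdir"],
            class_references=raw.get("class_references", {}),
            gmt=raw.get("gmt"),
            target_lists=list(raw.get("target_lists", [])),
            params=params,
        )
        for p in [cfg.hairpin_fasta, cfg.annotation_tsv, *cfg.reads.values(),
                  *cfg.class_references.values(),
                  *([cfg.gmt] if cfg.gmt else []), *cfg.target_lists]:
            if not Path(p).exists():
                raise FileNotFoundError(p)
        return cfg


def run(config: RunConfig) -> StudyResult:
    """Execute the full pipeline from files and write the report bundle."""
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    try:
        hairpins = read_hairpin_fasta(config.hairpin_fasta)
        annotations = read_mature_annotations(config.annotation_tsv, hairpins)
    except Exception as exc:
        raise RuntimeError(f"stage 'references' failed: {exc}") from exc
    reference_sets = [
        read_reference_fasta(path, label)
        for label, path in config.class_references.items()
    ]
    reads_by_library = {}
    for lib, path in config.reads.items():
        try:
            reads_by_library[lib] = [r.seq for r in read_fastx(path, lib)]
        except Exception as exc:
            raise RuntimeError(f"stage 'read-input:{lib}' failed: {exc}") from exc

    result = analyze_study(
        reads_by_library, hairpins, annotations, reference_sets, config.params
    )
    write_reports(result, out)

    if config.gmt and config.target_lists:
        from . import enrich as enrich_mod

        try:
            pathways = enrich_mod.read_gmt(config.gmt)
            union = enrich_mod.target_union(
                enrich_mod.read_gene_list(p) for p in config.target_lists
            )
            enrich_df = enrich_mod.enrich_targets(union, pathways)
        except Exception as exc:
            raise RuntimeError(f"stage 'enrichment' failed: {exc}") from exc
        enrich_mod.write_enrichment_tsv(enrich_df, out / "enrichment.tsv")
        enrichment_status = f"tested {len(enrich_df)} pathways"
    else:
        enrichment_status = "skipped (no GMT/target lists supplied)"

    manifest = {
        "enrichment": enrichment_status,
        "params": {**vars(config.params),
                   "cascade_order": list(config.params.cascade_order),
                   "libraries": list(config.params.libraries)},
        "inputs": {"hairpin_fasta": config.hairpin_fasta,
                   "annotation_tsv": config.annotation_tsv,
                   "reads": dict(config.reads),
                   "class_references": dict(config.class_references)},
        "stages": {
            lib: {
                "raw_reads": len(reads_by_library[lib]),
                "clean_unique": len(lr.clean_reads),
                "clean_count": sum(r.count for r in lr.clean_reads),
                "mirna_count": round(mapped_read_count(lr.alignments), 6),
                "cascade_count": sum(a.count for a in lr.assignments),
                "isomir_records": len(lr.records),
                "unassigned_alignments": len(lr.unassigned),
            }
            for lib, lr in result.libraries.items()
        },
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return result


def write_reports(result: StudyResult, outdir: str | Path) -> None:
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    summary = pd.DataFrame(
        [{"library": lib, **lr.summary} for lib, lr in result.libraries.items()]
    )
    summary.to_csv(out / "summary.tsv", sep="\t", index=False)
    write_category_tsv(
        {lib: lr.class_fractions for lib, lr in result.libraries.items()},
        out / "class_fractions.tsv",
    )
    for lib, lr in result.libraries.items():
        write_isomir_tsv(lr.records, out / f"isomirs_{lib}.tsv")
        shifts = pd.DataFrame(
            [{"end": end, "shift": s, "fraction": f}
             for end, dist in (("5p", lr.shift5), ("3p", lr.shift3))
             for s, f in dist.items()]
        )
        shifts.to_csv(out / f"shifts_{lib}.tsv", sep="\t", index=False)
        pd.DataFrame(
            [{"category": c, "fraction": f} for c, f in lr.mod_profile.items()]
        ).to_csv(out / f"modification_{lib}.tsv", sep="\t", index=False)
        write_alignments_tsv(lr.alignments, out / f"alignments_{lib}.tsv")
    result.fold_changes.to_csv(out / "fold_changes.tsv", sep="\t", index=False)
    result.arm_usage.to_csv(out / "arm_usage.tsv", sep="\t", index=False)
    result.expression.to_csv(out / "expression.tsv", sep="\t", index=False)
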