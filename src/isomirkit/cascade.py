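"""Ordered classification of non-miRNA reads into the remaining RNA classes.

Reads that fail hairpin mapping are matched against per-class reference sets
(mRNA, tRNA, rRNA, snoRNA, scaRNA, snRNA, other ncRNA, repeat) in a fixed,
first-match-wins order, allowing at most one nucleotide substitution (no
indels). A read matching no class is "unknown". Together with the miRNA
fraction from the mapper this yields a 10-class partition of every clean
read in a library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .preprocess import UniqueRead
from .refmodel import CASCADE_CLASSES, ReferenceSet

#: Default precedence of the reference classes (first match wins).
DEFAULT_ORDER = CASCADE_CLASSES

ALL_CLASSES = ("miRNA",) + CASCADE_CLASSES + ("unknown",)

_BASES = "ACGU"
_SEP = "#"


@dataclass(frozen=True)
class ClassAssignment:
    read_seq: str
    count: int
    library: str
    class_label: str
    mismatches: int  # 0 exact, 1 single substitution; 0 for unknown


class CascadeClassifier:
    """Substring matcher over ordered reference sets, tolerating 1 substitution.

    Each class's sequences are concatenated with separators; a read hits a
    class if the read itself, or any single-substitution variant of it,
    occurs as an exact substring. Exact matches are preferred (reported as
    0 mismatches) before variant matches within the same class.
    """

    def __init__(self, reference_sets: Sequence[ReferenceSet],
                 order: Sequence[str] = DEFAULT_ORDER):
        by_label = {rs.class_label: rs for rs in reference_sets}
        unknown_labels = set(by_label) - set(order)
        if unknown_labels:
            raise ValueError(f"reference sets outside the class order: {unknown_labels}")
        self.order = [lbl for lbl in order if lbl in by_label]
        self._texts = {
            lbl: _SEP + _SEP.join(s for _, s in by_label[lbl].sequences) + _SEP
            for lbl in self.order
        }

    def classify_seq(self, seq: str) -> tuple[str, int]:
        """Return (class_label, mismatches) for one sequence."""
        variants: list[str] | None = None
        for lbl in self.order:
            text = self._texts[lbl]
            if seq in text:
                return lbl, 0
            if variants is None:
                variants = _substitution_neighbors(seq)
            if any(v in text for v in variants):
                return lbl, 1
        return "unknown", 0

    def classify_read(self, read: UniqueRead) -> ClassAssignment:
        label, mm = self.classify_seq(read.seq)
        return ClassAssignment(
            read_seq=read.seq, count=read.count, library=read.library,
            class_label=label, mismatches=mm,
        )

    def classify_library(self, reads: Iterable[UniqueRead]) -> list[ClassAssignment]:
        return [self.classify_read(r) for r in reads]


def _substitution_neighbors(seq: str) -> list[str]:
    """All sequences at Hamming distance exactly 1 from ``seq``."""
    out = []
    for i, c in enumerate(seq):
        for b in _BASES:
            if b != c:
                out.append(seq[:i] + b + seq[i + 1 :])
    return out


def summarize_categories(
    assignments: Sequence[ClassAssignment],
    mirna_read_count: float,
) -> dict[str, float]:
    """Fractions of total clean reads per class (10 classes, summing to 1).

    ``mirna_read_count`` is the weighted count of hairpin-mapped reads; the
    assignments cover everything else. Assigning the same read sequence twice
    is an error (the partition would double-count).
    """
    seen: set[str] = set()
    totals: dict[str, float] = {lbl: 0.0 for lbl in ALL_CLASSES}
    totals["miRNA"] = mirna_read_count
    for a in assignments:
        if a.read_seq in seen:
            raise ValueError(f"read {a.read_seq!r} assigned more than once")
        seen.add(a.read_seq)
        totals[a.class_label] += a.count
    grand = sum(totals.values())
    if grand == 0:
        raise ValueError("empty library: nothing to summarize")
    return {lbl: c / grand for lbl, c in totals.items()}


def write_category_tsv(
    summaries: Mapping[str, Mapping[str, float]], path: str | Path
) -> None:
    """Write per-library class fractions, one row per library."""
    df = pd.DataFrame(
        [{"library": lib, **{c: s.get(c, 0.0) for c in ALL_CLASSES}}
         for lib, s in summaries.items()]
    )
    df.to_csv(path, sep="\t", index=False)
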