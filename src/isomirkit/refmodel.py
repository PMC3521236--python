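"""Reference sequences and mature-miRNA annotations.

Defines the coordinate convention used throughout the package: positions on a
pre-miRNA hairpin are 1-based and inclusive, so an annotation ``start=16,
end=36`` covers the 16th through 36th nucleotide of the hairpin. Sequences are
held internally in the RNA alphabet (A, C, G, U); DNA input is accepted and
converted on read.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

logger = logging.getLogger(__name__)

RNA_ALPHABET = frozenset("ACGU")

#: The nine non-miRNA classes of the classification cascade plus "unknown";
#: reference sets may be supplied for the first eight.
CASCADE_CLASSES = (
    "mRNA",
    "tRNA",
    "rRNA",
    "snoRNA",
    "scaRNA",
    "snRNA",
    "other ncRNA",
    "repeat",
)

MIN_HAIRPIN_LEN = 40
MATURE_LEN_RANGE = (16, 30)


def normalize_rna(seq: str) -> str:
    """Uppercase a nucleotide string and convert T to U."""
    return seq.upper().replace("T", "U")


@dataclass(frozen=True)
class Hairpin:
    """A pre-miRNA reference sequence (~70 nt: 5p arm, loop, 3p arm)."""

    id: str
    seq: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "seq", normalize_rna(self.seq))
        if len(self.seq) < MIN_HAIRPIN_LEN:
            raise ValueError(
                f"hairpin {self.id!r}: length {len(self.seq)} < {MIN_HAIRPIN_LEN}"
            )
        bad = set(self.seq) - RNA_ALPHABET
        if bad:
            raise ValueError(
                f"hairpin {self.id!r}: non-nucleotide characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def subseq(self, start: int, end: int) -> str:
        """Extract hairpin[start..end], 1-based inclusive."""
        if not (1 <= start <= end <= self.length):
            raise ValueError(f"coordinates {start}..{end} out of 1..{self.length}")
        return self.seq[start - 1 : end]


@dataclass(frozen=True)
class MatureAnnotation:
    """An annotated mature miRNA located on one arm of a hairpin.

    ``start``/``end`` are 1-based inclusive positions on the hairpin.
    """

    hairpin_id: str
    mature_name: str
    arm: str  # "5p" or "3p"
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.arm not in ("5p", "3p"):
            raise ValueError(f"{self.mature_name!r}: arm must be 5p or 3p, got {self.arm!r}")
        if not (1 <= self.start < self.end):
            raise ValueError(
                f"{self.mature_name!r}: require 1 <= start < end, got {self.start}..{self.end}"
            )
        n = self.end - self.start + 1
        lo, hi = MATURE_LEN_RANGE
        if not (lo <= n <= hi):
            raise ValueError(
                f"{self.mature_name!r}: mature length {n} outside [{lo}, {hi}]"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class ReferenceSet:
    """A named collection of reference sequences for one cascade class."""

    class_label: str
    sequences: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.class_label not in CASCADE_CLASSES:
            raise ValueError(
                f"class_label {self.class_label!r} not in {CASCADE_CLASSES}"
            )
        if not self.sequences:
            raise ValueError(f"reference set {self.class_label!r} is empty")
        self.sequences = [(sid, normalize_rna(s)) for sid, s in self.sequences]


def read_hairpin_fasta(path: str | Path) -> list[Hairpin]:
    """Read a hairpin reference FASTA (miRBase-style) into validated Hairpins.

    T is converted to U and case is folded. Duplicate identifiers and
    non-nucleotide characters are hard errors.
    """
    hairpins: list[Hairpin] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate hairpin id {rec.id!r} in {path}")
        seen.add(rec.id)
        hairpins.append(Hairpin(id=rec.id, seq=str(rec.seq)))
    if not hairpins:
        logger.warning("no records in hairpin FASTA %s", path)
    return hairpins


def write_hairpin_fasta(hairpins: Iterable[Hairpin], path: str | Path) -> None:
    records = [SeqRecord(Seq(h.seq), id=h.id, description="") for h in hairpins]
    SeqIO.write(records, str(path), "fasta")


def _check_annotation_against(ann: MatureAnnotation, by_id: dict[str, Hairpin]) -> None:
    if ann.hairpin_id not in by_id:
        raise ValueError(f"{ann.mature_name!r}: unknown hairpin {ann.hairpin_id!r}")
    hp = by_id[ann.hairpin_id]
    if ann.end > hp.length:
        raise ValueError(
            f"{ann.mature_name!r}: end {ann.end} beyond hairpin length {hp.length}"
        )


def validate_annotations(
    annotations: Sequence[MatureAnnotation], hairpins: Sequence[Hairpin]
) -> None:
    """Check coordinates against hairpin lengths and (hairpin, arm) uniqueness."""
    by_id = {h.id: h for h in hairpins}
    seen_arm: set[tuple[str, str]] = set()
    for ann in annotations:
        _check_annotation_against(ann, by_id)
        key = (ann.hairpin_id, ann.arm)
        if key in seen_arm:
            raise ValueError(f"duplicate annotation for {key}")
        seen_arm.add(key)


def read_mature_annotations(
    path: str | Path, hairpins: Sequence[Hairpin]
) -> list[MatureAnnotation]:
    """Read a tab-separated annotation table.

    Expected columns: ``hairpin_id  mature_name  arm  start  end`` with a
    header row; coordinates are validated against the hairpin set.
    """
    df = pd.read_csv(path, sep="\t", dtype={"hairpin_id": str, "mature_name": str, "arm": str})
    required = ["hairpin_id", "mature_name", "arm", "start", "end"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"annotation TSV {path}: missing columns {missing}")
    annotations = [
        MatureAnnotation(
            hairpin_id=row.hairpin_id,
            mature_name=row.mature_name,
            arm=row.arm,
            start=int(row.start),
            end=int(row.end),
        )
        for row in df.itertuples(index=False)
    ]
    validate_annotations(annotations, hairpins)
    return annotations


def write_mature_annotations(
    annotations: Iterable[MatureAnnotation], path: str | Path
) -> None:
    df = pd.DataFrame(
        [
            (a.hairpin_id, a.mature_name, a.arm, a.start, a.end)
            for a in annotations
        ],
        columns=["hairpin_id", "mature_name", "arm", "start", "end"],
    )
    df.to_csv(path, sep="\t", index=False)


def infer_arm(hairpin: Hairpin, start: int, end: int) -> str:
    """Assign 5p/3p by whether the interval midpoint lies in the 5' half.

    The terminal loop is not modelled; the hairpin midpoint is the divider.
    """
    mid = (start + end) / 2
    return "5p" if mid <= hairpin.length / 2 else "3p"


def locate_mature_by_sequence(
    mature_fasta: str | Path, hairpins: Sequence[Hairpin]
) -> list[MatureAnnotation]:
    """Build annotations by exact substring search of mature sequences.

    Each mature sequence must occur at a unique position within any hairpin
    that contains it; multiple occurrences in one hairpin are ambiguous and
    raise. Matures found in no hairpin are skipped with a warning. The arm is
    inferred from the match midpoint (see :func:`infer_arm`).
    """
    annotations: list[MatureAnnotation] = []
    for rec in SeqIO.parse(str(mature_fasta), "fasta"):
        mseq = normalize_rna(str(rec.seq))
        found = False
        for hp in hairpins:
            positions = []
            i = hp.seq.find(mseq)
            while i != -1:
                positions.append(i + 1)  # to 1-based
                i = hp.seq.find(mseq, i + 1)
            if not positions:
                continue
            if len(positions) > 1:
                raise ValueError(
                    f"mature {rec.id!r} occurs at multiple positions "
                    f"{positions} in hairpin {hp.id!r}"
                )
            start = positions[0]
            end = start + len(mseq) - 1
            annotations.append(
                MatureAnnotation(
                    hairpin_id=hp.id,
                    mature_name=rec.id,
                    arm=infer_arm(hp, start, end),
                    start=start,
                    end=end,
                )
            )
            found = True
        if not found:
            logger.warning("mature %s not found in any hairpin; skipped", rec.id)
    validate_annotations(annotations, list(hairpins))
    return annotations


def read_reference_fasta(path: str | Path, class_label: str) -> ReferenceSet:
    """Read one cascade-class reference FASTA into a ReferenceSet."""
    seqs = [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
    return ReferenceSet(class_label=class_label, sequences=seqs)
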