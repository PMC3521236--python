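"""Library-level quantification: TPM, fold changes, concordance, arm usage.

Libraries of unequal depth are compared in transcripts per million:
``TPM = count / library_total * 1e6`` where the denominator is by default the
library's total clean-read count (so miRNA and non-miRNA classes share one
scale). Fold changes between two libraries are plain TPM ratios; concordance
between two fold-change assays (e.g. sequencing vs qPCR) is measured as the
Pearson correlation of *log* fold changes — ratios are compared on the scale
where doubling and halving are symmetric.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .isomir import IsomiRRecord, modification_profile
from .mapper import HairpinAlignment, mapped_read_count
from .preprocess import UniqueRead
from .refmodel import MatureAnnotation


@dataclass(frozen=True)
class FoldChangeRecord:
    mature_name: str
    tpm_normal: float
    tpm_tumor: float
    fc: float  # tumor / normal
    preference: str  # "normal" | "tumor" | "tie"


@dataclass(frozen=True)
class ArmUsageRecord:
    """5p:3p usage of one dual-product hairpin in two libraries.

    Ratios are None when the denominator arm has zero counts (flagged, never
    fabricated); ``log2_ratio_change`` compares tumor vs normal ratios.
    """

    hairpin_id: str
    n5p: float
    n3p: float
    t5p: float
    t3p: float
    ratio_normal: float | None
    ratio_tumor: float | None
    log2_ratio_change: float | None


@dataclass(frozen=True)
class PreferenceCounts:
    normal: int
    tumor: int
    ties: int


def tpm_normalize(counts: Mapping[str, float], library_total: float) -> pd.DataFrame:
    """Scale per-miRNA counts to transcripts per million of ``library_total``."""
    if library_total <= 0:
        raise ValueError("library_total must be positive")
    rows = [
        {"mature_name": name, "raw_count": c, "tpm": c / library_total * 1e6}
        for name, c in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["mature_name", "raw_count", "tpm"])


def fold_change(tpm_normal: float, tpm_tumor: float, pseudo: float = 0.0) -> float:
    """Tumor/normal TPM ratio; NaN flags 0/0 with no pseudocount."""
    if tpm_normal < 0 or tpm_tumor < 0:
        raise ValueError("TPM values must be non-negative")
    num, den = tpm_tumor + pseudo, tpm_normal + pseudo
    if den == 0:
        return math.nan if num == 0 else math.inf
    return num / den


def fold_change_table(
    tpm_normal: Mapping[str, float],
    tpm_tumor: Mapping[str, float],
    pseudo: float = 0.0,
) -> list[FoldChangeRecord]:
    names = sorted(set(tpm_normal) | set(tpm_tumor))
    out = []
    for name in names:
        a = tpm_normal.get(name, 0.0)
        b = tpm_tumor.get(name, 0.0)
        fc = fold_change(a, b, pseudo)
        pref = "tie" if fc == 1.0 or math.isnan(fc) else ("tumor" if fc > 1 else "normal")
        out.append(FoldChangeRecord(name, a, b, fc, pref))
    return out


def preference_counts(records: Iterable[FoldChangeRecord]) -> PreferenceCounts:
    """Partition miRNAs into normal-preferring (fc < 1) vs tumor-preferring (fc > 1)."""
    n = t = ties = 0
    for r in records:
        if math.isnan(r.fc) or r.fc == 1.0:
            ties += 1
        elif r.fc > 1.0:
            t += 1
        else:
            n += 1
    return PreferenceCounts(normal=n, tumor=t, ties=ties)


def concordance(pairs: Sequence[tuple[float, float]]) -> tuple[float, int]:
    """Agreement between two fold-change assays over the same miRNAs.

    Returns (Pearson r of log fold changes, number of direction-consistent
    pairs). Direction-consistent means both assays call the same side of 1.
    The log makes r invariant to the base and to rescaling either assay.
    """
    if any(a <= 0 or b <= 0 for a, b in pairs):
        raise ValueError("fold changes must be positive")
    if len(pairs) < 3:
        raise ValueError("need at least 3 pairs for a correlation")
    la = np.log([a for a, _ in pairs])
    lb = np.log([b for _, b in pairs])
    r = float(stats.pearsonr(la, lb).statistic)
    consistent = sum(1 for a, b in pairs if (a > 1) == (b > 1))
    return r, consistent


def arm_usage(
    hairpin_id: str,
    normal_counts: tuple[float, float],
    tumor_counts: tuple[float, float],
) -> ArmUsageRecord:
    """5p:3p expression ratios of one hairpin in each library.

    ``normal_counts``/``tumor_counts`` are (5p, 3p) count pairs. Ratios with
    a zero denominator are flagged None; the log2 ratio change is
    antisymmetric under swapping the libraries.
    """
    n5p, n3p = normal_counts
    t5p, t3p = tumor_counts
    if n5p == n3p == t5p == t3p == 0:
        raise ValueError(f"{hairpin_id}: all four arm counts are zero")
    rn = n5p / n3p if n3p > 0 else None
    rt = t5p / t3p if t3p > 0 else None
    change = (
        math.log2(rt / rn) if rn is not None and rt is not None and rn > 0 and rt > 0
        else None
    )
    return ArmUsageRecord(hairpin_id, n5p, n3p, t5p, t3p, rn, rt, change)


def arm_usage_table(
    records: Iterable[IsomiRRecord],
    annotations: Sequence[MatureAnnotation],
    libraries: tuple[str, str] = ("normal", "tumor"),
) -> pd.DataFrame:
    """Arm-usage records for every hairpin annotated (or observed) on both arms."""
    per_arm: dict[tuple[str, str, str], float] = {}
    for r in records:
        key = (r.hairpin_id, r.arm, r.library)
        per_arm[key] = per_arm.get(key, 0.0) + r.count
    dual = sorted(
        {a.hairpin_id for a in annotations if a.arm == "5p"}
        & {a.hairpin_id for a in annotations if a.arm == "3p"}
    )
    rows = []
    lib_n, lib_t = libraries
    for hid in dual:
        counts = [per_arm.get((hid, arm, lib), 0.0)
                  for lib in (lib_n, lib_t) for arm in ("5p", "3p")]
        if all(c == 0 for c in counts):
            continue
        rec = arm_usage(hid, (counts[0], counts[1]), (counts[2], counts[3]))
        rows.append(
            {
                "hairpin_id": hid,
                "n5p": rec.n5p, "n3p": rec.n3p, "t5p": rec.t5p, "t3p": rec.t3p,
                "ratio_normal": rec.ratio_normal,
                "ratio_tumor": rec.ratio_tumor,
                "log2_ratio_change": rec.log2_ratio_change,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["hairpin_id", "n5p", "n3p", "t5p", "t3p",
                 "ratio_normal", "ratio_tumor", "log2_ratio_change"],
    )


def library_summary(
    clean_reads: Sequence[UniqueRead],
    alignments: Sequence[HairpinAlignment],
    records: Sequence[IsomiRRecord],
) -> dict[str, float]:
    """The six per-library headline statistics.

    A pre-miRNA or miRNA counts as "detected" when at least one clean read
    (the count >= 2 filter already applied upstream) is assigned to it.
    """
    total = sum(r.count for r in clean_reads)
    mirna_reads = mapped_read_count(alignments)
    annotated = [r for r in records if not r.opposite_arm]
    opposite = [r for r in records if r.opposite_arm]
    profile = modification_profile(records) if records else {"modified_fraction": 0.0}
    return {
        "n_clean_reads": total,
        "pct_mirna_reads": 100.0 * mirna_reads / total if total else 0.0,
        "n_detected_premirnas": len({a.hairpin_id for a in alignments}),
        "n_detected_mirnas": len({r.mature_name for r in annotated}),
        "n_detected_opposite_arm": len({r.mature_name for r in opposite}),
        "pct_modified": 100.0 * profile["modified_fraction"],
    }


def reference_top_fraction(aggregated: pd.DataFrame) -> dict[str, float]:
    """Fraction of detected miRNAs whose reference isoform is the most abundant.

    Reported under two denominators: annotated matures only, and all detected
    loci including opposite-arm (provisional) ones.
    """
    ann = aggregated[~aggregated["opposite_arm"]]
    out = {}
    out["annotated"] = (
        float(ann["reference_most_abundant"].mean()) if len(ann) else math.nan
    )
    out["all_detected"] = (
        float(aggregated["reference_most_abundant"].mean()) if len(aggregated) else math.nan
    )
    return out
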