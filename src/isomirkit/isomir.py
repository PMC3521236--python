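"""IsomiR classification: position shifts, 3' tails, arm and opposite-arm calls.

An isomiR is a read variant of a mature miRNA differing in its 5'/3' end
positions and/or carrying a 3' nontemplate tail. Shifts are signed offsets in
the hairpin coordinate frame (positive = toward the hairpin 3' end) between
the aligned window and the annotated mature window; the tail is *not* part of
the 3' shift — shift3 is computed on the matched (templated) end.

Reads aligning to a hairpin arm that carries no annotation are "opposite-arm"
products (e.g. a 3p product from a hairpin annotated 5p-only). Each such arm
defines a provisional locus named ``<hairpin>-<arm>-novel`` whose coordinates
are the modal (count-weighted) aligned window; shifts of opposite-arm records
are relative to that modal window.
"""

from __future__ import annotations

import logging
import math
from collections import defaultdict
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .mapper import HairpinAlignment
from .refmodel import Hairpin, MatureAnnotation, infer_arm

logger = logging.getLogger(__name__)

#: 3'-addition categories tracked individually; any other non-empty tail is
#: "other" and the empty tail is "none".
MOD_CATEGORIES = ("A", "U", "AA", "UU", "AU", "C", "G")
DEFAULT_SHIFT_WINDOW = 5


@dataclass(frozen=True)
class IsomiRRecord:
    mature_name: str
    hairpin_id: str
    arm: str
    shift5: int
    shift3: int
    mod_suffix: str
    mod_category: str
    count: float  # weighted; fractional after multi-map apportioning
    library: str
    opposite_arm: bool


def classify_modification(mod_suffix: str) -> str:
    """Map a 3' tail sequence to its category (A, U, AA, UU, AU, C, G, other, none)."""
    if not mod_suffix:
        return "none"
    return mod_suffix if mod_suffix in MOD_CATEGORIES else "other"


def _overlap(a_start: int, a_end: int, b_start: int, b_end: int) -> int:
    return max(0, min(a_end, b_end) - max(a_start, b_start) + 1)


def classify_alignments(
    alignments: Iterable[HairpinAlignment],
    annotations: Sequence[MatureAnnotation],
    hairpins: dict[str, Hairpin],
    shift_window: int = DEFAULT_SHIFT_WINDOW,
) -> tuple[list[IsomiRRecord], list[HairpinAlignment]]:
    """Turn hairpin alignments into isomiR records.

    Each alignment is assigned to the same-hairpin annotation whose interval
    it overlaps most, provided both resulting shifts are within
    ``shift_window``; otherwise, if the aligned arm carries no annotation, it
    joins that arm's provisional opposite-arm locus. Alignments on an
    annotated arm but outside the window are returned unassigned.

    Alignments of one read that end up with the same mature name are merged
    (weights summed) so a read counts once per name.
    """
    ann_by_hp: dict[str, list[MatureAnnotation]] = defaultdict(list)
    for a in annotations:
        ann_by_hp[a.hairpin_id].append(a)

    records: list[IsomiRRecord] = []
    unassigned: list[HairpinAlignment] = []
    # provisional loci: (hairpin, arm) -> list of (alignment, window)
    opposite: dict[tuple[str, str], list[HairpinAlignment]] = defaultdict(list)

    for aln in alignments:
        a_start = aln.start
        a_end = aln.start + aln.match_len - 1
        hp = hairpins[aln.hairpin_id]
        anns = ann_by_hp.get(aln.hairpin_id, [])
        best: MatureAnnotation | None = None
        best_ov = 0
        for ann in anns:
            ov = _overlap(a_start, a_end, ann.start, ann.end)
            if ov > best_ov or (ov == best_ov and ov > 0 and best is not None
                                and ann.start < best.start):
                best, best_ov = ann, ov
        if best is not None and best_ov > 0:
            s5 = a_start - best.start
            s3 = a_end - best.end
            if abs(s5) <= shift_window and abs(s3) <= shift_window:
                records.append(
                    IsomiRRecord(
                        mature_name=best.mature_name,
                        hairpin_id=aln.hairpin_id,
                        arm=best.arm,
                        shift5=s5,
                        shift3=s3,
                        mod_suffix=aln.mod_suffix,
                        mod_category=classify_modification(aln.mod_suffix),
                        count=aln.count * aln.weight,
                        library=aln.library,
                        opposite_arm=False,
                    )
                )
                continue
        arm = infer_arm(hp, a_start, a_end)
        if any(ann.arm == arm for ann in anns):
            # on an annotated arm but too far from the annotation: report, do
            # not silently bin into the shift distribution
            unassigned.append(aln)
            logger.debug(
                "alignment %s@%s:%d outside ±%d of any annotation",
                aln.read_seq, aln.hairpin_id, a_start, shift_window,
            )
        else:
            opposite[(aln.hairpin_id, arm)].append(aln)

    # second pass: provisional opposite-arm loci anchored at the modal window
    for (hid, arm), alns in sorted(opposite.items()):
        weights: dict[tuple[int, int], float] = defaultdict(float)
        for aln in alns:
            weights[(aln.start, aln.start + aln.match_len - 1)] += aln.count * aln.weight
        modal = max(sorted(weights), key=lambda w: weights[w])
        m_start, m_end = modal
        name = f"{hid}-{arm}-novel"
        for aln in alns:
            a_start, a_end = aln.start, aln.start + aln.match_len - 1
            records.append(
                IsomiRRecord(
                    mature_name=name,
                    hairpin_id=hid,
                    arm=arm,
                    shift5=a_start - m_start,
                    shift3=a_end - m_end,
                    mod_suffix=aln.mod_suffix,
                    mod_category=classify_modification(aln.mod_suffix),
                    count=aln.count * aln.weight,
                    library=aln.library,
                    opposite_arm=True,
                )
            )

    return _merge_multimapped(records), unassigned


def _merge_multimapped(records: list[IsomiRRecord]) -> list[IsomiRRecord]:
    """Merge records of one read sharing a mature name (paralog products)."""
    merged: dict[tuple, IsomiRRecord] = {}
    order: list[tuple] = []
    for r in records:
        # identical paralog hairpins give identical shifts; key on the
        # observable isoform, not the hairpin copy
        key = (r.library, r.mature_name, r.shift5, r.shift3, r.mod_suffix)
        if key in merged:
            merged[key] = replace(merged[key], count=merged[key].count + r.count)
        else:
            merged[key] = r
            order.append(key)
    return [merged[k] for k in order]


def summarize_shifts(
    records: Iterable[IsomiRRecord],
    end: str,
    include_opposite_arm: bool = False,
) -> dict[int, float]:
    """Count-weighted distribution of 5' or 3' position shifts.

    ``end`` is "5p" or "3p". Opposite-arm records are excluded by default:
    their shifts are relative to a provisional (modal) window rather than an
    annotated mature position.
    """
    if end not in ("5p", "3p"):
        raise ValueError("end must be '5p' or '3p'")
    totals: dict[int, float] = defaultdict(float)
    grand = 0.0
    for r in records:
        if r.opposite_arm and not include_opposite_arm:
            continue
        s = r.shift5 if end == "5p" else r.shift3
        totals[s] += r.count
        grand += r.count
    if grand == 0:
        raise ValueError("no records to summarize")
    return {s: c / grand for s, c in sorted(totals.items())}


def modification_profile(records: Iterable[IsomiRRecord]) -> dict[str, float]:
    """Count-weighted 3'-modification category fractions.

    Returns a mapping over categories (including "none") plus the key
    "modified_fraction" = 1 - fraction(none).
    """
    totals: dict[str, float] = defaultdict(float)
    grand = 0.0
    for r in records:
        totals[r.mod_category] += r.count
        grand += r.count
    if grand == 0:
        raise ValueError("no records to profile")
    profile = {c: t / grand for c, t in sorted(totals.items())}
    profile["modified_fraction"] = 1.0 - profile.get("none", 0.0)
    return profile


def aggregate_mirna(records: Iterable[IsomiRRecord]) -> pd.DataFrame:
    """Sum isomiR counts per (mature_name, library).

    The expression of a miRNA is the sum over its isomiRs. Also reports
    whether the reference isoform (shift 0,0 and no tail) is the most
    abundant one for each name, and whether the name is an opposite-arm
    (provisional) locus.
    """
    groups: dict[tuple[str, str], list[IsomiRRecord]] = defaultdict(list)
    for r in records:
        groups[(r.mature_name, r.library)].append(r)
    rows = []
    for (name, lib), recs in sorted(groups.items()):
        total = sum(r.count for r in recs)
        by_iso: dict[tuple[int, int, str], float] = defaultdict(float)
        for r in recs:
            by_iso[(r.shift5, r.shift3, r.mod_suffix)] += r.count
        top = max(by_iso.values())
        ref = by_iso.get((0, 0, ""), 0.0)
        rows.append(
            {
                "mature_name": name,
                "library": lib,
                "hairpin_id": recs[0].hairpin_id,
                "arm": recs[0].arm,
                "opposite_arm": recs[0].opposite_arm,
                "count": total,
                "n_isomirs": len(by_iso),
                "reference_most_abundant": math.isclose(ref, top) or ref > top,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["mature_name", "library", "hairpin_id", "arm", "opposite_arm",
                 "count", "n_isomirs", "reference_most_abundant"],
    )


def write_isomir_tsv(records: Iterable[IsomiRRecord], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (r.mature_name, r.hairpin_id, r.arm, r.shift5, r.shift3,
             r.mod_suffix, r.mod_category, r.count, r.library, r.opposite_arm)
            for r in records
        ],
        columns=["mature_name", "hairpin_id", "arm", "shift5", "shift3",
                 "mod_suffix", "mod_category", "count", "library", "opposite_arm"],
    )
    df.to_csv(path, sep="\t", index=False)


def hairpin_stack_report(
    hairpin: Hairpin,
    annotations: Sequence[MatureAnnotation],
    alignments: Iterable[HairpinAlignment],
) -> str:
    """Text report of the isomiR stack on one hairpin.

    The hairpin sequence is printed with each aligned isomiR beneath it at
    its matched position, the nontemplate tail in lowercase, and the read
    count and (shift5, shift3) pair against the best-overlapping annotation
    on the left — the conventional way to eyeball isomiR structure.
    """
    anns = [a for a in annotations if a.hairpin_id == hairpin.id]
    lines = []
    header = "; ".join(f"{a.arm}:{a.start}-{a.end}" for a in anns) or "no annotation"
    lines.append(f"{hairpin.id} ({header})")
    lines.append(f"{'':>16}{hairpin.seq}")
    rows = []
    for aln in alignments:
        if aln.hairpin_id != hairpin.id:
            continue
        a_end = aln.start + aln.match_len - 1
        best = None
        best_ov = 0
        for a in anns:
            ov = _overlap(aln.start, a_end, a.start, a.end)
            if ov > best_ov:
                best, best_ov = a, ov
        shifts = (
            f"{aln.start - best.start:+d},{a_end - best.end:+d}" if best else "-,-"
        )
        body = aln.read_seq[: aln.match_len] + aln.mod_suffix.lower()
        rows.append((aln.start, aln.count, shifts, body))
    for start, count, shifts, body in sorted(rows, key=lambda r: (r[0], -r[1])):
        lines.append(f"{count:>8} {shifts:>6} {' ' * (start - 1)}{body}")
    return "\n".join(lines) + "\n"
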