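"""Mismatch-free hairpin mapping with 3' tail recovery.

Each clean read is aligned to the pre-miRNA set by finding the longest read
prefix (>= 18 nt) that occurs *exactly* in at least one hairpin. Bases beyond
that prefix are the candidate 3' nontemplate addition ("tail"). This is
equivalent to iteratively trimming terminal 3' bases and re-mapping until a
perfect match of at least 18 nt remains, but is computed directly: the
iterative loop survives only as the brute-force oracle in the test suite.

Multi-mapping reads (paralogous hairpins) receive equal fractional weights
over their occurrences, so no read is ever counted more than once in total.
Only the sense strand is searched: mature miRNAs are co-linear with their
hairpin.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .preprocess import UniqueRead
from .refmodel import Hairpin

MATCH_FLOOR = 18


@dataclass(frozen=True)
class HairpinAlignment:
    """One exact-prefix placement of a read on a hairpin.

    ``start`` is 1-based on the hairpin; the matched prefix is
    ``hairpin[start .. start + match_len - 1]`` and ``mod_suffix`` holds the
    remaining 3' bases of the read (empty when the whole read matched).
    """

    read_seq: str
    count: int
    library: str
    hairpin_id: str
    start: int
    match_len: int
    mod_suffix: str
    weight: float


class HairpinIndex:
    """Exact-substring index over a hairpin set, seeded on 18-mers."""

    def __init__(self, hairpins: Sequence[Hairpin]):
        self.hairpins = {h.id: h for h in hairpins}
        if len(self.hairpins) != len(hairpins):
            raise ValueError("duplicate hairpin ids")
        self._seeds: dict[str, list[tuple[str, int]]] = {}
        for h in hairpins:
            s = h.seq
            for i in range(len(s) - MATCH_FLOOR + 1):
                self._seeds.setdefault(s[i : i + MATCH_FLOOR], []).append((h.id, i))

    def occurrences(self, seed: str) -> list[tuple[str, int]]:
        """All (hairpin_id, 0-based offset) where an 18-mer occurs."""
        if len(seed) != MATCH_FLOOR:
            raise ValueError(f"seed must be {MATCH_FLOOR} nt")
        return self._seeds.get(seed, [])


def map_read(read: UniqueRead, index: HairpinIndex) -> list[HairpinAlignment]:
    """Map one clean read; empty list means unmapped.

    Finds L* = the largest L >= 18 with read[:L] an exact substring of some
    hairpin, and reports one alignment per occurrence of that longest prefix,
    with equal weights summing to 1.
    """
    seq = read.seq
    if len(seq) < MATCH_FLOOR:
        raise ValueError(f"read shorter than the {MATCH_FLOOR}-nt match floor: {seq!r}")
    best_len = 0
    best: list[tuple[str, int]] = []
    for hid, off in index.occurrences(seq[:MATCH_FLOOR]):
        hseq = index.hairpins[hid].seq
        # extend the seed match as far as read and hairpin agree
        L = MATCH_FLOOR
        limit = min(len(seq), len(hseq) - off)
        while L < limit and seq[L] == hseq[off + L]:
            L += 1
        if L > best_len:
            best_len, best = L, [(hid, off)]
        elif L == best_len:
            best.append((hid, off))
    if not best:
        return []
    w = 1.0 / len(best)
    return [
        HairpinAlignment(
            read_seq=seq,
            count=read.count,
            library=read.library,
            hairpin_id=hid,
            start=off + 1,
            match_len=best_len,
            mod_suffix=seq[best_len:],
            weight=w,
        )
        for hid, off in best
    ]


def map_library(
    reads: Iterable[UniqueRead], index: HairpinIndex
) -> tuple[list[HairpinAlignment], list[UniqueRead]]:
    """Partition a library into hairpin alignments and unmapped reads.

    Read counts are conserved: every input read appears either among the
    alignments (with weights summing to 1) or in the unmapped set.
    """
    alignments: list[HairpinAlignment] = []
    unmapped: list[UniqueRead] = []
    for r in reads:
        alns = map_read(r, index)
        if alns:
            alignments.extend(alns)
        else:
            unmapped.append(r)
    return alignments, unmapped


def mapped_read_count(alignments: Iterable[HairpinAlignment]) -> float:
    """Total weighted read count represented by a set of alignments."""
    return sum(a.count * a.weight for a in alignments)


def write_alignments_tsv(alignments: Iterable[HairpinAlignment], path: str | Path) -> None:
    df = pd.DataFrame(
        [
            (a.read_seq, a.count, a.library, a.hairpin_id, a.start, a.match_len,
             a.mod_suffix, a.weight)
            for a in alignments
        ],
        columns=["read_seq", "count", "library", "hairpin_id", "start",
                 "match_len", "mod_suffix", "weight"],
    )
    df.to_csv(path, sep="\t", index=False)
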