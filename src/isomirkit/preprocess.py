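"""Clean-read production: adapter trimming, collapsing, count/length filters.

A "clean read" is an adapter-trimmed read that survived collapsing to unique
sequences and the confidence filters (read count >= 2, length window). All
sequences leave this module in the RNA alphabet.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

from .refmodel import RNA_ALPHABET, normalize_rna

logger = logging.getLogger(__name__)

DEFAULT_MIN_COUNT = 2
DEFAULT_MIN_LEN = 18
DEFAULT_MAX_LEN = 30
DEFAULT_MIN_OVERLAP = 6


@dataclass(frozen=True)
class RawRead:
    seq: str
    library: str


@dataclass(frozen=True)
class UniqueRead:
    """A collapsed read: one distinct sequence with its multiplicity."""

    seq: str
    count: int
    library: str


def trim_adapter(seq: str, adapter: str, min_overlap: int = DEFAULT_MIN_OVERLAP) -> str | None:
    """Cut a read at the leftmost exact match of a 3' adapter prefix.

    The adapter may be truncated at the read's 3' end; a match requires at
    least ``min_overlap`` adapter bases. Matching is exact (no mismatches).
    Returns the insert (possibly empty) or None when no adapter is found.
    """
    if min_overlap < 1 or len(adapter) < min_overlap:
        raise ValueError("require adapter length >= min_overlap >= 1")
    seq = normalize_rna(seq)
    adapter = normalize_rna(adapter)
    n = len(seq)
    for i in range(0, n - min_overlap + 1):
        k = min(len(adapter), n - i)
        if seq[i : i + k] == adapter[:k]:
            return seq[:i]
    return None


def collapse_reads(reads: Iterable[RawRead]) -> list[UniqueRead]:
    """Collapse a single library's reads to unique sequences with counts.

    The sum of output counts equals the number of input reads. Output is
    sorted by descending count, then sequence, for determinism.
    """
    counter: Counter[str] = Counter()
    library: str | None = None
    for r in reads:
        if library is None:
            library = r.library
        elif r.library != library:
            raise ValueError(
                f"mixed library labels in one collapse: {library!r} vs {r.library!r}"
            )
        counter[normalize_rna(r.seq)] += 1
    if library is None:
        return []
    return [
        UniqueRead(seq=s, count=c, library=library)
        for s, c in sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    ]


def filter_clean(
    reads: Iterable[UniqueRead],
    min_count: int = DEFAULT_MIN_COUNT,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
) -> list[UniqueRead]:
    """Keep collapsed reads with count >= min_count and length in the window.

    Reads containing characters outside A/C/G/U (e.g. N calls) are dropped:
    the downstream mapper is mismatch-free and cannot place them.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    kept = []
    for r in reads:
        if r.count < min_count:
            continue
        if not (min_len <= len(r.seq) <= max_len):
            continue
        if set(r.seq) - RNA_ALPHABET:
            continue
        kept.append(r)
    return kept


def read_fastx(path: str | Path, library: str) -> Iterator[RawRead]:
    """Stream reads from FASTQ or FASTA (by extension); quality is ignored."""
    p = Path(path)
    fmt = "fastq" if p.suffix.lower() in (".fastq", ".fq") else "fasta"
    for rec in SeqIO.parse(str(p), fmt):
        yield RawRead(seq=str(rec.seq), library=library)


def read_collapsed_fasta(path: str | Path, library: str) -> list[UniqueRead]:
    """Read a pre-collapsed FASTA whose headers carry counts as ``>id_xCOUNT``."""
    out = []
    for rec in SeqIO.parse(str(path), "fasta"):
        name = rec.id
        if "_x" not in name:
            raise ValueError(f"{path}: header {name!r} lacks the _xCOUNT suffix")
        count = int(name.rsplit("_x", 1)[1])
        out.append(UniqueRead(seq=normalize_rna(str(rec.seq)), count=count, library=library))
    return out


def write_collapsed_fasta(reads: Iterable[UniqueRead], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, r in enumerate(reads, 1):
            fh.write(f">read{i}_x{r.count}\n{r.seq}\n")


def preprocess_library(
    raw: Iterable[RawRead],
    adapter: str | None,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
    min_count: int = DEFAULT_MIN_COUNT,
    min_len: int = DEFAULT_MIN_LEN,
    max_len: int = DEFAULT_MAX_LEN,
    keep_untrimmed: bool = False,
) -> list[UniqueRead]:
    """Full preprocessing: trim -> collapse -> filter, for one library.

    Reads with no adapter hit are discarded unless ``keep_untrimmed`` — an
    untrimmed read would carry adapter bases into the 3'-tail detector.
    With ``adapter=None`` reads are taken as already trimmed.
    """
    trimmed: list[RawRead] = []
    n_in = n_noadapter = 0
    for r in raw:
        n_in += 1
        if adapter is None:
            trimmed.append(r)
            continue
        ins = trim_adapter(r.seq, adapter, min_overlap)
        if ins is None:
            n_noadapter += 1
            if keep_untrimmed:
                trimmed.append(r)
            continue
        if ins:
            trimmed.append(RawRead(seq=ins, library=r.library))
    collapsed = collapse_reads(trimmed)
    clean = filter_clean(collapsed, min_count=min_count, min_len=min_len, max_len=max_len)
    logger.info(
        "preprocess: %d raw, %d without adapter, %d unique, %d clean",
        n_in, n_noadapter, len(collapsed), len(clean),
    )
    return clean
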