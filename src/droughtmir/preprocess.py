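"""Raw FASTQ to clean reads and collapsed unique tags.

The filtering convention follows FASTX-era small-RNA practice: trim the 3'
adapter (full match anywhere, or a >= ``min_overlap`` adapter prefix at the
read 3' end), drop inserts containing N or with more than 20% of bases below
Q20, and keep inserts of 16-30 nt.  Identical inserts are then collapsed
into unique tags carrying per-library read counts, the unit all downstream
annotation and expression work operates on.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd
from Bio.SeqIO.QualityIO import FastqGeneralIterator

from ._seq import VALID_INPUT, normalize

MIN_LEN = 16
MAX_LEN = 30
MIN_OVERLAP = 6


@dataclass
class CleanReadSet:
    """Clean reads of one library plus per-cause accounting counters."""

    library: str
    reads: list[str] = field(default_factory=list)
    total_raw: int = 0
    adapter_dropped: int = 0
    quality_dropped: int = 0
    length_dropped: int = 0

    @property
    def retained(self) -> int:
        return len(self.reads)

    def check_conservation(self) -> bool:
        return (self.total_raw == self.retained + self.adapter_dropped
                + self.quality_dropped + self.length_dropped)


def trim_adapter(
    read: str,
    adapter: str,
    min_overlap: int = MIN_OVERLAP,
    max_insert: int = MAX_LEN,
) -> str | None:
    """Return the insert before the leftmost 3' adapter match, or None.

    A full adapter occurrence anywhere wins; otherwise the longest adapter
    prefix of at least ``min_overlap`` bases at the read 3' end is trimmed.
    Reads without any match are returned unchanged when they are short
    enough to be a complete insert (<= ``max_insert``), since an insert
    shorter than the read length need not show adapter read-through.
    """
    if not adapter:
        raise ValueError("adapter must be non-empty")
    read = normalize(read)
    if set(read) - VALID_INPUT:
        raise ValueError("non-nucleotide characters in read")
    adapter = normalize(adapter)
    idx = read.find(adapter)
    if idx >= 0:
        return read[:idx] or None
    for k in range(min(len(adapter) - 1, len(read)), min_overlap - 1, -1):
        if read.endswith(adapter[:k]):
            return read[:-k] or None
    if len(read) > max_insert:
        return None
    return read or None


def filter_clean(
    inserts: Iterable[tuple[str | None, str | None]],
    library: str,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
    max_low_quality_fraction: float = 0.2,
    min_quality: int = 20,
) -> CleanReadSet:
    """Apply quality and length filters to trimmed (insert, quality) pairs.

    ``None`` inserts (adapter failures) are counted as adapter-dropped.
    Every input read is accounted for exactly once.
    """
    out = CleanReadSet(library=library)
    qmin = chr(min_quality + 33)
    for insert, qual in inserts:
        out.total_raw += 1
        if insert is None:
            out.adapter_dropped += 1
            continue
        if "N" in insert or (
            qual is not None
            and sum(q < qmin for q in qual[:len(insert)])
            > max_low_quality_fraction * len(insert)
        ):
            out.quality_dropped += 1
            continue
        if not min_len <= len(insert) <= max_len:
            out.length_dropped += 1
            continue
        out.reads.append(insert)
    return out


def process_library(
    fastq_path: str | Path,
    adapter: str,
    library: str | None = None,
    min_overlap: int = MIN_OVERLAP,
    min_len: int = MIN_LEN,
    max_len: int = MAX_LEN,
) -> CleanReadSet:
    """Trim + filter one FASTQ library (Sanger/Phred+33)."""
    path = Path(fastq_path)
    library = library or path.stem

    def pairs():
        with open(path) as fh:
            for _, seq, qual in FastqGeneralIterator(fh):
                insert = trim_adapter(seq, adapter,
                                      min_overlap=min_overlap, max_insert=max_len)
                yield insert, qual
    return filter_clean(pairs(), library, min_len=min_len, max_len=max_len)


def collapse(
    clean_sets: list[CleanReadSet], min_count: int = 1
) -> pd.DataFrame:
    """Collapse clean reads into a unique-tag table (rows: sequence).

    Columns are the library ids in input order; values are occurrence
    counts.  ``min_count`` optionally drops tags whose summed count across
    libraries falls below it (default 1 = no abundance filter).
    """
    counters = {cs.library: Counter(cs.reads) for cs in clean_sets}
    tags = pd.DataFrame(counters).fillna(0).astype(int)
    tags = tags.sort_index()
    tags.index.name = "sequence"
    if min_count > 1:
        tags = tags[tags.sum(axis=1) >= min_count]
    return tags


def expand(tags: pd.DataFrame) -> dict[str, list[str]]:
    """Inverse of :func:`collapse` (sorted reads per library)."""
    return {
        lib: [seq for seq, n in tags[lib].items() for _ in range(int(n))]
        for lib in tags.columns
    }


def size_distribution(
    tags: pd.DataFrame, min_len: int = MIN_LEN, max_len: int = MAX_LEN
) -> pd.DataFrame:
    """Per-length unique-tag and total-read counts over 16..30 nt."""
    lengths = pd.Index(range(min_len, max_len + 1), name="length")
    out = pd.DataFrame(0, index=lengths,
                       columns=["unique_tags", "total_reads"])
    if len(tags):
        by_len = tags.groupby(tags.index.str.len())
        out["unique_tags"] = by_len.size().reindex(lengths, fill_value=0)
        out["total_reads"] = (
            by_len.sum().sum(axis=1).reindex(lengths, fill_value=0).astype(int))
    return out


def library_stats(total_raw: int, clean_total: int, unique_total: int) -> dict:
    """Percentage bookkeeping of one library (clean% and unique% of raw)."""
    if total_raw == 0:
        raise ValueError("cannot compute percentages of an empty library")
    if not 0 <= clean_total <= total_raw or unique_total < 0:
        raise ValueError("invalid totals")
    return {
        "total_raw": total_raw,
        "clean_total": clean_total,
        "unique_total": unique_total,
        "clean_pct": round(clean_total / total_raw * 100, 2),
        "unique_pct": round(unique_total / total_raw * 100, 2),
    }


def stats_table(clean_sets: list[CleanReadSet], tags: pd.DataFrame) -> pd.DataFrame:
    """Library summary table (raw / clean / unique counts with percentages)."""
    rows = []
    for cs in clean_sets:
        unique_total = int((tags[cs.library] > 0).sum()) if len(tags) else 0
        stats = library_stats(cs.total_raw, cs.retained, unique_total)
        stats["library"] = cs.library
        rows.append(stats)
    return pd.DataFrame(rows).set_index("library")
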