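"""Small-RNA read processing.

Raw reads are adapter-trimmed, collapsed to distinct sequences, exact-match
mapped to the genome on both strands (no mismatches — the analysis relies on
perfect identity throughout), purged of structural-RNA (t/r/sn/snoRNA)
contaminants, and normalized to transcripts per two million (TP2M).

Count conservation is maintained at every step and is checkable from the
returned objects: raw = trimmed-kept + trimmed-rejected, and
genome-matched = structural + retained.
"""

from __future__ import annotations

from bisect import bisect_left
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple

import pandas as pd

from . import io
from .seqtools import check_alphabet, revcomp

TP2M_SCALE = 2_000_000
TP10M_SCALE = 10_000_000


@dataclass
class ReadSet:
    """A collapsed small-RNA library: distinct sequences with counts."""

    library_id: str
    tissue: str = ""
    stage: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    trimmed: bool = False
    genome_matched: bool = False
    structural_removed: bool = False

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    @property
    def distinct(self) -> int:
        return len(self.counts)


class GenomeHit(NamedTuple):
    """Exact placement of a sequence on the genome (0-based half-open)."""

    chrom: str
    start: int
    end: int
    strand: str


@dataclass
class TrimStats:
    total: int = 0
    kept: int = 0
    rejected_no_adapter: int = 0
    rejected_length: int = 0
    rejected_alphabet: int = 0

    @property
    def rejected(self) -> int:
        return self.rejected_no_adapter + self.rejected_length + self.rejected_alphabet


@dataclass
class LibraryStats:
    """Per-library accounting mirroring the standard summary table columns."""

    library_id: str
    raw_total: int
    raw_trimmed: int
    genome_matched: int
    structural: int
    retained: int
    retained_distinct: int
    size_histogram: dict[int, float]  # insert length -> TP2M mass


def trim_adapter(
    raw_read: str,
    adapter3: str,
    min_overlap: int = 7,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[str | None, str]:
    """Trim the 3' adapter off a raw read.

    The insert is the prefix before the leftmost exact occurrence of the
    adapter's first ``min_overlap`` bases (a full-length internal adapter hit
    qualifies a fortiori).  Returns ``(insert, "ok")`` or ``(None, reason)``
    where reason is one of ``no_adapter`` / ``length`` / ``alphabet``.
    """
    if min_len > max_len or min_overlap < 1:
        raise ValueError("bad trimming parameters")
    raw = raw_read.upper()
    if not check_alphabet(raw, allow_n=True):
        return None, "alphabet"
    probe = adapter3.upper()[:min_overlap]
    pos = raw.find(probe)
    if pos < 0:
        return None, "no_adapter"
    insert = raw[:pos]
    if not (min_len <= len(insert) <= max_len):
        return None, "length"
    if "N" in insert:
        return None, "alphabet"
    return insert, "ok"


def trim_reads(
    raw_counts: Mapping[str, int],
    adapter3: str,
    library_id: str = "",
    tissue: str = "",
    stage: str = "",
    min_overlap: int = 7,
    min_len: int = 18,
    max_len: int = 30,
) -> tuple[ReadSet, TrimStats]:
    """Trim and collapse a raw library given as (raw read -> count)."""
    stats = TrimStats()
    inserts: Counter = Counter()
    for raw, n in raw_counts.items():
        stats.total += n
        insert, reason = trim_adapter(raw, adapter3, min_overlap, min_len, max_len)
        if insert is None:
            if reason == "no_adapter":
                stats.rejected_no_adapter += n
            elif reason == "length":
                stats.rejected_length += n
            else:
                stats.rejected_alphabet += n
        else:
            inserts[insert] += n
            stats.kept += n
    rs = ReadSet(
        library_id=library_id,
        tissue=tissue,
        stage=stage,
        counts=dict(sorted(inserts.items())),
        trimmed=True,
    )
    return rs, stats


class GenomeIndex:
    """Seed-and-verify exact matcher over a genome dict.

    Indexes every k-mer start position; a query is verified by direct string
    comparison at each seed hit, on both strands.  Hits are reported sorted by
    (chrom, start, strand) and are exact by construction.
    """

    def __init__(self, genome: Mapping[str, str], k: int = 12):
        self.genome = {c: s.upper() for c, s in genome.items()}
        self.k = k
        self._index: dict[str, list[tuple[str, int]]] = {}
        for chrom, seq in self.genome.items():
            for i in range(len(seq) - k + 1):
                self._index.setdefault(seq[i: i + k], []).append((chrom, i))

    def map_exact(self, sequence: str) -> list[GenomeHit]:
        """All exact occurrences of ``sequence`` on both strands."""
        seq = sequence.upper()
        n = len(seq)
        if n < self.k:
            raise ValueError(f"query shorter than index k-mer size ({self.k})")
        genome = self.genome
        index_get = self._index.get
        hits = []
        for query, strand in ((seq, "+"), (revcomp(seq), "-")):
            for chrom, i in index_get(query[: self.k], ()):
                if genome[chrom][i: i + n] == query:
                    hits.append(GenomeHit(chrom, i, i + n, strand))
        if len(hits) > 1:
            hits.sort()
        return hits

    def map_readset(self, readset: ReadSet) -> dict[str, list[GenomeHit]]:
        return {seq: self.map_exact(seq) for seq in readset.counts}


def split_genome_matched(
    readset: ReadSet, hits_by_seq: Mapping[str, list[GenomeHit]]
) -> tuple[ReadSet, int]:
    """Keep genome-matched sequences; return (matched readset, unmatched count)."""
    matched = {s: c for s, c in readset.counts.items() if hits_by_seq.get(s)}
    unmatched = readset.total - sum(matched.values())
    rs = ReadSet(
        library_id=readset.library_id,
        tissue=readset.tissue,
        stage=readset.stage,
        counts=matched,
        trimmed=readset.trimmed,
        genome_matched=True,
    )
    return rs, unmatched


def _structural_intervals(features: Iterable[io.Feature]) -> dict[str, tuple[list[int], list[int]]]:
    """Merged, start-sorted structural intervals per chromosome."""
    raw: dict[str, list[tuple[int, int]]] = {}
    for f in io.structural_features(features):
        raw.setdefault(f.chrom, []).append((f.start, f.end))
    merged: dict[str, tuple[list[int], list[int]]] = {}
    for chrom, ivs in raw.items():
        out: list[list[int]] = []
        for s, e in sorted(ivs):
            if out and s <= out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
            else:
                out.append([s, e])
        merged[chrom] = ([s for s, _ in out], [e for _, e in out])
    return merged


def filter_structural(
    readset: ReadSet,
    hits_by_seq: Mapping[str, list[GenomeHit]],
    features: Iterable[io.Feature],
) -> tuple[ReadSet, int]:
    """Remove sequences with ANY genome hit overlapping (>=1 nt, either
    strand) an annotated t/r/sn/snoRNA interval.  Returns (retained readset,
    structural read count); counts are conserved."""
    intervals = _structural_intervals(features)

    def overlaps(h: GenomeHit) -> bool:
        iv = intervals.get(h.chrom)
        if iv is None:
            return False
        starts, ends = iv
        i = bisect_left(starts, h.end) - 1  # rightmost interval starting before hit end
        return i >= 0 and ends[i] > h.start

    retained: dict[str, int] = {}
    structural = 0
    for seq, n in readset.counts.items():
        hits = hits_by_seq.get(seq)
        if hits is None:
            raise KeyError(f"no genome hits recorded for sequence {seq[:12]}...")
        is_structural = any(overlaps(h) for h in hits)
        if is_structural:
            structural += n
        else:
            retained[seq] = n
    rs = ReadSet(
        library_id=readset.library_id,
        tissue=readset.tissue,
        stage=readset.stage,
        counts=retained,
        trimmed=readset.trimmed,
        genome_matched=readset.genome_matched,
        structural_removed=True,
    )
    return rs, structural


def normalize(readset: ReadSet, scale: int = TP2M_SCALE) -> pd.Series:
    """Normalized abundance: count / retained total x scale (TP2M by default).

    Scale-invariant under uniform count multiplication; sums to ``scale``.
    """
    total = readset.total
    if total == 0:
        raise ValueError("cannot normalize an empty read set")
    ser = pd.Series(readset.counts, dtype=float) / total * scale
    ser.name = readset.library_id
    return ser


def library_stats(
    raw_total: int,
    trim_stats: TrimStats,
    matched: ReadSet,
    structural_count: int,
    retained: ReadSet,
    scale: int = TP2M_SCALE,
) -> LibraryStats:
    """Assemble per-library accounting plus the size-class histogram of
    normalized abundance over retained insert lengths."""
    abundance = normalize(retained, scale)
    hist: dict[int, float] = {}
    for seq, a in abundance.items():
        hist[len(seq)] = hist.get(len(seq), 0.0) + float(a)
    return LibraryStats(
        library_id=retained.library_id,
        raw_total=raw_total,
        raw_trimmed=trim_stats.kept,
        genome_matched=matched.total,
        structural=structural_count,
        retained=retained.total,
        retained_distinct=retained.distinct,
        size_histogram=dict(sorted(hist.items())),
    )


@dataclass
class ProcessedLibrary:
    """Everything downstream stages need from one library."""

    readset: ReadSet  # retained (trimmed, mapped, structural-removed)
    stats: LibraryStats
    hits_by_seq: dict[str, list[GenomeHit]]
    abundance: pd.Series  # TP2M over retained distinct sequences


def process_library(
    raw_counts: Mapping[str, int],
    adapter3: str,
    index: GenomeIndex,
    features: Iterable[io.Feature],
    library_id: str,
    tissue: str = "",
    stage: str = "",
    min_overlap: int = 7,
    min_len: int = 18,
    max_len: int = 30,
    scale: int = TP2M_SCALE,
) -> ProcessedLibrary:
    """Run the full per-library chain: trim, map, filter, normalize."""
    trimmed, tstats = trim_reads(
        raw_counts, adapter3, library_id, tissue, stage, min_overlap, min_len, max_len
    )
    hits = index.map_readset(trimmed)
    matched, _unmatched = split_genome_matched(trimmed, hits)
    retained, structural = filter_structural(matched, hits, features)
    stats = library_stats(tstats.total, tstats, matched, structural, retained, scale)
    hits_retained = {s: hits[s] for s in retained.counts}
    return ProcessedLibrary(
        readset=retained,
        stats=stats,
        hits_by_seq=hits_retained,
        abundance=normalize(retained, scale),
    )


def abundance_matrix(columns: Iterable[pd.Series]) -> pd.DataFrame:
    """Stack per-library abundance Series into a sequences x libraries matrix
    (absent sequences are 0)."""
    df = pd.concat(list(columns), axis=1).fillna(0.0)
    df.index.name = "sequence"
    return df


def stats_table(stats: Iterable[LibraryStats]) -> pd.DataFrame:
    rows = [
        {
            "library": s.library_id,
            "raw": s.raw_total,
            "raw_trimmed": s.raw_trimmed,
            "genome_matched": s.genome_matched,
            "structural": s.structural,
            "retained": s.retained,
            "retained_distinct": s.retained_distinct,
        }
        for s in stats
    ]
    return pd.DataFrame(rows).set_index("library")
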