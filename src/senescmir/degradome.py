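"""PARE (degradome) processing and cleavage validation.

PARE tags are 20-nt fragments whose 5' end marks the 5' end of an uncapped
decay intermediate; for an sRNA-guided cleavage event that is the target
position paired to sRNA base 10 (the bond between bases 10 and 11).  Reads
are exact-matched in transcript space — the fragments derive from mRNA — and
stacked into per-position 5'-end profiles; a predicted site is "supported"
when it carries signal and ranks among the transcript's top positions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

from .target_prediction import TargetAlignment

PARE_READ_LENGTH = 20
TP10M_SCALE = 10_000_000


@dataclass
class PareProfile:
    """Per-position 5'-end counts of PARE tags on one transcript."""

    transcript_id: str
    library_id: str
    counts: np.ndarray  # length = transcript length, raw 5'-end counts
    normalized: np.ndarray  # per ten million transcript-mapped reads

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class PareLibraryStats:
    library_id: str
    raw_total: int
    transcript_matched: int
    distinct: int  # distinct matched sequences


@dataclass
class PareLibrary:
    library_id: str
    profiles: dict[str, PareProfile]
    stats: PareLibraryStats
    unmatched: int


def _transcript_tag_index(
    transcripts: Mapping[str, str], read_length: int
) -> dict[str, list[tuple[str, int]]]:
    index: dict[str, list[tuple[str, int]]] = {}
    for tx, seq in transcripts.items():
        s = seq.upper()
        for p in range(len(s) - read_length + 1):
            index.setdefault(s[p: p + read_length], []).append((tx, p))
    return index


def build_profiles(
    reads: Mapping[str, int],
    transcripts: Mapping[str, str],
    library_id: str = "",
    read_length: int = PARE_READ_LENGTH,
    scale: int = TP10M_SCALE,
) -> PareLibrary:
    """Stack collapsed PARE reads into per-transcript 5'-end profiles.

    Every exact transcript occurrence of a read increments that position's
    count (multi-transcript tags count at each match).  Normalization is per
    ``scale`` transcript-mapped reads of the library; unmatched reads are
    tallied, not dropped silently.
    """
    index = _transcript_tag_index(transcripts, read_length)
    counts = {tx: np.zeros(len(seq), dtype=np.int64) for tx, seq in transcripts.items()}
    mapped = 0
    distinct = 0
    unmatched = 0
    for read, n in reads.items():
        hits = index.get(read.upper())
        if not hits:
            unmatched += n
            continue
        mapped += n
        distinct += 1
        for tx, p in hits:
            counts[tx][p] += n
    profiles = {}
    for tx, vec in counts.items():
        norm = vec * (scale / mapped) if mapped else vec.astype(float)
        profiles[tx] = PareProfile(
            transcript_id=tx, library_id=library_id, counts=vec, normalized=norm
        )
    stats = PareLibraryStats(
        library_id=library_id,
        raw_total=sum(reads.values()),
        transcript_matched=mapped,
        distinct=distinct,
    )
    return PareLibrary(library_id=library_id, profiles=profiles, stats=stats, unmatched=unmatched)


def genome_space_stats(
    reads: Mapping[str, int], genome_index, library_id: str = ""
) -> PareLibraryStats:
    """Library complexity stats with genome-space exact matching (summary-
    table parity); profile building itself stays in transcript space."""
    matched = 0
    distinct = 0
    for read, n in reads.items():
        if genome_index.map_exact(read):
            matched += n
            distinct += 1
    return PareLibraryStats(
        library_id=library_id,
        raw_total=sum(reads.values()),
        transcript_matched=matched,
        distinct=distinct,
    )


@dataclass
class CleavageEvidence:
    """PARE support for one predicted cleavage site."""

    alignment: TargetAlignment | None
    transcript_id: str
    expected_site: int  # 1-based transcript position (sRNA base-10 partner)
    window: int  # +- positions also accepted
    observed: float  # counts summed over accepted positions
    site_rank: int  # 1 = most abundant position of the transcript
    fraction: float  # share of the transcript's PARE mass at accepted positions
    supported: bool


def validate_cleavage(
    alignment: TargetAlignment,
    profile: PareProfile,
    window: int = 0,
    rank_max: int = 5,
) -> CleavageEvidence:
    """Check a predicted site against a transcript's PARE profile.

    The expected 5'-end position is the target base paired to sRNA position
    10; ``window`` widens acceptance to +-window positions (the looser
    "between bases 10 and 11" reading is window=1).  Supported iff the
    accepted positions carry any signal and the site ranks within
    ``rank_max`` among the transcript's positions.  Rank and positivity are
    scale-free, so the verdict is invariant to library depth.
    """
    site = alignment.cleavage_site
    return _validate_site(alignment, alignment.transcript_id, site, profile, window, rank_max)


def validate_site(
    transcript_id: str,
    site: int,
    profile: PareProfile,
    window: int = 0,
    rank_max: int = 5,
) -> CleavageEvidence:
    """Site-level variant of :func:`validate_cleavage` (no alignment object)."""
    return _validate_site(None, transcript_id, site, profile, window, rank_max)


def _validate_site(
    alignment: TargetAlignment | None,
    transcript_id: str,
    site: int,
    profile: PareProfile,
    window: int,
    rank_max: int,
) -> CleavageEvidence:
    n = len(profile.counts)
    if not (1 <= site <= n):
        raise ValueError(f"cleavage site {site} outside transcript of length {n}")
    lo = max(0, site - 1 - window)
    hi = min(n, site + window)
    observed = float(profile.counts[lo:hi].sum())
    peak = float(profile.counts[lo:hi].max())
    rank = int((profile.counts > peak).sum()) + 1
    total = profile.counts.sum()
    fraction = observed / total if total else 0.0
    return CleavageEvidence(
        alignment=alignment,
        transcript_id=transcript_id,
        expected_site=site,
        window=window,
        observed=observed,
        site_rank=rank,
        fraction=fraction,
        supported=(observed > 0) and (rank <= rank_max),
    )


def track_site_across_stages(
    alignments: list[TargetAlignment],
    libraries: dict[str, PareLibrary],
    stage_order: list[str],
    window: int = 0,
) -> pd.DataFrame:
    """Normalized site abundance per stage per predicted target, with a
    monotone-trend label from the sign of the Spearman correlation between
    stage order and site abundance (``increasing`` / ``decreasing`` / ``none``).

    ``libraries`` maps stage -> PareLibrary (one per stage).
    """
    if len(libraries) < 2:
        raise ValueError("need at least two stage profiles")
    rows = []
    for aln in alignments:
        row: dict = {"srna": aln.srna_id, "transcript": aln.transcript_id, "site": aln.cleavage_site}
        values = []
        for stage in stage_order:
            lib = libraries[stage]
            profile = lib.profiles[aln.transcript_id]
            lo = max(0, aln.cleavage_site - 1 - window)
            hi = min(len(profile.normalized), aln.cleavage_site + window)
            v = float(profile.normalized[lo:hi].sum())
            row[stage] = v
            values.append(v)
        if len(set(values)) <= 1:
            rho = 0.0
        else:
            rho = sp_stats.spearmanr(np.arange(len(values)), values).statistic
        row["spearman_rho"] = float(rho) if np.isfinite(rho) else 0.0
        row["trend"] = (
            "increasing" if row["spearman_rho"] > 0 else "decreasing" if row["spearman_rho"] < 0 else "none"
        )
        rows.append(row)
    return pd.DataFrame(rows)
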