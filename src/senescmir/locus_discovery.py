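"""Discovery of new senescence-inducible small-RNA loci.

The funnel: distinct sequences not matching any known miRNA and elevated
threefold or more in early- or late-senescence leaf libraries relative to
mature leaf (candidate sequences) -> genomic clustering of their exact hits
into windows -> strand-bias filter (> 90% of the window's retained sRNA mass
on one strand, as expected of a hairpin-derived locus) -> stem-loop folding of
the cluster core -> per-locus report of abundant sRNAs plus a precise-excision
(MIRNA annotation criteria) check.
"""

from __future__ import annotations

import warnings
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hairpin import HairpinReport, fold_hairpin
from .read_processing import GenomeHit
from .srna_quant import MirnaCatalog

LEAF = "leaf"


def candidate_sequences(
    matrix: pd.DataFrame,
    catalog: MirnaCatalog,
    tissue: str = LEAF,
    fold: float = 3.0,
    pseudocount: float = 1.0,
    floor: float = 50.0,
    reference_stage: str = "mature",
) -> list[str]:
    """Distinct sequences that are not known miRNAs, pass the abundance floor
    in some library of the tissue, and are ``fold``-elevated in early or late
    senescence relative to the mature stage."""
    ref_col = f"{tissue}_{reference_stage}"
    sen_cols = [
        c
        for c in (f"{tissue}_early_senescence", f"{tissue}_late_senescence")
        if c in matrix.columns
    ]
    if ref_col not in matrix.columns or not sen_cols:
        raise KeyError(f"matrix lacks the {tissue} stage columns")
    tissue_cols = [c for c in matrix.columns if c.startswith(f"{tissue}_")]
    known = set(catalog.by_sequence)
    passed_floor = (matrix[tissue_cols] >= floor).any(axis=1)
    fc = matrix[sen_cols].add(pseudocount).div(matrix[ref_col] + pseudocount, axis=0)
    elevated = (fc >= fold).any(axis=1)
    keep = passed_floor & elevated & ~matrix.index.isin(known)
    return list(matrix.index[keep])


@dataclass
class LocusCandidate:
    """A genomic window of clustered candidate sRNAs."""

    chrom: str
    start: int  # flanked window, 0-based half-open
    end: int
    core_start: int  # tight span of the member hits
    core_end: int
    members: list[str]  # candidate sequences with a hit in the window
    plus_mass: float
    minus_mass: float

    @property
    def strand_bias(self) -> float:
        total = self.plus_mass + self.minus_mass
        return max(self.plus_mass, self.minus_mass) / total if total > 0 else 0.0

    @property
    def strand(self) -> str:
        return "+" if self.plus_mass >= self.minus_mass else "-"


def _flatten_hits(
    hits_by_seq: dict[str, list[GenomeHit]], mass_by_seq: pd.Series
) -> dict[str, tuple[list[int], list[tuple[int, int, str, float, str]]]]:
    """Per-chromosome start-sorted (start, end, strand, mass, seq) lists."""
    per_chrom: dict[str, list[tuple[int, int, str, float, str]]] = {}
    for seq, hits in hits_by_seq.items():
        mass = float(mass_by_seq.get(seq, 0.0))
        for h in hits:
            per_chrom.setdefault(h.chrom, []).append((h.start, h.end, h.strand, mass, seq))
    out = {}
    for chrom, lst in per_chrom.items():
        lst.sort()
        out[chrom] = ([x[0] for x in lst], lst)
    return out


def cluster_and_bias(
    candidates: list[str],
    hits_by_seq: dict[str, list[GenomeHit]],
    mass_by_seq: pd.Series,
    flank: int = 250,
    merge_gap: int = 100,
    min_bias: float = 0.9,
    max_hit_len: int = 36,
) -> list[LocusCandidate]:
    """Merge candidate hits (extended by ``flank``) into windows and keep those
    whose strand bias — over ALL retained sRNA mass in the window, not just
    candidates — exceeds ``min_bias``.

    ``mass_by_seq`` is the per-sequence abundance mass (TP2M summed over
    libraries); a multi-mapping sequence contributes its full mass at every
    hit, per the locus-level counting convention.
    """
    candidate_set = set(candidates)
    intervals: dict[str, list[tuple[int, int]]] = {}
    for seq in candidates:
        hits = hits_by_seq.get(seq) or []
        if not hits:
            warnings.warn(f"candidate sequence without genome hits skipped: {seq[:14]}...")
            continue
        for h in hits:
            intervals.setdefault(h.chrom, []).append((max(0, h.start - flank), h.end + flank))

    flat = _flatten_hits(hits_by_seq, mass_by_seq)
    loci: list[LocusCandidate] = []
    for chrom in sorted(intervals):
        merged: list[list[int]] = []
        for s, e in sorted(intervals[chrom]):
            if merged and s - merged[-1][1] <= merge_gap:
                merged[-1][1] = max(merged[-1][1], e)
            else:
                merged.append([s, e])
        starts, records = flat.get(chrom, ([], []))
        for wstart, wend in merged:
            lo = bisect_left(starts, wstart - max_hit_len)
            hi = bisect_right(starts, wend)
            plus = minus = 0.0
            members: set[str] = set()
            member_hits: list[tuple[float, int, int]] = []
            for start, end, strand, mass, seq in records[lo:hi]:
                if end <= wstart or start >= wend:
                    continue
                if strand == "+":
                    plus += mass
                else:
                    minus += mass
                if seq in candidate_set:
                    members.add(seq)
                    member_hits.append((mass, start, end))
            if not member_hits:
                continue
            # the locus core is where the abundant members sit; trace-level
            # candidates drifting into the window must not stretch it
            peak = max(m for m, _, _ in member_hits)
            major = [(s, e) for m, s, e in member_hits if m >= 0.05 * peak]
            core_lo = min(s for s, _ in major)
            core_hi = max(e for _, e in major)
            loci.append(
                LocusCandidate(
                    chrom=chrom,
                    start=wstart,
                    end=wend,
                    core_start=core_lo,
                    core_end=core_hi,
                    members=sorted(members),
                    plus_mass=plus,
                    minus_mass=minus,
                )
            )
    return [l for l in loci if l.strand_bias > min_bias]


@dataclass
class AnnotationCriteriaReport:
    """Precise-excision (MIRNA annotation criteria) check: share of the locus
    mass carried by the single most abundant coterminal sRNA group per arm."""

    precision: float
    passes_meyers: bool
    top_groups: list[tuple[str, str, float]]  # (arm, representative seq, mass)


@dataclass
class LocusReport:
    candidate: LocusCandidate
    hairpin: HairpinReport
    fold_start: int  # genome coordinate of the folded core window
    abundant: pd.DataFrame  # columns: sequence, size, abundance (summed)
    criteria: AnnotationCriteriaReport
    track: pd.DataFrame  # per-position abundance (position, mass)


def _coterminal_groups(
    entries: list[tuple[str, int, int, float]], tol: int = 1
) -> list[tuple[str, float]]:
    """Greedy grouping of (seq, start, end, mass) by shared ends within +-tol;
    returns (representative seq, group mass) sorted by mass, descending."""
    groups: list[dict] = []
    for seq, start, end, mass in sorted(entries, key=lambda e: -e[3]):
        placed = False
        for g in groups:
            if abs(start - g["start"]) <= tol and abs(end - g["end"]) <= tol:
                g["mass"] += mass
                placed = True
                break
        if not placed:
            groups.append({"rep": seq, "start": start, "end": end, "mass": mass})
    return sorted(((g["rep"], g["mass"]) for g in groups), key=lambda x: -x[1])


def report_locus(
    candidate: LocusCandidate,
    hairpin: HairpinReport,
    fold_start: int,
    hits_by_seq: dict[str, list[GenomeHit]],
    mass_by_seq: pd.Series,
    abundance_floor: float = 200.0,
    precision_threshold: float = 0.75,
    coterminal_tol: int = 1,
) -> LocusReport:
    """Rank the locus's abundant sRNAs and evaluate the annotation criteria.

    ``abundance_floor`` is in the units of ``mass_by_seq`` (TP2M summed across
    all libraries by default).
    """
    # every retained sequence with a hit inside the window
    entries: list[tuple[str, int, int, float]] = []
    for seq, hits in hits_by_seq.items():
        for h in hits:
            if h.chrom == candidate.chrom and h.start < candidate.end and h.end > candidate.start:
                entries.append((seq, h.start, h.end, float(mass_by_seq.get(seq, 0.0))))
    total_mass = sum(m for _, _, _, m in entries)

    abundant_rows = [
        {"sequence": seq, "size": len(seq), "abundance": mass}
        for seq, start, end, mass in sorted(entries, key=lambda e: -e[3])
        if mass >= abundance_floor
    ]
    seen: set[str] = set()
    dedup = [r for r in abundant_rows if not (r["sequence"] in seen or seen.add(r["sequence"]))]
    abundant = pd.DataFrame(dedup, columns=["sequence", "size", "abundance"])

    # per-position abundance track over the window
    pos = np.arange(candidate.start, candidate.end)
    mass_track = np.zeros(len(pos))
    for _, start, end, mass in entries:
        lo = max(start, candidate.start) - candidate.start
        hi = min(end, candidate.end) - candidate.start
        mass_track[lo:hi] += mass
    track = pd.DataFrame({"position": pos, "mass": mass_track})

    # annotation criteria: best coterminal group per arm
    loop_genome = fold_start + hairpin.loop_center
    arm_entries: dict[str, list[tuple[str, int, int, float]]] = {"5p": [], "3p": []}
    for seq, start, end, mass in entries:
        arm = "5p" if (start + end) / 2.0 < loop_genome else "3p"
        arm_entries[arm].append((seq, start, end, mass))
    top_groups: list[tuple[str, str, float]] = []
    top_mass = 0.0
    for arm in ("5p", "3p"):
        grouped = _coterminal_groups(arm_entries[arm], coterminal_tol)
        if grouped:
            rep, mass = grouped[0]
            top_groups.append((arm, rep, mass))
            top_mass += mass
    precision = top_mass / total_mass if total_mass > 0 else 0.0
    criteria = AnnotationCriteriaReport(
        precision=precision,
        passes_meyers=precision >= precision_threshold,
        top_groups=top_groups,
    )
    return LocusReport(
        candidate=candidate,
        hairpin=hairpin,
        fold_start=fold_start,
        abundant=abundant,
        criteria=criteria,
        track=track,
    )


def discover_loci(
    matrix: pd.DataFrame,
    hits_by_seq: dict[str, list[GenomeHit]],
    genome: dict[str, str],
    catalog: MirnaCatalog,
    tissue: str = LEAF,
    fold: float = 3.0,
    pseudocount: float = 1.0,
    candidate_floor: float = 50.0,
    flank: int = 250,
    merge_gap: int = 100,
    min_bias: float = 0.9,
    min_loop: int = 3,
    min_helix: int = 5,
    hairpin_threshold: float = 0.6,
    fold_pads: tuple[int, ...] = (0, 30, 60, 90),
    abundance_floor: float = 200.0,
    precision_threshold: float = 0.75,
) -> list[LocusReport]:
    """End-to-end discovery: candidates -> windows -> bias -> hairpin -> report.

    The precursor boundaries are unknown a priori, so folding searches a small
    grid of asymmetric paddings of the tight member-hit span (each side padded
    by one of ``fold_pads`` nt, window widened to at least 50 nt) and keeps
    the best-scoring window; the flanked window serves only for merging,
    strand-bias mass and reporting.
    """
    mass_by_seq = matrix.sum(axis=1)
    cands = candidate_sequences(
        matrix, catalog, tissue=tissue, fold=fold, pseudocount=pseudocount, floor=candidate_floor
    )
    windows = cluster_and_bias(
        cands, hits_by_seq, mass_by_seq, flank=flank, merge_gap=merge_gap, min_bias=min_bias
    )
    reports = []
    for cand in windows:
        chrom_seq = genome[cand.chrom]
        hp, lo = None, 0
        for p5 in fold_pads:
            for p3 in fold_pads:
                a = max(0, cand.core_start - p5)
                b = min(len(chrom_seq), cand.core_end + p3)
                if b - a < 50:
                    extra = 50 - (b - a)
                    a = max(0, a - extra // 2)
                    b = min(len(chrom_seq), a + 50)
                if b - a < 50:
                    continue
                trial = fold_hairpin(
                    chrom_seq[a:b], min_loop=min_loop, min_helix=min_helix,
                    threshold=hairpin_threshold,
                )
                if hp is None or trial.score > hp.score:
                    hp, lo = trial, a
        if hp is None or not hp.passes:
            continue
        reports.append(
            report_locus(
                cand,
                hp,
                lo,
                hits_by_seq,
                mass_by_seq,
                abundance_floor=abundance_floor,
                precision_threshold=precision_threshold,
            )
        )
    return reports


def loci_bed(reports: list[LocusReport]) -> pd.DataFrame:
    """BED6 table of discovered loci (score = strand bias x 1000)."""
    rows = [
        {
            "chrom": r.candidate.chrom,
            "start": r.candidate.core_start,
            "end": r.candidate.core_end,
            "name": f"locus_{i + 1}",
            "score": int(round(r.candidate.strand_bias * 1000)),
            "strand": r.candidate.strand,
        }
        for i, r in enumerate(reports)
    ]
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "name", "score", "strand"])
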