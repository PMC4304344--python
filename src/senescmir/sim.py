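"""Synthetic study generator.

Emulates the sequencing design the pipeline is built for: eight small-RNA
libraries (leaf and silique at four stages: young, mature, early senescence,
late senescence) and six PARE libraries (four leaf stages plus replicated
early/late senescence), over a fully synthetic genome carrying

* structural-RNA intervals (tRNA/rRNA/snoRNA/snRNA) that contaminate libraries,
* planted miRNA-like loci with stage-dependent abundance (the differential
  screen's ground truth),
* a senescence-inducible inverted-repeat locus whose five abundant small RNAs
  are the published sen-sRNA1-5 sequences, and
* a transcriptome with perfect-complement target sites whose PARE signal reads
  start exactly at the position paired to sRNA base 10.

Every random draw derives from ``SimulationConfig.seed``; identical configs
give byte-identical outputs.  A truth ledger (TSV) records each planted
sequence, its genomic placement, per-library expected read fraction and the
expected cleavage site, so downstream tests read expectations from the ledger
rather than from constants.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .seqtools import revcomp

STAGES = ("young", "mature", "early_senescence", "late_senescence")
TISSUES = ("leaf", "silique")

# Table-2 published small RNAs of the senescence-inducible locus (DNA letters).
SEN_SRNA_SEQUENCES = {
    "sen_sRNA1": "TTCTTGAACCTTGGAAGAAAA",
    "sen_sRNA2": "TCTTGAACCTTGGAAGAAAAC",
    "sen_sRNA3": "TGCAAGGTTCAAGAACGGATC",
    "sen_sRNA4": "TCTTGCAAGGTTCAAGAACGGATC",
    "sen_sRNA5": "ATTCGACAAAGTGAAGGGTTT",
}
# Published summed abundances (per ten million) used as relative proportions.
SEN_SRNA_PROPORTIONS = {
    "sen_sRNA1": 8361,
    "sen_sRNA2": 5840,
    "sen_sRNA3": 5435,
    "sen_sRNA4": 2347,
    "sen_sRNA5": 2520,
}

# Insert-size distributions by tissue: leaf small RNA is dominated by 21-mers
# (miRNA-rich), silique by 24-mers (siRNA-rich).
LEAF_SIZE_P = {18: 0.03, 19: 0.05, 20: 0.08, 21: 0.40, 22: 0.08, 23: 0.06, 24: 0.22, 25: 0.05, 26: 0.03}
SILIQUE_SIZE_P = {18: 0.03, 19: 0.04, 20: 0.07, 21: 0.22, 22: 0.07, 23: 0.07, 24: 0.40, 25: 0.06, 26: 0.04}

_MUT = str.maketrans("ACGT", "CATG")  # deterministic point substitution


def _mutate(seq: str, positions) -> str:
    s = list(seq)
    for p in positions:
        s[p] = s[p].translate(_MUT)
    return "".join(s)


@dataclass
class SrnaLibrarySpec:
    tissue: str
    stage: str
    depth: int = 100_000

    @property
    def lib_id(self) -> str:
        return f"{self.tissue}_{self.stage}"


@dataclass
class PareLibrarySpec:
    stage: str
    replicate: int = 1
    depth: int = 100_000

    @property
    def lib_id(self) -> str:
        base = f"pare_{self.stage}"
        return base if self.replicate == 1 else f"{base}_r{self.replicate}"


@dataclass
class PlantedMature:
    """One small RNA produced by a planted locus.

    ``weights`` maps sRNA library id -> expected fraction of that library's
    reads; ``pare_weights`` maps stage -> expected fraction of PARE reads that
    are the cleavage-signal tag guided by this sRNA (requires
    ``target_transcript``).  ``known_as`` lists catalog (miRBase-style) ids for
    this sequence; empty means the sRNA is novel (screen must not know it).
    """

    name: str
    sequence: str
    weights: dict[str, float] = field(default_factory=dict)
    known_as: list[str] = field(default_factory=list)
    target_transcript: str | None = None
    pare_weights: dict[str, float] = field(default_factory=dict)


@dataclass
class PlantedLocus:
    name: str
    precursor: str
    matures: list[PlantedMature]
    chrom: str = "chr1"
    start: int | None = None  # None -> placed automatically
    strand: str = "+"

    def validate(self) -> None:
        for m in self.matures:
            if m.sequence not in self.precursor:
                raise ValueError(f"{m.name} is not a substring of precursor {self.name}")
            for w in list(m.weights.values()) + list(m.pare_weights.values()):
                if w < 0:
                    raise ValueError(f"negative abundance weight for {m.name}")


@dataclass
class SimulationConfig:
    seed: int = 0
    n_chromosomes: int = 2
    chrom_length: int = 150_000
    adapter3: str = "TCGTATGCCGTCTTCTGCTTG"
    raw_read_length: int = 36
    srna_libraries: list[SrnaLibrarySpec] = field(default_factory=list)
    pare_libraries: list[PareLibrarySpec] = field(default_factory=list)
    planted_loci: list[PlantedLocus] = field(default_factory=list)
    structural_fraction: float = 0.15
    background_fraction: float = 0.05  # guaranteed minimum background
    pare_offtarget_fraction: float = 0.3  # guaranteed minimum off-target
    pare_complexity: dict[str, float] = field(
        default_factory=lambda: {
            "young": 1.0,
            "mature": 1.0,
            "early_senescence": 0.12,
            "late_senescence": 0.04,
        }
    )
    n_transcripts: int = 20
    transcript_length: int = 600
    n_structural_per_chrom: int = 10

    def validate(self) -> None:
        for spec in self.srna_libraries:
            if spec.depth <= 0:
                raise ValueError("library depth must be positive")
            if spec.tissue not in TISSUES or spec.stage not in STAGES:
                raise ValueError(f"unknown tissue/stage {spec.tissue}/{spec.stage}")
        for spec in self.pare_libraries:
            if spec.depth <= 0:
                raise ValueError("library depth must be positive")
            if spec.stage not in STAGES:
                raise ValueError(f"unknown stage {spec.stage}")
        for frac in (self.structural_fraction, self.background_fraction, self.pare_offtarget_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        for locus in self.planted_loci:
            locus.validate()
        for spec in self.srna_libraries:
            signal = sum(m.weights.get(spec.lib_id, 0.0) for l in self.planted_loci for m in l.matures)
            if signal + self.structural_fraction + self.background_fraction > 1.0 + 1e-9:
                raise ValueError(f"library {spec.lib_id}: signal+structural+background exceeds 1")
        for spec in self.pare_libraries:
            signal = sum(
                m.pare_weights.get(spec.stage, 0.0) for l in self.planted_loci for m in l.matures
            )
            if signal + self.pare_offtarget_fraction > 1.0 + 1e-9:
                raise ValueError(f"PARE library {spec.lib_id}: signal+off-target exceeds 1")

    def srna_lib_ids(self) -> list[str]:
        return [s.lib_id for s in self.srna_libraries]

    def pare_lib_ids(self) -> list[str]:
        return [s.lib_id for s in self.pare_libraries]


# ---------------------------------------------------------------------------
# Default study fixture
# ---------------------------------------------------------------------------


def sen_srna_precursor() -> str:
    """Build the near-perfect inverted-repeat precursor of the bundled locus.

    The 5' arm carries sen-sRNA4 (which contains sen-sRNA3), sen-sRNA5 and a
    lightly mutated reverse complement of the sen-sRNA1/2 span; the 3' arm is
    the reverse complement of the 5' arm except that the sen-sRNA1/2 span is
    restored exactly and the images of sen-sRNA4/5 carry two substitutions
    each.  The result: all five published sequences occur exactly once, all on
    the plus strand, and the precursor pairs at ~93% of arm positions — a
    nearly perfect inverted repeat, as a hairpin small-RNA precursor should be.
    """
    s4 = SEN_SRNA_SEQUENCES["sen_sRNA4"]
    s5 = SEN_SRNA_SEQUENCES["sen_sRNA5"]
    # union span covering sen-sRNA1 and sen-sRNA2
    span12 = "TTCTTGAACCTTGGAAGAAAAC"
    rc12_m = _mutate(revcomp(span12), (8, 12))
    f1, f2, f3, f4 = "GAGA", "TCAC", "GATG", "CTTC"
    arm5 = f1 + s4 + f2 + s5 + f3 + rc12_m + f4
    arm3 = list(revcomp(arm5))
    n = len(arm5)

    def image(a: int, b: int) -> slice:  # arm5[a:b] -> its image in arm3
        return slice(n - b, n - a)

    # restore the exact sen-sRNA1/2 span on the 3' arm
    a = len(f1) + len(s4) + len(f2) + len(s5) + len(f3)
    arm3[image(a, a + len(span12))] = list(span12)
    # break the minus-strand images of sen-sRNA4 and sen-sRNA5
    a4 = len(f1)
    sl4 = image(a4, a4 + len(s4))
    arm3[sl4.start + 10] = arm3[sl4.start + 10].translate(_MUT)
    arm3[sl4.start + 14] = arm3[sl4.start + 14].translate(_MUT)
    a5 = len(f1) + len(s4) + len(f2)
    sl5 = image(a5, a5 + len(s5))
    arm3[sl5.start + 8] = arm3[sl5.start + 8].translate(_MUT)
    arm3[sl5.start + 12] = arm3[sl5.start + 12].translate(_MUT)

    loop = "GTTTAGAG"
    precursor = arm5 + loop + "".join(arm3)

    # construction self-check: every mature exactly once, plus strand only
    for name, seq in SEN_SRNA_SEQUENCES.items():
        if precursor.count(seq) != 1 or revcomp(seq) in precursor:
            raise AssertionError(f"precursor construction broke uniqueness of {name}")
    return precursor


#: per-library total read fraction of the senescence locus (sums over matures)
SEN_LOCUS_TOTALS = {
    "leaf_young": 0.002,
    "leaf_mature": 0.004,
    "leaf_early_senescence": 0.02,
    "leaf_late_senescence": 0.06,
    "silique_young": 0.002,
    "silique_mature": 0.004,
    "silique_early_senescence": 0.015,
    "silique_late_senescence": 0.05,
}


def sen_srna_locus() -> PlantedLocus:
    """The bundled senescence-inducible inverted-repeat locus."""
    precursor = sen_srna_precursor()
    prop_total = sum(SEN_SRNA_PROPORTIONS.values())
    matures = []
    for name, seq in SEN_SRNA_SEQUENCES.items():
        share = SEN_SRNA_PROPORTIONS[name] / prop_total
        weights = {lib: tot * share for lib, tot in SEN_LOCUS_TOTALS.items()}
        m = PlantedMature(name=name, sequence=seq, weights=weights)
        matures.append(m)
    # sen-sRNA3 guides cleavage of a tubulin-like transcript
    m3 = next(m for m in matures if m.name == "sen_sRNA3")
    m3.target_transcript = "tx05"
    m3.pare_weights = {
        "young": 0.01,
        "mature": 0.02,
        "early_senescence": 0.10,
        "late_senescence": 0.22,
    }
    return PlantedLocus(name="sen_sRNA_locus", precursor=precursor, matures=matures, chrom="chr1")


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, length)])


def default_screen_mirnas(seed: int, adapter3: str = "TCGTATGCCGTCTTCTGCTTG") -> list[PlantedLocus]:
    """Planted known miRNAs for the differential screen: folds 8/6/4 up, 1/6
    down, four unchanged, plus a two-member family sharing one sequence."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 77]))
    probe = adapter3[:7]

    def fresh_seq() -> str:
        # a planted mature must not contain the adapter probe, or trimming
        # would truncate it
        while True:
            seq = _random_seq(rng, 21)
            if probe not in seq:
                return seq

    def ramp(fold: float, base: float) -> dict[str, float]:
        w = {}
        for tissue in TISSUES:
            for stage in STAGES:
                lib = f"{tissue}_{stage}"
                if tissue == "leaf":
                    if stage == "early_senescence":
                        w[lib] = base * max(fold / 2.0, min(fold, 1.0))
                    elif stage == "late_senescence":
                        w[lib] = base * fold
                    else:
                        w[lib] = base
                else:
                    w[lib] = base
        return w

    # mature-stage abundances span ~an order of magnitude, as a real miRNA
    # complement does; regulated effects sit in the several-fold range typical
    # of senescence-responsive miRNAs
    plan = [
        ("mir_up_1", 8.0, 0.004),
        ("mir_up_2", 6.0, 0.002),
        ("mir_up_3", 4.0, 0.001),
        ("mir_down_1", 1.0 / 6.0, 0.003),
        ("mir_flat_1", 1.0, 0.0005),
        ("mir_flat_2", 1.0, 0.001),
        ("mir_flat_3", 1.0, 0.002),
        ("mir_flat_4", 1.0, 0.006),
    ]
    loci = []
    for name, fold, base in plan:
        seq = fresh_seq()
        mature = PlantedMature(name=name, sequence=seq, weights=ramp(fold, base), known_as=[name])
        loci.append(PlantedLocus(name=f"{name}_locus", precursor=seq, matures=[mature]))
    # family pair: two catalog ids, one sequence, flat profile
    fam_seq = fresh_seq()
    fam = PlantedMature(
        name="mir_fam_1", sequence=fam_seq, weights=ramp(1.0, 0.0015),
        known_as=["mir_fam_1a", "mir_fam_1b"],
    )
    loci.append(PlantedLocus(name="mir_fam_1_locus", precursor=fam_seq, matures=[fam]))
    # an up-regulated miRNA with PARE signal ramping across stages
    up1 = loci[0].matures[0]
    up1.target_transcript = "tx09"
    up1.pare_weights = {
        "young": 0.02,
        "mature": 0.04,
        "early_senescence": 0.12,
        "late_senescence": 0.25,
    }
    return loci


def default_config(seed: int = 0, depth: int = 100_000, with_planted: bool = True) -> SimulationConfig:
    """The bundled study design: 8 sRNA libraries, 6 PARE libraries."""
    srna = [SrnaLibrarySpec(t, s, depth) for t in TISSUES for s in STAGES]
    pare = [PareLibrarySpec(s, 1, depth) for s in STAGES]
    pare += [PareLibrarySpec("early_senescence", 2, depth), PareLibrarySpec("late_senescence", 2, depth)]
    loci = []
    if with_planted:
        loci = [sen_srna_locus()] + default_screen_mirnas(seed)
    cfg = SimulationConfig(seed=seed, srna_libraries=srna, pare_libraries=pare, planted_loci=loci)
    cfg.validate()
    return cfg


def build_catalog(config: SimulationConfig, include_absent: bool = True) -> dict[str, str]:
    """miRBase-style catalog of 'known' miRNAs: every planted mature that
    carries catalog ids, plus one entry absent from all libraries."""
    catalog: dict[str, str] = {}
    for locus in config.planted_loci:
        for m in locus.matures:
            for cid in m.known_as:
                catalog[cid] = m.sequence
    if include_absent:
        rng = np.random.default_rng(np.random.SeedSequence([config.seed, 78]))
        catalog["mir_absent_1"] = _random_seq(rng, 21)
    return catalog


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------


@dataclass
class Reference:
    config: SimulationConfig
    genome: dict[str, str]
    features: list[io.Feature]
    transcripts: dict[str, str]
    ledger: pd.DataFrame


def build_reference(config: SimulationConfig) -> Reference:
    """Generate genome, annotations, transcriptome and the truth ledger."""
    config.validate()
    rng_genome = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    chroms = [f"chr{i + 1}" for i in range(config.n_chromosomes)]
    genome = {c: _random_seq(rng_genome, config.chrom_length) for c in chroms}

    # place planted loci (auto positions spread along chr1, then chr2, ...)
    occupied: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    auto = [l for l in config.planted_loci if l.start is None]
    for i, locus in enumerate(auto):
        chrom = chroms[i % len(chroms)]
        step = config.chrom_length // (len(auto) // len(chroms) + 2)
        locus.chrom = chrom
        locus.start = step * (i // len(chroms) + 1)
    for locus in config.planted_loci:
        if locus.start + len(locus.precursor) > config.chrom_length:
            raise ValueError(f"locus {locus.name} does not fit on {locus.chrom}")
        ins = locus.precursor if locus.strand == "+" else revcomp(locus.precursor)
        g = genome[locus.chrom]
        genome[locus.chrom] = g[: locus.start] + ins + g[locus.start + len(ins):]
        occupied[locus.chrom].append((locus.start - 50, locus.start + len(ins) + 50))

    # structural-RNA intervals, disjoint from planted loci
    rng_struct = np.random.default_rng(np.random.SeedSequence([config.seed, 3]))
    types = ["rRNA", "tRNA", "snoRNA", "snRNA"]
    features: list[io.Feature] = []
    for chrom in chroms:
        placed = 0
        attempts = 0
        while placed < config.n_structural_per_chrom:
            attempts += 1
            if attempts > 1000:
                raise ValueError("could not place structural intervals without collision")
            length = int(rng_struct.integers(80, 300))
            start = int(rng_struct.integers(0, config.chrom_length - length))
            span = (start, start + length)
            clash = any(span[0] < e and s < span[1] for s, e in occupied[chrom])
            if clash:
                continue
            occupied[chrom].append(span)
            ftype = types[(placed + len(features)) % len(types)]
            features.append(
                io.Feature(chrom, start, start + length, "+", ftype, f"{ftype}_{chrom}_{placed}")
            )
            placed += 1
    features.sort(key=lambda f: (f.chrom, f.start))

    # transcriptome with planted perfect-complement target sites
    rng_tx = np.random.default_rng(np.random.SeedSequence([config.seed, 4]))
    transcripts = {
        f"tx{i + 1:02d}": _random_seq(rng_tx, config.transcript_length)
        for i in range(config.n_transcripts)
    }
    site_pos = config.transcript_length // 2
    cleavage: dict[str, tuple[str, int]] = {}
    for locus in config.planted_loci:
        for m in locus.matures:
            if m.target_transcript is None:
                continue
            if m.target_transcript not in transcripts:
                raise ValueError(f"declared target transcript {m.target_transcript} absent")
            t = transcripts[m.target_transcript]
            site = revcomp(m.sequence)
            transcripts[m.target_transcript] = (
                t[:site_pos] + site + t[site_pos + len(site):]
            )
            # 5' end of the downstream cleavage fragment: paired to sRNA base 10
            cleavage[m.name] = (m.target_transcript, site_pos + len(m.sequence) - 10)

    # truth ledger
    rows = []
    for locus in config.planted_loci:
        for m in locus.matures:
            offset = locus.precursor.index(m.sequence)
            if locus.strand == "+":
                start = locus.start + offset
            else:
                start = locus.start + len(locus.precursor) - offset - len(m.sequence)
            row = {
                "record": "mature",
                "name": m.name,
                "locus": locus.name,
                "sequence": m.sequence,
                "length": len(m.sequence),
                "chrom": locus.chrom,
                "start": start,
                "strand": locus.strand,
                "known_as": ",".join(m.known_as),
                "transcript": m.target_transcript or "",
                "cleavage_pos": cleavage[m.name][1] + 1 if m.name in cleavage else -1,
            }
            for lib in config.srna_lib_ids():
                row[f"w_{lib}"] = m.weights.get(lib, 0.0)
            for spec in config.pare_libraries:
                row[f"pw_{spec.lib_id}"] = m.pare_weights.get(spec.stage, 0.0)
            rows.append(row)
        rows.append(
            {
                "record": "locus",
                "name": locus.name,
                "locus": locus.name,
                "sequence": locus.precursor,
                "length": len(locus.precursor),
                "chrom": locus.chrom,
                "start": locus.start,
                "strand": locus.strand,
                "known_as": "",
                "transcript": "",
                "cleavage_pos": -1,
            }
        )
    columns = [
        "record", "name", "locus", "sequence", "length", "chrom", "start", "strand",
        "known_as", "transcript", "cleavage_pos",
    ] + [f"w_{lib}" for lib in config.srna_lib_ids()] + [
        f"pw_{lib}" for lib in config.pare_lib_ids()
    ]
    ledger = pd.DataFrame(rows).reindex(columns=columns).fillna(0.0)
    return Reference(config=config, genome=genome, features=features, transcripts=transcripts, ledger=ledger)


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------


def _size_dist(tissue: str) -> tuple[np.ndarray, np.ndarray]:
    dist = LEAF_SIZE_P if tissue == "leaf" else SILIQUE_SIZE_P
    lengths = np.array(sorted(dist))
    probs = np.array([dist[l] for l in lengths], dtype=float)
    return lengths, probs / probs.sum()


def _genomic_insert(genome: dict[str, str], chrom: str, pos: int, length: int, strand: str) -> str:
    s = genome[chrom][pos: pos + length]
    return s if strand == "+" else revcomp(s)


def simulate_srna_library(ref: Reference, tissue: str, stage: str) -> Counter:
    """Simulate one raw small-RNA library as collapsed (raw read -> count).

    Raw reads are insert + 3' adapter truncated to the configured raw read
    length.  Inserts are a seeded multinomial mix of planted matures (at their
    per-library weights), structural-interval fragments and uniform genomic
    background; read count equals the configured depth exactly.
    """
    config = ref.config
    try:
        spec_idx, spec = next(
            (i, s)
            for i, s in enumerate(config.srna_libraries)
            if s.tissue == tissue and s.stage == stage
        )
    except StopIteration:
        raise KeyError(f"no sRNA library configured for {tissue}/{stage}") from None
    lib_id = spec.lib_id
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 2, spec_idx]))

    matures = [m for locus in config.planted_loci for m in locus.matures]
    weights = np.array([m.weights.get(lib_id, 0.0) for m in matures])
    p_struct = config.structural_fraction
    p_bg = 1.0 - weights.sum() - p_struct
    if p_bg < -1e-9:
        raise ValueError("planted + structural fractions exceed 1")
    probs = np.concatenate([weights, [p_struct, max(p_bg, 0.0)]])
    counts = rng.multinomial(spec.depth, probs / probs.sum())

    raw_len = config.raw_read_length
    adapter = config.adapter3

    def to_raw(insert: str) -> str:
        return (insert + adapter)[:raw_len]

    reads: Counter = Counter()
    for m, c in zip(matures, counts[: len(matures)]):
        if c:
            reads[to_raw(m.sequence)] += int(c)

    lengths, length_p = _size_dist(tissue)

    n_struct = int(counts[len(matures)])
    structural = [f for f in ref.features if f.ftype in io.STRUCTURAL_TYPES]
    if n_struct and not structural:
        raise ValueError("structural_fraction > 0 but no structural intervals")
    if n_struct:
        idx = rng.integers(0, len(structural), n_struct)
        lens = rng.choice(lengths, n_struct, p=length_p)
        strands = np.where(rng.random(n_struct) < 0.5, "+", "-")
        offs = rng.random(n_struct)
        for i, L, st, off in zip(idx, lens, strands, offs):
            f = structural[i]
            L = int(min(L, f.end - f.start))
            pos = f.start + int(off * (f.end - f.start - L + 1))
            reads[to_raw(_genomic_insert(ref.genome, f.chrom, pos, L, st))] += 1

    n_bg = int(counts[-1])
    if n_bg:
        chrom_names = list(ref.genome)
        cidx = rng.integers(0, len(chrom_names), n_bg)
        lens = rng.choice(lengths, n_bg, p=length_p)
        strands = np.where(rng.random(n_bg) < 0.5, "+", "-")
        offs = rng.random(n_bg)
        for ci, L, st, off in zip(cidx, lens, strands, offs):
            chrom = chrom_names[ci]
            pos = int(off * (len(ref.genome[chrom]) - int(L) + 1))
            reads[to_raw(_genomic_insert(ref.genome, chrom, pos, int(L), st))] += 1

    assert sum(reads.values()) == spec.depth
    return reads


def simulate_pare_library(ref: Reference, stage: str, replicate: int = 1) -> Counter:
    """Simulate one PARE library as collapsed (20-nt read -> count).

    Signal reads are exactly the 20-nt transcript substring starting at the
    predicted cleavage site (paired to sRNA base 10); off-target reads start
    uniformly on transcripts, drawn from a per-stage position pool whose size
    shrinks with the configured complexity factor (senescence libraries lose
    distinct-sequence complexity, as the degradome does).
    """
    config = ref.config
    try:
        spec_idx, spec = next(
            (i, s)
            for i, s in enumerate(config.pare_libraries)
            if s.stage == stage and s.replicate == replicate
        )
    except StopIteration:
        raise KeyError(f"no PARE library configured for {stage} (rep {replicate})") from None
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 6, spec_idx]))

    guides = [
        m
        for locus in config.planted_loci
        for m in locus.matures
        if m.pare_weights.get(stage, 0.0) > 0
    ]
    weights = np.array([m.pare_weights[stage] for m in guides])
    p_off = 1.0 - weights.sum()
    probs = np.concatenate([weights, [max(p_off, 0.0)]])
    counts = rng.multinomial(spec.depth, probs / probs.sum())

    mature_rows = ref.ledger[ref.ledger.record == "mature"].set_index("name")
    reads: Counter = Counter()
    read_len = 20
    for m, c in zip(guides, counts[:-1]):
        if not c:
            continue
        site0 = int(mature_rows.loc[m.name, "cleavage_pos"]) - 1
        t = ref.transcripts[m.target_transcript]
        reads[t[site0: site0 + read_len]] += int(c)

    # stage-level off-target position pool (shared by replicates of a stage)
    positions = [
        (tx, p)
        for tx, seq in ref.transcripts.items()
        for p in range(len(seq) - read_len + 1)
    ]
    stage_idx = STAGES.index(stage)
    rng_pool = np.random.default_rng(np.random.SeedSequence([config.seed, 5, stage_idx]))
    perm = rng_pool.permutation(len(positions))
    c = config.pare_complexity.get(stage, 1.0)
    pool = perm[: max(1, int(np.ceil(c * len(positions))))]

    n_off = int(counts[-1])
    if n_off:
        picks = rng.integers(0, len(pool), n_off)
        for k in picks:
            tx, p = positions[pool[k]]
            reads[ref.transcripts[tx][p: p + read_len]] += 1

    assert sum(reads.values()) == spec.depth
    return reads


# ---------------------------------------------------------------------------
# On-disk study bundle
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig, outdir: str | Path) -> Reference:
    """Write the full synthetic study (reference + raw FASTQ libraries) to disk."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ref = build_reference(config)
    io.write_fasta(ref.genome, outdir / "genome.fa")
    io.write_gff3(ref.features, outdir / "annotations.gff3")
    io.write_fasta(ref.transcripts, outdir / "transcripts.fa")
    ref.ledger.to_csv(outdir / "truth_ledger.tsv", sep="\t", index=False)
    io.write_fasta(build_catalog(config), outdir / "mirna_catalog.fa")
    for spec in config.srna_libraries:
        reads = simulate_srna_library(ref, spec.tissue, spec.stage)
        io.write_fastq(reads, outdir / f"srna_{spec.lib_id}.fastq")
    for spec in config.pare_libraries:
        reads = simulate_pare_library(ref, spec.stage, spec.replicate)
        io.write_fastq(reads, outdir / f"{spec.lib_id}.fastq")
    return ref
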