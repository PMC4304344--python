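"""End-to-end orchestration: simulate -> process -> screen -> discover ->
targets -> PARE, from one seeded configuration, with per-stage read-count
accounting in a plain-text log and deterministic TSV outputs."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import degradome, io, locus_discovery, read_processing, sim, srna_quant, target_prediction
from .seqtools import dna_to_rna


@dataclass
class Thresholds:
    """All decision thresholds, defaulting to the screen's canonical values."""

    fold: float = 3.0
    floor: float = 50.0  # TP2M
    pseudocount: float = 1.0
    min_bias: float = 0.9
    hairpin_threshold: float = 0.6
    target_cutoff: float = 4.0
    cleavage_window: int = 0
    rank_max: int = 5
    abundance_floor: float = 200.0  # summed TP2M across libraries
    scale: int = read_processing.TP2M_SCALE


@dataclass
class RunConfig:
    simulation: sim.SimulationConfig
    thresholds: Thresholds = field(default_factory=Thresholds)
    outdir: str | Path = "senescmir_run"
    n_targets_per_locus: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        simraw = raw.get("simulation", {})
        simcfg = sim.default_config(seed=int(simraw.get("seed", 0)), depth=int(simraw.get("depth", 100_000)))
        for key in ("n_chromosomes", "chrom_length", "structural_fraction", "background_fraction"):
            if key in simraw:
                setattr(simcfg, key, simraw[key])
        simcfg.validate()
        thr = Thresholds(**raw.get("thresholds", {}))
        return cls(
            simulation=simcfg,
            thresholds=thr,
            outdir=raw.get("outdir", "senescmir_run"),
        )

    def digest(self) -> str:
        blob = yaml.safe_dump(
            {
                "simulation": repr(self.simulation),
                "thresholds": dataclasses.asdict(self.thresholds),
            },
            sort_keys=True,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


@dataclass
class RunResult:
    reference: sim.Reference
    processed: dict[str, read_processing.ProcessedLibrary]
    stats: pd.DataFrame
    matrix: pd.DataFrame  # sequence x library TP2M
    mirna_matrix: pd.DataFrame
    screens: dict[str, pd.DataFrame]
    loci: list[locus_discovery.LocusReport]
    targets: list[target_prediction.TargetAlignment]
    pare_libraries: dict[str, degradome.PareLibrary]
    evidence: pd.DataFrame
    stage_tracks: pd.DataFrame | None
    log_lines: list[str]


def run_pipeline(config: RunConfig, write: bool = True) -> RunResult:
    """Execute the full pipeline; optionally write the report bundle."""
    thr = config.thresholds
    log: list[str] = []

    def say(msg: str) -> None:
        log.append(msg)

    simcfg = config.simulation
    say(f"seed={simcfg.seed} config_hash={config.digest()}")
    ref = sim.build_reference(simcfg)
    say(
        f"reference: {len(ref.genome)} chromosomes x {simcfg.chrom_length} nt, "
        f"{len(ref.features)} structural intervals, {len(ref.transcripts)} transcripts, "
        f"{len(simcfg.planted_loci)} planted loci"
    )
    index = read_processing.GenomeIndex(ref.genome)
    catalog = srna_quant.MirnaCatalog.from_mapping(sim.build_catalog(simcfg))

    processed: dict[str, read_processing.ProcessedLibrary] = {}
    for spec in simcfg.srna_libraries:
        raw = sim.simulate_srna_library(ref, spec.tissue, spec.stage)
        p = read_processing.process_library(
            raw, simcfg.adapter3, index, ref.features,
            library_id=spec.lib_id, tissue=spec.tissue, stage=spec.stage, scale=thr.scale,
        )
        processed[spec.lib_id] = p
        s = p.stats
        say(
            f"library {spec.lib_id}: raw={s.raw_total} trimmed={s.raw_trimmed} "
            f"genome_matched={s.genome_matched} structural={s.structural} "
            f"retained={s.retained} distinct={s.retained_distinct}"
        )
        assert s.genome_matched == s.structural + s.retained, "count conservation violated"

    stats = read_processing.stats_table(p.stats for p in processed.values())
    matrix = read_processing.abundance_matrix(p.abundance for p in processed.values())
    mirnas = srna_quant.mirna_matrix(matrix, catalog)

    screens = {}
    for tissue in sim.TISSUES:
        if any(c.startswith(f"{tissue}_") for c in mirnas.columns):
            screens[tissue] = srna_quant.screen_differential(
                mirnas, tissue, floor=thr.floor, fold=thr.fold, pseudocount=thr.pseudocount
            )
            n_up = int(screens[tissue]["candidate_up"].sum())
            n_down = int(screens[tissue]["candidate_down"].sum())
            say(f"screen {tissue}: {n_up} up, {n_down} down candidates")

    hits_by_seq: dict[str, list[read_processing.GenomeHit]] = {}
    for p in processed.values():
        hits_by_seq.update(p.hits_by_seq)
    loci = locus_discovery.discover_loci(
        matrix, hits_by_seq, ref.genome, catalog,
        fold=thr.fold, pseudocount=thr.pseudocount, candidate_floor=thr.floor,
        min_bias=thr.min_bias, hairpin_threshold=thr.hairpin_threshold,
        abundance_floor=thr.abundance_floor,
    )
    say(f"discovery: {len(loci)} loci pass bias>{thr.min_bias} and hairpin>={thr.hairpin_threshold}")

    targets: list[target_prediction.TargetAlignment] = []
    for i, rep in enumerate(loci):
        for seq in rep.abundant["sequence"].head(config.n_targets_per_locus):
            targets.extend(
                target_prediction.predict_targets(
                    seq, ref.transcripts, cutoff=thr.target_cutoff,
                    srna_id=f"locus{i + 1}:{dna_to_rna(seq)}",
                )
            )
    say(f"target prediction: {len(targets)} sites at score<={thr.target_cutoff}")

    pare_libs: dict[str, degradome.PareLibrary] = {}
    evidence_rows = []
    stage_tracks = None
    if simcfg.pare_libraries:
        for spec in simcfg.pare_libraries:
            reads = sim.simulate_pare_library(ref, spec.stage, spec.replicate)
            lib = degradome.build_profiles(reads, ref.transcripts, library_id=spec.lib_id)
            pare_libs[spec.lib_id] = lib
            say(
                f"PARE {spec.lib_id}: raw={lib.stats.raw_total} "
                f"matched={lib.stats.transcript_matched} distinct={lib.stats.distinct}"
            )
        for aln in targets:
            for lib_id, lib in pare_libs.items():
                ev = degradome.validate_cleavage(
                    aln, lib.profiles[aln.transcript_id],
                    window=thr.cleavage_window, rank_max=thr.rank_max,
                )
                evidence_rows.append(
                    {
                        "srna": aln.srna_id,
                        "transcript": aln.transcript_id,
                        "site": ev.expected_site,
                        "library": lib_id,
                        "observed": ev.observed,
                        "rank": ev.site_rank,
                        "fraction": round(ev.fraction, 6),
                        "supported": ev.supported,
                    }
                )
        stage_libs = {
            spec.stage: pare_libs[spec.lib_id]
            for spec in simcfg.pare_libraries
            if spec.replicate == 1
        }
        if targets and len(stage_libs) >= 2:
            order = [s for s in sim.STAGES if s in stage_libs]
            stage_tracks = degradome.track_site_across_stages(targets, stage_libs, order)
    evidence = pd.DataFrame(
        evidence_rows,
        columns=["srna", "transcript", "site", "library", "observed", "rank", "fraction", "supported"],
    )
    say(f"cleavage evidence: {int(evidence['supported'].sum()) if len(evidence) else 0} supported site-library pairs")

    result = RunResult(
        reference=ref, processed=processed, stats=stats, matrix=matrix,
        mirna_matrix=mirnas, screens=screens, loci=loci, targets=targets,
        pare_libraries=pare_libs, evidence=evidence, stage_tracks=stage_tracks,
        log_lines=log,
    )
    if write:
        _write_bundle(config, result)
    return result


def targets_table(targets: list[target_prediction.TargetAlignment]) -> pd.DataFrame:
    rows = [
        {
            "srna": a.srna_id,
            "transcript": a.transcript_id,
            "window_start": a.window_start + 1,
            "window_end": a.window_end,
            "score": a.score,
            "cleavage_site": a.cleavage_site,
            "pairing": a.pairing,
        }
        for a in targets
    ]
    return pd.DataFrame(
        rows,
        columns=["srna", "transcript", "window_start", "window_end", "score", "cleavage_site", "pairing"],
    )


def abundant_table(loci: list[locus_discovery.LocusReport]) -> pd.DataFrame:
    frames = []
    for i, rep in enumerate(loci):
        df = rep.abundant.copy()
        df.insert(0, "locus", f"locus_{i + 1}")
        df["sequence"] = df["sequence"].map(dna_to_rna)
        frames.append(df)
    if not frames:
        return pd.DataFrame(columns=["locus", "sequence", "size", "abundance"])
    return pd.concat(frames, ignore_index=True)


def _write_bundle(config: RunConfig, result: RunResult) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_tsv(result.stats, outdir / "library_stats.tsv")
    io.write_tsv(result.mirna_matrix.round(3), outdir / "mirna_matrix.tsv")
    for tissue, df in result.screens.items():
        io.write_tsv(df.round(4), outdir / f"screen_{tissue}.tsv")
    io.write_tsv(locus_discovery.loci_bed(result.loci), outdir / "loci.bed", index=False)
    io.write_tsv(abundant_table(result.loci).round(1), outdir / "abundant_srnas.tsv", index=False)
    io.write_tsv(targets_table(result.targets).round(2), outdir / "targets.tsv", index=False)
    io.write_tsv(result.evidence, outdir / "cleavage_evidence.tsv", index=False)
    if result.pare_libraries:
        pstats = pd.DataFrame(
            [
                {
                    "library": l.stats.library_id,
                    "raw": l.stats.raw_total,
                    "transcript_matched": l.stats.transcript_matched,
                    "distinct": l.stats.distinct,
                }
                for l in result.pare_libraries.values()
            ]
        ).set_index("library")
        io.write_tsv(pstats, outdir / "pare_stats.tsv")
    if result.stage_tracks is not None:
        io.write_tsv(result.stage_tracks.round(3), outdir / "site_stage_tracks.tsv", index=False)
    for i, rep in enumerate(result.loci):
        track = rep.track
        with open(outdir / f"locus_{i + 1}.bedGraph", "w") as fh:
            for _, row in track.iterrows():
                if row["mass"] > 0:
                    fh.write(
                        f"{rep.candidate.chrom}\t{int(row['position'])}\t"
                        f"{int(row['position']) + 1}\t{row['mass']:.2f}\n"
                    )
    discovered = {
        f"locus_{i + 1}_{j + 1}": row.sequence
        for i, rep in enumerate(result.loci)
        for j, row in enumerate(rep.abundant.itertuples())
    }
    if discovered:
        io.write_fasta(discovered, outdir / "discovered_srnas.fa")
    summary = {
        "seed": config.simulation.seed,
        "config_hash": config.digest(),
        "libraries": list(result.processed),
        "n_loci": len(result.loci),
        "n_targets": len(result.targets),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    (outdir / "run.log").write_text("\n".join(result.log_lines) + "\n")
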