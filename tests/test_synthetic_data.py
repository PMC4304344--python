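"""The synthetic-study generator: determinism, conservation, planted truth."""

import numpy as np
import pytest

import senescmir as sm
from senescmir import io, sim
from senescmir.seqtools import revcomp


def small_config(seed=3, depth=10_000, **kw):
    cfg = sm.default_config(seed=seed, depth=depth)
    for k, v in kw.items():
        setattr(cfg, k, v)
    cfg.validate()
    return cfg


class TestPrecursorFixture:
    def test_all_five_matures_unique_plus_strand(self):
        pre = sim.sen_srna_precursor()
        for seq in sim.SEN_SRNA_SEQUENCES.values():
            assert pre.count(seq) == 1
            assert revcomp(seq) not in pre

    def test_mature_sizes(self):
        sizes = [len(s) for s in sim.SEN_SRNA_SEQUENCES.values()]
        assert sizes == [21, 21, 21, 24, 21]


class TestBuildReference:
    def test_precursors_planted_at_ledger_positions(self, study, mature_ledger):
        ref = study["reference"]
        led = ref.ledger
        for _, row in led[led.record == "locus"].iterrows():
            g = ref.genome[row["chrom"]][int(row["start"]): int(row["start"]) + int(row["length"])]
            assert g == row["sequence"]
        for _, row in mature_ledger.iterrows():
            g = ref.genome[row["chrom"]][int(row["start"]): int(row["start"]) + int(row["length"])]
            assert g == (row["sequence"] if row["strand"] == "+" else revcomp(row["sequence"]))

    def test_zero_planted_loci_gives_empty_ledger(self):
        cfg = sm.default_config(seed=5, depth=1000, with_planted=False)
        ref = sm.build_reference(cfg)
        assert len(ref.ledger) == 0
        assert len(ref.genome) == cfg.n_chromosomes

    def test_structural_intervals_disjoint_from_planted(self, study):
        ref = study["reference"]
        led = ref.ledger
        spans = [
            (row["chrom"], int(row["start"]), int(row["start"]) + int(row["length"]))
            for _, row in led[led.record == "locus"].iterrows()
        ]
        for f in ref.features:
            for chrom, s, e in spans:
                assert not (f.chrom == chrom and f.start < e and s < f.end)

    def test_same_seed_reproduces_outputs_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            sim.simulate_study(small_config(seed=9, depth=2000), tmp_path / d)
        for name in ("genome.fa", "annotations.gff3", "transcripts.fa",
                     "truth_ledger.tsv", "srna_leaf_young.fastq", "pare_young.fastq"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()

    def test_declared_target_absent_from_transcriptome_rejected(self):
        cfg = small_config()
        cfg.planted_loci[0].matures[2].target_transcript = "tx_nonexistent"
        with pytest.raises(ValueError, match="absent"):
            sm.build_reference(cfg)

    def test_gff3_roundtrip_preserves_intervals(self, tmp_path, study):
        ref = study["reference"]
        io.write_gff3(ref.features, tmp_path / "x.gff3")
        back = io.read_gff3(tmp_path / "x.gff3")
        assert {(f.chrom, f.start, f.end, f.ftype) for f in back} == {
            (f.chrom, f.start, f.end, f.ftype) for f in ref.features
        }


class TestSrnaLibraries:
    def test_depth_conservation(self, study):
        cfg = study["config"]
        reads = sim.simulate_srna_library(study["reference"], "leaf", "young")
        assert sum(reads.values()) == cfg.srna_libraries[0].depth

    def test_zero_weight_stage_emits_no_planted_reads(self):
        cfg = small_config(seed=4, depth=20_000)
        locus = cfg.planted_loci[0]
        for m in locus.matures:
            m.weights = {lib: (0.02 if lib == "leaf_late_senescence" else 0.0)
                         for lib in cfg.srna_lib_ids()}
        ref = sm.build_reference(cfg)
        adapter = cfg.adapter3
        raws = {
            stage: sim.simulate_srna_library(ref, "leaf", stage)
            for stage in ("mature", "late_senescence")
        }
        for m in locus.matures:
            raw_read = (m.sequence + adapter)[: cfg.raw_read_length]
            assert raws["mature"].get(raw_read, 0) == 0
            assert raws["late_senescence"].get(raw_read, 0) > 0

    def test_structural_read_fraction_binomial(self):
        # all non-structural reads planted -> structural count is a clean
        # binomial(depth, structural_fraction) draw
        cfg = small_config(seed=6, depth=10_000, structural_fraction=0.3)
        cfg.planted_loci = [cfg.planted_loci[0]]
        for m in cfg.planted_loci[0].matures:
            m.weights = {lib: 0.7 / 5 for lib in cfg.srna_lib_ids()}
            m.pare_weights = {}
        cfg.background_fraction = 0.0
        cfg.validate()
        ref = sm.build_reference(cfg)
        from senescmir import read_processing as rp

        index = rp.GenomeIndex(ref.genome)
        raw = sim.simulate_srna_library(ref, "leaf", "young")
        p = rp.process_library(raw, cfg.adapter3, index, ref.features, library_id="x")
        n, frac = 10_000, 0.3
        sigma = np.sqrt(n * frac * (1 - frac))
        assert abs(p.stats.structural - n * frac) <= 3 * sigma

    def test_raw_reads_have_fixed_length(self, study):
        reads = sim.simulate_srna_library(study["reference"], "silique", "mature")
        assert {len(r) for r in reads} == {study["config"].raw_read_length}

    def test_unknown_stage_rejected(self, study):
        with pytest.raises(KeyError):
            sim.simulate_srna_library(study["reference"], "leaf", "senile")


class TestPareLibraries:
    def test_every_read_is_20nt(self, study):
        reads = sim.simulate_pare_library(study["reference"], "young")
        assert {len(r) for r in reads} == {20}
        assert sum(reads.values()) == study["config"].pare_libraries[0].depth

    def test_pure_signal_library_has_single_start(self):
        cfg = small_config(seed=8, depth=5_000)
        for locus in cfg.planted_loci:
            for m in locus.matures:
                if m.name == "sen_sRNA3":
                    m.pare_weights = {"young": 1.0}
                else:
                    m.pare_weights = {}
        cfg.pare_offtarget_fraction = 0.0
        cfg.validate()
        ref = sm.build_reference(cfg)
        reads = sim.simulate_pare_library(ref, "young")
        led = ref.ledger[ref.ledger.record == "mature"].set_index("name")
        site0 = int(led.loc["sen_sRNA3", "cleavage_pos"]) - 1
        tx = ref.transcripts[led.loc["sen_sRNA3", "transcript"]]
        assert dict(reads) == {tx[site0: site0 + 20]: 5_000}

    def test_pure_offtarget_library_is_unenriched_at_site(self, mature_ledger):
        cfg = small_config(seed=8, depth=20_000)
        for locus in cfg.planted_loci:
            for m in locus.matures:
                m.pare_weights = {}
        ref = sm.build_reference(cfg)
        reads = sim.simulate_pare_library(ref, "young")
        row = mature_ledger.loc["sen_sRNA3"]
        tx = ref.transcripts[row["transcript"]]
        site0 = int(row["cleavage_pos"]) - 1
        site_count = reads.get(tx[site0: site0 + 20], 0)
        n_positions = sum(len(t) - 19 for t in ref.transcripts.values())
        expected = 20_000 / n_positions
        assert site_count <= expected + 5 * np.sqrt(expected) + 5

    def test_senescence_stage_complexity_drops(self, study):
        ref = study["reference"]
        young = sim.simulate_pare_library(ref, "young")
        late = sim.simulate_pare_library(ref, "late_senescence")
        assert len(late) < 0.25 * len(young)

    def test_replicates_share_stage_position_pool(self, study):
        ref = study["reference"]
        r1 = sim.simulate_pare_library(ref, "late_senescence", replicate=1)
        r2 = sim.simulate_pare_library(ref, "late_senescence", replicate=2)
        assert r1 != r2  # independent sampling
        assert len(set(r2) - set(r1)) / len(r2) < 0.2  # but a shared restricted pool


class TestConfigValidation:
    def test_overfull_fractions_rejected(self):
        cfg = small_config()
        cfg.structural_fraction = 0.95
        with pytest.raises(ValueError):
            cfg.validate()

    def test_nonpositive_depth_rejected(self):
        cfg = small_config()
        cfg.srna_libraries[0].depth = 0
        with pytest.raises(ValueError):
            cfg.validate()

    def test_mature_not_in_precursor_rejected(self):
        with pytest.raises(ValueError, match="substring"):
            sim.PlantedLocus(
                name="bad", precursor="ACGT" * 20,
                matures=[sim.PlantedMature(name="m", sequence="T" * 21)],
            ).validate()
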