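"""PARE profiles, cleavage validation, stage trends."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from senescmir import degradome as dg
from senescmir import sim
from senescmir.target_prediction import score_pairing
from senescmir.seqtools import revcomp


def rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestBuildProfiles:
    def test_pure_signal_single_position(self, study, mature_ledger):
        cfg = study["config"]
        row = mature_ledger.loc["sen_sRNA3"]
        tx = study["reference"].transcripts[row["transcript"]]
        site0 = int(row["cleavage_pos"]) - 1
        reads = {tx[site0: site0 + 20]: 500}
        lib = dg.build_profiles(reads, study["reference"].transcripts)
        profile = lib.profiles[row["transcript"]]
        nz = profile.counts.nonzero()[0]
        assert list(nz) == [site0]
        assert profile.counts[site0] == 500

    def test_multi_transcript_tag_counts_everywhere(self):
        rng = np.random.default_rng(1)
        shared = rand_seq(rng, 20)
        txs = {"a": rand_seq(rng, 100) + shared, "b": shared + rand_seq(rng, 100)}
        lib = dg.build_profiles({shared: 7}, txs)
        assert lib.profiles["a"].counts[100] == 7
        assert lib.profiles["b"].counts[0] == 7

    def test_mass_conservation_unique_tags(self):
        rng = np.random.default_rng(2)
        tx = rand_seq(rng, 400)
        reads = {tx[i: i + 20]: i + 1 for i in (0, 50, 123)}
        lib = dg.build_profiles(reads, {"t": tx})
        assert lib.profiles["t"].counts.sum() == sum(reads.values()) == lib.stats.transcript_matched

    def test_unmatched_reads_tallied(self):
        rng = np.random.default_rng(3)
        tx = rand_seq(rng, 100)
        lib = dg.build_profiles({"A" * 20: 9, tx[:20]: 1}, {"t": tx})
        assert lib.unmatched == 9 and lib.stats.transcript_matched == 1

    def test_distinct_matches_set_oracle(self, study):
        reads = sim.simulate_pare_library(study["reference"], "young")
        lib = dg.build_profiles(reads, study["reference"].transcripts)
        index_seqs = {
            t[i: i + 20]
            for t in study["reference"].transcripts.values()
            for i in range(len(t) - 19)
        }
        assert lib.stats.distinct == len(set(reads) & index_seqs)

    def test_uniform_offtarget_flattens_with_depth(self):
        """Uniform 5'-end draws: the max/mean position ratio shrinks toward 1
        as depth grows (multinomial concentration)."""
        rng = np.random.default_rng(4)
        tx = rand_seq(rng, 1000)
        ratios = []
        for depth in (2_000, 200_000):
            pos = rng.integers(0, 981, depth)
            counts = np.bincount(pos, minlength=981)
            reads = {}
            for p in np.nonzero(counts)[0]:
                reads[tx[p: p + 20]] = reads.get(tx[p: p + 20], 0) + int(counts[p])
            lib = dg.build_profiles(reads, {"t": tx})
            c = lib.profiles["t"].counts[:981]
            ratios.append(c.max() / c.mean())
        assert ratios[1] < ratios[0]
        # multinomial maximum stays within ~5 relative sd of the uniform mean
        assert ratios[1] < 1 + 5 / np.sqrt(200_000 / 981)


class TestValidateCleavage:
    @staticmethod
    def _profile(counts):
        vec = np.asarray(counts, dtype=np.int64)
        return dg.PareProfile("t", "lib", vec, vec * (1e7 / max(vec.sum(), 1)))

    def test_signal_at_site_supported_rank_one(self):
        counts = np.ones(100, dtype=int)
        counts[40] = 500
        ev = dg.validate_site("t", 41, self._profile(counts))
        assert ev.supported and ev.site_rank == 1
        assert ev.fraction == pytest.approx(500 / counts.sum())

    def test_zero_signal_unsupported(self):
        counts = np.ones(100, dtype=int)
        counts[40] = 0
        ev = dg.validate_site("t", 41, self._profile(counts))
        assert not ev.supported and ev.observed == 0

    def test_window_semantics_for_shifted_signal(self):
        counts = np.zeros(100, dtype=int)
        counts[43] = 300  # signal shifted +3 from the expected site
        assert not dg.validate_site("t", 41, self._profile(counts), window=0).supported
        assert dg.validate_site("t", 41, self._profile(counts), window=3).supported

    def test_verdict_invariant_to_depth_scaling(self):
        counts = np.ones(100, dtype=int)
        counts[40] = 50
        a = dg.validate_site("t", 41, self._profile(counts))
        b = dg.validate_site("t", 41, self._profile(counts * 10))
        assert (a.supported, a.site_rank) == (b.supported, b.site_rank)

    def test_site_outside_transcript_errors(self):
        with pytest.raises(ValueError):
            dg.validate_site("t", 101, self._profile(np.ones(100, dtype=int)))

    def test_alignment_based_validation(self, study, mature_ledger):
        row = mature_ledger.loc["sen_sRNA3"]
        tx_id = row["transcript"]
        tx = study["reference"].transcripts[tx_id]
        site = int(row["cleavage_pos"])
        w0 = tx.find(revcomp(row["sequence"]))
        aln = score_pairing(row["sequence"], tx[w0: w0 + 21], transcript_id=tx_id, window_start=w0)
        assert aln.cleavage_site == site
        reads = sim.simulate_pare_library(study["reference"], "late_senescence")
        lib = dg.build_profiles(reads, study["reference"].transcripts)
        ev = dg.validate_cleavage(aln, lib.profiles[tx_id])
        assert ev.supported and ev.site_rank == 1

    def test_null_false_support_rate_matches_exchangeable_expectation(self):
        """Uniform null PARE 5' ends: the rate of 'supported, rank<=5' at an
        arbitrary site stays within the exchangeable expectation (the share of
        positions holding rank <= 5, ties included) across 100 seeds."""
        rng = np.random.default_rng(99)
        n_pos, depth, seeds = 981, 10_000, 100
        false_hits = 0
        p_sum = 0.0
        for _ in range(seeds):
            counts = np.bincount(rng.integers(0, n_pos, depth), minlength=n_pos)
            site = int(rng.integers(0, n_pos))
            peak = counts[site]
            rank = int((counts > peak).sum()) + 1
            false_hits += (peak > 0) and (rank <= 5)
            ranks_all = (counts[None, :] > counts[:, None]).sum(axis=1) + 1
            p_sum += (ranks_all <= 5).mean()
        p_bar = p_sum / seeds
        bound = sp_stats.binom.ppf(0.999, seeds, p_bar)
        assert false_hits <= bound


class TestStageTracks:
    def test_ramping_signal_labelled_increasing(self, study, mature_ledger):
        ref = study["reference"]
        row = mature_ledger.loc["sen_sRNA3"]
        tx = ref.transcripts[row["transcript"]]
        w0 = tx.find(revcomp(row["sequence"]))
        aln = score_pairing(row["sequence"], tx[w0: w0 + 21],
                            transcript_id=row["transcript"], window_start=w0)
        libs = {
            stage: dg.build_profiles(sim.simulate_pare_library(ref, stage), ref.transcripts,
                                     library_id=stage)
            for stage in sim.STAGES
        }
        out = dg.track_site_across_stages([aln], libs, list(sim.STAGES))
        assert out.loc[0, "trend"] == "increasing"
        values = out.loc[0, list(sim.STAGES)].to_numpy(dtype=float)
        rho = sp_stats.spearmanr(np.arange(4), values).statistic
        assert out.loc[0, "spearman_rho"] == pytest.approx(rho)

    def test_flat_signal_has_no_trend(self):
        rng = np.random.default_rng(6)
        tx = rand_seq(rng, 200)
        aln = score_pairing("ACGTACGTACGTACGTACGTA", revcomp("ACGTACGTACGTACGTACGTA"),
                            transcript_id="t", window_start=50)
        counts = np.zeros(200, dtype=np.int64)
        counts[aln.cleavage_site - 1] = 100
        prof = dg.PareProfile("t", "x", counts, counts.astype(float))
        libs = {s: dg.PareLibrary(s, {"t": prof}, dg.PareLibraryStats(s, 100, 100, 1), 0)
                for s in ("a", "b", "c")}
        out = dg.track_site_across_stages([aln], libs, ["a", "b", "c"])
        assert out.loc[0, "trend"] == "none"

    def test_requires_two_stages(self):
        with pytest.raises(ValueError):
            dg.track_site_across_stages([], {}, [])


class TestGenomeSpaceStats:
    def test_matches_genome_mapped_tags(self):
        from senescmir import read_processing as rp

        rng = np.random.default_rng(17)
        genome = {"c": rand_seq(rng, 2000)}
        index = rp.GenomeIndex(genome)
        reads = {genome["c"][100:120]: 5, genome["c"][700:720]: 2, "A" * 20: 9}
        stats = dg.genome_space_stats(reads, index, library_id="x")
        assert stats.raw_total == 16
        assert stats.transcript_matched == 7  # genome-matched in this mode
        assert stats.distinct == 2
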