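"""Locus discovery: candidate filter, clustering/strand bias, hairpin DP,
locus reporting and annotation criteria."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from senescmir import locus_discovery as ld
from senescmir import sim
from senescmir.hairpin import fold_hairpin, stem_pairs
from senescmir.read_processing import GenomeHit
from senescmir.srna_quant import MirnaCatalog
from senescmir.seqtools import revcomp

dna = st.text(alphabet="ACGT", min_size=50, max_size=120)


def rand_seq(rng, n):
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])


class TestCandidateSequences:
    @staticmethod
    def _matrix():
        cols = ["leaf_young", "leaf_mature", "leaf_early_senescence", "leaf_late_senescence"]
        return pd.DataFrame(
            {
                "A" * 21: [50, 60, 300, 700],   # induced, unknown -> candidate
                "C" * 21: [50, 60, 320, 700],   # induced but catalogued -> excluded
                "G" * 21: [80, 90, 95, 100],    # flat -> excluded
                "T" * 21: [0, 1, 4, 5],         # induced but below floor -> excluded
            },
            index=cols,
        ).T

    def test_filter_logic(self):
        cat = MirnaCatalog.from_mapping({"known": "C" * 21})
        got = ld.candidate_sequences(self._matrix(), cat)
        assert got == ["A" * 21]

    def test_planted_matures_all_candidates(self, study):
        got = ld.candidate_sequences(study["matrix"], study["catalog"])
        assert set(sim.SEN_SRNA_SEQUENCES.values()) <= set(got)


class TestClusterAndBias:
    @staticmethod
    def _setup(plus_mass, minus_mass):
        cand = "A" * 21
        other = "C" * 21
        hits = {
            cand: [GenomeHit("c", 5000, 5021, "+")],
            other: [GenomeHit("c", 5050, 5071, "-")],
        }
        mass = pd.Series({cand: plus_mass, other: minus_mass})
        return cand, hits, mass

    def test_high_bias_window_kept(self):
        cand, hits, mass = self._setup(95.0, 5.0)
        wins = ld.cluster_and_bias([cand], hits, mass)
        assert len(wins) == 1
        assert wins[0].strand_bias == pytest.approx(0.95)

    def test_low_bias_window_dropped(self):
        cand, hits, mass = self._setup(60.0, 40.0)
        assert ld.cluster_and_bias([cand], hits, mass) == []

    def test_nearby_candidates_merge_into_one_window(self):
        a, b = "A" * 21, "G" * 21
        hits = {a: [GenomeHit("c", 5000, 5021, "+")], b: [GenomeHit("c", 5031, 5052, "+")]}
        mass = pd.Series({a: 100.0, b: 100.0})
        wins = ld.cluster_and_bias([a, b], hits, mass)
        assert len(wins) == 1
        assert set(wins[0].members) == {a, b}
        assert wins[0].core_start == 5000 and wins[0].core_end == 5052

    def test_candidate_without_hits_skipped_with_warning(self):
        with pytest.warns(UserWarning, match="without genome hits"):
            wins = ld.cluster_and_bias(["A" * 21], {"A" * 21: []}, pd.Series(dtype=float))
        assert wins == []

    def test_bias_uses_all_retained_mass_not_only_candidates(self):
        cand, hits, mass = self._setup(95.0, 5.0)
        # heavy non-candidate antisense neighbour drags bias below threshold
        mass["C" * 21] = 95.0
        assert ld.cluster_and_bias([cand], hits, mass) == []


class TestFoldHairpin:
    def test_perfect_inverted_repeat_scores_high(self):
        rng = np.random.default_rng(5)
        S = rand_seq(rng, 60)
        hp = fold_hairpin(S + "GTTTA" + revcomp(S))
        assert hp.score >= 0.9 and hp.passes

    def test_too_short_window_rejected(self):
        with pytest.raises(ValueError):
            fold_hairpin("ACGT" * 12)  # 48 nt

    def test_random_200mers_rarely_reach_threshold(self):
        """Monte-Carlo null: i.i.d. random 200-mers score below the 0.6
        default threshold in at least 95% of 200 draws."""
        rng = np.random.default_rng(2024)
        below = sum(fold_hairpin(rand_seq(rng, 200)).score < 0.6 for _ in range(200))
        assert below >= 190

    @given(seq=dna)
    def test_reverse_complement_invariance(self, seq):
        assert fold_hairpin(seq).score == pytest.approx(fold_hairpin(revcomp(seq)).score)

    def test_loop_center_splits_arms(self):
        rng = np.random.default_rng(6)
        S = rand_seq(rng, 60)
        hp = fold_hairpin(S + "GTTTA" + revcomp(S))
        assert 50 < hp.loop_center < 75
        assert hp.arm_of(10) == "5p" and hp.arm_of(110) == "3p"

    def test_min_helix_credits_only_long_stacks(self):
        # 4 consecutive pairs < min_helix=5 score nothing; >=5 score fully
        four = "GGGG" + "TTTT" + "CCCC" + "A" * 38
        five = "GGGGG" + "TTTT" + "CCCCC" + "A" * 36
        assert stem_pairs(four[:12], min_loop=3, min_helix=5)[0] == 0
        assert stem_pairs(five[:14], min_loop=3, min_helix=5)[0] == 5


class TestReportLocus:
    @staticmethod
    def _hairpin():
        rng = np.random.default_rng(7)
        S = rand_seq(rng, 100)
        return fold_hairpin(S + "GTTTA" + revcomp(S))

    def test_single_sequence_locus_precision_one(self):
        hp = self._hairpin()
        cand = ld.LocusCandidate("c", 900, 1400, 1010, 1031, ["A" * 21], 100.0, 0.0)
        hits = {"A" * 21: [GenomeHit("c", 1010, 1031, "+")]}
        mass = pd.Series({"A" * 21: 100.0})
        rep = ld.report_locus(cand, hp, 1000, hits, mass, abundance_floor=10.0)
        assert rep.criteria.precision == pytest.approx(1.0)
        assert rep.criteria.passes_meyers
        assert list(rep.abundant["sequence"]) == ["A" * 21]

    def test_uniform_ragged_locus_fails_meyers(self):
        hp = self._hairpin()
        rng = np.random.default_rng(8)
        hits, mass = {}, {}
        for i in range(50):
            seq = rand_seq(rng, 21)
            start = 1005 + 2 * i  # ends staggered beyond the +-1 tolerance
            hits[seq] = [GenomeHit("c", start, start + 21, "+")]
            mass[seq] = 10.0
        cand = ld.LocusCandidate("c", 900, 1400, 1005, 1126, list(hits), 500.0, 0.0)
        rep = ld.report_locus(cand, hp, 1000, hits, pd.Series(mass), abundance_floor=1.0)
        assert rep.criteria.precision == pytest.approx(0.04)
        assert not rep.criteria.passes_meyers

    def test_track_mass_concentrated_on_members(self):
        hp = self._hairpin()
        cand = ld.LocusCandidate("c", 900, 1400, 1010, 1031, ["A" * 21], 100.0, 0.0)
        hits = {"A" * 21: [GenomeHit("c", 1010, 1031, "+")]}
        rep = ld.report_locus(cand, hp, 1000, hits, pd.Series({"A" * 21: 100.0}))
        t = rep.track.set_index("position")["mass"]
        assert t.loc[1010:1030].min() == 100.0
        assert t.loc[:1009].sum() == 0.0


class TestEndToEndDiscovery:
    def test_planted_locus_discovered_with_consistent_report(self, study, mature_ledger):
        reports = ld.discover_loci(
            study["matrix"], study["hits"], study["reference"].genome, study["catalog"]
        )
        assert len(reports) == 1
        rep = reports[0]
        led = study["reference"].ledger
        locus_row = led[(led.record == "locus") & (led.name == "sen_sRNA_locus")].iloc[0]
        lstart, lend = int(locus_row["start"]), int(locus_row["start"]) + int(locus_row["length"])
        assert rep.candidate.chrom == locus_row["chrom"]
        assert rep.candidate.core_start < lend and rep.candidate.core_end > lstart
        # report is re-checkable: bias, hairpin and member induction all hold
        assert rep.candidate.strand_bias > 0.9
        assert rep.hairpin.passes and rep.hairpin.score >= 0.6
        m = study["matrix"]
        for seq in rep.candidate.members:
            fc = (m.loc[seq, ["leaf_early_senescence", "leaf_late_senescence"]] + 1).max() / (
                m.loc[seq, "leaf_mature"] + 1
            )
            assert fc >= 3.0
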