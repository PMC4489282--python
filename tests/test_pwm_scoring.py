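"""PWM handling, CRM scoring, track scoring, and score -> ranking."""

import math

import numpy as np
import pytest

from oracles import crm_score_oracle
from rankrecovery.pwm import PWM, read_pwms, write_pwms_cb
from rankrecovery.regions import GenomicRegion, RegionCollection
from rankrecovery.scoring import (
    GenomeSequences,
    crm_score,
    score_motif_over_regions,
    score_track_coverage,
    score_track_peaks,
    scores_to_ranking,
)
from rankrecovery.simulate import make_pwm


def coll(ivs, tag="toy", prefix="r", scores=None):
    return RegionCollection(
        [GenomicRegion(c, s, e, f"{prefix}{i}") for i, (c, s, e) in enumerate(ivs)],
        tag,
        scores,
    )


UNIFORM_PWM = PWM("uniform", np.full((6, 4), 0.25))


class TestPWM:
    def test_row_sum_and_positivity_enforced(self):
        with pytest.raises(ValueError):
            PWM("bad", np.array([[0.5, 0.5, 0.1, 0.0]]))
        mat = np.array([[0.7, 0.3, 0.0, 0.0]])
        with pytest.raises(ValueError, match="> 0"):
            PWM("bad", mat)

    def test_from_counts_applies_pseudocount(self):
        pwm = PWM.from_counts("m", np.array([[10, 0, 0, 0]]))
        assert pwm.matrix[0, 0] > 0.99 and pwm.matrix[0, 1] > 0

    def test_reverse_complement_is_an_involution(self):
        rng = np.random.default_rng(3)
        pwm = make_pwm(rng, "m", length=7)
        back = pwm.reverse_complement().reverse_complement()
        np.testing.assert_allclose(back.matrix, pwm.matrix)

    def test_cb_reader_round_trip(self, tmp_path):
        rng = np.random.default_rng(4)
        pwms = [make_pwm(rng, f"m{i}", length=5) for i in range(3)]
        path = tmp_path / "motifs.cb"
        write_pwms_cb(pwms, path)
        loaded = read_pwms(path)
        assert [p.motif_id for p in loaded] == ["m0", "m1", "m2"]
        np.testing.assert_allclose(loaded[0].matrix, pwms[0].matrix, atol=5e-3)

    def test_jaspar_reader(self, tmp_path):
        path = tmp_path / "m.jaspar"
        path.write_text(
            ">MA0001.1 test\nA [ 10 0 ]\nC [ 0 10 ]\nG [ 0 0 ]\nT [ 0 0 ]\n"
        )
        (pwm,) = read_pwms(path)
        assert pwm.consensus() == "AC" and len(pwm) == 2


class TestCrmScore:
    def test_uniform_pwm_scores_zero_everywhere(self):
        assert crm_score("ACGTACGTACGT", UNIFORM_PWM) == 0.0

    def test_single_consensus_site_equals_direct_log_odds(self):
        mat = np.tile([0.85, 0.05, 0.05, 0.05], (5, 1))
        pwm = PWM("m", mat)
        expected = 5 * math.log2(0.85 / 0.25)
        assert crm_score("AAAAA", pwm) == pytest.approx(expected)

    def test_reverse_strand_site_found(self):
        mat = np.tile([0.85, 0.05, 0.05, 0.05], (5, 1))
        pwm = PWM("m", mat)  # consensus AAAAA; revcomp site TTTTT
        assert crm_score("GGTTTTTGG", pwm) == pytest.approx(crm_score("AAAAA", pwm))

    def test_non_overlapping_sites_accumulate(self):
        mat = np.tile([0.85, 0.05, 0.05, 0.05], (4, 1))
        pwm = PWM("m", mat)
        one = crm_score("AAAA", pwm)
        two = crm_score("AAAACCGGAAAA", pwm)
        assert two == pytest.approx(2 * one)

    def test_short_and_all_n_sequences_score_zero(self):
        pwm = PWM("m", np.tile([0.85, 0.05, 0.05, 0.05], (6, 1)))
        assert crm_score("ACG", pwm) == 0.0
        assert crm_score("NNNNNNNNNN", pwm) == 0.0

    def test_invalid_character_rejected(self):
        with pytest.raises(ValueError, match="invalid character"):
            crm_score("ACGTX", UNIFORM_PWM)

    @pytest.mark.parametrize("seed", range(30))
    def test_equals_exhaustive_enumeration(self, seed):
        rng = np.random.default_rng(seed)
        pwm = make_pwm(rng, "m", length=int(rng.integers(4, 9)), info=3.0)
        n = int(rng.integers(10, 81))
        seq = "".join(rng.choice(list("ACGTN"), size=n, p=[0.24, 0.24, 0.24, 0.24, 0.04]))
        assert crm_score(seq, pwm) == pytest.approx(crm_score_oracle(seq, pwm), abs=1e-12)


class TestMultiGenomeScoring:
    def test_single_genome_equals_direct_map(self):
        crrs = coll([("c", 0, 10), ("c", 10, 20)])
        genome = GenomeSequences("g1", {"c": "ACGTACGTACGTACGTACGT"})
        pwm = PWM("m", np.tile([0.85, 0.05, 0.05, 0.05], (4, 1)))
        (scores,) = score_motif_over_regions(crrs, [genome], pwm)
        for r in crrs:
            assert scores[r.region_id] == crm_score(
                genome.fetch(r.chrom, r.start, r.end), pwm
            )

    def test_missing_ortholog_is_absent_not_zero(self):
        crrs = coll([("c", 0, 10), ("c", 10, 20)])
        genome2 = GenomeSequences(
            "g2", {"c": "A" * 20}, orthologs={"r0": ("c", 0, 10)}
        )
        (scores,) = score_motif_over_regions(crrs, [genome2], UNIFORM_PWM)
        assert "r1" not in scores and "r0" in scores

    def test_region_outside_bounds_errors(self):
        crrs = coll([("c", 0, 30)])
        genome = GenomeSequences("g1", {"c": "ACGT"})
        with pytest.raises(ValueError, match="bounds"):
            score_motif_over_regions(crrs, [genome], UNIFORM_PWM)


class TestTrackScoring:
    def test_maximum_signal_within_region(self):
        crrs = coll([("c", 0, 100)])
        peaks = coll(
            [("c", 10, 30), ("c", 50, 70)], prefix="p",
            scores={"p0": 3.2, "p1": 7.1},
        )
        assert score_track_peaks(crrs, peaks) == {"r0": 7.1}

    def test_region_without_peak_scores_zero(self):
        crrs = coll([("c", 0, 100), ("c", 500, 600)])
        peaks = coll([("c", 10, 30)], prefix="p", scores={"p0": 5.0})
        assert score_track_peaks(crrs, peaks)["r1"] == 0.0

    def test_one_bp_overlap_counts(self):
        crrs = coll([("c", 100, 200)])
        peaks = coll([("c", 50, 101)], prefix="p", scores={"p0": 2.5})
        assert score_track_peaks(crrs, peaks) == {"r0": 2.5}

    def test_negative_signal_warns_but_keeps(self):
        crrs = coll([("c", 0, 10)])
        peaks = coll([("c", 0, 10)], prefix="p", scores={"p0": -1.0})
        with pytest.warns(UserWarning, match="negative"):
            assert score_track_peaks(crrs, peaks) == {"r0": -1.0}

    def test_coverage_max_and_mean(self):
        crrs = coll([("c", 0, 10)])
        sig = np.zeros(20)
        sig[3] = 9.0
        assert score_track_coverage(crrs, {"c": sig}) == {"r0": 9.0}
        step = np.concatenate([np.full(5, 2.0), np.full(15, 4.0)])
        assert score_track_coverage(crrs, {"c": step}, "mean") == {"r0": 3.0}

    def test_missing_chromosome_warns_and_scores_zero(self):
        crrs = coll([("c", 0, 10)])
        with pytest.warns(UserWarning, match="no coverage"):
            assert score_track_coverage(crrs, {"other": np.ones(5)}) == {"r0": 0.0}


class TestScoresToRanking:
    def test_descending_order(self):
        fr = scores_to_ranking({"a": 5, "b": 3, "c": 9}, ["a", "b", "c"], "f")
        assert fr.order == ["c", "a", "b"]

    def test_same_seed_reproduces_tie_break(self):
        scores = {f"r{i}": 1.0 for i in range(50)}
        ids = list(scores)
        a = scores_to_ranking(scores, ids, "f", seed=7)
        b = scores_to_ranking(scores, ids, "f", seed=7)
        assert a.order == b.order

    def test_different_seeds_shuffle_ties_differently(self):
        scores = {f"r{i}": 1.0 for i in range(50)}
        ids = list(scores)
        orders = {tuple(scores_to_ranking(scores, ids, "f", seed=s).order) for s in range(10)}
        assert len(orders) > 5

    def test_absent_scores_rank_after_present(self):
        fr = scores_to_ranking({"a": 0.1}, ["a", "b", "c"], "f")
        assert fr.order[0] == "a" and set(fr.order[1:]) == {"b", "c"}

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError, match="outside the CRR universe"):
            scores_to_ranking({"z": 1.0}, ["a", "b"], "f")
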