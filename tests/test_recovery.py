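"""Recovery curves, AUC, NES, leading edge, and feature combination."""

import numpy as np
import pytest

from oracles import recovery_oracle
from rankrecovery.mapping import ForegroundSet
from rankrecovery.recovery import (
    EnrichmentParams,
    auc,
    combine_features,
    leading_edge,
    mean_sd_curves,
    nes_scores,
    recovery_curve,
    run_enrichment,
    threshold_rank,
)
from rankrecovery.recovery import RecoveryCurve
from rankrecovery.scoring import FeatureRanking, RankingDatabase


def fg_of(ids):
    return ForegroundSet(list(ids), {i: ["x"] for i in ids})


class TestThresholdRank:
    @pytest.mark.parametrize(
        "total,fraction,expected",
        [
            (1_223_024, 0.005, 6115),
            (938_376, 0.005, 4692),
            (136_353, 0.01, 1364),
            (100, 0.001, 1),
        ],
    )
    def test_printed_defaults_and_clamp(self, total, fraction, expected):
        assert threshold_rank(total, fraction) == expected

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            threshold_rank(100, 0.0)
        with pytest.raises(ValueError):
            threshold_rank(100, 1.5)


def simple_ranking(order):
    return FeatureRanking("f", "motif", list(order))


class TestRecoveryCurve:
    def test_counts_foreground_at_each_rank(self):
        ranking = simple_ranking([f"r{i}" for i in range(1, 11)])
        curve = recovery_curve(ranking, fg_of(["r2", "r5"]), 5)
        assert list(curve.rc) == [0, 1, 1, 1, 2]

    def test_full_foreground_recovers_linearly(self):
        ids = [f"r{i}" for i in range(10)]
        curve = recovery_curve(simple_ranking(ids), fg_of(ids), 10)
        assert list(curve.rc) == list(range(1, 11))

    def test_foreground_outside_universe_errors(self):
        with pytest.raises(ValueError, match="absent"):
            recovery_curve(simple_ranking(["a", "b"]), fg_of(["z"]), 2)


class TestAuc:
    def test_no_recovery_is_zero(self):
        curve = RecoveryCurve("f", np.zeros(10, dtype=int), F=3)
        assert auc(curve, 10) == 0.0

    def test_rank_one_foreground_is_one(self):
        curve = RecoveryCurve("f", np.ones(7, dtype=int), F=1)
        assert auc(curve, 7) == 1.0

    def test_two_region_example(self):
        # F=2 at ranks {1, 6}, T_auc=10 -> (5*0.5 + 5*1.0)/10 = 0.75
        ranking = simple_ranking(["a"] + [f"x{i}" for i in range(4)] + ["b"] + [f"y{i}" for i in range(4)])
        curve = recovery_curve(ranking, fg_of(["a", "b"]), 10)
        assert auc(curve, 10) == pytest.approx(0.75)


class TestNes:
    def test_all_equal_aucs_give_zero(self):
        out = nes_scores({"a": 0.3, "b": 0.3, "c": 0.3})
        assert all(e.nes == 0.0 for e in out.values())

    def test_population_sigma_example(self):
        out = nes_scores({"a": 0.9, "b": 0.1, "c": 0.1, "d": 0.1})
        assert out["a"].nes == pytest.approx(0.6 / np.sqrt(0.12))
        assert out["a"].mu == pytest.approx(0.3)

    def test_location_invariance(self):
        base = {"a": 0.2, "b": 0.5, "c": 0.9}
        shifted = {k: v + 0.05 for k, v in base.items()}
        n1 = {k: e.nes for k, e in nes_scores(base).items()}
        n2 = {k: e.nes for k, e in nes_scores(shifted).items()}
        for k in base:
            assert n1[k] == pytest.approx(n2[k])

    def test_fewer_than_two_features_rejected(self):
        with pytest.raises(ValueError):
            nes_scores({"a": 0.5})


class TestMeanSdCurves:
    def test_two_point_example(self):
        c1 = RecoveryCurve("a", [0, 2], F=2)
        c2 = RecoveryCurve("b", [2, 2], F=2)
        mean, sd = mean_sd_curves([c1, c2])
        assert list(mean) == [1, 2] and list(sd) == [1, 0]

    def test_identical_curves_have_zero_sd(self):
        cs = [RecoveryCurve(f"f{i}", [1, 2, 3], F=3) for i in range(4)]
        _, sd = mean_sd_curves(cs)
        assert np.all(sd == 0)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mean_sd_curves([RecoveryCurve("a", [1], F=1), RecoveryCurve("b", [1, 2], F=1)])


class TestLeadingEdge:
    def test_argmax_with_tie_to_smallest_rank(self):
        ranking = simple_ranking(["a", "b", "c", "d"])
        curve = recovery_curve(ranking, fg_of(["a", "c"]), 4)
        mean = np.zeros(4)
        sd = np.zeros(4)
        le = leading_edge(curve, mean, sd, 4, ranking, fg_of(["a", "c"]))
        # diffs [1,1,2,2]: first maximum at x=3
        assert le.le_rank == 3 and le.target_ids == ["a", "c"] and le.positive

    def test_curve_below_band_still_reports_rank(self):
        ranking = simple_ranking(["a", "b", "c", "d"])
        curve = recovery_curve(ranking, fg_of(["d"]), 4)
        mean = np.full(4, 3.0)
        sd = np.zeros(4)
        le = leading_edge(curve, mean, sd, 4, ranking, fg_of(["d"]))
        assert not le.positive and le.le_rank >= 1


class TestPipelineAgainstOracle:
    def test_random_fixture_matches_brute_force(self):
        rng = np.random.default_rng(11)
        n, n_feat = 300, 12
        ids = [f"r{i}" for i in range(n)]
        orders = {
            f"f{j}": [ids[i] for i in rng.permutation(n)] for j in range(n_feat)
        }
        fg_ids = set(rng.choice(ids, size=25, replace=False))
        T = 60
        _, o_aucs, o_nes, o_mean, o_sd, o_les = recovery_oracle(orders, fg_ids, T)
        fg = fg_of(sorted(fg_ids))
        curves = {
            fid: recovery_curve(FeatureRanking(fid, "motif", order), fg, T)
            for fid, order in orders.items()
        }
        aucs = {fid: auc(c, T) for fid, c in curves.items()}
        scores = nes_scores(aucs)
        mean_c, sd_c = mean_sd_curves(list(curves.values()))
        assert aucs == pytest.approx(o_aucs, abs=1e-12)
        for fid in orders:
            assert scores[fid].nes == pytest.approx(o_nes[fid], abs=1e-12)
        np.testing.assert_allclose(mean_c, o_mean, atol=1e-12)
        np.testing.assert_allclose(sd_c, o_sd, atol=1e-12)
        for fid, order in orders.items():
            le = leading_edge(
                curves[fid], mean_c, sd_c, T, FeatureRanking(fid, "motif", order), fg
            )
            x, targets, positive = o_les[fid]
            assert (le.le_rank, le.target_ids, le.positive) == (x, targets, positive)


def random_db(rng, n=100, n_feat=8, label="motifs"):
    ids = [f"r{i}" for i in range(n)]
    rankings = [
        FeatureRanking(f"f{j}", "motif", [ids[i] for i in rng.permutation(n)])
        for j in range(n_feat)
    ]
    return RankingDatabase(ids, rankings, label), ids


class TestRunEnrichment:
    def test_quick_mode_raises_threshold_and_filters_motifs(self, tiny_bundle, tiny_result):
        from rankrecovery.recovery import run_enrichment

        params = EnrichmentParams(
            auc_fraction=tiny_bundle.auc_fraction,
            quick=True,
            quick_subset={p.motif_id for p in tiny_bundle.pwms[:10]},
        )
        res = run_enrichment([tiny_result.motif_db], tiny_result.foreground, params)
        for es, _ in res:
            assert es.nes > 4.0
            assert es.feature_id in params.quick_subset
        full = [
            es for es, _ in tiny_result.results
            if es.feature_type == "motif" and 3.0 < es.nes <= 4.0
        ]
        reported = {es.feature_id for es, _ in res}
        assert all(es.feature_id not in reported for es in full)

    def test_feature_order_does_not_change_nes(self, tiny_result):
        db = tiny_result.motif_db
        reversed_db = RankingDatabase(
            db.crr_ids, [db.rankings[f] for f in reversed(db.feature_ids)], "motifs"
        )
        a = run_enrichment([db], tiny_result.foreground,
                           EnrichmentParams(auc_fraction=0.2))
        b = run_enrichment([reversed_db], tiny_result.foreground,
                           EnrichmentParams(auc_fraction=0.2))
        assert {e.feature_id: e.nes for e, _ in a} == {e.feature_id: e.nes for e, _ in b}

    def test_empty_foreground_rejected(self):
        db, _ = random_db(np.random.default_rng(0))
        with pytest.raises(ValueError):
            run_enrichment([db], ForegroundSet([], {}), EnrichmentParams())

    def test_random_foreground_rarely_exceeds_threshold(self):
        # empirical null: on average well under 1 feature in 20 passes NES > 3
        rng = np.random.default_rng(5)
        db, ids = random_db(rng, n=200, n_feat=20)
        n_hits = 0
        n_trials = 50
        for _ in range(n_trials):
            fg = fg_of(sorted(rng.choice(ids, size=20, replace=False)))
            res = run_enrichment([db], fg, EnrichmentParams(auc_fraction=0.2))
            n_hits += len(res)
        assert n_hits / (n_trials * 20) < 0.01


class TestCombineFeatures:
    def test_combining_identical_rankings_preserves_order(self):
        ids = [f"r{i}" for i in range(30)]
        fr = FeatureRanking("a", "motif", ids)
        fr2 = FeatureRanking("b", "motif", ids)
        db = RankingDatabase(ids, [fr, fr2], "motifs")
        combined = combine_features(db, ["a", "b"])
        assert combined.order == ids
        assert combined.feature_type == "combined"

    def test_unknown_feature_rejected(self):
        ids = ["a", "b"]
        db = RankingDatabase(
            ids, [FeatureRanking("f", "motif", ids), FeatureRanking("g", "motif", ids)]
        )
        with pytest.raises(ValueError, match="unknown feature"):
            combine_features(db, ["f", "nope"])

    def test_strong_plus_random_lands_between(self, tiny_bundle, tiny_result):
        """Combining an informative and a random ranking yields foreground
        AUC between the two singletons' AUCs."""
        db = tiny_result.motif_db
        fg = tiny_result.foreground
        T = 36
        planted = tiny_bundle.truth["planted_motif"]
        aucs = {}
        for fid in db.feature_ids:
            aucs[fid] = auc(recovery_curve(db.rankings[fid], fg, T), T)
        weakest = min(aucs, key=aucs.get)
        combined = combine_features(db, [planted, weakest], seed=1)
        a_comb = auc(recovery_curve(combined, fg, T), T)
        assert aucs[weakest] - 0.05 <= a_comb <= aucs[planted] + 0.05
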