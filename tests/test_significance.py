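"""Permutation null, CLT approximation, two-gene rule and the dynamic cut."""

import numpy as np
import pytest

from conftest import build_annotation, exact_permutation_p, full_hit
from synclust.clustering import build_dendrogram, build_forest
from synclust.hits import HitSet
from synclust.significance import (
    NullModel,
    SignificanceConfig,
    build_null_model,
    clt_moments,
    dynamic_cut,
    p_value_clt,
    p_value_permutation,
    passes_two_gene_rule,
    permuted_score,
    worst_case_correction,
)
from synclust.significance import _permuted_scores
from synclust import synthetic


def _null(pool_all, pool_beta=(), pool_gamma=()):
    return NullModel(
        pool_all=np.asarray(pool_all, dtype=float),
        pool_best_beta=np.asarray(pool_beta, dtype=float),
        pool_best_gamma=np.asarray(pool_gamma, dtype=float),
    )


class TestNullModel:
    def test_pool_sizes(self, toy_pair):
        ann_b, ann_g = toy_pair
        hs = HitSet.from_hits(
            [
                full_hit(ann_b, ann_g, "bg1.e1", "gg1.e1", 0.1),
                full_hit(ann_b, ann_g, "bg1.e1", "gg2.e1", 0.2),
                full_hit(ann_b, ann_g, "bg2.e1", "gg3.e1", 0.3),
                full_hit(ann_b, ann_g, "bg3.e1", "gg4.e1", 0.4),
            ],
            "beta", "gamma",
        )
        null = build_null_model(hs)
        assert len(null.pool_all) == 4
        assert len(null.pool_best_beta) == 3  # 3 beta exons carry hits
        assert len(null.pool_best_gamma) == 4

    def test_moments_match_hand_arithmetic(self):
        pool = [0.1, 0.2, 0.3, 0.4, 1.0]
        null = _null(pool)
        assert null.mean_all == pytest.approx(0.4)
        assert null.var_all == pytest.approx(np.var(pool))  # population variance

    def test_constant_pool_has_zero_variance(self):
        null = _null([0.7, 0.7, 0.7])
        assert null.var_all == pytest.approx(0.0, abs=1e-15)

    def test_empty_hitset_rejected(self):
        with pytest.raises(ValueError):
            build_null_model(HitSet([], "b", "g"))


class TestPermutedScore:
    def test_exhaustive_draw_is_deterministic(self):
        null = _null([0.2, 0.5, 0.9])
        rng = np.random.default_rng(0)
        for _ in range(5):
            assert permuted_score(null, 3, 0, 0, rng) == pytest.approx(2 * 1.6)

    def test_zero_draws_give_zero(self):
        null = _null([0.2, 0.5], [0.1], [0.3])
        assert permuted_score(null, 0, 0, 0, np.random.default_rng(0)) == 0.0

    def test_mean_matches_theory_within_three_se(self):
        rng = np.random.default_rng(42)
        null = _null(rng.random(100), rng.random(40), rng.random(30))
        n_c, n_cb, n_cg = 10, 5, 4
        draws = _permuted_scores(null, n_c, n_cb, n_cg, 10_000, np.random.default_rng(1))
        mean, var = clt_moments(null, n_c, n_cb, n_cg)
        se = np.sqrt(var / len(draws))
        assert abs(draws.mean() - mean) <= 3 * se


class TestPValuePermutation:
    def test_hopeless_score_early_stops_after_k_draws(self):
        null = _null([0.5] * 20)
        rec = p_value_permutation(
            null, s_obs=-1.0, n_c=3, n_cb=0, n_cg=0,
            max_perms=5000, early_stop_k=10, rng=np.random.default_rng(0),
        )
        assert rec.n_draws == 10 and rec.n_exceed == 10
        assert rec.p_raw == 1.0

    def test_unbeatable_score_reaches_floor(self):
        null = _null([0.5] * 20)
        rec = p_value_permutation(
            null, s_obs=1000.0, n_c=3, n_cb=0, n_cg=0,
            max_perms=999, early_stop_k=10, rng=np.random.default_rng(0),
        )
        assert rec.n_exceed == 0
        assert rec.p_raw == pytest.approx(1 / 1000)

    @pytest.mark.parametrize("s_obs", [0.4, 0.8, 1.4])
    def test_matches_exhaustive_enumeration(self, s_obs):
        pool_all = np.array([0.1, 0.3, 0.5, 0.7, 0.9])
        pool_b = np.array([0.2, 0.6, 0.8])
        pool_g = np.array([0.4, 0.5])
        null = _null(pool_all, pool_b, pool_g)
        p_exact = exact_permutation_p(pool_all, pool_b, pool_g, 2, 1, 1, s_obs)
        rec = p_value_permutation(
            null, s_obs, 2, 1, 1, max_perms=4000, early_stop_k=None,
            rng=np.random.default_rng(3),
        )
        se = np.sqrt(p_exact * (1 - p_exact) / rec.n_draws)
        assert abs(rec.p_raw - p_exact) <= 3 * se + 2 / rec.n_draws


class TestPValueClt:
    def test_observed_mean_gives_half(self):
        rng = np.random.default_rng(5)
        null = _null(rng.random(500), rng.random(200), rng.random(200))
        mean, _ = clt_moments(null, 50, 30, 30)
        rec = p_value_clt(null, mean, 50, 30, 30)
        assert rec.p_raw == pytest.approx(0.5)
        assert rec.method == "clt"

    def test_exhausted_pool_contributes_no_variance(self):
        null = _null(np.linspace(0, 1, 200), np.array([0.5, 0.6, 0.7]), np.array([]))
        _, var_full = clt_moments(null, 40, 3, 0)  # beta pool fully drawn: f = 0
        _, var_base = clt_moments(null, 40, 0, 0)
        assert var_full == pytest.approx(var_base)

    def test_small_cluster_rejected(self):
        null = _null(np.linspace(0, 1, 200), np.linspace(0, 1, 50), np.linspace(0, 1, 50))
        with pytest.raises(ValueError, match="too small"):
            p_value_clt(null, 1.0, 5, 0, 0, clt_min_n=30)

    def test_agrees_with_permutation_for_large_cluster(self):
        rng = np.random.default_rng(7)
        null = _null(rng.random(1000), rng.random(300), rng.random(300))
        n_c, n_cb, n_cg = 50, 10, 10
        mean, var = clt_moments(null, n_c, n_cb, n_cg)
        draws = _permuted_scores(null, n_c, n_cb, n_cg, 50_000, np.random.default_rng(8))
        for z in (-1.5, 0.0, 1.0, 2.0):
            s_obs = mean + z * np.sqrt(var)
            p_clt = p_value_clt(null, s_obs, n_c, n_cb, n_cg, clt_min_n=10).p_raw
            p_perm = (np.sum(draws >= s_obs) + 1) / (len(draws) + 1)
            assert abs(p_clt - p_perm) <= 0.01


class TestTwoGeneRule:
    def test_single_gene_pair_fails(self, toy_pair):
        ann_b, ann_g = toy_pair
        hits = [full_hit(ann_b, ann_g, "bg1.e1", "gg1.e1", e) for e in (0.0, 0.1)]
        node = build_dendrogram(HitSet.from_hits(hits, "beta", "gamma").hits)
        assert not passes_two_gene_rule(node, (ann_b, ann_g))

    def test_two_by_two_passes(self, toy_pair):
        ann_b, ann_g = toy_pair
        hits = [
            full_hit(ann_b, ann_g, "bg1.e1", "gg1.e1"),
            full_hit(ann_b, ann_g, "bg2.e1", "gg2.e1"),
        ]
        node = build_dendrogram(HitSet.from_hits(hits, "beta", "gamma").hits)
        assert passes_two_gene_rule(node, (ann_b, ann_g))

    def test_both_sides_must_have_two_genes(self, toy_pair):
        ann_b, ann_g = toy_pair
        hits = [
            full_hit(ann_b, ann_g, "bg1.e1", "gg1.e1"),
            full_hit(ann_b, ann_g, "bg2.e1", "gg1.e1"),  # 2 beta genes, 1 gamma gene
        ]
        node = build_dendrogram(HitSet.from_hits(hits, "beta", "gamma").hits)
        assert not passes_two_gene_rule(node, (ann_b, ann_g))


class TestWorstCaseCorrection:
    def test_formula(self, toy_pair):
        ann_b, ann_g = toy_pair
        hits = [full_hit(ann_b, ann_g, "bg1.e1", "gg1.e1")]
        assert worst_case_correction(HitSet.from_hits(hits * 1, "b", "g")) == 2
        assert worst_case_correction(HitSet([], "b", "g")) == 0


def _planted_spec(seed, n_noise=80):
    return synthetic.SyntheticSpec(
        seed=seed, genes_per_scaffold=20, n_noise=n_noise,
        blocks=(synthetic.BlockSpec(0, 3, 0, 3, 5),
                synthetic.BlockSpec(1, 6, 1, 6, 5)),
    )


def _run_cut(res, config=None, seed=0):
    forest = build_forest(res.hitset)
    null = build_null_model(res.hitset, seed=seed)
    return dynamic_cut(
        forest, res.annotation_beta, res.annotation_gamma, res.hitset, null,
        config or SignificanceConfig(), seed=seed,
    )


class TestDynamicCut:
    def test_forest_failing_two_gene_rule_reports_nothing(self, toy_pair):
        ann_b, ann_g = toy_pair
        hits = [full_hit(ann_b, ann_g, "bg1.e1", "gg1.e1", e) for e in (0.0, 0.1, 0.2)]
        hs = HitSet.from_hits(hits, "beta", "gamma")
        forest = build_forest(hs)
        clusters, ledger = dynamic_cut(
            forest, ann_b, ann_g, hs, build_null_model(hs), SignificanceConfig(), seed=0
        )
        assert clusters == [] and ledger == []

    def test_recovers_planted_blocks_amid_noise(self):
        res = synthetic.generate(_planted_spec(seed=21))
        clusters, _ = _run_cut(res, seed=21)
        for block_ids in res.truth.blocks.values():
            assert any(block_ids <= c.hit_ids for c in clusters)

    def test_reported_clusters_satisfy_all_contracts(self):
        res = synthetic.generate(_planted_spec(seed=22))
        config = SignificanceConfig()
        clusters, _ = _run_cut(res, config, seed=22)
        assert clusters
        bound = worst_case_correction(res.hitset)
        annotations = (res.annotation_beta, res.annotation_gamma)
        for c in clusters:
            assert c.p_raw * c.correction_factor <= config.alpha
            assert c.conservation_ratio >= config.tau
            assert len(c.genes_beta) >= 2 and len(c.genes_gamma) >= 2
            assert c.correction_factor <= bound
        for a in clusters:
            for b in clusters:
                if a.cluster_id != b.cluster_id:
                    assert not (a.hit_ids < b.hit_ids)  # mutually non-nested

    def test_child_with_lower_p_wins_over_significant_parent(self):
        # one tree: a 10-hit perfect block plus two adjacent zero-quality
        # hits; a filler tree supplies mediocre pool mass.  Analytically
        # (CLT) the block child has a strictly lower p than its parent.
        block = [(1000 + 100 * k + 1, 1000 + 100 * k + 60) for k in range(10)]
        zeros = [(3000, 3059), (3080, 3139)]
        filler = [(101 + 400 * k, 160 + 400 * k) for k in range(40)]
        ann_b = build_annotation(
            "beta", {"b1": 5000, "b2": 20000},
            [(f"blk{k}", "b1", "+", [iv]) for k, iv in enumerate(block)]
            + [(f"z{k}", "b1", "+", [iv]) for k, iv in enumerate(zeros)]
            + [(f"f{k}", "b2", "+", [iv]) for k, iv in enumerate(filler)],
        )
        ann_g = build_annotation(
            "gamma", {"g1": 5000, "g2": 20000},
            [(f"BLK{k}", "g1", "+", [iv]) for k, iv in enumerate(block)]
            + [(f"Z{k}", "g1", "+", [iv]) for k, iv in enumerate(zeros)]
            + [(f"F{k}", "g2", "+", [iv]) for k, iv in enumerate(filler)],
        )
        hits = (
            [full_hit(ann_b, ann_g, f"blk{k}.e1", f"BLK{k}.e1", 0.0) for k in range(10)]
            + [full_hit(ann_b, ann_g, f"z{k}.e1", f"Z{k}.e1", 1.0) for k in range(2)]
            + [full_hit(ann_b, ann_g, f"f{k}.e1", f"F{k}.e1", 0.7) for k in range(40)]
        )
        hs = HitSet.from_hits(hits, "beta", "gamma")
        forest = build_forest(hs)
        config = SignificanceConfig(clt_min_n=5)
        clusters, _ = dynamic_cut(
            forest, ann_b, ann_g, hs, build_null_model(hs), config, seed=0
        )
        block_hit_ids = {
            h.hit_id for h in hs.hits if h.exon_beta.startswith("blk")
        }
        assert any(c.hit_ids == frozenset(block_hit_ids) for c in clusters)
        # the 12-hit parent (block + zero-quality hits) is NOT the cut
        assert all(c.n_hits != 12 for c in clusters)

    def test_determinism_under_fixed_seed(self):
        res = synthetic.generate(_planted_spec(seed=23))
        a, _ = _run_cut(res, seed=5)
        b, _ = _run_cut(res, seed=5)
        assert a == b

    @pytest.mark.parametrize("seed", range(4))
    def test_early_stopping_never_changes_decisions(self, seed):
        spec = synthetic.SyntheticSpec(
            seed=300 + seed, genes_per_scaffold=15, scaffolds_beta=1,
            scaffolds_gamma=1, n_noise=60,
            blocks=(synthetic.BlockSpec(0, 4, 0, 4, 5),),
        )
        res = synthetic.generate(spec)
        with_stop, _ = _run_cut(
            res, SignificanceConfig(early_stop_k=10, max_perms=3000), seed=seed
        )
        without_stop, _ = _run_cut(
            res, SignificanceConfig(early_stop_k=None, max_perms=3000), seed=seed
        )
        assert {c.node_id for c in with_stop} == {c.node_id for c in without_stop}
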