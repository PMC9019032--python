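import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from isletid.genesets import GeneSet
from isletid.gsea import (
    GseaParams,
    RankedList,
    build_ranked_list,
    enrichment_score,
    gene_retrieval_rate,
    leading_edge,
    permutation_nes,
    run_gsea,
)

from oracles import naive_enrichment, naive_leading_edge


def ranked(n=20, seed=0):
    rng = np.random.default_rng(seed)
    return RankedList(
        genes=tuple(f"g{i}" for i in range(n)),
        scores=tuple(np.sort(rng.normal(0, 2, n))[::-1]),
    )


class TestRankedList:
    def test_sorted_descending_with_stable_ties(self):
        rl = RankedList(genes=("a", "b", "c"), scores=(1.0, 3.0, 1.0))
        assert rl.genes == ("b", "a", "c")

    def test_duplicate_genes_rejected(self):
        with pytest.raises(ValueError):
            RankedList(genes=("a", "a"), scores=(1.0, 2.0))

    def test_rnk_round_trip(self, tmp_path):
        rl = ranked(10)
        path = tmp_path / "list.rnk"
        rl.to_rnk(path)
        back = RankedList.from_rnk(path)
        assert back.genes == rl.genes
        np.testing.assert_allclose(back.score_array, rl.score_array)


class TestBuildRankedList:
    def table(self, padj, logfc):
        return pd.DataFrame(
            {"gene": [f"g{i}" for i in range(len(padj))], "padj": padj, "logfc": logfc}
        )

    def test_floor_caps_score_at_300(self):
        rl = build_ranked_list(self.table([1e-310], [1.0]))
        assert np.isclose(rl.scores[0], 300.0)

    def test_simple_scores(self):
        rl = build_ranked_list(self.table([0.01, 0.01], [1.0, -1.0]), signed=True)
        by_gene = dict(zip(rl.genes, rl.scores))
        assert np.isclose(by_gene["g0"], 2.0)
        assert np.isclose(by_gene["g1"], -2.0)

    def test_unsigned_ignores_direction(self):
        rl = build_ranked_list(self.table([0.01], [-1.0]), signed=False)
        assert np.isclose(rl.scores[0], 2.0)

    def test_duplicate_gene_rejected(self):
        t = self.table([0.1, 0.1], [1, 1])
        t["gene"] = ["x", "x"]
        with pytest.raises(ValueError):
            build_ranked_list(t)


class TestEnrichmentScore:
    def test_singleton_at_top_gives_unit_es(self):
        rl = ranked(10)
        info = enrichment_score(rl, GeneSet("s", "t", 1, (rl.genes[0],)))
        assert np.isclose(info.es, 1.0)

    def test_singleton_at_bottom_matches_stepwise_oracle(self):
        rl = ranked(10)
        gs = GeneSet("s", "t", 1, (rl.genes[-1],))
        info = enrichment_score(rl, gs)
        es, running, peak, _, _ = naive_enrichment(list(rl.genes), list(rl.scores), gs.genes)
        assert np.isclose(info.es, es)
        np.testing.assert_allclose(info.running_sum, running)

    def test_negating_scores_negates_es(self):
        # flipping every score reverses the ranking while preserving hit
        # weights, so the enrichment signal changes sign exactly
        n = 12
        scores = tuple(np.linspace(3, -3, n))
        genes = tuple(f"g{i}" for i in range(n))
        fwd = RankedList(genes=genes, scores=scores)
        rev = RankedList(genes=genes, scores=tuple(-s for s in scores))
        gs = GeneSet("s", "t", 1, ("g0", "g1", "g2"))
        a = enrichment_score(fwd, gs).es
        b = enrichment_score(rev, gs).es
        assert np.isclose(a, -b)

    @given(st.integers(min_value=0, max_value=10**6))
    def test_es_bounded(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 25))
        rl = RankedList(
            genes=tuple(f"g{i}" for i in range(n)),
            scores=tuple(rng.normal(0, 1, n)),
        )
        m = int(rng.integers(1, n))
        gs = GeneSet("s", "t", 1, tuple(f"g{i}" for i in rng.choice(n, m, replace=False)))
        info = enrichment_score(rl, gs)
        assert -1.0 - 1e-9 <= info.es <= 1.0 + 1e-9

    def test_full_coverage_rejected(self):
        rl = ranked(5)
        with pytest.raises(ValueError):
            enrichment_score(rl, GeneSet("s", "t", 1, rl.genes))

    def test_no_match_rejected(self):
        rl = ranked(5)
        with pytest.raises(ValueError):
            enrichment_score(rl, GeneSet("s", "t", 1, ("nope",)))


class TestLeadingEdge:
    def test_singleton_top_is_its_own_leading_edge(self):
        rl = ranked(10)
        gs = GeneSet("s", "t", 1, (rl.genes[0],))
        info = enrichment_score(rl, gs)
        assert leading_edge(rl, gs, info) == [rl.genes[0]]

    def test_members_after_peak_excluded(self):
        # strong positive block at the top plus one straggler at the bottom
        genes = tuple(f"g{i}" for i in range(20))
        scores = tuple(float(20 - i) for i in range(20))
        rl = RankedList(genes=genes, scores=scores)
        gs = GeneSet("s", "t", 1, ("g0", "g1", "g2", "g19"))
        info = enrichment_score(rl, gs)
        le = leading_edge(rl, gs, info)
        assert "g19" not in le
        assert set(le) == {"g0", "g1", "g2"}

    def test_matches_bruteforce_on_random_instances(self, rng):
        for _ in range(50):
            n = int(rng.integers(4, 20))
            genes = [f"g{i}" for i in range(n)]
            scores = list(rng.normal(0, 1, n))
            m = int(rng.integers(1, n))
            members = [f"g{i}" for i in rng.choice(n, m, replace=False)]
            rl = RankedList(genes=tuple(genes), scores=tuple(scores))
            gs = GeneSet("s", "t", 1, tuple(members))
            info = enrichment_score(rl, gs)
            assert leading_edge(rl, gs, info) == naive_leading_edge(genes, scores, members)


class TestGrr:
    def test_trivial_fractions(self):
        rl = ranked(10)
        assert gene_retrieval_rate(rl, GeneSet("s", "t", 1, rl.genes[:4])) == 1.0
        assert gene_retrieval_rate(rl, GeneSet("s", "t", 1, ("x", "y"))) == 0.0
        gs = GeneSet("s", "t", 1, (rl.genes[0], rl.genes[1], rl.genes[2], "x", "y"))
        assert gene_retrieval_rate(rl, gs) == 0.6

    def test_monotone_in_ranked_list_growth(self):
        gs = GeneSet("s", "t", 1, tuple(f"g{i}" for i in range(8)))
        grrs = [gene_retrieval_rate(ranked(n), gs) for n in (4, 6, 8, 12)]
        assert all(b >= a for a, b in zip(grrs, grrs[1:]))

    def test_empty_geneset_rejected(self):
        with pytest.raises(ValueError):
            gene_retrieval_rate(ranked(5), GeneSet("s", "t", 1, ()))


class TestPermutationNes:
    def test_seed_reproducibility(self):
        rl = ranked(200, seed=1)
        gs = GeneSet("s", "t", 1, rl.genes[:20])
        a = permutation_nes(rl, gs, n_perm=200, seed=9)
        b = permutation_nes(rl, gs, n_perm=200, seed=9)
        assert a.nes == b.nes and a.p == b.p

    def test_top_loaded_geneset_scores_high(self, rng):
        genes = tuple(f"g{i}" for i in range(1000))
        scores = tuple(np.sort(rng.normal(0, 2, 1000))[::-1])
        rl = RankedList(genes=genes, scores=scores)
        members = tuple(f"g{i}" for i in rng.choice(100, 30, replace=False))
        res = permutation_nes(rl, GeneSet("top", "t", 1, members), n_perm=1000, seed=0)
        assert res.nes > 1.5
        assert res.p < 0.01

    def test_null_nes_mean_near_one(self, rng):
        # the positive-side null, normalized by its own mean, must average ~1
        rl = ranked(300, seed=2)
        gs = GeneSet("s", "t", 1, rl.genes[::7][:30])
        res = permutation_nes(rl, gs, n_perm=10000, seed=4)
        pos = res.null_es[res.null_es >= 0]
        norm = pos / pos.mean()
        assert abs(norm.mean() - 1.0) < 0.05

    def test_min_permutations_enforced(self):
        rl = ranked(50)
        with pytest.raises(ValueError):
            permutation_nes(rl, GeneSet("s", "t", 1, rl.genes[:5]), n_perm=10)


class TestRunGsea:
    def big_ranked(self, n=600, seed=3):
        return ranked(n, seed=seed)

    def test_matching_gate_failure_and_boundaries(self):
        rl = self.big_ranked()
        sets = [
            GeneSet("too_few", "t", 1, rl.genes[:14]),
            GeneSet("at_floor", "t", 1, rl.genes[:15]),
            GeneSet("too_many", "t", 1, rl.genes[:501]),
            GeneSet("at_ceiling", "t", 1, rl.genes[:500]),
        ]
        res = {r.name: r for r in run_gsea(rl, sets, GseaParams(n_perm=100))}
        assert res["too_few"].status == "failed_too_few" and res["too_few"].nes is None
        assert res["too_many"].status == "failed_too_many" and res["too_many"].nes is None
        assert res["at_floor"].status == "ok" and res["at_floor"].nes is not None
        assert res["at_ceiling"].status == "ok"

    def test_failed_sets_still_carry_grr(self):
        rl = self.big_ranked()
        gs = GeneSet("few", "t", 1, rl.genes[:10] + ("absent1", "absent2"))
        res = run_gsea(rl, [gs], GseaParams(n_perm=100))[0]
        assert res.status == "failed_too_few"
        assert np.isclose(res.grr, 10 / 12)

    def test_empty_ranked_list_rejected(self):
        rl = RankedList(genes=(), scores=())
        with pytest.raises(ValueError):
            run_gsea(rl, [GeneSet("s", "t", 1, ("x",))])

    def test_q_values_attached_to_scored_sets(self, rng):
        rl = self.big_ranked()
        sets = [
            GeneSet(f"s{i}", "t", 1, tuple(f"g{j}" for j in rng.choice(600, 30, replace=False)))
            for i in range(5)
        ]
        res = run_gsea(rl, sets, GseaParams(n_perm=200))
        for r in res:
            assert r.status == "ok"
            assert r.q is not None and 0 <= r.q <= 1
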