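import numpy as np
import pytest

from conftest import make_random_tree
from wquartet import scoring, search
from wquartet.quartets import WeightScheme
from wquartet.scoring import all_tripartition_scores, weighted_quartet_score
from wquartet.search import (SearchParams, TripartitionStore,
                             all_binary_topologies, dac_tree, dp_optimal_tree,
                             greedy_round, run_search, score_placements)
from wquartet.treeio import parse_tree, write_tree

SCHEMES = ["unweighted", "support", "length", "hybrid"]


def perfect_genes(taxa, rng, k=6):
    tree = make_random_tree(list(taxa), rng, support_value=0.95,
                            length_value=0.05)
    return tree, [tree.copy() for _ in range(k)]


class TestScorePlacements:
    @pytest.mark.parametrize("seed", range(3))
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_equals_bruteforce_rescoring(self, seed, scheme):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(6)]
        backbone = make_random_tree(taxa, rng)
        genes = [make_random_tree(taxa + ["q"], rng) for _ in range(3)]
        scores = score_placements(backbone, "q", genes, scheme)
        assert len(scores) == 2 * len(taxa) - 3
        for key, got in scores.items():
            extended = backbone.copy()
            node = search._find_edge(extended, key)
            search._attach(extended, node, "q")
            want = weighted_quartet_score(extended, genes, scheme)
            assert got == pytest.approx(want, abs=1e-9)

    def test_perfect_signal_recovers_query_edge(self):
        rng = np.random.default_rng(1)
        tree, genes = perfect_genes([f"t{i}" for i in range(5)], rng, k=10)
        query = sorted(tree.leaf_names())[0]
        from wquartet.treeio import restrict
        backbone = restrict(tree, tree.leaf_names() - {query})
        scores = score_placements(backbone, query, genes, "unweighted")
        best = max(scores, key=lambda k: (scores[k], k))
        assert scores[best] == pytest.approx(10 * 5, abs=1e-9)  # 10 * C(5,4)
        extended = backbone.copy()
        search._attach(extended, search._find_edge(extended, best), query)
        assert extended.bipartitions() == tree.bipartitions()

    def test_uninformative_genes_give_constant_map(self):
        backbone = parse_tree("((a,b),(c,d));")
        genes = [parse_tree("((q:0,x:0)1.0:0,(y:0,z:0)1.0:0);")]
        scores = score_placements(backbone, "q", genes, "unweighted")
        assert len(set(round(v, 12) for v in scores.values())) == 1

    def test_query_already_placed_rejected(self):
        backbone = parse_tree("((a,b),(c,d));")
        with pytest.raises(ValueError, match="already"):
            score_placements(backbone, "a", [backbone.copy()], "unweighted")


class TestGreedyRound:
    def test_perfect_signal_recovery_any_order(self):
        rng = np.random.default_rng(7)
        tree, genes = perfect_genes([f"t{i}" for i in range(9)], rng)
        for seed in range(4):
            out, trips, score = greedy_round(genes, "hybrid",
                                             np.random.default_rng(seed))
            assert out.bipartitions() == tree.bipartitions()
            assert len(trips) == 9 - 2

    def test_four_taxa_picks_best_of_three(self, rng):
        taxa = list("abcd")
        genes = [make_random_tree(taxa, rng) for _ in range(5)]
        out, _, score = greedy_round(genes, "hybrid", np.random.default_rng(0))
        best = max(weighted_quartet_score(t, genes, "hybrid")
                   for t in all_binary_topologies(taxa))
        assert score == pytest.approx(best, abs=1e-9)

    def test_score_tracks_oracle(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        genes = [make_random_tree(taxa, rng) for _ in range(4)]
        out, trips, score = greedy_round(genes, "support",
                                         np.random.default_rng(3))
        assert score == pytest.approx(
            weighted_quartet_score(out, genes, "support"), abs=1e-9)
        assert 0.5 * sum(trips.values()) == pytest.approx(score, abs=1e-9)

    def test_too_few_taxa_rejected(self):
        genes = [parse_tree("((a,b),c);")]
        with pytest.raises(ValueError, match="4 taxa"):
            greedy_round(genes, "unweighted", np.random.default_rng(0))


class TestDP:
    def test_single_round_store_returns_that_tree(self, rng):
        taxa = [f"t{i}" for i in range(7)]
        genes = [make_random_tree(taxa, rng) for _ in range(3)]
        tree, trips, score = greedy_round(genes, "hybrid",
                                          np.random.default_rng(1))
        store = TripartitionStore()
        for k, v in trips.items():
            store.add(k, v)
        out, dp_score = dp_optimal_tree(store, taxa)
        assert out.bipartitions() == tree.bipartitions()
        assert dp_score == pytest.approx(2 * score, abs=1e-9)

    def test_dp_dominates_every_round(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        genes = [make_random_tree(taxa, rng) for _ in range(4)]
        store = TripartitionStore()
        round_scores = []
        for seed in range(4):
            _, trips, score = greedy_round(genes, "length",
                                           np.random.default_rng(seed),
                                           known_scores=store.scores)
            round_scores.append(score)
            for k, v in trips.items():
                store.add(k, v)
        out, dp_score = dp_optimal_tree(store, taxa)
        assert dp_score / 2 >= max(round_scores) - 1e-9
        assert dp_score / 2 == pytest.approx(
            weighted_quartet_score(out, genes, "length"), abs=1e-9)

    def test_full_store_recovers_global_optimum_n6(self, rng):
        taxa = [f"x{i}" for i in range(6)]
        genes = [make_random_tree(taxa, rng) for _ in range(4)]
        store = TripartitionStore()
        best, best_tree = -1.0, None
        for t in all_binary_topologies(taxa):
            w = weighted_quartet_score(t, genes, "hybrid")
            if w > best:
                best, best_tree = w, t
            for k, v in all_tripartition_scores(t, genes, "hybrid",
                                                known=store.scores).items():
                store.add(k, v)
        out, dp_score = dp_optimal_tree(store, taxa)
        assert dp_score / 2 == pytest.approx(best, abs=1e-9)
        assert out.bipartitions() == best_tree.bipartitions()

    def test_infeasible_store_raises(self):
        store = TripartitionStore()
        store.add((("a",), ("b",), ("c", "d")), 1.0)
        with pytest.raises(search.InfeasibleStoreError):
            dp_optimal_tree(store, ["a", "b", "c", "d", "e"])


class TestRunSearch:
    def test_perfect_signal_recovery(self):
        rng = np.random.default_rng(3)
        tree, genes = perfect_genes([f"t{i}" for i in range(10)], rng)
        for scheme in SCHEMES:
            out = run_search(genes, SearchParams(seed=5, scheme=scheme))
            assert out.bipartitions() == tree.bipartitions()

    def test_stops_after_first_unimproving_batch_on_perfect_signal(self):
        rng = np.random.default_rng(4)
        _, genes = perfect_genes([f"t{i}" for i in range(8)], rng)
        trace: list = []
        run_search(genes, SearchParams(seed=2, scheme="hybrid"), trace=trace)
        rounds = [t for t in trace if "round" in t]
        assert len(rounds) == 12 + 4  # one batch, then no improvement

    def test_deterministic_output(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        genes = [make_random_tree(taxa, rng) for _ in range(5)]
        out1 = run_search(genes, SearchParams(seed=9, scheme="hybrid"))
        out2 = run_search(genes, SearchParams(seed=9, scheme="hybrid"))
        assert write_tree(out1) == write_tree(out2)


class TestDAC:
    def test_below_threshold_falls_back_to_run_search(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        genes = [make_random_tree(taxa, rng) for _ in range(4)]
        params = SearchParams(seed=11, scheme="hybrid", dac_threshold=200)
        assert write_tree(dac_tree(genes, params)) == \
            write_tree(run_search(genes, params))

    def test_perfect_signal_recovery_through_clusters_and_merge(self):
        rng = np.random.default_rng(12)
        tree, genes = perfect_genes([f"s{i:02d}" for i in range(30)], rng, k=4)
        params = SearchParams(seed=1, scheme="hybrid", dac_threshold=20)
        out = dac_tree(genes, params)
        assert out.leaf_names() == tree.leaf_names()
        assert out.bipartitions() == tree.bipartitions()

    def test_graft_region_keeps_descendant_refinements(self):
        # hand-built: scaffold (a,(b,(c,d))); cluster tree refines edge {c,d}
        # by inserting x; a second cluster inserted y below on edge {d};
        # grafting the {c,d} region must not erase y.
        scaffold = parse_tree("(a,b,(c,d));")
        merged = scaffold.copy()
        tree_cd = parse_tree("(a,b,((c,d),x));")
        tree_d = parse_tree("(a,b,(c,(d,y)));")
        scaffold_set = {"a", "b", "c", "d"}
        for src, ekey in ((tree_d, ("d",)), (tree_cd, ("c", "d"))):
            top = search._region_top(src, ekey, scaffold_set)
            bottom = search._region_bottom(src, ekey, scaffold_set)
            target = search._find_edge(merged, ekey, restrict_to=scaffold_set)
            search._graft_region(target, top, bottom)
        want = parse_tree("(a,b,((c,(d,y)),x));")
        assert merged.bipartitions() == want.bipartitions()


def test_all_binary_topologies_counts():
    assert len(all_binary_topologies("abcd")) == 3
    assert len(all_binary_topologies("abcde")) == 15
    assert len(all_binary_topologies("abcdef")) == 105
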