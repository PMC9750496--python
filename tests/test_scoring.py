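import itertools

import numpy as np
import pytest

from conftest import make_random_tree, reference_score
from wquartet import scoring
from wquartet.quartets import WeightScheme
from wquartet.scoring import (QuadripartitionCounts, Tripartition,
                              all_tripartition_scores, quadripartition_counts,
                              tripartition_score, weighted_quartet_score)
from wquartet.treeio import parse_tree

SCHEMES = ["unweighted", "support", "length", "hybrid"]


def annotated(newick):
    return parse_tree(newick)


class TestWeightedQuartetScore:
    def test_perfect_agreement_counts_all_quartets(self):
        s = parse_tree("((((a:0,b:0)1.0:0,c:0)1.0:0,d:0)1.0:0,e:0);")
        for scheme in SCHEMES:
            assert weighted_quartet_score(s, [s.copy()], scheme) == \
                pytest.approx(5.0, abs=1e-9)  # C(5,4)

    def test_total_disagreement_scores_zero(self):
        s = parse_tree("((a:0,b:0)1.0:0,(c:0,d:0)1.0:0);")
        g = parse_tree("((a:0,c:0)1.0:0,(b:0,d:0)1.0:0);")
        for scheme in SCHEMES:
            assert weighted_quartet_score(s, [g], scheme) == 0.0

    @pytest.mark.parametrize("seed", range(4))
    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_matches_pure_python_reference(self, seed, scheme):
        rng = np.random.default_rng(seed)
        taxa = [f"t{i}" for i in range(7)]
        s = make_random_tree(taxa, rng)
        genes = [make_random_tree(taxa, rng) for _ in range(3)]
        if seed % 2:
            genes.append(make_random_tree(taxa[:5], rng))  # missing taxa
        assert weighted_quartet_score(s, genes, scheme) == \
            pytest.approx(reference_score(s, genes, scheme), abs=1e-9)

    def test_unweighted_score_is_integral(self, rng):
        taxa = [f"t{i}" for i in range(9)]
        s = make_random_tree(taxa, rng)
        genes = [make_random_tree(taxa, rng) for _ in range(5)]
        w = weighted_quartet_score(s, genes, "unweighted")
        assert abs(w - round(w)) < 1e-9

    def test_non_binary_species_tree_rejected(self):
        with pytest.raises(ValueError, match="binary"):
            weighted_quartet_score(parse_tree("(a,b,c,d,e);"),
                                   [parse_tree("((a,b),(c,d),e);")],
                                   "unweighted")


class TestTripartitionScore:
    def test_single_quartet_counted_once(self):
        gene = parse_tree("((a:0,x:0)1.0:0,(b:0,c:0)1.0:0);")
        tri = Tripartition((frozenset("ax"), frozenset("b"), frozenset("c")))
        for scheme in SCHEMES:
            assert tripartition_score(tri, [gene], scheme) == \
                pytest.approx(1.0, abs=1e-9)

    def test_all_singleton_blocks_score_zero(self):
        gene = parse_tree("((a:0,b:0)1.0:0,(c:0,d:0)1.0:0);")
        tri = Tripartition((frozenset("a"), frozenset("b"), frozenset("c")))
        assert tripartition_score(tri, [gene], "unweighted") == 0.0

    @pytest.mark.parametrize("scheme", SCHEMES)
    def test_matches_direct_quartet_enumeration(self, scheme, rng):
        taxa = [f"t{i}" for i in range(8)]
        genes = [make_random_tree(taxa, rng) for _ in range(3)]
        blocks = (frozenset(taxa[:3]), frozenset(taxa[3:5]), frozenset(taxa[5:]))
        got = tripartition_score(Tripartition(blocks), genes, scheme)
        want = _anchored_reference(blocks, genes, scheme)
        assert got == pytest.approx(want, abs=1e-9)

    def test_invalid_blocks_rejected(self):
        with pytest.raises(ValueError):
            Tripartition((frozenset("ab"), frozenset("bc"), frozenset("d")))
        with pytest.raises(ValueError):
            Tripartition((frozenset(), frozenset("a"), frozenset("b")))


def _anchored_reference(blocks, genes, scheme):
    from wquartet.quartets import quartet_weight, canonical_topology
    from wquartet.treeio import induced_quartet
    total = 0.0
    for gene in genes:
        present = gene.leaf_names()
        for i in range(3):
            same, o1, o2 = blocks[i], blocks[(i + 1) % 3], blocks[(i + 2) % 3]
            for x, y in itertools.combinations(sorted(same & present), 2):
                for u in sorted(o1 & present):
                    for v in sorted(o2 & present):
                        target = canonical_topology((x, y), (u, v))
                        obs = induced_quartet(gene, (x, y, u, v))
                        total += quartet_weight(obs, target, scheme)
    return total


class TestAnchoringIdentity:
    @pytest.mark.parametrize("seed", range(6))
    def test_half_sum_of_tripartitions_equals_score(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(6, 13))
        k = int(rng.integers(1, 6))
        taxa = [f"t{i}" for i in range(n)]
        s = make_random_tree(taxa, rng)
        genes = [make_random_tree(taxa, rng) for _ in range(k)]
        for scheme in SCHEMES:
            trips = all_tripartition_scores(s, genes, scheme)
            assert len(trips) == n - 2
            w = weighted_quartet_score(s, genes, scheme)
            assert 0.5 * sum(trips.values()) == pytest.approx(w, abs=1e-9)


class TestQuadripartitionCounts:
    def _branch(self, tree):
        return next(n for n in tree.postorder()
                    if not n.is_leaf and n is not tree.root)

    def test_identical_genes_give_x1_equals_k(self):
        s = parse_tree("(((a:0,b:0)1.0:0,(c:0,d:0)1.0:0)1.0:0,(e:0,f:0)1.0:0);")
        genes = [s.copy() for _ in range(7)]
        counts = quadripartition_counts(s, self._branch(s), genes, "unweighted")
        assert counts.x1 == pytest.approx(7.0)
        assert counts.x2 == counts.x3 == 0.0
        assert counts.effective_k == 7

    def test_single_gene_self_normalises(self, rng):
        taxa = [f"t{i}" for i in range(8)]
        s = make_random_tree(taxa, rng)
        gene = make_random_tree(taxa, rng)
        counts = quadripartition_counts(s, self._branch(s), [gene], "unweighted")
        assert counts.x1 + counts.x2 + counts.x3 == pytest.approx(1.0)

    def test_equal_per_gene_quartet_counts_match_prior_definition(self, rng):
        # with equal N_g the normalisation reduces to sum(n_g) / N
        taxa = [f"t{i}" for i in range(6)]
        s = make_random_tree(taxa, rng)
        genes = [make_random_tree(taxa, rng) for _ in range(5)]
        branch = self._branch(s)
        counts = quadripartition_counts(s, branch, genes, "unweighted")
        old = _old_definition(s, branch, genes)
        assert counts.x1 == pytest.approx(old[0], abs=1e-9)
        assert counts.x2 == pytest.approx(old[1], abs=1e-9)
        assert counts.x3 == pytest.approx(old[2], abs=1e-9)

    def test_part_relabelling_swaps_x2_x3(self, rng):
        # exchanging the two far parts C and D permutes the two alternative
        # resolutions; verified via the old-definition oracle on x2/x3 order
        taxa = [f"t{i}" for i in range(8)]
        s = make_random_tree(taxa, rng)
        genes = [make_random_tree(taxa, rng) for _ in range(4)]
        branch = self._branch(s)
        c = quadripartition_counts(s, branch, genes, "unweighted")
        a_, b_, cc, dd = scoring._branch_parts(s, branch)
        swapped = _counts_for_parts(a_, b_, dd, cc, genes)
        assert c.x2 == pytest.approx(swapped[2], abs=1e-9)
        assert c.x3 == pytest.approx(swapped[1], abs=1e-9)

    def test_no_gene_spanning_all_parts_flags_unsupported(self):
        s = parse_tree("(((a,b),(c,d)),(e,f));")
        gene = parse_tree("((a:0,b:0)1.0:0,(c:0,g:0)1.0:0);")
        counts = quadripartition_counts(s, self._branch(s), [gene], "unweighted")
        assert counts.unsupported
        assert (counts.x1, counts.x2, counts.x3) == (0.0, 0.0, 0.0)


def _old_definition(s, branch, genes):
    from wquartet.quartets import canonical_topology, quartet_weight
    from wquartet.treeio import induced_quartet
    a_, b_, c_, d_ = scoring._branch_parts(s, branch)
    return _counts_from_parts_old(a_, b_, c_, d_, genes)


def _counts_from_parts_old(A, B, C, D, genes):
    from wquartet.quartets import canonical_topology, quartet_weight
    from wquartet.treeio import induced_quartet
    xs = np.zeros(3)
    for gene in genes:
        P = gene.leaf_names()
        ng = np.zeros(3)
        Ng = 0
        for a in A & P:
            for b in B & P:
                for c in C & P:
                    for d in D & P:
                        Ng += 1
                        obs = induced_quartet(gene, (a, b, c, d))
                        for i, pairing in enumerate(
                                ((a, b), (a, c), (a, d))):
                            other = tuple({a, b, c, d} - set(pairing))
                            t = canonical_topology(pairing, other)
                            ng[i] += quartet_weight(obs, t, "unweighted")
        if Ng:
            xs += ng / Ng
    return xs


def _counts_for_parts(A, B, C, D, genes):
    """x counts with explicit part order, sharing the new normalisation."""
    from wquartet.quartets import canonical_topology, quartet_weight
    from wquartet.treeio import induced_quartet
    nums = np.zeros(3)
    roots = []
    for gene in genes:
        P = gene.leaf_names()
        ng = np.zeros(3)
        for a in A & P:
            for b in B & P:
                for c in C & P:
                    for d in D & P:
                        obs = induced_quartet(gene, (a, b, c, d))
                        for i, pairing in enumerate(((a, b), (a, c), (a, d))):
                            other = tuple({a, b, c, d} - set(pairing))
                            t = canonical_topology(pairing, other)
                            ng[i] += quartet_weight(obs, t, "unweighted")
        if ng.sum() > 0:
            nums += ng
            roots.append(np.sqrt(ng.sum()))
    denom = np.mean(roots) ** 2
    return nums / denom
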