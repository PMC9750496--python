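"""Shared fixtures: random annotated trees and a pure-Python reference
scorer built from the per-quartet primitives (independent of the vectorised
scoring path and of the search engine)."""

from __future__ import annotations

import itertools

import numpy as np
import pytest

from wquartet.quartets import WeightScheme, quartet_weight
from wquartet.treeio import AnnotatedTree, Node, induced_quartet


def make_random_tree(taxa, rng, supports=True, lengths=True,
                     support_value=None, length_value=None) -> AnnotatedTree:
    """Uniform random binary topology with random (or fixed) annotations."""
    taxa = list(taxa)
    rng.shuffle(taxa)
    root = Node(None)
    for t in taxa[:3]:
        root.add(Node(t))
    tree = AnnotatedTree(root)
    for t in taxa[3:]:
        edges = [n for n in tree.postorder() if n is not tree.root]
        edge = edges[int(rng.integers(len(edges)))]
        parent = edge.parent
        joint = Node(None)
        parent.children[parent.children.index(edge)] = joint
        joint.parent = parent
        joint.add(edge)
        joint.add(Node(t))
        tree = AnnotatedTree(tree.root)
    for n in tree.postorder():
        if n is tree.root:
            continue
        if lengths:
            n.length = (length_value if length_value is not None
                        else float(rng.exponential(0.3)))
        if supports and not n.is_leaf:
            n.supports = ((support_value if support_value is not None
                           else float(rng.uniform())),)
    return tree


def reference_score(species_tree: AnnotatedTree, genes,
                    scheme: "WeightScheme | str") -> float:
    """O(k n^4) reference via induced_quartet + quartet_weight only."""
    scheme = WeightScheme(scheme)
    total = 0.0
    staxa = sorted(species_tree.leaf_names())
    for gene in genes:
        shared = sorted(set(staxa) & gene.leaf_names())
        for quartet in itertools.combinations(shared, 4):
            target = induced_quartet(species_tree, quartet).topology
            obs = induced_quartet(gene, quartet)
            total += quartet_weight(obs, target, scheme)
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(20221006)


@pytest.fixture
def tree_factory():
    return make_random_tree
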