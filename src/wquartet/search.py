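"""Optimisation of the weighted quartet score.

The search follows a placement-first design: a species tree is grown by
inserting one taxon at a time at its optimal edge (optimal with respect to
the weighted quartet score, exactly), several such randomized greedy rounds
are run, the tripartition scores of every round tree are recorded, and a
final dynamic program assembles the best tree whose every internal
tripartition was seen in some round.  For large taxon sets a
divide-and-conquer wrapper builds a backbone on ~sqrt(n) taxa, places the
remaining taxa independently, grows per-edge subtrees, merges them over the
shared scaffold and re-places any orphans.

The placement step never rescoress whole trees: for a fixed backbone, the
score of attaching the query on edge e differs from the backbone score by
the total weight of gene quartets containing the query whose induced
resolution pairs the query with the leaf on e's side of the quartet's
Steiner vertex.  Accumulating those weights over subtree intervals gives
all per-edge scores in one pass per gene batch; the result provably equals
brute-force rescoring and is tested against it.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

from ._matrices import GeneMatrixBatch, pairing_sums_by_row
from ._treetables import TreeTables
from .quartets import WeightScheme
from .scoring import (all_tripartition_scores, ensure_batch,
                      weighted_quartet_score)
from .treeio import AnnotatedTree, Node

__all__ = [
    "SearchParams",
    "TripartitionStore",
    "InfeasibleStoreError",
    "score_placements",
    "greedy_round",
    "dp_optimal_tree",
    "run_search",
    "dac_tree",
    "all_binary_topologies",
]

class InfeasibleStoreError(RuntimeError):
    """No binary tree can be assembled from the stored tripartitions."""


@dataclass
class SearchParams:
    """Schedule of the randomized-greedy + DP search.

    Twelve initial rounds, then batches of four more rounds with a
    cumulative store, stopping when the DP score stops improving or after
    five batches (total rounds in [16, 32]).
    """

    initial_rounds: int = 12
    batch_size: int = 4
    max_batches: int = 5
    seed: int = 0
    scheme: WeightScheme = WeightScheme.HYBRID
    dac_threshold: int = 200

    def __post_init__(self):
        self.scheme = WeightScheme(self.scheme)
        if min(self.initial_rounds, self.batch_size, self.max_batches) < 1:
            raise ValueError("round counts must be positive")


class TripartitionStore:
    """Canonical tripartition -> aggregated score, with round provenance."""

    def __init__(self):
        self.scores: dict[tuple, float] = {}
        self.provenance: dict[tuple, int] = {}

    def add(self, key: tuple, score: float, round_id: int = -1) -> None:
        if key not in self.scores:
            self.scores[key] = score
            self.provenance[key] = round_id

    def __len__(self) -> int:
        return len(self.scores)

    def __contains__(self, key) -> bool:
        return key in self.scores


# ---------------------------------------------------------------------- #
# optimal single-taxon placement
# ---------------------------------------------------------------------- #
class _BackbonePlacer:
    """Per-backbone tables for optimal query placement.

    Edges are identified by their child node in the rooted representation
    (root has three children; every non-root node is one unrooted edge).
    """

    def __init__(self, tree: AnnotatedTree, batch: GeneMatrixBatch):
        self.tree = tree
        self.batch = batch
        tt = TreeTables(tree, batch.index)
        self.tt = tt
        self.nodes = tt.nodes
        m = tt.m

        # triples of local leaf ids
        tri = np.array(list(itertools.combinations(range(m), 3)),
                       dtype=np.int64)
        self.tri = tri
        X, Y, Z = tri[:, 0], tri[:, 1], tri[:, 2]
        dep = tt.depth
        mrca, ctow = tt.mrca, tt.ctow
        pair_m = np.stack([mrca[Y, Z], mrca[X, Z], mrca[X, Y]])  # m of others
        s_depth = np.maximum.reduce([dep[pair_m[0]], dep[pair_m[1]],
                                     dep[pair_m[2]]])
        # steiner vertex = deepest pairwise mrca
        self.steiner = np.where(
            dep[pair_m[2]] == s_depth, pair_m[2],
            np.where(dep[pair_m[1]] == s_depth, pair_m[1], pair_m[0]))
        # per triple column j (partner = X/Y/Z): component encoding
        self.comp = np.zeros((3, tri.shape[0]), dtype=np.int64)
        self.compl = np.zeros((3, tri.shape[0]), dtype=bool)
        others = [(Y, Z), (X, Z), (X, Y)]
        for j, (o1, o2) in enumerate(others):
            L = tri[:, j]
            m1 = mrca[L, o1]
            m2 = mrca[L, o2]
            use1 = dep[m1] >= dep[m2]
            mbest = np.where(use1, m1, m2)
            obest = np.where(use1, o1, o2)
            inside = dep[mbest] == s_depth
            self.comp[j] = np.where(inside, ctow[L, obest], self.steiner)
            self.compl[j] = ~inside

    def deltas(self, query: str) -> np.ndarray:
        """Score increment of attaching ``query`` on each edge; indexed by
        node id (entry for the root is meaningless)."""
        batch = self.batch
        tt = self.tt
        q = batch.index[query]
        N = len(self.nodes)
        sub = np.zeros(N)
        self_add = np.zeros(N)
        glob = 0.0
        T = self.tri.shape[0]
        if T:
            gl = tt.leaf_global
            gX = gl[self.tri[:, 0]]
            gY = gl[self.tri[:, 1]]
            gZ = gl[self.tri[:, 2]]
            ws = pairing_sums_by_row(batch, q, gX, gY, gZ)
            for j in range(3):
                w = ws[j]
                compl = self.compl[j]
                direct = ~compl
                np.add.at(sub, self.comp[j][direct], w[direct])
                if compl.any():
                    wc = w[compl]
                    s_nodes = self.steiner[compl]
                    glob += float(wc.sum())
                    np.add.at(sub, s_nodes, -wc)
                    np.add.at(self_add, s_nodes, wc)
        acc = np.zeros(N)
        for i in reversed(range(N - 1)):  # postorder: parents after children
            acc[i] = sub[i] + acc[self.tt.parent[i]]
        return glob + acc + self_add

    def best_edge(self, query: str):
        """(node, delta) of the optimal placement; ties break on the
        smallest canonical edge key (sorted leaf names below the edge)."""
        deltas = self.deltas(query)
        order = sorted(range(len(self.nodes) - 1),
                       key=lambda i: _edge_key(self.nodes[i]))
        best = order[0]
        for i in order[1:]:
            if deltas[i] > deltas[best]:
                best = i
        return self.nodes[best], float(deltas[best])


def _edge_key(node: Node) -> tuple:
    names = []
    stack = [node]
    while stack:
        n = stack.pop()
        if n.is_leaf:
            names.append(n.name)
        else:
            stack.extend(n.children)
    return tuple(sorted(names))


def score_placements(backbone: AnnotatedTree, query: str, genes,
                     scheme: "WeightScheme | str",
                     batch: GeneMatrixBatch | None = None,
                     backbone_score: float | None = None) -> dict:
    """Weighted quartet score of every possible attachment of ``query``.

    Returns a map from canonical edge key (sorted leaf names on the child
    side of the edge) to the full score of the extended tree; equals
    brute-force rescoring of each placement.
    """
    scheme = WeightScheme(scheme)
    if query in backbone.leaf_names():
        raise ValueError(f"query {query!r} already in the backbone")
    batch = ensure_batch(genes, scheme, batch,
                         extra_taxa=backbone.leaf_names() | {query})
    if backbone_score is None:
        backbone_score = (weighted_quartet_score(backbone, genes, scheme, batch)
                          if len(backbone.leaf_names()) >= 4 else 0.0)
    placer = _BackbonePlacer(backbone, batch)
    deltas = placer.deltas(query)
    return {_edge_key(n): backbone_score + float(deltas[i])
            for i, n in enumerate(placer.nodes) if n is not placer.tree.root
            and n.parent is not None}


def _attach(tree: AnnotatedTree, edge_node: Node, query: str) -> Node:
    """Attach a new leaf on the edge above ``edge_node``; returns the leaf."""
    parent = edge_node.parent
    w = Node(None)
    leaf = Node(query)
    parent.children[parent.children.index(edge_node)] = w
    w.parent = parent
    w.add(edge_node)
    w.add(leaf)
    return leaf


def _star3(taxa3) -> AnnotatedTree:
    root = Node(None)
    for t in taxa3:
        root.add(Node(t))
    return AnnotatedTree(root)


def greedy_round(genes, scheme: "WeightScheme | str", rng,
                 batch: GeneMatrixBatch | None = None,
                 taxa: "list[str] | None" = None,
                 known_scores: dict | None = None):
    """One randomized greedy insertion round.

    Taxa are inserted in a seeded random order, each at its optimal edge.
    Returns ``(tree, tripartition_scores, tree_score)`` where the
    tripartition scores cover every internal node of the final tree.
    """
    scheme = WeightScheme(scheme)
    batch = ensure_batch(genes, scheme, batch)
    if taxa is None:
        taxa = list(batch.taxa)
    if len(taxa) < 4:
        raise ValueError("need at least 4 taxa to search for a species tree")
    order = [taxa[i] for i in rng.permutation(len(taxa))]
    tree = _star3(order[:3])
    score = 0.0
    for query in order[3:]:
        placer = _BackbonePlacer(tree, batch)
        node, delta = placer.best_edge(query)
        _attach(tree, node, query)
        score += delta
    trip = all_tripartition_scores(tree, genes, scheme, batch,
                                   known=known_scores)
    return tree, trip, score


# ---------------------------------------------------------------------- #
# dynamic programming over recorded tripartitions
# ---------------------------------------------------------------------- #
def dp_optimal_tree(store: TripartitionStore, species) -> tuple:
    """Exact maximiser of the summed tripartition score over binary trees
    whose every internal tripartition appears in the store.

    Returns ``(tree, score)``; the score equals twice the weighted quartet
    score of the tree.  Rooted at the lexicographically smallest taxon.
    """
    species = sorted(species)
    if len(species) < 4:
        raise ValueError("need at least 4 species")
    pos = {t: i for i, t in enumerate(species)}
    rho_bit = 1
    full = (1 << len(species)) - 1

    def bits_of(names) -> int:
        b = 0
        for t in names:
            b |= 1 << pos[t]
        return b

    trans: dict[int, list[tuple[int, int, float]]] = {}
    for key, w in store.scores.items():
        blocks = [bits_of(b) for b in key]
        if (blocks[0] | blocks[1] | blocks[2]) != full:
            continue  # tripartition over a different taxon set
        zi = next(i for i, b in enumerate(blocks) if b & rho_bit)
        x, y = (blocks[i] for i in range(3) if i != zi)
        trans.setdefault(x | y, []).append((x, y, w))

    V: dict[int, float] = {1 << i: 0.0 for i in range(len(species))}
    choice: dict[int, tuple[int, int, float]] = {}
    for clade in sorted(trans, key=lambda b: b.bit_count()):
        best = None
        for x, y, w in trans[clade]:
            if x in V and y in V:
                cand = V[x] + V[y] + w
                if best is None or cand > best[0]:
                    best = (cand, x, y, w)
        if best is not None:
            V[clade] = best[0]
            choice[clade] = (best[1], best[2], best[3])

    goal = full & ~rho_bit
    if goal not in V:
        raise InfeasibleStoreError(
            "stored tripartitions do not assemble into any binary tree")

    def build(bits: int) -> Node:
        if bits.bit_count() == 1:
            return Node(species[bits.bit_length() - 1])
        x, y, _ = choice[bits]
        node = Node(None)
        node.add(build(x))
        node.add(build(y))
        return node

    root = Node(None)
    root.add(Node(species[0]))
    x, y, _ = choice[goal]
    root.add(build(x))
    root.add(build(y))
    return AnnotatedTree(root), float(V[goal])


# ---------------------------------------------------------------------- #
# full searches
# ---------------------------------------------------------------------- #
def _spawn_rngs(seed: int, n: int):
    return [np.random.default_rng(s)
            for s in np.random.SeedSequence(seed).spawn(n)]


def run_search(genes, params: SearchParams,
               batch: GeneMatrixBatch | None = None,
               taxa: "list[str] | None" = None,
               rounds_override: int | None = None,
               trace: list | None = None) -> AnnotatedTree:
    """Randomized greedy rounds + DP with the adaptive round schedule.

    When ``trace`` is a list, per-round greedy scores and per-batch DP
    scores are appended to it (DP scores are twice the quartet score).
    """
    batch = ensure_batch(genes, params.scheme, batch)
    if taxa is None:
        taxa = list(batch.taxa)
    max_rounds = params.initial_rounds + params.batch_size * params.max_batches
    rngs = _spawn_rngs(params.seed, max_rounds)
    store = TripartitionStore()
    round_id = 0

    def do_rounds(count: int):
        nonlocal round_id
        for _ in range(count):
            _, trip, score = greedy_round(genes, params.scheme, rngs[round_id],
                                          batch, taxa,
                                          known_scores=store.scores)
            for key, val in trip.items():
                store.add(key, val, round_id)
            if trace is not None:
                trace.append({"round": round_id, "greedy_score": score})
            round_id += 1

    if rounds_override is not None:
        do_rounds(rounds_override)
        tree, score = dp_optimal_tree(store, taxa)
        if trace is not None:
            trace.append({"dp_score": score})
        return tree

    do_rounds(params.initial_rounds)
    tree, best = dp_optimal_tree(store, taxa)
    if trace is not None:
        trace.append({"dp_score": best})
    for _ in range(params.max_batches):
        do_rounds(params.batch_size)
        tree2, score2 = dp_optimal_tree(store, taxa)
        if trace is not None:
            trace.append({"dp_score": score2})
        if score2 > best * (1.0 + 1e-12) + 1e-300:
            tree, best = tree2, score2
        else:
            break
    return tree


def dac_tree(genes, params: SearchParams,
             batch: GeneMatrixBatch | None = None) -> AnnotatedTree:
    """Divide-and-conquer search for large taxon sets.

    Backbone on ceil(sqrt(n)) random taxa (ceil(sqrt(n)) greedy rounds +
    DP), independent optimal placement of the remaining taxa grouped into
    per-edge clusters, sequential insertion per cluster with orphan
    removal, merge over the shared scaffold, and final placement of
    orphans.  Falls back to :func:`run_search` below ``params.dac_threshold``.
    """
    batch = ensure_batch(genes, params.scheme, batch)
    taxa = list(batch.taxa)
    n = len(taxa)
    if n < params.dac_threshold:
        return run_search(genes, params, batch)

    rng = np.random.default_rng(np.random.SeedSequence(params.seed).spawn(1)[0])
    m = math.isqrt(n)
    if m * m < n:
        m += 1
    backbone_taxa = sorted(rng.choice(np.array(taxa), size=m, replace=False)
                           .tolist())
    sub_params = SearchParams(initial_rounds=m, batch_size=params.batch_size,
                              max_batches=params.max_batches, seed=params.seed,
                              scheme=params.scheme)
    scaffold = run_search(genes, sub_params, batch, taxa=backbone_taxa,
                          rounds_override=m)

    # step 2: independent optimal placement -> per-edge clusters
    remaining = sorted(set(taxa) - set(backbone_taxa))
    placer = _BackbonePlacer(scaffold, batch)
    clusters: dict[tuple, list[str]] = {}
    for t in remaining:
        node, _ = placer.best_edge(t)
        clusters.setdefault(_edge_key(node), []).append(t)

    # step 3: sequential insertion per cluster with orphan removal
    scaffold_set = set(backbone_taxa)
    per_edge_trees: dict[tuple, AnnotatedTree] = {}
    orphans: list[str] = []
    for ekey in sorted(clusters):
        sub = scaffold.copy()
        derived = {_find_edge(sub, ekey)}
        for t in clusters[ekey]:
            p = _BackbonePlacer(sub, batch)
            node, _ = p.best_edge(t)
            if node not in derived:
                orphans.append(t)
                continue
            leaf = _attach(sub, node, t)
            derived.add(leaf)
            derived.add(node.parent)  # the new internal node
        per_edge_trees[ekey] = sub

    # step 4: merge per-edge trees over the shared scaffold
    merged = scaffold.copy()
    for ekey in sorted(per_edge_trees):
        src = per_edge_trees[ekey]
        if src.leaf_names() == scaffold_set:
            continue  # nothing was inserted on this edge
        top = _region_top(src, ekey, scaffold_set)
        bottom = _region_bottom(src, ekey, scaffold_set)
        if top is bottom:
            continue
        target = _find_edge(merged, ekey, restrict_to=scaffold_set)
        _graft_region(target, top, bottom)

    # step 5: place orphans on the merged tree
    for t in sorted(orphans):
        p = _BackbonePlacer(merged, batch)
        node, _ = p.best_edge(t)
        _attach(merged, node, t)
    return merged


def _find_edge(tree: AnnotatedTree, key: tuple,
               restrict_to: "set[str] | None" = None) -> Node:
    """Node whose (scaffold-restricted) child clade equals ``key``."""
    want = set(key)
    for node in tree.postorder():
        if node is tree.root:
            continue
        clade = set(_edge_key(node))
        if restrict_to is not None:
            clade &= restrict_to
        if clade == want:
            return node
    raise KeyError(f"edge {key} not found")


def _region_top(tree: AnnotatedTree, ekey: tuple, scaffold: set) -> Node:
    """Top node of the cluster region that replaced scaffold edge ``ekey``:
    the highest node whose scaffold-restricted clade equals the edge clade."""
    want = set(ekey)
    best: Node | None = None
    for node in tree.preorder():
        if node is tree.root:
            continue
        clade = set(_edge_key(node)) & scaffold
        if clade == want:
            best = node
            break  # preorder: first hit is the highest
    if best is None:
        raise KeyError(f"region for edge {ekey} not found")
    return best


def _region_bottom(tree: AnnotatedTree, ekey: tuple, scaffold: set) -> Node:
    """Lowest node whose scaffold-restricted clade equals the edge clade:
    the original (unsubdivided) child endpoint of the scaffold edge."""
    want = set(ekey)
    for node in tree.postorder():
        if node is tree.root:
            continue
        if set(_edge_key(node)) & scaffold == want:
            return node
    raise KeyError(f"region bottom for edge {ekey} not found")


def _graft_region(target: Node, top: Node, bottom: Node) -> None:
    """Insert the chain (and its hanging new-taxon subtrees) between
    ``top`` and ``bottom`` of a per-edge tree above ``target`` in the
    merged tree, keeping the merged tree's current subtree below the edge.
    """
    parent = target.parent

    def rec(src: Node) -> Node:
        if src is bottom:
            return target
        new = Node(src.name, src.length, src.supports)
        for c in src.children:
            new.add(rec(c))
        return new

    copy = rec(top)
    parent.children[parent.children.index(target)] = copy
    copy.parent = parent


def _copy_subtree(node: Node) -> Node:
    new = Node(node.name, node.length, node.supports)
    for c in node.children:
        new.add(_copy_subtree(c))
    return new


# ---------------------------------------------------------------------- #
# exhaustive topology enumeration (small n)
# ---------------------------------------------------------------------- #
def all_binary_topologies(taxa):
    """All (2n-5)!! unrooted binary topologies, as AnnotatedTrees."""
    taxa = sorted(taxa)
    if len(taxa) < 3:
        raise ValueError("need at least 3 taxa")

    def edges_of(tree: AnnotatedTree):
        return [n for n in tree.postorder() if n is not tree.root]

    trees = [_star3(taxa[:3])]
    for t in taxa[3:]:
        nxt = []
        for tr in trees:
            for i in range(len(edges_of(tr))):
                cp = tr.copy()
                _attach(cp, edges_of(cp)[i], t)
                nxt.append(cp)
        trees = nxt
    return trees
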