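"""Weighted quartet scores by explicit quartet enumeration.

This layer is the correctness reference for the search engine: the species
tree score sums, over genes and over every four-taxon subset of the species
tree, the weight of the species-tree resolution in the gene (which is zero
unless the gene displays the same resolution).  Per-node tripartition
scores and per-branch quadripartition counts (the input of localPP branch
support) are computed the same way.  All functions enumerate quartets in
O(n^4) (vectorised over genes and quartets); the search module avoids this
cost but must agree with these values.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from ._matrices import (GeneMatrixBatch, build_batch, pairing_sums_by_gene,
                        pairing_sums_by_row, tree_topo_matrix, union_taxa)
from ._treetables import TreeTables
from .quartets import WeightScheme
from .treeio import AnnotatedTree

__all__ = [
    "Tripartition",
    "QuadripartitionCounts",
    "weighted_quartet_score",
    "tripartition_score",
    "all_tripartition_scores",
    "quadripartition_counts",
    "ensure_batch",
]

_MAX_CELLS = 4_000_000  # elements per vectorised (gene x quartet) block


@dataclass(frozen=True)
class Tripartition:
    """Three disjoint taxon blocks covering the species set."""

    blocks: tuple[frozenset, frozenset, frozenset]

    def __post_init__(self):
        a, b, c = self.blocks
        if not (a and b and c):
            raise ValueError("tripartition blocks must be non-empty")
        if len(a | b | c) != len(a) + len(b) + len(c):
            raise ValueError("tripartition blocks must be disjoint")

    @property
    def key(self) -> tuple:
        return canonical_tripartition_key(*self.blocks)


def canonical_tripartition_key(a, b, c) -> tuple:
    return tuple(sorted((tuple(sorted(a)), tuple(sorted(b)), tuple(sorted(c)))))


@dataclass
class QuadripartitionCounts:
    """Normalised weighted quartet counts around one species-tree branch.

    ``x1`` belongs to the branch's own resolution (A∪B | C∪D), ``x2`` to
    (A∪C | B∪D) and ``x3`` to (A∪D | B∪C).  ``effective_k`` counts the
    genes that carry at least one taxon in every part and a positive total
    weight around the branch.
    """

    x1: float
    x2: float
    x3: float
    effective_k: int

    @property
    def unsupported(self) -> bool:
        return self.effective_k == 0


def ensure_batch(genes, scheme, batch: GeneMatrixBatch | None = None,
                 extra_taxa: "set[str] | None" = None) -> GeneMatrixBatch:
    if batch is not None:
        return batch
    taxa = set(union_taxa(genes))
    if extra_taxa:
        taxa |= set(extra_taxa)
    return build_batch(genes, scheme, sorted(taxa))


def _quartet_chunks(quartets: np.ndarray, k: int):
    if quartets.size == 0:
        return
    step = max(1, _MAX_CELLS // max(k, 1))
    for i in range(0, quartets.shape[0], step):
        yield quartets[i:i + step]


def weighted_quartet_score(species_tree: AnnotatedTree, genes,
                           scheme: "WeightScheme | str",
                           batch: GeneMatrixBatch | None = None) -> float:
    """Total weighted quartet score of a species tree (reference O(k n^4))."""
    scheme = WeightScheme(scheme)
    if not species_tree.is_binary():
        raise ValueError("species tree must be binary")
    batch = ensure_batch(genes, scheme, batch,
                         extra_taxa=species_tree.leaf_names())
    sidx = sorted(batch.index[t] for t in species_tree.leaf_names())
    if len(sidx) < 4:
        return 0.0
    stopo = tree_topo_matrix(species_tree, batch.taxa)
    total = 0.0
    combos = itertools.combinations(sidx, 4)
    while True:
        chunk = list(itertools.islice(combos, 2_000_000))
        if not chunk:
            break
        q = np.array(chunk, dtype=np.int64)
        a, b, c, d = q[:, 0], q[:, 1], q[:, 2], q[:, 3]
        s1 = stopo[a, b] + stopo[c, d]
        s2 = stopo[a, c] + stopo[b, d]
        s3 = stopo[a, d] + stopo[b, c]
        code = np.argmin(np.stack([s1, s2, s3]), axis=0)
        sums = pairing_sums_by_row(batch, a, b, c, d)
        total += float(sums[code, np.arange(sums.shape[1])].sum())
    return total


def _block_quartet_arrays(pair_block: np.ndarray, y_block: np.ndarray,
                          z_block: np.ndarray):
    """Index arrays for quartets with two taxa in ``pair_block`` and one in
    each of the other blocks; pairing is (p1,p2)|(y,z)."""
    if len(pair_block) < 2 or len(y_block) == 0 or len(z_block) == 0:
        return None
    pairs = np.array(list(itertools.combinations(pair_block.tolist(), 2)),
                     dtype=np.int64)
    py, pz = np.meshgrid(y_block, z_block, indexing="ij")
    py, pz = py.ravel(), pz.ravel()
    npairs, nyz = pairs.shape[0], py.shape[0]
    p1 = np.repeat(pairs[:, 0], nyz)
    p2 = np.repeat(pairs[:, 1], nyz)
    yy = np.tile(py, npairs)
    zz = np.tile(pz, npairs)
    return p1, p2, yy, zz


def tripartition_score(tri: "Tripartition | tuple", genes,
                       scheme: "WeightScheme | str",
                       batch: GeneMatrixBatch | None = None) -> float:
    """Total weight of gene quartets anchored at a tripartition.

    A quartet anchors here when two of its taxa fall in one block and the
    other two in the two remaining blocks; it contributes the weight of
    that same-block pairing.
    """
    scheme = WeightScheme(scheme)
    blocks = tri.blocks if isinstance(tri, Tripartition) else tuple(
        frozenset(b) for b in tri)
    batch = ensure_batch(genes, scheme, batch,
                         extra_taxa=set().union(*blocks))
    idx_blocks = [np.array(sorted(batch.index[t] for t in b), dtype=np.int64)
                  for b in blocks]
    total = 0.0
    for i in range(3):
        arrays = _block_quartet_arrays(idx_blocks[i], idx_blocks[(i + 1) % 3],
                                       idx_blocks[(i + 2) % 3])
        if arrays is None:
            continue
        p1, p2, yy, zz = arrays
        total += float(pairing_sums_by_row(batch, p1, p2, yy, zz)[0].sum())
    return total


def tree_tripartitions(species_tree: AnnotatedTree):
    """(key, blocks) of every internal node of the unrooted tree."""
    below: dict[int, frozenset] = {}
    all_names = frozenset(species_tree.leaf_names())
    out = []
    for node in species_tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        child_sets = [below[id(c)] for c in node.children]
        below[id(node)] = frozenset().union(*child_sets)
        if node is species_tree.root:
            if len(child_sets) == 3:
                blocks = tuple(child_sets)
            else:
                continue
        else:
            rest = all_names - below[id(node)]
            if not rest:
                continue
            blocks = (child_sets[0], child_sets[1], rest)
        out.append((canonical_tripartition_key(*blocks), blocks))
    return out


def all_tripartition_scores(species_tree: AnnotatedTree, genes,
                            scheme: "WeightScheme | str",
                            batch: GeneMatrixBatch | None = None,
                            known: dict | None = None) -> dict:
    """Scores of every internal-node tripartition of a binary species tree.

    Computed in a single pass over all quartets: each quartet's matched
    weight is credited to the two internal nodes of the species tree at
    which it anchors (the Steiner vertices of its two cherry-plus-one
    triples).  ``known`` maps canonical keys to already-computed scores and
    short-circuits the pass when the whole tree was seen before.
    """
    scheme = WeightScheme(scheme)
    if not species_tree.is_binary():
        raise ValueError("species tree must be binary")
    batch = ensure_batch(genes, scheme, batch,
                         extra_taxa=species_tree.leaf_names())
    tt = TreeTables(species_tree, batch.index)
    node_keys: dict[int, tuple] = {
        tt.node_of[id(node)]: key
        for key, node in _internal_node_keys(species_tree, tt)
    }
    if known is not None and all(k in known for k in node_keys.values()):
        return {k: known[k] for k in node_keys.values()}

    sidx = np.sort(tt.leaf_global)
    node_scores = np.zeros(len(tt.nodes))
    if len(sidx) >= 4:
        stopo = tree_topo_matrix(species_tree, batch.taxa)
        quartets = np.array(list(itertools.combinations(sidx.tolist(), 4)),
                            dtype=np.int64)
        a, b, c, d = (quartets[:, i] for i in range(4))
        s1 = stopo[a, b] + stopo[c, d]
        s2 = stopo[a, c] + stopo[b, d]
        s3 = stopo[a, d] + stopo[b, c]
        code = np.argmin(np.stack([s1, s2, s3]), axis=0)
        sums = pairing_sums_by_row(batch, a, b, c, d)
        w_matched = sums[code, np.arange(sums.shape[1])]
        x1 = a
        x2 = np.choose(code, [b, c, d])
        x3 = np.choose(code, [c, b, b])
        x4 = np.choose(code, [d, d, c])
        loc = tt.local_of_global
        anchor1 = tt.steiner(loc[x1], loc[x2], loc[x3])
        anchor2 = tt.steiner(loc[x3], loc[x4], loc[x1])
        np.add.at(node_scores, anchor1, w_matched)
        np.add.at(node_scores, anchor2, w_matched)
    return {key: float(node_scores[i]) for i, key in node_keys.items()}


def _internal_node_keys(species_tree: AnnotatedTree, tt: TreeTables):
    """(canonical key, node) for every internal node of the unrooted tree."""
    below: dict[int, frozenset] = {}
    all_names = frozenset(species_tree.leaf_names())
    for node in species_tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
            continue
        child_sets = [below[id(c)] for c in node.children]
        below[id(node)] = frozenset().union(*child_sets)
        if node is species_tree.root:
            if len(child_sets) != 3:
                continue
            blocks = tuple(child_sets)
        else:
            rest = all_names - below[id(node)]
            if not rest:
                continue
            blocks = (child_sets[0], child_sets[1], rest)
        yield canonical_tripartition_key(*blocks), node


def _branch_parts(species_tree: AnnotatedTree, branch_node):
    """Parts (A, B, C, D) around the internal edge above ``branch_node``;
    (A∪B)|(C∪D) is the edge's bipartition."""
    below: dict[int, frozenset] = {}
    for node in species_tree.postorder():
        if node.is_leaf:
            below[id(node)] = frozenset([node.name])
        else:
            below[id(node)] = frozenset().union(
                *(below[id(c)] for c in node.children))
    v = branch_node
    if v.is_leaf or v.parent is None:
        raise ValueError("branch must be an internal edge")
    if len(v.children) != 2:
        raise ValueError("species tree must be binary")
    a, b = (below[id(c)] for c in v.children)
    u = v.parent
    siblings = [c for c in u.children if c is not v]
    all_names = frozenset(species_tree.leaf_names())
    if u.parent is None and len(siblings) == 2:
        c_part, d_part = below[id(siblings[0])], below[id(siblings[1])]
    elif len(siblings) == 1:
        c_part = below[id(siblings[0])]
        d_part = all_names - a - b - c_part
    else:
        raise ValueError("species tree must be binary")
    if not (c_part and d_part):
        raise ValueError("branch must be internal (both far parts non-empty)")
    return a, b, c_part, d_part


def quadripartition_counts(species_tree: AnnotatedTree, branch_node, genes,
                           scheme: "WeightScheme | str",
                           batch: GeneMatrixBatch | None = None,
                           ) -> QuadripartitionCounts:
    """Normalised weighted counts (x1, x2, x3) around an internal branch.

    The shared denominator is the squared mean of per-gene square roots of
    the three-resolution weight total; genes with a zero total carry no
    vote and are excluded from both numerator and denominator.
    """
    scheme = WeightScheme(scheme)
    parts = _branch_parts(species_tree, branch_node)
    batch = ensure_batch(genes, scheme, batch,
                         extra_taxa=species_tree.leaf_names())
    ia, ib, ic, id_ = (np.array(sorted(batch.index[t] for t in p),
                                dtype=np.int64) for p in parts)
    has_all = batch.present[:, ia].any(axis=1)
    for arr in (ib, ic, id_):
        has_all &= batch.present[:, arr].any(axis=1)

    grids = np.meshgrid(ia, ib, ic, id_, indexing="ij")
    a, b, c, d = (g.ravel() for g in grids)
    sums = pairing_sums_by_gene(batch, a, b, c, d)
    totals = sums.sum(axis=0)
    use = has_all & (totals > 0.0)
    eff = int(use.sum())
    if eff == 0:
        return QuadripartitionCounts(0.0, 0.0, 0.0, 0)
    denom = float(np.sqrt(totals[use]).mean()) ** 2
    x1, x2, x3 = (float(sums[i, use].sum()) / denom for i in range(3))
    return QuadripartitionCounts(x1, x2, x3, eff)
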