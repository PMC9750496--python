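"""Vectorised structural tables for a rooted tree representation.

Used by the scorer (quartet anchor assignment) and the search engine
(placement components): postorder node arrays, depths, a leaf-pair MRCA
table and, for each leaf pair, the child of the MRCA on the path toward
the row leaf.
"""

from __future__ import annotations

import numpy as np

from .treeio import AnnotatedTree

__all__ = ["TreeTables"]


class TreeTables:
    def __init__(self, tree: AnnotatedTree, global_index: dict):
        self.tree = tree
        nodes = list(tree.postorder())  # root last; parents after children
        self.nodes = nodes
        self.node_of = {id(n): i for i, n in enumerate(nodes)}
        N = len(nodes)
        self.parent = np.full(N, -1, dtype=np.int64)
        self.depth = np.zeros(N, dtype=np.int64)
        for i, n in enumerate(nodes):
            if n.parent is not None:
                self.parent[i] = self.node_of[id(n.parent)]
        for i in reversed(range(N)):
            p = self.parent[i]
            if p >= 0:
                self.depth[i] = self.depth[p] + 1

        leaf_nodes = [i for i, n in enumerate(nodes) if n.is_leaf]
        self.leaf_nodes = np.array(leaf_nodes, dtype=np.int64)
        self.leaf_global = np.array(
            [global_index[nodes[i].name] for i in leaf_nodes], dtype=np.int64)
        self.m = len(leaf_nodes)
        #: local leaf position of each global taxon index (-1 if absent)
        self.local_of_global = np.full(max(global_index.values()) + 1, -1,
                                       dtype=np.int64)
        self.local_of_global[self.leaf_global] = np.arange(self.m)

        m = self.m
        mrca = np.zeros((m, m), dtype=np.int64)
        ctow = np.zeros((m, m), dtype=np.int64)
        local_of = {i: j for j, i in enumerate(leaf_nodes)}
        below: dict[int, list[int]] = {}
        for i, n in enumerate(nodes):
            if n.is_leaf:
                below[i] = [local_of[i]]
                mrca[below[i][0], below[i][0]] = i
                continue
            ch = [self.node_of[id(c)] for c in n.children]
            arrs = [np.array(below[c], dtype=np.int64) for c in ch]
            for a in range(len(ch)):
                for b in range(a + 1, len(ch)):
                    A, B = arrs[a], arrs[b]
                    mrca[np.ix_(A, B)] = i
                    mrca[np.ix_(B, A)] = i
                    ctow[np.ix_(A, B)] = ch[a]
                    ctow[np.ix_(B, A)] = ch[b]
            below[i] = [x for c in ch for x in below[c]]
        self.mrca = mrca
        self.ctow = ctow

    def steiner(self, x, y, z):
        """Steiner vertex (node id) of leaf-position triples, vectorised:
        the deepest of the three pairwise MRCAs."""
        mxy = self.mrca[x, y]
        mxz = self.mrca[x, z]
        myz = self.mrca[y, z]
        dep = self.depth
        out = np.where(dep[mxy] >= dep[mxz], mxy, mxz)
        return np.where(dep[out] >= dep[myz], out, myz)
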