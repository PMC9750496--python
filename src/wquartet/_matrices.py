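"""Per-gene pairwise path matrices.

Every quartet quantity used by the scorer and the search engine can be read
off three leaf-by-leaf matrices of a gene tree:

* ``topo`` — number of edges on the path between two leaves.  The four-point
  condition on these distances resolves the quartet topology (for a binary
  tree the minimising pairing is strict).
* ``su`` — substitution-unit path length; the length factor of a quartet
  with observed cherries (a,b),(c,d) is ``exp(-(su[a,b] + su[c,d]))``.
* ``logq`` — sum of ``log(1 - s)`` over the *internal* edges of the path.
  For an observed pairing (a,b)|(c,d) the product of ``1 - s`` over the
  anchor path equals ``exp((logq[a,c] + logq[b,d] - logq[a,b] - logq[c,d]) / 2)``
  because the pendant-side contributions cancel between the crossing and
  cherry paths.

Supports equal to 1 are clamped to ``1 - 1e-12`` inside ``logq`` so the
cancellation stays finite; the error this introduces in a weight is below
1e-11.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .quartets import MissingAnnotationError, WeightScheme
from .treeio import AnnotatedTree

__all__ = ["GeneMatrixBatch", "build_batch", "tree_topo_matrix", "union_taxa"]

_SUPPORT_CLAMP = 1.0 - 1e-12


def union_taxa(trees: "list[AnnotatedTree]") -> list[str]:
    taxa: set[str] = set()
    for t in trees:
        taxa |= t.leaf_names()
    return sorted(taxa)


@dataclass
class GeneMatrixBatch:
    """Stacked pairwise matrices for k gene trees over a global taxon list.

    Entries involving a taxon absent from a gene are ``inf`` (topo/su) or
    ``nan`` (logq); ``present`` masks which taxa each gene contains.
    """

    taxa: list[str]
    index: dict[str, int]
    present: np.ndarray          # (k, n) bool
    topo: np.ndarray             # (k, n, n)
    su: np.ndarray | None        # (k, n, n)
    logq: np.ndarray | None      # (k, n, n)
    scheme: WeightScheme

    @property
    def k(self) -> int:
        return self.present.shape[0]

    @property
    def n(self) -> int:
        return self.present.shape[1]

    def with_scheme(self, scheme: "WeightScheme | str") -> "GeneMatrixBatch":
        """Same matrices under a different weighting scheme (the matrices
        must have been built for a scheme needing at least as much)."""
        scheme = WeightScheme(scheme)
        if scheme.needs_support and self.logq is None:
            raise ValueError("batch was built without support matrices")
        if scheme.needs_length and self.su is None:
            raise ValueError("batch was built without length matrices")
        return GeneMatrixBatch(self.taxa, self.index, self.present,
                               self.topo, self.su, self.logq, scheme)


def _node_arrays(tree: AnnotatedTree):
    """Postorder node list with parent indices and edge annotations."""
    nodes = list(tree.postorder())
    idx = {id(n): i for i, n in enumerate(nodes)}
    parent = np.full(len(nodes), -1, dtype=np.int64)
    for i, n in enumerate(nodes):
        if n.parent is not None:
            parent[i] = idx[id(n.parent)]
    return nodes, parent


def _pairwise(tree: AnnotatedTree, need_su: bool, need_logq: bool,
              gene_label: str):
    """Leaf-by-leaf (topo, su, logq) matrices for one tree via per-node
    leaf-distance propagation (O(n * nodes))."""
    nodes, parent = _node_arrays(tree)
    leaves = [i for i, n in enumerate(nodes) if n.is_leaf]
    names = [nodes[i].name for i in leaves]
    m = len(leaves)
    leaf_pos = {i: j for j, i in enumerate(leaves)}

    # edge annotations per node (edge above the node)
    elen = np.zeros(len(nodes))
    eq = np.zeros(len(nodes))
    etopo = np.ones(len(nodes))
    for i, n in enumerate(nodes):
        if n.parent is None:
            etopo[i] = 0.0
            continue
        if need_su:
            if n.length is None:
                raise MissingAnnotationError(
                    f"branch length missing on an edge of {gene_label}; "
                    "length/hybrid weighting needs lengths everywhere")
            elen[i] = n.length
        if need_logq and not n.is_leaf:
            if not n.supports:
                raise MissingAnnotationError(
                    f"support missing on an internal edge of {gene_label}; "
                    "support/hybrid weighting needs supports everywhere")
            eq[i] = sum(math.log1p(-min(s, _SUPPORT_CLAMP)) for s in n.supports)

    # dist_to[node] = vector over leaves below the node
    topo = np.zeros((m, m))
    su = np.zeros((m, m)) if need_su else None
    lq = np.zeros((m, m)) if need_logq else None

    below: list[list[int]] = [[] for _ in nodes]
    dt: list[np.ndarray] = [np.zeros(0)] * len(nodes)
    ds: list[np.ndarray] = [np.zeros(0)] * len(nodes)
    dq: list[np.ndarray] = [np.zeros(0)] * len(nodes)
    for i, n in enumerate(nodes):
        if n.is_leaf:
            below[i] = [leaf_pos[i]]
            dt[i] = np.zeros(1)
            ds[i] = np.zeros(1)
            dq[i] = np.zeros(1)
            continue
        child_ids = [j for j in range(i) if parent[j] == i]
        for a in range(len(child_ids)):
            ca = child_ids[a]
            la = below[ca]
            ta = dt[ca] + etopo[ca]
            sa = ds[ca] + elen[ca]
            qa = dq[ca] + eq[ca]
            for cb in child_ids[a + 1:]:
                lb = below[cb]
                tb = dt[cb] + etopo[cb]
                sb = ds[cb] + elen[cb]
                qb = dq[cb] + eq[cb]
                ia = np.asarray(la)[:, None]
                ib = np.asarray(lb)[None, :]
                topo[ia, ib] = ta[:, None] + tb[None, :]
                topo[ib.T, ia.T] = topo[ia, ib].T
                if need_su:
                    su[ia, ib] = sa[:, None] + sb[None, :]
                    su[ib.T, ia.T] = su[ia, ib].T
                if need_logq:
                    lq[ia, ib] = qa[:, None] + qb[None, :]
                    lq[ib.T, ia.T] = lq[ia, ib].T
        below[i] = [x for j in child_ids for x in below[j]]
        dt[i] = np.concatenate([dt[j] + etopo[j] for j in child_ids])
        ds[i] = np.concatenate([ds[j] + elen[j] for j in child_ids])
        dq[i] = np.concatenate([dq[j] + eq[j] for j in child_ids])
        order = np.argsort(np.concatenate([np.asarray(below[j]) for j in child_ids]))
        cat = np.concatenate
        dt[i] = dt[i][order]
        ds[i] = ds[i][order]
        dq[i] = dq[i][order]
        below[i] = sorted(below[i])
    return names, topo, su, lq


def tree_topo_matrix(tree: AnnotatedTree, taxa: list[str]) -> np.ndarray:
    """(n, n) topological distances of one tree embedded in a taxon list."""
    names, topo, _, _ = _pairwise(tree, False, False, "tree")
    n = len(taxa)
    index = {t: i for i, t in enumerate(taxa)}
    out = np.full((n, n), np.inf)
    pos = np.array([index[nm] for nm in names])
    out[np.ix_(pos, pos)] = topo
    np.fill_diagonal(out, 0.0)
    return out


def build_batch(genes: "list[AnnotatedTree]", scheme: "WeightScheme | str",
                taxa: list[str] | None = None) -> GeneMatrixBatch:
    """Validate annotations and assemble the stacked matrices.

    Raises :class:`MissingAnnotationError` (naming the gene) before any
    scoring work when a scheme-required annotation is absent.
    """
    scheme = WeightScheme(scheme)
    if taxa is None:
        taxa = union_taxa(genes)
    n = len(taxa)
    k = len(genes)
    index = {t: i for i, t in enumerate(taxa)}
    present = np.zeros((k, n), dtype=bool)
    topo = np.full((k, n, n), np.inf)
    su = np.full((k, n, n), np.inf) if scheme.needs_length else None
    logq = np.zeros((k, n, n)) if scheme.needs_support else None

    for g, tree in enumerate(genes):
        if not tree.is_binary():
            raise ValueError(f"gene tree {g + 1} is not binary; "
                             "resolve polytomies first")
        names, t, s, q = _pairwise(tree, scheme.needs_length,
                                   scheme.needs_support, f"gene tree {g + 1}")
        pos = np.array([index[nm] for nm in names])
        present[g, pos] = True
        topo[g][np.ix_(pos, pos)] = t
        if su is not None:
            su[g][np.ix_(pos, pos)] = s
        if logq is not None:
            logq[g][np.ix_(pos, pos)] = q
    return GeneMatrixBatch(taxa=taxa, index=index, present=present,
                           topo=topo, su=su, logq=logq, scheme=scheme)


try:  # numba accelerates the quartet-weight accumulation kernels
    from numba import njit as _njit
except ImportError:  # pragma: no cover - numba is an optional accelerator
    _njit = None


def _kernel_row(topo, logq, su, use_s, use_l, A, B, C, D, out):
    k = topo.shape[0]
    T = A.shape[0]
    for g in range(k):
        tg = topo[g]
        for t in range(T):
            a, b, c, d = A[t], B[t], C[t], D[t]
            s1 = tg[a, b] + tg[c, d]
            s2 = tg[a, c] + tg[b, d]
            s3 = tg[a, d] + tg[b, c]
            if s1 < s2 and s1 < s3:
                code = 0
            elif s2 < s1 and s2 < s3:
                code = 1
            elif s3 < s1 and s3 < s2:
                code = 2
            else:
                continue
            w = 1.0
            if use_s:
                qg = logq[g]
                if code == 0:
                    e = qg[a, c] + qg[b, d] - qg[a, b] - qg[c, d]
                elif code == 1:
                    e = qg[a, b] + qg[c, d] - qg[a, c] - qg[b, d]
                else:
                    e = qg[a, c] + qg[b, d] - qg[a, d] - qg[b, c]
                w *= -math.expm1(0.5 * e)
            if use_l:
                lg = su[g]
                if code == 0:
                    L = lg[a, b] + lg[c, d]
                elif code == 1:
                    L = lg[a, c] + lg[b, d]
                else:
                    L = lg[a, d] + lg[b, c]
                w *= math.exp(-L)
            out[code, t] += w


def _kernel_gene(topo, logq, su, use_s, use_l, A, B, C, D, out):
    k = topo.shape[0]
    T = A.shape[0]
    for g in range(k):
        tg = topo[g]
        for t in range(T):
            a, b, c, d = A[t], B[t], C[t], D[t]
            s1 = tg[a, b] + tg[c, d]
            s2 = tg[a, c] + tg[b, d]
            s3 = tg[a, d] + tg[b, c]
            if s1 < s2 and s1 < s3:
                code = 0
            elif s2 < s1 and s2 < s3:
                code = 1
            elif s3 < s1 and s3 < s2:
                code = 2
            else:
                continue
            w = 1.0
            if use_s:
                qg = logq[g]
                if code == 0:
                    e = qg[a, c] + qg[b, d] - qg[a, b] - qg[c, d]
                elif code == 1:
                    e = qg[a, b] + qg[c, d] - qg[a, c] - qg[b, d]
                else:
                    e = qg[a, c] + qg[b, d] - qg[a, d] - qg[b, c]
                w *= -math.expm1(0.5 * e)
            if use_l:
                lg = su[g]
                if code == 0:
                    L = lg[a, b] + lg[c, d]
                elif code == 1:
                    L = lg[a, c] + lg[b, d]
                else:
                    L = lg[a, d] + lg[b, c]
                w *= math.exp(-L)
            out[code, g] += w


if _njit is not None:
    _kernel_row = _njit(cache=True)(_kernel_row)
    _kernel_gene = _njit(cache=True)(_kernel_gene)

_DUMMY = np.zeros((1, 1, 1))


def pairing_sums_by_row(batch: GeneMatrixBatch, a, b, c, d) -> np.ndarray:
    """(3, T): per-quartet weights of the three pairings of (a,b,c,d),
    summed over genes.  Row 0 pairs a with b, row 1 a with c, row 2 a with d.
    """
    a, b, c, d = (np.array(x, dtype=np.int64, copy=True)
                  for x in np.broadcast_arrays(a, b, c, d))
    out = np.zeros((3, a.shape[0]))
    _kernel_row(batch.topo,
                batch.logq if batch.logq is not None else _DUMMY,
                batch.su if batch.su is not None else _DUMMY,
                batch.scheme.needs_support, batch.scheme.needs_length,
                a, b, c, d, out)
    return out


def pairing_sums_by_gene(batch: GeneMatrixBatch, a, b, c, d) -> np.ndarray:
    """(3, k): per-gene totals of the three pairing weights over the given
    quartet rows."""
    a, b, c, d = (np.array(x, dtype=np.int64, copy=True)
                  for x in np.broadcast_arrays(a, b, c, d))
    out = np.zeros((3, batch.k))
    _kernel_gene(batch.topo,
                 batch.logq if batch.logq is not None else _DUMMY,
                 batch.su if batch.su is not None else _DUMMY,
                 batch.scheme.needs_support, batch.scheme.needs_length,
                 a, b, c, d, out)
    return out
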