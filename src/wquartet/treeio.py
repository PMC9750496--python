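"""Reading, writing and manipulating support/length-annotated trees.

Gene trees arrive as newick strings, one per line, with substitution-unit
branch lengths after ``:`` and branch supports stored as internal-node
labels (the convention used by RAxML, FastTree and IQ-TREE).  Supports are
normalised to [0, 1] according to a :class:`SupportConvention`.

Trees have unrooted semantics but are stored rooted.  After parsing, a
bifurcating root is suppressed so that the root has three (or, for tiny
trees, two) children and every non-root node corresponds to exactly one
unrooted edge.  Each edge carries an optional length and a *tuple* of
supports: a plain edge holds zero or one support value, while an edge
produced by suppressing degree-2 nodes (see :func:`restrict`) retains the
full multiset of supports along the suppressed path, which is what the
support-weighting product needs.
"""

from __future__ import annotations

import io
import logging
import math
from dataclasses import dataclass
from typing import Callable, Iterable, Iterator, Sequence

import dendropy

from .quartets import QuartetObservation, canonical_topology

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "AnnotatedTree",
    "SupportConvention",
    "SUPPORT_CONVENTIONS",
    "TreeParseError",
    "SupportValidationError",
    "parse_gene_trees",
    "parse_tree",
    "write_tree",
    "write_trees",
    "resolve_polytomies",
    "restrict",
    "induced_quartet",
]


class TreeParseError(ValueError):
    """Malformed newick input."""


class SupportValidationError(ValueError):
    """A raw support label lies outside its convention's admissible range."""


class Node:
    """A node of a rooted representation of an unrooted tree.

    The edge *above* the node carries ``length`` (may be ``None``) and
    ``supports`` — a tuple of support values in [0, 1], empty when the
    support is absent.  Edges merged by path suppression carry more than
    one value.
    """

    __slots__ = ("name", "children", "parent", "length", "supports")

    def __init__(self, name: str | None = None, length: float | None = None,
                 supports: tuple[float, ...] = ()):
        self.name = name
        self.children: list[Node] = []
        self.parent: Node | None = None
        self.length = length
        self.supports = supports

    @property
    def is_leaf(self) -> bool:
        return not self.children

    @property
    def support(self) -> float | None:
        """Combined support of the edge: 1 - prod(1 - s_i), or None if absent."""
        if not self.supports:
            return None
        if len(self.supports) == 1:
            return self.supports[0]
        prod = 1.0
        for s in self.supports:
            prod *= 1.0 - s
        return 1.0 - prod

    def add(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Node({self.name!r}, len={self.length}, sup={self.supports})"


class AnnotatedTree:
    """Rooted container with unrooted semantics.

    Invariants: leaf names are unique; after binarisation every non-root
    internal node has two children and the root has three (degree three in
    the unrooted view).
    """

    def __init__(self, root: Node):
        self.root = root

    # ------------------------------------------------------------------ #
    # traversal / bookkeeping
    # ------------------------------------------------------------------ #
    def postorder(self) -> Iterator[Node]:
        stack: list[tuple[Node, bool]] = [(self.root, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for c in node.children:
                    stack.append((c, False))

    def preorder(self) -> Iterator[Node]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_names(self) -> set[str]:
        return {n.name for n in self.leaves()}

    def find_leaf(self, name: str) -> Node:
        for n in self.postorder():
            if n.is_leaf and n.name == name:
                return n
        raise KeyError(f"taxon {name!r} not in tree")

    def is_binary(self) -> bool:
        """Degree-3 internal nodes in the unrooted view."""
        for n in self.postorder():
            if n.is_leaf:
                continue
            want = 3 if n is self.root else 2
            if len(n.children) != want:
                # 2- and 3-leaf trees are trivially "binary"
                if n is self.root and len(self.leaves()) < 4:
                    continue
                return False
        return True

    def copy(self) -> "AnnotatedTree":
        def rec(node: Node) -> Node:
            new = Node(node.name, node.length, node.supports)
            for c in node.children:
                new.add(rec(c))
            return new

        return AnnotatedTree(rec(self.root))

    # ------------------------------------------------------------------ #
    # unrooted comparisons
    # ------------------------------------------------------------------ #
    def bipartitions(self) -> set[frozenset[str]]:
        """Non-trivial bipartitions, each keyed by the side not containing
        the lexicographically smallest taxon."""
        all_names = frozenset(self.leaf_names())
        anchor = min(all_names)
        out: set[frozenset[str]] = set()
        below: dict[int, frozenset[str]] = {}
        for n in self.postorder():
            if n.is_leaf:
                below[id(n)] = frozenset([n.name])
            else:
                below[id(n)] = frozenset().union(*(below[id(c)] for c in n.children))
            if n is self.root:
                continue
            side = below[id(n)]
            if len(side) < 2 or len(all_names - side) < 2:
                continue
            out.add(side if anchor not in side else all_names - side)
        return out

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.postorder() if n is not self.root)


# ---------------------------------------------------------------------- #
# support conventions
# ---------------------------------------------------------------------- #
@dataclass(frozen=True)
class SupportConvention:
    """Mapping from raw internal-node labels to supports in [0, 1]."""

    name: str
    description: str
    raw_range: tuple[float, float]
    transform: Callable[[float], float]

    #: numeric-jitter tolerance before a raw value is rejected outright
    tolerance: float = 1e-3

    def normalize(self, raw: float, context: str = "") -> float:
        lo, hi = self.raw_range
        if raw < lo - self.tolerance or raw > hi + self.tolerance:
            raise SupportValidationError(
                f"support label {raw!r} outside admissible range [{lo}, {hi}] "
                f"for convention {self.name!r}{context}")
        value = self.transform(min(max(raw, lo), hi))
        if value < 0.0 or value > 1.0:
            logger.warning("support %r normalised outside [0,1]; clamping%s",
                           raw, context)
            value = min(max(value, 0.0), 1.0)
        return value


SUPPORT_CONVENTIONS: dict[str, SupportConvention] = {
    "raw01": SupportConvention(
        "raw01", "labels already in [0,1]; clamped pass-through",
        (0.0, 1.0), lambda s: s),
    "percent": SupportConvention(
        "percent", "bootstrap percentages; divided by 100",
        (0.0, 100.0), lambda s: s / 100.0),
    "abayes": SupportConvention(
        "abayes", "approximate Bayesian supports in [1/3,1]; (3s-1)/2",
        (1.0 / 3.0, 1.0), lambda s: (3.0 * s - 1.0) / 2.0),
    "sh_like": SupportConvention(
        "sh_like", "SH-like supports in [0,1]; clamped pass-through",
        (0.0, 1.0), lambda s: s),
}


def _convention(conv: "SupportConvention | str") -> SupportConvention:
    if isinstance(conv, SupportConvention):
        return conv
    try:
        return SUPPORT_CONVENTIONS[conv]
    except KeyError:
        raise ValueError(f"unknown support convention {conv!r}; expected one of "
                         f"{sorted(SUPPORT_CONVENTIONS)}") from None


# ---------------------------------------------------------------------- #
# parsing
# ---------------------------------------------------------------------- #
def _from_dendropy(dtree: dendropy.Tree, convention: SupportConvention,
                   context: str) -> AnnotatedTree:
    def rec(dnode) -> Node:
        if dnode.is_leaf():
            if dnode.taxon is None or dnode.taxon.label is None:
                raise TreeParseError(f"leaf without a taxon label{context}")
            return Node(dnode.taxon.label, dnode.edge.length)
        supports: tuple[float, ...] = ()
        if dnode.label not in (None, ""):
            try:
                raw = float(dnode.label)
            except ValueError:
                raise SupportValidationError(
                    f"non-numeric internal-node label {dnode.label!r}{context}; "
                    "bracket-comment or named-clade annotations are not supported"
                ) from None
            supports = (convention.normalize(raw, context),)
        node = Node(None, dnode.edge.length, supports)
        for c in dnode.child_nodes():
            node.add(rec(c))
        return node

    tree = AnnotatedTree(rec(dtree.seed_node))
    _suppress_root_bifurcation(tree)
    names = [n.name for n in tree.leaves()]
    if len(names) != len(set(names)):
        dup = sorted({x for x in names if names.count(x) > 1})
        raise TreeParseError(f"duplicate leaf labels {dup}{context}")
    return tree


def _suppress_root_bifurcation(tree: AnnotatedTree) -> None:
    """Merge the two root edges (one unrooted edge written twice)."""
    root = tree.root
    if len(root.children) != 2:
        return
    internal = [c for c in root.children if not c.is_leaf]
    if not internal:  # 2-taxon tree: keep as is
        return
    absorbed = internal[0]
    other = root.children[0] if root.children[1] is absorbed else root.children[1]
    if absorbed.length is not None or other.length is not None:
        other.length = (absorbed.length or 0.0) + (other.length or 0.0)
    # both children may carry a label for the same unrooted edge; prefer the
    # absorbed (internal) child's copy and never multiply them together
    other.supports = absorbed.supports if absorbed.supports else other.supports
    root.children = [c for c in root.children if c is not absorbed]
    for c in absorbed.children:
        root.add(c)
    if other.parent is not root:  # pragma: no cover - defensive
        other.parent = root


def parse_tree(text: str, convention: "SupportConvention | str" = "raw01",
               context: str = "") -> AnnotatedTree:
    """Parse a single newick string into an :class:`AnnotatedTree`."""
    convention = _convention(convention)
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except Exception as exc:
        raise TreeParseError(f"malformed newick{context}: {exc}") from exc
    return _from_dendropy(dtree, convention, context)


def parse_gene_trees(text: "str | io.TextIOBase",
                     convention: "SupportConvention | str" = "raw01",
                     ) -> list[AnnotatedTree]:
    """Parse newick gene trees, one per line.

    Leaf sets may differ across trees (missing data is allowed).  Raises
    :class:`TreeParseError` naming the offending line.
    """
    if hasattr(text, "read"):
        text = text.read()
    trees = []
    for lineno, line in enumerate(str(text).splitlines(), start=1):
        line = line.strip()
        if not line:
            continue
        trees.append(parse_tree(line, convention, context=f" (line {lineno})"))
    return trees


# ---------------------------------------------------------------------- #
# writing
# ---------------------------------------------------------------------- #
def write_tree(tree: AnnotatedTree, support_digits: int = 6,
               length_digits: int = 9,
               support_decimals: int | None = None) -> str:
    """Newick string with supports as internal labels, lengths after ':'.

    Supports use ``support_digits`` significant digits, or a fixed number
    of decimals when ``support_decimals`` is given.
    """

    def fmt_node(node: Node) -> str:
        if node.is_leaf:
            out = node.name or ""
        else:
            out = "(" + ",".join(fmt_node(c) for c in node.children) + ")"
            if node is not tree.root and node.supports:
                if support_decimals is not None:
                    out += f"{node.support:.{support_decimals}f}"
                else:
                    out += f"{node.support:.{support_digits}g}"
        if node is not tree.root and node.length is not None:
            text = f"{node.length:.{length_digits}f}".rstrip("0").rstrip(".")
            out += f":{text or '0'}"
        return out

    return fmt_node(tree.root) + ";"


def write_trees(trees: Iterable[AnnotatedTree], **kw) -> str:
    return "\n".join(write_tree(t, **kw) for t in trees) + "\n"


# ---------------------------------------------------------------------- #
# topology operations
# ---------------------------------------------------------------------- #
def resolve_polytomies(tree: AnnotatedTree, rng) -> AnnotatedTree:
    """Randomly binarise; introduced edges get length 0 and support 0.

    Deterministic given the numpy Generator ``rng``.  Non-introduced
    bipartitions are unchanged.
    """
    out = tree.copy()
    for node in list(out.postorder()):
        limit = 3 if node is out.root else 2
        while len(node.children) > limit:
            i, j = sorted(rng.choice(len(node.children), size=2, replace=False))
            a, b = node.children[i], node.children[j]
            joined = Node(None, 0.0, (0.0,))
            joined.add(a)
            joined.add(b)
            node.children = [c for c in node.children
                             if c is not a and c is not b]
            node.add(joined)
    return out


def restrict(tree: AnnotatedTree, taxa: "set[str] | Sequence[str]") -> AnnotatedTree:
    """Induced tree on ``taxa``.

    Suppressed degree-2 nodes merge their incident edges: lengths add and
    the support multiset along the suppressed path is retained on the
    merged edge.
    """
    taxa = set(taxa)
    missing = taxa - tree.leaf_names()
    if missing:
        raise KeyError(f"taxa not in tree: {sorted(missing)}")
    if len(taxa) < 2:
        raise ValueError("restriction needs at least 2 taxa")

    def rec(node: Node) -> Node | None:
        if node.is_leaf:
            if node.name in taxa:
                return Node(node.name, node.length)
            return None
        kept = [k for k in (rec(c) for c in node.children) if k is not None]
        if not kept:
            return None
        if len(kept) == 1:
            child = kept[0]
            merged = Node(child.name, None, ())
            merged.children = child.children
            for gc in merged.children:
                gc.parent = merged
            if node.length is not None or child.length is not None:
                merged.length = (node.length or 0.0) + (child.length or 0.0)
            merged.supports = node.supports + child.supports
            return merged
        new = Node(None, node.length, node.supports)
        for k in kept:
            new.add(k)
        return new

    new_root = rec(tree.root)
    assert new_root is not None
    # drop a dangling edge above the root of the induced tree
    new_root.length = None
    new_root.supports = ()
    out = AnnotatedTree(new_root)
    _suppress_root_bifurcation(out)
    return out


def _path_edges(x: Node, y: Node) -> list[Node]:
    """Edges (as their child nodes) on the unrooted path between two nodes."""
    anc_x: list[Node] = [x]
    node = x
    while node.parent is not None:
        node = node.parent
        anc_x.append(node)
    index = {id(n): i for i, n in enumerate(anc_x)}
    path_y: list[Node] = []
    node = y
    while id(node) not in index:
        path_y.append(node)
        node = node.parent
        if node is None:  # pragma: no cover - different trees
            raise ValueError("nodes do not share a root")
    meet = index[id(node)]
    return anc_x[:meet] + path_y


def induced_quartet(tree: AnnotatedTree, quartet: Sequence[str]) -> QuartetObservation:
    """Quartet observation (topology, anchor-path supports, cherry lengths)
    for four taxa of a binary tree.

    The anchor path is the set of edges between the two internal nodes of
    the induced four-leaf tree; cherry lengths are the two leaf–leaf path
    lengths within the cherries (anchor–anchor path excluded).
    """
    if len(set(quartet)) != 4:
        raise ValueError("quartet must contain 4 distinct taxa")
    if not tree.is_binary():
        raise ValueError("induced_quartet requires a binary tree")
    a, b, c, d = sorted(quartet)
    nodes = {name: tree.find_leaf(name) for name in (a, b, c, d)}
    paths: dict[tuple[str, str], list[Node]] = {}
    for i, x in enumerate((a, b, c, d)):
        for y in (a, b, c, d)[i + 1:]:
            paths[(x, y)] = _path_edges(nodes[x], nodes[y])

    def topo_len(p: tuple[str, str]) -> int:
        return len(paths[p])

    sums = {
        (a, b): topo_len((a, b)) + topo_len((c, d)),
        (a, c): topo_len((a, c)) + topo_len((b, d)),
        (a, d): topo_len((a, d)) + topo_len((b, c)),
    }
    partner = min(sums, key=sums.get)[1]
    rest = [x for x in (b, c, d) if x != partner]
    pair1, pair2 = (a, partner), (rest[0], rest[1])
    cross1, cross2 = (a, rest[0]), (partner, rest[1])
    # anchor path = edges common to the two crossing paths
    cross_ids = {id(n) for n in paths[tuple(sorted(cross1))]}
    anchor_edges = [n for n in paths[tuple(sorted(cross2))] if id(n) in cross_ids]

    supports: list[float] = []
    supports_ok = True
    for e in anchor_edges:
        if not e.supports:
            supports_ok = False
        supports.extend(e.supports)

    def path_length(p: tuple[str, str]) -> float | None:
        total = 0.0
        for e in paths[p]:
            if e.length is None:
                return None
            total += e.length
        return total

    l1 = path_length(tuple(sorted(pair1)))
    l2 = path_length(tuple(sorted(pair2)))
    return QuartetObservation(
        topology=canonical_topology(pair1, pair2),
        anchor_path_supports=tuple(supports) if supports_ok else None,
        cherry_lengths=(l1, l2) if l1 is not None and l2 is not None else None,
    )
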