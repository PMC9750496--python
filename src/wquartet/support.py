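"""Weighted local posterior probability (localPP) branch support.

Around an internal species-tree branch, the three possible resolutions
receive normalised weighted quartet counts (x1, x2, x3) (see
:func:`wquartet.scoring.quadripartition_counts`).  Under a Yule prior with
birth rate ``lambda`` on the branch length and the coalescent quartet
topology probabilities, the posterior probability that resolution ``i`` is
the true one has the closed form

    p_i = h(x_i) / (h(x1) + h(x2) + h(x3)),
    h(x) = 2^x * B(x + 1, m - x + 2*lambda) * (1 - I_{1/3}(x + 1, m - x + 2*lambda)),

with ``m = x1 + x2 + x3``, ``B`` the beta function and ``I`` the
regularised incomplete beta function.  ``h`` is evaluated in log space so
the computation stays finite for counts up to 1e6 and beyond.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import special

from .quartets import WeightScheme
from .scoring import QuadripartitionCounts, ensure_batch, quadripartition_counts
from .treeio import AnnotatedTree

logger = logging.getLogger(__name__)

__all__ = ["YulePrior", "localpp", "annotate_support", "log_h"]


@dataclass(frozen=True)
class YulePrior:
    """Birth rate of the Yule prior on species-tree branch lengths."""

    lam: float = 0.5

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("Yule birth rate must be positive")


class LocalPPDegenerateError(ArithmeticError):
    """All three h values vanished or were non-finite."""


def log_h(x: np.ndarray, m: "float | np.ndarray", lam: float) -> np.ndarray:
    """log h(x) for total count m; -inf where h underflows to zero."""
    x = np.asarray(x, dtype=float)
    a = x + 1.0
    b = np.asarray(m, dtype=float) - x + 2.0 * lam
    # 1 - I_{1/3}(a, b) = I_{2/3}(b, a)
    with np.errstate(divide="ignore"):
        tail = np.log(special.betainc(b, a, 2.0 / 3.0))
    return x * np.log(2.0) + special.betaln(a, b) + tail


def localpp(counts: "QuadripartitionCounts | tuple", prior: YulePrior = YulePrior()
            ) -> tuple[float, float, float]:
    """Posterior probabilities of the three resolutions around a branch.

    Accepts a :class:`QuadripartitionCounts` or a plain (x1, x2, x3)
    triple; returns (p1, p2, p3) summing to one.
    """
    if isinstance(counts, QuadripartitionCounts):
        x = np.array([counts.x1, counts.x2, counts.x3], dtype=float)
    else:
        x = np.asarray(counts, dtype=float)
    if x.shape != (3,) or not np.all(np.isfinite(x)) or np.any(x < 0):
        raise ValueError(f"counts must be three finite non-negative reals, got {x}")
    lh = log_h(x, x.sum(), prior.lam)
    top = np.max(lh)
    if not np.isfinite(top):
        raise LocalPPDegenerateError(
            f"posterior degenerate for counts {tuple(x)} with lambda={prior.lam}")
    p = np.exp(lh - top)
    p /= p.sum()
    return (float(p[0]), float(p[1]), float(p[2]))


def annotate_support(species_tree: AnnotatedTree, genes,
                     scheme: "WeightScheme | str",
                     prior: YulePrior = YulePrior(),
                     batch=None) -> AnnotatedTree:
    """Copy of the species tree with localPP of each internal branch's own
    resolution as its support.

    Branches around which no gene carries a quartet are left without a
    support value (and logged).
    """
    scheme = WeightScheme(scheme)
    if not species_tree.is_binary():
        raise ValueError("species tree must be binary")
    batch = ensure_batch(genes, scheme, batch,
                         extra_taxa=species_tree.leaf_names())
    out = species_tree.copy()
    for node in out.postorder():
        if node.is_leaf or node is out.root or node.parent is None:
            continue
        counts = quadripartition_counts(out, node, genes, scheme, batch)
        if counts.unsupported:
            logger.warning("no gene carries a quartet around branch %s; "
                           "support left absent",
                           sorted(n.name for n in node.children if n.is_leaf))
            node.supports = ()
            continue
        p1, _, _ = localpp(counts, prior)
        node.supports = (p1,)
    return out
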