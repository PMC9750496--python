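"""Per-quartet weights under the four weighting schemes.

A resolved four-taxon subtree of a gene tree is summarised by a
:class:`QuartetObservation`: its unrooted topology, the supports of the
edges on the path between its two internal nodes (the *anchors*), and the
two cherry path lengths in substitution units.  The weight of a candidate
topology is zero unless it matches the observed one; a matching topology is
weighted 1 (unweighted scheme), by the quartet support
``1 - prod(1 - s_e)`` over anchor-path edges (support scheme), by
``exp(-(l(a,b) + l(c,d)))`` over the two cherry paths (length scheme), or by
the product of both factors (hybrid scheme).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence, Tuple

__all__ = [
    "Topology",
    "canonical_topology",
    "topologies_for",
    "QuartetObservation",
    "WeightScheme",
    "MissingAnnotationError",
    "quartet_weight",
]

#: An unrooted 4-taxon topology: two sorted cherry pairs, the pair holding
#: the alphabetically smallest taxon first.
Topology = Tuple[Tuple[str, str], Tuple[str, str]]


def canonical_topology(pair1: Sequence[str], pair2: Sequence[str]) -> Topology:
    p1 = tuple(sorted(pair1))
    p2 = tuple(sorted(pair2))
    return (p1, p2) if p1[0] < p2[0] else (p2, p1)


def topologies_for(quartet: Sequence[str]) -> tuple[Topology, Topology, Topology]:
    """The three topologies on a quartet, ordered by the partner of the
    smallest taxon (the canonical order used throughout)."""
    a, b, c, d = sorted(quartet)
    return (
        canonical_topology((a, b), (c, d)),
        canonical_topology((a, c), (b, d)),
        canonical_topology((a, d), (b, c)),
    )


class WeightScheme(str, Enum):
    UNWEIGHTED = "unweighted"
    SUPPORT = "support"
    LENGTH = "length"
    HYBRID = "hybrid"

    @property
    def needs_support(self) -> bool:
        return self in (WeightScheme.SUPPORT, WeightScheme.HYBRID)

    @property
    def needs_length(self) -> bool:
        return self in (WeightScheme.LENGTH, WeightScheme.HYBRID)


class MissingAnnotationError(ValueError):
    """An annotation required by the chosen scheme is absent."""


@dataclass(frozen=True)
class QuartetObservation:
    """Observed quartet of one gene tree.

    ``anchor_path_supports`` is ``None`` when any anchor-path edge lacks a
    support; ``cherry_lengths`` is ``None`` when any involved edge lacks a
    length.  Missing annotations are *not* imputed; weighting raises
    instead.
    """

    topology: Topology
    anchor_path_supports: Optional[Tuple[float, ...]] = None
    cherry_lengths: Optional[Tuple[float, float]] = None

    def support_factor(self) -> float:
        if self.anchor_path_supports is None:
            raise MissingAnnotationError(
                "anchor-path support missing for quartet "
                f"{self.topology}; support/hybrid weighting needs supports on "
                "all internal edges (or an explicit default fill-in)")
        prod = 1.0
        for s in self.anchor_path_supports:
            prod *= 1.0 - s
        return 1.0 - prod

    def length_factor(self) -> float:
        if self.cherry_lengths is None:
            raise MissingAnnotationError(
                "branch length missing for quartet "
                f"{self.topology}; length/hybrid weighting needs lengths on "
                "all edges (or an explicit default fill-in)")
        # exp underflow for very long quartets is a valid weight of 0
        return math.exp(-(self.cherry_lengths[0] + self.cherry_lengths[1]))


def quartet_weight(obs: QuartetObservation, target_topology: Topology,
                   scheme: "WeightScheme | str") -> float:
    """Weight of ``target_topology`` given the observed quartet.

    Zero when the target does not match the observation; otherwise in
    [0, 1] according to the scheme.
    """
    scheme = WeightScheme(scheme)
    if target_topology != obs.topology:
        return 0.0
    if scheme is WeightScheme.UNWEIGHTED:
        return 1.0
    if scheme is WeightScheme.SUPPORT:
        return obs.support_factor()
    if scheme is WeightScheme.LENGTH:
        return obs.length_factor()
    return obs.support_factor() * obs.length_factor()
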