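"""Quartet-level model of gene tree discordance, estimation error and
branch support, plus a quartet coalescent
simulator with substitution-unit branch lengths.

The model for one quartet around a species-tree branch of coalescent-unit
length ``d`` (``theta = 1 - exp(-d)``):

* the *true* gene tree topology follows the coalescent probabilities
  ((1 + 2*theta)/3, (1 - theta)/3, (1 - theta)/3), topology 1 being the
  species-tree resolution;
* with probability ``alpha`` (a per-gene quality drawn from a fixed
  distribution) the estimated topology equals the true one; otherwise it is
  drawn from bias probabilities (p1, p2, p3) with ``|3 p_i - 1| <= beta``;
* the support of the estimated topology is ``alpha + (1 - alpha) p_i`` when
  it matches the true one and ``(1 - alpha) p_i`` otherwise.

The worst-case bias (3p1, 3p2, 3p3) = (1 - beta, 1 + beta, 1) tilts the
error toward the second topology; at that setting the closed-form
expectations of the unweighted and support-weighted per-gene margins (the
quantities whose signs decide statistical consistency) are exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "AlphaDistribution",
    "DegenerateAlpha",
    "BetaAlpha",
    "ErrorModelParams",
    "QuartetSample",
    "worst_case_bias",
    "msc_topology_probs",
    "sample_quartets",
    "sample_quartet",
    "joint_delta_table",
    "joint_weight_table",
    "expected_margins",
    "consistency_region",
    "margin_sweep_table",
    "simulate_quartet_genes",
    "coalescent_quartet_sim",
    "length_margin_slope",
]


# ---------------------------------------------------------------------- #
# parameters
# ---------------------------------------------------------------------- #
class AlphaDistribution:
    """Distribution of the per-gene quality parameter alpha on [0, 1]."""

    mean: float
    var: float

    def sample(self, rng, size: int) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


@dataclass(frozen=True)
class DegenerateAlpha(AlphaDistribution):
    value: float

    def __post_init__(self):
        if not 0.0 <= self.value <= 1.0:
            raise ValueError("alpha must be in [0, 1]")

    @property
    def mean(self) -> float:
        return self.value

    @property
    def var(self) -> float:
        return 0.0

    def sample(self, rng, size):
        return np.full(size, self.value)


@dataclass(frozen=True)
class BetaAlpha(AlphaDistribution):
    """Beta-distributed gene quality; Beta(0.5, 0.5) is the bimodal preset
    mixing high- and low-signal genes."""

    a: float = 0.5
    b: float = 0.5

    @property
    def mean(self) -> float:
        return self.a / (self.a + self.b)

    @property
    def var(self) -> float:
        s = self.a + self.b
        return self.a * self.b / (s * s * (s + 1.0))

    def sample(self, rng, size):
        return rng.beta(self.a, self.b, size)


def worst_case_bias(beta: float) -> tuple[float, float, float]:
    """Bias probabilities tilted maximally toward the second topology."""
    return ((1.0 - beta) / 3.0, (1.0 + beta) / 3.0, 1.0 / 3.0)


@dataclass(frozen=True)
class ErrorModelParams:
    theta: float
    alpha: AlphaDistribution
    beta: float
    bias_probs: tuple[float, float, float] | None = None

    def __post_init__(self):
        if not 0.0 <= self.theta < 1.0:
            raise ValueError("theta must be in [0, 1)")
        if not 0.0 <= self.beta <= 1.0:
            raise ValueError("beta must be in [0, 1]")
        if self.bias_probs is None:
            object.__setattr__(self, "bias_probs", worst_case_bias(self.beta))
        p = np.asarray(self.bias_probs, dtype=float)
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("bias probabilities must sum to 1")
        if np.any(np.abs(3.0 * p - 1.0) > self.beta + 1e-9):
            raise ValueError("|3 p_i - 1| must not exceed beta")


@dataclass(frozen=True)
class QuartetSample:
    true_topology: int      # 1..3; 1 = species-tree resolution
    estimated_topology: int
    support: float
    alpha: float


# ---------------------------------------------------------------------- #
# closed forms
# ---------------------------------------------------------------------- #
def msc_topology_probs(theta: float) -> tuple[float, float, float]:
    """Coalescent probabilities of the three quartet topologies."""
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must be in [0, 1)")
    return ((1.0 + 2.0 * theta) / 3.0,
            (1.0 - theta) / 3.0,
            (1.0 - theta) / 3.0)


def joint_delta_table(theta: float, alpha: float, beta: float,
                      bias_probs=None) -> np.ndarray:
    """3x3 joint probabilities P(estimated=i, true=j) for degenerate alpha.

    Row = estimated topology, column = true topology; worst-case bias by
    default.
    """
    p = np.asarray(worst_case_bias(beta) if bias_probs is None else bias_probs)
    ptrue = np.asarray(msc_topology_probs(theta))
    out = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            cond = (1.0 - alpha) * p[i] + (alpha if i == j else 0.0)
            out[i, j] = ptrue[j] * cond
    return out


def joint_weight_table(theta: float, alpha: float, beta: float,
                       bias_probs=None) -> np.ndarray:
    """3x3 expected support weights E[w_i * 1(true=j)] for degenerate alpha.

    The weight of the estimated topology is its support, which equals the
    conditional probability of estimating it given the true topology; hence
    each entry is the joint probability times that support.
    """
    p = np.asarray(worst_case_bias(beta) if bias_probs is None else bias_probs)
    joint = joint_delta_table(theta, alpha, beta, bias_probs)
    out = np.empty((3, 3))
    for i in range(3):
        for j in range(3):
            s = (1.0 - alpha) * p[i] + (alpha if i == j else 0.0)
            out[i, j] = joint[i, j] * s
    return out


def expected_margins(params: ErrorModelParams) -> tuple[float, float]:
    """Worst-case expectations of the per-gene topology-1-minus-topology-2
    margins, unweighted and support-weighted.

    ``delta_margin = theta*abar - (2/3)(1-abar)*beta`` and
    ``weight_margin = (1/9) theta (3+2 beta)(abar^2+var) +
    (2/9)(3-beta) theta abar - (4/9)(1-abar) beta``; both are exact at the
    worst-case bias and lower bounds otherwise.
    """
    th, b = params.theta, params.beta
    abar, avar = params.alpha.mean, params.alpha.var
    delta = th * abar - (2.0 / 3.0) * (1.0 - abar) * b
    weight = (th * (3.0 + 2.0 * b) * (abar * abar + avar) / 9.0
              + 2.0 / 9.0 * (3.0 - b) * th * abar
              - 4.0 / 9.0 * (1.0 - abar) * b)
    return delta, weight


# ---------------------------------------------------------------------- #
# sampling
# ---------------------------------------------------------------------- #
def sample_quartets(params: ErrorModelParams, size: int, rng) -> dict:
    """Vectorised draws from the model.

    Returns arrays ``true`` and ``est`` (topologies in {1,2,3}),
    ``support`` (support of the estimated topology) and ``alpha``.
    """
    ptrue = np.asarray(msc_topology_probs(params.theta))
    p = np.asarray(params.bias_probs)
    true = rng.choice(3, size=size, p=ptrue) + 1
    alpha = params.alpha.sample(rng, size)
    keep = rng.random(size) < alpha
    redraw = rng.choice(3, size=size, p=p) + 1
    est = np.where(keep, true, redraw)
    support = (1.0 - alpha) * p[est - 1] + alpha * (est == true)
    return {"true": true, "est": est, "support": support, "alpha": alpha}


def sample_quartet(params: ErrorModelParams, rng) -> QuartetSample:
    d = sample_quartets(params, 1, rng)
    return QuartetSample(int(d["true"][0]), int(d["est"][0]),
                         float(d["support"][0]), float(d["alpha"][0]))


# ---------------------------------------------------------------------- #
# consistency region
# ---------------------------------------------------------------------- #
def _bisect_root(func: Callable[[float], float], lo: float, hi: float,
                 tol: float = 1e-10) -> float | None:
    """Root of an increasing function on [lo, hi); None without a sign
    change."""
    flo, fhi = func(lo), func(hi)
    if flo > 0.0:
        return lo
    if fhi <= 0.0:
        return None
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if func(mid) <= 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def consistency_region(alpha: float, beta: float) -> tuple[float, float] | None:
    """Interval of coalescent-unit branch lengths where the support-weighted
    quartet vote is consistent but the unweighted one is not.

    Degenerate alpha; worst-case bias.  Returns (d_low, d_high) or None
    when empty (always empty at beta = 0).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    adist = DegenerateAlpha(alpha)

    def dmargin(th):
        return expected_margins(ErrorModelParams(th, adist, beta))[0]

    def wmargin(th):
        return expected_margins(ErrorModelParams(th, adist, beta))[1]

    hi = 1.0 - 1e-12
    th_w = _bisect_root(wmargin, 0.0, hi)
    th_d = _bisect_root(dmargin, 0.0, hi)
    if th_w is None:
        return None  # weighted vote never consistent on [0, 1)
    d_low = -math.log1p(-th_w)
    d_high = math.inf if th_d is None else -math.log1p(-th_d)
    if d_high <= d_low:
        return None
    return (d_low, d_high)


def margin_sweep_table(alphas, betas, thetas) -> pd.DataFrame:
    """Tidy table of both margins over a parameter grid (for plotting or
    CSV export)."""
    rows = []
    for a in alphas:
        for b in betas:
            for th in thetas:
                dm, wm = expected_margins(
                    ErrorModelParams(th, DegenerateAlpha(a), b))
                rows.append({"alpha": a, "beta": b, "theta": th,
                             "d_cu": -math.log1p(-th),
                             "delta_margin": dm, "weight_margin": wm})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------- #
# quartet coalescent simulator
# ---------------------------------------------------------------------- #
def simulate_quartet_genes(f: float, rate_multiplier: float, size: int, rng,
                           pendant: float = 1.0) -> dict:
    """Coalescent simulation of gene trees for a quartet species tree.

    Species tree ab|cd with internal branch ``f`` in coalescent units; the
    a,b lineage pair may coalesce along the internal branch (rate 1), after
    which all remaining lineages coalesce freely.  Terminal branch lengths
    are returned in substitution units (coalescent times scaled by
    ``rate_multiplier``; the common pendant offset is included).

    Returns arrays ``topology`` (1..3; 1 = matching) and ``terminal_su``
    with shape (size, 4) for leaves (a, b, c, d), plus
    ``weight = exp(-sum terminal_su)`` and the unweighted/weighted margin
    samples ``Y = d1 - d2`` and ``X = w*(d1 - d2)``.
    """
    if f < 0 or rate_multiplier <= 0:
        raise ValueError("need f >= 0 and a positive rate multiplier")
    t_ab = rng.exponential(1.0, size)
    coal = t_ab < f
    term = np.zeros((size, 4))
    term[:, 0] = np.where(coal, t_ab, f)
    term[:, 1] = term[:, 0]
    topology = np.ones(size, dtype=np.int64)

    # world A: a,b coalesced inside the branch; lineages {ab, c, d} at the
    # far anchor coalesce freely (topology stays ab|cd)
    nA = int(coal.sum())
    T1 = rng.exponential(1.0 / 3.0, nA)
    pair = rng.integers(0, 3, nA)            # 0:(c,d) 1:(ab,c) 2:(ab,d)
    T2 = rng.exponential(1.0, nA)
    c_term = np.where(pair == 1, T1, np.where(pair == 0, T1, T1 + T2))
    d_term = np.where(pair == 2, T1, np.where(pair == 0, T1, T1 + T2))
    term[coal, 2] = c_term
    term[coal, 3] = d_term

    # world B: four lineages coalesce freely; the first pair forms a cherry
    # that fixes the topology
    free = ~coal
    nB = int(free.sum())
    S1 = rng.exponential(1.0 / 6.0, nB)
    first = rng.integers(0, 6, nB)           # ab ac ad bc bd cd
    S2 = rng.exponential(1.0 / 3.0, nB)
    pick2 = rng.integers(0, 3, nB)           # 0: remaining leaves pair up
    S3 = rng.exponential(1.0, nB)
    pairs = np.array([[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]])
    P = pairs[first]
    adds = np.zeros((nB, 4))
    rows = np.arange(nB)
    adds[rows, P[:, 0]] = S1
    adds[rows, P[:, 1]] = S1
    mask = np.ones((nB, 4), dtype=bool)
    mask[rows, P[:, 0]] = False
    mask[rows, P[:, 1]] = False
    rem = np.argsort(~mask, axis=1, kind="stable")[:, :2]
    rem.sort(axis=1)
    both = pick2 == 0
    adds[rows[both], rem[both, 0]] = (S1 + S2)[both]
    adds[rows[both], rem[both, 1]] = (S1 + S2)[both]
    one = pick2 == 1
    adds[rows[one], rem[one, 0]] = (S1 + S2)[one]
    adds[rows[one], rem[one, 1]] = (S1 + S2 + S3)[one]
    two = pick2 == 2
    adds[rows[two], rem[two, 1]] = (S1 + S2)[two]
    adds[rows[two], rem[two, 0]] = (S1 + S2 + S3)[two]
    term[free] += adds
    topology[free] = np.array([1, 2, 3, 3, 2, 1])[first]

    term_su = rate_multiplier * (term + pendant)
    weight = np.exp(-term_su.sum(axis=1))
    d1 = (topology == 1).astype(float)
    d2 = (topology == 2).astype(float)
    return {"topology": topology, "terminal_su": term_su, "weight": weight,
            "Y": d1 - d2, "X": weight * (d1 - d2)}


def coalescent_quartet_sim(f: float, rate_multiplier: float, rng,
                           pendant: float = 1.0):
    """One gene tree draw, as a 4-leaf :class:`AnnotatedTree` with
    substitution-unit lengths (taxa a, b, c, d)."""
    from .treeio import AnnotatedTree, Node

    d = simulate_quartet_genes(f, rate_multiplier, 1, rng, pendant)
    topo = int(d["topology"][0])
    t = d["terminal_su"][0]
    names = "abcd"
    pairs = {1: ((0, 1), (2, 3)), 2: ((0, 2), (1, 3)), 3: ((0, 3), (1, 2))}
    (i, j), (u, v) = pairs[topo]
    root = Node(None)
    cherry = Node(None, 0.0)
    cherry.add(Node(names[i], float(t[i])))
    cherry.add(Node(names[j], float(t[j])))
    root.add(cherry)
    root.add(Node(names[u], float(t[u])))
    root.add(Node(names[v], float(t[v])))
    return AnnotatedTree(root)


def length_margin_slope(rate_multiplier: float) -> float:
    """Small-f slope of E[X]/sd(X) per unit of internal branch length,
    where X is the length-weighted per-gene margin of the matching topology
    over an alternative.

    Exact for the simulator's coalescent geometry:
    ``g(r) = (3+r)(3+4r) / ((3+2r)(1+r)) * sqrt((1+2r) / (2(3+2r)))``.
    ``g(0) = sqrt(3/2)`` recovers the unweighted margin's slope;
    ``g(r) > g(0)`` for every ``r > 0`` (the weighted vote is strictly more
    decisive per gene), with a maximum near ``r = 2`` and limit
    ``sqrt(2)`` as ``r`` grows.
    """
    r = rate_multiplier
    return ((3 + r) * (3 + 4 * r) / ((3 + 2 * r) * (1 + r))
            * math.sqrt((1 + 2 * r) / (2 * (3 + 2 * r))))
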