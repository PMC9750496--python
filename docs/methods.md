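# Methods

## The estimation problem

Given k unrooted binary gene trees G (newick, one per line) on overlapping
taxon sets, with branch supports s(e) ∈ [0,1] on internal edges and branch
lengths in substitution units (SU), the package searches for the binary
species tree S maximising the weighted quartet score

    W(S, G) = Σ_{G ∈ G} Σ_{Q ∈ Q(S)} w_G(S|Q),

where Q(S) ranges over the four-taxon subsets of S present in G and
w_G(ab|cd) is zero unless G restricted to {a,b,c,d} displays the pairing
ab|cd.  When it does, the weight is, by scheme:

* **unweighted** — 1 (the classic quartet count);
* **support** — `1 − Π_{e ∈ P} (1 − s(e))`, the product running over the
  edges of the path P between the two internal vertices (*anchors*) of the
  induced quartet.  This treats supports as independent probabilities of
  correctness, so the factor is the probability that at least one edge of
  the anchor path is real;
* **length** — `exp(−(l(a,b) + l(c,d)))`, where l(·,·) are the SU path
  lengths within the two cherries (the anchor–anchor path is excluded).
  Long quartets are both noisier (long-branch attraction) and, under the
  coalescent, enriched for discordance, since deep coalescence simultaneously
  causes discordance and lengthens terminal branches;
* **hybrid** (default) — the product of the support and length factors.

Maximising the unweighted score over gene trees drawn from the
multispecies coalescent (MSC) is a statistically consistent estimator of
the species tree; the weighted variants extend consistency into regimes of
biased gene tree estimation error (see "Quartet error model" below).

## Data model and input handling

Trees are stored rooted but carry unrooted semantics: after parsing, a
bifurcating root is suppressed so every non-root node corresponds to one
unrooted edge.  Supports come from internal-node labels under one of four
conventions: `raw01` and `sh_like` (pass-through with clamping), `percent`
(÷100), `abayes` (approximate Bayesian supports in [1/3, 1], mapped by
(3s−1)/2).  Labels slightly outside the admissible range (numeric jitter up
to 1e-3) are clamped with a warning; anything worse is a validation error
naming the edge, and non-numeric labels are rejected rather than guessed.
Missing supports or lengths are stored as absent, never imputed; a
weighting scheme that needs them fails fast before any search work unless
the caller supplies explicit fill-ins.  Polytomies are resolved randomly
with length 0 and support 0 on introduced edges, which gives those
resolutions zero weight under the support and hybrid schemes — an
unresolved quartet is equivalent to a polytomy.  Restriction to a taxon
subset merges suppressed paths by summing lengths and *retaining the
support multiset*, which is what the support product over the anchor path
requires.

## Scoring

Every quartet quantity is read off three leaf-pair matrices per gene:
topological distance (the four-point condition resolves the induced
topology; strict for binary trees), SU path length (the two cherry paths
give the length factor directly), and the path sum of log(1−s) over
internal edges.  The anchor-path product follows from the cancellation
`Π_P (1−s) = exp((q_ac + q_bd − q_ab − q_cd)/2)` — pendant-side
contributions appear once in a cherry path and once in a crossing path and
cancel.  Supports equal to 1 are clamped to 1−1e-12 inside the logs; the
induced error in any weight is below 1e-11, well inside the 1e-9
tolerances used throughout.  The reference scorer enumerates all C(n,4)
quartets (vectorised over genes via a compiled kernel, with a pure-Python
path used as an independent oracle in the tests).

Per-node *tripartition scores* — the total weight of quartets anchored at
an internal node, with two taxa in one of its three surrounding blocks and
one in each other — satisfy the anchoring identity
`W(S,G) = ½ Σ_nodes score(node)` because every quartet anchors at exactly
its two anchors.  This identity is tested to 1e-9 on random instances and
is what makes the dynamic program below exact.

## Search

**Optimal placement.**  Adding a taxon q to a backbone changes the score
by the total weight of gene quartets containing q.  For a backbone triple
{x,y,z} with Steiner vertex v, the gene's pairing partner of q (x, say)
determines that the quartet supports exactly the attachment edges lying in
x's component of the backbone minus v.  Accumulating each triple's weight
over that component (constant + subtree-interval updates, resolved by one
sweep from the root) yields the score of *every* placement edge in one
pass.  This equals brute-force rescoring of each extended tree to 1e-9 and
is verified edge-by-edge in the tests; ties break on the smallest
canonical edge key (sorted leaf names) for determinism.

**Greedy rounds + DP.**  One round inserts all taxa in a seeded random
order, each at its optimal edge, and records the tripartition scores of
the resulting tree in a store.  The dynamic program then assembles the
score-optimal binary tree whose every internal tripartition occurs in the
store: rooted at the smallest taxon, V(clade) maximises V(X)+V(Y)+score
over stored splits {X, Y, complement}.  Because round trees are always
recorded, the DP is feasible and dominates every round tree; on a store
containing all topologies' tripartitions it provably returns the global
optimum (tested exhaustively at n=7).  The schedule is 12 initial rounds,
then batches of 4 with a cumulative store, stopping when the DP score
stops improving (relative tolerance 1e-12) or after 5 batches.

**Divide and conquer (n ≥ 200).**  A backbone on ⌈√n⌉ random taxa is
built with ⌈√n⌉ rounds; remaining taxa are placed independently on the
backbone and clustered by edge; each cluster is inserted sequentially with
*orphan removal* (a taxon whose optimal edge falls outside the edges
derived from the cluster's own edge is deferred); the per-edge trees are
merged over the shared scaffold by grafting each edge's chain region while
keeping previously merged refinements below it; orphans are placed last.
Under a dominant-quartet signal every step is exact, so the method returns
the dominant topology (tested at n=250).  The ⌈√n⌉ sizes balance the
backbone search and the placement work.

## Branch support

Around an internal branch with surrounding parts A|B|C|D, the three
resolutions receive normalised weighted counts; the numerator of x_i sums
the scheme weights of quartets (a,b,c,d) ∈ A×B×C×D resolved as pairing i,
and the shared denominator is the *square of the mean of per-gene square
roots* of the three-resolution weight total.  Two notes on this choice:

* the square-root normalisation reflects that genes with larger weight
  totals also have proportionally larger variance in their contribution,
  so each gene's vote is scaled by a standard-deviation-like quantity;
  when all per-gene totals are equal it reduces exactly to the equal-vote
  normalisation (each gene contributing x1+x2+x3 = 1), which is also the
  unweighted/no-missing-data special case asserted in the tests;
* genes whose total weight around the branch is zero carry no information
  and are excluded from numerator and denominator alike, rather than
  deflating the denominator.

The local posterior probability of resolution i is p_i = h(x_i)/Σ h(x_j)
with

    h(x) = 2^x · B(x+1, m−x+2λ) · (1 − I_{1/3}(x+1, m−x+2λ)),

m = x1+x2+x3, B the beta function, I the regularised incomplete beta
function and λ the birth rate of a Yule prior on the branch length
(default 0.5).  This closed form is exactly the integral of the MSC
quartet likelihood `(1−(2/3)e^{−d})^{x_i} ((1/3)e^{−d})^{m−x_i}` against
the prior density 2λe^{−2λd}, up to factors common to the three
resolutions (substituting u = e^{−d} and then v = 2u/3 produces the 2^x
factor and the incomplete-beta tail; the tests verify agreement with
direct numeric quadrature to 1e-6).  The 2^x reading also gives the
correct uninformative limit p = 1/3 at x1=x2=x3=0.  Evaluation is in log
space (betaln + log-betainc), finite for counts up to 1e6 and beyond.

## Quartet error model

For one quartet around a species branch of CU length d (θ = 1−e^{−d}),
the true topology is drawn from ((1+2θ)/3, (1−θ)/3, (1−θ)/3).  A per-gene
quality α keeps the estimate equal to the truth with probability α;
otherwise the estimate is drawn from bias probabilities p with
|3p_i − 1| ≤ β, the worst case being (3p) = (1−β, 1+β, 1) — error tilted
toward the second topology.  Supports equal the conditional probability of
the estimated topology given the truth: α+(1−α)p_i on a match, (1−α)p_i
otherwise.  The exact worst-case expectations of the per-gene margins
(topology 1 minus topology 2) are

    unweighted:  θᾱ − (2/3)(1−ᾱ)β
    weighted:    (1/9)θ(3+2β)(ᾱ²+σ²) + (2/9)(3−β)θᾱ − (4/9)(1−ᾱ)β

(verified symbolically against the joint table).  Both are increasing in
θ, so each has a single root; between the weighted root and the unweighted
root lies the *consistency window* of CU branch lengths where the
support-weighted vote converges to the true topology while the unweighted
vote converges to the biased alternative.  The window is empty at β = 0
and widens with β.  The separation experiment picks a θ inside the window
by maximising the a-priori joint success probability of the two vote
frequencies under a normal approximation of the vote sums; this is a pure
design-stage computation from the closed forms, performed before any
simulation.  Note that at the experiment scale fixed by the validation
protocol (k = 10⁴ genes, 20 replicates) the per-replicate recovery
probabilities are about 0.97 and 0.04 even at the optimal θ, so the
all-or-nothing frequency thresholds are met only with moderate
probability; the margin signs themselves are deterministic.

## Quartet coalescent simulator and the length-weighting margin

The simulator draws gene trees for a quartet species tree ab|cd with
internal branch f CU: the a,b pair may coalesce along the internal branch
(rate 1), after which all remaining lineages coalesce freely at the far
anchor.  The topology distribution is exactly ((1+2θ)/3, (1−θ)/3,
(1−θ)/3) with θ = 1−e^{−f}, and terminal branch CU lengths are converted
to SU by a fixed rate multiplier r (the strict-clock model).  Writing
X = e^{−r·ΣCU}(δ₁−δ₂) for the length-weighted margin, a small-f expansion
of this geometry gives the exact slope

    E[X]/sd(X) = g(r)·f + O(f²),
    g(r) = (3+r)(3+4r)/((3+2r)(1+r)) · sqrt((1+2r)/(2(3+2r))),

derived by conditioning on whether the pair coalesces inside the internal
branch and evaluating the exponential moments of the Kingman waiting
times.  g(0) = √(3/2) is precisely the unweighted margin's slope
(E[Y] = θ ≈ f, Var[Y] = (2+θ)/3 → 2/3), g(r) > g(0) for every r > 0 —
length weighting strictly increases the per-gene signal-to-noise of the
quartet vote — with a maximum near r = 2 and limit √2 as r → ∞.  The
Monte-Carlo check regresses the simulated ratio on f ∈ {0.01, 0.02, 0.05}
with a linear finite-f correction term (the leading bias is ≈ −(½+r)f
relative) and compares the extrapolated slope to g(r) within 5%.  The
common pendant-length factor cancels between numerator and denominator,
so pendant branches are set to zero in this experiment.  The paired
dominance check (weighted vote fails no more often than the unweighted
vote over replicate gene sets) uses the same simulator draws for both
votes.

## Synthetic datasets

The generator emulates the statistical structure of simulated phylogenomic
benchmarks without sequence simulation:

* **species tree** — birth-only (Yule) topology with branch lengths scaled
  to a target height in CU; the height is the ILS dial (default 3.0 CU for
  30 taxa, giving mean true-gene-tree vs species-tree RF ≈ 0.4);
* **gene trees** — contained-coalescent simulation within the species
  tree (population size 1, so branch lengths are in CU);
* **estimation error** — each internal branch of CU length ℓ is hit by a
  random nearest-neighbour interchange with probability
  noise_scale·e^{−ℓ} (default 0.6), concentrating topological error on
  short branches as real estimation error does; at the defaults the final
  gene-vs-species RF is ≈ 0.66, emulating the high-error regime where
  weighting matters;
* **SU lengths** — CU lengths times su_rate_mean·exp(σ·N(0,1)) per branch
  (defaults 0.2 and 0.5), a lognormal rate-multiplier clock deviation;
* **supports** — Beta(ac, c) on unperturbed internal branches and
  Beta(c, ac) on perturbed ones, with c = 2 and a = support_concentration
  (default 4): mean 0.8 vs 0.2, so support is informative about
  correctness but noisy;
* **missing data** — optional i.i.d. leaf deletion (default off).

What passing the end-to-end comparison shows, and what it does not: it
shows that when supports and lengths carry the correlates the weighting
schemes assume, the hybrid search makes no more species-tree errors and no
more fully-supported-wrong branches than the unweighted search.  It does
not probe alignment error, paralogy, gene flow, rate heterotachy across
sites, or support estimators whose biases violate the
support-as-probability assumption.

## Numerical and design choices

* All tolerances for algebraic identities are 1e-9 absolute; they absorb
  only float summation-order effects plus the 1e-12 support clamp.
* Randomness flows from a single seed through named `SeedSequence`
  substreams (round permutations, polytomy resolution, simulation), so
  every entry point is bitwise reproducible; wall-clock timing is logged
  to stderr and deliberately kept out of result files.
* Placement ties break on the canonical (sorted leaf names) edge key;
  insertion order within DAC clusters is the sorted taxon order.
* Degenerate inputs: fewer than 4 taxa is an error for search; a branch
  with no gene spanning all four parts gets no support value (logged)
  rather than a fabricated one; an all-zero posterior is an explicit
  arithmetic error.
* Problem sizes in the validation suite (n ≤ 12 for identities, n = 7 for
  exhaustive optimality, n = 30/k = 200 for the end-to-end comparison,
  n = 250 for divide-and-conquer recovery, 10⁶–10⁷ Monte-Carlo draws)
  were chosen as the smallest scales at which each property is
  non-trivially exercised.

## Known limitations

* Branch lengths on the output species tree are not estimated (only
  topology and localPP supports are emitted).
* Multi-copy gene trees and multiple individuals per species are not
  supported; leaf labels must match species names.
* The support-weighting consistency analysis treats quartets as
  independent and supports as correct probabilities; both assumptions are
  approximations for real support estimators.
* The greedy+DP search is a heuristic for an NP-hard problem; optimality
  is guaranteed only within the recorded tripartition space (and globally
  under a dominant-quartet signal).
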