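"""Desk-scale synthetic datasets: a Yule species tree, coalescent gene
trees, topological estimation noise concentrated on short branches, and
support values correlated with branch correctness.

The generator emulates the statistical structure of simulated phylogenomic
benchmarks: incomplete lineage sorting is controlled by the species-tree
height in coalescent units (CU); gene tree *estimation* error is injected
as random nearest-neighbour interchanges (NNIs) whose probability decays
with the CU length of the branch (short branches are hard to estimate);
substitution-unit (SU) lengths are CU lengths times lognormal per-branch
rate multipliers; supports are Beta draws skewed high on unperturbed
branches and low on perturbed ones.  Sequence-level simulation and
re-inference are deliberately out of scope.
"""

from __future__ import annotations

import json
import math
import random as _pyrandom
from dataclasses import asdict, dataclass
from pathlib import Path

import dendropy
import numpy as np
from dendropy.simulate import treesim

from .treeio import AnnotatedTree, Node, parse_tree, write_tree, write_trees

__all__ = ["SimConfig", "simulate_dataset", "write_dataset"]


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of the generator.

    ``species_tree_height_cu`` dials ILS (taller = less discordance);
    ``noise_scale`` is the NNI probability of a zero-length branch (decaying
    as exp(-length) in CU); ``support_concentration`` controls how sharply
    supports separate correct from perturbed branches (Beta(a*c, c) vs
    Beta(c, a*c) with c = 2).
    """

    n_taxa: int = 30
    k_genes: int = 200
    species_tree_height_cu: float = 3.0
    birth_rate: float = 1.0
    su_rate_mean: float = 0.2
    rate_lognormal_sigma: float = 0.5
    noise_scale: float = 0.6
    support_concentration: float = 4.0
    missing_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.n_taxa < 5 or self.k_genes < 1:
            raise ValueError("need n_taxa >= 5 and k_genes >= 1")
        if not (0.0 <= self.missing_fraction < 1.0):
            raise ValueError("missing_fraction must be in [0, 1)")
        if min(self.species_tree_height_cu, self.birth_rate,
               self.su_rate_mean, self.support_concentration) <= 0:
            raise ValueError("rates, heights and concentrations must be positive")
        if self.noise_scale < 0 or self.rate_lognormal_sigma < 0:
            raise ValueError("noise_scale and sigma must be non-negative")


_BETA_C = 2.0


def _species_tree(config: SimConfig, pyrng) -> dendropy.Tree:
    tree = treesim.birth_death_tree(
        birth_rate=config.birth_rate, death_rate=0.0,
        num_extant_tips=config.n_taxa, rng=pyrng)
    tree.calc_node_ages()
    height = max(nd.age for nd in tree.preorder_node_iter())
    scale = config.species_tree_height_cu / height
    for e in tree.preorder_edge_iter():
        if e.length is not None:
            e.length *= scale
    return tree


def _gene_tree(species: dendropy.Tree, gene_map, pyrng) -> AnnotatedTree:
    g = treesim.contained_coalescent_tree(
        containing_tree=species, gene_to_containing_taxon_map=gene_map,
        default_pop_size=1.0, rng=pyrng)
    return parse_tree(g.as_string(schema="newick", suppress_rooting=True))


def _random_nni(node: Node, rng) -> None:
    """NNI across the edge above ``node`` (an internal, non-root node)."""
    parent = node.parent
    siblings = [c for c in parent.children if c is not node]
    s = siblings[int(rng.integers(len(siblings)))]
    child = node.children[int(rng.integers(len(node.children)))]
    si = parent.children.index(s)
    ci = node.children.index(child)
    parent.children[si], node.children[ci] = child, s
    child.parent, s.parent = parent, node


def simulate_dataset(config: SimConfig):
    """Returns ``(species_tree, gene_trees)``.

    The species tree carries CU lengths; gene trees carry SU lengths on all
    edges and supports in [0, 1] on internal edges.
    """
    seq = np.random.SeedSequence(config.seed)
    ss_species, ss_genes, ss_noise = seq.spawn(3)
    pyrng = _pyrandom.Random(int(ss_species.generate_state(1)[0]))
    rng = np.random.default_rng(ss_noise)

    dsp = _species_tree(config, pyrng)
    species = parse_tree(dsp.as_string(schema="newick", suppress_rooting=True))
    gene_map = dendropy.TaxonNamespaceMapping.create_contained_taxon_mapping(
        containing_taxon_namespace=dsp.taxon_namespace, num_contained=1,
        contained_taxon_label_fn=lambda taxon, idx: taxon.label)
    gene_pyrng = _pyrandom.Random(int(ss_genes.generate_state(1)[0]))

    a = config.support_concentration * _BETA_C
    genes = []
    for _ in range(config.k_genes):
        gt = _gene_tree(dsp, gene_map, gene_pyrng)
        # estimation noise: NNI with probability decaying in CU length
        perturbed: set[int] = set()
        if config.noise_scale > 0:
            for node in list(gt.postorder()):
                if node.is_leaf or node is gt.root or node.parent is None:
                    continue
                ell = node.length or 0.0
                if rng.random() < config.noise_scale * math.exp(-ell):
                    _random_nni(node, rng)
                    perturbed.add(id(node))
        # SU lengths and supports
        for node in gt.postorder():
            if node is gt.root:
                continue
            mult = config.su_rate_mean * math.exp(
                config.rate_lognormal_sigma * rng.standard_normal())
            node.length = (node.length or 0.0) * mult
            if not node.is_leaf:
                if id(node) in perturbed:
                    s = rng.beta(_BETA_C, a)
                else:
                    s = rng.beta(a, _BETA_C)
                node.supports = (float(s),)
        if config.missing_fraction > 0:
            keep = [nm for nm in sorted(gt.leaf_names())
                    if rng.random() >= config.missing_fraction]
            if len(keep) >= 4:
                from .treeio import restrict
                gt = restrict(gt, keep)
        genes.append(gt)
    return species, genes


def write_dataset(config: SimConfig, out_dir: "str | Path"):
    """Write species.nwk, genes.nwk and a JSON manifest of the conditions."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    species, genes = simulate_dataset(config)
    (out / "species.nwk").write_text(write_tree(species) + "\n")
    (out / "genes.nwk").write_text(write_trees(genes))
    (out / "manifest.json").write_text(
        json.dumps(asdict(config), indent=2, sort_keys=True) + "\n")
    return species, genes
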