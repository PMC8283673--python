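"""Multispecies-coalescent gene trees and multilocus pattern sampling.

Under the multispecies coalescent, the genealogy of a single locus is a
random gene tree drawn inside a (clock) species tree: within each
population (branch of the species tree), pairs of lineages coalesce at
rate C(j, 2) per unit of coalescent time (2N generations), and lineages
that fail to coalesce are handed to the ancestral population. For four
taxa the species-tree flattening of the resulting site-pattern
distribution has rank at most 10, so rank-10 SVD scores are the relevant
statistics.

Gene-tree branch lengths are kept in coalescent units internally and
converted to expected substitutions per site by a single multiplicative
``branch_scale`` when computing pattern distributions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import cached_property

import dendropy
import numpy as np

from .flattening import SitePatternCounts
from .models import SPLITS, TAXA, SitePatternDistribution, SubstitutionModel

__all__ = [
    "GeneTreeNode",
    "GeneTree",
    "SpeciesTreeModel",
    "sample_gene_tree",
    "coalescent_pattern_counts",
]


@dataclass
class GeneTreeNode:
    """A node of a rooted gene tree; ``age`` is in coalescent units."""

    age: float
    taxon: str | None = None
    children: list["GeneTreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class GeneTree:
    """A rooted four-taxon gene tree with ages in coalescent units."""

    root: GeneTreeNode
    branch_scale: float = 0.1

    @cached_property
    def quartet_split(self) -> str:
        """The unrooted quartet topology: determined by the first cherry."""
        # The earliest coalescence joins two leaves; that pair is a cherry
        # of the unrooted quartet.
        best: tuple[float, frozenset] | None = None
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                continue
            leaf_children = [c.taxon for c in node.children if c.is_leaf]
            if len(leaf_children) == 2 and (best is None or node.age < best[0]):
                best = (node.age, frozenset(leaf_children))
            stack.extend(node.children)
        assert best is not None, "a four-leaf binary tree always has a cherry"
        pair = best[1]
        for split in SPLITS:
            left, right = split.split("|")
            if pair == frozenset(left) or pair == frozenset(right):
                return split
        raise AssertionError("unreachable")

    def leaf_ages(self) -> dict[str, float]:
        out = {}
        stack = [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out[node.taxon] = node.age
            stack.extend(node.children)
        return out

    def pattern_distribution(self, model: SubstitutionModel) -> SitePatternDistribution:
        """Exact site-pattern distribution of this gene tree under ``model``.

        Standard pruning: partial likelihoods are propagated from the
        leaves to the root, with each branch's coalescent-unit duration
        multiplied by ``branch_scale`` to obtain substitution units.
        """

        def below(node: GeneTreeNode) -> tuple[list[str], np.ndarray]:
            if node.is_leaf:
                return [node.taxon], np.eye(4)
            parts: list[tuple[list[str], np.ndarray]] = []
            for child in node.children:
                leaves, b = below(child)
                t = (node.age - child.age) * self.branch_scale
                parts.append((leaves, model.transition_matrix(t) @ b))
            leaves, acc = parts[0]
            for more_leaves, arr in parts[1:]:
                acc = (acc[:, :, None] * arr[:, None, :]).reshape(4, -1)
                leaves = leaves + more_leaves
            return leaves, acc

        leaves, b_root = below(self.root)
        joint = (model.pi @ b_root).reshape((4,) * len(leaves))
        order = [leaves.index(t) for t in TAXA]
        probs = joint.transpose(order).reshape(256)
        return SitePatternDistribution(probs / probs.sum())


@dataclass(frozen=True)
class SpeciesTreeModel:
    """A rooted ultrametric four-taxon species tree for the coalescent.

    Parameters
    ----------
    newick:
        Rooted Newick with branch lengths in coalescent units (2N
        generations); leaf labels must be a, b, c, d. The tree must be
        ultrametric (all leaves at age 0).
    theta:
        The population-size parameter; constant across the tree. Retained
        as model metadata — the simulation operates in coalescent time,
        and the conversion of gene-tree branch lengths to substitution
        units is governed directly by ``branch_scale``.
    branch_scale:
        Substitutions per site per coalescent unit.
    """

    newick: str
    theta: float = 0.05
    branch_scale: float = 0.1

    def __post_init__(self) -> None:
        if self.theta <= 0:
            raise ValueError("theta must be positive")
        self._populations  # validate eagerly

    @cached_property
    def _populations(self):
        """Species-tree nodes with ages, children, and parent ages, in time order."""
        tree = dendropy.Tree.get(data=self.newick, schema="newick")
        labels = sorted(lf.taxon.label for lf in tree.leaf_node_iter())
        if labels != sorted(TAXA):
            raise ValueError(f"species tree must have leaves {TAXA}, found {labels}")
        ages: dict = {}
        for node in tree.postorder_node_iter():
            if node.is_leaf():
                ages[node] = 0.0
            else:
                child_ages = []
                for ch in node.child_nodes():
                    if ch.edge.length is None:
                        raise ValueError("species tree requires branch lengths")
                    child_ages.append(ages[ch] + ch.edge.length)
                if max(child_ages) - min(child_ages) > 1e-9 * max(1.0, max(child_ages)):
                    raise ValueError("species tree must be ultrametric (clock)")
                ages[node] = sum(child_ages) / len(child_ages)
        return tree, ages

    @property
    def root_age(self) -> float:
        tree, ages = self._populations
        return ages[tree.seed_node]


def sample_gene_tree(
    species_tree: SpeciesTreeModel, rng: np.random.Generator
) -> GeneTree:
    """Draw one gene tree from the multispecies coalescent on ``species_tree``.

    One lineage is sampled per species. Within each population, waiting
    times between coalescences are exponential with rate C(j, 2); pairs
    to merge are chosen uniformly. The root population runs until a
    single lineage remains.
    """
    tree, ages = species_tree._populations
    lineages: dict = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            lineages[node] = [GeneTreeNode(age=0.0, taxon=node.taxon.label)]
            continue
        pool: list[GeneTreeNode] = []
        for ch in node.child_nodes():
            pool.extend(lineages[ch])
        t = ages[node]
        t_end = math.inf if node.parent_node is None else ages[node.parent_node]
        while len(pool) > 1:
            j = len(pool)
            rate = j * (j - 1) / 2.0
            t_next = t + rng.exponential(1.0 / rate)
            if t_next > t_end:
                break
            t = t_next
            i1, i2 = rng.choice(j, size=2, replace=False)
            a, b = pool[i1], pool[i2]
            merged = GeneTreeNode(age=t, children=[a, b])
            pool = [x for k, x in enumerate(pool) if k not in (i1, i2)]
            pool.append(merged)
        lineages[node] = pool
    (root,) = lineages[tree.seed_node]
    return GeneTree(root=root, branch_scale=species_tree.branch_scale)


def coalescent_pattern_counts(
    species_tree: SpeciesTreeModel,
    model: SubstitutionModel,
    n_loci: int,
    sites_per_locus: int,
    rng: np.random.Generator,
) -> SitePatternCounts:
    """Multilocus site-pattern counts under the coalescent.

    For each locus one gene tree is drawn, its exact pattern distribution
    computed, and ``sites_per_locus`` sites sampled multinomially — sites
    within a locus share a genealogy, so across loci the counts follow
    the gene-tree mixture distribution rather than an i.i.d. multinomial.
    Use ``sites_per_locus=1`` for a strictly i.i.d. site model. Total
    count is always ``n_loci * sites_per_locus``.
    """
    if n_loci < 1 or sites_per_locus < 1:
        raise ValueError("n_loci and sites_per_locus must be >= 1")
    counts = np.zeros(256, dtype=np.int64)
    for _ in range(n_loci):
        gt = sample_gene_tree(species_tree, rng)
        p = gt.pattern_distribution(model).probs
        counts += rng.multinomial(sites_per_locus, p)
    return SitePatternCounts(counts=counts)
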