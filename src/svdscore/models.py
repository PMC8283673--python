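"""Exact site-pattern probability distributions for four-taxon trees.

A four-taxon alignment column is one of the 4^4 = 256 *site patterns*
``i1 i2 i3 i4`` assigning a nucleotide to each of the taxa (a, b, c, d).
Under a reversible substitution model (GTR or its JC69 submodel) on an
unrooted quartet tree with branch lengths, the pattern probabilities can
be computed exactly by summing over the states of the two internal nodes.
This module supplies:

* :func:`pattern_index` — the fixed base-4 encoding of patterns;
* :class:`SubstitutionModel` — GTR rate matrices, normalized so branch
  lengths are in expected substitutions per site, with transition
  matrices obtained through the symmetric (pi^(1/2)-scaled) spectral
  decomposition;
* :class:`QuartetTree` — the three unrooted leaf-labeled topologies with
  five branch lengths, round-tripping through Newick;
* :func:`site_pattern_distribution` — exact 256-entry distributions;
* :class:`NetworkModel` / :func:`mixture_distribution` — two-tree mixture
  distributions for a network displaying both trees;
* :func:`sample_gtr_parameters` — random GTR draws (exchangeabilities
  Uniform(0.5, 1.5), base frequencies Dirichlet(5,5,5,5)).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import cached_property

import dendropy
import numpy as np

__all__ = [
    "NUCLEOTIDES",
    "TAXA",
    "SPLITS",
    "pattern_index",
    "index_pattern",
    "SubstitutionModel",
    "transition_matrix",
    "QuartetTree",
    "SitePatternDistribution",
    "site_pattern_distribution",
    "NetworkModel",
    "mixture_distribution",
    "sample_gtr_parameters",
]

NUCLEOTIDES = "ACGT"
_NUC_INDEX = {c: i for i, c in enumerate(NUCLEOTIDES)}

#: Fixed, global taxon roles. All pattern vectors are indexed with taxon
#: ``a`` most significant.
TAXA = ("a", "b", "c", "d")

#: The three unrooted quartet topologies, named by their nontrivial split.
SPLITS = ("ab|cd", "ac|bd", "ad|bc")

# Unordered nucleotide pairs in the seq-gen rate order AC, AG, AT, CG, CT, GT.
_RATE_PAIRS = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))


def pattern_index(i1: str, i2: str, i3: str, i4: str) -> int:
    """Base-4 index of the site pattern ``i1 i2 i3 i4`` (A=0, C=1, G=2, T=3).

    Taxon ``a``'s state is the most significant digit, so e.g.
    ``pattern_index("C", "A", "A", "G") == 66``.
    """
    try:
        return (
            64 * _NUC_INDEX[i1.upper()]
            + 16 * _NUC_INDEX[i2.upper()]
            + 4 * _NUC_INDEX[i3.upper()]
            + _NUC_INDEX[i4.upper()]
        )
    except KeyError as exc:
        raise ValueError(f"non-nucleotide symbol in pattern: {exc.args[0]!r}") from None


def index_pattern(idx: int) -> str:
    """Inverse of :func:`pattern_index`: the four-letter pattern for an index."""
    if not 0 <= idx <= 255:
        raise ValueError(f"pattern index out of range: {idx}")
    return "".join(NUCLEOTIDES[(idx >> s) & 3] for s in (6, 4, 2, 0))


@dataclass(frozen=True)
class SubstitutionModel:
    """A time-reversible nucleotide substitution model (GTR family).

    Parameters
    ----------
    exchangeabilities:
        Five non-negative relative rates in the order (AG, AT, CG, CT, GT);
        the AC rate is fixed at 1.0, matching the convention of fixing the
        first rate of the six-rate GTR parameterization.
    base_frequencies:
        Stationary frequencies (pi_A, pi_C, pi_G, pi_T), positive, summing
        to one.

    The rate matrix ``Q`` (order A, C, G, T) has off-diagonal entries
    ``Q[i, j] = s_ij * pi_j`` and is rescaled so that the expected number
    of substitutions per unit branch length, ``-sum_i pi_i Q[i, i]``, is 1.
    Transition matrices ``P(t) = exp(Qt)`` are evaluated through the
    symmetric matrix ``diag(pi)^(1/2) Q diag(pi)^(-1/2)``, which is exactly
    symmetric under detailed balance and keeps the exponential numerically
    stable for long branches.
    """

    exchangeabilities: tuple[float, float, float, float, float] = (1.0, 1.0, 1.0, 1.0, 1.0)
    base_frequencies: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self) -> None:
        ex = tuple(float(x) for x in self.exchangeabilities)
        bf = tuple(float(x) for x in self.base_frequencies)
        if len(ex) != 5 or any(x < 0 for x in ex):
            raise ValueError("exchangeabilities must be five non-negative reals")
        if len(bf) != 4 or any(x <= 0 for x in bf):
            raise ValueError("base frequencies must be four positive reals")
        if abs(sum(bf) - 1.0) > 1e-8:
            raise ValueError("base frequencies must sum to 1")
        object.__setattr__(self, "exchangeabilities", ex)
        object.__setattr__(self, "base_frequencies", bf)

    @classmethod
    def jc69(cls) -> "SubstitutionModel":
        """The Jukes–Cantor model: all rates equal, uniform frequencies."""
        return cls()

    @property
    def pi(self) -> np.ndarray:
        return np.asarray(self.base_frequencies, dtype=float)

    @cached_property
    def rate_matrix(self) -> np.ndarray:
        """Normalized 4x4 GTR generator Q (rows sum to zero)."""
        s = np.zeros((4, 4))
        rates = (1.0, *self.exchangeabilities)
        for r, (i, j) in zip(rates, _RATE_PAIRS):
            s[i, j] = s[j, i] = r
        q = s * self.pi[None, :]
        np.fill_diagonal(q, 0.0)
        np.fill_diagonal(q, -q.sum(axis=1))
        mu = -np.sum(self.pi * np.diag(q))
        return q / mu

    @cached_property
    def _symmetric_eig(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        d = np.sqrt(self.pi)
        s = (self.rate_matrix * d[:, None]) / d[None, :]
        s = 0.5 * (s + s.T)  # exact symmetry despite round-off
        w, u = np.linalg.eigh(s)
        return w, u, d

    def transition_matrix(self, t: float) -> np.ndarray:
        """Stochastic matrix ``P(t) = exp(Q t)`` for branch length ``t >= 0``."""
        if t < 0:
            raise ValueError(f"branch length must be non-negative, got {t}")
        w, u, d = self._symmetric_eig
        p = (u * np.exp(w * t)) @ u.T
        p = p / d[:, None] * d[None, :]
        np.clip(p, 0.0, None, out=p)
        return p / p.sum(axis=1, keepdims=True)


def transition_matrix(model: SubstitutionModel, t: float) -> np.ndarray:
    """Functional alias for :meth:`SubstitutionModel.transition_matrix`."""
    return model.transition_matrix(t)


def _cherries(split: str) -> tuple[tuple[str, str], tuple[str, str]]:
    left, right = split.split("|")
    return (left[0], left[1]), (right[0], right[1])


@dataclass(frozen=True)
class QuartetTree:
    """An unrooted four-taxon tree: a split plus five branch lengths.

    ``branch_lengths`` maps each taxon role to its terminal branch length
    and ``"internal"`` to the internal branch, all in expected
    substitutions per site. A rooted Newick string is accepted on input;
    the root is suppressed and any lengths along the internal path are
    summed (root placement is statistically irrelevant for reversible
    models).
    """

    split: str
    branch_lengths: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}, got {self.split!r}")
        bl = {k: float(v) for k, v in self.branch_lengths.items()}
        missing = {*TAXA, "internal"} - bl.keys()
        if missing:
            raise ValueError(f"missing branch lengths: {sorted(missing)}")
        if any(v < 0 for v in bl.values()):
            raise ValueError("branch lengths must be non-negative")
        object.__setattr__(self, "branch_lengths", bl)

    @classmethod
    def from_lengths(
        cls, split: str, ta: float, tb: float, tc: float, td: float, internal: float
    ) -> "QuartetTree":
        return cls(split, {"a": ta, "b": tb, "c": tc, "d": td, "internal": internal})

    @classmethod
    def from_newick(cls, newick: str, taxa: tuple[str, str, str, str] = TAXA) -> "QuartetTree":
        """Parse a four-taxon Newick tree (rooted or unrooted, lengths required).

        ``taxa`` gives the leaf labels playing the roles (a, b, c, d).
        The split and the five branch lengths are recovered from the
        leaf-to-leaf path distances via the four-point condition, so any
        root placement along any edge yields the same quartet.
        """
        tree = dendropy.Tree.get(data=newick, schema="newick")
        labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
        if sorted(labels) != sorted(taxa):
            raise ValueError(f"expected leaves {taxa}, found {labels}")
        pdm = tree.phylogenetic_distance_matrix()
        tax = {t.label: t for t in tree.taxon_namespace}
        label = dict(zip(TAXA, taxa))
        dmat = {}
        for i, x in enumerate(TAXA):
            for y in TAXA[i + 1 :]:
                dmat[frozenset((x, y))] = pdm.patristic_distance(
                    tax[label[x]], tax[label[y]]
                )

        def dist(x: str, y: str) -> float:
            return dmat[frozenset((x, y))]

        sums = {}
        for sp in SPLITS:
            (p, q), (r, s) = _cherries(sp)
            sums[sp] = dist(p, q) + dist(r, s)
        split = min(SPLITS, key=lambda sp: sums[sp])
        internal = (max(sums.values()) - sums[split]) / 2.0
        (p, q), (r, s) = _cherries(split)
        lengths = {"internal": internal}
        for x, sib, other in ((p, q, r), (q, p, r), (r, s, p), (s, r, p)):
            lengths[x] = (dist(x, sib) + dist(x, other) - dist(sib, other)) / 2.0
        return cls(split, lengths)

    def to_newick(self, taxa: tuple[str, str, str, str] = TAXA) -> str:
        """Unrooted Newick string ``((p,q):internal,r,s);`` for this quartet."""
        names = dict(zip(TAXA, taxa))
        (p, q), (r, s) = _cherries(self.split)
        bl = self.branch_lengths
        return (
            f"(({names[p]}:{bl[p]:.12g},{names[q]}:{bl[q]:.12g}):{bl['internal']:.12g},"
            f"{names[r]}:{bl[r]:.12g},{names[s]}:{bl[s]:.12g});"
        )


@dataclass(frozen=True)
class SitePatternDistribution:
    """Exact length-256 probability vector over quartet site patterns."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.probs, dtype=float).reshape(256)
        if np.any(p < -1e-12):
            raise ValueError("pattern probabilities must be non-negative")
        if abs(p.sum() - 1.0) > 1e-12:
            raise ValueError(f"pattern probabilities must sum to 1, got {p.sum()!r}")
        p = np.clip(p, 0.0, None)
        p.setflags(write=False)
        object.__setattr__(self, "probs", p)

    def tensor(self) -> np.ndarray:
        """The probabilities as a (4,4,4,4) array indexed by taxon states."""
        return self.probs.reshape(4, 4, 4, 4)

    def __getitem__(self, pattern: str) -> float:
        return float(self.probs[pattern_index(*pattern)])

    def distinct_value_count(self, rtol: float = 1e-9) -> int:
        """Number of distinct entry values, merging entries within ``rtol``."""
        v = np.sort(self.probs)
        gaps = np.diff(v) > rtol * np.maximum(np.abs(v[1:]), 1e-300)
        return int(gaps.sum()) + 1


def site_pattern_distribution(
    tree: QuartetTree, model: SubstitutionModel
) -> SitePatternDistribution:
    """Exact site-pattern distribution for ``tree`` under ``model``.

    Sums over the states of the two internal nodes of the unrooted
    quartet. For a reversible model the result is independent of where a
    root is placed (pulley principle); the internal branch length is the
    full path between the two internal nodes.
    """
    (p, q), (r, s) = _cherries(tree.split)
    bl = tree.branch_lengths
    pp = model.transition_matrix(bl[p])
    pq = model.transition_matrix(bl[q])
    pr = model.transition_matrix(bl[r])
    ps = model.transition_matrix(bl[s])
    pint = model.transition_matrix(bl["internal"])
    joint = np.einsum(
        "x,xi,xj,xy,yk,yl->ijkl", model.pi, pp, pq, pint, pr, ps, optimize=True
    )
    # joint axes are in split order (p, q, r, s); rearrange to (a, b, c, d)
    order = [(p, q, r, s).index(t) for t in TAXA]
    probs = joint.transpose(order).reshape(256)
    return SitePatternDistribution(probs / probs.sum())


@dataclass(frozen=True)
class NetworkModel:
    """A two-tree mixture: sites come from ``tree_1`` w.p. ``gamma``, else ``tree_2``."""

    tree_1: QuartetTree
    tree_2: QuartetTree
    gamma: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError(f"mixture weight must lie in [0, 1], got {self.gamma}")


def mixture_distribution(
    network: NetworkModel, model: SubstitutionModel
) -> SitePatternDistribution:
    """Pattern distribution of the network: the gamma-weighted tree mixture."""
    p1 = site_pattern_distribution(network.tree_1, model).probs
    p2 = site_pattern_distribution(network.tree_2, model).probs
    mix = network.gamma * p1 + (1.0 - network.gamma) * p2
    return SitePatternDistribution(mix / mix.sum())


def sample_gtr_parameters(rng: np.random.Generator) -> SubstitutionModel:
    """Draw a random GTR model: rates ~ U(0.5, 1.5), frequencies ~ Dir(5,5,5,5)."""
    ex = tuple(rng.uniform(0.5, 1.5, size=5))
    bf = rng.dirichlet((5.0, 5.0, 5.0, 5.0))
    bf = tuple(bf / bf.sum())
    return SubstitutionModel(ex, bf)
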