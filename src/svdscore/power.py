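"""Power experiments and site-count approximations for the SVD-score tests.

The power of a test at sample size n is the fraction of simulated
replicates whose squared SVD score for the tested (discordant) split
exceeds the method's rejection threshold. Because the squared score of
the exact distribution scales as c^2 when the flattening is scaled by c,
the squared score of n sampled sites grows like coeff * n^2 for a
misspecified split, while thresholds grow like n — so the site count at
which rejection becomes possible is approximately threshold/coeff.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .coalescent import SpeciesTreeModel, coalescent_pattern_counts
from .flattening import SitePatternCounts, flatten, svd_score
from .hypotest import METHODS, rejection_threshold
from .models import SitePatternDistribution, SubstitutionModel

__all__ = [
    "PowerCurve",
    "sites_to_reject",
    "multinomial_sampler",
    "coalescent_sampler",
    "power_experiment",
]

#: A sampler maps (rng, n) to the pattern counts of one simulated data set.
CountsSampler = Callable[[np.random.Generator, int], SitePatternCounts]


def sites_to_reject(squared_score_coeff: float, threshold_coeff: float) -> int:
    """Smallest integer n with ``coeff * n^2 > threshold * n``.

    ``squared_score_coeff`` is the squared SVD score of the exact
    (probability-scale) distribution for the tested split;
    ``threshold_coeff`` is a rejection threshold in multiples of n.
    """
    if squared_score_coeff <= 0 or threshold_coeff <= 0:
        raise ValueError("both coefficients must be positive")
    ratio = threshold_coeff / squared_score_coeff
    n = math.floor(ratio) + 1  # strict inequality, so ties round up
    return max(n, 2) if ratio >= 1 else max(n, 1)


def multinomial_sampler(p: SitePatternDistribution) -> CountsSampler:
    """Sampler drawing n i.i.d. sites from a fixed pattern distribution."""

    def sample(rng: np.random.Generator, n: int) -> SitePatternCounts:
        return SitePatternCounts(counts=rng.multinomial(n, p.probs))

    return sample


def coalescent_sampler(
    species_tree: SpeciesTreeModel,
    model: SubstitutionModel,
    sites_per_locus: int = 100,
) -> CountsSampler:
    """Sampler drawing multilocus coalescent data; n must be a multiple of
    ``sites_per_locus`` (it is rounded up to the next multiple)."""

    def sample(rng: np.random.Generator, n: int) -> SitePatternCounts:
        n_loci = max(1, math.ceil(n / sites_per_locus))
        return coalescent_pattern_counts(
            species_tree, model, n_loci, sites_per_locus, rng
        )

    return sample


@dataclass(frozen=True)
class PowerCurve:
    """Empirical power of the SVD-score tests over a grid of sample sizes."""

    n_grid: tuple[int, ...]
    reps: int
    power: dict[str, np.ndarray]  # method -> fraction rejecting, per n
    n_at_target: dict[str, int | None]  # first grid n reaching target power
    target_power: float
    alpha: float
    rank: int
    split: str
    seed: int | None = None

    def as_frame(self):
        import pandas as pd

        return pd.DataFrame(self.power, index=list(self.n_grid)).rename_axis("n")


def power_experiment(
    sampler: CountsSampler,
    split: str,
    r: int,
    alpha: float,
    n_grid: Sequence[int],
    reps: int,
    rng: np.random.Generator | int,
    methods: tuple[str, ...] = METHODS,
    target_power: float = 0.95,
    k: int = 256,
) -> PowerCurve:
    """Estimate rejection power on a grid of sample sizes.

    For each n, ``reps`` data sets are drawn from ``sampler``; each
    method rejects when the squared rank-``r`` SVD score of the tested
    split exceeds its threshold at level ``alpha``. Reports per-method
    empirical power and the first grid n reaching ``target_power``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    n_grid = tuple(int(n) for n in n_grid)
    if list(n_grid) != sorted(n_grid):
        raise ValueError("n_grid must be sorted ascending")
    seed = rng if isinstance(rng, (int, np.integer)) else None
    gen = np.random.default_rng(rng) if seed is not None else rng
    coeffs = {m: rejection_threshold(m, alpha, n=1, k=k) for m in methods}
    power = {m: np.zeros(len(n_grid)) for m in methods}
    for i, n in enumerate(n_grid):
        rejections = {m: 0 for m in methods}
        for _ in range(reps):
            counts = sampler(gen, n)
            beta = svd_score(flatten(counts, split), r).squared
            for m in methods:
                if beta >= coeffs[m] * counts.n:
                    rejections[m] += 1
        for m in methods:
            power[m][i] = rejections[m] / reps
    n_at_target: dict[str, int | None] = {}
    for m in methods:
        hits = [n for n, pw in zip(n_grid, power[m]) if pw >= target_power]
        n_at_target[m] = hits[0] if hits else None
    return PowerCurve(
        n_grid=n_grid,
        reps=reps,
        power=power,
        n_at_target=n_at_target,
        target_power=target_power,
        alpha=alpha,
        rank=r,
        split=split,
        seed=seed,
    )
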