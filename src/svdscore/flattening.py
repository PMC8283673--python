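"""Flattening matrices and rank-r SVD scores for quartet splits.

The 256 site-pattern probabilities (or counts) of a four-taxon alignment
can be arranged into a 16x16 *flattening* matrix for each of the three
quartet splits: rows index the joint states of one sister pair, columns
the joint states of the other. When the data were generated on a tree
displaying the split, the flattening of the exact distribution has
reduced rank (4 for a single gene tree, 10 under the multispecies
coalescent), so the Frobenius distance from an empirical flattening to
the nearest rank-r matrix — by Eckart–Young, the square root of the tail
sum of squared singular values — measures support for the split.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

from .models import SPLITS, SitePatternDistribution

__all__ = [
    "SitePatternCounts",
    "FlatteningMatrix",
    "SVDScore",
    "SplitScores",
    "flatten",
    "svd_score",
    "score_all_splits",
]

# Axis order of the (4,4,4,4) pattern tensor, per split, as
# (row taxon 1, row taxon 2, column taxon 1, column taxon 2).
_SPLIT_AXES = {"ab|cd": (0, 1, 2, 3), "ac|bd": (0, 2, 1, 3), "ad|bc": (0, 3, 1, 2)}


@dataclass(frozen=True)
class SitePatternCounts:
    """Observed site-pattern counts q-hat from an alignment of n sites.

    The ``dropped`` field records alignment columns discarded for
    containing non-ACGT symbols; they are not part of ``n``.
    """

    counts: np.ndarray
    dropped: int = 0

    def __post_init__(self) -> None:
        c = np.asarray(self.counts)
        if c.shape != (256,):
            raise ValueError("counts must be a length-256 vector")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        c = c.astype(np.int64) if np.issubdtype(c.dtype, np.integer) else c.astype(float)
        c.setflags(write=False)
        object.__setattr__(self, "counts", c)

    @property
    def n(self) -> int:
        """Total number of sites."""
        return int(self.counts.sum())

    def frequencies(self) -> np.ndarray:
        """The normalized empirical distribution q = q-hat / n."""
        if self.n == 0:
            raise ValueError("cannot normalize empty counts")
        return self.counts / self.n


@dataclass(frozen=True)
class FlatteningMatrix:
    """A 16x16 flattening of a pattern vector for one quartet split."""

    values: np.ndarray
    split: str

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.shape != (16, 16):
            raise ValueError("flattening must be 16x16")
        if self.split not in SPLITS:
            raise ValueError(f"split must be one of {SPLITS}")
        v = v.copy()
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    @property
    def total(self) -> float:
        """Entry sum: 1 for probability flattenings, n for count flattenings."""
        return float(self.values.sum())

    @cached_property
    def singular_values(self) -> np.ndarray:
        """All 16 singular values, descending."""
        return np.linalg.svd(self.values, compute_uv=False)


@dataclass(frozen=True)
class SVDScore:
    """Distance from a flattening to the nearest rank-r matrix."""

    split: str
    rank: int
    score: float

    @property
    def squared(self) -> float:
        """The squared score beta, the scale used by the hypothesis tests."""
        return self.score**2


def flatten(
    patterns: SitePatternDistribution | SitePatternCounts | np.ndarray, split: str
) -> FlatteningMatrix:
    """Arrange a 256-vector into the 16x16 flattening for ``split``.

    For split ab|cd rows encode (i1, i2) base-4 and columns (i3, i4); the
    other splits pair (i1, i3)/(i2, i4) and (i1, i4)/(i2, i3). Indexing
    follows the global pattern order, so for ab|cd the (5, 3) entry
    (1-based) is the probability of pattern CAAG.
    """
    if split not in _SPLIT_AXES:
        raise ValueError(f"split must be one of {SPLITS}, got {split!r}")
    if isinstance(patterns, SitePatternDistribution):
        vec = patterns.probs
    elif isinstance(patterns, SitePatternCounts):
        vec = patterns.counts
    else:
        vec = np.asarray(patterns, dtype=float).reshape(256)
    tensor = vec.reshape(4, 4, 4, 4).transpose(_SPLIT_AXES[split])
    return FlatteningMatrix(tensor.reshape(16, 16), split)


def svd_score(flattening: FlatteningMatrix | np.ndarray, r: int) -> SVDScore:
    """SVD score S_r = sqrt(sum of squared singular values beyond the r-th).

    At r = 0 this is the Frobenius norm; at r = 16 it is zero; round-off
    negatives in the tail sum are clamped at zero.
    """
    if not 0 <= r <= 16:
        raise ValueError(f"rank must lie in [0, 16], got {r}")
    if isinstance(flattening, FlatteningMatrix):
        sv = flattening.singular_values
        split = flattening.split
    else:
        sv = np.linalg.svd(np.asarray(flattening, dtype=float), compute_uv=False)
        split = "ab|cd"
    tail = max(float(np.sum(sv[r:] ** 2)), 0.0)
    return SVDScore(split=split, rank=r, score=float(np.sqrt(tail)))


@dataclass(frozen=True)
class SplitScores:
    """SVD scores of all three splits at a common rank, plus the argmin."""

    scores: dict[str, SVDScore]
    rank: int

    @property
    def best_split(self) -> str:
        """The split with the smallest score — the point estimate of the quartet."""
        return min(SPLITS, key=lambda s: self.scores[s].score)

    def __getitem__(self, split: str) -> SVDScore:
        return self.scores[split]


def score_all_splits(
    patterns: SitePatternDistribution | SitePatternCounts | np.ndarray, r: int
) -> SplitScores:
    """SVD scores for all three quartet splits of one pattern vector."""
    return SplitScores(
        scores={s: svd_score(flatten(patterns, s), r) for s in SPLITS}, rank=r
    )
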