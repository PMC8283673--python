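"""Hypothesis tests built on the squared SVD score.

The null hypothesis is that the observed pattern counts q-hat are a
multinomial sample of n sites from *some* distribution p whose flattening
for the tested split has rank at most r. The test statistic

    Y = || X - n p ||_2^2,    X ~ Multinomial(n, p),

is bounded below by the squared SVD score beta = (S_r(q-hat))^2, so any
upper bound on Pr(Y >= beta) that holds uniformly over the probability
simplex is a valid p-value bound. Four such bounds are provided, driven
by two simplex-wide moment bounds (E[Y] <= n and Var[Y] <= n^2/2):

* ``markov``     — Markov's inequality: n / beta.
* ``chebyshev``  — Cantelli's one-sided inequality.
* ``logconcave`` — a Chebyshev-like bound for variables with log-concave
  CDF; Y is approximately a positive combination of one-degree chi-square
  variables (eigenvalues of the multinomial covariance as weights), which
  has a log-concave CDF.
* ``bhc``        — the Bretagnolle–Huber–Carol multinomial L1 inequality
  with k = 256 categories (constant 2^k).

Each bound inverts to a rejection threshold: the smallest beta/n that
rejects at level alpha.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize

from .flattening import SitePatternCounts, flatten, svd_score
from .models import SitePatternDistribution

__all__ = [
    "METHODS",
    "CovarianceSpectrum",
    "YSample",
    "TestResult",
    "covariance_spectrum",
    "mean_Y",
    "var_Y",
    "sample_Y_chisq",
    "sample_Y_multinomial",
    "pvalue_markov",
    "pvalue_chebyshev",
    "pvalue_logconcave",
    "pvalue_bhc",
    "rejection_threshold",
    "threshold_table",
    "test_quartet",
    "variance_functional",
    "verify_lemma32_optima",
]

METHODS = ("markov", "chebyshev", "logconcave", "bhc")

_LN2 = float(np.log(2.0))


def _as_prob_vector(p) -> np.ndarray:
    if isinstance(p, SitePatternDistribution):
        return p.probs
    v = np.asarray(p, dtype=float)
    if v.ndim != 1 or np.any(v < 0) or abs(v.sum() - 1.0) > 1e-9:
        raise ValueError("p must be a probability vector")
    return v


@dataclass(frozen=True)
class CovarianceSpectrum:
    """Spectrum of the multinomial covariance Sigma(p) = diag(p) - p p^T.

    ``trace`` is sum p_i (1 - p_i); ``trace_sq`` is tr(Sigma^2), which
    equals sum p_i^2 - 2 sum p_i^3 + (sum p_i^2)^2; the variance
    functional V(p) = 2 tr(Sigma^2) never exceeds 1/2 on the simplex.
    """

    eigenvalues: np.ndarray
    trace: float
    trace_sq: float

    @property
    def variance_functional(self) -> float:
        return 2.0 * self.trace_sq


def covariance_spectrum(p) -> CovarianceSpectrum:
    """Eigendecomposition of Sigma(p), validated against the trace identities.

    Accepts any probability vector (length k, not just 256). Eigenvalues
    are clamped at zero; the spectral traces must agree with the
    closed-form identities to 1e-10 or an assertion fires.
    """
    v = _as_prob_vector(p)
    sigma = np.diag(v) - np.outer(v, v)
    eig = np.linalg.eigvalsh(sigma)
    eig = np.clip(eig[::-1], 0.0, None)  # descending, non-negative
    s2 = float(np.sum(v**2))
    s3 = float(np.sum(v**3))
    trace = 1.0 - s2 if abs(v.sum() - 1.0) < 1e-12 else float(np.sum(v * (1 - v)))
    trace_sq = s2 - 2.0 * s3 + s2**2
    scale = max(trace, 1e-15)
    if abs(float(eig.sum()) - trace) > 1e-10 * max(1.0, scale):
        raise AssertionError("spectral trace disagrees with closed form")
    if abs(float(np.sum(eig**2)) - trace_sq) > 1e-10 * max(1.0, scale):
        raise AssertionError("spectral tr(Sigma^2) disagrees with closed form")
    return CovarianceSpectrum(eigenvalues=eig, trace=trace, trace_sq=trace_sq)


def mean_Y(p, n: int) -> float:
    """Approximate mean of Y: n * sum p_i (1 - p_i) = n * tr Sigma(p)."""
    v = _as_prob_vector(p)
    return float(n * np.sum(v * (1.0 - v)))


def var_Y(p, n: int) -> float:
    """Approximate variance of Y: 2 n^2 tr(Sigma(p)^2)."""
    v = _as_prob_vector(p)
    s2 = float(np.sum(v**2))
    s3 = float(np.sum(v**3))
    return 2.0 * n**2 * (s2 - 2.0 * s3 + s2**2)


def variance_functional(p: np.ndarray) -> np.ndarray:
    """V(p) = 2 tr(Sigma(p)^2) evaluated row-wise on an array of simplex points."""
    v = np.asarray(p, dtype=float)
    s2 = np.sum(v**2, axis=-1)
    s3 = np.sum(v**3, axis=-1)
    return 2.0 * (s2 - 2.0 * s3 + s2**2)


@dataclass(frozen=True)
class YSample:
    """Monte Carlo draws of the statistic Y for a fixed (n, p)."""

    values: np.ndarray
    n: int
    source: str  # "multinomial" or "chisq"

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if np.any(v < 0):
            raise ValueError("Y samples must be non-negative")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)


def sample_Y_chisq(p, n: int, reps: int, rng: np.random.Generator) -> YSample:
    """Sample the approximating distribution n * sum_i lambda_i Z_i.

    The Z_i are independent one-degree chi-square variables and the
    lambda_i are the eigenvalues of Sigma(p); zero eigenvalues contribute
    nothing, so no shrinkage of p is needed for singular Sigma.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    lam = covariance_spectrum(p).eigenvalues
    lam = lam[lam > 0]
    z = rng.chisquare(1.0, size=(reps, lam.size))
    return YSample(values=n * z @ lam, n=n, source="chisq")


def sample_Y_multinomial(p, n: int, reps: int, rng: np.random.Generator) -> YSample:
    """Sample Y exactly: draw X ~ Multinomial(n, p) and take ||X - np||^2."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    v = _as_prob_vector(p)
    x = rng.multinomial(n, v, size=reps)
    y = np.sum((x - n * v) ** 2, axis=1)
    return YSample(values=y, n=n, source="multinomial")


# ---------------------------------------------------------------------------
# p-value upper bounds
# ---------------------------------------------------------------------------

def pvalue_markov(beta: float, n: int) -> float:
    """Markov bound min(1, n/beta); beta <= 0 yields the trivial bound 1."""
    if beta <= 0:
        return 1.0
    return min(1.0, n / beta)


def pvalue_chebyshev(beta: float, n: int) -> float:
    """Cantelli bound (n^2/2) / ((beta - n)^2 + n^2/2), trivial for beta <= n."""
    if beta <= n:
        return 1.0
    half_n2 = n**2 / 2.0
    return min(1.0, half_n2 / ((beta - n) ** 2 + half_n2))


def _logconcave_rhs(rho: np.ndarray | float) -> np.ndarray | float:
    """sqrt(1 + 2 rho ln rho - rho^2) / (rho - ln rho - 1), increasing on (0, 1)."""
    lr = np.log(rho)
    return np.sqrt(np.maximum(1.0 + 2.0 * rho * lr - rho**2, 0.0)) / (rho - lr - 1.0)


def pvalue_logconcave(beta: float, n: int) -> tuple[float, float]:
    """Log-concave-CDF bound: returns (rho, p-value bound).

    Solves sqrt(1 + 2 rho ln rho - rho^2)/(rho - ln rho - 1) =
    1/(sqrt(2) (beta/n - 1)) for rho in (0, 1) by bracketed root-finding
    (tolerance 1e-12). The left side uses the simplex-wide bounds mu <= n
    and sigma <= n/sqrt(2), so the solution is a valid p-value bound for
    any p. Trivial bound 1 for beta <= n.
    """
    if beta <= n:
        return 1.0, 1.0
    target = 1.0 / (np.sqrt(2.0) * (beta / n - 1.0))
    # Near rho = 1 both numerator and denominator of the defining equation
    # vanish as O((1-rho)^3) / O((1-rho)^2) and float cancellation destroys
    # the quotient; at rho = 0.999 the RHS is still ~52, i.e. any root beyond
    # the bracket corresponds to beta/n - 1 < 0.014 where the bound is
    # effectively 1 (returned as such, conservatively).
    lo, hi = 1e-16, 0.999
    if target <= _logconcave_rhs(lo):
        return lo, lo
    if target >= _logconcave_rhs(hi):
        return 1.0, 1.0
    rho = optimize.brentq(
        lambda r: _logconcave_rhs(r) - target, lo, hi, xtol=1e-12, rtol=1e-12
    )
    return float(rho), min(1.0, float(rho))


def pvalue_bhc(beta: float, n: int, k: int = 256) -> float:
    """Bretagnolle–Huber–Carol bound min(1, 2^k exp(-beta/(2n))).

    Computed in log space: k ln 2 - beta/(2n) overflows the float range
    for k = 256 long before the bound leaves 1, so the exponential is only
    evaluated once the log is negative.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if beta <= 0:
        return 1.0
    log_bound = k * _LN2 - beta / (2.0 * n)
    if log_bound >= 0:
        return 1.0
    return float(np.exp(log_bound))


_ALPHAS_DEFAULT = (0.10, 0.05, 0.01, 0.001)


def rejection_threshold(
    method: str,
    alpha: float,
    n: int = 1,
    k: int = 256,
    chebyshev_variant: str = "table",
) -> float:
    """Smallest squared SVD score that rejects at level ``alpha``.

    Returned as ``n`` times a method-specific coefficient:

    * markov:     1/alpha
    * chebyshev:  1 + 1/sqrt(2 alpha) (``variant="table"``, the classical
      one-sided bound without the +sigma^2 term) or
      1 + sqrt((1/alpha - 1)/2) (``variant="cantelli"``, the exact
      inversion of :func:`pvalue_chebyshev`)
    * logconcave: 1 + (alpha - ln alpha - 1)/sqrt(2 (1 + 2 alpha ln alpha - alpha^2))
    * bhc:        2 (k ln 2 + ln(1/alpha))
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError(f"alpha must lie in (0, 1), got {alpha}")
    if method == "markov":
        coeff = 1.0 / alpha
    elif method == "chebyshev":
        if chebyshev_variant == "table":
            coeff = 1.0 + 1.0 / np.sqrt(2.0 * alpha)
        elif chebyshev_variant == "cantelli":
            coeff = 1.0 + np.sqrt((1.0 / alpha - 1.0) / 2.0)
        else:
            raise ValueError(f"unknown chebyshev variant {chebyshev_variant!r}")
    elif method == "logconcave":
        la = np.log(alpha)
        coeff = 1.0 + (alpha - la - 1.0) / np.sqrt(2.0 * (1.0 + 2.0 * alpha * la - alpha**2))
    elif method == "bhc":
        coeff = 2.0 * (k * _LN2 + np.log(1.0 / alpha))
    else:
        raise ValueError(f"unknown method {method!r}; expected one of {METHODS}")
    return float(coeff * n)


def threshold_table(
    alphas: tuple[float, ...] = _ALPHAS_DEFAULT, k: int = 256
):
    """Rejection-threshold coefficients (beta/n) as a methods x alphas table."""
    import pandas as pd

    data = {
        a: [rejection_threshold(m, a, n=1, k=k) for m in METHODS] for a in alphas
    }
    return pd.DataFrame(data, index=list(METHODS))


@dataclass(frozen=True)
class TestResult:
    """Outcome of the SVD-score test for one split at one rank."""

    split: str
    rank: int
    n: int
    statistic: float  # beta, the squared SVD score of the counts flattening
    alpha: float
    pvalues: dict[str, float]
    reject: dict[str, bool]
    rho: float | None = None  # auxiliary root of the log-concave bound
    score: float = field(default=0.0)

    def to_dict(self) -> dict:
        return {
            "split": self.split,
            "rank": self.rank,
            "n": self.n,
            "score": self.score,
            "squared_score": self.statistic,
            "alpha": self.alpha,
            "pvalue_bounds": dict(self.pvalues),
            "reject": dict(self.reject),
        }


def test_quartet(
    counts: SitePatternCounts,
    split: str,
    r: int = 4,
    alpha: float = 0.05,
    methods: tuple[str, ...] = METHODS,
    k: int = 256,
) -> TestResult:
    """Test whether ``counts`` could come from a rank-``r`` model on ``split``.

    The statistic is the squared SVD score of the counts flattening; each
    requested method contributes a p-value upper bound valid uniformly
    over the simplex, and the (conservative) decision rejects when the
    bound falls below ``alpha``.
    """
    n = counts.n
    if n < 1:
        raise ValueError("counts must contain at least one site")
    sc = svd_score(flatten(counts, split), r)
    beta = sc.squared
    pvals: dict[str, float] = {}
    rho = None
    for m in methods:
        if m == "markov":
            pvals[m] = pvalue_markov(beta, n)
        elif m == "chebyshev":
            pvals[m] = pvalue_chebyshev(beta, n)
        elif m == "logconcave":
            rho, pvals[m] = pvalue_logconcave(beta, n)
        elif m == "bhc":
            pvals[m] = pvalue_bhc(beta, n, k=k)
        else:
            raise ValueError(f"unknown method {m!r}")
    reject = {m: bool(p < alpha) for m, p in pvals.items()}
    return TestResult(
        split=split,
        rank=r,
        n=n,
        statistic=beta,
        alpha=alpha,
        pvalues=pvals,
        reject=reject,
        rho=rho,
        score=sc.score,
    )


# ---------------------------------------------------------------------------
# numerical verification of the simplex-wide variance bound
# ---------------------------------------------------------------------------

def _interior_family_value(kk: np.ndarray | float) -> np.ndarray | float:
    """V(p) at the one-distinct-entry-off interior critical family, as a function of k."""
    return (kk**4 + 4 * kk**3 - 16 * kk - 16) / (8 * kk**2 * (kk - 1) ** 2)


def verify_lemma32_optima(
    rng: np.random.Generator | None = None, n_random: int = 100_000
) -> dict:
    """Numerically confirm the structure of the maximum of V(p) on the simplex.

    Checks that V never exceeds 1/2 over random simplex points of varying
    dimension, that the value 1/2 is attained at two entries of 1/2, that
    the uniform family 2(k-1)/k^2 peaks at k = 2, and that the interior
    two-entry critical family peaks near 0.43608 at k = (5 + sqrt 13)/3.
    Returns a report dict with all computed quantities.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    max_random = 0.0
    total = 0
    dims = (2, 3, 4, 8, 16, 64, 256)
    per_dim = max(1, n_random // len(dims))
    for k in dims:
        remaining = per_dim
        while remaining > 0:
            chunk = min(remaining, 20_000)
            pts = rng.dirichlet(np.ones(k), size=chunk)
            max_random = max(max_random, float(variance_functional(pts).max()))
            remaining -= chunk
            total += chunk
    p_half = np.zeros(256)
    p_half[:2] = 0.5
    v_half = float(variance_functional(p_half))
    kk = np.arange(2, 257, dtype=float)
    uniform_vals = 2 * (kk - 1) / kk**2
    res = optimize.minimize_scalar(
        lambda x: -_interior_family_value(x), bounds=(1.0 + 1e-9, 50.0), method="bounded",
        options={"xatol": 1e-12},
    )
    k_star = float(res.x)
    return {
        "n_random_points": total,
        "max_over_random_points": max_random,
        "value_at_two_halves": v_half,
        "uniform_family_max": float(uniform_vals.max()),
        "uniform_family_argmax_k": int(kk[np.argmax(uniform_vals)]),
        "interior_family_max": float(_interior_family_value(k_star)),
        "interior_family_argmax_k": k_star,
        "interior_family_argmax_closed_form": (5.0 + np.sqrt(13.0)) / 3.0,
        "k4_m2_value": float(variance_functional(np.full(4, 0.25))),
        "global_max": 0.5,
    }
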