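# Methods

## Model and statistic

A quartet data set is a draw X ~ Multinomial(n, p) over the k = 256 site
patterns. The tested null is composite: p lies in the set of
distributions whose flattening for split T has rank ≤ r (r = 4 for
single-gene-tree models, r = 10 for the multispecies coalescent on a
clock species tree). The statistic Y = ‖X − np‖₂² has, for large n, the
distribution of n·Σᵢ λᵢZᵢ with Zᵢ ~ χ²₁ independent and λᵢ the
eigenvalues of the multinomial covariance Σ(p) = diag(p) − ppᵀ, giving

    E[Y] ≈ n·tr Σ(p) = n·Σ pᵢ(1−pᵢ),
    Var[Y] ≈ 2n²·tr Σ(p)² = 2n²·(Σpᵢ² − 2Σpᵢ³ + (Σpᵢ²)²).

Because the squared SVD score of the observed flattening never exceeds
the realized ‖X − np‖₂² when the null holds, a p-value upper bound
follows from any tail bound on Y that is uniform over the simplex. Two
moment bounds supply that uniformity: tr Σ ≤ 1 and V(p) = 2 tr Σ² ≤ 1/2,
the latter attained only at distributions with two entries of 1/2. The
package verifies the variance bound numerically (`verify_lemma32_optima`)
by random simplex search over dimensions 2–256 and by maximizing the
two critical families from the underlying Lagrange analysis: the uniform
family 2(k−1)/k², maximal (1/2) at k = 2, and the interior two-entry
family (k⁴+4k³−16k−16)/(8k²(k−1)²), maximal ≈ 0.43608 at k = (5+√13)/3.

## The four tail bounds

With μ ≤ n and σ ≤ n/√2 for every p:

* Markov: Pr(Y ≥ β) ≤ n/β. Threshold coefficient 1/α.
* Cantelli: Pr(Y ≥ β) ≤ (n²/2)/((β−n)² + n²/2) for β > n. The p-value
  bound implements this form. The tabulated threshold coefficient uses
  the variant without the additive σ² term, 1 + 1/√(2α), which is the
  form the reference threshold table reproduces (4.16 at α = 0.05 versus
  4.08 for the Cantelli inversion); both are exposed and labeled
  (`chebyshev_variant="table" | "cantelli"`).
* Log-concave CDF: a positive combination of independent χ²₁ variables
  has a log-concave CDF, and for such variables Pr(exceed β) ≤ ρ where
  σ/(β−μ) = √(1+2ρ ln ρ−ρ²)/(ρ−ln ρ−1). The left side is bounded by
  1/(√2(β/n−1)); the right side is increasing on (0,1), so ρ is found by
  bracketed root-finding (brentq, tolerance 1e-12) on [1e-16, 0.999].
  Near ρ = 1 the defining quotient degenerates as O((1−ρ)³)/O((1−ρ)²)
  and float cancellation destroys it; at the bracket top the right side
  is ≈ 52, so any root beyond corresponds to β/n − 1 < 0.014 where the
  bound is returned as 1 (conservative). Closed-form threshold
  coefficient: 1 + (α − ln α − 1)/√(2(1 + 2α ln α − α²)).
* Bretagnolle–Huber–Carol: Pr(‖X−np‖₁ ≥ 2λ√n) ≤ 2^k exp(−2λ²) with
  k = 256 categories, giving Pr(Y ≥ β) ≤ 2^k exp(−β/(2n)), evaluated in
  log space (2²⁵⁶ overflows otherwise). The constant is 2^k, not 2k —
  the only reading consistent with thresholds near 360n and with the
  method's observed impotence below millions of sites.

The ε-shrinkage p′ = (1−ε)p sometimes used to make Σ(p) invertible is
unnecessary here: the eigendecomposition of the singular Σ(p) is taken
directly, negatives from round-off are clamped at zero, and zero
eigenvalues contribute nothing to the χ² combination.

## Exact pattern distributions

GTR rate matrices use exchangeability order (AC, AG, AT, CG, CT, GT)
with AC ≡ 1 and base frequencies in A, C, G, T order; Q is normalized to
one expected substitution per unit branch length, so all branch lengths
are in substitutions per site. Transition matrices come from the
symmetric π^{1/2}-similarity eigendecomposition (exact under detailed
balance, stable for long branches; the JC69 closed form serves only as a
test oracle). Quartet distributions sum over the two internal-node
states via einsum; correctness is pinned against a scalar brute-force
quadruple sum, re-rooting invariance, and leaf-permutation equivariance.
Pattern indexing is base-4 with A=0…T=3 and taxon a most significant, so
the ab|cd flattening's 1-based (5,3) entry is p_CAAG.

A network with a tree clade is modeled as a two-tree mixture with weight
γ (default 1/2): its pattern distribution is the γ-weighted average of
the two displayed trees' distributions.

On a generic tree the JC69 distribution takes exactly 15 distinct values
among its 256 entries. The reference quartet
((a:0.5,b:0.05):0.05,(c:0.5,d:0.05):0.05) is *not* generic in this
respect: its length multiset is invariant under swapping the two
cherries, which merges the 15 classes down to 11. The distinct-count
reported by the acceptance script therefore uses randomly drawn
(generic) branch lengths.

Against this reference quartet the exact squared rank-4 score of the
discordant ac|bd flattening is 8.7503977×10⁻⁵ per unit n² (confirmed to
40-digit precision via the Gram-matrix eigenvalues and by an independent
expm-based computation); the other discordant split gives 8.5295×10⁻⁵.
With the 2.73n log-concave threshold this implies rejection of ac|bd
from roughly 31,200 sites.

## Coalescent simulator

The species tree is a rooted ultrametric four-taxon Newick with branch
lengths in coalescent units (2N generations); θ (default 0.05) is
carried as metadata and a single `branch_scale` (default 0.1) converts
gene-tree coalescent branch lengths to substitution units — the two are
deliberately decoupled because the mapping between them depends on a
mutation-rate convention that is left to the user. One lineage is
sampled per species; within each population pairs coalesce at rate
C(j,2), checked against the classical closed form: each discordant
quartet topology appears with probability (1/3)e^(−T) for total internal
duration T. Multilocus sampling draws one gene tree per locus and then
`sites_per_locus` multinomial sites from that gene tree's exact
distribution (default 100 bp/locus); sites within a locus share a
genealogy, so the data are deliberately *not* i.i.d. across sites —
setting `sites_per_locus=1` gives the clean i.i.d. regime used for
calibration checks.

## Synthetic data: what it does and does not emulate

Generated alignments are i.i.d. multinomial site draws from exact model
distributions — precisely the sampling model the tests assume. They do
not contain rate heterogeneity across sites, ambiguity codes, indels,
alignment error, or linkage beyond the per-locus sharing in the
coalescent mode, so passing tests certify the statistical machinery
under its stated assumptions, not robustness to real-data violations of
them. Columns of real alignments containing non-ACGT symbols are dropped
(and counted) before pattern tallying; that rule is this package's
convention, not a modeling claim.

## Numerical choices and problem sizes

* Full SVD of the 16×16 flattening; tail sums accumulated in descending
  order with negative round-off clamped at zero.
* Tie-break for the argmin split: fixed split order (ab|cd, ac|bd,
  ad|bc); exact ties are measure-zero for generic data.
* Quartet recovery from Newick goes through leaf-to-leaf path distances
  and the four-point condition, so any root placement is accepted and
  internal-path lengths are summed.
* Power experiments default to coarse grids with tens of replicates
  (e.g. 30–40 reps over ≤ 6 grid points up to 3×10⁵ sites), chosen as
  desk-scale settings that resolve the method ordering and the power
  transitions; denser grids and replicate counts are plain arguments.
* Monte Carlo assertions in the test suite use 3–4 standard-error bands
  at fixed seeds; the 4σ bands are used where Y's right skew makes 3σ
  marginal.

## Known limitations

* Four taxa only; no flattenings for larger splits, no quartet assembly
  or weighting.
* No rate heterogeneity (+I/+Γ) or non-reversible models.
* The tests are conservative by construction (simplex-wide bounds and
  the score's lower-bound slack); below ≈ 11,000 sites on the reference
  quartet the discordant scores frequently underestimate even the true
  sampling distance, so non-rejection at small n carries little
  information.
* The joint distribution of the three split scores is not modeled; the
  tests apply to one split at a time.
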