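# Methods

This note documents the statistical model behind each tool, the
conventions chosen where several are defensible, the defaults and why,
and what the synthetic benchmarks do and do not demonstrate.

## Data model

All statistics operate on a rooted phylogeny with non-negative branch
lengths (one consistent unit throughout) and a vector of continuous
trait values, one per tip. Trees are read from Newick (quoted labels and
bracket comments accepted; internal node labels kept for reporting but
never used by statistics). Missing branch lengths are an error by
default — every statistic depends on them — with an explicit
`assume_unit_lengths` escape hatch that substitutes 1.0. Trait rows are
aligned to the *canonical tip order*, the postorder traversal of the
tree as parsed, so matrices and trait vectors always agree positionally.
Binding a tree to a table is strict by default (exact label-set
equality, mismatches reported as the symmetric difference); an
`intersect` policy prunes both sides to the common tips (≥ 3 required).
Zero-length terminal branches are legal but warned about: they produce
zero patristic distances, under which inverse-distance weights are
undefined (the node-count and Gaussian schemes remain usable).

## Weight and covariance matrices

* **Patristic distance** d_ij: sum of branch lengths on the tip-to-tip
  path, computed as d_ij = V_ii + V_jj − 2V_ij from the covariance
  matrix below; the identity is exact and is asserted in tests.
* **Node-count distance**: number of internal nodes strictly between
  two tips, MRCA included — a cherry is at distance 1. Useful when long
  terminal branches should not dilute clade membership.
* **Abouheif proximity**: w_ij = 1/Π dd_k over the internal nodes on
  the i–j path, dd_k the child count of node k; the root counts when
  the path crosses it. Branch lengths play no role. We return the *raw*
  path product without any normalization: Moran's I divides by the
  total weight S0, so any global rescaling (such as the sum-to-one
  normalization some implementations apply) cancels exactly. Row-wise
  normalizations would not cancel and are deliberately not applied.
* **Gaussian kernel**: w_ij = exp(−(d_ij−μ)²/2σ²)/(σ√2π). The kernel is
  a *decaying* function of |d−μ| — influence is strongest at distance μ
  and falls off with bandwidth σ — which forces the negative sign in
  the exponent.
* **Brownian covariance** V: V_ij is the depth of the MRCA of tips i
  and j (shared root-to-tip branch length), V_ii the tip depth. Pagel's
  transform multiplies off-diagonal entries by λ ∈ [0, 1].

## Index conventions

Blomberg's K is R/E[R] with R = MSE0/MSE, MSE0 the mean square of tip
values about the GLS ancestral mean â = (1ᵀV⁻¹y)/(1ᵀV⁻¹1), MSE the
V⁻¹-weighted mean square of the same residuals, and
E[R] = [tr(V) − n/(1ᵀV⁻¹1)]/(n−1). K* replaces â by the arithmetic tip
mean in MSE0 with the matching expectation
E[R*] = [tr(V) − 1ᵀV1/n]/(n−1). The n−1 scalings cancel inside K, but
they must match across packages for cross-implementation equality; our
K and the λ likelihood were verified to agree with an independent R
implementation (phytools::phylosig) to optimizer tolerance. All solves
against V use a Cholesky factorization; V is never inverted explicitly.

Pagel's λ̂ maximizes the Gaussian profile log-likelihood
−½[n·ln(2πσ̂²) + ln|V(λ)| + n] with μ̂(λ) the GLS mean and
σ̂²(λ) = rᵀV(λ)⁻¹r/n, by bounded 1-D search on [0, 1] (tolerance 1e-8;
bounds are also evaluated, so a boundary optimum is exact). The search
space stops at 1 because λ > 1 can destroy positive-definiteness. On a
star-like covariance the profile is flat; we return λ̂ = 0 with a
warning rather than an arbitrary interior point.

Constant traits are errors everywhere, never NaN returns: silent NaNs
propagate into result tables.

## Tests

The null hypothesis is absence of signal: trait values exchangeable
across tips. For I, C_mean, K and K* the null distribution is built by
uniform permutation of the trait across tips (tree fixed), with
p = (1 + #{stat* ≥ obs})/(nrep + 1); p can never be 0 and its
resolution is 1/(nrep+1). The default alternative is "greater"
(signal = excess similarity); "less" and "two-sided" (doubled smaller
tail, capped at 1) are available. Default nrep = 999 gives 0.001
resolution. λ is tested by LRT against λ = 0 on χ²₁; because λ̂ sits on
the boundary under the null, this reference is conservative (measured
null rejection ≈ 0.01 at nominal 0.05), which we accept and document
rather than correct with a boundary mixture.

A single root seed spawns an independent substream per (trait, method)
pair — keyed by the trait index and the method's position in the
canonical order (Cmean, I, K, Kstar, Lambda) — so adding or removing a
method never changes the other methods' p-values, and seeded runs are
byte-reproducible end to end.

LIPA p-values are per-tip permutation tails of each I_i; raw p-values
are reported (an optional Benjamini–Hochberg adjustment sits behind a
flag, off by default, matching the common practice of coloring raw
p < 0.05).

## Correlogram

The curve evaluates Moran's I under Gaussian-kernel weights centred at
each μ_k on an even grid over (0, dist_max]; μ = 0 is excluded because
the kernel would concentrate on the (empty) diagonal. Defaults:
100 grid points, dist_max = maximum patristic distance, σ = five grid
steps — wide enough to smooth adjacent points, narrow enough to keep
the short-lag/medium-lag contrast; σ is exposed everywhere. The
envelope resamples *tips* with replacement (tips are the exchangeable
unit), recomputes the curve on the induced trait/distance submatrices
(duplicated tips sit at distance 0, which the kernel handles with
finite weight; the diagonal stays 0), and takes pointwise percentile
bounds at the confidence level (default 95%, 1000 replicates, no bias
correction — the simplest defensible envelope). Degenerate draws
(< 3 distinct tips or constant resampled trait) are redrawn, capped at
10× the replicate count. Points are classified positive/negative when
the envelope clears the no-signal reference h0 = −1/(n−1); the observed
curve can fall outside its own envelope at a few points by bootstrap
noise, which is flagged with a warning, not an error. The envelope is
pointwise, not simultaneous: with a bandwidth so wide that the whole
curve moves as one block, a single dataset can miss the reference
everywhere at once — coverage statements are therefore averages over
datasets, and bandwidths that resolve the grid are recommended.

The multivariate Mantel variant correlates (Pearson, over off-diagonal
pairs) the tip-pair Euclidean distance matrix of the column-standardized
traits with the Gaussian weight matrix at each μ_k; its reference value
is 0.

## Simulation and benchmarks

Brownian traits are simulated recursively: child = parent +
N(0, σ²·branch length), root value 0 and σ² = 1 by default (all indices
are location/scale invariant, so these defaults are inconsequential).
Yule trees use exponential waiting times at unit birth rate with a
uniformly chosen splitting lineage, plus a final waiting time so
terminal branches are positive; they are ultrametric by construction.

The gradient benchmark mixes a *standardized* BM trait with
*standardized* white noise, y(α) = α·z_BM + (1−α)·z_noise.
Standardize-then-mix ensures α moves only the phylogenetic structure,
not the trait variance, so rejection rates are comparable across the
grid. Defaults α = 0, 0.1, …, 1 and nsim = 99 per level give usable
Monte-Carlo resolution at desk scale. Exact equivalence with other
published mixing recipes is not claimed; the behavioral contract is
level ≈ 0.05 at α = 0, monotone power in α, and K centred on 1 at
α = 1.

Measured on 50-tip Yule trees, power at pure BM is ≈ 1 for C_mean, K,
K* and λ but only ≈ 0.6 for Moran's I with 1/d weights — an intrinsic
property of that weighting (similarity is averaged over the whole
tree), not an implementation artifact, and the reason C_mean is the
recommended autocorrelation index for clade-structured signal.

## Per-node and per-bootstrap-tree scans

The per-node scan extracts each internal node's clade (≥ min_tips
descendant tips; default 5, below which permutation p-resolution is
worse than 1/120), rebinds the traits, and reruns statistic + test;
the root row reproduces the whole-tree result. Statistics are
mean-invariant, so subtree traits are not re-standardized. Raw
p-values across nodes, optional BH flag, same policy as LIPA.
The bootstrap scan requires every replicate tree to match the trait
table exactly and summarizes the statistic distribution by quantiles.

## What the synthetic benchmarks do and do not show

The packaged fixture and all test data are generated by the package's
own simulators: ultrametric Yule trees, Gaussian BM increments,
i.i.d. Gaussian noise, and hard clade shifts. Real comparative data
differ in ways these generators do not emulate — non-ultrametric trees
with estimation error in branch lengths, non-Gaussian and bounded
traits, measurement error, and selection regimes (e.g.
Ornstein–Uhlenbeck pull) that are neither pure BM nor pure noise.
Passing benchmarks therefore demonstrate correctness of the statistics
and calibration of their tests *under their own null and BM models*,
not robustness to model violations. Problem sizes used in the shipped
calibration runs (up to 100-tip trees, 200–1000 simulation replicates,
199–999 permutations) were chosen as the smallest giving stable
Monte-Carlo estimates.

## Known limitations

* Nexus/PhyloXML input, tree inference/rerooting and polytomy
  resolution are out of scope; polytomies in the input are handled.
* The λ LRT is conservative near the boundary (see above).
* Randomization under a Brownian null (rather than exchangeability) is
  not implemented.
* The correlogram envelope is pointwise percentile; simultaneous bands
  and bias-corrected variants are not provided.
* Discrete distance-class correlograms are deliberately absent — the
  continuous kernel version exists to avoid their binning artifacts.
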