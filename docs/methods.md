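# Methods

## Model

Observed are event counts `c_it` for areal units i = 1..N over time points
t = 0..T-1, together with unit areas `A_i` and a binary rook/shared-border
adjacency matrix W. The response is the inverse-hyperbolic-sine transformed
density `y_it = asinh(c_it / A_i) - log 2`, a log-like variance-stabilizing
transform that is finite at zero counts; the time index is standardized to
mean zero and *sample* variance one (denominator T-1, so the slope design
norm is `sum_t x_t^2 = T - 1`). Each unit gets a linear trend:

    y_it | alpha, beta, sigma^2  ~  N(alpha_i + beta_i x_t, sigma^2).

Two latent spatial partitions — gamma(alpha) over intercepts, gamma(beta)
over slopes — carry independent truncated Ewens-Pitman priors
`eta^K prod_k (n_k-1)! 1(spatial)`. Within cluster k of gamma(alpha):

    alpha_k | alphabar_k ~ CAR(alphabar_k, a1 sigma^2, W_k),
    alphabar_k ~ N(0, a2 sigma^2),

with the Leroux CAR covariance `Sigma_CAR = [rho W* + (1-rho) I]^{-1}`
(W* the unweighted graph Laplacian of the cluster subgraph; `1/(1-rho)` for
a singleton), and analogously for beta with (b1, b2). Finally
`sigma^2 ~ IG(nu/2, nu*lambda/2)` (shape/rate, so lambda is a prior guess
of sigma^2).

## Marginal likelihood

Integrating the grand means gives per-cluster covariance multipliers
`V_k = a1 Sigma_CAR + a2 11'`. Because `sum_t x_t = 0`, the intercept and
slope designs are orthogonal, and conditional on sigma^2 the observation
covariance is `sigma^2 (I + Da V_a Da' + Db V_b Db')` with a block structure
that factorizes over clusters. Both the log determinant and the quadratic
form therefore decompose into independent per-cluster terms — intercept
clusters driven by the per-unit time sums `s_i = sum_t y_it` with design
norm T, slope clusters by `z_i = sum_t x_t y_it` with design norm T-1 —
plus the raw residual `sum y^2`. Integrating sigma^2 analytically yields a
multivariate-t log density; no quadrature is used outside test oracles.

Per-cluster terms are computed from Cholesky factors of the cluster
precision `P = rho W* + (1-rho) I` and of `P + d*a1*I`, with the rank-one
grand-mean correction handled by the Sherman-Morrison and matrix-determinant
identities (`P 1 = (1-rho) 1` because W* is a Laplacian, which collapses the
rank-one algebra to scalars). Terms are cached by cluster member set, so a
local move recomputes only the one or two clusters it touches; a warm cache
and a cold recomputation agree to machine precision (tested). Cholesky
failures receive a single 1e-10 jitter retry, then error.

Conditional posterior means are `(V_k^{-1} + d I)^{-1} s_k` per cluster and
are free of sigma^2 (every covariance scales with it); grand-mean estimates
follow as `(1-rho) sum_i theta_i / ((1-rho) n_k + a1/a2)`.

## Particle optimization

The ensemble objective is `sum_l w_l log p(y, gamma_l) + lambda H(Gamma, w)`
where H is the entropy of the approximating distribution over *distinct*
particles: duplicates are merged before computing H and the optimal weights
(softmax of `log_joint / lambda` over distinct support, shared equally among
duplicates for bookkeeping). At optimal weights the objective equals
`lambda * logsumexp(log_joints / lambda)`; the global optimum is the exact
top-L set for every lambda > 0.

Coordinate ascent sweeps the particles, updating gamma(alpha) then
gamma(beta) of each by one greedy move chosen from a pooled candidate set:

- **island**: units whose running estimate sits in the top or bottom
  `island_quantile` (default 5%) of their cluster move to a new singleton;
  clusters of size two make both members eligible (5% of 2 rounds to both
  tails), singletons are skipped;
- **border**: every unit adjacent to a foreign cluster, one candidate per
  distinct adjacent cluster;
- **merge**: each cluster with its spatially adjacent cluster of closest
  grand mean;
- **split**: 1-D k-means on within-cluster estimates for m = 2..split_cap
  (default 5) parts, deterministic (centers at m evenly spaced empirical
  quantiles, 25 Lloyd iterations, ties to the lower center);
- **split-and-merge**: each split piece is donated to the adjacent other
  cluster whose grand mean is closest to the piece's mean estimate; interior
  pieces stay separate.

Removing units can disconnect a donor cluster; its connected components
then become separate clusters, so every candidate is again spatial.
Candidates are scored by the full objective with weights held fixed (the
entropy term makes the L searches mutually aware), accepted only on strict
improvement, ties broken toward fewer clusters then lexicographically
smaller canonical form. Running estimates are refreshed from the
conditional means after every accepted move. Weights are refreshed in
closed form after each sweep — this never lowers the objective, so the full
trace is non-decreasing (asserted at run time in the test suite).
Termination requires both a relative sweep improvement below `rel_tol`
(1e-8) and a certificate that none of the N all-island moves on any
particle improves the objective; `max_sweeps` (100) bounds the run with a
warning.

Initialization runs k-means on the per-unit least-squares estimates of
alpha and of beta for K = 1..round(eta log N) clusters each (about 6 at
N = 400, a 36-particle grid), splits each k-means cluster into connected
components to land in the spatial-partition support, and samples L grid
particles with replacement proportionally to their untempered joint
posterior. Redundant initial particles are intentional: duplicates explore
around dominant modes and the entropy term pushes them apart.

Defaults follow the regime that works at N ≈ 400: rho = 0.9, eta = 1,
lambda = 100 (10 also works; 1 tends to collapse all particles onto one
point because entropy changes are bounded by log L), L = 10 for
simulation-scale problems and 20 for data-analysis scale.

## Hyperparameters

`fit_hyperparameters` sets the remaining six hyperparameters from data:

1. (nu, lambda) of the `IG(nu/2, nu*lambda/2)` prior are moment-matched to
   the per-unit residual variances `s_i^2` (denominator T-2):
   `nu = 2(2 + m^2/v)`, `lambda = m (nu-2)/nu` for sample mean m and
   variance v. A degenerate v falls back to nu = 6 with lambda chosen to
   preserve the prior mean m (the natural fallback: the general formulas
   also preserve m as v -> 0).
2. Temporary CAR scales come from a k-means partition of the least-squares
   estimates at K = round(eta log N): the between-cluster variance of
   cluster means sets a2 (b2), and the average within-cluster variance
   minus the least-squares sampling noise (m/T for intercepts, m/(T-1) for
   slopes) sets a1 (b1), floored at 1e-3. Separating within- from
   between-cluster spread matters: a provisional a1 tied to a2 (say a2/10)
   is typically orders of magnitude too large, and an overlarge a1 lets a
   merged cluster absorb between-mean steps into its CAR spread, locking
   the search into overly coarse partitions.
3. A MAP search (L = 1, lambda = 1) under the temporary values is followed
   by empirical Bayes: each of a1, a2, b1, b2 is optimized coordinate-wise
   over a 5-point log-spaced grid spanning 1e-2..1e2 times its initial
   value, two passes, keeping the incumbent on ties — so the marginal
   likelihood at the MAP never decreases.

## Synthetic-data generator

The generator reproduces a fixed reference design: a 20 x 20 rook-adjacency
grid (rook chosen; edge-sharing is the natural reading of "shared border"
on a grid), an intercept partition with 10 rectangular connected clusters
of sizes {237, 50, 30, 25, 20, 15, 12, 6, 4, 1} (ASCII map in the module
docstring), and a slope partition with clusters of sizes 188/100/100/12.
The ten intercept clusters share only five distinct means, two clusters per
mean; the two clusters sharing a mean are never spatially adjacent —
adjacent same-mean clusters would be unidentifiable (the posterior
correctly prefers their merge), which would make partition-recovery scores
meaningless.

Cluster-mean gaps define three separation settings: delta_alpha in
{2.0, 1.0, 0.5} and delta_beta in {1.5, 0.75, 0.35} for high/medium/low,
with sigma^2 = 1, T = 12, unit areas, and within-cluster CAR scale
a1 sigma^2 = 0.01. These values make the high setting visually obvious in
the least-squares estimates and the low setting not; at low separation the
posterior favors few large clusters over many similar ones, so low
recovery scores there reflect the posterior, not the search. Counts, when
needed, are `round(sinh(y + log 2))` floored at zero (unit areas).
`simulate_scaled` provides a 10 x 10 analogue (four quadrant intercept
clusters, three slope bands) for quick replication studies.

What the generator does *not* emulate: irregular adjacency graphs and
heterogeneous unit areas of real maps, non-Gaussian/overdispersed counts,
nonlinear trends, and covariates. Passing tests therefore demonstrate
correctness of the machinery and recovery under the stated Gaussian
conditions, not robustness to those real-data features.

## Numerical and design choices

- All comparisons use unnormalized log posteriors on a fixed graph; the
  intractable spatial-truncation constant of the partition prior cancels.
- Prediction and estimation average over *distinct* particles under
  untempered truncated-posterior weights (softmax of log joints); the
  tempered weights are the optimizer's internal quantity and are also
  exposed.
- Strict-improvement acceptance plus deterministic tie-breaks and seeded
  initialization make runs bit-reproducible for a fixed seed.
- Degenerate inputs: T < 3 (no residual degrees of freedom), nonpositive
  areas, missing responses, asymmetric adjacency, and non-spatial
  partitions all raise errors; a non-spatial partition has prior mass zero
  (-inf log prior).

## Problem sizes in the acceptance script

`scripts/acceptance.py` uses sizes chosen to finish in a few minutes on one
CPU while keeping every estimate stable: 50 seeded replicates of the 1 x 4
path enumeration study, 100 random instances for the dense-oracle
comparison, 30 seeded 6 x 6 runs for monotonicity, 3 replicates of the
20 x 20 high-separation design, and 10 replicates of the 10 x 10
medium-separation comparison against the per-unit least-squares baseline.
The test suite runs the larger versions (100 path replicates, 200 oracle
instances, 100 monotonicity runs, 10 high-separation replicates, 20
medium-separation replicates).

## Limitations

- The search is local: global top-L recovery is guaranteed only for the
  variational optimum, not for every run of the greedy optimizer. With L
  larger than the number of well-separated modes, surplus particles settle
  on single-move variants of the top particles.
- Per-unit credible intervals are not produced; uncertainty is summarized
  at the particle level.
- Count likelihoods (Poisson, negative binomial) are out of scope; the
  Gaussian model on transformed densities is exact only for the transformed
  scale.
- The empirical-Bayes grid is coordinate-wise and two-pass; it refines
  scales within four orders of magnitude of the moment-based start, not
  globally.
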