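# Methods

## The model

A plant trait network (PTN) is an undirected, unweighted graph over a
fixed set of functional traits measured on individual plants from one
population (here: one water body). For traits *i*, *j* the Pearson
product-moment correlation r_ij is computed on pairwise-complete
individuals, with the two-sided p-value from the exact transform
t = r·√((n−2)/(1−r²)) on n−2 degrees of freedom. The adjacency rule is

    a_ij = 1  iff  p_ij < α        (α = 0.05 by default, strict inequality)

and a_ij = 0 otherwise; the diagonal is zero. Sign and magnitude of r
are discarded by design — the network records only the presence of
trait coordination. Undefined pairs (a constant trait, or fewer than 3
complete observations) are flagged NaN and never become edges. Raw
p-values are binarised by default; Holm or Benjamini–Hochberg
adjustment is available (`correction=`) but off, because the analysis
this package implements thresholds unadjusted p-values. Ties at exactly
α are measure-zero; strictness is documented rather than consequential.

## Graph metrics and their conventions

All metrics are computed directly from the adjacency matrix
(breadth-first search; Brandes-style shortest-path counting). The
conventions that required a decision:

- **Closeness** is the reciprocal of the *mean* shortest-path length to
  reachable traits — not the reciprocal of the sum, the common library
  default, which differs by a factor of (number reachable). Isolated
  traits get C = 0; in a disconnected graph closeness is computed
  within the trait's component.
- **Betweenness** counts shortest paths through the focal trait with
  endpoints excluded; when several shortest paths tie, each carries an
  equal fraction. Counts are raw per unordered pair (the centre of a
  4-leaf star scores 6); pair-normalisation (÷ (n−1)(n−2)/2) is
  available as an option.
- **Average path length** is the mean over *connected* unordered
  pairs; disconnected pairs are excluded from the mean (and AL is NaN
  for an edgeless network). The field networks this emulates are dense
  enough that the convention rarely binds, but it must be fixed.
- **Average clustering** is the mean over nodes of
  2·(triangles through the node)/(k(k−1)), taking 0 where k < 2.
- **Modularity** is Newman–Girvan: Q = Σ_c (e_c/m − (d_c/2m)²).
  Q of the all-in-one-module partition is exactly 0, and Q = 0 with one
  module per node is reported for an edgeless network.

Module detection defaults to an in-house deterministic greedy
agglomerative maximiser: every trait starts as its own module and the
merge with the largest strictly positive ΔQ is applied repeatedly,
ties broken on the smallest module-index pair. Determinism was
preferred over the marginally better optima of stochastic methods; a
seeded Louvain alternative (via networkx) is selectable. On graphs
small enough for exhaustive search the greedy optimum tracks the true
maximum closely (tested), but it is a heuristic and the detected
module count should always be read alongside Q.

**Hubs and mediators.** Hubs rank by degree, then closeness,
descending; mediators by betweenness. Exact ties fall back to
trait-name order and are flagged. High-degree traits are interpreted
as hubs of phenotypic coordination and high-betweenness traits as
mediators bridging modules; the two roles are kept strictly separate.

## Trait variability

CV uses the sample (n−1) standard deviation over the mean, reported as
a dimensionless ratio (not ×100) — rankings are unaffected by the
convention. CVs are computed per trait within each group; a group's
variability score is the mean of its defined trait CVs. Undefined CVs
(zero mean, <2 observations) are NaN with a warning, excluded from
means, never silently zero. Trait rankings are offered both as the
mean of per-group CVs (default) and pooled across all individuals.
Values are analysed untransformed; distributional transforms belong to
hypothesis tests outside this package's scope.

The light extinction coefficient K = (1/d)·ln(I0/Id) (m⁻¹) is provided
for deriving the underwater light environment from paired PAR readings.

## Regression stages

Across water bodies, each topology metric is screened against each
environmental variable by two-sided Pearson correlation; variables with
p < α proceed. Backward elimination then starts from the full OLS model
and repeatedly drops the predictor with the largest p-value above
`p_remove` (default 0.10, configurable), refitting until all survivors
satisfy the threshold or one predictor remains — a p-value-based
criterion, equivalent to F-to-remove for single-predictor steps. With
one screened variable this is simple regression. Rank-deficient designs
raise an error naming the offending columns. With as few as 7 groups
and 2 predictors the fit is reported with a warning rather than
refused — matching how such field studies are actually analysed — and
`n_obs/predictors < 5` triggers that warning. A perfect fit reports
R² = 1 with the F statistic flagged infinite.

## The synthetic generator

The generator emulates the study design the pipeline expects: 7 water
bodies × 30 individuals × 18 traits (defaults). Traits are drawn from
a multivariate normal whose correlation matrix is block-structured —
ρ_in within planted modules (3 modules by default), ρ_out = 0.05
between — validated positive semi-definite before Cholesky sampling.
Each trait is then mean-shifted at fixed unit variance to hit its
target CV (value = z + 1/CV), an affine map that leaves correlations
untouched. Default CV targets span 0.75 down to 0.10 across traits,
the spread typical of field-collected morphometric and biomass traits,
ordered so stem-branch and biomass-allocation traits are most variable.

A group-level gradient u ∈ [0, 1] drives both the environment and the
correlation strength: TP rises over 0.014–0.055 mg/L (the realistic
oligo-mesotrophic range for these systems), DO falls over 12–6 mg/L,
and ρ_in rises linearly over 0.30–0.80. Environmental readings get 2%
jitter. The generative truth (module partition, per-group ρ_in, the
implied ρ_in-on-TP coefficients, CV targets, seed) is returned with
the data and written as a JSON sidecar. All randomness flows from one
explicit seed.

What the generator does *not* emulate: non-Gaussian trait marginals,
measurement error structure, within-lake spatial autocorrelation, or
any mechanistic growth model. Passing tests therefore demonstrate that
the pipeline recovers planted linear-Gaussian structure, not that real
trait data satisfy those assumptions.

A separate null generator draws fully independent standard-normal
traits; under it the expected fraction of significant pairs equals α
exactly, which calibrates the thresholding rule (the mean null edge
density at α = 0.05 measures 0.0495 over 500 replicates in the
acceptance script at seed 1).

## Numerical and design notes

- Correlation p-values use Student's t survival function; perfect
  |r| = 1 maps to p = 0. A vectorised path handles complete matrices,
  a pairwise loop handles missingness.
- Detected modularity is **not** monotone in ρ_in at the sparse end:
  near-random sparse graphs score high apparent modularity, so the
  detected Q at ρ_in = 0.1 can exceed that at ρ_in = 0.8. The
  modularity of the *planted* partition is monotone and is what the
  property tests assert. Relatedly, at ρ_in = 0.9 each block is nearly
  rank-1, so all between-block sample correlations share one latent
  factor correlation (sd ≈ 1/√n); an occasional large draw makes the
  network near-complete, where the optimal partition is a single
  module with Q exactly 0 (~1–2% of replicates at n = 30).
- The regression-recovery validation uses `p_remove` = 0.01: the
  elimination threshold is the per-decoy retention rate under the
  null, so the default 0.10 retains a pure-noise decoy in ~10% of
  replicates by construction; 0.01 matches the experiment's ≥95%
  joint-recovery bar a priori.
- Validation problem sizes — 500 null replicates, 200 random graphs of
  ≤8 nodes for brute-force comparison, 100 recovery replicates, a 6 ×
  10 ρ-grid — were chosen so every experiment's sampling error is
  small relative to its assertion margin while the whole suite runs in
  seconds.

## Limitations

Binary thresholding makes the network a step function of sampling
noise near α; no weighted or partial-correlation variants are offered.
With 7 groups the environmental regressions have 4–5 residual degrees
of freedom; their p-values are honest but fragile, which is why the
screening stage and the small-n warning exist. Community detection on
dense small networks often returns few modules with low Q — the module
count is algorithm-dependent and should be compared only under a fixed
method.
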