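# Methods

This note documents the statistical machinery in `urbancfd`: what each
stage assumes, which defaults matter, and what the synthetic-data tests do
and do not establish about real atlas data.

## Trait preparation

Raw tables carry five continuous traits (body mass in grams, tail length,
two plumage-colour scores on [0, 1], an ordinal crest class 0–3) and four
binary category groups (social degree: 3, nesting: 5, diet: 6, foraging: 8
categories; categories within a group are not mutually exclusive). Two
traits are derived before scaling:

- **relative tail length** — residuals of an OLS fit of log tail length on
  log body mass. Residuals are mean-zero, so the trait reads "long-tailed
  for its size" independent of size itself.
- **inverse body mass** (1/mass) — the small-size aesthetic proxy for the
  cultural set, used instead of raw mass to avoid collinearity with the
  tail residual.

All continuous traits are min–max scaled to [0, 1]; mass and tail length
are log-transformed first so a few heavy species do not compress the rest
of the range. Constant columns scale to all-zeros rather than NaN: they
carry no dissimilarity information either way, and zeros keep downstream
Gower means well-defined. Scaling is idempotent.

**Collinearity screen.** Within each service's trait set, any pair with
|Pearson r| strictly above the threshold (default 0.70; equality is
acceptable) loses one member — the one with the larger mean absolute
correlation against the other retained columns, a deterministic rule given
column order. The screen is per service because the two sets never enter
the same dissimilarity matrix; correlations between a cultural and a
regulating column are irrelevant to either Gower computation. Correlations
with constant columns are treated as zero.

## Functional space and dispersion

**Gower distance.** For a species pair, each trait group contributes the
mean absolute difference over its member columns; the distance is the mean
of group contributions. Single continuous traits are their own groups.
This gives the eight foraging categories jointly the same weight as one
colour score, which is the intended semantics of grouped categories; a
`group_weighting=False` flag gives every column equal weight instead. With
all inputs in [0, 1], distances are in [0, 1], symmetric, zero-diagonal,
and monotone in any single pair's trait mismatch.

**Neighbour joining.** Classical Saitou–Nei agglomeration. Two
determinism/robustness choices: Q-criterion ties (within 1e-12) are broken
by the lexicographically smallest pair of subtree representative labels
(the smallest tip label each cluster contains), and a negative branch
estimate — possible on non-additive input — is clamped to zero with the
deficit moved to its sister branch, preserving the joined pair's path
length. On additive input the reconstruction is exact: the patristic
matrix of the output reproduces the input to machine precision (tested to
1e-8 over random trees). Trees with ≤ 3 taxa are handled by the closed-form
unique unrooted topologies.

**Dispersion.** Community dispersion is the exhaustive mean of patristic
distances over all unordered pairs of present species — the exact limit of
"average distance of randomly chosen pairs", with no sampling noise.
Presence/absence only; no abundance weighting exists anywhere in the
package. Communities need ≥ 3 species: below that the "mean over pairs" is
a single pair and a biased diversity estimate, so such communities are
filtered before any dispersion computation.

## Corrected functional dispersion

The FD~PD regression is an ordinary least-squares fit with intercept,
pooled over all communities entering the analysis (including the
no-alien variants, so paired values share one regression); residuals are
exactly uncorrelated with PD by construction. The null model applies, per
iteration, one uniform random permutation of species names to **both** the
functional and the phylogenetic tree — a species keeps its community
memberships but moves, jointly, to a random position in both spaces, which
is equivalent to random community composition at fixed richness. An
`shared_permutation=False` flag shuffles the two trees independently for
sensitivity analysis. Within each iteration the FD~PD regression is refit
and its residuals stored, so "expected" values are internally consistent
with the iteration's own dispersion field.

SES uses the sample (n−1) standard deviation of the null residuals. A
degenerate null (sd = 0, e.g. equal-branch star trees where every
permutation is isometric) yields SES = NaN with a `degenerate` flag, never
±infinity.

Implementation note: relabelling tips is a row/column permutation of the
patristic matrix, so the null loop is three einsum contractions per
iteration rather than tree traversals; per-iteration RNG substreams are
spawned from one master seed, making results reproducible and independent
of execution order.

Defaults: 999 iterations (the conventional resolution for a two-sided 5%
test against a permutation null). Calibration under the null — random
communities from an unstructured pool — gives mean SES within ±0.1 of zero
and an |SES| > 1.96 rate of 5% ± 3% (checked at 200 communities × 999
iterations × 3 seeds).

## Community assembly and covariates

Filter order is fixed and logged with counts: FUA-overlap (cell kept when
≥ 50% of its area, boundary inclusive, lies in the FUA union) → optional
per-country occurrence filter → invasion classification (invaded iff ≥ 1
non-native present; empty cells are non-invaded and die at the next
filter) → minimum richness (≥ 3) → income join (cells without any
overlapping income polygon are missing, never zero, and are dropped
listwise from models).

The occurrence threshold is round-half-away-from-zero of
`fraction × n_cells` per country, floored at 1; at the default 1% this
gives 7 of 709 cells and 1 of 111 cells, and "at least" is inclusive. The
rare-species screen is a sensitivity variant, off by default. A species
passing the threshold in either country stays in the shared pool.

Cell income is the overlap-area-weighted mean of neighbourhood median
incomes, which prevents a neighbourhood straddling several cells from
being over-counted; weights are additive under polygon splitting. Incomes
are z-standardized per country (sample sd) so that two national income
distributions with different costs of living share a scale; z-scores are
invariant to currency conversion. All geometry is planar in one projected
coordinate system.

## Mixed models

**Richness (counts).** Negative binomial with log link,
variance = μ + μ²/θ, per-FUA random intercept b ~ N(0, σ²). The marginal
likelihood is maximized with a Laplace approximation: per-FUA posterior
modes found by a vectorized Newton inner loop, outer L-BFGS-B over
(β, log θ, log σ²), standard errors from a central-difference Hessian at
the optimum, and marginal (per-coefficient) Wald χ² tests. σ² at its lower
search bound is reported as 0 with a warning; non-convergence is flagged,
never silent. Calibration: type-I error controlled under a null income
effect; a simulated log-scale slope of 0.3 is recovered within ±0.1 at
n = 500; zero simulated FUA variance is estimated below 0.01.

**CFD (Gaussian).** REML through statsmodels `MixedLM`, same structure.
Per-term tests are approximate F (t², denominator df = n − p − n_FUAs,
containment-style). The optimizer chain starts with Powell at tight
tolerance: the default quasi-Newton path can fail on a singular profiled
system when the variance component approaches its boundary, and Powell also
reproduces the closed-form balanced one-way ANOVA variance components to
< 1e-6 where the quasi-Newton stops at ~1e-5.

**Paired invaded vs invaded-no-alien.** Intercept-only fixed part on the
per-cell CFD (or richness) difference, FUA random intercept retained — the
random structure is kept because the pairs cluster within FUAs exactly as
the cells do. A degenerate case (zero-variance differences) falls back to
the one-sample t construction.

**Overdispersion.** The Poisson analogue (fixed effects only) is fitted;
the sum of squared Pearson residuals is compared with χ² at the residual
df. Ratios near 1 under Poisson data; strong overdispersion (θ = 0.5) is
detected at p < 0.001 essentially always.

**Spatial correlogram.** Residuals are standardized; the correlation at
distance d is the mean cross-product of standardized residuals over cell
pairs in a distance bin (8 bins up to half the maximum pairwise distance,
where pair counts are still dense), smoothed by a 3-bin moving average.
95% envelopes are percentile intervals from bootstrap resampling of cells
(self-pairs of duplicated cells excluded); the verdict is "no spatial
autocorrelation" when every envelope contains zero. Bin count, range cap
and smoothing were chosen so the joint verdict is conservative — on iid
residuals the verdict holds in ≈ all replicates, while a smooth spatial
gradient is flagged at short distances.

## The synthetic-data generator

`SimConfig` encodes the ground truth the pipeline must recover: per-cell
expected richness `baseline_richness × exp(richness_income_slope × z)`
(Poisson draws); native species sampled without replacement with weights
`exp(service_income_slope × z × originality)`, where originality is a
species' mean Gower distance to the pool (z-scored) — a negative slope
makes wealthy cells draw functionally ordinary, mutually similar species;
non-natives occur independently with probability
`logistic(logit(0.05) + invasion_income_slope × z)`, the 5% base rate
chosen so that roughly half the cells are invaded at default pool sizes;
non-natives get a +0.4 shift on both colour scores (conspicuous cage-bird
escapes), which is what makes invaded communities culturally overdispersed.

Defaults (120 species of which 12 non-native, 20 FUAs × 25 cells ≈ 500
communities, slopes +0.3 / +1.0 / −1.0) give each effect a clearly
recoverable but not overwhelming signal at the default study size.
Landscapes are axis-aligned rectangles — overlap areas are exact, so the
income-overlay arithmetic is testable against closed forms; 1–4
neighbourhood strips tile each cell and share a cell-level wealth latent
(lognormal incomes, country-specific location so the per-country
standardization has real work to do).

Traits are drawn **independently of the phylogeny** by default. That makes
the FD~PD correction signal-free — the cleanest possible null for SES
calibration, since any systematic SES shift must then be an artifact. An
optional Brownian mode (`brownian_traits=True`) rank-maps continuous traits
onto a Brownian draw along the tree (covariance = shared path length) for
tests that need real phylogenetic signal while preserving each trait's
marginal distribution.

What the generator does **not** emulate: spatial autocorrelation between
neighbouring cells, species' range cohesion, detection error,
breeding-status grades, abundance, and realistic trait covariance
structures. Passing tests therefore demonstrate the correctness and
calibration of the machinery under the stated generative assumptions, not
the ecological conclusions one would draw from real atlases.

## Problem sizes in the validation suite

The acceptance checks use 200 communities × 999 iterations × 3 seeds for
SES calibration, 50 random 8-tip trees for the NJ inversion bound, all 120
relabelings of a 5-species pool against 999 sampled permutations (KS on
values rounded to 9 decimals so identical atoms coincide in the ECDFs),
25 pipeline replicates at 500 cells with 199-iteration nulls for sign
recovery, and 40 replicates at n = 300 for the overdispersion power check.
Unit tests run the same operations at smaller replicate counts.

## Known limitations

- The NB fitter handles a single scalar random intercept (the design used
  here), not crossed or nested random effects.
- Laplace approximation can bias variance components for very small
  groups (< 5 cells per FUA) with strongly non-Gaussian posteriors.
- The correlogram decision rule is intentionally conservative; it is a
  screening diagnostic, not an estimator of the spatial covariance
  function.
- Gower treats the ordinal crest class as continuous after scaling
  (0, 1/3, 2/3, 1), which assumes equal spacing between classes.
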