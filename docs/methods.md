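# Methods

## The growth model

Annualized diameter growth of focal tree *i* in group *j* is modelled as

y_ij = beta0_j + betaDBH_j * DBH_ij + sum_k lambda_jk * BA_ijk + eps_ij,
eps_ij ~ Normal(0, sigma^2),

with DBH in cm at the first census, growth in cm/yr, and BA_ijk the summed
basal area (pi (DBH/2)^2, cm^2 by default) of all competitor stems of group
*k* within a hard 7.5 m radius of the focal stem. The focal stem is excluded
from its own neighborhood by tag, so other stems of a multi-stemmed
individual do count as competitors; stems exactly at the radius are included
(<=, fixed for determinism). All *J* focal groups are fit jointly in one
block-structured design (p = 2J + J*K columns) sharing a single sigma^2, so
the parameter count is 2J + J*K + 1: 49, 441 and 1369 for J = K = 6, 20
and 36.

Focal trees are stems alive in both censuses, ignoring re-sprouts; each
individual contributes one observation (its largest-DBH stem at the first
census, when a `tree_id` column identifies multi-stemmed individuals).
Negative growth increments are retained as measurement error rather than
censored, which keeps the Gaussian error model honest. Competitor stems are
everything alive at the first census regardless of later fate. Focal trees
near the plot boundary are kept with truncated neighborhoods by default
(`edge_buffer` excludes them instead); truncation does not bias the
synthetic-data studies because the generator builds growth from the same
truncated neighborhoods the fitter sees.

The units choice (BA in cm^2) only rescales lambda: a lambda of -2e-5
cm/yr per cm^2 equals -0.2 cm/yr per m^2 of neighborhood basal area.

## Exact conjugate inference

The joint prior on (beta, sigma^2) is Normal-Inverse-Gamma NIG(mu0, V0, a0,
b0); the posterior is NIG with

mu* = (V0^-1 + X'X)^-1 (V0^-1 mu0 + X'y),
V*  = (V0^-1 + X'X)^-1,
a*  = a0 + n/2,
b*  = b0 + (mu0' V0^-1 mu0 + y'y - mu*' V*^-1 mu*)/2.

Coefficient marginals are multivariate-t(mu, (b/a) V, 2a); sigma^2 is
marginally Inverse-Gamma(a, b). (Some treatments write the Inverse-Gamma on
sigma rather than sigma^2; we follow the standard conjugate convention,
sigma^2 ~ IG.) The posterior predictive at new design X~ is
multivariate-t with location X~ mu*, shape (b*/a*)(I + X~ V* X~'), and
2a* degrees of freedom; fitted/predicted values are its means. Every solve
goes through a Cholesky factorization of the posterior precision
V0^-1 + X'X; no explicit inverse is formed except to report V* itself, and a
numerically singular precision raises an error advising a proper prior
rather than silently pseudo-inverting. On near-perfect fits b* can cancel
catastrophically; it is floored at the smallest positive float rather than
allowed to go non-positive.

Default prior: mu0 = 0, V0 = 100 I, a0 = b0 = 0.01. With growth measured in
cm/yr and BA in cm^2, a prior scale of 10 on every coefficient is effectively
uninformative for intercepts and DBH slopes and overwhelmingly so for
lambda (true values ~1e-5), while still proper — which is what the
permutation and CV refits need when a permuted or subset design makes some
group pair rare. V0 accepts a scalar, a diagonal, or a full matrix.

## Permutation test

H0: lambda_jk = lambda_j for all k (identity-free competition) vs HA: at
least one lambda_jk differs. Under H0 competitor group labels are
exchangeable, so the null distribution of the RMSE between observed and
predicted growth is generated by shuffling the labels across competitor
stems plot-wide, rebuilding the BA covariates, and refitting — B = 99
permutations is the reference configuration. The per-stem basal-area
contribution links are precomputed once (a sparse focal x competitor-stem
matrix), so each permutation's BA rebuild is a single sparse product and
each refit a single Cholesky solve.

p = (1 + #{null RMSE <= observed RMSE}) / (B + 1), one-sided (small RMSE is
evidence against H0); p is never 0 and its floor is 1/(B+1). Two variants
are exposed for sensitivity analysis: `mode="columns"` permutes the BA
column labels instead of individual stems (a coarser exchange), and
`pool="within_focal"` draws an independent stem relabelling per focal group,
since the exchangeability statement is per focal group and the pooling
choice is a judgment call. The statistic can also be the spatially
cross-validated RMSE (`statistic_mode="spatial_cv"`).

## Buffered spatial block cross-validation

Trees are binned into half-open square cells (default 100 m) from the plot
corner; empty cells are dropped, so irregular plots yield partial grids.
Each occupied block serves once as the test set; blocks sharing an edge or
corner with it (queen adjacency — 8 for an interior block, 5 on an edge, 3
in a corner) are the buffer and join neither side; the rest train the model.
Per-block RMSEs are averaged unweighted (a pooled-over-trees RMSE is also
reported). Only growth observations are partitioned: competitor stems are
never deleted, because a focal tree's covariates describe its real
neighborhood. With cell size >= twice the neighborhood radius the buffer
geometrically guarantees that no training tree's neighborhood overlaps any
test tree's neighborhood (asserted in the tests).

A 3x3 grid is degenerate — the center block's buffer swallows all eight
neighbors — so at least a 4x4 arrangement (or >= 3 occupied blocks with no
interior block) is required; the code raises a clear error otherwise.

## Synthetic forests

The generator emulates a temperate ForestGEO-style stand and is the
package's ground-truth harness. Defaults: ~1180 stems/ha above a 3.2 cm DBH
threshold (the density of a well-studied 23-ha oak–hickory plot),
DBH ~ lognormal(log 7 cm, 0.6) truncated at the threshold, group labels
multinomial (uniform by default), growth from the model above with
beta0 in 0.10–0.15 cm/yr, betaDBH in 0.003–0.007 cm/yr per cm,
lambda ~ -2e-5 to -5e-5 cm/yr per cm^2 (deterministic row/column structure,
so identity matters weakly by default), sigma = 0.08 cm/yr, a 5-year census
interval, and 10% independent mortality. Stems are placed uniformly, by a
Thomas cluster process (toroidally wrapped to preserve density), or
uniformly with a smooth Gaussian-bump growth-rate field (`smooth_field`)
that injects the spatially patterned residuals motivating spatial CV — the
tests verify residual autocorrelation is positive under that mode and
absent otherwise.

Noise is applied once per tree on the annual scale and converted to a
second-census DBH; the second census is not re-thresholded (a stem may
shrink below the recruitment threshold through measurement error), and
simulated DBH is floored at 0.1 cm, reachable only under deliberately
extreme competition. `species_per_group` splits each true group into
several species labels with identical dynamics, creating a controlled
overfitting scenario; `h0_spec` flattens each lambda row to its mean,
preserving total competitive load while destroying identity information.

What the generator does **not** emulate: recruitment, size- or
competition-dependent mortality, measurement-error structure beyond iid
Gaussian noise, interannual growth variation, and real spatial aggregation
of conspecifics (labels are iid over stems). Passing tests therefore
certify the estimator, test and CV machinery under the model's own
assumptions — not robustness to the ways real census data violate them.

## Validation studies and sizes

The studies in `treecomp.validation` (also run by `scripts/acceptance.py`)
use these problem sizes, chosen to give tight Monte-Carlo bounds in about a
minute of single-core compute:

- Null calibration: 200 forests of ~1000 focal trees (1 ha), J = K = 4,
  B = 99. Observed rejection at the 0.05 level ~0.03–0.07; p-values
  indistinguishable from uniform (KS).
- Power: 40 forests of ~2000 focal trees with lambda spread ~2e-4 across
  competitor groups (an order of magnitude above the default effect);
  the test attains its minimum p = 0.01 in every run.
- Overfitting: 50 forests of ~600 focal trees from a 3-group truth, fit
  with the 12-species grouping (169 parameters vs 22). CV RMSE exceeds
  in-sample RMSE in 100% of replicates and never ranks the big model ahead
  of the truth (4 ha, 50 m cells, 16 blocks).
- Coverage: 100 forests of ~3000 focal trees, J = K = 4; pooled 95%
  credible-interval coverage ~0.95.

## Numerical and design choices

- Trait clustering uses average-linkage (UPGMA) agglomeration on Euclidean
  distances, with the tree cut by replaying the merge sequence, which
  guarantees exactly k groups under tied heights and makes successive cuts
  nested. Traits are z-scored by default (`standardize=False` for raw
  scales, where plant height dominates the distance); species order is
  fixed lexicographically so results are order-independent.
- The p-value convention adds one to numerator and denominator, keeping the
  test exact and p > 0.
- Ties at the neighborhood radius are included; grid cells are half-open;
  cluster labels, block ids and design columns are all deterministic
  functions of sorted inputs — two runs on the same data are bit-identical.
- The BA contribution matrix is sparse (focal x competitor stems); designs
  are dense by default with a sparse option for very large J.
- Sampling-based checks compare moments within 3 Monte-Carlo standard
  errors; exact identities are asserted at 1e-6–1e-8.
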