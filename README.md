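# treecomp

Neighborhood competition models for repeat-censused forest stem maps.

Large mapped forest plots (ForestGEO-style censuses) record every woody stem
above a size threshold — position, species, and diameter at breast height
(DBH) — at multi-year intervals. A central question in forest ecology is
whether the **identity** of a tree's neighbors shapes its growth, and if so,
at what taxonomic or functional resolution: does each species interact
distinctly with each other species, or do families or trait-based groups
capture the competitive structure just as well with far fewer parameters?

`treecomp` implements the full analysis stack for that question:

1. **A group-structured growth regression.** Annualized diameter growth of
   focal tree *i* in species group *j* is

   *y*<sub>*ij*</sub> = β<sub>0,*j*</sub> + β<sub>DBH,*j*</sub>·DBH<sub>*ij*</sub> +
   Σ<sub>*k*</sub> λ<sub>*jk*</sub>·BA<sub>*ijk*</sub> + ε<sub>*ij*</sub>,
   ε<sub>*ij*</sub> ~ Normal(0, σ²),

   where BA<sub>*ijk*</sub> is the summed basal area of competitor stems of
   group *k* within 7.5 m of the focal tree and λ<sub>*jk*</sub> is the
   pairwise competition coefficient. With *J* focal and *K* competitor
   groups the joint model has 2*J* + *J·K* + 1 parameters.

2. **Exact conjugate Bayesian inference.** With a Normal-Inverse-Gamma prior
   NIG(μ₀, V₀, a₀, b₀) on (β, σ²) the posterior is again NIG in closed form;
   coefficient marginals are multivariate-t and the posterior predictive is
   multivariate-t. No MCMC — a fit is a single symmetric-positive-definite
   solve, which is what makes the two resampling procedures below feasible.

3. **A permutation (exact) test** of H₀: λ<sub>*jk*</sub> = λ<sub>*j*</sub>
   (competitor identity does not matter). Competitor group labels are
   shuffled across stems plot-wide, the basal-area covariates rebuilt, the
   model refit, and the RMSE between observed and predicted growth compared
   with the observed RMSE; p = (1 + #{null ≤ observed}) / (B + 1).

4. **Buffered spatial block cross-validation.** The plot is gridded into
   square blocks; each block in turn is the test set, the queen-adjacent
   blocks are discarded as a buffer against spatial autocorrelation, and the
   model is fit on the rest. Per-block RMSEs are averaged unweighted. This
   exposes the in-sample optimism of over-parameterized groupings.

5. **A synthetic forest generator** with known ground truth (spatial point
   pattern, truncated-lognormal DBH, growth from the model above), so the
   entire stack is testable end to end without access to any real plot data.

The conjugate regression is also exposed as a scikit-learn-style estimator
(`BayesianLinearRegression`) usable in ordinary sklearn workflows, and the
full model as `NeighborhoodGrowthModel`.

## Worked example

Simulate a 4-ha forest with four species groups, fit the growth model, test
whether competitor identity matters, and compare groupings under spatial CV:

```bash
treecomp simulate --out-prefix syn --seed 42 --extent 200 --density 600 --groups 4
# wrote 2442 stems to syn_census[12].csv

treecomp fit --census1 syn_census1.csv --census2 syn_census2.csv \
    --grouping family --outdir run
# n=2226 focal trees, J=K=4, 25 parameters, in-sample RMSE=0.0799 cm/yr

treecomp permtest --census1 syn_census1.csv --census2 syn_census2.csv \
    --grouping family --outdir run -B 99 --seed 1
# observed RMSE=0.0799, p=0.0500 (99 permutations, mode=insample)

treecomp compare --census1 syn_census1.csv --census2 syn_census2.csv \
    --groupings species,family --cell-size 50 --outdir run
# grouping  J  parameters  rmse_insample  rmse_cv
#  species  4          25       0.079922 0.081004
#   family  4          25       0.079922 0.081004
```

Reading the output: the in-sample RMSE (0.0799 cm/yr) estimates the residual
growth noise — the generator's true σ here is 0.08 cm/yr. The permutation
p-value of 0.05 reflects the generator's deliberately weak default identity
signal: competition coefficients differ across competitor groups by only a
few 10⁻⁵ cm/yr per cm² of basal area, near the detection limit at this
sample size. `run/coefficients.csv` holds the posterior mean, marginal-t
scale and degrees of freedom for every coefficient (enough to reconstruct
any credible interval), and `run/residuals.csv` maps residuals by stem
position for diagnosing spatial structure.

The same pipeline runs on real census exports: pass a YAML dialect mapping
your column names (`--config`), a species→family lookup CSV for the family
grouping, or a species×trait table (height, wood density, specific leaf
area) for the trait clustering (`cluster_traits`, UPGMA on Euclidean
distances, cut at *k* groups).

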