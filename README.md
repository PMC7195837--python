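# spaterich

Spatial Bayesian hierarchical Poisson models for plant species richness
along environmental gradients.

Space-for-time gradient surveys are a major source of evidence on how
atmospheric nitrogen deposition (Ndep) affects grassland plant
diversity, but the regression coefficients they yield are sensitive to
omitted covariates, collinear pollutant pairs, and unmodelled
broad-scale spatial autocorrelation. `spaterich` implements the full
analysis chain for plot-level richness counts from such surveys: it is
written for quantitative ecologists who want effect-size estimates (not
stepwise-selected "significant" predictors) from clustered or scattered
quadrat designs on a planar national grid.

## The model

A richness count in plot *i* of 1-km grid square *j* is modelled as

```
y_ij ~ Poisson(λ_ij)
λ_ij = exp( β₀ + Σ_m β_m X_mij + u_j + ω_ij )
```

* `X_m` — covariates rescaled by fixed divisors (altitude per 100 m,
  precipitation per 250 mm, ...) so coefficients have ecological units;
  covariates are never standardised to unit variance, and collinear
  pollutant pairs are retained and reported, never dropped.
* `u_j ~ N(0, θ²)` — an iid intercept per 1-km square (plots within a
  square share fine-scale history).
* `ω` — a zero-mean Matérn (ν = 1) Gaussian *Markov* random field for
  broad-scale spatial autocorrelation, represented by the SPDE/finite
  element approach on a Delaunay mesh over the occupied grid-square
  centroids: sparse precision `Q = τ²(κ⁴C + 2κ²G + G C⁻¹ G)`, range
  `ρ = √8/κ`, marginal sd `σ = 1/(√(4π) κ τ)`.

Inference is empirical-Bayes Laplace (Newton-optimised Gaussian
approximation of the latent field, hyperparameters integrated on an
adaptive rotated grid) with an exact one-block independence MCMC
sampler as a cross-check. Model variants with different spatial error
structures (`mesh_plus_square`, `square_only`, `mesh_only`, `none`) are
compared by DIC, and the random-effect variance is partitioned between
the structured field and the iid square effects. Multiplicative effect
sizes come from exponentiated coefficient quantiles, and partial-effect
curves trace predicted richness along the Ndep gradient with other
covariates at zero.

A synthetic gradient-survey generator (Gaussian-copula covariates with
target ranges and correlations, SPDE field, square effects, Poisson
counts) emulates the two classic UK designs — 68 clustered sites × 5
plots (340 plots, with a 320-plot archived variant) and 883 scattered
plots — so every stage is testable without any data download and
parameter recovery can be measured.

## Worked example

```python
import spaterich as sr

df, truth = sr.preset("sea04", seed=1)          # 340 clustered plots
for name, div in zip(truth.covariate_names, truth.divisors):
    if div != 1.0:
        df[name] = df[name] / div                # divisor rescaling

spec = sr.ModelSpec(covariates=truth.covariate_names,
                    structure="mesh_plus_square")
res = sr.fit(df, spec, mesh_options={"max_edge": 20_000.0})

print(res.summary.round(3))
print(sr.summarize_exp(res, "ndep_total"))
print(sr.dic(res, seed=1).dic, sr.variance_partition(res).percent_structured)
```

prints (abridged)

```
              mean     sd   q2.5  median  q97.5
name
(Intercept)  3.933  0.549  2.856   3.933  5.007
ndep_total  -0.008  0.004 -0.016  -0.008 -0.000
sdep_total   0.004  0.014 -0.024   0.004  0.032
...
(0.99, 0.98, 1.0)
1973.6 100.0
```

The exponentiated Ndep coefficient `(median, q2.5, q97.5) = (0.99,
0.98, 1.00)` reads as "a ~1% loss of species richness per kg N ha⁻¹
yr⁻¹ is most compatible with the data, with no effect inside the 95%
interval" — the generator's truth here is exp(β) = 0.99. The DIC value
is used to compare spatial-error structures, and `100.0` is the share
of random-effect variance attributed to the structured field (the
generating square-effect variance is tiny in this preset).

The same pipeline is available from the shell:

```bash
spaterich simulate --preset sea04 --seed 1 --out plots.csv --truth truth.json
spaterich fit --data plots.csv --covariates ndep_total,sdep_total --out run/
spaterich recover --preset sea04 --replicates 20 --seed 1 --out recovery.csv
```

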