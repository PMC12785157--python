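# paleochron

Bayesian divergence-time estimation for multigene supermatrices, built
around the calibration-strategy experiments used in deep-time plant
phylogenomics: soft-bounded fossil calibrations, a birth–death time prior,
an independent-rates relaxed clock, and approximate-likelihood MCMC dating
— together with the supermatrix diagnostics (GC heterogeneity, codon-usage
PCA, partition schemes), RELL-based topology tests, and synthetic-data
generators that let every stage be validated end to end without any
external data.

It is a library: you drive it from Python (see `examples/`), typically on
a fixed rooted topology with per-gene codon alignments and a fossil
calibration table.

## The model

For a rooted tree with fixed topology, internal-node ages
**t** (Ma), per-branch rates **r** (substitutions/site/100 Ma), locus mean
rate μ and log-rate variance σ², the posterior is

```
p(t, r, μ, σ² | D) ∝ f(t) · Γ(μ; a_μ, b_μ) · Γ(σ²; a_σ, b_σ)
                      · ∏_b LN(r_b; μ, σ²) · L(D | ℓ)
```

* **Time prior `f(t)`** — each calibrated node carries a soft-bounded
  uniform density: constant on `[t_min, t_max]`, a power-law lower tail
  with mass `pL` (`pL = 1e-300` makes the minimum effectively hard,
  `pL = 0.1` gives a soft minimum), and an exponential upper tail with
  mass `pU = 0.025`; uncalibrated nodes follow the birth–death-with-
  sampling kernel (λ, μ, ρ — e.g. λ = μ = 1, ρ = 0.0012 yields a nearly
  uniform kernel) conditional on the root age.
* **Clock** — rates are i.i.d. lognormal with `E[r] = μ` and
  `Var[log r] = σ²`; hyperpriors are gamma with shape/rate parameterisation
  derived from a target mean m and SD s as `a = (m/s)², b = m/s²` (so
  m = s = 0.03 gives the `Gamma(1, 33.3333)` rate prior, mean
  0.03/site/100 Ma); σ² ~ `Gamma(1, 10)` by default, `Gamma(10, 10)` for
  the high-heterogeneity variant.
* **Likelihood** — branch lengths `ℓ_b = r_b · Δt_b/100` enter either the
  exact GTR+Γ(+I) pruning likelihood or, by default, its second-order
  surrogate `logL(ℓ̂) + gᵀ(ℓ−ℓ̂) + ½(ℓ−ℓ̂)ᵀH(ℓ−ℓ̂)` around the
  branch-length MLE (gradient g, Hessian H).

Sampling is Metropolis-within-Gibbs with bounded age slides, rate and
hyperparameter multipliers and an age-scale/rate-inverse-scale mixing
move.  Running without data (`use_data=False`) yields the *effective time
prior*; stepping-stone sampling over a 32-level power-posterior ladder
estimates marginal likelihoods for clock-model comparison.

## Worked example

`examples/03_date_with_calibrations.py` simulates a 10-taxon dataset
(true focal-node age 716 Ma), fits the likelihood surrogate, and runs
posterior and effective-prior chains:

```
         mean  hpd_low  hpd_high  prior_mean
node
node10  985.0    749.0    1179.0       935.0
node11  729.0    540.0     904.0       740.0
node12  293.0    182.0     415.0       426.0
...

focal node: true age 716 Ma, posterior mean 729 Ma,
prior/posterior overlap 0.95
infinite-sites slope 0.553 (R^2 0.91)
```

`mean` and the HPD columns are posterior node ages in Ma; `prior_mean` is
what calibrations and the tree prior alone imply.  The focal posterior
mean lands within 2% of the truth, and the infinite-sites slope (HPD width
regressed through the origin on posterior mean age) quantifies how much of
the remaining uncertainty is calibration-driven rather than data-driven.

The other examples cover supermatrix diagnostics (`01`), dataset
simulation and serialisation (`02`), the seven calibration strategies and
the over-tight-maximum phenomenon (`04`), and the KH/bp-RELL/c-ELW/AU
topology tests (`05`).

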