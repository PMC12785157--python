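# Methods

This note documents the models, numerical conventions and design choices
behind paleochron, and what the synthetic validation does and does not
establish about behaviour on real data.

## Units and containers

Ages are in Ma everywhere a user sees them; rates are substitutions per
site per 100 Ma, so branch lengths in expected substitutions are
`r · Δt/100`.  Birth–death rates share the 100-Ma unit.  Trees are stored
as flat parent/age arrays (`TimeTree`) with tips first; branch lengths are
always derived as age differences, so a tree cannot carry inconsistent
lengths.  Newick I/O goes through dendropy, alignments through Biopython.

## Calibration densities

A calibration on the MRCA of two anchor tips uses the soft-bounded
uniform family.  With interior height `h = (1 − pL − pU)/(t_max − t_min)`:

* lower tail on `(0, t_min)`: `f(t) = (θ pL / t_min)(t/t_min)^{θ−1}` with
  `θ = h·t_min/pL`, giving mass `pL` and continuity at `t_min`.  With
  `pL = 1e-300` the minimum is effectively hard (θ ≈ 10³⁰⁰ and the tail
  density underflows to zero);
* upper tail on `(t_max, ∞)`: exponential with rate `h/pU`, giving mass
  `pU` (default 0.025) and continuity at `t_max`.

The whole density integrates to 1 (verified by quadrature in the tests).
A maximum-only constraint (used for the root, default `< 3500` Ma) is the
`t_min → 0` case; it is soft by default, with a hard-cap option.  A
minimum-only variant uses an exponential body above `t_min` with scale
`max(t_min, 1)` — a shape choice of this package, since only the tail
masses are externally prescribed.

## Birth–death node-age kernel

Uncalibrated interior nodes follow the birth–death-with-species-sampling
kernel conditional on the root age `t₁`:

```
g(t) = λ p₁(t) / v(t₁),   p₁(t) = ρ⁻¹ P(0,t)² e^{(μ−λ)t},
P(0,t) = ρ(λ−μ) / (ρλ + (λ(1−ρ) − μ) e^{(μ−λ)t}),
v(t₁) = 1 − P(0,t₁) e^{(μ−λ)t₁}/ρ,
```

with the λ = μ limit `g(t) = (1 + ρλt₁)/(t₁ (1 + ρλt)²)` taken
analytically when |λ−μ| < 1e−12.  With λ = μ = 1 and ρ = 0.0012 the
kernel is close to uniform on `(0, t₁)`.  Sampling uses inverse-CDF
interpolation on a 4097-point trapezoid grid.

The joint time prior is the sum of calibration log-densities at
calibrated nodes plus kernel log-densities at uncalibrated nodes, with
−∞ for any parent-younger-than-child configuration.  The order-statistics
factor of the full conditional birth–death construction is omitted; for a
fixed topology this changes the effective prior only through the
interaction already induced by the ordering constraints.  Because nested
calibrations truncate each other, the *effective* (marginal) prior at a
node generally differs from its user density; both are exposed — the
effective prior is sampled by running the chain with `use_data=False`.

## Likelihood and its surrogate

Exact likelihoods use Felsenstein pruning with site-pattern compression,
IUPAC ambiguity codes as state-presence vectors, and per-category scaling
to avoid underflow.  The discrete gamma uses 4 equal-probability
categories with analytically computed category means (incomplete-gamma
formula); a proportion of invariable sites is a fifth zero-rate class,
with variable-class rates rescaled so the mean rate stays 1.

Under a reversible model the likelihood depends only on the unrooted
tree, so the two root-child branch lengths are pooled into a single
parameter.  Branch-length MLEs are obtained by L-BFGS-B on that parameter
vector (natural scale, lower bound 1e−8); the gradient uses central
differences with step `1e−5·max(|b|, 0.01)` and the Hessian central
differences with step `1e−4·max(|b|, 0.01)`, symmetrised.  The surrogate
is the second-order expansion at the MLE.  Near-zero MLEs sit on the
boundary; the dating model only ever evaluates the surrogate at
nonnegative branch lengths (age ordering guarantees this), which is the
projection onto the nonnegative orthant.  A practical consequence: nodes
subtending near-identical sequences can have posteriors hugging age zero
— real pipelines share this behaviour, and deep calibrated nodes are
unaffected.  No branch-length transform is applied before expansion; a
transform hook would change surrogate accuracy far from the MLE.

## MCMC

Metropolis-within-Gibbs over internal ages, per-partition branch rates,
locus mean rates and σ².  Moves per sweep: a bounded uniform slide for
each internal age (reflected into the parent/children interval; the root
has no upper reflection), a log-scale multiplier for each branch rate and
each hyperparameter, and a whole-tree mixing move that multiplies all
ages by c and divides all rates (and μ) by c with the appropriate
Jacobian.  Proposal widths adapt in batches of 50 toward acceptance 0.3
(slides, mixing) or 0.4 (multipliers) during burn-in only — the first 25%
of iterations, which is also the discard fraction — and are frozen
afterwards to preserve detailed balance.  Initial ages are the input
tree's if feasible, otherwise a level-based ladder pushed above all hard
minima; rates start at the prior mean.

In effective-prior mode the branch rates are redrawn exactly from their
conditional prior each sweep (an exact Gibbs step — ages are independent
of rates under the prior) and the likelihood code path is never executed,
which an internal counter asserts.

Per-partition models (the 3-codon-position variant) carry independent
surrogates, rates, μ and σ² per partition.  The autocorrelated-rates
model is a minimal reference implementation (log r_child ~
Normal(log r_parent − s/2, s), s = σ²Δt) used only for the stepping-stone
comparison.

## Stepping-stone sampling

The ladder is `β_k = (k/K)^{1/0.3}` (quantiles of Beta(0.3, 1)), K = 32
by default, concentrating levels near β = 0.  Ratio k is estimated by
importance weighting samples drawn at the lower level (β = 0 is the
prior, where log-likelihood draws are evaluated on prior samples with
rates redrawn from their conditional prior).  High-variance ratio terms
trigger a warning (adjacent power posteriors barely overlap).  The
combiner is exact for a constant likelihood and recovers the closed-form
evidence of a conjugate normal–normal toy within 0.1 log units at 10 000
iterations per level (tested).

## Calibration strategies and diagnostics

The seven named strategies are encoded as pure data over a flagged
calibration table: the A subset (22 fossils), the early-embryophyte
maximum (conservative 515.5 Ma vs relaxed 1042 Ma; the conservative bound
is quoted as both 515 and 515.5 in different sources — 515.5 is used,
with 515 understood as the same setting), the crown-node minimum (469 Ma
hard vs 940.4 Ma soft with pL = 0.1), the three uncertain algal fossils
dropped in B2 (Pterospermella, Palaeastrum, Trochiliscus), three
codon-position partitions in B3, and σ² ~ Gamma(10,10) in B4.  Nodes
sharing the early maximum are marked by an explicit flag rather than
inferred from topology.  Sensitivity gradients S1–S4 drop calibrations at
or below Order, Class and Phylum rank in turn; agreement is summarised by
Pearson correlation of posterior mean ages (the correlation flavour is a
package choice) and mean absolute age difference against S1.

Prior/posterior overlap is the integral of the pointwise minimum of two
Gaussian KDEs on a shared 512-point grid (an overlap coefficient in
[0, 1]).  The infinite-sites regression fits HPD width against posterior
mean age through the origin (`slope = Σxy/Σx²`) with uncentred R².

## Topology tests

Per-site log-likelihoods are computed once per topology with branch
lengths ML-optimised per tree; bootstrap replicates resample site columns
without re-optimisation (RELL).  KH is two-sided with a normal
approximation on the centred RELL null of the log-likelihood difference
to the best tree; bp-RELL counts replicate wins, with exact ties split
equally among tied trees (deterministic, and unbiased in expectation);
c-ELW averages normalised likelihood weights.  The AU test uses ten
bootstrap scales 0.5–1.4, fits `z(r) = d√r + c/√r` to
`z = Φ⁻¹(1 − BP_r)` by weighted least squares (binomial/delta-method
weights) and reports `p = 1 − Φ(d − c)`; a tree that never (always) wins
at any scale receives p = 0 (p = 1), the standard degenerate-case
convention.  Defaults: B = 10 000 per scale, warning below B = 1000.

## Synthetic data: what it emulates, what it does not

The generator produces ultrametric birth–death trees conditioned by
rejection on the root age and on an exact sampled-tip count (with uniform
binomial tip subsampling at fraction ρ and the requirement that both root
children retain sampled descendants; bounded at 10 000 attempts),
i.i.d. lognormal branch rates, and root-to-tip GTR+Γ(+I) sequence
evolution with per-codon-position rate multipliers (normalised to mean 1)
and lineage-specific equilibrium GC implemented as a single frequency
switch on each lineage's stem branch.  Calibrations are built from true
node ages as `[min_frac·t, max_factor·t]` brackets, with a deliberate
`tight_max` mode placing the maximum below the truth.  A convenience
(`bd_for_target`) chooses birth–death rates whose expected survivor count
matches the requested tip count, keeping the rejection step efficient.

Not emulated: indels and alignment error, codon and amino-acid models,
RNA editing, horizontal transfer, continuous compositional drift (the
switch is a one-off), fossil misassignment, and non-contemporaneous tips.
Passing tests therefore demonstrate correctness of the machinery under
its own assumptions — hard bounds respected, effective priors matching
analytic densities, nominal HPD coverage, qualitative bound/removal
phenomena — not robustness to the model violations real data carry.

## Validation problem sizes

The statistical experiments run at sizes chosen to keep the full suite
in minutes while leaving the Monte-Carlo margins comfortable: the
effective-prior fidelity check uses a 3-tip tree and 100 000 retained
samples (KS < 0.02); the over-tight-bound contrast uses 10 replicate
12-taxon datasets of 900 sites with a 900-Ma focal node and maximum
bounds at 0.6× and 1.2× of the truth (mirroring the 515-vs-1042 geometry
against an ≈875-Ma node); calibration removal uses one 14-taxon dataset
with bracketing calibrations on every internal node; coverage uses 20
replicate 8-taxon datasets of 600 sites at σ² = 0.25.  Chains are 6 000
iterations with 25% burn-in and thinning 5, which passes the dual-run
HPD-overlap and ESS > 100 convergence gate on these problem sizes.

## Known limitations

* The quadratic surrogate is exact only near the MLE; strongly
  prior-data conflicted runs (the deliberate tight-bound scenario) push
  branch lengths away from the MLE, where the surrogate deforms the
  likelihood — the same caveat applies to any approximate-likelihood
  dating.
* ρ enters the kernel as stated (0.0012); deriving it as a sampled
  fraction of described species would give a slightly different value,
  and the kernel is insensitive to the difference.
* The sampler is a straightforward pure-Python implementation; for
  hundreds of taxa the per-sweep cost grows linearly in nodes and the
  defaults (iterations, thinning) need scaling up, as any full-matrix
  reanalysis with long chains would do.
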