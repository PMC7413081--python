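# Methods

## Model

A site model is the quadruple (substitution matrix, frequency source,
across-site rate variation, invariable-sites class). The chain state is
(time tree, clock, site model, Yule birth rate λ), and the posterior is
sampled by Metropolis–Hastings with the trans-dimensional moves described
below.

**Substitution process.** Exchangeabilities `Q` (symmetric, zero diagonal)
come from one of 15 packaged empirical models; the rate matrix is
`R = Q diag(F)` with the diagonal set so rows sum to zero, rescaled so the
expected substitution rate at stationarity is 1 — normalization is applied
after composing with the *active* frequency vector, so switching the
frequency source rescales `R` and branch lengths keep meaning expected
substitutions per site. Transition probabilities use the symmetrized
eigendecomposition `diag(√F) R diag(1/√F) = U Λ Uᵀ`, so
`P(t) = diag(1/√F) U e^{Λt} Uᵀ diag(√F)`; negative round-off is clipped at
zero and rows renormalized, with deviations of a row sum beyond 1e-9 from 1
treated as an error.

**Packaged matrices.** The 15 matrices were taken from the canonical
published sources as distributed with mainstream phylogenetics software, in
the standard lower-triangle text dialect (19 rows of exchangeabilities, 20
frequencies, `#` comments). Frequencies are renormalized to sum exactly to
1 at load; the raw file values (3–9 decimal rounding, per-model sums
0.9999999–1.000001) are retained, and the pooled-frequency summary uses the
**raw** pool — 300 values spanning 0.006–0.169 with mean 0.0500000. A
sha256 checksum per file (`data/checksums.json`) makes drift detectable.
The registry order is alphabetical-as-documented and the model indicator is
1-based everywhere a human sees it.

**Across-site rates.** The discrete gamma uses k = 4 equal-probability
categories by default. The default discretization is the **quantile
midpoint (median) rule** — category i gets the gamma quantile at
(2i−1)/(2k), rescaled to mean exactly 1 — which is the convention of the
mainstream Bayesian phylogenetics implementations and reproduces the
published collapse behaviour of the slow categories (slowest rate below
1.5e-4 already at shape 0.19, which the mean-per-bin rule does not give).
The mean-per-bin rule is available as
`rule="mean"` and is verified against numerical quadrature. With an
invariable class present, gamma rates are divided by (1 − p_inv) so the
full mixture keeps mean rate 1.

**Identifiability and the α prior.** At small shape the slow categories are
effectively rate zero: at α = 0.001 three of the four categories are
numerically zero, so the probability that a site is identical across all
tips approaches 3/4 — a +G model imitating p_inv = 0.75. This is why the
shape prior is an Exp(1) truncated below 0.1 (density renormalized over
[0.1, ∞)); `prob_invariable_site` computes the tip-identity probability by
pruning with every tip clamped to each residue in turn.

**Clock.** Strict, or uncorrelated lognormal: mean-one lognormal (meanlog
−s²/2 for sdlog s = `ucld_stdev`) discretized into one equal-probability
category per branch with bin-mean rates (so the categories average exactly
1); per-branch category assignments are uniform-prior MCMC state.

**Tree prior.** Conditioned pure-birth density
`log P = (n−1) log λ − λ (Σ_internal h_i + h_root)` (root counted twice).
The matching simulator spends Exp(kλ) with k lineages for k = 2..n, the
n-lineage interval ending at the present, splitting a uniformly chosen
lineage at each event; the equivalence of simulator and density is checked
algebraically (the interval reparameterization has unit Jacobian and
Σ k e_k = Σ h_i + h_root) and empirically by a two-sample test in the test
suite. Under the study hyperprior (λ lognormal with arithmetic real-space
mean 5.5 and log-sd 0.048, so meanlog = ln 5.5 − 0.048²/2) the implied
mean 16-taxon root height is (H₁₆ − 1)·E[1/λ] ≈ 0.434 substitutions/site.

**Hyperpriors.** `ucld_stdev` ~ Gamma(shape 0.5, scale 0.4) (mean 0.2);
p_inv ~ Beta(1, 4); estimated frequencies ~ Dirichlet(4,…,4) (component
mean 0.05, closely matching the pooled empirical-frequency distribution).

## Likelihood

Felsenstein pruning over the 20-state alphabet; `-`, `X` and unrecognized
letters are fully ambiguous (all-ones tip partials), so an all-gap column
contributes exactly 0 to the log-likelihood. Partials are rescaled by
their per-site maximum at every internal node with the log factors
accumulated separately, which is underflow-proof for alignments of
thousands of sites. Mixture categories are combined per site with
log-sum-exp. The engine caches the eigendecomposition of `R` keyed by
(model indicator, frequency vector) and recomputes partials per
evaluation: at the study scale (≤16 taxa, ≤250 sites) a full recompute is
a few milliseconds and avoids the bookkeeping risk of fine-grained partial
invalidation; the cache never affects values, only speed.

## MCMC

One seeded generator drives every stochastic decision in a fixed order, so
runs are bit-reproducible. Operators are drawn weight-proportionally:

* **indicator**: uniform re-draw over 1..M (symmetric; the current value may
  be re-proposed).
* **birth/death** for +G and +I: toggling the flag samples the newborn
  parameter from a density d (default: its prior). The proposal-density
  term enters the acceptance ratio as −log d(α′) for birth and +log d(α)
  for death (Jacobian 1), so with d equal to the prior the acceptance
  reduces to likelihood ratio × flag-prior ratio — the sample-from-prior
  reversible-jump identity. When a flag is off the parameter is excluded
  from the prior (the dimension genuinely drops) and its scale operator
  reports not-applicable.
* **frequency source bit flip**: Kuo–Mallick stochastic variable selection.
  The estimated vector persists across toggles and keeps its Dirichlet
  prior whether or not it is active, so the latent vector has a proper
  stationary density and the flip is an ordinary fixed-dimension move.
* **gated scale** moves for α (re-truncated at 0.1) and p_inv, plus scales
  for λ and `ucld_stdev`; the kernel multiplies by s uniform on
  [β, 1/β], β = 0.75 by default, with Hastings −log s. No auto-tuning, for
  reproducibility.
* **delta exchange** on the frequency simplex (δ uniform on (0, window),
  window 0.05; reject if a component would leave [0,1]).
* **AVMN**: additive log-ratio transform of the simplex, Gaussian random
  walk with covariance (2.38²/19)·(Σ̂ + 1e-6 I) where Σ̂ is the running
  covariance of the transformed chain history, used only after a 200-sample
  adaptation window (before that, an isotropic 0.05-step walk); Hastings is
  the log-Jacobian difference Σ log f′ − Σ log f.
* **tree moves**: whole-tree scale (Hastings (k−2) log s for k scaled
  heights), root scale, uniform internal-height re-draw, narrow exchange
  (NNI; symmetric selection, Hastings 0), wide exchange (non-ancestral
  subtree swap). This set is ergodic over ranked topologies at study scale;
  prune–regraft style moves were left out as redundant for ≤16 taxa.
* **clock moves**: uniform re-draw of one branch category; `ucld_stdev`
  scale.

Default weights put roughly 60% of proposals on tree/clock moves (scale 3,
root 2, heights 5, narrow 3, wide 1, categories 3, ucld 1, λ 1) and weight
1 on each site-model move (0.5 on each gated scale); the two frequency
operators both get weight 1, making them equally likely, which is also the
setting used for their efficiency comparison.

**Validation.** The strongest check the design supports is prior recovery:
with the likelihood disabled, the full operator mix must reproduce every
marginal prior. The test suite runs a 150k-step likelihood-off chain and
tests α (truncated exponential), p_inv (Beta(1,4)), the indicator (uniform
over 15), all three flags (50/50), the birth rate (lognormal), `ucld_stdev`
(gamma), one frequency component (Beta(4,76)), and the tree height
(two-sample test against the direct Yule simulator), thinning to the
autocorrelation-based effective sample size and testing at the 1% level.

## Simulator and the well-calibrated study

Truth is sampled **directly** from the prior (the prior factorizes given
the condition flags), not by a long MCMC from the prior; the prior-recovery
property guards the equivalence of the two routes. Sites in the invariable
category are simulated with rate exactly 0 (the child copies the parent),
never by post-hoc masking. The eight study conditions are the
with/without combinations of +G, +I and +F; the defaults are 16 taxa and
200 sites per alignment (the published study text says 200; its table
caption says 250 — `n_sites` is a config key, default 200).

The driver samples truth, simulates, re-infers with the same priors, and
tabulates per quantity the percentage of replicates where the truth falls
in the 95% HPD interval (continuous quantities and tree height) or 95%
credible set (model indicator, flags); rows a condition does not
parameterize are marked `x`. Coverage at N replicates is Binomial(N,
0.95), so the scaled-down script checks entries against the exact binomial
99% band. An oracle mode substitutes fresh prior draws for the posterior,
for which 95% coverage holds by construction — the calibration identity
used to test the bookkeeping separately from the sampler. Inference
failures are recorded per replicate, never fatal to the study.

## Summaries

HPD is the shortest-window estimator on sorted samples (earliest window on
ties); the credible set adds values by descending posterior frequency
(ties toward the smaller value) until the level is reached; ESS is
n/(1 + 2Σρ_k) with the autocorrelation sum truncated by the initial
positive-sequence rule, zero-variance series defined to have ESS n.
Clades are keyed by tip-label sets; the max support difference scans the
union of clades excluding the root clade. Default burn-in is 10% of
samples everywhere, configurable.

## What the simulator does and does not emulate

Simulated data are generated under exactly the inference model — the same
empirical matrices, discrete-gamma rates, invariable class, relaxed clock
and Yule prior. Passing the calibration study therefore demonstrates
self-consistency of the implementation (correct proposal ratios,
likelihood, and interval estimators), not robustness to real-data
violations: no among-site compositional heterogeneity, no alignment error,
no selection or covarion dynamics, and single-partition data only.

## Problem sizes and numerical choices

Test-suite runs use reduced sizes chosen as the package's own defaults for
desk-scale validation (4–16 taxa, 40–300 sites, chains up to 150k states;
the calibration band checks at 20 replicates live in scripts). Tip
partials are rescaled at every internal node; transition-matrix row sums
must be within 1e-9 of 1; simplex vectors are validated to 1e-9 and
renormalized before density evaluation; `p_inv = 1` and zero frequencies
are domain errors (they make R reducible). The Hastings convention for the
birth/death moves is fixed by requiring the sample-from-prior identity and
verified by prior recovery rather than taken from any verbal description.

## Known limitations

* No weighted mixtures of matrices, per-site model categories, free-rate
  models, or matrix-per-category mixtures; no coalescent or
  birth-death-sampling tree priors; no multi-partition support.
* No Metropolis coupling or checkpointing; chains are single-threaded.
* The AVMN operator learns a full 19×19 covariance although frequency
  components are nearly uncorrelated in practice; this costs little and is
  kept for fidelity to the adaptive-operator design.
* `ucld_stdev` coverage uses the per-branch category discretization; exact
  lognormal quantile parameterizations would differ slightly.
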