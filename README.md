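# aamava — Bayesian amino-acid site-model averaging

Choosing a site model for a Bayesian phylogenetic analysis of protein
sequences (which empirical substitution matrix? gamma rate heterogeneity?
invariable sites? empirical or estimated frequencies?) is usually done ad
hoc or with a separate likelihood-based model test, so model uncertainty
never reaches the posterior. `aamava` instead **averages over the site
model during the MCMC itself**: the sampler jointly infers the tree, the
clock, and a trans-dimensional site model, and every downstream estimate
(clade supports, node heights, rate parameters) automatically integrates
over site-model uncertainty.

It is a pure-Python library for phylogenetics researchers and method
developers, with a thin `aamava` command-line wrapper.

## The model

Per site, evolution follows a reversible 20-state CTMC with rate matrix

```
R = Q diag(F),   normalized so  -sum_i F_i R_ii = 1,
P(t) = exp(R t)
```

where the exchangeability matrix `Q` is one of 15 packaged empirical
models (Blosum62, CpREV, Dayhoff, DCMut, FLU, HIVb, HIVw, JTT, LG, MtArt,
MtMam, mtREV, RtREV, VT, WAG), selected by an integer **model indicator**
`I_M` that the chain resamples; `F` is either the chosen model's empirical
frequency vector or a frequency vector estimated from the data (a bit-flip
switches between the two, the estimated vector persisting while unused).
Across sites, rates are a mixture of an optional zero-rate invariable
class (weight `p_inv`) and an optional 4-category discrete gamma (shape
`α`); both classes are toggled by birth/death reversible-jump moves that
sample the newborn parameter from its prior. Tree and clock are a Yule
(pure-birth) time tree with an uncorrelated lognormal relaxed clock.

Priors: uniform over models and over each inclusion flag; Dirichlet(4,…,4)
on estimated frequencies; Beta(1,4) on `p_inv`; Exp(1) truncated below 0.1
on `α` — the truncation matters because below `α ≈ 0.1–0.2` the slow gamma
categories collapse to effectively zero rate and mimic invariable sites,
destroying identifiability of `α` and `p_inv`.

The likelihood is Felsenstein pruning with per-node rescaling; frequency
estimation uses a delta-exchange move and an adaptive multivariate-normal
(AVMN) random walk in log-ratio coordinates whose covariance is learned
during the run.

A simulator draws truths from the prior and simulates alignments, and a
**well-calibrated study driver** re-infers each simulated data set with the
same priors and tabulates how often the 95% HPD intervals / credible sets
cover the truth (they should ~95% of the time, binomially distributed).

## Worked example

```python
import numpy as np, aamava as am

rng = np.random.default_rng(12)
registry = am.builtin_registry()
truth = am.sample_prior_replicate(am.Hyperparameters(), am.StudyCondition(),
                                  rng, n_taxa=6, clock_kind="strict")
aln = am.simulate_alignment(truth.tree, truth.clock, truth.site, 300, rng)

cfg = am.RunConfig(chain_length=40_000, log_every=40, clock_kind="strict")
res = am.run_chain(cfg, seed=13, alignment=aln, registry=registry)
tr = res.trace.iloc[200:]                      # 20% burn-in
print(tr.modelIndicator.value_counts(normalize=True))
print(am.hpd_interval(tr["treeHeight"], 0.95))
```

Running this (it is `examples/04_inference.py`) prints

```
truth: model JTT, tree height 0.347, birth rate 5.49
posterior model support (801 samples):
  JTT        100.0%
95% credible set: ['JTT']  (contains truth: True)
treeHeight: 95% HPD [0.320, 0.445], truth 0.347, ESS 538
birthRate: 95% HPD [4.974, 5.981], truth 5.492, ESS 332
```

i.e. from 300 simulated sites the sampler puts all posterior mass on the
true substitution model, and the 95% HPD intervals for tree height and
birth rate contain the true values. The other scripts in `examples/`
walk through the registry and gamma collapse, simulation + likelihood,
prior sampling, the coverage study, and clade-support comparison; each
prints what it computes and what the numbers mean.

## Command line

```sh
aamava simulate --seed 5 --n-taxa 16 --n-sites 200 --condition +G+I --out rep
aamava run rep.fasta --seed 7 --out chain          # trace + NEXUS tree log
aamava summarize chain.log --burnin 0.1            # HPD / ESS / credible set
aamava compare-clades a.trees b.trees
aamava coverage-study --seed 1 --config study.json --out coverage.tsv
```

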