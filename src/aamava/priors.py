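"""Prior densities for the averaged site model, tree, and clock.

The joint prior factorizes as:

* uniform over the model indicator and over each inclusion flag
  (gamma heterogeneity, invariable sites, estimated frequencies);
* Dirichlet(4, ..., 4) on estimated frequencies (only when in use);
* exponential(rate 1) truncated below 0.1 on the gamma shape alpha (only
  when gamma heterogeneity is on) -- the truncation is what keeps alpha and
  the proportion of invariable sites jointly identifiable;
* Beta(1, 4) on the proportion of invariable sites (only when on);
* a conditioned pure-birth (Yule) density on the time tree;
* a lognormal hyperprior on the Yule birth rate (arithmetic real-space
  mean 5.5, log-space sd 0.048) and a Gamma(shape 0.5, scale 0.4) prior
  (mean 0.2) on the relaxed-clock ucld_stdev;
* uniform over relaxed-clock branch-rate category assignments.

Parameters whose flag is off are excluded from the prior entirely (the
dimension drops, matching the birth/death trans-dimensional construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .sitemodel import SiteModelState
from .tree import TimeTree

__all__ = [
    "Hyperparameters",
    "YuleParams",
    "truncated_exp_logpdf",
    "beta_logpdf",
    "symmetric_dirichlet_logpdf",
    "lognormal_logpdf",
    "gamma_logpdf",
    "log_prior_site_model",
    "yule_log_density",
    "log_prior_joint",
]


def _lognormal_meanlog(real_mean: float, sdlog: float) -> float:
    """meanlog of a lognormal specified by its arithmetic (real-space) mean."""
    return math.log(real_mean) - 0.5 * sdlog * sdlog


@dataclass(frozen=True)
class Hyperparameters:
    """Hyperparameters of all priors, with the study defaults."""

    dirichlet_concentration: float = 4.0
    pinv_beta: tuple[float, float] = (1.0, 4.0)
    alpha_rate: float = 1.0
    alpha_lower_bound: float = 0.1
    birthrate_real_mean: float = 5.5
    birthrate_sdlog: float = 0.048
    ucld_stdev_shape: float = 0.5
    ucld_stdev_scale: float = 0.4

    def __post_init__(self) -> None:
        for name in ("dirichlet_concentration", "alpha_rate", "birthrate_real_mean",
                     "birthrate_sdlog", "ucld_stdev_shape", "ucld_stdev_scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.alpha_lower_bound < 0:
            raise ValueError("alpha_lower_bound must be >= 0")

    @property
    def birthrate_meanlog(self) -> float:
        return _lognormal_meanlog(self.birthrate_real_mean, self.birthrate_sdlog)


@dataclass(frozen=True)
class YuleParams:
    """Pure-birth tree-prior parameter."""

    birth_rate: float

    def __post_init__(self) -> None:
        if not self.birth_rate > 0:
            raise ValueError("birth rate must be positive")


def truncated_exp_logpdf(x: float, rate: float = 1.0, lower: float = 0.1) -> float:
    """Log-density of an exponential truncated (and renormalized) to [lower, inf).

    log[rate e^{-rate x} / e^{-rate lower}] for x >= lower; -inf below.
    At x == lower the value is log(rate).
    """
    if rate <= 0:
        raise ValueError("rate must be positive")
    if x < lower:
        return -math.inf
    return math.log(rate) - rate * (x - lower)


def log_prior_site_model(state: SiteModelState, hyper: Hyperparameters) -> float:
    """Log prior of a site-model state (active components only).

    The uniform indicator and the three uniform flags contribute constants
    (taken as 0); inactive parameters are excluded.  Out-of-support values
    return -inf.
    """
    logp = 0.0
    if state.has_gamma:
        logp += truncated_exp_logpdf(state.alpha, hyper.alpha_rate,
                                     hyper.alpha_lower_bound)
    if state.has_inv:
        logp += beta_logpdf(state.p_inv, *hyper.pinv_beta)
    if state.use_estimated_freqs:
        logp += symmetric_dirichlet_logpdf(state.estimated_freqs,
                                           hyper.dirichlet_concentration)
    return logp


def beta_logpdf(x: float, a: float, b: float) -> float:
    """Beta(a, b) log-density; finite at the boundary where the pdf is
    (e.g. Beta(1, b) has density b at x = 0)."""
    if not 0.0 <= x <= 1.0:
        return -math.inf
    la = 0.0 if a == 1.0 else (a - 1.0) * (math.log(x) if x > 0 else -math.inf)
    lb = 0.0 if b == 1.0 else (b - 1.0) * (math.log1p(-x) if x < 1 else -math.inf)
    return la + lb + math.lgamma(a + b) - math.lgamma(a) - math.lgamma(b)


def symmetric_dirichlet_logpdf(f: np.ndarray, concentration: float) -> float:
    """Dirichlet(c, ..., c) log-density on the simplex (renormalizing f)."""
    f = np.asarray(f, float)
    f = f / f.sum()
    if np.any(f <= 0):
        return -math.inf
    d = f.size
    const = math.lgamma(concentration * d) - d * math.lgamma(concentration)
    return const + (concentration - 1.0) * float(np.log(f).sum())


def lognormal_logpdf(x: float, meanlog: float, sdlog: float) -> float:
    if x <= 0:
        return -math.inf
    z = (math.log(x) - meanlog) / sdlog
    return -0.5 * z * z - math.log(x * sdlog * math.sqrt(2.0 * math.pi))


def gamma_logpdf(x: float, shape: float, scale: float) -> float:
    if x < 0:
        return -math.inf
    if x == 0.0:
        return math.inf if shape < 1 else (-math.lgamma(shape) - shape * math.log(scale)
                                           if shape == 1 else -math.inf)
    return ((shape - 1.0) * math.log(x) - x / scale
            - math.lgamma(shape) - shape * math.log(scale))


def yule_log_density(tree: TimeTree, params: YuleParams) -> float:
    """Conditioned pure-birth log-density of a labelled time tree.

    With n tips and birth rate lambda, the density over node heights is

        (n - 1) log lambda - lambda (sum_internal h_i + h_root)

    (the root height counts twice).  This is the density of the generative
    process that spends Exp(k lambda) with k lineages for k = 2..n, the
    n-lineage interval ending at the present; the simulator cross-check
    property test pins the two to the same convention.  Topology constants
    are dropped (they cancel in MCMC over a fixed tip set).
    """
    lam = params.birth_rate
    if lam <= 0:
        raise ValueError("birth rate must be positive")
    n = tree.n_tips
    internal = np.arange(n, 2 * n - 1)
    total = float(tree.heights[internal].sum()) + tree.root_height()
    return (n - 1) * math.log(lam) - lam * total


def log_prior_joint(chain_state, hyper: Hyperparameters) -> float:
    """Joint log prior of a full chain state (tree, site model, clock, lambda)."""
    site = log_prior_site_model(chain_state.site, hyper)
    if not np.isfinite(site):
        return -math.inf
    lam = chain_state.yule.birth_rate
    tree_prior = yule_log_density(chain_state.tree, chain_state.yule)
    lam_prior = lognormal_logpdf(lam, hyper.birthrate_meanlog, hyper.birthrate_sdlog)
    total = site + tree_prior + lam_prior
    if chain_state.clock.kind == "ucln":
        total += gamma_logpdf(chain_state.clock.ucld_stdev,
                              hyper.ucld_stdev_shape, hyper.ucld_stdev_scale)
        # uniform category assignment contributes a constant; dropped
    return total
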