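"""Trans-dimensional MCMC over the averaged site model, tree, and clock.

The sampler is plain Metropolis-Hastings over a state made of a time tree,
a site-model state, a clock model, and the Yule birth rate.  The
model-averaging moves are:

* a uniform re-draw of the model indicator (symmetric);
* birth/death moves that toggle the gamma-heterogeneity and
  invariable-sites flags, sampling the newborn parameter from a density
  ``d`` (the matching prior by default) so the reversible-jump acceptance
  reduces to likelihood ratio x flag-prior ratio;
* a bit-flip between empirical and estimated frequencies; the estimated
  vector persists while unused (stochastic variable selection), and keeps
  its Dirichlet prior throughout so the flip is a fixed-dimension move;
* scale moves for alpha and p_inv that are gated on their flags;
* delta-exchange and adaptive multivariate-normal (AVMN) moves for the
  estimated frequency simplex;
* standard tree moves (whole-tree scale, root scale, uniform node height,
  narrow and wide exchange) and relaxed-clock moves (branch-category
  re-draw, gated ucld-stdev scale), plus a birth-rate scale.

Every stochastic decision draws from one seeded generator in a fixed
order, so traces are bit-reproducible given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional

import numpy as np
import pandas as pd

from .alignment import AminoAlignment
from .clock import ClockModel
from .empirical import ModelRegistry, builtin_registry
from .likelihood import LikelihoodEngine
from .priors import (
    Hyperparameters,
    YuleParams,
    beta_logpdf,
    log_prior_joint,
    symmetric_dirichlet_logpdf,
    truncated_exp_logpdf,
    yule_log_density,
)
from .sitemodel import SiteModelState, active_frequencies
from .tree import TimeTree

__all__ = [
    "ChainState",
    "ProposalOutcome",
    "AvmnAdaptation",
    "OperatorSchedule",
    "RunConfig",
    "ChainResult",
    "run_chain",
    "default_operators",
    "mh_step",
]


# ---------------------------------------------------------------------------
# state

@dataclass
class ChainState:
    """Full MCMC state with cached log prior and log likelihood."""

    tree: TimeTree
    site: SiteModelState
    clock: ClockModel
    yule: YuleParams
    log_prior: float = math.nan
    log_likelihood: float = math.nan

    @property
    def log_posterior(self) -> float:
        return self.log_prior + self.log_likelihood

    def replaced(self, **kwargs) -> "ChainState":
        new = replace(self, **kwargs)
        new.log_prior = math.nan
        new.log_likelihood = math.nan
        return new


@dataclass
class ProposalOutcome:
    """A proposed state together with its log Hastings ratio.

    ``log_hastings == -inf`` encodes an immediate reject;
    ``affects_likelihood`` lets the engine skip likelihood evaluation for
    prior-only moves.
    """

    state: Optional[ChainState]
    log_hastings: float
    affects_likelihood: bool = True


# ---------------------------------------------------------------------------
# prior for the MCMC target

def chain_log_prior(state: ChainState, hyper: Hyperparameters) -> float:
    """Joint prior targeted by the chain.

    Same as :func:`aamava.priors.log_prior_joint` except that the Dirichlet
    prior on the estimated frequency vector applies whether or not the
    vector is in use: the frequency source is selected by a bit flip with
    the vector persisting (Kuo-Mallick variable selection), so the latent
    vector needs a stationary density for the frequency moves to target.
    """
    logp = log_prior_joint(state, hyper)
    if not state.site.use_estimated_freqs:
        logp += symmetric_dirichlet_logpdf(state.site.estimated_freqs,
                                           hyper.dirichlet_concentration)
    return logp


# ---------------------------------------------------------------------------
# operators

class Operator:
    name: str = "operator"
    affects_likelihood: bool = True

    def propose(self, state: ChainState, rng: np.random.Generator
                ) -> Optional[ProposalOutcome]:
        raise NotImplementedError


def _scale_factor(rng: np.random.Generator, beta: float) -> float:
    """Multiplier from the standard scale kernel, uniform on [beta, 1/beta]."""
    return beta + rng.random() * (1.0 / beta - beta)


class IndicatorOperator(Operator):
    """Uniform re-draw of the model indicator over 1..M (symmetric)."""

    name = "indicator"

    def __init__(self, n_models: int):
        self.n_models = n_models

    def propose(self, state, rng):
        new = int(rng.integers(1, self.n_models + 1))
        return ProposalOutcome(
            state.replaced(site=state.site.with_(model_indicator=new)), 0.0)


class GammaBirthDeathOperator(Operator):
    """Toggle gamma heterogeneity, sampling alpha from density ``d`` at birth.

    With ``d`` equal to the (truncated exponential) prior, the
    dimension-matching term cancels the newborn parameter's prior in the
    acceptance ratio, leaving likelihood ratio x flag-prior ratio.
    """

    name = "gamma_birth_death"

    def __init__(self, hyper: Hyperparameters,
                 sample: Callable[[np.random.Generator], float] | None = None,
                 logpdf: Callable[[float], float] | None = None):
        self.hyper = hyper
        self.sample = sample or (lambda rng: hyper.alpha_lower_bound
                                 + rng.exponential(1.0 / hyper.alpha_rate))
        self.logpdf = logpdf or (lambda a: truncated_exp_logpdf(
            a, hyper.alpha_rate, hyper.alpha_lower_bound))

    def propose(self, state, rng):
        if state.site.has_gamma:  # death
            new = state.site.with_(has_gamma=False)
            return ProposalOutcome(state.replaced(site=new),
                                   self.logpdf(state.site.alpha))
        alpha = self.sample(rng)  # birth
        new = state.site.with_(has_gamma=True, alpha=alpha)
        return ProposalOutcome(state.replaced(site=new), -self.logpdf(alpha))


class InvBirthDeathOperator(Operator):
    """Toggle the invariable-sites flag, sampling p_inv from Beta(1,4) at birth."""

    name = "inv_birth_death"

    def __init__(self, hyper: Hyperparameters,
                 sample: Callable[[np.random.Generator], float] | None = None,
                 logpdf: Callable[[float], float] | None = None):
        a, b = hyper.pinv_beta
        self.sample = sample or (lambda rng: float(rng.beta(a, b)))
        self.logpdf = logpdf or (lambda p: beta_logpdf(p, a, b))

    def propose(self, state, rng):
        if state.site.has_inv:  # death
            return ProposalOutcome(
                state.replaced(site=state.site.with_(has_inv=False, p_inv=0.0)),
                self.logpdf(state.site.p_inv))
        p = self.sample(rng)
        if not 0.0 <= p < 1.0:
            return ProposalOutcome(None, -math.inf)
        new = state.site.with_(has_inv=True, p_inv=p)
        return ProposalOutcome(state.replaced(site=new), -self.logpdf(p))


class FreqSourceBitFlip(Operator):
    """Switch between empirical and estimated frequencies (symmetric)."""

    name = "freq_source_bitflip"

    def propose(self, state, rng):
        new = state.site.with_(use_estimated_freqs=not state.site.use_estimated_freqs)
        return ProposalOutcome(state.replaced(site=new), 0.0)


class AlphaScaleOperator(Operator):
    """Scale alpha; applies only while the gamma flag is set."""

    name = "alpha_scale"

    def __init__(self, hyper: Hyperparameters, beta: float = 0.75):
        self.hyper = hyper
        self.beta = beta

    def propose(self, state, rng):
        if not state.site.has_gamma:
            return None
        s = _scale_factor(rng, self.beta)
        alpha = state.site.alpha * s
        if alpha < self.hyper.alpha_lower_bound:
            return ProposalOutcome(None, -math.inf)
        return ProposalOutcome(
            state.replaced(site=state.site.with_(alpha=alpha)), -math.log(s))


class PinvScaleOperator(Operator):
    """Scale p_inv; applies only while the invariable-sites flag is set."""

    name = "pinv_scale"

    def __init__(self, beta: float = 0.75):
        self.beta = beta

    def propose(self, state, rng):
        if not state.site.has_inv:
            return None
        s = _scale_factor(rng, self.beta)
        p = state.site.p_inv * s
        if not 0.0 < p < 1.0:
            return ProposalOutcome(None, -math.inf)
        return ProposalOutcome(
            state.replaced(site=state.site.with_(p_inv=p)), -math.log(s))


class DeltaExchangeOperator(Operator):
    """Move mass delta between two random components of the frequency simplex."""

    name = "freq_delta_exchange"

    def __init__(self, window: float = 0.05):
        self.window = window

    def propose(self, state, rng):
        f = state.site.estimated_freqs
        a, b = rng.choice(len(f), size=2, replace=False)
        delta = rng.random() * self.window
        fa, fb = f[a] + delta, f[b] - delta
        if not (0.0 < fa < 1.0 and 0.0 < fb < 1.0):
            return ProposalOutcome(None, -math.inf)
        new = f.copy()
        new[a], new[b] = fa, fb
        out = state.replaced(site=state.site.with_(estimated_freqs=new))
        return ProposalOutcome(out, 0.0,
                               affects_likelihood=state.site.use_estimated_freqs)


@dataclass
class AvmnAdaptation:
    """Running mean/covariance of the log-ratio-transformed frequencies."""

    dim: int = 19
    count: int = 0
    mean: np.ndarray = field(default_factory=lambda: np.zeros(19))
    cov: np.ndarray = field(default_factory=lambda: np.zeros((19, 19)))
    burnin: int = 200         # samples before the learned covariance is used
    epsilon: float = 1e-6     # ridge keeping the proposal covariance PD
    initial_step: float = 0.05

    def update(self, y: np.ndarray) -> None:
        self.count += 1
        delta = y - self.mean
        self.mean += delta / self.count
        self.cov += (np.outer(delta, y - self.mean) - self.cov) / self.count

    def proposal_cov(self) -> np.ndarray:
        d = self.dim
        if self.count < self.burnin:
            return (self.initial_step ** 2 / d) * np.eye(d)
        scaled = (2.38 ** 2 / d) * (self.cov + self.epsilon * np.eye(d))
        return scaled


def alr_transform(f: np.ndarray) -> np.ndarray:
    """Additive log-ratio coordinates of a strictly positive simplex."""
    if np.any(f <= 0):
        raise ValueError("simplex components must be strictly positive")
    return np.log(f[:-1] / f[-1])


def alr_back_transform(y: np.ndarray) -> np.ndarray:
    e = np.exp(np.concatenate([y, [0.0]]) - max(0.0, float(np.max(y))))
    return e / e.sum()


class AvmnOperator(Operator):
    """Adaptive multivariate-normal random walk on transformed frequencies.

    Works in additive log-ratio coordinates; the proposal is a Gaussian
    random walk whose covariance is learned from the chain history (after a
    burn-in window, from accepted states only).  The Hastings ratio is the
    log-Jacobian difference sum(log f') - sum(log f) of the transform.
    """

    name = "freq_avmn"

    def __init__(self, adapt: AvmnAdaptation | None = None):
        self.adapt = adapt or AvmnAdaptation()

    def propose(self, state, rng):
        f = state.site.estimated_freqs
        y = alr_transform(f)
        self.adapt.update(y)
        cov = self.adapt.proposal_cov()
        try:
            chol = np.linalg.cholesky(cov)
        except np.linalg.LinAlgError:
            chol = np.sqrt(np.diag(np.diag(cov)) + 1e-12)
        y2 = y + chol @ rng.standard_normal(self.adapt.dim)
        f2 = alr_back_transform(y2)
        if np.any(f2 <= 0):
            return ProposalOutcome(None, -math.inf)
        log_jac = float(np.log(f2).sum() - np.log(f).sum())
        out = state.replaced(site=state.site.with_(estimated_freqs=f2))
        return ProposalOutcome(out, log_jac,
                               affects_likelihood=state.site.use_estimated_freqs)


# -- tree and clock moves ---------------------------------------------------

class TreeScaleOperator(Operator):
    """Scale every internal node height by a common factor."""

    name = "tree_scale"

    def __init__(self, beta: float = 0.9):
        self.beta = beta

    def propose(self, state, rng):
        s = _scale_factor(rng, self.beta)
        tree = state.tree.copy()
        internal = np.arange(tree.n_tips, tree.n_nodes)
        tree.heights[internal] *= s
        k = len(internal)
        return ProposalOutcome(state.replaced(tree=tree), (k - 2) * math.log(s))


class RootScaleOperator(Operator):
    """Scale the root height only."""

    name = "root_scale"

    def __init__(self, beta: float = 0.75):
        self.beta = beta

    def propose(self, state, rng):
        s = _scale_factor(rng, self.beta)
        tree = state.tree.copy()
        root = tree.root
        new_h = tree.heights[root] * s
        kids = tree.children[root]
        if new_h <= tree.heights[kids].max():
            return ProposalOutcome(None, -math.inf)
        tree.heights[root] = new_h
        return ProposalOutcome(state.replaced(tree=tree), -math.log(s))


class UniformHeightOperator(Operator):
    """Re-draw one non-root internal height uniformly between its bounds."""

    name = "uniform_height"

    def propose(self, state, rng):
        tree = state.tree
        candidates = [i for i in range(tree.n_tips, tree.n_nodes) if i != tree.root]
        if not candidates:
            return None
        node = candidates[int(rng.integers(len(candidates)))]
        lo = tree.heights[tree.children[node]].max()
        hi = tree.heights[tree.parent[node]]
        tree = tree.copy()
        tree.heights[node] = lo + rng.random() * (hi - lo)
        return ProposalOutcome(state.replaced(tree=tree), 0.0)


def _swap_parents(tree: TimeTree, a: int, b: int) -> None:
    pa, pb = tree.parent[a], tree.parent[b]
    ca = int(np.flatnonzero(tree.children[pa] == a)[0])
    cb = int(np.flatnonzero(tree.children[pb] == b)[0])
    tree.children[pa, ca] = b
    tree.children[pb, cb] = a
    tree.parent[a], tree.parent[b] = pb, pa


class NarrowExchangeOperator(Operator):
    """Swap a child of an internal node with that node's sibling (NNI)."""

    name = "narrow_exchange"

    def propose(self, state, rng):
        tree = state.tree
        candidates = [i for i in range(tree.n_tips, tree.n_nodes) if i != tree.root]
        if not candidates:
            return None
        node = candidates[int(rng.integers(len(candidates)))]
        parent = tree.parent[node]
        sibling = int(tree.children[parent][tree.children[parent] != node][0])
        child = int(tree.children[node][int(rng.integers(2))])
        if tree.heights[sibling] >= tree.heights[node]:
            return ProposalOutcome(None, -math.inf)
        tree = tree.copy()
        _swap_parents(tree, child, sibling)
        return ProposalOutcome(state.replaced(tree=tree), 0.0)


class WideExchangeOperator(Operator):
    """Swap two random non-adjacent subtrees when heights permit."""

    name = "wide_exchange"

    def propose(self, state, rng):
        tree = state.tree
        nodes = [i for i in range(tree.n_nodes) if i != tree.root]
        a, b = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(a)], nodes[int(b)]
        if tree.parent[a] == tree.parent[b]:
            return ProposalOutcome(None, -math.inf)
        # neither may be an ancestor of the other
        for x, y in ((a, b), (b, a)):
            node = y
            while node != -1:
                if node == x:
                    return ProposalOutcome(None, -math.inf)
                node = tree.parent[node]
        if (tree.heights[tree.parent[a]] <= tree.heights[b]
                or tree.heights[tree.parent[b]] <= tree.heights[a]):
            return ProposalOutcome(None, -math.inf)
        tree = tree.copy()
        _swap_parents(tree, a, b)
        return ProposalOutcome(state.replaced(tree=tree), 0.0)


class BranchCategoryOperator(Operator):
    """Re-draw one relaxed-clock branch-rate category uniformly."""

    name = "branch_category"

    def propose(self, state, rng):
        if state.clock.kind != "ucln":
            return None
        cats = state.clock.branch_categories.copy()
        i = int(rng.integers(cats.size))
        cats[i] = int(rng.integers(cats.size))
        return ProposalOutcome(
            state.replaced(clock=state.clock.with_(branch_categories=cats)), 0.0)


class UcldStdevScaleOperator(Operator):
    """Scale the relaxed-clock lognormal standard deviation."""

    name = "ucld_stdev_scale"

    def __init__(self, beta: float = 0.75):
        self.beta = beta

    def propose(self, state, rng):
        if state.clock.kind != "ucln":
            return None
        s = _scale_factor(rng, self.beta)
        return ProposalOutcome(
            state.replaced(clock=state.clock.with_(ucld_stdev=state.clock.ucld_stdev * s)),
            -math.log(s))


class BirthRateScaleOperator(Operator):
    """Scale the Yule birth rate (prior-only move)."""

    name = "birth_rate_scale"
    affects_likelihood = False

    def __init__(self, beta: float = 0.75):
        self.beta = beta

    def propose(self, state, rng):
        s = _scale_factor(rng, self.beta)
        out = state.replaced(yule=YuleParams(state.yule.birth_rate * s))
        return ProposalOutcome(out, -math.log(s), affects_likelihood=False)


# ---------------------------------------------------------------------------
# scheduling and the engine

@dataclass
class OperatorSchedule:
    """Weight-proportional random operator selection."""

    entries: list[tuple[Operator, float]]

    def __post_init__(self) -> None:
        if not self.entries:
            raise ValueError("schedule must have at least one operator")
        w = np.array([wt for _, wt in self.entries], float)
        if np.any(w <= 0):
            raise ValueError("operator weights must be positive")
        self._probs = w / w.sum()

    def draw(self, rng: np.random.Generator) -> Operator:
        return self.entries[int(rng.choice(len(self.entries), p=self._probs))][0]


def default_operators(hyper: Hyperparameters, n_models: int,
                      clock_kind: str = "ucln",
                      estimate_topology: bool = True,
                      site_moves: bool = True,
                      scale_beta: float = 0.75,
                      delta_window: float = 0.05) -> list[tuple[Operator, float]]:
    """The default operator mix (site-model weights per the averaging design;
    tree and clock moves carry the bulk of the proposal mass)."""
    ops: list[tuple[Operator, float]] = []
    if site_moves:
        ops += [
            (IndicatorOperator(n_models), 1.0),
            (GammaBirthDeathOperator(hyper), 1.0),
            (InvBirthDeathOperator(hyper), 1.0),
            (FreqSourceBitFlip(), 1.0),
            (AlphaScaleOperator(hyper, scale_beta), 0.5),
            (PinvScaleOperator(scale_beta), 0.5),
            (DeltaExchangeOperator(delta_window), 1.0),
            (AvmnOperator(), 1.0),
        ]
    tree_ops: list[tuple[Operator, float]] = [
        (TreeScaleOperator(), 3.0),
        (RootScaleOperator(scale_beta), 2.0),
        (UniformHeightOperator(), 5.0),
    ]
    if estimate_topology:
        tree_ops += [
            (NarrowExchangeOperator(), 3.0),
            (WideExchangeOperator(), 1.0),
        ]
    ops += tree_ops
    ops.append((BirthRateScaleOperator(scale_beta), 1.0))
    if clock_kind == "ucln":
        ops += [
            (BranchCategoryOperator(), 3.0),
            (UcldStdevScaleOperator(scale_beta), 1.0),
        ]
    return ops


@dataclass
class RunConfig:
    """Configuration of one MCMC run."""

    chain_length: int = 100_000
    log_every: int = 100
    hyper: Hyperparameters = field(default_factory=Hyperparameters)
    clock_kind: str = "ucln"
    gamma_categories: int = 4
    use_likelihood: bool = True
    estimate_topology: bool = True
    site_moves: bool = True
    scale_beta: float = 0.75
    delta_window: float = 0.05
    operators: list[tuple[Operator, float]] | None = None

    def validate(self) -> None:
        if self.chain_length <= 0 or self.log_every <= 0:
            raise ValueError("chain_length and log_every must be positive")
        if self.clock_kind not in ("strict", "ucln"):
            raise ValueError(f"unknown clock kind {self.clock_kind!r}")


@dataclass
class ChainResult:
    """Trace log plus sampled trees from one run."""

    trace: pd.DataFrame
    trees: list[TimeTree]
    acceptance: dict[str, tuple[int, int]]  # operator -> (accepted, tried)


def mh_step(state: ChainState, outcome: Optional[ProposalOutcome],
            rng: np.random.Generator, hyper: Hyperparameters,
            engine: LikelihoodEngine | None) -> tuple[ChainState, bool]:
    """One Metropolis-Hastings accept/reject decision.

    Returns the (possibly unchanged) state and whether the proposal was
    accepted.  ``outcome is None`` (operator not applicable) and
    ``-inf`` Hastings ratios leave the state untouched.
    """
    if outcome is None or outcome.state is None or outcome.log_hastings == -math.inf:
        return state, False
    prop = outcome.state
    prop.log_prior = chain_log_prior(prop, hyper)
    if prop.log_prior == -math.inf:
        return state, False
    if engine is None:
        prop.log_likelihood = 0.0
    elif not outcome.affects_likelihood:
        prop.log_likelihood = state.log_likelihood
    else:
        prop.log_likelihood = engine.loglik(prop.tree, prop.site, prop.clock)
    delta = (prop.log_posterior - state.log_posterior) + outcome.log_hastings
    if math.isnan(delta):
        raise FloatingPointError("non-finite posterior in MH step")
    if delta >= 0 or math.log(rng.random()) < delta:
        if not math.isfinite(prop.log_likelihood):
            raise FloatingPointError("accepted state has non-finite log-likelihood")
        return prop, True
    return state, False


def _trace_row(sample: int, state: ChainState, registry: ModelRegistry) -> dict:
    freqs = active_frequencies(state.site, registry)
    row = {
        "Sample": sample,
        "posterior": state.log_posterior,
        "likelihood": state.log_likelihood,
        "prior": state.log_prior,
        "modelIndicator": state.site.model_indicator,
        "hasGammaRates": int(state.site.has_gamma),
        "hasInvariableSites": int(state.site.has_inv),
        "useEstimatedFreqs": int(state.site.use_estimated_freqs),
        "gammaShape": state.site.alpha if state.site.has_gamma else math.nan,
        "proportionInvariable": state.site.p_inv if state.site.has_inv else math.nan,
    }
    for i in range(20):
        row[f"frequencies.{i + 1}"] = float(freqs[i])
    row["treeHeight"] = state.tree.root_height()
    row["birthRate"] = state.yule.birth_rate
    row["yuleDensity"] = yule_log_density(state.tree, state.yule)
    row["ucldStdev"] = (state.clock.ucld_stdev if state.clock.kind == "ucln"
                        else math.nan)
    return row


def run_chain(config: RunConfig, seed: int,
              alignment: AminoAlignment | None = None,
              registry: ModelRegistry | None = None,
              init: ChainState | None = None) -> ChainResult:
    """Run one MCMC chain and return its trace and tree log.

    With ``config.use_likelihood`` false (or no alignment) the chain
    samples the joint prior, which is the basis of the prior-recovery
    validation.  Fully reproducible given ``seed``.
    """
    from .simulate import sample_chain_state  # deferred: simulate imports mcmc types

    config.validate()
    registry = registry or builtin_registry()
    rng = np.random.default_rng(seed)
    if init is None:
        n_taxa = alignment.n_taxa if alignment is not None else 16
        labels = alignment.labels if alignment is not None else None
        init = sample_chain_state(config.hyper, n_taxa, rng,
                                  clock_kind=config.clock_kind, labels=labels)
    state = init
    engine = None
    if config.use_likelihood and alignment is not None:
        engine = LikelihoodEngine(alignment, registry, config.gamma_categories)
    state.log_prior = chain_log_prior(state, config.hyper)
    if not math.isfinite(state.log_prior):
        raise ValueError("initial state has zero prior probability")
    state.log_likelihood = (engine.loglik(state.tree, state.site, state.clock)
                            if engine is not None else 0.0)
    entries = config.operators if config.operators is not None else default_operators(
        config.hyper, len(registry), config.clock_kind,
        estimate_topology=config.estimate_topology, site_moves=config.site_moves,
        scale_beta=config.scale_beta, delta_window=config.delta_window)
    schedule = OperatorSchedule(entries)
    rows = [_trace_row(0, state, registry)]
    trees = [state.tree.copy()]
    tally: dict[str, list[int]] = {op.name: [0, 0] for op, _ in entries}
    for step in range(1, config.chain_length + 1):
        op = schedule.draw(rng)
        outcome = op.propose(state, rng)
        state, accepted = mh_step(state, outcome, rng, config.hyper, engine)
        if outcome is not None:
            tally[op.name][1] += 1
            tally[op.name][0] += int(accepted)
        if step % config.log_every == 0:
            rows.append(_trace_row(step, state, registry))
            trees.append(state.tree.copy())
    trace = pd.DataFrame(rows)
    return ChainResult(trace, trees,
                       {k: (v[0], v[1]) for k, v in tally.items()})
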