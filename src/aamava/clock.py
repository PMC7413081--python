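"""Molecular clock models.

Either a strict clock (one rate for every branch) or an uncorrelated
lognormal relaxed clock (ucln): each branch gets an independent multiplier
drawn from a mean-one lognormal whose log-space standard deviation is the
``ucld_stdev`` parameter.  As in the usual discretized construction, the
lognormal is approximated by one equal-probability category per branch
(category rate = bin mean, so the categories average exactly 1) and the
per-branch category assignment is part of the MCMC state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.stats import norm

from .tree import TimeTree

__all__ = ["ClockModel", "BranchRates", "ucln_category_rates", "realize_branch_rates"]


def ucln_category_rates(ucld_stdev: float, n_categories: int) -> np.ndarray:
    """Equal-probability bin means of the mean-one lognormal.

    The mean-one lognormal has meanlog = -s^2/2 for sdlog s;
    the partial expectation over quantile bin (q_i, q_{i+1}) is
    Phi(z_{i+1} - s) - Phi(z_i - s) with z the standard-normal quantiles,
    so the bin means average exactly 1.
    """
    if ucld_stdev < 0:
        raise ValueError("ucld_stdev must be >= 0")
    if ucld_stdev == 0.0:
        return np.ones(n_categories)
    z = norm.ppf(np.arange(n_categories + 1) / n_categories)
    cdf = norm.cdf(z - ucld_stdev)
    rates = n_categories * np.diff(cdf)
    return rates / rates.mean()


@dataclass(frozen=True)
class ClockModel:
    """Strict or uncorrelated-lognormal branch-rate model."""

    kind: str = "strict"  # "strict" | "ucln"
    clock_rate: float = 1.0
    ucld_stdev: float = 0.1
    branch_categories: np.ndarray = field(default_factory=lambda: np.zeros(0, np.int64))

    def __post_init__(self) -> None:
        if self.kind not in ("strict", "ucln"):
            raise ValueError(f"unknown clock kind {self.kind!r}")
        if self.clock_rate <= 0:
            raise ValueError("clock_rate must be positive")
        if self.kind == "ucln" and self.ucld_stdev < 0:
            raise ValueError("ucld_stdev must be >= 0")
        object.__setattr__(
            self, "branch_categories",
            np.asarray(self.branch_categories, dtype=np.int64).copy(),
        )

    def with_(self, **kwargs) -> "ClockModel":
        return replace(self, **kwargs)

    def n_branches_expected(self) -> int:
        return int(self.branch_categories.size)


@dataclass(frozen=True)
class BranchRates:
    """Realized multiplicative rate for the branch above each node."""

    rates: np.ndarray  # indexed by node; root slot is 1 and unused


def realize_branch_rates(tree: TimeTree, clock: ClockModel) -> BranchRates:
    """Per-branch rates implied by the clock model on a tree.

    Strict: every branch gets ``clock_rate``.  ucln: branch ``i`` (the edge
    above node ``i``) gets ``clock_rate`` times the bin-mean rate of its
    assigned category; the discretization has one category per branch.
    """
    n_nodes = tree.n_nodes
    if clock.kind == "strict":
        return BranchRates(np.full(n_nodes, clock.clock_rate))
    n_branches = n_nodes - 1
    cats = clock.branch_categories
    if cats.size != n_branches:
        raise ValueError(
            f"ucln clock needs {n_branches} branch categories, has {cats.size}"
        )
    table = ucln_category_rates(clock.ucld_stdev, n_branches)
    rates = np.ones(n_nodes)
    branch_nodes = [i for i in range(n_nodes) if i != tree.root]
    rates[branch_nodes] = clock.clock_rate * table[cats]
    return BranchRates(rates)
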