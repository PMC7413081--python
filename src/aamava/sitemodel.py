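"""The averaged site model.

A site model here is the four-part object that is averaged over by the
trans-dimensional MCMC:

* a model indicator ``I_M`` (1-based) choosing one empirical exchangeability
  matrix from the registry;
* a frequency source: the chosen model's empirical frequencies, or a
  frequency vector estimated from the data (Bayesian stochastic variable
  selection keeps the estimated vector in the state even while unused);
* optional discrete-gamma rate heterogeneity across sites (shape ``alpha``,
  four equal-weight categories by default);
* an optional zero-rate category of invariable sites with weight ``p_inv``.

This module also assembles the reversible rate matrix R from Q and F and
computes transition probabilities P = exp(R t) via the symmetrized
eigendecomposition.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special
from scipy.stats import gamma as gamma_dist

from .empirical import EmpiricalModel, ModelRegistry

__all__ = [
    "SiteModelState",
    "RateCategories",
    "discrete_gamma_rates",
    "mixture_categories",
    "build_rate_matrix",
    "transition_matrix",
    "active_frequencies",
    "RateMatrixEigen",
]


@dataclass(frozen=True)
class SiteModelState:
    """State of the averaged site model (one point of the MCMC chain)."""

    model_indicator: int = 1
    use_estimated_freqs: bool = False
    estimated_freqs: np.ndarray = field(default_factory=lambda: np.full(20, 0.05))
    has_gamma: bool = False
    alpha: float = 1.0
    has_inv: bool = False
    p_inv: float = 0.0

    def __post_init__(self) -> None:
        f = np.asarray(self.estimated_freqs, dtype=float)
        if f.shape != (20,) or abs(f.sum() - 1.0) > 1e-9 or np.any(f <= 0):
            raise ValueError("estimated_freqs must be a strictly positive 20-simplex")
        object.__setattr__(self, "estimated_freqs", f)
        if not (0.0 <= self.p_inv < 1.0):
            raise ValueError("p_inv must lie in [0, 1)")
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")

    def with_(self, **kwargs) -> "SiteModelState":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class RateCategories:
    """A finite mixture of relative rates with overall mean one."""

    rates: np.ndarray
    weights: np.ndarray

    def __post_init__(self) -> None:
        r = np.asarray(self.rates, float)
        w = np.asarray(self.weights, float)
        if abs(w.sum() - 1.0) > 1e-12:
            raise ValueError("category weights must sum to 1")
        if abs(float(w @ r) - 1.0) > 1e-9:
            raise ValueError("mean category rate must be 1")
        if np.any(np.diff(r) < 0):
            raise ValueError("rates must be sorted ascending")
        object.__setattr__(self, "rates", r)
        object.__setattr__(self, "weights", w)


def discrete_gamma_rates(alpha: float, k: int = 4, rule: str = "median") -> np.ndarray:
    """Equal-weight discrete approximation of mean-one gamma site rates.

    The mean-one gamma (shape ``alpha``, rate ``alpha``) is cut into ``k``
    equal-probability bins.  Under the default ``"median"`` rule each
    category rate is the gamma quantile at the midpoint of its bin (the
    convention of the mainstream Bayesian phylogenetics implementations);
    under ``"mean"`` it is the conditional mean of the bin.  Either way the
    k rates are rescaled to average exactly 1.  Small ``alpha`` collapses
    the slow categories toward rate 0 and pushes the fastest toward k.
    """
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if k < 1:
        raise ValueError("k must be >= 1")
    if k == 1:
        return np.ones(1)
    if rule == "median":
        rates = special.gammaincinv(alpha, (2.0 * np.arange(k) + 1.0) / (2 * k)) / alpha
    elif rule == "mean":
        # Bin edges are quantiles of Gamma(alpha, rate=alpha); the partial
        # expectation over a bin uses E[X; X<q] = F_{alpha+1}(q) for mean-one X.
        probs = np.arange(1, k) / k
        edges = special.gammaincinv(alpha, probs)  # edges of Gamma(alpha, 1)
        upper = np.concatenate([special.gammainc(alpha + 1.0, edges), [1.0]])
        lower = np.concatenate([[0.0], special.gammainc(alpha + 1.0, edges)])
        rates = k * (upper - lower)  # conditional means, already mean one
    else:
        raise ValueError(f"unknown discretization rule {rule!r}")
    rates = np.sort(rates)
    total = rates.sum()
    if total <= 0:  # all mass collapsed below double precision
        rates[-1] = float(k)
        return rates
    return rates / (total / k)


def mixture_categories(state: SiteModelState, k: int = 4) -> RateCategories:
    """Full site-rate mixture implied by a site-model state.

    Combines the optional invariable (zero-rate) category of weight
    ``p_inv`` with the optional discrete-gamma categories; gamma rates are
    divided by (1 - p_inv) so the whole mixture keeps mean rate 1 and branch
    lengths remain in expected substitutions per site.
    """
    if state.has_inv and state.p_inv >= 1.0:
        raise ValueError("p_inv must be < 1")
    if not state.has_gamma and not state.has_inv:
        return RateCategories(np.ones(1), np.ones(1))
    if state.has_gamma:
        g = discrete_gamma_rates(state.alpha, k)
        if state.has_inv:
            p = state.p_inv
            rates = np.concatenate([[0.0], g / (1.0 - p)])
            weights = np.concatenate([[p], np.full(k, (1.0 - p) / k)])
        else:
            rates = g
            weights = np.full(k, 1.0 / k)
    else:
        p = state.p_inv
        rates = np.array([0.0, 1.0 / (1.0 - p)])
        weights = np.array([p, 1.0 - p])
    return RateCategories(rates, weights)


def build_rate_matrix(model: EmpiricalModel, freqs: np.ndarray) -> np.ndarray:
    """Compose the reversible rate matrix R from Q and a frequency vector.

    Off-diagonal R[i, j] = Q[i, j] * f_j; the diagonal makes rows sum to
    zero; the whole matrix is rescaled so the expected substitution rate at
    stationarity, -sum_i f_i R[i, i], is 1.  Normalization is applied after
    composing with the *active* frequencies, so switching frequency source
    changes the scaling as it must for branch lengths to stay interpretable.
    """
    f = np.asarray(freqs, float)
    if np.any(f <= 0):
        raise ValueError("frequencies must be strictly positive")
    r = model.exchangeabilities * f[np.newaxis, :]
    np.fill_diagonal(r, 0.0)
    np.fill_diagonal(r, -r.sum(axis=1))
    mu = -float(f @ np.diag(r))
    if mu <= 0:
        raise ValueError("degenerate rate matrix")
    return r / mu


@dataclass(frozen=True)
class RateMatrixEigen:
    """Eigendecomposition of a reversible R for fast transition probabilities.

    For reversible R with stationary f, S = diag(sqrt f) R diag(1/sqrt f) is
    symmetric; with S = U diag(w) U', P(t) = diag(1/sqrt f) U e^{w t} U'
    diag(sqrt f).
    """

    eigenvalues: np.ndarray
    left: np.ndarray   # diag(1/sqrt f) @ U
    right: np.ndarray  # U' @ diag(sqrt f)
    freqs: np.ndarray

    @classmethod
    def from_rate_matrix(cls, r: np.ndarray, freqs: np.ndarray) -> "RateMatrixEigen":
        f = np.asarray(freqs, float)
        sq = np.sqrt(f)
        s = (sq[:, None] * r) / sq[None, :]
        s = 0.5 * (s + s.T)  # enforce exact symmetry against round-off
        w, u = np.linalg.eigh(s)
        return cls(w, u / sq[:, None], u.T * sq[None, :], f)

    def transition(self, distance: float) -> np.ndarray:
        if not np.isfinite(distance) or distance < 0:
            raise ValueError("distance must be finite and >= 0")
        p = (self.left * np.exp(self.eigenvalues * distance)) @ self.right
        np.clip(p, 0.0, None, out=p)
        rows = p.sum(axis=1)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise FloatingPointError("transition matrix rows deviate from 1")
        return p / rows[:, None]

    def transitions(self, distances: np.ndarray) -> np.ndarray:
        """Stack of transition matrices for several distances (m, 20, 20)."""
        d = np.asarray(distances, float)
        expw = np.exp(np.outer(d, self.eigenvalues))
        p = np.einsum("ij,mj,jk->mik", self.left, expw, self.right)
        np.clip(p, 0.0, None, out=p)
        rows = p.sum(axis=2)
        if np.any(np.abs(rows - 1.0) > 1e-9):
            raise FloatingPointError("transition matrix rows deviate from 1")
        return p / rows[:, :, None]


def transition_matrix(r: np.ndarray, distance: float, freqs: np.ndarray) -> np.ndarray:
    """P = exp(R * distance) for reversible R with stationary ``freqs``.

    Rows sum to 1; tiny negative eigen-solver round-off is clipped to zero
    and rows renormalized (deviations beyond 1e-9 raise).
    """
    return RateMatrixEigen.from_rate_matrix(r, freqs).transition(distance)


def active_frequencies(state: SiteModelState, registry: ModelRegistry) -> np.ndarray:
    """The frequency vector currently in force (empirical or estimated)."""
    if state.use_estimated_freqs:
        return state.estimated_freqs
    return registry.get(state.model_indicator).frequencies
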