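"""Felsenstein pruning likelihood for amino-acid alignments.

Computes the log-likelihood of a time tree given an alignment under the
averaged site model: per site, the likelihood is the mixture over rate
categories (invariable category and/or discrete-gamma categories) of the
pruning likelihood with branch distances
``branch length x branch rate x category rate``.

Partial likelihoods are rescaled per node and per site so alignments of
thousands of sites do not underflow with 20 states; scale factors are
accumulated in log space.  Eigendecompositions of the rate matrix are
cached keyed by the (model, frequency-vector) pair, which is where nearly
all the per-evaluation cost lives for study-scale trees.
"""

from __future__ import annotations

import numpy as np
from scipy.special import logsumexp

from .alignment import AminoAlignment
from .clock import ClockModel, realize_branch_rates
from .empirical import ModelRegistry
from .sitemodel import (
    RateMatrixEigen,
    SiteModelState,
    active_frequencies,
    build_rate_matrix,
    mixture_categories,
)
from .tree import TimeTree

__all__ = ["LikelihoodEngine", "pruning_loglik", "prob_invariable_site"]

_RESCALE_EVERY = True  # per-node max rescaling; cheap and underflow-proof


class LikelihoodEngine:
    """Reusable pruning-likelihood evaluator for one alignment.

    Encodes the alignment once and caches rate-matrix eigendecompositions.
    ``gamma_categories`` is the number of discrete-gamma bins (4 by
    default, as in the averaged site model).
    """

    def __init__(self, alignment: AminoAlignment, registry: ModelRegistry,
                 gamma_categories: int = 4):
        self.alignment = alignment
        self.registry = registry
        self.k = gamma_categories
        self._eigen_cache: dict[tuple, RateMatrixEigen] = {}

    def _eigen(self, state: SiteModelState) -> RateMatrixEigen:
        freqs = active_frequencies(state, self.registry)
        key = (state.model_indicator, state.use_estimated_freqs, freqs.tobytes())
        eig = self._eigen_cache.get(key)
        if eig is None:
            model = self.registry.get(state.model_indicator)
            r = build_rate_matrix(model, freqs)
            eig = RateMatrixEigen.from_rate_matrix(r, freqs)
            if len(self._eigen_cache) > 128:
                self._eigen_cache.clear()
            self._eigen_cache[key] = eig
        return eig

    def _tip_order(self, tree: TimeTree) -> np.ndarray:
        pos = {lb: i for i, lb in enumerate(self.alignment.labels)}
        try:
            return np.array([pos[lb] for lb in tree.labels])
        except KeyError as exc:
            raise ValueError(f"tree tip {exc} missing from alignment") from exc

    def site_logliks(self, tree: TimeTree, state: SiteModelState,
                     clock: ClockModel) -> np.ndarray:
        """Per-site log-likelihoods (length L)."""
        if sorted(tree.labels) != sorted(self.alignment.labels):
            raise ValueError("tree and alignment labels disagree")
        codes = self.alignment.codes[self._tip_order(tree)]
        cats = mixture_categories(state, self.k)
        eig = self._eigen(state)
        rates = realize_branch_rates(tree, clock).rates
        dists = tree.branch_lengths() * rates
        order = tree.postorder()
        n_tips, L = codes.shape
        per_cat = np.empty((len(cats.rates), L))
        for ci, crate in enumerate(cats.rates):
            per_cat[ci] = self._category_site_logliks(
                tree, codes, eig, dists * crate, order)
        return logsumexp(per_cat, axis=0, b=cats.weights[:, None])

    def _category_site_logliks(self, tree: TimeTree, codes: np.ndarray,
                               eig: RateMatrixEigen, dists: np.ndarray,
                               order: list[int]) -> np.ndarray:
        n_tips = codes.shape[0]
        L = codes.shape[1]
        trans = eig.transitions(dists)  # (n_nodes, 20, 20); root slot unused
        partials: dict[int, np.ndarray] = {}
        logscale = np.zeros(L)
        for node in order:
            if node < n_tips:
                continue
            prod = np.ones((L, 20))
            for child in tree.children[node]:
                p = trans[child]
                if child < n_tips:
                    c = codes[child]
                    contrib = np.ones((L, 20))
                    known = c >= 0
                    contrib[known] = p.T[c[known]]
                else:
                    contrib = partials.pop(child) @ p.T
                prod *= contrib
            if _RESCALE_EVERY:
                m = prod.max(axis=1)
                ok = m > 0
                prod[ok] /= m[ok, None]
                with np.errstate(divide="ignore"):
                    logscale += np.where(ok, np.log(m, where=ok,
                                                    out=np.zeros_like(m)), -np.inf)
            partials[node] = prod
        rootp = partials[tree.root]
        site = rootp @ eig.freqs
        with np.errstate(divide="ignore"):
            return np.log(site) + logscale

    def loglik(self, tree: TimeTree, state: SiteModelState,
               clock: ClockModel) -> float:
        return float(self.site_logliks(tree, state, clock).sum())


def pruning_loglik(tree: TimeTree, aln: AminoAlignment, state: SiteModelState,
                   clock: ClockModel, registry: ModelRegistry,
                   gamma_categories: int = 4) -> float:
    """One-shot pruning log-likelihood (see :class:`LikelihoodEngine`)."""
    return LikelihoodEngine(aln, registry, gamma_categories).loglik(tree, state, clock)


def prob_invariable_site(tree: TimeTree, state: SiteModelState, clock: ClockModel,
                         registry: ModelRegistry, gamma_categories: int = 4) -> float:
    """Probability that one site shows the same residue at every tip.

    Sums, over the 20 amino acids, the pruning probability of the constant
    column clamped to that residue.  Under strong rate heterogeneity (small
    gamma shape) this approaches the total weight of the effectively-zero
    rate categories, which is why a +G model can masquerade as +I.
    """
    n = len(tree.labels)
    codes = np.tile(np.arange(20), (n, 1))  # column a = all tips fixed to residue a
    aln = AminoAlignment(tree.labels, codes)
    engine = LikelihoodEngine(aln, registry, gamma_categories)
    return float(np.exp(engine.site_logliks(tree, state, clock)).sum())
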