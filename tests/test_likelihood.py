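"""Pruning likelihood against closed forms and an exhaustive oracle."""

import itertools

import numpy as np
import pytest
from scipy.linalg import expm

import aamava as am
from aamava.clock import ucln_category_rates
from aamava.sitemodel import build_rate_matrix, mixture_categories

from conftest import balanced_quartet, cherry


def exhaustive_loglik(tree, aln, state, clock, registry, k=4):
    """Independent oracle: sum over all internal-state assignments, with
    transition matrices from scipy's expm rather than the eigen path."""
    freqs = am.active_frequencies(state, registry)
    r = build_rate_matrix(registry.get(state.model_indicator), freqs)
    cats = mixture_categories(state, k)
    rates = am.realize_branch_rates(tree, clock).rates
    blens = tree.branch_lengths()
    codes = aln.reordered(tree.labels).codes
    n_tips = tree.n_tips
    internals = list(range(n_tips, tree.n_nodes))
    total = 0.0
    site_logliks = []
    for site in range(aln.n_sites):
        site_lik = 0.0
        for w, crate in zip(cats.weights, cats.rates):
            pmats = {node: expm(r * blens[node] * rates[node] * crate)
                     for node in range(tree.n_nodes) if node != tree.root}
            lik = 0.0
            for assign in itertools.product(range(20), repeat=len(internals)):
                full = {n: a for n, a in zip(internals, assign)}
                prob = freqs[full[tree.root]]
                for node in range(tree.n_nodes):
                    if node == tree.root:
                        continue
                    pa = full[tree.parent[node]]
                    if node < n_tips:
                        c = codes[node, site]
                        prob *= 1.0 if c < 0 else pmats[node][pa, c]
                    else:
                        prob *= pmats[node][pa, full[node]]
                lik += prob
            site_lik += w * lik
        site_logliks.append(np.log(site_lik))
    return float(np.sum(site_logliks))


class TestCherryClosedForm:
    def test_two_taxon_one_site(self, registry, wag):
        tree = cherry(0.25, 0.4)
        aln = am.AminoAlignment.from_sequences(["a", "b"], ["W", "V"])
        state = am.SiteModelState(model_indicator=15)
        clock = am.ClockModel()
        got = am.pruning_loglik(tree, aln, state, clock, registry)
        r = build_rate_matrix(wag, wag.frequencies)
        p1, p2 = expm(r * 0.25), expm(r * 0.4)
        iw, iv = am.AMINO_ACIDS.index("W"), am.AMINO_ACIDS.index("V")
        hand = np.log(sum(wag.frequencies[i] * p1[i, iw] * p2[i, iv]
                          for i in range(20)))
        assert got == pytest.approx(hand, abs=1e-12)

    def test_all_gap_column_contributes_zero(self, registry):
        tree = cherry()
        aln = am.AminoAlignment.from_sequences(["a", "b"], ["W-", "V-"])
        one = am.AminoAlignment.from_sequences(["a", "b"], ["W", "V"])
        state = am.SiteModelState()
        clock = am.ClockModel()
        assert am.pruning_loglik(tree, aln, state, clock, registry) == \
            pytest.approx(am.pruning_loglik(tree, one, state, clock, registry),
                          abs=1e-12)


class TestExhaustiveOracle:
    def test_quartet_three_sites(self, registry):
        tree = balanced_quartet()
        aln = am.AminoAlignment.from_sequences(
            list("abcd"), ["WVA", "WIA", "LVC", "-VX"])
        state = am.SiteModelState(model_indicator=8)
        clock = am.ClockModel()
        got = am.pruning_loglik(tree, aln, state, clock, registry)
        want = exhaustive_loglik(tree, aln, state, clock, registry)
        assert got == pytest.approx(want, abs=1e-10)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_random_states_and_alignments(self, registry, seed):
        rng = np.random.default_rng(seed)
        state = am.SiteModelState(
            model_indicator=int(rng.integers(1, 16)),
            use_estimated_freqs=bool(rng.integers(2)),
            estimated_freqs=rng.dirichlet(np.full(20, 4.0)),
            has_gamma=bool(rng.integers(2)),
            alpha=float(0.1 + rng.exponential(1.0)),
            has_inv=bool(rng.integers(2)),
            p_inv=float(rng.beta(1, 4)),
        )
        n_taxa = int(rng.integers(2, 5))
        lam = float(rng.lognormal(np.log(5.5), 0.048))
        tree = am.sample_yule_tree(n_taxa, lam, rng)
        nb = tree.n_nodes - 1
        clock = am.ClockModel(kind="ucln", ucld_stdev=float(rng.gamma(0.5, 0.4)),
                              branch_categories=rng.integers(0, nb, size=nb))
        aln = am.simulate_alignment(tree, clock, state, 2, rng, registry)
        got = am.pruning_loglik(tree, aln, state, clock, registry)
        want = exhaustive_loglik(tree, aln, state, clock, registry)
        assert got == pytest.approx(want, abs=1e-10)


class TestLikelihoodProperties:
    def test_gamma_collapse_at_huge_alpha(self, registry):
        tree = balanced_quartet()
        aln = am.AminoAlignment.from_sequences(list("abcd"),
                                               ["WVAL", "WIAL", "LVCA", "MVRL"])
        clock = am.ClockModel()
        plain = am.pruning_loglik(tree, aln, am.SiteModelState(), clock, registry)
        flat = am.pruning_loglik(
            tree, aln, am.SiteModelState(has_gamma=True, alpha=1e6), clock, registry)
        assert flat == pytest.approx(plain, abs=1e-6)

    def test_pulley_principle(self, registry):
        # reversible model: a cherry's likelihood depends only on d1 + d2
        aln = am.AminoAlignment.from_sequences(["a", "b"], ["WVAL", "MIAL"])
        state = am.SiteModelState(model_indicator=9)
        clock = am.ClockModel()
        ref = am.pruning_loglik(cherry(0.2, 0.2), aln, state, clock, registry)
        for d1 in (0.05, 0.15, 0.33):
            got = am.pruning_loglik(cherry(d1, 0.4 - d1), aln, state, clock,
                                    registry)
            assert got == pytest.approx(ref, abs=1e-9)

    def test_label_mismatch_raises(self, registry):
        aln = am.AminoAlignment.from_sequences(["a", "x"], ["W", "V"])
        with pytest.raises(ValueError):
            am.pruning_loglik(cherry(), aln, am.SiteModelState(),
                              am.ClockModel(), registry)

    def test_long_alignment_does_not_underflow(self, registry):
        rng = np.random.default_rng(5)
        tree = am.sample_yule_tree(8, 5.5, rng)
        state = am.SiteModelState(has_gamma=True, alpha=0.3)
        clock = am.ClockModel()
        aln = am.simulate_alignment(tree, clock, state, 2000, rng, registry)
        ll = am.pruning_loglik(tree, aln, state, clock, registry)
        assert np.isfinite(ll)


class TestProbInvariableSite:
    def test_zero_branch_lengths_give_one(self, registry):
        tree = cherry(1e-12, 1e-12)
        p = am.prob_invariable_site(tree, am.SiteModelState(), am.ClockModel(),
                                    registry)
        assert p == pytest.approx(1.0, abs=1e-6)

    def test_three_quarters_limit_at_tiny_alpha(self, registry):
        rng = np.random.default_rng(42)
        tree = am.sample_yule_tree(16, 5.5, rng)
        state = am.SiteModelState(has_gamma=True, alpha=0.001)
        p = am.prob_invariable_site(tree, state, am.ClockModel(), registry)
        assert p == pytest.approx(0.75, abs=0.01)

    def test_two_taxon_closed_form(self, registry, wag):
        tree = cherry(0.3, 0.3)
        state = am.SiteModelState(model_indicator=15)
        got = am.prob_invariable_site(tree, state, am.ClockModel(), registry)
        r = build_rate_matrix(wag, wag.frequencies)
        p = expm(r * 0.3)
        want = sum(wag.frequencies[i] * p[i, a] * p[i, a]
                   for a in range(20) for i in range(20))
        assert got == pytest.approx(want, abs=1e-12)

    def test_monotone_decreasing_in_alpha(self, registry):
        rng = np.random.default_rng(9)
        tree = am.sample_yule_tree(16, 5.5, rng)
        clock = am.ClockModel()
        probs = [am.prob_invariable_site(
            tree, am.SiteModelState(has_gamma=True, alpha=a), clock, registry)
            for a in (0.05, 0.1, 0.2, 0.5, 1.0)]
        assert np.all(np.diff(probs) < 0)
        assert 0.0 < probs[-1] < probs[0] < 1.0


class TestClock:
    def test_strict_rates_constant(self):
        tree = balanced_quartet()
        rates = am.realize_branch_rates(tree, am.ClockModel(clock_rate=2.0)).rates
        assert np.allclose(rates, 2.0)

    def test_ucln_degenerate_sd(self):
        tree = balanced_quartet()
        clock = am.ClockModel(kind="ucln", ucld_stdev=0.0,
                              branch_categories=np.zeros(6, np.int64))
        assert np.allclose(am.realize_branch_rates(tree, clock).rates, 1.0)

    def test_ucln_discretization_mean_one(self):
        for s, n in [(0.1, 6), (0.5, 30), (1.2, 14)]:
            assert ucln_category_rates(s, n).mean() == pytest.approx(1.0, abs=1e-9)

    def test_ucln_needs_matching_categories(self):
        tree = balanced_quartet()
        clock = am.ClockModel(kind="ucln", branch_categories=np.zeros(3, np.int64))
        with pytest.raises(ValueError):
            am.realize_branch_rates(tree, clock)
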