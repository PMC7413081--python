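"""Proposal kernels and the Metropolis-Hastings engine."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import aamava as am
from aamava.mcmc import (
    AlphaScaleOperator,
    AvmnOperator,
    DeltaExchangeOperator,
    FreqSourceBitFlip,
    GammaBirthDeathOperator,
    IndicatorOperator,
    InvBirthDeathOperator,
    NarrowExchangeOperator,
    OperatorSchedule,
    PinvScaleOperator,
    alr_back_transform,
    alr_transform,
    chain_log_prior,
    mh_step,
)

HYPER = am.Hyperparameters()


def prior_state(seed=0, n_taxa=6, clock_kind="ucln"):
    rng = np.random.default_rng(seed)
    st = am.sample_chain_state(HYPER, n_taxa, rng, clock_kind=clock_kind)
    st.log_prior = chain_log_prior(st, HYPER)
    st.log_likelihood = 0.0
    return st


class TestIndicatorProposal:
    def test_single_model_registry_always_self(self):
        op = IndicatorOperator(1)
        state = prior_state()
        for _ in range(5):
            out = op.propose(state, np.random.default_rng(1))
            assert out.state.site.model_indicator == 1
            assert out.log_hastings == 0.0

    def test_uniform_over_fifteen(self):
        op = IndicatorOperator(15)
        rng = np.random.default_rng(2)
        state = prior_state()
        draws = [op.propose(state, rng).state.site.model_indicator
                 for _ in range(30000)]
        counts = np.bincount(draws, minlength=16)[1:]
        assert stats.chisquare(counts).pvalue > 0.01

    def test_hastings_always_zero(self):
        op = IndicatorOperator(15)
        rng = np.random.default_rng(3)
        state = prior_state()
        assert all(op.propose(state, rng).log_hastings == 0.0 for _ in range(100))


class TestBirthDeath:
    def test_birth_then_death_restores_state(self):
        op = GammaBirthDeathOperator(HYPER)
        state = prior_state(1)
        state.site = state.site.with_(has_gamma=False)
        rng = np.random.default_rng(4)
        born = op.propose(state, rng).state
        assert born.site.has_gamma
        back = op.propose(born, rng).state
        assert not back.site.has_gamma
        assert back.site.model_indicator == state.site.model_indicator
        assert np.array_equal(back.site.estimated_freqs, state.site.estimated_freqs)

    def test_birth_draws_respect_lower_bound(self):
        op = GammaBirthDeathOperator(HYPER)
        state = prior_state(1)
        state.site = state.site.with_(has_gamma=False)
        rng = np.random.default_rng(5)
        alphas = [op.propose(state, rng).state.site.alpha for _ in range(2000)]
        assert min(alphas) >= 0.1

    def test_hastings_cancels_prior_of_newborn(self):
        # with d = prior, birth Hastings + newborn prior term must vanish
        op = GammaBirthDeathOperator(HYPER)
        state = prior_state(2)
        state.site = state.site.with_(has_gamma=False)
        rng = np.random.default_rng(6)
        out = op.propose(state, rng)
        prior_delta = (am.log_prior_site_model(out.state.site, HYPER)
                       - am.log_prior_site_model(state.site, HYPER))
        assert prior_delta + out.log_hastings == pytest.approx(0.0, abs=1e-12)

    def test_inv_birth_in_unit_interval(self):
        op = InvBirthDeathOperator(HYPER)
        state = prior_state(3)
        state.site = state.site.with_(has_inv=False, p_inv=0.0)
        rng = np.random.default_rng(7)
        draws = [op.propose(state, rng).state.site.p_inv for _ in range(2000)]
        assert all(0.0 <= p < 1.0 for p in draws)


class TestBitFlip:
    def test_double_toggle_restores(self):
        op = FreqSourceBitFlip()
        state = prior_state(4)
        rng = np.random.default_rng(8)
        once = op.propose(state, rng).state
        twice = op.propose(once, rng).state
        assert twice.site.use_estimated_freqs == state.site.use_estimated_freqs

    def test_never_mutates_estimated_freqs(self):
        op = FreqSourceBitFlip()
        state = prior_state(4)
        rng = np.random.default_rng(9)
        cur = state
        for _ in range(10):
            cur = op.propose(cur, rng).state
            assert np.array_equal(cur.site.estimated_freqs,
                                  state.site.estimated_freqs)


class TestGatedScale:
    def test_not_applicable_when_flag_off(self):
        state = prior_state(5)
        state.site = state.site.with_(has_gamma=False, has_inv=False)
        rng = np.random.default_rng(10)
        assert AlphaScaleOperator(HYPER).propose(state, rng) is None
        assert PinvScaleOperator().propose(state, rng) is None

    def test_degenerate_bounds_identity(self):
        state = prior_state(5)
        state.site = state.site.with_(has_gamma=True, alpha=0.7)
        out = AlphaScaleOperator(HYPER, beta=1.0).propose(
            state, np.random.default_rng(11))
        assert out.state.site.alpha == pytest.approx(0.7, rel=1e-12)
        assert out.log_hastings == pytest.approx(0.0, abs=1e-12)

    def test_below_truncation_rejected(self):
        state = prior_state(5)
        state.site = state.site.with_(has_gamma=True, alpha=0.1001)
        op = AlphaScaleOperator(HYPER, beta=0.5)
        rejected = 0
        rng = np.random.default_rng(12)
        for _ in range(200):
            out = op.propose(state, rng)
            if out.state is None:
                assert out.log_hastings == -math.inf
                rejected += 1
        assert rejected > 0


class _StubRng:
    """Deterministic stand-in driving one delta-exchange proposal."""

    def __init__(self, pair, u):
        self.pair = np.array(pair)
        self.u = u

    def choice(self, n, size, replace):
        return self.pair

    def random(self):
        return self.u


class TestDeltaExchange:
    def test_sum_preserved_exactly(self):
        op = DeltaExchangeOperator(0.05)
        state = prior_state(6)
        rng = np.random.default_rng(13)
        for _ in range(200):
            out = op.propose(state, rng)
            if out.state is not None:
                assert out.state.site.estimated_freqs.sum() == pytest.approx(
                    state.site.estimated_freqs.sum(), abs=1e-15)
                assert out.log_hastings == 0.0

    def test_out_of_bound_rejected(self):
        state = prior_state(6)
        f = state.site.estimated_freqs.copy()
        f[1] = 0.001
        f /= f.sum()
        state.site = state.site.with_(estimated_freqs=f)
        op = DeltaExchangeOperator(window=0.01)
        out = op.propose(state, _StubRng(pair=(0, 1), u=0.9999))
        assert out.state is None and out.log_hastings == -math.inf

    def test_pair_selection_symmetric(self):
        op = DeltaExchangeOperator(0.001)
        state = prior_state(6)
        rng = np.random.default_rng(14)
        counts = np.zeros((20, 20))
        for _ in range(20000):
            pair = rng.choice(20, size=2, replace=False)
            counts[pair[0], pair[1]] += 1
        sym = counts + counts.T
        flat = sym[np.triu_indices(20, 1)]
        assert stats.chisquare(flat).pvalue > 0.01


class TestAvmn:
    def test_transform_round_trip(self):
        rng = np.random.default_rng(15)
        f = rng.dirichlet(np.full(20, 4.0))
        assert np.allclose(alr_back_transform(alr_transform(f)), f, atol=1e-12)

    def test_vanishing_step_accepts_everything(self):
        from aamava.mcmc import AvmnAdaptation
        op = AvmnOperator(AvmnAdaptation(burnin=10 ** 9, initial_step=1e-7))
        state = prior_state(7)
        rng = np.random.default_rng(16)
        accepted = 0
        for _ in range(100):
            out = op.propose(state, rng)
            state, acc = mh_step(state, out, rng, HYPER, None)
            accepted += acc
        assert accepted >= 99

    def test_adaptation_learns_dirichlet_covariance(self):
        # run a frequency-only prior chain; the operator's learned covariance
        # must approach the true covariance of transformed Dirichlet samples
        op = AvmnOperator()
        cfg = am.RunConfig(chain_length=30000, log_every=1000,
                           use_likelihood=False,
                           operators=[(op, 1.0), (DeltaExchangeOperator(0.1), 1.0)])
        am.run_chain(cfg, seed=17)
        rng = np.random.default_rng(18)
        ys = np.array([alr_transform(rng.dirichlet(np.full(20, 4.0)))
                       for _ in range(20000)])
        truth = np.cov(ys.T)
        err = np.linalg.norm(op.adapt.cov - truth) / np.linalg.norm(truth)
        assert err < 0.20


class TestTreeMoves:
    def test_narrow_exchange_enumerates_both_alternatives(self):
        tree = am.TimeTree(["a", "b", "c"], np.array([3, 3, 4, 4, -1]),
                           np.array([[-1, -1]] * 3 + [[0, 1], [2, 3]]),
                           np.array([0, 0, 0, 0.1, 0.4]))
        state = prior_state(8, n_taxa=3)
        state.tree = tree
        op = NarrowExchangeOperator()
        rng = np.random.default_rng(19)
        seen = {"bc": 0, "ac": 0}
        for _ in range(4000):
            out = op.propose(state, rng)
            assert out.log_hastings == 0.0
            clades = set(out.state.tree.clade_bitsets().values())
            if frozenset({"b", "c"}) in clades:
                seen["bc"] += 1
            elif frozenset({"a", "c"}) in clades:
                seen["ac"] += 1
        assert stats.chisquare([seen["bc"], seen["ac"]]).pvalue > 0.01

    def test_height_moves_preserve_validity(self):
        from aamava.mcmc import (RootScaleOperator, TreeScaleOperator,
                                 UniformHeightOperator)
        state = prior_state(9, n_taxa=8)
        rng = np.random.default_rng(20)
        for op in (TreeScaleOperator(), RootScaleOperator(), UniformHeightOperator()):
            for _ in range(50):
                out = op.propose(state, rng)
                if out is not None and out.state is not None:
                    out.state.tree.validate()


class TestMhStep:
    def test_identity_proposal_always_accepted(self):
        from aamava.mcmc import ProposalOutcome
        state = prior_state(10)
        out = ProposalOutcome(state.replaced(), 0.0)
        new, accepted = mh_step(state, out, np.random.default_rng(21), HYPER, None)
        assert accepted

    def test_minus_inf_hastings_never_accepted(self):
        from aamava.mcmc import ProposalOutcome
        state = prior_state(10)
        out = ProposalOutcome(state.replaced(), -math.inf)
        new, accepted = mh_step(state, out, np.random.default_rng(22), HYPER, None)
        assert not accepted and new is state

    def test_two_state_balance(self):
        # bit-flip chain on the frequency-source flag: empirical transition
        # counts in the two directions must agree (detailed balance)
        cfg = am.RunConfig(chain_length=20000, log_every=1,
                           use_likelihood=False,
                           operators=[(FreqSourceBitFlip(), 1.0)])
        res = am.run_chain(cfg, seed=23)
        x = res.trace["useEstimatedFreqs"].to_numpy()
        up = int(np.sum((x[:-1] == 0) & (x[1:] == 1)))
        down = int(np.sum((x[:-1] == 1) & (x[1:] == 0)))
        assert stats.binomtest(up, up + down, 0.5).pvalue > 0.01


class TestRunChain:
    def test_same_seed_bit_identical(self):
        cfg = am.RunConfig(chain_length=2000, log_every=20, use_likelihood=False)
        a = am.run_chain(cfg, seed=99)
        b = am.run_chain(cfg, seed=99)
        pd.testing.assert_frame_equal(a.trace, b.trace)
        assert [t.to_newick() for t in a.trees] == [t.to_newick() for t in b.trees]

    def test_bsvs_freqs_only_touched_by_freq_operators(self):
        from aamava.mcmc import IndicatorOperator
        cfg = am.RunConfig(chain_length=3000, log_every=10, use_likelihood=False,
                           operators=[(FreqSourceBitFlip(), 1.0),
                                      (IndicatorOperator(15), 1.0)])
        res = am.run_chain(cfg, seed=24)
        est = res.trace[res.trace.useEstimatedFreqs == 1]
        assert len(est) > 10
        for i in range(1, 21):
            assert est[f"frequencies.{i}"].nunique() == 1

    def test_smoke_ess_on_quartet_alignment(self, registry):
        rng = np.random.default_rng(25)
        truth = am.sample_prior_replicate(
            HYPER, am.StudyCondition(), rng, n_taxa=4, clock_kind="strict")
        aln = am.simulate_alignment(truth.tree, truth.clock, truth.site, 100, rng,
                                    registry)
        cfg = am.RunConfig(log_every=50, clock_kind="strict")  # default length
        res = am.run_chain(cfg, seed=26, alignment=aln, registry=registry)
        trace = res.trace.iloc[200:]
        assert am.ess(trace["posterior"].to_numpy()) > 200

    def test_invalid_config_reported_before_sampling(self):
        with pytest.raises(ValueError):
            am.run_chain(am.RunConfig(chain_length=0), seed=1)
        with pytest.raises(ValueError):
            OperatorSchedule([])
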