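"""Shared fixtures.

The expensive prior-recovery MCMC run (likelihood disabled) is session
scoped and reused by every test that checks a marginal against its prior.
"""

from __future__ import annotations

import numpy as np
import pytest

import aamava as am


@pytest.fixture(scope="session")
def registry():
    return am.builtin_registry()


@pytest.fixture(scope="session")
def wag(registry):
    return registry.get(15)


@pytest.fixture(scope="session")
def prior_run():
    """A likelihood-off chain long enough for distributional checks."""
    cfg = am.RunConfig(chain_length=150_000, log_every=25, use_likelihood=False,
                       clock_kind="ucln")
    return am.run_chain(cfg, seed=20_260_924)


@pytest.fixture(scope="session")
def prior_trace(prior_run):
    trace = prior_run.trace
    return trace.iloc[int(0.1 * len(trace)):]


def balanced_quartet(heights=(0.1, 0.12, 0.3), labels=("a", "b", "c", "d")):
    """((a,b),(c,d)) with internal heights h_ab, h_cd, h_root."""
    h_ab, h_cd, h_root = heights
    parent = np.array([4, 4, 5, 5, 6, 6, -1])
    children = np.array([[-1, -1]] * 4 + [[0, 1], [2, 3], [4, 5]])
    h = np.array([0.0, 0.0, 0.0, 0.0, h_ab, h_cd, h_root])
    return am.TimeTree(list(labels), parent, children, h)


def cherry(d1=0.3, d2=0.3, labels=("a", "b")):
    """Two-taxon tree; tip heights allow unequal root-to-tip distances."""
    root = max(d1, d2)
    parent = np.array([2, 2, -1])
    children = np.array([[-1, -1], [-1, -1], [0, 1]])
    heights = np.array([root - d1, root - d2, root])
    return am.TimeTree(list(labels), parent, children, heights)
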