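"""Shared fixtures and independent oracles for the test suite.

The oracles deliberately avoid the package's own asymptotic machinery:
permutation and parametric-bootstrap p-values are computed by re-running a
test on resampled data and comparing on the p-value scale (smaller p = more
extreme), which is monotone-invariant to the statistic's direction.
"""
from __future__ import annotations

import numpy as np
import pytest

from circompare.core import CircularDataError, kappa_mle, summarize, trig_moment
from circompare.simulate import sample_von_mises


def permutation_pvalue(test_fn, a1, a2, nperm=2000, seed=0):
    """Permutation p-value of an arbitrary two-sample test.

    Extreme = asymptotic p-value at most the observed one; add-one rule.
    """
    p_obs = test_fn(a1, a2).p_value
    pooled = np.concatenate([a1, a2])
    n1 = len(a1)
    rng = np.random.default_rng(seed)
    hits = 0
    used = 0
    for _ in range(nperm):
        perm = rng.permutation(pooled)
        try:
            p = test_fn(perm[:n1], perm[n1:]).p_value
        except CircularDataError:
            continue
        used += 1
        if p <= p_obs + 1e-12:
            hits += 1
    return (hits + 1) / (used + 1)


def parametric_bootstrap_pvalue(test_fn, a1, a2, nboot=2000, seed=0):
    """Parametric-bootstrap p-value under a fitted common von Mises model."""
    p_obs = test_fn(a1, a2).p_value
    pooled = np.concatenate([a1, a2])
    s = summarize(pooled)
    mu = s.mu_hat if s.mu_defined else 0.0
    kappa = s.kappa_hat
    n1, n2 = len(a1), len(a2)
    rng = np.random.default_rng(seed)
    hits = 0
    used = 0
    for _ in range(nboot):
        b1 = sample_von_mises(n1, mu, kappa, rng)
        b2 = sample_von_mises(n2, mu, kappa, rng)
        try:
            p = test_fn(b1, b2).p_value
        except CircularDataError:
            continue
        used += 1
        if p <= p_obs + 1e-12:
            hits += 1
    return (hits + 1) / (used + 1)


def rejection_rate(test_fn, draw, nsim, alpha=0.05, seed=0):
    """Rejection proportion of ``test_fn`` over seeded replicate draws."""
    rej = 0
    used = 0
    for rep in range(nsim):
        rng = np.random.default_rng(np.random.SeedSequence([seed, rep]))
        a1, a2 = draw(rng)
        try:
            p = test_fn(a1, a2).p_value
        except CircularDataError:
            continue
        used += 1
        if p <= alpha:
            rej += 1
    return rej / used


@pytest.fixture(scope="session")
def vm_pair_kappa2():
    """Two von Mises(kappa=2) samples, means 0 and 60 degrees, n=15 each."""
    rng = np.random.default_rng(42)
    return (
        sample_von_mises(15, 0.0, 2.0, rng),
        sample_von_mises(15, np.deg2rad(60.0), 2.0, rng),
    )


@pytest.fixture(scope="session")
def vm_pair_null_n50():
    """Two samples from one von Mises(0, kappa=2) population, n=50 each."""
    rng = np.random.default_rng(7)
    return (
        sample_von_mises(50, 0.0, 2.0, rng),
        sample_von_mises(50, 0.0, 2.0, rng),
    )
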