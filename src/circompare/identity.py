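"""Tests of the null hypothesis that two circular distributions are identical.

Eight tests: Watson's two-sample U2 (WU2), the Kuiper two-sample test (Kui),
the uniform-scores test in its large-sample Mardia-Watson-Wheeler (MWW) and
Watson-Wheeler (WWe) guises, three one-way circular ANOVAs (embedding EmA,
likelihood-ratio LlA, heterogeneous-concentration HeA), and a MANOVA on the
(cos, sin) embedding (Man).

All p-values are asymptotic; permutation versions exist only as oracles in
the test suite.
"""
from __future__ import annotations

import numpy as np
from scipy import special

from .core import (
    CircularDataError,
    TestResult,
    as_angles,
    kappa_mle,
    uniform_scores,
)

NULL_IDENTITY = "identical-distribution"

__all__ = [
    "watson_u2",
    "kuiper_two",
    "uniform_scores_test",
    "embedding_anova",
    "lr_anova",
    "het_anova",
    "manova_trig",
]

_SERIES_TOL = 1e-12
_SERIES_MAX_TERMS = 1000


def _ecdf_diffs(a1: np.ndarray, a2: np.ndarray) -> np.ndarray:
    """F1 - F2 evaluated after each pooled order statistic (length N)."""
    n1, n2 = a1.size, a2.size
    vals = np.concatenate([a1, a2])
    steps = np.concatenate([np.full(n1, 1.0 / n1), np.full(n2, -1.0 / n2)])
    order = np.argsort(vals, kind="stable")
    return np.cumsum(steps[order])


def watson_u2_pvalue(u2: float) -> float:
    """Asymptotic tail probability 2 * sum (-1)^(m-1) exp(-2 m^2 pi^2 u2)."""
    if u2 <= 1e-10:
        return 1.0
    total = 0.0
    for m in range(1, _SERIES_MAX_TERMS + 1):
        term = (-1.0) ** (m - 1) * np.exp(-2.0 * m * m * np.pi**2 * u2)
        total += term
        if abs(term) < _SERIES_TOL:
            break
    return float(np.clip(2.0 * total, 0.0, 1.0))


def watson_u2(s1, s2) -> TestResult:
    """Watson's two-sample U2 test (rank-based, rotation invariant).

    U2 = n1*n2/N^2 * [sum d_k^2 - (sum d_k)^2 / N] with d_k the difference of
    the two empirical CDFs at the k-th pooled order statistic.  The asymptotic
    series is reliable for combined samples above 17; smaller pools are
    flagged, not rejected.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    n1, n2 = a1.size, a2.size
    n = n1 + n2
    d = _ecdf_diffs(a1, a2)
    u2 = n1 * n2 / n**2 * (np.sum(d * d) - np.sum(d) ** 2 / n)
    u2 = max(float(u2), 0.0)
    warnings = ("combined sample size <= 17; asymptotic p unreliable",) if n <= 17 else ()
    return TestResult("WU2", NULL_IDENTITY, u2, (), watson_u2_pvalue(u2), warnings)


def kuiper_pvalue(v: float, n_eff: float) -> float:
    """Stephens-corrected asymptotic Kuiper tail probability."""
    z = v * (np.sqrt(n_eff) + 0.155 + 0.24 / np.sqrt(n_eff))
    if z < 0.2:
        return 1.0
    total = 0.0
    for m in range(1, _SERIES_MAX_TERMS + 1):
        term = 2.0 * (4.0 * m * m * z * z - 1.0) * np.exp(-2.0 * m * m * z * z)
        total += term
        if abs(term) < _SERIES_TOL:
            break
    return float(np.clip(total, 0.0, 1.0))


def kuiper_two(s1, s2) -> TestResult:
    """Kuiper's two-sample test on the circle.

    V = sup(F1 - F2) + sup(F2 - F1) over the pooled circle, referred to the
    Stephens-type asymptotic series with effective size n1*n2/(n1+n2).  Known
    to over-reject at small sample sizes; that behaviour is reproduced here.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    n1, n2 = a1.size, a2.size
    d = _ecdf_diffs(a1, a2)
    v = float(max(d.max(), 0.0) - min(d.min(), 0.0))
    n_eff = n1 * n2 / (n1 + n2)
    return TestResult("Kui", NULL_IDENTITY, v, (), kuiper_pvalue(v, n_eff), ())


def uniform_scores_test(s1, s2, variant: str = "MWW", seed: int = 0) -> TestResult:
    """Uniform-scores (Mardia-Watson-Wheeler / Watson-Wheeler) test.

    With scores beta from :func:`circompare.core.uniform_scores`,
    W = 2 * sum_j (C_j^2 + S_j^2)/n_j is referred to chi-square with 2 df.
    The two variants share the statistic and differ only in their assumption
    guards: MWW warns when either group has n <= 10, WWe warns when ties had
    to be jittered.
    """
    if variant not in ("MWW", "WWe"):
        raise ValueError("variant must be 'MWW' or 'WWe'")
    a1, a2 = as_angles(s1), as_angles(s2)
    b1, b2, tied = uniform_scores(a1, a2, seed=seed)
    w = 0.0
    for b, nj in ((b1, a1.size), (b2, a2.size)):
        c = np.sum(np.cos(b))
        s = np.sum(np.sin(b))
        w += (c * c + s * s) / nj
    w *= 2.0
    p = float(special.chdtrc(2.0, w))
    warnings = []
    if variant == "MWW" and min(a1.size, a2.size) <= 10:
        warnings.append("group size <= 10; large-sample chi-square approximation unreliable")
    if variant == "WWe" and tied:
        warnings.append("tied angles jittered; data should be continuous (ungrouped)")
    return TestResult(variant, NULL_IDENTITY, float(w), (2.0,), p, tuple(warnings))


def _group_resultants(a1: np.ndarray, a2: np.ndarray):
    """Per-group and pooled resultant lengths (R1, R2, R)."""
    c1, s1 = np.sum(np.cos(a1)), np.sum(np.sin(a1))
    c2, s2 = np.sum(np.cos(a2)), np.sum(np.sin(a2))
    r1 = float(np.hypot(c1, s1))
    r2 = float(np.hypot(c2, s2))
    r = float(np.hypot(c1 + c2, s1 + s2))
    return r1, r2, r


def _resultant_decomposition(s1, s2, caller: str):
    """Shared plumbing of the two circular one-way ANOVAs (EmA, LlA).

    Returns 2 * kappa_hat * (R1 + R2 - R) with the common concentration
    estimated from the pooled mean resultant R/N.  Because the pooled
    concentration estimate collapses when the two samples sit on opposing
    directions, tests built on this decomposition lose power as the mean
    separation approaches 180 degrees (the hump-shaped power curve).
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    n1, n2 = a1.size, a2.size
    if min(n1, n2) < 2:
        raise CircularDataError(f"{caller} needs at least 2 observations per group")
    n = n1 + n2
    r1, r2, r = _group_resultants(a1, a2)
    kappa = kappa_mle(r / n)
    return 2.0 * kappa * max(r1 + r2 - r, 0.0)


def embedding_anova(s1, s2) -> TestResult:
    """Embedding-approach one-way ANOVA for circular data (EmA).

    The angles are embedded as unit vectors and the between-group component
    of the resultant decomposition, scaled by the pooled concentration
    estimate, is referred to chi-square with 2(g-1) degrees of freedom - the
    dimension of the embedded between-group variation.  The two-dimensional
    reference makes the test conservative for concentrated samples (where
    the variation is effectively tangential), which is why it is robust
    across situations but less powerful than the rank-based competitors.
    """
    stat = _resultant_decomposition(s1, s2, "embedding ANOVA")
    p = float(special.chdtrc(2.0, stat))
    return TestResult("EmA", NULL_IDENTITY, float(stat), (2.0,), p, ())


def lr_anova(s1, s2) -> TestResult:
    """Likelihood-ratio ANOVA for a common von Mises mean direction (LlA).

    Assumes each group is von Mises with a shared concentration estimated
    from the pooled mean resultant R/N; the statistic
    -2 log Lambda ~= 2 * kappa_hat * (R1 + R2 - R) is referred to chi-square
    with g - 1 df.  The one-dimensional reference is exact only for unimodal
    von Mises groups; for asymmetric bimodal mixtures the mean direction is
    noisier than the pooled concentration implies and the test over-rejects.
    """
    stat = _resultant_decomposition(s1, s2, "likelihood-ratio ANOVA")
    p = float(special.chdtrc(1.0, stat))
    return TestResult("LlA", NULL_IDENTITY, float(stat), (1.0,), p, ())


def het_anova(s1, s2) -> TestResult:
    """Equality of mean directions without a common concentration (HeA).

    Each group gets weight w_i = R_i * kappa_hat_i on its embedded mean
    direction; the statistic 2 * (sum w_i - |sum w_i u_i|) is referred to
    chi-square with g - 1 df.  Per-group concentration estimates make the
    test anti-conservative at small n.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    if min(a1.size, a2.size) < 2:
        raise CircularDataError("heterogeneous ANOVA needs at least 2 observations per group")
    sw = 0.0
    vx = 0.0
    vy = 0.0
    for a in (a1, a2):
        c, s = np.sum(np.cos(a)), np.sum(np.sin(a))
        ri = float(np.hypot(c, s))
        rbar = ri / a.size
        if rbar <= 1e-12:
            raise CircularDataError("undefined mean direction (zero resultant) in one group")
        w = ri * kappa_mle(rbar)
        sw += w
        vx += w * c / ri
        vy += w * s / ri
    stat = 2.0 * max(sw - float(np.hypot(vx, vy)), 0.0)
    p = float(special.chdtrc(1.0, stat))
    return TestResult("HeA", NULL_IDENTITY, float(stat), (1.0,), p, ())


def manova_trig(s1, s2) -> TestResult:
    """MANOVA on the (cos theta, sin theta) responses with a group factor (Man).

    Pillai's trace V = tr(H (H + E)^{-1}) with its standard F approximation;
    for two groups and two responses this is F = (N-3)/2 * V/(1-V) on
    (2, N-3) degrees of freedom.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    n1, n2 = a1.size, a2.size
    if min(n1, n2) < 3:
        raise CircularDataError("MANOVA needs at least 3 observations per group")
    n = n1 + n2
    y1 = np.column_stack([np.cos(a1), np.sin(a1)])
    y2 = np.column_stack([np.cos(a2), np.sin(a2)])
    m1 = y1.mean(axis=0)
    m2 = y2.mean(axis=0)
    grand = (n1 * m1 + n2 * m2) / n
    h = n1 * np.outer(m1 - grand, m1 - grand) + n2 * np.outer(m2 - grand, m2 - grand)
    d1 = y1 - m1
    d2 = y2 - m2
    e = d1.T @ d1 + d2.T @ d2
    t = h + e
    # Guard: all angles identical makes the within-group scatter singular.
    scale = float(np.trace(t))
    if scale <= 0.0 or np.linalg.det(t) < 1e-14 * scale**2:
        raise CircularDataError("singular within-group covariance of the embedded responses")
    v = float(np.trace(np.linalg.solve(t, h)))
    v = min(max(v, 0.0), 1.0 - 1e-15)
    f = (n - 3) / 2.0 * v / (1.0 - v)
    df = (2.0, float(n - 3))
    p = float(special.fdtrc(df[0], df[1], f))
    return TestResult("Man", NULL_IDENTITY, float(f), df, p, ())
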