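"""Tests of the null hypothesis that two circular samples share a concentration.

Four procedures: the two-sample von Mises concentration test with Fisher's
three-regime variance-stabilising construction (Con), Fisher's tangential
ANOVA of a common concentration (FM), the Wallraff rank-sum test on angular
deviations from the group medians (Wal), and the median-centred
(Brown-Forsythe) Levene test applied to the raw angle values on the fixed
frame [0, 2*pi) (Lev).  Rao's dispersion component (Rdi) also belongs to this
null class but is computed by :func:`circompare.meandir.rao_homogeneity`.

The Levene test deliberately treats angles as linear numbers: this exactly
reproduces the linear-statistics usage benchmarked in the study, and is the
mechanism behind its power against mean shifts (wraparound inflates the
linear variance of a group whose mean sits near 0/360 degrees).
"""
from __future__ import annotations

import numpy as np
from scipy import special

from .core import (
    CircularDataError,
    TestResult,
    angular_distance,
    as_angles,
    circular_median,
    trig_moment,
)

NULL_CONC = "identical-concentration"

__all__ = [
    "concentration_f_test",
    "fisher_concentration",
    "wallraff",
    "levene_circular",
]


def _oneway_f(z1: np.ndarray, z2: np.ndarray):
    """One-way ANOVA F for two groups; returns (F, df1, df2, upper-tail p)."""
    n1, n2 = z1.size, z2.size
    n = n1 + n2
    m1, m2 = z1.mean(), z2.mean()
    grand = (n1 * m1 + n2 * m2) / n
    ssb = n1 * (m1 - grand) ** 2 + n2 * (m2 - grand) ** 2
    ssw = float(np.sum((z1 - m1) ** 2) + np.sum((z2 - m2) ** 2))
    if ssw <= 0.0:
        raise CircularDataError("zero within-group deviation in both groups")
    f = (ssb / 1.0) / (ssw / (n - 2))
    p = float(special.fdtrc(1.0, float(n - 2), f))
    return float(f), 1.0, float(n - 2), p


def concentration_f_test(s1, s2) -> TestResult:
    """Two-sample von Mises equal-concentration test (Con).

    The regime is chosen by the weighted average of the per-group mean
    resultant lengths, r = (R1 + R2)/N:

    * r < 0.45 - variance-stabilised arcsine transform of 2*r_bar_j,
      compared as a standard normal deviate;
    * 0.45 <= r <= 0.70 - asinh((r_bar_j - 1.089)/0.258) transform,
      standard normal deviate with scale 0.893/sqrt(n_j - 3);
    * r > 0.70 - high-concentration variance ratio
      F = [(n1 - R1)/(n1 - 1)] / [(n2 - R2)/(n2 - 1)] on (n1-1, n2-1) df.

    All branches report a two-sided p-value.  Per-group (not pooled-sample)
    resultants drive both the regime choice and the statistic, so the test is
    insensitive to a pure difference in mean direction.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    n1, n2 = a1.size, a2.size
    if min(n1, n2) < 2:
        raise CircularDataError("concentration test needs at least 2 observations per group")
    rbar1, _ = trig_moment(a1, 1)
    rbar2, _ = trig_moment(a2, 1)
    rw = (n1 * rbar1 + n2 * rbar2) / (n1 + n2)
    if rw < 0.45:
        w1 = np.arcsin(min(2.0 * rbar1 * np.sqrt(3.0 / 8.0), 1.0))
        w2 = np.arcsin(min(2.0 * rbar2 * np.sqrt(3.0 / 8.0), 1.0))
        # variance-stabilised scale of asin(sqrt(3/8)*2*rbar) under von Mises
        # sampling is ~ (3/4)/n across the regime
        se = np.sqrt(3.0 / 4.0 * (1.0 / max(n1 - 4, 1) + 1.0 / max(n2 - 4, 1)))
        z = float((w1 - w2) / se)
        p = float(2.0 * special.ndtr(-abs(z)))
        return TestResult("Con", NULL_CONC, z, (), p, ())
    if rw <= 0.70:
        w1 = np.arcsinh((rbar1 - 1.089) / 0.258)
        w2 = np.arcsinh((rbar2 - 1.089) / 0.258)
        se = 0.893 * np.sqrt(1.0 / max(n1 - 3, 1) + 1.0 / max(n2 - 3, 1))
        z = float((w1 - w2) / se)
        p = float(2.0 * special.ndtr(-abs(z)))
        return TestResult("Con", NULL_CONC, z, (), p, ())
    r1, r2 = n1 * rbar1, n2 * rbar2
    f = ((n1 - r1) / (n1 - 1)) / ((n2 - r2) / (n2 - 1))
    df = (float(n1 - 1), float(n2 - 1))
    upper = float(special.fdtrc(df[0], df[1], f))
    lower = float(special.fdtr(df[0], df[1], f))
    p = float(np.clip(2.0 * min(upper, lower), 0.0, 1.0))
    return TestResult("Con", NULL_CONC, float(f), df, p, ())


def fisher_concentration(s1, s2) -> TestResult:
    """Fisher's tangential test of a common concentration parameter (FM).

    Each observation is reduced to its absolute tangential component
    d_ij = |sin(theta_ij - mu_hat_i)| about the group mean direction; a
    one-way ANOVA on the d_ij compares concentrations.  Robust for symmetric
    distributions, anti-conservative for strongly skewed (wrapped
    skew-normal) populations.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    if min(a1.size, a2.size) < 2:
        raise CircularDataError("Fisher's method needs at least 2 observations per group")
    ds = []
    for a in (a1, a2):
        rbar, mu = trig_moment(a, 1)
        if rbar <= 1e-12:
            raise CircularDataError("undefined mean direction (zero resultant) in one group")
        ds.append(np.abs(np.sin(a - mu)))
    f, df1, df2, p = _oneway_f(ds[0], ds[1])
    return TestResult("FM", NULL_CONC, f, (df1, df2), p, ())


def _rank_sum_normal(z1: np.ndarray, z2: np.ndarray):
    """Two-sided Wilcoxon rank-sum p (normal approximation, tie-corrected)."""
    n1, n2 = z1.size, z2.size
    n = n1 + n2
    pooled = np.concatenate([z1, z2])
    order = np.argsort(pooled, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    # midranks for ties
    sorted_vals = pooled[order]
    i = 0
    tie_term = 0.0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        if j > i:
            t = j - i + 1
            ranks[order[i : j + 1]] = 0.5 * (i + 1 + j + 1)
            tie_term += t**3 - t
        i = j + 1
    w = float(np.sum(ranks[:n1]))
    u = w - n1 * (n1 + 1) / 2.0
    mean_u = n1 * n2 / 2.0
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0.0:
        raise CircularDataError("all deviations tied; rank-sum variance is zero")
    # continuity correction toward the mean
    num = u - mean_u
    num = np.sign(num) * max(abs(num) - 0.5, 0.0)
    z = float(num / np.sqrt(var_u))
    p = float(2.0 * special.ndtr(-abs(z)))
    return float(u), z, min(p, 1.0)


def wallraff(s1, s2, center: str = "mean") -> TestResult:
    """Wallraff's rank-sum test of angular dispersion (Wal).

    Each observation is reduced to its angular distance from the own-group
    mean direction (``center='median'`` uses the circular median instead,
    kept as an option but not benchmarked); a two-sided Wilcoxon rank-sum
    test (normal approximation with tie correction) compares the two
    deviation samples.  Reported statistic is the Mann-Whitney U of the
    first sample.

    Mean-direction centering matters for the test's behaviour: the mean
    direction does not minimise the expected angular deviation of a skewed
    population, so centre noise propagates into the deviations at first
    order and the test over-rejects for skewed (wrapped skew-normal)
    populations while remaining calibrated for symmetric ones.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    devs = []
    tied = False
    for a in (a1, a2):
        if center == "median":
            ref = circular_median(a)
        elif center == "mean":
            rbar, mu = trig_moment(a, 1)
            if rbar <= 1e-12:
                raise CircularDataError("undefined mean direction (zero resultant) in one group")
            ref = mu
        else:
            raise ValueError("center must be 'mean' or 'median'")
        devs.append(angular_distance(a, ref))
    pooled = np.concatenate(devs)
    tied = np.unique(pooled).size < pooled.size
    u, _, p = _rank_sum_normal(devs[0], devs[1])
    warnings = ("tied deviations; data should be continuous (ungrouped)",) if tied else ()
    return TestResult("Wal", NULL_CONC, u, (), p, warnings)


def levene_circular(s1, s2) -> TestResult:
    """Brown-Forsythe (median-centred) Levene test on raw angle values (Lev).

    Angles are treated as plain numbers on the fixed frame [0, 2*pi); the
    test statistic is the one-way ANOVA F of the absolute deviations from
    each group's linear median, on (1, N-2) df.  Deliberately not rotation
    invariant.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    if min(a1.size, a2.size) < 2:
        raise CircularDataError("Levene's test needs at least 2 observations per group")
    z1 = np.abs(a1 - np.median(a1))
    z2 = np.abs(a2 - np.median(a2))
    f, df1, df2, p = _oneway_f(z1, z2)
    return TestResult("Lev", NULL_CONC, f, (df1, df2), p, ())
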