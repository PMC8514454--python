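"""Tests of the null hypothesis that two circular samples share a mean/median.

Five procedures: the Watson-Williams F test (WWi), Watson's large-sample
nonparametric test (Wat), Fisher's nonparametric common-median test (FPg),
the asymptotic P-test of Rumcheva & Presnell (Pt), and Rao's two-part
homogeneity test whose polar component (Rpo) compares mean directions through
the tangents of the group resultants and whose dispersion component (Rdi) is
surfaced by the equal-concentration registry.
"""
from __future__ import annotations

import numpy as np
from scipy import special

from .core import (
    CircularDataError,
    TestResult,
    as_angles,
    circular_median,
    kappa_mle,
    trig_moment,
)

NULL_MEAN = "identical-mean"
NULL_CONC = "identical-concentration"

__all__ = [
    "watson_williams",
    "watson_large_sample",
    "fisher_common_median",
    "p_test_asymptotic",
    "rao_homogeneity",
]


def _resultants(a1: np.ndarray, a2: np.ndarray):
    c1, s1 = np.sum(np.cos(a1)), np.sum(np.sin(a1))
    c2, s2 = np.sum(np.cos(a2)), np.sum(np.sin(a2))
    r1 = float(np.hypot(c1, s1))
    r2 = float(np.hypot(c2, s2))
    r = float(np.hypot(c1 + c2, s1 + s2))
    return r1, r2, r


def watson_williams(s1, s2) -> TestResult:
    """Watson-Williams F test of a common mean direction (WWi).

    F = (1 + 3/(8 kappa_hat)) * (N-2)(R1 + R2 - R) / (N - R1 - R2) on
    (1, N-2) df, with kappa_hat from the pooled within-group mean resultant
    (R1 + R2)/N.  Assumes von Mises groups of common concentration; a warning
    is attached when kappa_hat <= 2.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    n1, n2 = a1.size, a2.size
    n = n1 + n2
    if n < 3:
        raise CircularDataError("Watson-Williams needs a combined sample of at least 3")
    r1, r2, r = _resultants(a1, a2)
    if n - (r1 + r2) < 1e-10:
        raise CircularDataError("no within-group spread (all angles identical within groups)")
    kappa = kappa_mle((r1 + r2) / n)
    if kappa <= 0.0:
        raise CircularDataError("pooled resultant length of zero; correction factor undefined")
    f = (1.0 + 3.0 / (8.0 * kappa)) * (n - 2) * max(r1 + r2 - r, 0.0) / (n - r1 - r2)
    p = float(special.fdtrc(1.0, float(n - 2), f))
    warnings = ("estimated concentration <= 2; von Mises F approximation unreliable",) if kappa <= 2.0 else ()
    return TestResult("WWi", NULL_MEAN, float(f), (1.0, float(n - 2)), p, warnings)


def watson_large_sample(s1, s2) -> TestResult:
    """Watson's large-sample nonparametric test of common mean direction (Wat).

    Each group's embedded mean direction is weighted by w_i = n_i / disp_i
    (disp_i the per-group circular dispersion); the statistic
    Y = 2 * (sum w_i - |sum w_i u_i|) is referred to chi-square with g - 1 df.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    if min(a1.size, a2.size) < 2:
        raise CircularDataError("Watson's large-sample test needs at least 2 observations per group")
    sw = 0.0
    vx = 0.0
    vy = 0.0
    for a in (a1, a2):
        rbar, mu = trig_moment(a, 1)
        if rbar <= 1e-12:
            raise CircularDataError("undefined mean direction (zero resultant) in one group")
        rho2, _ = trig_moment(a, 2)
        disp = (1.0 - rho2) / (2.0 * rbar**2)
        if disp <= 1e-12:
            raise CircularDataError("zero circular dispersion in one group")
        w = a.size / disp
        sw += w
        vx += w * np.cos(mu)
        vy += w * np.sin(mu)
    stat = 2.0 * max(sw - float(np.hypot(vx, vy)), 0.0)
    p = float(special.chdtrc(1.0, stat))
    return TestResult("Wat", NULL_MEAN, float(stat), (1.0,), p, ())


def fisher_common_median(s1, s2) -> TestResult:
    """Fisher's nonparametric test of a common circular median (FPg).

    With theta the pooled circular median and m_i the count of sample-i
    observations on the half circle [theta, theta + pi), the statistic
    Pg = N^2/(M(N-M)) * sum m_i^2/n_i - N*M/(N-M) is chi-square with g - 1 df.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    n1, n2 = a1.size, a2.size
    n = n1 + n2
    if n < 4:
        raise CircularDataError("common-median test needs a combined sample of at least 4")
    pooled = np.concatenate([a1, a2])
    med = circular_median(pooled)
    m1 = int(np.sum(np.mod(a1 - med, 2.0 * np.pi) < np.pi))
    m2 = int(np.sum(np.mod(a2 - med, 2.0 * np.pi) < np.pi))
    m = m1 + m2
    if m == 0 or m == n:
        raise CircularDataError("all observations on one side of the pooled median")
    pg = n**2 / (m * (n - m)) * (m1**2 / n1 + m2**2 / n2) - n * m / (n - m)
    pg = max(float(pg), 0.0)
    p = float(special.chdtrc(1.0, pg))
    return TestResult("FPg", NULL_MEAN, pg, (1.0,), p, ())


def p_test_asymptotic(s1, s2) -> TestResult:
    """Asymptotic P-test of a common mean direction (Pt).

    Based on the pooled-resultant ratio P = (R1 + R2 - R)/(N - R); under the
    high-concentration theory for directional data, (N-2) P/(1-P) is referred
    to F(1, N-2).  Anti-conservative for small or weakly concentrated
    samples, which is the behaviour reported for this test.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    n1, n2 = a1.size, a2.size
    if min(n1, n2) < 2:
        raise CircularDataError("P-test needs at least 2 observations per group")
    n = n1 + n2
    r1, r2, r = _resultants(a1, a2)
    if n - r < 1e-10:
        raise CircularDataError("no spread in the pooled sample")
    p_stat = max(r1 + r2 - r, 0.0) / (n - r)
    if p_stat >= 1.0 - 1e-12:
        raise CircularDataError("degenerate resultant configuration")
    f = (n - 2) * p_stat / (1.0 - p_stat)
    p = float(special.fdtrc(1.0, float(n - 2), f))
    return TestResult("Pt", NULL_MEAN, float(f), (1.0, float(n - 2)), p, ())


def _cos_sin_moments(a: np.ndarray):
    """Means and estimated (co)variances of the means of cos and sin."""
    n = a.size
    c = np.cos(a)
    s = np.sin(a)
    cbar = float(c.mean())
    sbar = float(s.mean())
    denom = n * (n - 1)
    vc = float((np.sum(c * c) - n * cbar**2) / denom)
    vs = float((np.sum(s * s) - n * sbar**2) / denom)
    vcs = float((np.sum(c * s) - n * cbar * sbar) / denom)
    return cbar, sbar, vc, vs, vcs


def rao_homogeneity(s1, s2):
    """Rao's two-part homogeneity test: polar vectors and dispersions.

    Polar component (Rpo): compares the tangents t_i = sbar_i/cbar_i of the
    group resultants using delta-method variances; because the tangent has
    period pi, directions 180 degrees apart are indistinguishable and the
    weights vanish when a group mean lies near +-90 degrees, producing the
    characteristic power trough at orthogonal separations.

    Dispersion component (Rdi): the analogous weighted comparison of the
    per-group mean resultant lengths.

    Both statistics are chi-square with g - 1 df.  Returns
    ``(polar_result, dispersion_result)``.
    """
    a1, a2 = as_angles(s1), as_angles(s2)
    if min(a1.size, a2.size) < 2:
        raise CircularDataError("Rao's homogeneity test needs at least 2 observations per group")
    ts, vts, rs, vrs = [], [], [], []
    for a in (a1, a2):
        cbar, sbar, vc, vs, vcs = _cos_sin_moments(a)
        if abs(cbar) < 1e-12:
            raise CircularDataError(
                "polar component undefined: group mean direction orthogonal or polar opposite"
            )
        t = sbar / cbar
        vt = (cbar**2 * vs - 2.0 * cbar * sbar * vcs + sbar**2 * vc) / cbar**4
        rbar = float(np.hypot(cbar, sbar))
        if rbar < 1e-12:
            raise CircularDataError("zero resultant length; dispersion component undefined")
        vr = (cbar**2 * vc + 2.0 * cbar * sbar * vcs + sbar**2 * vs) / rbar**2
        if vt <= 0.0 or vr <= 0.0:
            raise CircularDataError("degenerate variance estimate in Rao's test")
        ts.append(t)
        vts.append(vt)
        rs.append(rbar)
        vrs.append(vr)

    def _homog(vals, variances):
        w = 1.0 / np.asarray(variances)
        v = np.asarray(vals)
        return float(np.sum(v * v * w) - np.sum(v * w) ** 2 / np.sum(w))

    h_pol = max(_homog(ts, vts), 0.0)
    h_disp = max(_homog(rs, vrs), 0.0)
    polar = TestResult("Rpo", NULL_MEAN, h_pol, (1.0,), float(special.chdtrc(1.0, h_pol)), ())
    disp = TestResult("Rdi", NULL_CONC, h_disp, (1.0,), float(special.chdtrc(1.0, h_disp)), ())
    return polar, disp
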