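"""Angle handling and descriptive circular statistics.

Shared machinery for every two-sample test in the package: the validated
sample container, trigonometric moments, mean direction and resultant
length, Fisher's circular dispersion, the circular median, the maximum
likelihood estimate of the von Mises concentration, and the uniform-scores
(circular rank) transform used by the Mardia-Watson-Wheeler family of
tests.

All angles are stored internally in radians on [0, 2*pi).  Degree input is
converted on ingestion.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import special

TWO_PI = 2.0 * np.pi

__all__ = [
    "TWO_PI",
    "CircularDataError",
    "CircularSample",
    "CircSummary",
    "TestResult",
    "as_angles",
    "wrap_angles",
    "angular_distance",
    "trig_moment",
    "bessel_ratio",
    "kappa_mle",
    "circular_median",
    "uniform_scores",
    "summarize",
]


class CircularDataError(ValueError):
    """Raised for empty, malformed or degenerate angular input."""


def wrap_angles(angles):
    """Reduce angles (radians) to the canonical interval [0, 2*pi)."""
    return np.mod(np.asarray(angles, dtype=float), TWO_PI)


class CircularSample:
    """A validated vector of angles in radians on [0, 2*pi).

    Parameters
    ----------
    angles : array-like
        Angle observations.  Scalars are promoted to length-1 samples.
    unit : {"radians", "degrees"}
        Unit of the input; internal storage is always radians.
    label : str
        Free-text identifier carried through reports.
    """

    __slots__ = ("angles", "label")

    def __init__(self, angles, unit: str = "radians", label: str = ""):
        a = np.atleast_1d(np.asarray(angles, dtype=float))
        if a.ndim != 1:
            raise CircularDataError("angles must be a one-dimensional vector")
        if a.size == 0:
            raise CircularDataError("empty sample")
        if not np.all(np.isfinite(a)):
            raise CircularDataError("angles must be finite")
        if unit == "degrees":
            a = np.deg2rad(a)
        elif unit != "radians":
            raise CircularDataError(f"unknown angle unit {unit!r}")
        self.angles = np.mod(a, TWO_PI)
        self.label = label

    @classmethod
    def from_degrees(cls, angles, label: str = "") -> "CircularSample":
        return cls(angles, unit="degrees", label=label)

    @property
    def n(self) -> int:
        return self.angles.size

    def __len__(self) -> int:
        return self.angles.size

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        lab = f" label={self.label!r}" if self.label else ""
        return f"CircularSample(n={self.n}{lab})"


def as_angles(sample) -> np.ndarray:
    """Coerce a CircularSample or array-like of radians to a wrapped vector."""
    if isinstance(sample, CircularSample):
        return sample.angles
    a = np.atleast_1d(np.asarray(sample, dtype=float))
    if a.size == 0:
        raise CircularDataError("empty sample")
    if not np.all(np.isfinite(a)):
        raise CircularDataError("angles must be finite")
    return np.mod(a, TWO_PI)


def angular_distance(a, b):
    """Shortest arc length between directions ``a`` and ``b`` (radians).

    Symmetric, lies in [0, pi]; equals pi - |pi - |a - b| mod 2*pi|.
    Broadcasts over array input.
    """
    d = np.mod(np.abs(np.asarray(a, dtype=float) - np.asarray(b, dtype=float)), TWO_PI)
    return np.pi - np.abs(np.pi - d)


def trig_moment(angles, p: int = 1):
    """p-th (uncentred) trigonometric moment: resultant length and direction.

    Returns ``(rho_p, mu_p)`` with ``rho_p = |mean exp(i p theta)|`` and
    ``mu_p = arg mean exp(i p theta)`` wrapped to [0, 2*pi).  The length is
    invariant under rotation of the sample, so the same value serves for the
    centred moment wherever only the magnitude is needed.
    """
    a = np.asarray(angles, dtype=float)
    c = np.mean(np.cos(p * a))
    s = np.mean(np.sin(p * a))
    rho = float(np.hypot(c, s))
    mu = float(np.mod(np.arctan2(s, c), TWO_PI))
    return rho, mu


def bessel_ratio(kappa):
    """A(kappa) = I1(kappa)/I0(kappa), the von Mises mean resultant length."""
    k = np.asarray(kappa, dtype=float)
    return special.i1e(k) / special.i0e(k)


_KAPPA_CAP = 1e10


def kappa_mle(r_bar: float, tol: float = 1e-10, max_iter: int = 100) -> float:
    """Invert A(kappa) = I1/I0 at the observed mean resultant length.

    Newton iteration from the standard three-regime starting value
    (2r + r^3 + 5 r^5/6 for r < 0.53, -0.4 + 1.39 r + 0.43/(1-r) for
    0.53 <= r < 0.85, 1/(r^3 - 4 r^2 + 3 r) above), using
    A'(k) = 1 - A(k)^2 - A(k)/k.
    """
    r = float(r_bar)
    if not 0.0 <= r <= 1.0:
        raise CircularDataError("mean resultant length must lie in [0, 1]")
    if r < 1e-12:
        return 0.0
    if r > 1.0 - 1e-10:
        return _KAPPA_CAP
    if r < 0.53:
        k = 2.0 * r + r**3 + 5.0 * r**5 / 6.0
    elif r < 0.85:
        k = -0.4 + 1.39 * r + 0.43 / (1.0 - r)
    else:
        k = 1.0 / (r**3 - 4.0 * r**2 + 3.0 * r)
    for _ in range(max_iter):
        a = float(bessel_ratio(k))
        f = a - r
        if abs(f) < tol:
            break
        deriv = 1.0 - a * a - a / k
        if deriv <= 0.0:  # numerically flat; keep the current iterate
            break
        step = f / deriv
        k = max(k - step, k * 0.1)
        if k > _KAPPA_CAP:
            return _KAPPA_CAP
    return float(k)


def circular_median(angles, mu_hat: float | None = None) -> float:
    """Circular median: the observation minimising mean angular distance.

    Candidates are the data points themselves.  Among minimisers (to 1e-12)
    the direction closest to the sample mean direction is returned; if the
    mean direction is undefined the numerically smallest angle wins.
    """
    a = as_angles(angles)
    if a.size == 1:
        return float(a[0])
    d = angular_distance(a[:, None], a[None, :])
    mean_dist = d.mean(axis=1)
    best = mean_dist.min()
    cand = np.flatnonzero(mean_dist <= best + 1e-12)
    if cand.size == 1:
        return float(a[cand[0]])
    if mu_hat is None:
        rho, mu = trig_moment(a)
        mu_hat = mu if rho > 1e-12 else None
    if mu_hat is None:
        return float(np.min(a[cand]))
    dist_to_mu = angular_distance(a[cand], mu_hat)
    order = np.lexsort((a[cand], dist_to_mu))
    return float(a[cand[order[0]]])


def uniform_scores(s1, s2, seed: int = 0):
    """Circular rank (uniform-score) transform of two pooled samples.

    The pooled sample of size N is sorted; observation of rank k receives the
    score ``beta_k = 2*pi*k/N``.  Tied values are separated by seeded uniform
    jitter smaller than half the smallest nonzero circular gap, which keeps
    the continuous-data contract of the Watson-Wheeler test while remaining
    reproducible.

    Returns
    -------
    beta1, beta2 : ndarray
        Scores of the observations of each sample (input order preserved).
    tied : bool
        Whether jitter was applied.
    """
    a1 = as_angles(s1)
    a2 = as_angles(s2)
    pooled = np.concatenate([a1, a2])
    n = pooled.size
    if n < 2:
        raise CircularDataError("need a combined sample of at least 2")
    uniq = np.unique(pooled)
    tied = uniq.size < n
    vals = pooled
    if tied:
        if uniq.size > 1:
            gaps = np.diff(uniq)
            gap = min(float(gaps.min()), float(uniq[0] + TWO_PI - uniq[-1]))
        else:
            gap = TWO_PI
        rng = np.random.default_rng(seed)
        vals = pooled + rng.uniform(0.0, 0.499 * gap, size=n)
    order = np.argsort(vals, kind="stable")
    ranks = np.empty(n, dtype=float)
    ranks[order] = np.arange(1, n + 1)
    beta = TWO_PI * ranks / n
    return beta[: a1.size], beta[a1.size :], tied


@dataclass(frozen=True)
class CircSummary:
    """Descriptive summary of one circular sample."""

    n: int
    mu_hat: float          # mean direction, radians; nan when undefined
    mu_defined: bool       # False iff r_bar == 0 (antipodal cancellation)
    r_bar: float           # mean resultant length in [0, 1]
    R: float               # resultant length, n * r_bar
    disp_hat: float        # Fisher's circular dispersion (1 - rho2)/(2 r_bar^2)
    median_hat: float      # circular median, radians
    kappa_hat: float       # von Mises concentration MLE


def summarize(sample) -> CircSummary:
    """Compute all standard descriptive circular statistics of a sample."""
    a = as_angles(sample)
    n = a.size
    r_bar, mu = trig_moment(a, 1)
    mu_defined = r_bar > 1e-12
    rho2, _ = trig_moment(a, 2)
    if mu_defined:
        disp = (1.0 - rho2) / (2.0 * r_bar**2)
    else:
        disp = np.inf
    med = circular_median(a, mu if mu_defined else None)
    return CircSummary(
        n=int(n),
        mu_hat=float(mu) if mu_defined else float("nan"),
        mu_defined=bool(mu_defined),
        r_bar=float(r_bar),
        R=float(n * r_bar),
        disp_hat=float(disp),
        median_hat=float(med),
        kappa_hat=kappa_mle(r_bar),
    )


@dataclass(frozen=True)
class TestResult:
    """Outcome of one two-sample test.

    ``df`` holds zero, one or two degrees-of-freedom values depending on the
    reference distribution; ``warnings`` lists assumption violations (they
    never abort the test).
    """

    test_id: str
    null_class: str
    statistic: float
    df: tuple
    p_value: float
    warnings: tuple = field(default_factory=tuple)

    def __post_init__(self):
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError("p-value outside [0, 1]")
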