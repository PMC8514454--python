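"""Samplers for the benchmark's circular distribution families.

Von Mises and wrapped skew-normal components and their unimodal, axial,
bimodal and trimodal equal-weight mixtures.  The family catalog follows the
benchmark design: six named families (A unimodal von Mises, B unimodal
wrapped skew-normal, C axial von Mises with modes 0/-180 degrees, D
asymmetric bimodal 0/-120, E symmetric trimodal 0/-120/-240, F asymmetric
trimodal 0/-90/-200), with base sample-size pairs (10,10), (20,20), (50,50),
(20,30), (10,50) doubled for bimodal and tripled for trimodal families.

All components of a mixture share one concentration (kappa for von Mises,
dispersion rho for the wrapped skew-normal); the wrapped skew-normal uses a
fixed skewness of 30 unless overridden.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import TWO_PI, CircularDataError, CircularSample, wrap_angles

__all__ = [
    "sample_von_mises",
    "sample_wrapped_skew_normal",
    "MixtureSpec",
    "sample_mixture",
    "FAMILIES",
    "BASE_SIZE_PAIRS",
    "family_spec",
    "family_size_pairs",
    "DEFAULT_SKEW",
]

DEFAULT_SKEW = 30.0


def sample_von_mises(n: int, mu: float, kappa: float, rng: np.random.Generator) -> np.ndarray:
    """Draw n von Mises(mu, kappa) angles (radians, wrapped to [0, 2*pi)).

    Uses the Best-Fisher rejection sampler (numpy's generator); kappa = 0
    falls back to the circular uniform distribution.
    """
    if n < 1:
        raise CircularDataError("need at least one draw")
    if kappa < 0:
        raise CircularDataError("kappa must be nonnegative")
    if kappa == 0.0:
        return rng.uniform(0.0, TWO_PI, size=n)
    return wrap_angles(rng.vonmises(mu, kappa, size=n))


def sample_wrapped_skew_normal(
    n: int, xi: float, rho: float, lam: float, rng: np.random.Generator
) -> np.ndarray:
    """Draw n wrapped skew-normal angles.

    X = xi + rho * (delta |Z0| + sqrt(1 - delta^2) Z1) with
    delta = lam / sqrt(1 + lam^2) and Z0, Z1 iid standard normal, wrapped to
    [0, 2*pi).  ``rho`` is the scale (dispersion) parameter: larger rho means
    a more dispersed circular distribution.
    """
    if n < 1:
        raise CircularDataError("need at least one draw")
    if rho <= 0:
        raise CircularDataError("dispersion rho must be positive")
    delta = lam / np.sqrt(1.0 + lam * lam)
    z0 = np.abs(rng.standard_normal(n))
    z1 = rng.standard_normal(n)
    x = xi + rho * (delta * z0 + np.sqrt(1.0 - delta * delta) * z1)
    return wrap_angles(x)


@dataclass(frozen=True)
class MixtureSpec:
    """A finite mixture of von Mises or wrapped skew-normal components.

    ``components`` is a tuple of (mean direction in degrees, weight) pairs;
    all components share one concentration ``conc`` (kappa for family 'vm',
    dispersion rho for family 'wsn').  Negative-degree means are normalised
    modulo 360.
    """

    family: str
    components: tuple  # ((mu_degrees, weight), ...)
    conc: float
    skew: float = DEFAULT_SKEW

    def __post_init__(self):
        if self.family not in ("vm", "wsn"):
            raise CircularDataError("family must be 'vm' or 'wsn'")
        if not self.components:
            raise CircularDataError("at least one component required")
        weights = np.array([w for _, w in self.components], dtype=float)
        if np.any(weights < 0) or not np.isclose(weights.sum(), 1.0, atol=1e-8):
            raise CircularDataError("component weights must be nonnegative and sum to 1")
        if self.family == "vm" and self.conc < 0:
            raise CircularDataError("kappa must be nonnegative")
        if self.family == "wsn" and self.conc <= 0:
            raise CircularDataError("dispersion rho must be positive")

    @property
    def means_rad(self) -> np.ndarray:
        return np.deg2rad(np.mod([m for m, _ in self.components], 360.0))

    @property
    def weights(self) -> np.ndarray:
        return np.array([w for _, w in self.components], dtype=float)

    def shifted(self, shift_deg: float) -> "MixtureSpec":
        """Rotate every component mean by ``shift_deg`` degrees."""
        comps = tuple((float(np.mod(m + shift_deg, 360.0)), w) for m, w in self.components)
        return MixtureSpec(self.family, comps, self.conc, self.skew)

    def to_dict(self) -> dict:
        return {
            "family": self.family,
            "components": [[float(m), float(w)] for m, w in self.components],
            "conc": float(self.conc),
            "skew": float(self.skew),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        comps = tuple((float(m), float(w)) for m, w in d["components"])
        return cls(d["family"], comps, float(d["conc"]), float(d.get("skew", DEFAULT_SKEW)))


def sample_mixture(spec: MixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n angles from a mixture: component chosen per draw by weight."""
    if n < 1:
        raise CircularDataError("need at least one draw")
    means = spec.means_rad
    counts = rng.multinomial(n, spec.weights)
    parts = []
    for mu, cnt in zip(means, counts):
        if cnt == 0:
            continue
        if spec.family == "vm":
            parts.append(sample_von_mises(int(cnt), float(mu), spec.conc, rng))
        else:
            parts.append(sample_wrapped_skew_normal(int(cnt), float(mu), spec.conc, spec.skew, rng))
    out = np.concatenate(parts)
    rng.shuffle(out)
    return out


def sample_mixture_as_sample(spec: MixtureSpec, n: int, rng: np.random.Generator, label: str = "") -> CircularSample:
    return CircularSample(sample_mixture(spec, n, rng), label=label)


# --- family catalog -------------------------------------------------------

BASE_SIZE_PAIRS = ((10, 10), (20, 20), (50, 50), (20, 30), (10, 50))

#: family -> (distribution kind, component mean directions in degrees, size multiplier)
FAMILIES = {
    "A": ("vm", (0.0,), 1),
    "B": ("wsn", (0.0,), 1),
    "C": ("vm", (0.0, -180.0), 2),
    "D": ("vm", (0.0, -120.0), 2),
    "E": ("vm", (0.0, -120.0, -240.0), 3),
    "F": ("vm", (0.0, -90.0, -200.0), 3),
}


def family_spec(family: str, conc: float, shift_deg: float = 0.0, skew: float = DEFAULT_SKEW) -> MixtureSpec:
    """MixtureSpec of a named family at one concentration, optionally rotated."""
    if family not in FAMILIES:
        raise CircularDataError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    kind, means, _ = FAMILIES[family]
    w = 1.0 / len(means)
    comps = tuple((float(np.mod(m + shift_deg, 360.0)), w) for m in means)
    return MixtureSpec(kind, comps, conc, skew)


def family_size_pairs(family: str):
    """The family's sample-size pairs: base pairs times the modality multiplier."""
    if family not in FAMILIES:
        raise CircularDataError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")
    mult = FAMILIES[family][2]
    return tuple((n1 * mult, n2 * mult) for n1, n2 in BASE_SIZE_PAIRS)
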