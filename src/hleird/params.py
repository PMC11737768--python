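"""Parameter containers for the half-logistic exponentiated inverse Rayleigh law.

The distribution carries a scale ``sigma`` and two shape parameters ``alpha``
and ``lam``, but the law depends on the shapes only through their product
``theta = alpha * lam`` (the cdf raises ``1 - exp(-(sigma/x)**2)`` to the power
``alpha*lam`` and nowhere else touches them individually).  ``theta`` is
therefore a derived, always-recomputed attribute, and the pair ``(theta,
sigma)`` is the identifiable parameterization used by every estimator.
"""

from __future__ import annotations

from dataclasses import dataclass


def _require_positive_finite(name: str, value: float) -> float:
    value = float(value)
    if not (value > 0.0) or value != value or value == float("inf"):
        raise ValueError(f"{name} must be a positive finite real, got {value!r}")
    return value


@dataclass(frozen=True)
class HleirdParams:
    """Parameter triple (sigma, alpha, lam) with the identified product theta.

    Parameters
    ----------
    sigma : float
        Scale parameter, in the units of the data (> 0).
    alpha : float
        First shape parameter (> 0).
    lam : float
        Second shape parameter (> 0).

    Notes
    -----
    ``theta = alpha * lam`` is the only shape quantity the law depends on;
    any split of ``theta`` into ``(alpha, lam)`` yields the same distribution
    (the "identifiability ridge").
    """

    sigma: float
    alpha: float
    lam: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "sigma", _require_positive_finite("sigma", self.sigma))
        object.__setattr__(self, "alpha", _require_positive_finite("alpha", self.alpha))
        object.__setattr__(self, "lam", _require_positive_finite("lam", self.lam))

    @property
    def theta(self) -> float:
        """Identified shape product ``alpha * lam`` (recomputed, never stored)."""
        return self.alpha * self.lam

    @classmethod
    def from_theta(cls, theta: float, sigma: float) -> "HleirdParams":
        """Build parameters from the identifiable pair, with the ``alpha = 1`` split."""
        theta = _require_positive_finite("theta", theta)
        return cls(sigma=sigma, alpha=1.0, lam=theta)

    def with_split(self, alpha: float) -> "HleirdParams":
        """Re-split the same law's theta as ``(alpha, theta/alpha)``."""
        alpha = _require_positive_finite("alpha", alpha)
        return HleirdParams(sigma=self.sigma, alpha=alpha, lam=self.theta / alpha)


@dataclass(frozen=True)
class SeriesControl:
    """Truncation control for the double-series expansions.

    ``max_terms_j``/``max_terms_k`` bound the outer/inner summation index and
    ``abs_tol`` is the absolute truncation-tail target the summation must
    certify before returning.
    """

    max_terms_j: int = 200
    max_terms_k: int = 200
    abs_tol: float = 1e-10

    def __post_init__(self) -> None:
        if self.max_terms_j < 1 or self.max_terms_k < 1:
            raise ValueError("max_terms must be >= 1")
        if not self.abs_tol > 0:
            raise ValueError("abs_tol must be > 0")


@dataclass(frozen=True)
class ShapeMeasures:
    """Quantile-based shape summary: Galton skewness and Moors kurtosis."""

    galton_skewness: float
    moors_kurtosis: float

    def __post_init__(self) -> None:
        if not -1.0 < self.galton_skewness < 1.0:
            raise ValueError("Galton skewness must lie in (-1, 1)")
        if not self.moors_kurtosis > 0.0:
            raise ValueError("Moors kurtosis must be positive")
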