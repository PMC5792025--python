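"""Effect-size calibration for scenario construction.

The selection effect is expressed as a fraction ``rho`` of Cohen's f for the
trial at hand: ``eta = rho * f(m, K)``, where f is the effect size at which a
balanced one-way ANOVA with K groups of m patients attains a target power.
Convention: noncentrality ``lambda = f^2 * N`` with ``N = m*K``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

__all__ = [
    "CalibrationError",
    "PowerSpec",
    "anova_power",
    "cohens_f",
    "delta_for_power",
    "mean_vector",
]

MEAN_PATTERNS = ("last-arm-only", "first-arm-only", "equally-spaced")


class CalibrationError(ValueError):
    pass


@dataclass(frozen=True)
class PowerSpec:
    """Target operating characteristics of the design: level, power, size."""

    n_arms: int
    per_arm: int
    alpha: float = 0.05
    power: float = 0.8

    def __post_init__(self) -> None:
        if self.n_arms < 2 or self.per_arm < 1:
            raise CalibrationError("need n_arms >= 2 and per_arm >= 1")
        if not 0.0 < self.alpha < self.power < 1.0:
            raise CalibrationError(
                f"need 0 < alpha < power < 1, got alpha={self.alpha}, power={self.power}"
            )

    @property
    def n_total(self) -> int:
        return self.n_arms * self.per_arm


def anova_power(ncp: float, df1: int, df2: int, alpha: float) -> float:
    """Power of the F-test at noncentrality ``ncp``."""
    crit = stats.f.isf(alpha, df1, df2)
    return float(stats.ncf.sf(crit, df1, df2, ncp))


def cohens_f(spec: PowerSpec) -> float:
    """Effect size f with design power equal to the target.

    Solves ``anova_power(f^2 * N) = power`` by bracketed root finding on the
    noncentrality; the power function is strictly increasing so the root is
    unique.  Absolute power error of the returned solution is below 1e-8.
    """
    df1, df2 = spec.n_arms - 1, spec.n_total - spec.n_arms
    if df2 < 1:
        raise CalibrationError(f"no residual degrees of freedom (N={spec.n_total}, K={spec.n_arms})")

    def gap(ncp: float) -> float:
        return anova_power(ncp, df1, df2, spec.alpha) - spec.power

    hi = 1.0
    while gap(hi) < 0.0:
        hi *= 2.0
        if hi > 1e8:
            raise CalibrationError("target power unreachable")
    ncp = optimize.brentq(gap, 0.0, hi, xtol=1e-12, rtol=8.9e-16)
    return float(np.sqrt(ncp / spec.n_total))


def mean_vector(delta: float, n_arms: int, pattern: str = "last-arm-only") -> np.ndarray:
    """Group-mean vector of a named shape, scaled by ``delta``."""
    if pattern in ("last-arm-only", "first-arm-only"):
        mu = np.zeros(n_arms)
        mu[-1 if pattern == "last-arm-only" else 0] = delta
        return mu
    if pattern == "equally-spaced":
        return delta * np.arange(n_arms) / (n_arms - 1)
    raise CalibrationError(f"unknown pattern {pattern!r}; expected one of {MEAN_PATTERNS}")


def _pattern_f_per_delta(n_arms: int, pattern: str) -> float:
    # Cohen's f of the unit-delta pattern: sd of the group means (sigma = 1).
    mu = mean_vector(1.0, n_arms, pattern)
    return float(np.sqrt(np.mean((mu - mu.mean()) ** 2)))


def delta_for_power(spec: PowerSpec, pattern: str = "last-arm-only") -> float:
    """Scale ``delta`` so the pattern's design power meets the target.

    For the last-arm-only pattern ``f = delta * sqrt(K-1) / K``, so
    ``delta = f * K / sqrt(K-1)``.
    """
    return cohens_f(spec) / _pattern_f_per_delta(spec.n_arms, pattern)
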