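"""Doubly noncentral F distribution and exact conditional rejection probability.

Under selective enrollment the response model gains a mean shift ``eta * b``
that the one-way ANOVA ignores.  Both ANOVA quadratic forms then become
noncentral chi-square, so the F statistic follows a *doubly* noncentral F
law with numerator noncentrality ``lambda1 = eta^2 b'Ab`` and denominator
noncentrality ``lambda2 = eta^2 b'Bb``, where A and B are the between-group
and residual projection matrices.  The CDF is the double Poisson mixture of
regularized incomplete beta functions; no pre-built implementation exists
in scipy, so the series is evaluated here with a certified truncation bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import special, stats

from .designs import AllocationSequence, DesignError
from .policies import BiasVector

__all__ = [
    "DnfError",
    "ConvergenceError",
    "NoncentralityPair",
    "noncentrality",
    "noncentrality_batch",
    "dnf_cdf",
    "rejection_probability",
    "rejection_probabilities",
]


class DnfError(ValueError):
    """Invalid input to a distribution routine."""


class ConvergenceError(RuntimeError):
    """The series could not reach the requested tolerance within the term cap."""


@dataclass(frozen=True)
class NoncentralityPair:
    """Noncentralities and degrees of freedom of the biased F statistic."""

    lambda1: float
    lambda2: float
    df1: int
    df2: int

    @property
    def total(self) -> float:
        """lambda1 + lambda2 = eta^2 (b'b - (b'1)^2 / N), an exact identity."""
        return self.lambda1 + self.lambda2


def noncentrality_batch(
    treatments: np.ndarray,
    bias: np.ndarray,
    eta: float,
    n_arms: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Noncentrality pairs for a batch of (sequence, bias-vector) rows.

    For a balanced design (n = N/K patients per arm)::

        lambda1 = eta^2 [ (1/n) sum_k (b'x_k)^2 - (1/N) (b'1)^2 ]
        lambda2 = eta^2 [ b'b - (1/n) sum_k (b'x_k)^2 ]

    where x_k is the indicator column of arm k.  Returns two length-r arrays.
    """
    t = np.atleast_2d(np.asarray(treatments, dtype=np.int64))
    b = np.atleast_2d(np.asarray(bias, dtype=np.float64))
    if t.shape != b.shape:
        raise DnfError(f"sequence batch {t.shape} and bias batch {b.shape} differ")
    n_total = t.shape[1]
    if n_total % n_arms:
        raise DnfError("total sample size is not a multiple of the number of arms")
    n = n_total // n_arms

    group_sq = np.zeros(t.shape[0])
    for k in range(1, n_arms + 1):
        mask = t == k
        if not np.all(mask.sum(axis=1) == n):
            raise DnfError(
                "unbalanced sequence in batch: the noncentrality formula "
                "requires exactly N/K allocations per arm"
            )
        group_sq += (b * mask).sum(axis=1) ** 2

    eta2 = float(eta) ** 2
    lam1 = eta2 * (group_sq / n - b.sum(axis=1) ** 2 / n_total)
    lam2 = eta2 * ((b**2).sum(axis=1) - group_sq / n)
    # exact zeros for eta == 0; clip roundoff otherwise
    return np.maximum(lam1, 0.0), np.maximum(lam2, 0.0)


def noncentrality(
    seq: AllocationSequence, b: BiasVector | np.ndarray, eta: float
) -> NoncentralityPair:
    """Noncentrality pair for a single sequence and bias vector."""
    bv = b.values if isinstance(b, BiasVector) else np.asarray(b)
    k = seq.params.n_arms
    lam1, lam2 = noncentrality_batch(seq.treatments[None, :], bv[None, :], eta, k)
    return NoncentralityPair(
        float(lam1[0]), float(lam2[0]), df1=k - 1, df2=seq.params.n_total - k
    )


def _poisson_window(mu: float, eps: float, cap: int) -> tuple[np.ndarray, np.ndarray]:
    """Indices around the Poisson(mu) mode carrying all but <= 2*eps mass."""
    if mu == 0.0:
        return np.array([0]), np.array([1.0])
    lo = int(stats.poisson.ppf(eps, mu))
    hi = int(stats.poisson.isf(eps, mu))
    if hi - lo + 1 > cap:
        raise ConvergenceError(
            f"Poisson window of {hi - lo + 1} terms exceeds cap {cap} "
            f"(mu={mu}); raise max_terms or loosen tol"
        )
    idx = np.arange(lo, hi + 1)
    return idx, stats.poisson.pmf(idx, mu)


def dnf_cdf(
    x: float,
    df1: int,
    df2: int,
    lambda1: float,
    lambda2: float,
    tol: float = 1e-10,
    max_terms: int = 100_000,
) -> float:
    """CDF of the doubly noncentral F distribution.

    ``P(F'' <= x)`` for ``F'' = (chi2_df1(lambda1)/df1) / (chi2_df2(lambda2)/df2)``,
    evaluated as the double Poisson mixture::

        sum_{j,k} pois(j; l1/2) pois(k; l2/2) I_u(df1/2 + j, df2/2 + k)

    with ``u = df1*x / (df1*x + df2)`` and ``I`` the regularized incomplete
    beta function.  Truncating each Poisson series to a window of mass
    ``>= 1 - tol/2`` bounds the absolute error by ``tol`` because every beta
    factor lies in [0, 1].
    """
    if df1 < 1 or df2 < 1:
        raise DnfError(f"degrees of freedom must be >= 1, got ({df1}, {df2})")
    if lambda1 < 0 or lambda2 < 0 or not np.isfinite([lambda1, lambda2]).all():
        raise DnfError(f"noncentralities must be finite and >= 0, got ({lambda1}, {lambda2})")
    if x <= 0:
        return 0.0
    j, wj = _poisson_window(lambda1 / 2.0, tol / 4.0, max_terms)
    k, wk = _poisson_window(lambda2 / 2.0, tol / 4.0, max_terms)
    u = df1 * x / (df1 * x + df2)
    beta = special.betainc(df1 / 2.0 + j[:, None], df2 / 2.0 + k[None, :], u)
    val = float(wj @ beta @ wk)
    return min(max(val, 0.0), 1.0)


def rejection_probabilities(
    lambda1: np.ndarray,
    lambda2: np.ndarray,
    df1: int,
    df2: int,
    alpha: float,
    tol: float = 1e-10,
) -> np.ndarray:
    """Conditional type I error for a batch of noncentrality pairs.

    Computes ``1 - dnf_cdf(q, ...)`` with ``q`` the central-F ``1 - alpha``
    quantile, deduplicating identical (lambda1, lambda2) pairs.  The central
    pair (0, 0) returns ``alpha`` exactly.
    """
    if not 0.0 < alpha < 1.0:
        raise DnfError(f"alpha must be in (0, 1), got {alpha}")
    q = stats.f.isf(alpha, df1, df2)
    pairs = np.round(np.column_stack([np.ravel(lambda1), np.ravel(lambda2)]), 12)
    uniq, inverse = np.unique(pairs, axis=0, return_inverse=True)
    out = np.empty(len(uniq))
    for i, (l1, l2) in enumerate(uniq):
        if l1 == 0.0 and l2 == 0.0:
            out[i] = alpha
        else:
            out[i] = 1.0 - dnf_cdf(q, df1, df2, l1, l2, tol=tol)
    return out[np.ravel(inverse)]


def rejection_probability(
    seq: AllocationSequence,
    b: BiasVector | np.ndarray,
    eta: float,
    alpha: float,
    tol: float = 1e-10,
) -> float:
    """Exact conditional probability that the nominal-level F-test rejects.

    Given the realized sequence and bias vector, the test statistic follows
    the doubly noncentral F law; the rejection probability is its upper tail
    beyond the central-F critical value.  With ``eta = 0`` this is exactly
    ``alpha``.
    """
    nc = noncentrality(seq, b, eta)
    return float(
        rejection_probabilities(
            np.array([nc.lambda1]), np.array([nc.lambda2]), nc.df1, nc.df2, alpha, tol
        )[0]
    )
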