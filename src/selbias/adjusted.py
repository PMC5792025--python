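"""Outcome simulation, the unadjusted ANOVA F-test, and the bias-adjusted test.

Responses follow ``y_i = mu_{t_i} + eta * b_i + eps_i`` with iid normal
errors.  The unadjusted test is the classical one-way ANOVA.  The adjusted
test augments the design matrix with the bias vector as a covariate and
tests equality of the group means via the extra sum of squares of the group
factor given {intercept, b} — the type III group test in this model — which
restores the nominal level and yields a least-squares estimate of eta.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .designs import AllocationSequence, DesignError, DesignParams, sample_pbd
from .policies import BiasVector, PolicySpec, bias_vectors

__all__ = [
    "ModelError",
    "OutcomeModel",
    "TestResult",
    "generate_outcomes",
    "f_test_unadjusted",
    "f_test_adjusted",
    "power_simulation",
]

_DEGENERACY_RTOL = 1e-10


class ModelError(ValueError):
    pass


@dataclass(frozen=True)
class OutcomeModel:
    """Response-generating model: group means, residual SD, selection shift."""

    mu: np.ndarray
    sigma: float = 1.0
    eta: float = 0.0
    b: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "mu", np.asarray(self.mu, dtype=np.float64))
        if self.sigma <= 0:
            raise ModelError(f"sigma must be > 0, got {self.sigma}")
        if self.b is not None:
            bv = self.b.values if isinstance(self.b, BiasVector) else np.asarray(self.b, float)
            object.__setattr__(self, "b", bv)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df1: int
    df2: int
    p_value: float
    reject: bool
    alpha: float
    adjusted: bool = False
    eta_hat: float | None = None
    degenerate: bool = False


def generate_outcomes(
    seq: AllocationSequence,
    model: OutcomeModel,
    rng_seed: int | np.random.Generator,
) -> np.ndarray:
    """Draw one response vector from the (possibly biased) outcome model."""
    if len(model.mu) != seq.params.n_arms:
        raise ModelError(
            f"mu has {len(model.mu)} entries for K={seq.params.n_arms} arms"
        )
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    y = model.mu[seq.treatments - 1]
    if model.eta != 0.0:
        if model.b is None or len(model.b) != len(seq):
            raise ModelError("eta != 0 requires a bias vector of matching length")
        y = y + model.eta * model.b
    return y + model.sigma * rng.standard_normal(len(seq))


# --- batch internals (vectorized across replicates) ---------------------------

def _group_sums(Y: np.ndarray, T: np.ndarray, n_arms: int) -> np.ndarray:
    sums = np.empty((Y.shape[0], n_arms))
    for k in range(n_arms):
        sums[:, k] = np.where(T == k + 1, Y, 0.0).sum(axis=1)
    return sums


def _anova_ss(Y: np.ndarray, T: np.ndarray, n_arms: int) -> tuple[np.ndarray, np.ndarray]:
    """Between-group and residual sums of squares for balanced batches."""
    n = Y.shape[1]
    if n % n_arms:
        raise ModelError("batch ANOVA assumes a balanced design")
    m = n // n_arms
    gs = _group_sums(Y, T, n_arms)
    total = Y.sum(axis=1)
    ss_between = (gs**2).sum(axis=1) / m - total**2 / n
    ss_within = (Y**2).sum(axis=1) - (gs**2).sum(axis=1) / m
    return np.maximum(ss_between, 0.0), np.maximum(ss_within, 0.0)


def _f_unadjusted_batch(Y: np.ndarray, T: np.ndarray, n_arms: int) -> np.ndarray:
    ssb, ssw = _anova_ss(Y, T, n_arms)
    df1, df2 = n_arms - 1, Y.shape[1] - n_arms
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / df1) / (ssw / df2)
    f = np.where(ssb == 0.0, 0.0, f)  # constant y -> no group effect
    return f


def _f_adjusted_batch(
    Y: np.ndarray, T: np.ndarray, B: np.ndarray, n_arms: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Adjusted group F, eta estimates, and a degeneracy mask per replicate.

    Uses residualization: with b_perp the residual of b on the group
    indicators, RSS_full = RSS_groups - (b_perp'y)^2 / (b_perp'b_perp), and
    the group test compares against the reduced model {intercept, b}.
    Replicates where b lies in the group-indicator span (b_perp = 0) are
    flagged degenerate; callers fall back to the unadjusted test there.
    """
    n = Y.shape[1]
    m = n // n_arms
    B = B.astype(np.float64)
    ssb, rss_groups = _anova_ss(Y, T, n_arms)

    gs_b = _group_sums(B, T, n_arms) / m
    b_perp = B.copy()
    for k in range(n_arms):
        b_perp -= np.where(T == k + 1, gs_b[:, k][:, None], 0.0)
    bp_ss = (b_perp**2).sum(axis=1)
    degenerate = bp_ss <= _DEGENERACY_RTOL * np.maximum((B**2).sum(axis=1), 1.0)

    with np.errstate(divide="ignore", invalid="ignore"):
        eta_hat = (b_perp * Y).sum(axis=1) / bp_ss
        rss_full = rss_groups - (b_perp * Y).sum(axis=1) ** 2 / bp_ss

        # reduced model {intercept, b}
        b_c = B - B.mean(axis=1, keepdims=True)
        y_c = Y - Y.mean(axis=1, keepdims=True)
        b_c_ss = (b_c**2).sum(axis=1)
        slope_num = (b_c * y_c).sum(axis=1)
        rss_red = (y_c**2).sum(axis=1) - np.where(
            b_c_ss > 0, slope_num**2 / np.maximum(b_c_ss, 1e-300), 0.0
        )
        df1, df2 = n_arms - 1, n - n_arms - 1
        f = ((rss_red - rss_full) / df1) / (rss_full / df2)
    f = np.where(np.maximum(rss_red - rss_full, 0.0) == 0.0, 0.0, f)
    return f, eta_hat, degenerate


# --- single-sample public API -------------------------------------------------

def f_test_unadjusted(
    y: np.ndarray, seq: AllocationSequence, alpha: float = 0.05
) -> TestResult:
    """Classical one-way ANOVA F-test of equal group means."""
    y = np.asarray(y, dtype=np.float64)
    if y.shape != (len(seq),):
        raise ModelError(f"y has shape {y.shape}, expected ({len(seq)},)")
    k, n = seq.params.n_arms, len(seq)
    if n <= k:
        raise ModelError("need N > K for the unadjusted test")
    f = float(_f_unadjusted_batch(y[None, :], seq.treatments[None, :], k)[0])
    df1, df2 = k - 1, n - k
    p = float(stats.f.sf(f, df1, df2))
    return TestResult(f, df1, df2, p, p <= alpha, alpha)


def f_test_adjusted(
    y: np.ndarray,
    seq: AllocationSequence,
    b: BiasVector | np.ndarray,
    alpha: float = 0.05,
) -> TestResult:
    """Bias-adjusted F-test of equal group means with b as covariate.

    Returns the extra-sum-of-squares F with (K-1, N-K-1) degrees of freedom
    and the least-squares estimate of the selection effect.  If b lies in
    the span of the group indicators (including b constant or all zero) the
    covariate carries no information; the unadjusted test is returned with
    ``degenerate=True``.
    """
    y = np.asarray(y, dtype=np.float64)
    bv = b.values if isinstance(b, BiasVector) else np.asarray(b, dtype=np.float64)
    k, n = seq.params.n_arms, len(seq)
    if y.shape != (len(seq),) or bv.shape != (len(seq),):
        raise ModelError("y and b must both have length N")
    if n <= k + 1:
        raise ModelError("need N > K + 1 for the adjusted test")
    f, eta_hat, degenerate = _f_adjusted_batch(
        y[None, :], seq.treatments[None, :], bv[None, :], k
    )
    if degenerate[0]:
        base = f_test_unadjusted(y, seq, alpha)
        return TestResult(
            base.statistic, base.df1, base.df2, base.p_value, base.reject,
            alpha, adjusted=True, eta_hat=None, degenerate=True,
        )
    df1, df2 = k - 1, n - k - 1
    p = float(stats.f.sf(float(f[0]), df1, df2))
    return TestResult(
        float(f[0]), df1, df2, p, p <= alpha, alpha,
        adjusted=True, eta_hat=float(eta_hat[0]),
    )


def power_simulation(
    n_arms: int,
    per_arm: int,
    policy: PolicySpec,
    mu: np.ndarray,
    effect_size_f: float,
    rhos: Sequence[float] = (0.0, 0.5, 1.0, 2.0),
    schemes: Sequence[str] = ("PBD_K", "PBD_N_HALF", "PBD_N"),
    alpha: float = 0.05,
    replicates: int = 10_000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Rejection rates of the adjusted and unadjusted tests under bias.

    For each (scheme, rho): draw fresh sequences, derive bias vectors under
    ``policy``, simulate ``y = X mu + rho*f*b + eps`` and apply both tests.
    Returns a tidy frame with columns (block_scheme, rho, test, replicates,
    power, mc_se, degenerate_frac).
    """
    if replicates < 1:
        raise ModelError(f"replicates must be >= 1, got {replicates}")
    mu = np.asarray(mu, dtype=np.float64)
    if len(mu) != n_arms:
        raise ModelError(f"mu has {len(mu)} entries for K={n_arms} arms")
    n = n_arms * per_arm
    crit_un = stats.f.isf(alpha, n_arms - 1, n - n_arms)
    crit_adj = stats.f.isf(alpha, n_arms - 1, n - n_arms - 1)
    rows = []
    for i, scheme in enumerate(schemes):
        params = DesignParams.from_scheme(scheme, n_arms, per_arm)
        for j, rho in enumerate(rhos):
            rng = np.random.default_rng(None if seed is None else [seed, i, j])
            T = sample_pbd(params, replicates, rng)
            B = bias_vectors(T, n_arms, policy)
            Y = mu[T - 1] + rho * effect_size_f * B + rng.standard_normal(T.shape)
            f_un = _f_unadjusted_batch(Y, T, n_arms)
            f_adj, _, degenerate = _f_adjusted_batch(Y, T, B, n_arms)
            rej_un = f_un > crit_un
            rej_adj = np.where(degenerate, f_un > crit_un, f_adj > crit_adj)
            for test, rej in (("unadjusted", rej_un), ("adjusted", rej_adj)):
                p = float(np.mean(rej))
                rows.append(
                    {
                        "block_scheme": scheme,
                        "rho": rho,
                        "test": test,
                        "replicates": replicates,
                        "power": p,
                        "mc_se": float(np.sqrt(p * (1 - p) / replicates)),
                        "degenerate_frac": float(np.mean(degenerate)),
                    }
                )
    return pd.DataFrame(rows)
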