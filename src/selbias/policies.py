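"""Biasing policies: map unmasked allocation histories to bias vectors.

An investigator who favours a subset ``F`` of the arms and knows the past
group counts ``N_k(i-1)`` may selectively enroll a patient with better
(+1), neutral (0), or worse (-1) expected response before each allocation.
Two policies are provided:

* Policy I (strict): +1 only when *every* favoured arm is strictly smaller
  than every non-favoured arm, -1 only when every favoured arm is strictly
  larger than every non-favoured arm.
* Policy II: compares the smallest favoured arm with the smallest
  non-favoured arm, so ties across favoured arms do not block a guess.

For two arms and a single favoured arm both policies reduce to the classic
convergence strategy: guess the arm that is currently behind.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable

import numpy as np
import pandas as pd

from .designs import AllocationSequence, DesignError

__all__ = [
    "PolicyKind",
    "PolicySpec",
    "BiasVector",
    "PolicyError",
    "bias_vector",
    "bias_vectors",
    "blackwell_hodges_guess",
    "policy_table",
]


class PolicyError(DesignError):
    """Invalid policy specification."""


class PolicyKind(str, Enum):
    POLICY_I = "I"
    POLICY_II = "II"


@dataclass(frozen=True)
class PolicySpec:
    """A biasing policy: kind, favoured arm set, and preference direction.

    ``favoured`` must be a non-empty proper subset of {1..K}.  ``direction``
    flips the sign of the produced bias vector; +1 means a patient with
    higher expected response is enrolled when a favoured arm is guessed.

    ``policy2_strict_minus`` selects a variant of Policy II whose -1 branch
    fires only when the smallest favoured arm exceeds the *largest*
    non-favoured arm (instead of the smallest); the default mirrors the +1
    branch.  No worked example discriminates the two, so both are exposed.
    """

    kind: PolicyKind
    favoured: frozenset[int]
    direction: int = 1
    policy2_strict_minus: bool = False

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", PolicyKind(self.kind))
        object.__setattr__(self, "favoured", frozenset(int(a) for a in self.favoured))
        if self.direction not in (-1, 1):
            raise PolicyError(f"direction must be +1 or -1, got {self.direction}")
        if not self.favoured:
            raise PolicyError("favoured set must be non-empty")

    def validate(self, n_arms: int) -> None:
        if not self.favoured <= set(range(1, n_arms + 1)):
            raise PolicyError(
                f"favoured arms {sorted(self.favoured)} not within 1..{n_arms}"
            )
        if len(self.favoured) >= n_arms:
            raise PolicyError(
                "favoured set must be a proper subset of the arms "
                f"(got all {n_arms} arms)"
            )


@dataclass(frozen=True)
class BiasVector:
    """Per-patient enrollment bias, entries in {-1, 0, +1}; b_1 is always 0."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=np.int64)
        if not np.isin(v, (-1, 0, 1)).all():
            raise PolicyError("bias entries must be in {-1, 0, +1}")
        v.setflags(write=False)
        object.__setattr__(self, "values", v)

    def __len__(self) -> int:
        return len(self.values)


def bias_vectors(
    treatments: np.ndarray, n_arms: int, policy: PolicySpec
) -> np.ndarray:
    """Vectorized bias computation for a (r, N) batch of sequences.

    Returns an (r, N) integer matrix of entries in {-1, 0, +1}.
    """
    policy.validate(n_arms)
    t = np.atleast_2d(np.asarray(treatments, dtype=np.int64))
    r, n = t.shape
    onehot = (t[:, :, None] == np.arange(1, n_arms + 1)[None, None, :]).astype(np.int32)
    # counts[:, i, k] = allocations to arm k before patient i+1
    counts = np.zeros((r, n, n_arms), dtype=np.int32)
    np.cumsum(onehot[:, :-1, :], axis=1, out=counts[:, 1:, :])

    fav = np.array(sorted(policy.favoured)) - 1
    non = np.array(sorted(set(range(1, n_arms + 1)) - policy.favoured)) - 1
    max_f = counts[:, :, fav].max(axis=2)
    min_f = counts[:, :, fav].min(axis=2)
    max_c = counts[:, :, non].max(axis=2)
    min_c = counts[:, :, non].min(axis=2)

    if policy.kind is PolicyKind.POLICY_I:
        plus = max_f < min_c
        minus = min_f > max_c
    else:
        plus = min_f < min_c
        minus = (min_f > max_c) if policy.policy2_strict_minus else (min_f > min_c)
    b = plus.astype(np.int64) - minus.astype(np.int64)
    return policy.direction * b


def bias_vector(seq: AllocationSequence, policy: PolicySpec) -> BiasVector:
    """Bias vector for a single allocation sequence under the given policy."""
    b = bias_vectors(seq.treatments[None, :], seq.params.n_arms, policy)[0]
    return BiasVector(b)


def blackwell_hodges_guess(seq: AllocationSequence) -> BiasVector:
    """Two-arm convergence strategy: guess the arm currently behind.

    Equivalent to Policy I with favoured set {1}; the result equals
    ``sign(N_2(i-1) - N_1(i-1))`` elementwise.
    """
    if seq.params.n_arms != 2:
        raise PolicyError(
            f"the convergence strategy is defined for 2 arms, got K={seq.params.n_arms}"
        )
    return bias_vector(seq, PolicySpec(PolicyKind.POLICY_I, frozenset({1})))


def policy_table(seq: AllocationSequence, policy: PolicySpec) -> pd.DataFrame:
    """Worked-example table: allocations, running counts and bias per patient.

    Columns: patient i, the indicator columns x_1..x_K, the pre-enrollment
    counts N_1(i-1)..N_K(i-1), and b_i.
    """
    k = seq.params.n_arms
    x = seq.design_matrix().astype(int)
    counts = seq.group_counts()[:-1]
    b = bias_vector(seq, policy).values
    data: dict[str, Iterable[int]] = {"patient": np.arange(1, len(seq) + 1)}
    for j in range(k):
        data[f"x_{j + 1}"] = x[:, j]
    for j in range(k):
        data[f"N_{j + 1}"] = counts[:, j]
    data["b"] = b
    return pd.DataFrame(data)
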