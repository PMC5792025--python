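"""Permuted block designs: generation, enumeration, and sequence probabilities.

A permuted block design with ``K`` arms, ``c`` patients per arm per block and
``M`` blocks allocates ``N = c*K*M`` patients.  Within every block of length
``c*K`` each arm label appears exactly ``c`` times, so the trial is balanced
after each block.  A single block of length ``N`` is the random allocation
rule (RAR).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from sympy.utilities.iterables import multiset_permutations

__all__ = [
    "DesignError",
    "InvalidSequenceError",
    "EnumerationCapError",
    "DesignParams",
    "AllocationSequence",
    "BLOCK_SCHEMES",
    "generate_pbd",
    "sample_pbd",
    "enumerate_pbd",
    "n_sequences",
    "sequence_probability",
    "group_counts",
    "read_sequence_file",
    "write_sequences_csv",
]

#: Block-length schemes used throughout the numerical comparisons:
#: blocks of length K (c=1), two blocks of length N/2, or one block of length N.
BLOCK_SCHEMES = ("PBD_K", "PBD_N_HALF", "PBD_N")


class DesignError(ValueError):
    """Invalid design parameters."""


class InvalidSequenceError(DesignError):
    """An allocation sequence that violates the block-balance constraints."""


class EnumerationCapError(DesignError):
    """Exhaustive enumeration refused because the design space is too large."""


@dataclass(frozen=True)
class DesignParams:
    """Parameters of a permuted block design PBD(c*K) with M complete blocks.

    Attributes
    ----------
    n_arms :
        Number of treatment groups ``K`` (>= 2).
    c :
        Patients allocated to each arm within one block (>= 1).
    n_blocks :
        Number of blocks ``M`` (>= 1).  The last block is always complete,
        so the total sample size is ``N = c * K * M``.
    """

    n_arms: int
    c: int
    n_blocks: int

    def __post_init__(self) -> None:
        for name, value in (("n_arms", self.n_arms), ("c", self.c), ("n_blocks", self.n_blocks)):
            if not isinstance(value, (int, np.integer)):
                raise DesignError(f"{name} must be an integer, got {value!r}")
        if self.n_arms < 2:
            raise DesignError(f"n_arms must be >= 2, got {self.n_arms}")
        if self.c < 1:
            raise DesignError(f"c must be >= 1, got {self.c}")
        if self.n_blocks < 1:
            raise DesignError(f"n_blocks must be >= 1, got {self.n_blocks}")

    @property
    def n_total(self) -> int:
        """Total sample size N = c*K*M."""
        return self.c * self.n_arms * self.n_blocks

    @property
    def per_arm(self) -> int:
        """Patients per arm m = N/K = c*M."""
        return self.c * self.n_blocks

    @property
    def block_length(self) -> int:
        return self.c * self.n_arms

    @classmethod
    def from_scheme(cls, scheme: str, n_arms: int, per_arm: int) -> "DesignParams":
        """Build parameters for one of the standard block-length schemes.

        ``PBD_K`` uses blocks of length K (c=1), ``PBD_N_HALF`` two blocks of
        length N/2, and ``PBD_N`` a single block of length N (the RAR).
        """
        if scheme == "PBD_K":
            return cls(n_arms, 1, per_arm)
        if scheme == "PBD_N_HALF":
            if per_arm % 2:
                raise DesignError(
                    f"PBD_N_HALF requires an even per-arm size, got m={per_arm}"
                )
            return cls(n_arms, per_arm // 2, 2)
        if scheme == "PBD_N":
            return cls(n_arms, per_arm, 1)
        raise DesignError(f"unknown block scheme {scheme!r}; expected one of {BLOCK_SCHEMES}")


def _validate_treatments(t: np.ndarray, params: DesignParams) -> None:
    if t.ndim != 1 or t.shape[0] != params.n_total:
        raise InvalidSequenceError(
            f"sequence length {t.shape} does not match N={params.n_total}"
        )
    if t.min(initial=1) < 1 or t.max(initial=params.n_arms) > params.n_arms:
        raise InvalidSequenceError(
            f"treatment labels must lie in 1..{params.n_arms}"
        )
    blocks = t.reshape(params.n_blocks, params.block_length)
    for j, block in enumerate(blocks):
        counts = np.bincount(block, minlength=params.n_arms + 1)[1:]
        if not np.all(counts == params.c):
            raise InvalidSequenceError(
                f"block {j + 1} has arm counts {counts.tolist()}, expected "
                f"{params.c} per arm"
            )


@dataclass(frozen=True)
class AllocationSequence:
    """A realized randomization list ``t_1..t_N`` with labels in 1..K.

    The equivalent 0/1 design matrix is derived on demand via
    :meth:`design_matrix`; it has unit row sums and column sums N/K.
    """

    treatments: np.ndarray
    params: DesignParams

    def __post_init__(self) -> None:
        t = np.asarray(self.treatments, dtype=np.int64)
        _validate_treatments(t, self.params)
        t.setflags(write=False)
        object.__setattr__(self, "treatments", t)

    def __len__(self) -> int:
        return self.params.n_total

    def design_matrix(self) -> np.ndarray:
        """Return the N x K indicator matrix of allocations."""
        n, k = self.params.n_total, self.params.n_arms
        x = np.zeros((n, k))
        x[np.arange(n), self.treatments - 1] = 1.0
        return x

    def group_counts(self) -> np.ndarray:
        """Return the (N+1) x K trajectory of pre-enrollment group counts.

        Row ``i`` holds the number of allocations to each arm among the first
        ``i`` patients; row 0 is all zeros and row ``i-1`` is what an
        unmasked observer knows before patient ``i`` is enrolled.
        """
        onehot = np.zeros((len(self), self.params.n_arms), dtype=np.int64)
        onehot[np.arange(len(self)), self.treatments - 1] = 1
        traj = np.zeros((len(self) + 1, self.params.n_arms), dtype=np.int64)
        np.cumsum(onehot, axis=0, out=traj[1:])
        return traj


def sample_pbd(params: DesignParams, size: int, rng: np.random.Generator) -> np.ndarray:
    """Draw ``size`` independent PBD sequences as a (size, N) label matrix.

    Each block is an independent uniformly random arrangement of ``c`` copies
    of each arm label.
    """
    base = np.tile(np.repeat(np.arange(1, params.n_arms + 1), params.c), (size, 1))
    blocks = [rng.permuted(base, axis=1) for _ in range(params.n_blocks)]
    return np.concatenate(blocks, axis=1)


def generate_pbd(params: DesignParams, rng_seed: int | np.random.Generator) -> AllocationSequence:
    """Generate a single permuted-block-design sequence, reproducibly."""
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    return AllocationSequence(sample_pbd(params, 1, rng)[0], params)


def n_sequences(params: DesignParams) -> int:
    """Number of distinct sequences the design can produce.

    Per block there are ``(cK)! / (c!)^K`` arrangements; blocks are
    independent, so the total is that count to the power M.
    """
    per_block = math.factorial(params.block_length) // math.factorial(params.c) ** params.n_arms
    return per_block ** params.n_blocks


def sequence_probability(seq: AllocationSequence) -> float:
    """Probability of one realized sequence: ``((c!)^K / (cK)!)^M``.

    All admissible sequences are equally likely, so this is 1/|Omega|.
    """
    return 1.0 / n_sequences(seq.params)


def enumerate_pbd(
    params: DesignParams, cap: int = 10**6
) -> tuple[np.ndarray, np.ndarray]:
    """Exhaustively enumerate the design space.

    Returns
    -------
    treatments :
        (n, N) integer matrix, one row per distinct sequence.
    probabilities :
        Length-n vector of sequence probabilities (all equal, summing to 1).

    Raises
    ------
    EnumerationCapError
        If the number of sequences exceeds ``cap``; use Monte Carlo sampling
        (:func:`sample_pbd`) instead.
    """
    total = n_sequences(params)
    if total > cap:
        raise EnumerationCapError(
            f"design has {total} sequences (> cap {cap}); use Monte Carlo "
            "sampling via sample_pbd/assess_monte_carlo instead"
        )
    multiset = list(np.repeat(np.arange(1, params.n_arms + 1), params.c))
    block_arrangements = [list(p) for p in multiset_permutations(multiset)]
    rows = [
        list(itertools.chain.from_iterable(combo))
        for combo in itertools.product(block_arrangements, repeat=params.n_blocks)
    ]
    treatments = np.array(rows, dtype=np.int64)
    assert treatments.shape[0] == total
    probabilities = np.full(total, 1.0 / total)
    return treatments, probabilities


def group_counts(seq: AllocationSequence) -> np.ndarray:
    """Pre-enrollment group-count trajectory; see AllocationSequence.group_counts."""
    return seq.group_counts()


# --- plain-text interfaces ----------------------------------------------------

def read_sequence_file(path: str | Path, params: DesignParams) -> list[AllocationSequence]:
    """Read sequences from a text file, one trial per line.

    Lines are comma-separated treatment labels, e.g. ``1,2,1,3,3,2``.  Every
    line is validated against ``params``.
    """
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        try:
            labels = np.array([int(tok) for tok in line.split(",")], dtype=np.int64)
        except ValueError as exc:
            raise InvalidSequenceError(f"line {lineno}: {exc}") from exc
        out.append(AllocationSequence(labels, params))
    return out


def write_sequences_csv(sequences: Iterable[AllocationSequence], path: str | Path) -> None:
    """Write a batch of sequences in long format: seq_id, position, treatment."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("seq_id,position,treatment\n")
        for sid, seq in enumerate(sequences, start=1):
            for pos, label in enumerate(seq.treatments, start=1):
                fh.write(f"{sid},{pos},{label}\n")
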