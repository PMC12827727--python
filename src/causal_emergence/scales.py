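"""Partitions of the state space, macroscale TPMs, and consistency tests.

A coarse grain of an n-state system is a set partition of its state
indices; each block becomes one macrostate.  Partitions are written in the
canonical text form ``"(0,1,2),(3)"``: indices sorted within blocks, blocks
ordered by their smallest member.  The discrete (all-singleton) partition is
the microscale.

A macroscale is only a valid description of its microscale if it is
*dynamically consistent*: evolving a distribution under the micro TPM and
then lumping it must agree with lumping first and evolving under the macro
TPM.  Inconsistent macroscales are discarded from all automated searches.
The check used here starts a uniform distribution on each macrostate's
members and compares the two routes over a short horizon in total-variation
distance — a lump-vs-evolve criterion that reduces to weak lumpability at
the uniform prior and is exact (error 0) for strongly lumpable partitions
such as equivalency classes of identical rows.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np
from sympy.utilities.iterables import multiset_partitions

from .config import DEFAULT_TOLERANCES
from .markov import InterventionDistribution, TransitionMatrix

__all__ = [
    "Partition",
    "ConsistencyResult",
    "InvalidPartitionError",
    "parse_partition",
    "coarse_grain_tpm",
    "is_refinement",
    "enumerate_partitions",
    "consistency_check",
    "coarsen_distribution",
]


class InvalidPartitionError(ValueError):
    """A block structure fails the partition invariants."""


@dataclass(frozen=True)
class Partition:
    """A grouping of the state indices 0..n-1 into disjoint, exhaustive blocks."""

    blocks: tuple[tuple[int, ...], ...]
    n_micro: int

    def __post_init__(self) -> None:
        blocks = tuple(sorted(tuple(sorted(int(i) for i in b)) for b in self.blocks))
        seen: list[int] = []
        for b in blocks:
            if not b:
                raise InvalidPartitionError("empty block")
            seen.extend(b)
        if len(seen) != len(set(seen)):
            raise InvalidPartitionError("duplicate state index across blocks")
        if sorted(seen) != list(range(self.n_micro)):
            raise InvalidPartitionError(
                f"blocks must cover exactly 0..{self.n_micro - 1}, got {sorted(seen)}"
            )
        object.__setattr__(self, "blocks", blocks)

    @classmethod
    def discrete(cls, n: int) -> "Partition":
        """The microscale: every state in its own block."""
        return cls(tuple((i,) for i in range(n)), n)

    @property
    def n_blocks(self) -> int:
        return len(self.blocks)

    @property
    def label(self) -> str:
        return ",".join("(" + ",".join(str(i) for i in b) + ")" for b in self.blocks)

    def __str__(self) -> str:
        return self.label

    def block_of(self) -> np.ndarray:
        """Length-n_micro vector mapping each microstate to its block index."""
        out = np.empty(self.n_micro, dtype=int)
        for k, b in enumerate(self.blocks):
            out[list(b)] = k
        return out

    def indicator(self) -> np.ndarray:
        """n_micro x n_blocks 0/1 lumping matrix."""
        mat = np.zeros((self.n_micro, self.n_blocks))
        mat[np.arange(self.n_micro), self.block_of()] = 1.0
        return mat

    def merge(self, i: int, j: int) -> "Partition":
        """New partition with blocks i and j merged."""
        if i == j:
            raise InvalidPartitionError("cannot merge a block with itself")
        keep = [b for k, b in enumerate(self.blocks) if k not in (i, j)]
        keep.append(tuple(sorted(self.blocks[i] + self.blocks[j])))
        return Partition(tuple(keep), self.n_micro)

    def is_discrete(self) -> bool:
        return self.n_blocks == self.n_micro


@dataclass(frozen=True)
class ConsistencyResult:
    """Outcome of the lump-vs-evolve dynamical-consistency test."""

    consistent: bool
    max_error: float
    horizon_checked: int


_PARTITION_RE = re.compile(r"^\(\d+(,\d+)*\)(,\(\d+(,\d+)*\))*$")


def parse_partition(text: str, n: int) -> Partition:
    """Parse the canonical ``"(0,1,2),(3)"`` notation over states 0..n-1."""
    compact = text.replace(" ", "")
    if not _PARTITION_RE.match(compact):
        raise InvalidPartitionError(f"malformed partition text {text!r}")
    blocks = [
        tuple(int(x) for x in grp.split(","))
        for grp in re.findall(r"\(([^()]*)\)", compact)
    ]
    return Partition(tuple(blocks), n)


def is_refinement(finer: Partition, coarser: Partition) -> bool:
    """True iff every block of ``finer`` lies inside some block of ``coarser``."""
    if finer.n_micro != coarser.n_micro:
        raise InvalidPartitionError("partitions are over different state counts")
    owner = coarser.block_of()
    return all(len({owner[i] for i in b}) == 1 for b in finer.blocks)


def enumerate_partitions(n: int, limit: int | None = None, force: bool = False):
    """Yield every set partition of 0..n-1 exactly once (Bell(n) of them)."""
    if limit is None:
        limit = DEFAULT_TOLERANCES.enumeration_limit
    if n > limit and not force:
        raise ValueError(
            f"n = {n} exceeds the enumeration limit {limit} "
            "(Bell numbers explode); pass force=True to override"
        )
    if n == 0:
        yield Partition((), 0)
        return
    for blocks in multiset_partitions(list(range(n))):
        yield Partition(tuple(tuple(b) for b in blocks), n)


def coarse_grain_tpm(
    tm: TransitionMatrix, part: Partition, weights=None
) -> TransitionMatrix:
    """Macroscale TPM with one state per block.

    Each macro row is the average of its member microstates' rows, lumped by
    column: P(B | A) = (1/|A|) sum_{i in A} sum_{j in B} P(j | i).  Passing
    ``weights`` (a micro distribution, e.g. the stationary law) replaces the
    uniform within-block average with a weights-proportional one.
    Macro labels join the member labels with '+'.
    """
    if part.n_micro != tm.n:
        raise InvalidPartitionError(
            f"partition over {part.n_micro} states applied to {tm.n}-state TPM"
        )
    ind = part.indicator()
    if weights is None:
        w = np.full(tm.n, 1.0)
    else:
        w = np.asarray(weights, dtype=float).ravel()
        if w.size != tm.n or np.any(w < 0):
            raise InvalidPartitionError("weights must be a nonnegative micro vector")
    agg = (w[:, None] * ind).T  # n_blocks x n_micro
    norm = agg.sum(axis=1)
    if np.any(norm <= 0):
        # fall back to uniform within blocks that carry zero weight
        for k in np.where(norm <= 0)[0]:
            agg[k, list(part.blocks[k])] = 1.0
            norm[k] = len(part.blocks[k])
    macro = (agg / norm[:, None]) @ tm.probs @ ind
    labels = tuple("+".join(tm.labels[i] for i in b) for b in part.blocks)
    return TransitionMatrix(labels, macro, tol=tm.tol)


def coarsen_distribution(
    pc: InterventionDistribution, part: Partition
) -> InterventionDistribution:
    """Lump a micro distribution: each block's mass is the sum of its members'."""
    if part.n_micro != pc.n:
        raise InvalidPartitionError(
            f"partition over {part.n_micro} states applied to length-{pc.n} distribution"
        )
    return InterventionDistribution(pc.weights @ part.indicator(), mode=pc.mode)


def consistency_check(
    tm: TransitionMatrix,
    part: Partition,
    tol: float | None = None,
    horizon: int | None = None,
) -> ConsistencyResult:
    """Lump-vs-evolve agreement over ``horizon`` steps, per macrostate.

    For each macrostate A the uniform distribution over A's members is (a)
    evolved t steps under the micro TPM and then lumped, and (b) lumped to a
    point mass on A and evolved t steps under the macro TPM.  ``max_error``
    is the largest total-variation distance between the two routes over all
    macrostates and t = 1..horizon.
    """
    if tol is None:
        tol = DEFAULT_TOLERANCES.consistency
    if horizon is None:
        horizon = DEFAULT_TOLERANCES.horizon
    if horizon < 1:
        raise ValueError("horizon must be >= 1")
    macro = coarse_grain_tpm(tm, part)
    ind = part.indicator()
    # one row per macrostate: uniform over members (micro), point mass (macro)
    micro_d = (ind / ind.sum(axis=0)).T
    macro_d = np.eye(part.n_blocks)
    max_err = 0.0
    for _ in range(horizon):
        micro_d = micro_d @ tm.probs
        macro_d = macro_d @ macro.probs
        err = 0.5 * np.abs(micro_d @ ind - macro_d).sum(axis=1).max()
        max_err = max(max_err, float(err))
    return ConsistencyResult(max_err <= tol, max_err, horizon)
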