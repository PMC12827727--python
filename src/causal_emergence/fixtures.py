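"""Deterministic generators for benchmark systems and sweep experiments.

The generators build the small Markov systems used throughout the package's
tests and documentation: block models made of equivalency classes (sets of
states with identical transition rows), a deterministic-cycle-plus-noisy-
block composite, mesoscale variants in which one member per block is
distinguishable from its class, and permutation matrices (the fully
deterministic, non-degenerate, zero-emergence limit).

Two sweep experiments are provided: a probability-redistribution sweep that
morphs a block model into a permutation matrix while tracking both the
CP-based gain at a fixed macroscale and the EI-based gain it is compared
against, and a noise sweep that blends a TPM toward the uniform matrix.  A
singular-value statistic of the TPM is included as a cheap screening
heuristic for dynamical reversibility.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass
from typing import NamedTuple, Sequence

import numpy as np
import pandas as pd

from .markov import InterventionDistribution, TransitionMatrix
from .primitives import PrimitiveScores, cp_scores
from .paths import scale_scores
from .scales import Partition

__all__ = [
    "SweepRecord",
    "make_block_model",
    "make_cycle_plus_block",
    "make_mesoscale_variant",
    "make_permutation",
    "redistribution_sweep",
    "noise_sweep",
    "svd_reversibility",
    "SvdReversibility",
]


def _labels(n: int) -> tuple[str, ...]:
    return tuple(str(i) for i in range(n))


def make_block_model(
    block_sizes: Sequence[int], within_block="uniform"
) -> TransitionMatrix:
    """Block-diagonal TPM whose blocks are equivalency classes.

    All rows within a block are identical.  ``within_block="uniform"``
    spreads each row evenly over its own block; alternatively pass a mapping
    from block index to a probability row over that block's states.
    """
    sizes = [int(s) for s in block_sizes]
    if not sizes or any(s < 1 for s in sizes):
        raise ValueError(f"block sizes must be positive integers, got {block_sizes}")
    n = sum(sizes)
    probs = np.zeros((n, n))
    start = 0
    for b, size in enumerate(sizes):
        sl = slice(start, start + size)
        if within_block == "uniform":
            row = np.full(size, 1.0 / size)
        else:
            row = np.asarray(within_block[b], dtype=float)
            if row.size != size:
                raise ValueError(f"custom row for block {b} has length {row.size}, expected {size}")
        probs[sl, sl] = row
        start += size
    return TransitionMatrix(_labels(n), probs)


def make_cycle_plus_block(cycle_len: int, block_len: int) -> TransitionMatrix:
    """Deterministic cycle over the first states, uniform equivalency-class
    block over the rest.

    States 0..cycle_len-1 follow a p = 1 cycle; states cycle_len..n-1 each
    transition uniformly over the block, forming an equivalency class whose
    coarse grain is a single macrostate with a self-loop of p = 1.
    """
    if cycle_len < 1 or block_len < 2:
        raise ValueError("need cycle_len >= 1 and block_len >= 2")
    n = cycle_len + block_len
    probs = np.zeros((n, n))
    for i in range(cycle_len):
        probs[i, (i + 1) % cycle_len] = 1.0
    probs[cycle_len:, cycle_len:] = 1.0 / block_len
    return TransitionMatrix(_labels(n), probs)


def make_mesoscale_variant(
    block_sizes: Sequence[int], distinct_member_row: Sequence[float]
) -> TransitionMatrix:
    """Block model in which each block's first member is distinguishable.

    The first state of every block takes ``distinct_member_row`` (a
    distribution over its own block) instead of the class's uniform row, so
    the endpoint macrostates are no longer pure equivalency classes while
    block-level outflows — and hence the endpoint's dynamical consistency —
    are preserved.  Interior merges of the remaining identical members then
    carry their own CP gains, creating mesoscale structure.
    """
    row = np.asarray(distinct_member_row, dtype=float)
    sizes = [int(s) for s in block_sizes]
    if any(s != row.size for s in sizes):
        raise ValueError(
            f"distinct row of length {row.size} must match every block size {sizes}"
        )
    if abs(row.sum() - 1.0) > 1e-9 or np.any(row < 0):
        raise ValueError("distinct row must be a distribution over its block")
    tm = make_block_model(sizes, "uniform")
    probs = tm.probs.copy()
    start = 0
    for size in sizes:
        probs[start, start : start + size] = row
        start += size
    return TransitionMatrix(tm.labels, probs)


def make_permutation(n: int, mapping: Sequence[int] | None = None) -> TransitionMatrix:
    """One-hot TPM sending state i to mapping[i]; identity when omitted."""
    if mapping is None:
        mapping = range(n)
    mapping = [int(m) for m in mapping]
    if sorted(mapping) != list(range(n)):
        raise ValueError(f"mapping {mapping} is not a permutation of 0..{n - 1}")
    probs = np.zeros((n, n))
    probs[np.arange(n), mapping] = 1.0
    return TransitionMatrix(_labels(n), probs)


@dataclass(frozen=True)
class SweepRecord:
    """One step of the redistribution sweep at a fixed macroscale."""

    step: int
    tm_checksum: str
    micro_cp: float
    macro_cp: float
    ce2_gain: float
    ei_micro: float
    ei_macro: float
    ei_gain: float
    ce1_emergence: float


def _checksum(probs: np.ndarray) -> str:
    return hashlib.sha256(np.ascontiguousarray(probs).tobytes()).hexdigest()[:16]


def redistribution_sweep(
    tm: TransitionMatrix,
    macro: Partition,
    steps: int = 50,
    pc_mode: str = "uniform",
    measure: str = "cp_info",
) -> list[SweepRecord]:
    """Incrementally move within-block mass onto self-loops; track CE at a
    fixed macroscale.

    At step t (t = 0..steps) a fraction t/steps of every state's non-self
    within-block probability is added to its self-loop, ending at the
    identity permutation.  Each record compares the CP gain at the fixed
    macro partition (the CE 2.0 quantity) with the EI gain; ``ce1_emergence``
    is the causal emergence CE 1.0 would report, max(0, ei_gain), since a
    negative EI difference means the macroscale loses information and no
    emergence is detected.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    owner = macro.block_of()
    same_block = owner[:, None] == owner[None, :]
    if np.any(tm.probs[~same_block] > 0):
        raise ValueError("TPM must be block-diagonal with respect to the macro partition")
    base = tm.probs
    eye = np.eye(tm.n, dtype=bool)
    records = []
    for t in range(steps + 1):
        f = t / steps
        probs = base * (1.0 - f)
        probs[eye] = base[eye] + f * (1.0 - base[eye])
        step_tm = TransitionMatrix(tm.labels, probs, tol=tm.tol)
        micro = scale_scores(step_tm, Partition.discrete(tm.n), pc_mode)
        mac = scale_scores(step_tm, macro, pc_mode)
        micro_cp, macro_cp = getattr(micro, measure), getattr(mac, measure)
        ei_gain = mac.ei - micro.ei
        records.append(
            SweepRecord(
                step=t,
                tm_checksum=_checksum(probs),
                micro_cp=micro_cp,
                macro_cp=macro_cp,
                ce2_gain=macro_cp - micro_cp,
                ei_micro=micro.ei,
                ei_macro=mac.ei,
                ei_gain=ei_gain,
                ce1_emergence=max(0.0, ei_gain),
            )
        )
    return records


def sweep_to_frame(records: list[SweepRecord]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


def noise_sweep(
    tm: TransitionMatrix,
    lambdas: Sequence[float],
    pc: InterventionDistribution | None = None,
) -> pd.DataFrame:
    """Primitive scores of (1 - lam) * TPM + lam * uniform for each lam."""
    rows = []
    uniform = np.full((tm.n, tm.n), 1.0 / tm.n)
    for lam in lambdas:
        if not 0.0 <= lam <= 1.0:
            raise ValueError(f"lambda {lam} outside [0, 1]")
        blended = TransitionMatrix(
            tm.labels, (1.0 - lam) * tm.probs + lam * uniform, tol=tm.tol
        )
        scores = cp_scores(blended, pc)
        rows.append({"lambda": lam, **scores.to_dict()})
    return pd.DataFrame(rows)


class SvdReversibility(NamedTuple):
    total: float
    normalized: float
    alpha: float


def svd_reversibility(tm: TransitionMatrix, alpha: float = 1.0) -> SvdReversibility:
    """Sum of the TPM's singular values raised to ``alpha``, and its /n form.

    A screening heuristic for dynamical reversibility: permutation matrices
    score n (normalized 1), the uniform matrix scores 1 (normalized 1/n),
    and more reversible (deterministic, non-degenerate) dynamics score
    higher.  This is a heuristic correlate of the causal-primitive analysis,
    not a CP computation.
    """
    if not 0.0 < alpha <= 2.0:
        raise ValueError(f"alpha must lie in (0, 2], got {alpha}")
    sv = np.linalg.svd(tm.probs, compute_uv=False)
    total = float(np.sum(sv**alpha))
    return SvdReversibility(total=total, normalized=total / tm.n, alpha=alpha)
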