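"""Micro-to-macro paths: endpoint search, chain construction, apportioning.

The degree of causal emergence (CE) in a system is the total gain in the
combined causal-primitive score CP accumulated along an ordered chain of
consistent coarse grains from the microscale (discrete partition) to an
endpoint macroscale.  By telescoping, CE = CP(endpoint) - CP(microscale),
and 1 - CP(microscale) bounds the CE attainable by any endpoint.

Endpoint selection is either exhaustive (score every consistent partition;
the maximizer wins, ties broken in favor of the *least* dimensionality
reduction, i.e. most macrostates, then lexicographically by label) or
greedy with a diminishing-returns stop.  Path construction merges two
blocks per step, greedily choosing the consistent merge with the largest
CP gain, which makes contribution profiles reproducible.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_TOLERANCES, Tolerances
from .markov import InterventionDistribution, TransitionMatrix, stationary_distribution
from .primitives import PrimitiveScores, cp_scores
from .scales import (
    ConsistencyResult,
    Partition,
    coarse_grain_tpm,
    coarsen_distribution,
    consistency_check,
    enumerate_partitions,
    is_refinement,
)

__all__ = [
    "PathAnalysis",
    "EndpointChoice",
    "InconsistentEndpointError",
    "scale_scores",
    "find_endpoint_exhaustive",
    "find_endpoint_greedy",
    "build_path",
    "apportion",
    "ce_upper_bound",
]

logger = logging.getLogger(__name__)

MEASURES = ("cp_info", "cp_primitive")


class InconsistentEndpointError(ValueError):
    """A user-supplied endpoint fails the dynamical-consistency test."""


@dataclass(frozen=True)
class EndpointChoice:
    partition: Partition
    cp: float
    n_macro_states: int
    search_mode: str


@dataclass
class PathAnalysis:
    """An ordered chain of scales from microscale to endpoint with per-step gains."""

    scales: list[Partition]
    cp_values: list[float]
    measure: str
    pc_mode: str
    consistency: list[ConsistencyResult]
    scores: list[PrimitiveScores] = field(default_factory=list)
    flags: tuple[str, ...] = ()

    @property
    def deltas(self) -> list[float]:
        return [
            self.cp_values[i] - self.cp_values[i - 1]
            for i in range(1, len(self.cp_values))
        ]

    @property
    def total_ce(self) -> float:
        return self.cp_values[-1] - self.cp_values[0]

    @property
    def L(self) -> int:
        """Number of steps beyond the microscale."""
        return len(self.scales) - 1


def _pc_at_scale(
    macro_tm: TransitionMatrix,
    part: Partition,
    pc_mode: str,
    custom_pc: InterventionDistribution | None,
) -> InterventionDistribution:
    """P(C) regenerated at one scale.

    Uniform mode treats the states of each scale equally; stationary mode
    uses the observed long-run law of that scale's own TPM; custom mode
    lumps a user-supplied micro-level distribution.
    """
    if pc_mode == "uniform":
        return InterventionDistribution.uniform(macro_tm.n)
    if pc_mode == "stationary":
        return stationary_distribution(macro_tm)
    if pc_mode == "custom":
        if custom_pc is None:
            raise ValueError("pc_mode='custom' requires a micro-level distribution")
        return coarsen_distribution(custom_pc, part)
    raise ValueError(f"unknown pc_mode {pc_mode!r}")


def scale_scores(
    tm: TransitionMatrix,
    part: Partition,
    pc_mode: str = "uniform",
    custom_pc: InterventionDistribution | None = None,
) -> PrimitiveScores:
    """Primitive scores of the coarse grain of ``tm`` induced by ``part``."""
    macro = coarse_grain_tpm(tm, part)
    pc = _pc_at_scale(macro, part, pc_mode, custom_pc)
    return cp_scores(macro, pc)


def _cp(scores: PrimitiveScores, measure: str) -> float:
    if measure not in MEASURES:
        raise ValueError(f"measure must be one of {MEASURES}, got {measure!r}")
    return getattr(scores, measure)


def ce_upper_bound(
    tm: TransitionMatrix,
    pc_mode: str = "uniform",
    measure: str = "cp_info",
    custom_pc: InterventionDistribution | None = None,
) -> float:
    """1 - CP(microscale): the CE attainable by any endpoint."""
    micro = Partition.discrete(tm.n)
    return 1.0 - _cp(scale_scores(tm, micro, pc_mode, custom_pc), measure)


def find_endpoint_exhaustive(
    tm: TransitionMatrix,
    pc_mode: str = "uniform",
    measure: str = "cp_info",
    custom_pc: InterventionDistribution | None = None,
    tol: Tolerances | None = None,
) -> EndpointChoice:
    """Score every consistent partition; return the CP maximizer.

    CP values within ``tol.cp_tie`` are treated as tied; among ties the
    partition with the most macrostates wins (least dimensionality
    reduction), then the lexicographically smallest canonical label.
    """
    tol = tol or DEFAULT_TOLERANCES
    best: tuple[float, int, str, Partition] | None = None
    n_consistent = 0
    for part in enumerate_partitions(tm.n, limit=tol.enumeration_limit):
        check = consistency_check(tm, part, tol.consistency, tol.horizon)
        if not check.consistent:
            continue
        n_consistent += 1
        cp = _cp(scale_scores(tm, part, pc_mode, custom_pc), measure)
        logger.debug("partition %s: %s = %.6f", part.label, measure, cp)
        if best is None:
            best = (cp, part.n_blocks, part.label, part)
            continue
        if cp > best[0] + tol.cp_tie:
            better = True
        elif cp >= best[0] - tol.cp_tie:
            # tie: prefer more blocks, then smaller label
            better = part.n_blocks > best[1] or (
                part.n_blocks == best[1] and part.label < best[2]
            )
            cp = max(cp, best[0])
        else:
            better = False
        if better:
            best = (cp, part.n_blocks, part.label, part)
    assert best is not None  # the discrete partition is always consistent
    logger.info("exhaustive search: %d consistent partitions", n_consistent)
    return EndpointChoice(best[3], best[0], best[1], "exhaustive")


def _consistent_merges(
    tm: TransitionMatrix,
    current: Partition,
    pc_mode: str,
    measure: str,
    custom_pc: InterventionDistribution | None,
    tol: Tolerances,
    endpoint: Partition | None = None,
):
    """Yield (cp, partition) for every consistent single pairwise block merge.

    When ``endpoint`` is given, only merges of blocks that share an endpoint
    block are considered, keeping the chain on a path to that endpoint.
    """
    owner = endpoint.block_of() if endpoint is not None else None
    for i in range(current.n_blocks):
        for j in range(i + 1, current.n_blocks):
            if owner is not None and owner[current.blocks[i][0]] != owner[current.blocks[j][0]]:
                continue
            cand = current.merge(i, j)
            if not consistency_check(tm, cand, tol.consistency, tol.horizon).consistent:
                continue
            cp = _cp(scale_scores(tm, cand, pc_mode, custom_pc), measure)
            yield cp, cand


def _best_merge(candidates) -> tuple[float, Partition] | None:
    """Largest-CP candidate; ties broken by the smaller canonical label."""
    best = None
    for cp, cand in candidates:
        if best is None or cp > best[0] + 1e-15 or (
            abs(cp - best[0]) <= 1e-15 and cand.label < best[1].label
        ):
            best = (cp, cand)
    return best


def find_endpoint_greedy(
    tm: TransitionMatrix,
    pc_mode: str = "uniform",
    measure: str = "cp_info",
    epsilon: float = 1e-6,
    window: int = 3,
    custom_pc: InterventionDistribution | None = None,
    tol: Tolerances | None = None,
) -> EndpointChoice:
    """Greedy merging with a diminishing-returns stop.

    At each step the single consistent pairwise merge with the largest CP
    gain is applied.  The march stops once the best available gain has been
    below ``epsilon`` for ``window`` consecutive steps, or once the gain
    ratio delta_{i+1}/delta_i has been strictly decreasing (and < 1)
    throughout a window, or when no consistent merge remains.  The endpoint
    returned is the last scale whose incoming gain was at least ``epsilon``
    (the microscale if there is none) — the scale reached before the
    transition to diminishing returns.
    """
    if epsilon <= 0:
        raise ValueError("epsilon must be positive")
    if window < 1:
        raise ValueError("window must be >= 1")
    tol = tol or DEFAULT_TOLERANCES
    current = Partition.discrete(tm.n)
    cp = _cp(scale_scores(tm, current, pc_mode, custom_pc), measure)
    chain = [(current, cp)]
    deltas: list[float] = []
    small_streak = 0
    while current.n_blocks > 1:
        best = _best_merge(
            _consistent_merges(tm, current, pc_mode, measure, custom_pc, tol)
        )
        if best is None:
            break
        new_cp, current = best
        deltas.append(new_cp - cp)
        cp = new_cp
        chain.append((current, cp))
        small_streak = small_streak + 1 if deltas[-1] < epsilon else 0
        if small_streak >= window:
            break
        if len(deltas) > window and all(d > 0 for d in deltas[-(window + 1):]):
            ratios = [
                deltas[k + 1] / deltas[k]
                for k in range(len(deltas) - window - 1, len(deltas) - 1)
            ]
            if all(r < 1 for r in ratios) and all(
                ratios[k + 1] < ratios[k] for k in range(len(ratios) - 1)
            ):
                break
    last_good = 0
    for i, d in enumerate(deltas):
        if d >= epsilon:
            last_good = i + 1
    part, cp = chain[last_good]
    logger.info("greedy search stopped at %s (%s = %.6f)", part.label, measure, cp)
    return EndpointChoice(part, cp, part.n_blocks, "greedy")


def build_path(
    tm: TransitionMatrix,
    endpoint: Partition,
    pc_mode: str = "uniform",
    measure: str = "cp_info",
    custom_pc: InterventionDistribution | None = None,
    tol: Tolerances | None = None,
) -> PathAnalysis:
    """Longest chain of consistent scales from the microscale to ``endpoint``.

    One pairwise block merge per step; among consistent merges on the way to
    the endpoint the one with the largest CP gain is taken (ties broken
    lexicographically).  If the chain gets stuck before the endpoint, the
    path jumps directly to the endpoint and is flagged ``"no_full_chain"``.
    """
    tol = tol or DEFAULT_TOLERANCES
    micro = Partition.discrete(tm.n)
    is_refinement(micro, endpoint)  # raises on a state-count mismatch
    end_check = consistency_check(tm, endpoint, tol.consistency, tol.horizon)
    if not end_check.consistent:
        raise InconsistentEndpointError(
            f"endpoint {endpoint.label} is dynamically inconsistent "
            f"(max TV error {end_check.max_error:.3g})"
        )
    flags: list[str] = []
    current = micro
    scores = [scale_scores(tm, current, pc_mode, custom_pc)]
    scales = [current]
    checks = [consistency_check(tm, current, tol.consistency, tol.horizon)]
    while current != endpoint:
        best = _best_merge(
            _consistent_merges(
                tm, current, pc_mode, measure, custom_pc, tol, endpoint=endpoint
            )
        )
        if best is None:
            flags.append("no_full_chain")
            current = endpoint
            scores.append(scale_scores(tm, current, pc_mode, custom_pc))
            scales.append(current)
            checks.append(end_check)
            break
        _, current = best
        scores.append(scale_scores(tm, current, pc_mode, custom_pc))
        scales.append(current)
        checks.append(consistency_check(tm, current, tol.consistency, tol.horizon))
    return PathAnalysis(
        scales=scales,
        cp_values=[_cp(s, measure) for s in scores],
        measure=measure,
        pc_mode=pc_mode,
        consistency=checks,
        scores=scores,
        flags=tuple(flags),
    )


def apportion(path: PathAnalysis) -> list[tuple[str, float]]:
    """Per-scale causal contributions: CP(micro) first, then each step's gain.

    Contributions sum to CP(endpoint) by telescoping.
    """
    out = [(path.scales[0].label, path.cp_values[0])]
    out.extend(
        (path.scales[i].label, d) for i, d in enumerate(path.deltas, start=1)
    )
    return out
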