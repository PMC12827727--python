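"""Numerical tolerances and limits, collected in one configurable object."""

from __future__ import annotations

from dataclasses import dataclass


@dataclass
class Tolerances:
    """Default numerical tolerances used across the package.

    Attributes
    ----------
    row_sum
        Maximum deviation of a TPM row sum from 1 before it is rejected.
    distribution
        Same, for probability vectors (intervention distributions).
    stationary
        Required accuracy of the fixed-point identity ``pi @ T == pi``.
    stationary_step
        Per-iteration convergence threshold of the stationary solver.
    stationary_max_iter
        Iteration budget of the stationary solver.
    consistency
        Total-variation threshold below which a macroscale counts as
        dynamically consistent with its microscale.
    horizon
        Number of time steps over which consistency is checked.
    cp_tie
        Two CP values closer than this are treated as tied during endpoint
        search (floating-point log2 makes exact ties unreliable).
    telescoping
        Tolerance on the telescoping identity total_ce = CP(end) - CP(micro).
    enumeration_limit
        Largest n for which all Bell(n) partitions are enumerated without an
        explicit override (Bell(10) = 115975).
    """

    row_sum: float = 1e-9
    distribution: float = 1e-9
    stationary: float = 1e-8
    stationary_step: float = 1e-10
    stationary_max_iter: int = 100_000
    consistency: float = 1e-9
    horizon: int = 3
    cp_tie: float = 1e-9
    telescoping: float = 1e-12
    enumeration_limit: int = 10


DEFAULT_TOLERANCES = Tolerances()
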