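"""Emergent complexity: the entropy of the per-step causal contributions.

The per-step CP gains along a micro-to-macro path, normalized to a
probability distribution p over the L steps (microscale excluded), measure
how widely a system's causal workings are spread across its scales.  The
emergent complexity EC = -sum p_i log2 p_i reaches log2(L) when every step
contributes equally, and 0 when a single emergent scale carries the whole
gain.  EC / log2(L) normalizes across paths of different length.

Negative per-step gains (possible on user-chosen paths) are clamped to 0
before normalization and flagged.  A path with no positive gain has no
contribution distribution: EC is reported as NaN with a flag, which keeps
"no emergence at all" distinct from "all emergence at one scale" (EC = 0).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .paths import PathAnalysis

__all__ = ["ComplexityReport", "emergent_complexity", "normalized_ec", "classify_profile"]


@dataclass(frozen=True)
class ComplexityReport:
    gains: tuple[float, ...]
    p: tuple[float, ...]
    ec_bits: float
    ec_normalized: float
    L: int
    profile: str
    flags: tuple[str, ...] = ()


def _entropy_bits(p: np.ndarray) -> float:
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def emergent_complexity(path: PathAnalysis, zero_steps: str = "include") -> ComplexityReport:
    """EC of a path's gain distribution.

    ``zero_steps`` controls the convention for steps with zero gain:
    "include" (default) keeps them in the distribution (they contribute no
    entropy but count toward L); "exclude" drops them from both the
    distribution and the normalizing length.
    """
    if zero_steps not in ("include", "exclude"):
        raise ValueError(f"zero_steps must be 'include' or 'exclude', got {zero_steps!r}")
    gains = list(path.deltas)
    if not gains:
        raise ValueError("path has no steps beyond the microscale")
    flags = []
    if any(g < 0 for g in gains):
        flags.append(
            "clamped_negative_steps:"
            + ",".join(str(i + 1) for i, g in enumerate(gains) if g < 0)
        )
    clamped = np.array([max(g, 0.0) for g in gains])
    if zero_steps == "exclude":
        effective = clamped[clamped > 0]
    else:
        effective = clamped
    L = int(effective.size)
    total = clamped.sum()
    if total <= 0 or L == 0:
        flags.append("no_positive_gain")
        # zero total gain is "no emergence", reported distinctly from the
        # EC = 0 case of a lone dominant scale
        return ComplexityReport(
            gains=tuple(gains), p=(), ec_bits=float("nan"),
            ec_normalized=float("nan"), L=L, profile="bottom_heavy",
            flags=tuple(flags),
        )
    p = effective / total
    ec = _entropy_bits(p)
    if L > 1:
        ec_norm = ec / math.log2(L)
    else:
        flags.append("single_step_normalization_undefined")
        ec_norm = 0.0
    report = ComplexityReport(
        gains=tuple(gains), p=tuple(float(x) for x in p), ec_bits=ec,
        ec_normalized=ec_norm, L=L, profile="", flags=tuple(flags),
    )
    return ComplexityReport(
        gains=report.gains, p=report.p, ec_bits=report.ec_bits,
        ec_normalized=report.ec_normalized, L=report.L,
        profile=classify_profile(path, report), flags=report.flags,
    )


def normalized_ec(report: ComplexityReport) -> float:
    """EC / log2(L); flagged 0 when L = 1 leaves the normalization undefined."""
    return report.ec_normalized


def classify_profile(path: PathAnalysis, report: ComplexityReport | None) -> str:
    """Contribution-profile descriptor.

    top_heavy   - the final step holds the strictly largest gain;
    mesoscale   - an earlier (interior) step holds the strictly largest gain;
    bottom_heavy- no step dominates and the microscale's own CP exceeds the
                  total path gain (including the no-positive-gain case);
    flat        - none of the above (e.g. equal positive gains from a weak
                  microscale).

    Gains within 1e-9 of the maximum count as tied (telescoped differences
    of equal analytic gains differ in the last bits).
    """
    gains = [max(g, 0.0) for g in path.deltas]
    total = sum(gains)
    micro_cp = path.cp_values[0]
    if total > 0:
        mx = max(gains)
        dominant = [i for i, g in enumerate(gains) if mx - g <= 1e-9]
        if len(dominant) == 1:
            return "top_heavy" if dominant[0] == len(gains) - 1 else "mesoscale"
    return "bottom_heavy" if micro_cp > total else "flat"
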