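"""Causal primitives and their information-theoretic generalizations.

For one scale of a Markov system (a TPM plus an intervention distribution
P(C) over causes) this module computes:

- sufficiency  suff(e, c) = P(e | c): certainty of an effect given a cause;
- necessity    nec(e, c) = 1 - P(e | C, not-c): certainty that no other
  viable cause would have produced the effect;
- their system-wide expectations, weighted by pc(c) * P(e | c) over
  transitions;
- determinism  = E_c[1 - H(E|c) / log2 n], the entropy generalization of
  sufficiency (1 for one-hot rows, 0 for all-uniform rows);
- degeneracy   = 1 - H(E) / log2 n with P(E) the pc-mixture of rows, the
  inclusive inverse generalization of necessity; specificity = 1 - degeneracy;
- combined causal-primitive (CP) scores:
  cp_primitive = suff_sys + nec_sys - 1 and
  cp_info = determinism + specificity - 1 (the CE 1.0 "effectiveness");
- effective information  EI = (determinism - degeneracy) * log2 n, which
  equals the mutual information I(C; E) under P(C).

CP scores can in pathological cases leave [0, 1]; they are reported
un-clamped and flagged rather than silently truncated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .markov import InterventionDistribution, TransitionMatrix, shannon_entropy

__all__ = [
    "PrimitiveScores",
    "sufficiency",
    "necessity",
    "system_sufficiency",
    "system_necessity",
    "determinism_coefficient",
    "degeneracy_coefficient",
    "cp_scores",
    "effective_information",
]


@dataclass(frozen=True)
class PrimitiveScores:
    """Every scale-level causal quantity for one TPM + P(C)."""

    suff_sys: float
    nec_sys: float
    determinism: float
    degeneracy: float
    specificity: float
    cp_primitive: float
    cp_info: float
    effectiveness: float
    ei: float
    n_states: int
    pc_mode: str
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "suff_sys": self.suff_sys,
            "nec_sys": self.nec_sys,
            "determinism": self.determinism,
            "degeneracy": self.degeneracy,
            "specificity": self.specificity,
            "cp_primitive": self.cp_primitive,
            "cp_info": self.cp_info,
            "effectiveness": self.effectiveness,
            "ei": self.ei,
            "n_states": self.n_states,
            "pc_mode": self.pc_mode,
            "flags": list(self.flags),
        }


def _resolve_pc(tm: TransitionMatrix, pc: InterventionDistribution | None) -> InterventionDistribution:
    if pc is None:
        return InterventionDistribution.uniform(tm.n)
    if pc.n != tm.n:
        raise ValueError(f"P(C) has {pc.n} entries for an {tm.n}-state TPM")
    return pc


def sufficiency(tm: TransitionMatrix, c: int, e: int) -> float:
    """P(e | c), read directly from the TPM."""
    return float(tm.probs[c, e])


def _alternative_effect_probs(tm: TransitionMatrix, c: int, w: np.ndarray) -> np.ndarray:
    """P(e | C, not-c): the pc-mixture of rows with cause c excluded."""
    wc = w[c]
    if 1.0 - wc <= 0:
        raise ValueError(f"P(C) places all mass on cause {c}; necessity undefined")
    return (w @ tm.probs - wc * tm.probs[c]) / (1.0 - wc)


def necessity(
    tm: TransitionMatrix, c: int, e: int, pc: InterventionDistribution | None = None
) -> float:
    """1 - P(e | C, not-c): how irreplaceable cause c is for effect e."""
    if tm.n < 2:
        raise ValueError("necessity needs at least two states (alternative causes)")
    w = _resolve_pc(tm, pc).weights
    return float(1.0 - _alternative_effect_probs(tm, c, w)[e])


def system_sufficiency(tm: TransitionMatrix, pc: InterventionDistribution | None = None) -> float:
    """Expectation of suff(e, c) under the transition weight pc(c) * P(e|c)."""
    w = _resolve_pc(tm, pc).weights
    return float(w @ np.sum(tm.probs**2, axis=1))


def system_necessity(tm: TransitionMatrix, pc: InterventionDistribution | None = None) -> float:
    """Expectation of nec(e, c) under the transition weight pc(c) * P(e|c)."""
    if tm.n < 2:
        raise ValueError("necessity needs at least two states (alternative causes)")
    w = _resolve_pc(tm, pc).weights
    total = 0.0
    for c in range(tm.n):
        if w[c] == 0.0:
            continue
        alt = _alternative_effect_probs(tm, c, w)
        total += w[c] * float(tm.probs[c] @ (1.0 - alt))
    return total


def determinism_coefficient(
    tm: TransitionMatrix, pc: InterventionDistribution | None = None
) -> float:
    """pc-weighted mean of 1 - H(E|c)/log2(n) over causes c."""
    if tm.n < 2:
        raise ValueError("determinism coefficient undefined for n = 1 (log2 n = 0)")
    w = _resolve_pc(tm, pc).weights
    logn = np.log2(tm.n)
    row_ent = np.array([shannon_entropy(r) for r in tm.probs])
    return float(w @ (1.0 - row_ent / logn))


def degeneracy_coefficient(
    tm: TransitionMatrix, pc: InterventionDistribution | None = None
) -> float:
    """1 - H(E)/log2(n), with P(E) the pc-mixture of the TPM's rows."""
    if tm.n < 2:
        raise ValueError("degeneracy coefficient undefined for n = 1 (log2 n = 0)")
    w = _resolve_pc(tm, pc).weights
    return float(1.0 - shannon_entropy(w @ tm.probs) / np.log2(tm.n))


def effective_information(
    tm: TransitionMatrix, pc: InterventionDistribution | None = None
) -> float:
    """EI = (determinism - degeneracy) * log2 n = I(C; E) under P(C), bits."""
    if tm.n == 1:
        return 0.0
    pc = _resolve_pc(tm, pc)
    eff = determinism_coefficient(tm, pc) - degeneracy_coefficient(tm, pc)
    return float(eff * np.log2(tm.n))


def cp_scores(tm: TransitionMatrix, pc: InterventionDistribution | None = None) -> PrimitiveScores:
    """All primitive scores for one scale.

    A single-state scale supports no causal distinctions: its lone state is
    fully sufficient (P = 1) and fully degenerate (every cause yields the
    same effect), so every CP-type score and the EI are exactly 0.
    """
    pc = _resolve_pc(tm, pc)
    if tm.n == 1:
        return PrimitiveScores(
            suff_sys=1.0, nec_sys=0.0, determinism=1.0, degeneracy=1.0,
            specificity=0.0, cp_primitive=0.0, cp_info=0.0, effectiveness=0.0,
            ei=0.0, n_states=1, pc_mode=pc.mode, flags=("single_state",),
        )
    suff = system_sufficiency(tm, pc)
    nec = system_necessity(tm, pc)
    det = determinism_coefficient(tm, pc)
    deg = degeneracy_coefficient(tm, pc)
    spec = 1.0 - deg
    cp_prim = suff + nec - 1.0
    eff = det - deg
    cp_inf = det + spec - 1.0
    flags = []
    if cp_prim < 0 or cp_prim > 1:
        flags.append("cp_primitive_out_of_bounds")
    if cp_inf < 0 or cp_inf > 1:
        flags.append("cp_info_out_of_bounds")
    return PrimitiveScores(
        suff_sys=suff, nec_sys=nec, determinism=det, degeneracy=deg,
        specificity=spec, cp_primitive=cp_prim, cp_info=cp_inf,
        effectiveness=eff, ei=float(eff * np.log2(tm.n)),
        n_states=tm.n, pc_mode=pc.mode, flags=tuple(flags),
    )
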