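"""End-to-end analysis: endpoint selection, path, apportioning, complexity.

``analyze`` ties the modules together into one run over a TPM and returns a
self-describing report dictionary that serializes to stable JSON: endpoint
choice, per-scale CP values and gains, total causal emergence, the
1 - CP(micro) upper bound, the emergent-complexity statistic and profile,
and (optionally) the EI-based comparison and the SVD reversibility
heuristic.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import asdict, dataclass, field

from . import __version__
from .complexity import ComplexityReport, classify_profile, emergent_complexity
from .config import DEFAULT_TOLERANCES, Tolerances
from .fixtures import svd_reversibility
from .markov import InterventionDistribution, TransitionMatrix, load_tpm
from .paths import (
    InconsistentEndpointError,
    PathAnalysis,
    apportion,
    build_path,
    ce_upper_bound,
    find_endpoint_exhaustive,
    find_endpoint_greedy,
    scale_scores,
)
from .scales import Partition, consistency_check, parse_partition

__all__ = ["AnalysisConfig", "AnalysisError", "analyze", "render_report", "write_report"]

logger = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Options for one analysis run.

    ``measure`` selects the CP definition ("cp_info" = determinism +
    specificity - 1, the default used in all figures; "cp_primitive" =
    sufficiency + necessity - 1).  ``endpoint_mode`` is "exhaustive",
    "greedy", or "fixed" (which requires ``fixed_endpoint``, a partition
    string).  ``epsilon``/``window`` parameterize the greedy
    diminishing-returns stop.
    """

    measure: str = "cp_info"
    pc_mode: str = "uniform"
    endpoint_mode: str = "exhaustive"
    fixed_endpoint: str | None = None
    epsilon: float = 1e-6
    window: int = 3
    consistency_tol: float = DEFAULT_TOLERANCES.consistency
    horizon: int = DEFAULT_TOLERANCES.horizon
    zero_steps: str = "include"
    include_ce1: bool = True
    include_svd: bool = True
    svd_alpha: float = 1.0
    seed: int | None = None
    custom_pc: InterventionDistribution | None = None

    def __post_init__(self) -> None:
        if self.epsilon <= 0 or self.consistency_tol <= 0:
            raise ValueError("tolerances must be positive")
        if self.endpoint_mode == "fixed" and not self.fixed_endpoint:
            raise ValueError("endpoint_mode='fixed' requires a partition string")

    def tolerances(self) -> Tolerances:
        t = Tolerances()
        t.consistency = self.consistency_tol
        t.horizon = self.horizon
        return t

    def to_dict(self) -> dict:
        return {
            "measure": self.measure,
            "pc_mode": self.pc_mode,
            "endpoint_mode": self.endpoint_mode,
            "fixed_endpoint": self.fixed_endpoint,
            "epsilon": self.epsilon,
            "window": self.window,
            "consistency_tol": self.consistency_tol,
            "horizon": self.horizon,
            "zero_steps": self.zero_steps,
            "seed": self.seed,
        }


class AnalysisError(RuntimeError):
    """An analysis stage failed; ``stage`` names the failing stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            logger.info("stage: %s", name)
            try:
                return fn(*args, **kwargs)
            except (AnalysisError, InconsistentEndpointError):
                raise
            except Exception as exc:  # noqa: BLE001 - rewrap with stage name
                raise AnalysisError(name, exc) from exc
        return wrapper
    return deco


def analyze(tpm_source, config: AnalysisConfig | None = None) -> dict:
    """Run the full multiscale causal analysis and return the report dict."""
    config = config or AnalysisConfig()
    tol = config.tolerances()

    tm = _load(tpm_source)
    micro_scores = _micro(tm, config)
    endpoint = _endpoint(tm, config, tol)
    path = _path(tm, endpoint.partition, config, tol)
    complexity = _complexity(path, config)

    report = {
        "generator": f"causal-emergence {__version__}",
        "config": config.to_dict(),
        "system": {"labels": list(tm.labels), "n": tm.n},
        "scores": micro_scores.to_dict(),
        "ce_upper_bound": 1.0 - getattr(micro_scores, config.measure),
        "endpoint": {
            "partition": endpoint.partition.label,
            "cp": endpoint.cp,
            "n_macro_states": endpoint.n_macro_states,
            "search_mode": endpoint.search_mode,
        },
        "path": {
            "scales": [s.label for s in path.scales],
            "cp": list(path.cp_values),
            "delta_cp": list(path.deltas),
            "total_ce": path.total_ce,
            "consistent": [c.consistent for c in path.consistency],
            "max_errors": [c.max_error for c in path.consistency],
            "flags": list(path.flags),
        },
        "apportionment": [
            {"scale": label, "contribution": value} for label, value in apportion(path)
        ],
        "emergent_complexity": {
            "gains": list(complexity.gains),
            "p": list(complexity.p),
            "ec_bits": complexity.ec_bits,
            "ec_normalized": complexity.ec_normalized,
            "L": complexity.L,
            "profile": complexity.profile,
            "flags": list(complexity.flags),
        },
    }
    if config.include_ce1:
        end_scores = path.scores[-1]
        report["ce1"] = {
            "ei_micro": micro_scores.ei,
            "ei_endpoint": end_scores.ei,
            "ei_gain": end_scores.ei - micro_scores.ei,
            "ce1_emergence": max(0.0, end_scores.ei - micro_scores.ei),
        }
    if config.include_svd:
        sv = svd_reversibility(tm, config.svd_alpha)
        report["svd_reversibility"] = {
            "alpha": sv.alpha,
            "total": sv.total,
            "normalized": sv.normalized,
            "heuristic": True,
        }
    return report


@_stage("load")
def _load(tpm_source) -> TransitionMatrix:
    if isinstance(tpm_source, TransitionMatrix):
        return tpm_source
    return load_tpm(tpm_source)


@_stage("microscale-scores")
def _micro(tm: TransitionMatrix, config: AnalysisConfig):
    return scale_scores(tm, Partition.discrete(tm.n), config.pc_mode, config.custom_pc)


@_stage("endpoint-selection")
def _endpoint(tm: TransitionMatrix, config: AnalysisConfig, tol: Tolerances):
    from .paths import EndpointChoice

    if config.endpoint_mode == "exhaustive":
        return find_endpoint_exhaustive(
            tm, config.pc_mode, config.measure, config.custom_pc, tol
        )
    if config.endpoint_mode == "greedy":
        return find_endpoint_greedy(
            tm, config.pc_mode, config.measure, config.epsilon, config.window,
            config.custom_pc, tol,
        )
    if config.endpoint_mode == "fixed":
        part = parse_partition(config.fixed_endpoint, tm.n)
        check = consistency_check(tm, part, tol.consistency, tol.horizon)
        if not check.consistent:
            raise InconsistentEndpointError(
                f"fixed endpoint {part.label} is dynamically inconsistent "
                f"(max TV error {check.max_error:.3g})"
            )
        scores = scale_scores(tm, part, config.pc_mode, config.custom_pc)
        return EndpointChoice(part, getattr(scores, config.measure), part.n_blocks, "fixed")
    raise ValueError(f"unknown endpoint_mode {config.endpoint_mode!r}")


@_stage("path-construction")
def _path(tm, endpoint: Partition, config: AnalysisConfig, tol: Tolerances) -> PathAnalysis:
    return build_path(tm, endpoint, config.pc_mode, config.measure, config.custom_pc, tol)


@_stage("emergent-complexity")
def _complexity(path: PathAnalysis, config: AnalysisConfig) -> ComplexityReport:
    if path.L == 0:
        # endpoint == microscale: no steps, hence no contribution distribution
        return ComplexityReport(
            gains=(), p=(), ec_bits=float("nan"), ec_normalized=float("nan"),
            L=0, profile=classify_profile(path, None), flags=("no_steps",),
        )
    return emergent_complexity(path, config.zero_steps)


# ---- report serialization ------------------------------------------------


def _round12(obj):
    """Normalize floats to 12 significant digits for stable report output."""
    if isinstance(obj, float):
        if math.isnan(obj):
            return None
        return float(f"{obj:.12g}")
    if isinstance(obj, dict):
        return {k: _round12(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round12(v) for v in obj]
    return obj


def render_report(report: dict) -> str:
    """Deterministic JSON text (12 significant digits, stable key order)."""
    return json.dumps(_round12(report), indent=2) + "\n"


def write_report(report: dict, path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(render_report(report))
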