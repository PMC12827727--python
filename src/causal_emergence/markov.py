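"""Transition-matrix data model, validation, entropies, stationary laws, I/O.

A discrete Markov system is fully described by a row-stochastic transition
probability matrix (TPM): ``probs[i, j]`` is the probability that the system
occupies state ``j`` at time t+1 given that it occupies state ``i`` at time
t.  Rows are causes, columns are effects.  All causal quantities in this
package are computed relative to an *intervention distribution* P(C) over
causes — the set of counterfactuals or interventions considered viable —
which is uniform by default and independent of the observed dynamics.
"""

from __future__ import annotations

import csv
import io
import json
import math
import os
from dataclasses import dataclass, field

import numpy as np

from .config import DEFAULT_TOLERANCES, Tolerances

__all__ = [
    "TransitionMatrix",
    "InterventionDistribution",
    "InvalidTPMError",
    "InvalidDistributionError",
    "StationaryConvergenceError",
    "load_tpm",
    "write_tpm",
    "validate_stochastic",
    "stationary_distribution",
    "shannon_entropy",
]


class InvalidTPMError(ValueError):
    """A matrix fails the transition-probability-matrix invariants."""


class InvalidDistributionError(ValueError):
    """A vector fails the probability-distribution invariants."""


class StationaryConvergenceError(RuntimeError):
    """The stationary-distribution solver exhausted its iteration budget."""


def _as_float_matrix(probs) -> np.ndarray:
    arr = np.asarray(probs, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
        raise InvalidTPMError(f"TPM must be square, got shape {arr.shape}")
    return arr


@dataclass(frozen=True)
class TransitionMatrix:
    """An n-state Markov causal model at one scale.

    Parameters
    ----------
    labels
        State identifiers, positionally aligned with both rows and columns.
    probs
        Row-stochastic n x n matrix, ``probs[i, j] = P(j at t+1 | i at t)``.
    """

    labels: tuple[str, ...]
    probs: np.ndarray
    tol: Tolerances = field(default_factory=Tolerances, compare=False, repr=False)

    def __post_init__(self) -> None:
        arr = _as_float_matrix(self.probs)
        labels = tuple(str(x) for x in self.labels)
        if len(labels) != arr.shape[0]:
            raise InvalidTPMError(
                f"{len(labels)} labels for a {arr.shape[0]}-state matrix"
            )
        if len(set(labels)) != len(labels):
            raise InvalidTPMError("duplicate state labels")
        if np.any(arr < 0):
            i, j = np.argwhere(arr < 0)[0]
            raise InvalidTPMError(f"negative entry {arr[i, j]} at ({i}, {j})")
        if np.any(arr > 1 + self.tol.row_sum):
            i, j = np.argwhere(arr > 1 + self.tol.row_sum)[0]
            raise InvalidTPMError(f"entry {arr[i, j]} > 1 at ({i}, {j})")
        sums = arr.sum(axis=1)
        bad = np.where(np.abs(sums - 1.0) > self.tol.row_sum)[0]
        if bad.size:
            i = int(bad[0])
            raise InvalidTPMError(f"row {i} sums to {float(sums[i])!r}, expected 1")
        arr = arr.copy()
        arr.flags.writeable = False
        object.__setattr__(self, "probs", arr)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.labels)

    def row(self, i: int) -> np.ndarray:
        return self.probs[i]

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, TransitionMatrix)
            and self.labels == other.labels
            and np.array_equal(self.probs, other.probs)
        )

    # ---- serialization ---------------------------------------------------

    def to_csv(self) -> str:
        """CSV text: a label header row, then one probability row per state."""
        buf = io.StringIO()
        w = csv.writer(buf, lineterminator="\n")
        w.writerow(self.labels)
        for row in self.probs:
            w.writerow([repr(float(x)) for x in row])
        return buf.getvalue()

    def to_json(self) -> str:
        return json.dumps(
            {"labels": list(self.labels), "probs": [[float(x) for x in r] for r in self.probs]}
        )

    def to_dict(self) -> dict:
        return {"labels": list(self.labels), "probs": self.probs.tolist()}


@dataclass(frozen=True)
class InterventionDistribution:
    """A distribution P(C) over causes: the interventions considered viable.

    ``mode`` records provenance: "uniform" (the maximum-entropy default used
    throughout a causal analysis), "stationary" (the observed long-run law of
    the chain), or "custom".
    """

    weights: np.ndarray
    mode: str = "custom"

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float).ravel()
        if np.any(w < 0):
            raise InvalidDistributionError("negative probability mass")
        if abs(w.sum() - 1.0) > DEFAULT_TOLERANCES.distribution:
            raise InvalidDistributionError(f"weights sum to {w.sum()!r}, expected 1")
        if self.mode not in ("uniform", "stationary", "custom"):
            raise InvalidDistributionError(f"unknown mode {self.mode!r}")
        w = w.copy()
        w.flags.writeable = False
        object.__setattr__(self, "weights", w)

    @classmethod
    def uniform(cls, n: int) -> "InterventionDistribution":
        if n < 1:
            raise InvalidDistributionError("need at least one state")
        return cls(np.full(n, 1.0 / n), mode="uniform")

    @property
    def n(self) -> int:
        return self.weights.size

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, InterventionDistribution)
            and self.mode == other.mode
            and np.array_equal(self.weights, other.weights)
        )


# ---- I/O -----------------------------------------------------------------


def _looks_like_path(source) -> bool:
    if isinstance(source, os.PathLike):
        return True
    return isinstance(source, str) and "\n" not in source and not source.lstrip().startswith("{")


def load_tpm(source, format: str | None = None) -> TransitionMatrix:
    """Load a TPM from a CSV/JSON file path or from literal text.

    CSV dialect: first row is the comma-separated state labels, subsequent
    rows are probabilities ('.' decimal separator, UTF-8).  JSON documents
    have the shape ``{"labels": [...], "probs": [[...], ...]}``.
    """
    if _looks_like_path(source):
        path = os.fspath(source)
        if format is None:
            format = "json" if path.endswith(".json") else "csv"
        with open(path, encoding="utf-8") as fh:
            text = fh.read()
    else:
        text = str(source)
        if format is None:
            format = "json" if text.lstrip().startswith("{") else "csv"

    if format == "json":
        doc = json.loads(text)
        try:
            labels, probs = doc["labels"], doc["probs"]
        except (TypeError, KeyError) as exc:
            raise InvalidTPMError("JSON TPM needs 'labels' and 'probs' keys") from exc
        return TransitionMatrix(tuple(str(x) for x in labels), _parse_rows(probs))
    if format == "csv":
        rows = [r for r in csv.reader(io.StringIO(text)) if r]
        if len(rows) < 2:
            raise InvalidTPMError("CSV TPM needs a label header and data rows")
        labels = tuple(x.strip() for x in rows[0])
        return TransitionMatrix(labels, _parse_rows(rows[1:]))
    raise ValueError(f"unknown format {format!r}")


def _parse_rows(rows) -> np.ndarray:
    try:
        return np.array([[float(x) for x in r] for r in rows], dtype=float)
    except (TypeError, ValueError) as exc:
        raise InvalidTPMError(f"non-numeric matrix entry: {exc}") from exc


def write_tpm(tm: TransitionMatrix, path, format: str | None = None) -> None:
    path = os.fspath(path)
    if format is None:
        format = "json" if path.endswith(".json") else "csv"
    text = tm.to_json() if format == "json" else tm.to_csv()
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(text)


# ---- core numerics -------------------------------------------------------


def validate_stochastic(tm: TransitionMatrix, tol: float | None = None) -> TransitionMatrix:
    """Renormalize rows whose sums sit within ``tol`` of 1; raise otherwise."""
    if tol is None:
        tol = tm.tol.row_sum
    sums = tm.probs.sum(axis=1)
    bad = np.where(np.abs(sums - 1.0) > tol)[0]
    if bad.size:
        i = int(bad[0])
        raise InvalidTPMError(
            f"row {i} sums to {float(sums[i])!r}, beyond tolerance {tol}"
        )
    return TransitionMatrix(tm.labels, tm.probs / sums[:, None], tol=tm.tol)


def shannon_entropy(dist) -> float:
    """Shannon entropy of a probability vector, in bits; 0*log(0) := 0."""
    p = np.asarray(dist, dtype=float).ravel()
    if np.any(p < 0):
        raise InvalidDistributionError("negative probability mass")
    if p.sum() > 1 + DEFAULT_TOLERANCES.distribution:
        raise InvalidDistributionError(f"mass {p.sum()!r} exceeds 1")
    nz = p[p > 0]
    return float(-np.sum(nz * np.log2(nz)))


def stationary_distribution(
    tm: TransitionMatrix, tol: Tolerances | None = None
) -> InterventionDistribution:
    """Long-run occupation law of the chain, started uniformly.

    Computed as the time-averaged (Cesaro) limit of a uniform start, which
    exists for every row-stochastic matrix and coincides with the unique
    stationary law when the chain is irreducible.  The limit is obtained by
    power-iterating the lazy chain (I + T)/2, which shares the Cesaro limit
    but converges geometrically even for periodic dynamics.
    """
    tol = tol or tm.tol
    lazy = 0.5 * (np.eye(tm.n) + tm.probs)
    x = np.full(tm.n, 1.0 / tm.n)
    for _ in range(tol.stationary_max_iter):
        nxt = x @ lazy
        if np.abs(nxt - x).sum() < tol.stationary_step:
            x = nxt
            break
        x = nxt
    else:
        raise StationaryConvergenceError(
            f"no convergence within {tol.stationary_max_iter} iterations"
        )
    x = x / x.sum()
    if np.abs(x @ tm.probs - x).sum() > tol.stationary * tm.n:
        raise StationaryConvergenceError("iterate does not satisfy pi @ T = pi")
    return InterventionDistribution(x, mode="stationary")
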