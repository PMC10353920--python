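"""Asymptotic perturbation analysis of a projection matrix.

Given a nonnegative projection matrix A, the analysis yields the dominant
eigenvalue ``lambda`` (the asymptotic annual growth multiplier), the stable
stage distribution w (right eigenvector, scaled to sum to 1), reproductive
values v (left eigenvector, scaled so <v, w> = 1), sensitivities
``s_ij = v_i * w_j`` and elasticities

    e_ij = (a_ij / lambda) * v_i * w_j,

the proportional contributions of each matrix element to lambda.
Elasticities are nonnegative, sum to 1 over the matrix, and have equal row
and column sums per stage.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .lifecycle import STAGES, ProjectionMatrix

__all__ = [
    "PerturbationResult",
    "EIDER_GROUPING",
    "EIDER_TRANSITION_GROUPS",
    "growth_rate",
    "eigen_structure",
    "elasticity_matrix",
    "group_elasticities",
    "nonbreeder_pathway_summary",
    "round_percent",
]


class DegeneracyError(ValueError):
    """The dominant eigenvalue is not well separated or not usable."""


def _as_array(matrix) -> tuple[np.ndarray, tuple[str, ...]]:
    if isinstance(matrix, ProjectionMatrix):
        return matrix.entries, matrix.stage_order
    a = np.asarray(matrix, dtype=float)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError("projection matrix must be square")
    labels = tuple(f"stage{i}" for i in range(a.shape[0]))
    return a, labels


def _validate(a: np.ndarray) -> None:
    if not np.all(np.isfinite(a)):
        raise ValueError("matrix entries must be finite")
    if np.any(a < 0):
        raise ValueError("matrix entries must be nonnegative")


def growth_rate(matrix) -> float:
    """Dominant eigenvalue: the asymptotic per-year growth multiplier."""
    a, _ = _as_array(matrix)
    _validate(a)
    eigvals = np.linalg.eigvals(a)
    lam = eigvals[np.argmax(eigvals.real)]
    # Perron root of a nonnegative matrix is real; discard numerical fuzz.
    return float(lam.real)


def eigen_structure(matrix) -> tuple[np.ndarray, np.ndarray]:
    """Stable stage distribution w and reproductive values v.

    w is the right eigenvector at the dominant eigenvalue, scaled to sum to
    1; v is the left eigenvector scaled so that <v, w> = 1.  For a
    reducible matrix, stages unreachable at stationarity carry zero mass in
    w (and symmetrically for v).
    """
    a, _ = _as_array(matrix)
    _validate(a)
    eigvals, right = np.linalg.eig(a)
    order = np.argsort(-eigvals.real)
    i = order[0]
    if len(order) > 1:
        gap = abs(eigvals[order[0]].real - abs(eigvals[order[1]]))
        if abs(eigvals[order[0]].imag) > 1e-9:
            raise DegeneracyError("dominant eigenvalue is complex beyond tolerance")
    w = right[:, i].real
    w = np.where(np.abs(w) < 1e-12, 0.0, w)
    if w.sum() < 0:
        w = -w
    if np.any(w < -1e-9):
        raise DegeneracyError("dominant right eigenvector is not sign-consistent")
    w = np.clip(w, 0.0, None)
    w = w / w.sum()

    eigvals_l, left = np.linalg.eig(a.T)
    j = np.argmax(eigvals_l.real)
    v = left[:, j].real
    v = np.where(np.abs(v) < 1e-12, 0.0, v)
    if v.sum() < 0:
        v = -v
    if np.any(v < -1e-9):
        raise DegeneracyError("dominant left eigenvector is not sign-consistent")
    v = np.clip(v, 0.0, None)
    denom = float(v @ w)
    if denom <= 0:
        raise DegeneracyError("left and right eigenvectors are orthogonal")
    v = v / denom
    return w, v


@dataclass(frozen=True)
class PerturbationResult:
    """Growth rate, eigenvectors and the sensitivity/elasticity matrices."""

    lambda_: float
    w: np.ndarray
    v: np.ndarray
    sensitivity: np.ndarray
    elasticity: np.ndarray
    stage_order: tuple[str, ...] = STAGES

    def elasticity_entry(self, to_stage: str, from_stage: str) -> float:
        i = self.stage_order.index(to_stage)
        j = self.stage_order.index(from_stage)
        return float(self.elasticity[i, j])


def elasticity_matrix(matrix) -> PerturbationResult:
    """Full perturbation analysis: lambda, w, v, sensitivities, elasticities."""
    a, labels = _as_array(matrix)
    lam = growth_rate(matrix)
    if lam == 0:
        raise DegeneracyError("elasticities undefined at lambda = 0")
    w, v = eigen_structure(matrix)
    sens = np.outer(v, w)
    elas = a * sens / lam
    return PerturbationResult(
        lambda_=lam, w=w, v=v, sensitivity=sens, elasticity=elas, stage_order=labels
    )


#: Transition-group map for the eider matrix: each structurally nonzero cell
#: (to_stage, from_stage) is assigned to exactly one of three groups.
#: "Recruitment" covers all prebreeder transitions (recruiting or deferring),
#: "Breeding transitions" the four adult breeder/nonbreeder cells, and
#: "Reproduction" the fertility element.
EIDER_GROUPING: dict[tuple[str, str], str] = {
    ("PB2", "1yo"): "Recruitment",
    ("B", "1yo"): "Recruitment",
    ("PB3", "PB2"): "Recruitment",
    ("B", "PB2"): "Recruitment",
    ("PB4", "PB3"): "Recruitment",
    ("B", "PB3"): "Recruitment",
    ("B", "PB4"): "Recruitment",
    ("B", "B"): "Breeding transitions",
    ("NB", "B"): "Breeding transitions",
    ("B", "NB"): "Breeding transitions",
    ("NB", "NB"): "Breeding transitions",
    ("1yo", "B"): "Reproduction",
}

#: Group labels in presentation order.
EIDER_TRANSITION_GROUPS: tuple[str, ...] = (
    "Recruitment",
    "Breeding transitions",
    "Reproduction",
)


def group_elasticities(
    result: PerturbationResult,
    grouping: Mapping[tuple[str, str], str],
) -> dict[str, float]:
    """Sum elasticities by transition group.

    Every nonzero elasticity cell must be covered by ``grouping``; the group
    sums then total 1.
    """
    sums: dict[str, float] = {g: 0.0 for g in dict.fromkeys(grouping.values())}
    n = len(result.stage_order)
    for i in range(n):
        for j in range(n):
            e = result.elasticity[i, j]
            if e == 0:
                continue
            key = (result.stage_order[i], result.stage_order[j])
            if key not in grouping:
                raise ValueError(
                    f"nonzero elasticity cell {key} is not covered by the grouping"
                )
            sums[grouping[key]] += float(e)
    return sums


def nonbreeder_pathway_summary(result: PerturbationResult) -> dict[str, float]:
    """Headline elasticities of the adult breeding/nonbreeding pathway.

    Returns the elasticity of continued breeding (B->B), of the state
    switches between breeding and nonbreeding (B->NB plus NB->B), of
    continued nonbreeding (NB->NB), and of fertility (B->1yo).
    """
    e = result.elasticity_entry
    return {
        "continued_breeding": e("B", "B"),
        "state_switching": e("NB", "B") + e("B", "NB"),
        "continued_nonbreeding": e("NB", "NB"),
        "fertility": e("1yo", "B"),
    }


def round_percent(x: float) -> int:
    """Fraction -> integer percent, rounding half away from zero."""
    import math

    scaled = 100.0 * x
    return int(math.floor(scaled + 0.5)) if scaled >= 0 else -int(math.floor(-scaled + 0.5))
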