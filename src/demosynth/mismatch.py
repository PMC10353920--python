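"""Study effort versus demographic importance: deviation and null model.

For each transition group the analysis pairs its summed elasticity
("importance") with its fractional study effort (contributing studies over
total studies) and asks how probable a deviation at least as large, on the
same side of the 1:1 line, would be if effort were assigned at random.
Under a Uniform(0, 1) null for effort, independent of importance:

- over-representation (effort f > importance): P = 1 - f;
- under-representation (effort f < importance): P = f;
- exact match: P = 1 (any draw deviates at least zero).

A complementary simulation draws importance sets uniformly on the simplex
(flat Dirichlet) to illustrate why random fraction sets tend to have one
high value forcing the others low.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .records import StudyEffortTable

__all__ = [
    "MismatchResult",
    "fractional_effort",
    "chance_probability",
    "mismatch_table",
    "contour_grid",
    "SimplexNullResult",
    "simplex_null_simulation",
]


@dataclass(frozen=True)
class MismatchResult:
    """Effort-importance comparison for one transition group."""

    group: str
    importance: float
    effort: float
    deviation: float  # effort - importance
    side: str  # "over" | "under" | "exact"
    chance_probability: float


def fractional_effort(table: StudyEffortTable) -> dict[str, float]:
    """Per-group study count divided by the total study count."""
    if table.total_studies <= 0:
        raise ZeroDivisionError("fractional effort undefined with zero total studies")
    return {g: c / table.total_studies for g, c in table.group_counts.items()}


def chance_probability(
    importance: float, effort: float, group: str = ""
) -> MismatchResult:
    """Probability of a chance deviation at least as extreme, same side."""
    for name, x in (("importance", importance), ("effort", effort)):
        if not 0.0 <= x <= 1.0:
            raise ValueError(f"{name}={x} outside [0, 1]")
    deviation = effort - importance
    if deviation > 0:
        side, prob = "over", 1.0 - effort
    elif deviation < 0:
        side, prob = "under", effort
    else:
        side, prob = "exact", 1.0
    return MismatchResult(group, importance, effort, deviation, side, prob)


def mismatch_table(
    importances: Mapping[str, float],
    efforts: Mapping[str, float],
) -> pd.DataFrame:
    """Tabulate the effort-importance comparison across groups.

    Groups are taken from ``importances``; each must have a matching entry
    in ``efforts``.
    """
    rows = []
    for group, imp in importances.items():
        if group not in efforts:
            raise KeyError(f"no study-effort fraction for group {group!r}")
        r = chance_probability(imp, efforts[group], group)
        rows.append(
            {
                "group": r.group,
                "importance": r.importance,
                "effort": r.effort,
                "deviation": r.deviation,
                "side": r.side,
                "chance_probability": r.chance_probability,
            }
        )
    return pd.DataFrame(rows)


def contour_grid(step: float = 0.01) -> pd.DataFrame:
    """Closed-form null probability over the unit square, long format.

    Columns: importance, effort, probability.  Suitable for contour/heatmap
    plotting of the chance-deviation surface.
    """
    if not 0.0 < step <= 0.1:
        raise ValueError("grid step must be in (0, 0.1]")
    axis = np.round(np.arange(0.0, 1.0 + step / 2, step), 12)
    imp, eff = np.meshgrid(axis, axis, indexing="ij")
    imp, eff = imp.ravel(), eff.ravel()
    prob = np.where(eff > imp, 1.0 - eff, np.where(eff < imp, eff, 1.0))
    return pd.DataFrame({"importance": imp, "effort": eff, "probability": prob})


@dataclass(frozen=True)
class SimplexNullResult:
    """Draws of random fraction sets summing to 1, with summaries."""

    k: int
    draws: int
    fractions: np.ndarray  # shape (draws, k)
    max_fractions: np.ndarray  # shape (draws,)

    def prob_max_at_least(self, threshold: float) -> float:
        """Empirical P(largest fraction >= threshold)."""
        return float(np.mean(self.max_fractions >= threshold))

    def deviation_probability(
        self, d: float, side: str, rng: np.random.Generator | None = None
    ) -> float:
        """Empirical P(uniform effort deviates >= d from a simplex importance).

        Importance is the first component of each simplex draw; effort is an
        independent Uniform(0, 1) draw.  ``side`` selects over- ("over") or
        under- ("under") representation.
        """
        if side not in ("over", "under"):
            raise ValueError("side must be 'over' or 'under'")
        rng = rng or np.random.default_rng(0)
        effort = rng.uniform(size=self.draws)
        dev = effort - self.fractions[:, 0]
        if side == "over":
            return float(np.mean(dev >= d))
        return float(np.mean(-dev >= d))


def simplex_null_simulation(
    k: int, draws: int, seed: int
) -> SimplexNullResult:
    """Sample fraction sets uniformly on the (k-1)-simplex.

    A flat Dirichlet(1, ..., 1) draw is uniform over all nonnegative
    fraction sets summing to 1 — the reference distribution for a random
    assignment of elasticities across k transition groups.
    """
    if k < 2:
        raise ValueError("need at least two groups")
    if draws < 1:
        raise ValueError("need at least one draw")
    rng = np.random.default_rng(seed)
    fractions = rng.dirichlet(np.ones(k), size=draws)
    return SimplexNullResult(
        k=k, draws=draws, fractions=fractions, max_fractions=fractions.max(axis=1)
    )
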