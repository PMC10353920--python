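"""Six-stage prebreeding projection matrix for an intermittently breeding duck.

The life cycle is female-only with a prebreeding census: the youngest
tracked class is just under one year old.  Stages are

    [1yo, PB2, PB3, PB4, B, NB]

— a 1-year-old, prebreeders aged 2–4, breeders and nonbreeders.  A
surviving 1-year-old either recruits (with propensity ``BP2``) or moves to
the 2-year-old prebreeder stage; each subsequent prebreeder year offers
recruitment with propensity ``BP3``..``BP5``, with ``BP5 = 1`` because no
recruitment deferral beyond age 5 is observed.  Established breeders breed
again with propensity ``BPeb`` and otherwise pass to a discrete, reversible
nonbreeder stage; nonbreeders return to breeding with the same propensity.
Breeding and nonbreeding adults are assumed to share the adult survival
rate ``sa``, and the 1-year-old column uses second-year survival ``s2``.

Fertility (breeder to next year's 1-year-olds) is half the product of
clutch size, hatching success and first-year survival — halved for the
even sex ratio at hatching, since only daughters are projected.  First-year
survival is available through two measurement pathways: directly from
hatching (``s1h``), or as fledging success times survival from fledging
(``FS * s1f``).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd

__all__ = [
    "STAGES",
    "FERTILITY_MODES",
    "VitalRateSet",
    "ProjectionMatrix",
    "EIDER_MEAN_RATES",
    "effective_first_year_survival",
    "fertility",
    "build_matrix",
]

#: Fixed stage order used for all matrices and serialisations.
STAGES: tuple[str, ...] = ("1yo", "PB2", "PB3", "PB4", "B", "NB")

#: First-year-survival pathways for the fertility term.
FERTILITY_MODES: tuple[str, ...] = ("direct", "fledging_product", "pooled")


class ConstructionError(ValueError):
    """A vital-rate set cannot be assembled into a valid matrix."""


def _check_prob(name: str, value: float | None, allow_none: bool = False) -> None:
    if value is None:
        if allow_none:
            return
        raise ConstructionError(f"vital rate {name} is required")
    if not 0.0 <= value <= 1.0:
        raise ConstructionError(f"vital rate {name}={value} outside [0, 1]")


@dataclass(frozen=True)
class VitalRateSet:
    """The twelve parameters needed to build the projection matrix.

    ``s1h`` (first-year survival from hatching) may be given directly, or
    derived from ``FS`` and ``s1f``; at least one pathway must be complete.
    ``BP5`` is pinned at 1.  All rates are probabilities except ``CS``
    (clutch size, eggs per nest).
    """

    s2: float
    sa: float
    BP2: float
    BP3: float
    BP4: float
    BPeb: float
    CS: float
    HS: float
    BP5: float = 1.0
    s1h: float | None = None
    s1f: float | None = None
    FS: float | None = None

    def __post_init__(self) -> None:
        for name in ("s2", "sa", "BP2", "BP3", "BP4", "BP5", "BPeb", "HS"):
            _check_prob(name, getattr(self, name))
        for name in ("s1h", "s1f", "FS"):
            _check_prob(name, getattr(self, name), allow_none=True)
        if self.CS < 0:
            raise ConstructionError(f"clutch size CS={self.CS} must be nonnegative")
        if self.BP5 != 1.0:
            raise ConstructionError("BP5 must equal 1: all individuals recruit by age 5")
        if self.s1h is None and (self.s1f is None or self.FS is None):
            raise ConstructionError(
                "first-year survival unavailable: provide s1h, or both s1f and FS"
            )

    @classmethod
    def from_dict(cls, d: dict) -> "VitalRateSet":
        return cls(**{k: v for k, v in d.items() if v is not None})


#: Species-wide mean vital rates for the common eider (Somateria mollissima),
#: synthesised across the published literature; the default parameterisation
#: used throughout the examples and acceptance checks.
EIDER_MEAN_RATES = VitalRateSet(
    s1h=0.37,
    s1f=0.75,
    FS=0.22,
    s2=0.87,
    sa=0.86,
    BP2=0.17,
    BP3=0.58,
    BP4=0.71,
    BP5=1.0,
    BPeb=0.72,
    CS=4.08,
    HS=0.61,
)


def effective_first_year_survival(rates: VitalRateSet, mode: str = "pooled") -> float:
    """First-year survival under a measurement pathway.

    - ``direct``: the survival-from-hatching estimate ``s1h``;
    - ``fledging_product``: ``FS * s1f``;
    - ``pooled``: the unweighted mean of the two pathway values (both must
      be available).
    """
    if mode == "direct":
        if rates.s1h is None:
            raise ConstructionError("mode 'direct' requires s1h")
        return rates.s1h
    if mode == "fledging_product":
        if rates.s1f is None or rates.FS is None:
            raise ConstructionError("mode 'fledging_product' requires s1f and FS")
        return rates.FS * rates.s1f
    if mode == "pooled":
        if rates.s1h is None:
            return effective_first_year_survival(rates, "fledging_product")
        if rates.s1f is None or rates.FS is None:
            return rates.s1h
        return 0.5 * (rates.s1h + rates.FS * rates.s1f)
    raise ConstructionError(f"unknown first-year-survival mode {mode!r}")


def fertility(rates: VitalRateSet, mode: str = "pooled") -> float:
    """Expected daughters per breeder reaching the next census.

    ``F = 0.5 * CS * HS * s1``, with ``s1`` the first-year survival under
    the chosen pathway and the factor 0.5 for the even hatching sex ratio.
    """
    return 0.5 * rates.CS * rates.HS * effective_first_year_survival(rates, mode)


@dataclass(frozen=True)
class ProjectionMatrix:
    """A labelled 6x6 prebreeding projection matrix.

    ``entries[i, j]`` is the contribution of stage ``STAGES[j]`` in year t
    to stage ``STAGES[i]`` in year t+1.  Structural zeros mark impossible
    transitions; each column's non-fertility entries sum to that column's
    survival rate.
    """

    entries: np.ndarray
    stage_order: tuple[str, ...] = STAGES

    def __post_init__(self) -> None:
        a = np.asarray(self.entries, dtype=float)
        if a.shape != (len(self.stage_order),) * 2:
            raise ConstructionError(
                f"matrix shape {a.shape} does not match stages {self.stage_order}"
            )
        if not np.all(np.isfinite(a)) or np.any(a < 0):
            raise ConstructionError("matrix entries must be finite and nonnegative")
        object.__setattr__(self, "entries", a)

    def __getitem__(self, key: tuple[str, str]) -> float:
        """Entry by ``(to_stage, from_stage)`` labels."""
        to_stage, from_stage = key
        return float(
            self.entries[self.stage_order.index(to_stage), self.stage_order.index(from_stage)]
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries, index=list(self.stage_order), columns=list(self.stage_order)
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_dataframe().to_csv(path)

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps(
            {"stages": list(self.stage_order), "entries": self.entries.tolist()},
            indent=2,
        )
        if path is not None:
            Path(path).write_text(payload)
        return payload

    def edge_list(self) -> Iterator[tuple[str, str, float]]:
        """Yield (from_stage, to_stage, value) for every nonzero transition."""
        for i, to_stage in enumerate(self.stage_order):
            for j, from_stage in enumerate(self.stage_order):
                if self.entries[i, j] != 0:
                    yield (from_stage, to_stage, float(self.entries[i, j]))


def build_matrix(rates: VitalRateSet, mode: str = "pooled") -> ProjectionMatrix:
    """Assemble the 6-stage matrix from a vital-rate set.

    Recruitment propensities ``BP_x`` are conditional on not having
    recruited yet, so they enter the matrix elements directly: a surviving
    prebreeder of age x recruits with probability ``BP_{x+1}`` next spring
    and defers otherwise.  Breeders and nonbreeders swap states with the
    complementary propensities ``BPeb`` and ``1 - BPeb`` under shared adult
    survival.
    """
    F = fertility(rates, mode)
    A = np.zeros((6, 6))
    s = {name: i for i, name in enumerate(STAGES)}

    A[s["PB2"], s["1yo"]] = rates.s2 * (1 - rates.BP2)
    A[s["B"], s["1yo"]] = rates.s2 * rates.BP2
    A[s["PB3"], s["PB2"]] = rates.sa * (1 - rates.BP3)
    A[s["B"], s["PB2"]] = rates.sa * rates.BP3
    A[s["PB4"], s["PB3"]] = rates.sa * (1 - rates.BP4)
    A[s["B"], s["PB3"]] = rates.sa * rates.BP4
    A[s["B"], s["PB4"]] = rates.sa * rates.BP5
    A[s["B"], s["B"]] = A[s["B"], s["NB"]] = rates.sa * rates.BPeb
    A[s["NB"], s["B"]] = A[s["NB"], s["NB"]] = rates.sa * (1 - rates.BPeb)
    A[s["1yo"], s["B"]] = F

    non_fertility = A.copy()
    non_fertility[s["1yo"], s["B"]] = 0.0
    if np.any(non_fertility > 1.0):
        raise ConstructionError("a survival-borne transition exceeds 1")
    return ProjectionMatrix(A)
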