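"""Vital-rate evidence database: record model, CSV I/O and screening.

The evidence table holds one row per published vital-rate estimate, with
provenance flags used for screening (verification status, range-midpoint
precision, independence grouping, sex of the sampled birds).  Twelve
vital-rate codes are recognised:

================  ====================================================
code              meaning
================  ====================================================
``s1h``           first-year survival from hatching
``s1f``           first-year survival from fledging
``s2``            second-year survival
``sa``            adult annual survival
``FB2``–``FB5``   recruitment propensity at ages 2–5 (first breeding)
``BPeb``          breeding propensity of established breeders
``CS``            clutch size (eggs per nest)
``HS``            hatching success
``FS``            fledging success
================  ====================================================

All rates are probabilities in [0, 1] except clutch size, which is a
nonnegative count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "VITAL_RATES",
    "SURVIVAL_RATES",
    "EstimateRecord",
    "StudyEffortTable",
    "ScreeningPolicy",
    "ScreenResult",
    "SchemaError",
    "ValidationError",
    "UnresolvedIndependenceError",
    "read_database",
    "write_database",
    "screen",
    "resolve_independence",
    "count_study_effort",
]

#: Recognised vital-rate codes.
VITAL_RATES: tuple[str, ...] = (
    "s1h", "s1f", "s2", "sa",
    "FB2", "FB3", "FB4", "FB5",
    "BPeb", "CS", "HS", "FS",
)

#: Rates that are survival probabilities; the female-only screen applies here,
#: because survival of males and of mixed-sex samples does not inform a
#: female-based projection model.
SURVIVAL_RATES: frozenset[str] = frozenset({"s1h", "s1f", "s2", "sa"})

_SEXES = ("female", "male", "aggregated")

_MANDATORY_COLUMNS = ("study_id", "vital_rate", "value")
_OPTIONAL_COLUMNS = (
    "se", "variance", "n", "sex", "verified", "midpoint",
    "independence_group", "replicate_site", "replicate_year",
    "subspecies", "provenance",
)


class SchemaError(ValueError):
    """The input table is missing a mandatory column."""


class ValidationError(ValueError):
    """One or more rows violate the record contract; row indices attached."""

    def __init__(self, message: str, row_errors: list[tuple[int, str]] | None = None):
        super().__init__(message)
        self.row_errors = row_errors or []


class UnresolvedIndependenceError(ValueError):
    """An independence group has several candidate records and no rule."""

    def __init__(self, groups: Sequence[str]):
        super().__init__(
            "no applicable selection rule for independence group(s): "
            + ", ".join(sorted(groups))
        )
        self.groups = tuple(groups)


def _rate_domain_ok(vital_rate: str, value: float) -> bool:
    if vital_rate == "CS":
        return value >= 0
    return 0.0 <= value <= 1.0


@dataclass
class EstimateRecord:
    """One published vital-rate estimate with provenance and screening flags.

    ``se`` and ``variance`` are alternative precision statements; at most one
    is stored and, when ``se`` is given, the variance is derived as ``se**2``.
    Records with neither still take part in precision-weighted synthesis
    through the mean-adjusted weighting scheme (see :mod:`demosynth.meta`).
    """

    study_id: str
    vital_rate: str
    value: float
    se: float | None = None
    variance: float | None = None
    n: int | None = None
    sex: str = "female"
    verified: bool = True
    midpoint: bool = False
    independence_group: str | None = None
    replicate_site: str | None = None
    replicate_year: str | None = None
    subspecies: str | None = None
    provenance: str | None = None

    def __post_init__(self) -> None:
        if self.vital_rate not in VITAL_RATES:
            raise ValidationError(
                f"unknown vital rate {self.vital_rate!r}; expected one of {VITAL_RATES}"
            )
        if not _rate_domain_ok(self.vital_rate, self.value):
            domain = "[0, inf)" if self.vital_rate == "CS" else "[0, 1]"
            raise ValidationError(
                f"value {self.value} outside legal domain {domain} for rate "
                f"{self.vital_rate!r}"
            )
        if self.sex not in _SEXES:
            raise ValidationError(f"sex must be one of {_SEXES}, got {self.sex!r}")
        if self.se is not None and self.variance is not None:
            if not math.isclose(self.variance, self.se**2, rel_tol=1e-6):
                warnings.warn(
                    f"record {self.study_id}/{self.vital_rate}: se and variance "
                    "inconsistent; keeping se and deriving variance as se**2",
                    stacklevel=2,
                )
            self.variance = None
        if self.n is not None:
            if self.n != int(self.n) or self.n <= 0:
                raise ValidationError(f"n must be a positive integer, got {self.n}")
            self.n = int(self.n)

    @property
    def sampling_variance(self) -> float | None:
        """Study-level variance: ``se**2`` when an SE was reported."""
        if self.se is not None:
            return self.se**2
        return self.variance


@dataclass(frozen=True)
class StudyEffortTable:
    """Unique-study counts per transition group plus the overall total.

    Studies may estimate rates in several groups, so group counts need not
    sum to the total.
    """

    group_counts: Mapping[str, int]
    total_studies: int

    def __post_init__(self) -> None:
        for group, count in self.group_counts.items():
            if count > self.total_studies:
                raise ValidationError(
                    f"group {group!r} count {count} exceeds total {self.total_studies}"
                )


# ---------------------------------------------------------------------------
# CSV I/O


def _parse_bool(x, default: bool) -> bool:
    if x is None or (isinstance(x, float) and math.isnan(x)) or x == "":
        return default
    if isinstance(x, bool):
        return x
    s = str(x).strip().lower()
    if s in ("true", "t", "yes", "y", "1", "1.0"):
        return True
    if s in ("false", "f", "no", "n", "0", "0.0"):
        return False
    raise ValueError(f"cannot interpret {x!r} as a flag")


def _opt_float(x) -> float | None:
    if x is None or x == "" or (isinstance(x, float) and math.isnan(x)):
        return None
    return float(x)


def _opt_str(x) -> str | None:
    if x is None or x == "" or (isinstance(x, float) and math.isnan(x)):
        return None
    return str(x)


def read_database(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[EstimateRecord]:
    """Read an evidence table from CSV.

    Parameters
    ----------
    path
        CSV file with a header row.  Mandatory columns: ``study_id``,
        ``vital_rate``, ``value``.  Optional columns (missing values left
        empty, never imputed): ``se``, ``variance``, ``n``, ``sex``,
        ``verified``, ``midpoint``, ``independence_group``,
        ``replicate_site``, ``replicate_year``, ``subspecies``.
    column_map
        Mapping from the file's header names to the canonical names above,
        to adapt externally formatted deposits.

    Raises
    ------
    SchemaError
        If a mandatory column is absent.
    ValidationError
        If any row fails parsing or domain validation; ``row_errors`` lists
        (0-based row index, message) pairs.
    """
    df = pd.read_csv(path, comment="#")
    if column_map:
        df = df.rename(columns=dict(column_map))
    for col in _MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"mandatory column {col!r} missing from {path}")

    records: list[EstimateRecord] = []
    row_errors: list[tuple[int, str]] = []
    for idx, row in df.iterrows():
        try:
            n_raw = _opt_float(row.get("n"))
            records.append(
                EstimateRecord(
                    study_id=str(row["study_id"]),
                    vital_rate=str(row["vital_rate"]).strip(),
                    value=float(row["value"]),
                    se=_opt_float(row.get("se")),
                    variance=_opt_float(row.get("variance")),
                    n=None if n_raw is None else int(n_raw),
                    sex=_opt_str(row.get("sex")) or "female",
                    verified=_parse_bool(row.get("verified"), True),
                    midpoint=_parse_bool(row.get("midpoint"), False),
                    independence_group=_opt_str(row.get("independence_group")),
                    replicate_site=_opt_str(row.get("replicate_site")),
                    replicate_year=_opt_str(row.get("replicate_year")),
                    subspecies=_opt_str(row.get("subspecies")),
                    provenance=_opt_str(row.get("provenance")),
                )
            )
        except (ValueError, TypeError) as exc:
            row_errors.append((int(idx), str(exc)))
    if row_errors:
        raise ValidationError(
            f"{len(row_errors)} row(s) failed validation in {path}: "
            + "; ".join(f"row {i}: {m}" for i, m in row_errors[:5]),
            row_errors,
        )
    return records


def write_database(records: Iterable[EstimateRecord], path: str | Path) -> None:
    """Write records back out with the canonical schema plus provenance."""
    rows = []
    for r in records:
        rows.append(
            {
                "study_id": r.study_id,
                "vital_rate": r.vital_rate,
                "value": r.value,
                "se": r.se,
                "variance": r.variance,
                "n": r.n,
                "sex": r.sex,
                "verified": r.verified,
                "midpoint": r.midpoint,
                "independence_group": r.independence_group,
                "replicate_site": r.replicate_site,
                "replicate_year": r.replicate_year,
                "subspecies": r.subspecies,
                "provenance": r.provenance,
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Screening


@dataclass(frozen=True)
class ScreeningPolicy:
    """Which provenance classes survive screening.

    The default retains unverified and range-midpoint estimates (their
    inclusion is checked separately by sensitivity analysis) and keeps only
    female-based survival estimates; non-survival rates are nest-based and
    inherently female, so the sex filter does not apply to them.
    """

    drop_unverified: bool = False
    drop_midpoint: bool = False
    survival_sexes: tuple[str, ...] = ("female",)


@dataclass(frozen=True)
class ScreenResult:
    kept: tuple[EstimateRecord, ...]
    dropped: tuple[EstimateRecord, ...]

    @property
    def n_dropped(self) -> int:
        return len(self.dropped)

    def __iter__(self):
        return iter(self.kept)

    def __len__(self) -> int:
        return len(self.kept)


def screen(
    records: Iterable[EstimateRecord],
    policy: ScreeningPolicy = ScreeningPolicy(),
) -> ScreenResult:
    """Apply a screening policy; returns retained and dropped records."""
    kept, dropped = [], []
    for r in records:
        ok = True
        if policy.drop_unverified and not r.verified:
            ok = False
        if policy.drop_midpoint and r.midpoint:
            ok = False
        if r.vital_rate in SURVIVAL_RATES and r.sex not in policy.survival_sexes:
            ok = False
        (kept if ok else dropped).append(r)
    return ScreenResult(tuple(kept), tuple(dropped))


# ---------------------------------------------------------------------------
# Independence resolution

#: rule value forms understood by :func:`resolve_independence`
_RuleValue = str | Mapping[str, str] | Callable


def _most_precise(group: Sequence[EstimateRecord]) -> EstimateRecord:
    with_var = [r for r in group if r.sampling_variance is not None]
    if not with_var:
        raise UnresolvedIndependenceError(
            [group[0].independence_group or group[0].study_id]
        )
    return min(with_var, key=lambda r: r.sampling_variance)


def _largest_n(group: Sequence[EstimateRecord]) -> EstimateRecord:
    with_n = [r for r in group if r.n is not None]
    if not with_n:
        raise UnresolvedIndependenceError(
            [group[0].independence_group or group[0].study_id]
        )
    return max(with_n, key=lambda r: r.n)


def resolve_independence(
    records: Iterable[EstimateRecord],
    rules: Mapping[str, _RuleValue] | None = None,
) -> list[EstimateRecord]:
    """Collapse each independence group to a single estimate.

    Records sharing an ``independence_group`` label draw on the same
    underlying data and must not enter a synthesis as separate replicates.
    Groups whose members are spatiotemporal replicates of one study are
    collapsed by sub-meta-analysis; other groups need an entry in ``rules``
    mapping the group label to one of:

    - ``"most_precise"`` — keep the record with the smallest variance;
    - ``"largest_n"`` — keep the record with the largest sample size;
    - ``"sub_meta"`` — force a sub-meta-analysis collapse;
    - ``{"keep": study_id}`` — keep the named study's record;
    - a callable ``group -> record``.

    All input records must belong to a single vital rate.

    Raises
    ------
    UnresolvedIndependenceError
        If a multi-record group has no applicable rule.
    """
    from . import meta  # local import to avoid a cycle

    records = list(records)
    if not records:
        return []
    rates = {r.vital_rate for r in records}
    if len(rates) > 1:
        raise ValidationError(
            f"resolve_independence expects a single vital rate, got {sorted(rates)}"
        )
    rules = dict(rules or {})

    groups: dict[str, list[EstimateRecord]] = {}
    order: list[str] = []
    for i, r in enumerate(records):
        key = r.independence_group if r.independence_group is not None else f"__solo_{i}"
        if key not in groups:
            groups[key] = []
            order.append(key)
        groups[key].append(r)

    out: list[EstimateRecord] = []
    unresolved: list[str] = []
    for key in order:
        group = groups[key]
        if len(group) == 1:
            out.append(group[0])
            continue
        rule = rules.get(key)
        same_study = len({r.study_id for r in group}) == 1
        is_replicated = any(
            r.replicate_site is not None or r.replicate_year is not None for r in group
        )
        if rule is None and same_study and is_replicated:
            rule = "sub_meta"
        if rule is None:
            unresolved.append(key)
            continue
        if callable(rule):
            chosen = rule(group)
            out.append(replace(chosen, provenance="rule:callable"))
        elif rule == "sub_meta":
            out.append(meta.sub_meta_analysis(group))
        elif rule == "most_precise":
            out.append(replace(_most_precise(group), provenance="rule:most_precise"))
        elif rule == "largest_n":
            out.append(replace(_largest_n(group), provenance="rule:largest_n"))
        elif isinstance(rule, Mapping) and "keep" in rule:
            matches = [r for r in group if r.study_id == rule["keep"]]
            if not matches:
                unresolved.append(key)
                continue
            out.append(replace(matches[0], provenance=f"rule:keep:{rule['keep']}"))
        else:
            raise ValueError(f"unknown independence rule {rule!r} for group {key!r}")
    if unresolved:
        raise UnresolvedIndependenceError(unresolved)
    return out


# ---------------------------------------------------------------------------
# Study effort


def count_study_effort(
    records: Iterable[EstimateRecord],
    grouping: Mapping[str, str | Sequence[str]],
) -> StudyEffortTable:
    """Count unique contributing studies per transition group.

    ``grouping`` maps each vital-rate code to one or more transition-group
    labels (a rate like adult survival underlies several transition types).
    A study contributes to a group if it supplies at least one estimate of
    any rate mapped there; a study estimating rates in several groups counts
    toward each.  ``total_studies`` counts unique studies across all rates.
    """
    records = list(records)
    norm: dict[str, tuple[str, ...]] = {
        rate: (g,) if isinstance(g, str) else tuple(g) for rate, g in grouping.items()
    }
    present = {r.vital_rate for r in records}
    unmapped = present - set(norm)
    if unmapped:
        raise ValidationError(
            f"vital rate(s) {sorted(unmapped)} not mapped to a transition group"
        )
    labels = list(dict.fromkeys(g for gs in norm.values() for g in gs))
    group_studies: dict[str, set[str]] = {g: set() for g in labels}
    all_studies: set[str] = set()
    for r in records:
        for g in norm[r.vital_rate]:
            group_studies[g].add(r.study_id)
        all_studies.add(r.study_id)
    return StudyEffortTable(
        group_counts={g: len(s) for g, s in group_studies.items()},
        total_studies=len(all_studies),
    )
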