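"""Simple-mean and mean-adjusted precision-weighted random-effects synthesis.

The weighted synthesis is a one-sample random-effects model with a
mean-adjusted error variance.  Writing ``delta_i`` for the study-level mean,
``s_i^2`` for the study-level variance (a squared standard error where one
was reported) and ``n_i`` for the sample size, the scheme pools the
available study variances into their arithmetic mean ``s2`` and assigns
every study the error variance

    v_i = s2 / n_i.

Using the pooled ``s2`` rather than each study's own variance removes the
bias that poorly replicated studies would otherwise introduce, and lets a
study that reports replication but no variance still be precision-weighted.
Between-study variance is estimated by a Cochran-type moment estimator,

    T2 = max(0, var(delta_i) - mean(v_i)),

with ``var`` the (k-1)-divisor sample variance, and the random-effects
weights, synthesis mean and meta-variance are

    W_i = 1 / (v_i + T2),
    mean = sum(W_i * delta_i) / sum(W_i),
    meta-variance = 1 / sum(W_i).

Vital rates with few independent estimates and widespread missing sample
sizes are synthesised with a plain arithmetic mean instead
(:func:`choose_method`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Iterable, Sequence

import numpy as np

from .records import EstimateRecord

__all__ = [
    "MetaResult",
    "SensitivityResult",
    "NoDataError",
    "choose_method",
    "simple_mean",
    "random_effects_meta",
    "sub_meta_analysis",
    "sensitivity_compare",
    "synthesize",
]


class NoDataError(ValueError):
    """No estimates were supplied for a synthesis."""


@dataclass(frozen=True)
class MetaResult:
    """A synthesised vital-rate mean with its uncertainty and bookkeeping.

    ``variance`` is the meta-variance ``1/sum(W_i)`` for weighted syntheses
    and the sample variance of the estimates for simple means.  ``weights``
    and ``T2`` are populated only on the weighted path.
    """

    mean: float
    variance: float
    method: str  # "simple" | "meta" | "sub_meta"
    k: int
    T2: float | None = None
    weights: tuple[float, ...] | None = None
    s2_pooled: float | None = None

    def __post_init__(self) -> None:
        if self.method not in ("simple", "meta", "sub_meta"):
            raise ValueError(f"unknown method tag {self.method!r}")
        if self.T2 is not None and self.T2 < 0:
            raise ValueError("between-study variance must be nonnegative")

    def ci(self, z: float = 1.96) -> tuple[float, float]:
        """Normal-theory interval ``mean +/- z * sqrt(variance)``."""
        half = z * math.sqrt(self.variance)
        return (self.mean - half, self.mean + half)


def choose_method(
    records: Sequence[EstimateRecord],
    min_estimates: int = 20,
    max_missing_n_fraction: float = 1 / 3,
) -> str:
    """Decide between the weighted synthesis and a simple mean.

    A vital rate falls back to a simple mean only when both sparsity
    conditions hold: fewer than ``min_estimates`` independent estimates AND
    more than ``max_missing_n_fraction`` of them lacking a sample size.
    Either condition alone leaves enough information for the weighted
    scheme.
    """
    records = list(records)
    if not records:
        raise NoDataError("cannot choose a synthesis method with no estimates")
    k = len(records)
    missing_n = sum(1 for r in records if r.n is None) / k
    if k < min_estimates and missing_n > max_missing_n_fraction:
        return "simple"
    return "meta"


def simple_mean(values: Iterable[float]) -> MetaResult:
    """Arithmetic mean with the (k-1)-divisor sample variance (0 when k=1)."""
    vals = np.asarray(list(values), dtype=float)
    if vals.size == 0:
        raise NoDataError("simple_mean needs at least one value")
    var = float(vals.var(ddof=1)) if vals.size > 1 else 0.0
    return MetaResult(mean=float(vals.mean()), variance=var, method="simple", k=vals.size)


def random_effects_meta(
    deltas: Sequence[float],
    variances: Sequence[float | None],
    ns: Sequence[int],
    method_tag: str = "meta",
) -> MetaResult:
    """Mean-adjusted precision-weighted random-effects synthesis.

    Parameters
    ----------
    deltas
        Study-level means ``delta_i``.
    variances
        Study-level variances ``s_i^2`` (``None`` where a study reported no
        variance); at least one must be present to define the pooled ``s2``.
    ns
        Study sample sizes; required for every study because the error
        variance is ``s2 / n_i``.  Callers must exclude studies without
        sample sizes before synthesis.
    """
    deltas = np.asarray(deltas, dtype=float)
    k = deltas.size
    if k < 2:
        raise NoDataError("weighted synthesis needs at least two studies")
    if len(variances) != k or len(ns) != k:
        raise ValueError("deltas, variances and ns must have equal length")
    if any(n is None for n in ns):
        raise ValueError(
            "every study in a weighted synthesis needs a sample size; "
            "exclude estimates without one before calling"
        )
    ns_arr = np.asarray(ns, dtype=float)
    if np.any(ns_arr <= 0):
        raise ValueError("sample sizes must be positive")
    avail = [v for v in variances if v is not None]
    if not avail:
        raise ValueError("all study variances missing; pooled variance undefined")

    s2 = float(np.mean(avail))
    v = s2 / ns_arr
    T2 = max(0.0, float(deltas.var(ddof=1)) - float(v.mean()))
    W = 1.0 / (v + T2)
    mean = float(np.sum(W * deltas) / np.sum(W))
    variance = float(1.0 / np.sum(W))
    return MetaResult(
        mean=mean,
        variance=variance,
        method=method_tag,
        k=k,
        T2=T2,
        weights=tuple(float(w) for w in W),
        s2_pooled=s2,
    )


def sub_meta_analysis(replicates: Sequence[EstimateRecord]) -> EstimateRecord:
    """Collapse spatiotemporal replicates within one study to one estimate.

    Follows the same protocol as the cross-study synthesis: the weighted
    scheme when every replicate has a sample size and at least one has a
    variance, otherwise a simple mean.  The output record's ``n`` is the sum
    of replicate sample sizes where all are known.  A single replicate
    passes through unchanged.
    """
    replicates = list(replicates)
    if not replicates:
        raise NoDataError("sub_meta_analysis needs at least one replicate")
    if len({r.study_id for r in replicates}) != 1:
        raise ValueError("sub_meta_analysis collapses replicates of a single study")
    if len(replicates) == 1:
        return replicates[0]

    template = replicates[0]
    all_n = all(r.n is not None for r in replicates)
    any_var = any(r.sampling_variance is not None for r in replicates)
    if all_n and any_var:
        result = random_effects_meta(
            [r.value for r in replicates],
            [r.sampling_variance for r in replicates],
            [r.n for r in replicates],
            method_tag="sub_meta",
        )
    else:
        result = simple_mean([r.value for r in replicates])
    total_n = sum(r.n for r in replicates) if all_n else None
    return replace(
        template,
        value=result.mean,
        se=None,
        variance=result.variance,
        n=total_n,
        replicate_site=None,
        replicate_year=None,
        provenance="sub_meta",
    )


@dataclass(frozen=True)
class SensitivityResult:
    """Synthesis with and without a flagged subset, and an overlap verdict.

    ``overlapping`` is True when each mean lies inside the other's
    ``mean +/- 1.96*sqrt(variance)`` interval, i.e. excluding the flagged
    estimates does not meaningfully move the synthesis.
    """

    with_flagged: MetaResult
    without_flagged: MetaResult
    overlapping: bool
    flag: str
    n_flagged: int


def _in_interval(x: float, result: MetaResult, z: float = 1.96) -> bool:
    lo, hi = result.ci(z)
    return lo <= x <= hi


def sensitivity_compare(
    records: Sequence[EstimateRecord],
    flag: str,
    synthesizer=None,
) -> SensitivityResult:
    """Compare the synthesis with and without a flagged record subset.

    ``flag`` is ``"unverified"`` (excludes records with ``verified=False``)
    or ``"midpoint"`` (excludes records with ``midpoint=True``).
    """
    if flag == "unverified":
        flagged = [r for r in records if not r.verified]
        clean = [r for r in records if r.verified]
    elif flag == "midpoint":
        flagged = [r for r in records if r.midpoint]
        clean = [r for r in records if not r.midpoint]
    else:
        raise ValueError(f"flag must be 'unverified' or 'midpoint', got {flag!r}")

    synthesizer = synthesizer or synthesize
    full = synthesizer(records)
    if not flagged or not clean:
        import warnings

        warnings.warn(
            f"nothing to exclude for flag {flag!r}; comparison is degenerate",
            stacklevel=2,
        )
        return SensitivityResult(full, full, True, flag, len(flagged))
    reduced = synthesizer(clean)
    overlapping = _in_interval(full.mean, reduced) and _in_interval(reduced.mean, full)
    return SensitivityResult(full, reduced, overlapping, flag, len(flagged))


def synthesize(
    records: Sequence[EstimateRecord],
    min_estimates: int = 20,
    max_missing_n_fraction: float = 1 / 3,
) -> MetaResult:
    """Method-selected synthesis of independent estimates for one rate.

    Applies :func:`choose_method`; on the weighted path, estimates without a
    sample size are excluded first (they cannot receive an error variance).
    If fewer than two usable estimates remain, or no variance is available
    to pool, falls back to the simple mean of all estimates.
    """
    records = list(records)
    method = choose_method(records, min_estimates, max_missing_n_fraction)
    if method == "simple":
        return simple_mean([r.value for r in records])
    usable = [r for r in records if r.n is not None]
    if len(usable) < 2 or all(r.sampling_variance is None for r in usable):
        return simple_mean([r.value for r in records])
    return random_effects_meta(
        [r.value for r in usable],
        [r.sampling_variance for r in usable],
        [r.n for r in usable],
    )
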