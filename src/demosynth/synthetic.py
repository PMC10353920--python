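"""Synthetic vital-rate evidence databases with known ground truth.

The generator emulates the structure of a literature-derived evidence
table — study identifiers, per-study point estimates, optionally reported
variances and sample sizes, verification/midpoint flags, and multi-year
replicate series — under the same random-effects model the synthesis
assumes: study i observes

    delta_i ~ Normal(theta, T2_true + sigma2 / n_i),

truncated to the rate's legal domain, where theta is the true cross-study
mean, T2_true the between-study variance and sigma2 the within-study
(observation-level) variance.  The reported study variance is a
chi-square-distributed estimate of sigma2 with n_i - 1 degrees of freedom,
as a sample variance would be.

Each study draws from its own deterministic substream (seeded by the
configuration seed and the study index), so enlarging a database never
perturbs previously generated studies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .lifecycle import VitalRateSet
from .records import VITAL_RATES, EstimateRecord

__all__ = [
    "RateConfig",
    "SyntheticConfig",
    "generate_rate_estimates",
    "generate_database",
    "generate_vital_rate_set",
]


@dataclass(frozen=True)
class RateConfig:
    """Generating parameters for one vital rate.

    ``true_mean`` is theta; ``between_study_sd`` is sqrt(T2_true);
    ``within_study_variance`` is sigma2 (the observation-level variance, so
    a study of size n has error variance sigma2/n).  ``missing_*_fraction``
    set the probabilities that a record omits its variance or sample size;
    ``replicate_fraction`` the probability a study reports a multi-year
    series instead of one estimate.
    """

    true_mean: float
    between_study_sd: float = 0.0
    within_study_variance: float = 0.0
    n_studies: int = 10
    n_range: tuple[int, int] = (20, 200)
    missing_n_fraction: float = 0.0
    missing_variance_fraction: float = 0.0
    replicate_fraction: float = 0.0
    replicate_years: int = 3
    unverified_fraction: float = 0.0
    midpoint_fraction: float = 0.0

    def __post_init__(self) -> None:
        for name in (
            "missing_n_fraction",
            "missing_variance_fraction",
            "replicate_fraction",
            "unverified_fraction",
            "midpoint_fraction",
        ):
            x = getattr(self, name)
            if not 0.0 <= x <= 1.0:
                raise ValueError(f"{name}={x} outside [0, 1]")
        if self.n_studies < 1:
            raise ValueError("n_studies must be >= 1")
        if self.between_study_sd < 0 or self.within_study_variance < 0:
            raise ValueError("spread parameters must be nonnegative")
        if not (1 <= self.n_range[0] <= self.n_range[1]):
            raise ValueError(f"invalid n_range {self.n_range}")


@dataclass(frozen=True)
class SyntheticConfig:
    """Per-rate generating parameters plus the master seed."""

    rates: Mapping[str, RateConfig]
    seed: int = 0

    def __post_init__(self) -> None:
        for code, rc in self.rates.items():
            if code not in VITAL_RATES:
                raise ValueError(f"unknown vital rate code {code!r}")
            lo, hi = (0.0, np.inf) if code == "CS" else (0.0, 1.0)
            if not lo <= rc.true_mean <= hi:
                raise ValueError(
                    f"true mean {rc.true_mean} outside domain for rate {code!r}"
                )


def _domain(code: str) -> tuple[float, float]:
    return (0.0, np.inf) if code == "CS" else (0.0, 1.0)


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, lo: float, hi: float,
    max_tries: int = 1000,
) -> float:
    if sd == 0.0:
        return float(np.clip(mean, lo, hi))
    for _ in range(max_tries):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    warnings.warn(
        f"truncated-normal rejection failed after {max_tries} tries "
        f"(mean={mean}, sd={sd}); clamping to the domain",
        stacklevel=2,
    )
    return float(np.clip(mean, lo, hi))


def generate_rate_estimates(
    code: str, rc: RateConfig, seed: int
) -> list[EstimateRecord]:
    """Generate the evidence records for one vital rate."""
    lo, hi = _domain(code)
    rate_index = VITAL_RATES.index(code)  # stable across runs, unlike hash()
    records: list[EstimateRecord] = []
    for i in range(rc.n_studies):
        rng = np.random.default_rng((seed, rate_index, i))
        n_i = int(rng.integers(rc.n_range[0], rc.n_range[1] + 1))
        sd = float(np.sqrt(rc.between_study_sd**2 + rc.within_study_variance / n_i))
        study_id = f"study_{code}_{i:03d}"
        unverified = rng.uniform() < rc.unverified_fraction
        midpoint = rng.uniform() < rc.midpoint_fraction
        miss_n = rng.uniform() < rc.missing_n_fraction
        miss_var = rng.uniform() < rc.missing_variance_fraction
        replicated = rng.uniform() < rc.replicate_fraction

        def _variance(local_rng: np.random.Generator, n: int) -> float | None:
            if miss_var or rc.within_study_variance == 0.0:
                return None
            if n <= 1:
                return rc.within_study_variance
            # sample-variance noise around sigma2 with n-1 df
            return float(
                rc.within_study_variance * local_rng.chisquare(n - 1) / (n - 1)
            )

        if replicated:
            for year in range(rc.replicate_years):
                delta = _truncated_normal(rng, rc.true_mean, sd, lo, hi)
                records.append(
                    EstimateRecord(
                        study_id=study_id,
                        vital_rate=code,
                        value=delta,
                        variance=_variance(rng, n_i),
                        n=None if miss_n else n_i,
                        verified=not unverified,
                        midpoint=midpoint,
                        independence_group=study_id,
                        replicate_year=str(2000 + year),
                    )
                )
        else:
            delta = _truncated_normal(rng, rc.true_mean, sd, lo, hi)
            records.append(
                EstimateRecord(
                    study_id=study_id,
                    vital_rate=code,
                    value=delta,
                    variance=_variance(rng, n_i),
                    n=None if miss_n else n_i,
                    verified=not unverified,
                    midpoint=midpoint,
                )
            )
    return records


def generate_database(config: SyntheticConfig) -> list[EstimateRecord]:
    """Generate a full multi-rate evidence database.

    Deterministic for a fixed configuration: each (rate, study) pair has
    its own counter-based substream, so output is byte-for-byte
    reproducible and insensitive to the order or number of other rates.
    """
    records: list[EstimateRecord] = []
    for code in VITAL_RATES:  # fixed iteration order for determinism
        if code in config.rates:
            records.extend(generate_rate_estimates(code, config.rates[code], config.seed))
    return records


def generate_vital_rate_set(
    seed: int, center: VitalRateSet, jitter: float = 0.1
) -> VitalRateSet:
    """Multiplicatively jitter a vital-rate set for property sweeps.

    Each rate is scaled by ``1 + Uniform(-jitter, jitter)`` and clamped to
    its domain; ``BP5`` stays pinned at 1.
    """
    if jitter < 0:
        raise ValueError("jitter must be nonnegative")
    rng = np.random.default_rng(seed)

    def _jit(x: float | None, hi: float = 1.0) -> float | None:
        if x is None:
            return None
        return float(np.clip(x * (1 + rng.uniform(-jitter, jitter)), 0.0, hi))

    return VitalRateSet(
        s1h=_jit(center.s1h),
        s1f=_jit(center.s1f),
        FS=_jit(center.FS),
        s2=_jit(center.s2),
        sa=_jit(center.sa),
        BP2=_jit(center.BP2),
        BP3=_jit(center.BP3),
        BP4=_jit(center.BP4),
        BP5=1.0,
        BPeb=_jit(center.BPeb),
        CS=_jit(center.CS, hi=np.inf),
        HS=_jit(center.HS),
    )
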