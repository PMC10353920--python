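"""Shared fixtures: published mean rates and literature-scale synthetic databases."""

import pytest

from demosynth import EIDER_MEAN_RATES, EstimateRecord


@pytest.fixture
def eider_rates():
    """Published species-wide mean vital rates for the common eider."""
    return EIDER_MEAN_RATES


def _rec(study, rate, value, **kw):
    return EstimateRecord(study_id=study, vital_rate=rate, value=value, **kw)


@pytest.fixture(scope="session")
def literature_scale_db():
    """Synthetic evidence base engineered to the published study-count margins.

    129 unique studies: adult survival in 35, second-year survival in 7
    (3 overlapping adult survival), recruitment propensities in 7,
    breeding propensity in 7 (4 overlapping adult survival), and the five
    fertility-component rates spread over 103 unique studies (16 of them
    overlapping the survival studies).  The per-group unique-study counts
    are then Recruitment 39, Breeding transitions 38, Reproduction 103.
    """
    records = []
    sa_studies = [f"S{i:03d}" for i in range(1, 36)]
    for s in sa_studies:
        records.append(_rec(s, "sa", 0.85))
    # second-year survival: 3 overlapping + 4 new recruitment-only studies
    for s in sa_studies[:3] + [f"R{i:03d}" for i in range(36, 40)]:
        records.append(_rec(s, "s2", 0.87))
    # age-stratified recruitment: 7 studies already inside the survival set
    for s in sa_studies[3:10]:
        records.append(_rec(s, "FB2", 0.17))
    for s in sa_studies[3:9]:
        records.append(_rec(s, "FB3", 0.58))
    for s in sa_studies[3:5]:
        records.append(_rec(s, "FB4", 0.71))
        records.append(_rec(s, "FB5", 1.0))
    # breeding propensity: 4 overlapping + 3 new studies
    for s in sa_studies[:4] + [f"B{i:03d}" for i in range(40, 43)]:
        records.append(_rec(s, "BPeb", 0.72))
    # reproduction: 103 unique studies, 16 overlapping the survival set
    repro = sa_studies[:16] + [f"P{i:03d}" for i in range(1, 88)]
    for i, s in enumerate(repro):
        records.append(_rec(s, "CS", 4.0))
        if i % 4 == 0:
            records.append(_rec(s, "HS", 0.61))
    return records


@pytest.fixture
def mixed_sex_survival_db():
    """Female database plus 14 male/aggregated survival estimates in 8 studies."""
    records = [_rec(f"F{i:02d}", "sa", 0.86) for i in range(10)]
    records.append(_rec("F00", "CS", 4.1, sex="aggregated"))  # non-survival: kept
    male_studies = [f"M{i:02d}" for i in range(8)]
    k = 0
    for s in male_studies:
        records.append(_rec(s, "sa", 0.9, sex="male"))
        k += 1
    for s in male_studies[:6]:
        records.append(_rec(s, "s2", 0.88, sex="aggregated"))
        k += 1
    assert k == 14
    return records
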