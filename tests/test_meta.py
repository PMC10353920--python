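"""Synthesis estimators: method choice, means, weighting, sub-meta, sensitivity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from demosynth import (
    EstimateRecord,
    choose_method,
    random_effects_meta,
    sensitivity_compare,
    simple_mean,
    sub_meta_analysis,
    synthesize,
)
from demosynth.meta import NoDataError


def _recs(values, ns=None, **kw):
    ns = ns or [None] * len(values)
    return [
        EstimateRecord(study_id=f"s{i}", vital_rate="sa", value=v, n=n, **kw)
        for i, (v, n) in enumerate(zip(values, ns))
    ]


class TestChooseMethod:
    @pytest.mark.parametrize(
        "k,missing_frac,expected",
        [
            (25, 0.1, "meta"),     # enough estimates
            (10, 0.5, "simple"),   # both sparsity conditions hold
            (10, 0.0, "meta"),     # few estimates but sample sizes present
            (25, 0.5, "meta"),     # many estimates despite missing n
        ],
    )
    def test_conjunctive_rule(self, k, missing_frac, expected):
        n_missing = round(k * missing_frac)
        ns = [None] * n_missing + [50] * (k - n_missing)
        assert choose_method(_recs([0.8] * k, ns)) == expected

    def test_empty_raises(self):
        with pytest.raises(NoDataError):
            choose_method([])

    def test_thresholds_configurable(self):
        records = _recs([0.8] * 10, [None] * 5 + [50] * 5)
        assert choose_method(records, min_estimates=5) == "meta"


class TestSimpleMean:
    def test_hand_example(self):
        result = simple_mean([0.2, 0.4, 0.6])
        assert result.mean == pytest.approx(0.4)
        assert result.variance == pytest.approx(0.04)
        assert result.method == "simple" and result.k == 3
        assert result.T2 is None and result.weights is None

    def test_single_estimate(self):
        result = simple_mean([0.75])
        assert result.mean == 0.75 and result.variance == 0.0

    def test_empty_raises(self):
        with pytest.raises(NoDataError):
            simple_mean([])


class TestRandomEffectsMeta:
    def test_two_study_worked_example(self):
        """Hand-derived values for delta={0.8,0.9}, s2={0.01,0.01}, n={10,40}."""
        result = random_effects_meta([0.8, 0.9], [0.01, 0.01], [10, 40])
        assert result.s2_pooled == pytest.approx(0.01)
        assert result.T2 == pytest.approx(0.004375)
        assert result.weights[0] == pytest.approx(1 / 0.005375)
        assert result.weights[1] == pytest.approx(1 / 0.004625)
        assert result.mean == pytest.approx(0.85375, abs=5e-6)
        assert result.variance == pytest.approx(0.0024859, abs=5e-7)
        # meta-variance identity holds exactly
        assert result.variance == pytest.approx(1 / sum(result.weights), rel=1e-14)

    def test_identical_studies_truncate_T2(self):
        result = random_effects_meta([0.5, 0.5], [0.02, 0.02], [5, 5])
        assert result.T2 == 0.0
        assert result.mean == pytest.approx(0.5)
        assert result.variance == pytest.approx(0.002)

    def test_equal_weights_reduce_to_unweighted_mean(self):
        result = random_effects_meta([0.2, 0.4, 0.6], [0.03, 0.03, 0.03], [10, 10, 10])
        assert result.mean == pytest.approx(0.4)
        assert result.T2 == pytest.approx(0.037)

    def test_missing_n_rejected(self):
        with pytest.raises(ValueError, match="sample size"):
            random_effects_meta([0.8, 0.9], [0.01, 0.01], [10, None])

    def test_all_variances_missing_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            random_effects_meta([0.8, 0.9], [None, None], [10, 40])

    def test_single_study_rejected(self):
        with pytest.raises(NoDataError):
            random_effects_meta([0.8], [0.01], [10])

    def test_unreported_variances_still_weighted(self):
        """A study with n but no variance receives the pooled error variance."""
        result = random_effects_meta([0.8, 0.9, 0.7], [0.01, None, None], [10, 40, 20])
        assert len(result.weights) == 3
        assert all(w > 0 for w in result.weights)
        assert result.s2_pooled == pytest.approx(0.01)

    @given(
        deltas=st.lists(st.floats(0.1, 0.9), min_size=2, max_size=8),
        c=st.floats(0.5, 5.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_scale_equivariance(self, deltas, c):
        ns = [20] * len(deltas)
        base = random_effects_meta(deltas, [0.01] * len(deltas), ns)
        scaled = random_effects_meta(
            [c * d for d in deltas], [c * c * 0.01] * len(deltas), ns
        )
        assert scaled.mean == pytest.approx(c * base.mean, rel=1e-9)
        assert scaled.variance == pytest.approx(c * c * base.variance, rel=1e-9)

    @given(
        deltas=st.lists(st.floats(0.1, 0.9), min_size=2, max_size=8),
        s2=st.floats(0.001, 0.1),
    )
    @settings(max_examples=50, deadline=None)
    def test_equal_error_variances_give_unweighted_mean(self, deltas, s2):
        k = len(deltas)
        result = random_effects_meta(deltas, [s2] * k, [25] * k)
        assert result.mean == pytest.approx(float(np.mean(deltas)), rel=1e-9)

    @given(deltas=st.lists(st.floats(0.1, 0.9), min_size=2, max_size=8))
    @settings(max_examples=50, deadline=None)
    def test_meta_variance_never_exceeds_best_study(self, deltas):
        k = len(deltas)
        ns = list(range(10, 10 + 7 * k, 7))[:k]
        result = random_effects_meta(deltas, [0.02] * k, ns)
        best = min(result.s2_pooled / n + result.T2 for n in ns)
        assert result.variance <= best + 1e-12

    def test_mean_within_input_range(self):
        result = random_effects_meta([0.3, 0.6, 0.9], [0.01, 0.02, None], [5, 50, 500])
        assert 0.3 <= result.mean <= 0.9


class TestEstimatorCalibration:
    """Monte-Carlo recovery of the between-study variance and the mean."""

    def test_T2_estimator_recovery(self):
        rng = np.random.default_rng(2024)
        T2_true, sigma2, n_i, k = 0.01, 0.05, 20, 30
        estimates = []
        for _ in range(1000):
            deltas = rng.normal(0.7, np.sqrt(T2_true + sigma2 / n_i), k)
            si2 = sigma2 * rng.chisquare(n_i - 1, k) / (n_i - 1)
            result = random_effects_meta(deltas, list(si2), [n_i] * k)
            estimates.append(result.T2)
        assert np.mean(estimates) == pytest.approx(T2_true, rel=0.10)

    def test_meta_mean_unbiased(self):
        rng = np.random.default_rng(99)
        theta, T2_true, sigma2, n_i, k = 0.7, 0.01, 0.05, 20, 30
        means = []
        for _ in range(1000):
            deltas = rng.normal(theta, np.sqrt(T2_true + sigma2 / n_i), k)
            si2 = sigma2 * rng.chisquare(n_i - 1, k) / (n_i - 1)
            means.append(random_effects_meta(deltas, list(si2), [n_i] * k).mean)
        assert abs(np.mean(means) - theta) < 0.005


class TestSubMeta:
    def test_simple_mean_path_without_sample_sizes(self):
        reps = [
            EstimateRecord(study_id="s", vital_rate="CS", value=v,
                           replicate_year=str(2000 + i))
            for i, v in enumerate([4.0, 4.2, 4.4])
        ]
        out = sub_meta_analysis(reps)
        assert out.value == pytest.approx(4.2)
        assert out.provenance == "sub_meta"
        assert out.n is None

    def test_weighted_path(self):
        reps = [
            EstimateRecord(study_id="s", vital_rate="sa", value=0.6, n=30,
                           variance=0.01, replicate_year=str(2000 + i))
            for i in range(2)
        ]
        out = sub_meta_analysis(reps)
        assert out.value == pytest.approx(0.6)
        assert out.n == 60

    def test_single_replicate_passthrough(self):
        rec = EstimateRecord(study_id="s", vital_rate="sa", value=0.9)
        assert sub_meta_analysis([rec]) is rec

    def test_multiple_studies_rejected(self):
        recs = [
            EstimateRecord(study_id="a", vital_rate="sa", value=0.8),
            EstimateRecord(study_id="b", vital_rate="sa", value=0.9),
        ]
        with pytest.raises(ValueError, match="single study"):
            sub_meta_analysis(recs)


class TestSensitivity:
    def test_identical_estimates_overlap(self):
        records = _recs([0.5] * 6)
        records[0] = EstimateRecord(
            study_id="s0", vital_rate="sa", value=0.5, verified=False
        )
        result = sensitivity_compare(records, "unverified")
        assert result.overlapping
        assert result.with_flagged.mean == result.without_flagged.mean

    def test_flagged_outlier_breaks_overlap(self):
        records = _recs([0.50, 0.501, 0.499, 0.5005, 0.4995])
        records.append(
            EstimateRecord(study_id="out", vital_rate="sa", value=0.99, midpoint=True)
        )
        result = sensitivity_compare(records, "midpoint")
        assert not result.overlapping

    def test_near_identical_subset_overlaps(self):
        values = [0.70, 0.71, 0.69, 0.705, 0.695, 0.7]
        records = _recs(values)
        records[2] = EstimateRecord(
            study_id="s2", vital_rate="sa", value=0.69, verified=False
        )
        result = sensitivity_compare(records, "unverified")
        assert result.overlapping
        shift = abs(result.with_flagged.mean - result.without_flagged.mean)
        assert shift / result.with_flagged.mean < 0.01

    def test_degenerate_comparison_warns(self):
        with pytest.warns(UserWarning, match="degenerate"):
            result = sensitivity_compare(_recs([0.5, 0.6]), "midpoint")
        assert result.with_flagged == result.without_flagged


class TestSynthesize:
    def test_routes_sparse_rate_to_simple_mean(self):
        records = _recs([0.2, 0.25, 0.3])  # no sample sizes at all
        result = synthesize(records)
        assert result.method == "simple"

    def test_routes_rich_rate_to_weighted(self):
        rng = np.random.default_rng(5)
        records = [
            EstimateRecord(study_id=f"s{i}", vital_rate="sa",
                           value=float(rng.uniform(0.7, 0.9)),
                           variance=0.01, n=50)
            for i in range(25)
        ]
        result = synthesize(records)
        assert result.method == "meta"
        assert result.k == 25
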