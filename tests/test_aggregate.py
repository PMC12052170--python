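"""Hjorth-style segment aggregation and multi-domain fusion."""

import numpy as np
import pytest

import eegpathlab as epl
from eegpathlab.aggregate import AggregatedFeatures, aggregate, fuse, fused_length
from eegpathlab.errors import ValidationError
from eegpathlab.spatial import SpatialFeatureVector
from helpers import make_segmented


def _brute_var(x):
    m = sum(x) / len(x)
    return sum((v - m) ** 2 for v in x) / len(x)


def _brute_mobility(x):
    d = [b - a for a, b in zip(x, x[1:])]
    v = _brute_var(x)
    return _brute_var(d) / v if v > 0 else 0.0


class TestActivity:
    def test_constant(self):
        assert epl.hjorth_activity(np.full(10, 2.5)) == 2.5

    def test_ramp(self):
        L = 9
        assert epl.hjorth_activity(np.arange(1, L + 1.0)) == (L + 1) / 2

    def test_matches_mean_oracle(self, rng):
        x = rng.standard_normal(57)
        assert epl.hjorth_activity(x) == pytest.approx(sum(x) / len(x))

    def test_classical_convention_is_variance(self, rng):
        x = rng.standard_normal(40)
        assert epl.hjorth_activity(x, "classical") == pytest.approx(_brute_var(list(x)))


class TestMobility:
    def test_linear_ramp_is_zero(self):
        assert epl.hjorth_mobility(np.arange(20.0)) == 0.0

    def test_constant_is_zero(self):
        assert epl.hjorth_mobility(np.ones(20)) == 0.0

    def test_alternating_series_matches_bruteforce(self):
        x = [(-1.0) ** i for i in range(100)]
        assert epl.hjorth_mobility(np.array(x)) == pytest.approx(_brute_mobility(x))

    def test_random_matches_bruteforce(self, rng):
        x = list(rng.standard_normal(64))
        assert epl.hjorth_mobility(np.array(x)) == pytest.approx(_brute_mobility(x))

    def test_classical_is_square_root(self, rng):
        x = list(rng.standard_normal(64))
        assert epl.hjorth_mobility(np.array(x), "classical") == pytest.approx(
            np.sqrt(_brute_mobility(x))
        )


class TestComplexity:
    def test_linear_ramp_is_zero(self):
        assert epl.hjorth_complexity(np.arange(20.0)) == 0.0

    def test_constant_is_zero(self):
        assert epl.hjorth_complexity(np.zeros(20)) == 0.0

    def test_random_matches_composition_oracle(self, rng):
        x = list(rng.standard_normal(64))
        d = [b - a for a, b in zip(x, x[1:])]
        assert epl.hjorth_complexity(np.array(x)) == pytest.approx(
            _brute_mobility(d) / _brute_mobility(x)
        )

    def test_too_short_rejected(self):
        with pytest.raises(ValidationError):
            epl.hjorth_complexity(np.array([1.0, 2.0]))


class TestAggregate:
    def test_full_size_shapes(self):
        m = epl.build_feature_matrix(make_segmented(21, 100))
        agg = aggregate(m)
        for mat in (agg.activity, agg.mobility, agg.complexity):
            assert mat.shape == (21, 24)

    def test_toy_shapes(self):
        agg = aggregate(epl.build_feature_matrix(make_segmented(2, 4)))
        assert agg.activity.shape == (2, 24)

    def test_matches_scalar_aggregators(self):
        """The vectorized reduction must equal the per-trajectory scalar
        aggregators applied to every (channel, band, stat) series."""
        m = epl.build_feature_matrix(make_segmented(2, 6, seed=9))
        agg = aggregate(m)
        traj = m.F.reshape(2, 6, 24)
        for ch in range(2):
            for j in range(24):
                series = traj[ch, :, j]
                assert agg.activity[ch, j] == pytest.approx(epl.hjorth_activity(series))
                assert agg.mobility[ch, j] == pytest.approx(epl.hjorth_mobility(series))
                assert agg.complexity[ch, j] == pytest.approx(epl.hjorth_complexity(series))

    def test_segment_permutation_preserves_activity_only(self):
        m = epl.build_feature_matrix(make_segmented(2, 8, seed=2))
        perm = np.random.default_rng(0).permutation(8)
        f_perm = m.F.reshape(2, 8, 24)[:, perm].reshape(2, -1)
        m_perm = epl.TimeFreqFeatureMatrix(recording_id="p", F=f_perm, n_segments=8)
        a, b = aggregate(m), aggregate(m_perm)
        np.testing.assert_allclose(b.activity, a.activity, atol=1e-12)
        assert not np.allclose(b.mobility, a.mobility)

    def test_degenerate_input_is_finite(self):
        f = np.ones((3, 5 * 24))
        m = epl.TimeFreqFeatureMatrix(recording_id="c", F=f, n_segments=5)
        agg = aggregate(m)
        for mat in (agg.activity, agg.mobility, agg.complexity):
            assert np.isfinite(mat).all()

    def test_fewer_than_three_segments_rejected(self):
        m = epl.build_feature_matrix(make_segmented(2, 3))
        m2 = epl.TimeFreqFeatureMatrix(recording_id="x", F=m.F[:, :48], n_segments=2)
        with pytest.raises(ValidationError):
            aggregate(m2)


class TestFuse:
    def _agg(self, c):
        z = np.zeros((c, 24))
        return AggregatedFeatures(activity=z, mobility=z, complexity=z, recording_id="r")

    def _spatial(self, n):
        return SpatialFeatureVector(f=np.full(n, -np.log(n)), recording_id="r")

    def test_reference_length_1521(self):
        fv = fuse(self._agg(21), self._spatial(8), age_years=60.0)
        assert len(fv.x) == 3 * 21 * 24 + 8 + 1 == 1521
        assert len(fv.feature_names) == 1521
        assert fv.feature_names[-1] == "age"
        assert fv.x[-1] == 60.0

    def test_toy_length(self):
        assert len(fuse(self._agg(2), self._spatial(2), 30.0).x) == 147

    def test_spatial_ablation_length(self):
        fv = fuse(self._agg(21), None, 60.0)
        assert len(fv.x) == 3 * 21 * 24 + 1

    def test_aggregator_subset(self):
        fv = fuse(self._agg(4), self._spatial(2), 10.0, aggregators=("activity",))
        assert len(fv.x) == 4 * 24 + 2 + 1

    def test_no_aggregation_uses_raw_matrix(self):
        m = epl.TimeFreqFeatureMatrix(recording_id="r", F=np.zeros((3, 5 * 24)), n_segments=5)
        fv = fuse(None, self._spatial(2), 10.0, raw=m)
        assert len(fv.x) == 3 * 5 * 24 + 2 + 1

    def test_missing_age_errors_without_imputation(self):
        with pytest.raises(ValidationError):
            fuse(self._agg(2), None, None)

    def test_missing_age_uses_imputation_when_given(self):
        fv = fuse(self._agg(2), None, None, impute_age=47.5)
        assert fv.x[-1] == 47.5

    @pytest.mark.parametrize("c,n_csp,n_agg", [(21, 8, 3), (2, 2, 3), (5, 4, 1)])
    def test_length_formula(self, c, n_csp, n_agg):
        assert fused_length(c, n_csp, n_agg) == n_agg * c * 24 + n_csp + 1
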