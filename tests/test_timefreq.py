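"""Wavelet sub-band statistics: band edges, decomposition, moments, layout."""

import numpy as np
import pytest
import pywt
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

import eegpathlab as epl
from eegpathlab.errors import DecompositionError, ValidationError
from eegpathlab.timefreq import (
    RETAINED_BANDS,
    TimeFreqFeatureMatrix,
    dwt_decompose,
    stat_features,
)
from helpers import make_segmented


class TestBandRange:
    @pytest.mark.parametrize(
        "band,fs,expected",
        [
            ("D3", 250.0, (15.625, 31.25)),
            ("D4", 250.0, (7.8125, 15.625)),
            ("D5", 250.0, (3.90625, 7.8125)),
            ("A5", 250.0, (0.0, 3.90625)),
            ("D1", 256.0, (64.0, 128.0)),
        ],
    )
    def test_dyadic_edges(self, band, fs, expected):
        assert epl.band_range(band, fs) == pytest.approx(expected)

    def test_high_edge_halves_per_level(self):
        highs = [epl.band_range(f"D{j}", 250.0)[1] for j in range(1, 6)]
        for a, b in zip(highs, highs[1:]):
            assert b == pytest.approx(a / 2)

    def test_a5_abuts_d5(self):
        assert epl.band_range("A5", 250.0)[1] == epl.band_range("D5", 250.0)[0]


class TestDWT:
    def test_constant_input_has_vanishing_details(self):
        x = np.full(1250, 3.7)
        bands = dwt_decompose(x)
        for b in ("D3", "D4", "D5"):
            assert np.abs(bands[b]).max() < 1e-8 * np.abs(x).max()

    def test_perfect_reconstruction(self, rng):
        x = rng.standard_normal(1250)
        coeffs = pywt.wavedec(x, "sym6", mode="symmetric", level=5)
        back = pywt.waverec(coeffs, "sym6", mode="symmetric")[: len(x)]
        assert np.abs(back - x).max() < 1e-10 * np.abs(x).max()

    def test_parseval_under_periodization(self, rng):
        """With periodization padding the level-5 sym6 transform is exactly
        orthogonal, so coefficient energy equals signal energy."""
        x = rng.standard_normal(1280)
        coeffs = pywt.wavedec(x, "sym6", mode="periodization", level=5)
        energy = sum(float(np.sum(c**2)) for c in coeffs)
        assert energy == pytest.approx(float(np.sum(x**2)), rel=1e-9)

    def test_coefficient_lengths_match_closed_form(self, rng):
        """Retained coefficient lengths follow the cascade of the standard
        symmetric-padding length recursion."""
        x = rng.standard_normal(1250)
        bands = dwt_decompose(x)
        flen = pywt.Wavelet("sym6").dec_len
        lengths = {}
        n = 1250
        for level in range(1, 6):
            n = pywt.dwt_coeff_len(n, flen, "symmetric")
            lengths[f"D{level}"] = n
        lengths["A5"] = lengths["D5"]
        for b in RETAINED_BANDS:
            assert len(bands[b]) == lengths[b]

    def test_retains_exactly_four_bands(self, rng):
        bands = dwt_decompose(rng.standard_normal(1250))
        assert set(bands) == set(RETAINED_BANDS)

    def test_too_short_input_errors(self):
        with pytest.raises(DecompositionError):
            dwt_decompose(np.zeros(64), level=5)


class TestStatFeatures:
    def test_constant_vector_degenerate_convention(self):
        np.testing.assert_allclose(stat_features(np.ones(4)), [1, 0, 0, 1, 0, 0])

    def test_symmetric_vector_hand_values(self):
        mu, rho, sigma, mav, skew, kurt = stat_features(np.array([-2.0, -1.0, 1.0, 2.0]))
        assert mu == pytest.approx(0.0)
        assert rho == pytest.approx(1.5)
        assert sigma == pytest.approx(np.sqrt(2.5))
        assert mav == pytest.approx(1.5)
        assert skew == pytest.approx(0.0, abs=1e-12)

    def test_gaussian_kurtosis_is_three(self):
        x = np.random.default_rng(0).standard_normal(200_000)
        assert stat_features(x)[5] == pytest.approx(3.0, abs=0.05)

    @settings(max_examples=50, deadline=None)
    @given(
        arrays(np.float64, st.integers(2, 50),
               elements=st.floats(-1e3, 1e3, allow_nan=False))
    )
    def test_matches_bruteforce_population_moments(self, x):
        mu, rho, sigma, mav, skew, kurt = stat_features(x)
        n = len(x)
        m = sum(x) / n
        var = sum((v - m) ** 2 for v in x) / n
        assert mu == pytest.approx(m, rel=1e-9, abs=1e-9)
        assert rho == pytest.approx(sum(abs(v - m) for v in x) / n, rel=1e-9, abs=1e-9)
        assert sigma == pytest.approx(np.sqrt(var), rel=1e-9, abs=1e-9)
        assert mav == pytest.approx(sum(abs(v) for v in x) / n, rel=1e-9, abs=1e-9)
        if var > 1e-12 * max(abs(x.max()), 1.0) ** 2:
            assert skew == pytest.approx(
                sum((v - m) ** 3 for v in x) / n / var**1.5, rel=1e-6, abs=1e-6
            )
            assert kurt == pytest.approx(
                sum((v - m) ** 4 for v in x) / n / var**2, rel=1e-6, abs=1e-6
            )

    def test_empty_vector_rejected(self):
        with pytest.raises(ValidationError):
            stat_features(np.array([]))


class TestFeatureMatrix:
    def test_full_size_dimensions(self):
        seg = make_segmented(21, 100)
        m = epl.build_feature_matrix(seg)
        assert m.F.shape == (21, 2400)
        assert m.F.size == 50400

    def test_toy_dimensions(self):
        m = epl.build_feature_matrix(make_segmented(2, 3))
        assert m.F.shape == (2, 72)

    def test_layout_first_column_is_first_segment_d3_mean(self):
        assert TimeFreqFeatureMatrix.column_index(0, 0, 0) == 0
        assert TimeFreqFeatureMatrix.column_descriptor(0) == (0, "D3", "mean")
        # spot-check: column content equals the mean of that segment's D3
        seg = make_segmented(2, 3, seed=4)
        m = epl.build_feature_matrix(seg)
        d3 = dwt_decompose(seg.segments[1, 2])["D3"]
        col = TimeFreqFeatureMatrix.column_index(2, 0, 0)
        assert m.F[1, col] == pytest.approx(d3.mean())

    def test_channel_permutation_equivariance(self):
        seg = make_segmented(4, 3, seed=5)
        perm = [2, 0, 3, 1]
        seg_p = epl.SegmentedRecording(
            recording_id="p", segments=seg.segments[perm], fs=seg.fs,
            channel_labels=[seg.channel_labels[i] for i in perm],
        )
        a = epl.build_feature_matrix(seg)
        b = epl.build_feature_matrix(seg_p)
        np.testing.assert_allclose(b.F, a.F[perm])


class TestZScore:
    def _mats(self, n=5, c=2, l=3, seed=0):
        return [epl.build_feature_matrix(make_segmented(c, l, seed=seed + i)) for i in range(n)]

    def test_train_columns_standardized(self):
        mats = self._mats()
        model = epl.zscore_fit(mats)
        z = np.stack([epl.zscore_apply(model, m).F for m in mats])
        np.testing.assert_allclose(z.mean(axis=0), 0.0, atol=1e-9)
        np.testing.assert_allclose(z.std(axis=0), 1.0, atol=1e-9)

    def test_constant_feature_maps_to_zero(self):
        mats = self._mats(n=3)
        for m in mats:
            m.F[:, 0] = 4.2
        model = epl.zscore_fit(mats)
        z = epl.zscore_apply(model, mats[0])
        np.testing.assert_array_equal(z.F[:, 0], 0.0)

    def test_heldout_uses_training_statistics(self):
        m1 = self._mats(n=2)
        model = epl.zscore_fit(m1)
        model.mean[:] = 5.0
        model.sd[:] = 2.0
        test = m1[0]
        test.F[:] = 9.0
        z = epl.zscore_apply(model, test)
        np.testing.assert_allclose(z.F, 2.0)

    def test_requires_two_training_matrices(self):
        with pytest.raises(ValidationError):
            epl.zscore_fit(self._mats(n=1))
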