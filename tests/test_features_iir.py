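"""Band-pass feature path: statistic kernels, sub-band filters, sample entropy."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pdeeg.bands import BANDS, get_band
from pdeeg.features_iir import (IIR_FEATURE_NAMES, extract_iir_features, mad, rmav,
                                sample_entropy, spectral_features, subband_filter,
                                time_stats)
from pdeeg.synthetic import band_power_1d

finite_vectors = st.lists(
    st.floats(min_value=-1e6, max_value=1e6, allow_nan=False), min_size=4, max_size=64
).map(np.asarray)


def _sampen_brute(x, m=2, r=None):
    """Naive O(n²) reference implementation (template counting by definition)."""
    x = np.asarray(x, dtype=float)
    if x.std() == 0:
        return 0.0
    r = 0.2 * x.std() if r is None else r
    n = len(x)
    a = b = 0
    for i in range(n - m):
        for j in range(i + 1, n - m):
            if max(abs(x[i + k] - x[j + k]) for k in range(m)) <= r:
                b += 1
                if abs(x[i + m] - x[j + m]) <= r:
                    a += 1
    if a == 0 or b == 0:
        return math.inf
    return -math.log(a / b)


class TestMad:
    def test_worked_example(self):
        assert mad(np.array([1.0, 2.0, 3.0, 4.0])) == pytest.approx(1.0)

    def test_constant_vector_zero(self):
        assert mad(np.full(10, 3.3)) == 0.0

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mad(np.array([]))

    @settings(max_examples=50, derandomize=True)
    @given(finite_vectors, st.floats(min_value=-100, max_value=100, allow_nan=False))
    def test_scale_equivariance(self, x, c):
        assert mad(c * x) == pytest.approx(abs(c) * mad(x), rel=1e-9, abs=1e-6)


class TestTimeStats:
    def test_worked_example(self):
        ts = time_stats(np.array([1.0, 2.0, 3.0, 4.0]))
        assert ts.mean == pytest.approx(2.5)
        assert ts.abs_mean == pytest.approx(2.5)
        assert ts.power_mean == pytest.approx(7.5)  # (1+4+9+16)/4
        assert ts.iqr == pytest.approx(1.5)
        assert ts.std == pytest.approx(np.sqrt(1.25))  # population denominator

    def test_gaussian_limits(self, rng):
        x = rng.standard_normal(100_000)
        ts = time_stats(x)
        assert abs(ts.skewness) < 0.05
        assert abs(ts.kurtosis) < 0.05  # excess kurtosis

    def test_symmetric_vector(self):
        ts = time_stats(np.array([-2.0, 0.0, 0.0, 2.0]))
        assert ts.mean == 0.0
        assert ts.skewness == 0.0

    @settings(max_examples=50, derandomize=True)
    @given(finite_vectors, st.floats(min_value=-50, max_value=50, allow_nan=False))
    def test_translation_and_scale_behaviour(self, x, c):
        base = time_stats(x)
        shifted = time_stats(x + c)
        assert shifted.mean == pytest.approx(base.mean + c, rel=1e-6, abs=1e-6)
        assert shifted.std == pytest.approx(base.std, rel=1e-6, abs=1e-6)
        assert shifted.mad == pytest.approx(base.mad, rel=1e-6, abs=1e-6)
        if base.std > 1e-6:
            doubled = time_stats(2.0 * x)
            assert doubled.skewness == pytest.approx(base.skewness, rel=1e-6, abs=1e-9)
            assert doubled.kurtosis == pytest.approx(base.kurtosis, rel=1e-6, abs=1e-9)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            time_stats(np.array([1.0, 2.0, 3.0]))


class TestRmav:
    def test_direct_ratio(self):
        assert rmav(np.array([2.0, -2.0]), np.array([0.5, 0.5])) == pytest.approx(4.0)

    def test_identical_bands_unity(self, rng):
        x = rng.standard_normal(100)
        assert rmav(x, x) == pytest.approx(1.0)

    def test_reciprocal_property(self, rng):
        a, b = rng.standard_normal(50), rng.standard_normal(50) + 1.0
        assert rmav(a, b) * rmav(b, a) == pytest.approx(1.0)

    def test_zero_denominator_raises(self):
        with pytest.raises(ZeroDivisionError):
            rmav(np.ones(4), np.zeros(4))


class TestSpectralFeatures:
    def test_pure_sine_centroid(self):
        t = np.arange(2000) / 500.0
        fc, _, rmsf = spectral_features(np.sin(2 * np.pi * 10 * t), 500.0)
        assert fc == pytest.approx(10.0, abs=0.25)
        assert rmsf == pytest.approx(10.0, abs=0.25)

    def test_two_tone_centroid_between(self):
        t = np.arange(2000) / 500.0
        x = np.sin(2 * np.pi * 5 * t) + np.sin(2 * np.pi * 15 * t)
        fc, _, _ = spectral_features(x, 500.0)
        assert fc == pytest.approx(10.0, abs=0.5)

    def test_centroid_bounded_by_rms(self, rng):
        for _ in range(10):
            fc, _, rmsf = spectral_features(rng.standard_normal(512), 500.0)
            assert 0 <= fc <= rmsf <= 250.0

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            spectral_features(np.zeros(2000), 500.0)


class TestSampleEntropy:
    def test_periodic_sequence_zero(self):
        x = np.array([1.0, 2.0] * 100)
        assert sample_entropy(x) == pytest.approx(0.0, abs=1e-12)
        assert _sampen_brute(x) == pytest.approx(0.0, abs=1e-12)

    def test_constant_zero_by_convention(self):
        assert sample_entropy(np.full(100, 2.0)) == 0.0

    def test_matches_brute_force(self, rng):
        for _ in range(5):
            x = rng.standard_normal(120)
            assert sample_entropy(x) == pytest.approx(_sampen_brute(x), rel=1e-12)

    def test_noise_more_irregular_than_sine(self):
        t = np.arange(2000) / 500.0
        sine = np.sin(2 * np.pi * 10 * t)
        wins = 0
        for seed in range(20):
            noise = np.random.default_rng(seed).uniform(-1, 1, 2000)
            wins += sample_entropy(noise) > sample_entropy(sine)
        assert wins >= 19


class TestSubbandFilter:
    def test_alpha_passes_10hz(self):
        t = np.arange(2000) / 500.0
        x = np.sin(2 * np.pi * 10 * t)
        out = subband_filter(x, get_band("alpha"), 500.0)
        assert band_power_1d(out, 500, 1, 249) >= 0.8 * band_power_1d(x, 500, 1, 249)

    def test_delta_blocks_10hz(self):
        t = np.arange(2000) / 500.0
        x = np.sin(2 * np.pi * 10 * t)
        out = subband_filter(x, get_band("delta"), 500.0)
        assert band_power_1d(out, 500, 1, 249) <= 0.01 * band_power_1d(x, 500, 1, 249)

    def test_zero_in_zero_out(self):
        assert np.allclose(subband_filter(np.zeros(2000), get_band("beta"), 500.0), 0.0)


class TestExtractBlock:
    def test_78_finite_values(self, rng):
        blk = extract_iir_features(rng.standard_normal(2000), 500.0)
        assert blk.values.shape == (6, 13)
        assert blk.valid
        assert np.isfinite(blk.values).all()
        assert blk.feature_names == IIR_FEATURE_NAMES

    def test_zero_variance_segment_flagged_invalid(self):
        blk = extract_iir_features(np.zeros(2000), 500.0)
        assert not blk.valid
        assert blk.values[0, IIR_FEATURE_NAMES.index("sampen")] == 0.0
        assert blk.values[0, IIR_FEATURE_NAMES.index("mean")] == 0.0

    def test_sine_segment_band_selectivity(self):
        t = np.arange(2000) / 500.0
        blk = extract_iir_features(np.sin(2 * np.pi * 10 * t), 500.0)
        names = list(b.name for b in BANDS)
        p = blk.values[:, IIR_FEATURE_NAMES.index("power_mean")]
        assert p[names.index("alpha")] / p[names.index("delta")] > 100

    def test_deterministic(self, rng):
        x = rng.standard_normal(2000)
        a = extract_iir_features(x, 500.0).values
        b = extract_iir_features(x, 500.0).values
        assert np.array_equal(a, b)
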