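"""IMS preprocessing chain: each step against an independent oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from melafuse import (AxisSpec, Spectrum, build_peak_matrix, detect_peaks,
                      mean_spectrum, realign_spectrum, resample_to_axis,
                      subtract_baseline, tic_normalize)
from melafuse.spectra import PeakList, SpectrumError, ZeroTICError


def _spec(intensity, mz=None, spot_id="s0"):
    intensity = np.asarray(intensity, dtype=float)
    if mz is None:
        mz = np.arange(len(intensity), dtype=float) + 700.0
    return Spectrum(mz=mz, intensity=intensity, spot_id=spot_id)


class TestResample:
    def test_identity_when_already_on_axis(self):
        axis = AxisSpec(700, 710, 11)
        s = _spec(np.arange(11.0), mz=axis.centers)
        out = resample_to_axis(s, axis)
        np.testing.assert_array_equal(out.intensity, s.intensity)

    def test_hand_linear_interpolation(self):
        s = Spectrum(mz=np.array([700.0, 702.0]), intensity=np.array([0.0, 2.0]))
        axis = AxisSpec(700, 702, 3)  # centers 700, 701, 702
        out = resample_to_axis(s, axis)
        np.testing.assert_allclose(out.intensity, [0.0, 1.0, 2.0])

    def test_outside_support_is_zero(self):
        s = Spectrum(mz=np.array([1000.0, 1001.0]), intensity=np.array([5.0, 5.0]))
        axis = AxisSpec(700, 3500, 50)
        out = resample_to_axis(s, axis)
        assert out.intensity[(axis.centers < 1000) | (axis.centers > 1001)].sum() == 0

    def test_all_zero_input_stays_zero(self):
        s = _spec(np.zeros(20))
        out = resample_to_axis(s, AxisSpec(700, 719, 40))
        assert np.all(out.intensity == 0)

    def test_no_overlap_names_the_spot(self):
        s = Spectrum(mz=np.array([100.0, 200.0]), intensity=np.array([1.0, 1.0]),
                     spot_id="bad_spot")
        with pytest.raises(SpectrumError, match="bad_spot"):
            resample_to_axis(s, AxisSpec(700, 3500, 10))


def _oracle_baseline(y, window):
    """Brute-force rolling min then rolling mean with edge replication."""
    n = len(y)
    h = window // 2
    padded = np.r_[np.full(h, y[0]), y, np.full(h, y[-1])]
    rmin = np.array([padded[i:i + window].min() for i in range(n)])
    padded2 = np.r_[np.full(h, rmin[0]), rmin, np.full(h, rmin[-1])]
    rmean = np.array([padded2[i:i + window].mean() for i in range(n)])
    return np.maximum(y - rmean, 0.0)


class TestBaseline:
    def test_constant_spectrum_removed_entirely(self):
        out = subtract_baseline(_spec(np.full(50, 7.0)), window=5)
        np.testing.assert_allclose(out.intensity, 0.0, atol=1e-12)

    def test_offset_plus_peak_against_brute_force(self):
        y = np.full(101, 5.0)
        y[50] += 10.0
        out = subtract_baseline(_spec(y), window=21)
        np.testing.assert_allclose(out.intensity, _oracle_baseline(y, 21), atol=1e-12)
        assert abs(out.intensity[50] - 10.0) < 0.6  # rolling-mean edge effect

    def test_random_spectrum_against_brute_force(self, rng):
        y = np.abs(rng.normal(5, 2, size=80))
        out = subtract_baseline(_spec(y), window=9)
        np.testing.assert_allclose(out.intensity, _oracle_baseline(y, 9), atol=1e-12)

    def test_never_negative(self, rng):
        for _ in range(20):
            y = rng.normal(0, 3, size=60)
            out = subtract_baseline(_spec(y), window=7)
            assert np.all(out.intensity >= 0)

    def test_window_validation(self):
        with pytest.raises(SpectrumError):
            subtract_baseline(_spec(np.ones(10)), window=4)  # even
        with pytest.raises(SpectrumError):
            subtract_baseline(_spec(np.ones(10)), window=11)  # too long


class TestTICNormalize:
    def test_hand_example(self):
        out = tic_normalize(_spec([1.0, 3.0]))
        np.testing.assert_allclose(out.intensity, [0.25, 0.75])

    def test_identity_when_already_at_target(self):
        out = tic_normalize(_spec([0.25, 0.75]))
        np.testing.assert_allclose(out.intensity, [0.25, 0.75], rtol=1e-12)

    @given(c=st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, max_examples=30)
    def test_scale_invariance(self, c):
        base = np.array([0.5, 1.5, 3.0, 0.1])
        a = tic_normalize(_spec(base)).intensity
        b = tic_normalize(_spec(c * base)).intensity
        np.testing.assert_allclose(a, b, rtol=1e-9)

    def test_idempotence(self, rng):
        y = np.abs(rng.normal(1, 0.5, 30)) + 0.01
        once = tic_normalize(_spec(y))
        twice = tic_normalize(once)
        np.testing.assert_allclose(once.intensity, twice.intensity, rtol=1e-9)
        assert abs(once.intensity.sum() - 1.0) < 1e-9

    def test_zero_spectrum_names_spot(self):
        with pytest.raises(ZeroTICError, match="dead"):
            tic_normalize(_spec(np.zeros(5), spot_id="dead"))


def _oracle_best_lag(x, ref, max_shift):
    """Exhaustive lag scan with tie preference toward zero."""
    best, best_corr = 0, -np.inf
    for lag in sorted(range(-max_shift, max_shift + 1), key=lambda l: (abs(l), l)):
        n = len(x)
        c = np.dot(x[lag:], ref[:n - lag]) if lag >= 0 \
            else np.dot(x[:n + lag], ref[-lag:])
        if c > best_corr:
            best_corr, best = c, lag
    return best


class TestRealign:
    def _toy(self, peak_at, n=200):
        y = np.zeros(n)
        idx = np.arange(n)
        y += 10 * np.exp(-0.5 * ((idx - peak_at) / 2.0) ** 2)
        return _spec(y)

    def test_identity(self):
        ref = self._toy(100)
        out, shift = realign_spectrum(ref, ref, max_shift=5)
        assert shift == 0
        np.testing.assert_array_equal(out.intensity, ref.intensity)

    def test_recovers_injected_shift(self):
        ref = self._toy(100)
        shifted = self._toy(102)  # displaced +2 bins
        out, shift = realign_spectrum(shifted, ref, max_shift=5)
        assert shift == 2
        assert int(np.argmax(out.intensity)) == 100

    def test_max_shift_zero_forces_zero(self):
        out, shift = realign_spectrum(self._toy(103), self._toy(100), max_shift=0)
        assert shift == 0

    def test_matches_exhaustive_scan_on_random_spectra(self, rng):
        for _ in range(20):
            ref = np.abs(rng.normal(1, 1, 200))
            x = np.abs(rng.normal(1, 1, 200))
            _, shift = realign_spectrum(_spec(x), _spec(ref), max_shift=4)
            assert shift == _oracle_best_lag(x, ref, 4)

    def test_exact_recovery_noise_free(self):
        # noise-free toys: every injected shift within max_shift recovered
        # exactly and the realigned spectrum equals the unshifted original
        for s in range(-3, 4):
            ref = self._toy(100)
            shifted = self._toy(100 + s)
            out, shift = realign_spectrum(shifted, ref, max_shift=5)
            assert shift == s
            np.testing.assert_allclose(out.intensity, ref.intensity, atol=1e-9)


class TestDetectPeaks:
    def test_flat_spectrum_no_peaks(self):
        assert len(detect_peaks(_spec(np.ones(50)))) == 0

    def test_monotone_ramp_no_peaks(self):
        assert len(detect_peaks(_spec(np.arange(50.0)))) == 0

    def test_two_bumps_recovered_over_seeds(self):
        idx = np.arange(300)
        for seed in range(20):
            r = np.random.default_rng(seed)
            noise = r.normal(0, 0.1, 300)
            y = 5 * np.exp(-0.5 * ((idx - 80) / 3.0) ** 2) \
                + 5 * np.exp(-0.5 * ((idx - 220) / 3.0) ** 2) + noise
            peaks = detect_peaks(_spec(np.maximum(y, 0)), snr_min=3.0)
            # oracle: brute local-maxima scan near known centers
            centers_bins = np.array([np.argmin(np.abs(_spec(y).mz - c))
                                     for c in peaks.centers])
            near = [b for b in centers_bins if min(abs(b - 80), abs(b - 220)) <= 1]
            assert len(near) == 2

    def test_snr_validation(self):
        with pytest.raises(SpectrumError):
            detect_peaks(_spec(np.ones(10)), snr_min=0.0)


class TestPeakMatrix:
    def test_shape_contract(self):
        spectra = [_spec(np.ones(30), spot_id=f"s{i}") for i in range(3)]
        peaks = PeakList(centers=spectra[0].mz[[5, 10, 15, 20]], window_halfwidth=1)
        m = build_peak_matrix(spectra, peaks)
        assert m.shape == (3, 4)
        assert list(m.index) == ["s0", "s1", "s2"]

    def test_indicator_column(self):
        y = np.zeros(30)
        y[10] = 1.0
        peaks = PeakList(centers=_spec(y).mz[[10, 20]], window_halfwidth=1)
        m = build_peak_matrix([_spec(y)], peaks)
        np.testing.assert_allclose(m.to_numpy(), [[1.0, 0.0]])

    def test_hand_three_bin_sums(self, rng):
        y = rng.uniform(0, 5, 30)
        s = _spec(y)
        peaks = PeakList(centers=s.mz[[7, 15]], window_halfwidth=1)
        m = build_peak_matrix([s], peaks)
        np.testing.assert_allclose(
            m.to_numpy()[0], [y[6:9].sum(), y[14:17].sum()], rtol=1e-12)

    def test_center_outside_axis_rejected(self):
        s = _spec(np.ones(30))
        with pytest.raises(SpectrumError):
            build_peak_matrix([s], PeakList(centers=np.array([9999.0])))


def test_mean_spectrum_requires_common_axis():
    a, b = _spec(np.ones(10)), _spec(np.ones(12))
    with pytest.raises(SpectrumError):
        mean_spectrum([a, b])
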