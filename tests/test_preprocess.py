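import numpy as np
import pytest

from ramantdm.core_io import SampleMeta, Spectrum
from ramantdm.errors import (
    CalibrationError,
    DegenerateFitError,
    NormalizationError,
    RangeError,
)
from ramantdm.preprocess import (
    apply_calibration,
    emsc_correct,
    fit_wavenumber_calibration,
    normalize,
    savgol_smooth,
    snip_baseline,
    truncate,
)


def _spec(w, y, sid="x"):
    return Spectrum(np.asarray(w, float), np.asarray(y, float), SampleMeta(sid))


class TestWavenumberCalibration:
    peaks = np.array([900.0, 1100.0, 1300.0, 1500.0, 1700.0])

    def test_identity(self):
        cmap = fit_wavenumber_calibration(self.peaks, self.peaks, degree=1)
        assert cmap.residual_rms < 1e-9
        assert np.allclose(cmap(self.peaks), self.peaks)

    def test_pure_offset(self):
        cmap = fit_wavenumber_calibration(self.peaks - 2.0, self.peaks, degree=1)
        probe = np.array([950.0, 1234.0])
        assert np.allclose(cmap(probe), probe + 2.0)

    def test_quadratic_distortion_interpolated_exactly_at_three_peaks(self):
        # degree-2 least squares through 3 peaks is exact interpolation
        peaks = np.array([900.0, 1300.0, 1700.0])
        measured = peaks + 1e-4 * peaks ** 2
        cmap = fit_wavenumber_calibration(measured, peaks, degree=2)
        assert cmap.residual_rms < 1e-7
        assert np.allclose(cmap(measured), peaks, atol=1e-6)

    def test_non_monotonic_map_rejected(self):
        measured = np.array([1000.0, 1001.0, 1002.0, 1003.0])
        reference = np.array([1000.0, 1050.0, 1010.0, 1060.0])
        with pytest.raises(CalibrationError):
            fit_wavenumber_calibration(measured, reference, degree=3)

    def test_apply_identity_map_on_own_grid(self):
        w = np.linspace(900.0, 1700.0, 201)
        spec = _spec(w, np.sin(w / 50.0))
        cmap = fit_wavenumber_calibration(self.peaks, self.peaks, degree=1)
        out = apply_calibration(spec, cmap, w)
        assert np.allclose(out.intensities, spec.intensities)

    def test_shifted_gaussian_recenters(self):
        # linear interpolation after an offset map must put the band apex
        # back at the reference position, within one grid step
        w = np.arange(900.0, 1701.0)
        shift = 3.0
        spec = _spec(w, np.exp(-0.5 * ((w - (1300.0 + shift)) / 8.0) ** 2))
        cmap = fit_wavenumber_calibration(self.peaks + shift, self.peaks, 1)
        target = np.arange(950.0, 1651.0)
        out = apply_calibration(spec, cmap, target)
        apex = target[np.argmax(out.intensities)]
        assert abs(apex - 1300.0) <= 1.0

    def test_extrapolation_rejected(self):
        w = np.linspace(900.0, 1700.0, 100)
        spec = _spec(w, np.ones_like(w))
        cmap = fit_wavenumber_calibration(self.peaks, self.peaks, degree=1)
        with pytest.raises(RangeError):
            apply_calibration(spec, cmap, np.linspace(800.0, 1700.0, 10))


class TestTruncate:
    def test_channel_counts_for_standard_windows(self):
        w = np.arange(600.0, 1901.0)
        spec = _spec(w, np.zeros_like(w))
        assert truncate(spec, 800.0, 1800.0).n_channels == 1001
        assert truncate(spec, 1150.0, 1750.0).n_channels == 601

    def test_full_range_is_identity(self):
        w = np.arange(600.0, 1901.0)
        spec = _spec(w, np.arange(w.size, dtype=float))
        out = truncate(spec, 600.0, 1900.0)
        assert np.array_equal(out.intensities, spec.intensities)

    def test_empty_result_rejected(self):
        spec = _spec([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        with pytest.raises(RangeError):
            truncate(spec, 10.0, 20.0)


class TestSavgol:
    def test_quadratic_reproduced_to_machine_precision(self):
        w = np.arange(800.0, 1801.0)
        spec = _spec(w, 0.001 * w ** 2 - 0.5 * w + 3.0)
        out = savgol_smooth(spec, p=2, n=5)
        assert np.allclose(out.intensities, spec.intensities, atol=1e-8)

    def test_constant_unchanged(self):
        spec = _spec(np.arange(10.0), np.full(10, 4.2))
        assert np.allclose(savgol_smooth(spec).intensities, 4.2)

    def test_noise_variance_reduction_matches_coefficients(self):
        # interior variance shrinks by the sum of squared window weights,
        # 595/1225 = 0.4857 for p=2, n=5
        rng = np.random.default_rng(42)
        noise = rng.normal(size=(400, 251))
        w = np.arange(251.0)
        ratios = []
        for row in noise:
            out = savgol_smooth(_spec(w, row)).intensities
            ratios.append(np.var(out[5:-5]) / np.var(row[5:-5]))
        assert np.isclose(np.mean(ratios), 595.0 / 1225.0, atol=0.01)

    def test_window_validation(self):
        spec = _spec(np.arange(10.0), np.zeros(10))
        with pytest.raises(ValueError):
            savgol_smooth(spec, p=2, n=4)
        with pytest.raises(ValueError):
            savgol_smooth(_spec(np.arange(3.0), np.zeros(3)), p=2, n=5)


class TestEMSC:
    w = np.arange(800.0, 1801.0)
    reference_y = (
        np.exp(-0.5 * ((w - 1300.0) / 8.0) ** 2)
        + 0.5 * np.exp(-0.5 * ((w - 1600.0) / 10.0) ** 2)
    )

    def _ref(self):
        return _spec(self.w, self.reference_y, "ref")

    def test_reference_maps_to_itself(self):
        out = emsc_correct([self._ref()], self._ref())[0]
        assert np.allclose(out.intensities, self.reference_y, atol=1e-10)

    def test_affine_distortion_removed_exactly(self):
        distorted = _spec(self.w, 2.0 * self.reference_y + 5.0)
        out = emsc_correct([distorted], self._ref())[0]
        assert np.allclose(out.intensities, self.reference_y, atol=1e-9)

    def test_degree6_polynomial_contamination_removed(self):
        wt = 2.0 * (self.w - self.w[0]) / (self.w[-1] - self.w[0]) - 1.0
        contamination = 5.0 * wt ** 6 - 3.0 * wt ** 3 + 2.0 * wt + 7.0
        distorted = _spec(self.w, self.reference_y + contamination)
        out = emsc_correct([distorted], self._ref(), degree=6)[0]
        assert np.max(np.abs(out.intensities - self.reference_y)) < 1e-8

    def test_degenerate_scale_rejected(self):
        wt = 2.0 * (self.w - self.w[0]) / (self.w[-1] - self.w[0]) - 1.0
        pure_poly = _spec(self.w, 3.0 + 2.0 * wt)
        with pytest.raises(DegenerateFitError):
            emsc_correct([pure_poly], self._ref())


class TestSNIP:
    w = np.arange(800.0, 1801.0)

    def test_constant_spectrum_is_all_baseline(self):
        spec = _spec(self.w, np.full(self.w.size, 7.0))
        baseline, corrected = snip_baseline(spec)
        assert np.allclose(baseline.intensities, 7.0, atol=1e-9)
        assert np.allclose(corrected.intensities, 0.0, atol=1e-9)

    def test_gaussian_peak_recovery_on_zero_baseline(self):
        peak = 100.0 * np.exp(-0.5 * ((self.w - 1300.0) / 8.0) ** 2)
        _, corrected = snip_baseline(_spec(self.w, peak), iterations=20, order=2)
        apex = corrected.intensities[np.argmin(np.abs(self.w - 1300.0))]
        assert apex >= 95.0

    def test_gaussian_on_ramp_baseline(self):
        peak = 100.0 * np.exp(-0.5 * ((self.w - 1300.0) / 8.0) ** 2)
        ramp = 0.05 * (self.w - 800.0) + 20.0
        _, corrected = snip_baseline(_spec(self.w, peak + ramp))
        apex = corrected.intensities[np.argmin(np.abs(self.w - 1300.0))]
        assert apex >= 95.0
        off_band = np.abs(self.w - 1300.0) > 80.0
        assert np.mean(np.abs(corrected.intensities[off_band])) < 2.0

    def test_reapplication_removes_little_further_signal(self):
        peak = 100.0 * np.exp(-0.5 * ((self.w - 1300.0) / 8.0) ** 2)
        ramp = 0.05 * (self.w - 800.0) + 20.0
        _, corrected = snip_baseline(_spec(self.w, peak + ramp))
        _, twice = snip_baseline(corrected)
        removed = np.abs(corrected.intensities - twice.intensities)
        assert removed.max() < 0.02 * 100.0

    def test_invalid_order_rejected(self):
        with pytest.raises(ValueError):
            snip_baseline(_spec(self.w, np.zeros_like(self.w)), order=3)


class TestNormalize:
    def test_vector_idempotent_and_scale_invariant(self):
        spec = _spec(np.arange(5.0), [3.0, 4.0, 0.0, 0.0, 0.0])
        once = normalize(spec, "vector")
        assert np.isclose(np.linalg.norm(once.intensities), 1.0)
        twice = normalize(once, "vector")
        assert np.allclose(once.intensities, twice.intensities)
        scaled = normalize(_spec(np.arange(5.0), 7.0 * spec.intensities), "vector")
        assert np.allclose(scaled.intensities, once.intensities)

    def test_zero_norm_rejected(self):
        with pytest.raises(NormalizationError):
            normalize(_spec(np.arange(3.0), np.zeros(3)), "vector")

    def test_max_at_sets_band_apex_to_one(self):
        w = np.arange(800.0, 1801.0)
        y = 50.0 * np.exp(-0.5 * ((w - 1605.0) / 8.0) ** 2) + \
            20.0 * np.exp(-0.5 * ((w - 1000.0) / 8.0) ** 2)
        out = normalize(_spec(w, y), "max_at", center=1605.0)
        window = np.abs(w - 1605.0) <= 15.0
        assert np.isclose(out.intensities[window].max(), 1.0)

    def test_max_at_nonpositive_window_max_rejected(self):
        w = np.arange(800.0, 1801.0)
        with pytest.raises(NormalizationError):
            normalize(_spec(w, -np.ones_like(w)), "max_at", center=1605.0)


class TestChainInvariance:
    def test_affine_distortion_invariance_of_full_chain(self):
        """Conditioning output is insensitive to per-spectrum gain/offset."""
        from ramantdm.core_io import SpectraSet
        from ramantdm.pipeline import PreprocessParams, preprocess_set

        rng = np.random.default_rng(3)
        w = np.arange(600.0, 1901.0)
        base = (
            300.0 * np.exp(-0.5 * ((w - 1611.0) / 8.0) ** 2)
            + 150.0 * np.exp(-0.5 * ((w - 1050.0) / 8.0) ** 2)
            + 100.0 * np.exp(-0.5 * ((w - 1355.0) / 8.0) ** 2)
        )
        spectra = []
        for r, (g, o) in enumerate([(1.0, 0.0), (0.5, -30.0), (2.0, 30.0)], 1):
            y = g * base + o + rng.normal(0, 0.01, w.size)
            spectra.append(Spectrum(w.copy(), y, SampleMeta("a", replicate=r)))
        out = preprocess_set(SpectraSet(spectra), PreprocessParams())
        ref = out.spectra[0].intensities
        scale = np.sqrt(np.mean(ref ** 2))
        for s in out.spectra[1:]:
            rms = np.sqrt(np.mean((s.intensities - ref) ** 2))
            assert rms / scale < 0.01
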