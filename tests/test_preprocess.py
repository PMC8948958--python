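"""Pre-treatment tests: ROI crop, iterative polynomial baseline,
cross-correlation alignment, vector normalization."""

import numpy as np
import pandas as pd
import pytest

import trichospec as ts
from trichospec.synthetic import _baseline_curve


def _dataset(grid, rows, classes=None):
    n = len(rows)
    labels = pd.DataFrame({
        "class": classes or ["A"] * n, "genetics": ["Sativa"] * n,
        "trichome_id": ["t"] * n, "point_id": range(n)})
    return ts.SpectraDataset(grid, np.asarray(rows, dtype=float), labels)


class TestCropRoi:
    grid = np.arange(200.0, 4001.0, 10.0)

    def test_identity_when_roi_covers_grid(self):
        ds = _dataset(np.arange(200.0, 1801.0), [np.ones(1601)])
        out = ts.crop_roi(ds, (200, 1800))
        assert np.array_equal(out.grid, ds.grid)

    def test_wide_grid_cropped_to_fingerprint_region(self):
        ds = _dataset(self.grid, [np.ones(self.grid.size)])
        out = ts.crop_roi(ds, (200, 1800))
        assert out.grid[-1] <= 1800
        assert out.grid[0] >= 200

    def test_disjoint_roi_errors(self):
        ds = _dataset(np.arange(200.0, 1801.0), [np.ones(1601)])
        with pytest.raises(ValueError, match="overlap"):
            ts.crop_roi(ds, (5000, 6000))


class TestBaseline:
    grid = np.arange(200.0, 1801.0)

    def test_polynomial_input_is_fixed_point(self):
        coeffs = np.array([2.0, 0.5, -0.4, 0.3, -0.2, 0.1])
        y = _baseline_curve(self.grid, coeffs)
        spec = ts.Spectrum(self.grid, y)
        base = ts.fit_baseline(spec, poly_order=5)
        assert np.max(np.abs(y - base)) < 1e-6 * np.max(np.abs(y))

    def test_order_zero_constant(self):
        spec = ts.Spectrum(self.grid, np.full(self.grid.size, 3.5))
        base = ts.fit_baseline(spec, poly_order=0)
        assert np.allclose(base, 3.5)

    def test_peak_recovery_within_five_percent(self):
        """A strong Lorentzian on a curved background: after correction the
        apparent peak height matches the planted amplitude within 5%."""
        coeffs = np.array([1.0, 0.3, -0.2, 0.1, 0.2, -0.1])
        background = _baseline_curve(self.grid, coeffs)
        amplitude = 10.0 * (background.max() - background.min())
        band = ts.Band(center=1438, fwhm=12, amplitude=amplitude)
        spec = ts.generate_spectrum(self.grid, [band], baseline_coeffs=coeffs,
                                    noise_sd=0.0)
        base = ts.fit_baseline(spec, poly_order=5)
        corrected = ts.subtract_baseline(spec, base)
        peak = corrected.intensities[np.argmin(np.abs(self.grid - 1438))]
        assert abs(peak - amplitude) < 0.05 * amplitude

    def test_correction_never_raises_clamped_points(self):
        rng = np.random.default_rng(0)
        y = _baseline_curve(self.grid, [1, 0.2, 0.3, 0, 0, 0]) \
            + np.abs(rng.normal(0, 0.2, self.grid.size))
        spec = ts.Spectrum(self.grid, y)
        base = ts.fit_baseline(spec, poly_order=5)
        # baseline stays at or below the signal envelope's polynomial part
        assert np.mean(y >= base) > 0.5

    def test_too_few_points_errors(self):
        spec = ts.Spectrum(np.arange(3.0), np.zeros(3))
        with pytest.raises(ValueError, match="at least"):
            ts.fit_baseline(spec, poly_order=5)


class TestSubtract:
    def test_own_baseline_of_flat_is_zero(self):
        spec = ts.Spectrum(np.arange(10.0), np.full(10, 2.0))
        out = ts.subtract_baseline(spec, np.full(10, 2.0))
        assert np.all(out.intensities == 0)

    def test_zero_curve_identity_and_linearity(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=20)
        a, b = rng.normal(size=20), rng.normal(size=20)
        spec = ts.Spectrum(np.arange(20.0), y)
        assert np.array_equal(ts.subtract_baseline(spec, np.zeros(20)).intensities, y)
        lhs = ts.subtract_baseline(ts.subtract_baseline(spec, a), b).intensities
        rhs = ts.subtract_baseline(spec, a + b).intensities
        assert np.allclose(lhs, rhs, atol=1e-12)


class TestAlign:
    grid = np.arange(200.0, 1001.0)

    def _bands_spectrum(self, shift=0.0):
        lib = [ts.Band(350, 8, 1.0), ts.Band(500, 10, 0.7), ts.Band(800, 12, 0.5)]
        return ts.generate_spectrum(self.grid, lib, global_shift=shift, noise_sd=0.0)

    def test_identical_to_reference_unchanged(self):
        ref = self._bands_spectrum()
        ds = _dataset(self.grid, [ref.intensities, ref.intensities.copy()])
        out = ts.align_to_reference(ds)
        assert out.labels["wavenumber_shift"][1] == 0.0
        assert np.allclose(out.matrix[1], ds.matrix[1])

    def test_planted_integer_shift_recovered(self):
        ref = self._bands_spectrum()
        shifted = self._bands_spectrum(shift=4.0)
        ds = _dataset(self.grid, [ref.intensities, shifted.intensities])
        out = ts.align_to_reference(ds, max_shift=10.0)
        delta = out.labels["wavenumber_shift"][1]
        assert delta == pytest.approx(4.0, abs=0.5)
        # sub-grid refinement leaves a small interpolation residual
        interior = slice(20, -20)
        err = np.abs(out.matrix[1][interior] - ref.intensities[interior])
        assert err.max() < 1e-2 * ref.intensities.max()

    def test_max_shift_zero_disables_estimation(self):
        ref = self._bands_spectrum()
        shifted = self._bands_spectrum(shift=4.0)
        ds = _dataset(self.grid, [ref.intensities, shifted.intensities])
        out = ts.align_to_reference(ds, max_shift=0.0)
        assert out.labels["wavenumber_shift"][1] == 0.0
        assert np.allclose(out.matrix[1], shifted.intensities)

    def test_flat_spectrum_gets_zero_shift(self, caplog):
        ref = self._bands_spectrum()
        ds = _dataset(self.grid, [ref.intensities, np.zeros(self.grid.size)])
        out = ts.align_to_reference(ds)
        assert out.labels["wavenumber_shift"][1] == 0.0


class TestVectorNormalize:
    def test_closed_form(self):
        spec = ts.Spectrum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        out = ts.vector_normalize(spec)
        expected = np.array([-1, 0, 1]) / np.sqrt(2)
        assert np.allclose(out.intensities, expected, atol=1e-12)

    def test_postconditions_and_idempotence(self):
        rng = np.random.default_rng(3)
        spec = ts.Spectrum(np.arange(50.0), rng.normal(size=50))
        out = ts.vector_normalize(spec)
        assert abs(out.intensities.mean()) < 1e-12
        assert abs((out.intensities ** 2).sum() - 1.0) < 1e-12
        again = ts.vector_normalize(out)
        assert np.allclose(again.intensities, out.intensities, atol=1e-12)

    def test_constant_spectrum_rejected(self):
        spec = ts.Spectrum(np.arange(5.0), np.full(5, 2.0))
        with pytest.raises(ValueError, match="constant"):
            ts.vector_normalize(spec)


def test_pipeline_runner_output_normalized(two_class_dataset):
    clean = ts.preprocess_dataset(two_class_dataset,
                                  ts.PreprocessConfig(roi=(200, 600)))
    assert clean.grid[0] >= 200 and clean.grid[-1] <= 600
    assert np.allclose(clean.matrix.mean(axis=1), 0.0, atol=1e-12)
    assert np.allclose((clean.matrix ** 2).sum(axis=1), 1.0, atol=1e-12)
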