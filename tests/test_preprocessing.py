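"""Spectral pre-treatments: exactness, invariances, oracles."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import gingerspec as gs
from gingerspec.preprocessing import CANONICAL_TREATMENTS, make_treatment


class TestSnv:
    def test_unit_row_example(self):
        out = gs.snv(np.array([[1.0, 2.0, 3.0]]))
        np.testing.assert_allclose(out, [[-1.0, 0.0, 1.0]], atol=1e-14)

    def test_postconditions_on_random_rows(self, rng):
        out = gs.snv(rng.random((10, 30)))
        np.testing.assert_allclose(out.mean(axis=1), 0.0, atol=1e-12)
        np.testing.assert_allclose(out.std(axis=1, ddof=1), 1.0, atol=1e-12)

    def test_idempotent_on_normalised_input(self, rng):
        once = gs.snv(rng.random((5, 20)))
        np.testing.assert_allclose(gs.snv(once), once, atol=1e-12)

    def test_zero_variance_row_names_sample(self):
        X = np.vstack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.raises(ValueError, match="sample 1"):
            gs.snv(X)

    @given(a=st.floats(0.1, 10), b=st.floats(-5, 5))
    def test_removes_per_row_affine_distortion(self, a, b):
        rng = np.random.default_rng(0)
        X = rng.random((4, 25))
        np.testing.assert_allclose(gs.snv(a * X + b), gs.snv(X), atol=1e-9)


class TestMsc:
    def test_reference_spectrum_is_fixed_point(self, rng):
        X = rng.random((6, 15))
        ref = gs.msc_fit(X)
        out = gs.msc_apply(ref.reference_spectrum[None, :], ref)
        np.testing.assert_allclose(out[0], ref.reference_spectrum, atol=1e-12)

    def test_exact_inversion_of_known_affine(self, rng):
        X = rng.random((6, 15))
        ref = gs.msc_fit(X)
        distorted = 2.0 * ref.reference_spectrum + 0.1
        out = gs.msc_apply(distorted[None, :], ref)
        np.testing.assert_allclose(out[0], ref.reference_spectrum, atol=1e-12)

    def test_recovers_spectra_from_affine_scatter(self, rng):
        """Per-sample affine distortions of the reference are inverted
        exactly when the correction was fitted on undistorted spectra."""
        X = rng.random((8, 20))
        ref = gs.msc_fit(X)
        a = 1.0 + 0.5 * rng.random(8)
        b = 0.2 * rng.standard_normal(8)
        distorted = a[:, None] * ref.reference_spectrum[None, :] + b[:, None]
        out = gs.msc_apply(distorted, ref)
        np.testing.assert_allclose(out, np.tile(ref.reference_spectrum, (8, 1)), atol=1e-10)

    def test_fitted_lines_match_normal_equations_oracle(self, rng):
        X = rng.random((5, 5))
        ref = gs.msc_fit(X)
        gs.msc_apply(X, ref)
        for i in range(5):
            design = np.column_stack([ref.reference_spectrum, np.ones(5)])
            slope, intercept = np.linalg.lstsq(design, X[i], rcond=None)[0]
            assert ref.slopes[i] == pytest.approx(slope, abs=1e-12)
            assert ref.intercepts[i] == pytest.approx(intercept, abs=1e-12)

    def test_near_zero_slope_names_sample(self, rng):
        X = rng.random((4, 10))
        ref = gs.msc_fit(X)
        flat = np.full((1, 10), 3.0)  # constant spectrum: slope 0 against any reference
        with pytest.raises(ValueError, match="sample 0"):
            gs.msc_apply(flat, ref)

    def test_needs_two_training_spectra(self, rng):
        with pytest.raises(ValueError, match="at least 2"):
            gs.msc_fit(rng.random((1, 10)))


class TestMeanFilter:
    def test_constant_spectrum_invariant(self):
        X = np.full((2, 20), 0.6)
        np.testing.assert_allclose(gs.mean_filter(X, 5), X, atol=1e-14)

    def test_linear_ramp_interior_invariant(self):
        x = np.arange(20.0)[None, :]
        out = gs.mean_filter(x, 5)
        np.testing.assert_allclose(out[0, 2:-2], x[0, 2:-2], atol=1e-12)

    @pytest.mark.parametrize("width", [5, 9])
    def test_matches_naive_truncated_window_oracle(self, rng, width):
        X = rng.random((3, 20))
        got = gs.mean_filter(X, width)
        h = width // 2
        oracle = np.array([
            [np.mean(row[max(0, j - h): j + h + 1]) for j in range(20)]
            for row in X
        ])
        np.testing.assert_allclose(got, oracle, atol=1e-12)

    def test_even_width_rejected(self, rng):
        with pytest.raises(ValueError, match="odd"):
            gs.mean_filter(rng.random((2, 10)), 4)

    def test_width_exceeding_band_count_rejected(self, rng):
        with pytest.raises(ValueError):
            gs.mean_filter(rng.random((2, 5)), 7)


class TestSavgolDerivative:
    def test_first_derivative_of_line_is_slope(self):
        lam = np.arange(30.0)
        X = (0.3 + 0.02 * lam)[None, :]
        out = gs.savgol_derivative(X, 1, window=11, polyorder=2)
        np.testing.assert_allclose(out, 0.02, atol=1e-12)

    def test_second_derivative_of_quadratic_is_constant(self):
        lam = np.arange(30.0)
        X = (0.005 * lam**2)[None, :]
        out = gs.savgol_derivative(X, 2, window=11, polyorder=3)
        np.testing.assert_allclose(out, 2 * 0.005, atol=1e-10)

    def test_matches_per_window_polyfit_oracle(self, rng):
        X = rng.random((1, 25))
        w, p = 7, 2
        got = gs.savgol_derivative(X, 1, window=w, polyorder=p)
        h = w // 2
        for j in range(h, 25 - h):
            idx = np.arange(-h, h + 1, dtype=float)
            coefs = np.polyfit(idx, X[0, j - h: j + h + 1], p)
            # derivative of the local fit at the window centre (x = 0)
            assert got[0, j] == pytest.approx(coefs[-2], abs=1e-10)

    def test_per_nm_units_from_wavelength_axis(self, rng):
        wl = np.linspace(400.0, 1000.0, 31)   # 20 nm spacing
        lamfun = 0.3 + 0.001 * wl
        sm = gs.SpectraMatrix(lamfun[None, :], wl)
        out = gs.savgol_derivative(sm, 1)
        np.testing.assert_allclose(out.X, 0.001, atol=1e-12)

    def test_parameter_violations_listed(self, rng):
        X = rng.random((1, 30))
        with pytest.raises(ValueError, match="odd"):
            gs.savgol_derivative(X, 1, window=10)
        with pytest.raises(ValueError, match="polyorder"):
            gs.savgol_derivative(X, 1, window=5, polyorder=5)
        with pytest.raises(ValueError, match="deriv_order"):
            gs.savgol_derivative(X, 2, window=7, polyorder=1)


def test_spatial_mean_filter_smooths_image_plane(rng):
    wl = np.linspace(400, 700, 4)
    cube = gs.HyperCube(rng.random((8, 8, 4)), wl)
    out = gs.spatial_mean_filter(cube, 5)
    assert out.shape == cube.shape
    assert out.data.std() < cube.data.std()


@pytest.mark.parametrize("tag", CANONICAL_TREATMENTS)
def test_every_treatment_preserves_shape_and_axis(small_dataset, tag):
    t = make_treatment(tag)
    sm = small_dataset.spectra
    out = t.fit_transform(sm)
    assert out.X.shape == sm.X.shape
    np.testing.assert_array_equal(out.wavelengths, sm.wavelengths)
    assert out.treatment_tag in (tag, "raw")


@pytest.mark.parametrize("tag", CANONICAL_TREATMENTS)
def test_treatments_are_pure(small_dataset, tag):
    sm = small_dataset.spectra
    before = sm.X.copy()
    make_treatment(tag).fit_transform(sm)
    np.testing.assert_array_equal(sm.X, before)


def test_unknown_treatment_rejected():
    with pytest.raises(ValueError, match="unknown treatment"):
        make_treatment("osc")


def test_msc_treatment_requires_fit_before_transform(small_dataset):
    t = make_treatment("msc")
    with pytest.raises(RuntimeError, match="fitted"):
        t.transform(small_dataset.spectra)
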