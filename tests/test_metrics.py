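import numpy as np
import pytest

from blinkcomp import (EmitterSet, PixelGrid, ResolutionCurve,
                       build_system_matrix, compute_components, cross_profile,
                       diagonal_profile, first_resolved_separation, fwhm,
                       inflection_point, magnitude_curve,
                       magnitude_ratio_curve, mean_image, min_max_ratio)
from blinkcomp.metrics import WidthError


def r_curve(delta_ys, profile_kind, grid, psf):
    """R as a function of separation, for the mean image or diag(C2)."""
    vals = []
    x = grid.centers
    for d in delta_ys:
        sm = build_system_matrix(EmitterSet.uniform(2, float(d)), grid, psf)
        if profile_kind == "meanimg":
            prof = mean_image(sm)
        else:
            _, C2, _ = compute_components(sm)
            prof = diagonal_profile(C2)
        vals.append(min_max_ratio(prof, x))
    return ResolutionCurve(np.asarray(delta_ys, float), np.asarray(vals),
                           "R", profile_kind)


class TestProfiles:
    def test_identity_diagonal(self):
        np.testing.assert_array_equal(diagonal_profile(np.eye(4)), np.ones(4))

    def test_coincident_pair_diag_C1_is_squared_mean_image(self, psf,
                                                           ideal_grid):
        g = build_system_matrix(EmitterSet((0.0,)), ideal_grid, psf).G[:, 0]
        G = np.stack([g, g], axis=1)
        C1, _, _ = compute_components(G)
        np.testing.assert_allclose(diagonal_profile(C1),
                                   (2 * g / 2) ** 2, atol=1e-14)

    def test_C2_minus_C3_diagonal_small_between_emitters(self, pair_100nm,
                                                         ideal_grid):
        _, C2, C3 = compute_components(pair_100nm)
        x = ideal_grid.centers
        between = np.abs(x) <= 25
        d = diagonal_profile(C2 - C3)
        d3 = diagonal_profile(C3)
        assert d3[between].min() > 0
        # the auto and cross terms cancel at the midpoint and stay small
        # strictly between the emitters
        assert float(np.interp(0.0, x, d)) < 1e-3 * d.max()
        assert d[between].max() < 0.2 * d.max()

    def test_cross_profile_mirror_symmetry(self, pair_100nm, ideal_grid):
        _, C2, _ = compute_components(pair_100nm)
        x = ideal_grid.centers
        left = cross_profile(C2, x, -50.0)
        right = cross_profile(C2, x, +50.0)
        np.testing.assert_allclose(left, right[::-1], atol=1e-12)

    def test_C1_cross_profile_proportional_to_mean_image(self, pair_100nm,
                                                         ideal_grid):
        C1, _, _ = compute_components(pair_100nm)
        x = ideal_grid.centers
        row = cross_profile(C1, x, -50.0)
        gt = mean_image(pair_100nm)
        ratio = row / gt
        np.testing.assert_allclose(ratio, ratio[0], rtol=1e-9)

    def test_cross_profile_single_maximum(self, pair_100nm, ideal_grid, psf):
        # dense-grid oracle: evaluate the C2 kernel row at r' = -50 nm on a
        # 0.25-nm grid and locate its (single) maximum
        _, C2, _ = compute_components(pair_100nm)
        x = ideal_grid.centers
        row = cross_profile(C2, x, -50.0)
        from scipy.signal import find_peaks
        idx, _ = find_peaks(row, height=0.5 * row.max())
        assert len(idx) == 1
        fine = np.arange(-400.0, 400.0, 0.25)
        kernel = (psf.profile(-50.0 - (-50.0)) * psf.profile(fine + 50.0)
                  + psf.profile(-50.0 - 50.0) * psf.profile(fine - 50.0)) / 2
        oracle_peak = fine[np.argmax(kernel)]
        assert x[idx[0]] == pytest.approx(oracle_peak, abs=1.0)

    def test_cross_profile_outside_grid(self, pair_100nm, ideal_grid):
        _, C2, _ = compute_components(pair_100nm)
        with pytest.raises(ValueError):
            cross_profile(C2, ideal_grid.centers, 5000.0)


class TestFWHM:
    def test_triangle_closed_form(self):
        x = np.linspace(-10, 10, 201)
        w = 4.0
        prof = np.clip(1 - np.abs(x) / w, 0, None)
        assert fwhm(prof, x) == pytest.approx(w, abs=1e-9)

    def test_scale_invariance(self, psf, ideal_grid):
        prof = psf.profile(ideal_grid.centers)
        a = fwhm(prof, ideal_grid.centers)
        b = fwhm(37.0 * prof, ideal_grid.centers)
        assert a == b

    def test_no_crossing_raises(self):
        x = np.linspace(-1, 1, 11)
        with pytest.raises(WidthError):
            fwhm(np.ones(11) + 0.01 * np.exp(-x ** 2), x)


class TestMinMaxRatio:
    def test_single_peak_is_one(self, psf, ideal_grid):
        prof = psf.profile(ideal_grid.centers)
        assert min_max_ratio(prof, ideal_grid.centers) == 1.0

    def test_asymmetric_profile_warns(self):
        x = np.linspace(-5, 5, 101)
        prof = np.exp(-(x - 1.5) ** 2)
        with pytest.warns(UserWarning):
            min_max_ratio(prof, x)

    def test_R_monotone_for_mean_image(self, psf, ideal_grid):
        dys = np.arange(100.0, 251.0, 2.0)
        curve = r_curve(dys, "meanimg", ideal_grid, psf)
        assert np.all(np.diff(curve.values) <= 1e-12)

    def test_fwhm_ordering_in_unresolved_regime(self, pair_100nm, ideal_grid):
        C1, C2, C3 = compute_components(pair_100nm)
        x = ideal_grid.centers
        widths = [fwhm(diagonal_profile(C3), x),
                  fwhm(diagonal_profile(C1), x),
                  fwhm(diagonal_profile(C2), x),
                  fwhm(mean_image(pair_100nm), x)]
        assert widths == sorted(widths)


class TestMagnitudeCurve:
    def test_C2_minus_C3_vanishes_for_coincident_pair(self, psf):
        grid = PixelGrid.sliding(700.0, 100.0, 2.0)
        curve = magnitude_curve([0.01, 10.0], "C2minusC3", grid, psf)
        assert curve.values[0] < 1e-4
        assert curve.values[0] < curve.values[1]

    def test_equal_magnitudes_below_threshold(self, psf):
        grid = PixelGrid.sliding(700.0, 100.0, 2.0)
        dys = np.arange(60.0, 111.0, 10.0)
        c1 = magnitude_curve(dys, "C1", grid, psf).values
        c2 = magnitude_curve(dys, "C2", grid, psf).values
        c3 = magnitude_curve(dys, "C3", grid, psf).values
        np.testing.assert_allclose(c1, c2, atol=1e-6)
        np.testing.assert_allclose(c2, c3, atol=1e-6)


class TestInflection:
    def test_cubic_analytic(self):
        x = np.arange(10.0, 201.0, 2.0)
        curve = ResolutionCurve(x, (x - 100.0) ** 3, "magnitude", "C1")
        assert inflection_point(curve, min_delta_y=10.0) == pytest.approx(
            100.0, abs=0.5)

    def test_requires_fine_uniform_grid(self):
        x = np.arange(10.0, 201.0, 10.0)
        curve = ResolutionCurve(x, x ** 2, "magnitude", "C1")
        with pytest.raises(ValueError):
            inflection_point(curve)


class TestMagnitudeRatio:
    def test_ratio_large_at_small_separation(self, psf):
        grid = PixelGrid.sliding(700.0, 100.0, 2.0)
        curve = magnitude_ratio_curve(np.array([10.0, 50.0]), grid, psf)
        assert curve.values[0] > 100
        assert curve.values[0] > curve.values[1]

    def test_loglog_linearity(self, psf):
        grid = PixelGrid.sliding(700.0, 100.0, 4.0)
        dys = np.arange(10.0, 151.0, 4.0)
        curve = magnitude_ratio_curve(dys, grid, psf)
        assert curve.meta["loglog_r2"] > 0.98
        assert curve.meta["loglog_slope"] < 0

    def test_noise_reduces_ratio(self, psf):
        grid = PixelGrid.sliding(700.0, 100.0, 4.0)
        dys = np.array([50.0, 80.0])
        clean = magnitude_ratio_curve(dys, grid, psf)
        noisy = magnitude_ratio_curve(dys, grid, psf, noise_peak_snr=16.0,
                                      n_realizations=20, rng_seed=3)
        assert np.all(noisy.values < clean.values)


class TestTwoPointThresholds:
    def test_diag_C2_resolves_just_above_118nm(self, psf, ideal_grid):
        curve = r_curve([112.0, 116.0, 120.0, 124.0], "C2", ideal_grid, psf)
        sep = first_resolved_separation(curve)
        assert sep in (120.0, 124.0)  # threshold 118 +- grid step

    def test_mean_image_resolves_just_above_172nm(self, psf, ideal_grid):
        curve = r_curve([166.0, 170.0, 174.0, 178.0], "meanimg",
                        ideal_grid, psf)
        sep = first_resolved_separation(curve)
        assert sep in (174.0, 178.0)
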