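"""Spatial-correlation chain: fluctuation, autocorrelation, radial average,
normalization/truncation, Whittle-Matern evaluation and fitting."""

import numpy as np
import pytest

from chromatex.correlation import (
    CorrelationCurve,
    CurveTruncationError,
    autocorrelation_2d,
    classify_correlation,
    density_fluctuation,
    fit_whittle_matern,
    normalize_and_truncate,
    rotational_average,
    whittle_matern,
)
from chromatex.io import Micrograph, NucleusMask

from .conftest import direct_autocorrelation, masked_fluctuation


def _micro(pixels, pixel_size=1.0, resolution=1.0):
    return Micrograph(pixels=np.asarray(pixels, float), pixel_size_nm=pixel_size,
                      resolution_nm=resolution)


def bessel_k0_series(x: float, terms: int = 40) -> float:
    """Independent series evaluation of K_0 for small-to-moderate x:
    K0(x) = -(ln(x/2) + gamma) I0(x) + sum_k (x^2/4)^k / (k!)^2 * H_k."""
    gamma = 0.57721566490153286060651209008240243
    q = x * x / 4.0
    i0 = 1.0
    s = 0.0
    term = 1.0
    harmonic = 0.0
    for k in range(1, terms + 1):
        term *= q / (k * k)
        harmonic += 1.0 / k
        i0 += term
        s += term * harmonic
    return -(np.log(x / 2.0) + gamma) * i0 + s


class TestDensityFluctuation:
    def test_constant_image_gives_zero(self):
        mask = NucleusMask(nucleus=np.ones((6, 6), bool))
        f = density_fluctuation(_micro(np.full((6, 6), 42.0)), mask)
        assert np.all(f.values == 0.0)

    def test_checkerboard_gives_plus_minus_c(self):
        c, m = 7.0, 100.0
        yy, xx = np.mgrid[:8, :8]
        pixels = m + c * np.where((yy + xx) % 2 == 0, 1.0, -1.0)
        mask = NucleusMask(nucleus=np.ones((8, 8), bool))
        f = density_fluctuation(_micro(pixels), mask)
        assert np.allclose(np.abs(f.values), c)

    def test_mean_zero_over_valid_pixels(self, rng):
        pixels = rng.random((20, 20)) * 200
        nucleus = rng.random((20, 20)) > 0.3
        f = density_fluctuation(_micro(pixels), NucleusMask(nucleus=nucleus))
        assert abs(f.values[f.valid].mean()) < 1e-10 * pixels.max()

    def test_nucleoli_excluded_from_mean(self):
        pixels = np.full((10, 10), 10.0)
        nucleolus = np.zeros((10, 10), bool)
        nucleolus[4:6, 4:6] = True
        pixels[nucleolus] = 1000.0
        mask = NucleusMask(nucleus=np.ones((10, 10), bool), nucleoli=[nucleolus])
        f = density_fluctuation(_micro(pixels), mask)
        assert np.all(f.values[f.valid] == 0.0)
        assert np.all(f.values[nucleolus] == 0.0)


class TestAutocorrelation:
    def test_white_noise_variance_at_zero_lag(self, rng):
        vals = rng.normal(size=(64, 64))
        valid = np.ones((64, 64), bool)
        f = masked_fluctuation(vals, valid)
        ac = autocorrelation_2d(f, min_pair_count=1)
        i0, j0 = 63, 63
        assert ac.B[i0, j0] == pytest.approx(f.values.var(), rel=1e-12)
        off = np.abs(ac.B[ac.defined])
        assert np.median(off[off > 0]) < 0.05  # uncorrelated beyond lag 0

    def test_point_reflection_symmetry(self, rng):
        vals = rng.normal(size=(12, 9))
        valid = rng.random((12, 9)) > 0.3
        ac = autocorrelation_2d(masked_fluctuation(vals, valid), min_pair_count=1)
        B = np.where(ac.defined, ac.B, 0.0)
        assert np.allclose(B, B[::-1, ::-1], atol=1e-12)
        assert np.array_equal(ac.counts, ac.counts[::-1, ::-1])

    def test_matches_direct_summation_with_arbitrary_mask(self, rng):
        vals = rng.normal(size=(8, 8))
        valid = rng.random((8, 8)) > 0.4
        f = masked_fluctuation(vals, valid)
        ac = autocorrelation_2d(f, min_pair_count=1)
        B_direct, counts_direct = direct_autocorrelation(f.values, valid)
        assert np.array_equal(ac.counts, counts_direct)
        sel = counts_direct > 0
        scale = np.abs(B_direct[sel]).max()
        assert np.allclose(ac.B[sel], B_direct[sel], atol=1e-9 * scale)

    def test_min_pair_count_masks_rim_lags(self, rng):
        vals = rng.normal(size=(10, 10))
        f = masked_fluctuation(vals, np.ones((10, 10), bool))
        ac = autocorrelation_2d(f, min_pair_count=16)
        assert not ac.defined[0, 0]  # corner lag realized by a single pair
        assert ac.defined[9, 9]


class TestRotationalAverage:
    def test_isotropic_input_reproduced(self):
        n = 33
        dy = np.arange(-(n // 2), n // 2 + 1)
        rr = np.hypot(dy[:, None], dy[None, :])
        B = np.exp(-rr / 5.0)
        from chromatex.correlation import Autocorrelation2D

        ac = Autocorrelation2D(B=B, counts=np.ones_like(B, dtype=int),
                               defined=np.ones_like(B, bool), dy=dy, dx=dy)
        curve = rotational_average(ac, pixel_size_nm=2.0)
        # within a one-pixel bin the exponential varies by ~e^{1/5}: allow
        # discretization error of that order
        want = np.exp(-(curve.r_nm / 2.0) / 5.0)
        assert np.allclose(curve.B, want, rtol=0.12)

    def test_equal_count_lags_average_plainly(self):
        from chromatex.correlation import Autocorrelation2D

        dy = np.array([-1, 0, 1])
        B = np.array([[np.nan, 1.0, np.nan], [3.0, 10.0, 5.0], [np.nan, 7.0, np.nan]])
        defined = ~np.isnan(B)
        ac = Autocorrelation2D(B=B, counts=np.where(defined, 4, 0), defined=defined,
                               dy=dy, dx=dy)
        curve = rotational_average(ac, pixel_size_nm=1.0)
        # the four unit-radius lags land in bin 1 with equal weights
        assert curve.B[1] == pytest.approx((1 + 3 + 5 + 7) / 4.0)

    def test_pair_count_weighting(self):
        from chromatex.correlation import Autocorrelation2D

        dy = np.array([0, 1])
        B = np.array([[0.0, 2.0], [4.0, np.nan]])
        defined = ~np.isnan(B)
        counts = np.array([[10, 1], [3, 0]])
        ac = Autocorrelation2D(B=B, counts=counts, defined=defined, dy=dy, dx=dy)
        curve = rotational_average(ac, pixel_size_nm=1.0)
        assert curve.B[1] == pytest.approx((2.0 * 1 + 4.0 * 3) / 4.0)


class TestNormalizeTruncate:
    def _exp_curve(self, l=20.0, dr=1.0, n=200):
        r = (np.arange(n) + 0.5) * dr
        return CorrelationCurve(r_nm=r, B=np.exp(-r / l), pixel_size_nm=dr)

    def test_normalized_at_r_min(self):
        nc = normalize_and_truncate(self._exp_curve(), resolution_nm=3.0)
        assert nc.r_min_nm == 3.0
        assert nc.B[0] == 1.0
        assert nc.B[-1] == pytest.approx(0.02)

    def test_exponential_r_max_closed_form(self):
        l = 20.0
        nc = normalize_and_truncate(self._exp_curve(l=l), resolution_nm=3.0)
        # exp(-(r_max - r_min)/l) = 0.02  =>  r_max = r_min + l ln 50
        want = 3.0 + l * np.log(50.0)
        assert nc.r_max_nm == pytest.approx(want, abs=1.0)

    def test_never_decaying_curve_is_skipped(self):
        r = np.arange(1.0, 50.0)
        curve = CorrelationCurve(r_nm=r, B=np.full(r.size, 0.5), pixel_size_nm=1.0)
        with pytest.raises(CurveTruncationError):
            normalize_and_truncate(curve, resolution_nm=2.0)

    def test_idempotence(self):
        nc = normalize_and_truncate(self._exp_curve(), resolution_nm=3.0)
        nc2 = normalize_and_truncate(nc, resolution_nm=3.0)
        assert np.allclose(nc2.r_nm, nc.r_nm)
        assert np.allclose(nc2.B, nc.B)
        assert nc2.r_max_nm == pytest.approx(nc.r_max_nm)

    def test_nonpositive_normalization_value_errors(self):
        r = np.arange(1.0, 30.0)
        curve = CorrelationCurve(r_nm=r, B=-np.exp(-r / 5.0), pixel_size_nm=1.0)
        with pytest.raises(ValueError):
            normalize_and_truncate(curve, resolution_nm=2.0)


class TestWhittleMatern:
    def test_exponential_member_closed_form(self):
        # nu = 1/2: K_{1/2}(x) = sqrt(pi/(2x)) e^{-x}  =>  B = A sqrt(pi/2) e^{-r/lc}
        r = np.array([0.3, 1.0, 2.5, 7.0])
        got = whittle_matern(r, D=4.0, lc=1.0, A=1.0)
        want = np.sqrt(np.pi / 2.0) * np.exp(-r)
        assert np.allclose(got, want, rtol=1e-12)

    def test_logarithmic_member_against_series(self):
        for x in (0.3, 1.0, 2.0):
            got = whittle_matern(np.array([x]), D=3.0, lc=1.0)[0]
            assert got == pytest.approx(bessel_k0_series(x), rel=1e-10)

    def test_zero_amplitude(self):
        assert np.all(whittle_matern(np.linspace(0.1, 5, 20), D=3.5, lc=2.0, A=0.0) == 0.0)

    def test_rejects_nonpositive_r_or_lc(self):
        with pytest.raises(ValueError):
            whittle_matern(np.array([0.0, 1.0]), D=3.0, lc=1.0)
        with pytest.raises(ValueError):
            whittle_matern(np.array([1.0]), D=3.0, lc=-1.0)

    def test_gaussian_like_limit_is_locally_flat(self):
        # second difference at small r, relative to B(r_min): near-flat as D -> 6
        r = np.array([0.05, 0.10, 0.15])
        def curvature(D):
            b = whittle_matern(r, D=D, lc=1.0)
            b = b / b[0]
            return abs(b[0] - 2 * b[1] + b[2])
        assert curvature(5.9) < 0.05 * curvature(3.1)


class TestFit:
    def _curve_from_wm(self, D, lc_frac, r_min=3.0, r_max=100.0, n=80):
        lc = lc_frac * r_max
        r = np.linspace(r_min, r_max, n)
        m = whittle_matern(r, D, lc)
        m0 = whittle_matern(np.array([r_min]), D, lc)[0]
        return CorrelationCurve(r_nm=r, B=m / m0, pixel_size_nm=1.0, r_min_nm=r_min,
                                r_max_nm=r_max, normalized=True)

    def test_on_grid_self_consistency(self):
        # lc grid point 30 of 60 over [0.66, 1]*r_max
        lc_frac = 0.66 + (1.0 - 0.66) * 30 / 59
        curve = self._curve_from_wm(D=3.2, lc_frac=lc_frac)
        fit = fit_whittle_matern(curve)
        assert fit.D == pytest.approx(3.2, abs=1e-9)
        assert fit.lc_nm == pytest.approx(lc_frac * 100.0, rel=1e-9)
        assert fit.r_squared > 1 - 1e-10

    def test_pure_exponential_identified_as_d4(self):
        r_min, r_max = 3.0, 100.0
        l = 0.8 * r_max
        r = np.linspace(r_min, r_max, 80)
        B = np.exp(-(r - r_min) / l)
        curve = CorrelationCurve(r_nm=r, B=B, pixel_size_nm=1.0, r_min_nm=r_min,
                                 r_max_nm=r_max, normalized=True)
        fit = fit_whittle_matern(curve)
        assert fit.D == pytest.approx(4.0, abs=0.05 + 1e-12)
        assert fit.correlation_class == "exponential"

    def test_r_squared_decreases_away_from_optimum(self):
        lc_frac = 0.66 + (1.0 - 0.66) * 30 / 59
        curve = self._curve_from_wm(D=3.2, lc_frac=lc_frac)
        r = curve.r_nm

        def r2_at(D, lc):
            m = whittle_matern(r, D, lc)
            m0 = whittle_matern(np.array([curve.r_min_nm]), D, lc)[0]
            resid = curve.B - m / m0
            ss_tot = np.sum((curve.B - curve.B.mean()) ** 2)
            return 1 - np.sum(resid**2) / ss_tot

        lc0 = lc_frac * 100.0
        for d_off in (0.2, 0.5, 1.0):
            assert r2_at(3.2 + d_off, lc0) < r2_at(3.2 + d_off - 0.1, lc0) + 1e-12
        for lc_off in (5.0, 10.0):
            assert r2_at(3.2, lc0 + lc_off) < r2_at(3.2, lc0 + lc_off - 2.5) + 1e-12

    def test_requires_normalized_curve_and_enough_samples(self):
        raw = CorrelationCurve(r_nm=np.arange(1.0, 10.0), B=np.exp(-np.arange(1.0, 10.0)),
                               pixel_size_nm=1.0)
        with pytest.raises(ValueError):
            fit_whittle_matern(raw)
        small = CorrelationCurve(r_nm=np.array([3.0, 4.0, 5.0]), B=np.array([1.0, 0.5, 0.2]),
                                 pixel_size_nm=1.0, r_min_nm=3.0, r_max_nm=5.0, normalized=True)
        with pytest.raises(ValueError):
            fit_whittle_matern(small)

    def test_refinement_does_not_worsen_fit(self):
        curve = self._curve_from_wm(D=3.27, lc_frac=0.81)
        coarse = fit_whittle_matern(curve)
        refined = fit_whittle_matern(curve, refine=True)
        assert refined.r_squared >= coarse.r_squared - 1e-12
        assert abs(refined.D - 3.27) <= abs(coarse.D - 3.27) + 1e-12


class TestClassify:
    @pytest.mark.parametrize("D,want", [
        (2.8, "power_law_fractal"),
        (3.5, "stretched_exponential"),
        (4.0, "exponential"),
        (4.024, "exponential"),     # within half a grid step of 4
        (4.5, "gaussian_like"),
        (2.0, "power_law_fractal"),
    ])
    def test_class_boundaries(self, D, want):
        assert classify_correlation(D) == want

    def test_monotone_in_d(self):
        order = ["power_law_fractal", "stretched_exponential", "exponential", "gaussian_like"]
        ranks = [order.index(classify_correlation(d)) for d in np.arange(2.0, 6.01, 0.05)]
        assert all(a <= b for a, b in zip(ranks, ranks[1:]))
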