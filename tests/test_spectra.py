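"""Grids, resampling, AUC normalization, luminance and chromaticity."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from substim import (
    CANONICAL_GRID,
    GridMismatchError,
    SpectralError,
    Spectrum,
    WavelengthGrid,
    cie1964_xy,
    luminance_of,
    normalize_auc,
    resample,
    scale_to_luminance,
)
from substim.spectra import KM_LM_PER_W
from substim.synth import gaussian_led


def riemann(values, step):
    """Independent left-Riemann integration oracle (explicit loop)."""
    total = 0.0
    for v in values:
        total += float(v) * step
    return total


class TestWavelengthGrid:
    @pytest.mark.parametrize(
        "start,stop,step",
        [(390, 780, -2), (390, 780, 0), (780, 390, 2), (390, 781, 2)],
    )
    def test_invalid_grids_rejected(self, start, stop, step):
        with pytest.raises(ValueError):
            WavelengthGrid(start, stop, step)

    def test_canonical_grid_is_390_780_2nm(self):
        assert CANONICAL_GRID.wavelengths[0] == 390
        assert CANONICAL_GRID.wavelengths[-1] == 780
        assert np.all(np.diff(CANONICAL_GRID.wavelengths) == 2)
        assert len(CANONICAL_GRID) == 196


class TestSpectrum:
    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(CANONICAL_GRID, np.ones(5))

    def test_negative_sensitivity_rejected_but_density_allowed(self):
        vals = -np.ones(len(CANONICAL_GRID))
        with pytest.raises(ValueError):
            Spectrum(CANONICAL_GRID, vals, "sensitivity")
        Spectrum(CANONICAL_GRID, vals, "optical_density")  # no raise

    def test_nonfinite_rejected(self):
        vals = np.ones(len(CANONICAL_GRID))
        vals[3] = np.nan
        with pytest.raises(ValueError):
            Spectrum(CANONICAL_GRID, vals)


class TestResample:
    def test_identity_on_same_grid(self):
        s = gaussian_led(520, 20)
        assert resample(s, CANONICAL_GRID) is s

    def test_1nm_input_matches_at_even_wavelengths(self):
        fine = WavelengthGrid(390, 780, 1)
        values = np.cos(fine.wavelengths / 50.0) ** 2
        s = Spectrum(fine, values)
        out = resample(s, CANONICAL_GRID)
        # direct index check: every canonical point exists in the 1 nm table
        idx = np.searchsorted(fine.wavelengths, CANONICAL_GRID.wavelengths)
        np.testing.assert_allclose(out.values, values[idx], rtol=0, atol=1e-12)

    def test_outside_source_support_is_zero(self):
        src = WavelengthGrid(400, 700, 2)
        s = Spectrum(src, np.ones(len(src)))
        out = resample(s, CANONICAL_GRID)
        wl = out.wavelengths
        assert np.all(out.values[wl < 400] == 0)
        assert np.all(out.values[wl > 700] == 0)
        assert np.all(out.values[(wl >= 400) & (wl <= 700)] == 1)

    def test_empty_overlap_raises(self):
        src = WavelengthGrid(200, 300, 2)
        s = Spectrum(src, np.ones(len(src)))
        with pytest.raises(SpectralError):
            resample(s, CANONICAL_GRID)

    def test_resample_is_idempotent(self):
        fine = WavelengthGrid(395, 775, 1)
        s = Spectrum(fine, np.linspace(0, 1, len(fine)))
        once = resample(s, CANONICAL_GRID)
        twice = resample(once, CANONICAL_GRID)
        np.testing.assert_array_equal(once.values, twice.values)

    def test_unit_preserved(self):
        fine = WavelengthGrid(390, 780, 1)
        s = Spectrum(fine, np.ones(len(fine)), "sensitivity")
        assert resample(s, CANONICAL_GRID).unit == "sensitivity"


class TestNormalizeAuc:
    def test_integral_is_one(self):
        rng = np.random.default_rng(7)
        s = Spectrum(CANONICAL_GRID, rng.uniform(0, 5, len(CANONICAL_GRID)))
        out = normalize_auc(s)
        assert riemann(out.values, 2.0) == pytest.approx(1.0, abs=1e-12)
        assert out.unit == "W/(m^2*sr*nm)"

    @settings(max_examples=30, derandomize=True, deadline=None)
    @given(k=st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariant(self, k):
        s = gaussian_led(520, 20)
        scaled = s.with_values(s.values * k)
        np.testing.assert_allclose(
            normalize_auc(scaled).values, normalize_auc(s).values, rtol=1e-12
        )

    def test_idempotent(self):
        s = gaussian_led(640, 25)
        out = normalize_auc(normalize_auc(s))
        np.testing.assert_allclose(out.values, normalize_auc(s).values, rtol=1e-14)

    def test_all_zero_raises(self):
        s = Spectrum(CANONICAL_GRID, np.zeros(len(CANONICAL_GRID)))
        with pytest.raises(SpectralError):
            normalize_auc(s)


class TestLuminance:
    def test_zero_spd_gives_zero(self, vlambda):
        s = Spectrum(CANONICAL_GRID, np.zeros(len(CANONICAL_GRID)), "W/(m^2*sr*nm)")
        assert luminance_of(s, vlambda) == 0

    def test_monochromatic_line_at_v_peak_gives_one_candela(self, vlambda):
        # a line carrying 1/683 W/(m^2 sr) where V(lambda) = 1 is 1 cd/m^2
        idx = int(np.argmax(vlambda.values))
        assert vlambda.values[idx] == 1.0
        vals = np.zeros(len(CANONICAL_GRID))
        vals[idx] = (1.0 / KM_LM_PER_W) / CANONICAL_GRID.step
        s = Spectrum(CANONICAL_GRID, vals, "W/(m^2*sr*nm)")
        assert luminance_of(s, vlambda) == pytest.approx(1.0, rel=1e-12)

    def test_matches_brute_force_summation(self, vlambda):
        s = gaussian_led(520, 20)
        expected = KM_LM_PER_W * riemann(s.values * vlambda.values, 2.0)
        assert luminance_of(s, vlambda) == pytest.approx(expected, rel=1e-12)

    def test_linearity(self, vlambda):
        rng = np.random.default_rng(3)
        a = Spectrum(CANONICAL_GRID, rng.uniform(0, 1, len(CANONICAL_GRID)))
        b = Spectrum(CANONICAL_GRID, rng.uniform(0, 1, len(CANONICAL_GRID)))
        combo = Spectrum(CANONICAL_GRID, 2.0 * a.values + 3.0 * b.values)
        assert luminance_of(combo, vlambda) == pytest.approx(
            2 * luminance_of(a, vlambda) + 3 * luminance_of(b, vlambda), rel=1e-12
        )

    def test_grid_mismatch_raises(self, vlambda):
        other = WavelengthGrid(390, 780, 5)
        s = Spectrum(other, np.ones(len(other)))
        with pytest.raises(GridMismatchError):
            luminance_of(s, vlambda)


class TestScaleToLuminance:
    def test_fixed_point(self, vlambda):
        s = gaussian_led(640, 25)
        L = luminance_of(s, vlambda)
        out = scale_to_luminance(s, L, vlambda)
        np.testing.assert_allclose(out.values, s.values, rtol=1e-12)

    def test_doubling_target_doubles_values(self, vlambda):
        s = gaussian_led(640, 25)
        one = scale_to_luminance(s, 40.0, vlambda)
        two = scale_to_luminance(s, 80.0, vlambda)
        np.testing.assert_allclose(two.values, 2 * one.values, rtol=1e-12)

    def test_red_primary_reaches_80_cd_m2(self, vlambda):
        red = gaussian_led(640, 20)
        out = scale_to_luminance(red, 80.0, vlambda)
        assert luminance_of(out, vlambda) == pytest.approx(80.0, rel=1e-12)

    @pytest.mark.parametrize("L", [0.0, -5.0])
    def test_nonpositive_luminance_rejected(self, vlambda, L):
        with pytest.raises(ValueError, match="zero luminance"):
            scale_to_luminance(gaussian_led(640, 20), L, vlambda)


class TestChromaticity:
    def test_equal_energy_hits_white_point(self, cmfs):
        s = Spectrum(CANONICAL_GRID, np.ones(len(CANONICAL_GRID)))
        xy = cie1964_xy(s, cmfs)
        assert xy.x == pytest.approx(1 / 3, abs=1e-3)
        assert xy.y == pytest.approx(1 / 3, abs=1e-3)

    def test_scale_invariant(self, cmfs):
        s = gaussian_led(600, 30)
        a = cie1964_xy(s, cmfs)
        b = cie1964_xy(s.with_values(s.values * 123.0), cmfs)
        assert (a.x, a.y) == pytest.approx((b.x, b.y), rel=1e-12)

    def test_matches_direct_tristimulus_summation(self, cmfs):
        s = gaussian_led(480, 25)
        X, Y, Z = (riemann(s.values * cmf.values, 2.0) for cmf in cmfs)
        xy = cie1964_xy(s, cmfs)
        assert xy.x == pytest.approx(X / (X + Y + Z), rel=1e-12)
        assert xy.y == pytest.approx(Y / (X + Y + Z), rel=1e-12)

    def test_all_zero_spd_raises(self, cmfs):
        s = Spectrum(CANONICAL_GRID, np.zeros(len(CANONICAL_GRID)))
        with pytest.raises(SpectralError):
            cie1964_xy(s, cmfs)
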