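"""Spectral machinery: finite-difference derivatives, TCFs, FFT spectra,
smoothing, Kramers–Kronig, band positions and red-shift thermochemistry."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from hydrashell import (
    DipoleSeries,
    autocorrelation,
    band_position,
    dipole_derivative,
    enthalpy_increase,
    gaussian_smooth,
    generate_harmonic_dipole,
    hbond_enthalpy,
    ir_spectrum,
    kramers_kronig_refractive_correction,
    red_shift,
    spectrum_from_tcf,
)
from hydrashell.core import Spectrum
from hydrashell.spectra import kk_refractive_index
from hydrashell.units import C_CM_PER_FS


def _series(values: np.ndarray, dt: float = 2.0) -> DipoleSeries:
    return DipoleSeries(times=np.arange(len(values)) * dt,
                        dipoles=values[:, None, None] * np.eye(3)[0])


class TestDerivative:
    def test_linear_ramp(self):
        t = np.arange(64) * 2.0
        s = _series(0.3 * t)
        d = dipole_derivative(s)
        np.testing.assert_allclose(d.dipoles[:, 0, 0], 0.3, atol=1e-12)

    def test_constant_series(self):
        d = dipole_derivative(_series(np.full(32, 1.85)))
        np.testing.assert_allclose(d.dipoles, 0.0, atol=1e-14)

    def test_cosine_derivative_amplitude(self):
        nu, amp, dt = 400.0, 1.5, 2.0
        s = generate_harmonic_dipole(nu, amp, dt, 4096)
        d = dipole_derivative(s)
        omega = 2.0 * np.pi * C_CM_PER_FS * nu
        expected = -amp * omega * np.sin(omega * s.times)
        np.testing.assert_allclose(d.dipoles[2:-2, 0, 0], expected[2:-2],
                                   atol=amp * omega**3 * dt**2 / 6 * 1.01)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dipole_derivative(_series(np.ones(2)))


class TestAutocorrelation:
    def test_white_noise_is_delta(self, rng):
        x = rng.standard_normal(100_000)
        tcf = autocorrelation(x, dt=1.0, max_lag=200.0)
        sigma = tcf.values[0] / np.sqrt(len(x))
        assert np.abs(tcf.values[1:]).max() < 5 * sigma

    def test_cosine_tcf_is_cosine(self):
        nu, dt = 1000.0, 2.0
        s = generate_harmonic_dipole(nu, 1.0, dt, 32768)
        tcf = autocorrelation(dipole_derivative(s).total()[:, 0], dt=dt,
                              max_lag=400.0)
        omega = 2.0 * np.pi * C_CM_PER_FS * nu
        expected = tcf.values[0] * np.cos(omega * tcf.lags)
        np.testing.assert_allclose(tcf.values, expected, atol=0.02 * tcf.values[0])

    def test_scaling_quadratic(self, rng):
        x = rng.standard_normal(4096)
        a = autocorrelation(x, dt=1.0).values
        b = autocorrelation(3.0 * x, dt=1.0).values
        np.testing.assert_allclose(b, 9.0 * a, rtol=1e-10)

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation(np.ones(100), dt=1.0, max_lag=150.0)

    def test_ensemble_average(self, rng):
        xs = [rng.standard_normal(2048) for _ in range(4)]
        mean_tcf = autocorrelation(xs, dt=1.0).values
        indiv = np.mean([autocorrelation(x, dt=1.0).values for x in xs], axis=0)
        np.testing.assert_allclose(mean_tcf, indiv, rtol=1e-12)


class TestSpectrum:
    def test_single_cosine_peak_position(self):
        s = generate_harmonic_dipole(1000.0, 1.0, 2.0, 8192)
        spec = ir_spectrum(s, smoothing=0.0, prefactor="none")
        peak = spec.wavenumbers[np.argmax(spec.values)]
        assert abs(peak - 1000.0) <= 2.0

    def test_two_mode_linearity(self):
        s1 = generate_harmonic_dipole(1000.0, 1.0, 2.0, 8192)
        s2 = generate_harmonic_dipole(3400.0, 1.0, 2.0, 8192,
                                      direction=np.array([0.0, 1.0, 0.0]))
        both = DipoleSeries(times=s1.times, dipoles=s1.dipoles + s2.dipoles)
        spec = ir_spectrum(both, smoothing=0.0, prefactor="none")
        for target in (1000.0, 3400.0):
            sel = np.abs(spec.wavenumbers - target) <= 10.0
            local = spec.wavenumbers[sel][np.argmax(spec.values[sel])]
            assert abs(local - target) <= 2.0
        # orthogonal modes → no cross term: spectrum is the sum of the parts
        a = ir_spectrum(s1, smoothing=0.0, prefactor="none").values
        b = ir_spectrum(s2, smoothing=0.0, prefactor="none").values
        np.testing.assert_allclose(spec.values, a + b, atol=1e-6 * max(a.max(), b.max()))

    def test_replicated_signal_same_peak(self):
        s = generate_harmonic_dipole(800.0, 1.0, 2.0, 2048)
        tiled = DipoleSeries(times=np.arange(3 * 2048) * 2.0,
                             dipoles=np.tile(s.dipoles, (3, 1, 1)))
        p1 = ir_spectrum(s, smoothing=0.0, prefactor="none")
        p2 = ir_spectrum(tiled, smoothing=0.0, prefactor="none")
        assert abs(p1.wavenumbers[np.argmax(p1.values)]
                   - p2.wavenumbers[np.argmax(p2.values)]) <= 2.0

    def test_zero_tcf_gives_zero_spectrum(self):
        from hydrashell.core import TCF

        tcf = TCF(lags=np.arange(64.0), values=np.zeros(64))
        spec = spectrum_from_tcf(tcf)
        assert np.all(spec.values == 0.0)

    def test_parseval_consistency(self):
        """Integral of the raw (window-free, prefactor-free) power spectrum
        over the full frequency axis equals the lag-0 TCF value."""
        s = generate_harmonic_dipole(1200.0, 0.8, 2.0, 8192)
        tcf = autocorrelation(dipole_derivative(s))
        raw = spectrum_from_tcf(tcf, prefactor="none", window="none",
                                resolution=None)
        dnu = raw.wavenumbers[1] - raw.wavenumbers[0]
        integral = (raw.values[0] + 2.0 * raw.values[1:-1].sum()
                    + raw.values[-1]) * dnu
        assert integral == pytest.approx(tcf.values[0], rel=1e-6)


class TestSmoothing:
    def test_delta_becomes_gaussian_of_width(self):
        grid = np.arange(0.0, 2000.0, 1.0)
        vals = np.zeros_like(grid)
        vals[1000] = 1.0
        sm = gaussian_smooth(Spectrum(grid, vals), width=20.0)
        # second moment about the peak equals the filter variance
        var = np.sum(sm.values * (grid - 1000.0) ** 2) / np.sum(sm.values)
        assert np.sqrt(var) == pytest.approx(20.0, rel=0.01)

    def test_constant_unchanged(self):
        grid = np.arange(0.0, 500.0, 1.0)
        sm = gaussian_smooth(Spectrum(grid, np.full_like(grid, 3.3)), width=20.0)
        np.testing.assert_allclose(sm.values, 3.3, rtol=1e-12)

    def test_doublet_resolved(self):
        grid = np.arange(0.0, 2000.0, 1.0)
        vals = np.zeros_like(grid)
        vals[900] = vals[1000] = 1.0
        sm = gaussian_smooth(Spectrum(grid, vals), width=20.0)
        for target in (900.0, 1000.0):
            sel = np.abs(grid - target) <= 40.0
            assert abs(grid[sel][np.argmax(sm.values[sel])] - target) <= 1.0

    @settings(max_examples=15, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_integral_preserved(self, seed):
        rng = np.random.default_rng(seed)
        grid = np.arange(0.0, 1000.0, 1.0)
        vals = rng.random(grid.size)
        sm = gaussian_smooth(Spectrum(grid, vals), width=20.0)
        assert sm.values.sum() == pytest.approx(vals.sum(), rel=1e-6)

    def test_width_below_spacing_rejected(self):
        grid = np.arange(0.0, 100.0, 2.0)
        with pytest.raises(ValueError):
            gaussian_smooth(Spectrum(grid, np.ones_like(grid)), width=1.0)


class TestKramersKronig:
    @staticmethod
    def _lorentz(nu, n_inf=1.3325, nu0=3400.0, gamma=150.0, strength=4e5):
        eps = n_inf**2 + strength / (nu0**2 - nu**2 - 1j * gamma * nu)
        nk = np.sqrt(eps)
        return nk.real, nk.imag

    def test_zero_absorption_is_identity(self):
        grid = np.arange(0.0, 4000.0, 2.0)
        spec = Spectrum(grid, np.zeros_like(grid))
        out = kramers_kronig_refractive_correction(spec)
        np.testing.assert_array_equal(out.values, spec.values)

    def test_lorentz_oscillator_index_recovered(self):
        nu = np.arange(1.0, 8000.0, 2.0)
        n_exact, k_exact = self._lorentz(nu)
        n_rec = kk_refractive_index(nu, k_exact, n_inf=1.3325)
        away = np.abs(nu - 3400.0) > 300.0
        rel = np.abs(n_rec[away] - n_exact[away]) / n_exact[away]
        assert rel.max() < 0.01

    def test_weak_absorption_linearity(self):
        nu = np.arange(1.0, 8000.0, 4.0)
        _, k = self._lorentz(nu, strength=1e4)
        d1 = kk_refractive_index(nu, k, 1.3325) - 1.3325
        d2 = kk_refractive_index(nu, 2.0 * k, 1.3325) - 1.3325
        np.testing.assert_allclose(d2, 2.0 * d1, rtol=1e-8, atol=1e-12)

    def test_edge_warning_flag(self):
        grid = np.arange(0.0, 1000.0, 1.0)
        vals = np.ones_like(grid)  # band not decayed at the edges
        out = kramers_kronig_refractive_correction(Spectrum(grid, vals))
        assert out.metadata.get("kk_edge_warning") is True


class TestBandsAndEnthalpy:
    @staticmethod
    def _band(center, width=60.0):
        grid = np.arange(2500.0, 4000.0, 1.0)
        vals = np.exp(-((grid - center) ** 2) / (2 * width**2))
        return Spectrum(grid, vals)

    def test_symmetric_band_position_is_center(self):
        assert band_position(self._band(3377.0), (3000.0, 3700.0)) == pytest.approx(
            3377.0, abs=0.01
        )

    def test_red_shift_of_bulk_band(self):
        pos = band_position(self._band(3377.0), (3000.0, 3700.0))
        assert red_shift(pos) == pytest.approx(283.0, abs=0.01)

    def test_position_invariant_under_scaling(self):
        s = self._band(3322.0)
        scaled = Spectrum(s.wavenumbers, 7.3 * s.values)
        assert band_position(s, (3000.0, 3700.0)) == band_position(
            scaled, (3000.0, 3700.0)
        )

    def test_centroid_mode(self):
        pos = band_position(self._band(3300.0), (3000.0, 3600.0), mode="centroid")
        assert pos == pytest.approx(3300.0, abs=1.0)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            band_position(self._band(3300.0), (5000.0, 6000.0))

    def test_enthalpy_increase_z_conformer(self):
        # 283 → 309 cm⁻¹: ~1 kJ/mol per bond
        dd = enthalpy_increase(283.0, 309.0)
        assert dd == pytest.approx(0.98, abs=0.01)
        assert round(dd) == 1

    def test_enthalpy_increase_e_conformer(self):
        # 283 → 338 cm⁻¹: ~2 kJ/mol per bond
        dd = enthalpy_increase(283.0, 338.0)
        assert dd == pytest.approx(2.03, abs=0.01)
        assert round(dd) == 2

    def test_equal_shifts_no_increase(self):
        assert enthalpy_increase(300.0, 300.0) == 0.0

    def test_negative_shift_rejected(self):
        with pytest.raises(ValueError):
            hbond_enthalpy(-5.0)
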