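"""Spatial spectral decompositions: Gaussian dipole density, radially
resolved cross spectra, carved-sphere dipoles, cutoff selection, and the
affected-water count."""

import numpy as np
import pytest

from hydrashell import (
    DipoleSeries,
    carve_sphere_dipole,
    count_waters_within,
    dipole_density,
    distance_dependent_spectrum,
    ir_spectrum,
    radially_resolved_spectrum,
    select_cutoff,
)
from hydrashell.spectra import cross_correlation, spectrum_from_tcf
from hydrashell.units import C_CM_PER_FS


def _coherent_series(n_steps=400, dt=2.0, cell=12.0, shell_phase=0.0):
    """Solute at the box center, 4 waters in a 2.8 Å shell, all oscillating
    at 1000 cm⁻¹ with a controlled phase relation."""
    t = np.arange(n_steps) * dt
    omega = 2.0 * np.pi * C_CM_PER_FS * 1000.0
    coms = np.broadcast_to(
        np.array([[6.0, 6.0, 6.0], [8.8, 6.0, 6.0], [6.0, 8.8, 6.0],
                  [6.0, 6.0, 8.8], [3.2, 6.0, 6.0]]),
        (n_steps, 5, 3),
    ).copy()
    dip = np.zeros((n_steps, 5, 3))
    dip[:, 0, 0] = 7.0 * np.cos(omega * t)
    for i in range(1, 5):
        dip[:, i, 0] = 1.8 * np.cos(omega * t + shell_phase)
    return DipoleSeries(times=t, dipoles=dip,
                        tags=["solute"] + ["water"] * 4, coms=coms, cell_edge=cell)


class TestDipoleDensity:
    def test_single_molecule_integral(self):
        fld = dipole_density(np.array([[1.0, 0.0, 0.0]]), np.array([[5.0, 5.0, 5.0]]),
                             cell_edge=10.0, spacing=0.5, sigma=1.0)
        np.testing.assert_allclose(fld.integral(), [1.0, 0.0, 0.0], atol=0.005)

    def test_corner_molecule_periodic_wrap(self):
        fld = dipole_density(np.array([[0.0, 2.0, 0.0]]), np.array([[0.1, 0.1, 9.9]]),
                             cell_edge=10.0, spacing=0.5, sigma=1.0)
        np.testing.assert_allclose(fld.integral(), [0.0, 2.0, 0.0], atol=0.01)

    def test_two_distant_molecules_additive(self):
        mus = np.array([[1.0, 0.0, 0.0], [0.0, -2.0, 0.0]])
        coms = np.array([[3.0, 3.0, 3.0], [9.0, 9.0, 9.0]])
        both = dipole_density(mus, coms, cell_edge=12.0, spacing=0.5, sigma=0.8)
        a = dipole_density(mus[:1], coms[:1], cell_edge=12.0, spacing=0.5, sigma=0.8)
        b = dipole_density(mus[1:], coms[1:], cell_edge=12.0, spacing=0.5, sigma=0.8)
        np.testing.assert_allclose(both.field, a.field + b.field, atol=1e-12)

    def test_sigma_below_spacing_rejected(self):
        with pytest.raises(ValueError):
            dipole_density(np.ones((1, 3)), np.ones((1, 3)), 10.0,
                           spacing=1.0, sigma=0.5)


class TestRadialSpectrum:
    def test_sum_rule_matches_direct_cross_spectrum(self):
        series = _coherent_series()
        rs = radially_resolved_spectrum(series, sigma=0.6, r_bin=0.1,
                                        smoothing=0.0, resolution=2.0,
                                        prefactor="none")
        radial_integral = rs.values.sum(axis=1) * 0.1
        mu_s_dot = np.gradient(series.dipoles[:, 0, :], series.times, axis=0)
        m_dot = np.gradient(series.total(), series.times, axis=0)
        tcf = cross_correlation(mu_s_dot, m_dot, dt=series.dt)
        direct = spectrum_from_tcf(tcf, prefactor="none", resolution=2.0)
        peak = np.argmax(np.abs(direct.values))
        np.testing.assert_allclose(radial_integral[peak], direct.values[peak],
                                   rtol=1e-4)

    def test_in_phase_shell_positive_band(self):
        series = _coherent_series(shell_phase=0.0)
        rs = radially_resolved_spectrum(series, sigma=0.6, r_bin=0.1,
                                        smoothing=0.0, resolution=2.0,
                                        prefactor="none")
        i = np.argmin(np.abs(rs.wavenumbers - 1000.0))
        j = np.argmin(np.abs(rs.radii - 2.8))
        assert rs.values[i, j] > 0.0

    def test_antiphase_shell_negative_band(self):
        series = _coherent_series(shell_phase=np.pi)
        rs = radially_resolved_spectrum(series, sigma=0.6, r_bin=0.1,
                                        smoothing=0.0, resolution=2.0,
                                        prefactor="none")
        i = np.argmin(np.abs(rs.wavenumbers - 1000.0))
        j = np.argmin(np.abs(rs.radii - 2.8))
        assert rs.values[i, j] < 0.0

    def test_zero_solvent_dipoles_confined_to_origin(self):
        series = _coherent_series()
        dip = series.dipoles.copy()
        dip[:, 1:, :] = 0.0
        quiet = DipoleSeries(times=series.times, dipoles=dip, tags=series.tags,
                             coms=series.coms, cell_edge=series.cell_edge)
        rs = radially_resolved_spectrum(quiet, sigma=0.4, r_bin=0.1,
                                        smoothing=0.0, resolution=2.0,
                                        prefactor="none")
        i = np.argmin(np.abs(rs.wavenumbers - 1000.0))
        near = rs.radii < 1.6        # within 4σ of the solute
        far = rs.radii > 2.4
        assert np.abs(rs.values[i, far]).max() < 1e-3 * np.abs(rs.values[i, near]).max()

    def test_missing_solute_rejected(self):
        series = _coherent_series()
        series.tags[0] = "water"
        with pytest.raises(ValueError, match="solute"):
            radially_resolved_spectrum(series)


class TestCarvedSphere:
    def test_logistic_midpoint_weight(self):
        series = _coherent_series()
        carved = carve_sphere_dipole(series, cutoff=2.8, width=0.25)
        np.testing.assert_allclose(carved.weights[0], 0.5, atol=1e-9)

    def test_all_far_solvent_reduces_to_solute(self):
        series = _coherent_series()
        carved = carve_sphere_dipole(series, cutoff=0.3, width=0.02)
        np.testing.assert_allclose(carved.mu, series.dipoles[:, 0, :], atol=1e-9)
        np.testing.assert_allclose(carved.norm, 1.0, atol=1e-9)

    def test_single_inside_equal_dipole_sqrt2(self):
        series = _coherent_series()
        dip = series.dipoles.copy()
        dip[:, 2:, :] = 0.0
        dip[:, 1, :] = dip[:, 0, :]
        coms = series.coms.copy()
        coms[:, 2:, :] = 1.0           # push the others far away
        s = DipoleSeries(times=series.times, dipoles=dip, tags=series.tags,
                         coms=coms, cell_edge=series.cell_edge)
        carved = carve_sphere_dipole(s, cutoff=6.0, width=0.05)
        np.testing.assert_allclose(
            carved.mu, np.sqrt(2.0) * series.dipoles[:, 0, :], atol=1e-6
        )

    def test_small_cutoff_limit_is_bare_solute_spectrum(self):
        series = _coherent_series()
        sp_c = distance_dependent_spectrum(series, cutoff=0.3, width=0.02,
                                           smoothing=0.0, prefactor="none")
        bare = DipoleSeries(times=series.times,
                            dipoles=series.dipoles[:, :1, :], tags=["solute"])
        sp_b = ir_spectrum(bare, smoothing=0.0, prefactor="none")
        np.testing.assert_allclose(sp_c.values, sp_b.values,
                                   atol=1e-9 * sp_b.values.max())

    def test_large_cutoff_limit_is_normalized_total(self):
        series = _coherent_series()
        sp_c = distance_dependent_spectrum(series, cutoff=5.9, width=0.01,
                                           smoothing=0.0, prefactor="none")
        total = DipoleSeries(times=series.times,
                             dipoles=series.total()[:, None, :] / np.sqrt(5.0),
                             tags=["all"])
        sp_t = ir_spectrum(total, smoothing=0.0, prefactor="none")
        np.testing.assert_allclose(sp_c.values, sp_t.values,
                                   rtol=1e-6, atol=1e-9 * sp_t.values.max())

    def test_solvent_free_system_cutoff_independent(self):
        t = np.arange(256) * 2.0
        omega = 2.0 * np.pi * C_CM_PER_FS * 800.0
        dip = np.zeros((256, 1, 3))
        dip[:, 0, 2] = 4.0 * np.cos(omega * t)
        coms = np.full((256, 1, 3), 5.0)
        s = DipoleSeries(times=t, dipoles=dip, tags=["solute"], coms=coms,
                         cell_edge=10.0)
        a = distance_dependent_spectrum(s, cutoff=1.0, smoothing=0.0)
        b = distance_dependent_spectrum(s, cutoff=4.5, smoothing=0.0)
        np.testing.assert_allclose(a.values, b.values, atol=1e-12)


class TestCutoffSelection:
    def test_analytic_logistic_inflection(self):
        rc = np.linspace(1.0, 7.0, 25)
        y = 1.0 + 2.0 / (1.0 + np.exp(-(rc - 3.7) / 0.3))
        assert select_cutoff(rc, y) == pytest.approx(3.7, abs=0.05)

    def test_mirrored_curve_same_inflection(self):
        rc = np.linspace(1.0, 7.0, 25)
        y = 1.0 + 2.0 / (1.0 + np.exp(-(rc - 4.0) / 0.3))
        up = select_cutoff(rc, y)
        down = select_cutoff(rc, y[::-1].copy())
        assert up == pytest.approx(2.0 * 4.0 - down, abs=0.05)

    def test_linear_curve_rejected(self):
        rc = np.linspace(1.0, 7.0, 13)
        with pytest.raises(ValueError, match="sigmoidal"):
            select_cutoff(rc, 0.5 * rc)

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError, match="8"):
            select_cutoff(np.arange(5.0), np.arange(5.0) ** 2)


class TestWaterCount:
    def test_fixed_waters_inside(self):
        series = _coherent_series()      # 4 waters at 2.8 Å
        soft, hard = count_waters_within(series, cutoff=4.0, width=0.1)
        assert soft == pytest.approx(4.0, abs=0.01)
        assert hard == 4.0

    def test_all_beyond_cutoff_zero(self):
        series = _coherent_series()
        soft, hard = count_waters_within(series, cutoff=0.5, width=0.05)
        assert soft == pytest.approx(0.0, abs=1e-6)
        assert hard == 0.0

    def test_uniform_solvent_volume_count(self, rng):
        """Sharp weights on an ideal-gas solvent give (4/3)πR³ρ."""
        n_t, n_solv, L, rc = 60, 220, 12.0, 4.0
        coms = np.empty((n_t, n_solv + 1, 3))
        coms[:, 0] = L / 2.0
        coms[:, 1:] = rng.uniform(0.0, L, size=(n_t, n_solv, 3))
        dip = np.zeros((n_t, n_solv + 1, 3))
        s = DipoleSeries(times=np.arange(n_t) * 2.0, dipoles=dip,
                         tags=["solute"] + ["water"] * n_solv,
                         coms=coms, cell_edge=L)
        soft, hard = count_waters_within(s, cutoff=rc, width=0.02)
        expected = 4.0 / 3.0 * np.pi * rc**3 * (n_solv / L**3)
        assert soft == pytest.approx(expected, rel=0.07)
        assert hard == pytest.approx(expected, rel=0.07)
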