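"""Wiener-Khinchin estimators, susceptibility routes and spectral algebra."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from protonspec.constants import (
    SPEED_OF_LIGHT_CM_FS,
    time_from_wavenumber,
    transfer_path_wavenumber,
    wavenumber_from_time,
)
from protonspec.spectra import (
    CorrelationFunction,
    DipoleSeries,
    Spectrum,
    autocorrelation_direct,
    autocorrelation_wk,
    current_from_dipole,
    current_spectrum,
    difference_spectrum,
    dipole_from_frames,
    scalar_power_spectrum,
    smooth_gaussian,
    subsystem_decomposition,
    susceptibility,
)
from protonspec.traj_io import AtomicFrame, Trajectory, TrajectoryMeta

META = TrajectoryMeta(temperature=300.0, volume=8000.0)


class TestAutocorrelation:
    @pytest.mark.parametrize("n,ncomp", [(256, 1), (1000, 3), (4096, 3)])
    def test_fft_equals_direct_lag_sum(self, rng, n, ncomp):
        x = rng.standard_normal((n, ncomp)).cumsum(axis=0)  # correlated input
        series = DipoleSeries(dt=0.5, vectors=x)
        corr = autocorrelation_wk(series)
        ref = autocorrelation_direct(series, len(corr.values))
        np.testing.assert_allclose(corr.values, ref, rtol=1e-10, atol=1e-8)

    def test_cosine_input_has_cosine_correlation(self):
        dt = 0.5
        t = np.arange(8192) * dt
        omega0 = 2 * np.pi / 64.0
        series = DipoleSeries(dt=dt, vectors=np.cos(omega0 * t))
        corr = autocorrelation_wk(series, max_lag_fraction=0.25)
        expected = 0.5 * np.cos(omega0 * corr.times)
        np.testing.assert_allclose(corr.values, expected, atol=0.02)

    def test_white_noise_decorrelates(self, rng):
        n = 20000
        series = DipoleSeries(dt=1.0, vectors=rng.standard_normal(n))
        corr = autocorrelation_wk(series, max_lag_fraction=0.1)
        bound = 5.0 / np.sqrt(n - np.arange(1, len(corr.values)))
        assert np.all(np.abs(corr.values[1:]) < bound)

    def test_c0_is_mean_square_fluctuation(self, rng):
        x = rng.standard_normal(5000) + 3.0
        corr = autocorrelation_wk(DipoleSeries(dt=1.0, vectors=x))
        assert corr.values[0] == pytest.approx(np.var(x), rel=1e-10)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            autocorrelation_wk(DipoleSeries(dt=1.0, vectors=np.array([1.0])))


class TestSusceptibility:
    def test_debye_closed_form(self):
        # analytic C(t) = C0 exp(-t/tau): chi'' = pref*(w/2) C0 tau/(1+w^2 tau^2)
        dt, n, tau, c0 = 1.0, 4096, 50.0, 2.0
        t = np.arange(n) * dt
        corr = CorrelationFunction(dt=dt, values=c0 * np.exp(-t / tau))
        spec = susceptibility(corr, META, n_dim=3)
        from protonspec.spectra import _si_prefactor

        pref = _si_prefactor(META, 3)
        omega_fs = 2 * np.pi * SPEED_OF_LIGHT_CM_FS * spec.wavenumbers
        omega_si = omega_fs * 1e15
        chi2_ref = pref * (omega_si / 2.0) * c0 * tau / (1 + omega_fs ** 2 * tau ** 2)
        expected = omega_si * chi2_ref
        sel = spec.wavenumbers < spec.wavenumbers[-1] / 4
        # relative agreement on the value; discretization error < 1 %
        np.testing.assert_allclose(spec.values[sel][5:], expected[sel][5:],
                                   rtol=0.01)

    def test_positivity_on_random_equilibrium_series(self, rng):
        series = DipoleSeries(dt=0.5, vectors=rng.standard_normal((4000, 3)))
        spec = susceptibility(autocorrelation_wk(series), META, 3)
        assert np.all(spec.values >= -1e-12 * np.abs(spec.values).max())

    def test_missing_volume_is_configuration_error(self, rng):
        series = DipoleSeries(dt=0.5, vectors=rng.standard_normal(128))
        with pytest.raises(ValueError, match="volume"):
            susceptibility(autocorrelation_wk(series),
                           TrajectoryMeta(temperature=300.0), 1)


class TestCurrentRoute:
    def test_routes_agree_for_band_limited_signal(self):
        dt, n = 0.5, 16384
        t = np.arange(n) * dt
        m = n // 10  # integer number of periods, below Nyquist/4
        omega0 = 2 * np.pi * m / (n * dt)
        p = DipoleSeries(dt=dt, vectors=np.sin(omega0 * t))
        s_pol = susceptibility(autocorrelation_wk(p), META, 1)
        s_cur = current_spectrum(current_from_dipole(p), META)
        nu0 = omega0 / (2 * np.pi * SPEED_OF_LIGHT_CM_FS)
        window = (nu0 * 0.9, nu0 * 1.1)
        a = np.trapezoid(*_band(s_pol, window))
        b = np.trapezoid(*_band(s_cur, window))
        assert b == pytest.approx(a, rel=0.01)

    def test_constant_dipole_gives_zero_spectrum(self):
        p = DipoleSeries(dt=0.5, vectors=np.full(512, 3.3))
        spec = current_spectrum(current_from_dipole(p), META)
        assert np.allclose(spec.values, 0.0)

    def test_linear_drift_stays_flat_at_low_frequency(self):
        # charged-subsystem drift: p linear in t diverges through the
        # polarization route but the current route sees a constant current
        dt, n = 0.5, 4096
        p = DipoleSeries(dt=dt, vectors=0.01 * np.arange(n) * dt)
        s_cur = current_spectrum(current_from_dipole(p), META)
        low = s_cur.values[s_cur.wavenumbers < 200]
        assert np.all(np.abs(low) <= 1e-6 * max(1.0, np.abs(s_cur.values).max()))

    def test_zero_frequency_excluded(self, rng):
        p = DipoleSeries(dt=0.5, vectors=rng.standard_normal(256))
        spec = current_spectrum(current_from_dipole(p), META)
        assert spec.wavenumbers[0] > 0


def _band(spec: Spectrum, window):
    sel = (spec.wavenumbers >= window[0]) & (spec.wavenumbers <= window[1])
    return spec.values[sel], spec.wavenumbers[sel]


class TestScalarPowerSpectrum:
    def test_cosine_peaks_at_its_frequency(self):
        dt, n = 0.5, 8192
        t = np.arange(n) * dt
        m = 200
        omega0 = 2 * np.pi * m / (n * dt)
        spec = scalar_power_spectrum(0.1 * np.cos(omega0 * t), dt, META)
        nu0 = omega0 / (2 * np.pi * SPEED_OF_LIGHT_CM_FS)
        assert spec.peak_wavenumber() == pytest.approx(nu0, rel=0.01)

    def test_zero_series_gives_zero_spectrum(self):
        spec = scalar_power_spectrum(np.zeros(512), 0.5, META)
        assert np.allclose(spec.values, 0.0)

    def test_surrogate_roo_peak_near_ground_truth(self, medium_run):
        spec = scalar_power_spectrum(
            medium_run.roo - medium_run.roo.mean(), medium_run.dt, META
        )
        peak = smooth_gaussian(spec, 50.0).peak_wavenumber(100, 1500)
        gt = wavenumber_from_time(medium_run.roo_period_fs)
        # anharmonic + damped: peak within the R band around the harmonic mode
        assert 0.5 * gt < peak < 1.8 * gt


class TestSmoothing:
    def _spec(self, n=601):
        nu = np.linspace(0, 1200, n)
        v = np.exp(-0.5 * ((nu - 400) / 30) ** 2)
        return Spectrum(wavenumbers=nu, values=v)

    def test_sigma_zero_is_identity(self):
        s = self._spec()
        np.testing.assert_array_equal(smooth_gaussian(s, 0.0).values, s.values)

    def test_delta_impulse_response(self):
        nu = np.arange(0.0, 1201.0, 2.0)
        v = np.zeros_like(nu)
        v[300] = 1.0
        out = smooth_gaussian(Spectrum(wavenumbers=nu, values=v), 50.0)
        ref = np.exp(-0.5 * ((nu - nu[300]) / 50.0) ** 2)
        ref /= ref.sum()
        np.testing.assert_allclose(out.values, ref, atol=1e-10)

    def test_integral_preserved_away_from_edges(self):
        s = self._spec()
        out = smooth_gaussian(s, 40.0)
        assert np.trapezoid(out.values, s.wavenumbers) == pytest.approx(
            np.trapezoid(s.values, s.wavenumbers), rel=1e-6
        )

    def test_negative_sigma_rejected(self):
        with pytest.raises(ValueError):
            smooth_gaussian(self._spec(), -1.0)


class TestDifferenceSpectrum:
    def test_identical_inputs_cancel(self):
        nu = np.linspace(10, 600, 100)
        s = Spectrum(wavenumbers=nu, values=np.sin(nu / 50) ** 2)
        out = difference_spectrum(s, s, c_w=55.5, c_w0=55.5)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-15)

    def test_offset_grids_interpolate(self):
        nu = np.linspace(10, 600, 300)
        f = lambda x: np.exp(-0.5 * ((x - 300) / 80) ** 2)  # noqa: E731
        sol = Spectrum(wavenumbers=nu, values=f(nu))
        wat = Spectrum(wavenumbers=nu + 1.0, values=f(nu + 1.0))
        out = difference_spectrum(sol, wat, c_w=50.0, c_w0=55.5)
        expected = f(nu) / 50.0 - f(nu) / 55.5
        np.testing.assert_allclose(out.values, expected, atol=1e-3)

    def test_concentration_scaling_collapses(self, rng):
        # one single-proton response scaled to three concentrations
        nu = np.linspace(10, 600, 200)
        proton = np.exp(-0.5 * ((nu - 200) / 60) ** 2)
        water = 0.5 + 0.3 * np.sin(nu / 90)
        curves = []
        for c_hcl in (2.0, 4.0, 6.0):
            c_w = 55.5 - 1.5 * c_hcl
            sol_vals = c_w * (water / 55.5 + c_hcl * proton)
            sol = Spectrum(wavenumbers=nu, values=sol_vals)
            wat = Spectrum(wavenumbers=nu, values=water)
            out = difference_spectrum(sol, wat, c_w=c_w, c_w0=55.5, c_hcl=c_hcl)
            curves.append(out.values)
        for c in curves[1:]:
            np.testing.assert_allclose(c, curves[0], atol=1e-12)

    def test_nonpositive_concentration_rejected(self):
        nu = np.linspace(10, 600, 50)
        s = Spectrum(wavenumbers=nu, values=np.ones_like(nu))
        with pytest.raises(ValueError):
            difference_spectrum(s, s, c_w=0.0, c_w0=55.5)


class TestSubsystemDecomposition:
    def test_zero_part_attributes_everything_to_remainder(self, rng):
        total = DipoleSeries(dt=0.5, vectors=rng.standard_normal((2048, 3)))
        part = DipoleSeries(dt=0.5, vectors=np.zeros((2048, 3)))
        s_part, s_rem = subsystem_decomposition(total, part, META)
        s_total = susceptibility(autocorrelation_wk(total), META, 3)
        np.testing.assert_allclose(s_part.values, 0.0,
                                   atol=1e-10 * s_total.values.max())
        np.testing.assert_allclose(s_rem.values, s_total.values, rtol=1e-10)

    def test_full_part_leaves_no_remainder(self, rng):
        x = rng.standard_normal((2048, 3))
        total = DipoleSeries(dt=0.5, vectors=x)
        part = DipoleSeries(dt=0.5, vectors=x.copy())
        s_part, s_rem = subsystem_decomposition(total, part, META)
        assert np.allclose(s_rem.values, 0.0)

    def test_independent_signals_have_vanishing_cross_terms(self, rng):
        n = 2 ** 15
        a = rng.standard_normal((n, 3))
        b = rng.standard_normal((n, 3))
        total = DipoleSeries(dt=0.5, vectors=a + b)
        part = DipoleSeries(dt=0.5, vectors=a)
        s_part, _ = subsystem_decomposition(total, part, META)
        s_auto = susceptibility(autocorrelation_wk(part), META, 3)
        # integrated weights agree within sampling noise
        w1 = np.trapezoid(s_part.values, s_part.wavenumbers)
        w2 = np.trapezoid(s_auto.values, s_auto.wavenumbers)
        assert w1 == pytest.approx(w2, rel=0.05)


class TestDipoleAssembly:
    def _traj(self, frames):
        return Trajectory(frames=frames, dt=2.0)

    def test_two_point_charges(self):
        fr = AtomicFrame(time=0.0, cell_edge=20.0, elements=("H", "Cl"),
                         positions=np.array([[1.0, 0, 0], [0.0, 0, 0]]))
        series = dipole_from_frames(
            self._traj([fr]), charge_map={"H": 1.0, "Cl": -1.0},
            subsystem=np.array([0, 1]), subsystem_label="pair",
        )
        np.testing.assert_allclose(series.vectors[0], [1.0, 0, 0], atol=1e-12)

    def test_neutral_atom_with_coincident_centers(self):
        # O nucleus (+6) with three coincident double-occupancy centers = -6
        fr = AtomicFrame(time=0.0, cell_edge=20.0, elements=("O",),
                         positions=np.array([[5.0, 5, 5]]),
                         wannier_positions=np.array([[5.0, 5, 5]] * 3))
        series = dipole_from_frames(self._traj([fr]))
        np.testing.assert_allclose(series.vectors[0], 0.0, atol=1e-12)

    def test_water_fixture_matches_hand_sum(self):
        pos = np.array([[5.0, 5, 5], [5.8, 5.5, 5], [5.8, 4.5, 5]])
        wc = np.array([[5.2, 5.1, 5], [5.2, 4.9, 5], [4.8, 5.2, 5], [4.8, 4.8, 5]])
        fr = AtomicFrame(time=0.0, cell_edge=20.0, elements=("O", "H", "H"),
                         positions=pos, wannier_positions=wc)
        series = dipole_from_frames(self._traj([fr]))
        hand = 6 * pos[0] + pos[1] + pos[2] - 2 * wc.sum(axis=0)
        np.testing.assert_allclose(series.vectors[0], hand, atol=1e-12)

    def test_full_system_without_wannier_is_error(self):
        fr = AtomicFrame(time=0.0, cell_edge=20.0, elements=("O",),
                         positions=np.array([[1.0, 1, 1]]))
        with pytest.raises(ValueError, match="Wannier"):
            dipole_from_frames(self._traj([fr]))


class TestConversions:
    def test_printed_shoulder_position(self):
        assert wavenumber_from_time(280.0) == pytest.approx(119.1, abs=0.05)
        assert round(wavenumber_from_time(280.0), -1) == 120  # 2 s.f.

    def test_printed_continuum_band_times(self):
        assert round(time_from_wavenumber(3000.0)) == 11
        assert round(time_from_wavenumber(2000.0)) == 17

    def test_transfer_path_factor_two(self):
        assert transfer_path_wavenumber(14.1) == pytest.approx(1183, abs=1)
        assert transfer_path_wavenumber(12.7) == pytest.approx(1313, abs=1)

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.floats(min_value=1e-3, max_value=1e6))
    def test_round_trip_identity(self, tau):
        assert wavenumber_from_time(tau) * tau * SPEED_OF_LIGHT_CM_FS == \
            pytest.approx(1.0, rel=1e-12)

    def test_nonpositive_rejected(self):
        for f in (wavenumber_from_time, time_from_wavenumber,
                  transfer_path_wavenumber):
            with pytest.raises(ValueError):
                f(0.0)


class TestParseval:
    def test_energy_conservation(self, rng):
        n = 4096
        dt = 0.5
        x = rng.standard_normal(n)
        xf = np.fft.rfft(x) * dt
        lhs = np.sum(x ** 2) * dt
        weights = np.full(len(xf), 2.0)
        weights[0] = 1.0
        if n % 2 == 0:
            weights[-1] = 1.0
        rhs = np.sum(weights * np.abs(xf) ** 2) / (n * dt)
        assert rhs == pytest.approx(lhs, rel=1e-8)
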