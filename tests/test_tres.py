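"""TRES reconstruction: Jacobian transform, spline maxima, tau summaries."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import agnckit as ak
from agnckit.tres import (SpectrumRecord, TRESDataset, average_decay_spectrum,
                          build_tres, fit_dataset, interpolate_spectrum,
                          to_wavelength, to_wavenumber, weighted_average_tau)


class TestJacobian:
    def test_hand_values(self):
        s = SpectrumRecord(axis=np.array([756.0, 1000.0]),
                           intensity=np.array([1.0, 1.0]))
        w = to_wavenumber(s)
        # axis ascending in wavenumber: 1000 nm -> 1e4 cm^-1 comes first
        assert w.axis[0] == pytest.approx(1.0e4)
        assert w.intensity[0] == pytest.approx(0.1)
        assert w.axis[1] == pytest.approx(13227.5, abs=0.05)

    def test_area_conservation(self):
        lam = np.linspace(600, 900, 4001)
        band = SpectrumRecord(axis=lam,
                              intensity=np.exp(-0.5 * ((lam - 756) / 40) ** 2))
        nu = to_wavenumber(band)
        assert abs(nu.area()) == pytest.approx(band.area(), rel=1e-4)

    def test_round_trip(self):
        lam = np.arange(650.0, 826.0, 5.0)
        s = SpectrumRecord(axis=lam, intensity=np.random.default_rng(0).uniform(1, 2, lam.size))
        back = to_wavelength(to_wavenumber(s))
        assert np.allclose(back.axis, s.axis, rtol=1e-8)
        assert np.allclose(back.intensity, s.intensity, rtol=1e-8)

    def test_nonpositive_wavelength_rejected(self):
        with pytest.raises(ValueError):
            to_wavenumber(SpectrumRecord(axis=np.array([-1.0, 500.0]),
                                         intensity=np.array([1.0, 1.0])))


class TestInterpolation:
    def test_parabola_vertex(self):
        x = np.arange(700.0, 801.0, 10.0)
        y = -(x - 756.0) ** 2 + 100.0
        res = interpolate_spectrum(SpectrumRecord(axis=x, intensity=y))
        assert res.max_position == pytest.approx(756.0, abs=0.001)

    def test_passes_through_data_points(self):
        lam = np.arange(650.0, 826.0, 5.0)
        y = np.exp(-0.5 * ((lam - 756) / 40) ** 2)
        res = interpolate_spectrum(SpectrumRecord(axis=lam, intensity=y))
        dense = res.spectrum
        for xi, yi in zip(lam, y):
            j = int(np.argmin(np.abs(dense.axis - xi)))
            assert abs(dense.intensity[j] - yi) <= 1e-10 * max(abs(yi), 1.0)

    def test_gaussian_band_maximum(self):
        lam = np.arange(650.0, 826.0, 5.0)
        y = np.exp(-0.5 * ((lam - 756.0) / 40.0) ** 2)
        res = interpolate_spectrum(SpectrumRecord(axis=lam, intensity=y))
        assert res.max_position_nm == pytest.approx(756.0, abs=0.1)

    def test_few_points_fallback(self):
        res = interpolate_spectrum(SpectrumRecord(
            axis=np.array([740.0, 756.0, 770.0]),
            intensity=np.array([0.5, 1.0, 0.6])))
        assert 740.0 < res.max_position_nm < 770.0

    def test_single_point_degenerate(self):
        res = interpolate_spectrum(SpectrumRecord(axis=np.array([700.0]),
                                                  intensity=np.array([2.0])))
        assert res.max_position == 700.0


class TestBuildTres:
    def test_zero_shift_slices_identical(self, tres_flat):
        cfg, ds = tres_flat
        spectra = build_tres(ds, [1.0, 4.0, 10.0], mode="fitted", n_exp=1,
                             normalize=True)
        for sp in spectra[1:]:
            assert np.allclose(sp.intensity, spectra[0].intensity, atol=0.03)

    def test_relaxation_trajectory_recovered(self):
        """Slice maxima follow the planted nu(t) = nu_inf + dnu e^(-t/tau)."""
        cfg = ak.RelaxationSimConfig(
            total_shift=500.0, relaxation_time=2.0,
            decay=ak.DecaySimConfig(n_channels=2048, channel_width=0.032,
                                    total_counts=1e6, seed=3))
        ds = ak.simulate_tres(cfg, noiseless=True)
        ic = cfg.decay.irf_center
        slices = [0.5, 1.0, 2.0, 4.0, 8.0]
        spectra = build_tres(ds, [ic + t for t in slices], mode="raw")
        tol = cfg.band_width / 50.0
        for t, sp in zip(slices, spectra):
            got = interpolate_spectrum(to_wavenumber(sp)).max_position
            assert got == pytest.approx(cfg.band_center(t), abs=tol)

    def test_single_wavelength_degenerate(self):
        cfg = ak.DecaySimConfig(n_channels=512, total_counts=1e4, seed=1)
        d = ak.simulate_decay(cfg)
        ds = TRESDataset(wavelengths=np.array([756.0]), decays=[d])
        spectra = build_tres(ds, [2.0], mode="raw")
        assert spectra[0].axis.size == 1

    def test_slice_outside_axis_rejected(self, tres_flat):
        _, ds = tres_flat
        with pytest.raises(ValueError):
            build_tres(ds, [1e5], mode="raw")

    def test_detector_correction_applied(self, tres_flat):
        _, ds = tres_flat
        lam = ds.wavelengths
        flat = build_tres(ds, [2.0], mode="raw")[0]
        ds_corr = TRESDataset(wavelengths=lam, decays=ds.decays,
                              steady_state=ds.steady_state, irf=ds.irf,
                              detector_correction=(lam, np.full(lam.size, 2.0)))
        doubled = build_tres(ds_corr, [2.0], mode="raw")[0]
        assert np.allclose(doubled.intensity, 2.0 * flat.intensity)


class TestTauSummaries:
    def test_flat_series_for_relaxation_free_data(self, tres_flat):
        """Without spectral relaxation the average decay time is flat
        across the emission band."""
        _, ds = tres_flat
        fits = fit_dataset(ds, n_exp=1, mode="individual")
        series = average_decay_spectrum(ds, fits)
        assert len(series) == ds.wavelengths.size
        rel_spread = series.tau_ns.std() / series.tau_ns.mean()
        assert rel_spread < 0.02
        assert series.tau_ns.mean() == pytest.approx(3.42, rel=0.02)

    def test_weighted_tau_hand_arithmetic(self):
        # I_ss = (1, 3), tau = (2, 4) -> 3.5 ns
        lam = np.array([700.0, 750.0])
        d = ak.simulate_decay(ak.DecaySimConfig(n_channels=256, total_counts=1e4))
        ds = TRESDataset(wavelengths=lam, decays=[d, d],
                         steady_state=(lam, np.array([1.0, 3.0])))
        fits = [_fake_fit(2.0), _fake_fit(4.0)]
        assert weighted_average_tau(ds, fits) == pytest.approx(3.5)

    def test_weighted_tau_uniform_weights_is_mean(self):
        lam = np.array([700.0, 750.0, 800.0])
        d = ak.simulate_decay(ak.DecaySimConfig(n_channels=256, total_counts=1e4))
        ds = TRESDataset(wavelengths=lam, decays=[d] * 3,
                         steady_state=(lam, np.ones(3)))
        fits = [_fake_fit(t) for t in (1.0, 2.0, 6.0)]
        assert weighted_average_tau(ds, fits) == pytest.approx(3.0)

    def test_weighted_tau_rescaling_invariance(self):
        lam = np.array([700.0, 750.0])
        d = ak.simulate_decay(ak.DecaySimConfig(n_channels=256, total_counts=1e4))
        fits = [_fake_fit(2.0), _fake_fit(4.0)]
        base = weighted_average_tau(
            TRESDataset(wavelengths=lam, decays=[d, d],
                        steady_state=(lam, np.array([1.0, 3.0]))), fits)
        scaled = weighted_average_tau(
            TRESDataset(wavelengths=lam, decays=[d, d],
                        steady_state=(lam, np.array([10.0, 30.0]))), fits)
        assert scaled == pytest.approx(base, rel=1e-12)

    def test_unconverged_fits_excluded(self):
        lam = np.array([700.0, 750.0])
        d = ak.simulate_decay(ak.DecaySimConfig(n_channels=256, total_counts=1e4))
        ds = TRESDataset(wavelengths=lam, decays=[d, d])
        bad = _fake_fit(2.0)
        bad.converged = False
        series = average_decay_spectrum(ds, [bad, _fake_fit(3.0)])
        assert len(series) == 1
        assert series.tau_ns.iloc[0] == pytest.approx(3.0)


def _fake_fit(tau):
    """Minimal converged mono-exponential FitResult for summary math."""
    from agnckit.fitting import DecayFitResults
    return DecayFitResults(
        method="tail", n_exp=1, amplitudes=np.array([1.0]),
        lifetimes=np.array([tau]), scatter_fraction=0.0, background=0.0,
        irf_shift=0.0, reduced_chi2=1.0, fitted=np.zeros(1),
        window=slice(0, 1), converged=True)


@given(st.floats(300.0, 1500.0))
@settings(max_examples=50, deadline=None)
def test_wavenumber_wavelength_involution(lam):
    nu = 1.0e7 / lam
    assert 1.0e7 / nu == pytest.approx(lam, rel=1e-12)
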