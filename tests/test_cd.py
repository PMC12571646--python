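"""CD population equation, spectral maximum, melt fits, difference spectra."""

import numpy as np
import pytest

from ppiihelix import (
    CDMelt,
    CDSpectrum,
    MeltTrace,
    default_cd_basis,
    difference_spectrum,
    fit_melt,
    linearity_check,
    ppii_population,
    simulate_cd_series,
    theta_max,
)
from ppiihelix.cd import mre_from_millidegrees


def _gauss_spectrum(peak_nm=212.0, amp=1000.0, lo=200.0, hi=260.0, temperature=0.0):
    wl = np.arange(lo, hi + 1.0)
    mre = amp * np.exp(-(((wl - peak_nm) / 8.0) ** 2))
    return CDSpectrum(wavelengths=wl, mre=mre, temperature=temperature)


class TestThetaMax:
    def test_single_peak_found(self):
        wl, th = theta_max(_gauss_spectrum(amp=1000.0))
        assert (wl, th) == (212.0, 1000.0)

    def test_tie_breaks_to_lower_wavelength(self):
        wl = np.arange(200.0, 261.0)
        spec = CDSpectrum(wavelengths=wl, mre=np.zeros_like(wl))
        assert theta_max(spec) == (210.0, 0.0)

    def test_coverage_precondition(self):
        wl = np.arange(220.0, 261.0)
        spec = CDSpectrum(wavelengths=wl, mre=np.zeros_like(wl))
        with pytest.raises(ValueError):
            theta_max(spec, lo=210.0, hi=230.0)


class TestPopulationEquation:
    @pytest.mark.parametrize(
        "theta, percent",
        [(1000.0, 43.329), (1600.0, 47.292), (-5560.0, 0.0), (9580.0, 100.0)],
    )
    def test_calibration_values(self, theta, percent):
        assert ppii_population(theta) == pytest.approx(percent, abs=5e-3)

    def test_affine_and_increasing(self):
        thetas = np.array([-5560.0, -1000.0, 0.0, 1000.0, 9580.0])
        pops = np.array([ppii_population(t) for t in thetas])
        assert np.all(np.diff(pops) > 0)
        slopes = np.diff(pops) / np.diff(thetas)
        assert np.allclose(slopes, 100.0 / 15140.0)

    def test_out_of_range_warns_but_is_not_clamped(self):
        with pytest.warns(UserWarning):
            pop = ppii_population(12000.0)
        assert pop > 100.0
        with pytest.warns(UserWarning):
            assert ppii_population(-7000.0) < 0.0


class TestMeltFit:
    @pytest.mark.parametrize(
        "intercept, slope",
        [(835.0, -10.8), (13200.0, -15.8)],
        ids=["weak-PPII-band", "strong-PPII-band"],
    )
    def test_noiseless_linear_recovery(self, intercept, slope):
        T = np.arange(0.0, 66.0, 5.0)
        trace = MeltTrace(temperatures=T, mre=intercept + slope * T)
        fit = fit_melt(trace)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert abs(fit.r) == pytest.approx(1.0, abs=1e-9)
        assert fit.slope < 0  # signal loss on heating

    def test_flat_trace_is_degenerate_not_error(self):
        trace = MeltTrace(temperatures=np.array([0.0, 10.0, 20.0]), mre=np.full(3, 5.0))
        fit = fit_melt(trace)
        assert fit.degenerate and fit.slope == 0.0 and fit.r == 0.0

    def test_identical_temperatures_rejected(self):
        trace = MeltTrace(temperatures=np.full(3, 25.0), mre=np.array([1.0, 2.0, 3.0]))
        with pytest.raises(ValueError):
            fit_melt(trace)

    def test_scaling_equivariance(self):
        T = np.arange(0.0, 66.0, 5.0)
        rng = np.random.default_rng(2)
        y = 500.0 - 7.0 * T + rng.normal(0, 20.0, T.size)
        f1 = fit_melt(MeltTrace(temperatures=T, mre=y))
        f2 = fit_melt(MeltTrace(temperatures=T, mre=3.5 * y))
        assert f2.intercept == pytest.approx(3.5 * f1.intercept, rel=1e-12)
        assert f2.slope == pytest.approx(3.5 * f1.slope, rel=1e-12)
        assert f2.r == pytest.approx(f1.r, abs=1e-12)

    def test_model_results_summary(self):
        T = np.arange(0.0, 66.0, 5.0)
        res = CDMelt(MeltTrace(temperatures=T, mre=835.0 - 10.8 * T)).fit()
        assert res.params["intercept"] == pytest.approx(835.0, rel=1e-9)
        assert "R = " in res.summary()
        assert res.population_at(0.0) == pytest.approx(ppii_population(835.0))


class TestDifferenceSpectrum:
    def test_self_difference_is_zero(self):
        s = _gauss_spectrum()
        d = difference_spectrum(s, s)
        assert np.allclose(d.mre, 0.0)

    def test_antisymmetry(self):
        a = _gauss_spectrum(amp=900.0, temperature=5.0)
        b = _gauss_spectrum(amp=300.0, temperature=65.0)
        assert np.allclose(
            difference_spectrum(a, b).mre, -difference_spectrum(b, a).mre
        )

    def test_grid_mismatch_policy(self):
        a = _gauss_spectrum()
        wl = a.wavelengths + 0.5
        b = CDSpectrum(wavelengths=wl, mre=np.zeros_like(wl))
        with pytest.raises(ValueError):
            difference_spectrum(a, b)
        with pytest.raises(ValueError):  # disjoint even after intersection
            difference_spectrum(a, b, on_mismatch="intersect")

    def test_two_state_mixture_recovers_ppii_basis_shape(self):
        spectra, _ = simulate_cd_series(pop0=43.3, slope_pop=-0.09)
        basis = default_cd_basis()
        diff = difference_spectrum(spectra[0], spectra[-1])
        cos = np.dot(diff.mre, basis.ppii) / (
            np.linalg.norm(diff.mre) * np.linalg.norm(basis.ppii)
        )
        assert cos > 0.999
        assert np.all(diff.mre[diff.wavelengths == 212.0] > 0)


class TestLinearity:
    def test_exact_linear_trace_passes(self):
        T = np.arange(0.0, 66.0, 5.0)
        rep = linearity_check(MeltTrace(temperatures=T, mre=835.0 - 10.8 * T))
        assert rep.is_linear and rep.longest_sign_run == 0

    def test_sigmoidal_cooperative_melt_fails(self):
        T = np.arange(0.0, 66.0, 2.5)
        mre = 1000.0 / (1.0 + np.exp((T - 30.0) / 3.0))  # steep two-state melt
        rep = linearity_check(MeltTrace(temperatures=T, mre=mre))
        assert not rep.is_linear
        assert rep.runs_pvalue < 0.01  # systematic residual sign runs

    def test_noisy_linear_trace_passes(self):
        T = np.arange(0.0, 66.0, 5.0)
        rng = np.random.default_rng(31)
        amplitude = 10.8 * 65.0
        mre = 835.0 - 10.8 * T + rng.normal(0.0, 0.05 * amplitude, T.size)
        rep = linearity_check(MeltTrace(temperatures=T, mre=mre))
        assert rep.is_linear

    def test_population_linear_in_temperature_for_linear_mixture(self):
        spectra, _ = simulate_cd_series(pop0=43.3, slope_pop=-0.09)
        temps = np.array([s.temperature for s in spectra])
        pops = np.array([ppii_population(theta_max(s)[1]) for s in spectra])
        fit = np.polyfit(temps, pops, 1)
        resid = pops - np.polyval(fit, temps)
        assert np.max(np.abs(resid)) < 1e-9 * np.max(np.abs(pops))
        assert fit[0] == pytest.approx(-0.09, rel=1e-9)


class TestMREConversion:
    def test_per_bond_normalisation(self):
        # 100 mdeg, MRW = 1300/13 bonds = 100 -> 100*100/(10*0.1*1) = 10000
        assert mre_from_millidegrees(100.0, 1300.0, 14, 0.1, 1.0) == pytest.approx(10000.0)

    def test_invalid_cell_rejected(self):
        with pytest.raises(ValueError):
            mre_from_millidegrees(1.0, 1300.0, 14, 0.0, 1.0)
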