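import numpy as np
import pytest

from qustex.data_model import RFFrame
from qustex.simulate import ReferencePhantomSpec
from qustex.spectral import (
    NP_PER_DB,
    AttenuationModel,
    BSCCurve,
    ScattererEstimate,
    SpectrumEstimate,
    compute_bsc,
    compute_window_spectrum,
    estimate_ace_spectral_difference,
    fit_gaussian_form_factor,
    fit_linear_spectrum,
    theoretical_bsc,
)
from oracles import least_squares_line

BAND = (3.0, 8.0)


def make_spectrum(freq, power_db, r_cm=1.0, dz_cm=0.2, n_lines=1):
    return SpectrumEstimate(freq_mhz=freq, power_db=power_db,
                            n_lines_averaged=n_lines, window_geometry=(r_cm, dz_cm))


class TestWindowSpectrum:
    def test_tone_peaks_at_its_frequency(self, small_geometry):
        g = small_geometry
        t = np.arange(g.axial_samples) / g.sampling_frequency
        tone = np.sin(2 * np.pi * 5e6 * t)
        frame = RFFrame(np.tile(tone[:, None], (1, g.n_lines)), g)
        spec = compute_window_spectrum(frame, axial=(0, 256), lines=(0, 4))
        peak = spec.freq_mhz[np.argmax(spec.power_db)]
        assert peak == pytest.approx(5.0, abs=0.1)

    def test_identical_lines_average_is_single_line(self, small_geometry, rng):
        g = small_geometry
        line = rng.standard_normal(g.axial_samples)
        frame = RFFrame(np.tile(line[:, None], (1, g.n_lines)), g)
        one = compute_window_spectrum(frame, axial=(10, 138), lines=(0, 1))
        many = compute_window_spectrum(frame, axial=(10, 138), lines=(0, 8))
        np.testing.assert_allclose(many.power_db, one.power_db, atol=1e-9)
        assert many.n_lines_averaged == 8

    def test_window_geometry(self, small_geometry, rng):
        g = small_geometry
        frame = RFFrame(rng.standard_normal((g.axial_samples, g.n_lines)), g)
        spec = compute_window_spectrum(frame, axial=(100, 200), lines=(0, 4))
        assert spec.window_geometry[0] == pytest.approx(100 * g.axial_step * 100)
        assert spec.window_geometry[1] == pytest.approx(100 * g.axial_step * 100)

    def test_averaging_reduces_periodogram_variance(self, small_geometry, rng):
        g = small_geometry
        n_real = 200
        win = (0, 128)
        vals_1, vals_17 = [], []
        for _ in range(n_real):
            frame = RFFrame(rng.standard_normal((g.axial_samples, g.n_lines)), g)
            s1 = compute_window_spectrum(frame, axial=win, lines=(0, 1))
            s17 = compute_window_spectrum(frame, axial=win, lines=(0, 17))
            k = np.searchsorted(s1.freq_mhz, 5.0)
            vals_1.append(10 ** (s1.power_db[k] / 10))
            vals_17.append(10 ** (s17.power_db[k] / 10))
        ratio = np.var(vals_17) / np.var(vals_1)
        assert ratio == pytest.approx(1 / 17, rel=0.5)

    def test_too_short_window_rejected(self, small_geometry, rng):
        g = small_geometry
        frame = RFFrame(rng.standard_normal((g.axial_samples, g.n_lines)), g)
        with pytest.raises(ValueError, match="4 axial samples"):
            compute_window_spectrum(frame, axial=(0, 3), lines=(0, 2))


class TestSpectralDifferenceACE:
    def _spectra_pair(self, delta_beta, n_depths=6, beta_ref=0.786):
        """Forward-construct dB spectra whose log-ratio slope encodes delta_beta."""
        freq = np.linspace(1.0, 10.0, 40)
        sample, reference = [], []
        for k in range(n_depths):
            z = 1.0 + 0.3 * k  # cm to window center (dz=0 for exactness)
            ref_db = -0.5 * freq  # arbitrary common shape
            # two-way power loss: 2 * beta * f dB per cm of one-way depth
            diff_db = -2.0 * delta_beta * freq * z
            sample.append(make_spectrum(freq, ref_db + diff_db, r_cm=z, dz_cm=0.0))
            reference.append(make_spectrum(freq, ref_db, r_cm=z, dz_cm=0.0))
        return sample, reference

    def test_exact_recovery(self):
        sample, reference = self._spectra_pair(delta_beta=0.214)
        ace = estimate_ace_spectral_difference(sample, reference, BAND)
        assert ace.slope_db_cm_mhz == pytest.approx(1.000, abs=1e-9)
        assert ace.provenance == "estimated_tumour"

    def test_zero_difference_returns_reference_slope(self):
        sample, reference = self._spectra_pair(delta_beta=0.0)
        ace = estimate_ace_spectral_difference(sample, reference, BAND)
        assert ace.slope_db_cm_mhz == pytest.approx(0.786, abs=1e-12)

    def test_negative_excess_attenuation(self):
        sample, reference = self._spectra_pair(delta_beta=-0.2)
        ace = estimate_ace_spectral_difference(sample, reference, BAND)
        assert ace.slope_db_cm_mhz == pytest.approx(0.586, abs=1e-9)

    def test_too_few_depths_rejected(self):
        sample, reference = self._spectra_pair(0.1, n_depths=2)
        with pytest.raises(ValueError, match="3 depth"):
            estimate_ace_spectral_difference(sample, reference, BAND)

    def test_mismatched_grids_rejected(self):
        sample, reference = self._spectra_pair(0.1)
        bad = [make_spectrum(r.freq_mhz * 1.01, r.power_db,
                             r.window_geometry[0], r.window_geometry[1])
               for r in reference]
        with pytest.raises(ValueError, match="grid"):
            estimate_ace_spectral_difference(sample, bad, BAND)


def flat_phantom(freq, sigma=1.0, slope=0.786):
    return ReferencePhantomSpec(attenuation_slope=slope, speed_of_sound=1540.0,
                                bsc_curve=(freq, np.full_like(freq, sigma)))


class TestComputeBSC:
    freq = np.linspace(2.0, 9.0, 50)

    def test_identity(self):
        """Matched spectra and attenuations return sigma_r exactly."""
        phantom = flat_phantom(self.freq, sigma=0.37)
        s = make_spectrum(self.freq, -3.3 * self.freq + 7)
        bsc = compute_bsc(s, s, phantom, AttenuationModel(0.786))
        np.testing.assert_allclose(bsc.sigma, 0.37, rtol=1e-12)

    def test_linearity_in_power_ratio(self):
        phantom = flat_phantom(self.freq)
        ref = make_spectrum(self.freq, np.zeros_like(self.freq))
        sample = make_spectrum(self.freq, np.full_like(self.freq, 10 * np.log10(2.0)))
        bsc = compute_bsc(sample, ref, phantom, AttenuationModel(0.786))
        np.testing.assert_allclose(bsc.sigma, 2.0, rtol=1e-12)

    def test_attenuation_correction_exponent(self):
        # alpha_m - alpha_r = 0.1 Np/cm at every in-band f, R + dz/2 = 2 cm
        # -> correction factor e^{4*0.1*2} = e^0.8
        phantom = flat_phantom(self.freq, slope=0.5)
        spec = make_spectrum(self.freq, np.zeros_like(self.freq), r_cm=1.9, dz_cm=0.2)
        # slope difference chosen so (beta_m - beta_r) * f * NP_PER_DB = 0.1 at f = 5 MHz
        beta_m = 0.5 + 0.1 / NP_PER_DB / 5.0
        bsc = compute_bsc(spec, spec, phantom, AttenuationModel(beta_m),
                          alpha_r=AttenuationModel(0.5))
        k = np.searchsorted(bsc.freq_mhz, 5.0)
        assert bsc.sigma[k] == pytest.approx(np.exp(0.8), rel=1e-6)

    def test_nonpositive_reference_curve_rejected(self):
        phantom = flat_phantom(self.freq)
        phantom.bsc_curve = (self.freq, np.zeros_like(self.freq))
        s = make_spectrum(self.freq, np.zeros_like(self.freq))
        with pytest.raises(ValueError, match="positive"):
            compute_bsc(s, s, phantom, AttenuationModel(1.0))


class TestLinearFit:
    freq = np.linspace(1.0, 10.0, 91)

    def test_exact_linear_input(self):
        fit = fit_linear_spectrum(make_spectrum(self.freq, 2 * self.freq + 3), BAND)
        assert fit.ss_db_mhz == pytest.approx(2.0)
        assert fit.si_db == pytest.approx(3.0)
        assert fit.mbf_db == pytest.approx(14.0)  # f_c = 5.5
        assert fit.mbf_db == pytest.approx(fit.ss_db_mhz * fit.f_center_mhz + fit.si_db)

    def test_constant_spectrum(self):
        fit = fit_linear_spectrum(make_spectrum(self.freq, np.full_like(self.freq, 7.0)), BAND)
        assert fit.ss_db_mhz == pytest.approx(0.0, abs=1e-12)
        assert fit.si_db == pytest.approx(7.0)
        assert fit.mbf_db == pytest.approx(7.0)

    def test_matches_normal_equations_oracle(self, rng):
        y = 1.7 * self.freq - 4.0 + rng.normal(0, 2.0, self.freq.size)
        fit = fit_linear_spectrum(make_spectrum(self.freq, y), BAND)
        sel = (self.freq >= 3.0) & (self.freq <= 8.0)
        slope, intercept = least_squares_line(self.freq[sel], y[sel])
        assert fit.ss_db_mhz == pytest.approx(slope, abs=1e-10)
        assert fit.si_db == pytest.approx(intercept, abs=1e-10)

    def test_band_outside_grid_rejected(self):
        with pytest.raises(ValueError):
            fit_linear_spectrum(make_spectrum(self.freq, self.freq), (20.0, 30.0))


class TestGaussianFormFactorFit:
    freq = np.linspace(3.0, 8.0, 64)

    def test_noiseless_round_trip(self):
        sigma = theoretical_bsc(self.freq, asd_um=50.0, aac_db=37.0)
        est = fit_gaussian_form_factor(BSCCurve(self.freq, sigma))
        assert est.asd_um == pytest.approx(50.0, abs=1.0)  # grid resolution
        assert est.aac_db == pytest.approx(37.0, abs=0.01)
        assert est.fit_residual < 1e-6
        assert not est.low_confidence

    def test_f4_limit_selects_smallest_candidate(self):
        sigma = (self.freq * 1e6) ** 4 * 1e-20  # F == 1 (Rayleigh regime)
        est = fit_gaussian_form_factor(BSCCurve(self.freq, sigma),
                                       asd_grid_um=np.arange(10.0, 201.0, 1.0))
        assert est.asd_um == 10.0

    def test_deterministic_for_fixed_grid(self):
        sigma = theoretical_bsc(self.freq, asd_um=88.0, aac_db=20.0)
        a = fit_gaussian_form_factor(BSCCurve(self.freq, sigma))
        b = fit_gaussian_form_factor(BSCCurve(self.freq, sigma))
        assert (a.asd_um, a.aac_db) == (b.asd_um, b.aac_db)

    def test_noisy_recovery_median_error(self, rng):
        errs = []
        for _ in range(50):
            sigma_db = 10 * np.log10(theoretical_bsc(self.freq, 50.0, 30.0))
            noisy = 10 ** ((sigma_db + rng.normal(0, 0.5, self.freq.size)) / 10)
            est = fit_gaussian_form_factor(BSCCurve(self.freq, noisy))
            errs.append(abs(est.asd_um - 50.0) / 50.0)
        assert np.median(errs) < 0.10

    def test_scatterer_estimate_type(self):
        sigma = theoretical_bsc(self.freq, asd_um=50.0, aac_db=37.0)
        est = fit_gaussian_form_factor(BSCCurve(self.freq, sigma))
        assert isinstance(est, ScattererEstimate)
        assert est.fit_residual >= 0
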