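"""Spectral estimation: windowed power spectra, reference-phantom
normalization, attenuation estimation/correction, backscatter coefficients,
linear spectral fits (MBF/SS/SI) and Gaussian form-factor fits (ASD/AAC).

Unit conventions
----------------
* frequencies on spectrum grids are in MHz; power is 10*log10 of the
  line-averaged periodogram (dB, arbitrary reference);
* attenuation slopes are user-facing in dB/cm/MHz with a linear frequency
  dependence alpha(f) = beta * f; the backscatter correction exponent works
  in Np/cm (amplitude nepers, 1 dB = 0.11513 Np);
* backscatter coefficients are in 1/(cm*sr) when the reference curve is
  absolute; otherwise in the reference curve's relative units;
* the scatterer model works in CGS internally (f in Hz, radii in cm,
  concentrations in 1/cm^3).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

NP_PER_DB = np.log(10.0) / 20.0  # 0.11512925: amplitude nepers per dB
GAUSS_FF_CONST = 0.827  # spherical Gaussian form factor: F = exp(-0.827 k^2 a^2)

__all__ = [
    "SpectrumEstimate",
    "AttenuationModel",
    "BSCCurve",
    "LinearSpectralFit",
    "ScattererEstimate",
    "compute_window_spectrum",
    "estimate_ace_spectral_difference",
    "compute_bsc",
    "fit_linear_spectrum",
    "fit_gaussian_form_factor",
    "theoretical_bsc",
    "gaussian_form_factor",
]


@dataclass
class SpectrumEstimate:
    """Line-averaged windowed power spectrum in dB on a uniform MHz grid."""

    freq_mhz: np.ndarray
    power_db: np.ndarray
    n_lines_averaged: int
    window_geometry: tuple[float, float]  # (R: cm to proximal window edge, dz: cm window length)

    def __post_init__(self) -> None:
        self.freq_mhz = np.asarray(self.freq_mhz, dtype=float)
        self.power_db = np.asarray(self.power_db, dtype=float)
        if self.freq_mhz.shape != self.power_db.shape:
            raise ValueError("freq and power grids differ in shape")
        if np.any(np.diff(self.freq_mhz) <= 0):
            raise ValueError("frequency grid must be strictly increasing")
        if self.n_lines_averaged < 1:
            raise ValueError("n_lines_averaged must be >= 1")

    def band_slice(self, band_mhz: tuple[float, float]) -> np.ndarray:
        lo, hi = band_mhz
        sel = (self.freq_mhz >= lo) & (self.freq_mhz <= hi)
        return sel


@dataclass(frozen=True)
class AttenuationModel:
    """Linear-in-frequency attenuation alpha(f) = slope * f.

    ``slope_db_cm_mhz`` is the per-MHz slope in dB/cm/MHz; ``provenance``
    records how it was obtained (assumed intervening tissue, estimated
    tumour ACE, or the reference phantom value).
    """

    slope_db_cm_mhz: float
    provenance: str = "assumed_intervening"

    def __post_init__(self) -> None:
        if self.slope_db_cm_mhz < 0:
            raise ValueError("attenuation slope must be non-negative")

    def np_per_cm(self, freq_mhz) -> np.ndarray:
        """alpha(f) in amplitude Np/cm at frequencies in MHz."""
        return self.slope_db_cm_mhz * np.asarray(freq_mhz, dtype=float) * NP_PER_DB


@dataclass
class BSCCurve:
    """Attenuation-corrected backscatter coefficient on a MHz grid."""

    freq_mhz: np.ndarray
    sigma: np.ndarray

    def __post_init__(self) -> None:
        self.freq_mhz = np.asarray(self.freq_mhz, dtype=float)
        self.sigma = np.asarray(self.sigma, dtype=float)
        if self.freq_mhz.shape != self.sigma.shape:
            raise ValueError("freq grid and sigma differ in shape")
        if np.any(self.sigma <= 0):
            raise ValueError("backscatter coefficient must be strictly positive")

    @property
    def sigma_db(self) -> np.ndarray:
        return 10.0 * np.log10(self.sigma)


@dataclass(frozen=True)
class LinearSpectralFit:
    """Line-fit parameters of the dB spectrum over the analysis band."""

    mbf_db: float   # fitted line at the band-center frequency
    ss_db_mhz: float  # slope
    si_db: float    # 0-MHz intercept
    f_center_mhz: float


@dataclass(frozen=True)
class ScattererEstimate:
    """Gaussian form-factor fit: scatterer diameter and acoustic concentration."""

    asd_um: float      # average scatterer diameter, 2 * a_eff
    aac_db: float      # 10*log10(n_z / 1 cm^-3)
    fit_residual: float  # mean squared dB error over the band
    low_confidence: bool = False


# ---------------------------------------------------------------------------
# power spectra
# ---------------------------------------------------------------------------

def _next_pow2(n: int) -> int:
    return 1 << int(np.ceil(np.log2(max(n, 1))))


def mean_periodogram(segments: np.ndarray, nfft: int) -> np.ndarray:
    """Hanning-tapered mean periodogram of ``segments`` (..., n_lines, n_samples).

    Returns the average squared-magnitude rFFT over the lines axis.
    """
    n = segments.shape[-1]
    taper = np.hanning(n)
    spec = np.fft.rfft(segments * taper, n=nfft, axis=-1)
    return np.mean(np.abs(spec) ** 2, axis=-2)


def compute_window_spectrum(frame, axial: tuple[int, int], lines: tuple[int, int],
                            nfft: int | None = None) -> SpectrumEstimate:
    """Averaged power spectrum of a rectangular RF window.

    Each scan line's gated segment (half-open index ranges) is
    Hanning-tapered, zero-padded to ``nfft`` (default: next power of two
    >= 4x the window length), Fourier transformed and squared; the
    periodograms are averaged across lines and returned in dB.
    """
    i0, i1 = axial
    j0, j1 = lines
    geom = frame.geometry
    if not (0 <= i0 < i1 <= geom.axial_samples and 0 <= j0 < j1 <= geom.n_lines):
        raise ValueError(f"window axial={axial}, lines={lines} exceeds frame bounds")
    if i1 - i0 < 4:
        raise ValueError("window must span at least 4 axial samples")
    if nfft is None:
        nfft = _next_pow2(4 * (i1 - i0))
    seg = frame.samples[i0:i1, j0:j1].T  # (n_lines, n_samples)
    power = mean_periodogram(seg, nfft)
    freq_mhz = np.fft.rfftfreq(nfft, d=1.0 / geom.sampling_frequency) / 1e6
    with np.errstate(divide="ignore"):
        power_db = 10.0 * np.log10(power)
    r_cm = geom.axial_depth_m(i0) * 100.0
    dz_cm = (i1 - i0) * geom.axial_step * 100.0
    return SpectrumEstimate(freq_mhz=freq_mhz, power_db=power_db,
                            n_lines_averaged=j1 - j0, window_geometry=(r_cm, dz_cm))


# ---------------------------------------------------------------------------
# spectral-difference attenuation estimation
# ---------------------------------------------------------------------------

def estimate_ace_spectral_difference(sample_spectra, reference_spectra,
                                     band_mhz: tuple[float, float],
                                     reference_slope_db_cm_mhz: float = 0.786,
                                     ) -> AttenuationModel:
    """Local attenuation slope via the spectral-difference method.

    For each in-band frequency the slope of the sample-minus-reference dB
    power versus window-center depth (cm, one-way) is fitted; assuming a
    linear frequency dependence of attenuation, per-frequency slopes
    ``m(f)`` are then regressed through the origin against f. Since the
    received power declines by ``2 * beta * f`` dB per cm of one-way depth
    (round-trip travel), the excess slope is ``delta_beta = -m_f / 2`` and
    ACE = reference slope + delta_beta.
    """
    if len(sample_spectra) < 3:
        raise ValueError("spectral-difference ACE needs at least 3 depth positions")
    if len(sample_spectra) != len(reference_spectra):
        raise ValueError("sample and reference depth grids differ in length")
    f0 = sample_spectra[0].freq_mhz
    depths = []
    diffs = []
    for sm, sr in zip(sample_spectra, reference_spectra):
        if sm.freq_mhz.shape != f0.shape or not np.allclose(sm.freq_mhz, f0):
            raise ValueError("sample spectra must share one frequency grid")
        if sr.freq_mhz.shape != f0.shape or not np.allclose(sr.freq_mhz, f0):
            raise ValueError("reference spectra frequency grid does not match sample grid")
        if not np.allclose(sm.window_geometry, sr.window_geometry):
            raise ValueError("sample and reference depth grids do not match")
        r_cm, dz_cm = sm.window_geometry
        depths.append(r_cm + dz_cm / 2.0)
        diffs.append(sm.power_db - sr.power_db)
    z = np.asarray(depths)
    if np.ptp(z) <= 0:
        raise ValueError("depth positions must not be all identical")
    d = np.vstack(diffs)  # (n_depths, n_freq)
    sel = (f0 >= band_mhz[0]) & (f0 <= band_mhz[1])
    if sel.sum() < 2:
        raise ValueError("analysis band contains fewer than 2 frequency bins")
    zc = z - z.mean()
    m_f = zc @ d[:, sel] / np.dot(zc, zc)  # per-frequency dB/cm slope
    f = f0[sel]
    slope_per_mhz = float(np.dot(f, m_f) / np.dot(f, f))  # m(f) = slope * f, through origin
    delta_beta = -slope_per_mhz / 2.0
    return AttenuationModel(slope_db_cm_mhz=max(reference_slope_db_cm_mhz + delta_beta, 0.0),
                            provenance="estimated_tumour")


# ---------------------------------------------------------------------------
# backscatter coefficient (reference-phantom normalization)
# ---------------------------------------------------------------------------

def compute_bsc(sample: SpectrumEstimate, reference: SpectrumEstimate,
                phantom, alpha_m: AttenuationModel,
                alpha_r: AttenuationModel | None = None) -> BSCCurve:
    """Reference-phantom normalized, attenuation-corrected backscatter.

    sigma_m(f) = sigma_r(f) * |S_m|^2/|S_r|^2 * exp{4 (alpha_m - alpha_r) (R + dz/2)}
    with alpha in amplitude Np/cm and R, dz in cm (two-way travel gives the
    factor 4 on the neper scale).
    """
    if sample.freq_mhz.shape != reference.freq_mhz.shape or \
            not np.allclose(sample.freq_mhz, reference.freq_mhz):
        raise ValueError("sample and reference spectra must share one frequency grid")
    if not np.allclose(sample.window_geometry, reference.window_geometry):
        raise ValueError("sample and reference spectra must share window geometry (R, dz)")
    if alpha_r is None:
        alpha_r = AttenuationModel(phantom.attenuation_slope, provenance="reference")
    f_ref, sigma_ref = phantom.bsc_curve
    f_ref = np.asarray(f_ref, dtype=float)
    sigma_ref = np.asarray(sigma_ref, dtype=float)
    if np.any(sigma_ref <= 0):
        raise ValueError("reference backscatter curve must be strictly positive")
    lo = max(sample.freq_mhz[0], f_ref[0])
    hi = min(sample.freq_mhz[-1], f_ref[-1])
    sel = (sample.freq_mhz >= lo) & (sample.freq_mhz <= hi)
    f = sample.freq_mhz[sel]
    sigma_r = np.interp(f, f_ref, sigma_ref)
    ratio = 10.0 ** ((sample.power_db[sel] - reference.power_db[sel]) / 10.0)
    r_cm, dz_cm = sample.window_geometry
    path = r_cm + dz_cm / 2.0
    corr = np.exp(4.0 * (alpha_m.np_per_cm(f) - alpha_r.np_per_cm(f)) * path)
    return BSCCurve(freq_mhz=f, sigma=sigma_r * ratio * corr)


# ---------------------------------------------------------------------------
# linear spectral fit (MBF / SS / SI)
# ---------------------------------------------------------------------------

def fit_linear_spectrum(spectrum, band_mhz: tuple[float, float]) -> LinearSpectralFit:
    """Ordinary least-squares line fit of the dB spectrum over the band.

    Accepts a :class:`SpectrumEstimate` (uses ``power_db``) or a
    :class:`BSCCurve` (uses ``10*log10 sigma``). SS is the slope in
    dB/MHz, SI the 0-MHz intercept, and MBF the fitted line evaluated at
    the band midpoint.
    """
    if isinstance(spectrum, BSCCurve):
        f, y = spectrum.freq_mhz, spectrum.sigma_db
    else:
        f, y = spectrum.freq_mhz, spectrum.power_db
    sel = (f >= band_mhz[0]) & (f <= band_mhz[1])
    if sel.sum() < 3:
        raise ValueError("analysis band must contain at least 3 frequency points")
    ss, si = np.polyfit(f[sel], y[sel], 1)
    fc = 0.5 * (band_mhz[0] + band_mhz[1])
    return LinearSpectralFit(mbf_db=float(ss * fc + si), ss_db_mhz=float(ss),
                             si_db=float(si), f_center_mhz=fc)


# ---------------------------------------------------------------------------
# Gaussian form-factor fit (ASD / AAC)
# ---------------------------------------------------------------------------

def gaussian_form_factor(freq_mhz, a_eff_cm: float, c_l_m_s: float = 1540.0) -> np.ndarray:
    """Spherical Gaussian form factor F(f, a_eff) = exp(-0.827 k^2 a_eff^2)."""
    k = 2.0 * np.pi * np.asarray(freq_mhz, dtype=float) * 1e6 / (c_l_m_s * 100.0)
    return np.exp(-GAUSS_FF_CONST * (k * a_eff_cm) ** 2)


def theoretical_bsc(freq_mhz, asd_um: float, aac_db: float, c_l_m_s: float = 1540.0) -> np.ndarray:
    """Forward Gaussian-scatterer backscatter model.

    sigma(f) = C f^4 a_eff^6 n_z F(f, a_eff) with C = pi^2 / (36 c_l^4),
    F = exp(-0.827 k^2 a_eff^2), k = 2 pi f / c_l, evaluated in CGS units
    (f in Hz, a_eff in cm, n_z in 1/cm^3); result in 1/(cm*sr).
    """
    f_hz = np.asarray(freq_mhz, dtype=float) * 1e6
    c_cm = c_l_m_s * 100.0
    a_cm = (asd_um / 2.0) * 1e-4
    n_z = 10.0 ** (aac_db / 10.0)
    k = 2.0 * np.pi * f_hz / c_cm
    const = np.pi ** 2 / (36.0 * c_cm ** 4)
    return const * f_hz ** 4 * a_cm ** 6 * n_z * np.exp(-GAUSS_FF_CONST * (k * a_cm) ** 2)


def _model_db_matrix(freq_mhz: np.ndarray, asd_grid_um: np.ndarray,
                     c_l_m_s: float) -> np.ndarray:
    """dB forward model for unit concentration: rows = ASD candidates."""
    f_hz = freq_mhz * 1e6
    c_cm = c_l_m_s * 100.0
    a_cm = (asd_grid_um[:, None] / 2.0) * 1e-4
    k = 2.0 * np.pi * f_hz[None, :] / c_cm
    const = np.pi ** 2 / (36.0 * c_cm ** 4)
    ln10 = np.log(10.0)
    return (10.0 * np.log10(const * f_hz ** 4)[None, :]
            + 60.0 * np.log10(a_cm)
            - 10.0 / ln10 * GAUSS_FF_CONST * (k * a_cm) ** 2)


def fit_gaussian_form_factor_batch(sigma_db: np.ndarray, freq_mhz: np.ndarray,
                                   c_l_m_s: float = 1540.0,
                                   asd_grid_um: np.ndarray | None = None):
    """Vectorized Gaussian form-factor fit for many dB BSC curves at once.

    ``sigma_db`` has shape (n_curves, n_freq). For each ASD candidate the
    optimal concentration is the closed-form mean dB offset; the candidate
    minimizing the mean squared dB error wins. Returns arrays
    (asd_um, aac_db, residual, low_confidence).
    """
    if asd_grid_um is None:
        asd_grid_um = np.arange(10.0, 201.0, 1.0)
    asd_grid_um = np.asarray(asd_grid_um, dtype=float)
    if asd_grid_um.size == 0:
        raise ValueError("ASD search grid is empty")
    sigma_db = np.atleast_2d(np.asarray(sigma_db, dtype=float))
    model = _model_db_matrix(np.asarray(freq_mhz, dtype=float), asd_grid_um, c_l_m_s)
    nf = sigma_db.shape[1]
    mc = model - model.mean(axis=1, keepdims=True)          # (n_asd, nf)
    bc = sigma_db - sigma_db.mean(axis=1, keepdims=True)    # (n_curves, nf)
    # mse[w, a] = mean((bc[w] - mc[a])^2)
    mse = (np.mean(bc ** 2, axis=1)[:, None]
           + np.mean(mc ** 2, axis=1)[None, :]
           - 2.0 / nf * bc @ mc.T)
    best = np.argmin(mse, axis=1)
    residual = np.maximum(mse[np.arange(len(best)), best], 0.0)
    offsets = sigma_db.mean(axis=1) - model.mean(axis=1)[best]
    flat = np.ptp(mse, axis=1) < 1e-9
    return asd_grid_um[best], offsets, residual, flat


def fit_gaussian_form_factor(bsc: BSCCurve, c_l_m_s: float = 1540.0,
                             asd_grid_um: np.ndarray | None = None,
                             band_mhz: tuple[float, float] | None = None) -> ScattererEstimate:
    """Grid-search Gaussian form-factor fit of one measured BSC curve.

    Minimizes the mean squared error between ``10*log10 sigma_m`` and the
    dB forward model over the band; for each candidate effective radius
    the optimal concentration has the closed form ``10^(mean offset/10)``.
    A flat objective is flagged low-confidence rather than raised.
    """
    f, y = bsc.freq_mhz, bsc.sigma_db
    if band_mhz is not None:
        sel = (f >= band_mhz[0]) & (f <= band_mhz[1])
        f, y = f[sel], y[sel]
    if f.size < 2:
        raise ValueError("need at least 2 in-band frequencies for the form-factor fit")
    asd, aac, res, flat = fit_gaussian_form_factor_batch(
        y[None, :], f, c_l_m_s=c_l_m_s, asd_grid_um=asd_grid_um)
    return ScattererEstimate(asd_um=float(asd[0]), aac_db=float(aac[0]),
                             fit_residual=float(res[0]), low_confidence=bool(flat[0]))
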