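"""Sliding-window QUS parametric images and core/margin region summaries.

A 2 mm x 2 mm kernel slides over the frame with 94% overlap (step =
kernel x (1 - overlap)); at every lattice position the windowed spectrum
is normalized by the reference phantom, attenuation-corrected and fitted,
giving one pixel in each of the five co-registered maps (MBF, SS, SI,
ASD, AAC). Kernel positions whose window would exit the frame are
dropped rather than padded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from qustex.data_model import PixelGrid, RFFrame, ROIMask
from qustex.spectral import (
    NP_PER_DB,
    AttenuationModel,
    SpectrumEstimate,
    estimate_ace_spectral_difference,
    fit_gaussian_form_factor_batch,
    mean_periodogram,
)

MAP_NAMES = ("MBF", "SS", "SI", "ASD", "AAC")


@dataclass(frozen=True)
class SlidingWindowConfig:
    """Kernel size (mm) and fractional overlap of the sliding window."""

    kernel_mm: tuple[float, float] = (2.0, 2.0)  # (axial, lateral)
    overlap: float = 0.94

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap < 1.0:
            raise ValueError("overlap must be in [0, 1)")
        if min(self.kernel_mm) <= 0:
            raise ValueError("kernel dimensions must be positive")

    @property
    def step_mm(self) -> tuple[float, float]:
        return (self.kernel_mm[0] * (1.0 - self.overlap),
                self.kernel_mm[1] * (1.0 - self.overlap))


def lattice_count(extent_mm: float, kernel_mm: float, step_mm: float) -> int:
    """Number of kernel positions fully inside ``extent_mm``."""
    if extent_mm < kernel_mm:
        return 0
    return int(np.floor((extent_mm - kernel_mm) / step_mm + 1e-9)) + 1


def kernel_contents(cfg: SlidingWindowConfig, geometry) -> tuple[int, int]:
    """(whole wavelengths axially, whole scan lines laterally) in the kernel."""
    lam_mm = geometry.wavelength * 1e3
    pitch_mm = geometry.line_spacing * 1e3
    return (int(cfg.kernel_mm[0] / lam_mm), int(cfg.kernel_mm[1] / pitch_mm))


@dataclass
class ParametricImageSet:
    """Co-registered MBF/SS/SI/ASD/AAC maps on one pixel grid."""

    maps: dict[str, np.ndarray]
    grid: PixelGrid
    frame_id: str
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {name: m.shape for name, m in self.maps.items()}
        if set(self.maps) != set(MAP_NAMES):
            raise ValueError(f"expected maps {MAP_NAMES}, got {sorted(self.maps)}")
        if len(set(shapes.values())) != 1 or next(iter(shapes.values())) != self.grid.shape:
            raise ValueError(f"maps must share the grid shape {self.grid.shape}, got {shapes}")


@dataclass(frozen=True)
class RegionSummary:
    """Per-map mean and population standard deviation over a region."""

    mean: float
    std: float
    pixel_count: int


def region_summary(map_values: np.ndarray, mask: ROIMask) -> RegionSummary:
    """Arithmetic mean and population (N-denominator) std over masked pixels."""
    if map_values.shape != mask.mask.shape:
        raise ValueError(f"map shape {map_values.shape} != mask shape {mask.mask.shape}")
    vals = map_values[mask.mask]
    if vals.size == 0:
        raise ValueError("region mask selects no pixels")
    return RegionSummary(mean=float(vals.mean()), std=float(vals.std(ddof=0)),
                         pixel_count=int(vals.size))


def compute_cmr(core: RegionSummary, margin: RegionSummary) -> float:
    """Core-to-margin ratio: mean(core) / std(margin); NaN if std(margin)=0."""
    if margin.std == 0.0:
        return float("nan")
    return core.mean / margin.std


def compute_cmcr(core: RegionSummary, margin: RegionSummary) -> float:
    """Core-to-margin contrast ratio: |mean_c - mean_m| / mean of the stds."""
    denom = 0.5 * (core.std + margin.std)
    if denom == 0.0:
        return float("nan")
    return abs(core.mean - margin.mean) / denom


# ---------------------------------------------------------------------------
# image construction
# ---------------------------------------------------------------------------

def _reference_axial_spectra(phantom, axial_starts, n_ax: int, nfft: int,
                             geometry) -> dict[int, np.ndarray]:
    """Line- and frame-averaged reference periodogram per axial window start."""
    if not phantom.frames:
        raise ValueError("reference phantom has no matched RF frames")
    out: dict[int, np.ndarray] = {}
    stacks = [f.samples for f in phantom.frames]
    for i0 in sorted(set(int(i) for i in axial_starts)):
        segs = np.concatenate([s[i0:i0 + n_ax, :].T for s in stacks], axis=0)
        out[i0] = mean_periodogram(segs, nfft)
    return out


def effective_attenuation_slope(z_center_cm: float, z_boundary_cm: float,
                                intervening: float, tumour: float) -> float:
    """Path-averaged attenuation slope down to ``z_center_cm``.

    Intervening tissue (1 dB/cm/MHz by default) applies above the proximal
    tumour depth, the estimated tumour slope below it.
    """
    if z_center_cm <= 0:
        return intervening
    if z_center_cm <= z_boundary_cm:
        return intervening
    return (intervening * z_boundary_cm + tumour * (z_center_cm - z_boundary_cm)) / z_center_cm


def estimate_frame_ace(frame: RFFrame, phantom, contour_mm, n_ax: int, nfft: int,
                       band_mhz: tuple[float, float]) -> AttenuationModel:
    """Single tumour ACE per frame via the spectral-difference method.

    Depth windows of ``n_ax`` samples step by half a window over the
    contour's depth extent, averaging all scan lines in its lateral
    extent; falls back to the 1 dB/cm/MHz intervening assumption when the
    tumour is too shallow for 3 windows.
    """
    geom = frame.geometry
    contour = np.asarray(contour_mm, dtype=float)
    # spectral-difference assumes homogeneous scattering over the ROI, so
    # work inside the contour's inscribed box (extents shrunk 1/sqrt(2)
    # about the centroid) to keep boundary-mixed windows out of the fit
    shrink = 1.0 / np.sqrt(2.0)
    cx, cz = contour.mean(axis=0)
    half_x = (contour[:, 0].max() - contour[:, 0].min()) / 2.0 * shrink
    half_z = (contour[:, 1].max() - contour[:, 1].min()) / 2.0 * shrink
    j0 = max(int((cx - half_x) / (geom.line_spacing * 1e3)), 0)
    j1 = min(int(np.ceil((cx + half_x) / (geom.line_spacing * 1e3))) + 1, geom.n_lines)
    i_lo = max(int((cz - half_z) / (geom.axial_step * 1e3)), 0)
    i_hi = min(int(np.ceil((cz + half_z) / (geom.axial_step * 1e3))), geom.axial_samples)
    step = max(n_ax // 4, 1)
    starts = list(range(i_lo, i_hi - n_ax + 1, step))
    if len(starts) < 3 or j1 - j0 < 1:
        return AttenuationModel(1.0, provenance="assumed_intervening")
    freq_mhz = np.fft.rfftfreq(nfft, d=1.0 / geom.sampling_frequency) / 1e6
    ref = _reference_axial_spectra(phantom, starts, n_ax, nfft, geom)
    sample_spectra, ref_spectra = [], []
    with np.errstate(divide="ignore"):
        for i0 in starts:
            wg = (geom.axial_depth_m(i0) * 100.0, n_ax * geom.axial_step * 100.0)
            pm = mean_periodogram(frame.samples[i0:i0 + n_ax, j0:j1].T, nfft)
            sample_spectra.append(SpectrumEstimate(freq_mhz, 10 * np.log10(pm),
                                                   j1 - j0, wg))
            ref_spectra.append(SpectrumEstimate(freq_mhz, 10 * np.log10(ref[i0]),
                                                1, wg))
    return estimate_ace_spectral_difference(sample_spectra, ref_spectra, band_mhz,
                                            reference_slope_db_cm_mhz=phantom.attenuation_slope)


def build_parametric_images(frame: RFFrame, phantom,
                            cfg: SlidingWindowConfig,
                            tumour_contour_mm,
                            intervening_slope: float = 1.0,
                            band_mhz: tuple[float, float] | None = None,
                            asd_grid_um: np.ndarray | None = None,
                            ) -> ParametricImageSet:
    """Compute the five QUS parametric maps for one RF frame.

    The tumour ACE is estimated once per frame over the contour and
    applied (path-averaged with the intervening-tissue assumption) to all
    windows at and below the proximal tumour depth; windows above it use
    the intervening slope alone.
    """
    geom = frame.geometry
    if band_mhz is None:
        band_mhz = geom.analysis_band
    ax_step_mm = geom.axial_step * 1e3
    lat_step_mm = geom.line_spacing * 1e3
    n_ax = max(int(round(cfg.kernel_mm[0] / ax_step_mm)), 4)
    n_lat = max(int(round(cfg.kernel_mm[1] / lat_step_mm)), 2)
    if n_ax > geom.axial_samples or n_lat > geom.n_lines:
        raise ValueError("kernel is larger than the frame")
    extent_z = geom.depth * 1e3
    extent_x = geom.lateral_fov * 1e3
    step_z, step_x = cfg.step_mm
    n_rows = lattice_count(extent_z, n_ax * ax_step_mm, step_z)
    n_cols = lattice_count(extent_x, n_lat * lat_step_mm, step_x)
    if n_rows < 1 or n_cols < 1:
        raise ValueError("kernel is larger than the frame")
    row_starts = np.minimum(np.round(np.arange(n_rows) * step_z / ax_step_mm).astype(int),
                            geom.axial_samples - n_ax)
    col_starts = np.minimum(np.round(np.arange(n_cols) * step_x / lat_step_mm).astype(int),
                            geom.n_lines - n_lat)
    nfft = 1 << int(np.ceil(np.log2(4 * n_ax)))
    freq_mhz = np.fft.rfftfreq(nfft, d=1.0 / geom.sampling_frequency) / 1e6
    sel = (freq_mhz >= band_mhz[0]) & (freq_mhz <= band_mhz[1])
    if sel.sum() < 3:
        raise ValueError("analysis band must contain at least 3 FFT bins")
    f = freq_mhz[sel]
    fc = 0.5 * (band_mhz[0] + band_mhz[1])

    f_ref_curve, sigma_ref_curve = phantom.bsc_curve
    sigma_r = np.interp(f, np.asarray(f_ref_curve, dtype=float),
                        np.asarray(sigma_ref_curve, dtype=float))
    if np.any(sigma_r <= 0):
        raise ValueError("reference backscatter curve must be positive on the band")

    ace = estimate_frame_ace(frame, phantom, tumour_contour_mm, n_ax, nfft, band_mhz)
    z_tumour_top_cm = float(np.asarray(tumour_contour_mm)[:, 1].min()) / 10.0

    ref_spec = _reference_axial_spectra(phantom, row_starts, n_ax, nfft, geom)
    # least-squares design for the in-band line fit
    design = np.vstack([f, np.ones_like(f)])
    pinv = np.linalg.pinv(design.T)  # (2, n_f)

    maps = {name: np.empty((n_rows, n_cols)) for name in MAP_NAMES}
    for r, i0 in enumerate(row_starts):
        segs = np.stack([frame.samples[i0:i0 + n_ax, j0:j0 + n_lat].T
                         for j0 in col_starts])  # (n_cols, n_lat, n_ax)
        pm = mean_periodogram(segs, nfft)[:, sel]  # (n_cols, n_f)
        ratio = pm / ref_spec[i0][sel][None, :]
        z_cm = geom.axial_depth_m(i0) * 100.0
        path = z_cm + (n_ax * geom.axial_step * 100.0) / 2.0
        beta_m = effective_attenuation_slope(path, z_tumour_top_cm,
                                             intervening_slope, ace.slope_db_cm_mhz)
        corr = np.exp(4.0 * (beta_m - phantom.attenuation_slope) * f * NP_PER_DB * path)
        sigma_m = sigma_r[None, :] * ratio * corr[None, :]
        nps_db = 10.0 * np.log10(np.maximum(sigma_m, 1e-300))
        coeffs = pinv @ nps_db.T  # (2, n_cols): slope, intercept
        maps["SS"][r, :] = coeffs[0]
        maps["SI"][r, :] = coeffs[1]
        maps["MBF"][r, :] = coeffs[0] * fc + coeffs[1]
        asd, aac, _res, _flat = fit_gaussian_form_factor_batch(
            nps_db, f, c_l_m_s=geom.speed_of_sound, asd_grid_um=asd_grid_um)
        maps["ASD"][r, :] = asd
        maps["AAC"][r, :] = aac

    grid = PixelGrid(
        origin_mm=((n_lat * lat_step_mm) / 2.0, (n_ax * ax_step_mm) / 2.0),
        spacing_mm=(step_x, step_z),
        shape=(n_rows, n_cols),
    )
    meta = {
        "ace_db_cm_mhz": ace.slope_db_cm_mhz,
        "ace_provenance": ace.provenance,
        "intervening_db_cm_mhz": intervening_slope,
        "band_mhz": list(band_mhz),
        "std_convention": "population",
    }
    return ParametricImageSet(maps=maps, grid=grid, frame_id=frame.frame_id, metadata=meta)
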