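"""Containers, physical-coordinate geometry and file I/O for RF studies.

Conventions used throughout the package:

* all array indices are 0-based; windows are half-open ``[start, stop)``;
* RF frames are stored axial-sample-major: ``samples[i, j]`` is axial
  sample ``i`` of scan line ``j``;
* the depth coordinate of axial sample ``i`` is ``z = i * c / (2 * fs)``
  and the lateral coordinate of line ``j`` is ``x = j * fov / n_lines``;
* on-disk format: one ``frame_XXX.bin`` (little-endian float32,
  axial-sample-major) per frame, a ``study.json`` sidecar with the
  acquisition geometry and a ``rois.json`` with per-frame core contours
  as lists of ``[x_mm, z_mm]`` vertices.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from shapely.prepared import prep
from shapely import points as shapely_points


class StudyFormatError(ValueError):
    """Raised when on-disk study metadata is missing or contradictory."""


# ---------------------------------------------------------------------------
# geometry
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AcquisitionGeometry:
    """Physical description of one beamformed RF acquisition.

    Parameters
    ----------
    sampling_frequency : float
        RF sampling frequency in Hz.
    speed_of_sound : float
        Assumed propagation speed in m/s.
    center_frequency : float
        Transducer center frequency in Hz.
    analysis_band : tuple of float
        ``(f_lo, f_hi)`` analysis bandwidth in MHz.
    n_lines : int
        Number of scan lines across the lateral field of view.
    lateral_fov : float
        Lateral field of view in m.
    axial_samples : int
        Number of axial samples per line.
    """

    sampling_frequency: float
    speed_of_sound: float
    center_frequency: float
    analysis_band: tuple[float, float]
    n_lines: int
    lateral_fov: float
    axial_samples: int

    def __post_init__(self) -> None:
        f_lo, f_hi = self.analysis_band
        if not 0 < f_lo < f_hi:
            raise ValueError(f"analysis_band must satisfy 0 < f_lo < f_hi, got {self.analysis_band}")
        if self.sampling_frequency <= 2.0 * f_hi * 1e6:
            raise ValueError(
                f"sampling_frequency {self.sampling_frequency:g} Hz violates Nyquist for "
                f"f_hi = {f_hi} MHz"
            )
        if self.n_lines < 1 or self.lateral_fov <= 0:
            raise ValueError("need n_lines >= 1 and lateral_fov > 0")
        if self.speed_of_sound <= 0 or self.center_frequency <= 0:
            raise ValueError("speed_of_sound and center_frequency must be positive")
        if self.axial_samples < 1:
            raise ValueError("axial_samples must be >= 1")

    @property
    def wavelength(self) -> float:
        """Acoustic wavelength at the center frequency, in m."""
        return self.speed_of_sound / self.center_frequency

    @property
    def line_spacing(self) -> float:
        """Lateral spacing between adjacent scan lines, in m."""
        return self.lateral_fov / self.n_lines

    @property
    def axial_step(self) -> float:
        """Depth increment per axial sample, in m (two-way travel)."""
        return self.speed_of_sound / (2.0 * self.sampling_frequency)

    @property
    def depth(self) -> float:
        """Total imaged depth in m."""
        return self.axial_samples * self.axial_step

    def axial_depth_m(self, i) -> np.ndarray | float:
        return np.asarray(i) * self.axial_step

    def lateral_position_m(self, j) -> np.ndarray | float:
        return np.asarray(j) * self.line_spacing

    def to_dict(self) -> dict:
        return {
            "sampling_frequency_hz": self.sampling_frequency,
            "speed_of_sound_m_s": self.speed_of_sound,
            "center_frequency_hz": self.center_frequency,
            "analysis_band_mhz": list(self.analysis_band),
            "n_lines": self.n_lines,
            "lateral_fov_m": self.lateral_fov,
            "axial_samples": self.axial_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionGeometry":
        required = [
            "sampling_frequency_hz", "speed_of_sound_m_s", "center_frequency_hz",
            "analysis_band_mhz", "n_lines", "lateral_fov_m", "axial_samples",
        ]
        for key in required:
            if key not in d:
                raise StudyFormatError(f"study metadata is missing required field '{key}'")
        return cls(
            sampling_frequency=float(d["sampling_frequency_hz"]),
            speed_of_sound=float(d["speed_of_sound_m_s"]),
            center_frequency=float(d["center_frequency_hz"]),
            analysis_band=tuple(float(v) for v in d["analysis_band_mhz"]),
            n_lines=int(d["n_lines"]),
            lateral_fov=float(d["lateral_fov_m"]),
            axial_samples=int(d["axial_samples"]),
        )


def axial_samples_for_depth(depth_m: float, geometry_or_c, fs: float | None = None) -> int:
    """Number of axial samples needed to image ``depth_m`` (round-trip)."""
    if fs is None:
        c, fs = geometry_or_c.speed_of_sound, geometry_or_c.sampling_frequency
    else:
        c = geometry_or_c
    return int(round(2.0 * depth_m / c * fs))


# ---------------------------------------------------------------------------
# RF frames / study
# ---------------------------------------------------------------------------

@dataclass
class RFFrame:
    """One beamformed RF frame: ``samples[axial, line]`` plus its geometry."""

    samples: np.ndarray
    geometry: AcquisitionGeometry
    frame_id: str = "frame"

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        expected = (self.geometry.axial_samples, self.geometry.n_lines)
        if self.samples.shape != expected:
            raise StudyFormatError(
                f"frame '{self.frame_id}': samples shape {self.samples.shape} does not match "
                f"geometry (axial_samples, n_lines) = {expected}"
            )
        if not np.all(np.isfinite(self.samples)):
            raise StudyFormatError(f"frame '{self.frame_id}' contains non-finite samples")


@dataclass
class RFStudy:
    """A set of co-registered RF frames with per-frame core contours (mm)."""

    frames: list[RFFrame]
    geometry: AcquisitionGeometry
    contours: dict[str, np.ndarray] = field(default_factory=dict)
    label: str | None = None
    study_id: str = "study"


def save_rf_study(study: RFStudy, path) -> Path:
    """Write a study directory (float32 frames + JSON sidecars)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {
        "study_id": study.study_id,
        "geometry": study.geometry.to_dict(),
        "frame_ids": [f.frame_id for f in study.frames],
    }
    if study.label is not None:
        meta["label"] = study.label
    (path / "study.json").write_text(json.dumps(meta, indent=1))
    for k, frame in enumerate(study.frames):
        frame.samples.astype("<f4").tofile(path / f"frame_{k:03d}.bin")
    rois = {fid: np.asarray(c).tolist() for fid, c in study.contours.items()}
    (path / "rois.json").write_text(json.dumps(rois, indent=1))
    return path


def load_rf_study(path) -> RFStudy:
    """Load a study directory written by :func:`save_rf_study`.

    Raises :class:`StudyFormatError` naming the offending field when the
    sidecar metadata is missing or inconsistent with the binary frames.
    """
    path = Path(path)
    meta_path = path / "study.json"
    if not meta_path.exists():
        raise StudyFormatError(f"missing sidecar metadata: {meta_path}")
    meta = json.loads(meta_path.read_text())
    if "geometry" not in meta:
        raise StudyFormatError("study.json is missing required field 'geometry'")
    geometry = AcquisitionGeometry.from_dict(meta["geometry"])
    frame_ids = meta.get("frame_ids")
    if frame_ids is None:
        raise StudyFormatError("study.json is missing required field 'frame_ids'")
    n_per_frame = geometry.axial_samples * geometry.n_lines
    frames = []
    for k, fid in enumerate(frame_ids):
        fpath = path / f"frame_{k:03d}.bin"
        if not fpath.exists():
            raise StudyFormatError(f"missing frame file {fpath}")
        raw = np.fromfile(fpath, dtype="<f4")
        if raw.size != n_per_frame:
            raise StudyFormatError(
                f"frame file {fpath.name} has {raw.size} samples but geometry implies "
                f"axial_samples*n_lines = {n_per_frame}"
            )
        samples = raw.astype(np.float64).reshape(geometry.axial_samples, geometry.n_lines)
        frames.append(RFFrame(samples=samples, geometry=geometry, frame_id=fid))
    contours: dict[str, np.ndarray] = {}
    roi_path = path / "rois.json"
    if roi_path.exists():
        rois = json.loads(roi_path.read_text())
        contours = {fid: np.asarray(v, dtype=float) for fid, v in rois.items()}
    return RFStudy(
        frames=frames,
        geometry=geometry,
        contours=contours,
        label=meta.get("label"),
        study_id=meta.get("study_id", path.name),
    )


# ---------------------------------------------------------------------------
# pixel grid / ROI masks
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PixelGrid:
    """Regular pixel grid of a parametric image, in physical mm.

    ``origin_mm`` is the (x, z) position of the center of pixel
    ``[0, 0]``; rows index depth z, columns index lateral x.
    """

    origin_mm: tuple[float, float]
    spacing_mm: tuple[float, float]  # (dx, dz)
    shape: tuple[int, int]  # (n_rows=z, n_cols=x)

    def __post_init__(self) -> None:
        dx, dz = self.spacing_mm
        if dx <= 0 or dz <= 0:
            raise ValueError("pixel spacing must be positive")

    @property
    def x_centers_mm(self) -> np.ndarray:
        return self.origin_mm[0] + np.arange(self.shape[1]) * self.spacing_mm[0]

    @property
    def z_centers_mm(self) -> np.ndarray:
        return self.origin_mm[1] + np.arange(self.shape[0]) * self.spacing_mm[1]


@dataclass
class ROIMask:
    """Boolean region mask aligned to a parametric-image pixel grid."""

    mask: np.ndarray
    grid: PixelGrid
    region_kind: str = "core"
    source_contour: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.grid.shape:
            raise ValueError(f"mask shape {self.mask.shape} != grid shape {self.grid.shape}")

    @property
    def usable(self) -> bool:
        return bool(self.mask.any())

    @property
    def pixel_count(self) -> int:
        return int(self.mask.sum())


def rasterize_roi(contour_mm, grid: PixelGrid, region_kind: str = "core") -> ROIMask:
    """Rasterize a closed polygon (mm coordinates) onto a pixel grid.

    A pixel is inside iff its center lies inside the polygon (even-odd
    rule); centers exactly on the boundary count as inside.
    """
    contour = np.asarray(contour_mm, dtype=float)
    if contour.ndim != 2 or contour.shape[1] != 2 or contour.shape[0] < 3:
        raise ValueError("contour must be an (N>=3, 2) array of [x_mm, z_mm] vertices")
    poly = Polygon(contour)
    if not poly.is_valid:
        raise ValueError("contour polygon is degenerate or self-intersecting")
    xs, zs = np.meshgrid(grid.x_centers_mm, grid.z_centers_mm)
    pts = shapely_points(np.column_stack([xs.ravel(), zs.ravel()]))
    inside = prep(poly).covers(pts)  # covers: boundary points count as inside
    mask = np.asarray(inside, dtype=bool).reshape(grid.shape)
    return ROIMask(mask=mask, grid=grid, region_kind=region_kind, source_contour=contour)


def build_margin(core: ROIMask, distance_mm: float = 5.0) -> ROIMask:
    """Peritumoural margin: pixels within ``distance_mm`` of the core, outside it.

    Distances are Euclidean in physical mm (anisotropic pixels respected),
    clipped at the image bounds. The margin is disjoint from the core by
    construction.
    """
    if distance_mm <= 0:
        raise ValueError("margin distance must be positive")
    if not core.usable:
        raise ValueError("core mask is empty; cannot build a margin")
    dx, dz = core.grid.spacing_mm
    # distance (mm) from every non-core pixel center to the nearest core pixel center
    dist = ndimage.distance_transform_edt(~core.mask, sampling=(dz, dx))
    mask = (dist <= distance_mm) & ~core.mask
    return ROIMask(mask=mask, grid=core.grid, region_kind="margin",
                   source_contour=core.source_contour)
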