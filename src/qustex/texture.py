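"""Masked gray-level texture analysis of parametric images.

Implements 16-level quantization, symmetric gray-level co-occurrence
matrices (GLCM, 4 features), gray-level run-length matrices (GRLM, 14
features) and gray-level size-zone matrices (GLSZM, 14 features), with the
irregular-ROI conventions used throughout the package:

* pixel pairs count only when both pixels are masked;
* runs and zones are broken at mask boundaries;
* the pixel-count normalizers in run/zone percentage use the number of
  masked pixels.

Entropy and variance features are evaluated on count matrices normalized
to probabilities (by the total run count ``s`` or zone count ``N_Z``), so
that the row/column means entering the variances are proper expectations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from qustex.data_model import ROIMask
from qustex.parametric import MAP_NAMES, compute_cmcr, compute_cmr, region_summary

N_LEVELS_DEFAULT = 16
GLCM_DISTANCES = (1, 2, 3, 4, 5)
ANGLES_DEG = (0, 45, 90, 135)

GLCM_FEATURES = ("CON", "COR", "ENE", "HOM")
GRLM_FEATURES = ("SRE", "LRE", "GLN", "RLN", "RP", "LGRE", "HGRE",
                 "SRLGE", "SRHGE", "LRLGE", "LRHGE", "GV", "RV", "RE")
GLSZM_FEATURES = ("SAE", "LAE", "GLN-SZ", "SZN", "ZP", "LGZE", "HGZE",
                  "SALGE", "SAHGE", "LALGE", "LAHGE", "GV-SZ", "ZV", "ZE")

METHOD_FEATURES = {"GLCM": GLCM_FEATURES, "GRLM": GRLM_FEATURES, "GLSZM": GLSZM_FEATURES}

# (drow, dcol) unit offsets; rows index depth, columns lateral position
_ANGLE_OFFSETS = {0: (0, 1), 45: (-1, 1), 90: (-1, 0), 135: (-1, -1)}


@dataclass
class QuantizedImage:
    """Integer gray levels 1..n_levels on masked pixels; 0 elsewhere."""

    levels: np.ndarray
    mask: np.ndarray
    n_levels: int
    bounds: tuple[float, float]


def quantize_roi(map_values: np.ndarray, mask, n_levels: int = N_LEVELS_DEFAULT) -> QuantizedImage:
    """Linearly scale the masked value range into ``n_levels`` gray levels.

    ``level = 1 + floor(n * (v - min) / (max - min))`` with the maximum
    mapped to ``n_levels``; a constant region maps entirely to level 1.
    """
    m = mask.mask if isinstance(mask, ROIMask) else np.asarray(mask, dtype=bool)
    if map_values.shape != m.shape:
        raise ValueError("map and mask shapes differ")
    if not m.any():
        raise ValueError("mask is empty")
    vals = map_values[m]
    if not np.all(np.isfinite(vals)):
        raise ValueError("masked map values must be finite")
    vmin, vmax = float(vals.min()), float(vals.max())
    levels = np.zeros(map_values.shape, dtype=np.int32)
    if vmax == vmin:
        levels[m] = 1
    else:
        scaled = 1 + np.floor(n_levels * (map_values[m] - vmin) / (vmax - vmin))
        levels[m] = np.minimum(scaled, n_levels).astype(np.int32)
    return QuantizedImage(levels=levels, mask=m, n_levels=n_levels, bounds=(vmin, vmax))


# ---------------------------------------------------------------------------
# GLCM
# ---------------------------------------------------------------------------

@dataclass
class GLCMMatrix:
    p: np.ndarray  # (n_levels, n_levels) probabilities, symmetric
    distance: int
    angle_deg: int


def compute_glcm(q: QuantizedImage, distance: int, angle_deg: int) -> GLCMMatrix:
    """Symmetric co-occurrence probabilities at one distance/angle.

    Pairs are counted when both endpoints are masked; the count matrix is
    symmetrized by adding its transpose before normalization.
    """
    dr, dc = _ANGLE_OFFSETS[angle_deg]
    dr, dc = dr * distance, dc * distance
    n = q.n_levels
    lev = q.levels
    rows, cols = lev.shape
    r0s, r0e = max(0, -dr), min(rows, rows - dr)
    c0s, c0e = max(0, -dc), min(cols, cols - dc)
    a = lev[r0s:r0e, c0s:c0e]
    b = lev[r0s + dr:r0e + dr, c0s + dc:c0e + dc]
    valid = (a > 0) & (b > 0)
    if not valid.any():
        raise ValueError(
            f"no valid pixel pairs in ROI at distance {distance}, angle {angle_deg}")
    counts = np.zeros((n, n))
    np.add.at(counts, (a[valid] - 1, b[valid] - 1), 1.0)
    counts = counts + counts.T
    return GLCMMatrix(p=counts / counts.sum(), distance=distance, angle_deg=angle_deg)


def glcm_features(m: GLCMMatrix) -> dict[str, float]:
    """Contrast, correlation, energy and homogeneity of one GLCM.

    Correlation is NaN for a constant region (zero marginal variance).
    """
    p = m.p
    n = p.shape[0]
    i = np.arange(1, n + 1)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    pi = p.sum(axis=1)
    pj = p.sum(axis=0)
    mu_i = float(np.dot(i, pi))
    mu_j = float(np.dot(i, pj))
    var_i = float(np.dot((i - mu_i) ** 2, pi))
    var_j = float(np.dot((i - mu_j) ** 2, pj))
    contrast = float(np.sum(np.abs(ii - jj) ** 2 * p))
    energy = float(np.sum(p ** 2))
    homogeneity = float(np.sum(p / (1.0 + np.abs(ii - jj))))
    if var_i * var_j > 0:
        correlation = float(np.sum((ii - mu_i) * (jj - mu_j) * p)
                            / np.sqrt(var_i * var_j))
    else:
        correlation = float("nan")
    return {"CON": contrast, "COR": correlation, "ENE": energy, "HOM": homogeneity}


# ---------------------------------------------------------------------------
# GRLM
# ---------------------------------------------------------------------------

@dataclass
class GRLMMatrix:
    counts: np.ndarray  # (n_levels, longest run)
    angle_deg: int
    n_masked: int

    @property
    def s(self) -> float:
        return float(self.counts.sum())


def _direction_paths(shape: tuple[int, int], angle_deg: int):
    """Index sequences of all maximal lines through the grid along an angle."""
    rows, cols = shape
    if angle_deg == 0:
        for r in range(rows):
            yield np.full(cols, r), np.arange(cols)
    elif angle_deg == 90:
        for c in range(cols):
            yield np.arange(rows), np.full(rows, c)
    elif angle_deg == 45:  # direction (-1, +1): walk up-right; enumerate anti-diagonals
        for d in range(rows + cols - 1):
            r = np.arange(min(d, rows - 1), max(0, d - cols + 1) - 1, -1)
            c = d - r
            yield r, c
    elif angle_deg == 135:  # direction (-1, -1): walk up-left; enumerate diagonals
        for d in range(-(rows - 1), cols):
            r = np.arange(rows - 1, -1, -1)
            c = r + d
            ok = (c >= 0) & (c < cols)
            yield r[ok], c[ok]
    else:
        raise ValueError(f"unsupported angle {angle_deg}")


def _run_lengths(seq: np.ndarray):
    """(level, length) of maximal constant runs in ``seq``; 0 breaks runs."""
    out = []
    prev = 0
    length = 0
    for v in seq:
        if v == prev and v != 0:
            length += 1
        else:
            if prev != 0:
                out.append((prev, length))
            prev, length = v, 1
    if prev != 0:
        out.append((prev, length))
    return out


def compute_grlm(q: QuantizedImage, angle_deg: int) -> GRLMMatrix:
    """Run-length counts: maximal collinear constant-level runs per angle."""
    runs: list[tuple[int, int]] = []
    for r, c in _direction_paths(q.levels.shape, angle_deg):
        runs.extend(_run_lengths(q.levels[r, c]))
    if not runs:
        counts = np.zeros((q.n_levels, 1))
    else:
        max_len = max(length for _, length in runs)
        counts = np.zeros((q.n_levels, max_len))
        for lev, length in runs:
            counts[lev - 1, length - 1] += 1.0
    return GRLMMatrix(counts=counts, angle_deg=angle_deg, n_masked=int(q.mask.sum()))


def grlm_features(m: GRLMMatrix) -> dict[str, float]:
    """The 14 run-length features of one direction's count matrix."""
    p = m.counts
    s = p.sum()
    if s < 1:
        raise ValueError("run-length matrix is empty")
    n_g, n_r = p.shape
    i = np.arange(1, n_g + 1)[:, None].astype(float)
    j = np.arange(1, n_r + 1)[None, :].astype(float)
    ri = p.sum(axis=1)  # per-level run totals
    rj = p.sum(axis=0)  # per-length run totals
    jv = j.ravel()
    iv = i.ravel()
    feats = {
        "SRE": float(np.dot(rj, 1.0 / jv ** 2) / s),
        "LRE": float(np.dot(rj, jv ** 2) / s),
        "GLN": float(np.dot(ri, ri) / s),
        "RLN": float(np.dot(rj, rj) / s),
        "RP": float(s / m.n_masked),
        "LGRE": float(np.dot(ri, 1.0 / iv ** 2) / s),
        "HGRE": float(np.dot(ri, iv ** 2) / s),
        "SRLGE": float(np.sum(p / (i ** 2 * j ** 2)) / s),
        "SRHGE": float(np.sum(p * i ** 2 / j ** 2) / s),
        "LRLGE": float(np.sum(p * j ** 2 / i ** 2) / s),
        "LRHGE": float(np.sum(p * i ** 2 * j ** 2) / s),
    }
    # variance/entropy on the probability-normalized matrix
    pn = p / s
    mu_i = float(np.sum(pn * i))
    mu_j = float(np.sum(pn * j))
    feats["GV"] = float(np.sum(pn * (i - mu_i) ** 2))
    feats["RV"] = float(np.sum(pn * (j - mu_j) ** 2))
    nz = pn[pn > 0]
    feats["RE"] = float(-np.sum(nz * np.log2(nz)))
    return feats


# ---------------------------------------------------------------------------
# GLSZM
# ---------------------------------------------------------------------------

@dataclass
class GLSZMMatrix:
    counts: np.ndarray  # (n_levels, largest zone size)
    n_masked: int

    @property
    def n_zones(self) -> float:
        return float(self.counts.sum())


_EIGHT_CONNECTED = np.ones((3, 3), dtype=int)


def compute_glszm(q: QuantizedImage) -> GLSZMMatrix:
    """Size-zone counts: 8-connected equal-level components within the mask."""
    zones: list[tuple[int, int]] = []
    for lev in range(1, q.n_levels + 1):
        binary = q.levels == lev
        if not binary.any():
            continue
        labelled, n = ndimage.label(binary, structure=_EIGHT_CONNECTED)
        if n:
            sizes = np.bincount(labelled.ravel())[1:]
            zones.extend((lev, int(sz)) for sz in sizes)
    if not zones:
        raise ValueError("quantized image has no masked pixels")
    max_size = max(sz for _, sz in zones)
    counts = np.zeros((q.n_levels, max_size))
    for lev, sz in zones:
        counts[lev - 1, sz - 1] += 1.0
    return GLSZMMatrix(counts=counts, n_masked=int(q.mask.sum()))


def glszm_features(m: GLSZMMatrix) -> dict[str, float]:
    """The 14 size-zone features of the zone count matrix."""
    p = m.counts
    nz_total = p.sum()
    if nz_total < 1:
        raise ValueError("size-zone matrix is empty")
    n_g, n_s = p.shape
    i = np.arange(1, n_g + 1)[:, None].astype(float)
    j = np.arange(1, n_s + 1)[None, :].astype(float)
    zi = p.sum(axis=1)
    zj = p.sum(axis=0)
    iv, jv = i.ravel(), j.ravel()
    feats = {
        "SAE": float(np.dot(zj, 1.0 / jv ** 2) / nz_total),
        "LAE": float(np.dot(zj, jv ** 2) / nz_total),
        "GLN-SZ": float(np.dot(zi, zi) / nz_total),
        "SZN": float(np.dot(zj, zj) / nz_total),
        "ZP": float(nz_total / m.n_masked),
        "LGZE": float(np.dot(zi, 1.0 / iv ** 2) / nz_total),
        "HGZE": float(np.dot(zi, iv ** 2) / nz_total),
        "SALGE": float(np.sum(p / (i ** 2 * j ** 2)) / nz_total),
        "SAHGE": float(np.sum(p * i ** 2 / j ** 2) / nz_total),
        "LALGE": float(np.sum(p * j ** 2 / i ** 2) / nz_total),
        "LAHGE": float(np.sum(p * i ** 2 * j ** 2) / nz_total),
    }
    pn = p / nz_total
    mu_i = float(np.sum(pn * i))
    mu_j = float(np.sum(pn * j))
    feats["GV-SZ"] = float(np.sum(pn * (i - mu_i) ** 2))
    feats["ZV"] = float(np.sum(pn * (j - mu_j) ** 2))
    nzp = pn[pn > 0]
    feats["ZE"] = float(-np.sum(nzp * np.log2(nzp)))
    return feats


# ---------------------------------------------------------------------------
# sweeps, aggregation and feature tables
# ---------------------------------------------------------------------------

def aggregate_texture(per_config: list[dict[str, float]], expected: int) -> dict[str, float]:
    """Average feature dicts over a complete distance/angle sweep.

    Missing values (NaN) are averaged over the non-missing configurations;
    a feature missing everywhere stays missing.
    """
    if len(per_config) != expected:
        raise ValueError(f"incomplete sweep: got {len(per_config)} of {expected} configurations")
    keys = set(per_config[0])
    if any(set(d) != keys for d in per_config):
        raise ValueError("inconsistent feature names across configurations")
    out = {}
    for k in per_config[0]:
        vals = np.array([d[k] for d in per_config], dtype=float)
        finite = vals[np.isfinite(vals)]
        out[k] = float(finite.mean()) if finite.size else float("nan")
    return out


def texture_feature_set(map_values: np.ndarray, mask, method: str,
                        n_levels: int = N_LEVELS_DEFAULT,
                        distances=GLCM_DISTANCES, angles=ANGLES_DEG) -> dict[str, float]:
    """Sweep-averaged texture features of one map over one region.

    GLCM averages over 5 distances x 4 angles, GRLM over 4 angles; GLSZM
    is direction independent.
    """
    q = quantize_roi(map_values, mask, n_levels=n_levels)
    if method == "GLCM":
        per = [glcm_features(compute_glcm(q, d, a)) for d in distances for a in angles]
        return aggregate_texture(per, len(distances) * len(angles))
    if method == "GRLM":
        per = [grlm_features(compute_grlm(q, a)) for a in angles]
        return aggregate_texture(per, len(angles))
    if method == "GLSZM":
        return aggregate_texture([glszm_features(compute_glszm(q))], 1)
    raise ValueError(f"unknown texture method {method!r}")


EXPECTED_COLUMNS = {  # (method, configuration) -> feature column count
    ("GLCM", "core"): 25, ("GLCM", "margin"): 25, ("GLCM", "core+margin"): 60,
    ("GRLM", "core"): 75, ("GRLM", "margin"): 75, ("GRLM", "core+margin"): 160,
    ("GLSZM", "core"): 75, ("GLSZM", "margin"): 75, ("GLSZM", "core+margin"): 160,
}


def feature_columns(method: str, configuration: str) -> list[str]:
    """Ordered feature names for one method/region configuration."""
    if method not in METHOD_FEATURES:
        raise ValueError(f"unknown texture method {method!r}")
    regions = {"core": ["Core"], "margin": ["Margin"],
               "core+margin": ["Core", "Margin"]}.get(configuration)
    if regions is None:
        raise ValueError(f"unknown configuration {configuration!r}")
    cols = []
    for region in regions:
        cols.extend(f"{region}-{p}" for p in MAP_NAMES)
        cols.extend(f"{region}-{p}-{feat}" for p in MAP_NAMES
                    for feat in METHOD_FEATURES[method])
    if configuration == "core+margin":
        cols.extend(f"CMR-{p}" for p in MAP_NAMES)
        cols.extend(f"CMCR-{p}" for p in MAP_NAMES)
    assert len(cols) == EXPECTED_COLUMNS[(method, configuration)]
    return cols


def lesion_features_from_maps(image_set, core: ROIMask, margin: ROIMask,
                              method: str, n_levels: int = N_LEVELS_DEFAULT) -> dict[str, float]:
    """Mean-value, texture and CMR/CMCR features of one scan plane."""
    feats: dict[str, float] = {}
    summaries = {}
    for region, mask in (("Core", core), ("Margin", margin)):
        for pname in MAP_NAMES:
            summ = region_summary(image_set.maps[pname], mask)
            summaries[(region, pname)] = summ
            feats[f"{region}-{pname}"] = summ.mean
            feats.update({f"{region}-{pname}-{k}": v
                          for k, v in texture_feature_set(
                              image_set.maps[pname], mask, method,
                              n_levels=n_levels).items()})
    for pname in MAP_NAMES:
        feats[f"CMR-{pname}"] = compute_cmr(summaries[("Core", pname)],
                                            summaries[("Margin", pname)])
        feats[f"CMCR-{pname}"] = compute_cmcr(summaries[("Core", pname)],
                                              summaries[("Margin", pname)])
    feats["_roi_pixels"] = core.pixel_count + margin.pixel_count
    return feats


def assemble_feature_table(lesions: list[dict], configuration: str, method: str) -> pd.DataFrame:
    """Cohort feature table: one row per lesion plus a ``label`` column.

    ``lesions`` holds dicts with keys ``lesion_id``, ``label`` and
    ``features`` (full core+margin feature dict); the configuration
    selects which columns are kept.
    """
    cols = feature_columns(method, configuration)
    rows = []
    for lesion in lesions:
        feats = lesion["features"]
        missing = [c for c in cols if c not in feats]
        if missing:
            raise ValueError(
                f"lesion {lesion.get('lesion_id')} is missing features: {missing[:5]}")
        rows.append([feats[c] for c in cols] + [lesion["label"]])
    df = pd.DataFrame(rows, columns=cols + ["label"],
                      index=[lesion.get("lesion_id", k) for k, lesion in enumerate(lesions)])
    return df
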