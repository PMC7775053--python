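"""End-to-end glue: RF study -> parametric maps -> lesion feature vector.

Per-frame features are computed per scan plane and averaged across planes
weighted by each plane's ROI pixel count; the result feeds
:func:`qustex.texture.assemble_feature_table`.
"""

from __future__ import annotations

import numpy as np

from qustex.data_model import RFStudy, build_margin, rasterize_roi
from qustex.parametric import SlidingWindowConfig, build_parametric_images
from qustex.texture import assemble_feature_table, lesion_features_from_maps


def compute_lesion_features(study: RFStudy, phantom,
                            cfg: SlidingWindowConfig | None = None,
                            method: str = "GLSZM",
                            margin_mm: float = 5.0,
                            intervening_slope: float = 1.0,
                            band_mhz: tuple[float, float] | None = None,
                            asd_grid_um: np.ndarray | None = None,
                            n_levels: int = 16) -> dict[str, float]:
    """Full core+margin feature dict for one lesion (all planes averaged)."""
    if cfg is None:
        cfg = SlidingWindowConfig()
    per_frame: list[dict[str, float]] = []
    weights: list[float] = []
    for frame in study.frames:
        contour = study.contours.get(frame.frame_id)
        if contour is None:
            continue
        image_set = build_parametric_images(
            frame, phantom, cfg, contour, intervening_slope=intervening_slope,
            band_mhz=band_mhz, asd_grid_um=asd_grid_um)
        core = rasterize_roi(contour, image_set.grid, region_kind="core")
        if not core.usable:
            continue
        margin = build_margin(core, margin_mm)
        feats = lesion_features_from_maps(image_set, core, margin, method,
                                          n_levels=n_levels)
        weights.append(feats.pop("_roi_pixels"))
        per_frame.append(feats)
    if not per_frame:
        raise ValueError(f"study {study.study_id} has no usable contoured frames")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()
    out: dict[str, float] = {}
    for key in per_frame[0]:
        vals = np.array([f[key] for f in per_frame], dtype=float)
        finite = np.isfinite(vals)
        out[key] = float(np.dot(vals[finite], w[finite]) / w[finite].sum()) \
            if finite.any() else float("nan")
    return out


def cohort_feature_table(studies, phantom, method: str = "GLSZM",
                         configuration: str = "core+margin",
                         cfg: SlidingWindowConfig | None = None,
                         **kwargs):
    """Feature table for a labelled cohort of RF studies."""
    lesions = []
    for study in studies:
        feats = compute_lesion_features(study, phantom, cfg=cfg, method=method, **kwargs)
        lesions.append({"lesion_id": study.study_id, "label": study.label,
                        "features": feats})
    return assemble_feature_table(lesions, configuration, method)
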