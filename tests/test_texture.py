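import numpy as np
import pytest
from scipy import ndimage

from qustex import texture
from qustex.texture import (
    GLCM_FEATURES,
    GLSZM_FEATURES,
    GRLM_FEATURES,
    QuantizedImage,
    aggregate_texture,
    assemble_feature_table,
    compute_glcm,
    compute_glszm,
    compute_grlm,
    feature_columns,
    glcm_features,
    glszm_features,
    grlm_features,
    quantize_roi,
    texture_feature_set,
)
import oracles
from conftest import random_masked_levels


def qimage(levels):
    levels = np.asarray(levels, dtype=np.int32)
    return QuantizedImage(levels=levels, mask=levels > 0,
                          n_levels=int(levels.max()), bounds=(0.0, 1.0))


class TestQuantize:
    def test_linear_ramp_hits_every_level(self):
        vals = np.linspace(0.0, 1.0, 16).reshape(4, 4)
        q = quantize_roi(vals, np.ones((4, 4), dtype=bool), n_levels=16)
        assert sorted(q.levels.ravel()) == list(range(1, 17))

    def test_constant_region_all_level_one(self):
        q = quantize_roi(np.full((3, 3), 2.5), np.ones((3, 3), dtype=bool))
        assert np.all(q.levels == 1)

    def test_boundary_mapping(self, rng):
        vals = rng.normal(size=(8, 8))
        mask = rng.random((8, 8)) < 0.7
        mask[0, 0] = True
        q = quantize_roi(vals, mask, n_levels=16)
        masked = vals[mask]
        assert q.levels[mask][np.argmin(masked)] == 1
        assert q.levels[mask][np.argmax(masked)] == 16
        assert np.all(q.levels[~mask] == 0)
        assert np.all((q.levels[mask] >= 1) & (q.levels[mask] <= 16))

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            quantize_roi(np.ones((3, 3)), np.zeros((3, 3), dtype=bool))


class TestGLCM:
    def test_two_row_example(self):
        # [[1,1],[2,2]] at d=1, 0 deg: two horizontal pairs -> p(1,1)=p(2,2)=0.5
        m = compute_glcm(qimage([[1, 1], [2, 2]]), 1, 0)
        assert m.p[0, 0] == pytest.approx(0.5)
        assert m.p[1, 1] == pytest.approx(0.5)
        assert m.p.sum() == pytest.approx(1.0)

    def test_two_row_example_features(self):
        f = glcm_features(compute_glcm(qimage([[1, 1], [2, 2]]), 1, 0))
        assert f["CON"] == pytest.approx(0.0)
        assert f["ENE"] == pytest.approx(0.5)
        assert f["HOM"] == pytest.approx(1.0)
        assert f["COR"] == pytest.approx(1.0)

    def test_constant_image(self):
        m = compute_glcm(qimage([[1, 1], [1, 1]]), 1, 0)
        assert m.p[0, 0] == pytest.approx(1.0)
        f = glcm_features(m)
        assert f["CON"] == 0.0 and f["ENE"] == 1.0 and f["HOM"] == 1.0
        assert np.isnan(f["COR"])

    def test_checkerboard_contrast(self):
        levels = np.indices((6, 6)).sum(axis=0) % 2 * 15 + 1  # levels 1 / 16
        f = glcm_features(compute_glcm(qimage(levels), 1, 0))
        assert f["CON"] == pytest.approx(225.0)

    def test_unmasked_pixels_excluded_from_pairs(self):
        # middle column unmasked: every d=1 horizontal pair has an unmasked
        # endpoint, so no valid pairs remain
        levels = np.array([[1, 0, 2]] * 3)
        with pytest.raises(ValueError, match="no valid"):
            compute_glcm(qimage(levels), 1, 0)
        # d=2 pairs the two masked halves across the gap (both endpoints masked)
        m = compute_glcm(qimage(levels), 2, 0)
        assert m.p[0, 1] == pytest.approx(0.5)

    def test_symmetry_and_normalization(self, rng):
        levels, _ = random_masked_levels(rng, (7, 7), 4)
        for d in (1, 2):
            for a in (0, 45, 90, 135):
                try:
                    m = compute_glcm(qimage(levels), d, a)
                except ValueError:
                    continue
                np.testing.assert_allclose(m.p, m.p.T)
                assert m.p.sum() == pytest.approx(1.0)
                assert np.all(m.p >= 0)


class TestGRLM:
    def test_row_runs(self):
        m = compute_grlm(qimage([[1, 1, 2]]), 0)
        assert m.s == 2
        assert m.counts[0, 1] == 1  # level 1, length 2
        assert m.counts[1, 0] == 1  # level 2, length 1

    def test_row_features(self):
        f = grlm_features(compute_grlm(qimage([[1, 1, 2]]), 0))
        assert f["SRE"] == pytest.approx(0.5 * (1 / 4 + 1))
        assert f["LRE"] == pytest.approx(0.5 * (4 + 1))
        assert f["RP"] == pytest.approx(2 / 3)

    def test_all_distinct_row(self):
        levels = np.arange(1, 7)[None, :]
        m = compute_grlm(qimage(levels), 0)
        assert m.counts.shape[1] == 1 and m.s == 6
        f = grlm_features(m)
        assert f["SRE"] == 1.0 and f["LRE"] == 1.0 and f["RP"] == 1.0

    def test_constant_square(self):
        n = 5
        m = compute_grlm(qimage(np.ones((n, n), dtype=int)), 0)
        assert m.s == n
        assert m.counts[0, n - 1] == n

    def test_single_run_gray_level_emphasis(self):
        g, n = 4, 6
        m = compute_grlm(qimage(np.full((1, n), g)), 0)
        f = grlm_features(m)
        assert f["HGRE"] == pytest.approx(g ** 2)
        assert f["LGRE"] == pytest.approx(1 / g ** 2)

    def test_mask_breaks_runs(self):
        m = compute_grlm(qimage([[1, 0, 1]]), 0)
        assert m.counts[0, 0] == 2  # two runs of length 1


class TestGLSZM:
    def test_two_zones(self):
        m = compute_glszm(qimage([[1, 1], [2, 2]]))
        assert m.n_zones == 2
        assert m.counts[0, 1] == 1 and m.counts[1, 1] == 1

    def test_two_zone_features(self):
        f = glszm_features(compute_glszm(qimage([[1, 1], [2, 2]])))
        assert f["SAE"] == pytest.approx(0.25)
        assert f["LAE"] == pytest.approx(4.0)
        assert f["ZP"] == pytest.approx(0.5)

    def test_constant_image_single_zone(self):
        n = 4
        m = compute_glszm(qimage(np.ones((n, n), dtype=int)))
        assert m.n_zones == 1
        f = glszm_features(m)
        assert f["SAE"] == pytest.approx(1 / n ** 4)
        assert f["LAE"] == pytest.approx(n ** 4)
        assert f["ZP"] == pytest.approx(1 / n ** 2)

    def test_diagonal_pair_is_one_zone(self):
        m = compute_glszm(qimage([[1, 0], [0, 1]]))
        assert m.n_zones == 1
        assert m.counts[0, 1] == 1

    def test_high_gray_level_zone_emphasis(self):
        f = glszm_features(compute_glszm(qimage([[1, 1], [4, 4]])))
        assert f["HGZE"] == pytest.approx((1 + 16) / 2)


class TestBruteForceOracle:
    """Exhaustive-enumeration equivalence on random small masked images."""

    @pytest.mark.parametrize("seed", range(12))
    def test_glcm_matrix_and_features(self, seed):
        rng = np.random.default_rng(seed)
        levels, _ = random_masked_levels(rng, (6, 6), 4)
        q = qimage(np.maximum(levels, 0))
        q.n_levels = 4
        for d in (1, 2):
            for a in (0, 45, 90, 135):
                counts = oracles.glcm_counts_brute(levels, d, a, 4)
                if counts.sum() == 0:
                    with pytest.raises(ValueError):
                        compute_glcm(q, d, a)
                    continue
                m = compute_glcm(q, d, a)
                np.testing.assert_allclose(m.p, counts / counts.sum(), atol=1e-14)
                got = glcm_features(m)
                exp = oracles.glcm_features_brute(counts / counts.sum())
                for k in GLCM_FEATURES:
                    if np.isnan(exp[k]):
                        assert np.isnan(got[k])
                    else:
                        assert got[k] == pytest.approx(exp[k], abs=1e-12), k

    @pytest.mark.parametrize("seed", range(12))
    def test_grlm_matrix_and_features(self, seed):
        rng = np.random.default_rng(seed)
        levels, mask = random_masked_levels(rng, (6, 6), 4)
        q = qimage(levels)
        q.n_levels = 4
        for a in (0, 45, 90, 135):
            m = compute_grlm(q, a)
            exp_m = oracles.grlm_matrix_brute(levels, a, 4)
            np.testing.assert_array_equal(m.counts, exp_m)
            got = grlm_features(m)
            exp = oracles.grlm_features_brute(exp_m, int(mask.sum()))
            for k in GRLM_FEATURES:
                assert got[k] == pytest.approx(exp[k], abs=1e-12), k

    @pytest.mark.parametrize("seed", range(12))
    def test_glszm_matrix_and_features(self, seed):
        rng = np.random.default_rng(seed)
        levels, mask = random_masked_levels(rng, (6, 6), 4)
        q = qimage(levels)
        q.n_levels = 4
        m = compute_glszm(q)
        exp_m = oracles.glszm_matrix_brute(levels, 4)
        np.testing.assert_array_equal(m.counts, exp_m)
        got = glszm_features(m)
        exp = oracles.glszm_features_brute(exp_m, int(mask.sum()))
        for k in GLSZM_FEATURES:
            assert got[k] == pytest.approx(exp[k], abs=1e-12), k


class TestInvariants:
    @pytest.mark.parametrize("seed", range(8))
    def test_mass_conservation(self, seed):
        rng = np.random.default_rng(100 + seed)
        levels, mask = random_masked_levels(rng, (8, 8), 5)
        q = qimage(levels)
        q.n_levels = 5
        n = int(mask.sum())
        for a in (0, 45, 90, 135):
            m = compute_grlm(q, a)
            j = np.arange(1, m.counts.shape[1] + 1)
            assert int((m.counts * j).sum()) == n
        z = compute_glszm(q)
        j = np.arange(1, z.counts.shape[1] + 1)
        assert int((z.counts * j).sum()) == n

    @pytest.mark.parametrize("seed", range(8))
    def test_glcm_feature_ranges(self, seed):
        rng = np.random.default_rng(200 + seed)
        levels, _ = random_masked_levels(rng, (8, 8), 6, mask_p=0.9)
        q = qimage(levels)
        q.n_levels = 6
        f = glcm_features(compute_glcm(q, 1, 0))
        assert 0 < f["ENE"] <= 1
        assert 0 < f["HOM"] <= 1
        assert f["CON"] >= 0
        if not np.isnan(f["COR"]):
            assert -1 - 1e-12 <= f["COR"] <= 1 + 1e-12

    def test_blurring_monotonicity_paired_over_seeds(self):
        # smoothing a random field must not (in paired aggregate) raise GLCM
        # contrast or lower GLSZM large-area emphasis; requantization noise
        # makes the per-seed comparison occasionally flip, so test the
        # 20-seed paired ensemble
        d_con, d_lae = [], []
        for seed in range(20):
            rng = np.random.default_rng(300 + seed)
            field = rng.standard_normal((24, 24))
            smooth = ndimage.gaussian_filter(field, sigma=1.5)
            mask = np.ones(field.shape, dtype=bool)
            d_con.append(texture_feature_set(smooth, mask, "GLCM")["CON"]
                         - texture_feature_set(field, mask, "GLCM")["CON"])
            d_lae.append(texture_feature_set(smooth, mask, "GLSZM")["LAE"]
                         - texture_feature_set(field, mask, "GLSZM")["LAE"])
        assert np.mean(d_con) < 0
        assert np.mean([d < 0 for d in d_con]) >= 0.8
        assert np.mean(d_lae) > 0
        assert np.mean([d > 0 for d in d_lae]) >= 0.8


class TestAggregation:
    def test_identical_configs(self):
        d = {"CON": 2.0, "ENE": 0.5}
        assert aggregate_texture([d, d, d], 3) == d

    def test_mean_over_configs(self):
        out = aggregate_texture([{"CON": 1.0}, {"CON": 3.0}], 2)
        assert out["CON"] == pytest.approx(2.0)

    def test_missing_propagation(self):
        nan = float("nan")
        out = aggregate_texture([{"COR": nan}, {"COR": nan}], 2)
        assert np.isnan(out["COR"])
        out = aggregate_texture([{"COR": nan}, {"COR": 0.4}], 2)
        assert out["COR"] == pytest.approx(0.4)

    def test_incomplete_sweep_rejected(self):
        with pytest.raises(ValueError, match="incomplete"):
            aggregate_texture([{"CON": 1.0}], 2)

    def test_sweep_sizes(self, rng):
        vals = rng.normal(size=(12, 12))
        mask = np.ones((12, 12), dtype=bool)
        assert set(texture_feature_set(vals, mask, "GLCM")) == set(GLCM_FEATURES)
        assert set(texture_feature_set(vals, mask, "GRLM")) == set(GRLM_FEATURES)
        assert set(texture_feature_set(vals, mask, "GLSZM")) == set(GLSZM_FEATURES)


def _fake_lesion(rng, k=0):
    feats = {}
    for col in feature_columns("GLCM", "core+margin") + \
            feature_columns("GRLM", "core+margin") + feature_columns("GLSZM", "core+margin"):
        feats[col] = float(rng.normal())
    return {"lesion_id": f"l{k}", "label": "benign" if k % 2 else "malignant",
            "features": feats}


class TestFeatureTable:
    @pytest.mark.parametrize("method,configuration,expected", [
        ("GLCM", "core", 25), ("GLCM", "margin", 25), ("GLCM", "core+margin", 60),
        ("GRLM", "core", 75), ("GRLM", "margin", 75), ("GRLM", "core+margin", 160),
        ("GLSZM", "core", 75), ("GLSZM", "margin", 75), ("GLSZM", "core+margin", 160),
    ])
    def test_column_counts(self, rng, method, configuration, expected):
        lesions = [_fake_lesion(rng, k) for k in range(4)]
        table = assemble_feature_table(lesions, configuration, method)
        assert table.shape == (4, expected + 1)  # + label
        assert table.columns[-1] == "label"

    def test_naming_convention(self, rng):
        table = assemble_feature_table([_fake_lesion(rng)], "core+margin", "GLSZM")
        assert "Core-MBF" in table.columns
        assert "Margin-MBF-GLN-SZ" in table.columns
        assert "Core-MBF-GV-SZ" in table.columns
        assert "Margin-MBF-SALGE" in table.columns
        assert "CMR-AAC" in table.columns and "CMCR-MBF" in table.columns

    def test_missing_feature_rejected(self, rng):
        lesion = _fake_lesion(rng)
        del lesion["features"]["Core-MBF"]
        with pytest.raises(ValueError, match="missing"):
            assemble_feature_table([lesion], "core", "GLCM")
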