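"""Tissue metrics against independent oracles and invariances."""

from dataclasses import replace

import numpy as np
import pytest

import retinotex as rt
from conftest import random_scan_with_layers


def roi_from_matrix(img, top=0, bottom=None):
    """Wrap a full matrix (or a row band of it) as a single-layer ROI."""
    img = np.asarray(img, dtype=float)
    n_rows, n_cols = img.shape
    bottom = n_rows if bottom is None else bottom
    scan = rt.BScan(img, 2.0, 6.0, n_cols // 2)
    return rt.LayerROI(
        layer_name="RNFL",
        region_name="across_all",
        columns=np.arange(n_cols),
        top_rows=np.full(n_cols, top),
        bottom_rows=np.full(n_cols, bottom),
        scan=scan,
    )


def brute_force_contrast(levels, mask, offsets, n_levels):
    """Pair-enumeration oracle for co-occurrence contrast."""
    counts = {}
    n_rows, n_cols = levels.shape
    for dr, dc in offsets:
        for r in range(n_rows):
            for c in range(n_cols):
                r2, c2 = r + dr, c + dc
                if r2 < n_rows and c2 < n_cols and mask[r, c] and mask[r2, c2]:
                    for pair in ((levels[r, c], levels[r2, c2]),
                                 (levels[r2, c2], levels[r, c])):
                        counts[pair] = counts.get(pair, 0) + 1
    total = sum(counts.values())
    return sum((i - j) ** 2 * n / total for (i, j), n in counts.items())


class TestThickness:
    def test_uniform_height(self):
        roi = roi_from_matrix(np.ones((30, 5)), top=2, bottom=21)  # 19 rows
        assert rt.thickness(roi, 2.0).value == pytest.approx(38.0)

    def test_mean_of_heights(self):
        roi = roi_from_matrix(np.ones((30, 2)))
        roi.top_rows = np.array([0, 0])
        roi.bottom_rows = np.array([10, 20])
        assert rt.thickness(roi, 2.0).value == pytest.approx(30.0)

    def test_empty_roi_is_undefined(self):
        roi = roi_from_matrix(np.ones((10, 4)))
        roi.columns = roi.top_rows = roi.bottom_rows = np.array([], dtype=int)
        mv = rt.thickness(roi, 2.0)
        assert not mv.is_defined and mv.n_columns_used == 0


class TestContrast:
    def test_constant_roi_zero(self):
        roi = roi_from_matrix(np.full((12, 12), 5.0))
        assert rt.glcm_contrast(roi).value == pytest.approx(0.0)

    def test_two_level_stripes(self):
        # vertical stripes alternating min/max level; horizontal offset 1
        # -> every pair differs by (L-1), contrast = (L-1)^2
        n_levels = 8
        img = np.zeros((10, 10))
        img[:, 1::2] = 1.0
        roi = roi_from_matrix(img)
        mv = rt.glcm_contrast(roi, n_levels=n_levels, offsets=((0, 1),), range_quantile=1.0)
        assert mv.value == pytest.approx((n_levels - 1) ** 2)

    def test_checkerboard_exceeds_constant(self):
        img = np.indices((12, 12)).sum(axis=0) % 2
        assert rt.glcm_contrast(roi_from_matrix(img)).value > 0

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        scan, seg = random_scan_with_layers(rng, n_rows=32, n_cols=16)
        roi = rt.build_layer_roi(scan, seg, "GCL+IPL", "foveal")
        n_levels, offsets = 16, ((0, 1), (1, 0))
        mv = rt.glcm_contrast(roi, n_levels=n_levels, offsets=offsets)
        q = np.quantile(scan.reflectivity, 0.99)
        levels = np.minimum(
            (scan.reflectivity / q * n_levels).astype(int), n_levels - 1
        )
        expected = brute_force_contrast(levels, roi.mask(), offsets, n_levels)
        assert mv.value == pytest.approx(expected, rel=1e-12)


class TestFractalDimension:
    @pytest.mark.parametrize("beta,expected", [(2.0, 1.5), (0.0, 2.5)])
    def test_known_spectral_exponent_recovered(self, beta, expected):
        rng = np.random.default_rng(11)
        profiles = np.stack(
            [rt.power_law_profile(64, beta, rng) for _ in range(40)], axis=1
        )
        roi = roi_from_matrix(profiles - profiles.min() + 0.01)
        assert rt.fractal_dimension(roi).value == pytest.approx(expected, abs=0.05)

    def test_gain_invariance(self):
        rng = np.random.default_rng(3)
        profile = rt.power_law_profile(64, 1.5, rng)
        img = (profile - profile.min() + 0.1)[:, None] * np.ones((1, 3))
        fd1 = rt.fractal_dimension(roi_from_matrix(img)).value
        fd2 = rt.fractal_dimension(roi_from_matrix(img * 40.0)).value
        assert fd1 == pytest.approx(fd2, abs=1e-9)

    def test_short_and_flat_profiles_skipped(self):
        img = np.ones((6, 4))  # below the 8-sample minimum
        mv = rt.fractal_dimension(roi_from_matrix(img))
        assert not mv.is_defined


class TestTotalReflectance:
    def test_uniform_column_sum(self):
        # 20 pixels of 0.5 per column -> TR = 10 -> 10 dB
        roi = roi_from_matrix(np.full((20, 6), 0.5))
        assert rt.total_reflectance(roi).value == pytest.approx(10.0)

    def test_doubling_height_adds_3dB(self):
        a = rt.total_reflectance(roi_from_matrix(np.full((20, 6), 0.5))).value
        b = rt.total_reflectance(roi_from_matrix(np.full((40, 6), 0.5))).value
        assert b - a == pytest.approx(10 * np.log10(2), abs=1e-9)

    def test_monotone_in_height_at_fixed_reflectance(self):
        values = [
            rt.total_reflectance(roi_from_matrix(np.full((h, 4), 0.7))).value
            for h in (10, 20, 30, 40)
        ]
        assert np.all(np.diff(values) > 0)


class TestLayerIndex:
    def test_saturated_column(self):
        # every pixel equals I_sa -> LI = layer height in pixels
        roi = roi_from_matrix(np.full((30, 5), 3.0))
        assert rt.layer_index(roi).value == pytest.approx(30.0)

    def test_gain_invariance(self):
        rng = np.random.default_rng(4)
        img = rng.uniform(0.1, 2.0, (24, 8))
        li1 = rt.layer_index(roi_from_matrix(img)).value
        li2 = rt.layer_index(roi_from_matrix(img * 0.1)).value
        assert li1 == pytest.approx(li2, rel=1e-12)

    def test_zero_image_rejected(self):
        with pytest.raises(ValueError, match="I_sa"):
            rt.layer_index(roi_from_matrix(np.zeros((20, 4))))


class TestColumnSumOracles:
    @pytest.mark.parametrize("seed", range(5))
    def test_tr_and_li_equal_direct_sums(self, seed):
        """Eq-style identities: MR_k * H_k / dy equals the plain column sum."""
        rng = np.random.default_rng(100 + seed)
        scan, seg = random_scan_with_layers(rng)
        for layer in ("RNFL", "GCC", "ONL+IS"):
            roi = rt.build_layer_roi(scan, seg, layer, "perifoveal")
            sums = []
            for c, t, b in zip(roi.columns, roi.top_rows, roi.bottom_rows):
                mr = scan.reflectivity[t:b, c].mean()
                sums.append(mr * (b - t))  # MR_k * H_k in pixel units
            tr = rt.total_reflectance(roi).value
            assert tr == pytest.approx(10 * np.log10(np.mean(sums)), rel=1e-9)
            isa = np.quantile(scan.reflectivity, 0.99)
            li = rt.layer_index(roi).value
            assert li == pytest.approx(np.mean(sums) / isa, rel=1e-9)


class TestExtractFeatures:
    def test_thickness_matches_ground_truth(self, preprocessed_eye, phantom_eye):
        _, truth = phantom_eye
        scan_set, shadows = preprocessed_eye
        table = rt.extract_features(scan_set, shadows)
        thick = table[table.metric == "thickness_um"]
        for _, row in thick.iterrows():
            expected = truth["thickness_um"][row.layer][row.region]
            assert row.value == pytest.approx(expected, abs=2.0), (
                row.layer,
                row.region,
            )

    def test_gcc_thickness_is_sum_of_sublayers(self, preprocessed_eye):
        scan_set, shadows = preprocessed_eye
        table = rt.extract_features(scan_set, shadows)
        thick = table[table.metric == "thickness_um"].set_index(["layer", "region"])
        for region in ("foveal", "parafoveal", "perifoveal", "across_all"):
            gcc = thick.loc[("GCC", region), "value"]
            parts = (
                thick.loc[("RNFL", region), "value"]
                + thick.loc[("GCL+IPL", region), "value"]
            )
            assert gcc == pytest.approx(parts, abs=1e-9)

    def test_foveolar_rows_only_for_outer_layers(self, preprocessed_eye):
        scan_set, shadows = preprocessed_eye
        table = rt.extract_features(scan_set, shadows)
        foveolar_layers = set(table[table.region == "foveolar"].layer)
        assert foveolar_layers == {"ONL+IS", "OS", "RPE"}

    def test_undefined_metric_reported_missing_not_zero(self, preprocessed_eye):
        # RPE is ~6-7 px thick at 2 um spacing: below the FD minimum length
        scan_set, shadows = preprocessed_eye
        table = rt.extract_features(scan_set, shadows)
        rpe_fd = table[
            (table.layer == "RPE") & (table.metric == "fractal_dimension_au")
        ]
        assert rpe_fd.value.isna().all()
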