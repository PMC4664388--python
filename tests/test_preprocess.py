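"""Denoising, shadow exclusion, RPE normalization and quality gating."""

import numpy as np
import pytest

import retinotex as rt
from retinotex.types import BOUNDARY_NAMES


def flat_segmentation(n_cols, ilm=4.0, heights=(6, 8, 5, 5, 10, 3, 3)):
    rows = [np.full(n_cols, float(ilm))]
    for h in heights:
        rows.append(rows[-1] + h)
    return rt.LayerSegmentation(np.vstack(rows))


class TestComplexDiffusion:
    def test_constant_image_unchanged(self):
        img = np.full((32, 32), 7.0)
        out = rt.denoise_complex_diffusion(img, iterations=10)
        assert np.allclose(out, img)

    def test_zero_iterations_is_identity(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 100, (20, 20))
        assert np.array_equal(rt.denoise_complex_diffusion(img, iterations=0), img)

    def test_step_edge_preserved_while_noise_shrinks(self):
        rng = np.random.default_rng(1)
        img = np.full((40, 80), 50.0)
        img[:, 40:] = 200.0
        noisy = img + rng.normal(0, 10, img.shape)
        noisy -= noisy.min()  # keep non-negative
        out = rt.denoise_complex_diffusion(noisy, iterations=10)
        # off-edge variance strictly decreases
        assert out[:, :30].var() < noisy[:, :30].var()
        assert out[:, 50:].var() < noisy[:, 50:].var()
        # the step location (max |lateral gradient| column) is unchanged
        grad_before = np.abs(np.diff(noisy.mean(axis=0)))
        grad_after = np.abs(np.diff(out.mean(axis=0)))
        assert np.argmax(grad_after) == np.argmax(grad_before)

    def test_mean_preserved(self):
        rng = np.random.default_rng(2)
        img = rng.gamma(4.0, 25.0, (64, 64))
        out = rt.denoise_complex_diffusion(img, iterations=10)
        assert abs(out.mean() - img.mean()) / img.mean() < 0.05

    def test_non_finite_input_rejected(self):
        img = np.ones((8, 8))
        img[3, 3] = np.nan
        with pytest.raises(ValueError, match="non-finite"):
            rt.denoise_complex_diffusion(img)


class TestShadowDetection:
    def test_planted_shadows_recovered(self, phantom_eye, small_spec):
        scan_set, truth = phantom_eye
        detected = rt.detect_vessel_shadows(
            scan_set.scans[0], scan_set.segmentations[0]
        )
        assert detected >= set(truth["shadow_columns"])
        # at most 2 spurious columns per shadow edge (dilation allowance)
        spurious = detected - set(truth["shadow_columns"])
        n_runs = 2  # the planted columns form two contiguous runs
        assert len(spurious) <= 2 * 2 * n_runs

    def test_uniform_image_has_no_shadows(self):
        n_cols = 64
        scan = rt.BScan(np.full((48, n_cols), 100.0), 2.0, 6.0, 32)
        assert rt.detect_vessel_shadows(scan, flat_segmentation(n_cols)) == frozenset()

    def test_all_zero_image_skipped_with_empty_result(self):
        n_cols = 32
        scan = rt.BScan(np.zeros((48, n_cols)), 2.0, 6.0, 16)
        assert rt.detect_vessel_shadows(scan, flat_segmentation(n_cols)) == frozenset()

    def test_no_attenuation_no_detection(self):
        spec = rt.PhantomSpec(
            n_columns=96, n_rows=384, shadow_depth_factor=1.0, seed=3
        )
        scan_set, _ = rt.generate_phantom_eye(spec)
        detected = rt.detect_vessel_shadows(scan_set.scans[0], scan_set.segmentations[0])
        assert detected == frozenset()


class TestNRPE:
    def test_divides_by_rpe_band_mean(self):
        n_cols = 16
        seg = flat_segmentation(n_cols)
        img = np.full((48, n_cols), 100.0)
        top, bottom = seg.layer_interval("RPE")
        img[top[0] : bottom[0], :] = 400.0
        scan = rt.BScan(img, 2.0, 6.0, 8)
        out = rt.normalize_to_rpe(scan, seg)
        assert np.allclose(out.reflectivity[0, 0], 100.0 / 400.0)

    def test_rpe_band_mean_becomes_one(self, phantom_eye):
        scan_set, _ = phantom_eye
        scan, seg = scan_set.scans[0], scan_set.segmentations[0]
        out = rt.normalize_to_rpe(scan, seg)
        top, bottom = seg.layer_interval("RPE")
        values = np.concatenate(
            [out.reflectivity[top[c] : bottom[c], c] for c in range(out.n_columns)]
        )
        assert abs(values.mean() - 1.0) < 1e-9

    def test_global_gain_invariance(self, phantom_eye):
        from dataclasses import replace

        scan_set, _ = phantom_eye
        scan, seg = scan_set.scans[0], scan_set.segmentations[0]
        out1 = rt.normalize_to_rpe(scan, seg)
        scaled = replace(scan, reflectivity=scan.reflectivity * 3.7)
        out2 = rt.normalize_to_rpe(scaled, seg)
        assert np.allclose(out1.reflectivity, out2.reflectivity)

    def test_idempotent(self, phantom_eye):
        scan_set, _ = phantom_eye
        scan, seg = scan_set.scans[0], scan_set.segmentations[0]
        once = rt.normalize_to_rpe(scan, seg)
        twice = rt.normalize_to_rpe(once, seg)
        assert np.allclose(once.reflectivity, twice.reflectivity)

    def test_zero_reference_rejected(self):
        n_cols = 8
        scan = rt.BScan(np.zeros((48, n_cols)), 2.0, 6.0, 4)
        with pytest.raises(ValueError, match="no reference signal"):
            rt.normalize_to_rpe(scan, flat_segmentation(n_cols))


def scan_set_with_cpts(cpts_um):
    """Six flat-layer scans whose total-retina thickness at the fovea is given."""
    n_cols, dy = 16, 2.0
    scans, segs = [], []
    for cpt in cpts_um:
        total_rows = cpt / dy
        # six equal layers from the ILM to the OS/RPE junction, then the RPE
        seg_rows = [np.full(n_cols, 4.0)]
        for _ in range(6):
            seg_rows.append(seg_rows[-1] + total_rows / 6.0)
        seg_rows.append(seg_rows[-1] + 5)
        segs.append(rt.LayerSegmentation(np.vstack(seg_rows)))
        scans.append(rt.BScan(np.ones((200, n_cols)), dy, 6.0, 8, signal_strength=9))
    return rt.RadialScanSet(scans, segs)


class TestQualityGate:
    def test_equal_cpts_give_sqf_one(self):
        report = rt.compute_sqf(scan_set_with_cpts([210] * 6))
        assert report.cpt_sd_percent == 0 and report.sqf == 1

    def test_one_outlier_fails_the_ten_percent_rule(self):
        report = rt.compute_sqf(scan_set_with_cpts([200, 200, 200, 200, 200, 260]))
        assert report.cpt_sd_percent == pytest.approx(11.66, abs=0.01)
        assert report.sqf == 0

    def test_small_spread_passes(self):
        report = rt.compute_sqf(scan_set_with_cpts([200, 202, 198, 201, 199, 200]))
        # sample SD sqrt(2)/200: well under the 10% rule
        assert report.cpt_sd_percent == pytest.approx(0.7071, abs=0.001)
        assert report.sqf == 1

    @pytest.mark.parametrize(
        "signal,sqf_cpts,accepted",
        [
            (6, [210] * 6, False),  # SS <= 6 excluded
            (7, [210] * 6, True),
            (9, [200, 200, 200, 200, 200, 260], False),  # SQF=0 regardless of SS
        ],
    )
    def test_gate(self, signal, sqf_cpts, accepted):
        scan_set = scan_set_with_cpts(sqf_cpts)
        for s in scan_set.scans:
            s.signal_strength = signal
        ok, reasons = rt.gate_scan_set(scan_set)
        assert ok is accepted
        if not accepted:
            assert reasons
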