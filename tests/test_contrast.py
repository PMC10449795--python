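"""Contrast statistic, percent increase, block selection, CIELAB, cohort tables."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from redpupil.contrast import (
    BlockPlacementError,
    PixelBlock,
    ZeroContrastError,
    contrast_percent_increase,
    cross_device_table,
    iris_luminance,
    pupil_iris_contrast,
    select_pixel_blocks,
    spectral_contrast_comparison,
)
from redpupil.datasets import load_cross_device_reference, reference_participant_means
from redpupil.segmentation import PupilDetection, detect_pupil
from redpupil.simulate import (
    FAR_RED,
    FULL_VISIBLE,
    SpectralEyeParams,
    iris_reflectance,
    render_eye_frame,
)


class TestBlockSelection:
    def test_iris_block_at_twice_radius_on_diagonal(self, dark_eye):
        frame = render_eye_frame(dark_eye, 60.0, FAR_RED, seed=0)
        det = PupilDetection(valid=True, center=(120.0, 160.0), diameter_px=60.0, confidence=1.0)
        pupil_blk, iris_blk = select_pixel_blocks(frame, det)
        assert pupil_blk.top_left == (113, 153)  # centered on the pupil
        ir = iris_blk.top_left[0] + 7
        ic = iris_blk.top_left[1] + 7
        dist = np.hypot(ir - 120.0, ic - 160.0)
        assert dist == pytest.approx(60.0, abs=1.5)  # 2 x radius
        assert abs(abs(ir - 120.0) - abs(ic - 160.0)) <= 1.5  # on a 45-degree diagonal

    def test_glare_on_candidate_moves_selection(self, dark_eye):
        import dataclasses

        # saturate the 45-degree (upper-right) candidate position
        d = 60.0
        r, c = 120.0 - d / np.sqrt(2), 160.0 + d / np.sqrt(2)
        eye = dataclasses.replace(dark_eye, glare_spots=((r, c, 6.0, 255.0),))
        frame = render_eye_frame(eye, d, FAR_RED, seed=0)
        det = PupilDetection(valid=True, center=(120.0, 160.0), diameter_px=d, confidence=1.0)
        _, iris_blk = select_pixel_blocks(frame, det)
        ir, ic = iris_blk.top_left[0] + 7, iris_blk.top_left[1] + 7
        assert not (ir < 120 and ic > 160)  # not the glare-bearing upper-right diagonal
        assert not (iris_blk.pixels(frame) >= 240).any()

    def test_invalid_detection_rejected(self, study_frame):
        with pytest.raises(BlockPlacementError):
            select_pixel_blocks(study_frame, PupilDetection(valid=False))

    def test_out_of_frame_signalled(self):
        frame = np.full((40, 40), 100, np.uint8)
        det = PupilDetection(valid=True, center=(20.0, 20.0), diameter_px=38.0, confidence=1.0)
        with pytest.raises(BlockPlacementError):
            select_pixel_blocks(frame, det)


class TestPupilIrisContrast:
    def _frame_with_blocks(self, pupil_value, iris_value):
        frame = np.full((60, 60), 128, np.uint8)
        pupil = PixelBlock(top_left=(5, 5), label="pupil")
        iris = PixelBlock(top_left=(30, 30), label="iris")
        frame[pupil.slices()] = pupil_value
        frame[iris.slices()] = iris_value
        return frame, pupil, iris

    def test_uniform_blocks(self):
        frame, pupil, iris = self._frame_with_blocks(50, 200)
        m = pupil_iris_contrast(frame, pupil, iris)
        assert (m.pupil_intensity, m.iris_intensity, m.contrast) == (50.0, 200.0, 150.0)

    def test_identical_blocks_zero_contrast(self):
        frame, pupil, _ = self._frame_with_blocks(77, 77)
        m = pupil_iris_contrast(frame, pupil, pupil)
        assert m.contrast == 0.0

    def test_simulator_closed_form(self, dark_eye):
        frame = render_eye_frame(dark_eye, 60.0, FAR_RED, seed=0)
        det = detect_pupil(frame)
        pupil_blk, iris_blk = select_pixel_blocks(frame, det)
        m = pupil_iris_contrast(frame, pupil_blk, iris_blk)
        expected = 255.0 * (iris_reflectance(dark_eye, FAR_RED) - dark_eye.pupil_reflectance)
        assert m.contrast == pytest.approx(expected, abs=1.0)  # 8-bit quantisation

    def test_rejects_multichannel(self, dark_eye):
        frame = render_eye_frame(dark_eye, 60.0, FULL_VISIBLE, seed=0)
        blk = PixelBlock(top_left=(10, 10))
        with pytest.raises(ValueError):
            pupil_iris_contrast(frame, blk, blk)

    def test_affine_sensitivity(self):
        frame, pupil, iris = self._frame_with_blocks(40, 180)
        base = pupil_iris_contrast(frame, pupil, iris).contrast
        shifted = pupil_iris_contrast(frame.astype(float) + 17.0, pupil, iris).contrast
        scaled = pupil_iris_contrast(frame.astype(float) * 1.7, pupil, iris).contrast
        assert shifted == pytest.approx(base, abs=1e-9)
        assert scaled == pytest.approx(1.7 * base, rel=1e-12)


class TestPercentIncrease:
    @pytest.mark.parametrize(
        "far,full,expected",
        [(10.0, 2.0, 400.0), (5.0, -5.0, 200.0), (7.3, 7.3, 0.0), (2.0, 10.0, -80.0)],
    )
    def test_examples(self, far, full, expected):
        assert contrast_percent_increase(far, full) == pytest.approx(expected, rel=1e-12)

    def test_zero_denominator_signalled(self):
        with pytest.raises(ZeroContrastError):
            contrast_percent_increase(5.0, 0.0)

    @given(
        far=st.floats(-500, 500),
        full=st.floats(-500, 500).filter(lambda v: abs(v) > 1e-6),
    )
    def test_matches_direct_formula(self, far, full):
        direct = 100.0 * (far - full) / abs(full)
        assert contrast_percent_increase(far, full) == pytest.approx(direct, rel=1e-12, abs=1e-9)


class TestIrisLuminance:
    def _uniform_rgb(self, value):
        return np.full((30, 30, 3), value, np.uint8)

    def test_white_and_black_anchor_points(self):
        blk = PixelBlock(top_left=(5, 5))
        assert iris_luminance(self._uniform_rgb(255), blk).iris_luminance == pytest.approx(100.0, abs=1e-6)
        assert iris_luminance(self._uniform_rgb(0), blk).iris_luminance == pytest.approx(0.0, abs=1e-6)

    def test_mid_gray_matches_srgb_reference(self):
        # oracle: linearise 119/255 with the sRGB transfer function, then L* = 116 f(Y) - 16
        srgb = 119.0 / 255.0
        y = ((srgb + 0.055) / 1.055) ** 2.4
        expected = 116.0 * y ** (1.0 / 3.0) - 16.0
        blk = PixelBlock(top_left=(5, 5))
        got = iris_luminance(self._uniform_rgb(119), blk).iris_luminance
        assert got == pytest.approx(expected, abs=0.05)

    def test_monotone_in_gray_level(self):
        blk = PixelBlock(top_left=(5, 5))
        values = [iris_luminance(self._uniform_rgb(v), blk).iris_luminance for v in range(0, 256, 32)]
        assert np.all(np.diff(values) > 0)

    def test_rejects_single_channel(self):
        with pytest.raises(ValueError):
            iris_luminance(np.zeros((30, 30), np.uint8), PixelBlock(top_left=(5, 5)))


class TestSpectralClosure:
    def test_percent_increase_positive_and_monotone_in_melanin(self):
        increases = []
        for load in (0.3, 1.0, 1.8, 2.5):
            eye = SpectralEyeParams(melanin_load=load, noise_sd=0.0)
            far = render_eye_frame(eye, 60.0, FAR_RED, seed=0)
            full = render_eye_frame(eye, 60.0, FULL_VISIBLE, seed=0)
            cmp_ = spectral_contrast_comparison(far, full, detect_pupil(far))
            increases.append(cmp_.percent_increase)
        assert all(v > 0 for v in increases)
        assert np.all(np.diff(increases) > 0)


class TestCrossDeviceTable:
    def test_constant_entries(self):
        df = pd.DataFrame(
            {
                "participant": [1, 1, 2, 2],
                "device": ["a", "b", "a", "b"],
                "percent_increase": [5.0, 5.0, 5.0, 5.0],
            }
        )
        summary = cross_device_table(df)
        assert np.allclose(summary.per_participant["mean"], 5.0)
        assert np.allclose(summary.per_participant["std"], 0.0)
        assert summary.grand_mean() == pytest.approx(5.0)

    def test_single_device_std_undefined(self):
        df = pd.DataFrame({"participant": [1], "device": ["a"], "percent_increase": [3.0]})
        summary = cross_device_table(df)
        assert summary.per_participant["mean"].iloc[0] == 3.0
        assert np.isnan(summary.per_participant["std"].iloc[0])

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cross_device_table(pd.DataFrame(columns=["participant", "device", "percent_increase"]))

    def test_reference_cohort_aggregates(self):
        summary = cross_device_table(reference_participant_means())
        assert summary.n_participants == 11
        assert summary.grand_mean() == pytest.approx(451.5, abs=0.1)
        assert summary.grand_mean("dark_brown") == pytest.approx(624.6, abs=0.1)

    def test_reference_table_shape(self):
        wide = load_cross_device_reference()
        assert len(wide) == 11
        assert (wide["eye_color"] == "dark_brown").sum() == 7
        # luminance decreases monotonically down the cohort (light -> dark irises)
        assert (wide["iris_luminance"].diff().dropna() <= 0).all()
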