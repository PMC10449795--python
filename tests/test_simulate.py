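"""Simulator: spectral model, pupil kinetics, frame rendering, video assembly."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from redpupil.simulate import (
    FAR_RED,
    FULL_VISIBLE,
    GroundTruthTrace,
    PLRProtocol,
    PupilDynamicsParams,
    SpectralBand,
    SpectralEyeParams,
    iris_reflectance,
    render_eye_frame,
    render_plr_video,
    simulate_plr_diameter,
)


class TestIrisReflectance:
    def test_closed_form(self):
        # independent evaluation of base * exp(-load * absorption)
        params = SpectralEyeParams(melanin_load=2.0, iris_base_reflectance=0.8)
        band = SpectralBand("test", 0.5)
        assert iris_reflectance(params, band) == pytest.approx(0.8 * math.exp(-1.0), rel=1e-12)

    def test_zero_melanin_returns_base(self):
        params = SpectralEyeParams(melanin_load=0.0, iris_base_reflectance=0.61)
        for band in (FAR_RED, FULL_VISIBLE):
            assert iris_reflectance(params, band) == pytest.approx(0.61, rel=1e-12)

    @given(load=st.floats(0.05, 5.0), delta=st.floats(0.05, 2.0))
    def test_strictly_decreasing_in_melanin(self, load, delta):
        lo = SpectralEyeParams(melanin_load=load)
        hi = SpectralEyeParams(melanin_load=load + delta)
        for band in (FAR_RED, FULL_VISIBLE):
            assert iris_reflectance(hi, band) < iris_reflectance(lo, band)

    @given(load=st.floats(0.01, 5.0))
    def test_far_red_brighter_than_full_visible(self, load):
        params = SpectralEyeParams(melanin_load=load)
        assert iris_reflectance(params, FAR_RED) > iris_reflectance(params, FULL_VISIBLE)

    def test_band_invariant_enforced(self):
        assert FAR_RED.effective_melanin_absorption < FULL_VISIBLE.effective_melanin_absorption
        with pytest.raises(ValueError):
            SpectralBand("bad", -0.1)
        with pytest.raises(ValueError):
            SpectralBand("bad", 1.0, channel_absorption=(2.0, 1.5, 1.0))


class TestPupilDynamics:
    def test_zero_amplitude_gives_constant_trace(self):
        dyn = PupilDynamicsParams(baseline_diameter_px=55.0, constriction_amplitude=0.0)
        trace = simulate_plr_diameter(dyn, PLRProtocol())
        assert np.allclose(trace.diameter_px, 55.0)

    def test_minimum_reaches_constricted_diameter(self):
        dyn = PupilDynamicsParams(baseline_diameter_px=60.0, constriction_amplitude=0.3)
        trace = simulate_plr_diameter(dyn, PLRProtocol())
        # asymptote gap after the 1 s stimulus is far below one sample's change
        assert trace.diameter_px.min() == pytest.approx(42.0, abs=0.5)
        assert np.all(trace.diameter_px > 0)
        assert np.all(trace.diameter_px <= 60.0 + 1e-9)

    def test_latency_holds_baseline(self):
        dyn = PupilDynamicsParams(baseline_diameter_px=60.0, constriction_amplitude=0.3, latency_s=0.2)
        trace = simulate_plr_diameter(dyn, PLRProtocol())
        before = trace.timestamps_s < 1.2 - 1e-9
        assert np.allclose(trace.diameter_px[before], 60.0)

    def test_redilation_recovers_stated_fraction(self):
        dyn = PupilDynamicsParams(
            baseline_diameter_px=60.0, constriction_amplitude=0.3, redilation_fraction=0.6
        )
        protocol = PLRProtocol()
        trace = simulate_plr_diameter(dyn, protocol)
        d_min = trace.diameter_px.min()
        # last sample is one step before t=5 s; allow that step's worth of slack
        recovered = (trace.diameter_px[-1] - d_min) / (60.0 - d_min)
        assert recovered == pytest.approx(0.6, abs=0.02)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            PupilDynamicsParams(baseline_diameter_px=-5.0)
        with pytest.raises(ValueError):
            PupilDynamicsParams(constriction_amplitude=1.0)
        with pytest.raises(ValueError):
            PLRProtocol(frame_rate_hz=0.0)

    def test_frame_count_follows_protocol(self):
        assert PLRProtocol().n_frames == 300
        assert PLRProtocol(frame_rate_hz=30).n_frames == 150
        assert PLRProtocol(frame_rate_hz=29.97).n_frames == round(5 * 29.97)


class TestRenderFrame:
    def test_pupil_block_is_constant_without_noise(self):
        params = SpectralEyeParams(pupil_reflectance=0.2, noise_sd=0.0)
        frame = render_eye_frame(params, 60.0, FAR_RED, seed=0)
        block = frame[113:128, 153:168]  # central 15x15, center (120, 160)
        assert block.shape == (15, 15)
        assert np.all(block == 51)  # 255 * 0.2

    def test_determinism_same_seed(self, study_eye):
        a = render_eye_frame(study_eye, 60.0, FAR_RED, seed=42)
        b = render_eye_frame(study_eye, 60.0, FAR_RED, seed=42)
        assert np.array_equal(a, b)
        c = render_eye_frame(study_eye, 60.0, FAR_RED, seed=43)
        assert not np.array_equal(a, c)

    def test_dark_iris_contrast_larger_in_far_red(self):
        params = SpectralEyeParams(melanin_load=3.0, noise_sd=0.0)
        far = render_eye_frame(params, 60.0, FAR_RED, seed=0).astype(float)
        full = render_eye_frame(params, 60.0, FULL_VISIBLE, seed=0)[..., 0].astype(float)
        pupil = (slice(113, 128), slice(153, 168))
        iris = (slice(113, 128), slice(203, 218))  # on the iris annulus, right of center
        contrast_far = far[iris].mean() - far[pupil].mean()
        contrast_full = full[iris].mean() - full[pupil].mean()
        assert contrast_far > contrast_full > 0

    def test_full_visible_is_reddest_in_red(self, dark_eye):
        frame = render_eye_frame(dark_eye, 60.0, FULL_VISIBLE, seed=0).astype(int)
        iris = frame[113:128, 203:218]
        assert iris[..., 0].mean() >= iris[..., 1].mean() >= iris[..., 2].mean()

    def test_rejects_pupil_larger_than_iris(self, dark_eye):
        with pytest.raises(ValueError):
            render_eye_frame(dark_eye, 2 * dark_eye.iris_radius_px, FAR_RED, seed=0)

    def test_intensities_are_8bit(self, study_frame):
        assert study_frame.dtype == np.uint8


class TestRenderVideo:
    def test_frame_count_and_blink_free_flags(self, dark_eye, default_dynamics):
        frames, truth = render_plr_video(dark_eye, default_dynamics, PLRProtocol(), FAR_RED, seed=0)
        assert len(frames) == 300
        assert len(truth) == 300
        assert not truth.blink_flag.any()

    def test_blink_window_flags_exact_samples(self, dark_eye, default_dynamics):
        frames, truth = render_plr_video(
            dark_eye, default_dynamics, PLRProtocol(), FAR_RED, blink_times_s=(2.0,), seed=0
        )
        idx = np.flatnonzero(truth.blink_flag)
        assert idx.tolist() == list(range(120, 129))  # [2.0 s, 2.15 s) at 60 Hz
        # occluded frames are visibly different from the open-eye render
        open_frames, _ = render_plr_video(dark_eye, default_dynamics, PLRProtocol(), FAR_RED, seed=0)
        assert not np.array_equal(frames[124], open_frames[124])

    def test_overlapping_blinks_rejected(self, dark_eye, default_dynamics):
        with pytest.raises(ValueError):
            render_plr_video(
                dark_eye, default_dynamics, PLRProtocol(), FAR_RED, blink_times_s=(2.0, 2.1), seed=0
            )
        with pytest.raises(ValueError):
            render_plr_video(
                dark_eye, default_dynamics, PLRProtocol(), FAR_RED, blink_times_s=(9.0,), seed=0
            )

    def test_video_determinism(self, dark_eye, default_dynamics, short_protocol):
        a, _ = render_plr_video(dark_eye, default_dynamics, short_protocol, FAR_RED, seed=5)
        b, _ = render_plr_video(dark_eye, default_dynamics, short_protocol, FAR_RED, seed=5)
        assert np.array_equal(a, b)


def test_ground_truth_trace_invariants():
    with pytest.raises(ValueError):
        GroundTruthTrace(
            timestamps_s=np.array([0.0, 1.0]),
            diameter_px=np.array([60.0]),
            blink_flag=np.array([False, False]),
            center_px=np.zeros((2, 2)),
        )
    with pytest.raises(ValueError):
        GroundTruthTrace(
            timestamps_s=np.array([0.0, 0.0]),
            diameter_px=np.array([60.0, 60.0]),
            blink_flag=np.array([False, False]),
            center_px=np.zeros((2, 2)),
        )
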