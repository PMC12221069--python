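from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, strategies as st

import twinkledop as td
from twinkledop.slowtime import SlowTimeWindowSpec

P = td.DopplerPhysicsParams()  # 6.5 MHz, 1540 m/s, theta 0, tPRI 250 ms


class TestPhysics:
    def test_cw_shift_hand_values(self):
        assert td.doppler_shift_cw(0.0, P) == 0.0
        # 2 * 0.01 * 6.5e6 / 1540 = 84.4156 Hz
        assert td.doppler_shift_cw(0.01, P) == pytest.approx(84.4156, abs=0.01)
        side = replace(P, theta_rad=np.pi / 2)
        assert td.doppler_shift_cw(0.5, side) == pytest.approx(0.0, abs=1e-9)

    def test_received_freq_algebraic_values(self):
        assert td.received_freq(0.0, P) == pytest.approx(P.f0_hz)
        assert td.doppler_shift_exact(0.0, P) == 0.0
        # (c + c/3) / (c - c/3) = 2
        assert td.received_freq(P.c0_m_s / 3, P) == pytest.approx(2 * P.f0_hz)

    def test_exact_and_cw_agree_to_first_order(self):
        v = 1e-4 * P.c0_m_s
        cw = td.doppler_shift_cw(v, P)
        exact = td.doppler_shift_exact(v, P)
        assert abs(exact - cw) / cw < 2e-4

    def test_delay_change_hand_value(self):
        # 2 * 1 mm/s * 0.25 s / 1540 m/s = 3.2468e-7 s
        assert td.delay_change(1e-3, P) == pytest.approx(3.2468e-7, rel=1e-4)
        assert td.delay_change(0.0, P) == 0.0

    @given(st.floats(-1.0, 1.0), st.floats(-1.4, 1.4))
    def test_delay_round_trip_is_identity(self, v, theta):
        params = replace(P, theta_rad=theta)
        assert td.velocity_from_delay(td.delay_change(v, params),
                                      params) == pytest.approx(v, abs=1e-12)

    def test_velocity_from_delay_rejects_perpendicular_beam(self):
        with pytest.raises(ValueError, match="pi/2"):
            td.velocity_from_delay(1e-7, replace(P, theta_rad=np.pi / 2))

    @given(st.floats(-10, 10), st.floats(-np.pi, np.pi))
    def test_slowtime_freq_equals_cw_shift(self, v, theta):
        params = replace(P, theta_rad=theta)
        assert td.slowtime_freq(v, params) == td.doppler_shift_cw(v, params)

    def test_superluminal_velocity_rejected(self):
        with pytest.raises(ValueError):
            td.doppler_shift_cw(2000.0, P)
        with pytest.raises(ValueError):
            td.received_freq(1540.0, P)


class TestPhaseDiff:
    def test_hand_computed_wrapped_values(self):
        assert td.phase_diff_frequency(0.3, 0.3, 0.25) == 0.0
        # (pi/2) / (2 pi * 0.25) = 1 Hz
        assert td.phase_diff_frequency(0.0, np.pi / 2, 0.25) == pytest.approx(1.0)
        # 3 pi/2 wraps to -pi/2 -> -1 Hz
        assert td.phase_diff_frequency(0.0, 3 * np.pi / 2, 0.25) == pytest.approx(-1.0)
        # pi maps to +Nyquist, not -Nyquist
        assert td.phase_diff_frequency(0.0, np.pi, 0.25) == pytest.approx(2.0)

    def test_nonpositive_dt_rejected(self):
        with pytest.raises(ValueError):
            td.phase_diff_frequency(0.0, 1.0, 0.0)

    @given(st.floats(-50, 50), st.floats(-50, 50))
    def test_bounded_by_slow_time_nyquist(self, a, b):
        f = td.phase_diff_frequency(a, b, 0.25)
        assert -2.0 < f <= 2.0 + 1e-12


def lesion_median_freq(images, cfg, geometry, margin_mm=1.0):
    from conftest import lesion_pixel_bounds
    s0, s1, l0, l1 = lesion_pixel_bounds(cfg, geometry, margin_mm)
    meds = []
    for im in images:
        px = im.freq_hz[l0:l1, s0:s1]
        px = px[px != 0]
        if px.size:
            meds.append(np.median(px))
    return float(np.median(meds))


def coherent_config(small_geometry, small_timing, v, seed=11, noise=0.05):
    g = small_geometry
    return td.PhantomConfig(
        geometry=g, timing=small_timing,
        lesion_center_mm=(g.depth_extent_mm / 2, g.width_extent_mm / 2),
        lesion_depth_mm=3.0, lesion_width_mm=4.0,
        lesion_motion=td.MotionModel(kind="coherent", velocity_m_s=v),
        noise_sigma=noise, seed=seed)


class TestConstructDopplerFrames:
    def test_forty_frames_give_31_windows_30_images(self, default_jitter_run):
        images = default_jitter_run["images_during"]
        assert len(images) == 30
        seq = default_jitter_run["seq"]
        binmax = td.construct_doppler_frames(seq, estimator="binmax")
        assert len(binmax) == 31

    def test_static_zero_noise_phantom_gives_all_zero_images(
            self, small_geometry, small_timing):
        cfg = coherent_config(small_geometry, small_timing, v=0.0, noise=0.0)
        cfg = replace(cfg, lesion_motion=td.MotionModel())
        images = td.construct_doppler_frames(td.generate_sequence(cfg))
        for im in images:
            assert np.all(im.freq_hz == 0.0)

    def test_coherent_motion_recovers_slowtime_frequency(
            self, small_geometry, small_timing):
        params = replace(P, t_pri_s=small_timing.frame_interval_s)
        f_true = 1.2
        v = f_true * params.c0_m_s / (2 * params.f0_hz)
        cfg = coherent_config(small_geometry, small_timing, v)
        seq = td.generate_sequence(cfg)
        images = td.construct_doppler_frames(seq)
        med = lesion_median_freq(images, cfg, seq.geometry)
        bin_width = 1.0 / (10 * small_timing.frame_interval_s)
        assert abs(med - td.slowtime_freq(v, params)) < bin_width

    def test_reversed_motion_negates_recovered_frequency(
            self, small_geometry, small_timing):
        params = replace(P, t_pri_s=small_timing.frame_interval_s)
        v = 1.2 * params.c0_m_s / (2 * params.f0_hz)
        meds = []
        for vel in (v, -v):
            cfg = coherent_config(small_geometry, small_timing, vel)
            seq = td.generate_sequence(cfg)
            meds.append(lesion_median_freq(
                td.construct_doppler_frames(seq), cfg, seq.geometry))
        assert meds[0] > 0 > meds[1]
        assert meds[0] == pytest.approx(-meds[1], rel=0.1)

    def test_binmax_and_phasediff_agree_on_coherent_motion(
            self, small_geometry, small_timing):
        params = replace(P, t_pri_s=small_timing.frame_interval_s)
        v = 1.2 * params.c0_m_s / (2 * params.f0_hz)
        cfg = coherent_config(small_geometry, small_timing, v)
        seq = td.generate_sequence(cfg)
        med_pd = lesion_median_freq(
            td.construct_doppler_frames(seq), cfg, seq.geometry)
        med_bm = lesion_median_freq(
            td.construct_doppler_frames(seq, estimator="binmax"),
            cfg, seq.geometry)
        bin_width = 1.0 / (10 * small_timing.frame_interval_s)
        assert np.sign(med_pd) == np.sign(med_bm)
        assert abs(med_pd - med_bm) <= bin_width

    def test_outputs_bounded_by_nyquist_and_masked_pixels_zero(
            self, default_jitter_run):
        nyq = 0.5 / default_jitter_run["seq"].timing.frame_interval_s
        for im in default_jitter_run["images_during"][:5]:
            assert np.all(np.abs(im.freq_hz) <= nyq + 1e-9)

    def test_too_few_frames_error_names_minimum(self, small_sequence):
        with pytest.raises(ValueError, match="at least 21"):
            td.construct_doppler_frames(
                small_sequence, spec=SlowTimeWindowSpec(window_len=20, step=1))
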