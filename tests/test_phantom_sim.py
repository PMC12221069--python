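from dataclasses import replace

import numpy as np
import pytest
from scipy.signal import correlate, hilbert

import twinkledop as td
from twinkledop.phantom_sim import Scatterers, generate_scatterers


def tiny_geometry():
    return td.AcquisitionGeometry(n_samples=400, n_lines=4,
                                  depth_extent_mm=7.7, width_extent_mm=1.3,
                                  center_freq_hz=6.5e6)


class TestScatterers:
    def test_zero_density_gives_empty_set(self, small_config):
        cfg = replace(small_config, scatterer_density=0.0)
        assert generate_scatterers(cfg).n == 0

    def test_seed_determinism(self, small_config):
        a = generate_scatterers(small_config)
        b = generate_scatterers(small_config)
        assert np.array_equal(a.z_m, b.z_m)
        assert np.array_equal(a.reflectivity, b.reflectivity)

    def test_count_matches_poisson_expectation(self):
        g = tiny_geometry()
        density = 5.0
        counts = []
        for seed in range(200):
            cfg = td.PhantomConfig(geometry=g, scatterer_density=density,
                                   lesion_center_mm=(3.85, 0.65),
                                   lesion_depth_mm=1.0, lesion_width_mm=0.5,
                                   seed=seed)
            counts.append(generate_scatterers(cfg).n)
        expected = density * g.depth_extent_mm * g.width_extent_mm
        # Monte-Carlo mean vs Poisson expectation, ~4 sigma band
        tol = 4 * np.sqrt(expected / 200)
        assert abs(np.mean(counts) - expected) < tol

    def test_in_lesion_flag_respects_rectangle(self, small_config):
        sc = generate_scatterers(small_config)
        cd, cw = small_config.lesion_center_mm
        depth_mm = sc.z_m * 1000.0
        inside = np.abs(depth_mm - cd) <= small_config.lesion_depth_mm / 2
        # every flagged scatterer is axially inside the rectangle
        assert np.all(inside[sc.in_lesion])


class TestSynthesizeFrame:
    def test_no_scatterers_gives_zero_frame(self):
        g = tiny_geometry()
        sc = Scatterers(z_m=np.array([]), line=np.array([], dtype=int),
                        reflectivity=np.array([]),
                        in_lesion=np.array([], dtype=bool))
        frame = td.synthesize_frame(sc, g, np.array([]))
        assert frame.shape == (4, 400)
        assert np.all(frame == 0)

    def test_single_scatterer_echo_lands_at_analytic_time(self):
        g = tiny_geometry()
        z = 0.004  # 4 mm
        sc = Scatterers(z_m=np.array([z]), line=np.array([1]),
                        reflectivity=np.array([1.0]),
                        in_lesion=np.array([False]))
        frame = td.synthesize_frame(sc, g, np.zeros(1))
        envelope = np.abs(hilbert(frame[1].astype(float)))
        expected = 2 * z / g.speed_of_sound_m_s * g.sampling_freq_hz
        assert abs(np.argmax(envelope) - expected) <= 1.0
        assert np.all(frame[0] == 0) and np.all(frame[2:] == 0)

    def test_axial_shift_moves_echo_by_round_trip_samples(self):
        g = tiny_geometry()
        rng = np.random.default_rng(0)
        n = 30
        sc = Scatterers(z_m=rng.uniform(0.002, 0.0055, n),
                        line=np.zeros(n, dtype=int),
                        reflectivity=rng.normal(size=n),
                        in_lesion=np.zeros(n, dtype=bool))
        dz = 120e-6
        a = td.synthesize_frame(sc, g, np.zeros(n))[0].astype(float)
        b = td.synthesize_frame(sc, g, np.full(n, dz))[0].astype(float)
        lag = np.argmax(correlate(b, a, mode="full")) - (len(a) - 1)
        expected = round(2 * dz / g.speed_of_sound_m_s * g.sampling_freq_hz)
        assert lag == expected

    def test_displaced_outside_field_is_excluded(self):
        g = tiny_geometry()
        sc = Scatterers(z_m=np.array([0.004]), line=np.array([0]),
                        reflectivity=np.array([1.0]),
                        in_lesion=np.array([False]))
        frame = td.synthesize_frame(sc, g, np.array([1.0]))  # 1 m away
        assert np.all(frame == 0)


class TestGenerateSequence:
    def test_default_timing_gives_81_frames(self, small_geometry):
        cfg = td.PhantomConfig(
            geometry=small_geometry,
            lesion_center_mm=(small_geometry.depth_extent_mm / 2,
                              small_geometry.width_extent_mm / 2),
            lesion_depth_mm=2.0, lesion_width_mm=2.0,
            scatterer_density=20.0, seed=2)
        seq = td.generate_sequence(cfg)
        assert seq.n_frames == 81
        assert seq.phase_labels[:16] == ["pre"] * 16

    def test_bit_identical_under_fixed_seed(self, small_config,
                                            small_sequence):
        again = td.generate_sequence(small_config)
        assert np.array_equal(again.data, small_sequence.data)

    def test_static_lesion_keeps_during_frames_identical_at_zero_noise(
            self, small_config):
        cfg = replace(small_config, lesion_motion=td.MotionModel(),
                      noise_sigma=0.0)
        seq = td.generate_sequence(cfg)
        dur = seq.timing.phase_range("during")
        ref = seq.data[dur.start]
        for k in range(dur.start + 1, dur.stop):
            assert np.allclose(seq.data[k], ref)

    def test_coherent_motion_delay_matches_pulsed_doppler_relation(
            self, small_geometry, small_timing):
        # closing velocity -> echoes move to smaller depth by 2 v dt/c0 * fs
        # samples per frame; check over the whole exposure by correlation.
        g = small_geometry
        v = 154e-6  # m/s: 2 fast-time samples per frame interval
        cfg = td.PhantomConfig(
            geometry=g, timing=small_timing,
            lesion_center_mm=(g.depth_extent_mm / 2, g.width_extent_mm / 2),
            lesion_depth_mm=3.0, lesion_width_mm=4.0,
            lesion_motion=td.MotionModel(kind="coherent", velocity_m_s=v),
            noise_sigma=0.0, seed=9)
        seq = td.generate_sequence(cfg)
        dur = seq.timing.phase_range("during")
        nsteps = dur.stop - 1 - dur.start
        a = seq.data[dur.start, 8].astype(float)
        b = seq.data[dur.stop - 1, 8].astype(float)
        lag = np.argmax(correlate(b, a, mode="full")) - (len(a) - 1)
        dtau = td.delay_change(v, td.DopplerPhysicsParams(
            t_pri_s=small_timing.frame_interval_s))
        expected = -round(nsteps * dtau * g.sampling_freq_hz)
        assert abs(lag - expected) <= 1

    def test_post_frames_gain_echogenicity(self, small_config):
        cfg = replace(small_config, lesion_motion=td.MotionModel(),
                      noise_sigma=0.0, lesion_echogenicity_gain=3.0)
        seq = td.generate_sequence(cfg)
        pre = seq.data[0].astype(float)
        post = seq.data[-1].astype(float)
        g = cfg.geometry
        cd, cw = cfg.lesion_center_mm
        s0 = int((cd - 0.5) / g.mm_per_sample)
        s1 = int((cd + 0.5) / g.mm_per_sample)
        l0 = int((cw - 0.5) / g.mm_per_line)
        l1 = int((cw + 0.5) / g.mm_per_line)
        rms_pre = np.sqrt(np.mean(pre[l0:l1, s0:s1] ** 2))
        rms_post = np.sqrt(np.mean(post[l0:l1, s0:s1] ** 2))
        assert rms_post == pytest.approx(3.0 * rms_pre, rel=0.05)

    def test_invalid_lesion_rectangle_rejected(self, small_geometry):
        with pytest.raises(ValueError, match="outside the field"):
            td.PhantomConfig(geometry=small_geometry,
                             lesion_center_mm=(0.5, 2.0),
                             lesion_depth_mm=5.0, lesion_width_mm=1.0)
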