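import numpy as np
import pytest
from hypothesis import settings

import twinkledop as td

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def table1():
    return td.table1_geometry()


@pytest.fixture(scope="session")
def small_geometry():
    """A small grid with the same per-sample/per-line pitch as the full frame."""
    full = td.table1_geometry()
    return td.AcquisitionGeometry(
        n_samples=300, n_lines=16,
        depth_extent_mm=300 * full.mm_per_sample,
        width_extent_mm=16 * full.mm_per_line,
        center_freq_hz=full.center_freq_hz)


@pytest.fixture(scope="session")
def small_timing():
    return td.AcquisitionTiming(n_pre=2, n_during=14, n_post_immediate=1,
                                n_post_late=2)


@pytest.fixture(scope="session")
def small_config(small_geometry, small_timing):
    """A fast phantom: small grid, short acquisition, small centred lesion."""
    return td.PhantomConfig(
        geometry=small_geometry, timing=small_timing,
        lesion_center_mm=(small_geometry.depth_extent_mm / 2,
                          small_geometry.width_extent_mm / 2),
        lesion_depth_mm=2.0, lesion_width_mm=2.0, seed=7)


@pytest.fixture(scope="session")
def small_sequence(small_config):
    return td.generate_sequence(small_config)


@pytest.fixture(scope="session")
def default_jitter_run():
    """One full default phantom processed over the whole acquisition.

    Shared by the acceptance tests that look at window counts, pre-exposure
    quiescence and twinkling contrast.
    """
    cfg = td.PhantomConfig(seed=1)
    seq = td.generate_sequence(cfg)
    images_all = td.construct_doppler_frames(seq, frames="all")
    images_during = td.construct_doppler_frames(seq, frames="during")
    return {"config": cfg, "seq": seq, "images_all": images_all,
            "images_during": images_during}


def lesion_pixel_bounds(cfg, geometry, margin_mm=0.0):
    """(s0, s1, l0, l1) pixel bounds of the configured lesion rectangle."""
    cd, cw = cfg.lesion_center_mm
    hd = cfg.lesion_depth_mm / 2 - margin_mm
    hw = cfg.lesion_width_mm / 2 - margin_mm
    s0 = int(np.ceil((cd - hd) / geometry.mm_per_sample))
    s1 = int((cd + hd) / geometry.mm_per_sample)
    l0 = int(np.ceil((cw - hw) / geometry.mm_per_line))
    l1 = int((cw + hw) / geometry.mm_per_line)
    return s0, s1, l0, l1
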