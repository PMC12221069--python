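"""Doppler physics and slow-time frequency estimation.

The pulsed-Doppler chain implemented here: a scatterer moving along the beam
axis at velocity ``v`` shifts a continuous-wave echo by ``fD = 2 v f0 cos(theta)
/ c0``; in a pulsed system the same motion changes the echo delay by ``dtau =
2 v cos(theta) tPRI / c0`` per transmit, which advances the slow-time signal's
phase by ``dphi = 2 pi fc dtau`` per frame, so the slow-time signal's center
frequency is ``f = 2 v cos(theta) fc / c0`` — the same expression as the CW
shift.  Estimating that frequency per pixel and per sliding window, and
rendering the per-pixel estimates, yields Doppler images of the twinkling
artifact.

Two estimators are provided: ``phasediff`` (default) differences the peak-bin
phase of consecutive windows, wrapped to (-pi, pi], giving a signed frequency
bounded by the slow-time Nyquist 1/(2 tPRI); ``binmax`` reports each window's
peak-bin frequency directly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import hilbert

from .rf_io import RFFrameSequence, RegionSpec, select_region
from .slowtime import (SlowTimeWindowSpec, build_threshold_mask, n_windows,
                       spectral_peak_grid)

__all__ = [
    "DopplerPhysicsParams",
    "DopplerImage",
    "doppler_shift_cw",
    "received_freq",
    "doppler_shift_exact",
    "delay_change",
    "velocity_from_delay",
    "slowtime_freq",
    "phase_diff_frequency",
    "wrap_phase",
    "construct_doppler_frames",
]


@dataclass(frozen=True)
class DopplerPhysicsParams:
    """Physical constants of the Doppler chain.

    f0_hz : transmitted / imaging center frequency (fc)
    c0_m_s : speed of sound in the medium
    theta_rad : angle between the beam axis and the motion direction
    t_pri_s : pulse (here: frame) repetition interval
    """

    f0_hz: float = 6.5e6
    c0_m_s: float = 1540.0
    theta_rad: float = 0.0
    t_pri_s: float = 0.25

    def __post_init__(self):
        if self.f0_hz <= 0 or self.c0_m_s <= 0 or self.t_pri_s <= 0:
            raise ValueError("f0, c0 and tPRI must all be > 0")

    @property
    def nyquist_hz(self) -> float:
        return 0.5 / self.t_pri_s


@dataclass
class DopplerImage:
    """Per-pixel Doppler frequency shift (Hz) for one window pair.

    ``freq_hz`` is a (line, sample) grid on the selected region; pixels that
    failed the amplitude gate are exactly 0.
    """

    freq_hz: np.ndarray
    window_pair_index: int
    region: RegionSpec


def doppler_shift_cw(v: float, params: DopplerPhysicsParams) -> float:
    """Continuous-wave Doppler shift ``2 v f0 cos(theta) / c0``."""
    v = np.asarray(v, dtype=float)
    if np.any(np.abs(v) >= params.c0_m_s):
        raise ValueError("|v| must be < c0")
    out = 2.0 * v * params.f0_hz * np.cos(params.theta_rad) / params.c0_m_s
    return out if out.ndim else float(out)


def received_freq(v: float, params: DopplerPhysicsParams) -> float:
    """Received frequency from a scatterer closing at v: ``f0 (c+v)/(c-v)``."""
    v = np.asarray(v, dtype=float)
    c = params.c0_m_s
    if np.any(v >= c):
        raise ValueError("v must be < c")
    out = params.f0_hz * (c + v) / (c - v)
    return out if out.ndim else float(out)


def doppler_shift_exact(v: float, params: DopplerPhysicsParams) -> float:
    """Exact (relativity-free) shift ``fR - f0 = f0 * 2v / (c - v)``.

    Agrees with :func:`doppler_shift_cw` at theta = 0 to first order in v/c.
    """
    v = np.asarray(v, dtype=float)
    c = params.c0_m_s
    if np.any(v >= c):
        raise ValueError("v must be < c")
    out = params.f0_hz * 2.0 * v / (c - v)
    return out if out.ndim else float(out)


def delay_change(v: float, params: DopplerPhysicsParams) -> float:
    """Per-transmit echo-delay change ``dtau = 2 v cos(theta) tPRI / c0``."""
    v = np.asarray(v, dtype=float)
    out = 2.0 * v * np.cos(params.theta_rad) * params.t_pri_s / params.c0_m_s
    return out if out.ndim else float(out)


def velocity_from_delay(dtau: float, params: DopplerPhysicsParams) -> float:
    """Invert :func:`delay_change`: ``v = c0 dtau / (2 tPRI cos(theta))``."""
    cos_t = np.cos(params.theta_rad)
    if abs(cos_t) < 1e-12:
        raise ValueError("theta = pi/2: axial velocity unobservable")
    dtau = np.asarray(dtau, dtype=float)
    out = params.c0_m_s * dtau / (2.0 * params.t_pri_s * cos_t)
    return out if out.ndim else float(out)


def slowtime_freq(v: float, params: DopplerPhysicsParams) -> float:
    """Slow-time center frequency ``2 v cos(theta) fc / c0``.

    Identical to the CW Doppler shift with f0 = fc: the slow-time frequency
    IS the Doppler shift, which is why slow-time spectral peaks can be
    rendered as Doppler images.
    """
    return doppler_shift_cw(v, params)


def wrap_phase(dphi):
    """Wrap a phase difference to (-pi, pi]."""
    dphi = np.asarray(dphi, dtype=float)
    out = np.pi - np.mod(np.pi - dphi, 2.0 * np.pi)
    return out if out.ndim else float(out)


def phase_diff_frequency(phase_k, phase_k1, dt_s: float):
    """Frequency from the wrapped phase advance between consecutive records.

    ``f = wrap(phase_k1 - phase_k) / (2 pi dt)``; bounded by 1/(2 dt).
    """
    if dt_s <= 0:
        raise ValueError("dt must be > 0")
    phase_k = np.asarray(phase_k, dtype=float)
    phase_k1 = np.asarray(phase_k1, dtype=float)
    if not (np.all(np.isfinite(phase_k)) and np.all(np.isfinite(phase_k1))):
        raise ValueError("phases must be finite")
    out = np.asarray(wrap_phase(phase_k1 - phase_k)) / (2.0 * np.pi * dt_s)
    return out if out.ndim else float(out)


def _resolve_frames(seq: RFFrameSequence, frames) -> range:
    if frames is None or frames == "during":
        return seq.timing.phase_range("during")
    if frames == "all":
        return range(seq.n_frames)
    if isinstance(frames, str):
        return seq.timing.phase_range(frames)
    return range(frames.start, frames.stop)


def construct_doppler_frames(seq: RFFrameSequence,
                             region: RegionSpec | None = None,
                             spec: SlowTimeWindowSpec = SlowTimeWindowSpec(),
                             ratio: float = 0.1,
                             estimator: str = "phasediff",
                             frames="during",
                             demean: bool = True,
                             reference: str = "global",
                             analytic: bool = True) -> list[DopplerImage]:
    """Construct the sequence of Doppler images for a frame range.

    For every pixel of ``region`` the slow-time signal over ``frames``
    (default: the during-exposure phase) is cut into sliding windows and each
    window's spectral peak is computed.  With ``estimator="phasediff"`` image
    k is formed from the peak-bin phases of windows k and k+1 with
    ``dt = step * frame_interval``, giving ``n_windows - 1`` images — e.g. 40
    during-frames with 10-sample windows and step 1 give 31 windows and 30
    images.  With ``estimator="binmax"`` each window's peak-bin frequency is
    the image, giving ``n_windows`` images.

    The amplitude gate (:func:`~twinkledop.slowtime.build_threshold_mask`,
    fraction ``ratio`` of the ``reference`` maximum) zeroes gated pixels; in
    phasediff mode a pixel must pass the gate in both windows of the pair.

    With ``analytic=True`` (default) each RF line is quadrature-demodulated
    (analytic signal along fast time) before the slow-time pixels are taken,
    so slow-time windows are complex and the estimated frequency carries the
    motion sign.  A real per-pixel slow-time signal has an even spectrum —
    ``cos`` is even, so approaching and receding motion are indistinguishable
    from a single real sample per frame — which is why directional Doppler
    systems demodulate first.
    """
    if estimator not in ("phasediff", "binmax"):
        raise ValueError(f"unknown estimator {estimator!r}")
    if region is None:
        region = RegionSpec.full(seq.geometry)
    sub = select_region(seq, region)
    frame_range = _resolve_frames(seq, frames)
    nf = len(frame_range)
    min_frames = spec.window_len + (spec.step if estimator == "phasediff" else 0)
    if nf < min_frames:
        raise ValueError(
            f"{nf} frames in range but {estimator} needs at least {min_frames} "
            f"(window_len {spec.window_len}, step {spec.step})")
    cube = sub.data[frame_range.start:frame_range.stop]
    if analytic:
        cube = hilbert(np.asarray(cube, dtype=np.float64), axis=-1)
    dt_frame = seq.timing.frame_interval_s
    amp, phase, freq = spectral_peak_grid(cube, dt_frame, spec, demean=demean)
    mask = build_threshold_mask(amp, ratio=ratio, reference=reference)
    nw = n_windows(nf, spec)

    images: list[DopplerImage] = []
    if estimator == "phasediff":
        dt = spec.step * dt_frame
        for k in range(nw - 1):
            f = phase_diff_frequency(phase[k], phase[k + 1], dt)
            f = np.where(mask[k] & mask[k + 1], f, 0.0)
            images.append(DopplerImage(freq_hz=f, window_pair_index=k,
                                       region=region))
    else:
        for k in range(nw):
            f = np.where(mask[k], freq[k], 0.0)
            images.append(DopplerImage(freq_hz=f, window_pair_index=k,
                                       region=region))
    return images
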