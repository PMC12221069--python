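"""Seeded point-scatterer phantom generator for RF frame sequences.

The generator emulates an ex vivo HIFU monitoring acquisition: a field of
random point scatterers imaged over 81 frames (16 pre / 40 during / 9
immediately post / 16 late post by default).  A rectangular lesion region is
given its own motion model during the exposure phase — axial jitter as a
surrogate for the radiation-force vibration that produces the twinkling
artifact, or coherent axial drift for parameter-recovery experiments — and an
echogenicity gain after it, mimicking the hyperechoic appearance of
coagulated tissue.

Each RF line is synthesized by summing, over the scatterers assigned to that
line, a Gaussian-enveloped cosine at the imaging center frequency centred at
the echo's exact (sub-sample) fast-time position ``2 * (z + dz) / c0 * fs``.
There is no lateral point-spread function, diffraction, attenuation or
nonlinearity: a scatterer contributes only to its own line.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from .rf_io import (AcquisitionGeometry, AcquisitionTiming, RFFrameSequence,
                    table1_geometry)

__all__ = [
    "MotionModel",
    "PhantomConfig",
    "Scatterers",
    "generate_scatterers",
    "synthesize_frame",
    "generate_sequence",
    "selected_region_geometry",
]


@dataclass(frozen=True)
class MotionModel:
    """Axial motion applied to a scatterer population.

    kinds
        ``static``   — no displacement.
        ``coherent`` — constant axial velocity: cumulative displacement after
                       k frames is ``k * v * cos(theta) * frame_interval``.
        ``jitter``   — i.i.d. Gaussian axial displacement about the rest
                       position each frame (std ``jitter_sigma_m``),
                       independent per scatterer.  This decorrelates slow-time
                       phase frame to frame, the twinkling surrogate.

    ``velocity_m_s`` follows the Doppler convention: positive v closes on the
    transducer (decreasing depth) and produces a positive frequency shift.
    """

    kind: str = "static"
    velocity_m_s: float = 0.0
    jitter_sigma_m: float = 0.0
    angle_rad: float = 0.0

    def __post_init__(self):
        if self.kind not in ("static", "coherent", "jitter"):
            raise ValueError(f"unknown motion kind {self.kind!r}")

    def displacements(self, n_frames: int, n_scatterers: int,
                      frame_interval_s: float,
                      rng: np.random.Generator) -> np.ndarray:
        """Depth-axis displacement (m) of each scatterer at each frame.

        Returns an array of shape ``(n_frames, n_scatterers)``; frame index k
        is the k-th frame *after motion onset* (k = 0 already displaced one
        interval for coherent motion, so a phase of n frames spans n steps).
        Positive values are displacements to larger depth, so coherent motion
        at positive (closing) velocity yields negative depth displacement of
        magnitude ``k * v * cos(theta) * frame_interval``.
        """
        if self.kind == "static" or n_frames == 0 or n_scatterers == 0:
            return np.zeros((n_frames, n_scatterers))
        if self.kind == "coherent":
            k = np.arange(1, n_frames + 1)[:, None]
            step = -self.velocity_m_s * np.cos(self.angle_rad) * frame_interval_s
            return np.broadcast_to(k * step, (n_frames, n_scatterers)).copy()
        # jitter: i.i.d. per frame, per scatterer, projected on the beam axis
        return (rng.normal(0.0, self.jitter_sigma_m, (n_frames, n_scatterers))
                * np.cos(self.angle_rad))


def selected_region_geometry(center_freq_hz: float = 6.5e6) -> AcquisitionGeometry:
    """Geometry matching the analysed sub-region of the full frame.

    1000 samples x 40 lines spanning 19.25 mm x 13.33 mm, with the same
    per-sample and per-line pitch (and hence the same ~40 MHz fast-time rate)
    as the full 4680 x 192 frame.
    """
    full = table1_geometry(center_freq_hz)
    return AcquisitionGeometry(
        n_samples=1000, n_lines=40,
        depth_extent_mm=1000 * full.mm_per_sample,
        width_extent_mm=40 * full.mm_per_line,
        center_freq_hz=center_freq_hz,
        speed_of_sound_m_s=full.speed_of_sound_m_s)


def _default_geometry():
    return selected_region_geometry()


@dataclass(frozen=True)
class PhantomConfig:
    """Full seeded description of a synthetic acquisition.

    Defaults describe a desk-scale acquisition on the analysed sub-region
    grid: 81 frames at 250 ms, 6.5 MHz center frequency, ~40 MHz fast-time
    rate, a 12 mm x 8 mm lesion centred in the field whose scatterers jitter
    axially (sigma 20 µm, ~1 rad of round-trip phase at 6.5 MHz) during the
    exposure and double in reflectivity afterwards.

    ``scatterer_density`` (per mm^2 of the depth x width plane) defaults to
    ~10 scatterers per resolution cell — one line pitch (0.333 mm) by the
    pulse's axial FWHM (~0.24 mm at 2 cycles) — giving fully developed
    speckle.
    """

    geometry: AcquisitionGeometry = field(default_factory=_default_geometry)
    timing: AcquisitionTiming = field(default_factory=AcquisitionTiming)
    scatterer_density: float = 125.0
    lesion_center_mm: tuple[float, float] = (9.625, 20.0 / 3.0)
    lesion_depth_mm: float = 12.0
    lesion_width_mm: float = 8.0
    lesion_motion: MotionModel = field(
        default_factory=lambda: MotionModel(kind="jitter", jitter_sigma_m=20e-6))
    background_motion: MotionModel = field(default_factory=MotionModel)
    lesion_echogenicity_gain: float = 2.0
    noise_sigma: float = 0.05
    pulse_cycles: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.scatterer_density < 0:
            raise ValueError("scatterer_density must be >= 0")
        if self.lesion_depth_mm < 0 or self.lesion_width_mm < 0:
            raise ValueError("lesion extents must be >= 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.pulse_cycles <= 0:
            raise ValueError("pulse_cycles must be > 0")
        cd, cw = self.lesion_center_mm
        g = self.geometry
        if (cd - self.lesion_depth_mm / 2 < 0
                or cd + self.lesion_depth_mm / 2 > g.depth_extent_mm
                or cw - self.lesion_width_mm / 2 < 0
                or cw + self.lesion_width_mm / 2 > g.width_extent_mm):
            raise ValueError("lesion rectangle extends outside the field of view")

    @classmethod
    def full_frame(cls, **kwargs) -> "PhantomConfig":
        """Config on the full 4680 x 192 frame grid, lesion at the depth and
        lateral position of the analysed region's centre."""
        kwargs.setdefault("geometry", table1_geometry())
        kwargs.setdefault("lesion_center_mm", (71.24, 36.0))
        return cls(**kwargs)


@dataclass
class Scatterers:
    """A point-scatterer population on the (depth, line) grid."""

    z_m: np.ndarray          # axial rest position, metres
    line: np.ndarray         # lateral scan-line index, int
    reflectivity: np.ndarray
    in_lesion: np.ndarray    # bool

    @property
    def n(self) -> int:
        return self.z_m.size


def generate_scatterers(config: PhantomConfig,
                        rng: np.random.Generator | None = None) -> Scatterers:
    """Draw a Poisson-distributed scatterer population.

    Count ~ Poisson(density * field area); positions uniform over the depth x
    width plane; reflectivities zero-mean unit Gaussian; the in-lesion flag is
    set from the configured rectangle.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    g = config.geometry
    area_mm2 = g.depth_extent_mm * g.width_extent_mm
    n = int(rng.poisson(config.scatterer_density * area_mm2))
    depth_mm = rng.uniform(0.0, g.depth_extent_mm, n)
    width_mm = rng.uniform(0.0, g.width_extent_mm, n)
    refl = rng.normal(0.0, 1.0, n)
    line = np.minimum((width_mm / g.mm_per_line).astype(np.int64), g.n_lines - 1)
    cd, cw = config.lesion_center_mm
    in_lesion = ((np.abs(depth_mm - cd) <= config.lesion_depth_mm / 2)
                 & (np.abs(width_mm - cw) <= config.lesion_width_mm / 2))
    return Scatterers(z_m=depth_mm / 1000.0, line=line, reflectivity=refl,
                      in_lesion=in_lesion)


def _pulse_sigma_s(center_freq_hz: float, pulse_cycles: float) -> float:
    # Gaussian envelope std from an FWHM of `pulse_cycles` carrier periods.
    fwhm_s = pulse_cycles / center_freq_hz
    return fwhm_s / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def synthesize_frame(scatterers: Scatterers, geometry: AcquisitionGeometry,
                     displacements: np.ndarray,
                     pulse_cycles: float = 2.0,
                     amplitudes: np.ndarray | None = None) -> np.ndarray:
    """Synthesize one RF frame ``(n_lines, n_samples)`` from a scatterer set.

    Each scatterer contributes ``refl * exp(-t^2 / 2 sigma^2) * cos(2 pi fc t)``
    with ``t`` measured from its exact echo time ``2 (z + dz) / c0``; delays
    are continuous (sub-sample).  Scatterers whose echo centre falls outside
    the fast-time grid are silently excluded.  No noise is added here.
    """
    g = geometry
    fs = g.sampling_freq_hz
    fc = g.center_freq_hz
    sigma_t = _pulse_sigma_s(fc, pulse_cycles)
    half = int(np.ceil(3.0 * sigma_t * fs))
    frame = np.zeros(g.n_lines * g.n_samples, dtype=np.float64)
    if scatterers.n == 0:
        return frame.reshape(g.n_lines, g.n_samples).astype(np.float32)

    refl = scatterers.reflectivity if amplitudes is None else amplitudes
    center_idx = 2.0 * (scatterers.z_m + displacements) / g.speed_of_sound_m_s * fs
    keep = (center_idx >= 0) & (center_idx < g.n_samples)
    if not np.all(keep):
        center_idx = center_idx[keep]
        refl = refl[keep]
        lines = scatterers.line[keep]
    else:
        lines = scatterers.line

    base = np.rint(center_idx).astype(np.int64)
    offsets = np.arange(-half, half + 1)
    idx = base[:, None] + offsets[None, :]                    # (n, support)
    t_rel = (idx - center_idx[:, None]) / fs
    contrib = (refl[:, None]
               * np.exp(-0.5 * (t_rel / sigma_t) ** 2)
               * np.cos(2.0 * np.pi * fc * t_rel))
    valid = (idx >= 0) & (idx < g.n_samples)
    flat = (lines[:, None] * g.n_samples + idx)[valid]
    frame += np.bincount(flat, weights=contrib[valid],
                         minlength=g.n_lines * g.n_samples)
    return frame.reshape(g.n_lines, g.n_samples).astype(np.float32)


def generate_sequence(config: PhantomConfig) -> RFFrameSequence:
    """Generate the full seeded RF frame sequence for a phantom.

    Frame schedule:

    * pre frames — background motion only (default: everything static);
    * during frames — the lesion motion model drives lesion scatterers
      (cumulative for ``coherent``, i.i.d. for ``jitter``);
    * post frames — lesion scatterers frozen at their final during-phase
      displacement and scaled by ``lesion_echogenicity_gain``.

    White Gaussian noise with std ``noise_sigma`` x (RMS of the noiseless pre
    frames) is added to every frame.  Identical config + seed gives
    bit-identical output.
    """
    t = config.timing
    g = config.geometry
    rng = np.random.default_rng(config.seed)
    sc = generate_scatterers(config, rng)

    les = np.flatnonzero(sc.in_lesion)
    bg = np.flatnonzero(~sc.in_lesion)
    n_frames = t.n_frames

    # Per-frame axial displacement of every scatterer.
    disp = np.zeros((n_frames, sc.n))
    bg_disp = config.background_motion.displacements(
        n_frames, bg.size, t.frame_interval_s, rng)
    disp[:, bg] = bg_disp
    during = t.phase_range("during")
    les_disp = config.lesion_motion.displacements(
        t.n_during, les.size, t.frame_interval_s, rng)
    if t.n_during and les.size:
        disp[during.start:during.stop, les] = les_disp
        disp[during.stop:, les] = les_disp[-1]  # frozen after exposure

    # Per-frame reflectivity: lesion gain applies to post frames.
    amp = np.repeat(sc.reflectivity[None, :], n_frames, axis=0)
    post_start = during.stop
    amp[post_start:, les] *= config.lesion_echogenicity_gain

    frames = np.empty((n_frames, g.n_lines, g.n_samples), dtype=np.float32)
    for k in range(n_frames):
        frames[k] = synthesize_frame(sc, g, disp[k],
                                     pulse_cycles=config.pulse_cycles,
                                     amplitudes=amp[k])

    if config.noise_sigma > 0:
        ref = frames[:t.n_pre] if t.n_pre else frames
        rms = float(np.sqrt(np.mean(ref.astype(np.float64) ** 2)))
        frames += rng.normal(0.0, config.noise_sigma * rms,
                             frames.shape).astype(np.float32)

    return RFFrameSequence(data=frames, geometry=g, timing=t)


def config_to_dict(config: PhantomConfig) -> dict:
    """Plain-dict form of a config (YAML/JSON serializable)."""
    d = asdict(config)
    d["lesion_center_mm"] = list(config.lesion_center_mm)
    return d


def config_from_dict(d: dict) -> PhantomConfig:
    d = dict(d)
    if "geometry" in d and isinstance(d["geometry"], dict):
        d["geometry"] = AcquisitionGeometry(**d["geometry"])
    if "timing" in d and isinstance(d["timing"], dict):
        d["timing"] = AcquisitionTiming(**d["timing"])
    for key in ("lesion_motion", "background_motion"):
        if key in d and isinstance(d[key], dict):
            d[key] = MotionModel(**d[key])
    if "lesion_center_mm" in d:
        d["lesion_center_mm"] = tuple(d["lesion_center_mm"])
    return PhantomConfig(**d)
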