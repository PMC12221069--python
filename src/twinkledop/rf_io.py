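"""Data model and I/O for beamformed RF frame sequences.

An acquisition is a stack of real-valued RF frames indexed
``[frame, line, sample]`` together with the geometry (how many lines and
fast-time samples, and the physical extents they span) and the timing of the
HIFU exposure protocol (how many frames before, during and after the
exposure, and the inter-frame interval).

Coordinate conversions are span based: a count of ``n`` samples corresponds
to ``n * mm_per_sample`` millimetres, with ``mm_per_sample =
depth_extent_mm / n_samples``, and likewise for lines.  All index ranges are
0-based and half-open.

Two on-disk dialects are supported: a single HDF5 file with dataset ``/rf``
and one attribute per metadata field, and a raw little-endian float32 binary
with a JSON sidecar carrying the same keys.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "AcquisitionGeometry",
    "AcquisitionTiming",
    "RFFrameSequence",
    "RegionSpec",
    "FormatError",
    "sample_span_to_mm",
    "line_span_to_mm",
    "select_region",
    "read_sequence",
    "write_sequence",
    "table1_geometry",
]

PHASES = ("pre", "during", "post_immediate", "post_late")

#: Default speed of sound in soft tissue, m/s.
DEFAULT_C0 = 1540.0


class FormatError(ValueError):
    """Raised when an on-disk sequence is missing or has malformed metadata."""


def _derive_sampling_freq(n_samples: int, depth_extent_mm: float, c0: float) -> float:
    # Fast-time samples cover the two-way travel time of the full depth.
    return n_samples / (2.0 * depth_extent_mm / 1000.0 / c0)


@dataclass(frozen=True)
class AcquisitionGeometry:
    """Geometry of one RF frame: grid counts and the physical span they cover.

    ``sampling_freq_hz`` may be omitted, in which case it is derived from the
    depth extent and the speed of sound (the fast-time sampling rate is fixed
    by how many samples cover the two-way travel time of the full depth).  If
    given, it must be consistent with that derivation to within 1%.
    """

    n_samples: int
    n_lines: int
    depth_extent_mm: float
    width_extent_mm: float
    center_freq_hz: float
    speed_of_sound_m_s: float = DEFAULT_C0
    sampling_freq_hz: float | None = None

    def __post_init__(self):
        if self.n_samples < 1 or self.n_lines < 1:
            raise ValueError("grid counts must be >= 1")
        for name in ("depth_extent_mm", "width_extent_mm", "center_freq_hz",
                     "speed_of_sound_m_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        derived = _derive_sampling_freq(
            self.n_samples, self.depth_extent_mm, self.speed_of_sound_m_s)
        if self.sampling_freq_hz is None:
            object.__setattr__(self, "sampling_freq_hz", derived)
        elif abs(self.sampling_freq_hz - derived) > 0.01 * derived:
            raise ValueError(
                f"sampling_freq_hz {self.sampling_freq_hz:.6g} inconsistent with "
                f"geometry-derived value {derived:.6g} (tolerance 1%)")

    @property
    def mm_per_sample(self) -> float:
        return self.depth_extent_mm / self.n_samples

    @property
    def mm_per_line(self) -> float:
        return self.width_extent_mm / self.n_lines


@dataclass(frozen=True)
class AcquisitionTiming:
    """Frame counts per exposure phase and the inter-frame interval.

    Defaults follow the acquisition protocol this package emulates: 81 frames
    split 16 pre / 40 during / 9 immediately post / 16 late post, captured at
    250 ms intervals during the exposure.
    """

    n_pre: int = 16
    n_during: int = 40
    n_post_immediate: int = 9
    n_post_late: int = 16
    frame_interval_s: float = 0.25

    def __post_init__(self):
        for name in ("n_pre", "n_during", "n_post_immediate", "n_post_late"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.frame_interval_s <= 0:
            raise ValueError("frame_interval_s must be > 0")

    @property
    def n_frames(self) -> int:
        return (self.n_pre + self.n_during + self.n_post_immediate
                + self.n_post_late)

    def phase_labels(self) -> list[str]:
        """Per-frame phase labels in acquisition order."""
        return (["pre"] * self.n_pre
                + ["during"] * self.n_during
                + ["post_immediate"] * self.n_post_immediate
                + ["post_late"] * self.n_post_late)

    def phase_range(self, phase: str) -> range:
        """Half-open frame-index range of one exposure phase."""
        if phase not in PHASES:
            raise ValueError(f"unknown phase {phase!r}; expected one of {PHASES}")
        counts = {"pre": self.n_pre, "during": self.n_during,
                  "post_immediate": self.n_post_immediate,
                  "post_late": self.n_post_late}
        start = 0
        for name in PHASES:
            if name == phase:
                return range(start, start + counts[name])
            start += counts[name]
        raise AssertionError("unreachable")


@dataclass
class RFFrameSequence:
    """A stack of RF frames ``data[frame, line, sample]`` plus metadata."""

    data: np.ndarray
    geometry: AcquisitionGeometry
    timing: AcquisitionTiming
    phase_labels: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.data = np.asarray(self.data)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D [frame, line, sample]")
        nf, nl, ns = self.data.shape
        if nl != self.geometry.n_lines or ns != self.geometry.n_samples:
            raise ValueError(
                f"data shape {self.data.shape} inconsistent with geometry "
                f"({self.geometry.n_lines} lines x {self.geometry.n_samples} samples)")
        if nf != self.timing.n_frames:
            raise ValueError(
                f"{nf} frames inconsistent with timing total {self.timing.n_frames}")
        if not self.phase_labels:
            self.phase_labels = self.timing.phase_labels()
        if len(self.phase_labels) != nf:
            raise ValueError("phase_labels length inconsistent with frame count")
        order = [PHASES.index(p) for p in self.phase_labels]
        if any(b < a for a, b in zip(order, order[1:])):
            raise ValueError("phase_labels must be ordered pre -> during -> "
                             "post_immediate -> post_late")

    @property
    def n_frames(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class RegionSpec:
    """Half-open 0-based index ranges selecting a (line, sample) sub-grid."""

    sample_start: int
    sample_stop: int
    line_start: int
    line_stop: int

    def __post_init__(self):
        if self.sample_start < 0 or self.line_start < 0:
            raise ValueError("region starts must be >= 0")
        if self.sample_stop <= self.sample_start:
            raise ValueError("empty sample range")
        if self.line_stop <= self.line_start:
            raise ValueError("empty line range")

    def validate(self, geometry: AcquisitionGeometry) -> None:
        if self.sample_stop > geometry.n_samples:
            raise ValueError(
                f"sample_stop {self.sample_stop} exceeds n_samples "
                f"{geometry.n_samples}")
        if self.line_stop > geometry.n_lines:
            raise ValueError(
                f"line_stop {self.line_stop} exceeds n_lines {geometry.n_lines}")

    @property
    def n_samples(self) -> int:
        return self.sample_stop - self.sample_start

    @property
    def n_lines(self) -> int:
        return self.line_stop - self.line_start

    @classmethod
    def full(cls, geometry: AcquisitionGeometry) -> "RegionSpec":
        return cls(0, geometry.n_samples, 0, geometry.n_lines)


def table1_geometry(center_freq_hz: float = 6.5e6,
                    speed_of_sound_m_s: float = DEFAULT_C0) -> AcquisitionGeometry:
    """The full-frame geometry of the emulated acquisition.

    4680 samples spanning 90.10 mm of depth and 192 lines spanning 64.00 mm of
    width; the implied fast-time sampling rate is ~40 MHz at c0 = 1540 m/s.
    """
    return AcquisitionGeometry(
        n_samples=4680, n_lines=192, depth_extent_mm=90.10,
        width_extent_mm=64.00, center_freq_hz=center_freq_hz,
        speed_of_sound_m_s=speed_of_sound_m_s)


def sample_span_to_mm(n_samples_selected: int,
                      geometry: AcquisitionGeometry) -> float:
    """Axial length in mm covered by a span of fast-time samples."""
    if not 0 <= n_samples_selected <= geometry.n_samples:
        raise ValueError(
            f"sample span {n_samples_selected} outside [0, {geometry.n_samples}]")
    return n_samples_selected * geometry.mm_per_sample


def line_span_to_mm(n_lines_selected: int,
                    geometry: AcquisitionGeometry) -> float:
    """Lateral length in mm covered by a span of scan lines."""
    if not 0 <= n_lines_selected <= geometry.n_lines:
        raise ValueError(
            f"line span {n_lines_selected} outside [0, {geometry.n_lines}]")
    return n_lines_selected * geometry.mm_per_line


def select_region(seq: RFFrameSequence, region: RegionSpec) -> RFFrameSequence:
    """Restrict a sequence to a rectangular (line, sample) region.

    The returned sequence's geometry extents are rescaled to the selected
    span; frame count and timing are unchanged.
    """
    region.validate(seq.geometry)
    g = seq.geometry
    new_geom = AcquisitionGeometry(
        n_samples=region.n_samples,
        n_lines=region.n_lines,
        depth_extent_mm=region.n_samples * g.mm_per_sample,
        width_extent_mm=region.n_lines * g.mm_per_line,
        center_freq_hz=g.center_freq_hz,
        speed_of_sound_m_s=g.speed_of_sound_m_s,
        sampling_freq_hz=g.sampling_freq_hz,
    )
    sub = seq.data[:, region.line_start:region.line_stop,
                   region.sample_start:region.sample_stop]
    return RFFrameSequence(data=sub, geometry=new_geom, timing=seq.timing,
                           phase_labels=list(seq.phase_labels))


_GEOM_KEYS = ("n_samples", "n_lines", "depth_extent_mm", "width_extent_mm",
              "center_freq_hz", "speed_of_sound_m_s", "sampling_freq_hz")
_TIMING_KEYS = ("n_pre", "n_during", "n_post_immediate", "n_post_late",
                "frame_interval_s")


def _metadata_dict(seq: RFFrameSequence) -> dict:
    md = {k: getattr(seq.geometry, k) for k in _GEOM_KEYS}
    md.update({k: getattr(seq.timing, k) for k in _TIMING_KEYS})
    return md


def _sequence_from_metadata(data: np.ndarray, md: dict, where: str) -> RFFrameSequence:
    missing = [k for k in _GEOM_KEYS + _TIMING_KEYS if k not in md]
    if missing:
        raise FormatError(f"{where}: missing metadata field(s): {', '.join(missing)}")
    try:
        geometry = AcquisitionGeometry(
            n_samples=int(md["n_samples"]), n_lines=int(md["n_lines"]),
            depth_extent_mm=float(md["depth_extent_mm"]),
            width_extent_mm=float(md["width_extent_mm"]),
            center_freq_hz=float(md["center_freq_hz"]),
            speed_of_sound_m_s=float(md["speed_of_sound_m_s"]),
            sampling_freq_hz=float(md["sampling_freq_hz"]))
        timing = AcquisitionTiming(
            n_pre=int(md["n_pre"]), n_during=int(md["n_during"]),
            n_post_immediate=int(md["n_post_immediate"]),
            n_post_late=int(md["n_post_late"]),
            frame_interval_s=float(md["frame_interval_s"]))
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{where}: malformed metadata: {exc}") from exc
    return RFFrameSequence(data=data, geometry=geometry, timing=timing)


def write_sequence(seq: RFFrameSequence, path) -> None:
    """Write a sequence to disk.

    ``.h5``/``.hdf5`` paths get a single HDF5 file with dataset ``/rf``
    (float32) and one root attribute per metadata field; any other suffix gets
    a raw little-endian float32 binary plus a ``<path>.json`` sidecar.
    """
    path = Path(path)
    data = np.ascontiguousarray(seq.data, dtype=np.float32)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "w") as f:
            f.create_dataset("rf", data=data)
            for k, v in _metadata_dict(seq).items():
                f.attrs[k] = v
    else:
        data.astype("<f4").tofile(path)
        md = _metadata_dict(seq)
        md["shape"] = list(data.shape)
        md["dtype"] = "<f4"
        Path(str(path) + ".json").write_text(json.dumps(md, indent=1, sort_keys=True))


def read_sequence(path) -> RFFrameSequence:
    """Read a sequence written by :func:`write_sequence` (either dialect)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix in (".h5", ".hdf5"):
        with h5py.File(path, "r") as f:
            if "rf" not in f:
                raise FormatError(f"{path}: missing dataset /rf")
            data = f["rf"][...]
            md = dict(f.attrs)
        return _sequence_from_metadata(data, md, str(path))
    sidecar = Path(str(path) + ".json")
    if not sidecar.exists():
        raise FormatError(f"{path}: missing JSON sidecar {sidecar}")
    md = json.loads(sidecar.read_text())
    if "shape" not in md:
        raise FormatError(f"{sidecar}: missing metadata field(s): shape")
    data = np.fromfile(path, dtype=md.get("dtype", "<f4")).reshape(md["shape"])
    return _sequence_from_metadata(data, md, str(path))
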