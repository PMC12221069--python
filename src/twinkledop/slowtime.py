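"""Slow-time signal extraction, sliding-window spectra and amplitude gating.

A slow-time signal is the sequence of RF amplitudes at one fixed
(line, sample) pixel across successive frames; at a 250 ms frame interval its
Nyquist frequency is 2 Hz.  The signal is cut into short sliding windows
(default 10 samples, 1-frame step), each window is demeaned and Fourier
transformed, and the largest non-DC spectral component's amplitude, phase and
signed frequency are recorded.  Pixels whose peak amplitude falls below a
fraction (default one tenth) of a reference maximum are gated out as noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "SlowTimeWindowSpec",
    "SpectralRecord",
    "extract_slow_time",
    "segment_windows",
    "n_windows",
    "spectral_peak",
    "spectral_peak_grid",
    "build_threshold_mask",
]

# Relative tolerance for spectral-magnitude ties.  A real-valued window has
# exactly mirror-symmetric magnitudes at bins k and N-k; float rounding makes
# them differ at ~1e-16, so ties are resolved within this tolerance in favour
# of the lower |frequency| (positive over negative at equal |frequency|).
_TIE_RTOL = 1e-9


@dataclass(frozen=True)
class SlowTimeWindowSpec:
    """Sliding-window segmentation: window length (frames) and step."""

    window_len: int = 10
    step: int = 1

    def __post_init__(self):
        if self.window_len < 1:
            raise ValueError("window_len must be >= 1")
        if self.step < 1:
            raise ValueError("step must be >= 1")


@dataclass(frozen=True)
class SpectralRecord:
    """Peak non-DC spectral component of one slow-time window."""

    peak_amplitude: float
    peak_phase_rad: float
    peak_freq_hz: float
    window_index: int = 0


def extract_slow_time(seq, line: int, sample: int,
                      frame_range: range | None = None) -> np.ndarray:
    """The slow-time signal at one (line, sample) pixel, in frame order."""
    nf, nl, ns = seq.data.shape
    if not 0 <= line < nl:
        raise IndexError(f"line {line} outside [0, {nl})")
    if not 0 <= sample < ns:
        raise IndexError(f"sample {sample} outside [0, {ns})")
    if frame_range is None:
        frame_range = range(nf)
    if len(frame_range) == 0:
        raise IndexError("empty frame range")
    if frame_range.start < 0 or frame_range.stop > nf or frame_range.step != 1:
        raise IndexError(f"frame range {frame_range} outside [0, {nf}) or strided")
    return np.asarray(seq.data[frame_range.start:frame_range.stop, line, sample])


def n_windows(signal_len: int, spec: SlowTimeWindowSpec) -> int:
    """Number of sliding windows: floor((len - window_len)/step) + 1."""
    if signal_len < spec.window_len:
        raise ValueError(
            f"signal of length {signal_len} shorter than window "
            f"({spec.window_len})")
    return (signal_len - spec.window_len) // spec.step + 1


def segment_windows(signal: np.ndarray,
                    spec: SlowTimeWindowSpec = SlowTimeWindowSpec()) -> np.ndarray:
    """Cut a 1-D signal into sliding windows; rows start at 0, step, 2*step...

    Returns an array of shape ``(n_windows, window_len)`` (a copy).
    """
    signal = np.asarray(signal)
    count = n_windows(signal.shape[-1], spec)
    view = np.lib.stride_tricks.sliding_window_view(signal, spec.window_len,
                                                    axis=-1)
    return view[..., ::spec.step, :][..., :count, :].copy()


def _peak_components(windows: np.ndarray, frame_interval_s: float,
                     demean: bool = True):
    """Vectorized peak pick over the last axis of a stack of windows.

    Returns (amplitude, phase, freq) arrays of shape ``windows.shape[:-1]``.
    The peak is the largest-magnitude non-DC bin; bins above Nyquist map to
    negative frequencies; magnitude ties (within ``_TIE_RTOL``) resolve to the
    lowest |frequency|, positive first.  All-zero windows yield (0, 0, 0).

    Windows may be complex (quadrature-demodulated pixels), in which case the
    spectrum is asymmetric and the peak frequency carries the motion sign; a
    real window's spectrum is even, so its peak frequency is reported on the
    positive side.
    """
    w = np.asarray(windows)
    if not np.issubdtype(w.dtype, np.complexfloating):
        w = w.astype(np.float64)
    if w.shape[-1] < 2:
        raise ValueError("window length must be >= 2")
    if demean:
        w = w - w.mean(axis=-1, keepdims=True)
    spec = np.fft.fft(w, axis=-1)
    nbins = w.shape[-1]
    freqs = np.fft.fftfreq(nbins, d=frame_interval_s)
    mag = np.abs(spec[..., 1:])                       # exclude DC
    # tie-break key: smallest |f| wins, positive preferred at equal |f|
    key = np.abs(freqs[1:]) - 1e-12 * (freqs[1:] > 0)
    mmax = mag.max(axis=-1, keepdims=True)
    tied = mag >= mmax * (1.0 - _TIE_RTOL)
    pick = np.argmin(np.where(tied, key, np.inf), axis=-1)
    picked = np.take_along_axis(spec[..., 1:], pick[..., None],
                                axis=-1)[..., 0]
    amplitude = np.abs(picked)
    zero = mmax[..., 0] == 0.0
    phase = np.where(zero, 0.0, np.angle(picked))
    freq = np.where(zero, 0.0, freqs[1:][pick])
    return amplitude, phase, freq


def spectral_peak(window: np.ndarray, frame_interval_s: float,
                  demean: bool = True, window_index: int = 0) -> SpectralRecord:
    """Peak non-DC spectral component of a single slow-time window."""
    amp, phase, freq = _peak_components(np.atleast_1d(window),
                                        frame_interval_s, demean)
    return SpectralRecord(peak_amplitude=float(amp),
                          peak_phase_rad=float(phase),
                          peak_freq_hz=float(freq),
                          window_index=window_index)


def spectral_peak_grid(cube: np.ndarray, frame_interval_s: float,
                       spec: SlowTimeWindowSpec = SlowTimeWindowSpec(),
                       demean: bool = True, chunk_lines: int = 16):
    """Windowed spectral peaks for every pixel of a frame stack.

    ``cube`` is ``(n_frames, n_lines, n_samples)``.  Returns three arrays
    ``(n_windows, n_lines, n_samples)``: peak amplitude, peak phase (rad) and
    signed peak frequency (Hz).  Lines are processed in chunks to bound
    memory.
    """
    cube = np.asarray(cube)
    nf, nl, ns = cube.shape
    nw = n_windows(nf, spec)
    amp = np.empty((nw, nl, ns))
    phase = np.empty((nw, nl, ns))
    freq = np.empty((nw, nl, ns))
    for lo in range(0, nl, chunk_lines):
        hi = min(lo + chunk_lines, nl)
        # (frames, lines, samples) -> (lines, samples, windows, window_len)
        block = np.moveaxis(cube[:, lo:hi, :], 0, -1)
        wins = np.lib.stride_tricks.sliding_window_view(
            block, spec.window_len, axis=-1)[..., ::spec.step, :][..., :nw, :]
        a, p, f = _peak_components(wins, frame_interval_s, demean)
        amp[:, lo:hi, :] = np.moveaxis(a, -1, 0)
        phase[:, lo:hi, :] = np.moveaxis(p, -1, 0)
        freq[:, lo:hi, :] = np.moveaxis(f, -1, 0)
    return amp, phase, freq


def build_threshold_mask(peak_amplitude: np.ndarray, ratio: float = 0.1,
                         reference: str = "global") -> np.ndarray:
    """Amplitude gate: true where peak amplitude >= ratio x reference maximum.

    ``peak_amplitude`` has the window index on axis 0 and pixel axes after it.
    ``reference`` selects the scope of the maximum: ``"global"`` (default) uses
    the single largest amplitude of the whole run, ``"per_window"`` uses each
    window index's own maximum over the pixel grid.

    The mask is monotone in ``ratio``: raising it never turns a False entry
    True.  Ratio 0 passes everything; ratio 1 passes only the argmax (ties
    all pass, since the comparison is >=).
    """
    amp = np.asarray(peak_amplitude)
    if amp.size == 0:
        raise ValueError("empty amplitude grid")
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must be in [0, 1]")
    if reference == "global":
        ref = amp.max()
    elif reference == "per_window":
        ref = amp.reshape(amp.shape[0], -1).max(axis=1).reshape(
            (amp.shape[0],) + (1,) * (amp.ndim - 1))
    else:
        raise ValueError(f"unknown reference scope {reference!r}")
    return amp >= ratio * ref
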