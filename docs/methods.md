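# Methods

## Signal model and processing chain

An acquisition is a stack of real beamformed RF frames `data[frame, line,
sample]`.  Fast time (the sample axis) covers the two-way travel time of the
imaged depth, so the sampling rate is fixed by the geometry: with 4680
samples over 90.10 mm and c₀ = 1540 m/s, fs ≈ 40 MHz.  Slow time (the frame
axis) is sampled at the frame interval tPRI = 250 ms during exposure, giving
a slow-time Nyquist of 1/(2·tPRI) = 2 Hz.

A scatterer at depth z echoes at delay 2z/c₀.  If it moves along the beam
with closing velocity v, the delay changes by Δτ = 2 v cosθ · tPRI / c₀ per
frame, the slow-time phase advances by Δφ = 2π f_c Δτ, and the slow-time
signal's centre frequency is

    f = 2 v cosθ f_c / c₀,

identical in form to the continuous-wave Doppler shift 2 v f₀ cosθ / c₀.
The `doppler` module implements these relations (plus the exact two-way form
f_D = f₀·2v/(c−v), which reduces to the CW expression to first order in
v/c), and the pipeline estimates f per pixel as follows:

1. each RF line is quadrature-demodulated (analytic signal along fast time),
   so slow-time pixels are complex and the spectrum keeps the motion sign;
2. the slow-time signal at each pixel is cut into sliding windows
   (default 10 frames, step 1; 40 during-frames → 31 windows);
3. each window is demeaned and DFT'd, and the largest non-DC bin's
   amplitude, phase and signed frequency are recorded;
4. pixels whose peak amplitude is below `ratio` (default 0.1) of the
   reference maximum are gated to zero;
5. the Doppler image for window pair k is f = wrap(φ_{k+1} − φ_k)/(2π·Δt)
   with Δt = step·tPRI, wrapped to (−π, π], so |f| ≤ Nyquist; 31 windows
   give 30 images (the alternative `binmax` estimator reports each window's
   peak-bin frequency, 31 images).

Lesion dimensions come from each image: |f| is 3×3 median-smoothed,
thresholded at `frac` of its maximum, reduced to the largest 4-connected
component (components under `min_pixels` count as empty), and the bounding
box of that component is converted to mm through the per-sample and per-line
pitches.  Per-image measurements are summarised as mean, SD (n−1), 95% CI
(t-based half-width), percentage error vs a reference, and a two-sided
one-sample t-test p-value against that reference.

### Why quadrature demodulation

A real slow-time sample sequence cos(ψ − θn) is indistinguishable from
cos(−ψ + θn): the spectrum of a real signal is even, so a single real sample
per frame cannot tell approaching from receding motion.  Directional pulsed
Doppler therefore demodulates the RF to complex baseband first; the pipeline
does the same with a Hilbert transform along each line (`analytic=True`,
default).  With `analytic=False` the chain still runs but reports unsigned
frequencies (mirror-symmetric spectral peaks are resolved toward the
positive bin, lowest |frequency| first, for determinism).

### Threshold reference scope

The amplitude gate needs a reference maximum.  The default is the global
maximum over all windows of the processing run: a per-window reference
renormalises quiescent segments (e.g. pre-exposure frames) to their own
noise maximum, making pure noise pass the gate and twinkle.  With a global
reference, windows before the exposure gate to zero and the pre-HIFU images
are silent, which is the physically meaningful behaviour.  `per_window` is
available as an option.

### Segmentation threshold

Twinkling pixels have essentially random phase steps between consecutive
windows, so their |f| values spread almost uniformly over (0, Nyquist].
Thresholding at half the image maximum would keep only ~half of the lesion
interior — below the ~0.59 site-percolation threshold of 4-connectivity —
and the largest component would fragment.  Since the amplitude gate already
zeroes the background exactly, the segmentation threshold only has to
separate twinkle support from true zeros; the default `frac = 0.1` mirrors
the amplitude gate's one-tenth ratio.  Note the 3×3 median filter always
removes the four corner pixels of an ideal rectangle (a corner has five
zero neighbours of nine); bounding-box dimensions are unaffected.

## The synthetic phantom

`phantom_sim` generates the conditions the pipeline is designed for:

* **Timing** — 16 pre / 40 during / 9 immediately-post / 16 late-post frames
  (81 total), 250 ms apart.
* **Geometry** — by default the analysed sub-region grid: 1000 samples ×
  40 lines spanning 19.25 mm × 13.33 mm with the same pitch (and the same
  ~40 MHz fs, 6.5 MHz f_c) as the full 4680 × 192 frame;
  `PhantomConfig.full_frame()` builds the full grid.
* **Scatterers** — Poisson-distributed point scatterers (default
  125 per mm² ≈ 10 per resolution cell of one line pitch × the pulse's
  axial FWHM, giving fully developed speckle), reflectivities N(0, 1).
* **Pulse** — Gaussian-enveloped cosine at f_c with an FWHM of
  `pulse_cycles` carrier periods (default 2.0, ≈ 1.4 MHz bandwidth, axial
  FWHM ≈ 0.24 mm).  Echo delays are continuous (sub-sample), which
  phase-based estimation requires.
* **Lesion** — a rectangle (default 12 mm × 8 mm, centred) whose scatterers
  follow a motion model during exposure.  The twinkling surrogate is i.i.d.
  per-frame axial jitter about the rest position, default σ = 20 µm (≈1 rad
  of round-trip phase at 6.5 MHz): enough to decorrelate slow-time phase
  frame to frame while keeping the ground-truth rectangle exact (a random
  walk would let scatterers diffuse out of it).  A `coherent` mode moves the
  lesion at constant axial velocity for parameter-recovery experiments
  (positive v closes on the transducer, by the Doppler sign convention).
  After exposure the lesion's reflectivity is multiplied by
  `lesion_echogenicity_gain` (default 2.0, the hyperechoic appearance of
  coagulum) and its displacement is frozen.
* **Noise** — white Gaussian, σ = `noise_sigma` × the RMS of the noiseless
  pre frames (default 0.05).

Identical config + seed gives bit-identical output.

What the phantom does **not** emulate: lateral beam spread (a scatterer
contributes only to its own line, so lateral resolution is exactly one line
pitch), diffraction, focusing, attenuation, nonlinear propagation, thermal
lesion growth over time, physiological motion, and any physical model of
*why* coagulum vibrates — the jitter amplitude is a modelling choice, not a
measured quantity.  Passing tests therefore demonstrate that the processing
chain recovers what its own signal model implies (frequencies from motion,
dimensions from a twinkling region), not that real coagulum produces this
exact signature.

## Parameter defaults

| parameter | default | units | meaning |
|---|---|---|---|
| `window_len` | 10 | frames | slow-time window length |
| `step` | 1 | frames | window advance |
| `ratio` | 0.1 | — | amplitude gate vs global maximum |
| `estimator` | `phasediff` | — | consecutive-pair phase differencing |
| `analytic` | true | — | quadrature demodulation along fast time |
| `frac` | 0.1 | — | segmentation threshold vs image max \|f\| |
| `min_pixels` | 10 | pixels | smallest accepted component |
| `frame_interval_s` | 0.25 | s | tPRI during exposure |
| `c0` | 1540 | m/s | soft-tissue sound speed |
| `scatterer_density` | 125 | mm⁻² | ~10 per resolution cell |
| `jitter_sigma_m` | 20e-6 | m | per-frame axial jitter of lesion scatterers |
| `pulse_cycles` | 2.0 | cycles | Gaussian pulse FWHM |
| `noise_sigma` | 0.05 | — | additive noise vs pre-frame RMS |

## Numerical choices

* Index ranges are 0-based and half-open; span↔mm conversions are count ×
  pitch, which reproduces the published 19.25 mm / 13.33 mm sub-region
  conversions exactly.
* Spectral-peak ties (exact mirror bins of real windows) are resolved within
  a 1e-9 relative tolerance toward the lowest |frequency|, positive first.
* Phase wrapping maps to (−π, π]; a phase difference of exactly π reports
  +Nyquist.
* All-zero windows yield amplitude 0, phase 0, frequency 0, and pass the
  gate only when the reference maximum is itself 0.
* An all-zero Doppler image segments to an empty mask and measures (0, 0).
* SD uses the n−1 denominator; with SD = 0 the t-test p-value is defined as
  1 when the mean equals the reference and 0 otherwise.
* The during-exposure phase is processed by default; windows never span a
  phase boundary unless `frames="all"` is requested.

## Problem sizes

The bundled experiments run at the analysed-region scale (81 frames of
40 × 1000 pixels): one phantom simulates in ~5 s and processes in ~2 s on a
single CPU, so the 10-phantom accuracy experiment in
`scripts/acceptance.py` completes in under a minute.  Full-frame
(192 × 4680) generation is supported through the same API and CLI.

## Known limitations

* Dimension accuracy inherits a small positive axial bias (~0.1–0.2 mm per
  edge) from the pulse's axial extent: jitter power leaks one envelope
  length beyond the true rectangle.  Lateral width is exact to the line
  pitch (0.33 mm) because the phantom has no lateral point-spread function.
* The 2 Hz slow-time Nyquist means physiological or coherent velocities
  above ~0.24 mm/s alias; no unwrapping across window pairs is attempted.
* The amplitude gate's global reference assumes the processed run contains
  the bright (twinkling) segment; processing a quiescent segment alone
  renormalises to noise, as any relative threshold must.
* Statistics assume per-image measurements are independent; consecutive
  window pairs share 9 of 10 frames, so the reported CIs on phantom runs
  are optimistic.  The t-test mirrors the published table's columns rather
  than a claim of ideal test calibration.
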