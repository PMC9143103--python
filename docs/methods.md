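# Methods

## Measurement model

The system emulated here is a circular array of M ultra-wideband antennas
(default M = 16, diameter 340 mm) in a homogeneous background of relative
permittivity ε_r (default 1.0, air — the permittivity of the emulated
bench experiment; for tissue work it is configurable, e.g. ~42 for healthy
brain).  Each antenna performs a monostatic reflection measurement: a
frequency sweep of the complex reflection coefficient over a uniform grid
(default 1.2–5 GHz, 191 points → 20 MHz step).

The forward model treats the scene as a set of independent point
scatterers.  For antenna m and scatterer k at distance d_mk, the
contribution to the reflection spectrum is a_k·exp(−j2πf·τ_mk) with the
round-trip delay τ_mk = 2·d_mk/v, v = c/√ε_r.  Assumptions: single
scattering (no multiple bounces), isotropic antennas (no patterns or
mutual coupling), 2-D propagation, and — by default — no amplitude decay
with distance (a 1/d² round-trip spreading option exists, off by default
because the delay-sum formulation carries no amplitude term).  Additive
complex circular Gaussian noise of standard deviation `noise_sd` per
frequency point models the residual after VNA calibration; a seed is
mandatory whenever noise is on.

Parametric shapes (circle, ellipse, rectangle outlines) are rendered to
point sets at a configurable arc density (default one point per 2 mm of
perimeter).  A shape's `reflectivity` is its **aggregate** amplitude,
divided uniformly over the rendered points.  The per-point convention was
rejected because closely spaced points add nearly coherently, making scene
brightness an artifact of rendering density rather than of the object.

## Pulse synthesis

The swept band is tapered (default Hann; any `scipy.signal.get_window`
name, or none), embedded at its physical frequencies into a one-sided
spectrum whose bin spacing equals the sweep step Δf, zero-padded by an
integer factor (default 4), and inverse-transformed (`irfft`) to a real
pulse.  The sample rate is fs = n_fft·Δf (40 GHz for the default sweep and
padding, i.e. 25 ps per sample, ~3.7 mm of round-trip range).  Band edges
that are not integer multiples of Δf are rounded to the nearest bin
(error < Δf/2).  The default 191-point sweep was chosen so that both band
edges land exactly on bins.  The unambiguous time range is 1/Δf = 50 ns,
comfortably beyond any in-array round trip.

Pulse metrics: group delay is −(1/2π)·d(unwrapped phase)/df via central
differences (one-sided at the endpoints); the system fidelity factor (SFF)
is the peak magnitude of the cross-correlation of two pulses normalised by
the product of their root energies, evaluated over all integer lags — 1
for a scaled delayed replica, bounded in [0, 1] by Cauchy–Schwarz.

## Image formation

DAS back-projects: per pixel, each channel is sampled at its round-trip
delay (fractional indices via linear interpolation; nearest-sample mode
available), the channels are summed (unit weights by default, a per-channel
weight vector is accepted), squared, and integrated over a window.  DMAS
sums the M(M−1)/2 signed pairwise products of the aligned channels before
squaring; the pair sum is evaluated through the exact algebraic identity
Σ_{m<j} x_m x_j = (S²−Q)/2, which is O(M) per sample and verified
bit-level against a naive triple loop in the tests.

Numerical choices:

* **Integration window.** The window is centred on the aligned arrival
  (t ∈ [−T_win/2, +T_win/2] around each pixel's delay) because the
  synthesised wavelet is symmetric about its arrival time; a one-sided
  window would discard half the pulse energy.  The default length is 100%
  of the excitation wavelet's −20 dB envelope duration (0.875 ns ≈ 35
  samples for the default sweep), configurable as a percentage.
* **Delay convention.** Round trip (τ = 2d/v) everywhere, matching the
  monostatic forward model; a `one_way` flag provides the literal one-way
  reading for interoperability with data recorded under that convention.
* **Out-of-range samples** (delays beyond the trace) contribute zero.
* **Grid.** Physical (0, 0) at the grid centre, row 0 at maximum y.  The
  default test grid is 1 mm pitch; the benchmark-scale grid
  (0.1922 × 0.2255 mm pitch, 1300 × 1301 pixels) is supported but not the
  default, purely for runtime.

Both images are nonnegative by construction; scaling all traces by α
scales DAS by α² and DMAS by α⁴ (so normalised tracking output is
amplitude-invariant).

## Tracking pipeline

Per acquisition: subtract the empty-reference sweep, synthesise pulses,
reconstruct, subtract the previous reconstruction, normalise, binarize,
extract the centroid.  The first position yields no estimate (no prior
image).  Design choices:

* Differential negatives are **clipped** to zero by default: the departed
  position leaves a negative residue that is irrelevant to the new
  position ('abs' and 'none' modes are available as config options, since
  either reading of the subtraction is defensible).
* Threshold semantics are ≥ (a pixel exactly at the threshold is white),
  so the global maximum always survives.
* Among 8-connected white components the **largest by area** is selected;
  ties break toward the component nearest the physical origin (the tool
  converges inward).  The centroid is the unweighted mean of the pixel
  centres.
* A degenerate differential image or an empty mask is a recoverable
  per-position 'no-detection', not a pipeline failure.

## Error analysis

Detection error is the Euclidean distance detected–reference.  Range
summaries treat the axes independently: with signed differences
δ_i = detected_i − reference_i, the mean error is |mean(δ)| (the magnitude
of the systematic bias — *not* the mean absolute deviation, which was
verified to be inconsistent with the embedded benchmark's published
summary table) and the spread is the n−1 sample standard deviation of δ.
Report output rounds half-up at 4 decimals; the rounding first quantizes
the double at 12 decimals so that statistics whose exact decimal expansion
ends in 5 round the way decimal arithmetic would.  Three cells of the
benchmark's published summary table sit one unit low in the 4th decimal
relative to any consistent rounding of the published coordinates
(3.34565 is a decimal tie; 7.052651 and 3.181261 are not ties at all), so
those cells are reproduced to the printed precision rather than exactly —
they were most likely computed from unrounded centroids.

## Synthetic demo: what it emulates and what it does not

`run_demo` replays the benchmark experiment: an elliptical cranium shell
(128 × 170 mm section, aggregate reflectivity 0.3 — printed plastic, weak
contrast), a static tumor (25 mm square outline at (0, 26) mm, aggregate
1.0 — water-filled phantom, strong contrast), and a metal tool tip (point,
1.0) advancing through 8 positions along the benchmark's robot trajectory
(p2–p8 are collinear in the benchmark data; p1 is extrapolated outward
along the same line beyond the antenna ring).  Noise is 1e-3 per frequency
point (~−60 dB of the tool return, a typical calibrated-VNA residual).
The reconstruction grid is 280 × 280 mm at 1 mm pitch, wide enough for the
outermost in-array position.

What passing the demo does and does not show: the synthetic model is
single-scattering with isotropic elements, so it validates the *geometry*
of the processing chain — delay consistency, differential cancellation of
static objects, centroid localization, error statistics — but not
robustness to antenna patterns, multiple scattering, heterogeneous tissue
velocity, or cable/switch artifacts, all of which affect physical data.
Measured antenna quantities (group-delay curves, SFF of a physical antenna
pair) require hardware S21 data and are out of scope; the formulas are
implemented and tested on synthetic pulses.

## Problem sizes

Default test and acceptance runs use the 191-point sweep, 4× zero padding,
20 random scatterer positions for the localization study, and 1 mm pixel
grids (141×141 for localization, 281×281 for the demo) — sizes chosen so a
full run completes in well under a minute per study on one CPU while
keeping the grid pitch an order of magnitude below the acceptance bound of
5 mm.

## Known limitations

* 2-D only; the benchmark's out-of-plane (z) approach component is not
  modeled.
* The forward model is linear in reflectivity; occlusion and shadowing are
  absent, so differential cancellation of static objects is exact up to
  noise and beamformer cross-terms, which is optimistic relative to
  physical data.
* No adaptive or robust beamformers; homogeneous velocity only.
* Touchstone support covers 1-port files (and S11 of 2-port files), RI/MA/DB
  dialects, Hz–GHz units; noise parameters and mixed-mode extensions are not
  parsed.
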