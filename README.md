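# mwtrack

Microwave circular-array imaging and surgical-tool tracking: a synthetic
monostatic forward model for a ring of ultra-wideband antennas, confocal
DAS/DMAS image formation, differential tool tracking with centroid
localization, and the associated error-analysis toolkit.

## The problem

Surgical navigation needs the instantaneous position of the tool tip.
Optical trackers lose the target when line of sight is blocked;
electromagnetic trackers are disturbed by metallic equipment.  Microwave
imaging is an alternative: a ring of wideband antennas surrounds the
surgical area, each antenna in turn transmits a radar-like pulse and
records the reflected signal, and dielectric-contrast boundaries (cranium,
tumor, metal tool) show up as echoes.  This package implements the full
signal chain of such a system — with the measurement hardware replaced by
an analytic point-scatterer forward model — so the image formation,
tracking, and error-analysis procedures can be developed and tested on a
desk.

The modeled system is a ring of 16 antennas equally spaced on a 34 cm
circle (one every 22.5°), each performing a monostatic reflection
measurement (S11) over a 1.2–5 GHz sweep.

## Method

Per antenna *m*, the frequency sweep is converted to a time-domain pulse
X_m(t) (tapered band, zero-padded inverse FFT).  For every image pixel
r₀, each antenna's echo from r₀ arrives at the round-trip delay
τ_m(r₀) = 2·d_m(r₀)/v with v = c/√ε_r.  Delay-and-sum (DAS) forms

  I(r₀) = Σ_t [ Σ_m X_m(t + τ_m(r₀)) ]²

and delay-multiply-and-sum (DMAS) replaces the channel sum with the sum of
pairwise products of the aligned traces (M(M−1)/2 pairs), rewarding
inter-channel coherence:

  I(r₀) = Σ_t [ Σ_{m<j} X_m(t + τ_m) · X_j(t + τ_j) ]²

Tracking subtracts the previous reconstruction from the current one so
only the moved object (the tool tip) remains, binarizes the normalised
differential image at a luminance threshold (default 0.8), and maps the
centroid of the largest white component to millimetres.  Detection error
is the Euclidean distance to the reference position; track summaries
report, per axis, the magnitude of the mean signed difference and the
sample standard deviation of the signed differences.

The package also embeds the coordinate tables of a robot-guided benchmark
experiment recorded with the physical 16-antenna system (detected DAS/DMAS
and robot reference positions of a tool advancing toward a tumor phantom
inside a 128 × 170 mm cranium model), used to validate the error-analysis
routines and to define the trajectory replayed by the synthetic demo.

## Worked example

```python
import mwtrack as mw

geom = mw.build_circular_array(16, 340.0, eps_r=1.0)
scene = mw.Scene(label="tool").add_point(0.0, 26.0, 1.0)
meas = mw.simulate_reflection_sweep(scene, geom, mw.DEFAULT_SWEEP)
traces = mw.to_time_domain(meas)

grid = mw.ImageGrid.from_extent(120, 120, 1.0)
img = mw.das_image(traces, geom, grid, t_win=0.9e-9)
print(img.argmax_mm())
```

prints

```
(0.0, 26.0)
```

— the DAS image peaks at the true scatterer position (on-grid positions
localize exactly; off-grid positions within the central region localize to
about a millimetre).

The full synthetic navigation experiment (cranium + static tumor + tool
advancing through 8 positions, both algorithms, trajectory CSVs, error
summaries, threshold sweep, PNG snapshots):

```
mwtrack demo --seed 1 --out demo_out
```

which ends with (seed 1):

```
final (DAS): detection error 2.54 mm
final (DMAS): detection error 2.27 mm
```

Both algorithms track the tool to within a few millimetres while the
static tumor is fully removed from every differential estimate.  The
embedded benchmark tables can be summarised directly:

```
mwtrack evaluate --fixture benchmark
```

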