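# Methods

This note records the models, conventions and numerical choices behind
`lsmkit`, in the spirit of a methods section: what each component
assumes, which parameters matter, and what the simulated-hardware tests
do and do not demonstrate about a physical rig.

## Units and conventions

Positions are micrometres (μm), times milliseconds (ms), command
voltages volts (V), rates hertz (Hz). All output trains share one
sample clock, `sample_rate` (default 50 kHz — comfortably above any
galvo/piezo bandwidth while keeping a 1 s volume at 50 k samples). One
volume lasts `n_planes / frame_rate`; plane *i*'s period starts at
sample `round(i · sample_rate / frame_rate)` and its nominal axial
position is `do_start + i · plane_spacing`.

## Scan program and defaults

The default configuration is the whole-brain preset: 45 planes at 5 μm
spacing, 1 volume/s (45 frames/s), 20 ms exposure. Trigger amplitudes
are 4.5 / 4.0 / 3.5 V (first / middle / last plane) over a 0 V baseline
with a 3.3 V detection threshold; validation enforces
`trigger_low < threshold < every amplitude`, so any valid program keeps
all pulses detectable. Degenerate single-plane volumes emit one pulse
at the first-plane amplitude: downstream behaviour software counts
volume *starts*, so the start marker wins.

Choices the hardware does not dictate, fixed here and documented:

* **Trigger pulse width** 1 ms; validated against the frame period so
  pulses cannot overlap.
* **Piezo gain** 0.1 V/μm for expressing objective positions as
  commands (real rigs substitute their drive's gain).
* **Flyback** occupies the final 5% of the volume period as a
  cosine-eased return — the paper-thin requirement is continuity of the
  scan ramp; the ease avoids commanding instantaneous velocity jumps.
* **Piezo delay** (default 15 ms, typical range 10–20 ms) is a circular
  shift of the steady-state periodic waveform: scanning is continuous,
  so advancing the command is a rotation, not zero-padding.
* **Sheet sweep** is a sawtooth with flat shoulders: the linear sweep
  spans the `shutter_open_fraction` (default 0.8) central part of the
  exposure, holding at the endpoints otherwise, so illumination falls
  inside the rolling shutter's fully-open interval.

## Focus measure

Given an image, we take the 2-D power spectrum (fft-shifted), zero the
DC pixel, resample on a polar grid (one radial bin per pixel distance up
to `min(H, W)//2`, 360 angular bins, bilinear interpolation), average
over angle, and take `log(· + ε)` with `ε = 1e-12 · max(power)`. The DC
pixel must be zeroed *before* resampling: bilinear interpolation at
radius ~1 would otherwise leak the enormous DC power into the first
bins. Making ε proportional to the spectrum maximum renders the whole
measure exactly invariant under multiplicative intensity scaling.

The threshold is `mean + 3·σ` over the **baseline band**: the outer 25%
of radial bins (configurable). In a real image that band is camera
noise, so the threshold tracks the noise floor. The focus measure is
the count of bins above threshold; `f_max` is the largest such radius
(ties resolved toward the largest — the literal maximum resolved
frequency), feeding the resolution estimate
`r = image_dim · pixel_dim / (2 · f_max)` with the shorter image
dimension and a default pixel size of 0.405 μm.

A consequence worth stating: the measure quantifies sharpness *relative
to the noise floor*. Low-pass filtering an already-captured noisy image
suppresses the floor together with the signal and can leave the count
unchanged; defocus on a rig (blur imposed before photon and read noise)
erodes only the signal band and decreases the count monotonically. The
blur-monotonicity tests therefore apply blur to the clean scene and add
noise afterwards, which is exactly what the defocus model does.

## Sweep, fit, calibration

A sweep scores 41 beam offsets at 1 μm spacing centred on the current
linear estimate, normalizes counts to [0, 1] (`(x − min)/(max − min)`;
an all-equal sweep is an error, not a silent guess), and fits
`a·exp(−(x−c)²/2w²) + b` by bounded least squares. Initialization:
center at the argmax, amplitude 1, offset 0, width a quarter of the
sweep span; bounds keep amplitude in [0.05, 2], offset in [−1, 1],
width in [step/2, 2·span], and allow the center one span beyond the
sweep. The fit is rejected (caller may widen the sweep) when the
optimizer fails, R² < 0.5, the width collapses onto its floor (a
single-sample spike is not a focus peak), or the center leaves the
swept range.

Calibration runs one sweep at each of 5 DO positions evenly spanning
[do_start, do_end], converts best offsets to command voltages through
the linear gain, and interpolates the knots with a not-a-knot cubic
spline (the classic cubic `interp1d` behaviour; quadratic/linear for 3
or 2 knots). Evaluation is exact at knots and refuses extrapolation.
`max_dev_from_linear` is measured on a 1001-point grid against the line
through the end knots. On the simulated rig with a quadratic 0.04 V
mid-range sag, the recovered mapping is accurate to well under one
sweep step (≈0.03 μm mid-range error in the bundled example).

## Eye exclusion

The ellipse is specified in μm in the lateral (y–z) projection. Plane
*i* uses its nominal z only (planes are thin relative to an eye); the
off interval is the analytic chord
`center_y ± semi_y·sqrt(1 − ((z−center_z)/semi_z)²)`, and samples whose
decoded beam position (sheet command / sheet gain) falls inside it —
boundary included, safety-first — are gated off. Only the side-beam
gate is ever modified. An ROI wholly outside the scanned volume warns
and leaves the gate on; no padding margin is applied beyond the ellipse.

## Streaming pipeline

Reader and writer run as separate threads around an unbounded FIFO
queue. The reader never blocks the source: it drains the source's
bounded circular buffer (overwrite-oldest, overflows counted as source
drops and reported separately) as fast as frames appear. The writer
drains strictly in arrival order into uncompressed HDF5 — per-volume
files (`vol_%06d.h5`) or 100-frame chunks (`chunk_%06d.h5`), a short
final file holding any remainder at stop. Frames carry source-assigned
sequence numbers, so loss and ordering are provable from the files
alone. The reader watches queue depth against a high-water mark
(default 2 volumes or 400 single-plane frames) with a 5 s grace period;
a sustained breach aborts the run with statistics attached rather than
exhausting memory. Every run directory also receives a timestamped
settings XML.

Desk-scale stand-ins for the rig-level benchmarks: zero-loss ordered
streaming is verified for 1000 frames from a seeded simulated source,
and bounded memory for 60 s of scan time at the whole-brain frame rate
(2700 frames) executed with 20× time compression — source paced at
900 frames/s wall time and the writer throttled to the same per-frame
interval on an absolute schedule (transient stalls are caught up rather
than accumulated). These verify the pipeline's contracts, not any
particular disk throughput.

## Phantom and simulated camera

The phantom packs 600 Gaussian-profile nuclei (radius 2–2.5 μm, profile
σ = radius/2, brightness 600–1200 counts) into a 256×160×160 μm volume
at 1 μm isotropic voxels over a 10-count background, with centre
separations of at least the radius sum plus 1 μm. The default scan
range (DO 10–235 μm) sits inside the populated region so every probed
plane contains structure. Rendering extracts the focal slice (linear
interpolation in z), blurs with
`σ = base_blur (0.5 px) + blur_gain (0.6 px/μm) · |misalignment|`,
where the misalignment is the distance between the commanded beam
voltage and the hidden true mapping in beam-gain units, then applies
Poisson shot noise and σ = 2 counts of read noise and quantizes to
uint16. Noise defaults were chosen small enough to keep the
focus-vs-misalignment curve unimodal at default brightness. The noise
RNG is keyed on (seed, plane, misalignment), so rendering is a pure
function and streams are reproducible regardless of consumer speed.

True mappings available as ground truth: linear (identity rig),
constant offset, and quadratic with configurable end-anchored sag.

What the simulator does **not** model: a physical PSF (defocus is an
isotropic Gaussian, adequate as a monotone sharpness ground truth but
not a diffraction model), depth-dependent scattering blur, sample
drift, and camera hot pixels or fixed-pattern noise. Passing tests
therefore demonstrate algorithmic correctness against a known ground
truth, not imaging performance in a living fish.

## Degenerate inputs and tie-breaks

All-zero images, all-equal sweeps, f_max = 0 resolutions, empty frame
lists and impossible nucleus packings raise typed errors rather than
returning sentinel values. Validation errors name the offending
field(s). Settings floats are serialized with `repr` so round trips are
bit-faithful; unknown XML elements are preserved in the free-form
device-parameter map, never dropped.

## Known limitations

* The GUI, device drivers (camera SDK, DAQ, serial, piezo), stage
  motion and collision avoidance of a physical rig are out of scope;
  the module boundaries leave seams where drivers would attach.
* The focus metric's baseline band (outer 25%) presumes
  noise-dominated high frequencies; images that are sharp to Nyquist
  would need a different baseline choice.
* Single-threaded HDF5 writing is the only sink; no TIFF path.
* Throughput numbers of any real camera/disk pairing cannot be inferred
  from the simulated runs.
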