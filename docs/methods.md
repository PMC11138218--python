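# Methods

`clptrack` implements, end to end and without hardware, the processing chain
of a contact-lens-pointer (CLP) eye tracker: a scleral contact lens carries
two near-infrared VCSELs that co-rotate with the eye; an eye camera behind an
IR bandpass filter therefore sees a dark frame with just two bright spots,
and gaze estimation reduces to locating those spots and mapping their
centroids to world coordinates.  Because the physical system is evaluated on
a motorized model eye, every stage has analytic ground truth — which is what
this package reproduces with a synthetic rig.

## Forward model (the synthetic bench)

A frame is rendered as

```
I(x, y) = clip( B(t) + Σ_s A(θ) · exp(−((x−x_s)² + (y−y_s)²) / 2σ²), 0, 255 )
```

with one term per spot.  The model and its parameters:

* **Geometry.**  The two spot centers sit symmetrically about the image
  center, `spot_separation` = 60 px apart, and translate rigidly with the eye
  pose at `px_per_degree` = 8 px/°.  Rigid translation is a small-angle
  approximation: over the ±10° working range of the device the spot
  trajectory on the sensor is linear in pose to well below the centroid
  noise, and it keeps ground truth closed-form.  The true VCSEL mount
  geometry and camera focal length are free parameters of the simulator; the
  defaults place the chart trajectory comfortably inside the 400×400 px
  sensor (the configured limit `px_per_degree · 20° < width/2` guarantees
  it).
* **Spot profile.**  Isotropic Gaussian, `spot_sigma` = 3 px, peak
  `spot_peak` = 230 counts.  The beam is highly directional:
  the peak is attenuated by `exp(−ln2 · (θ/divergence_halfangle)²)` where θ
  is the off-axis gaze angle and `divergence_halfangle` = 15°.  At the chart
  corners (θ ≈ 14.1°) the peak is ≈124 counts — still safely above the
  detection threshold — while beyond ±15–20° spots fade below it, which is
  the mechanism that limits the useful range of the real device to about
  ±10°.
* **Stage quantization.**  Commanded poses are snapped to the rotation
  stage's step grid: 0.5° horizontally, 0.02° vertically (the vertical figure
  is treated as a step size).  The recorded ground truth is the quantized
  pose — what the stage actually does, and what the bench's embedded
  red-laser pointer would indicate.  All default chart targets lie on the
  grid, so quantization never biases calibration.
* **Background.**  Ambient light reaches the sensor only through the IR
  bandpass filter.  The leakage table maps illuminance to background mean:
  1 lx → 0.0, 250 lx → 0.5, 50 klux → 25.0 counts, with
  sd = max(1, √mean) (shot-noise scaling over a one-count read-noise floor).
  Indoor lighting is thus essentially invisible to the camera; direct
  sunlight, with its large IR component, is not.
* **Saturation.**  With a per-frame Bernoulli probability (nonzero only for
  the outdoor profile, 0.001) one spot's amplitude is scaled ×10 before
  clipping.  Two consequences are modeled: a clipped flat-top plateau, and
  column blooming — the overflowing charge spills down the sensor column as
  a clip-level exponential tail of e-folding length `bloom_length` = 4 px.
  The blooming term matters: a symmetric clipped Gaussian alone has
  near-zero centroid bias (and its amplified wings actually *increase* SNR),
  so without it saturated frames would paradoxically track better than clean
  ones.  With it, saturation biases the intensity-weighted centroid by
  roughly a pixel, reproducing the documented failure mode at a magnitude
  that degrades but does not break tracking.
* **Determinism.**  A run seed feeds a `SeedSequence` whose two children
  drive (1) the per-frame saturation Bernoulli stream and (2) the background
  noise stream, in that fixed order.  Identical configuration and seed give
  bit-identical frame sequences, and the saturation flags can be re-drawn
  independently of how much noise each frame consumed.

## Lighting conditions

| name   | illuminance | background (mean ± sd) | saturation p | protocol |
|--------|-------------|------------------------|--------------|----------|
| C-In   | 250 lx      | 0.5 ± 1.0              | 0            | chart replay |
| C-Dark | 1 lx        | 0.0 ± 1.0              | 0            | chart replay |
| C-Alt  | 1/250 lx, 3 s period | toggling 0.0/0.5 ± 1.0 | 0    | static (0°,0°), 20 s |
| C-Out  | 50 klux     | 25 ± 5                 | 0.001        | chart replay |

The alternating condition starts lights-on and toggles every 3 s; frames
straddling a transition are kept.  Saturation is modeled as
condition-dependent only for the outdoor profile.  This is a deliberate
simplification: on the physical bench saturation is a pose-dependent
direct-beam effect that also occurs indoors, which the per-condition
Bernoulli model does not represent — simulated indoor poor-detection rates
are therefore ≈0 rather than a few percent.

## Detection

Frames are binarized at a fixed threshold (100/255 — exposure is fixed
before calibration and no auto-exposure runs), 8-connected components are
labeled, components smaller than 3 px are rejected as hot pixels, and each
survivor's centroid is the intensity-weighted mean of its member pixels'
*raw* values.  Intensity weighting is what couples saturation to centroid
error.  The two largest-mass blobs form the spot pair, assigned left/right
by x (ties broken by smaller y); pairs wider than twice the expected spot
separation, or frames with fewer than two blobs, count as *no detection* —
a value the protocol tallies, not an error.

## Calibration

The gaze map is a second-order polynomial with crossed terms in the four
centroid coordinates:

```
X = a0 + a1·xl + a2·yl + a3·xr + a4·yr + a5·xl·yr + a6·xr·yl
       + a7·xl² + a8·yl² + a9·xr² + a10·yr²
```

and identically for Y with `b0..b10`.  World coordinates are expressed in
degrees of visual angle (the chart geometry is angular; a world-camera pixel
scale would only add a fixed linear factor).  The calibration chart is five
fixation targets — the center and the corners of a 20°-side square — visited
center first, then bottom-right corner clockwise to top-right, each held for
1 s at 120 Hz, every frame pooled as a sample.

Five targets cannot identify eleven coefficients; worse, on this chart the
functions az² and el² coincide on the sample set, so part of the quadratic
subspace is invisible to the data no matter how many frames are pooled.  The
solver therefore uses a *degree-weighted* ridge: features are standardized
(intercept unpenalized), the penalty is `ridge_lambda` (default 1e-6) on
linear terms and `ridge_lambda · second_order_weight` (default ×1000) on the
crossed and squared terms, and coefficients are de-standardized back to the
raw polynomial.  The weighting acts as a weak smoothness prior: it resolves
the rank deficiency toward the lowest-order mapping consistent with the
data, which recovers the rig's (affine) geometry essentially exactly — an
isotropic penalty instead leaks an az²−el² component of several tenths of a
degree into interior predictions — while genuine curvature remains fittable
whenever richer calibration data demand it.  `ridge_lambda = 0` on the
five-target chart raises an explicit singular-fit error.

Angular error is the Euclidean distance in the (X, Y) degree plane (flat
small-angle approximation, exact to <0.3% at 10°).

## Robustness protocol and reporting

Each condition is replayed end to end and every frame is classified:
*no detection*; *poor* (detected, error > 1°); *good* (detected, error ≤ 1°),
with the boundary exactly at 1°.  The report gives, per condition, mean ± sd
angular error and the three percentages (which sum to 100 by construction).
Accuracy is computed over all detected frames by default — poor frames are
reported in their own column, not dropped — with a switch to restrict to
good frames.  For the static-pose alternating run the accuracy cell is
rendered "NA": a single fixation cannot characterize accuracy across the
field of view.

## What the simulator does and does not show

Passing tests demonstrate that the *algorithmic chain* — two-spot centroid
detection, the crossed-quadratic fit, the classification bookkeeping — is
correct and robust to the modeled noise, clutter-free backgrounds, sensor
saturation with blooming, and illumination switching.  The simulator does
not model: optical raytracing or corneal refraction, pupil/iris texture,
blinks (the physical evaluation also used a blink-free artificial eye),
laser speckle, lens slippage on a real eye, pose-dependent indoor
saturation, or world-camera parallax.  Simulated accuracies (~0.01°) are
correspondingly better than what physical hardware achieves (~0.2–0.3°);
the simulation bounds check that errors stay under the 1° usability
threshold, not that they match bench values.

## Numerical and scale choices

* Rendering clips to [0, 255] and rounds to uint8; spots are evaluated on a
  ±6σ window (the tail beyond is below half a count even when amplified).
* Fit solves are 11-parameter normal equations per output; conditioned by
  feature standardization.
* Protocol sizes: calibration 600 frames (5 × 1 s × 120 Hz), chart-replay
  runs 600 frames, alternating run 2400 frames (20 s × 120 Hz).  Unit tests
  use a geometrically similar 120×120 px rig at 2 px/° to keep the suite
  fast; the acceptance script and acceptance tests run the full-size rig.
* Degenerate inputs: empty frames yield empty blob lists; identical
  calibration targets yield a constant (intercept-only) model; out-of-range
  poses (> ±20°) raise; off-sensor spots render their visible subset and
  flag the frame.

## Known limitations

The simulator's free parameters (`px_per_degree`, `spot_separation`,
divergence width, leakage table, bloom length) are physically plausible
choices, not measured values of any specific bench; conclusions about the
pipeline transfer to hardware only insofar as the two-spots-on-dark-frame
image model holds.  The CLI's `report` subcommand re-summarizes recorded
CSVs and cannot recover information a run did not log.
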