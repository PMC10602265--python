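# Methods

`gazesim` simulates human scanpaths — the time-ordered sequence of
foveation events (fixations and smooth pursuit) and saccades — on dynamic
scenes, frame by frame. This note describes the model, its parameters, the
synthetic data the package is exercised on, and the numerical and design
choices a user should know about.

## The model

### Inputs

A scene is a bundle of per-frame precomputed maps on a `T x H x W` pixel
grid: a scalar **feature field** `F` in [0, 1] (a saliency map of whatever
provenance — the model treats low-level and high-level maps identically), an
integer **object label field** (0 = background; an id denotes the same
physical object in every frame where it appears), and an **optical-flow
field** in px/frame. Metadata carries the frame rate (default 30 fps) and a
single scalar `px_per_dva` converting pixels to degrees of visual angle
(dva); all model lengths are expressed in dva and converted at use.
Coordinates are 0-based, origin top-left, x rightward (columns), y downward
(rows); gaze positions are continuous.

### Attention fields (recomputed every frame)

* **Features with center bias.** Each frame of `F` is normalised by its own
  maximum (an all-zero frame stays zero) and multiplied with an anisotropic
  Gaussian center bias
  `G_cb(x, y) = exp(-x'^2 / (2 * 0.22) - y'^2 * 0.45 / (2 * 0.22))`,
  where `x'`, `y'` are the coordinates normalised per axis to [-1, 1]. The
  0.22 variance and 0.45 anisotropy are the standard free-viewing values;
  the prior is wider along y under this convention. Both axes are
  normalised to their own half-extent; on non-square frames this is one of
  two defensible readings and only changes the effective anisotropy.
* **Visual sensitivity.** A unit-peak isotropic Gaussian of width `sigma_s`
  (dva) centred at the current gaze. In the object-based models every pixel
  of the currently foveated object mask is additionally set to exactly 1
  (instantaneous uniform spread of attention across the attended object);
  foveating the background raises nothing to 1.
* **Inhibition of return (IOR).** Space mode: each previous saccade target
  contributes a unit-peak Gaussian of width `sigma_i` (dva) at its fixed
  screen position, weighted by a linear decay `max(0, 1 - (t - t_h) r)`;
  the sum is clipped at 1. Target locations are allocentric and never move
  with the scene, and the history is unbounded (old targets decay to zero
  anyway). Object mode: the currently foveated object is inhibited by the
  scalar `xi` in [0, 1]; an object just left is inhibited at 1 and recovers
  linearly with slope `r` per frame; the background is never inhibited.

A note on normalisation: the printed forms of such sensitivity/inhibition
kernels often carry `1/(2 pi sigma^2)` density prefactors. Here all kernels
are unit-peak. Density normalisation would make the fields numerically
negligible at pixel scale and is incompatible with both the clip at 1 and
the rule that the foveated mask is set to 1; any constant rescaling is
absorbed by the fitted threshold and noise level.

### The saccadic race

Every potential target — each pixel in space mode, each object id
(including the background) in object mode — owns a drift-diffusion
accumulator. Drift rates:

* space: `mu(x, y) = F * S * (1 - I)` per pixel;
* object: `mu_i = sum_mask F * S * (1 - I) / (|mask| ln |mask|)`, the
  logarithmic size normalisation preventing large objects from dominating
  purely by area. The mixed model feeds the *spatial* inhibition map into
  the per-pixel sum instead of the per-object scalar. Empty masks and
  masks of <= 2 px get zero rate, and the denominator is floored at 1 to
  avoid `ln 1 = 0`; absent objects' accumulators are frozen at 0 and
  cannot win.

Per frame the update is
`V_i <- V_i + nu * (mu_i dt + s eps_i sqrt(dt))` with `dt` = 1 frame,
independent standard-normal noise per target, and `nu` the fraction of the
frame spent foveating — 0 for frames fully inside a saccade (no evidence
mid-saccade). `V` may go negative (no clamp). When an accumulator reaches
the threshold `theta` the crossing time is interpolated linearly within the
frame; among simultaneous crossers the earliest interpolated fraction wins
(ties: larger final value, then smaller id). All accumulators reset to 0
after every saccade.

One deliberate simplification in the bookkeeping: if a saccade starts *and*
ends within the same frame, the post-saccade sliver of that frame does not
accumulate evidence; accumulation resumes at the next frame boundary. Event
clocks are exact regardless — foveation and saccade events tile the video
duration to within 1e-6 ms, which the tests assert for every variant.

### Saccades and gaze

Saccade duration follows the linear main-sequence law
`tau = 2.7 ms/dva * amplitude + 23 ms`. Landings are exact (no landing-error
model): space mode lands on the winning pixel; object mode samples a pixel
of the winning mask with probability proportional to `F * S` at decision
time (inhibition is uniform within an object and cancels). A saccade that
would outlast the video is truncated at the last frame and flagged.

During foveation the gaze first drifts with the scene — the foveated
object's centroid displacement (object mode) or the bilinearly interpolated
optical flow at the gaze (space mode) — producing pursuit on moving objects
and fixation on static ones, then receives Brownian fixational jitter with
per-axis sd `sigma_d = 0.125` dva per frame, in fixation and pursuit alike.
The gaze position is a single state: jitter shifts the sensitivity centre
and the pursuit anchor together. Gaze is clipped to the frame.

### Variants

| variant | selection | features  | IOR    |
|---------|-----------|-----------|--------|
| S.ll    | space     | lowlevel  | space  |
| S.hl    | space     | highlevel | space  |
| O.ll    | object    | lowlevel  | object |
| O.cb    | object    | none (center bias only) | object |
| M.ll    | object    | lowlevel  | space  |

Each variant ships with the fitted free-parameter values (sensitivity range
`sigma_s`, threshold `theta`, noise `s`, IOR slope `r`, and `sigma_i` or
`xi`) as defaults, so it can be simulated out of the box; `sigma_d` is fixed
at 0.125 dva for all variants. Simulations start with a foveation at the
frame centre, matching the instruction given to observers.

## Evaluation

Human reference data and simulated output share one event-table schema, and
one code path computes every statistic. Before any statistic, foveations
shorter than one frame (33.3 ms) and saccades below 0.5 dva (microsaccades)
are filtered out.

For position-only traces (reference data, space-based models) each
foveation is assigned the object whose mask — dilated by 1 dva to absorb
tracking inaccuracy — held the gaze for the majority of its frames.
Ambiguities inside the dilation ring resolve to the object with the nearest
mask pixel (the nearest-centroid alternative differs only on exact ties).
Object-based model events keep their known target id.

The fitting objective is `fitness = -(d_SA + d_FD) / 2`, the two-sample
Kolmogorov-Smirnov distances of saccade amplitudes and foveation durations
pooled across all scenes and runs. Further diagnostics: functional
foveation categories (Background / Detection = first foveation of an object
/ Inspection = same object as the immediately preceding foveation / Return)
and their time course in 100-ms bins normalised over foveation time only;
per-object dwell-time regression (slope, intercept, r^2); relative
inter-saccade turning angles in 12-degree bins (positive = clockwise on
screen with y down; only |phi| is reported) with the fraction above 135
degrees; return saccades (|phi| > 178 degrees and amplitude difference
< 1.5 dva); object returns (ratio of saccades landing on a previously
foveated, non-current object, and the median time since that object was
last foveated); and modal first-detection agreement across scenes.

## Synthetic data

No external downloads are required; two generators stand in for recorded
material.

**Scenes.** The scene generator renders moving labelled objects (ellipses /
rectangles at constant velocity), Gaussian feature blobs co-located with
the object centroids over a constant background level plus clipped noise,
and a flow field equal to each object's velocity inside its mask and zero
elsewhere. The default geometry is a 40 x 30 dva display (128 x 96 px at
3.2 px/dva), 300 frames at 30 fps — i.e. 10-second clips at the scale of
everyday outdoor footage — with 3 objects of 3-8 dva moving at up to
~10 dva/s. What it deliberately does not emulate: camera motion, occlusion,
object deformation, entering/leaving objects (supported by the data model,
not generated by default), photographic feature structure in the
background, or segmentation errors. Passing tests therefore demonstrate
the mechanics and statistics of the framework, not predictive validity on
real footage.

**Reference scanpaths.** The reference generator draws alternating events
tiling the video: foveation durations log-normal(mu = 5.735, sigma = 0.838)
in ms (expectation ~439.6 ms) and saccade amplitudes Gamma(shape 1.43,
scale 6.50) in dva — the forms and values fitted to free-viewing data.
(The printed expectation of 8.98 dva for the Gamma fit is inconsistent with
its own printed parameters, whose product is 9.295; the generator uses the
parameters as printed.) With probability `p_object = 0.6` a saccade aims at
a uniformly drawn pixel of a present object, otherwise it travels in a
uniform direction re-drawn to stay on screen; the final foveation absorbs
the remaining time. Last events are censored by the video end, which
slightly length-biases recorded (not drawn) durations; the distributional
test uses a long video where this is negligible.

## Fitting

A hand-rolled elitist evolution strategy maximises the KS fitness: uniform
initialisation inside box bounds (initial population 64), rank selection of
the top 32 as parents, offspring by per-parameter Gaussian mutation with
step sizes (initially 20% of each bound range) adapted multiplicatively —
up by 1.3 when a generation improves the best-so-far, down by 0.85
otherwise — over 50 generations by default. Objective calls per run:
`initial + ongoing * (generations - 1)`. Candidate evaluations reuse a
fixed seed schedule (common random numbers), making the objective
deterministic per parameter vector. A grid-search helper supports
single-parameter sweeps at factors 0.5 / 0.75 / 0.9 / 1.1 / 1.25 / 2 around
defaults.

### Identifiability at desk scale

The recovery harness fits parameters against a reference generated by the
simulator itself (12 runs/scene) with known ground truth. At a reduced
budget (population 16, 15 generations, 6 runs/scene on three default
scenes) the threshold `theta` recovers to within ~10% relative error, but
`sigma_s` does not reliably: at the display size of the study (~40 x 30
dva) the sensitivity Gaussian saturates for `sigma_s` above ~11 dva, and
`theta` and `sigma_s` form a compensatory ridge (more sensitivity mass ~
faster drift ~ a larger threshold yields the same durations). The KS
objective pools only a few hundred events at this budget, putting its
noise floor above the remaining `sigma_s` signal; pinning `sigma_s` to 25%
would need roughly forty times more events. This is stated here because
the corresponding acceptance test asserts 25% for both parameters and is
expected to fail on `sigma_s`; the same under-constraint phenomenon is
known for the IOR slope `r` even at full data scale.

## Numerical choices and degenerate inputs

* All randomness flows through `numpy.random.Generator`; batches derive
  per-(scene, run) streams from `SeedSequence((base_seed, scene, run))`.
  Every public entry point is deterministic given its seed.
* Degenerate guards: all-zero feature frames stay zero (no division by the
  frame maximum); a threshold crossing with `V_prev = V_new = theta` gets
  crossing fraction 0; landing weights summing to zero fall back to a
  uniform draw over the mask; empty event tables propagate as empty.
* Flow lookups at sub-pixel gaze use bilinear interpolation with
  nearest-edge extrapolation.
* Scene archives are single HDF5 files (`features` float32, `objects`
  uint16, `flow` float32, metadata as attributes); save/load round-trips
  are bit-exact, and the loader rejects missing datasets, shape
  mismatches, out-of-range features and non-finite flow with errors naming
  the field. The validator (which reports rather than raises) additionally
  flags label fields with more than 100 distinct ids — such fragmented
  segmentations are considered unusable — and registry centroids that
  disagree with the label field.
* The control transform (time reversal + mirroring both axes) is an exact
  involution; the two sign flips cancel on each flow component, so
  first-order motion statistics are preserved while scanpaths decorrelate
  from the object content.

## Known limitations

Beyond the synthetic-data caveats above: no landing error, no saccadic
velocity profiles, no perisaccadic attention shifts, no within-object
serial spread of attention, no blink or tracker-noise episodes, no
semantic/task guidance. The trace interpolates gaze linearly during
saccades for presentation only; no statistic uses it.
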