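# Methods

This note documents the models, numerical choices, and synthetic-data
design behind `impactkit`, in the spirit of a methods appendix: what each
stage assumes, which knobs matter, and what passing the test suite does and
does not demonstrate about real data.

## Head kinematics pipeline

**Inputs.** A `MarkerTrack`: X,Y coordinates of two head markers (cheek
paint mark, snout floss mark) at a uniform frame rate, SI units.  Uniform
sampling is enforced to 1 ns; missing frames are rejected rather than
interpolated, because derivative estimates silently degrade across gaps.

**Filtering.** 4th-order low-pass Butterworth applied forward–backward
(`scipy.signal.sosfiltfilt`), DC gain exactly 1.  A bidirectional pass
squares the magnitude response, so the design cutoff is pre-warped by
`(√2 − 1)^(−1/(2n))` (≈ 1.117 for n = 4) to keep the effective −3 dB point
at the nominal 400 Hz.  Zero-phase filtering is essential here: a causal
filter would delay every time-to-peak by the group delay.  The order is
configurable; 4th order bidirectional is a deliberately conservative choice
and the frequency-response tests pin the passband (±1 % at 50 Hz) and
stopband (<1 % at 2 kHz) behavior.

**Differentiation.** Central differences (`numpy.gradient`), one-sided at
the ends; end frames are excluded from peak searches.  For polynomial
motion up to degree 2 the interior estimates are exact, which the tests
verify.  Resultant linear velocity/acceleration are Euclidean magnitudes of
the component derivatives of the cheek marker.  The head angle is the
unwrapped angle of the snout→cheek line above the horizon, minus the mean
of the first five frames (the pre-impact baseline); angular rate and
acceleration are its successive derivatives, reported as magnitudes in peak
summaries.

**Peak summaries.** Impactor contact is detected as the first interior
frame whose resultant linear acceleration exceeds `onset_frac` (default
5 %) of its global maximum; times-to-peak are measured from that frame.
The default is a pragmatic convention — the true contact instant is not
observable from kinematics alone — and is exposed as configuration.  With
tracking noise the threshold crossing can trigger a few frames early, which
shifts reported times but not peak values.  ΔV is set to the peak resultant
velocity (valid because the head starts at rest).  The coefficient of
variation is SD/mean (sample SD) across animals of per-animal day-averaged
peaks; pooling all impacts instead is available via `cv_mode="pooled"`.

**Energy.** `KE = ½ · M_e · ΔV²` with the effective mass approximated by
head mass, 3.4 g for the adult mouse.  Reported to two decimals in joules.

## Synthetic impact trajectories

The generator's role is to produce marker tracks whose *measured*
kinematics satisfy a six-peak constraint set — (value, time) for
displacement, deflection, linear velocity, linear acceleration, angular
velocity, angular acceleration — with the default constraint set being the
measured mouse vertex-impact peaks at 5,000 frames/s.  Only peak summaries
of the real waveforms are available, so the waveform shape between peaks is
a modeling choice; the shapes below are smooth minimal constructions, not
reconstructions of the real motion.

**Geometry.** Motion is planar (sagittal).  The cheek marker translates
along a fixed 60°-elevated direction; the snout marker sits 15 mm from it
at an angle that follows the deflection profile, so the marker pair is
exactly rigid.  The head is strictly stationary for a 2 ms (10-frame)
lead-in.  A return phase recovers 40 % of the peak excursion so the
displacement rises to a single maximum and decreases, like the looped
trajectory of a real impact.  Tracking noise is isotropic Gaussian per
marker coordinate, default SD 0.05 mm (sub-pixel jitter; the real
magnitude is instrument-specific).

**Linear channel.** The speed profile rises to the peak velocity as the
integral of a beta-density acceleration pulse — the two beta exponents pin
the acceleration peak's time and value — then decays as a raised-cosine
power whose exponent is solved so the excursion peaks at the prescribed
displacement and time.  A fixed-point loop (≤ 8 iterations) rescales the
continuous targets until the *sampled* track's central-difference peaks hit
the requested values, compensating the attenuation inherent in discrete
differentiation of millisecond-scale pulses.

**Angular channel.** The angular constraint set is qualitatively harder:
the reference angular-acceleration peak is a *filtered* measurement, and
for these pulse widths a 400-Hz zero-phase filter both attenuates any
non-negative acceleration pulse by ≳ 8 % (the angular-velocity peak caps
the pulse area, which bounds the filtered peak of every admissible
waveform) and rings the step response into the filtered rate series.  No
closed-form pulse family satisfies all the angular constraints at once, so
the rise is designed directly at frame resolution by a small two-stage
linear program: stage one maximizes the joint margin on the inequality
constraints (rate bounds with the peak pinned at its frame, unfiltered
acceleration peaking at its frame, filtered acceleration equal to the
target at its frame and nowhere larger, filtered rate peaking within two
frames of the rate peak); stage two fixes half that margin (capped at 1 %)
and minimizes total curvature for a smooth profile.  The angle is then
reconstructed by inverting the central-difference operator
(`θ_{j+1} = θ_{j−1} + 2Δt·ω_j`), so the discrete oracle recovers the
designed rate samples exactly.  The solved waveform carries a brief
angular-acceleration transient about 3× the filtered peak — physically
sensible, since filtering real impact transients hides exactly such
structure — and a shallow post-peak rate dip that cancels filter ringing.

**Verification contract.** After construction the generator re-measures its
own output and raises `InfeasibleImpactSpec`, naming the violated
constraint, if any check fails — it never returns a best-effort track.
Five quantities are checked on unfiltered central differences (2 %
relative, 1 frame); the angular-acceleration peak is checked through the
standard 400-Hz pipeline instead, because matching it in both domains at
once is provably impossible (see above).  The full pipeline (filter +
differentiation) recovers all six peaks within 5 %, which the acceptance
tests assert.

## Interspecies scaling

Equal-stress/equal-velocity scaling: a single length ratio
λ = (target brain mass / source brain mass)^(1/3), with velocity invariant.
The per-quantity exponents follow dimensionally: lengths and times × λ,
linear acceleration × 1/λ, angular velocity × 1/λ, angular acceleration
× 1/λ².  The mouse→human constant λ = 13.8 is shipped as an opaque default
(the underlying brain masses are a convention of the scaling literature);
`ScalingFactor.from_brain_masses` derives λ when masses are known.  Tables
are flagged after scaling and re-scaling is refused unless forced, to
prevent silent double application.

## Impactor calibration

Velocity-domain fit: exit velocity is the measured quantity, so the
quadratic is fitted to v(p) over all replicate shots individually (not
replicate means), and energy follows as E = ½·m·v².  r² is the ordinary
coefficient of determination on the fitted points.  `required_pressure`
inverts the energy relation by Brent root-finding restricted to the
calibrated pressure interval; targets outside the calibrated energy range
raise rather than extrapolate.  The default synthetic calibration law
(v = −0.015 p² + 0.75 p + 0.30 m/s over 0.5–10 psi) spans 0.01–1 J for the
50 g piston, matching the impactor's usable murine range, with three
replicates per pressure.

## Histomorphometry

**Box-counting fractal dimension.** Binarize (Otsu for grayscale input),
keep the largest connected component, extract the one-pixel morphological
perimeter (foreground minus its erosion) unless `outline=False`, then crop
to the foreground bounding box so the counting grid is anchored to the
shape — this makes the estimate translation-invariant.  For each dyadic
scale ε (2 px up to a quarter of the foreground extent, ≥ 4 scales spanning
≥ 2 octaves required), N(ε) is the minimum occupied-box count over four
grid offsets; D is the negated slope of the least-squares line of log N on
log ε.  The estimator reproduces analytic dimensions within ±0.05 on a
line (1), a filled square (2), and a depth-7 Sierpinski gasket
(log 3/log 2 ≈ 1.585).  D is meaningful only over the measured scale range;
objects smaller than ~128 px are rejected rather than silently fitted on
too few scales.

**Cell density and stain burden.** Density is a manual count divided by the
ROI mask area converted through px/mm (automated detection is deliberately
out of scope — counts are upstream inputs).  Percent-positive is the
fraction of ROI pixels strictly above a threshold (absolute, or Otsu on the
ROI histogram as the reproducible stand-in for manual thresholding), and is
monotone non-increasing in the threshold.

**Synthetic microglia.** Single-cell silhouettes on a 256-px canvas (any
size ≥ 128): a soma disk plus recursively branching jittered processes,
with branching depth and process length decreasing and process thickness
increasing along ramified → hypertrophic → bushy → amoeboid; the amoeboid
cell is a smooth blob with bounded low-order Fourier boundary modulation.
Parameters were chosen so the mean outline fractal dimension decreases
strictly along the continuum (≈ 1.49 / 1.27 / 1.14 / 1.04 at 256 px),
matching the direction and rough magnitude of fractal analyses of real
microglia.  The generator mimics silhouette *geometry* only — no staining
texture, overlap, or background — so passing the ordering tests shows the
estimator ranks morphologies correctly, not that it segments real images.

## Behavioral indices

The 14 in × 24 in open field is partitioned into 60 equal squares — 6
columns across the short side and 10 rows along the long side, giving
near-square cells — of which the perimeter ring of 28 forms the peripheral
zone and the interior 32 the central zone.  Samples on a cell boundary
belong to the cell whose half-open interval (left/bottom edge inclusive)
contains them; points on the far arena edges fold into the last cell.
TI = (T_P − T_C)/(T_P + T_C) with dwell times as sample counts over the
sampling rate.  The synthetic track generator places an exact rounded count
of samples in each zone (uniform within the zone, randomized order), so the
realized peripheral fraction matches the target within one sample.

NSS is the count of failed tasks among exactly ten boolean outcomes (task
definitions are protocol-specific and treated as opaque).  Passive-
avoidance latency caps at 300 s, with non-crossers assigned the cap.  Fold
change is the group mean over the sham mean at the matched timepoint;
`bonferroni_alpha(5)` gives the 0.01 threshold used for five timepoint
comparisons.  Group-level inference (repeated-measures ANOVA, post-hoc
tests) is intentionally delegated to standard statistics packages; this
module produces the tidy per-animal tables those routines consume.

## Problem sizes and determinism

The analysis scripts simulate 8 animals × 2 impacts at 5,000 frames/s for
40 ms (201 frames per track), 8–20 cells per morphology at 256 px, and
10 animals per behavioral group — cohort sizes of the same order as the
study design they emulate.  All randomness flows through explicit
`numpy.random.default_rng` seeds; the acceptance script's reported targets
are computed from noiseless inputs and are exactly reproducible.

## Known limitations

* The trajectory generator matches peak summaries, not full waveforms; any
  statistic sensitive to waveform shape between peaks (e.g. impulse
  duration, loading rate) reflects the synthetic construction.
* The onset-detection rule and filter order are conventions; comparisons
  against analyses using different conventions should align these settings.
* λ = 13.8 is a fixed constant; scaling across other species pairs requires
  brain masses.
* The box-counting estimator is validated on synthetic geometry; real
  histology adds staining variability, touching cells, and segmentation
  error that are out of scope here.
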