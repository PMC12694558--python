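# Methods

This note documents the models, the numerical choices and the limits of
what the synthetic test bed demonstrates.

## Signal containers and I/O

All signals are uniformly sampled; the sampling rate of a CSV log is
inferred as the reciprocal of the median timestamp spacing, and a log is
rejected if any spacing deviates from the median by more than 10% — a
dropout-sensitive rule chosen because every downstream operator (filters,
Welch PSD, trapezoidal integration) silently assumes uniform Δt.
Quaternions are stored scalar-first and renormalized on construction
(tolerance 1e-6).  Accelerometer logs recorded in g are converted with
g = 9.80665 m/s².  Indices are 0-based; all intervals are half-open.

## IMU gait pipeline

**Filtering.** A 4th-order Butterworth band-pass (0.3–5 Hz) applied
forward-backward (zero phase) conditions the mediolateral gyroscope.
The band keeps walking-cycle content (0.5–2.5 Hz fundamentals plus a few
harmonics) while rejecting drift and tremor-range noise; zero-phase
application matters because event *timing* is the output.

**Event detection.** Mid-swing is the prominent positive peak of the
filtered mediolateral angular velocity; toe-off and heel strike are the
nearest preceding/following negative valleys.  The prominence threshold
is 30% of the 95th percentile of the filtered |signal| with a 0.4 s
minimum peak separation (caps detectable cadence at 150 steps/min, the
normal-walking range).  Peaks must additionally *exceed* the prominence
value in absolute height: prominence alone promotes small noise bumps
sitting between two deep valleys.  Valleys use a quarter of the peak
threshold and no separation constraint, because toe-off and heel-strike
minima fall less than half a step period apart.

**Step length.** The double time-integral of forward acceleration over
each heel-strike→heel-strike interval diverges under any accelerometer
bias, so two standard corrections are applied per step: velocity is reset
to zero at the step start (zero-velocity update — the foot is momentarily
stationary at heel strike), and a linear velocity ramp is removed so the
end-of-step velocity is also zero.  The reported step length is the
absolute displacement.  Cadence is returned as 60·N/t in steps/min
(the count/time form is unit-free; the per-minute scale is the one the
validation tables use), evaluated over the span between first and last
detected heel strikes — the same interval whose steps are measured.

**Heading.** The yaw angle is extracted per sample from the quaternion
stream and applied samplewise in the forward-acceleration projection.
With a fixed heading the distinction is immaterial; with slow heading
drift the per-sample form is the correct one.

## Plantar-pressure pipeline

**Adaptive weighted sliding filter.** For a centered window of 7 samples
(0.14 s at 50 Hz), the local range R sets α = R/(R+κ) and the output is
α·x + (1−α)·mean.  Quiet stretches are averaged; sharp load transitions
pass nearly intact (a unit step keeps ≥ 90% of its jump versus ≈ 14% for
the plain 7-point moving average).  κ defaults to 10% of the global
signal range: well above sensor noise, well below contact transitions.
The filter is length-preserving, idempotent on constants, and uses
shrunken windows at the edges.

**Stance events.** Cycles are segmented where the total load drops below
5% of its global maximum (the swing gap).  Within a cycle a channel is in
contact while above 5% of its own within-cycle peak — a *relative*
threshold, so event times are invariant to the ±10% gain spread typical
of thin-film force sensors and to overall amplitude scaling.  Channels
whose cycle peak is below 5% of the strongest channel are treated as
unloaded.  Isolated single-sample contacts are discarded (debouncing):
real foot contact persists for many samples, whereas a lone crossing is
either noise or the sliding filter leaking a neighbouring cycle's onset
backward by up to half a window.  The five events are then: IFC — first
heel contact; IMC — first metatarsal contact after IFC; IFFC — first
instant heel, midfoot and metatarsal groups are simultaneously loaded
(the operational definition of forefoot-flat contact); HO — first instant
after IFFC with both heel channels off; LFC — last contact in the cycle.
A cycle that cannot be ordered IFC < IMC < IFFC < HO < LFC raises a
detection failure rather than returning a corrupt segmentation.

**Features.** Peak pressure and trapezoidal impulse are computed per
channel per IFC→IFC cycle and averaged across cycles; impulse proportions
divide by the total so they sum to 1.  The impulse is the time integral
of pressure (units·s); sub-phase durations are simple differences of the
event times and satisfy the partition identities exactly.

## sEMG pipeline

Conditioning: zero-phase 4th-order Butterworth 20–450 Hz (the
physiological sEMG band), an IIR notch at 50 Hz with Q = 30, then mean
removal.  Time-domain features use their standard forms — iEMG as the
*rectified* sum Σ|xᵢ| (the unrectified sum cancels on a zero-mean
signal), ZCR as the count of strict sign changes with an optional
deadband, variance with the population divisor N (so RMS² = VAR + mean²
holds exactly).  The PSD is a Welch estimate (Hann window, 1 s segments,
50% overlap — enough spectral resolution at 2000 Hz while averaging
several segments per window).  MPF is the trapezoidal spectral centroid;
MF is the half-power split point with linear interpolation between bins,
the standard median-frequency definition (a literal "half the total
power" is a power, not a frequency, and is not a usable fatigue marker).

## Calibration

The flexible-vs-rigid fit is ordinary least squares on the per-load
average voltages with the flexible surface as predictor.  RMSE uses the
divisor-n convention √(SSE/n) — this is the convention under which the
bundled table reproduces its reference statistics — while SEE carries the
n−2 (degrees-of-freedom) convention separately.  The bundled calibration
table ships the per-load average column as recorded in the source log;
when a table provides only repetition columns, their mean is used.

## Agreement statistics

Relative error is |Y−Yr|/Yr·100%.  The paired t uses the sample (n−1) SD
and df = n−1; Pearson r and both p-values come from scipy.  ICC(2,1) is
the Shrout–Fleiss two-way random-effects, absolute-agreement,
single-measures form, implemented directly from the ANOVA mean squares
and cross-checked against pingouin in the tests.  Confidence intervals
are t-based (not normal-based), consistent with the small-n experiments
the suite summarizes.  The bias summary in the full agreement report
(mean ± SD with 95% CI) describes the paired differences
measured − reference.

## Synthetic generators

The generators trade biomechanical realism for analytic ground truth:

* **IMU walk** — per-step forward acceleration is one sine period, whose
  double integral is exactly the requested step length and whose
  velocity is zero at both step boundaries (so the ZUPT and drift
  corrections are exact no-ops at zero noise).  The gyro is a train of
  Gaussian bumps at the designed toe-off/mid-swing/heel-strike times.
  Defaults mirror a straight-walkway validation walk: 16 steps of
  1.13 m at 100 steps/min (~18 m), with 0.1 m/s² accelerometer and
  5 °/s gyro noise.
* **Pressure walk** — trapezoidal loading per channel with two-sample
  ramps and grid-aligned on/off times, ordered heel-first/forefoot-later
  so the five stance events are known exactly; channel amplitude ratios
  loosely follow a normal barefoot distribution (heel and central
  metatarsals highest, midfoot lowest).  The midfoot plateau is kept
  above ~40% of the cycle maximum so its 5% contact threshold clears the
  sliding filter's onset leak.
* **sEMG** — low-pass Gaussian noise (≈30 Hz two-sided bandwidth)
  heterodyned onto a carrier drifting linearly between the requested
  start/end frequencies: the PSD is symmetric about the carrier, so the
  spectral centroid trajectory is known.  Burst amplitude modulation at
  the step rate emulates gait-locked activation.

What passing these loops does *not* show: robustness to pathological
gait, turning, double-support pressure overlap between feet, electrode
artifacts, crosstalk between muscles, or sensor saturation — none of
which the waveform families contain.  The closed-loop accuracy envelope
(cadence within 2.2%, step length within 8% mean relative error over 50
seeds) characterizes the pipeline under these idealized conditions.

## Problem sizes and determinism

All generators take explicit seeds and are bit-reproducible.  The test
suite and the acceptance script use 8–16-step walks, 12–20 s EMG records
and 50-seed ensembles — sizes at which every statistic above is stable to
well inside its asserted tolerance while the whole suite runs in
seconds.

## Known limitations

* Step length and stride length are treated as the same per-cycle
  forward displacement; with heel-strike→heel-strike integration windows
  the distinction is a naming one here, and the validation table is used
  as given.
* The IMU pipeline assumes straight walking with a near-constant
  heading; no magnetometer fusion or turning detection.
* Stance detection assumes a clean swing gap in the total load; shuffling
  gait with no unloaded phase will fail cycle segmentation (by design,
  with an explicit error).
* The calibration module maps voltages between mounting conditions; it
  deliberately does not model voltage→Newton transduction or hysteresis.
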