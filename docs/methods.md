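# Methods

This note documents the models implemented in `gaitevents`, the choices made
where the design was genuinely open, and what the synthetic test bed does and
does not establish.

## Sensor calibration

A tri-axial accelerometer (or gyroscope) is calibrated with a 3×7 matrix:

    C · [m + B, |m + B|, 1] = k

where `m` is the measured vector, `B` a bias observed during a quiet period,
and `k` the known reference value. The three signed columns capture scale
and cross-axis terms, the three absolute-magnitude columns capture
positive/negative scale asymmetry, and the last column absorbs residual
offset. Given the regressor the model is linear in `C`, so fitting is
ordinary least squares row by row; `B` is estimated first from the quiet
period and held fixed (the alternative — estimating it jointly — makes the
bias column and `B` mutually unidentifiable without extra constraints). A
rank check names deficient regressor columns when the pose grid is too poor
(e.g., a single orientation). The forward map is only piecewise linear
because of the absolute values, so the simulator inverts it per sample by
sign-consistent case analysis over the 2³ orthants.

The centrifuge simulator reproduces the canonical calibration design: six
axis-aligned orientations × 16 magnitudes, 0–41.42 g for accelerometers and
0–78.54 rad/s for gyroscopes. On this grid the noiseless fit recovers a
generating matrix to machine precision, and with noise the per-element error
shrinks as 1/√n.

## Preprocessing chain

Units: accelerations are stored in g (1 g = 9.8 m/s²) throughout, angular
velocity in rad/s, time in seconds from record start. Axes follow the ISB
mapping +x anterior, +y proximal, +z right.

* **Quiet periods** are maximal intervals with gyro magnitude < 0.5 rad/s
  and jerk < 0.01 m/s³ for ≥ 100 ms. That jerk bound is far below the noise
  floor of raw 1000 Hz differentiation, so the derivative is taken on 5 Hz
  low-pass-filtered acceleration by default; both the threshold and the
  pre-filter are configurable.
* **Bias removal** subtracts the quiet-period gyro mean and rescales the
  quiet-period acceleration to exactly 1 g along its own (gravity)
  direction. Only the gravity-axis component of accelerometer bias is
  identifiable from a single still pose; full 3-axis accelerometer bias
  belongs to the calibration step.
* **Saturation**: frames with any primary-accelerometer component beyond
  15.5 g are replaced whole by the wide-range secondary channel.
* **Filtering**: 4th-order 50 Hz Butterworth, zero-phase
  (forward-backward) by default. Zero-phase is the right choice for offline
  event timing — a causal pass would delay every landmark by a
  frequency-dependent lag and bias all event estimates one way. A causal
  mode is available behind a flag. Note the two-pass magnitude response is
  the square of the single-pass response (≈ 99.7 % attenuation at 100 Hz
  for 1000 Hz sampling).
* **Orientation and gravity removal**: a gradient-descent complementary
  filter (Madgwick-type, IMU variant, implemented in-package) fuses gyro
  integration with the accelerometer's gravity reference. Gain β defaults
  to 0.033 — the common literature default; nothing in our use is sensitive
  to it within a factor of a few. The filter is initialized from the
  quiet-period gravity direction, and the gravity correction is applied
  only when the acceleration magnitude is within a band around 1 g
  (impacts are not gravity evidence). The estimated sensor-frame gravity is
  subtracted to yield specific force.
* **Segment coordinate system**: +z is the first principal axis of the
  running angular velocity (running is dominated by sagittal rotation about
  the medial-lateral axis), +y the quiet-standing gravity direction
  orthogonalized against z, +x their cross product. PCA leaves the z sign
  ambiguous; it is chosen so the skew of the projected angular velocity is
  positive (swing-phase peaks positive, the convention the detector
  registry assumes), falling back to the input frame's +z for skewless
  inputs. If the first component explains < 60 % of variance the result
  carries an "ambiguous medial-lateral axis" warning. The output is always
  a proper rotation (det = +1, asserted per call).
* **Synchronization** maximizes the cross-correlation of two pulse trains;
  ties break toward the smallest absolute lag. **Segmentation** cuts the
  sub-record between two speed-gate crossings and re-bases time, keeping
  the original origin in metadata.

Position dead-reckoning is deliberately not implemented: orientation plus
gravity removal is sufficient for every detector in the registry, and
double-integrated position adds drift without adding event information.

## Detection methods

Each of the 21 registry entries declares placement, input signals, native
sampling rate, provided events, and named parameters. The dispatcher
resamples the input to the native rate because window lengths and
thresholds in the source methods are tied to those rates; downsampling is
anti-aliased (zero-phase low-pass at 0.4× the target rate) before linear
interpolation onto the native grid. Events are reported in the recording's
own clock.

The heuristics fall into three families:

* **Shank accelerometer**: IC at the axial/resultant/anteroposterior/
  medial-lateral impact transient (which signal varies by method), TC at
  the push-off maximum inside a post-IC stance window (60–400 ms). Schmidt
  uses an absolute 8 g impact threshold calibrated for sprinting and
  therefore fails at lower speeds — a documented design-range property,
  not a defect.
* **Shank gyroscope**: each stride is anchored at the mid-swing positive
  peak of sagittal angular velocity; IC is the first qualifying trough
  after the peak and TC the last qualifying trough before it (qualifying =
  interior local minimum below zero and at least half as deep as the
  window's deepest). The walking-derived variants (Greene/McGrath,
  Aminian/O'Donovan) keep their original walking-cadence window lengths and
  peak spacing, which at running cadence skip or mislabel events from
  neighbouring steps; the `_modified` variants rescale windows to fractions
  of the measured inter-peak interval.
* **Sacrum**: per-step peaks in vertical, anteroposterior, resultant, or
  high-passed angular-velocity magnitude give IC; the following trough
  gives TC; the sign of the medial-lateral acceleration at IC gives the
  side (+z = right). Reenalda projects onto a slow (0.5 Hz low-pass)
  gravity estimate to obtain a gravity-aligned vertical axis without a full
  orientation filter.

Two implementation rules apply to every heuristic and exist to guarantee
determinism and time-shift equivariance (same input delayed by Δ ⇒ same
events delayed by Δ, within one native-rate frame): peak sets are pruned
greedily in *time* order rather than height order (height order lets
near-tied peaks swap under resampling phase changes), and trough selection
uses peak adjacency plus a depth qualification rather than a bare argmin.

The Bach method is an Echo State Network: a fixed sparse random reservoir
(100 units, spectral radius 0.9, leak 0.3, seed-pinned) with a ridge
readout mapping z-scored tri-axial acceleration to IC/TC likelihood traces,
peak-picked at a threshold (0.5; the `_modified` variant uses 0.3). Only
the readout is trainable, and the network ships untrained — its published
performance is bound to its training distribution, so we provide
`train_bach` and train it on simulator trials in the test suite rather than
pretending to reproduce the original weights. An untrained network reports
a failed detection rather than guessing.

**Matching**: detected events are paired to ground truth greedily in
ascending order of absolute time difference within ±250 ms (just beyond the
widest limits of agreement a usable method shows). Greedy pairing equals
optimal assignment whenever true events are separated by more than twice
the detection jitter — always the case for running cadences — and the test
suite checks this against a brute-force optimal-assignment oracle.
**Side-label smoothing**: `enforce_alternation` scores both left/right
phase assignments against the raw labels and keeps the majority, tying
toward the first labeled event.

## Agreement statistics

Errors (method time − ground-truth time, ms) from many methods on the same
trials are *linked replicates*. The model is

    y[m,p,t] = a[m] + b[p] + c[p,t] + d[m,p] + e[m,p,t]

with fixed per-method biases `a` and independent zero-mean normal random
effects: participant `b`, participant-by-trial `c` (shared across methods —
the linkage), method-by-participant `d`, residual `e`. It is fitted by REML
as a mixed linear model with participant groups, a random intercept, and
variance components for trial and method within participant (the paper
names the model but not the estimator; REML is the standard choice for
variance components and matches lme4 on identical data to four decimals).
Negative component estimates are truncated at zero with a warning.

Limits of agreement are `a[m] ± 1.96 × SD(error)` where the error SD is
composed from the components that vary between a method's replicate
measurements of the same true event: √(σ_d² + σ_e²) by default, with flags
to include σ_c² (trial) and σ_b² (participant) for users who want the
prediction interval for a new trial or a new participant. The within-method
SD (repeatability) is √σ_e². With a single method, b/d and c/e are pairwise
confounded; the model collapses to a participant intercept and the summary
reduces to the raw mean ± 1.96 SD.

A caution from the recovery experiments: at 100 participants × 10 trials ×
2 methods, σ_b is the weakly identified component (it enters only through
cross-method, cross-trial covariance) and its REML estimate carries 10–20 %
relative sampling error; the other components recover to a few percent.

Explanatory models add surface (floor-vs-track intercept shift, ms), speed
(ms per m/s) and foot-strike angle (ms per rad) as fixed effects to the
within-method reduction of the same random structure. Fixed-effect p-values
are Wald normal approximations (statsmodels does not provide
Satterthwaite-type degrees of freedom; at the group counts used here the
approximation's null false-positive rate calibrates to ≈ 5 %, which the
acceptance script measures). A constant covariate is reported as undefined,
never as a zero effect. Predicted mean-absolute-error surfaces are
|intercept + effects| over a speed × angle grid, defaulting to 2.5–7.5 m/s
and −0.25–0.75 rad, with an extrapolation warning outside those ranges; the
absolute value of a signed-error prediction is an interpretation, flagged
as such.

Failure rate is the mean across participants of each participant's fraction
of trials with no recognized events (participants weigh equally). Side
accuracy counts `unknown` as incorrect. Side-misidentification over n
independent segments is p^n, which is what makes the predictable
left-right alternation of running so forgiving: 0.18 per 5 m segment
becomes 0.0324 over 10 m and ~10⁻¹⁴⁹ over a kilometre.

## The synthetic signal model

The simulator is phenomenological, not biomechanical: a trial is a quiet
standing lead-in followed by strides whose IC/TC schedule comes from a
speed-dependent timing model (stride frequency 1.25 + 0.07·v Hz; contact
time 0.35 − 0.03·v s, so stance shortens and a flight phase opens as speed
grows). Sagittal kinematics are built as an angular-velocity waveform —
mid-swing peak, IC/TC troughs, a stance-phase counter-rotation chosen so
every stride integrates to zero — integrated to a pitch angle; the gravity
component of the accelerometer signal is rotated by that angle, so gyro,
orientation, and gravity are mutually consistent and the orientation filter
can be tested against exact truth. Specific-force features are then added
in the sensor frame: an IC impact transient whose sharpness and amplitude
grow with foot-strike angle (heel-first landings hit harder) and speed, a
TC push-off bump, braking/propulsive anteroposterior features, a
medial-lateral impact for shank records, and side-signed medial-lateral
bumps at the sacrum. At high speeds the impact exceeds the 15.5 g primary
range; the primary channel clips at ±16 g while the secondary stays
faithful, with the clipped-frame count recorded as truth. Gaussian sensor
noise (default SD 0.02 g / 0.02 rad/s — a modest MEMS-plus-soft-tissue
level) is applied to the running portion; the standing lead-in is left
noise-free so the printed quiet-period thresholds remain meaningful.
Surface changes only noise amplitude and impact sharpness by 5 %, since
surface effects on method error were not expected to matter.

Ground-truth IC/TC are defined as the 10 N threshold crossings of a
synthetic vertical force curve built to cross exactly at the scheduled
sample times. Event times are snapped to the sample grid.

Error tables for the agreement models are drawn exactly from the
linked-replicates generative model with independent normal components and
optional injected covariate effects, with the generating parameters stored
for recovery tests.

**What passing tests show — and don't.** The simulator guarantees that each
method's landmark exists at a known time, so detector tests verify the
landmark logic, the registry contracts (determinism, shift equivariance,
failure handling, native-rate resampling) and the statistics pipeline
end-to-end. They do not certify real-world accuracy: real signals contain
soft-tissue artifact, inter-individual waveform variation, placement error,
and landmark timing that is itself offset from force-plate truth —
precisely the error sources that dominate published validations. Millisecond
medians on synthetic data are a correctness statement, not a performance
claim.

## Numerical and interface choices

* Standard fixture suite: 3 speeds (3.0/4.5/6.5 m/s) × 3 foot-strike
  classes (−0.15/0.05/0.45 rad) × 2 placements × 5 seeds = 90 trials of 6
  strides at 1000 Hz; it generates in under a second, and the statistical
  recovery experiments (20-seed medians, 100-seed null calibration at 30
  participants × 8 trials) were sized to keep the whole suite and the
  acceptance script comfortably fast while leaving the estimators' behavior
  clearly measurable.
* All randomness is seed-derived; fixed seeds give bit-identical
  recordings, reports, and fits. Pipeline reports include per-method
  wall-clock timings as informational fields excluded from the determinism
  contract.
* Recordings serialize as CSV plus a JSON metadata sidecar (rate, frame,
  placement, units); event times are written at microsecond precision, one
  order below the millisecond scale of interest. Files without gyro columns
  load with a flag that makes gyro-based detectors refuse them explicitly.
* Known limitations: no magnetometer handling (heading is unobservable and
  unneeded); no position estimation; left/right is convention-bound (+z =
  right) and must be honored by the mounting; the Bach network's accuracy
  is entirely a function of the data it is trained on; and the trial
  exclusion policies of any particular experimental protocol (e.g., keeping
  only trials containing a synchronization event) are considered experiment
  design, outside the library.
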