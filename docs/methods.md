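# Methods

This note records the modeling assumptions, parameter choices and
numerical conventions behind `i2spair`, and what the synthetic validation
does and does not demonstrate.

## Signal model and units

A recording is a synchronous pair of tri-axial angular velocity (deg/s)
and acceleration (g, gravity included) sampled at a known rate (default
200 Hz).  All thresholds in the pipeline are expressed in these units
(10 deg/s and 1.3 g for the motionless rule, 5 deg/s for foot flat), so
m/s² inputs are converted on load.  The central assumption is steady
walking: bouts of at least two gait cycles, without turns or transitions
dominating the signal.  The method's orientation independence rests on two
facts: vector norms are invariant under rotation of the sensor frame, and
functional calibration can recover the anatomical axes of a foot sensor
from the movement itself.

## Filtering

All channels are low-pass filtered with a 4th-order Butterworth at 4 Hz
before spectral analysis and feature extraction.  The filter is applied
forward-backward (zero phase): the one-pass variant delays gait events by
a group delay that would shift foot-flat edges and push-off peaks, and the
squared amplitude response is harmless because the classifier consumes
amplitude statistics, not calibrated magnitudes.

Side identification (foot-flat detection, functional calibration, the
three side features, and the shank/thigh rule) deliberately runs on the
*unfiltered* signals.  The 5 deg/s foot-flat threshold is a physical
quantity: at high cadence (stride times toward 0.45 s) a 4 Hz low-pass
retains little beyond the stride fundamental, and a band-limited signal
cannot stay below 5 deg/s for 15% of the cycle, so filtering would make
foot-flat detection impossible exactly where it must still work.  Sensor
noise at realistic levels (~1 deg/s) is negligible against that threshold.

## Stride time

* FFT candidates: each channel is mean-removed (raw acceleration has a
  gravity DC component), zero-padded to a ~0.01 Hz grid, and its amplitude
  spectrum normalized to a maximum of 1 inside the admissible band
  0.3–3.5 Hz (stride times ~0.29–3.3 s, covering 0.5–2.2 m/s walking while
  excluding DC leakage).  Scanning upward in frequency, the first strict
  local maximum with normalized amplitude ≥ 0.5 defines the candidate.
  Channels that are numerically constant are skipped.
* Residual sweep: window sizes start at 0.3 s (no walking stride is
  shorter) and advance in 1/fs steps up to min(3.0 s, bout/2); integrals
  are trapezoidal; windows tile the bout from sample 0 without overlap;
  the per-axis reduction over windows is the median (robust to gait
  initiation/termination); the smallest window within 1e-9 relative of the
  global minimum wins.
* The residual curve of a periodic signal has near-zero minima at *every*
  multiple of the period, and at half the period whenever the window count
  is even — the min-argmin alone is therefore only trusted to land on a
  member of the period comb.  The fused estimate is the FFT candidate
  closest to the residual minimizer, which resolves the comb: candidate
  sets contain the true stride (limb sensors) and possibly the halved step
  period (pelvis/trunk), and any comb member is closer to the true
  candidate than to its half.
* With several sensors the bout value is the median of per-sensor fused
  estimates (even counts: mean of the central pair), which rejects the
  occasional pelvis/trunk sensor whose candidates are all halved.

The frequency-only comparator (`fft_only_estimate`) used in the validation
takes each channel's dominant in-band peak and the median over channels —
what the spectrum alone yields with no time-domain arbitration.

## Features and the segment model

Statistics are computed on the stride-scaled norms and norm derivatives.
Scaling multiplies each channel by the mean stride time once; amplitude
statistics then become approximately speed-invariant (amplitude scales
roughly with cadence), while derivative statistics retain a residual 1/T
dependence the tree must absorb — one reason the classifier is trained
across the full speed range.  Windows are one stride long, anchored at
sample 0, incomplete tails discarded, and features aggregated across
windows by the median.  Conventions: kurtosis is non-excess (normal = 3)
and skewness the moment coefficient, both from population moments, with
the degenerate constant-window case fixed at 3 and 0; std uses ddof 1;
percentiles interpolate linearly; mad is the mean absolute deviation from
the mean; peaks/valleys are strict local extrema with prominence ≥ 5% of
the window range (pure noise should not dominate the counts); a zero
sample joins the following sign for zero crossings.  The motionless rule
(|Gyr| < 10 deg/s and |Acc| < 1.3 g) applies to the unscaled signals —
physical thresholds have no meaning in scaled units.

MRMR ranks features by mutual information with the segment label
(equal-frequency 10-bin discretization) minus the mean mutual information
with already-selected features (difference form); ties fall back to column
order, making the ranking deterministic.  The feature count is chosen as
the smallest k whose development-set misclassification error is within
0.005 of the sweep minimum.  On the simulator's healthy cohorts the dev
curves flatten after two or three features because synthetic classes are
cleaner than real ones; the shipped default model nevertheless uses the
established seven-feature set listed in the README, which is more
redundant and markedly more robust on held-out pathological cohorts, and
the final tree is refit on all healthy subjects once the curves have been
inspected.  Trees are CART/gini with min 3 samples per leaf, no depth
limit, fixed random state; trained trees are exported to a plain nested
dictionary (split feature, threshold, leaf class counts) that serializes
to JSON and is walked directly at predict time, so shipped models contain
no pickled estimators.

Evaluation is one-vs-rest per class (accuracy, precision, sensitivity,
specificity, F1) with support-weighted overall rows, appropriate for the
imbalanced design (one sacrum and one trunk per bout versus two of each
limb segment).  Majority voting across repeated bouts of one sensor
breaks ties by mean leaf purity.

## Side identification

Foot flat: maximal runs of |Gyr| < 5 deg/s lasting at least 15% of the
stride.  Calibration: (1) the mean accelerometer vector during foot flat
(the +1 g gravity reaction) is rotated to +Y; (2) PCA on swing-phase
gyroscope samples — foot-flat samples are near zero and would dilute the
dominant axis — gives the plantar/dorsiflexion axis, rejected as
degenerate when the two leading eigenvalues are within 1%; (3) a rotation
about Y aligns it with Z; (4) the median pitch angular velocity at the
first post-foot-flat |Gyr| peak (prominence ≥ 20% of the bout maximum)
must be negative (hindfoot lifts first); otherwise the frame is flipped
180° about Y.  The same peaks provide the side features, medianed over
cycles.  The foot-side tree is trained rather than replaced by hard-coded
sign rules, as the features' signs near-mirror but their magnitudes carry
additional margin.  The shank/thigh rule requires both pair members and
declares ambiguity when their foot-flat |Gyr| means are within 5% —
single-shank configurations are rejected by design.

## The simulator

`gait_sim` emulates the structural properties the pipeline exploits; it is
a stride-locked bump/oscillation model, not a forward-dynamics simulation.
Study conditions (defaults): 200 Hz; stride times uniform on 0.45–2.4 s;
2–10 complete cycles per bout plus a random partial boundary tail (real
bout boundaries are arbitrary relative to the cycle); uniformly random
sensor orientations; white noise of 1 deg/s (gyro) and 0.02 g (acc);
per-cycle amplitude gains with 5% SD shared across sensors (stride-to-
stride variability, constant within a cycle so the attitude stays
periodic); per-subject amplitude factors (8% global, 5% per segment, 8%
for pelvis/trunk), timing jitter and a foot-flat fraction of 22–32% of the
cycle.  Segment gyro scales at a 1 s stride are 380/200/100/26/16 deg/s
for foot/shank/thigh/sacrum/trunk, all proportional to 1/stride-time, so
unscaled features are genuinely speed-confounded.  Anatomical sign
conventions are built in exactly (push-off: negative Gyr_z on both feet;
positive Gyr_x, Gyr_y, Acc_z on the right, mirrored left; left signals are
the sagittal mirror of the right shifted by half a stride).  Pelvis and
trunk move predominantly at the step frequency — with stride-periodic
obliquity/rotation/lateral-sway components — which reproduces the
halved-candidate failure mode the fusion must reject.  Sharp transients
(push-off, landing, heel strike) have a duration floor equal to their
value at a 1 s stride, because real event durations do not shrink
proportionally at high cadence, while swing-phase rotations keep their
cycle fraction; the shank carries a short high-jerk heel-strike transient
that the knee damps out before the thigh; shank and thigh never rest
completely (a small circular rotation component keeps their |Gyr| floor
above the foot's).  The pathology switch shortens foot flat to 17–23% of
the cycle and attenuates left-side amplitudes by 5–15%, emulating
asymmetric deviated gait.

What the simulator does **not** emulate: soft-tissue artifact, sensor
drift and bias, turning or non-steady gait, ground-reaction forces,
stride-length/TIME covariation, and the full idiosyncrasy of human
waveforms.  Passing the synthetic validation therefore shows the
algorithms are correct and robust under the structural assumptions they
encode — not that the shipped default tree transfers to a particular
recording system without retraining on matching data.

## Validation experiments and sizes

The packaged experiments mirror the shape of a training/test study:
504 healthy bouts (12 subjects × 42) for training and development
(75–25 split by subject, so no subject straddles the split) and 528
pathological bouts (22 × 24) for testing, all eight sensors per bout.
Stride-time recovery is measured on 200 bouts spanning the full stride
range.  Foot-side and shank/thigh-side accuracy use 100 held-out bouts
(200 foot sensors, 400 limb assignments).  These sizes were chosen to
match the study design at desk scale; `run_experiment` exposes all of
them as parameters.

## Known limitations

* Stride times at the extremes of the 0.45–2.4 s range interact with the
  fixed 4 Hz filter: fast-gait signals lose most harmonics, which is why
  side identification runs unfiltered and why classification accuracy is
  hardest at the range edges.
* Two-cycle bouts carry spectral leakage beyond one FFT bin; stride
  estimates there are accurate to a few percent rather than to the grid.
* The residual analysis alone cannot distinguish period multiples; it is
  only meaningful fused with the spectral candidates.
* Side identification requires at least one foot sensor; shank/thigh
  sides additionally require both pair members.
* The simulator's class separability is cleaner than real data's; real
  deployments should retrain the trees on recordings from their own
  sensor setup using the same pipeline.
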