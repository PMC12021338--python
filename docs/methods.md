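# Methods

## Pose representation and conventions

A head pose is `(rx, ry, rz, tx, ty, tz)`: rotations in degrees about the
scanner x/y/z axes, translations in mm.  Rotations are intrinsic, applied
x → y → z; the rotation center is the scanner isocenter unless an explicit
center offset is passed.  These conventions are configurable at every
boundary because registration tools differ in their Euler and sign
conventions; FSL-style `.par` files store rotations in radians and are
converted exactly once, in `navpmc.io`.

Per-volume registration poses are up-sampled to shot rate by anchoring each
volume at its k-space center shot (shot 14 of 21 by default, the shot that
dominates image contrast) and interpolating each parameter linearly between
anchors, holding the boundary value outside the first/last anchor.  Linear
per-parameter interpolation (rather than quaternion slerp) is adequate
because inter-volume pose deltas are small (volumes are 0.42 s apart);
the error is second-order in the delta.

## The RMS deviation metric

Two rigid transforms are compared by the RMS displacement they induce on
points uniformly distributed in a solid sphere (radius 80 mm, the scale of
a head).  With `M = T1 T2⁻¹`, `A = M_rot − I`, and `t = M_trans + A·c`
for rotation center `c`:

    RMS = sqrt( R²/5 · Tr(AᵀA) + tᵀt )

The `R²/5` weight is the solid-ball second moment; it is exact (not a
small-angle approximation) and is verified in the tests against a
Monte-Carlo average over ≥10⁵ ball points to 0.5%.  The same metric against
the identity transform quantifies motion magnitude.

## Navigator extraction

FIDnav: per channel, drop `trim = 4` samples at each end of the 512-sample
ADC (filter transients), average the first `n_avg = 4` retained complex
samples, and emit real parts then imaginary parts.  Short averages track
rotations better than the full 504-sample average because late samples
dephase; the trade-off is exposed via `n_avg`.  Extraction is linear in the
raw signal, so any DC-bin/spectral variant is equivalent up to scaling and
is deliberately not duplicated.

Probe field offsets: per probe, sequentially unwrap the phase of the
windowed fluorine samples and fit phase vs. time by magnitude-weighted
linear least squares; the offset is `slope/2π` in Hz.  Magnitude weighting
approximates inverse-variance weighting (phase noise scales as 1/SNR per
sample) and keeps the decayed tail of the FID from inflating the variance.
The fit window defaults to all samples; both window and weighting are
configurable because the optimal choice depends on probe T2 and noise.
A probe with zero magnitude throughout the window raises a dead-probe
error rather than returning a silent NaN.

Exciting probes every 20-ms shot saturates them; the steady-state factor
`(1 − E)/(1 − E cos α)`, `E = exp(−TR_shot/T1)`, scales the simulated probe
amplitude (0.221 at TR 20 ms, T1 80 ms, α 90°), which is how the
update-rate/precision trade-off enters the simulation.

## Eddy-current correction

Eddy currents from the imaging gradients imprint a motion-independent
pattern on the navigators locked to the phase-encode schedule: echo-time
shifting makes it repeat every `cycle_length` shots (10 for the segmented
high-resolution protocol; per volume, i.e. 21, for the time-series
protocol).  The baseline is the per-cycle-position mean over an initial
motion-free, update-free window (10 s = 500 shots by default), after
removing the window grand mean — the DC term is left to the calibration's
mean-centering so it is not counted twice.  Application is a causal
per-shot subtraction.  On a noiseless stream of pattern + affine motion
signal the correction is exact to machine precision (tested).

The slow per-volume variation of the high-resolution sequence is estimated
from a motion-free (phantom) stream by folding at the volume length,
averaging per position, and smoothing with a centered moving average.  A
moving average is not a projection, so subtract-and-re-estimate is exactly
null only for `smooth_size = 1`; for larger sizes the re-estimated trend
contracts but does not vanish — the tests pin both behaviors.

Moving-average filters come in a causal flavor (real-time path: average of
the most recent `min(size, t+1)` samples, group delay ≈ (size−1)/2 shots)
and a centered flavor with shrink-to-valid edges (retrospective path).

## Calibration

The fit runs on mean-centered X (navigator values) and Y (6-DOF poses,
degrees and mm shared in one target matrix without weighting).  The
normal-equations formula defines the estimator; the implementation uses an
SVD least-squares factorization because the 80 combined columns are
strongly correlated.  Ridge regression standardizes columns internally so
one λ spans FIDnav and probe units, then de-standardizes β.  Calibration
means are frozen into the model; prediction never re-centers on test data.

A noise-free simulated world produces a design of rank ≤ 6 (features are
exactly affine in the pose), which a strict OLS would reject.  `calibrate`
therefore raises on rank deficiency by default (advising regularization,
the right answer for measured data) but offers
`allow_rank_deficient=True`, returning the SVD minimum-norm solution whose
fitted values are still the exact projection — the path used by the
identifiability tests.

## The synthetic world

The generator is phenomenological: the tracking method assumes local
linearizability, so the simulator provides exactly that structure plus the
controlled violations needed to probe failure modes.  Per shot and channel,

    s_c(t) = a_c (1 + L_c·m + κ Q_c·q(m) + e_c[k]) e^(−t/T2*) + n,

with complex baseline `a_c`, complex linear sensitivities `L_c`
(sd 0.01 per deg/mm — percent-level FIDnav changes per degree, the in-vivo
order of magnitude), and `q(m)` the 21 second-order products `m_i m_j`.
The cross products are the essential part of the nonlinearity: motions
confined to one instructed axis never excite them, so a model calibrated on
shaking + nodding has no way to learn them, and multi-axis test motion
(figures-of-8) then degrades with κ — the mechanism behind the simulated
scale-dependence of tracking error.  (A *diagonal* quadratic term would be
silently absorbed by the linear fit, and a calibration that explores all of
pose space lets an 80-column linear model decode pose exactly through the
quadratic embedding; both were verified and are why the κ experiments use
the instructed-motion calibration.)

Probe off-resonances are linear in pose (sd 10 Hz per deg/mm, baselines
±50 Hz) plus an optional susceptibility-like term `w_p · rx²` applied to
probes only: nodding (Rx) rotations re-orient the head against the main
field and produce the largest, least-linear extracranial field changes at
fixed probe positions.  Enabling it reproduces the probe-specific nodding
deficit.  Receiver noise is complex Gaussian (sd 0.002 per sample for both
streams by default); probe amplitudes are scaled by the saturation factor.
Eddy patterns are random per cycle position (channel sd 1% of baseline,
probe sd 2 Hz at the default `eddy_amp = 0.01`).

Instructed motions are defined directly in parameter space from two fixed
directions — shaking `e_rz + 0.3·e_ty`, nodding `e_rx + 0.3·e_tz` (0.3
mm/deg emulates rotation about a neck pivot) — with 24-s cycles holding 5 s
at each extreme; figures-of-8 are continuous combinations of the same two
directions; resting is a smoothed random walk.  Superposing fixed
directions (rather than composing rotations about a pivot) is a deliberate
idealization: it makes the generalization premise — shaking + nodding span
the figures-of-8 poses — hold exactly in the linear world, so the
generalization test has a sharp expected answer.  Every session starts with
a 10-s motion-free lead-in so the baseline-window assumption holds;
violations can be constructed explicitly for robustness studies.
The calibration session is 250 volumes (1:45): shaking and nodding, twice
each, at 8° default amplitude.  Registration output is emulated as the true
center-shot pose perturbed by a random rigid transform of exactly 0.1 mm
RMS deviation (the accuracy scale of volume registration); real image
registration is out of scope and its output is an input here.

Randomness: one session seed; world draws, navigator noise and trajectory
jitter use fixed sub-streams (`SeedSequence([seed, k])`), so identical
seeds give bit-identical sessions.

## The closed PMC loop

FIDnavs and probes are acquired gradient-free, so an FOV update — a
gradient re-orientation plus RF frequency/phase adjustment — does not
change what they measure: the head's pose relative to the stationary coil
and probes.  The simulated controller therefore sees the total pose each
shot, eddy-corrects causally, optionally filters (causal moving average),
predicts with the calibrated model, and schedules the prediction as the
FOV update `latency_shots` later (default 1, the sub-TR-shot contract).
Residual motion — what the image experiences — is the true pose composed
with the inverse of the update in effect.  No updates are issued during the
baseline window.

Two consequences are worth stating.  First, with an exact model and no
noise the residual vanishes (to ~1e-14) one latency step after any motion
change, and continuous motion leaves exactly speed × latency (0.1° per
shot at 5°/s and 20 ms).  Second, the alternative architecture — feeding
back the *residual*-frame measurement with unit gain — is linearly
unstable once a moving-average filter of size ≥ 5 is in the loop (the
characteristic polynomial `z^N − z^{N−1} + (1/N)Σz^k` leaves the unit
circle), which is why the feedforward reading of the physics is also the
one that matches a stably operating real system.

Retrospective ground truth for a PMC scan is reconstructed the way it must
be when no external tracker exists: per-volume residuals (image
registration of the corrected series) interpolated to shot rate, composed
with the applied updates smoothed by a centered one-volume (21-shot)
moving average to match temporal resolutions.  Smoothing acts on the
decomposed 6-DOF parameters, consistent with the interpolation convention
used everywhere else.

## Metrics

Tracking reports re-reference both series to their first sample (series
start at zero), then give per-parameter MAE and STDerr (reported per
parameter plus rotation/translation group means and a pooled STDerr, since
degrees and mm must not be averaged together), the mean RMS deviation of
the error, and the mean RMS magnitude of the ground truth.  NRMSE is
`‖img − ref‖/‖ref‖`; SSIM uses the canonical Gaussian window (σ 1.5,
truncated at 3.5σ, K1 = 0.01, K2 = 0.03, edge region cropped) and matches
scikit-image's Gaussian-weighted implementation to 1e-6 (cross-checked in
the tests).  Both image metrics require registered, shape-matched volumes
and refuse to resample.

## Problem sizes and defaults used in the shipped runs

Tests and the acceptance script run the default protocol (32 channels ×
512 samples, 16 probes × 64 samples, 21 shots/volume at 20 ms).  The
calibration session uses 250 volumes where a single run is reported and
150 volumes inside parameter grids; test sessions use 40–120 volumes.
These sizes keep full-pipeline runs in the tens of seconds while leaving
every rate and ratio unchanged; unit tests additionally use a 4-channel,
3-probe miniature protocol where only structure matters.

## Known limitations

* The forward model is not an electromagnetic simulation: coil
  sensitivities, probe responses and the Rx² susceptibility term are
  random draws with realistic magnitudes, not fields computed from
  anatomy.  Passing tests show the *method* behaves as designed under its
  own assumptions, not that a specific scanner will reach a specific
  accuracy.
* Spurious spin/stimulated echoes in rapidly excited probes are
  represented only as excess noise, not mechanistically.
* No k-space/image synthesis: image-quality metrics operate on volumes the
  caller supplies; registration is likewise external.
* Eddy behavior is an additive cycle-locked pattern, not a multi-exponential
  gradient impulse response; within-scan drift of the pattern is not
  modeled.
* Ridge regularization is exposed but no λ-selection rule is claimed; in
  the simulated worlds OLS (or min-norm) is optimal and regularization only
  becomes interesting for very large motions or long readouts.
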