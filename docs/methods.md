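# Methods

## The measurement problem

Stretch reflexes are usually probed with the limb at rest, but their
excitability is actively modulated by descending drive during movement.
Quantifying that modulation requires (i) a perturbation fast enough to
elicit the reflex (here, ramp-and-hold elbow-extension at 270 deg/s),
(ii) precise timing of the perturbation relative to the phase of a
volitional reach, and (iii) an EMG statistic that separates the
perturbation-evoked response from the volitional activity it rides on.
This package implements that pipeline end to end, together with a
synthetic participant so every stage is testable without recordings.

## Arm model and frames

The arm is a planar two-link chain: upper arm (shoulder to elbow, length
L_u) and forearm-plus-orthosis (elbow to endpoint, length L_f).  The
table frame has its origin at the shoulder, +x anterior, +y toward the
contralateral side.  The shoulder angle is CCW-positive from +x; the
elbow angle is the interior angle (180 deg = full extension), so an
extension perturbation increases it.  The task plane sits at a fixed
shoulder abduction, making abduction a constant of the setup and
reducing endpoint speed to its planar magnitude.  Inverse kinematics is
the standard two-link closed form; the elbow branch is fixed by
handedness and never switches within a trial, so the mapping is
deterministic.  Joint velocities solve the 2x2 Jacobian relation; at
full extension or flexion the Jacobian is singular and the API directs
callers to a finite-difference fallback instead of returning garbage.

## Perturbation generator

The commanded elbow angular velocity rises linearly from its value at
onset (v0) to a 270 deg/s plateau in 20 ms, holds 30 ms, and returns to
v0 in 20 ms.  Closed-form swept angle:

    theta = v0*T + (v_p - v0) * (t_up/2 + t_hold + t_down/2)

which is 13.5 deg from rest with the defaults.  Per-tick angular
increments are the analytic integral of the piecewise-linear profile
over each tick, so the displacement is independent of the update rate
(1 kHz by default).  The commanded endpoint advances along a circular
arc of radius L_f centered at the instantaneous elbow position,
recomputed every tick so the arc follows a moving limb; by default the
shoulder continues at its onset angular velocity during the window (a
freeze-shoulder flag is available).  A safety layer rejects any
commanded stream whose equivalent elbow angular velocity exceeds
300 deg/s, or that leaves a configured rectangular work area; the limit
applies to commanded, not measured, velocity.

Phase triggers: *pre-motion* fires at a fixed 2 s after home-target
acquisition; *early* and *peak motion* fire at the first sample where
endpoint speed reaches 15% and 90% of the subject's maximal voluntary
velocity (MVV), restricted to the acceleration phase.  The acceleration
phase is [movement onset, first local speed maximum), with movement
onset defined as the first crossing of 5% MVV — no onset rule is
standard, so this one is explicit and configurable.  A threshold never
crossed before the speed peak yields a no-trigger outcome and the trial
is flagged unperturbable rather than perturbed late.

## Synthetic participant

The simulator emulates the study conditions, not any individual record:

* **Reaches** follow a minimum-jerk endpoint path (bell-shaped speed,
  peak 1.875 d/T at midpoint).  Per-trial peak speed is drawn from a
  normal distribution centered on the subject's MVV with 5% fractional
  SD — enough jitter that trial cleaning has something to do, little
  enough that nearly all trials clear the 90% MVV retention gate.
* **EMG envelopes** are background tone plus flat-top volitional bursts
  with raised-cosine edges: extensor (TRI, with ADL/PEC) burst leading
  movement onset by the configured agonist lead, a flexor (BIC) braking
  burst after peak speed, and a second extensor burst — the triphasic
  pattern of ballistic movement.  The stroke preset sustains the
  extensor burst for several hundred milliseconds and nearly removes
  the braking burst.
* **Reflex bursts** are threshold-linear in stretch velocity, proxied by
  elbow extension velocity (constant moment arm absorbed into the
  gains): amplitude = gain * (v_stretch - v_threshold)+ scaled by
  (1 - rho * antagonist activation), where rho is the
  reciprocal-inhibition coefficient.  Bursts occupy the 25-75 ms (SLR)
  and 75-125 ms (LLR) windows with short flanks outside them, so the
  window-averaged amplitude equals the injected amplitude.
* **Raw signals** are envelope-modulated zero-mean broadband noise plus
  60 Hz mains, so the notch/rectify/smooth chain is genuinely
  exercised; MVC normalization cancels the rectified-noise scale factor
  because maximal-contraction trials pass through the same chain.
* **Sessions** interleave perturbed catch trials (random phase among
  those still owed) with Uniform{1..5} unperturbed trials until each
  phase has its quota, plus three MVC trials per muscle and three MVV
  reaches.  All per-trial seeds spawn from one session seed.

Default presets encode the cohort contrast: control — MVV 1.09 m/s,
background tone 1.6% MVC, reflex threshold 300 deg/s (above the 270
deg/s plateau, so no reflex at the tested velocity), rho 0.9; stroke —
MVV 0.78 m/s, tone 3.9% MVC, threshold 150 deg/s, higher gains, rho 0.3
(weakened reciprocal inhibition), longer agonist lead.  These are
defaults for qualitative contrast, not reproduction targets; no
quantitative stretch-velocity-to-amplitude law exists for this task, so
the threshold-linear form and its parameters are a modeling choice.

During a perturbation the simulated elbow velocity follows the
commanded profile exactly (the robot is in position-control mode); the
displacement gained relative to the volitional path then decays
passively with a 250 ms time constant, emulating a subject instructed
to relax rather than react.

What the simulator does *not* model: musculotendon or spindle dynamics,
motor-unit structure in the EMG (the envelope-modulated-noise model has
no spectral shaping by force), out-of-plane motion, admittance-control
force dynamics, fatigue, or anticipation.  Passing tests therefore show
the *pipeline* is correct and calibrated, not that real cohorts will
match the presets.

## EMG conditioning chain

Stage order is fixed: optional 20-450 Hz 4th-order Butterworth
band-limit (applied to synthetic raw signals; acquisition hardware does
this for real recordings), 6th-order elliptical notch at 60 Hz (order-3
band-stop prototype, 1 Hz half-bandwidth, 1 dB ripple, 40 dB
attenuation) applied forward-backward for zero phase, least-squares
linear detrend, full-wave rectification, zero-phase 11-sample centered
moving average (10 ms at 1 kHz, odd length for exact zero phase,
reflected edges), then division by the per-muscle MVC times 100.

MVC per muscle: three isometric trials; per trial the peak is located
on the smoothed envelope and the *rectified, unsmoothed* signal is
averaged over a 500 ms window centered there (truncated symmetrically
at edges); the three values are averaged.  Peak localization on a long
flat noisy plateau can land near a plateau edge, which biases single
trials; the three-trial, six-muscle averages used downstream are stable
(see the test suite).  MVV is the mean of the three per-trial peak
endpoint speeds.

The narrow notch rings for roughly half a second at record edges;
quantities measured near trial boundaries (none of the reflex windows
are) would need padding.  Zero-phase filtering also smears signal
onsets backward in time by ~10-25 ms, which lengthens the measured
agonist-onset lead; the effect is documented in the onset tests.

## Reflexive EMG

Trials are cleaned first: any trial with peak speed <= 90% MVV is
discarded, and perturbed trials must track the commanded elbow velocity
within an RMS tolerance of 10% of the plateau over the window (the
conformance criterion needs a number; 27 deg/s RMS is well above
tracking jitter and well below a failed perturbation).

For each muscle, phase, and window the statistic is

    mean over retained perturbed trials of the window-averaged envelope
  - mean over all retained unperturbed trials of the envelope averaged
    over the equivalent window,

in % MVC.  The equivalent window in an unperturbed trial is anchored
where that phase's trigger would have fired in that trial (fixed delay
for pre-motion; the %MVV crossing for early/peak), then offset by the
SLR/LLR window bounds.  Windows are half-open ([25, 75) and [75, 125)
ms), so SLR and LLR never share samples.  Averaging perturbed trials
before or after the subtraction is equivalent for the mean; per-trial
differences are also reported so dispersion can be computed either way.
Cells with no perturbed trial or no alignable unperturbed trial are
NaN, never silently zero.  Group aggregation across subjects is left to
the caller on the tidy output table and is purely descriptive — no
inferential testing is in scope.

## Numerical and design choices

* Trigger detection returns the first sample at or above threshold;
  identical streams always yield identical trigger samples.
* `velocity_profile` rejects v0 at or above the plateau (the
  perturbation would decelerate the stretch); the zero-amplitude
  identity of the arc-advance step is exposed through the lower-level
  increment interface instead.
* Near full extension, inverse kinematics clamps to 180 deg within a
  1e-6 m tolerance band and warns; beyond it, it raises with the
  annulus bounds.
* Problem sizes in the test suite (session counts of 200 for the null
  calibration, 12 seeded sessions per injected amplitude, 1000-point
  round-trip checks) were chosen as the smallest sizes at which the
  Monte-Carlo standard errors are decisively below the tolerances being
  checked.

## Known limitations

* The threshold-linear reflex model is a stand-in; its gains and
  thresholds are free parameters, so only qualitative cohort contrasts
  (positive stroke SLR, null control SLR) are meaningful.
* The literal catch-trial schedule (each perturbed trial followed by
  1-5 unperturbed) yields 27 unperturbed trials per session in
  expectation; experimental sessions typically add warm-up and
  familiarization reaches on top of that schedule.
* Endpoint speed is planar; recordings from a tilted or vertical task
  plane would need projecting before use.
* The CSV trial format stores one row per millisecond; very long
  sessions are better kept in memory or trimmed.
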