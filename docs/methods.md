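# Methods

This note documents the models and procedures implemented in
`balancegait`, the design choices made where the design was genuinely
open, and what validation on synthetic data does and does not establish.

## Coordinate and unit conventions

x is medial-lateral (positive right), y anterior, z up. Positions are in
mm, angles in degrees, forces in N, moments in N·m, times in seconds
internally; onset times are reported in ms. Marker and joint-angle
streams are sampled at 250 Hz, force-plate and EMG streams at 1000 Hz,
all sharing the time origin t = 0.

## Stimulus protocol

The visual fall stimulus rotates the scene about the anterior-posterior
axis: constant angular acceleration `a` (default 60 °/s²) for
`accel_duration` (0.6 s), giving the closed-form peak angle
`½·a·accel_duration²` = 10.8°; the peak is held for 2 s and then removed
at constant angular velocity over 1 s ("uniform speed" is read as linear
in angle). Stimuli are triggered on heelstrikes; after each stimulus
returns to neutral, a washout of g steps, g drawn uniformly from
{10,…,13}, elapses before the next trigger. **Open question resolved:**
the washout counts heelstrikes of *both* feet, the literal reading of a
"step"; a per-foot count would double the washout. Online heelstrike
triggering uses a downward crossing of the standing heel-marker height
plus 3 mm. A collection block is five 30 s metronome phases (90 bpm)
alternating with five 120 s stimulus phases: 12.5 min.

## Preprocessing

All filters are 4th-order Butterworth applied forward-backward
(zero-phase), preserving event timing; the default cutoffs are 10 Hz
for kinematics, 50 Hz for forces, and 6 Hz for rectified EMG, the
standard choices for offline gait analysis. Marker
occlusions up to 100 ms are filled with a local cubic spline through up
to 8 finite samples on each side; longer runs are left NaN and any step
overlapping them is excluded. Filtering is applied piecewise over finite
runs so an occlusion does not poison a whole channel.

The CoM is the mass-fraction-weighted mean of per-segment CoM positions
using a simplified 11-entry fraction table (trunk split into pelvis /
torso / head, per-side thigh, shank, foot, lumped arm). This is a
deliberate simplification of full anthropometric regression tables:
synthetic validation generates and analyzes with the same table, so the
simplification cancels; with real data the table can be replaced via
`SegmentMassTable`. CoM velocity and acceleration are successive central
differences of the filtered position (the derivative scheme is not
otherwise constrained; central differences are symmetric and preserve
event timing).

Per-plate lateral CoP is `origin + 1000·M/F_z` (mm); the whole-body CoP
is the vertical-force-weighted mean over plates carrying more than 20 N.
Samples with no loaded plate are flagged invalid. EMG envelopes are
full-wave rectified and low-passed at 6 Hz, then scaled per channel so
the control-stride grand mean is 100 %.

## Gait events

Heelstrikes are minima of the vertical heel trajectory with topographic
prominence > 20 mm; a 250 ms minimum spacing is enforced greedily,
keeping the more prominent of any conflicting pair (the tie rule is not
otherwise specified; prominence is the quantity already thresholded).
Push-offs are the first peak of the 2nd-metatarsal vertical velocity
with prominence > 350 mm/s after each ipsilateral heelstrike; steps with
no qualifying peak are flagged. Event times are sample-quantized (4 ms
at 250 Hz), below the precision of reported onsets. Feet must alternate;
violations are flagged, never silently repaired. A review mechanism
applies add/remove/move corrections from a table and rejects edits that
would violate per-foot ordering or spacing.

## Steps, responses, outcomes

A step runs from a heelstrike to the contralateral heelstrike. Around
each stimulus, steps −2, −1 (controls) and +1…+4 are analyzed; each
trajectory is resampled to 100 evenly spaced points including both
endpoints. Responses are stimulus-step trajectories minus the pointwise
mean of control steps with the same stance foot, computed *before*
mirroring; left-triggered responses (including their controls) are then
mirrored (lateral channels negated) so positive is toward the triggering
leg. Conditions are classified *toward* when the roll direction matches
the triggering side, else *away*.

The foot-placement model regresses, per subject on control steps only,
the relative foot placement (swing minus stance heel x at the
step-ending heelstrike, control mean removed) on the CoM lateral
position and velocity responses at midstance. **Midstance is
operationalized as the 50 % point of normalized step time** — the term
is otherwise undefined; the fraction is configurable
(`midstance_fraction`). The stimulus-induced foot-placement change is
the observed change minus the model prediction.

The seven step-ONE outcomes follow the standard definitions: (i)
foot-placement change, (ii) stimulus-induced foot-placement change,
(iii) swing-hip ab/adduction at the step-ending heelstrike, (iv)
integrated swing-leg gluteus medius EMG, (v) integrated CoP-minus-CoM,
(vi) stance-ankle in/eversion at the step-ending heelstrike, (vii)
integrated stance-leg peroneus longus EMG. Integrals run over the first
post-stimulus swing phase — from the swing-leg (contralateral) push-off
event to the step-ending heelstrike — in real time (s), scaled from the
normalized trajectories by step duration, hence units of mm·s and %·s.
The same window is used for (iv), (v) and (vii). Spatial outcomes are
inverted for *away* stimuli and body-relative outcomes for *toward*, so
positive means a response in the direction the stimulus predicts.

## Onset estimation

For a pooled set of step +1 responses: (1) pointwise 95 % CI of the mean
(t-based, independence assumed per time point); (2) the range of
interest is the longest contiguous region, at least 50 ms long, where
the CI excludes zero (the minimum length suppresses isolated chance
exclusions at small n); (3) within it, the first local maximum of the
mean's rate of change (central differences, no additional smoothing),
ignoring minor wiggles below half the region's peak rate — a region that
begins after the rate peak anchors at its largest-rate sample; (4) the
tangent at that point is extrapolated to zero; the crossing is the onset
in ms after the trigger. Onsets are undefined (reported as such) when no
exclusion region exists. Pooling is across all repeats (steps), not
per-subject averages; a per-condition mode exists, and by default the two
directions are pooled after sign-flipping the side with the negative
expected response. The CoP onset is estimated on the whole-body CoP
response; the CoP-relative-to-CoM trace is reserved for outcome (v),
since its CoM component adds sampling noise that perturbs the tangent at
small n.

## Synthetic walker

The walker is kinematic — prescribed trajectories, not simulated
dynamics — because the claims under test concern the analysis chain, and
a prescribed construction makes every target quantity exact:

- **Cadence** 90 steps/min (step period 0.667 s), step width 100 mm,
  double-stance 0.15 s, ~700 N body weight split across two plates with
  linear weight transfer.
- **Heel height** is `A·|sin(π·phase)|` of stride phase (A = 80 mm):
  sharp minima exactly at the true heelstrikes, clamped half a stride
  beyond each foot's first/last heelstrike so the periodic pattern
  creates no spurious edge minima.
- **2nd-metatarsal height** is a raised-cosine swing bump placed so its
  maximum upward velocity (≈ 470 mm/s) falls exactly at the true
  push-off.
- **CoM** = stride-locked sway (20 mm, toward the stance foot) plus a
  smooth stochastic component constructed as a cubic Hermite interpolant
  through independent draws of (position, velocity) at each step's
  midstance (SDs 3 mm, 10 mm/s). The CoM state at midstance is therefore
  exactly the drawn value and serially uncorrelated across steps, which
  makes the placement regression identifiable and unbiased.
- **Foot placements** follow the linear CoM-state law exactly and
  cumulatively: each landing is the previous stance position plus the
  base step width, plus `c_pos·CoM(t_mid) + c_vel·v_CoM(t_mid)`
  (defaults 1.0, 0.15 s), placement noise (2 mm), and the injected
  stimulus shift. Absolute placements therefore random-walk slowly (as
  the law integrates), but every analyzed quantity is relative; the
  per-plate CoP is anchored to each side's base position (plus a
  stride-locked 5 mm progression) rather than to the walked placements,
  so the injected CoP shift is the only stimulus-locked CoP component.
- **Injected responses** (CoP shift 8 mm at 300 ms; foot-placement shift
  5 mm at 420 ms; ankle eversion 0.5° at 340 ms; push-off plantarflexion
  2° at 420 ms; hip abduction 0.15° at 550 ms; EMG modulations of
  peroneus longus, gastrocnemius and gluteus medius at 200 ms) use a
  ramp that is linear from the nominal onset with a symmetric quadratic
  corner blend and a smooth saturation. The symmetric blend means the
  backward extrapolation of the linear segment crosses zero exactly at
  the nominal onset — the tangent estimator's target — and the C¹ corner
  avoids zero-phase filter ringing that would otherwise bias the anchor.
  Responses hold for 1.4 s and fade over 0.3 s. Signs follow the
  expected physiology: spatial responses go with the perceived fall;
  eversion/abduction/PL increase for *away*, plantarflexion/gastrocnemius
  for *toward*.
- **Noise and artifacts**: marker noise 0.5 mm, angle noise 0.05°, plate
  moment noise 0.7 N·m (≈1.4 mm CoP), EMG generated as
  envelope-modulated Gaussian carriers plus additive noise (0.05 a.u.;
  setting the EMG noise to zero switches to deterministic envelopes so
  null-generator identity tests are exact), and optional contiguous
  marker dropouts with geometric lengths, some exceeding the 100 ms
  fill limit to exercise the exclusion rule. All randomness derives from
  one seed; regeneration is bit-identical.

What the walker does **not** emulate: musculoskeletal dynamics, realistic
ground-reaction waveforms, multi-joint kinematic consistency, CoM
reaction to the injected responses (no closed loop, hence no cross-over
effects in later steps), soft-tissue artifact, or between-subject
variability within one trial. Passing recovery tests therefore shows the
analysis chain is correct and unbiased under the stated signal model; it
does not certify performance under real-data pathologies beyond those
modeled (noise, dropouts, event jitter).

## Mixed-effects inference

Each outcome is modeled as
`outcome ~ trigger_foot * direction + (1 | subject)` with sum-to-zero
(±1) factor coding, fitted by REML. The random-intercept model's REML
likelihood is closed-form; the residual variance is profiled out
analytically and the variance ratio optimized in 1-D, which is exact and
stable on the zero-variance boundary (a case the calibration tests
exercise deliberately). Type-III F tests (each effect a single contrast,
so F = t²) use Satterthwaite denominator degrees of freedom computed
from the numerical Hessian of the REML log-likelihood; when the subject
variance collapses the df reduce to the OLS residual df exactly.
Least-squares means fix one factor's code and average over the other;
their 95 % CIs use the Satterthwaite df of the corresponding contrast,
and an effect is flagged significant when its CI excludes zero.
Kenward-Roger CIs are not available in this ecosystem; Satterthwaite is
used instead and recorded in the fit metadata — on the balanced and
near-balanced designs produced here the two agree, and the fit, F tests,
Satterthwaite df and LS-mean CIs are verified against R's
lmerTest/emmeans in the test suite. p-values are reported but
de-emphasized; the CI criterion is primary. No multiple-testing
correction is applied across the seven outcomes.

Power analysis simulates balanced outcome tables from the fitted model
family (direction effect expressed as the between-direction difference in
outcome units), refits, and tests the direction effect at α = 0.05;
power is the significant fraction, and the minimum N for a target power
is found by scanning N upward.

## Validation scales and numerical choices

The test suite and the acceptance script validate at these scales,
chosen to keep a full run within minutes on one CPU while leaving
Monte-Carlo error well below the tolerances: noiseless closure pools 6
trials of 120 steps (gain within 1 %, onsets within one normalized-time
sample); the noisy recovery study uses 50 trials of 170 steps (~500
stimuli; |gain bias| < 0.5 mm, onsets within 20 ms); null calibration
uses 500 refits of 10 subjects × 5 per cell (rejection rate within
binomial 95 % bounds of α, LS-mean coverage ≈ 95 %). Degenerate inputs
are handled explicitly: flat signals yield no events, all-NaN channels
are excluded with a warning, steps shorter than 50 ms are rejected,
rank-deficient placement designs raise, constant outcomes raise, and an
absent CI-exclusion region yields an undefined onset rather than a
number.
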