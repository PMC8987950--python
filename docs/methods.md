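# Methods

## Coordinate frame and target geometry

All computation is planar, in the midsagittal plane: origin at the midpoint
of the feet on the floor, +x anterior, +z up. The hip pivot is assumed to
lie on the vertical through the origin (upright-stance calibration). The
reference posture is trunk vertical with the arm horizontal forward, i.e.
the arm perpendicular to the trunk; targets for an isolated trunk-flexion
angle θ are obtained by rotating trunk+arm rigidly about the hip pivot.
The perpendicular-arm reference is a modelling convention — the simplest
configuration consistent with "reaching if the participant moved only at
the trunk" — and other arm references would shift all four targets
consistently without changing any downstream contract. Under this
convention the hand-to-pivot distance √(L_t²+L_a²) is independent of θ and
target height decreases strictly with θ, which the tests verify to 1e-12 m
against a rotation-matrix oracle.

## Ballistics

Projectiles are point masses under gravity only (g = 9.81 m/s² by default),
so flights are parabolas and both inverse problems are closed-form.

* Fixed launch speed (dodgeball): the launch-angle quadratic in tan α has
  two real roots when the target is reachable; the smaller (low, flat arc)
  is always returned, matching how the dodgeball game is played. A negative
  discriminant raises an unreachable-target error naming the offending
  speed.
* Fixed apex (fish): the apex height H must strictly exceed both release
  and intercept heights; the intercept is placed on the descending limb.
  The apex of the solved flight equals H analytically; `apex_height`
  evaluates the vertex in closed form because a sampled trajectory visits
  the true apex only to O(dt²).

Launch sites default to (3.0, 1.6) m for the dodgeball thrower and
(2.5, 0.0) m for the fish (water surface), with v0 = 8 m/s and H = 2.0 m.
These are plausible gameplay values, configurable in `SuiteConfig`; nothing
downstream depends on the specific numbers and no reproduced statistic
uses them as inputs.

## Protocol

The session order is fixed (Reachality → Fishality → Dodgeality).
Reachality presents the four heights highest→lowest with 5 right- then 5
left-hand reaches per height (~15 s rest between reaches, ~2 min between
heights). Each launch game is 2 sets of 15 launches; "equal and randomized
distribution across the 4 target heights and ducking" is realized as
exactly 3 launches per category per set — the only integer-balanced
reading — with the within-set order drawn as a uniform permutation from a
seeded generator. Inter-launch timing is not prescribed by the protocol
and defaults to 5 s, exposed as configuration. Duck events carry only an
audio-cue tag; ducking kinematics are out of analysis scope.

## Synthetic motion generator

The generator stands in for cohort motion-capture data, which is not
distributable; its purpose is pipeline validation with known ground truth,
not biomechanical fidelity.

The participant is a two-link chain (trunk L_t, arm L_a) about the hip
pivot. Reaching a point p solves the two-link inverse kinematics for a
total trunk reorientation φ and an arm elevation ψ; a point is reachable
iff its distance from the hip pivot lies in [|L_t−L_a|, L_t+L_a]. The
lumbar angle receives `lumbar_share·φ` (plus any anticipation, below) and a
lumped hip/lower-limb angle the remainder — the kinematic redundancy that
lets real participants trade spine motion against hips and legs. Angles
follow the minimum-jerk profile s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, whose peak rate
is 1.875·A/T; with `lumbar_share = 1`, amplitude 40° and duration 1 s the
pipeline must recover 40° excursion and 75°/s peak velocity, which the
acceptance suite checks through the full filter chain.

Timing per trial: quiet stance (0.5 s), cue, reaction latency, movement.
For launch games the cue precedes release (the opponent winds up; the fish
is signalled above the water): lead 0.4 s for dodgeball, 1.0 s for fish.
The movement duration is the preferred time `movement_time / speed_gain`
(speed gains 1.0 / 1.15 / 2.2 for reach / fish / dodge), shortened when the
flight leaves less time, floored at 0.2 s — rushed trials may legitimately
miss. The intercept is chosen along the sampled flight: by default both
launch games intercept the reachable sample closest to the intended target
(dodgeballs are blocked at the body, fish are caught around the intended
contact point); the earliest-reachable alternative (first sample inside
the reach annulus `| |p−hip| − L_t | ≤ reach_envelope`) models lunging at
full extension and is available per game. The chosen intercept is snapped
down onto the 100 Hz grid so the ball and the hand can actually coincide
at a sample; contact is registered when hand and ball come within 5 cm
(1 cm for pass-through of static targets).

Dodgeality additionally adds anticipatory lumbar flexion at the higher
targets (12° at the highest, tapering to 0 at the lowest), compensated by
the hip component so the hand still meets the ball: players start ducking
downward before they resolve the incoming flat, fast ball. This, plus the
per-game pacing, is what produces the cohort-level pattern — dodgeball
velocity above fish velocity at every height with a game×height
interaction — that the acceptance suite tests at n=31.

Cohort traits are drawn per participant: segment lengths around a
young-adult stature (hip 0.93±0.05 m, trunk 0.47±0.03 m, arm 0.70±0.04 m),
lumbar share 0.70±0.08 (clipped to [0.30, 0.95]), reaction 0.25±0.03 s,
preferred movement time 1.1±0.12 s, angle noise SD 0.3°. Noise is added to
the recorded lumbar channel only; the hand channel is treated as a
separately tracked, effectively noise-free signal.

What the generator does *not* emulate: multi-segment spine kinematics,
out-of-plane motion, trial-to-trial motor variability beyond noise and
reaction jitter, fatigue or learning across the session, and realistic
ducking. Passing tests therefore demonstrate that the pipeline and
statistics are correct on data with this structure, not that the specific
effect magnitudes generalize to human cohorts.

## Kinematic reduction

Series are smoothed and differentiated with a 41-point, 4th-order
Savitzky–Golay filter at 100 Hz; the derivative is scaled by the sampling
interval, and boundaries are mirror-padded (the filter is exact for
polynomials up to degree 4 in the interior; near edges a mirror extension
cannot track asymmetric signals, so analytic-accuracy checks exclude the
half-window at each end). The analysis window runs from the movement cue to
200 ms after contact, clipped to the recording; for missed-but-attempted
trials it ends at the peak forward hand displacement (the natural end of an
attempt that never made contact).

Excursion is peak-minus-onset of the smoothed lumbar angle within the
window — the right reading of "flexion excursion" for a flex-and-hold
reach; a net (end-minus-onset) mode is provided as an option. Peak velocity
is the window maximum of the smoothed derivative. Both are invariant to
constant angle offsets. Impact location is the hand sample nearest the
contact event, in the feet-midpoint frame.

Screening replaces the study-style visual review with a reproducible rule:
a trial is excluded iff its excursion is below 2° (configurable); misses
with a genuine attempt are retained. Aggregation drops left-hand reaches
and duck events (only right-hand reaching is analyzed), averages included
trials per participant × game × height, and reports any empty cells —
the ANOVA requires the complete 3×4 within-subject design.

## Repeated-measures statistics

The two-way within-subject ANOVA uses the classical cell-mean
decomposition, testing each effect against its subject×effect interaction
(no pooling). Sphericity is assessed per effect by Mauchly's test on the
orthonormalized-contrast covariance (Helmert contrasts; Kronecker products
for the interaction), using Box's chi-square approximation with the
second-order term, matching SPSS/ezANOVA behaviour. When Mauchly's p < .05
(the conventional trigger), Greenhouse–Geisser
ε̂ = tr(S)²/((k−1)·tr(S²)) multiplies both degrees of freedom; ε is exactly
1 for two-level factors, and the test is reported as unavailable when
n − 1 ≤ effect df (the contrast covariance is singular). Partial η² is
SS_effect/(SS_effect+SS_error), algebraically F·df1/(F·df1+df2); bands
>0.25 moderate and >0.64 strong. LSD post hocs are uncorrected pairwise
paired t-tests, by definition of the method; simple effects fit a one-way
RM-ANOVA of game at each height with its own error term. Shapiro–Wilk
normality screening delegates to SciPy's Royston implementation.

Degenerate inputs: sums of squares within 1e-12 of rounding noise at the
table's scale are treated as exactly zero, so a flat table yields F = 0,
p = 1 rather than a 0/0 artifact.

Correctness is established two ways: exact agreement (≤1e-10) with an
independently coded loop-based sums-of-squares oracle on small tables, and
agreement with pingouin on F, p, Mauchly and ε in the cross-check tests.
Type-I error calibration uses 2000 Monte-Carlo replicates of a spherical
null at n=31 — enough to pin the rejection rate to ±1% while keeping the
whole suite fast — simulated directly at the cell-mean level (subject
intercept + i.i.d. noise), since the null concerns the ANOVA, not the
motion generator.

## Problem sizes and determinism

Default validation sizes: 1000 random geometries per ballistic solver, a
500-point θ grid × 20 anthropometries for target geometry, 10 small tables
for the ANOVA oracle, 2000 null replicates, and one full 31-participant
cohort (3100 trials) for the pattern-level check. A single integer seed
drives every random quantity; identical seeds reproduce every artifact
bit-for-bit on one platform, and the end-to-end runner writes a SHA-256
manifest to make that checkable.

## Known limitations

* The two-link, planar participant model cannot reproduce between-game
  differences in anterior reach distance that arise from whole-body
  strategies; impact locations mostly track the intended targets.
* Effect magnitudes in the synthetic cohort (particularly dodgeball peak
  velocities) are larger than typical human values; comparisons are
  meaningful at the pattern level only.
* The GG ε for the interaction term uses the Kronecker-contrast covariance;
  software differs in this corner (pingouin warns about its own two-way ε),
  so cross-checks pin down the one-way case and the uncorrected F/p
  everywhere.
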